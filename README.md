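# tripletmi

Triplet mutual information between RNA and protein alignment columns, with
contact enrichment against a 3D structure.

## The problem

Residues that interact in a folded complex tend to change together over
evolution. Pairwise covariation analyses have long exploited this within
proteins and within RNAs, but dependence between an RNA chain and a protein
chain — e.g. a ribosomal protein packed against rRNA — often only shows up at
*third* order: one nucleotide coupled to an unordered pair of amino acids.
`tripletmi` scores all such (nucleotide, amino acid, amino acid) column
triplets across a species-joined pair of multiple sequence alignments, ranks
them, and asks whether the top-ranked triplets sit close together in a
structure.

The core statistic is the interaction information of three alignment columns
X, Y (protein) and Z (RNA),

    I(X;Y;Z) = I(X;Y|Z) − I(X;Y)
             = H(X,Y) + H(X,Z) + H(Y,Z) − H(X) − H(Y) − H(Z) − H(X,Y,Z),

estimated by plug-in frequencies over gap-free rows and reported normalized
by the joint entropy, MI/H = I(X;Y;Z)/H(X,Y,Z) ∈ [−1, 1]. Positive values are
synergy (the X–Y dependence appears only once Z is known), negative values
redundancy; rank analyses use the positive side. Supporting machinery:
species joining of independently built alignments, per-column conservation
filtering (entropy < 0.3 bits excluded), a minimum of 125 gap-free sequences
per score, a centroid-based three-body distance with an inclusive 12 Å
contact call, contact-fraction-vs-rank curves (with a polar-residue subset),
per-nucleotide conditional amino-acid distributions, and structural
connectivity reports for the top triplets of a nucleotide.

Because the original alignments and crystal structures are external
resources, the package ships a first-class synthetic module that generates
paired alignments with *planted* triplet dependencies and matching synthetic
structures, so recovery and enrichment are measurable ground-truth
benchmarks.

## Worked example

`examples/02_planted_recovery.py` hides one coupled triplet among 629
background triplets at the realistic scale of 393 species and asks the
ranking to find it:

```
alignment: 393 species, 6 RNA columns, 15 protein columns
scored 630 triplets (0 below the 125-sequence floor); top five by MI/H:
  1. rna 1 / aa 1,2: MI/H +0.0600 (MI +0.1814 bits, n=373)  <- planted
  2. rna 6 / aa 9,15: MI/H +0.0223 (MI +0.1095 bits, n=369)
  ...
recovered fraction in top 5: 100%; planted ranks: {(1, 1, 2): 1}
```

The planted triplet ranks first, with MI/H well above the plug-in noise
floor of the decoys (and on the same order as the ≈0.08 seen for real
rRNA/protein triplets). `examples/03_contact_enrichment.py` adds structure:

```
triplets: contact base rate  0.92%; top-5 contact fraction 60.00%
pairs   : contact base rate  0.00%; top-5 contact fraction  0.00%
```

High-MI/H triplets concentrate at close three-body distance (a 65-fold
enrichment over the base rate at rank 5) while the matched pairwise ranking,
built from the same alignments, shows nothing — the planted dependence is
invisible at second order by construction.

The other examples demonstrate the sign convention of interaction
information (`01`) and the purine/pyrimidine switch in conditional
amino-acid distributions (`04`).

## Command line

The same pipeline is available as a thin CLI:

```sh
tripletmi simulate --out bundle --plant 1,1,2,xor,0.9,proximal
tripletmi run-all --rna-msa bundle/rna.fasta --protein-msa bundle/protein.fasta \
    --structure bundle/structure.pdb --neighbor-radius 15 --outdir out
```

`run-all` writes score tables (`pair_scores.tsv`, `triplet_scores.tsv`),
contact curves, conditional-distribution grids, a cluster report and a
manifest of stage counts. Individual stages (`score-triplets`, `contacts`,
`rank`, `curve`, `distributions`, `cluster`) are independently invokable.
Exit codes: 0 success, 2 input error, 3 configuration error.

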