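# Methods

## Statistic and estimators

All information quantities are plug-in (maximum-likelihood) estimates over
the empirical symbol frequencies of gap-free rows, in bits by default
(`unit="nats"` is available). For columns X, Y (protein) and Z (RNA):

* entropy H(X) = −Σ p log₂ p with 0·log 0 ≡ 0;
* pairwise MI I(X;Y) = H(X) + H(Y) − H(X,Y) ∈ [0, min(H(X), H(Y))];
* conditional MI I(X;Y|Z) = H(X,Z) + H(Y,Z) − H(Z) − H(X,Y,Z) ≥ 0;
* interaction information
  I(X;Y;Z) = I(X;Y|Z) − I(X;Y)
  = H(X,Y) + H(X,Z) + H(Y,Z) − H(X) − H(Y) − H(Z) − H(X,Y,Z),
  symmetric in all six argument orders, bounded by |I| ≤ H(X,Y,Z), and of
  either sign: positive = synergy, negative = redundancy. (A decomposition
  sometimes quoted in the literature claims the "overlap" term is always
  non-negative; the XOR construction is a counterexample, so the
  conditional-minus-marginal form above is taken as the operational
  definition.)

Scores are reported as MI/H, the statistic divided by the joint entropy of
the same columns — dimensionless, in [−1, 1], and empirically a better
signal-to-noise normalization than raw MI. No pseudocounts and no
average-product or phylogenetic corrections are applied; noise control
comes from the normalization, the conservation filter, and the sequence
floor below.

Two implementations exist deliberately: a readable `Counter`-based reference
(`infotheory`) and an integer-coded `bincount` engine for exhaustive scans
(`coevolution`). The test suite holds them to 1e−12 agreement, and both are
checked against an independent dict-based contingency-table oracle.
Magnitudes below 1e−12 are snapped to zero so the sign classification of
near-zero triplets is stable.

## Filtering and ranking

* **Gaps and ambiguity codes.** Gap characters are `-` and `.`; any symbol
  outside {A,C,G,U} (RNA) or the 20 canonical amino acids (protein) is
  treated as a gap. A row is dropped per requested column tuple whenever any
  requested position is gapped — gaps never enter a count.
* **Conservation.** Column entropy is computed on the species-joined rows,
  gap-excluded. Columns with entropy < 0.3 bits, or with fewer than two
  distinct canonical symbols, are conserved and excluded: a conserved column
  cannot coevolve. The cutoff (0.3 bits) follows common practice in
  MI-based contact prediction; the log base is a configuration option, so
  the cutoff is interpreted in the configured unit.
* **Sequence floor.** Pairs and triplets retaining fewer than 125 gap-free
  rows are skipped (recorded in a skip log, never silently dropped):
  plug-in MI at smaller samples is dominated by background noise.
* **Ranking.** Descending MI/H; by default only positive triplet MI enters
  the ranking (negative values mostly flag independently evolving columns),
  with a flag to re-include them. Ties break on higher raw MI, then
  lexicographic positions, so outputs are reproducible to the byte.
* **Species joining.** Alignments built from independent resources are
  joined on a normalized species key: lowercase, split on whitespace and
  underscores, first two tokens kept (genus + species), strain suffixes
  discarded. Collisions keep the first record and are logged. Rows are
  emitted sorted by key.

## Structure conventions

* **Representative atoms.** One coordinate per residue: Cα for amino acids;
  P for nucleotides with a C1′ fallback (5′-terminal residues often lack a
  phosphate). Residues lacking both are dropped with a log entry. First
  altloc kept; insertion codes produce composite residue numbers.
* **Three-body distance.** d(a,b,c) = √(Σᵢ‖rᵢ − centroid‖²): zero iff the
  points coincide, rigid-motion invariant, symmetric, and in Å. A literal
  "squared sum of centroid distances" has Å² units and is inconsistent with
  contact distances quoted in Å for compact triplets, so the
  root-sum-of-squares form is the default; `squared_sum` and `sum` variants
  are selectable for comparison.
* **Contacts.** Inclusive threshold: distance ≤ 12 Å (pairwise distance for
  pairs, the centroid metric for triplets).
* **Neighbor selection.** Nucleotides within `neighbor_radius` of any
  protein residue (representative-atom distances, default 10 Å) define the
  RNA positions eligible for scoring. Synthetic layouts use 15 Å (see
  below).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *data regime* of a curated rRNA alignment
joined with a ClustalW protein alignment: 393 species by default, skewed
nucleotide backgrounds (A 5%, C 10%, G 15%, U 70% — the frequencies observed
at the worked nucleotide of the real system), low-entropy protein background
columns (a 4-residue support per column with weights 0.4/0.3/0.2/0.1,
≈1.85 bits), and i.i.d. 2% gaps. Species are exchangeable (no phylogeny):
the estimator applies no phylogenetic correction, so an i.i.d. generator is
the matching null. Real alignments violate this — shared ancestry inflates
apparent covariation — so passing benchmarks here demonstrate estimator and
pipeline correctness, not robustness to phylogenetic confounding.

**fig3 coupling.** Mimics the purine/pyrimidine switching pattern of high-MI
proximal triplets. X is Arg/Asn with equal weight in *both* branches; Y
defaults to a three-residue polar background (D/E/S). When Z is a
pyrimidine, the pair snaps with probability `coupling_strength` to the tight
pairing R→D / N→E, anchored at the canonical Arg/Asp contact; purine rows
are always independent and broad. The branch-matched X marginal is
essential: a pure marginal shift toward a fixed (R,D) cell makes Z a common
cause of X and Y and drives the interaction information *negative*
(redundancy ≈ −0.14 bits at coupling 0.9) — such a planting is unrecoverable
under positive-MI ranking and non-monotone in the coupling. The conditional
pairing instead gives positive interaction information that increases with
coupling (MI/H ≈ +0.05–0.10 at high coupling, the same order as real
high-MI triplets), at the price that the pyrimidine table at full coupling
is the two-cell pairing {(R,D), (N,E)} rather than a point mass. The purine
branch is kept at three residues rather than all ten polars because at the
393-species scale a ten-residue branch buries the planted signal under the
decoys' plug-in noise.

**xor coupling.** A categorical parity model that is *exactly* pairwise
independent: Z uniform over A/C/G/U, X uniform over R/N, and Y = D or E by
the parity of (pyrimidine, X=R) with probability `coupling_strength`. All
three pairwise MIs vanish in the generating distribution, so any pairwise
analysis is blind to the planting — this model drives the triplet-vs-pair
contrast benchmark.

**Geometry.** The protein lies on a line at 5 Å spacing. A proximal planted
nucleotide *bridges* its two amino acids: perpendicular to their midpoint at
a height placing the triplet inside the 12 Å centroid contact but every
pairwise distance just above 12 Å. Three-body proximity therefore exists
without any two-body contact, making the triplet/pair contrast a property of
the construction rather than of sampling luck (bridging is feasible only for
amino-acid pairs closer than 12 Å; infeasible requests raise a geometry
error). Distal planted nucleotides sit ≥ 20 Å from both partners; background
nucleotides hover at 14.5 Å, just outside triplet contact of every pair.
Because representative-atom (P/Cα) separations run larger than all-atom
minimum distances — and the bridging construction needs the neighbor shell
to clear the 12 Å pairwise floor — synthetic layouts use a 15 Å neighbor
radius (`SYNTHETIC_NEIGHBOR_RADIUS`) instead of the 10 Å default used for
real structures.

## Benchmarks and problem sizes

Two named study conditions are shared by the test suite and
`scripts/acceptance.py`:

* **Recovery** (`recovery_benchmark_spec`): 393 species, 6 RNA × 15 protein
  columns (630 triplets, 629 decoys), one fig3 triplet at coupling 0.9, 2%
  gaps; 100 replicates; the planted triplet is required to rank first by
  MI/H in at least 95.
* **Contact enrichment** (`contact_benchmark_spec`): 393 species, 10 RNA ×
  18 protein columns (1530 triplets), five proximal xor triplets plus two
  distal xor decoys at coupling 0.9. The triplet contact fraction at rank 5
  must exceed twice the triplet base rate; the pair curve must not exceed
  twice the pair base rate.

Estimator cross-checks run on 1,000 random column triples (n ≤ 60,
alphabets ≤ 4) for oracle agreement and the two-route identity at 1e−12,
and 10,000 for symmetry and bounds. These sizes give sub-minute runtimes
while leaving the binomial margins of the stochastic checks wide.

## Numerical choices and degenerate inputs

* Zero-snapping at 1e−12 (above); normalization by a zero joint entropy is
  an error — such columns are constant and removed by the conservation
  filter upstream.
* Empty columns (all gaps) raise shape errors in profiles and are skipped by
  the conservation mask.
* All randomness flows through a single integer seed per generator spec;
  the acceptance script spawns independent substreams from its `--seed`.
* Scores not mappable to a structure residue keep `distance = None`, are
  excluded from curves, and are counted in the logs.

## Limitations

* No phylogenetic-bias correction, shuffling null, or average-product
  correction; plug-in estimates carry a positive finite-sample bias that
  grows with alphabet size, which the MI/H normalization tempers but does
  not remove.
* The synthetic geometry is schematic (a line plus planted nucleotides),
  not a folded complex; enrichment numbers on it are construction
  properties, not biological effect sizes.
* Pipeline numbering assumes either identity column numbering (synthetic
  bundles) or a single ungapped reference sequence per chain for mapping
  alignment columns to structure residue numbers.
* No statistical significance testing of enrichment curves; outputs are
  descriptive tables and reports.
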