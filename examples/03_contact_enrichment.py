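"""Triplet-vs-pair contact enrichment on a synthetic structure.

Builds the contact benchmark: five proximal xor-coupled triplets whose
nucleotide bridges its two amino acids (three-body contact at <= 12 A
without any two-body contact), two distal decoys, and a matching layout.
Runs the full pipeline and compares the rank-5 contact fraction of triplets
and pairs against their base rates.
"""

import tempfile
from pathlib import Path

import pandas as pd

from tripletmi import RunConfig, run_pipeline
from tripletmi.synthetic import (
    SYNTHETIC_NEIGHBOR_RADIUS,
    contact_benchmark_spec,
    generate_paired_msa,
    generate_structure_layout,
)

spec = contact_benchmark_spec(seed=3)
paired, truth = generate_paired_msa(spec)
model = generate_structure_layout(spec, truth)

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "run"
    manifest = run_pipeline(
        RunConfig(outdir=str(out), neighbor_radius=SYNTHETIC_NEIGHBOR_RADIUS),
        paired=paired, model=model)
    triplets = pd.read_csv(out / "triplet_scores.tsv", sep="\t")
    pairs = pd.read_csv(out / "pair_scores.tsv", sep="\t")
    curves = pd.read_csv(out / "contact_curves.tsv", sep="\t")

print("stage counts:", manifest["stages"]["score"])
for label, table in (("triplets", triplets), ("pairs", pairs)):
    base = table["in_contact"].mean()
    top5 = curves.query(f"subset == '{label}_all' and rank == 5")[
        "contact_fraction"].iloc[0]
    print(f"{label:8s}: contact base rate {base:6.2%}; "
          f"top-5 contact fraction {top5:6.2%}")
print("high-MI/H triplets concentrate at close three-body distance while "
      "the matched pair ranking stays at its base rate.")
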