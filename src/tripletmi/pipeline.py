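"""End-to-end pipeline: join -> filter -> score -> contacts -> rank -> reports.

Given the two alignments, an optional structure and a configuration, the
pipeline produces deterministic TSV/JSON outputs: pair and triplet score
tables, contact-fraction-vs-rank curves (all scores and the polar subset),
conditional amino-acid distributions for the top triplet, and a cluster
report for the top nucleotide. Identical inputs and configuration yield
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import alignments as aln
from . import coevolution as coev
from . import structure as struct

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "PipelineError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid configuration value."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    rna_msa: Optional[str] = None
    protein_msa: Optional[str] = None
    structure: Optional[str] = None
    outdir: str = "tripletmi_out"
    rna_format: str = "fasta"
    protein_format: str = "fasta"
    rna_chain: str = "R"
    protein_chain: str = "P"
    entropy_cutoff: float = 0.3
    neighbor_radius: float = 10.0
    contact_threshold: float = 12.0
    min_rows: int = 125
    max_rank: int = 100
    cluster_k: int = 10
    cluster_edge_cutoff: float = 8.0
    positive_only: bool = True
    unit: str = "bits"
    triplet_distance_variant: str = "rms_centroid"
    excluded_rna_positions: tuple = ()
    excluded_protein_positions: tuple = ()
    rna_reference_species: Optional[str] = None
    protein_reference_species: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        for name in ("entropy_cutoff", "neighbor_radius", "contact_threshold",
                     "cluster_edge_cutoff"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("min_rows", "max_rank", "cluster_k"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.unit not in {"bits", "nats"}:
            raise ConfigError("unit must be 'bits' or 'nats'")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        for key in ("excluded_rna_positions", "excluded_protein_positions"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig,
                 paired: Optional[aln.PairedAlignment] = None,
                 model: Optional[struct.StructureModel] = None) -> dict:
    """Run every stage and write the outputs; returns the run manifest.

    ``paired`` and ``model`` may be passed directly (e.g. from the synthetic
    generator) instead of reading the configured paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": {}, "files": []}
    stages = manifest["stages"]

    @_stage("read")
    def read_inputs():
        nonlocal paired, model
        if paired is None:
            rna = aln.read_alignment(config.rna_msa, config.rna_format, "rna")
            prot = aln.read_alignment(config.protein_msa,
                                      config.protein_format, "protein")
            stages["read"] = {"rna_records": len(rna.records),
                              "protein_records": len(prot.records)}
            paired = aln.join_by_species(rna, prot)
        if model is None and config.structure is not None:
            model = struct.read_structure(
                config.structure,
                {"rna": config.rna_chain, "protein": config.protein_chain})
        return paired, model

    paired, model = read_inputs()
    stages["join"] = {"rows": len(paired),
                      "rna_length": paired.rna_length,
                      "protein_length": paired.protein_length}

    @_stage("conservation")
    def masks():
        rna_var = aln.conservation_mask(paired, "rna", config.entropy_cutoff,
                                        config.unit)
        prot_var = aln.conservation_mask(paired, "protein",
                                         config.entropy_cutoff, config.unit)
        rna_var -= set(config.excluded_rna_positions)
        prot_var -= set(config.excluded_protein_positions)
        return rna_var, prot_var

    rna_var, prot_var = masks()
    stages["conservation"] = {
        "variable_rna_positions": len(rna_var),
        "conserved_rna_positions": paired.rna_length - len(rna_var),
        "variable_protein_positions": len(prot_var),
        "conserved_protein_positions": paired.protein_length - len(prot_var),
    }

    rna_map = {p: p for p in range(1, paired.rna_length + 1)}
    prot_map = {p: p for p in range(1, paired.protein_length + 1)}

    @_stage("neighbors")
    def neighbors():
        nonlocal rna_var, rna_map, prot_map
        if model is None:
            return None
        if config.rna_reference_species:
            rna_al = aln.Alignment.from_records(
                [(sid, seq) for sid, seq, _ in paired.rows], "rna")
            rna_map = aln.map_to_reference_numbering(
                rna_al, config.rna_reference_species)
        if config.protein_reference_species:
            prot_al = aln.Alignment.from_records(
                [(sid, seq) for sid, _, seq in paired.rows], "protein")
            prot_map = aln.map_to_reference_numbering(
                prot_al, config.protein_reference_species)
        near = struct.rna_neighbors(model, config.neighbor_radius)
        near_numbers = {r.number for r in near}
        rna_var = {p for p in rna_var
                   if rna_map.get(p) is not None
                   and str(rna_map[p]) in near_numbers}
        return len(near)

    n_near = neighbors()
    if n_near is not None:
        stages["neighbors"] = {"rna_neighbors": n_near,
                               "variable_neighbor_positions": len(rna_var)}

    @_stage("score")
    def score():
        pairs, pair_skips = coev.score_all_pairs(
            paired, rna_var, prot_var, config.min_rows, config.unit)
        triplets, triplet_skips = coev.score_all_triplets(
            paired, rna_var, prot_var, config.min_rows, config.unit)
        return pairs, pair_skips, triplets, triplet_skips

    pairs, pair_skips, triplets, triplet_skips = score()
    stages["score"] = {"pairs_scored": len(pairs),
                       "pairs_skipped_low_n": len(pair_skips),
                       "triplets_scored": len(triplets),
                       "triplets_skipped_low_n": len(triplet_skips)}

    @_stage("contacts")
    def contacts():
        if model is None:
            return pairs, triplets, 0
        apairs, un_p = coev.attach_contacts(
            pairs, model, config.rna_chain, config.protein_chain,
            config.contact_threshold, config.triplet_distance_variant,
            rna_map, prot_map)
        atrip, un_t = coev.attach_contacts(
            triplets, model, config.rna_chain, config.protein_chain,
            config.contact_threshold, config.triplet_distance_variant,
            rna_map, prot_map)
        return apairs, atrip, len(un_p) + len(un_t)

    pairs, triplets, n_unmapped = contacts()
    stages["contacts"] = {"unmapped_scores": n_unmapped,
                          "structure_used": model is not None}

    def write_frame(frame, name):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["files"].append(name)

    write_frame(coev.scores_to_frame(
        coev.rank_scores(pairs, positive_only=False)) if pairs else
        coev.scores_to_frame([]), "pair_scores.tsv")
    write_frame(coev.scores_to_frame(
        coev.rank_scores(triplets, positive_only=False)) if triplets else
        coev.scores_to_frame([]), "triplet_scores.tsv")

    @_stage("rank")
    def rank():
        rp = coev.rank_scores(pairs, positive_only=config.positive_only) \
            if pairs else []
        rt = coev.rank_scores(triplets, positive_only=config.positive_only) \
            if triplets else []
        return rp, rt

    ranked_pairs, ranked_triplets = rank()
    stages["rank"] = {"ranked_pairs": len(ranked_pairs),
                      "ranked_triplets": len(ranked_triplets)}

    @_stage("curves")
    def curves():
        if model is None:
            return []
        out = []
        for label, ranked in (("triplets", ranked_triplets),
                              ("pairs", ranked_pairs)):
            usable = [s for s in ranked if s.in_contact is not None]
            if usable:
                out.append((f"{label}_all", coev.contact_fraction_curve(
                    usable, config.max_rank, f"{label}_all")))
            polar = coev.polar_subset(usable, paired)
            if polar:
                out.append((f"{label}_polar", coev.contact_fraction_curve(
                    polar, config.max_rank, f"{label}_polar")))
        return out

    curve_list = curves()
    if curve_list:
        import pandas as pd
        rows = [{"rank": r, "contact_fraction": f, "subset": label}
                for label, curve in curve_list
                for r, f in zip(curve.ranks, curve.contact_fraction)]
        write_frame(pd.DataFrame(rows), "contact_curves.tsv")
    stages["curves"] = {"subsets": [label for label, _ in curve_list]}

    @_stage("reports")
    def reports():
        written = {}
        if not ranked_triplets:
            return written
        top = ranked_triplets[0]
        dist = coev.conditional_distributions(paired, *top.positions)
        for label, table in dist.tables.items():
            if table is None:
                continue
            name = f"distribution_{label}.tsv"
            table.to_csv(outdir / name, sep="\t")
            manifest["files"].append(name)
        written["distribution_triplet"] = list(top.positions)
        written["nucleotide_frequencies"] = dist.nucleotide_frequencies
        if model is not None:
            n_for_top = sum(1 for s in ranked_triplets
                            if s.rna_position == top.rna_position)
            if n_for_top >= config.cluster_k:
                report = coev.top_cluster_report(
                    ranked_triplets, top.rna_position, model,
                    config.protein_chain, config.cluster_k,
                    config.cluster_edge_cutoff, prot_map)
                with open(outdir / "cluster_report.json", "w") as fh:
                    json.dump(report, fh, indent=2, sort_keys=True)
                manifest["files"].append("cluster_report.json")
                written["cluster_nucleotide"] = top.rna_position
        return written

    stages["reports"] = reports()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
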