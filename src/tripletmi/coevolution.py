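"""Exhaustive pair/triplet scoring, ranking and structure-aware reports.

A pair couples one RNA column with one protein column; a triplet couples one
RNA column with an unordered pair of protein columns. Scores are the plug-in
mutual information (pairs) or interaction information (triplets) normalized by
the joint entropy of the same columns (MI/H), computed on gap-filtered rows.

The scan here is an integer-coded, bincount-based engine tuned for exhaustive
enumeration; :mod:`tripletmi.infotheory` is the readable reference
implementation, and the two agree to 1e-12 (enforced by the test suite).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .alignments import PROTEIN_ALPHABET, RNA_ALPHABET, PairedAlignment
from .structure import StructureModel, classify_contact

logger = logging.getLogger(__name__)

__all__ = [
    "POLAR_RESIDUES",
    "PairScore",
    "TripletScore",
    "RankCurve",
    "ConditionalDistribution",
    "score_all_pairs",
    "score_all_triplets",
    "rank_scores",
    "attach_contacts",
    "contact_fraction_curve",
    "polar_subset",
    "conditional_distributions",
    "top_cluster_report",
    "scores_to_frame",
]

#: residues counted as polar (surface-prone, RNA-interacting)
POLAR_RESIDUES = frozenset("DEHKNQRSTY")

_RNA_ORDER = "ACGU"
_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class PairScore:
    rna_position: int
    aa_position: int
    mi: float
    joint_entropy: float
    mi_over_h: float
    n_used: int
    distance: Optional[float] = None
    in_contact: Optional[bool] = None

    @property
    def positions(self) -> tuple:
        return (self.rna_position, self.aa_position)

    @property
    def aa_positions(self) -> tuple:
        return (self.aa_position,)


@dataclass(frozen=True)
class TripletScore:
    rna_position: int
    aa_position_1: int
    aa_position_2: int
    mi: float
    joint_entropy: float
    mi_over_h: float
    n_used: int
    distance: Optional[float] = None
    in_contact: Optional[bool] = None

    def __post_init__(self):
        if not self.aa_position_1 < self.aa_position_2:
            raise ValueError("amino-acid positions must satisfy aa1 < aa2")

    @property
    def positions(self) -> tuple:
        return (self.rna_position, self.aa_position_1, self.aa_position_2)

    @property
    def aa_positions(self) -> tuple:
        return (self.aa_position_1, self.aa_position_2)


@dataclass(frozen=True)
class RankCurve:
    ranks: tuple
    contact_fraction: tuple
    subset_label: str = "all"


@dataclass(frozen=True)
class ConditionalDistribution:
    """Amino-acid pair frequencies of one triplet, conditioned on the RNA."""

    triplet: tuple  # (rna_position, aa_position_1, aa_position_2)
    tables: dict  # class label -> 20x20 DataFrame (rows aa1, cols aa2), or None
    row_counts: dict  # class label -> rows in that class
    nucleotide_frequencies: dict  # A/C/G/U -> empirical frequency


def _encode(paired: PairedAlignment):
    """Integer-code both chains; -1 marks gaps/non-canonical symbols."""
    rna_lut = np.full(256, -1, dtype=np.int8)
    for i, s in enumerate(_RNA_ORDER):
        rna_lut[ord(s)] = i
    aa_lut = np.full(256, -1, dtype=np.int8)
    for i, s in enumerate(_AA_ORDER):
        aa_lut[ord(s)] = i
    rna = np.frombuffer("".join(r[1] for r in paired.rows).encode("latin-1"),
                        dtype=np.uint8).reshape(len(paired), paired.rna_length)
    prot = np.frombuffer("".join(r[2] for r in paired.rows).encode("latin-1"),
                         dtype=np.uint8).reshape(len(paired), paired.protein_length)
    return rna_lut[rna], aa_lut[prot]


def _entropy_bits(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _snap(x: float) -> float:
    return 0.0 if abs(x) < _ZERO_TOL else x


def score_all_pairs(paired: PairedAlignment,
                    rna_positions: Iterable[int],
                    protein_positions: Iterable[int],
                    min_rows: int = 125,
                    unit: str = "bits") -> tuple:
    """Score every (RNA column, protein column) pair.

    Returns ``(scores, skipped)`` where ``skipped`` lists ``(positions, n)``
    for combinations that retained fewer than ``min_rows`` gap-free rows.
    """
    rna_codes, prot_codes = _encode(paired)
    scale = 1.0 if unit == "bits" else float(np.log(2.0))
    scores, skipped = [], []
    for zp in sorted(rna_positions):
        z = rna_codes[:, zp - 1]
        for ap in sorted(protein_positions):
            x = prot_codes[:, ap - 1]
            valid = (z >= 0) & (x >= 0)
            n = int(valid.sum())
            if n < min_rows:
                skipped.append(((zp, ap), n))
                continue
            zv = z[valid].astype(np.int64)
            xv = x[valid].astype(np.int64)
            hz = _entropy_bits(np.bincount(zv, minlength=4), n)
            hx = _entropy_bits(np.bincount(xv, minlength=20), n)
            hzx = _entropy_bits(np.bincount(zv * 20 + xv, minlength=80), n)
            mi = _snap((hz + hx - hzx) * scale)
            h = hzx * scale
            scores.append(PairScore(
                rna_position=zp, aa_position=ap, mi=mi, joint_entropy=h,
                mi_over_h=_snap(mi / h) if h > 0 else 0.0, n_used=n))
    if skipped:
        logger.info("score_all_pairs: skipped %d pairs below min_rows=%d",
                    len(skipped), min_rows)
    return scores, skipped


def score_all_triplets(paired: PairedAlignment,
                       rna_positions: Iterable[int],
                       protein_positions: Iterable[int],
                       min_rows: int = 125,
                       unit: str = "bits") -> tuple:
    """Score every (RNA column, unordered protein-column pair) triplet.

    All scored triplets are returned, including those with negative
    interaction information; :func:`rank_scores` applies the positive-only
    filter used for ranking. Returns ``(scores, skipped)`` as in
    :func:`score_all_pairs`.
    """
    rna_codes, prot_codes = _encode(paired)
    scale = 1.0 if unit == "bits" else float(np.log(2.0))
    protein_positions = sorted(protein_positions)
    scores, skipped = [], []
    for zp in sorted(rna_positions):
        z = rna_codes[:, zp - 1]
        zok = z >= 0
        for ap, bp in itertools.combinations(protein_positions, 2):
            x = prot_codes[:, ap - 1]
            y = prot_codes[:, bp - 1]
            valid = zok & (x >= 0) & (y >= 0)
            n = int(valid.sum())
            if n < min_rows:
                skipped.append(((zp, ap, bp), n))
                continue
            zv = z[valid].astype(np.int64)
            xv = x[valid].astype(np.int64)
            yv = y[valid].astype(np.int64)
            xy = xv * 20 + yv
            hz = _entropy_bits(np.bincount(zv, minlength=4), n)
            hx = _entropy_bits(np.bincount(xv, minlength=20), n)
            hy = _entropy_bits(np.bincount(yv, minlength=20), n)
            hxy = _entropy_bits(np.bincount(xy, minlength=400), n)
            hxz = _entropy_bits(np.bincount(zv * 20 + xv, minlength=80), n)
            hyz = _entropy_bits(np.bincount(zv * 20 + yv, minlength=80), n)
            hxyz = _entropy_bits(np.bincount(zv * 400 + xy, minlength=1600), n)
            mi = _snap((hxy + hxz + hyz - hx - hy - hz - hxyz) * scale)
            h = hxyz * scale
            scores.append(TripletScore(
                rna_position=zp, aa_position_1=ap, aa_position_2=bp,
                mi=mi, joint_entropy=h,
                mi_over_h=_snap(mi / h) if h > 0 else 0.0, n_used=n))
    if skipped:
        logger.info("score_all_triplets: skipped %d triplets below min_rows=%d",
                    len(skipped), min_rows)
    return scores, skipped


def rank_scores(scores: Sequence, key: str = "mi_over_h",
                positive_only: bool = True) -> list:
    """Rank descending by ``key`` with deterministic tie-breaking.

    With ``positive_only`` (the default) only scores with ``mi > 0`` enter
    the ranking; negative interaction information mostly flags independently
    evolving columns and is excluded from rank analyses. Ties break on higher
    ``mi`` then on lexicographic positions.
    """
    if not scores:
        raise ValueError("no scores to rank")
    pool = [s for s in scores if s.mi > 0] if positive_only else list(scores)
    return sorted(pool, key=lambda s: (-getattr(s, key), -s.mi, s.positions))


def attach_contacts(scores: Sequence, model: StructureModel,
                    rna_chain: str, protein_chain: str,
                    contact_threshold: float = 12.0,
                    triplet_variant: str = "rms_centroid",
                    rna_map: Optional[dict] = None,
                    protein_map: Optional[dict] = None) -> tuple:
    """Annotate scores with 2/3-body distances and contact calls.

    ``rna_map``/``protein_map`` translate alignment columns to structure
    residue numbers (identity when omitted, as for synthetic bundles). Scores
    whose positions do not map to a structure residue keep ``distance=None``
    and are returned separately as unmapped.
    """
    rna_map = rna_map or {}
    protein_map = protein_map or {}
    annotated, unmapped = [], []
    for s in scores:
        try:
            members = [model.get(rna_chain, rna_map.get(s.rna_position,
                                                        s.rna_position))]
            for ap in s.aa_positions:
                members.append(model.get(protein_chain,
                                         protein_map.get(ap, ap)))
        except KeyError:
            unmapped.append(s)
            annotated.append(s)
            continue
        call = classify_contact(members, threshold=contact_threshold,
                                triplet_variant=triplet_variant)
        annotated.append(replace(s, distance=call.distance,
                                 in_contact=call.in_contact))
    if unmapped:
        logger.info("attach_contacts: %d scores not mappable to the structure",
                    len(unmapped))
    return annotated, unmapped


def contact_fraction_curve(ranked: Sequence, max_rank: int = 100,
                           subset_label: str = "all") -> RankCurve:
    """Cumulative fraction of the top-r scores that are in contact, r <= max_rank."""
    usable = ranked[:max_rank]
    if not usable:
        raise ValueError("no ranked scores for the contact curve")
    fractions, hits = [], 0
    for r, s in enumerate(usable, start=1):
        if s.in_contact is None:
            raise ValueError(f"score at rank {r} has no contact call")
        hits += bool(s.in_contact)
        fractions.append(hits / r)
    return RankCurve(ranks=tuple(range(1, len(usable) + 1)),
                     contact_fraction=tuple(fractions),
                     subset_label=subset_label)


def _polar_columns(paired: PairedAlignment, mode: str) -> set:
    polar = set()
    from .alignments import column_profile, AlignmentShapeError
    for pos in range(1, paired.protein_length + 1):
        try:
            prof = column_profile(paired, "protein", pos)
        except AlignmentShapeError:
            continue
        if mode == "majority":
            top = max(sorted(prof.counts), key=lambda s: prof.counts[s])
            if top in POLAR_RESIDUES:
                polar.add(pos)
        elif mode == "mean_fraction":
            frac = sum(c for s, c in prof.counts.items()
                       if s in POLAR_RESIDUES) / prof.n_ungapped
            if frac >= 0.5:
                polar.add(pos)
        else:
            raise ValueError(f"unknown polar mode {mode!r}")
    return polar


def polar_subset(scores: Sequence, paired: PairedAlignment,
                 mode: str = "majority") -> list:
    """Scores whose every protein column is polar-dominated.

    A column qualifies when its majority residue is polar (default), or, with
    ``mode="mean_fraction"``, when at least half the ungapped rows are polar.
    """
    polar = _polar_columns(paired, mode)
    return [s for s in scores if all(p in polar for p in s.aa_positions)]


def conditional_distributions(paired: PairedAlignment, rna_position: int,
                              aa_position_1: int, aa_position_2: int,
                              ) -> ConditionalDistribution:
    """Per-nucleotide 20x20 amino-acid pair frequency tables for one triplet.

    Rows of the paired alignment are partitioned by the nucleotide at the RNA
    column; each class's (aa1, aa2) frequencies are tabulated and normalized.
    Purine (A/G) and pyrimidine (C/U) pooled tables are included. Classes with
    no rows carry ``None`` tables (flagged, not an error).
    """
    from .alignments import extract_columns
    tuples = extract_columns(paired, rna_position,
                             [aa_position_1, aa_position_2])
    classes = {nt: [] for nt in _RNA_ORDER}
    for z, x, y in tuples:
        classes[z].append((x, y))
    classes["purine"] = classes["A"] + classes["G"]
    classes["pyrimidine"] = classes["C"] + classes["U"]
    tables, row_counts = {}, {}
    for label, rows in classes.items():
        row_counts[label] = len(rows)
        if not rows:
            tables[label] = None
            continue
        grid = pd.DataFrame(0.0, index=list(_AA_ORDER), columns=list(_AA_ORDER))
        for x, y in rows:
            grid.loc[x, y] += 1
        tables[label] = grid / len(rows)
    n = len(tuples)
    freqs = {nt: (row_counts[nt] / n if n else 0.0) for nt in _RNA_ORDER}
    return ConditionalDistribution(
        triplet=(rna_position, aa_position_1, aa_position_2),
        tables=tables, row_counts=row_counts, nucleotide_frequencies=freqs)


def top_cluster_report(ranked: Sequence, rna_position: int,
                       model: StructureModel, protein_chain: str,
                       k: int = 10, edge_cutoff: float = 8.0,
                       protein_map: Optional[dict] = None) -> dict:
    """Connectivity of the residues in the k best triplets of one nucleotide.

    Collects the amino-acid residues of the ``k`` highest-ranked triplets
    containing ``rna_position``, links residues closer than ``edge_cutoff``
    Angstrom, and reports the connected components and whether one component
    spans every collected residue.
    """
    protein_map = protein_map or {}
    mine = [s for s in ranked if s.rna_position == rna_position
            and len(s.aa_positions) == 2]
    if not mine:
        raise KeyError(f"no ranked triplets for RNA position {rna_position}")
    top = mine[:k]
    residues = sorted({ap for s in top for ap in s.aa_positions})
    graph = nx.Graph()
    graph.add_nodes_from(residues)
    from .structure import pair_distance
    for a, b in itertools.combinations(residues, 2):
        ra = model.get(protein_chain, protein_map.get(a, a))
        rb = model.get(protein_chain, protein_map.get(b, b))
        if pair_distance(ra, rb) <= edge_cutoff:
            graph.add_edge(a, b)
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c))
    return {
        "rna_position": rna_position,
        "k": len(top),
        "edge_cutoff_A": edge_cutoff,
        "residues": residues,
        "triplets": [list(s.positions) for s in top],
        "components": components,
        "single_spanning_component": len(components) == 1,
    }


def scores_from_frame(frame: pd.DataFrame) -> list:
    """Rebuild PairScore/TripletScore objects from an exported score table."""
    scores = []
    for row in frame.itertuples(index=False):
        distance = None if pd.isna(row.distance_A) else float(row.distance_A)
        in_contact = None if pd.isna(row.in_contact) else bool(row.in_contact)
        common = dict(mi=float(row.mi_bits),
                      joint_entropy=float(row.joint_entropy_bits),
                      mi_over_h=float(row.mi_over_h), n_used=int(row.n_used),
                      distance=distance, in_contact=in_contact)
        if pd.isna(row.aa_pos2):
            scores.append(PairScore(rna_position=int(row.rna_pos),
                                    aa_position=int(row.aa_pos1), **common))
        else:
            scores.append(TripletScore(rna_position=int(row.rna_pos),
                                       aa_position_1=int(row.aa_pos1),
                                       aa_position_2=int(row.aa_pos2), **common))
    return scores


def scores_to_frame(scores: Sequence) -> pd.DataFrame:
    """Tabulate scores for TSV export (pairs leave aa_pos2 empty)."""
    rows = []
    for s in scores:
        aa = s.aa_positions
        rows.append({
            "rna_pos": s.rna_position,
            "aa_pos1": aa[0],
            "aa_pos2": aa[1] if len(aa) == 2 else pd.NA,
            "mi_bits": s.mi,
            "joint_entropy_bits": s.joint_entropy,
            "mi_over_h": s.mi_over_h,
            "n_used": s.n_used,
            "distance_A": round(s.distance, 3) if s.distance is not None else pd.NA,
            "in_contact": s.in_contact if s.in_contact is not None else pd.NA,
        })
    return pd.DataFrame(rows)
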