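"""Alignment I/O, species joining and column-level filtering.

An RNA alignment and a protein alignment, built independently (e.g. a curated
rRNA alignment versus a ClustalW alignment of ribosomal-protein sequences),
are joined on a normalized species key; every downstream statistic is computed
on the joined rows only. Gaps are never counted: a row is dropped, per
requested column tuple, whenever any requested position holds a gap or a
non-canonical symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .infotheory import shannon_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "RNA_ALPHABET",
    "PROTEIN_ALPHABET",
    "GAP_CHARS",
    "Alignment",
    "PairedAlignment",
    "ColumnProfile",
    "AlignmentShapeError",
    "JoinError",
    "normalize_species_id",
    "read_alignment",
    "write_alignment",
    "join_by_species",
    "extract_columns",
    "column_profile",
    "conservation_mask",
    "map_to_reference_numbering",
]

RNA_ALPHABET = frozenset("ACGU")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = frozenset("-.")

_CANONICAL = {"rna": RNA_ALPHABET, "protein": PROTEIN_ALPHABET}


class AlignmentShapeError(ValueError):
    """Sequences of unequal length, empty input, or bad positions."""


class JoinError(ValueError):
    """No species shared between the two alignments."""


def canonical_symbols(alphabet_kind: str) -> frozenset:
    try:
        return _CANONICAL[alphabet_kind]
    except KeyError:
        raise ValueError(f"alphabet_kind must be 'rna' or 'protein', got {alphabet_kind!r}")


def normalize_species_id(raw: str) -> str:
    """Collapse a species label to a lowercase genus+species key.

    Splits on whitespace and underscores and keeps the first two tokens,
    discarding strain/isolate suffixes; single-token ids pass through
    lowercased. Two independently curated resources rarely agree on full
    strain labels, so matching is done on this key.
    """
    tokens = raw.strip().lower().replace("_", " ").split()
    if not tokens:
        return ""
    return "_".join(tokens[:2])


@dataclass(frozen=True)
class Alignment:
    """One multiple sequence alignment with a declared alphabet."""

    records: tuple  # of (species_id, sequence)
    length: int
    alphabet_kind: str  # 'rna' | 'protein'

    def __post_init__(self):
        canonical_symbols(self.alphabet_kind)
        if not self.records:
            raise AlignmentShapeError("alignment has no records")
        for sid, seq in self.records:
            if len(seq) != self.length:
                raise AlignmentShapeError(
                    f"record {sid!r} has length {len(seq)}, expected {self.length}")

    @classmethod
    def from_records(cls, records: Iterable[tuple], alphabet_kind: str) -> "Alignment":
        records = tuple(records)
        if not records:
            raise AlignmentShapeError("alignment has no records")
        return cls(records=records, length=len(records[0][1]),
                   alphabet_kind=alphabet_kind)

    @property
    def species_ids(self) -> tuple:
        return tuple(sid for sid, _ in self.records)


@dataclass(frozen=True)
class PairedAlignment:
    """Species-joined rows of an RNA alignment and a protein alignment."""

    rows: tuple  # of (species_id, rna_sequence, protein_sequence)
    rna_length: int
    protein_length: int

    def __post_init__(self):
        for sid, rna, prot in self.rows:
            if len(rna) != self.rna_length or len(prot) != self.protein_length:
                raise AlignmentShapeError(f"row {sid!r} has inconsistent lengths")

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, chain: str, pos: int) -> list:
        """Raw symbols of one 1-based column, gaps included."""
        if chain == "rna":
            self._check(pos, self.rna_length)
            return [row[1][pos - 1] for row in self.rows]
        if chain == "protein":
            self._check(pos, self.protein_length)
            return [row[2][pos - 1] for row in self.rows]
        raise ValueError(f"chain must be 'rna' or 'protein', got {chain!r}")

    @staticmethod
    def _check(pos: int, length: int):
        if not 1 <= pos <= length:
            raise IndexError(f"position {pos} outside 1..{length}")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("species_id\trna_sequence\tprotein_sequence\n")
            for sid, rna, prot in self.rows:
                fh.write(f"{sid}\t{rna}\t{prot}\n")

    @classmethod
    def from_tsv(cls, path) -> "PairedAlignment":
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("species_id"):
                raise AlignmentShapeError("not a paired-alignment TSV")
            for line in fh:
                sid, rna, prot = line.rstrip("\n").split("\t")
                rows.append((sid, rna, prot))
        if not rows:
            raise AlignmentShapeError("paired-alignment TSV has no rows")
        return cls(rows=tuple(rows), rna_length=len(rows[0][1]),
                   protein_length=len(rows[0][2]))


@dataclass(frozen=True)
class ColumnProfile:
    """Gap-excluded symbol counts and Shannon entropy of one column."""

    position: int
    counts: dict
    n_ungapped: int
    entropy: float  # bits by default


def read_alignment(path, fmt: str = "fasta", alphabet_kind: str = "rna") -> Alignment:
    """Read a FASTA/Clustal/Stockholm alignment.

    Sequences are uppercased; for RNA, T is normalized to U (DNA-convention
    inputs are common for rRNA).
    """
    if fmt not in {"fasta", "clustal", "stockholm"}:
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        if "No records found" in str(exc) or path.stat().st_size == 0:
            raise AlignmentShapeError(f"{path}: empty alignment file") from exc
        raise AlignmentShapeError(f"{path}: {exc}") from exc
    records = []
    for rec in msa:
        seq = str(rec.seq).upper()
        if alphabet_kind == "rna":
            seq = seq.replace("T", "U")
        records.append((rec.id, seq))
    return Alignment.from_records(records, alphabet_kind)


def write_alignment(aln: Alignment, path, fmt: str = "fasta") -> None:
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records])
    AlignIO.write(msa, str(path), fmt)


def join_by_species(rna: Alignment, protein: Alignment,
                    id_normalizer: Callable[[str], str] = normalize_species_id,
                    ) -> PairedAlignment:
    """Join two alignments on normalized species ids (sorted, deterministic).

    Collisions after normalization keep the first record and are logged.
    """
    def index(aln: Alignment) -> dict:
        out = {}
        for sid, seq in aln.records:
            key = id_normalizer(sid)
            if key in out:
                logger.warning("species-id collision on %r; keeping first record", key)
                continue
            out[key] = seq
        return out

    rna_idx = index(rna)
    prot_idx = index(protein)
    shared = sorted(rna_idx.keys() & prot_idx.keys())
    if not shared:
        raise JoinError(
            f"no shared species between RNA alignment ({len(rna_idx)} ids) "
            f"and protein alignment ({len(prot_idx)} ids)")
    rows = tuple((key, rna_idx[key], prot_idx[key]) for key in shared)
    return PairedAlignment(rows=rows, rna_length=rna.length,
                           protein_length=protein.length)


def extract_columns(paired: PairedAlignment, rna_pos: Optional[int],
                    protein_positions: Sequence[int] = ()) -> list:
    """Co-occurring symbol tuples for the requested columns.

    Any row holding a gap or non-canonical symbol at any requested position is
    dropped for this tuple (gaps never enter the counts). Tuple order is
    (rna_symbol, aa_symbol, ...) matching the request.
    """
    if rna_pos is not None:
        PairedAlignment._check(rna_pos, paired.rna_length)
    for p in protein_positions:
        PairedAlignment._check(p, paired.protein_length)
    tuples = []
    for _, rna, prot in paired.rows:
        symbols = []
        ok = True
        if rna_pos is not None:
            s = rna[rna_pos - 1]
            if s not in RNA_ALPHABET:
                ok = False
            symbols.append(s)
        if ok:
            for p in protein_positions:
                s = prot[p - 1]
                if s not in PROTEIN_ALPHABET:
                    ok = False
                    break
                symbols.append(s)
        if ok:
            tuples.append(tuple(symbols))
    return tuples


def column_profile(paired: PairedAlignment, chain: str, pos: int,
                   unit: str = "bits") -> ColumnProfile:
    """Counts over canonical symbols only, with Shannon entropy."""
    canonical = RNA_ALPHABET if chain == "rna" else PROTEIN_ALPHABET
    symbols = paired.column(chain, pos)
    counts: dict = {}
    for s in symbols:
        if s in canonical:
            counts[s] = counts.get(s, 0) + 1
    n = sum(counts.values())
    if n == 0:
        raise AlignmentShapeError(
            f"{chain} column {pos}: no ungapped canonical symbols")
    return ColumnProfile(position=pos, counts=counts, n_ungapped=n,
                         entropy=shannon_entropy(counts, unit))


def conservation_mask(paired: PairedAlignment, chain: str,
                      cutoff: float = 0.3, unit: str = "bits") -> set:
    """Positions variable enough to score: column entropy >= cutoff (bits).

    Conserved columns (entropy below the cutoff) cannot coevolve by
    definition and are excluded; columns with fewer than two distinct
    canonical symbols are always conserved, whatever the cutoff.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    length = paired.rna_length if chain == "rna" else paired.protein_length
    variable = set()
    for pos in range(1, length + 1):
        try:
            profile = column_profile(paired, chain, pos, unit)
        except AlignmentShapeError:
            continue
        if len(profile.counts) >= 2 and profile.entropy >= cutoff:
            variable.add(pos)
    return variable


def map_to_reference_numbering(aln: Alignment, reference_species_id: str,
                               id_normalizer: Callable[[str], str] = normalize_species_id,
                               ) -> dict:
    """Map 1-based alignment columns to the reference sequence's residue numbers.

    Columns where the reference is gapped map to None; ungapped reference
    residues are numbered 1..n consecutively (the convention used to report
    positions in a standard numbering).
    """
    key = id_normalizer(reference_species_id)
    ref_seq = None
    for sid, seq in aln.records:
        if id_normalizer(sid) == key:
            ref_seq = seq
            break
    if ref_seq is None:
        raise KeyError(f"reference species {reference_species_id!r} not in alignment")
    mapping: dict = {}
    counter = 0
    canonical = canonical_symbols(aln.alphabet_kind)
    for col, symbol in enumerate(ref_seq, start=1):
        if symbol in GAP_CHARS or symbol not in canonical:
            mapping[col] = None
        else:
            counter += 1
            mapping[col] = counter
    return mapping
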