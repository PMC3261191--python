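"""Structure parsing, representative backbone atoms and 2/3-body distances.

Each residue is reduced to a single representative backbone coordinate:
C-alpha for amino acids; the phosphate P for nucleotides, falling back to C1'
(5'-terminal residues often lack a phosphate). All distances below are between
these representative atoms.

The three-body distance generalizes pairwise distance via the spread of the
three points about their centroid:

    d(a, b, c) = sqrt( sum_i || r_i - centroid ||^2 )   [Angstrom]

which is zero iff the points coincide, rigid-motion invariant, and symmetric
in its arguments. A literal squared-sum variant and a plain sum-of-distances
variant are selectable for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "StructureModel",
    "ContactCall",
    "read_structure",
    "write_structure",
    "pair_distance",
    "triplet_distance",
    "rna_neighbors",
    "classify_contact",
]

_AA_REPRESENTATIVE = ("CA",)
_NT_REPRESENTATIVE = ("P", "C1'")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    number: str  # residue number, with insertion code appended when present
    kind: str  # 'nucleotide' | 'amino_acid'
    coord: tuple  # (x, y, z) in Angstrom

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass(frozen=True)
class ContactCall:
    members: tuple  # 2 or 3 Residue references
    distance: float  # Angstrom
    in_contact: bool


@dataclass
class StructureModel:
    """Residues of the RNA and protein chains with one coordinate each."""

    residues: list

    def __post_init__(self):
        keys = [(r.chain_id, r.number) for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain_id, residue_number) in structure")
        self._index = {k: r for k, r in zip(keys, self.residues)}

    def get(self, chain_id: str, number) -> Residue:
        return self._index[(chain_id, str(number))]

    def __contains__(self, key) -> bool:
        chain_id, number = key
        return (chain_id, str(number)) in self._index

    def by_kind(self, kind: str) -> list:
        return [r for r in self.residues if r.kind == kind]


def read_structure(path, chain_map: dict) -> StructureModel:
    """Read a PDB file, keeping the mapped RNA and protein chains.

    ``chain_map`` is ``{"rna": chain_id, "protein": chain_id}``. The first
    altloc of the representative atom is kept; insertion-coded residues get a
    composite number like ``"42A"``. Residues lacking every candidate
    representative atom are dropped with a log entry.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: unparseable structure: {exc}") from exc
    if not len(st):
        raise ValueError(f"{path}: structure has no models")
    model = st[0]
    chains = {c.name: c for c in model}
    residues = []
    for role in ("rna", "protein"):
        chain_id = chain_map[role]
        if chain_id not in chains:
            raise KeyError(
                f"chain {chain_id!r} ({role}) not in structure; "
                f"available: {sorted(chains)}")
        kind = "nucleotide" if role == "rna" else "amino_acid"
        wanted = _NT_REPRESENTATIVE if role == "rna" else _AA_REPRESENTATIVE
        for res in chains[chain_id]:
            atom = None
            for name in wanted:
                for a in res:
                    if a.name == name:
                        atom = a
                        break
                if atom is not None:
                    break
            if atom is None:
                logger.warning("dropping %s %s%s: no representative atom (%s)",
                               chain_id, res.name, res.seqid.num, "/".join(wanted))
                continue
            icode = res.seqid.icode.strip()
            number = f"{res.seqid.num}{icode}"
            residues.append(Residue(
                chain_id=chain_id, number=number, kind=kind,
                coord=(atom.pos.x, atom.pos.y, atom.pos.z)))
    return StructureModel(residues=residues)


def write_structure(model: StructureModel, path, chain_names=None) -> None:
    """Write a minimal single-atom-per-residue PDB (representative atoms only)."""
    st = gemmi.Structure()
    gm = gemmi.Model("1")
    chains: dict = {}
    for res in model.residues:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        gres = gemmi.Residue()
        if res.kind == "nucleotide":
            gres.name, atom_name, element = "U", "P", "P"
        else:
            gres.name, atom_name, element = "ALA", "CA", "C"
        num = res.number
        icode = " "
        if num and not num.lstrip("-").isdigit():
            num, icode = num[:-1], num[-1]
        gres.seqid = gemmi.SeqId(int(num), icode)
        atom = gemmi.Atom()
        atom.name = atom_name
        atom.element = gemmi.Element(element)
        atom.pos = gemmi.Position(*res.coord)
        gres.add_atom(atom)
        chains[res.chain_id].add_residue(gres)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def pair_distance(a: Residue, b: Residue) -> float:
    """Euclidean distance between representative coordinates, in Angstrom."""
    return float(np.linalg.norm(a.xyz - b.xyz))


def triplet_distance(a: Residue, b: Residue, c: Residue,
                     variant: str = "rms_centroid") -> float:
    """Three-body distance about the centroid (see module docstring).

    variant:
      - ``rms_centroid`` (default): sqrt of the summed squared distances of
        the three points from their centroid; Angstrom units.
      - ``squared_sum``: the square of the summed centroid distances
        (Angstrom^2; for comparison only).
      - ``sum``: the plain sum of centroid distances (Angstrom).
    """
    pts = np.stack([a.xyz, b.xyz, c.xyz])
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    if variant == "rms_centroid":
        return float(np.sqrt((d ** 2).sum()))
    if variant == "squared_sum":
        return float(d.sum() ** 2)
    if variant == "sum":
        return float(d.sum())
    raise ValueError(f"unknown triplet-distance variant {variant!r}")


def rna_neighbors(model: StructureModel, radius: float = 10.0) -> set:
    """Nucleotides within ``radius`` Angstrom of any protein residue."""
    nts = model.by_kind("nucleotide")
    aas = model.by_kind("amino_acid")
    if not nts or not aas:
        raise ValueError("structure must contain both a nucleotide and a "
                         "protein chain to compute RNA neighbors")
    nt_xyz = np.stack([r.xyz for r in nts])
    aa_xyz = np.stack([r.xyz for r in aas])
    d2 = ((nt_xyz[:, None, :] - aa_xyz[None, :, :]) ** 2).sum(-1)
    keep = (d2.min(axis=1) <= radius * radius)
    return {r for r, k in zip(nts, keep) if k}


def classify_contact(members: Sequence[Residue], threshold: float = 12.0,
                     triplet_variant: str = "rms_centroid") -> ContactCall:
    """Contact call at the (inclusive) distance threshold, default 12 A."""
    members = tuple(members)
    if len(members) == 2:
        d = pair_distance(*members)
    elif len(members) == 3:
        d = triplet_distance(*members, variant=triplet_variant)
    else:
        raise ValueError(f"expected 2 or 3 members, got {len(members)}")
    return ContactCall(members=members, distance=d, in_contact=d <= threshold)
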