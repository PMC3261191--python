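"""Plug-in information-theoretic estimators over alignment columns.

All quantities are computed from empirical (maximum-likelihood) symbol
frequencies, with no pseudocounts: the downstream ranking relies on
joint-entropy normalization (MI/H) rather than smoothing for noise control.

Definitions, in bits unless ``unit="nats"``:

* ``shannon_entropy``: H = -sum p log p, with 0 log 0 = 0.
* ``mi_pair``: I(X;Y) = H(X) + H(Y) - H(X,Y), always >= 0.
* ``conditional_mi``: I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z), >= 0.
* ``mi_triplet``: the interaction information
  I(X;Y;Z) = I(X;Y|Z) - I(X;Y)
           = H(X,Y) + H(X,Z) + H(Y,Z) - H(X) - H(Y) - H(Z) - H(X,Y,Z),
  which may be negative (redundancy), zero, or positive (synergy), and is
  bounded in magnitude by the joint entropy H(X,Y,Z).

Triplet scores are reported normalized by the joint entropy (MI/H), which is
dimensionless and lies in [-1, 1].
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

__all__ = [
    "JointCounts",
    "MIResult",
    "InsufficientDataError",
    "DegenerateDistributionError",
    "shannon_entropy",
    "joint_entropy",
    "mi_pair",
    "conditional_mi",
    "mi_triplet",
    "normalize",
]

#: magnitudes below this are snapped to zero to stabilize sign classification
ZERO_TOL = 1e-12


class InsufficientDataError(ValueError):
    """Raised when fewer observations remain than the configured floor."""


class DegenerateDistributionError(ValueError):
    """Raised when a normalizing joint entropy is zero (all columns constant)."""


def _log(unit: str):
    if unit == "bits":
        return math.log2
    if unit == "nats":
        return math.log
    raise ValueError(f"unknown unit {unit!r}; expected 'bits' or 'nats'")


@dataclass(frozen=True)
class JointCounts:
    """Empirical counts of co-occurring symbol tuples of a fixed arity."""

    arity: int
    counts: Mapping[tuple, int]
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise InsufficientDataError("empty distribution (n = 0)")
        if self.n != sum(self.counts.values()):
            raise ValueError("n does not match the sum of counts")
        for key in self.counts:
            if len(key) != self.arity:
                raise ValueError(
                    f"tuple {key!r} has length {len(key)}, expected arity {self.arity}"
                )

    @classmethod
    def from_columns(cls, *columns: Sequence[Hashable]) -> "JointCounts":
        lengths = {len(c) for c in columns}
        if len(lengths) != 1:
            raise ValueError(f"columns have unequal lengths {sorted(lengths)}")
        counts = Counter(zip(*columns))
        return cls(arity=len(columns), counts=counts, n=len(columns[0]))

    def marginal(self, *axes: int) -> "JointCounts":
        out: Counter = Counter()
        for key, c in self.counts.items():
            out[tuple(key[a] for a in axes)] += c
        return JointCounts(arity=len(axes), counts=out, n=self.n)

    def entropy(self, unit: str = "bits") -> float:
        log = _log(unit)
        n = self.n
        h = 0.0
        for c in self.counts.values():
            if c:
                p = c / n
                h -= p * log(p)
        return _snap(h)


@dataclass(frozen=True)
class MIResult:
    """A mutual-information value with its normalizer and provenance."""

    mi: float
    joint_entropy: float
    normalized: float
    n_used: int
    component_entropies: Mapping[str, float] = field(default_factory=dict)


def _snap(x: float) -> float:
    return 0.0 if abs(x) < ZERO_TOL else x


def shannon_entropy(counts: JointCounts | Mapping[Hashable, int],
                    unit: str = "bits") -> float:
    """Shannon entropy of a single empirical distribution.

    Accepts either an arity-1 :class:`JointCounts` or a plain symbol->count
    mapping.
    """
    if not isinstance(counts, JointCounts):
        jc = Counter({(k,): v for k, v in counts.items() if v})
        if not jc:
            raise InsufficientDataError("empty distribution (n = 0)")
        counts = JointCounts(arity=1, counts=jc, n=sum(jc.values()))
    if counts.arity != 1:
        raise ValueError("shannon_entropy expects arity-1 counts")
    return counts.entropy(unit)


def joint_entropy(tuples: Sequence[tuple], unit: str = "bits") -> float:
    """Shannon entropy of the empirical distribution of symbol tuples."""
    if not tuples:
        raise InsufficientDataError("no tuples")
    arities = {len(t) for t in tuples}
    if len(arities) != 1:
        raise ValueError(f"mixed tuple arities {sorted(arities)}")
    jc = JointCounts(arity=arities.pop(), counts=Counter(tuples), n=len(tuples))
    return jc.entropy(unit)


def mi_pair(col_x: Sequence[Hashable], col_y: Sequence[Hashable],
            min_rows: int = 1, unit: str = "bits") -> MIResult:
    """Pairwise mutual information I(X;Y) = H(X) + H(Y) - H(X,Y)."""
    joint = JointCounts.from_columns(col_x, col_y)
    if joint.n < min_rows:
        raise InsufficientDataError(
            f"{joint.n} rows < min_rows {min_rows}")
    hx = joint.marginal(0).entropy(unit)
    hy = joint.marginal(1).entropy(unit)
    hxy = joint.entropy(unit)
    mi = _snap(hx + hy - hxy)
    return MIResult(
        mi=mi,
        joint_entropy=hxy,
        normalized=normalize(mi, hxy) if hxy > 0 else 0.0,
        n_used=joint.n,
        component_entropies={"H(X)": hx, "H(Y)": hy, "H(X,Y)": hxy},
    )


def conditional_mi(col_x: Sequence[Hashable], col_y: Sequence[Hashable],
                   col_z: Sequence[Hashable], unit: str = "bits") -> float:
    """Conditional mutual information I(X;Y|Z); non-negative."""
    joint = JointCounts.from_columns(col_x, col_y, col_z)
    hxz = joint.marginal(0, 2).entropy(unit)
    hyz = joint.marginal(1, 2).entropy(unit)
    hz = joint.marginal(2).entropy(unit)
    hxyz = joint.entropy(unit)
    return _snap(hxz + hyz - hz - hxyz)


def mi_triplet(col_x: Sequence[Hashable], col_y: Sequence[Hashable],
               col_z: Sequence[Hashable], min_rows: int = 1,
               unit: str = "bits") -> MIResult:
    """Interaction information I(X;Y;Z) = I(X;Y|Z) - I(X;Y).

    Computed via the symmetric entropy-sum form; positive values indicate
    synergy (conditioning on the third column strengthens the dependence of
    the other two), negative values redundancy.
    """
    joint = JointCounts.from_columns(col_x, col_y, col_z)
    if joint.n < min_rows:
        raise InsufficientDataError(
            f"{joint.n} rows < min_rows {min_rows}")
    hx = joint.marginal(0).entropy(unit)
    hy = joint.marginal(1).entropy(unit)
    hz = joint.marginal(2).entropy(unit)
    hxy = joint.marginal(0, 1).entropy(unit)
    hxz = joint.marginal(0, 2).entropy(unit)
    hyz = joint.marginal(1, 2).entropy(unit)
    hxyz = joint.entropy(unit)
    mi = _snap(hxy + hxz + hyz - hx - hy - hz - hxyz)
    return MIResult(
        mi=mi,
        joint_entropy=hxyz,
        normalized=normalize(mi, hxyz) if hxyz > 0 else 0.0,
        n_used=joint.n,
        component_entropies={
            "H(X)": hx, "H(Y)": hy, "H(Z)": hz,
            "H(X,Y)": hxy, "H(X,Z)": hxz, "H(Y,Z)": hyz,
            "H(X,Y,Z)": hxyz,
        },
    )


def normalize(mi: float, joint_entropy: float) -> float:
    """MI divided by the joint entropy of the same columns (dimensionless)."""
    if joint_entropy < 0:
        raise ValueError("joint entropy must be non-negative")
    if joint_entropy == 0:
        raise DegenerateDistributionError(
            "joint entropy is zero (all columns constant); "
            "such triplets are excluded upstream by the conservation filter")
    return _snap(mi / joint_entropy)
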