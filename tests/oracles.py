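"""Independent brute-force oracles for the information-theoretic estimators.

Deliberately separate code paths from the package: plain-dict contingency
tables, probability-ratio (KL) summation for pairwise MI, and a stratified
per-stratum route for conditional MI. Used to cross-check the package's
entropy-sum implementations.
"""

import math
from collections import defaultdict


def oracle_entropy(column):
    table = defaultdict(int)
    for s in column:
        table[s] += 1
    n = len(column)
    return -sum((c / n) * math.log2(c / n) for c in table.values())


def oracle_mi_pair(col_x, col_y):
    """I(X;Y) as the KL divergence of the joint from the product marginal."""
    n = len(col_x)
    joint = defaultdict(int)
    px = defaultdict(int)
    py = defaultdict(int)
    for x, y in zip(col_x, col_y):
        joint[(x, y)] += 1
        px[x] += 1
        py[y] += 1
    mi = 0.0
    for (x, y), c in joint.items():
        p = c / n
        mi += p * math.log2(p * n * n / (px[x] * py[y]))
    return mi


def oracle_conditional_mi(col_x, col_y, col_z):
    """I(X;Y|Z) = sum_z p(z) * I(X;Y | Z=z), stratified brute force."""
    n = len(col_z)
    strata = defaultdict(list)
    for x, y, z in zip(col_x, col_y, col_z):
        strata[z].append((x, y))
    cmi = 0.0
    for rows in strata.values():
        xs, ys = zip(*rows)
        cmi += (len(rows) / n) * oracle_mi_pair(xs, ys)
    return cmi


def oracle_mi_triplet(col_x, col_y, col_z):
    """Interaction information via the conditional-minus-marginal route."""
    return (oracle_conditional_mi(col_x, col_y, col_z)
            - oracle_mi_pair(col_x, col_y))
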