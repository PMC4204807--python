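"""Tamura-Nei distances, neighbor-joining and bootstrap support.

Distances are the Tamura-Nei (1993) closed form, distinguishing the two
transition classes (A<->G, C<->T) from transversions, with an optional
gamma rate-heterogeneity correction; the Jukes-Cantor model is available
as a degenerate option.  Trees are built by Saitou-Nei neighbor joining
with deterministic tie-breaking, and supported by nonparametric bootstrap
(column resampling, majority counting of the full-data tree's
bipartitions).  Trees are scikit-bio ``TreeNode`` objects and serialize to
Newick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from .seqio import GAP, MsAlignment, SequenceRecord

VALID_BASES = frozenset("ACGT")

# the paper-family fit of the gamma shape parameter for TN93+G
DEFAULT_GAMMA_SHAPE = 0.8094


class SaturationError(ValueError):
    """Distance undefined (logarithm argument non-positive)."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal; inf marks saturated pairs
    model: str = "TN93"  # {"TN93", "TN93+G", "JC69", "JC69+G"}
    gamma_shape: Optional[float] = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def saturated_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if not math.isfinite(self.d[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def _pairwise_sites(a: str, b: str) -> tuple[str, str]:
    """Pairwise deletion: keep sites where both sequences have an
    unambiguous base (IUPAC ambiguity codes are treated as missing)."""
    xs, ys = [], []
    for x, y in zip(a, b):
        if x in VALID_BASES and y in VALID_BASES:
            xs.append(x)
            ys.append(y)
    return "".join(xs), "".join(ys)


def _gamma_term(k: float, w: float, shape: Optional[float]) -> float:
    """-k*log(w), or its gamma-corrected analogue k*a*(w**(-1/a)-1)."""
    if k == 0.0:
        return 0.0
    if w <= 0.0:
        raise SaturationError("log argument non-positive")
    if shape is None:
        return -k * math.log(w)
    return k * shape * (w ** (-1.0 / shape) - 1.0)


def tn93_distance(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    gamma_shape: Optional[float] = None,
) -> float:
    """Tamura-Nei (1993) distance between two aligned sequences.

    Base frequencies are estimated from the pooled bases of the pair
    (pairwise-deletion convention).  With ``gamma_shape`` the standard
    gamma-corrected form is used.  Returns ``inf`` for saturated pairs;
    raises on zero comparable sites.
    """
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    if len(sa) != len(sb):
        raise ValueError("sequences have different gapped lengths")
    xa, xb = _pairwise_sites(sa.upper(), sb.upper())
    n = len(xa)
    if n == 0:
        raise ValueError("no comparable (non-gap, unambiguous) sites")

    pooled = xa + xb
    gA = pooled.count("A") / (2 * n)
    gC = pooled.count("C") / (2 * n)
    gG = pooled.count("G") / (2 * n)
    gT = pooled.count("T") / (2 * n)
    gR, gY = gA + gG, gC + gT

    P1 = P2 = Q = 0
    for x, y in zip(xa, xb):
        if x == y:
            continue
        pair = {x, y}
        if pair == {"A", "G"}:
            P1 += 1
        elif pair == {"C", "T"}:
            P2 += 1
        else:
            Q += 1
    P1 /= n
    P2 /= n
    Q /= n
    if P1 + P2 + Q == 0:
        return 0.0

    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2 * (
        gR * gY
        - (gA * gG * gY / gR if gR > 0 else 0.0)
        - (gC * gT * gR / gY if gY > 0 else 0.0)
    )
    try:
        if k1 == 0.0 and P1 > 0:
            raise SaturationError("transition class A/G unobservable")
        if k2 == 0.0 and P2 > 0:
            raise SaturationError("transition class C/T unobservable")
        w1 = 1 - P1 / k1 - Q / (2 * gR) if k1 > 0 else 1.0
        w2 = 1 - P2 / k2 - Q / (2 * gY) if k2 > 0 else 1.0
        w3 = 1 - Q / (2 * gR * gY) if gR * gY > 0 else 1.0
        return (
            _gamma_term(k1, w1, gamma_shape)
            + _gamma_term(k2, w2, gamma_shape)
            + _gamma_term(k3, w3, gamma_shape)
        )
    except SaturationError:
        return math.inf


def jc69_distance(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    gamma_shape: Optional[float] = None,
) -> float:
    """Jukes-Cantor distance (equal frequencies, one rate class)."""
    sa = a.seq if isinstance(a, SequenceRecord) else a
    sb = b.seq if isinstance(b, SequenceRecord) else b
    xa, xb = _pairwise_sites(sa.upper(), sb.upper())
    n = len(xa)
    if n == 0:
        raise ValueError("no comparable sites")
    p = sum(1 for x, y in zip(xa, xb) if x != y) / n
    w = 1 - 4 * p / 3
    try:
        return _gamma_term(0.75, w, gamma_shape)
    except SaturationError:
        return math.inf


def build_distance_matrix(
    aln: MsAlignment,
    model: str = "TN93",
    gamma_shape: Optional[float] = None,
) -> DistanceMatrix:
    """All pairwise distances under the chosen model.

    ``model`` in {"TN93", "TN93+G", "JC69"}; TN93+G uses ``gamma_shape``
    (default 0.8094, the family's fitted value) unless given.
    """
    if model == "TN93+G" and gamma_shape is None:
        gamma_shape = DEFAULT_GAMMA_SHAPE
    if model not in ("TN93", "TN93+G", "JC69"):
        raise ValueError(f"unknown model {model!r}")
    dist = tn93_distance if model.startswith("TN93") else jc69_distance
    shape = gamma_shape if model.endswith("+G") else None
    n = aln.nrows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist(
                aln.records[i], aln.records[j], gamma_shape=shape
            )
    return DistanceMatrix(ids=list(aln.ids), d=d, model=model, gamma_shape=shape)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-matrix ties are broken by the lowest (row, column) index pair in the
    current node ordering; negative branch lengths are clamped to zero
    with the deficit moved to the sibling edge.  The returned tree is
    unrooted (trifurcating root).
    """
    if dm.n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    bad = dm.saturated_pairs()
    if bad:
        raise ValueError(f"non-finite distances for pairs: {bad}")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    D = dm.d.astype(float).copy()

    def clamp(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        vi, vj = clamp(vi, vj)
        u = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = vi, vj
        u.extend([ni, nj_])
        newD = np.zeros((m - 1, m - 1))
        keep = [x for x in range(m) if x not in (i, j)]
        for a_, x in enumerate(keep):
            for b_, y in enumerate(keep):
                newD[a_, b_] = D[x, y]
            newD[a_, m - 2] = newD[m - 2, a_] = 0.5 * (
                D[i, x] + D[j, x] - D[i, j]
            )
        D = newD
        nodes = [nodes[x] for x in keep] + [u]

    # terminal three-way join (closed form)
    root = TreeNode()
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    root.extend([a, b, c])
    return root


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, taxa: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical tip-name frozensets (the side
    not containing the lexicographically first taxon)."""
    ref = min(taxa)
    out = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if ref in side:
            side = taxa - side
        out.add(side)
    return out


def bootstrap_support(
    aln: MsAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "TN93",
    gamma_shape: Optional[float] = None,
) -> TreeNode:
    """NJ tree with bootstrap support on internal edges.

    Columns are resampled with replacement ``n_reps`` times; support for
    each internal edge of the full-data tree is the fraction of replicate
    trees containing the same bipartition.  Supports are stored on the
    nodes as ``node.support`` (a fraction) and mirrored into internal node
    names for Newick output.
    """
    if aln.nrows < 4:
        raise ValueError("bootstrap support needs at least 4 sequences")
    rng = np.random.default_rng(seed)
    full_dm = build_distance_matrix(aln, model=model, gamma_shape=gamma_shape)
    tree = nj_tree(full_dm)
    taxa = frozenset(aln.ids)

    counts: dict[frozenset[str], int] = {}
    full_parts = _bipartitions(tree, taxa)
    for p in full_parts:
        counts[p] = 0
    ncols = aln.ncols
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep = aln.take_columns(list(cols))
        rep_dm = build_distance_matrix(rep, model=model, gamma_shape=gamma_shape)
        if rep_dm.saturated_pairs():
            continue  # replicate uninformative for support counting
        rep_parts = _bipartitions(nj_tree(rep_dm), taxa)
        for p in full_parts & rep_parts:
            counts[p] += 1

    ref = min(taxa)
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if ref in side:
            side = taxa - side
        frac = counts[side] / n_reps
        node.support = frac
        node.name = f"{frac:g}"
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def distance_matrix_to_tsv(dm: DistanceMatrix, path) -> None:
    dm.to_df().to_csv(path, sep="\t", index_label="id")


def distance_matrix_from_tsv(path, model: str = "TN93") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(ids=[str(c) for c in df.columns], d=df.to_numpy(), model=model)
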