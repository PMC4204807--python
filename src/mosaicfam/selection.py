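"""Per-codon selection analysis: SLAC, FEL/IFEL and subsample consensus.

Three per-site tests of selective pressure on a codon alignment with a
fixed tree:

* **SLAC** — ancestral codons are reconstructed by Fitch parsimony (ties
  resolved by seeded sampling, averaged); per-branch codon changes are
  decomposed into synonymous/nonsynonymous steps by averaging over minimal
  substitution paths that avoid stop codons (Nei-Gojobori convention), and
  the observed nonsynonymous count is compared to its neutral expectation
  with a two-tailed binomial test.
* **FEL** — per-site maximum likelihood fit of a synonymous rate alpha and
  nonsynonymous rate beta under an MG94xHKY codon model on the fixed tree,
  with a chi-squared(1) likelihood-ratio test of beta = alpha.
* **IFEL** — the same machinery with the nonsynonymous rate freed only on
  internal branches (external branches keep beta = alpha).

The family-level procedure mirrors the published protocol: repeated random
subsamples of the alignment, an NJ tree per subsample, all three methods
per replicate, method-majority calls within replicates and a strict
replicate majority for the final per-codon verdict.  A seeded MG94xHKY
simulator provides ground-truth alignments for validation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from skbio import TreeNode

from .phylo import DistanceMatrix, build_distance_matrix, nj_tree
from .seqio import GAP, MsAlignment, SequenceRecord

BASES = "ACGT"
SENSE_CODONS: list[str] = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
]
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
STOPS = frozenset(("TAA", "TAG", "TGA"))

_AA = {}  # codon -> amino acid, standard code
from Bio.Data.CodonTable import standard_dna_table as _tbl  # noqa: E402

_AA.update(_tbl.forward_table)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

RATE_LOWER, RATE_UPPER = 1e-6, 100.0


# ---------------------------------------------------------------------------
# Codon alignment container
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame, stop-free gapped codon alignment."""

    aln: MsAlignment

    def __post_init__(self):
        if self.aln.ncols % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        for rec in self.aln:
            for i in range(0, self.aln.ncols, 3):
                codon = rec.seq[i : i + 3]
                if codon in STOPS:
                    raise ValueError(
                        f"{rec.id}: internal stop codon {codon} at column {i}"
                    )

    @property
    def ncodons(self) -> int:
        return self.aln.ncols // 3

    @property
    def nrows(self) -> int:
        return self.aln.nrows

    @property
    def ids(self) -> list[str]:
        return self.aln.ids

    def codon(self, row: int, site: int) -> Optional[str]:
        """Codon of one row at one site, or None if gapped/ambiguous."""
        c = self.aln.records[row].seq[3 * site : 3 * site + 3]
        return c if c in CODON_INDEX else None

    def site_codons(self, site: int) -> list[Optional[str]]:
        return [self.codon(r, site) for r in range(self.nrows)]

    def subsample(self, rows: Sequence[int]) -> "CodonAlignment":
        recs = [self.aln.records[r] for r in rows]
        return CodonAlignment(MsAlignment(recs))

    @classmethod
    def from_alignment(cls, aln: MsAlignment, trim_terminal_stop: bool = True):
        """Build from an in-frame nucleotide alignment, optionally dropping
        a trailing stop-codon column triple."""
        if trim_terminal_stop and aln.ncols >= 3:
            last = [r.seq[-3:] for r in aln.records]
            if any(c in STOPS for c in last) and all(
                c in STOPS or GAP in c for c in last
            ):
                aln = aln.slice_columns(0, aln.ncols - 3)
        return cls(aln)


# ---------------------------------------------------------------------------
# Nei-Gojobori counting machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of a sense codon.

    At each position the fraction of non-stop single-nucleotide neighbours
    that are synonymous defines the synonymous weight; stops are excluded
    from the denominator and the three positions each carry weight 1, so
    the counts sum to 3.
    """
    syn = 0.0
    for pos in range(3):
        s = n = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOPS:
                continue
            if _AA[alt] == _AA[codon]:
                s += 1
            else:
                n += 1
        if s + n:
            syn += s / (s + n)
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) substitution steps between two sense codons, averaged
    over all minimal mutational paths that avoid stop codons.

    If every ordering passes through a stop, all orderings are averaged.
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        syn = sum(
            1.0 for a, b in steps if a not in STOPS and b not in STOPS
            and _AA.get(a) == _AA.get(b)
        )
        # stop-involving steps count as nonsynonymous in the fallback
        nonsyn = len(steps) - syn
        paths.append((blocked, syn, nonsyn))
    open_paths = [p for p in paths if not p[0]]
    use = open_paths if open_paths else paths
    syn = sum(p[1] for p in use) / len(use)
    nonsyn = sum(p[2] for p in use) / len(use)
    return syn, nonsyn


def pairwise_ng86(
    codons_a: Sequence[str], codons_b: Sequence[str]
) -> dict[str, float]:
    """Classic pairwise Nei-Gojobori counting over paired codon lists.

    Returns site counts (S, N), substitution counts (Sd, Nd), the
    proportions pS, pN and Jukes-Cantor-corrected dS, dN.
    """
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if ca not in CODON_INDEX or cb not in CODON_INDEX:
            continue
        sa, na = codon_site_counts(ca)
        sb, nb = codon_site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        s, n = path_counts(ca, cb)
        Sd += s
        Nd += n

    def jc(p):
        x = 1 - 4 * p / 3
        return -0.75 * math.log(x) if x > 0 else math.inf

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    return {
        "S": S, "N": N, "Sd": Sd, "Nd": Nd,
        "pS": pS, "pN": pN, "dS": jc(pS), "dN": jc(pN),
    }


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class SiteSelectionResult:
    site: int
    method: str  # {"SLAC", "FEL", "IFEL"}
    dn_proxy: float
    ds_proxy: float
    p_value: float
    call: str  # {"positive", "negative", "neutral"}


@dataclass
class ConsensusSelection:
    site: int
    replicate_calls: list[dict[str, str]]  # per replicate: method -> call
    replicate_consensus: list[str]  # per replicate: method-majority call
    final_call: str


# ---------------------------------------------------------------------------
# Tree cache for likelihood and parsimony
# ---------------------------------------------------------------------------

class _TreeCache:
    """Indexed, immutable view of a (possibly multifurcating) rooted tree."""

    def __init__(self, tree: TreeNode, tip_order: Sequence[str]):
        self.nodes = list(tree.postorder(include_self=True))
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.lengths = np.array(
            [float(n.length or 0.0) for n in self.nodes]
        )
        self.is_tip = [n.is_tip() for n in self.nodes]
        self.is_root = [n.is_root() for n in self.nodes]
        self.root = len(self.nodes) - 1
        self.parent = [-1] * len(self.nodes)
        for i, ch in enumerate(self.children):
            for c in ch:
                self.parent[c] = i
        tip_row = {name: r for r, name in enumerate(tip_order)}
        self.tip_to_row = {}
        for i, n in enumerate(self.nodes):
            if self.is_tip[i]:
                if n.name not in tip_row:
                    raise ValueError(f"tree tip {n.name!r} not in alignment")
                self.tip_to_row[i] = tip_row[n.name]
        if len(self.tip_to_row) != len(tip_order):
            raise ValueError("tree tips do not match alignment rows")
        # internal branch = edge above a non-tip, non-root node
        self.internal_edge = [
            (not self.is_tip[i]) and (not self.is_root[i])
            for i in range(len(self.nodes))
        ]


# ---------------------------------------------------------------------------
# SLAC
# ---------------------------------------------------------------------------

def _fitch_sets(tc: _TreeCache, leaf_states: list[Optional[str]]):
    """Bottom-up Fitch state sets; None marks uninformative subtrees."""
    sets: list[Optional[frozenset]] = [None] * len(tc.nodes)
    for i in range(len(tc.nodes)):
        if tc.is_tip[i]:
            st = leaf_states[tc.tip_to_row[i]]
            sets[i] = frozenset((st,)) if st is not None else None
        else:
            cur: Optional[frozenset] = None
            for c in tc.children[i]:
                if sets[c] is None:
                    continue
                if cur is None:
                    cur = sets[c]
                else:
                    inter = cur & sets[c]
                    cur = inter if inter else cur | sets[c]
            sets[i] = cur
    return sets


def _fitch_assign(tc, sets, leaf_states, rng) -> list[Optional[str]]:
    """Top-down assignment; ties sampled uniformly from sorted state sets."""
    assign: list[Optional[str]] = [None] * len(tc.nodes)
    root_set = sets[tc.root]
    if root_set is not None:
        choices = sorted(root_set)
        assign[tc.root] = choices[rng.integers(len(choices))]
    order = [tc.root]
    while order:
        i = order.pop()
        for c in tc.children[i]:
            if tc.is_tip[c]:
                assign[c] = leaf_states[tc.tip_to_row[c]]
                continue
            if sets[c] is None or assign[i] in sets[c]:
                assign[c] = assign[i]
            else:
                choices = sorted(sets[c])
                assign[c] = choices[rng.integers(len(choices))]
            order.append(c)
    return assign


def _binom_two_tailed(k: int, n: int, p: float) -> float:
    """Equal-tail two-sided binomial p-value."""
    if n == 0:
        return 1.0
    lo = stats.binom.cdf(k, n, p)
    hi = stats.binom.sf(k - 1, n, p)
    return min(1.0, 2.0 * min(lo, hi))


def slac_site_test(
    caln: CodonAlignment,
    tree: TreeNode,
    alpha: float = 0.1,
    seed: int = 0,
    n_tie_samples: int = 20,
    branch_set: str = "all",
) -> list[SiteSelectionResult]:
    """SLAC-style counting test at every codon site.

    Per site: Fitch ancestors (averaged over ``n_tie_samples`` seeded tie
    resolutions), per-branch syn/nonsyn decomposition via
    :func:`path_counts`, and an equal-tail binomial test of the observed
    nonsynonymous count against the neutral expectation derived from the
    site's observed codons.
    """
    tc = _TreeCache(tree, caln.ids)
    rng = np.random.default_rng(seed)
    results = []
    for site in range(caln.ncodons):
        leaf_states = caln.site_codons(site)
        observed = [c for c in leaf_states if c is not None]
        if not observed:
            results.append(
                SiteSelectionResult(site, "SLAC", 0.0, 0.0, 1.0, "neutral")
            )
            continue
        es = float(np.mean([codon_site_counts(c)[0] for c in observed]))
        en = 3.0 - es
        p_exp = en / 3.0

        sets = _fitch_sets(tc, leaf_states)
        tot_s = tot_n = 0.0
        for _ in range(n_tie_samples):
            assign = _fitch_assign(tc, sets, leaf_states, rng)
            for i in range(len(tc.nodes)):
                if tc.is_root[i]:
                    continue
                if branch_set == "internal_only" and tc.is_tip[i]:
                    continue
                a, b = assign[tc.parent[i]], assign[i]
                if a is None or b is None or a == b:
                    continue
                s, n = path_counts(a, b)
                tot_s += s
                tot_n += n
        sd = tot_s / n_tie_samples
        nd = tot_n / n_tie_samples
        n_subs = int(round(sd + nd))
        k = int(round(nd))
        k = min(k, n_subs)
        p = _binom_two_tailed(k, n_subs, p_exp)
        if n_subs == 0 or p > alpha:
            call = "neutral"
        else:
            call = "positive" if k / n_subs > p_exp else "negative"
        results.append(SiteSelectionResult(site, "SLAC", nd, sd, p, call))
    return results


# ---------------------------------------------------------------------------
# MG94xHKY codon model
# ---------------------------------------------------------------------------

def _single_nt_changes():
    """All ordered sense-codon pairs differing at one position."""
    out = []
    for i, c1 in enumerate(SENSE_CODONS):
        for pos in range(3):
            for b in BASES:
                if b == c1[pos]:
                    continue
                c2 = c1[:pos] + b + c1[pos + 1 :]
                j = CODON_INDEX.get(c2)
                if j is None:
                    continue
                is_ts = (c1[pos], b) in TRANSITIONS
                is_syn = _AA[c1] == _AA[c2]
                out.append((i, j, is_ts, BASES.index(b), is_syn))
    return out

_CHANGES = _single_nt_changes()


def f1x4_frequencies(caln: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(nucleotide freqs, F1x4 sense-codon equilibrium freqs)."""
    counts = np.zeros(4)
    for rec in caln.aln:
        for b in rec.seq:
            i = BASES.find(b)
            if i >= 0:
                counts[i] += 1
    if counts.sum() == 0:
        counts[:] = 1.0
    pi_nt = counts / counts.sum()
    pi_nt = np.clip(pi_nt, 1e-6, None)
    pi_nt /= pi_nt.sum()
    pi_cod = np.array(
        [
            pi_nt[BASES.index(c[0])]
            * pi_nt[BASES.index(c[1])]
            * pi_nt[BASES.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    pi_cod /= pi_cod.sum()
    return pi_nt, pi_cod


class Mg94Model:
    """MG94xHKY codon rate matrix family on 61 sense codons.

    ``q(c1 -> c2) = rate * kappa^[transition] * pi_nt(target)`` where
    ``rate`` is the synonymous rate alpha or the nonsynonymous rate beta.
    The matrix is reversible with respect to the F1x4 codon frequencies;
    stop codons are unreachable.  The overall scale is normalised so that
    alpha = beta = 1 gives one expected substitution per codon per unit of
    codon time; branch lengths (nucleotide substitutions/site) are
    multiplied by 3 to convert to codon time.
    """

    def __init__(self, kappa: float, pi_nt: np.ndarray):
        self.kappa = float(kappa)
        self.pi_nt = np.asarray(pi_nt, dtype=float)
        self.pi_cod = np.array(
            [
                self.pi_nt[BASES.index(c[0])]
                * self.pi_nt[BASES.index(c[1])]
                * self.pi_nt[BASES.index(c[2])]
                for c in SENSE_CODONS
            ]
        )
        self.pi_cod /= self.pi_cod.sum()
        n = len(SENSE_CODONS)
        Qs = np.zeros((n, n))
        Qn = np.zeros((n, n))
        for i, j, is_ts, tgt, is_syn in _CHANGES:
            r = (self.kappa if is_ts else 1.0) * self.pi_nt[tgt]
            (Qs if is_syn else Qn)[i, j] = r
        # normalise so alpha=beta=1 has mean rate 1 per codon
        Q1 = Qs + Qn
        rho = float(self.pi_cod @ Q1.sum(axis=1))
        self.Qs = Qs / rho
        self.Qn = Qn / rho
        self._sqrt_pi = np.sqrt(self.pi_cod)

    def eig(self, alpha: float, beta: float):
        """Symmetric eigendecomposition of Q(alpha, beta)."""
        Q = alpha * self.Qs + beta * self.Qn
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        S = self._sqrt_pi
        B = (S[:, None] * Q) / S[None, :]
        B = 0.5 * (B + B.T)  # symmetrise numerical noise
        lam, U = np.linalg.eigh(B)
        return lam, U

    def propagate(self, lam, U, t: float, v: np.ndarray) -> np.ndarray:
        """P(t) @ v computed through the eigenbasis (no full matrix)."""
        S = self._sqrt_pi
        w = U.T @ (S * v)
        w = np.exp(lam * t) * w
        out = (U @ w) / S
        return np.clip(out, 0.0, None)

    def transition_matrix(self, alpha: float, beta: float, t: float):
        lam, U = self.eig(alpha, beta)
        S = self._sqrt_pi
        P = (U * np.exp(lam * t)) @ U.T
        P = (P / S[:, None]) * S[None, :]
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=1, keepdims=True)
        return P


def fit_kappa(caln: CodonAlignment, tree: TreeNode) -> float:
    """Global transition/transversion ratio by 4-state HKY ML on the tree.

    Uses the nucleotide columns of the codon alignment with the fixed tree
    branch lengths; one bounded 1-D optimisation.
    """
    tc = _TreeCache(tree, caln.ids)
    counts = np.zeros(4)
    cols = []
    for j in range(caln.aln.ncols):
        col = [rec.seq[j] for rec in caln.aln]
        idx = [BASES.find(b) for b in col]
        for i in idx:
            if i >= 0:
                counts[i] += 1
        cols.append(idx)
    pi = np.clip(counts / max(counts.sum(), 1), 1e-6, None)
    pi /= pi.sum()
    # collapse identical columns for speed
    uniq: dict[tuple, int] = {}
    for idx in cols:
        key = tuple(idx)
        uniq[key] = uniq.get(key, 0) + 1

    sqrt_pi = np.sqrt(pi)

    def hky_eig(kappa):
        Q = np.zeros((4, 4))
        for i, a in enumerate(BASES):
            for j, b in enumerate(BASES):
                if i == j:
                    continue
                Q[i, j] = (kappa if (a, b) in TRANSITIONS else 1.0) * pi[j]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rho = -float(pi @ np.diag(Q))
        Q /= rho
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        B = 0.5 * (B + B.T)
        return np.linalg.eigh(B)

    def negll(log_kappa):
        lam, U = hky_eig(math.exp(log_kappa))
        ll = 0.0
        for key, mult in uniq.items():
            partial = {}
            logscale = 0.0
            for i in range(len(tc.nodes)):
                if tc.is_tip[i]:
                    v = np.ones(4)
                    b = key[tc.tip_to_row[i]]
                    if b >= 0:
                        v = np.zeros(4)
                        v[b] = 1.0
                    partial[i] = v
                else:
                    v = np.ones(4)
                    for c in tc.children[i]:
                        t = tc.lengths[c]
                        w = U.T @ (sqrt_pi * partial[c])
                        w = np.exp(lam * t) * w
                        pv = np.clip((U @ w) / sqrt_pi, 0.0, None)
                        v = v * pv
                    mx = v.max()
                    if mx > 0 and mx < 1e-100:
                        v /= mx
                        logscale += math.log(mx)
                    partial[i] = v
            L = float(pi @ partial[tc.root])
            if L <= 0:
                return 1e10
            ll += mult * (math.log(L) + logscale)
        return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(math.log(0.05), math.log(50.0)), method="bounded",
        options={"xatol": 1e-4},
    )
    return float(math.exp(res.x))


def _site_negll_factory(model: Mg94Model, tc: _TreeCache, leaf_states, branch_set: str):
    """Build the per-site negative log-likelihood function of (alpha, beta).

    For ``internal_only`` the nonsynonymous rate on external branches is
    pinned to alpha in every model.
    """
    n = len(SENSE_CODONS)
    leaf_vec = {}
    for i in range(len(tc.nodes)):
        if tc.is_tip[i]:
            st = leaf_states[tc.tip_to_row[i]]
            if st is None:
                leaf_vec[i] = np.ones(n)
            else:
                v = np.zeros(n)
                v[CODON_INDEX[st]] = 1.0
                leaf_vec[i] = v

    def negll(alpha: float, beta: float) -> float:
        eig_main = model.eig(alpha, beta)
        if branch_set == "internal_only":
            eig_ext = model.eig(alpha, alpha)
        else:
            eig_ext = eig_main
        partial = {}
        logscale = 0.0
        for i in range(len(tc.nodes)):
            if tc.is_tip[i]:
                partial[i] = leaf_vec[i]
            else:
                v = np.ones(n)
                for c in tc.children[i]:
                    lam, U = eig_main if tc.internal_edge[c] else eig_ext
                    t = 3.0 * tc.lengths[c]
                    v = v * model.propagate(lam, U, t, partial[c])
                mx = v.max()
                if mx <= 0:
                    return 1e10
                if mx < 1e-100:
                    v = v / mx
                    logscale += math.log(mx)
                partial[i] = v
        L = float(model.pi_cod @ partial[tc.root])
        if L <= 0:
            return 1e10
        return -(math.log(L) + logscale)

    return negll


def fel_site_test(
    caln: CodonAlignment,
    tree: TreeNode,
    branch_set: str = "all",
    alpha: float = 0.1,
    kappa: Optional[float] = None,
) -> list[SiteSelectionResult]:
    """FEL (branch_set='all') or IFEL (branch_set='internal_only') per-site
    likelihood-ratio tests.

    Global parameters (kappa, F1x4 frequencies) are fitted once on the
    whole alignment; per site the synonymous rate alpha_s and
    nonsynonymous rate beta_s are fitted by bounded ML (rates in
    [1e-6, 100], tolerance 1e-6) and beta_s = alpha_s is tested against
    the free model with a chi-squared(1) LRT.
    """
    if branch_set not in ("all", "internal_only"):
        raise ValueError(f"unknown branch_set {branch_set!r}")
    method = "FEL" if branch_set == "all" else "IFEL"
    tc = _TreeCache(tree, caln.ids)
    if kappa is None:
        kappa = fit_kappa(caln, tree)
    pi_nt, _ = f1x4_frequencies(caln)
    model = Mg94Model(kappa, pi_nt)

    lo, hi = math.log(RATE_LOWER), math.log(RATE_UPPER)
    results = []
    for site in range(caln.ncodons):
        leaf_states = caln.site_codons(site)
        if all(s is None for s in leaf_states):
            results.append(
                SiteSelectionResult(site, method, 0.0, 0.0, 1.0, "neutral")
            )
            continue
        negll = _site_negll_factory(model, tc, leaf_states, branch_set)
        try:
            res0 = optimize.minimize_scalar(
                lambda lw: negll(math.exp(lw), math.exp(lw)),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            w0 = math.exp(res0.x)
            ll0 = -res0.fun
            res1 = optimize.minimize(
                lambda p: negll(math.exp(p[0]), math.exp(p[1])),
                x0=np.array([res0.x, res0.x]),
                method="L-BFGS-B",
                bounds=[(lo, hi), (lo, hi)],
                options={"ftol": 1e-10, "gtol": 1e-8},
            )
            a_hat, b_hat = math.exp(res1.x[0]), math.exp(res1.x[1])
            ll1 = -res1.fun
        except (ValueError, FloatingPointError) as e:  # pragma: no cover
            warnings.warn(f"site {site}: {method} fit failed ({e}); neutral")
            results.append(
                SiteSelectionResult(site, method, 0.0, 0.0, 1.0, "neutral")
            )
            continue
        lrt = max(0.0, 2.0 * (ll1 - ll0))
        if lrt < 1e-10:
            lrt = 0.0
        p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
        if p <= alpha and b_hat != a_hat:
            call = "positive" if b_hat > a_hat else "negative"
        else:
            call = "neutral"
        results.append(
            SiteSelectionResult(site, method, b_hat, a_hat, p, call)
        )
    return results


# ---------------------------------------------------------------------------
# Subsample consensus
# ---------------------------------------------------------------------------

def _sanitize_dm(dm: DistanceMatrix) -> DistanceMatrix:
    """Cap saturated (non-finite) distances so NJ can proceed."""
    d = dm.d.copy()
    finite = d[np.isfinite(d)]
    cap = 2.0 * finite.max() if finite.size else 1.0
    if not np.isfinite(d).all():
        warnings.warn("saturated distances capped for tree building")
        d[~np.isfinite(d)] = cap
    return DistanceMatrix(dm.ids, d, model=dm.model, gamma_shape=dm.gamma_shape)


def consensus_selection(
    caln: CodonAlignment,
    subsample_size: int = 100,
    n_replicates: int = 10,
    seed: int = 0,
    methods: Sequence[str] = ("SLAC", "FEL", "IFEL"),
    alpha: float = 0.1,
    gamma_shape: Optional[float] = None,
) -> list[ConsensusSelection]:
    """The family-level subsample-consensus selection procedure.

    Per replicate a random subsample (without replacement) of
    ``subsample_size`` sequences is drawn, an NJ tree is built from TN93
    distances, and every requested method is run.  Within a replicate a
    site is called in a direction when a strict majority of the methods
    (2 of 3, or all of fewer) agree at p <= ``alpha``; the final call is
    the direction held in a strict majority of replicates.  All
    randomness derives from ``seed``.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("methods set is empty")
    rng = np.random.default_rng(seed)
    nrows = caln.nrows
    if nrows < subsample_size:
        warnings.warn(
            f"alignment has {nrows} < subsample_size={subsample_size} rows; "
            "running a single replicate on all rows"
        )
        replicate_rows = [list(range(nrows))]
    else:
        replicate_rows = [
            sorted(rng.choice(nrows, size=subsample_size, replace=False))
            for _ in range(n_replicates)
        ]

    method_majority = len(methods) // 2 + 1
    per_site_rep_calls: list[list[dict[str, str]]] = [
        [] for _ in range(caln.ncodons)
    ]
    per_site_rep_consensus: list[list[str]] = [[] for _ in range(caln.ncodons)]

    for rep, rows in enumerate(replicate_rows):
        sub = caln.subsample(rows)
        dm = _sanitize_dm(
            build_distance_matrix(
                sub.aln,
                model="TN93+G" if gamma_shape else "TN93",
                gamma_shape=gamma_shape,
            )
        )
        tree = nj_tree(dm)
        # deterministic per-replicate seed, reproducible from (seed, rep)
        rep_seed = replicate_seed(seed, rep)
        all_results: dict[str, list[SiteSelectionResult]] = {}
        kappa = None
        for m in methods:
            if m == "SLAC":
                all_results[m] = slac_site_test(
                    sub, tree, alpha=alpha, seed=rep_seed
                )
            elif m in ("FEL", "IFEL"):
                if kappa is None:
                    kappa = fit_kappa(sub, tree)
                all_results[m] = fel_site_test(
                    sub,
                    tree,
                    branch_set="all" if m == "FEL" else "internal_only",
                    alpha=alpha,
                    kappa=kappa,
                )
            else:
                raise ValueError(f"unknown method {m!r}")
        for site in range(caln.ncodons):
            calls = {m: all_results[m][site].call for m in methods}
            per_site_rep_calls[site].append(calls)
            per_site_rep_consensus[site].append(
                vote_calls(list(calls.values()), method_majority)
            )

    rep_majority = len(replicate_rows) // 2 + 1
    out = []
    for site in range(caln.ncodons):
        final = vote_calls(per_site_rep_consensus[site], rep_majority)
        out.append(
            ConsensusSelection(
                site=site,
                replicate_calls=per_site_rep_calls[site],
                replicate_consensus=per_site_rep_consensus[site],
                final_call=final,
            )
        )
    return out


def replicate_seed(seed: int, rep: int) -> int:
    """Deterministic sub-seed for replicate ``rep`` of a run seeded with
    ``seed`` (stable across runs; below 2**31)."""
    return int(np.random.default_rng([seed, rep]).integers(2**31 - 1))


def vote_calls(calls: Sequence[str], threshold: int) -> str:
    """Directional majority vote: a non-neutral direction wins iff held by
    at least ``threshold`` of the calls; otherwise neutral."""
    for direction in ("positive", "negative"):
        if sum(1 for c in calls if c == direction) >= threshold:
            return direction
    return "neutral"


def selection_to_df(consensus: list[ConsensusSelection]):
    """Table in the shape of the published per-codon summary: codon number,
    per-replicate consensus signs and the final verdict."""
    import pandas as pd

    sign = {"positive": "+", "negative": "-", "neutral": "0"}
    rows = []
    for c in consensus:
        rows.append(
            {
                "codon_1based": c.site + 1,
                "replicate_calls": "".join(
                    sign[x] for x in c.replicate_consensus
                ),
                "final_call": sign[c.final_call],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MG94xHKY simulator
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree: TreeNode,
    omega_per_site: Sequence[float],
    kappa: float = 2.0,
    seed: int = 0,
    pi_nt: Optional[Sequence[float]] = None,
) -> CodonAlignment:
    """Simulate codon evolution along a tree under MG94xHKY.

    Root codons are drawn from the stop-free equilibrium; each branch
    applies the exact transition probabilities (matrix exponential via the
    model's eigendecomposition).  Branch lengths are interpreted as
    nucleotide substitutions/site, as produced by the distance/NJ stack.
    """
    omega = np.asarray(list(omega_per_site), dtype=float)
    if (omega <= 0).any():
        raise ValueError("omega values must be positive")
    if pi_nt is None:
        pi_nt = np.full(4, 0.25)
    model = Mg94Model(kappa, np.asarray(pi_nt, dtype=float))
    rng = np.random.default_rng(seed)
    nsites = len(omega)

    # transition matrices per (unique omega, unique branch length)
    eigs = {w: model.eig(1.0, w) for w in sorted(set(omega.tolist()))}
    nodes = list(tree.postorder(include_self=True))
    Ps: dict[tuple[float, float], np.ndarray] = {}

    def P_for(w: float, t: float) -> np.ndarray:
        key = (w, t)
        if key not in Ps:
            lam, U = eigs[w]
            S = model._sqrt_pi
            P = (U * np.exp(lam * 3.0 * t)) @ U.T
            P = (P / S[:, None]) * S[None, :]
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            Ps[key] = P
        return Ps[key]

    root_states = rng.choice(
        len(SENSE_CODONS), size=nsites, p=model.pi_cod
    )
    states: dict[int, np.ndarray] = {id(tree): root_states}
    for node in tree.preorder(include_self=False):
        parent_states = states[id(node.parent)]
        t = float(node.length or 0.0)
        child = np.empty(nsites, dtype=int)
        if t == 0.0:
            child[:] = parent_states
        else:
            for s in range(nsites):
                P = P_for(float(omega[s]), t)
                child[s] = rng.choice(len(SENSE_CODONS), p=P[parent_states[s]])
        states[id(node)] = child

    records = []
    for tip in tree.tips():
        seq = "".join(SENSE_CODONS[i] for i in states[id(tip)])
        records.append(SequenceRecord(id=str(tip.name), seq=seq, moltype="dna"))
    return CodonAlignment(MsAlignment(records))
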