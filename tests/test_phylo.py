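import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

import mosaicfam as mf
from mosaicfam.phylo import DistanceMatrix


def oracle_tn93(a, b, shape=None):
    """Independent direct evaluation of the Tamura-Nei closed form."""
    keep = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
    n = len(keep)
    from collections import Counter

    cnt = Counter()
    for x, y in keep:
        cnt[x] += 1
        cnt[y] += 1
    g = {k: cnt[k] / (2 * n) for k in "ACGT"}
    gR, gY = g["A"] + g["G"], g["C"] + g["T"]
    P1 = sum(1 for x, y in keep if {x, y} == {"A", "G"}) / n
    P2 = sum(1 for x, y in keep if {x, y} == {"C", "T"}) / n
    Q = sum(
        1 for x, y in keep
        if x != y and {x, y} not in ({"A", "G"}, {"C", "T"})
    ) / n
    k1 = 2 * g["A"] * g["G"] / gR
    k2 = 2 * g["C"] * g["T"] / gY
    k3 = 2 * (gR * gY - g["A"] * g["G"] * gY / gR - g["C"] * g["T"] * gR / gY)
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if shape is None:
        return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    return shape * (
        k1 * w1 ** (-1 / shape)
        + k2 * w2 ** (-1 / shape)
        + k3 * w3 ** (-1 / shape)
        - (k1 + k2 + k3)
    )


def random_pair(seed, L=300, nmut=20):
    rng = np.random.default_rng(seed)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
    b = list(a)
    for j in rng.choice(L, size=nmut, replace=False):
        b[j] = "ACGT"[rng.integers(0, 4)]
    return a, "".join(b)


class TestTn93:
    def test_identical_sequences_zero(self):
        assert mf.tn93_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_oracle(self, seed):
        a, b = random_pair(seed)
        assert mf.tn93_distance(a, b) == pytest.approx(
            oracle_tn93(a, b), abs=1e-10
        )
        assert mf.tn93_distance(a, b, 0.8094) == pytest.approx(
            oracle_tn93(a, b, 0.8094), abs=1e-10
        )

    def test_symmetry(self):
        a, b = random_pair(33)
        assert mf.tn93_distance(a, b) == mf.tn93_distance(b, a)

    def test_jukes_cantor_collapse(self):
        """Equal base frequencies and a uniform substitution spectrum
        collapse TN93 to the Jukes-Cantor distance exactly."""
        bg = "ACGT" * 30
        a, b = list(bg), list(bg)
        used = set()
        for x, y in [("A", "G"), ("C", "T"), ("A", "C"), ("A", "T"),
                     ("G", "C"), ("G", "T")]:
            for u, v in ((x, y), (y, x)):
                site = next(
                    j for j in range(120) if a[j] == u and j not in used
                )
                used.add(site)
                b[site] = v
        a, b = "".join(a), "".join(b)
        assert mf.tn93_distance(a, b) == pytest.approx(
            mf.jc69_distance(a, b), abs=1e-12
        )

    def test_gamma_shape_to_infinity_converges(self):
        a = "ACGT" * 100
        b = a[:50] + "T" + a[51:]
        d0 = mf.tn93_distance(a, b)
        dg = mf.tn93_distance(a, b, gamma_shape=1e6)
        assert abs(dg - d0) / d0 < 1e-6

    def test_gap_sites_removed_pairwise(self):
        a = "ACGTACGTAC-TACGTACGT"
        b = "ACGTACGTACGTACG-ACGT"
        # only the 18 doubly-ungapped sites are compared; identical there
        assert mf.tn93_distance(a, b) == 0.0

    def test_zero_comparable_sites_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            mf.tn93_distance("----", "ACGT")

    def test_saturation_flagged_inf(self):
        # wildly divergent pair drives a log argument non-positive
        a = "A" * 30 + "C" * 30
        b = "G" * 30 + "T" * 30
        assert math.isinf(mf.tn93_distance(a, b))

    def test_triangle_inequality_on_low_divergence_family(self):
        # full-length sequences (one pattern, no indels) so every pair is
        # compared on the same sites; pairwise deletion over disjoint
        # element sets would not be a metric
        fam = mf.generate_family(
            mf.GeneratorConfig(
                seed=19, n_sequences=10, n_patterns=1, indel_rate=0.0,
                frameshift_rate=0.0, premature_stop_rate=0.0,
            )
        )
        dm = mf.build_distance_matrix(fam.alignment)
        n = dm.n
        # the log correction is concave, so strict additivity only holds in
        # expectation; allow a small relative slack for sampling noise
        for i, j, k in itertools.permutations(range(n), 3):
            assert dm.d[i, j] <= 1.02 * (dm.d[i, k] + dm.d[k, j]) + 1e-9


class TestNj:
    def test_additive_matrix_exact_recovery(self):
        # tree ((a:2,b:3):1,(c:4,d:5))
        ids = ["a", "b", "c", "d"]
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        tree = mf.nj_tree(DistanceMatrix(ids, D))
        for x, y in itertools.combinations(ids, 2):
            assert tree.find(x).distance(tree.find(y)) == pytest.approx(
                D[ids.index(x), ids.index(y)], abs=1e-9
            )
        # topology: a,b are siblings
        assert tree.find("a").parent is tree.find("b").parent

    def test_matches_skbio_topology(self):
        rng = np.random.default_rng(4)
        n = 6
        ids = [f"t{i}" for i in range(n)]
        # random additive matrix from random tree via random splits: use a
        # perturbed metric; compare bipartitions with the skbio oracle
        base = rng.uniform(0.5, 1.5, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0.0)
        ours = mf.nj_tree(DistanceMatrix(ids, D))
        theirs = skbio_nj(SkbioDM(D, ids))

        def parts(tree):
            taxa = frozenset(ids)
            out = set()
            for node in tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    out.add(min(side, taxa - side, key=sorted))
            return out

        assert parts(ours) == parts(theirs)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = mf.nj_tree(DistanceMatrix(["x", "y", "z"], D))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"x": 1.0, "y": 2.0, "z": 3.0}

    def test_identical_rows_joined_first_with_zero_lengths(self):
        D = np.array(
            [[0, 0, 4, 5], [0, 0, 4, 5], [4, 4, 0, 3], [5, 5, 3, 0]], float
        )
        tree = mf.nj_tree(DistanceMatrix(["a", "b", "c", "d"], D))
        a, b = tree.find("a"), tree.find("b")
        assert a.parent is b.parent
        assert a.length == 0.0 and b.length == 0.0

    def test_branch_lengths_never_negative(self, default_family):
        dm = mf.build_distance_matrix(default_family.alignment)
        tree = mf.nj_tree(dm)
        assert all(
            (n.length or 0.0) >= 0.0 for n in tree.traverse(include_self=False)
        )

    def test_nonfinite_distances_rejected(self):
        D = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="non-finite"):
            mf.nj_tree(DistanceMatrix(["a", "b", "c"], D))


@pytest.fixture(scope="module")
def clade_alignment():
    from skbio import TreeNode

    tree = TreeNode.read(["((a:0.02,b:0.02):0.3,(c:0.02,d:0.02):0.3);"])
    return mf.simulate_codon_alignment(tree, [1.0] * 150, kappa=2.0, seed=5).aln


class TestBootstrap:

    def test_clear_split_gets_full_support(self, clade_alignment):
        tree = mf.bootstrap_support(clade_alignment, n_reps=50, seed=3)
        supports = [
            n.support for n in tree.non_tips() if hasattr(n, "support")
        ]
        assert supports and max(supports) == 1.0

    def test_single_replicate_support_is_binary(self, clade_alignment):
        tree = mf.bootstrap_support(clade_alignment, n_reps=1, seed=8)
        for n in tree.non_tips():
            if hasattr(n, "support"):
                assert n.support in (0.0, 1.0)

    def test_same_seed_same_supports(self, clade_alignment):
        t1 = mf.bootstrap_support(clade_alignment, n_reps=25, seed=11)
        t2 = mf.bootstrap_support(clade_alignment, n_reps=25, seed=11)
        assert str(t1) == str(t2)

    def test_newick_roundtrip(self, tmp_path, clade_alignment):
        tree = mf.bootstrap_support(clade_alignment, n_reps=10, seed=1)
        p = tmp_path / "tree.nwk"
        mf.write_newick(tree, p)
        back = mf.read_newick(p)
        assert sorted(t.name for t in back.tips()) == ["a", "b", "c", "d"]


class TestProperties:
    """Derandomised hypothesis checks of the distance contracts."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    dna = st.text(alphabet="ACGT", min_size=40, max_size=40)

    @given(a=dna, b=dna)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_tn93_symmetric_and_nonnegative(self, a, b):
        try:
            d1 = mf.tn93_distance(a, b)
        except ValueError:
            return
        assert d1 == mf.tn93_distance(b, a)
        assert d1 >= 0.0 or math.isinf(d1)

    @given(a=dna)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_self_distance_zero(self, a):
        assert mf.tn93_distance(a, a) == 0.0
        assert mf.jc69_distance(a, a) == 0.0
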