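import numpy as np
import pytest
from skbio import TreeNode

import mosaicfam as mf


@pytest.fixture(scope="session")
def default_family():
    """Synthetic family under default study conditions (fixed seed)."""
    return mf.generate_family(mf.GeneratorConfig(seed=1, n_sequences=60))


@pytest.fixture(scope="session")
def gene_family():
    """Gene-mode synthetic family (intron with its own patterns)."""
    return mf.generate_family(
        mf.GeneratorConfig(seed=3, gene_mode=True, n_sequences=39)
    )


@pytest.fixture()
def toy_alignment():
    """4 sequences, one 18-column gap block shared by rows 3-4."""
    left = "ACGTACGTACGTACGTACGT"  # 20 cols
    mid = "ACGTACGTACGTACGTAC"  # 18 cols
    right = "GTACGTACGTACGTACGTACGT"  # 22 cols
    rows = [left + mid + right] * 2 + [left + "-" * 18 + right] * 2
    return mf.MsAlignment(
        [
            mf.SequenceRecord(f"t{i+1}", row, "dna")
            for i, row in enumerate(rows)
        ]
    )


def balanced_tree(n: int, blen: float = 0.05) -> TreeNode:
    """Balanced binary tree over n tips with uniform branch lengths."""
    nodes = [TreeNode(name=f"s{i:02d}") for i in range(n)]
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            p = TreeNode()
            nodes[i].length = blen
            nodes[i + 1].length = blen
            p.extend([nodes[i], nodes[i + 1]])
            nxt.append(p)
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return nodes[0]


@pytest.fixture(scope="session")
def tree8():
    return TreeNode.read(
        [
            "(((a:0.1,b:0.1):0.05,(c:0.1,d:0.1):0.05):0.025,"
            "((e:0.1,f:0.1):0.05,(g:0.1,h:0.1):0.05):0.025);"
        ]
    )


@pytest.fixture(scope="session")
def null_fel_pvalues(tree8):
    """FEL p-values for 500 sites simulated under neutrality (omega=1).

    Session-scoped: shared by the calibration and uniformity checks.
    """
    caln = mf.simulate_codon_alignment(
        tree8, [1.0] * 500, kappa=2.0, seed=101
    )
    res = mf.fel_site_test(caln, tree8)
    return np.array([r.p_value for r in res])
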