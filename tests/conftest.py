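import numpy as np
import pytest

from urheimat.cognates import CognateMatrix
from urheimat.simulate import (SimConfig, kartvelian_reference_tree,
                               simulate_cognate_matrix)
from urheimat.trees import DatedTree, TreeNode


@pytest.fixture(scope="session")
def reference_tree() -> DatedTree:
    return kartvelian_reference_tree()


@pytest.fixture(scope="session")
def small_matrix() -> CognateMatrix:
    """A 3-language toy matrix with two concepts."""
    return CognateMatrix(
        languages=["A", "B", "C"],
        tip_dates={"A": 0.0, "B": 0.0, "C": 0.0},
        column_concepts=["hand", "hand", "go", "go", "go"],
        column_ids=["hand_1", "hand_2", "go_1", "go_2", "go_3"],
        cells=np.array([
            [1, 0, 1, 0, 2],
            [1, 1, 0, 1, 0],
            [0, 1, 0, 1, 1],
        ], dtype=np.int8),
    )


@pytest.fixture(scope="session")
def sim_matrix(reference_tree) -> CognateMatrix:
    """A study-sized simulated cognate matrix on the reference chronology."""
    return simulate_cognate_matrix(reference_tree, SimConfig(seed=3))


def two_tip_tree(t1: float = 1000.0, tip_ages=(0.0, 0.0)) -> DatedTree:
    a = TreeNode("A", tip_ages[0])
    b = TreeNode("B", tip_ages[1])
    root = TreeNode(age=t1)
    root.add_child(a)
    root.add_child(b)
    return DatedTree(root)


def three_tip_tree(x0: float, x1: float, names=("A", "B", "C")) -> DatedTree:
    a, b, c = (TreeNode(n, 0.0) for n in names)
    inner = TreeNode(age=x1)
    inner.add_child(a)
    inner.add_child(b)
    root = TreeNode(age=x0)
    root.add_child(inner)
    root.add_child(c)
    return DatedTree(root)
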