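import numpy as np
import pytest

from aortoiliac.model import Centerline, CenterlineTree
from aortoiliac.synthetic import make_aortoiliac_tree


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform_tree(tree: CenterlineTree, rot: np.ndarray, shift: np.ndarray) -> CenterlineTree:
    out = tree.copy()
    for b, cl in out.branches.items():
        out.branches[b] = Centerline(cl.points @ rot.T + shift, cl.radius)
    return out


def rigid_transform_line(cl: Centerline, rot: np.ndarray, shift: np.ndarray) -> Centerline:
    return Centerline(cl.points @ rot.T + shift, cl.radius)


@pytest.fixture
def symmetric_tree():
    tree, truth = make_aortoiliac_tree(takeoff_left_deg=26.0, takeoff_right_deg=26.0)
    return tree, truth


@pytest.fixture
def unlabeled(symmetric_tree):
    tree, _ = symmetric_tree
    out = tree.copy()
    out.label = {b: "unlabeled" for b in out.branches}
    return out


@pytest.fixture
def straight_line():
    x = np.linspace(0.0, 100.0, 21)
    return Centerline(np.column_stack([x, np.zeros_like(x), np.zeros_like(x)]))
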