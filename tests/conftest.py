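import numpy as np
import pytest

from villimorph.tree_model import Branch, VillousTree

Y_SWC = """\
# Y-shaped villous tree: stem with interior point, node, two terminal leaves
1 0 0.0 0.0 0.0 1.0 -1
2 0 0.0 0.0 5.0 1.0 1
3 0 0.0 0.0 10.0 1.5 2
4 0 5.0 0.0 15.0 0.5 3
5 0 -5.0 0.0 15.0 0.5 3
"""

# chain root -> node A -> node B, one leaf off A, two leaves off B
CATERPILLAR_SWC = """\
1 0 0.0 0.0 0.0 1.0 -1
2 0 0.0 0.0 1.0 1.0 1
3 0 1.0 0.0 1.0 1.0 2
4 0 0.0 0.0 2.0 1.0 2
5 0 1.0 0.0 2.0 1.0 4
6 0 -1.0 0.0 2.0 1.0 4
"""


@pytest.fixture
def y_swc(tmp_path):
    p = tmp_path / "y.swc"
    p.write_text(Y_SWC)
    return p


@pytest.fixture
def caterpillar_swc(tmp_path):
    p = tmp_path / "caterpillar.swc"
    p.write_text(CATERPILLAR_SWC)
    return p


def straight_branch(points, diameters=None, bid="b0", parent=None, terminal=True):
    """Build a Branch from a coordinate list with constant diameter 2 by default."""
    xyz = np.asarray(points, dtype=float)
    if diameters is None:
        diameters = np.full(len(xyz), 2.0)
    return Branch(bid, xyz, np.asarray(diameters, float),
                  parent_id=parent, ends_terminal=terminal)


@pytest.fixture
def y_tree():
    """The Y tree built directly from Branch objects (no file round-trip)."""
    stem = straight_branch([[0, 0, 0], [0, 0, 5], [0, 0, 10]],
                           [2.0, 2.0, 3.0], bid="stem", terminal=False)
    left = straight_branch([[0, 0, 10], [5, 0, 15]], [3.0, 1.0],
                           bid="left", parent="stem")
    right = straight_branch([[0, 0, 10], [-5, 0, 15]], [3.0, 1.0],
                            bid="right", parent="stem")
    return VillousTree("y", {b.branch_id: b for b in (stem, left, right)}, "stem")
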