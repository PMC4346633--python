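import numpy as np
import pytest

from cyclekin.lineage import build_tree


def quartet_records(
    *,
    d_divided: bool = True,
    d_child_markers: bool = True,
    tree_id: str = "T1",
    well_id: str = "W1",
):
    """Canonical 3-level division tree: C1 -> M1,M2 -> D1..D4.

    With ``d_divided`` the D cells complete their cycles (observed to the
    next division); ``d_child_markers`` appends their censored children so
    the binary-tree invariant holds.
    """
    rows = [
        dict(tree_id=tree_id, well_id=well_id, cell_id="C1", parent_id=None,
             birth_time_min=0.0, end_time_min=600.0, fate="DIVIDED",
             generation_offset=1),
        dict(tree_id=tree_id, well_id=well_id, cell_id="M1", parent_id="C1",
             birth_time_min=600.0, end_time_min=1300.0, fate="DIVIDED",
             generation_offset=1),
        dict(tree_id=tree_id, well_id=well_id, cell_id="M2", parent_id="C1",
             birth_time_min=600.0, end_time_min=1400.0, fate="DIVIDED",
             generation_offset=1),
    ]
    d_fate = "DIVIDED" if d_divided else "CENSORED"
    d_cells = [
        ("D1", "M1", 1300.0, 2000.0),
        ("D2", "M1", 1300.0, 2100.0),
        ("D3", "M2", 1400.0, 2200.0),
        ("D4", "M2", 1400.0, 2350.0),
    ]
    for cid, pid, b, e in d_cells:
        rows.append(dict(tree_id=tree_id, well_id=well_id, cell_id=cid,
                         parent_id=pid, birth_time_min=b, end_time_min=e,
                         fate=d_fate, generation_offset=1))
        if d_divided and d_child_markers:
            for k in (1, 2):
                rows.append(dict(tree_id=tree_id, well_id=well_id,
                                 cell_id=f"{cid}x{k}", parent_id=cid,
                                 birth_time_min=e, end_time_min=3000.0,
                                 fate="CENSORED", generation_offset=1))
    return rows


@pytest.fixture
def quartet_tree():
    return build_tree(quartet_records())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def complete_tree_records(depth: int, cycle: float = 700.0):
    """Complete binary tree of the given depth: every internal node
    (depth < ``depth``) is DIVIDED; leaves at ``depth`` are censored."""
    rows = []

    def add(cell_id, parent_id, birth, d):
        divided = d < depth
        end = birth + cycle if divided else birth + 50.0
        rows.append(dict(tree_id="T1", well_id="W1", cell_id=cell_id,
                         parent_id=parent_id, birth_time_min=birth,
                         end_time_min=end,
                         fate="DIVIDED" if divided else "CENSORED",
                         generation_offset=1))
        if divided:
            for k in (1, 2):
                add(f"{cell_id}.{k}", cell_id, end, d + 1)

    add("R", None, 0.0, 0)
    return rows
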