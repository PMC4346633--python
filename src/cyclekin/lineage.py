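"""Division-tree data model, kinship extraction and tracking QC.

Trees are rooted binary division pedigrees built from per-cell track
records (one row per tracked cell, linked by ``parent_id``).  The founder
of each tree carries the sorted generation of the well (``generation_offset``),
so a cell's absolute generation is ``generation_offset + depth``.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Fate",
    "KinshipLabel",
    "Relation",
    "SpeedCategory",
    "CellNode",
    "LineageTree",
    "SpeedThresholds",
    "PairSet",
    "TreeStructureError",
    "TreeTimingError",
    "build_tree",
    "build_trees",
    "qc_filter",
    "extract_cycle_times",
    "kinship_pairs",
    "classify_division_speed",
    "early_late_divider",
]


class Fate(str, enum.Enum):
    DIVIDED = "DIVIDED"
    DIED = "DIED"
    CENSORED = "CENSORED"


class KinshipLabel(str, enum.Enum):
    C1 = "C1"
    M1 = "M1"
    M2 = "M2"
    D1 = "D1"
    D2 = "D2"
    D3 = "D3"
    D4 = "D4"
    DEEPER = "DEEPER"


class Relation(str, enum.Enum):
    SIBLING = "SIBLING"
    COUSIN = "COUSIN"
    MOTHER_DAUGHTER = "MOTHER_DAUGHTER"
    NON_RELATIVE = "NON_RELATIVE"


class SpeedCategory(str, enum.Enum):
    FAST = "FAST"
    MEDIUM = "MEDIUM"
    INTERMEDIATE = "INTERMEDIATE"
    SLOW = "SLOW"
    NO_DIVISION = "NO_DIVISION"


class TreeStructureError(ValueError):
    """Raised when track records do not form a valid division tree."""


class TreeTimingError(ValueError):
    """Raised when child birth times disagree with the parent's division time."""


@dataclass
class CellNode:
    """One tracked cell: a node of a division tree.

    ``cycle_time`` (minutes) is only meaningful when ``fate == DIVIDED``;
    for censored cells ``end_time - birth_time`` is the observed
    division-free span instead.
    """

    cell_id: str
    parent_id: str | None
    tree_id: str
    birth_time: float
    end_time: float
    fate: Fate
    generation_offset: int = 1
    depth: int = 0
    kinship_label: KinshipLabel = KinshipLabel.C1
    size_class: str | None = None
    cd62l_class: str | None = None
    latent_state: str | None = None
    children: list["CellNode"] = field(default_factory=list, repr=False)

    @property
    def cycle_time(self) -> float | None:
        if self.fate is Fate.DIVIDED:
            return self.end_time - self.birth_time
        return None

    @property
    def observed_span(self) -> float:
        return self.end_time - self.birth_time

    @property
    def generation_abs(self) -> int:
        return self.generation_offset + self.depth

    @property
    def is_root(self) -> bool:
        return self.parent_id is None


@dataclass
class LineageTree:
    tree_id: str
    well_id: str
    root: CellNode
    imaging_end: float
    qc_status: str = "INCLUDED"
    qc_reason: str | None = None

    def nodes(self) -> list[CellNode]:
        """All nodes in deterministic pre-order."""
        out: list[CellNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def node_map(self) -> dict[str, CellNode]:
        return {n.cell_id: n for n in self.nodes()}

    def n_divided(self) -> int:
        return sum(1 for n in self.nodes() if n.fate is Fate.DIVIDED)

    def validate(self) -> None:
        nodes = self.nodes()
        if len(nodes) != 1 + 2 * self.n_divided():
            raise TreeStructureError(
                f"tree {self.tree_id}: node count {len(nodes)} != 1 + 2*divided"
            )
        for n in nodes:
            if n.end_time < n.birth_time:
                raise TreeTimingError(
                    f"cell {n.cell_id}: end_time {n.end_time} < birth_time {n.birth_time}"
                )
            n_children = len(n.children)
            if n.fate is Fate.DIVIDED and n_children != 2:
                raise TreeStructureError(
                    f"cell {n.cell_id}: DIVIDED with {n_children} children"
                )
            if n.fate is not Fate.DIVIDED and n_children != 0:
                raise TreeStructureError(
                    f"cell {n.cell_id}: fate {n.fate.value} with children"
                )


@dataclass(frozen=True)
class SpeedThresholds:
    """Division-speed category boundaries, minutes.

    The 800-1000 min band is reported as an explicit INTERMEDIATE category;
    it is never merged into MEDIUM or SLOW.
    """

    fast_max: float = 600.0
    medium_max: float = 800.0
    slow_min: float = 1000.0
    no_division_min: float = 1800.0
    day_boundary: float = 1440.0

    def __post_init__(self) -> None:
        if not (self.fast_max <= self.medium_max <= self.slow_min < self.no_division_min):
            raise ValueError("require fast_max <= medium_max <= slow_min < no_division_min")


@dataclass
class PairSet:
    relation: Relation
    pairs: list[tuple[float, float]]
    cell_ids: list[tuple[str, str]]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def values(self) -> tuple[list[float], list[float]]:
        return [p[0] for p in self.pairs], [p[1] for p in self.pairs]


_LABELS_BY_PATH: Mapping[tuple[int, ...], KinshipLabel] = {
    (): KinshipLabel.C1,
    (0,): KinshipLabel.M1,
    (1,): KinshipLabel.M2,
    (0, 0): KinshipLabel.D1,
    (0, 1): KinshipLabel.D2,
    (1, 0): KinshipLabel.D3,
    (1, 1): KinshipLabel.D4,
}


def _assign_labels(root: CellNode) -> None:
    stack: list[tuple[CellNode, tuple[int, ...]]] = [(root, ())]
    while stack:
        node, path = stack.pop()
        node.kinship_label = _LABELS_BY_PATH.get(path, KinshipLabel.DEEPER)
        node.depth = len(path)
        for i, child in enumerate(node.children):
            stack.append((child, path + (i,)))


def build_tree(
    records: Sequence[Mapping] | pd.DataFrame,
    *,
    timing_tolerance: float = 4.0,
) -> LineageTree:
    """Assemble and validate one LineageTree from per-cell track records.

    Children are ordered by record order within each division (the
    earlier-listed child becomes the lower kinship index).  Child birth
    times must match the parent's division time within ``timing_tolerance``
    minutes (one sampling frame).
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    if not records:
        raise TreeStructureError("no records")

    nodes: dict[str, CellNode] = {}
    order: dict[str, int] = {}
    wells = set()
    tree_ids = set()
    for i, rec in enumerate(records):
        pid = rec.get("parent_id")
        if pid is not None and (pid == "" or (isinstance(pid, float) and math.isnan(pid))):
            pid = None
        cid = str(rec["cell_id"])
        node = CellNode(
            cell_id=cid,
            parent_id=None if pid is None else str(pid),
            tree_id=str(rec["tree_id"]),
            birth_time=float(rec["birth_time_min"]),
            end_time=float(rec["end_time_min"]),
            fate=Fate(rec["fate"]),
            generation_offset=int(rec.get("generation_offset", 1)),
            size_class=rec.get("size_class") or None,
            cd62l_class=rec.get("cd62l_class") or None,
            latent_state=rec.get("latent_state") or None,
        )
        if node.birth_time < 0:
            raise TreeTimingError(f"cell {cid}: negative birth_time")
        if cid in nodes:
            raise TreeStructureError(f"duplicate cell_id {cid}")
        nodes[cid] = node
        order[cid] = i
        wells.add(str(rec.get("well_id", "")))
        tree_ids.add(node.tree_id)

    if len(wells) > 1:
        raise TreeStructureError(f"records span multiple wells: {sorted(wells)}")
    if len(tree_ids) > 1:
        raise TreeStructureError(f"records span multiple trees: {sorted(tree_ids)}")

    roots = [n for n in nodes.values() if n.parent_id is None]
    if len(roots) != 1:
        raise TreeStructureError(f"expected exactly one root record, found {len(roots)}")
    root = roots[0]

    for node in nodes.values():
        if node.parent_id is None:
            continue
        parent = nodes.get(node.parent_id)
        if parent is None:
            raise TreeStructureError(
                f"cell {node.cell_id}: parent_id {node.parent_id} not found in well"
            )
        parent.children.append(node)
        if abs(node.birth_time - parent.end_time) > timing_tolerance:
            raise TreeTimingError(
                f"cell {node.cell_id}: birth_time {node.birth_time} != parent "
                f"end_time {parent.end_time} beyond tolerance {timing_tolerance}"
            )
    for node in nodes.values():
        node.children.sort(key=lambda c: order[c.cell_id])

    _assign_labels(root)
    imaging_end = max(n.end_time for n in nodes.values())
    well_id = next(iter(wells)) if wells else ""
    tree = LineageTree(
        tree_id=root.tree_id, well_id=well_id, root=root, imaging_end=imaging_end
    )
    tree.validate()
    return tree


def build_trees(
    records: Sequence[Mapping] | pd.DataFrame, *, timing_tolerance: float = 4.0
) -> list[LineageTree]:
    """Group a mixed track table by tree_id and build every tree."""
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records
    trees = []
    for _, grp in df.groupby("tree_id", sort=True):
        trees.append(build_tree(grp, timing_tolerance=timing_tolerance))
    return trees


_QC_RULES = ("death", "multiple_initial_cells", "foreign_cell_entry")


def qc_filter(
    trees: Iterable[LineageTree],
    *,
    rules: Sequence[str] = _QC_RULES,
) -> tuple[list[LineageTree], pd.DataFrame]:
    """Apply the per-well tracking exclusion rules.

    A well is excluded when a tracked cell died during imaging, when more
    than one cell was present at the start of imaging, or when cells from
    another lineage appear in the same well.  Exclusion is per well: every
    tree in a flagged well is excluded.
    """
    trees = list(trees)
    unknown = set(rules) - set(_QC_RULES)
    if unknown:
        raise ValueError(f"unknown QC rules: {sorted(unknown)}")

    by_well: dict[str, list[LineageTree]] = {}
    for t in trees:
        by_well.setdefault(t.well_id, []).append(t)

    log_rows = []
    excluded_wells: dict[str, tuple[str, str]] = {}
    for well, well_trees in by_well.items():
        if "multiple_initial_cells" in rules:
            founders = [t for t in well_trees if t.root.birth_time == 0.0]
            if len(founders) > 1:
                excluded_wells[well] = (
                    "multiple_initial_cells",
                    f"{len(founders)} cells present at imaging start",
                )
                continue
        if "foreign_cell_entry" in rules and len(well_trees) > 1:
            excluded_wells[well] = (
                "foreign_cell_entry",
                f"{len(well_trees)} distinct lineages in one well",
            )
            continue
        if "death" in rules:
            for t in well_trees:
                dead = [n.cell_id for n in t.nodes() if n.fate is Fate.DIED]
                if dead:
                    excluded_wells[well] = (
                        "death",
                        f"death during imaging (cells: {', '.join(dead)})",
                    )
                    break

    included = []
    for t in trees:
        if t.well_id in excluded_wells:
            rule, detail = excluded_wells[t.well_id]
            t.qc_status = "EXCLUDED"
            t.qc_reason = rule
            log_rows.append(
                {"tree_id": t.tree_id, "well_id": t.well_id, "rule": rule, "detail": detail}
            )
        else:
            t.qc_status = "INCLUDED"
            t.qc_reason = None
            included.append(t)
    log = pd.DataFrame(log_rows, columns=["tree_id", "well_id", "rule", "detail"])
    return included, log


def extract_cycle_times(tree: LineageTree, *, complete_only: bool = True) -> pd.DataFrame:
    """Per-cell cycle-time table.

    With ``complete_only`` (the measurement rule used on real tracks) the
    founder — whose cycle start was never observed — is excluded and only
    DIVIDED cells appear.  Otherwise every node is listed, with NaN
    cycle_time for cells that did not complete a cycle.
    """
    rows = []
    for n in tree.nodes():
        if complete_only and (n.is_root or n.fate is not Fate.DIVIDED):
            continue
        rows.append(
            {
                "cell_id": n.cell_id,
                "tree_id": tree.tree_id,
                "depth": n.depth,
                "generation_abs": n.generation_abs,
                "cycle_time": n.cycle_time if n.cycle_time is not None else float("nan"),
                "fate": n.fate.value,
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_id", "tree_id", "depth", "generation_abs", "cycle_time", "fate"]
    )


def _complete(node: CellNode) -> bool:
    return node.fate is Fate.DIVIDED


def _sibling_pairs(tree: LineageTree):
    for n in tree.nodes():
        if n.fate is Fate.DIVIDED:
            a, b = n.children
            if _complete(a) and _complete(b):
                yield a, b


def _mother_daughter_pairs(tree: LineageTree, include_founder: bool = False):
    for n in tree.nodes():
        if n.fate is not Fate.DIVIDED or not _complete(n):
            continue
        if n.is_root and not include_founder:
            # founder cycle start unobserved: anchors kinship, never a data point
            continue
        for child in n.children:
            if _complete(child):
                yield n, child


def _cousin_pairs(tree: LineageTree):
    for n in tree.nodes():
        if n.fate is not Fate.DIVIDED:
            continue
        m1, m2 = n.children
        if m1.fate is not Fate.DIVIDED or m2.fate is not Fate.DIVIDED:
            continue
        for a in m1.children:
            for b in m2.children:
                if _complete(a) and _complete(b):
                    yield a, b


def kinship_pairs(
    trees: Iterable[LineageTree] | LineageTree,
    relation: Relation | str,
    *,
    include_founder_cycles: bool = False,
) -> PairSet:
    """Extract kinship-classified cycle-time pairs.

    SIBLING: the two daughters of one division (unordered, counted once).
    MOTHER_DAUGHTER: (mother, daughter) dyads, mother value first; founders
    are excluded as mothers unless ``include_founder_cycles`` (their cycle
    start predates imaging).  COUSIN: all four cross pairs between the
    daughter sets of two sibling mothers.  NON_RELATIVE: cells from
    different trees paired by birth-order rank, min(n_a, n_b) pairs per
    tree pair taken over consecutive tree pairs.
    """
    relation = Relation(relation)
    if isinstance(trees, LineageTree):
        trees = [trees]
    trees = list(trees)

    pairs: list[tuple[float, float]] = []
    ids: list[tuple[str, str]] = []

    def _add(a: CellNode, b: CellNode) -> None:
        pairs.append((a.cycle_time, b.cycle_time))  # type: ignore[arg-type]
        ids.append((a.cell_id, b.cell_id))

    if relation is Relation.NON_RELATIVE:
        cells_per_tree = []
        for t in trees:
            cells = [n for n in t.nodes() if _complete(n) and not n.is_root]
            cells.sort(key=lambda n: (n.birth_time, n.cell_id))
            cells_per_tree.append(cells)
        for ca, cb in zip(cells_per_tree[0::2], cells_per_tree[1::2]):
            for a, b in zip(ca, cb):
                _add(a, b)
    else:
        if relation is Relation.MOTHER_DAUGHTER:
            for t in trees:
                for a, b in _mother_daughter_pairs(t, include_founder_cycles):
                    _add(a, b)
        else:
            gen = {
                Relation.SIBLING: _sibling_pairs,
                Relation.COUSIN: _cousin_pairs,
            }[relation]
            for t in trees:
                for a, b in gen(t):
                    _add(a, b)

    return PairSet(relation=relation, pairs=pairs, cell_ids=ids)


def classify_division_speed(
    duration: float,
    thresholds: SpeedThresholds = SpeedThresholds(),
    *,
    divided: bool = True,
) -> SpeedCategory | None:
    """Map a cycle time (or an undivided observed span) to a speed category.

    For divided cells the categories partition [0, inf):
    FAST < fast_max <= MEDIUM <= medium_max < INTERMEDIATE <= slow_min < SLOW.
    For undivided cells, NO_DIVISION when the division-free span exceeds
    ``no_division_min``; otherwise None (too short to call).
    """
    if duration < 0:
        raise ValueError(f"negative duration: {duration}")
    if not divided:
        return SpeedCategory.NO_DIVISION if duration > thresholds.no_division_min else None
    if duration < thresholds.fast_max:
        return SpeedCategory.FAST
    if duration <= thresholds.medium_max:
        return SpeedCategory.MEDIUM
    if duration <= thresholds.slow_min:
        return SpeedCategory.INTERMEDIATE
    return SpeedCategory.SLOW


def early_late_divider(
    tree: LineageTree, thresholds: SpeedThresholds = SpeedThresholds()
) -> str:
    """Founder classification: EARLY (first cytokinesis on imaging day 1),
    LATE (day 2), NONE otherwise."""
    root = tree.root
    if root.fate is not Fate.DIVIDED:
        return "NONE"
    t = root.end_time
    if t < thresholds.day_boundary:
        return "EARLY"
    if t < 2 * thresholds.day_boundary:
        return "LATE"
    return "NONE"


def sibling_dyads(tree: LineageTree) -> list[tuple[str, str]]:
    """Cell-id pairs of co-daughters, regardless of fate (structural dyads)."""
    out = []
    for n in tree.nodes():
        if n.fate is Fate.DIVIDED:
            a, b = n.children
            out.append((a.cell_id, b.cell_id))
    return out


def all_unordered_pairs(values: Sequence) -> list[tuple]:
    """Brute-force helper: all unordered pairs (used by tests and demos)."""
    return list(itertools.combinations(values, 2))
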