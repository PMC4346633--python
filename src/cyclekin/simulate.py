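"""Branching-process simulator of clonally expanding Fucci reporter T cells.

Produces division trees (the lineage schema), per-cell fluorescence traces,
a ground-truth log for oracle tests, and population readouts: Fucci-state
fractions over time, dye-dilution (CTV) histograms, BrdU pulse labelling
and single-cell expansion counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .fucci import FluorescenceTrace
from .lineage import CellNode, Fate, LineageTree, _assign_labels

__all__ = [
    "CellTruth",
    "SimulationResult",
    "PopulationSnapshot",
    "simulate_trees",
    "synthesize_trace",
    "simulate_cohort",
    "ctv_intensity",
    "ctv_histogram",
    "brdu_pulse",
    "single_cell_expansion",
]

FAST, SLOW = "FAST", "SLOW"


@dataclass
class CellTruth:
    """Generator-side ground truth for one cell (never visible to analysis)."""

    cell_id: str
    tree_id: str
    depth: int
    latent_state: str
    birth: float
    end: float
    fate: str
    intended_cycle: float | None   # None for arrested cells
    t_dn_end: float                # DN -> KO_POS boundary
    t_g1_end: float                # KO_POS -> AG_POS boundary (inf if never reached)
    division_shock: float | None = None

    @property
    def d_dn(self) -> float:
        return min(self.t_dn_end, self.end) - self.birth

    @property
    def d_ko(self) -> float:
        if self.end <= self.t_dn_end:
            return 0.0
        return min(self.t_g1_end, self.end) - self.t_dn_end

    @property
    def d_ag(self) -> float:
        return max(0.0, self.end - self.t_g1_end) if math.isfinite(self.t_g1_end) else 0.0


@dataclass
class SimulationResult:
    config: SimulationConfig
    trees: list[LineageTree]
    traces: dict[str, FluorescenceTrace]
    truth: dict[str, CellTruth]
    imaging_end: float
    frame_interval: float

    def truth_records(self) -> pd.DataFrame:
        rows = []
        for t in self.truth.values():
            rows.append(
                {
                    "cell_id": t.cell_id, "tree_id": t.tree_id, "depth": t.depth,
                    "latent_state": t.latent_state, "birth": t.birth, "end": t.end,
                    "fate": t.fate, "intended_cycle": t.intended_cycle,
                    "t_dn_end": t.t_dn_end, "t_g1_end": t.t_g1_end,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PopulationSnapshot:
    time: float
    cells: pd.DataFrame = field(repr=False)

    @property
    def n_live(self) -> int:
        return len(self.cells)

    def state_fractions(self) -> dict[str, float]:
        if not len(self.cells):
            return {}
        return self.cells["fucci_state"].value_counts(normalize=True).to_dict()


# ---------------------------------------------------------------------------
# core branching process


def _phase_boundaries(
    cfg: SimulationConfig, birth: float, cycle: float | None, state: str
) -> tuple[float, float]:
    """(t_dn_end, t_g1_end) for a cell; arrested cells stay KO+ forever."""
    if cycle is None:
        return birth + cfg.dn_duration_min, math.inf
    d_dn = min(cfg.dn_duration_min, 0.2 * cycle)
    g1_frac = cfg.g1_frac_slow if state == SLOW else cfg.g1_frac_fast
    d_g1 = g1_frac * (cycle - d_dn)
    return birth + d_dn, birth + d_dn + d_g1


def _draw_fast_cycle(cfg: SimulationConfig, rng, depth: int, family: float,
                     drift: float, shock: float) -> float:
    # drift depth saturates at the tracked-depth cap so that deep expansion
    # (cohort mode) keeps a constant arithmetic mean instead of the k^2
    # mean correction driving cycle times to zero
    k = min(depth, cfg.max_depth)
    gp = cfg.gen_params(cfg.generation_offset)
    eps = rng.normal(0.0, math.sqrt(gp.var_individual))
    return math.exp(gp.location(k) + family + drift * k + shock + eps)


def _draw_slow_cycle(cfg: SimulationConfig, rng) -> float:
    return math.exp(cfg.slow_mu_log + cfg.slow_sigma_log * rng.standard_normal())


def _child_state(cfg: SimulationConfig, rng, mother_state: str, child_gen_abs: int) -> str:
    if mother_state == SLOW:
        return SLOW if rng.random() < cfg.p_stay else FAST
    if child_gen_abs >= cfg.g_onset and rng.random() < cfg.p_on:
        return SLOW
    return FAST


def _phenotype(cfg: SimulationConfig, state: str, depth: int, gen_abs: int):
    if state == SLOW:
        return "SMALL", "HI"
    if depth >= 1:
        return "LARGE", ("INT" if gen_abs < cfg.g_onset else "LO")
    return None, None


def _grow_tree(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    tree_id: str,
    well_id: str,
    founder_birth: float,
    window_end: float,
    max_depth: int | None,
    founder_state: str | None = None,
) -> tuple[LineageTree, dict[str, CellTruth]]:
    gp = cfg.gen_params(cfg.generation_offset)
    family = rng.normal(0.0, math.sqrt(gp.var_family))
    drift = rng.normal(0.0, math.sqrt(gp.var_drift))

    if founder_state is None:
        founder_state = SLOW if (
            cfg.generation_offset >= cfg.g_onset and rng.random() < cfg.p_on
        ) else FAST

    truth: dict[str, CellTruth] = {}

    def make_cell(path: str, birth: float, depth: int, state: str,
                  shock: float) -> CellNode:
        cell_id = f"{tree_id}:{path}"
        arrested = False
        if state == SLOW:
            arrested = rng.random() < cfg.p_arrest
            cycle = None if arrested else _draw_slow_cycle(cfg, rng)
        else:
            cycle = _draw_fast_cycle(cfg, rng, depth, family, drift, shock)

        death_time = math.inf
        if cfg.death_hazard_per_min > 0:
            death_time = birth + rng.exponential(1.0 / cfg.death_hazard_per_min)

        division_time = math.inf if cycle is None else birth + cycle
        tracked = max_depth is None or depth < max_depth

        if death_time <= min(division_time, window_end):
            fate, end = Fate.DIED, death_time
        elif tracked and division_time <= window_end:
            fate, end = Fate.DIVIDED, division_time
        elif not tracked:
            # tracking cap: observation of this branch stops at the cell's
            # next event, so a would-divide cell is censored at that event
            # rather than mislabelled as a no-division observation
            fate, end = Fate.CENSORED, min(division_time, window_end)
        else:
            fate, end = Fate.CENSORED, window_end

        gen_abs = cfg.generation_offset + depth
        size_class, cd62l = _phenotype(cfg, state, depth, gen_abs)
        node = CellNode(
            cell_id=cell_id,
            parent_id=None,
            tree_id=tree_id,
            birth_time=birth,
            end_time=end,
            fate=fate,
            generation_offset=cfg.generation_offset,
            depth=depth,
            size_class=size_class,
            cd62l_class=cd62l,
            latent_state=state,
        )
        t_dn_end, t_g1_end = _phase_boundaries(cfg, birth, cycle, state)
        truth[cell_id] = CellTruth(
            cell_id=cell_id, tree_id=tree_id, depth=depth, latent_state=state,
            birth=birth, end=end, fate=fate.value, intended_cycle=cycle,
            t_dn_end=t_dn_end, t_g1_end=min(t_g1_end, math.inf),
            division_shock=shock if state == FAST else None,
        )

        if fate is Fate.DIVIDED:
            child_shock = rng.normal(0.0, math.sqrt(gp.var_division))
            child_gen = gen_abs + 1
            for i in (1, 2):
                child_state = _child_state(cfg, rng, state, child_gen)
                child = make_cell(f"{path}.{i}", end, depth + 1, child_state, child_shock)
                child.parent_id = cell_id
                node.children.append(child)
        return node

    founder_shock = rng.normal(0.0, math.sqrt(gp.var_division))
    root = make_cell("R", founder_birth, 0, founder_state, founder_shock)
    _assign_labels(root)
    tree = LineageTree(
        tree_id=tree_id, well_id=well_id, root=root, imaging_end=window_end
    )
    tree.validate()
    return tree, truth


def simulate_trees(
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
    include_traces: bool = False,
    window_override: float | None = None,
) -> SimulationResult:
    """Simulate ``n_founders`` single-cell wells under one imaging session.

    One imaging window and one frame interval are drawn per call (a shared
    clock, as in a single time-lapse run).  Founders are present at t=0 and
    already cycling; depth is capped at ``config.max_depth`` division
    rounds, beyond which cells are censored.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    window = (
        float(window_override)
        if window_override is not None
        else float(rng.uniform(config.window_lo_min, config.window_hi_min))
    )
    frame = float(rng.uniform(config.frame_lo_min, config.frame_hi_min))

    trees: list[LineageTree] = []
    truth: dict[str, CellTruth] = {}
    for i in range(config.n_founders):
        tid = f"T{i:05d}"
        tree, tr = _grow_tree(
            config, rng, tid, well_id=f"W{i:05d}", founder_birth=0.0,
            window_end=window, max_depth=config.max_depth,
        )
        trees.append(tree)
        truth.update(tr)

    traces: dict[str, FluorescenceTrace] = {}
    if include_traces:
        for tree in trees:
            for node in tree.nodes():
                tr = synthesize_trace(truth[node.cell_id], config, frame, rng)
                if tr is not None:
                    traces[node.cell_id] = tr

    return SimulationResult(
        config=config, trees=trees, traces=traces, truth=truth,
        imaging_end=window, frame_interval=frame,
    )


# ---------------------------------------------------------------------------
# fluorescence traces


def _reporter_curves(
    cfg: SimulationConfig, t: np.ndarray, truth: CellTruth, quiescent: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless piecewise-linear mKO2/mAG intensities at times ``t``.

    Ramps are placed so each channel crosses 20% of its plateau exactly at
    the ground-truth phase boundary.
    """
    if quiescent:
        return np.full_like(t, cfg.ko_high_plateau_au), np.zeros_like(t)
    plateau = cfg.plateau_au
    ko = np.zeros_like(t)
    ag = np.zeros_like(t)

    # mKO2: rise through threshold at t_dn_end, decay through it at t_g1_end
    rise_start = truth.t_dn_end - 0.2 * cfg.rise_min
    ko = np.clip((t - rise_start) / cfg.rise_min, 0.0, 1.0) * plateau
    if math.isfinite(truth.t_g1_end):
        decay_start = truth.t_g1_end - 0.8 * cfg.decay_min
        decay = 1.0 - np.clip((t - decay_start) / cfg.decay_min, 0.0, 1.0)
        ko = np.minimum(ko, decay * plateau)
        # mAG: rise through threshold at t_g1_end, cut at division
        ag_start = truth.t_g1_end - 0.2 * cfg.rise_min
        ag = np.clip((t - ag_start) / cfg.rise_min, 0.0, 1.0) * plateau
    return ko, ag


def synthesize_trace(
    truth: CellTruth,
    config: SimulationConfig,
    frame_interval: float,
    rng: np.random.Generator | None = None,
    *,
    quiescent: bool = False,
) -> FluorescenceTrace | None:
    """Sample one cell's reporter trace on the shared frame clock.

    Returns None for cells alive for fewer than 3 frames.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    first = math.ceil(truth.birth / frame_interval)
    last = math.floor(truth.end / frame_interval)
    t = np.arange(first, last + 1) * frame_interval
    if len(t) < 3:
        return None
    ko, ag = _reporter_curves(config, t, truth, quiescent)
    if config.noise_cv > 0:
        s = math.sqrt(math.log(1.0 + config.noise_cv**2))
        ko = ko * np.exp(rng.normal(0.0, s, size=len(t)))
        ag = ag * np.exp(rng.normal(0.0, s, size=len(t)))
    return FluorescenceTrace(cell_id=truth.cell_id, times=t, ko2=ko, ag=ag)


# ---------------------------------------------------------------------------
# population readouts


def _fucci_state_at(truth: CellTruth, t: float) -> str:
    if t < truth.t_dn_end:
        return "DN"
    if t < truth.t_g1_end:
        return "KO_POS"
    return "AG_POS"


def simulate_cohort(
    config: SimulationConfig,
    observation_times,
    *,
    rng: np.random.Generator | None = None,
    window_override: float | None = None,
) -> tuple[list[PopulationSnapshot], SimulationResult]:
    """Unbounded-depth expansion with quiescent founders and activation lag.

    Founders sit in G0 (mKO2++ mAG-) until ``activation_lag_min``, then
    cycle.  Snapshots list every live cell with its Fucci state, absolute
    generation, CTV intensity and phenotype.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    window = (
        float(window_override)
        if window_override is not None
        else float(rng.uniform(config.window_lo_min, config.window_hi_min))
    )
    lag = min(config.activation_lag_min, window)

    trees: list[LineageTree] = []
    truth: dict[str, CellTruth] = {}
    for i in range(config.n_founders):
        tid = f"T{i:05d}"
        tree, tr = _grow_tree(
            config, rng, tid, well_id=f"W{i:05d}", founder_birth=lag,
            window_end=window, max_depth=None,
        )
        trees.append(tree)
        truth.update(tr)

    result = SimulationResult(
        config=config, trees=trees, traces={}, truth=truth,
        imaging_end=window, frame_interval=float(config.frame_lo_min),
    )

    snapshots = []
    for t in observation_times:
        if not (0 <= t <= window):
            raise ValueError(f"observation time {t} outside [0, {window}]")
        rows = []
        for tree in trees:
            if t < lag:
                root = tree.root
                rows.append(_snapshot_row(config, rng, root.cell_id, 0,
                                          config.generation_offset, "KO_HIGH",
                                          None, None))
                continue
            for node in tree.nodes():
                alive = node.birth_time <= t and (
                    t < node.end_time
                    or (node.end_time == t and node.fate is not Fate.DIVIDED)
                )
                if not alive:
                    continue
                state = _fucci_state_at(truth[node.cell_id], t)
                rows.append(_snapshot_row(
                    config, rng, node.cell_id, node.depth, node.generation_abs,
                    state, node.size_class, node.cd62l_class,
                ))
        cells = pd.DataFrame(
            rows,
            columns=["cell_id", "depth", "generation", "fucci_state",
                     "ctv_au", "ctv_diluted_out", "size_class", "cd62l_class"],
        )
        snapshots.append(PopulationSnapshot(time=float(t), cells=cells))
    return snapshots, result


def _snapshot_row(cfg, rng, cell_id, depth, generation, state, size_class, cd62l):
    ctv = ctv_intensity(generation, cfg, rng=rng)
    return {
        "cell_id": cell_id, "depth": depth, "generation": generation,
        "fucci_state": state, "ctv_au": ctv,
        "ctv_diluted_out": generation >= cfg.ctv_floor_generation,
        "size_class": size_class, "cd62l_class": cd62l,
    }


def ctv_intensity(
    generation: int,
    config: SimulationConfig,
    *,
    rng: np.random.Generator | None = None,
) -> float:
    """Dye intensity after ``generation`` divisions: median halves per
    division, with lognormal spread; beyond the detection floor the value is
    still returned but is flagged indistinguishable from background."""
    if generation < 0:
        raise ValueError("generation must be >= 0")
    median = config.ctv_founder_au / (2.0 ** generation)
    if rng is None or config.ctv_cv == 0:
        return median
    s = math.sqrt(math.log(1.0 + config.ctv_cv**2))
    return float(median * math.exp(rng.normal(0.0, s)))


def ctv_histogram(snapshot: PopulationSnapshot) -> pd.DataFrame:
    """Per-generation CTV intensity summary for one snapshot."""
    if not len(snapshot.cells):
        return pd.DataFrame(columns=["generation", "n", "median_au", "diluted_out"])
    g = snapshot.cells.groupby("generation")
    out = g.agg(
        n=("cell_id", "size"),
        median_au=("ctv_au", "median"),
        diluted_out=("ctv_diluted_out", "any"),
    ).reset_index()
    return out


def brdu_pulse(
    result: SimulationResult,
    t0: float,
    delta: float,
    *,
    activation_lag: float | None = None,
) -> pd.DataFrame:
    """BrdU pulse (t0, t0+delta]: label cells whose S phase overlaps the
    pulse, inherit the label through divisions, and report the labelled
    fraction within each Fucci state among cells alive at harvest.

    S phase is the leading ``f_s`` fraction of each cell's mAG segment.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    cfg = result.config
    harvest = t0 + delta
    lag = cfg.activation_lag_min if activation_lag is None else activation_lag

    labelled: set[str] = set()
    for tree in result.trees:
        for node in tree.nodes():  # pre-order: parents precede children
            tr = result.truth[node.cell_id]
            lab = node.parent_id in labelled if node.parent_id else False
            if not lab and math.isfinite(tr.t_g1_end):
                ag_end = tr.end if tr.fate == "DIVIDED" else min(tr.end, harvest)
                s_end = tr.t_g1_end + cfg.f_s * max(0.0, ag_end - tr.t_g1_end)
                lab = (tr.t_g1_end < harvest) and (s_end > t0) and (
                    min(s_end, harvest) > max(tr.t_g1_end, t0)
                )
            if lab:
                labelled.add(node.cell_id)

    rows = []
    for tree in result.trees:
        for node in tree.nodes():
            alive = node.birth_time <= harvest and (
                harvest < node.end_time
                or (node.end_time == harvest and node.fate is not Fate.DIVIDED)
            )
            if not alive:
                continue
            if harvest < lag and node.is_root:
                state = "KO_HIGH"
            else:
                state = _fucci_state_at(result.truth[node.cell_id], harvest)
            rows.append({"fucci_state": state, "brdu": node.cell_id in labelled})
    df = pd.DataFrame(rows, columns=["fucci_state", "brdu"])
    if not len(df):
        return pd.DataFrame(columns=["fucci_state", "n", "brdu_pos_fraction"])
    out = df.groupby("fucci_state").agg(
        n=("brdu", "size"), brdu_pos_fraction=("brdu", "mean")
    ).reset_index()
    return out


def single_cell_expansion(
    config: SimulationConfig,
    *,
    initial_state: str = FAST,
    horizon: float = 2880.0,
    replicates: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Live-cell count at ``horizon`` for ``replicates`` single founders."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    counts = np.empty(replicates, dtype=int)
    for r in range(replicates):
        tree, _ = _grow_tree(
            config, rng, f"E{r:05d}", well_id=f"E{r:05d}", founder_birth=0.0,
            window_end=horizon, max_depth=None, founder_state=initial_state,
        )
        counts[r] = sum(
            1 for n in tree.nodes()
            if n.fate is Fate.CENSORED or (n.fate is Fate.DIED and n.end_time > horizon)
        )
    return counts
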