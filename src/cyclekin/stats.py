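"""Kinship statistics: cycle-time summaries, Spearman correlation with a
permutation null, division-speed category fractions, mother-to-daughter
inheritance contingency (chi-square), and two-colour synchrony metrics."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .lineage import (
    Fate,
    LineageTree,
    PairSet,
    Relation,
    SpeedCategory,
    SpeedThresholds,
    classify_division_speed,
)

__all__ = [
    "SummaryStats",
    "CorrelationResult",
    "PermutationResult",
    "InheritanceTable",
    "DegenerateTableError",
    "summarize_cycle_times",
    "spearman",
    "permutation_null",
    "category_fractions",
    "inheritance_table",
    "synchrony_metrics",
    "compare_expansion",
]

MOTHER_CATEGORIES = (SpeedCategory.FAST, SpeedCategory.MEDIUM, SpeedCategory.SLOW)
DAUGHTER_CATEGORIES = (
    SpeedCategory.FAST,
    SpeedCategory.MEDIUM,
    SpeedCategory.SLOW,
    SpeedCategory.NO_DIVISION,
)


class DegenerateTableError(ValueError):
    pass


@dataclass(frozen=True)
class SummaryStats:
    mu: float
    sigma: float
    n: int
    unit: str
    degenerate: bool = False


def summarize_cycle_times(values, unit: str) -> SummaryStats:
    """Arithmetic mean and n-1 sample s.d. of durations in the stated unit."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    if np.any(arr < 0):
        raise ValueError("durations must be nonnegative")
    if arr.size == 1:
        return SummaryStats(mu=float(arr[0]), sigma=0.0, n=1, unit=unit, degenerate=True)
    return SummaryStats(
        mu=float(arr.mean()), sigma=float(arr.std(ddof=1)), n=int(arr.size), unit=unit
    )


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    relation: str | None = None
    p_exact: float | None = None


def _pair_values(pairs) -> tuple[np.ndarray, np.ndarray, str | None]:
    if isinstance(pairs, PairSet):
        x, y = pairs.values()
        return np.asarray(x, float), np.asarray(y, float), pairs.relation.value
    x, y = pairs
    return np.asarray(x, float), np.asarray(y, float), None


def _check_margins(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a margin: rho undefined")


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman(pairs, *, exact_max_n: int = 8) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    The two-sided p-value uses the t-distribution approximation; for
    n <= ``exact_max_n`` an exact full-enumeration permutation p-value is
    also computed.
    """
    x, y, relation = _pair_values(pairs)
    _check_margins(x, y)
    rho, p = sps.spearmanr(x, y)
    rho, p = float(rho), float(p)

    p_exact = None
    n = len(x)
    if n <= exact_max_n:
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        observed = abs(_rank_rho(rx, ry))
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rank_rho(rx, ry[list(perm)])) >= observed - 1e-12:
                hits += 1
        p_exact = hits / total
    return CorrelationResult(rho=rho, p_value=p, n=n, relation=relation, p_exact=p_exact)


@dataclass
class PermutationResult:
    observed_rho: float
    null_rhos: np.ndarray = field(repr=False)
    empirical_p: float
    n_perm: int
    seed: int | None


def permutation_null(pairs, n_perm: int = 1000, seed: int | None = 0) -> PermutationResult:
    """Randomization null for the Spearman statistic.

    The second member of every pair is permuted uniformly across pairs,
    destroying kinship structure while preserving both marginals.
    empirical_p = (1 + #{|null| >= |observed|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, y, _ = _pair_values(pairs)
    _check_margins(x, y)
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    observed = _rank_rho(rx, ry)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    null = (pc @ rxc) / np.sqrt((rxc @ rxc) * (pc * pc).sum(axis=1))
    p = (1 + int(np.sum(np.abs(null) >= abs(observed) - 1e-12))) / (n_perm + 1)
    return PermutationResult(
        observed_rho=float(observed), null_rhos=null, empirical_p=float(p),
        n_perm=n_perm, seed=seed,
    )


def _daughter_category(node, thresholds: SpeedThresholds) -> SpeedCategory | None:
    """Speed category of a non-founder cell, or None when uncallable."""
    if node.fate is Fate.DIVIDED:
        return classify_division_speed(node.cycle_time, thresholds)
    if node.fate is Fate.CENSORED:
        return classify_division_speed(node.observed_span, thresholds, divided=False)
    return None


def category_fractions(
    trees: list[LineageTree],
    thresholds: SpeedThresholds = SpeedThresholds(),
) -> pd.DataFrame:
    """Division-speed category fractions of tracked non-founder cells, per
    sorted generation cohort.  Censored cells too short to call NO_DIVISION
    are reported as UNCALLABLE; fractions sum to 1 per cohort."""
    cats = [c.value for c in SpeedCategory] + ["UNCALLABLE"]
    counts: dict[int, dict[str, int]] = {}
    for tree in trees:
        gen = tree.root.generation_offset
        row = counts.setdefault(gen, {c: 0 for c in cats})
        for node in tree.nodes():
            if node.is_root or node.fate is Fate.DIED:
                continue
            cat = _daughter_category(node, thresholds)
            row[cat.value if cat is not None else "UNCALLABLE"] += 1
    rows = []
    for gen in sorted(counts):
        row = counts[gen]
        n = sum(row.values())
        rec = {"generation_offset": gen, "n": n}
        for c in cats:
            rec[c] = row[c] / n if n else float("nan")
        rows.append(rec)
    return pd.DataFrame(rows, columns=["generation_offset", "n"] + cats)


@dataclass
class InheritanceTable:
    counts: pd.DataFrame
    row_fractions: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    n_dyads: int
    low_expected: bool
    side_counts: dict[str, int]
    collapsed: bool = False


def inheritance_table(
    trees: list[LineageTree],
    thresholds: SpeedThresholds = SpeedThresholds(),
    *,
    collapse_daughters: bool = False,
    daughters_per_division: int = 1,
) -> InheritanceTable:
    """Mother speed-category x daughter speed-category contingency table.

    Mothers are non-founder cells with complete observed cycles in
    {FAST, MEDIUM, SLOW}; INTERMEDIATE mothers/daughters are side-counted,
    never silently merged.  Daughters censored before ``no_division_min``
    without dividing are uncallable and excluded.  The chi-square test of
    independence (no continuity correction) runs on non-empty rows/columns;
    with ``collapse_daughters`` the daughter outcome is binarized to
    slow-or-no-division vs other.

    ``daughters_per_division`` defaults to 1: each division contributes one
    mother (its first-listed child, when that child later divides) and one
    callable daughter.  Co-daughters share a division-level shock, so
    entering both sides of every division treats near-duplicate
    observations as independent and inflates the chi-square statistic far
    beyond its nominal null.  Pass 2 to count every dyad instead.
    """
    if daughters_per_division not in (1, 2):
        raise ValueError("daughters_per_division must be 1 or 2")
    dedup = daughters_per_division == 1
    mother_rows = {c.value: {d.value: 0 for d in DAUGHTER_CATEGORIES}
                   for c in MOTHER_CATEGORIES}
    side = {"mother_intermediate": 0, "daughter_intermediate": 0, "uncallable": 0}
    n_dyads = 0
    for tree in trees:
        first_children = {
            n.children[0].cell_id for n in tree.nodes() if n.fate is Fate.DIVIDED
        }
        for node in tree.nodes():
            if node.fate is not Fate.DIVIDED or node.is_root:
                continue
            if dedup and node.cell_id not in first_children:
                continue
            mcat = classify_division_speed(node.cycle_time, thresholds)
            used = 0
            for child in node.children:
                if used >= daughters_per_division:
                    break
                dcat = _daughter_category(child, thresholds)
                if dcat is None:
                    if child.fate is Fate.CENSORED:
                        side["uncallable"] += 1
                    continue
                if mcat is SpeedCategory.INTERMEDIATE:
                    side["mother_intermediate"] += 1
                    used += 1
                    continue
                if dcat is SpeedCategory.INTERMEDIATE:
                    side["daughter_intermediate"] += 1
                    used += 1
                    continue
                mother_rows[mcat.value][dcat.value] += 1
                n_dyads += 1
                used += 1

    counts = pd.DataFrame(mother_rows).T
    counts.index.name = "mother"
    counts.columns.name = "daughter"

    table = counts.copy()
    if collapse_daughters:
        slow = table[SpeedCategory.SLOW.value] + table[SpeedCategory.NO_DIVISION.value]
        other = table[SpeedCategory.FAST.value] + table[SpeedCategory.MEDIUM.value]
        table = pd.DataFrame({"SLOW_OR_NO_DIVISION": slow, "OTHER": other})
        table.index.name = "mother"

    trimmed = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if trimmed.shape[0] < 2:
        raise DegenerateTableError(
            f"only {trimmed.shape[0]} non-empty mother categories"
        )
    if trimmed.shape[1] < 2:
        raise DegenerateTableError("fewer than 2 non-empty daughter outcomes")
    chi2, p, dof, expected = sps.chi2_contingency(trimmed.to_numpy(), correction=False)

    row_sums = counts.sum(axis=1)
    fractions = counts.div(row_sums.replace(0, np.nan), axis=0)
    return InheritanceTable(
        counts=counts,
        row_fractions=fractions,
        chi2=float(chi2),
        df=int(dof),
        p_value=float(p),
        n_dyads=n_dyads,
        low_expected=bool((expected < 5).any()),
        side_counts=side,
        collapsed=collapse_daughters,
    )


def synchrony_metrics(
    trees_a: list[LineageTree],
    trees_b: list[LineageTree],
    *,
    window: float = 60.0,
    seed: int | None = 0,
) -> dict:
    """Two-colour co-culture analysis: same-label sibling division synchrony
    vs cross-label division proximity, plus a non-relative correlation from
    randomly paired cycle times across the two labels."""
    if not trees_a or not trees_b:
        raise ValueError("both populations must be non-empty")

    def _sibling_sync(trees):
        flags = []
        for tree in trees:
            for node in tree.nodes():
                if node.fate is not Fate.DIVIDED:
                    continue
                a, b = node.children
                if a.fate is Fate.DIVIDED and b.fate is Fate.DIVIDED:
                    flags.append(abs(a.end_time - b.end_time) <= window)
        return flags

    def _division_times(trees):
        return sorted(
            n.end_time for t in trees for n in t.nodes() if n.fate is Fate.DIVIDED
        )

    def _cycles(trees):
        return [
            n.cycle_time for t in trees for n in t.nodes()
            if n.fate is Fate.DIVIDED and not n.is_root
        ]

    same_flags = _sibling_sync(trees_a) + _sibling_sync(trees_b)
    if not same_flags:
        raise ValueError("no sibling division pairs to compare")

    # co-culture is emulated by interleaving the two tree sets pairwise into
    # shared wells; cross-label synchrony compares each division in one
    # lineage with the nearest division of the other lineage in its well
    cross_flags = []
    for ta, tb in zip(trees_a, trees_b):
        div_a = _division_times([ta])
        arr_b = np.asarray(_division_times([tb]))
        if not div_a or not len(arr_b):
            continue
        idx = np.searchsorted(arr_b, div_a)
        for t, i in zip(div_a, idx):
            nearest = min(
                abs(t - arr_b[j]) for j in (i - 1, i) if 0 <= j < len(arr_b)
            )
            cross_flags.append(nearest <= window)
    if not cross_flags:
        raise ValueError("no cross-label division events to compare")

    rng = np.random.default_rng(seed)
    ca, cb = _cycles(trees_a), _cycles(trees_b)
    k = min(len(ca), len(cb))
    xa = rng.permutation(ca)[:k]
    xb = rng.permutation(cb)[:k]
    corr = spearman((xa, xb)) if k >= 3 else None

    return {
        "same_label_sync_fraction": float(np.mean(same_flags)),
        "n_same_label_pairs": len(same_flags),
        "cross_label_sync_fraction": float(np.mean(cross_flags)),
        "n_cross_label_pairs": len(cross_flags),
        "cross_label_correlation": corr,
        "window_min": window,
    }


def compare_expansion(counts_a, counts_b, *, alternative: str = "greater"):
    """Mann-Whitney U for simulated single-cell expansion counts (the only
    rank-sum comparison in scope)."""
    u, p = sps.mannwhitneyu(counts_a, counts_b, alternative=alternative)
    return float(u), float(p)
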