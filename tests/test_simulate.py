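import math

import numpy as np
import pandas as pd
import pytest

from cyclekin.config import SimulationConfig
from cyclekin.fucci import FucciGate, segment_trace
from cyclekin.io import tracks_frame
from cyclekin.lineage import Fate, extract_cycle_times
from cyclekin.simulate import (
    CellTruth,
    SimulationResult,
    brdu_pulse,
    ctv_histogram,
    ctv_intensity,
    simulate_cohort,
    simulate_trees,
    single_cell_expansion,
    synthesize_trace,
)
from cyclekin.stats import compare_expansion

from cyclekin.lineage import CellNode, LineageTree, _assign_labels


def deterministic_config(mean_h=12.0, **kw):
    return SimulationConfig(
        gen1_mean_h=mean_h, gen1_sd_h=1e-6, frac_family=0.0, frac_drift=0.0,
        frac_division=0.0, frac_individual=1.0, noise_cv=0.0, **kw
    )


class TestSimulateTrees:
    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=17, n_founders=25)
        a = simulate_trees(cfg, include_traces=True)
        b = simulate_trees(cfg, include_traces=True)
        assert tracks_frame(a.trees).to_csv() == tracks_frame(b.trees).to_csv()
        assert set(a.traces) == set(b.traces)
        for cid in a.traces:
            np.testing.assert_array_equal(a.traces[cid].ko2, b.traces[cid].ko2)
            np.testing.assert_array_equal(a.traces[cid].ag, b.traces[cid].ag)

    def test_generation1_has_no_slow_cells(self):
        res = simulate_trees(SimulationConfig(seed=2, n_founders=50))
        assert all(t.latent_state == "FAST" for t in res.truth.values())

    def test_slow_switch_rate_within_binomial_ci(self):
        cfg = SimulationConfig(seed=4, generation_offset=8, n_founders=1500, p_on=0.3)
        res = simulate_trees(cfg, window_override=20000.0)
        n = k = 0
        for tree in res.trees:
            root = tree.root
            if res.truth[root.cell_id].latent_state != "FAST":
                continue
            if root.fate is not Fate.DIVIDED:
                continue
            for child in root.children:
                n += 1
                k += res.truth[child.cell_id].latent_state == "SLOW"
        assert n >= 1000
        phat = k / n
        half = 2.576 * math.sqrt(0.3 * 0.7 / n)
        assert abs(phat - 0.3) <= half

    def test_tree_conservation_and_validation(self):
        res = simulate_trees(SimulationConfig(seed=9, n_founders=40))
        for tree in res.trees:
            tree.validate()
            nodes = tree.nodes()
            divided = sum(1 for x in nodes if x.fate is Fate.DIVIDED)
            assert len(nodes) == 1 + 2 * divided
            for node in nodes:
                for child in node.children:
                    assert child.birth_time == pytest.approx(node.end_time)
                    assert child.depth == node.depth + 1

    def test_all_end_times_within_window(self):
        res = simulate_trees(SimulationConfig(seed=9, n_founders=40))
        for tree in res.trees:
            for node in tree.nodes():
                assert node.end_time <= res.imaging_end + 1e-9

    def test_phenotype_rules(self):
        res = simulate_trees(
            SimulationConfig(seed=5, generation_offset=8, n_founders=200)
        )
        for tree in res.trees:
            for node in tree.nodes():
                if node.latent_state == "SLOW":
                    assert node.size_class == "SMALL"
                    assert node.cd62l_class == "HI"
                elif node.depth >= 1:
                    assert node.size_class == "LARGE"
                    assert node.cd62l_class == "LO"  # generation >= g_onset

    def test_parameter_recovery_generation1(self):
        cfg = SimulationConfig(seed=1, n_founders=900)
        res = simulate_trees(cfg, window_override=20000.0)
        cyc = pd.concat(
            [extract_cycle_times(t) for t in res.trees], ignore_index=True
        )["cycle_time"] / 60.0
        assert len(cyc) >= 5000
        se = cyc.std(ddof=1) / math.sqrt(len(cyc))
        assert abs(cyc.mean() - 13.4) <= 2 * se * 2.0  # clustered design factor
        assert cyc.std(ddof=1) == pytest.approx(5.4, rel=0.1)


class TestSynthesizeTrace:
    def test_noiseless_roundtrip_exact(self):
        cfg = SimulationConfig(seed=3, n_founders=10, noise_cv=0.0)
        res = simulate_trees(cfg, include_traces=True)
        gate = FucciGate()
        tol = res.frame_interval + 1e-9
        checked = 0
        for cid, trace in res.traces.items():
            truth = res.truth[cid]
            if truth.fate != "DIVIDED":
                continue
            seg = segment_trace(trace, gate)
            assert abs(seg.d_DN - truth.d_dn) <= 2 * tol
            assert abs(seg.d_KO - truth.d_ko) <= 2 * tol
            assert abs(seg.d_AG - truth.d_ag) <= 2 * tol
            checked += 1
        assert checked > 10

    def test_slow_cell_g1_fraction(self):
        cfg = SimulationConfig(seed=6, generation_offset=8, n_founders=150,
                               noise_cv=0.0, p_arrest=0.0)
        res = simulate_trees(cfg, window_override=15000.0)
        fr = [
            t.d_ko / t.intended_cycle
            for t in res.truth.values()
            if t.latent_state == "SLOW" and t.fate == "DIVIDED"
        ]
        assert len(fr) > 30
        # d_KO approximates the configured SLOW G1 fraction of the cycle
        assert np.median(fr) == pytest.approx(0.7, abs=0.05)

    def test_quiescent_trace_constant_ko_high(self):
        cfg = SimulationConfig()
        truth = CellTruth(
            cell_id="q", tree_id="t", depth=0, latent_state="FAST",
            birth=0.0, end=500.0, fate="CENSORED", intended_cycle=None,
            t_dn_end=60.0, t_g1_end=math.inf,
        )
        tr = synthesize_trace(truth, cfg, 3.5, np.random.default_rng(0),
                              quiescent=True)
        assert np.all(tr.ko2 > cfg.ko_high_plateau_au * 0.8)
        assert np.all(tr.ag == 0.0)


class TestCohort:
    def test_quiescent_at_time_zero(self):
        snaps, _ = simulate_cohort(
            SimulationConfig(seed=7, n_founders=30), [0.0], window_override=4200.0
        )
        fr = snaps[0].state_fractions()
        assert fr == {"KO_HIGH": 1.0}
        assert snaps[0].n_live == 30

    def test_mid_expansion_ag_exceeds_ko(self):
        snaps, _ = simulate_cohort(
            SimulationConfig(seed=7, n_founders=40), [3000.0], window_override=4200.0
        )
        fr = snaps[0].state_fractions()
        assert fr.get("AG_POS", 0) + fr.get("DN", 0) > fr.get("KO_POS", 0)

    def test_snapshot_count_matches_live_leaves(self):
        t = 2500.0
        snaps, res = simulate_cohort(
            SimulationConfig(seed=8, n_founders=20), [t], window_override=4200.0
        )
        live = sum(
            1
            for tree in res.trees
            for n in tree.nodes()
            if n.birth_time <= t
            and (t < n.end_time or (n.end_time == t and n.fate is not Fate.DIVIDED))
        )
        assert snaps[0].n_live == live

    def test_observation_time_outside_window(self):
        with pytest.raises(ValueError):
            simulate_cohort(SimulationConfig(seed=1, n_founders=2), [9999999.0])


class TestCtv:
    def test_generation_zero_is_founder_intensity(self):
        cfg = SimulationConfig()
        assert ctv_intensity(0, cfg) == cfg.ctv_founder_au

    def test_three_divisions_eighth_noise_off(self):
        cfg = SimulationConfig(ctv_cv=0.0)
        assert ctv_intensity(3, cfg, rng=np.random.default_rng(0)) == pytest.approx(
            cfg.ctv_founder_au / 8.0
        )

    def test_negative_generation_rejected(self):
        with pytest.raises(ValueError):
            ctv_intensity(-1, SimulationConfig())

    def test_floor_flagged_in_snapshots(self):
        cfg = SimulationConfig(seed=3, generation_offset=8, n_founders=60)
        snaps, _ = simulate_cohort(cfg, [3000.0], window_override=4200.0)
        cells = snaps[0].cells
        assert (cells["ctv_diluted_out"] == (cells["generation"] >= 9)).all()

    def test_median_halves_per_generation(self):
        cfg = SimulationConfig(ctv_cv=0.15)
        rng = np.random.default_rng(11)
        meds = []
        for g in range(5):
            vals = [ctv_intensity(g, cfg, rng=rng) for _ in range(2000)]
            meds.append(np.median(vals))
        for g in range(4):
            assert meds[g] / meds[g + 1] == pytest.approx(2.0, rel=0.1)


def _toy_result(cfg):
    """Hand-built 3-cell tree with pinned phase boundaries."""
    root = CellNode("R", None, "T", 0.0, 600.0, Fate.DIVIDED)
    c1 = CellNode("C1", "R", "T", 600.0, 2000.0, Fate.CENSORED)
    c2 = CellNode("C2", "R", "T", 600.0, 2000.0, Fate.CENSORED)
    root.children = [c1, c2]
    _assign_labels(root)
    tree = LineageTree("T", "W", root, imaging_end=2000.0)
    truth = {
        "R": CellTruth("R", "T", 0, "FAST", 0.0, 600.0, "DIVIDED", 600.0,
                       t_dn_end=60.0, t_g1_end=200.0),
        "C1": CellTruth("C1", "T", 1, "FAST", 600.0, 2000.0, "CENSORED", None,
                        t_dn_end=660.0, t_g1_end=900.0),
        "C2": CellTruth("C2", "T", 1, "FAST", 600.0, 2000.0, "CENSORED", None,
                        t_dn_end=660.0, t_g1_end=1800.0),
    }
    return SimulationResult(config=cfg, trees=[tree], traces={}, truth=truth,
                            imaging_end=2000.0, frame_interval=3.5)


class TestBrdu:
    def test_three_cell_worked_case(self):
        cfg = SimulationConfig(f_s=0.6)
        res = _toy_result(cfg)
        # pulse (300, 500]: R's S phase [200, 440] overlaps; R alive, AG+
        out = brdu_pulse(res, 300.0, 200.0, activation_lag=0.0)
        out = out.set_index("fucci_state")
        assert out.loc["AG_POS", "n"] == 1
        assert out.loc["AG_POS", "brdu_pos_fraction"] == 1.0
        # pulse (1000, 1300]: C1's S [900, 1140] overlaps, C2's S starts 1800
        out = brdu_pulse(res, 1000.0, 300.0, activation_lag=0.0).set_index("fucci_state")
        assert out.loc["AG_POS", "brdu_pos_fraction"] == 1.0   # C1
        assert out.loc["KO_POS", "brdu_pos_fraction"] == 0.0   # C2

    def test_label_inherited_by_daughters(self):
        cfg = SimulationConfig(f_s=0.6)
        res = _toy_result(cfg)
        # pulse (350, 750]: R labelled in S, divides at 600; both daughters
        # inherit and sit in KO_POS at harvest
        out = brdu_pulse(res, 350.0, 400.0, activation_lag=0.0).set_index("fucci_state")
        assert out.loc["KO_POS", "n"] == 2
        assert out.loc["KO_POS", "brdu_pos_fraction"] == 1.0

    def test_arrested_g1_population_never_labelled(self):
        cfg = SimulationConfig(f_s=0.6)
        res = _toy_result(cfg)
        # pulse entirely before any S phase entry
        out = brdu_pulse(res, 0.0, 50.0, activation_lag=0.0)
        assert (out["brdu_pos_fraction"] == 0.0).all()

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            brdu_pulse(_toy_result(SimulationConfig()), 100.0, 0.0)

    def test_monotone_in_delta_and_ag_dominates_early(self):
        cfg = SimulationConfig(seed=13, n_founders=50)
        _, res = simulate_cohort(cfg, [0.0], window_override=4200.0)
        t0 = 2400.0
        prev = None
        for delta in (180.0, 300.0, 480.0):
            out = brdu_pulse(res, t0, delta).set_index("fucci_state")[
                "brdu_pos_fraction"
            ]
            if prev is not None:
                shared = prev.index.intersection(out.index)
                assert (out[shared] >= prev[shared] - 1e-12).all()
            prev = out
        short = brdu_pulse(res, t0, 180.0).set_index("fucci_state")
        assert (
            short.loc["AG_POS", "brdu_pos_fraction"]
            > short.loc["KO_POS", "brdu_pos_fraction"]
        )


class TestExpansion:
    def test_deterministic_twelve_hour_cycles(self):
        counts = single_cell_expansion(
            deterministic_config(), horizon=3000.0, replicates=3,
            rng=np.random.default_rng(0),
        )
        assert list(counts) == [16, 16, 16]

    def test_arrested_founder_stays_single(self):
        cfg = SimulationConfig(seed=1, generation_offset=8, p_arrest=1.0, p_stay=1.0)
        counts = single_cell_expansion(
            cfg, initial_state="SLOW", horizon=2880.0, replicates=5,
            rng=np.random.default_rng(0),
        )
        assert list(counts) == [1] * 5

    def test_slow_founders_expand_less(self):
        cfg = SimulationConfig(seed=7, generation_offset=8)
        fast = single_cell_expansion(cfg, initial_state="FAST", horizon=2880.0,
                                     replicates=200, rng=np.random.default_rng(1))
        slow = single_cell_expansion(cfg, initial_state="SLOW", horizon=2880.0,
                                     replicates=200, rng=np.random.default_rng(2))
        _, p = compare_expansion(fast, slow, alternative="greater")
        assert p < 1e-3
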