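"""Population analyses: optic-disc alignment, the full screen with
exclusion accounting, desensitization split, masking comparison, speed
tuning, clustering, paired condition comparisons."""
import numpy as np
import pandas as pd
import pytest

from premotion import (RetinaGeometry, RunConfig, SimCellParams,
                       align_to_optic_disc, cluster_full_field,
                       condition_comparison, desensitization_split,
                       masking_comparison, run_screen,
                       sensitivity_sweep_central_radius,
                       speed_tuning_analysis)
from premotion.asymmetry import DirectionalResponse, classify_window
from premotion.population import MissingProtocolError
from premotion.simulate import (MovingBarProtocol, StaticBarProtocol,
                                make_population, simulate_protocol,
                                simulate_session)


class TestOpticDiscAlignment:
    def test_translation(self):
        geom = RetinaGeometry.rectangle(4000, 4000, optic_disc=(100.0, 50.0))
        out = align_to_optic_disc([(100.0, 50.0)], geom)
        assert out.loc[0, "x"] == 0.0 and out.loc[0, "y"] == 0.0

    def test_left_eye_mirroring(self):
        geom = RetinaGeometry.rectangle(4000, 4000)
        out = align_to_optic_disc([(-200.0, 300.0)], geom, eye_side="left")
        assert out.loc[0, "x"] == 200.0 and out.loc[0, "y"] == 300.0

    def test_region_labels(self):
        geom = RetinaGeometry.rectangle(4000, 4000)
        out = align_to_optic_disc([(300.0, 300.0), (-300.0, 300.0),
                                   (300.0, -300.0)], geom)
        assert list(out["region"]) == ["temporal-dorsal", "nasal-dorsal",
                                       "other"]


class TestRunScreen:
    def test_empty_recording_empty_report(self, bar_recording):
        import dataclasses
        rec = dataclasses.replace(
            bar_recording, spikes=bar_recording.spikes.iloc[:0],
            ground_truth=())
        res = run_screen(rec, rf_source="ground_truth")
        assert len(res.reports) == 0
        assert len(res.exclusions) == 0

    def test_missing_bar_protocol_aborts(self, geom):
        from premotion.simulate import FullFieldProtocol
        cells = make_population(1, seed=0, geometry=geom)
        rec = simulate_protocol(cells, FullFieldProtocol(), geom, seed=0)
        with pytest.raises(MissingProtocolError):
            run_screen(rec, rf_source="ground_truth")

    def test_exclusion_accounting(self, geom):
        """Every cell lands in exactly one of reports/exclusions, and each
        excluded cell carries a reason string."""
        cells = make_population(4, seed=3, geometry=geom)
        # place one cell too close to the tissue edge
        near_edge = SimCellParams("edge", rf_center=(700.0, 0.0))
        rec = simulate_protocol(cells + [near_edge], MovingBarProtocol(),
                                geom, seed=4)
        res = run_screen(rec, rf_source="ground_truth")
        assert len(res.reports) + len(res.exclusions) == 5
        assert "edge" in set(res.exclusions["cell_id"])
        assert res.exclusions["reason"].str.len().gt(0).all()

    def test_screen_is_seed_deterministic(self, bar_recording):
        a = run_screen(bar_recording, seed=5, rf_source="ground_truth")
        b = run_screen(bar_recording, seed=5, rf_source="ground_truth")
        pd.testing.assert_frame_equal(a.reports, b.reports)

    def test_estimate_mode_screen(self, battery_recording):
        """Full pipeline with STA-estimated RFs, typing and DS flags."""
        res = run_screen(battery_recording, seed=1, rf_source="estimate")
        assert len(res.reports) >= 4
        truth = {c.cell_id: c for c in battery_recording.ground_truth}
        for _, r in res.reports.iterrows():
            gt = truth[r["cell_id"]]
            err = np.hypot(r["x"] - gt.rf_center[0], r["y"] - gt.rf_center[1])
            assert err < 50.0
            assert r["polarity"] == "ON"
        # zone cells detected, symmetric cells not
        for _, r in res.reports.iterrows():
            assert r["pre_asymmetric"] == truth[r["cell_id"]].has_activation_zone


class TestSensitivitySweep:
    def test_zone_absorbed_by_large_central_area(self):
        # deeper tissue so the annulus still exists at a 900 um radius;
        # a stronger zone keeps detection robust under the longer (more
        # baseline-diluted) PRE window that comes with it
        geom = RetinaGeometry.rectangle(2200, 2200)
        cells = make_population(8, seed=7, geometry=geom, frac_az=1.0,
                                az_angle="random", scatter=80.0,
                                az_gain=40.0)
        rec = simulate_protocol(cells, MovingBarProtocol(), geom, seed=8)
        out = sensitivity_sweep_central_radius(rec, [250.0, 350.0, 900.0],
                                               seed=9)
        f250, f350, f900 = out["pre_fraction"]
        # zone (600 +- 2*150 um) lies outside both small radii...
        assert f250 == pytest.approx(f350, abs=0.25)
        assert f350 >= 0.75
        # ...but inside a 900 um Central area
        assert f900 <= 0.2


def _desens_protocol(n_blocks=6, gap=40):
    """Blocks of far bars with an occasional Central flash right before a
    zone probe; alternating blocks probe the zone without any recent
    Central stimulation."""
    bars = ((0.0, 0.0), (0.0, -600.0), (0.0, 900.0))  # central, zone, far
    seq = []
    for b in range(n_blocks):
        seq.extend([2] * gap)
        if b % 2 == 0:
            seq.append(0)
        else:
            seq.append(2)
        seq.append(1)
    return StaticBarProtocol(bars=bars, sequence=tuple(seq))


class TestDesensitizationSplit:
    @pytest.mark.parametrize("strength,lo,hi", [
        (0.0, 0.80, 1.20),
        (0.5, 0.40, 0.68),
    ])
    def test_ratio_tracks_injected_strength(self, geom, strength, lo, hi):
        cells = [SimCellParams(f"c{i}", rf_center=(0.0, 0.0),
                               has_activation_zone=True,
                               desens_strength=strength, desens_tau=20.0)
                 for i in range(4)]
        rec = simulate_protocol(cells, _desens_protocol(n_blocks=16), geom,
                                seed=30 + int(10 * strength))
        ratios = []
        for c in cells:
            out = desensitization_split(
                rec.spikes_of(c.cell_id, 0), rec.trials, c.rf_center,
                pd_deg=0.0, central_radius=350.0, annulus_radius=800.0,
                baseline_rate=c.baseline_rate)
            ratios.append(out["ratio"])
        assert lo <= np.mean(ratios) <= hi

    def test_shuffled_history_breaks_the_split(self, geom):
        """Permuting the previous-trial labels (breaking the history
        covariate) brings the ratio back to ~1 even with desensitization
        on."""
        cell = SimCellParams("c", rf_center=(0.0, 0.0),
                             has_activation_zone=True, desens_strength=0.5,
                             desens_tau=20.0)
        rec = simulate_protocol([cell], _desens_protocol(n_blocks=16), geom,
                                seed=41)
        ratios = []
        for k in range(8):
            out = desensitization_split(
                rec.spikes_of("c", 0), rec.trials, cell.rf_center,
                pd_deg=0.0, central_radius=350.0, annulus_radius=800.0,
                baseline_rate=cell.baseline_rate, shuffle_history_seed=k)
            ratios.append(out["ratio"])
        intact = desensitization_split(
            rec.spikes_of("c", 0), rec.trials, cell.rf_center, pd_deg=0.0,
            central_radius=350.0, annulus_radius=800.0,
            baseline_rate=cell.baseline_rate)
        assert intact["ratio"] < 0.7
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.25)

    def test_too_few_trials_dropped(self, geom):
        cell = SimCellParams("c", has_activation_zone=True)
        proto = StaticBarProtocol(bars=((0.0, 0.0), (0.0, -600.0)),
                                  sequence=(0, 1))
        rec = simulate_protocol([cell], proto, geom, seed=1)
        with pytest.raises(ValueError, match="too few"):
            desensitization_split(rec.spikes_of("c", 0), rec.trials,
                                  cell.rf_center, 0.0, 350.0, 800.0)


@pytest.fixture(scope="session")
def masked_pair(geom):
    mk = dict(rf_center=(0.0, 0.0), has_activation_zone=True, az_angle=0.0)
    cells = [
        SimCellParams("pure_desens", desens_strength=0.8, az_ds_gain=1.0,
                      **mk),
        SimCellParams("inherent_ds", az_ds_gain=2.0, **mk),
        SimCellParams("plain", rf_center=(0.0, 0.0)),
    ]
    unmasked = simulate_protocol(cells, MovingBarProtocol(n_repeats=20),
                                 geom, seed=51)
    masked = simulate_protocol(
        cells, MovingBarProtocol(n_repeats=20, masked=True), geom, seed=52)
    return unmasked, masked


class TestMaskingComparison:
    def test_non_pre_cell_strongly_suppressed(self, masked_pair):
        out = masking_comparison(*masked_pair, seed=1).set_index("cell_id")
        assert out.loc["plain", "central_suppression"] >= 0.95

    def test_mechanism_dissociation(self, masked_pair):
        out = masking_comparison(*masked_pair, seed=1).set_index("cell_id")
        r1 = out.loc["pure_desens", "pd_nd_ratio_masked"]
        r2 = out.loc["inherent_ds", "pd_nd_ratio_masked"]
        assert 0.8 <= r1 <= 1.25
        assert r2 > 1.5
        assert not out.loc["pure_desens", "inherent_ds"]
        assert out.loc["inherent_ds", "inherent_ds"]

    def test_mask_preserves_preferred_direction(self, masked_pair):
        out = masking_comparison(*masked_pair, seed=1).set_index("cell_id")
        assert abs(out.loc["inherent_ds", "delta_pd_mask"]) <= 22.5


class TestSpeedTuning:
    def test_speed_invariant_zone(self, geom):
        cells = make_population(5, seed=61, geometry=geom, frac_az=1.0,
                                az_angle="random")
        per_speed = {}
        for i, v in enumerate([400.0, 600.0, 800.0]):
            rec = simulate_protocol(cells, MovingBarProtocol(speed=v), geom,
                                    seed=62 + i)
            scr = run_screen(rec, seed=63, rf_source="ground_truth")
            per_speed[v] = {
                cid: (scr.responses[cid]["pre"],
                      classify_window(scr.responses[cid]["pre"],
                                      seed=[64, j]))
                for j, cid in enumerate(scr.responses)}
        out = speed_tuning_analysis(per_speed, ref_speed=600.0)
        assert len(out["cells"]) >= 4
        for v in (400.0, 800.0):
            mean_dpd = np.rad2deg(np.angle(np.mean(
                np.exp(1j * np.deg2rad(out["delta_pd"][v])))))
            assert abs(mean_dpd) <= 22.5
        # alignment puts the reference-speed peak at 0 deg
        curves = out["aligned_curves"][600.0]
        assert (np.argmax(curves, axis=1) == 0).mean() >= 0.8

    def test_identical_tuning_gives_friedman_ns(self):
        resp = DirectionalResponse(
            "PRE", np.tile([9, 4, 2, 1, 1, 1, 2, 4], (5, 1)).T, 1.0)
        summ = classify_window(resp, seed=0)
        per_speed = {v: {"c": (resp, summ)}
                     for v in (400.0, 600.0, 800.0, 1000.0)}
        out = speed_tuning_analysis(per_speed)
        assert out["friedman_p"] == pytest.approx(1.0)
        assert all(d == 0 for v in out["delta_pd"] for d in out["delta_pd"][v])


class TestClusterFullField:
    def _archetypes(self, n_copies, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 4, 80)
        shapes = [np.exp(-t / 0.3), np.exp(-t / 2.0),
                  (t < 2).astype(float), np.roll(np.exp(-t / 0.3), 40),
                  np.sin(np.pi * t / 4)]
        x, labels = [], []
        for k, s in enumerate(shapes):
            for _ in range(n_copies):
                x.append(10 * s + noise_sd * 10 * rng.standard_normal(t.size))
                labels.append(k)
        return np.array(x), np.array(labels)

    def test_noiseless_archetypes_exactly_recovered(self):
        x, truth = self._archetypes(20)
        labels, k, info = cluster_full_field(x, k_range=range(2, 8))
        from sklearn.metrics import adjusted_rand_score
        assert k == 5
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_noisy_archetypes_mostly_recovered(self):
        x, truth = self._archetypes(20, noise_sd=0.2, seed=1)
        labels, k, info = cluster_full_field(x, k_range=range(2, 8))
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_single_archetype_degenerate(self):
        x = np.tile(np.exp(-np.linspace(0, 4, 80) / 0.5), (12, 1))
        labels, k, info = cluster_full_field(x, k_range=range(2, 5))
        assert info["degenerate"] or np.isnan(info["silhouette"])

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            cluster_full_field(np.zeros((2, 10)), k_range=range(2, 5))


class TestConditionComparison:
    def test_identical_conditions(self):
        out = condition_comparison([3, 4, 5, 6, 7], [3, 4, 5, 6, 7])
        assert out["p"] == 1.0

    def test_zone_block_reduces_pre_counts(self, geom):
        """Zeroing the activation-zone drive (pharmacology emulation) drops
        PRE counts; a sham repetition (identical parameters, fresh noise)
        does not."""
        cells = make_population(15, seed=71, geometry=geom, frac_az=1.0,
                                az_angle="random")
        blocked = [
            SimCellParams(**{**c.__dict__, "az_gain": 0.0}) for c in cells]
        before = simulate_protocol(cells, MovingBarProtocol(), geom, seed=72)
        after = simulate_protocol(blocked, MovingBarProtocol(), geom,
                                  seed=73)
        sham = simulate_protocol(cells, MovingBarProtocol(), geom, seed=74)
        from premotion import build_windows, direction_spike_counts

        def pre_counts(rec):
            out = []
            for c in cells:
                w = build_windows(c.rf_center, geom, 900.0, 600.0)
                s = rec.spikes_of(c.cell_id, 0)
                pre = direction_spike_counts(s, rec.trials, w, "PRE",
                                             c.rf_center)
                out.append(pre.mean_counts.max())
            return out
        base = pre_counts(before)
        drug = condition_comparison(base, pre_counts(after))
        ctrl = condition_comparison(base, pre_counts(sham))
        assert drug["p"] < 0.05 and drug["mean_after"] < drug["mean_before"]
        assert ctrl["p"] > 0.05

    def test_small_n_warning(self):
        out = condition_comparison([1, 2, 3], [2, 3, 4])
        assert out["small_n"]
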