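"""Retention-time alignment, XIC reconstruction and fold-change recovery."""

import numpy as np
import pandas as pd
import pytest

from lensphos.quant import (
    AlignmentModel,
    FeatureMap,
    IDENTITY_ALIGNMENT,
    QuantConfig,
    apply_alignment,
    build_global_list,
    extract_xic,
    fit_alignment,
    invert_alignment,
    quantify,
    xic_area,
)
from lensphos.synthdata import SimulationConfig, simulate_experiment


def ids_frame(rows):
    return pd.DataFrame(rows, columns=["run_id", "key", "rt", "mz"])


def noiseless_config(seed=5, **overrides):
    base = dict(seed=seed, noise_cv=0.0, rt_slope=1.0, rt_intercept=0.0,
                rt_bumps=(), id_rt_jitter=0.0, dropout=0.0, n_peptides=20)
    base.update(overrides)
    return SimulationConfig(**base)


class TestGlobalList:
    def test_same_peptide_in_two_runs_merges(self):
        entries = build_global_list(ids_frame([
            ("r1", "PEPK|1:Phospho|2", 30.0, 500.0),
            ("r2", "PEPK|1:Phospho|2", 31.0, 500.0)]))
        assert len(entries) == 1
        assert entries[0].run_times == {"r1": 30.0, "r2": 31.0}

    def test_charge_states_stay_separate(self):
        entries = build_global_list(ids_frame([
            ("r1", "RAEFSGECSNLADR|9:Phospho|2", 30.0, 817.84),
            ("r1", "RAEFSGECSNLADR|9:Phospho|3", 30.0, 545.56)]))
        assert len(entries) == 2

    def test_no_duplicates_count(self):
        rng = np.random.default_rng(2)
        rows = [("r1", f"PEP{i}|1:Phospho|2", float(rng.uniform(5, 115)),
                 float(rng.uniform(400, 1600))) for i in range(100)]
        assert len(build_global_list(ids_frame(rows))) == 100

    def test_conflicting_mz_flagged(self):
        entries = build_global_list(ids_frame([
            ("r1", "PEPK|1:Phospho|2", 30.0, 500.0),
            ("r2", "PEPK|1:Phospho|2", 31.0, 500.2)]))
        assert entries[0].flagged


class TestAlignment:
    def test_noiseless_line_recovered(self):
        src = np.linspace(5, 110, 40)
        model = fit_alignment(list(zip(src, 1.05 * src + 2.0)))
        assert model.slope == pytest.approx(1.05, abs=1e-9)
        assert model.intercept == pytest.approx(2.0, abs=1e-9)
        assert all(off == pytest.approx(0.0, abs=1e-9) for *_, off in model.segments)

    def test_segment_bump_recovered(self):
        src = np.linspace(5, 110, 200)
        ref = 1.05 * src + 2.0
        bump = (ref >= 40) & (ref < 60)
        model = fit_alignment(list(zip(src, ref + 0.5 * bump)))
        offsets = {(s, e): o for s, e, o in model.segments}
        assert offsets[(40.0, 50.0)] == pytest.approx(0.5, abs=0.05)
        assert offsets[(50.0, 60.0)] == pytest.approx(0.5, abs=0.05)
        corrected = apply_alignment(model, src)
        assert np.median(np.abs(corrected - (ref + 0.5 * bump))) < 0.05

    def test_two_anchors_interpolate_exactly(self):
        model = fit_alignment([(10.0, 12.0), (50.0, 55.0)])
        assert apply_alignment(model, 10.0) == pytest.approx(12.0, abs=1e-6)
        assert apply_alignment(model, 50.0) == pytest.approx(55.0, abs=1e-6)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            fit_alignment([(10.0, 12.0)])
        with pytest.raises(ValueError):
            fit_alignment([(10.0, 12.0), (10.0, 13.0)])

    def test_identity_model_is_identity(self):
        t = np.array([0.0, 33.3, 119.0])
        assert np.allclose(apply_alignment(IDENTITY_ALIGNMENT, t), t)

    def test_linear_inversion_roundtrip(self):
        model = AlignmentModel(1.05, 2.0)
        t = np.linspace(0, 120, 50)
        assert np.allclose(model.invert_linear(model.linear(t)), t, atol=1e-9)

    def test_times_outside_segments_get_linear_only(self):
        model = AlignmentModel(1.0, 0.0, ((40.0, 60.0, 0.5),))
        assert apply_alignment(model, 50.0) == pytest.approx(50.5)
        assert apply_alignment(model, 130.0) == pytest.approx(130.0)

    def test_simulated_distortions_recovered(self):
        """Slope/intercept/bump grids with jittered anchors: median absolute
        residual after correction stays below 0.1 min."""
        rng = np.random.default_rng(17)
        for slope in (0.95, 1.0, 1.05):
            for intercept in (-2.0, 0.0, 2.0):
                bumps = [(20.0, 30.0, 0.6), (50.0, 60.0, -0.4), (80.0, 90.0, 0.3)]
                src = rng.uniform(5, 110, size=60)
                ref = slope * src + intercept
                for s, e, o in bumps:
                    ref = ref + o * ((ref >= s) & (ref < e))
                jittered = ref + rng.normal(0, 0.05, size=src.size)
                model = fit_alignment(list(zip(src, jittered)))
                residual = apply_alignment(model, src) - ref
                assert np.median(np.abs(residual)) < 0.1


def gaussian_map(amp=1000.0, sigma=0.1, apex=50.0, step=0.01, mz=500.0):
    t = np.arange(apex - 4 * sigma, apex + 4 * sigma + step / 2, step)
    return FeatureMap("r1", "normal", pd.DataFrame({
        "mz": mz, "rt": t, "intensity": amp * np.exp(-0.5 * ((t - apex) / sigma) ** 2)}))


class TestXic:
    def test_single_point_trace(self):
        fmap = FeatureMap("r1", "normal",
                          pd.DataFrame({"mz": [500.0], "rt": [50.0], "intensity": [10.0]}))
        trace = extract_xic(fmap, 500.0, 0.05, (49.0, 51.0))
        assert len(trace) == 1

    def test_gaussian_peak_fully_captured(self):
        fmap = gaussian_map()
        trace = extract_xic(fmap, 500.0, 0.05, (49.0, 51.0))
        assert len(trace) == len(fmap.points)

    def test_window_outside_gradient_rejected(self):
        with pytest.raises(ValueError):
            extract_xic(gaussian_map(), 500.0, 0.05, (130.0, 140.0))
        with pytest.raises(ValueError):
            extract_xic(gaussian_map(), 500.0, 0.05, (51.0, 49.0))

    def test_rectangle_area(self):
        trace = pd.DataFrame({"rt": [10.0, 10.5], "intensity": [200.0, 200.0]})
        assert xic_area(trace) == pytest.approx(100.0)

    def test_gaussian_area_matches_analytic_integral(self):
        trace = extract_xic(gaussian_map(), 500.0, 0.05, (49.0, 51.0))
        expected = 1000.0 * 0.1 * np.sqrt(2 * np.pi)
        assert xic_area(trace) == pytest.approx(expected, rel=0.01)

    def test_empty_trace_area_is_zero(self):
        assert xic_area(pd.DataFrame(columns=["rt", "intensity"])) == 0.0


class TestQuantify:
    def test_identical_runs_give_unit_ratios(self):
        exp = simulate_experiment(noiseless_config(ratio_range=(1.0, 1.0)))
        entries = build_global_list(exp.identifications)
        results = quantify(exp.feature_maps, entries)
        assert results and all(r.fold_change == pytest.approx(1.0, abs=1e-12)
                               for r in results)

    def test_halved_intensity_gives_half_ratio(self):
        exp = simulate_experiment(noiseless_config(ratio_range=(0.5, 0.5)))
        entries = build_global_list(exp.identifications)
        results = quantify(exp.feature_maps, entries)
        assert results and all(r.fold_change == pytest.approx(0.5, rel=1e-9)
                               for r in results)

    def test_invariant_to_point_and_run_order(self):
        exp = simulate_experiment(noiseless_config(ratio_range=(0.25, 4.0)))
        entries = build_global_list(exp.identifications)
        baseline = {r.key: r.fold_change for r in quantify(exp.feature_maps, entries)}
        shuffled = [
            FeatureMap(m.run_id, m.condition,
                       m.points.sample(frac=1.0, random_state=1).reset_index(drop=True),
                       m.gradient)
            for m in reversed(exp.feature_maps)
        ]
        permuted = {r.key: r.fold_change for r in quantify(shuffled, entries)}
        assert permuted == baseline

    def test_cross_assignment_matches_direct_identification(self):
        """On noiseless data a peptide quantifies identically whether its
        identification in the case run is present or masked."""
        exp = simulate_experiment(noiseless_config())
        ids = exp.identifications
        key = ids["key"].iloc[0]
        masked = ids[~((ids["key"] == key) & (ids["run_id"] == "cataract_1"))]
        full = {r.key: r for r in quantify(exp.feature_maps, build_global_list(ids))}
        part = {r.key: r for r in quantify(exp.feature_maps, build_global_list(masked))}
        assert part[key].cross_assigned_runs == ("cataract_1",)
        assert part[key].fold_change == pytest.approx(full[key].fold_change, rel=1e-9)

    def test_missing_condition_rejected(self):
        exp = simulate_experiment(noiseless_config())
        controls = [m for m in exp.feature_maps if m.condition == "normal"]
        with pytest.raises(ValueError, match="cataract"):
            quantify(controls, build_global_list(exp.identifications))

    @pytest.mark.parametrize("cv", [0.05, 0.10, 0.20])
    def test_ratio_recovery_over_noise_grid(self, cv):
        """Known log-uniform ratios in [0.1, 10]: the log2 estimation error is
        centred near zero, and at CV 10% at least 90% of peptides fall within
        a quarter log2 unit of truth."""
        config = SimulationConfig(seed=23, noise_cv=cv, ratio_range=(0.1, 10.0))
        exp = simulate_experiment(config)
        entries = build_global_list(exp.identifications)
        results = quantify(exp.feature_maps, entries)
        errors = np.array([
            np.log2(r.fold_change / exp.ledger.true_ratio(r.key))
            for r in results if r.fold_change is not None])
        assert errors.size >= 40
        assert abs(np.median(errors)) < 0.05
        if cv <= 0.10:
            assert np.mean(np.abs(errors) < 0.25) >= 0.90
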