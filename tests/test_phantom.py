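"""Phantom generator: AIF, residues, geometry, ground truth, noise, treatment."""

import numpy as np
import pytest

from ctperf import (
    AIFParams,
    LesionSpec,
    PhantomSpec,
    TimeGrid,
    add_noise,
    build_phantom,
    compute_relative_maps,
    forward,
    make_aif,
    make_residue,
    simulate_treatment_effect,
)
from ctperf.phantom import residue_area


class TestTimeGrid:
    def test_frame_times(self):
        g = TimeGrid(n_frames=5, dt=1.5, t0=2.0)
        assert np.allclose(g.times, [2.0, 3.5, 5.0, 6.5, 8.0])

    def test_validation(self):
        with pytest.raises(ValueError):
            TimeGrid(n_frames=3)
        with pytest.raises(ValueError):
            TimeGrid(dt=-1.0)


class TestMakeAif:
    def test_zero_before_arrival(self, grid20):
        aif = make_aif(AIFParams(onset=6.0), grid20)
        pre = grid20.times <= 6.0
        assert np.all(aif.values[pre] == 0.0)
        assert np.all(aif.values >= 0) and np.all(np.isfinite(aif.values))

    def test_discrete_peak_near_continuous_peak(self, grid20):
        p = AIFParams()
        aif = make_aif(p, grid20)
        t_disc = grid20.times[np.argmax(aif.values)]
        assert abs(t_disc - p.peak_time) <= grid20.dt

    def test_peak_against_dense_argmax_oracle(self):
        p = AIFParams(alpha=3.0, beta=1.5, onset=4.0)
        grid = TimeGrid(n_frames=200, dt=0.1)
        aif = make_aif(p, grid)
        fine = TimeGrid(n_frames=2000, dt=0.01)
        dense = make_aif(p, fine)
        t_oracle = fine.times[np.argmax(dense.values)]
        t_disc = grid.times[np.argmax(aif.values)]
        assert abs(t_disc - t_oracle) <= 0.1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            AIFParams(amplitude=-1.0)
        with pytest.raises(ValueError):
            AIFParams(beta=np.nan)


class TestMakeResidue:
    def test_box_piecewise_constant(self):
        grid = TimeGrid(n_frames=6, dt=1.0)
        G = make_residue("box", cbf=2.0, mtt=3.0, delay=0.0, grid=grid)
        assert np.array_equal(G, [2, 2, 2, 0, 0, 0])
        assert residue_area(G, grid) == pytest.approx(5.0)  # trapezoid of the samples

    def test_exponential_peak_at_first_frame_after_delay(self):
        grid = TimeGrid(n_frames=30, dt=0.5)
        G = make_residue("exponential", cbf=1.7, mtt=4.0, delay=3.2, grid=grid)
        k = np.argmax(G)
        assert grid.times[k] >= 3.2 and grid.times[k] - 3.2 < 0.5
        assert G.max() == G[k] and np.all(np.diff(G[k:]) <= 0)

    def test_fine_grid_integral_converges(self):
        grid = TimeGrid(n_frames=10001, dt=0.01)
        G = make_residue("exponential", cbf=1.0, mtt=10.0, delay=0.0, grid=grid)
        assert residue_area(G, grid) == pytest.approx(10.0, rel=0.005)

    def test_under_resolved_warns(self):
        grid = TimeGrid(n_frames=10, dt=2.0)
        with pytest.warns(UserWarning, match="under-resolved"):
            make_residue("box", cbf=1.0, mtt=1.0, delay=0.0, grid=grid)

    def test_invalid_rejected(self, grid20):
        with pytest.raises(ValueError):
            make_residue("exponential", cbf=-1.0, mtt=1.0, delay=0.0, grid=grid20)
        with pytest.raises(ValueError):
            make_residue("triangle", cbf=1.0, mtt=1.0, delay=0.0, grid=grid20)


class TestBuildPhantom:
    def test_lesion_free_relative_maps_exactly_100(self):
        spec = PhantomSpec(lesions=())
        data = build_phantom(spec)
        rel = compute_relative_maps(
            data.truth.as_perfusion_maps(spec.consts), data.brain_mask, spec.affected_side
        )
        for name in ("rcbf", "rcbv", "rmtt", "rttp"):
            vals = rel[name][np.isfinite(rel[name])]
            assert vals.size > 0
            assert np.all(vals == 100.0)

    def test_noiseless_series_is_forward_model_of_truth(self, small_phantom):
        C = forward(small_phantom.system, small_phantom.truth.residue)
        assert np.allclose(C, small_phantom.series, atol=1e-12, rtol=0)

    def test_central_volume_identity(self, small_phantom):
        t = small_phantom.truth
        m = t.brain_mask & (t.cbf > 0)
        assert np.allclose(t.mtt[m], 60.0 * t.cbv[m] / t.cbf[m], rtol=1e-9)

    def test_mirror_symmetry_outside_lesions(self, small_phantom):
        labels = small_phantom.truth.labels
        series = small_phantom.series
        normal = labels == 1
        mirrored_normal = normal & normal[::-1]
        assert np.array_equal(series[mirrored_normal], series[::-1][mirrored_normal])

    def test_labels_partition_brain(self, small_phantom):
        labels = small_phantom.truth.labels
        assert set(np.unique(labels)) == {0, 1, 2, 3}
        assert np.array_equal(small_phantom.brain_mask, labels > 0)

    def test_determinism(self, small_spec):
        a = build_phantom(small_spec)
        b = build_phantom(small_spec)
        assert np.array_equal(a.series, b.series)
        assert np.array_equal(a.truth.residue, b.truth.residue)

    def test_severity_recovery(self, default_phantom):
        """Ground-truth relative maps reproduce the requested severities:
        rCBF/rCBV/rMTT to well under 2%, rTTP to the frame-quantization
        bound dt / TTP_normal (the arrival delay is frame-aligned)."""
        spec = default_phantom.spec
        t = default_phantom.truth
        rel = compute_relative_maps(
            t.as_perfusion_maps(spec.consts), t.brain_mask, spec.affected_side
        )
        ttp_norm = np.nanmean(t.ttp[t.labels == 1])
        for les in spec.lesions:
            m = t.labels == les.label
            req = les.severities()
            for key in ("rcbf", "rcbv", "rmtt"):
                realized = np.nanmean(rel[key][m])
                assert realized == pytest.approx(req[key], rel=0.02), (les.kind, key)
            realized_ttp = np.nanmean(rel["rttp"][m])
            bound = 100.0 * spec.time.dt / ttp_norm + 1e-9
            assert abs(realized_ttp - req["rttp"]) <= bound, les.kind

    def test_pi_rcbf_matches_cohort_mean(self, default_phantom):
        """The default penumbra rCBF severity (the cohort's pre-treatment
        mean, 18.37%) is realized on the ground-truth maps within 2%."""
        spec = default_phantom.spec
        t = default_phantom.truth
        rel = compute_relative_maps(
            t.as_perfusion_maps(spec.consts), t.brain_mask, spec.affected_side
        )
        realized = np.nanmean(rel["rcbf"][t.labels == 2])
        assert realized == pytest.approx(18.37, rel=0.02)

    def test_fine_dt_ground_truth_converges_to_nominal(self):
        """The grid-realized gt CBV tends to the nominal class value as dt->0."""
        spec = PhantomSpec(shape=(8, 8, 1), lesions=(), time=TimeGrid(n_frames=601, dt=0.1))
        data = build_phantom(spec)
        gray = data.truth.labels == 1
        cbv_vals = np.unique(np.round(data.truth.cbv[gray], 6))
        assert np.any(np.abs(cbv_vals - spec.gray.cbv) / spec.gray.cbv < 0.02)

    def test_overlapping_lesions_rejected(self, small_spec):
        from dataclasses import replace

        bad = replace(
            small_spec,
            lesions=(
                replace(small_spec.lesions[0], center=(21.0, 14.0, 0.0)),
                small_spec.lesions[1],
            ),
        )
        with pytest.raises(ValueError, match="overlap"):
            build_phantom(bad)

    def test_lesion_outside_grid_rejected(self, small_spec):
        from dataclasses import replace

        bad = replace(
            small_spec,
            lesions=(replace(small_spec.lesions[0], center=(31.0, 16.0, 0.0)),) + small_spec.lesions[1:],
        )
        with pytest.raises(ValueError):
            build_phantom(bad)

    def test_odd_nx_rejected(self):
        with pytest.raises(ValueError, match="even"):
            PhantomSpec(shape=(63, 64, 1))


class TestAddNoise:
    def test_sigma_zero_identity(self, small_phantom):
        out = add_noise(small_phantom.series, 0.0, seed=1)
        assert out is small_phantom.series

    def test_seed_determinism(self, small_phantom):
        a = add_noise(small_phantom.series, 2.0, seed=42)
        b = add_noise(small_phantom.series, 2.0, seed=42)
        assert np.array_equal(a, b)
        c = add_noise(small_phantom.series, 2.0, seed=43)
        assert not np.array_equal(a, c)

    def test_sample_sd_matches_sigma(self):
        clean = np.zeros((50, 50, 1, 50))  # 125000 samples
        noisy = add_noise(clean, 3.0, seed=0)
        assert np.std(noisy - clean) == pytest.approx(3.0, rel=0.02)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros(4), -1.0, seed=0)


class TestSimulateTreatmentEffect:
    def test_zero_recovery_is_identity(self, small_spec):
        assert simulate_treatment_effect(small_spec, 0.0) == small_spec

    def test_full_recovery_normalizes_penumbra_only(self, small_spec):
        post = simulate_treatment_effect(small_spec, 1.0)
        by_kind = {l.kind: l for l in post.lesions}
        assert by_kind["penumbra"].rcbf == 100.0
        assert by_kind["penumbra"].rmtt == 100.0
        assert by_kind["penumbra"].rttp == 100.0
        assert by_kind["penumbra"].rcbv == 100.0
        assert by_kind["core"] == next(l for l in small_spec.lesions if l.kind == "core")

    def test_linear_interpolation(self, small_spec):
        post = simulate_treatment_effect(small_spec, 0.5)
        pi = next(l for l in post.lesions if l.kind == "penumbra")
        assert pi.rcbf == pytest.approx(59.185)  # halfway from 18.37 to 100

    def test_fraction_out_of_range(self, small_spec):
        with pytest.raises(ValueError):
            simulate_treatment_effect(small_spec, 1.5)
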