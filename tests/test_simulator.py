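import numpy as np
import pytest

from contactdiff import (
    add_domain_structure,
    add_tad,
    call_boundaries,
    correlation_score,
    insulation_track,
    make_benchmark,
    make_canvas,
    make_pair,
    mse_score,
    perturb_contrast,
    perturb_intensity,
    perturb_noise,
    perturb_resolution,
    perturb_size,
    perturb_substructure,
    plan_screen,
    sweep,
)


class TestCanvas:
    def test_zero_sd_gives_blank_map(self):
        m = make_canvas(n_bins=32, background_sd=0.0, seed=1)
        assert np.all(m.values == 0)

    def test_seed_determinism(self):
        a = make_canvas(n_bins=64, seed=7)
        b = make_canvas(n_bins=64, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_realized_sd_near_target(self):
        m = make_canvas(n_bins=448, background_sd=0.02, seed=0)
        assert 0.005 <= m.values.std() <= 0.05

    def test_symmetric(self):
        m = make_canvas(n_bins=64, seed=2)
        assert m.is_symmetric()


class TestDomainStructure:
    def test_zero_amplitudes_leave_map_unchanged(self):
        base = make_canvas(n_bins=64, seed=1)
        out = add_tad(base, amplitude=0, boundary_depth=0, loop_amp=0, clip=False)
        assert out.values == pytest.approx(base.values)

    def test_insulation_minima_near_boundaries(self):
        m = add_tad(make_canvas(n_bins=64, seed=5), 0.25, 0.75)
        t = insulation_track(m, window=5)
        vals = np.where(t.defined, t.values, np.inf)
        for b in (16, 48):
            local = np.argmin(vals[b - 4:b + 5]) + b - 4
            assert abs(local - b) <= 2

    def test_boundary_caller_finds_both_boundaries(self):
        m = add_tad(make_canvas(n_bins=64, seed=5), 0.25, 0.75)
        fs = call_boundaries(m)
        assert len(fs) == 2
        assert all(min(abs(b - t) for t in (16, 48)) <= 2 for b in fs.boundaries)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            add_tad(make_canvas(n_bins=32, seed=0), 0.8, 0.2)


class TestPerturbationIdentities:
    def test_null_parameters_are_exact_identities(self):
        base = add_tad(make_canvas(n_bins=64, seed=3))
        sub = add_domain_structure(base, [32])
        for out in [
            perturb_noise(base, 0.0, seed=1),
            perturb_resolution(base, base.bin_size),
            perturb_contrast(base, 1.0),
            perturb_intensity(base, 0.0),
            perturb_size(base, 1.0),
            perturb_substructure(base, sub, 0.0),
        ]:
            assert np.array_equal(out.values, base.values)

    def test_noise_reproducible_and_calibrated(self):
        base = make_canvas(n_bins=448, seed=2)
        a = perturb_noise(base, 0.2, seed=9)
        b = perturb_noise(base, 0.2, seed=9)
        assert np.array_equal(a.values, b.values)
        resid = a.values - base.values
        assert abs(resid.std() - 0.2) / 0.2 <= 0.1


class TestResolution:
    def test_coarse_shape_without_expansion(self):
        base = make_canvas(n_bins=448, seed=1)
        out = perturb_resolution(base, 4096, expand_back=False)
        assert out.n_bins == 224
        assert out.bin_size == 4096

    def test_mean_conserved_on_divisible_shapes(self):
        base = make_canvas(n_bins=448, seed=1)
        for new_bin in (4096, 8192):
            out = perturb_resolution(base, new_bin, expand_back=True)
            assert out.values.mean() == pytest.approx(base.values.mean())
            assert out.n_bins == 448

    def test_expand_back_restores_shape_on_remainders(self):
        base = make_canvas(n_bins=448, seed=1)
        out = perturb_resolution(base, 3 * 2048, expand_back=True)
        assert out.n_bins == 448


class TestContrastIntensity:
    def test_correlation_blind_mse_sensitive(self):
        base = add_tad(make_canvas(n_bins=64, seed=4))
        contrast = make_pair(base, perturb_contrast(base, 1.7))
        intensity = make_pair(base, perturb_intensity(base, 0.15))
        for pair in (contrast, intensity):
            assert correlation_score(pair).aligned == pytest.approx(0.0, abs=1e-12)
        assert mse_score(intensity).aligned == pytest.approx(0.15**2)
        expected = 0.7**2 * np.mean(
            base.values[np.triu_indices(64)] ** 2)
        assert mse_score(contrast).aligned == pytest.approx(expected)


class TestSize:
    def test_shape_preserved(self):
        base = add_tad(make_canvas(n_bins=64, seed=6))
        out = perturb_size(base, 1.1)
        assert out.n_bins == 64

    def test_boundary_position_scales(self):
        base = add_tad(make_canvas(n_bins=128, seed=6), 0.25, 0.75)
        f = 1.1
        out = perturb_size(base, f)
        fs = call_boundaries(out)
        assert len(fs) >= 1
        # the first boundary (bin 32) should move to ~32 * f
        assert min(abs(b - 32 * f) for b in fs.boundaries) <= 3


class TestSubstructure:
    def test_midpoint_blend(self):
        base = add_tad(make_canvas(n_bins=64, seed=3))
        sub = add_domain_structure(base, [32])
        out = perturb_substructure(base, sub, 0.5)
        assert out.values == pytest.approx((base.values + sub.values) / 2)

    def test_full_blend_is_sub_map(self):
        base = add_tad(make_canvas(n_bins=64, seed=3))
        sub = add_domain_structure(base, [32])
        assert np.array_equal(perturb_substructure(base, sub, 1.0).values, sub.values)


class TestSweep:
    def test_parameter_grid_spans_range(self):
        base = make_canvas(n_bins=32, seed=0)
        series = sweep(base, "noise", K=100, seed=1)
        params = [spec.parameter for spec, _ in series]
        assert params == pytest.approx(list(np.linspace(0, 0.2, 100)))

    def test_first_degree_of_contrast_is_identity(self):
        base = add_tad(make_canvas(n_bins=32, seed=0))
        spec, first = sweep(base, "contrast", K=10, seed=1)[0]
        assert spec.parameter == 1.0
        assert np.array_equal(first.values, base.values)

    def test_intensity_mse_strictly_increasing(self):
        base = add_tad(make_canvas(n_bins=32, seed=0))
        scores = [
            mse_score(make_pair(base, pm)).aligned
            for _, pm in sweep(base, "intensity", K=10, seed=1)
        ]
        assert all(b > a for a, b in zip(scores, scores[1:]))


class TestBenchmark:
    def test_pair_counts_and_labels(self):
        pairs = make_benchmark(n=4, negative_kind="noise", seed=0, n_bins=64)
        assert len(pairs) == 8
        assert sum(p.label == "positive" for p in pairs) == 4
        assert sum(p.label == "negative" for p in pairs) == 4

    def test_seed_determinism(self):
        a = make_benchmark(n=2, negative_kind="resolution", seed=11, n_bins=64)
        b = make_benchmark(n=2, negative_kind="resolution", seed=11, n_bins=64)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.map_a.values, pb.map_a.values)
            assert np.array_equal(pa.map_b.values, pb.map_b.values)
            assert pa.provenance == pb.provenance

    def test_positive_partner_loses_middle_boundary_clean_construction(self):
        # well-separated boundaries: the caller sees 3 on the neutral map and
        # 2 after the middle element is removed
        canvas = make_canvas(n_bins=128, seed=9)
        bounds = [30, 64, 98]
        neutral = add_domain_structure(canvas, bounds)
        positive = add_domain_structure(canvas, [bounds[0], bounds[2]])
        assert len(call_boundaries(neutral)) == 3
        assert len(call_boundaries(positive)) == 2

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            make_benchmark(n=0)


class TestScreenPlanner:
    def test_default_record_count(self):
        manifest = plan_screen()
        assert len(manifest) == 22_500
        assert set(manifest["category"].unique()) == {"insertion", "deletion", "random-deletion"}

    def test_one_per_category(self):
        assert len(plan_screen(per_category=1)) == 3

    def test_deterministic_under_seed(self):
        a = plan_screen(per_category=5, seed=3)
        b = plan_screen(per_category=5, seed=3)
        assert a.equals(b)
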