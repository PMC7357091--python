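import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from discmri import phantom
from discmri.phantom import (
    CohortConfig,
    ConfigurationError,
    GeometryError,
    build_cohort,
    default_grade_probabilities,
    make_fieldmap,
    rasterize_subject,
    simulate_dixon,
    simulate_multiecho,
    simulate_t2w,
)

from conftest import single_disc, uniform_tables


class TestBuildCohort:
    def test_default_cohort_counts(self):
        discs = build_cohort(CohortConfig(seed=0))
        assert len(discs) == 606
        assert len({d.subject_id for d in discs}) == 101
        by_group = {}
        for d in discs:
            by_group[d.group] = by_group.get(d.group, 0) + 1
        assert by_group == {"sedentary": 144, "cyclist": 132, "jogger": 180, "runner": 150}

    def test_degenerate_draw_equals_means(self):
        tables = phantom.default_parameter_tables()
        tables = dataclasses.replace(
            tables,
            nucleus_by_grade={m: (v[0], (0.0,) * 4) for m, v in tables.nucleus_by_grade.items()},
            ratio_by_grade={m: (v[0], (0.0,) * 4) for m, v in tables.ratio_by_grade.items()},
        )
        cfg = CohortConfig(
            subjects_per_group=(1, 0, 0, 0),
            levels=("L4/L5",),
            grade_probabilities={g: (1.0, 0, 0, 0) for g in phantom.GROUPS},
            parameter_tables=tables,
            group_effects=False,
            seed=7,
        )
        (disc,) = build_cohort(cfg)
        assert disc.pfirrmann_grade == 1
        assert disc.t2_nucleus == pytest.approx(166.0)
        assert disc.t2_annulus == pytest.approx(166.0 / 1.8)
        assert disc.water_pct_nucleus == pytest.approx(87.2)

    def test_grade_marginals_within_multinomial_envelope(self):
        # oracle: per-grade marginal of a multinomial is binomial(n, p_g)
        discs = build_cohort(CohortConfig(seed=0))
        counts = np.bincount([d.pfirrmann_grade for d in discs], minlength=5)[1:]
        probs = default_grade_probabilities()
        n = len(discs)
        for count, p in zip(counts, probs):
            lo, hi = sps.binom.interval(0.95, n, p)
            assert lo <= count <= hi

    def test_reproducible_for_fixed_seed(self):
        a = build_cohort(CohortConfig(seed=3))
        b = build_cohort(CohortConfig(seed=3))
        assert [vars(x) for x in a] == [vars(y) for y in b]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"subjects_per_group": (-1, 0, 0, 0)},
            {"grade_probabilities": {g: (0.5, 0.5, 0.5, -0.5) for g in phantom.GROUPS}},
            {"grade_probabilities": {g: (0.2, 0.2, 0.2, 0.2) for g in phantom.GROUPS}},
            {"sd_vs_sem": "nonsense"},
        ],
    )
    def test_configuration_errors(self, kwargs):
        with pytest.raises(ConfigurationError):
            build_cohort(CohortConfig(**kwargs))

    def test_all_water_percent_in_range(self):
        discs = build_cohort(CohortConfig(seed=11))
        for d in discs:
            assert 0.0 <= d.water_pct_nucleus <= 100.0
            assert 0.0 <= d.water_pct_annulus <= 100.0
            assert d.t2_nucleus > 0 and d.t2_annulus > 0


class TestRasterize:
    def test_nucleus_on_all_disc_slices(self, single_disc_phantom):
        discs, labels, _, _ = single_disc_phantom
        nuc, _ = labels.compartments[discs[0].disc_id]
        for z in range(discs[0].slice_start, discs[0].slice_stop):
            assert np.count_nonzero(labels.data[z] == nuc) > 0

    def test_two_stacked_discs_disjoint(self):
        cfg = CohortConfig(
            subjects_per_group=(1, 0, 0, 0), levels=("L3/L4", "L4/L5"), uniform_discs=True, seed=0
        )
        discs = build_cohort(cfg)
        labels = rasterize_subject(discs, phantom.multiecho_params())
        m0 = labels.disc_mask(discs[0].disc_id)
        m1 = labels.disc_mask(discs[1].disc_id)
        assert not np.any(m0 & m1)

    def test_six_levels_by_exhaustive_census(self):
        discs = build_cohort(
            CohortConfig(subjects_per_group=(1, 0, 0, 0), uniform_discs=True, seed=0)
        )
        labels = rasterize_subject(discs, phantom.multiecho_params())
        codes = set(np.unique(labels.data)) - {0, 1}
        # brute-force scan: each disc contributes one nucleus + one annulus code
        assert len(codes) == 12
        assert len(labels.compartments) == 6
        for nuc, ann in labels.compartments.values():
            assert nuc in codes and ann in codes

    def test_out_of_fov_raises(self):
        cfg = CohortConfig(
            subjects_per_group=(1, 0, 0, 0), levels=("L4/L5",), disc_ap_width=200.0
        )
        discs = build_cohort(cfg)
        with pytest.raises(GeometryError):
            rasterize_subject(discs, phantom.multiecho_params())

    def test_overlapping_discs_raise(self):
        cfg = CohortConfig(
            subjects_per_group=(1, 0, 0, 0),
            levels=("L3/L4", "L4/L5"),
            disc_row_spacing=2.0,
        )
        discs = build_cohort(cfg)
        with pytest.raises(GeometryError):
            rasterize_subject(discs, phantom.multiecho_params())


class TestSimulateMultiecho:
    def test_noiseless_signal_value(self):
        discs, labels, _, params = single_disc(t2=100.0)
        d = dataclasses.replace(discs[0], t2_nucleus=100.0, t2_annulus=100.0,
                                pd_nucleus=1000.0, pd_annulus=1000.0)
        stack = simulate_multiecho(labels, [d], params, noise_sigma=0.0)
        nuc, _ = labels.compartments[d.disc_id]
        voxel = np.argwhere(labels.data == nuc)[0]
        expected = 1000.0 * np.exp(-15.75 / 100.0)
        assert stack.volumes[(0, *voxel)] == pytest.approx(expected, rel=1e-12)

    def test_noiseless_strictly_decreasing(self, single_disc_phantom):
        discs, labels, _, params = single_disc_phantom
        stack = simulate_multiecho(labels, discs, params, noise_sigma=0.0)
        in_disc = labels.disc_mask(discs[0].disc_id)
        sig = stack.volumes[:, in_disc]
        assert np.all(np.diff(sig, axis=0) < 0)

    def test_background_rayleigh_mean(self, rng):
        # oracle: Monte-Carlo draws of |sigma*(g1 + i g2)| vs sigma*sqrt(pi/2)
        discs, labels, _, params = single_disc()
        sigma = 20.0
        stack = simulate_multiecho(labels, discs, params, noise_sigma=sigma, seed=5)
        background = labels.data == 0
        measured = stack.volumes[0][background].mean()
        mc = np.abs(sigma * (rng.normal(size=100_000) + 1j * rng.normal(size=100_000))).mean()
        expected = sigma * np.sqrt(np.pi / 2)
        assert measured == pytest.approx(expected, rel=0.02)
        assert mc == pytest.approx(expected, rel=0.02)

    def test_seed_determinism(self, single_disc_phantom):
        discs, labels, _, params = single_disc_phantom
        a = simulate_multiecho(labels, discs, params, noise_sigma=10.0, seed=9)
        b = simulate_multiecho(labels, discs, params, noise_sigma=10.0, seed=9)
        assert np.array_equal(a.volumes, b.volumes)

    def test_nonnegative_magnitudes(self, single_disc_phantom):
        discs, labels, _, params = single_disc_phantom
        stack = simulate_multiecho(labels, discs, params, noise_sigma=15.0, seed=2)
        assert np.all(stack.volumes >= 0)


class TestSimulateT2w:
    def test_noiseless_value(self):
        discs, labels, _, _ = single_disc()
        d = dataclasses.replace(discs[0], t2_nucleus=100.0, t2_annulus=100.0,
                                pd_nucleus=1000.0, pd_annulus=1000.0)
        params = phantom.t2w_params()
        image = simulate_t2w(labels, [d], params)
        nuc, _ = labels.compartments[d.disc_id]
        voxel = np.argwhere(labels.data == nuc)[0]
        assert image.data[tuple(voxel)] == pytest.approx(1000.0 * np.exp(-0.70), rel=1e-12)

    def test_doubling_t2_increases_signal(self):
        discs, labels, _, _ = single_disc()
        params = phantom.t2w_params()
        base = simulate_t2w(labels, discs, params)
        doubled = [
            dataclasses.replace(d, t2_nucleus=2 * d.t2_nucleus, t2_annulus=2 * d.t2_annulus)
            for d in discs
        ]
        out = simulate_t2w(labels, doubled, params)
        in_disc = labels.disc_mask(discs[0].disc_id)
        assert np.all(out.data[in_disc] > base.data[in_disc])

    def test_grade1_nucleus_brighter_than_annulus(self):
        # grade-1-style contrast: nucleus T2w-SI 551 vs annulus 551/3.7
        cfg = CohortConfig(
            subjects_per_group=(1, 0, 0, 0),
            levels=("L4/L5",),
            grade_probabilities={g: (1.0, 0, 0, 0) for g in phantom.GROUPS},
            parameter_tables=dataclasses.replace(
                phantom.default_parameter_tables(),
                nucleus_by_grade={
                    m: (v[0], (0.0,) * 4)
                    for m, v in phantom.default_parameter_tables().nucleus_by_grade.items()
                },
                ratio_by_grade={
                    m: (v[0], (0.0,) * 4)
                    for m, v in phantom.default_parameter_tables().ratio_by_grade.items()
                },
            ),
            group_effects=False,
            seed=0,
        )
        discs = build_cohort(cfg)
        labels = rasterize_subject(discs, phantom.multiecho_params())
        image = simulate_t2w(labels, discs, phantom.t2w_params())
        nuc, ann = labels.compartments[discs[0].disc_id]
        # oracle: direct voxel means over the two label masks
        nuc_mean = image.data[labels.data == nuc].mean()
        ann_mean = image.data[labels.data == ann].mean()
        assert nuc_mean > ann_mean
        assert nuc_mean == pytest.approx(551.0, rel=1e-9)


class TestSimulateDixon:
    def test_pure_water_zero_field_collapses(self):
        discs, labels, _, _ = single_disc(water_pct=100.0)
        params = phantom.dixon_params()
        fm = phantom.FieldMap(np.zeros(params.shape))
        data = simulate_dixon(labels, discs, fm, params)
        in_disc = labels.disc_mask(discs[0].disc_id)
        w = discs[0].pd_nucleus  # W amplitude: pd * 100%
        assert np.allclose(data.echo1[in_disc].imag, 0.0, atol=1e-9)
        assert np.allclose(data.echo2[in_disc].imag, 0.0, atol=1e-9)
        s1 = data.echo1[labels.data == labels.compartments[discs[0].disc_id][0]]
        assert np.allclose(s1.real, w, rtol=1e-12)

    def test_opposed_phase_cancellation(self):
        # c(TE) = -1 at TE = 1/(2 |f_fat|); with W = F the first echo vanishes
        discs, labels, _, _ = single_disc(water_pct=50.0)
        te1 = 1000.0 / (2 * 434.0)  # ms
        params = phantom.dixon_params(n_slices=12)
        params = dataclasses.replace(params, echo_times=(te1, 2 * te1))
        fm = phantom.FieldMap(np.zeros(params.shape))
        data = simulate_dixon(labels, discs, fm, params, fat_shift_hz=-434.0)
        in_disc = labels.disc_mask(discs[0].disc_id)
        assert np.allclose(np.abs(data.echo1[in_disc]), 0.0, atol=1e-9)

    def test_matches_literal_model_formula(self):
        # oracle: independent literal evaluation of the closed-form model
        discs, labels, _, _ = single_disc(water_pct=87.0)
        d = dataclasses.replace(discs[0], pd_nucleus=100.0, pd_annulus=100.0,
                                water_pct_nucleus=87.0, water_pct_annulus=87.0)
        params = phantom.dixon_params()
        psi = np.full(params.shape, 50.0)
        data = simulate_dixon(labels, [d], phantom.FieldMap(psi), params)
        in_disc = labels.disc_mask(d.disc_id)
        W, F = 87.0, 13.0
        for te_ms, echo in zip(params.echo_times, (data.echo1, data.echo2)):
            te = te_ms * 1e-3
            c = np.exp(2j * np.pi * (-434.0) * te)
            expected = (W + c * F) * np.exp(2j * np.pi * 50.0 * te)
            assert np.allclose(echo[in_disc], expected, rtol=1e-12)

    def test_fieldmap_peak_and_warning(self, caplog):
        fm = make_fieldmap((8, 16, 16), max_abs_hz=60.0, smoothness_vox=3.0, seed=2)
        assert np.abs(fm.psi_hz).max() == pytest.approx(60.0)
        discs, labels, _, _ = single_disc()
        params = phantom.dixon_params()
        alias = 1000.0 / (2 * (params.echo_times[1] - params.echo_times[0]))
        big = phantom.FieldMap(np.full(params.shape, alias * 1.5))
        with caplog.at_level("WARNING"):
            simulate_dixon(labels, discs, big, params)
        assert any("aliasing" in rec.message for rec in caplog.records)
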