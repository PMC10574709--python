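"""Bucketing, TMS normalization, scaling and the stratified split."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrpattern import (BucketConfig, CohortDesign, Spectrum, assemble_table,
                        bucket_edges, bucket_spectrum, normalize_to_tms,
                        apply_scaling, scale_columns, simulate_cohort,
                        split_train_test)
from nmrpattern.io import (read_bucket_table, read_jcamp, read_spectrum_csv,
                           write_bucket_table, write_spectrum_csv)
from nmrpattern.synthetic import _lorentzian


def _flat_spectrum(height=2.0, n=4001):
    ppm = np.linspace(-0.5, 10.5, n)
    return Spectrum(ppm=ppm, intensity=np.full(n, height), sample_id="flat", label="x")


class TestBucketing:
    def test_default_range_gives_200_buckets(self):
        b = bucket_spectrum(_flat_spectrum())
        assert b.shape == (200,)
        edges = bucket_edges()
        # V1 at the high-ppm end, V186 in the saponin methyl region
        assert edges[0] == pytest.approx((9.925, 9.975))
        assert edges[185] == pytest.approx((0.675, 0.725))

    def test_constant_spectrum_integrates_to_height_times_width(self):
        b = bucket_spectrum(_flat_spectrum(height=3.0))
        np.testing.assert_allclose(b, 3.0 * 0.05, rtol=1e-12)

    def test_narrow_peak_at_0p70_lands_in_V186(self):
        ppm = np.linspace(-0.5, 10.5, 60001)
        inten = _lorentzian(ppm, 0.70, 0.004, 1.0)
        sp = Spectrum(ppm=ppm, intensity=inten, sample_id="pk", label="x")
        b = bucket_spectrum(sp)
        assert int(np.argmax(b)) == 185  # V186, [0.675, 0.725] ppm
        # quadrature oracle: analytic Lorentzian area over the bucket
        lo, hi = bucket_edges()[185]
        expected = 0.004 * (np.arctan((hi - 0.70) / 0.004) - np.arctan((lo - 0.70) / 0.004))
        np.testing.assert_allclose(b[185], expected, rtol=1e-4)

    def test_grid_coverage_enforced(self):
        ppm = np.linspace(0.5, 9.0, 1000)
        sp = Spectrum(ppm=ppm, intensity=np.ones(1000), sample_id="s", label="x")
        with pytest.raises(ValueError, match="cover"):
            bucket_spectrum(sp)

    def test_width_must_tile_range(self):
        with pytest.raises(ValueError, match="tile"):
            bucket_spectrum(_flat_spectrum(), width=0.037)

    def test_descending_grid_equivalent(self):
        sp = _flat_spectrum()
        rev = Spectrum(ppm=sp.ppm[::-1], intensity=sp.intensity[::-1],
                       sample_id="r", label="x")
        np.testing.assert_allclose(bucket_spectrum(sp), bucket_spectrum(rev), rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_additivity_and_total_integral(self, seed):
        """Buckets are linear in the intensity and sum to the full-range
        trapezoid integral."""
        rng = np.random.default_rng(seed)
        ppm = np.linspace(-0.5, 10.5, 2201)
        y1 = rng.normal(size=ppm.size) ** 2
        y2 = rng.normal(size=ppm.size) ** 2
        s1 = Spectrum(ppm=ppm, intensity=y1, sample_id="a", label="x")
        s2 = Spectrum(ppm=ppm, intensity=y2, sample_id="b", label="x")
        s12 = Spectrum(ppm=ppm, intensity=y1 + y2, sample_id="c", label="x")
        np.testing.assert_allclose(bucket_spectrum(s12),
                                   bucket_spectrum(s1) + bucket_spectrum(s2),
                                   rtol=1e-9, atol=1e-12)
        from nmrpattern.preprocess import _cumulative_integral_at
        total = (_cumulative_integral_at(ppm, y1, np.array([9.975]))
                 - _cumulative_integral_at(ppm, y1, np.array([-0.025])))[0]
        np.testing.assert_allclose(bucket_spectrum(s1).sum(), total, rtol=1e-9)


class TestNormalization:
    def test_scalar_division(self):
        edges = [(0.05, 0.10), (-0.025, 0.025)]
        out = normalize_to_tms(np.array([1.0, 2.0]), edges)
        np.testing.assert_allclose(out, [0.5, 1.0])

    def test_idempotent(self):
        edges = [(0.05, 0.10), (-0.025, 0.025)]
        v = normalize_to_tms(np.array([3.0, 2.0]), edges)
        np.testing.assert_array_equal(normalize_to_tms(v, edges), v)

    def test_missing_reference_rejected(self):
        edges = [(0.05, 0.10), (-0.025, 0.025)]
        with pytest.raises(ValueError, match="reference peak missing"):
            normalize_to_tms(np.array([1.0, 0.0]), edges)

    def test_global_intensity_scale_invariance_noise_free(self):
        """Scaling whole spectra (receiver gain) leaves the normalized table
        unchanged — the purpose of TMS normalization."""
        means = {"A": {"sweroside": 1.0}, "B": {"macranthoidin A": 1.0}}
        d = CohortDesign(class_sizes={"A": 2, "B": 2}, concentration_means=means,
                         noise_sd=0.0, seed=4)
        spectra = simulate_cohort(d)
        doubled = [Spectrum(ppm=sp.ppm, intensity=2.0 * sp.intensity,
                            sample_id=sp.sample_id, label=sp.label) for sp in spectra]
        t1 = assemble_table(spectra)
        t2 = assemble_table(doubled)
        np.testing.assert_allclose(t1.values, t2.values, rtol=1e-9, atol=1e-12)


class TestAssembleTable:
    def test_full_cohort_shape(self, species_table):
        assert species_table.values.shape == (100, 200)
        assert species_table.variable_names[0] == "V1"
        assert species_table.variable_names[-1] == "V200"
        # every row's TMS bucket is exactly 1
        tms_col = species_table.variable_names.index("V200")
        np.testing.assert_array_equal(species_table.values[:, tms_col], 1.0)

    def test_identical_spectra_identical_rows(self):
        d = CohortDesign(class_sizes={"A": 1}, concentration_means={"A": {"sweroside": 1.0}},
                         noise_sd=0.0, seed=1)
        sp = simulate_cohort(d)[0]
        table = assemble_table([sp, sp])
        np.testing.assert_array_equal(table.values[0], table.values[1])

    def test_requires_two_spectra(self):
        sp = _flat_spectrum()
        with pytest.raises(ValueError, match="two spectra"):
            assemble_table([sp])

    def test_exclude_windows_drops_buckets(self):
        d = CohortDesign(class_sizes={"A": 2}, concentration_means={"A": {}}, seed=0)
        cfg = BucketConfig(exclude_windows=((3.28, 3.35),))  # residual CD3OD region
        table = assemble_table(simulate_cohort(d), cfg)
        assert table.n_buckets < 200
        assert all(hi <= 3.28 or lo >= 3.35 for lo, hi in table.bucket_edges)

    def test_csv_round_trip(self, tmp_path, small_table):
        path = tmp_path / "table.csv"
        write_bucket_table(small_table, path)
        back = read_bucket_table(path)
        np.testing.assert_allclose(back.values, small_table.values, rtol=0, atol=1e-12)
        assert back.labels == small_table.labels
        assert back.bucket_edges == pytest.approx(small_table.bucket_edges)


class TestScaling:
    def test_uv_gives_unit_variance(self, rng):
        X = rng.normal(size=(30, 5)) * np.array([1, 10, 0.1, 3, 7])
        Xs, rec = scale_columns(X, "uv")
        np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, rtol=1e-10)
        np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-12)

    def test_center_symmetric_rows(self):
        X = np.array([[1.0, 4.0], [3.0, 8.0]])
        Xs, _ = scale_columns(X, "center")
        np.testing.assert_allclose(Xs[0], -Xs[1])
        np.testing.assert_allclose(Xs[1], [1.0, 2.0])

    def test_pareto_identity(self, rng):
        """pareto == uv followed by multiplication with sqrt(sd)."""
        X = rng.normal(size=(25, 4)) * np.array([2, 5, 0.5, 9])
        Xp, _ = scale_columns(X, "pareto")
        Xu, rec = scale_columns(X, "uv")
        sd = X.std(axis=0, ddof=1)
        np.testing.assert_allclose(Xp, Xu * np.sqrt(sd), rtol=1e-10)

    def test_zero_variance_column_warns_and_passes_centered(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            Xs, rec = scale_columns(X, "uv")
        np.testing.assert_array_equal(Xs[:, 0], 0.0)

    def test_apply_scaling_matches_fit(self, rng):
        X = rng.normal(size=(20, 6))
        Xs, rec = scale_columns(X, "uv")
        np.testing.assert_allclose(apply_scaling(X, rec), Xs, rtol=1e-12)
        with pytest.raises(ValueError, match="column count"):
            apply_scaling(X[:, :3], rec)


class TestSplit:
    def test_study_split_counts(self, species_table):
        part = split_train_test(species_table, {"cLJF": 47, "wLJF": 6, "LF": 8}, seed=1)
        assert len(part.train_indices) == 61
        assert len(part.test_indices) == 39
        assert part.stratum_counts == {"cLJF": (47, 30), "wLJF": (6, 4), "LF": (8, 5)}

    def test_deterministic(self, species_table):
        a = split_train_test(species_table, {"cLJF": 47, "wLJF": 6, "LF": 8}, seed=5)
        b = split_train_test(species_table, {"cLJF": 47, "wLJF": 6, "LF": 8}, seed=5)
        np.testing.assert_array_equal(a.train_indices, b.train_indices)

    def test_empty_test_needs_flag(self, small_table):
        counts = {lab: small_table.labels.count(lab) for lab in set(small_table.labels)}
        with pytest.raises(ValueError, match="empty test set"):
            split_train_test(small_table, counts, seed=0)
        part = split_train_test(small_table, counts, seed=0, allow_empty_test=True)
        assert len(part.test_indices) == 0

    def test_infeasible_counts_rejected(self, small_table):
        with pytest.raises(ValueError, match="requested"):
            split_train_test(small_table, {"cLJF": 10_000}, seed=0)


class TestSpectrumIO:
    def test_csv_round_trip(self, tmp_path):
        d = CohortDesign(class_sizes={"A": 1}, concentration_means={"A": {"sweroside": 1.0}},
                         seed=2)
        sp = simulate_cohort(d)[0]
        path = tmp_path / "s.csv"
        write_spectrum_csv(sp, path)
        back = read_spectrum_csv(path, label="A")
        # the format quantizes ppm and intensity to 6 significant digits
        np.testing.assert_allclose(back.intensity, sp.intensity, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(bucket_spectrum(back), bucket_spectrum(sp),
                                   rtol=2e-3, atol=1e-8)

    def test_jcamp_reader_matches_csv(self, tmp_path):
        ppm = np.linspace(-0.5, 10.5, 41)
        inten = np.round(np.linspace(0, 4, 41) ** 2, 4)
        lines = ["##TITLE=synthetic test block", "##JCAMP-DX=4.24",
                 "##XUNITS=PPM", "##YUNITS=ARBITRARY",
                 f"##FIRSTX={ppm[0]}", f"##LASTX={ppm[-1]}", "##NPOINTS=41",
                 "##XYDATA=(X++(Y..Y))"]
        for i in range(0, 41, 5):
            chunk = inten[i:i + 5]
            lines.append(" ".join([f"{ppm[i]:.6f}"] + [f"{v:.4f}" for v in chunk]))
        lines.append("##END=")
        path = tmp_path / "s.jdx"
        path.write_text("\n".join(lines))
        sp = read_jcamp(path)
        np.testing.assert_allclose(sp.ppm, ppm, atol=1e-9)
        np.testing.assert_allclose(sp.intensity, inten, atol=1e-9)

    def test_jcamp_requires_ppm_units(self, tmp_path):
        path = tmp_path / "bad.jdx"
        path.write_text("##XUNITS=HZ\n##XYDATA=(X++(Y..Y))\n0 1 2\n##END=\n")
        with pytest.raises(ValueError, match="PPM"):
            read_jcamp(path)
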