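import io

import numpy as np
import pytest

from bodycomp import (
    BIOMARKER_NAMES,
    Cohort,
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    inject_missingness,
)
from bodycomp.synthetic_cohort import (
    BILATERAL_PAIRS,
    CohortSpecError,
    _nearest_correlation_fixed,
)


class TestSpec:
    def test_default_spec_calibration(self, default_spec):
        assert default_spec.group_sizes == {"male": 245, "female": 270}
        assert len(default_spec.biomarker_names) == 44
        assert default_spec.marginals["male"]["ALM"] == (21.88, 7.95)
        assert default_spec.marginals["female"]["ALM"] == (15.77, 4.24)
        assert default_spec.marginals["female"]["BFP"] == (34.71, 7.37)
        assert default_spec.marginals["male"]["BMD"] == (1.07, 0.19)

    def test_bilateral_pairs_are_left_right(self):
        assert len(BILATERAL_PAIRS) == 14
        for left, right in BILATERAL_PAIRS:
            assert left in BIOMARKER_NAMES and right in BIOMARKER_NAMES
            assert right == left.replace("left", "right")

    def test_correlation_matrix_is_psd_and_keeps_calibrated_entries(self, default_spec):
        names = default_spec.variable_names
        idx = {n: i for i, n in enumerate(names)}
        for sex in ("male", "female"):
            C = default_spec.correlation_matrix(sex)
            assert np.linalg.eigvalsh(C)[0] >= -1e-8
            assert np.allclose(C, C.T)
            for target, corr in default_spec.target_correlations[sex].items():
                for name, rho in corr.items():
                    assert C[idx[name], idx[target]] == pytest.approx(rho, abs=1e-4)

    def test_invalid_specs_rejected(self, default_spec):
        bad = default_cohort_spec()
        bad.group_sizes["male"] = 0
        with pytest.raises(CohortSpecError):
            bad.validate()
        bad2 = default_cohort_spec()
        bad2.marginals["male"]["ALM"] = (21.88, -1.0)
        with pytest.raises(CohortSpecError):
            bad2.validate()

    def test_yaml_round_trip(self, default_spec, tmp_path):
        path = tmp_path / "spec.yaml"
        default_spec.to_yaml(path)
        back = CohortSpec.from_yaml(path)
        assert back.group_sizes == default_spec.group_sizes
        assert back.biomarker_names == default_spec.biomarker_names
        assert back.marginals == default_spec.marginals

    def test_infeasible_correlations_raise(self):
        # rho(a,b)=+1 with rho(a,c)=+1 and rho(b,c)=-1 has no PSD completion
        C = np.array([[1, 1, 1], [1, 1, -1], [1, -1, 1.0]])
        fixed = ~np.eye(3, dtype=bool)
        with pytest.raises(CohortSpecError):
            _nearest_correlation_fixed(C, fixed)


class TestGenerate:
    def test_row_counts_and_columns(self, default_cohort):
        assert default_cohort.n == 515
        assert (default_cohort.sex == "male").sum() == 245
        assert (default_cohort.sex == "female").sum() == 270
        assert default_cohort.X.shape == (515, 44)

    def test_seed_determinism_byte_identical(self, default_spec):
        a = generate_cohort(default_spec, seed=7).to_csv_string()
        b = generate_cohort(default_spec, seed=7).to_csv_string()
        assert a == b
        c = generate_cohort(default_spec, seed=8).to_csv_string()
        assert a != c

    def test_bfp_within_physical_bounds(self, default_cohort):
        bfp = default_cohort.frame["BFP"]
        assert (bfp > 0).all() and (bfp < 100).all()

    def test_csv_round_trip(self, default_cohort):
        buf = io.StringIO(default_cohort.to_csv_string())
        back = Cohort.from_csv(buf)
        assert back.n == default_cohort.n
        np.testing.assert_allclose(back.X, default_cohort.X)

    def test_moment_recovery_large_n(self):
        spec = default_cohort_spec()
        spec.group_sizes = {"male": 10_000, "female": 1}
        frame = generate_cohort(spec, seed=11).frame
        male = frame[frame.sex == "male"]
        for name, (mean, sd) in spec.marginals["male"].items():
            assert male[name].mean() == pytest.approx(mean, rel=0.01)
            assert male[name].std() == pytest.approx(sd, rel=0.03)

    def test_correlation_recovery_large_n(self):
        spec = default_cohort_spec()
        spec.group_sizes = {"male": 10_000, "female": 1}
        frame = generate_cohort(spec, seed=12)
        male = frame.frame[frame.frame.sex == "male"]
        for target, corr in spec.target_correlations["male"].items():
            for name, rho in corr.items():
                emp = np.corrcoef(male[name], male[target])[0, 1]
                assert emp == pytest.approx(rho, abs=0.05)

    def test_combined_mean_is_size_weighted_mean(self):
        # grand mean over 10 seeds: ALM combined ~ (245*21.88 + 270*15.77)/515
        spec = default_cohort_spec()
        expected = (245 * 21.88 + 270 * 15.77) / 515
        vals = np.concatenate(
            [generate_cohort(spec, seed=s).frame["ALM"].to_numpy() for s in range(20, 25)]
        )
        se = 6.98 / np.sqrt(vals.size)
        assert abs(vals.mean() - expected) < 4 * se
        assert expected == pytest.approx(18.68, abs=0.01)

    def test_alm_positively_skewed(self):
        spec = default_cohort_spec()
        spec.group_sizes = {"male": 5000, "female": 1}
        male = generate_cohort(spec, seed=13).frame.query("sex == 'male'")
        assert male["ALM"].mean() > male["ALM"].median()
        assert male["Age (years)"].mean() > male["Age (years)"].median()


class TestMissingness:
    def test_exact_row_count_blanked(self, default_spec):
        spec = default_cohort_spec()
        spec.group_sizes = {"male": 403, "female": 444}
        cohort = generate_cohort(spec, seed=2)
        assert cohort.n == 847
        damaged = inject_missingness(cohort, 332, seed=3)
        incomplete = damaged.frame[list(cohort.biomarker_names)].isna().any(axis=1)
        assert int(incomplete.sum()) == 332

    def test_zero_is_noop(self, default_cohort):
        out = inject_missingness(default_cohort, 0, seed=1)
        assert out.to_csv_string() == default_cohort.to_csv_string()

    def test_saturation_blanks_every_row(self, default_spec):
        spec = default_cohort_spec()
        spec.group_sizes = {"male": 3, "female": 2}
        cohort = generate_cohort(spec, seed=4)
        damaged = inject_missingness(cohort, 5, seed=5)
        assert damaged.frame[list(cohort.biomarker_names)].isna().any(axis=1).all()

    def test_untouched_cells_preserved(self, default_spec):
        spec = default_cohort_spec()
        spec.group_sizes = {"male": 20, "female": 20}
        cohort = generate_cohort(spec, seed=6)
        damaged = inject_missingness(cohort, 10, seed=7)
        orig = cohort.frame[list(cohort.biomarker_names)].to_numpy()
        new = damaged.frame[list(cohort.biomarker_names)].to_numpy()
        mask = ~np.isnan(new)
        np.testing.assert_array_equal(orig[mask], new[mask])

    def test_too_many_rows_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            inject_missingness(default_cohort, default_cohort.n + 1, seed=1)
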