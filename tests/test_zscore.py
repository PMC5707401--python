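"""Asymmetric z-score normalization and interactor calling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stablepull import (
    SimulationConfig,
    apply_quant_filters,
    call_interactors,
    classify_rnase,
    fit_asymmetric_z,
    generate_pulldown,
    log2_transform,
    rnase_z_scores,
    z_score,
)

from conftest import make_table


class TestLog2Transform:
    @pytest.mark.parametrize("ratio,expected", [(1.0, 0.0), (4.0, 2.0),
                                                (0.25, -2.0)])
    def test_exact_powers(self, ratio, expected):
        assert log2_transform([ratio])[0] == pytest.approx(expected)

    def test_nonpositive_ratio_names_position(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            log2_transform([2.0, -1.0, 4.0])

    def test_missing_stays_missing(self):
        out = log2_transform([2.0, np.nan])
        assert np.isnan(out[1])


class TestFitAsymmetricZ:
    def test_worked_seven_point_fit(self):
        # {-3..3}: mean 0, median 0, q3 = 1.5, s_up = 1.5/0.6745 ~ 2.2239
        p = fit_asymmetric_z([-3, -2, -1, 0, 1, 2, 3], min_n=7)
        assert p.center == pytest.approx(0.0)
        assert p.median == pytest.approx(0.0)
        assert p.q3 == pytest.approx(1.5)
        assert p.s_up == pytest.approx(2.2239, abs=1e-3)

    def test_symmetric_data_equal_scales(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=501)
        x = np.concatenate([x, -x])  # exactly symmetric
        p = fit_asymmetric_z(x)
        assert p.s_up == pytest.approx(p.s_lo)

    def test_normal_calibration_of_the_quartile_constant(self):
        # half-IQR / 0.6745 estimates sigma: within 2% at n = 1e5
        x = np.random.default_rng(7).normal(size=100_000)
        p = fit_asymmetric_z(x)
        assert p.s_up == pytest.approx(1.0, rel=0.02)
        assert p.s_lo == pytest.approx(1.0, rel=0.02)

    def test_oracle_equivalence_symmetric_robust_z(self):
        # for symmetric data the asymmetric z equals the ordinary robust
        # z computed independently from the full IQR
        from scipy.stats import iqr

        x = np.array([-3.0, -2, -1, 0, 1, 2, 3])
        p = fit_asymmetric_z(x, min_n=7)
        s_robust = iqr(x) / (2 * 0.6744897501960817)
        expected = (x - x.mean()) / s_robust
        np.testing.assert_allclose(z_score(x, p), expected, atol=1e-12)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_asymmetric_z([1.0] * 20)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            fit_asymmetric_z([0.0, 1.0, 2.0])

    def test_positive_scheme_uses_positive_values(self):
        x = np.array([-5.0, -1, -1, 0, 1.0, 2.0, 3.0, 4.0])
        p = fit_asymmetric_z(x, scheme="positive")
        pos = x[x > 0]
        assert p.center == pytest.approx(pos.mean())
        assert p.s_up == pytest.approx(pos.std(ddof=1))
        assert p.s_up == p.s_lo


class TestZScore:
    def params(self):
        return fit_asymmetric_z([-3, -2, -1, 0, 1, 2, 3], min_n=7)

    def test_center_maps_to_zero(self):
        p = self.params()
        assert z_score(p.center, p) == pytest.approx(0.0)

    def test_worked_continuation(self):
        # x = 3 with the seven-point fit: 3 / 2.2239 ~ 1.349
        assert z_score(3.0, self.params()) == pytest.approx(1.349, abs=1e-3)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=20, unique=True))
    def test_order_preserving(self, xs):
        p = self.params()
        zs = z_score(np.sort(xs), p)
        assert np.all(np.diff(zs) > 0)

    @given(st.floats(-10, 10), st.floats(0.1, 10))
    def test_affine_equivariance(self, shift, scale):
        # shifting all log2 ratios shifts only the center; scaling by
        # k > 0 leaves every z-score exactly unchanged
        x = np.array([-3.0, -1.5, -0.5, 0, 0.25, 1, 2, 4])
        base = z_score(x, fit_asymmetric_z(x, min_n=8))
        shifted = z_score(x + shift, fit_asymmetric_z(x + shift, min_n=8))
        scaled = z_score(x * scale, fit_asymmetric_z(x * scale, min_n=8))
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        np.testing.assert_allclose(scaled, base, atol=1e-9)


def _synthetic_tables(seed, **kw):
    cfg = SimulationConfig(seed=seed, **kw)
    tables, truth = generate_pulldown(cfg)
    return [apply_quant_filters(t)[0] for t in tables], truth


class TestCallInteractors:
    def z_table(self, zs, rep, params):
        # table whose single extra protein lands at the requested z
        base = np.linspace(-2, 2, 41)  # fixed, symmetric background
        x = params.center + np.where(np.asarray(zs) >= 0,
                                     params.s_up, params.s_lo) * np.asarray(zs)
        return x, base

    def test_mean_z_inclusive_boundary(self):
        # mean of (2.5, 1.9) = 2.2 >= 2 -> called
        tables = []
        base = np.linspace(-2, 2, 41)
        for rep, z_target in (("r1", 2.5), ("r2", 1.9)):
            # fixed point: the target value itself enters the fit
            x = 2.0
            for _ in range(100):
                p = fit_asymmetric_z(np.append(base, x))
                x = p.center + p.s_up * z_target
            ratios = np.exp2(np.append(base, x))
            rows = [{"protein_group_id": f"B{i:03d}", "ratio_hl": r}
                    for i, r in enumerate(ratios)]
            rows[-1]["protein_group_id"] = "TARGET"
            tables.append(make_table(rows, replicate_id=rep))
        calls, _ = call_interactors(tables, z_cut=2.0, min_reps=2)
        row = calls[calls.protein_group_id == "TARGET"].iloc[0]
        assert row.mean_z == pytest.approx(2.2, abs=1e-6)
        assert bool(row.is_interactor)

    def test_single_replicate_support_not_called(self):
        base = np.exp2(np.linspace(-2, 2, 41))
        rows = [{"protein_group_id": f"B{i:03d}", "ratio_hl": r}
                for i, r in enumerate(base)]
        t1 = make_table(rows + [{"protein_group_id": "ONLY_ONE",
                                 "ratio_hl": 20.0}], replicate_id="r1")
        t2 = make_table(rows, replicate_id="r2")
        t3 = make_table(rows, replicate_id="r3")
        calls, _ = call_interactors([t1, t2, t3], min_reps=2)
        assert "ONLY_ONE" not in set(calls.protein_group_id)

    def test_planted_interactors_recovered(self):
        # default conditions plant mean z ~ 4; expect >= 18/20 recovered
        tables, truth = _synthetic_tables(1, n_background=500, n_true=20,
                                          n_transient=0, n_replicates=3)
        calls, _ = call_interactors(tables)
        called = set(calls.loc[calls.is_interactor, "protein_group_id"])
        stable = set(truth.loc[truth.klass == "stable", "protein_id"])
        assert len(called & stable) >= 18

    def test_raising_cut_never_adds_interactors(self):
        tables, _ = _synthetic_tables(3)
        lo, _ = call_interactors(tables, z_cut=1.5)
        hi, _ = call_interactors(tables, z_cut=2.5)
        lo_set = set(lo.loc[lo.is_interactor, "protein_group_id"])
        hi_set = set(hi.loc[hi.is_interactor, "protein_group_id"])
        assert hi_set <= lo_set

    def test_background_call_rate_matches_nominal_tail(self):
        # with no planted effect and a single replicate, the fraction
        # called at z >= 2 approximates the standard-normal upper tail
        fractions = []
        for seed in range(20):
            tables, _ = _synthetic_tables(seed, n_background=500, n_true=0,
                                          n_transient=0, n_replicates=1,
                                          contaminant_frac=0.0,
                                          detect_prob=1.0)
            calls, _ = call_interactors(tables, min_reps=1)
            fractions.append(calls.is_interactor.mean())
        nominal = 0.02275  # 1 - Phi(2)
        assert np.mean(fractions) == pytest.approx(nominal, abs=0.01)

    def test_output_sorted_by_mean_z(self):
        tables, _ = _synthetic_tables(5)
        calls, _ = call_interactors(tables)
        assert (calls.mean_z.diff().dropna() <= 1e-12).all()


class TestClassifyRnase:
    def calls_frame(self, n=16):
        import pandas as pd

        return pd.DataFrame({
            "protein_group_id": [f"P{i:03d}" for i in range(n)],
            "gene_name": [f"G{i:03d}" for i in range(n)],
            "mean_z": 3.0,
            "is_interactor": True,
        })

    def test_boundary_minus_one_is_dependent(self):
        import pandas as pd

        calls = self.calls_frame(2)
        rz = pd.Series([-1.0, -0.99], index=calls.protein_group_id)
        out = classify_rnase(calls, rz)
        assert out.rna_class.tolist() == ["rna_dependent", "rna_independent"]

    def test_missing_channel_not_applicable(self):
        import pandas as pd

        calls = self.calls_frame(1)
        out = classify_rnase(calls, pd.Series(dtype=float))
        assert out.rna_class.tolist() == ["not_applicable"]

    def test_five_of_sixteen_lost_after_rnase(self):
        import pandas as pd

        calls = self.calls_frame(16)
        zs = [-2.0, -1.5, -1.2, -1.0, -1.01] + [0.0] * 11
        rz = pd.Series(zs, index=calls.protein_group_id)
        out = classify_rnase(calls, rz)
        assert (out.rna_class == "rna_dependent").sum() == 5

    def test_conventional_simulation_recovers_dependence(self):
        tables, truth = _synthetic_tables(11, protocol="conventional")
        calls, _ = call_interactors(tables)
        out = classify_rnase(calls, rnase_z_scores(tables))
        merged = out.merge(truth, left_on="protein_group_id",
                           right_on="protein_id")
        dep = merged[merged.rna_dependent & (merged.klass == "stable")]
        indep = merged[~merged.rna_dependent & (merged.klass == "stable")]
        assert (dep.rna_class == "rna_dependent").mean() > 0.7
        assert (indep.rna_class == "rna_independent").mean() > 0.7
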