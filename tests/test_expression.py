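"""Normalization, model fit, moderation and bias-calling checks."""

import numpy as np
import pandas as pd
import pytest

from mirsexbias.io_tables import CountExperiment
from mirsexbias.expression import (
    bh_adjust,
    base_means,
    call_sex_biased,
    filter_expressed,
    fit_sex_model,
    median_of_ratios,
    moderated_test,
    sex_bias_analysis,
    tmm_factors,
)


def make_experiment(counts: np.ndarray, sex, batch=None, ids=None) -> CountExperiment:
    n = counts.shape[1]
    samples = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "sex": sex,
            "tissue": ["whole"] * n,
            "batch": batch if batch is not None else [f"b{i}" for i in range(n)],
        },
        index=pd.Index(samples),
    )
    idx = ids or [f"l{i}" for i in range(counts.shape[0])]
    return CountExperiment(pd.DataFrame(counts, index=idx, columns=samples), meta)


class TestMedianOfRatios:
    def test_identical_samples_unit_factors(self):
        c = np.tile([[5], [50], [500]], (1, 3))
        assert median_of_ratios(c) == pytest.approx([1, 1, 1])

    def test_doubled_sample_from_definition(self):
        c = np.array([[10, 20], [30, 60], [7, 14]])
        assert median_of_ratios(c) == pytest.approx([2**-0.5, 2**0.5])

    def test_zero_containing_loci_excluded_from_reference(self):
        # the zero-containing locus would otherwise drag sample 2's median
        c = np.array([[10, 20], [30, 60], [1000, 0]])
        assert median_of_ratios(c) == pytest.approx([2**-0.5, 2**0.5])

    def test_all_zero_rows_need_fallback(self):
        c = np.array([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            median_of_ratios(c)
        f = median_of_ratios(c, pseudo_reference=True)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        # scaling one sample scales its factor, up to the geomean-1 convention
        c = rng.integers(1, 1000, size=(50, 4))
        f = median_of_ratios(c)
        c2 = c.astype(float).copy()
        c2[:, 2] *= 7.5
        f2 = median_of_ratios(c2)
        ratio = f2 / f
        assert ratio[2] / ratio[0] == pytest.approx(7.5, rel=1e-9)
        assert ratio[1] / ratio[0] == pytest.approx(1.0, rel=1e-9)


class TestTmm:
    def test_identical_samples_unit_factors(self):
        c = np.tile([[8], [80], [800], [8000]], (1, 3))
        assert tmm_factors(c) == pytest.approx([1, 1, 1])

    def test_scaled_sample_factor_ratio(self, rng):
        c = rng.integers(10, 2000, size=(200, 3)).astype(float)
        scaled = c.copy()
        scaled[:, 1] *= 4
        f = tmm_factors(c, ref_sample=0)
        f2 = tmm_factors(scaled, ref_sample=0)
        ratio = f2 / f
        assert ratio[1] / ratio[0] == pytest.approx(4.0, rel=1e-6)

    def test_against_unweighted_trimmed_mean_oracle(self, rng):
        """The weighted TMM factor stays within 10% of a brute-force
        unweighted trimmed mean of M-values on random tables."""
        for _ in range(20):
            c = rng.integers(5, 5000, size=(120, 2)).astype(float)
            f = tmm_factors(c, ref_sample=0)
            lib = c.sum(axis=0)
            m = np.log2((c[:, 1] / lib[1]) / (c[:, 0] / lib[0]))
            lo, hi = np.quantile(m, [0.3, 0.7])
            keep = (m >= lo) & (m <= hi)
            oracle = lib[1] * 2 ** np.mean(m[keep])
            oracle_factors = np.array([lib[0], oracle])
            oracle_factors = oracle_factors / np.exp(
                np.mean(np.log(oracle_factors))
            )
            assert f[1] == pytest.approx(oracle_factors[1], rel=0.10)


class TestFilterExpressed:
    def test_all_zero_in_one_sex_dropped(self):
        c = np.array([[0, 0, 5, 9], [3, 4, 5, 6]])
        exp = make_experiment(c, sex=["male", "male", "female", "female"])
        kept = filter_expressed(exp, np.ones(4))
        assert list(kept) == ["l1"]

    def test_base_mean_boundary_inclusive_at_one(self):
        # base means exactly 0.75 and 1.0 with unit factors
        c = np.array([[1, 1, 1, 0], [1, 1, 1, 1]])
        exp = make_experiment(c, sex=["male", "male", "female", "female"])
        kept = filter_expressed(exp, np.ones(4))
        assert list(kept) == ["l1"]

    def test_all_ones_matrix_all_kept(self):
        c = np.ones((5, 4), dtype=int)
        exp = make_experiment(c, sex=["male", "female", "male", "female"])
        assert len(filter_expressed(exp, np.ones(4))) == 5


class TestFitSexModel:
    def _planted(self, fc=1.0, base=200.0, n=3):
        male = base * 2**fc
        c = np.tile([[male] * n + [base] * n], (4, 1)).astype(int)
        return make_experiment(
            c, sex=["male"] * n + ["female"] * n,
            batch=["b1", "b2", "b3"] * 2,
        )

    def test_noise_free_recovery_bias_below_005(self):
        exp = self._planted(fc=1.0, base=200.0)
        fit = fit_sex_model(exp, np.ones(6), design="paired")
        assert fit["log2fc"].to_numpy() == pytest.approx(1.0, abs=0.05)

    def test_label_swap_negates_log2fc(self):
        exp = self._planted(fc=1.3, base=128.0)
        swapped = CountExperiment(
            exp.counts.copy(),
            exp.samples.assign(
                sex=exp.samples["sex"].map({"male": "female", "female": "male"})
            ),
        )
        a = fit_sex_model(exp, np.ones(6), "paired")["log2fc"]
        b = fit_sex_model(swapped, np.ones(6), "paired")["log2fc"]
        assert np.allclose(a, -b)

    def test_batch_shift_invariance_in_paired_design(self):
        # exact on the log scale; the 0.5 pseudocount perturbs it only at
        # O(1/count), far below the tolerance at these depths
        exp = self._planted(fc=1.0, base=2**14)
        shifted = exp.counts.copy()
        b2 = exp.samples.index[exp.samples["batch"] == "b2"]
        shifted[b2] = shifted[b2] * 4  # constant log-shift for one batch
        exp2 = CountExperiment(shifted, exp.samples.copy())
        a = fit_sex_model(exp, np.ones(6), "paired")["log2fc"]
        b = fit_sex_model(exp2, np.ones(6), "paired")["log2fc"]
        assert np.allclose(a, b, atol=1e-5)

    def test_confounded_design_raises(self):
        c = np.ones((3, 4), dtype=int) * 10
        exp = make_experiment(
            c, sex=["male", "male", "female", "female"],
            batch=["b1", "b1", "b2", "b2"],  # sex == batch
        )
        with pytest.raises(ValueError, match="confounded"):
            fit_sex_model(exp, np.ones(4), design="paired")


class TestModeratedTest:
    def _fit_frame(self, rng, n=400, df=4.0):
        s2 = rng.chisquare(df, n) / df * 0.3
        fc = rng.normal(0, 0.05, n)
        return pd.DataFrame(
            {
                "log2fc": fc, "se": np.sqrt(s2 * 0.5), "s2": s2,
                "df": df, "v": 0.5, "amean": rng.normal(8, 1, n),
            }
        )

    def test_d0_zero_equals_ordinary_t(self, rng):
        from scipy import stats as sps

        fit = self._fit_frame(rng)
        out = moderated_test(fit, d0=0.0)
        t = fit["log2fc"] / np.sqrt(fit["s2"] * fit["v"])
        p = 2 * sps.t.sf(np.abs(t), 4.0)
        assert np.allclose(out["p"], p)

    def test_d0_infinite_uses_pooled_variance_everywhere(self, rng):
        fit = self._fit_frame(rng)
        out = moderated_test(fit, d0=np.inf, s0_sq=0.3)
        t = fit["log2fc"] / np.sqrt(0.3 * fit["v"])
        assert np.allclose(np.abs(out["t"]), np.abs(t))

    def test_p_monotone_in_abs_t(self, rng):
        fit = self._fit_frame(rng)
        out = moderated_test(fit)
        order = np.argsort(np.abs(out["t"].to_numpy()))
        assert (np.diff(out["p"].to_numpy()[order]) <= 1e-12).all()


class TestBhAdjust:
    def test_step_up_hand_computation(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_all_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_propagates_and_reduces_m(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[0] == pytest.approx(0.02)  # m = 2, not 3

    def test_order_preserving(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert ((p[:, None] <= p[None, :]) | (q[:, None] >= q[None, :])).all()


class TestCallSexBiased:
    @pytest.mark.parametrize(
        "q,fc,expect",
        [
            (0.05, 0.40, "male"),
            (0.05, 0.25, "none"),  # 0.25 < log2(1.25) ~ 0.3219
            (0.15, 2.0, "none"),
            (0.05, -0.40, "female"),
            (0.05, np.log2(1.25), "male"),  # boundary inclusive
        ],
    )
    def test_threshold_rules(self, q, fc, expect):
        frame = pd.DataFrame({"q": [q], "log2fc": [fc]})
        assert call_sex_biased(frame).iloc[0] == expect


class TestWorkflowProperties:
    def test_fold_change_concordance_with_naive_ratio(self):
        """Model fold-changes track a naive normalized mean-ratio estimator
        (the two methods agree on simulated data, r > 0.95)."""
        from mirsexbias.simulate import (
            SimulationConfig, simulate_annotation, simulate_counts,
        )

        cfg = SimulationConfig(seed=77, n_loci=250, n_clusters=40,
                               n_replicates_per_sex=3, nb_dispersion=0.05,
                               mean_log_expression=7.0, mean_log_sd=1.0)
        _, ann2, truth = simulate_annotation(cfg)
        exp = simulate_counts(ann2, truth, cfg)
        res = sex_bias_analysis(exp).dropna(subset=["log2fc"])
        sf = median_of_ratios(exp.counts)
        normed = exp.counts.to_numpy(float) / sf
        male = exp.samples["sex"].to_numpy() == "male"
        naive = np.log2(
            (normed[:, male].mean(axis=1) + 0.5)
            / (normed[:, ~male].mean(axis=1) + 0.5)
        )
        naive = pd.Series(naive, index=exp.counts.index).loc[res.index]
        assert np.corrcoef(res["log2fc"], naive)[0, 1] > 0.95

    def test_biased_fraction_controlled_under_null(self):
        """With no effects anywhere, the fraction of loci called biased at
        FDR 10% stays at or below 12% (Monte-Carlo tolerance)."""
        from mirsexbias.simulate import (
            SimulationConfig, simulate_annotation, simulate_counts,
        )

        total = called = 0
        for seed in range(6):
            cfg = SimulationConfig(
                seed=600 + seed, n_loci=250, n_clusters=40,
                sex_effect_log2=0.0, conserved_effect_sd=0.0,
                n_replicates_per_sex=3,
            )
            _, ann2, truth = simulate_annotation(cfg)
            exp = simulate_counts(ann2, truth, cfg)
            res = sex_bias_analysis(exp)
            sub = res.dropna(subset=["q"])
            total += len(sub)
            called += (sub["biased"] != "none").sum()
        assert called / total <= 0.12
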