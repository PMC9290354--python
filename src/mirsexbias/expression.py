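"""Sex-bias differential-expression analysis for small-RNA count tables.

The analysis mirrors the standard count-based DGE workflow for a two-sex
design with paired sequencing batches: size-factor normalization
(median-of-ratios or TMM), an expression filter, a per-locus linear model on
``log2(normalized count + 0.5)`` with the design ``expression ~ batch + sex``,
empirical-Bayes variance moderation, Benjamini-Hochberg adjustment, and a
bias call at FDR < 0.10 with a fold-change of at least 25%.

The sex coefficient is log2(male/female): positive values are male-biased.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_tables import CountExperiment

__all__ = [
    "median_of_ratios",
    "tmm_factors",
    "base_means",
    "filter_expressed",
    "fit_sex_model",
    "moderated_test",
    "bh_adjust",
    "call_sex_biased",
    "sex_bias_analysis",
    "DEFAULT_FDR",
    "DEFAULT_MIN_FC",
]

DEFAULT_FDR = 0.10
DEFAULT_MIN_FC = 1.25


# ---------------------------------------------------------------------------
# normalization


def _rescale_geomean(factors: np.ndarray) -> np.ndarray:
    return factors / np.exp(np.mean(np.log(factors)))


def median_of_ratios(
    counts: pd.DataFrame | np.ndarray, pseudo_reference: bool = False
) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference for each locus is the geometric mean of its counts across
    samples; loci containing any zero are excluded from the reference set.
    If no locus is positive in every sample, ``pseudo_reference=True`` falls
    back to geometric means over positive counts only.
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("counts must be a loci x samples matrix")
    all_positive = (mat > 0).all(axis=1)
    if all_positive.any() and not pseudo_reference:
        sub = mat[all_positive]
        logref = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - logref[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        if not pseudo_reference:
            raise ValueError(
                "no locus has positive counts in every sample; rerun with "
                "pseudo_reference=True to use positive-count geometric means"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.where(mat > 0, np.log(np.maximum(mat, 1e-300)), np.nan)
        logref = np.nanmean(logs, axis=1)
        keep = np.isfinite(logref)
        ratios = logs[keep] - logref[keep, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    if not np.all(np.isfinite(factors)) or (factors <= 0).any():
        raise ValueError("degenerate size factors; check the count matrix")
    return _rescale_geomean(factors)


def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    ref_sample: int | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values size factors (library size x TMM factor),
    rescaled to geometric mean 1.

    M-values (log2 ratio of proportions vs the reference sample) are trimmed
    by ``m_trim`` on each tail and A-values by ``a_trim``, and the surviving
    M-values are averaged with inverse asymptotic-variance (delta-method
    binomial) weights.  The weights are computed from the count proportions
    at a common nominal depth, which makes the factors exactly equivariant
    under rescaling any single sample's counts.
    """
    mat = np.asarray(counts, dtype=float)
    libsize = mat.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("every sample needs a positive library size")
    props = mat / libsize
    if ref_sample is None:
        uq = np.array([np.quantile(p[p > 0], 0.75) if (p > 0).any() else 0.0
                       for p in props.T])
        ref_sample = int(np.argmin(np.abs(uq - uq.mean())))
    ref = props[:, ref_sample]
    nref = libsize[ref_sample]
    log_tmm = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_sample:
            continue
        obs = props[:, j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() == 0:
            raise ValueError(f"sample {j} shares no expressed locus with reference")
        m = np.log2(obs[ok] / ref[ok])
        a = 0.5 * np.log2(obs[ok] * ref[ok])
        w = 1.0 / ((1 - obs[ok]) / obs[ok] + (1 - ref[ok]) / ref[ok])
        keep = np.ones(ok.sum(), dtype=bool)
        if keep.sum() > 2:
            lo_m, hi_m = np.quantile(m, [m_trim, 1 - m_trim])
            lo_a, hi_a = np.quantile(a, [a_trim, 1 - a_trim])
            keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0:
            keep[:] = True
        log_tmm[j] = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
    factors = libsize * np.exp2(log_tmm)
    return _rescale_geomean(factors)


def base_means(counts: pd.DataFrame, size_factors: np.ndarray | None = None) -> pd.Series:
    """Mean normalized count per locus; the normalization is always
    median-of-ratios (pseudo-reference fallback) regardless of which factors
    feed the model, so the expression filter is method-independent."""
    if size_factors is None:
        try:
            size_factors = median_of_ratios(counts)
        except ValueError:
            size_factors = median_of_ratios(counts, pseudo_reference=True)
    normed = counts.to_numpy(dtype=float) / np.asarray(size_factors)[None, :]
    return pd.Series(normed.mean(axis=1), index=counts.index, name="base_mean")


# ---------------------------------------------------------------------------
# filtering


def filter_expressed(
    experiment: CountExperiment,
    size_factors: np.ndarray | None = None,
    min_base_mean: float = 1.0,
) -> pd.Index:
    """Loci kept for the fold-change analyses: at least one raw read in at
    least one sample of *each* sex, and base mean >= ``min_base_mean``."""
    sexes = experiment.samples["sex"]
    if not {"male", "female"} <= set(sexes):
        raise ValueError("both sexes must be present to filter on sex coverage")
    counts = experiment.counts
    male_any = counts.loc[:, sexes == "male"].sum(axis=1) > 0
    female_any = counts.loc[:, sexes == "female"].sum(axis=1) > 0
    bm = base_means(counts, size_factors)
    keep = male_any & female_any & (bm >= min_base_mean)
    return counts.index[keep]


# ---------------------------------------------------------------------------
# model fit


def _design_matrix(samples: pd.DataFrame, design: str) -> tuple[np.ndarray, list[str]]:
    n = len(samples)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if design == "paired":
        batches = sorted(samples["batch"].unique())
        for b in batches[1:]:
            cols.append((samples["batch"] == b).to_numpy(float))
            names.append(f"batch[{b}]")
    elif design != "unpaired":
        raise ValueError(f"unknown design {design!r}")
    cols.append((samples["sex"] == "male").to_numpy(float))
    names.append("sex[male]")
    return np.column_stack(cols), names


def fit_sex_model(
    experiment: CountExperiment,
    size_factors: np.ndarray,
    design: Literal["paired", "unpaired"] = "paired",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-locus OLS of log2(normalized count + pseudocount) on
    ``~ batch + sex`` (paired) or ``~ sex`` (unpaired).

    Returns a frame with the male-vs-female coefficient ``log2fc``, its
    standard error, the residual variance ``s2``, residual degrees of freedom
    ``df`` and the unit coefficient variance ``v`` (so se = sqrt(s2 * v)).
    """
    samples = experiment.samples
    if set(samples["sex"].unique()) != {"male", "female"}:
        raise ValueError("need samples of both sexes")
    X, names = _design_matrix(samples, design)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # find which batch dummies are collinear with sex
        rank_wo_sex = np.linalg.matrix_rank(X[:, :-1])
        if rank_wo_sex == np.linalg.matrix_rank(X):
            raise ValueError(
                "rank-deficient design: sex is confounded with batch "
                f"(columns {names})"
            )
        raise ValueError(f"rank-deficient design matrix (columns {names})")
    if n - p < 1:
        raise ValueError(
            f"no residual degrees of freedom: {n} samples, {p} coefficients"
        )
    Y = np.log2(
        experiment.counts.to_numpy(float) / np.asarray(size_factors)[None, :]
        + pseudocount
    )
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv  # loci x p
    resid = Y - beta @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    v = xtx_inv[-1, -1]
    se = np.sqrt(s2 * v)
    return pd.DataFrame(
        {
            "log2fc": beta[:, -1],
            "se": se,
            "s2": s2,
            "df": float(df),
            "v": v,
            "amean": Y.mean(axis=1),
        },
        index=experiment.counts.index,
    )


# ---------------------------------------------------------------------------
# moderated test


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(
    s2: np.ndarray, df: float, abundance: np.ndarray | None = None
) -> tuple[float, np.ndarray | float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) to the observed
    log residual variances, as in empirical-Bayes moderated-t pipelines.

    When ``abundance`` (average log2 expression) is supplied the prior
    variance follows a lowess trend in abundance rather than a single pooled
    value, which keeps the test calibrated when count data put more variance
    on weakly expressed loci; ``d0`` is then estimated from the spread around
    the trend.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if abundance is not None and ok.sum() >= 10 and np.ptp(abundance[ok]) > 0:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        a = np.asarray(abundance, dtype=float)[ok]
        # non-robust smooth: the digamma offset in e assumes the conditional
        # MEAN of log s2; robustness iterations would chase the median of the
        # left-skewed log-chi-square and bias the prior variance upward
        fitted = lowess(e, a, frac=0.5, it=0, xvals=np.sort(a))
        order = np.argsort(a)
        trend_sorted = np.empty_like(fitted)
        trend_sorted[order] = fitted  # undo the sort to align with e
        trend = trend_sorted
        trend_full = np.interp(np.asarray(abundance, float), np.sort(a), fitted)
    else:
        trend = np.full(ok.sum(), np.mean(e))
        trend_full = np.full(s2.shape, np.mean(e))
    resid = e - trend
    evar = np.var(resid, ddof=1)
    surplus = evar - special.polygamma(1, df / 2.0)
    if surplus <= 0:
        return np.inf, np.exp(trend_full)
    d0 = 2.0 * _trigamma_inverse(surplus)
    s0_sq = np.exp(trend_full + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), s0_sq


def moderated_test(
    fit: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | np.ndarray | None = None,
    var_floor: float = 1e-8,
    trend: bool = True,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test on the sex coefficient.

    Per-locus variances are shrunk toward the prior: s2_post = (d0*s0^2 +
    df*s2) / (d0 + df); the t statistic log2fc / sqrt(s2_post * v) is referred
    to a t distribution on d0 + df degrees of freedom.  ``d0=0`` reproduces
    the ordinary per-locus t-test; ``d0=inf`` uses the pooled prior variance
    for every locus.  When ``d0`` is not given, (d0, s0^2) are estimated by
    method of moments on the log variances.
    """
    df = float(fit["df"].iloc[0])
    s2 = np.maximum(fit["s2"].to_numpy(float), var_floor)
    abundance = fit["amean"].to_numpy(float) if (trend and "amean" in fit) else None
    if d0 is None:
        d0, s0_sq = estimate_prior(s2, df, abundance)
    elif s0_sq is None:
        s0_sq = float(np.mean(s2))
    if np.isinf(d0):
        s2_post = np.broadcast_to(np.asarray(s0_sq, float), s2.shape).copy()
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    t = fit["log2fc"].to_numpy(float) / np.sqrt(s2_post * fit["v"].to_numpy(float))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fit.copy()
    out["t"] = t
    out["p"] = p
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate and are
    excluded from the number of tests."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_sex_biased(
    result: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    min_fc: float = DEFAULT_MIN_FC,
) -> pd.Series:
    """Label loci male/female/none: q < fdr and |log2fc| >= log2(min_fc)
    (boundary inclusive on the fold-change, matching 'a difference of 25%
    or over')."""
    thresh = np.log2(min_fc)
    q = result["q"].to_numpy(float)
    fc = result["log2fc"].to_numpy(float)
    call = np.where(
        (q < fdr) & (fc >= thresh),
        "male",
        np.where((q < fdr) & (fc <= -thresh), "female", "none"),
    )
    return pd.Series(call, index=result.index, name="biased")


# ---------------------------------------------------------------------------
# one-call workflow


def sex_bias_analysis(
    experiment: CountExperiment,
    design: Literal["paired", "unpaired"] = "paired",
    norm: Literal["mor", "tmm"] = "mor",
    fdr: float = DEFAULT_FDR,
    min_fc: float = DEFAULT_MIN_FC,
    d0: float | None = None,
) -> pd.DataFrame:
    """Full sex-bias workflow on one count experiment.

    Returns a frame indexed by locus with base_mean, log2fc, se, p, q and the
    bias call; loci failing the expression filter carry NaN statistics and
    ``biased='none'``.
    """
    counts = experiment.counts
    try:
        mor = median_of_ratios(counts)
    except ValueError:
        mor = median_of_ratios(counts, pseudo_reference=True)
    factors = mor if norm == "mor" else tmm_factors(counts)
    bm = base_means(counts, mor)
    kept = filter_expressed(experiment, mor)
    sub = experiment.subset_loci(kept)
    fit = fit_sex_model(sub, factors, design=design)
    tested = moderated_test(fit, d0=d0)
    tested["q"] = bh_adjust(tested["p"].to_numpy())
    out = pd.DataFrame(
        {
            "base_mean": bm,
            "log2fc": tested["log2fc"].reindex(counts.index),
            "se": tested["se"].reindex(counts.index),
            "p": tested["p"].reindex(counts.index),
            "q": tested["q"].reindex(counts.index),
        },
        index=counts.index,
    )
    calls = call_sex_biased(tested.assign(q=tested["q"]), fdr=fdr, min_fc=min_fc)
    out["biased"] = calls.reindex(counts.index).fillna("none")
    out.index.name = "locus"
    out.attrs["d0"] = tested.attrs.get("d0")
    out.attrs["design"] = design
    out.attrs["norm"] = norm
    return out
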