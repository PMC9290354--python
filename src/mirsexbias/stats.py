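"""Rank-based and regression statistics for fold-change comparisons.

The central tool is the Scheirer-Ray-Hare test: a two-factor extension of
Kruskal-Wallis computed as an ANOVA on the joint mid-ranks, with each
effect's H = SS_effect / MS_total referred to a chi-square distribution.
MS_total is the realized variance of the ranks, so tie correction is
implicit.  Sums of squares are type II (each main effect adjusted for the
other), the standard choice for unbalanced factorial layouts such as a
handful of X-linked novel loci against many autosomal conserved ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SrhResult",
    "LinearFit",
    "scheirer_ray_hare",
    "kruskal_wallis",
    "linear_fit",
]


@dataclass(frozen=True)
class EffectTest:
    H: float
    df: int
    p: float


@dataclass(frozen=True)
class SrhResult:
    """Per-effect H statistics of the rank-based two-factor test."""

    effects: dict  # name -> EffectTest; keys: factor names and "interaction"
    n: int
    ms_total: float
    tie_correction: float

    def p(self, name: str) -> float:
        return self.effects[name].p


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p: float
    n: int


def _tie_correction(values: np.ndarray) -> float:
    n = values.size
    if n < 2:
        return 1.0
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - np.sum(counts**3 - counts) / (n**3 - n)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels, drop_first=True).to_numpy(float)


def scheirer_ray_hare(
    values,
    factor_a,
    factor_b=None,
    names: tuple[str, str] = ("A", "B"),
    interaction: bool = True,
) -> SrhResult:
    """Scheirer-Ray-Hare test on ``values`` for two categorical factors.

    Values are mid-ranked jointly; two-way type-II sums of squares on the
    ranks are divided by MS_total = SS_total/(N-1) to give chi-square
    distributed H statistics with (a-1), (b-1) and (a-1)(b-1) degrees of
    freedom.  With ``factor_b=None`` the one-way version is computed, which
    reduces exactly to tie-corrected Kruskal-Wallis.  Cells absent from an
    unbalanced layout drop the interaction term with a warning.
    """
    y = np.asarray(values, dtype=float)
    if np.isnan(y).any():
        raise ValueError("values contain NaN")
    fa = pd.Series(list(factor_a), dtype="object")
    if len(fa) != y.size:
        raise ValueError("factor A length does not match values")
    if fa.nunique() < 2:
        raise ValueError(
            f"factor {names[0]!r} is constant; use kruskal_wallis on the "
            "other factor instead"
        )
    ranks = sps.rankdata(y)
    n = y.size
    ss_total = float(np.sum((ranks - ranks.mean()) ** 2))
    tie_c = _tie_correction(y)

    if ss_total == 0.0:  # all values identical: every effect is null
        eff = {names[0]: EffectTest(0.0, int(fa.nunique() - 1), 1.0)}
        if factor_b is not None:
            fb = pd.Series(list(factor_b), dtype="object")
            eff[names[1]] = EffectTest(0.0, int(fb.nunique() - 1), 1.0)
            if interaction:
                eff["interaction"] = EffectTest(
                    0.0, int((fa.nunique() - 1) * (fb.nunique() - 1)), 1.0
                )
        return SrhResult(eff, n, 0.0, tie_c)

    ms_total = ss_total / (n - 1)
    ones = np.ones((n, 1))
    A = _dummies(fa)

    if factor_b is None:
        rss_null = _rss(ranks, ones)
        rss_a = _rss(ranks, np.hstack([ones, A]))
        h_a = (rss_null - rss_a) / ms_total
        df_a = fa.nunique() - 1
        eff = {names[0]: EffectTest(h_a, int(df_a), float(sps.chi2.sf(h_a, df_a)))}
        return SrhResult(eff, n, ms_total, tie_c)

    fb = pd.Series(list(factor_b), dtype="object")
    if len(fb) != y.size:
        raise ValueError("factor B length does not match values")
    if fb.nunique() < 2:
        raise ValueError(
            f"factor {names[1]!r} is constant; use kruskal_wallis on "
            f"{names[0]!r} instead"
        )
    a_levels, b_levels = fa.nunique(), fb.nunique()
    n_cells_seen = pd.crosstab(fa, fb).to_numpy()
    if n < a_levels * b_levels + 1:
        raise ValueError("need more observations than cells")
    B = _dummies(fb)
    AB = np.hstack([ones, A, B])
    rss_ab = _rss(ranks, AB)
    rss_a_only = _rss(ranks, np.hstack([ones, A]))
    rss_b_only = _rss(ranks, np.hstack([ones, B]))
    h_a = (rss_b_only - rss_ab) / ms_total
    h_b = (rss_a_only - rss_ab) / ms_total
    df_a, df_b = a_levels - 1, b_levels - 1
    eff = {
        names[0]: EffectTest(
            max(h_a, 0.0), int(df_a), float(sps.chi2.sf(max(h_a, 0.0), df_a))
        ),
        names[1]: EffectTest(
            max(h_b, 0.0), int(df_b), float(sps.chi2.sf(max(h_b, 0.0), df_b))
        ),
    }
    if interaction:
        if (n_cells_seen == 0).any():
            warnings.warn(
                "empty cells in the two-way layout: interaction term dropped"
            )
        else:
            inter_cols = []
            for i in range(A.shape[1]):
                for j in range(B.shape[1]):
                    inter_cols.append(A[:, i] * B[:, j])
            full = np.hstack([AB, np.column_stack(inter_cols)])
            rss_full = _rss(ranks, full)
            h_i = (rss_ab - rss_full) / ms_total
            df_i = df_a * df_b
            eff["interaction"] = EffectTest(
                max(h_i, 0.0), int(df_i), float(sps.chi2.sf(max(h_i, 0.0), df_i))
            )
    return SrhResult(eff, n, ms_total, tie_c)


def kruskal_wallis(values, labels) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H via the textbook rank-sum formula
    (kept deliberately distinct from the regression route used by
    :func:`scheirer_ray_hare`, so the two can check each other)."""
    y = np.asarray(values, dtype=float)
    lab = pd.Series(list(labels), dtype="object")
    if lab.nunique() < 2:
        raise ValueError("need at least two groups")
    if (lab.value_counts() < 1).any() or len(lab) != y.size:
        raise ValueError("labels must be one non-empty group label per value")
    n = y.size
    ranks = sps.rankdata(y)
    h = 0.0
    for _, idx in lab.groupby(lab).groups.items():
        r = ranks[np.asarray(idx)]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    c = _tie_correction(y)
    if c == 0.0:  # all observations tied
        return 0.0, int(lab.nunique() - 1), 1.0
    h /= c
    df = int(lab.nunique() - 1)
    return float(h), df, float(sps.chi2.sf(h, df))


def linear_fit(x, y) -> LinearFit:
    """Ordinary least-squares line with the two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; no slope is identifiable")
    if np.ptp(y) == 0:
        return LinearFit(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = sps.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p=float(res.pvalue),
        n=int(x.size),
    )
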