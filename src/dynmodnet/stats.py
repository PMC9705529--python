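"""Condition-comparison statistics.

The battery used to compare metric values between two conditions: two-tailed
paired t-tests with Benjamini–Hochberg FDR control (alpha = 0.05) within
each contrast family, Cohen's dz effect sizes (mean of condition differences
over their n-1 standard deviation), Anderson–Darling normality checks,
Pearson correlation of percent-change magnitudes against an ordinal
experience code, and analytic post hoc power for the paired t-test via the
noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PairedSample:
    """Equal-length per-trial metric vectors from two conditions."""

    x1: np.ndarray
    x2: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float)
        x2 = np.asarray(self.x2, dtype=float)
        if x1.shape != x2.shape or x1.ndim != 1:
            raise StatsError("x1 and x2 must be equal-length 1-D vectors")
        if x1.size < 3:
            raise StatsError("paired sample needs n >= 3")
        if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
            raise StatsError("paired sample contains non-finite values")
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)

    @property
    def diffs(self) -> np.ndarray:
        return self.x1 - self.x2

    @property
    def n(self) -> int:
        return self.x1.size


def paired_t(sample: PairedSample) -> tuple[float, float]:
    """Classical paired t-test; returns (t, two-tailed p)."""
    d = sample.diffs
    sd = d.std(ddof=1)
    if sd == 0:
        raise StatsError("degenerate sample: zero-variance differences")
    t = d.mean() / (sd / np.sqrt(sample.n))
    p = 2.0 * sps.t.sf(abs(t), df=sample.n - 1)
    return float(t), float(p)


def cohens_dz(sample: PairedSample) -> float:
    """Paired effect size dz = mean(X1-X2) / SD(X1-X2), n-1 denominator."""
    d = sample.diffs
    sd = d.std(ddof=1)
    if sd == 0:
        raise StatsError("dz undefined: zero-variance differences")
    return float(d.mean() / sd)


def fdr_bh(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up; returns (q-values, rejection mask)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def normality_ad(x) -> tuple[float, float]:
    """Anderson–Darling normality test with estimated mean and variance.

    Applies the case-3 small-sample correction A*^2 = A^2 (1 + 0.75/n +
    2.25/n^2) and the standard piecewise exponential p-value approximation
    (D'Agostino & Stephens).  Returns (A*^2, p).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise StatsError("Anderson–Darling test needs n >= 8")
    if x.std(ddof=1) == 0:
        raise StatsError("constant vector: normality test undefined")
    y = np.sort((x - x.mean()) / x.std(ddof=1))
    logcdf = sps.norm.logcdf(y)
    logsf = sps.norm.logsf(y)
    i = np.arange(1, n + 1)
    a2 = float(-n - np.sum((2 * i - 1) * (logcdf + logsf[::-1])) / n)
    a2s = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    if a2s >= 0.6:
        p = np.exp(1.2937 - 5.709 * a2s + 0.0186 * a2s**2)
    elif a2s > 0.34:
        p = np.exp(0.9177 - 4.279 * a2s - 1.38 * a2s**2)
    elif a2s > 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a2s - 59.938 * a2s**2)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a2s - 223.73 * a2s**2)
    return a2s, float(np.clip(p, 0.0, 1.0))


def experience_correlation(magnitudes, experience_codes) -> tuple[float, float, tuple[float, float]]:
    """Pearson r between percent-change magnitudes and an ordinal code.

    The experience code is ordinal (e.g. experienced = 1, rudimentary = 2,
    naive = 3).  Returns (r, two-tailed p, 95% CI via Fisher z).
    """
    y = np.asarray(magnitudes, dtype=float)
    c = np.asarray(experience_codes, dtype=float)
    if y.size != c.size or y.size < 3:
        raise StatsError("need >= 3 paired observations")
    if np.unique(c).size < 2 or y.std() == 0:
        raise StatsError("constant input: correlation undefined")
    res = sps.pearsonr(c, y)
    r, p = float(res.statistic), float(res.pvalue)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(y.size - 3)
    zc = sps.norm.ppf(0.975)
    ci = (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))
    return r, p, ci


def power_paired_t(dz: float, n: int, alpha: float = 0.05) -> float:
    """Achieved power of a two-tailed paired t-test at effect size dz.

    Uses the noncentral t distribution with ncp = dz * sqrt(n) and df = n-1
    (the analytic computation behind standard post hoc power tools).
    """
    if n < 2:
        raise StatsError("power needs n >= 2")
    if not np.isfinite(dz):
        raise StatsError("dz must be finite")
    df = n - 1
    ncp = dz * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    # far tails of the noncentral t can underflow to nan; they contribute 0
    upper = np.nan_to_num(sps.nct.sf(tcrit, df, ncp), nan=0.0)
    lower = np.nan_to_num(sps.nct.cdf(-tcrit, df, ncp), nan=0.0)
    return float(np.clip(upper + lower, 0.0, 1.0))


def significance_stars(p: float) -> str:
    """Figure-legend convention: ***p<0.005, **p<0.01, *p<0.05."""
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def aggregate_repeats(frame: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Average metric values over repeated trials within a grouping column."""
    keys = [c for c in (group_col, "condition", "unit", "metric") if c in frame.columns]
    return frame.groupby(keys, as_index=False)["value"].mean()


def compare_conditions(
    frame1: pd.DataFrame,
    frame2: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    contrast: str = "",
) -> pd.DataFrame:
    """Per-unit paired comparison of one metric between two condition frames.

    Trials are paired by index (counts must match); all units tested for one
    metric within one contrast form a single FDR family.  Returns a table
    with columns contrast, unit, metric, n, t, p, q, reject, dz, power,
    normality_p and stars.
    """
    rows = []
    units = [u for u in frame1.loc[frame1["metric"] == metric, "unit"].unique()]
    for unit in units:
        v1 = frame1.query("metric == @metric and unit == @unit").sort_values("trial")["value"].to_numpy()
        v2 = frame2.query("metric == @metric and unit == @unit").sort_values("trial")["value"].to_numpy()
        if v1.size != v2.size:
            raise StatsError(
                f"unequal trial counts for unit {unit!r} ({v1.size} vs {v2.size}); "
                "aggregate repeats first"
            )
        sample = PairedSample(v2, v1, label=unit)   # positive dz = increase over frame1
        t, p = paired_t(sample)
        try:
            _, ad_p = normality_ad(sample.diffs)
        except StatsError:
            ad_p = np.nan
        rows.append(
            dict(contrast=contrast, unit=unit, metric=metric, n=sample.n,
                 t=t, p=p, dz=cohens_dz(sample), normality_p=ad_p)
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise StatsError(f"no units found for metric {metric!r}")
    q, reject = fdr_bh(out["p"].to_numpy(), alpha=alpha)
    out["q"] = q
    out["reject"] = reject
    out["power"] = [
        power_paired_t(dz, n, alpha) for dz, n in zip(out["dz"], out["n"])
    ]
    out["stars"] = [significance_stars(p) for p in out["p"]]
    return out
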