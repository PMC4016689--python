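"""Group summaries and two-sample comparisons for per-animal estimates.

Summaries report the group mean and the coefficient of variation
CV = SD/mean, with SD the sample (n-1) standard deviation.  Comparisons use
the two-tailed independent-samples t-test; the classical pooled-variance
Student form is the default, Welch is available.  Somal-size distributions
are compared on common bins with per-animal SEM and a location-shift sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "summarize_group",
    "t_test",
    "t_test_from_summary",
    "compare_distributions",
]

Variant = Literal["pooled", "welch"]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    @property
    def cv(self) -> float:
        return self.sd / self.mean

    def __str__(self) -> str:
        return f"{self.mean:.4g} (CV {self.cv:.2f}, n={self.n})"


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "significant": self.significant,
        }


def summarize_group(values: Sequence[float]) -> GroupSummary:
    """Mean and CV (= SD/mean) of per-animal values; requires n >= 2."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 animals for a group summary")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean == 0.0 and sd > 0.0:
        raise ValueError("CV undefined: zero mean with nonzero SD")
    return GroupSummary(n=int(v.size), mean=mean, sd=sd)


def _finish(parameter, mean_a, mean_b, t, df, p, alpha) -> ComparisonResult:
    return ComparisonResult(
        parameter=parameter,
        mean_a=float(mean_a),
        mean_b=float(mean_b),
        t=float(t),
        df=float(df),
        p=float(p),
        alpha=alpha,
    )


def t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: Variant = "pooled",
    parameter: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-tailed independent-samples t-test.

    Degenerate input (zero variance in both groups with equal means) returns
    t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        df = a.size + b.size - 2
        if a.mean() == b.mean():
            return _finish(parameter, a.mean(), b.mean(), 0.0, df, 1.0, alpha)
        return _finish(parameter, a.mean(), b.mean(), math.inf, df, 0.0, alpha)
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = a.size + b.size - 2 if variant == "pooled" else float(res.df)
    return _finish(parameter, a.mean(), b.mean(), res.statistic, df, res.pvalue, alpha)


def t_test_from_summary(
    mean_a: float,
    cv_a: float,
    n_a: int,
    mean_b: float,
    cv_b: float,
    n_b: int,
    variant: Variant = "pooled",
    parameter: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """t-test reconstructed from (mean, CV, n) summaries.

    SDs are recovered as mean x CV; this allows parity checks against
    published summary tables without per-animal raw data.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 values")
    if cv_a < 0 or cv_b < 0:
        raise ValueError("CVs must be >= 0")
    sd_a = abs(mean_a) * cv_a
    sd_b = abs(mean_b) * cv_b
    if sd_a == 0 and sd_b == 0:
        if mean_a == mean_b:
            return _finish(parameter, mean_a, mean_b, 0.0, n_a + n_b - 2, 1.0, alpha)
        return _finish(parameter, mean_a, mean_b, math.inf, n_a + n_b - 2, 0.0, alpha)
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return _finish(parameter, mean_a, mean_b, res.statistic, df, res.pvalue, alpha)


def compare_distributions(
    volumes_a: Sequence[Sequence[float]] | Sequence[float],
    volumes_b: Sequence[Sequence[float]] | Sequence[float],
    bin_width: float | None = None,
    bin_max: float | None = None,
) -> pd.DataFrame:
    """Common-bin histograms of per-cell somal volumes for two groups.

    ``volumes_a``/``volumes_b`` are either flat pools of per-cell volumes or
    per-animal lists (one sequence per animal).  Per-bin mean fractions are
    averaged across animals with their SEM; single-animal groups carry NaN
    SEM (flagged, not an error).  The result table has one row per bin plus
    summary attributes ``mean_shift`` (mean_b - mean_a) and ``shift_sign``.
    """
    a_lists = _as_animal_lists(volumes_a)
    b_lists = _as_animal_lists(volumes_b)
    if not a_lists or not b_lists:
        raise ValueError("both groups must be non-empty")
    all_v = np.concatenate([np.concatenate(a_lists), np.concatenate(b_lists)])
    hi = bin_max if bin_max is not None else float(all_v.max())
    if bin_width is None:
        bin_width = max(hi / 10.0, 1e-12)
    n_bins = max(int(math.ceil(hi / bin_width)), 1)
    edges = bin_width * np.arange(n_bins + 1)

    def group_hist(lists: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        fracs = []
        for v in lists:
            counts, _ = np.histogram(v, bins=edges)
            fracs.append(counts / max(len(v), 1))
        f = np.vstack(fracs)
        mean = f.mean(axis=0)
        sem = (
            f.std(axis=0, ddof=1) / math.sqrt(f.shape[0])
            if f.shape[0] > 1
            else np.full(n_bins, np.nan)
        )
        return mean, sem

    mean_a_bins, sem_a = group_hist(a_lists)
    mean_b_bins, sem_b = group_hist(b_lists)
    df = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "frac_a": mean_a_bins,
            "sem_a": sem_a,
            "frac_b": mean_b_bins,
            "sem_b": sem_b,
        }
    )
    mu_a = float(np.mean([v.mean() for v in a_lists]))
    mu_b = float(np.mean([v.mean() for v in b_lists]))
    df.attrs["mean_a"] = mu_a
    df.attrs["mean_b"] = mu_b
    df.attrs["mean_shift"] = mu_b - mu_a
    df.attrs["shift_sign"] = int(np.sign(mu_b - mu_a))
    return df


def _as_animal_lists(values) -> list[np.ndarray]:
    seq = list(values)
    if not seq:
        return []
    if np.isscalar(seq[0]) or isinstance(seq[0], (int, float, np.floating)):
        return [np.asarray(seq, dtype=float)]
    return [np.asarray(v, dtype=float) for v in seq if len(v)]
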