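"""Agreement and paired-comparison statistics for the validation battery.

Three tools: the intraclass correlation coefficient ICC(2,1) for
triplicate re-analyses, Bland-Altman limits of agreement for
contralateral comparability, and an exact Wilcoxon signed-rank test for
paired BV/TV differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "icc_triplicate",
    "BlandAltmanResult",
    "bland_altman",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "AgreementReport",
    "split_mouth_report",
]

EXACT_N_MAX = 25  # exact signed-rank null distribution up to this many pairs


def icc_triplicate(measurements: np.ndarray, form: str = "ICC(2,1)") -> tuple[float, str]:
    """Intraclass correlation from an (n subjects x k repeats) matrix.

    ICC(2,1): two-way random effects, absolute agreement, single
    measurement — the appropriate form when each repeat is a full
    re-execution of the measurement procedure.  ICC(3,1) (consistency) is
    available for comparison.  Computed from the ANOVA mean squares:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
        ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

    With identical repeats per subject and at least two distinct
    subjects, both forms equal exactly 1.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be an (n subjects x k repeats) matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need >= 2 subjects and >= 2 repeats, got {n} x {k}")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("all measurements identical; ICC undefined (zero total variance)")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    residual = x - row_means[:, None] - col_means[None, :] + grand
    sse = float((residual**2).sum())
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    # clamp float dust so identical repeats give exactly 1
    tiny = 1e-12 * max(msr, 1.0)
    msc = 0.0 if msc < tiny else msc
    mse = 0.0 if mse < tiny else mse
    if form == "ICC(2,1)":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form == "ICC(3,1)":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unsupported ICC form {form!r}")
    if denom == 0:
        raise ValueError("zero denominator; ICC undefined")
    return (msr - mse) / denom, form


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    critical_diff: float
    n: int
    pair_means: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement of paired series (differences d = a - b).

    Limits of agreement are mean(d) +/- 1.96 sd(d) with the n-1
    denominator; the critical difference (repeatability coefficient) is
    1.96 sd(d).  Pair means and differences are returned as plotting
    coordinates.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D series of equal length")
    if a.size < 2:
        raise ValueError(f"need >= 2 pairs, got {a.size}")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        critical_diff=1.96 * sd,
        n=a.size,
        pair_means=(a + b) / 2.0,
        differences=d,
    )


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after zero-difference removal
    method: str  # exact | normal


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray, alternative: str) -> float:
    """Exact p from the null distribution of W+ given the (mid-)ranks.

    Under H0 each pair's sign is an independent fair coin, so W+ is the
    sum of an independent random subset of the ranks; its distribution is
    built by convolution over ranks doubled to integers (mid-ranks are
    multiples of 1/2).
    """
    r2 = np.round(ranks * 2).astype(np.int64)
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(w_plus * 2))
    cdf_le = float(pmf[: w2 + 1].sum())
    cdf_ge = float(pmf[w2:].sum())
    if alternative == "greater":
        return min(cdf_ge, 1.0)
    if alternative == "less":
        return min(cdf_le, 1.0)
    return min(2.0 * min(cdf_le, cdf_ge), 1.0)


def wilcoxon_signed_rank(
    a: np.ndarray,
    b: np.ndarray | None = None,
    alternative: str = "two-sided",
    exact_n_max: int = EXACT_N_MAX,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired series (or one difference series).

    Zero differences are discarded (classical convention); tied absolute
    differences receive mid-ranks.  For up to ``exact_n_max`` remaining
    pairs the p value comes from the exact null distribution of W+; above
    that a normal approximation with tie correction (no continuity
    correction) is used.  The reported statistic is W+.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    if d.ndim != 1 or (b is not None and np.asarray(b).shape != a.shape):
        raise ValueError("inputs must be 1D paired series of equal length")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_n_max:
        p = _exact_signed_rank_p(w_plus, ranks, alternative)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= float((counts**3 - counts).sum()) / 48.0
        z = (w_plus - mean) / np.sqrt(var)
        if alternative == "greater":
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            p = float(sps.norm.cdf(z))
        else:
            p = float(2.0 * sps.norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(statistic=w_plus, p_value=min(p, 1.0), n_used=n, method=method)


@dataclass
class AgreementReport:
    """Combined validation statistics for a paired (split-mouth) table."""

    icc: float | None
    icc_form: str
    ba: BlandAltmanResult
    wilcoxon: WilcoxonResult
    n_pairs: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.wilcoxon.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "icc_form": self.icc_form,
            "ba_mean_diff": self.ba.mean_diff,
            "ba_sd_diff": self.ba.sd_diff,
            "ba_loa_low": self.ba.loa_low,
            "ba_loa_high": self.ba.loa_high,
            "ba_critical_diff": self.ba.critical_diff,
            "wilcoxon_stat": self.wilcoxon.statistic,
            "wilcoxon_p": self.wilcoxon.p_value,
            "wilcoxon_method": self.wilcoxon.method,
            "n_pairs": self.n_pairs,
            "alpha": self.alpha,
            "significant": self.significant,
        }


def split_mouth_report(
    study_table: pd.DataFrame,
    repeats: pd.DataFrame | np.ndarray | None = None,
    icc_form: str = "ICC(2,1)",
    alpha: float = 0.05,
) -> AgreementReport:
    """Full agreement report from a paired per-animal BV/TV table.

    ``study_table`` needs columns ``bv_tv_test`` and ``bv_tv_control``
    (one row per animal, as produced by :func:`morphometry.compare_sites`).
    If a ``repeats`` matrix (n subjects x k repeated analyses) is given,
    the ICC quantifies procedure repeatability across those repeats;
    otherwise the two sides act as the repeated measurements, which
    requires at least two animals.
    """
    for col in ("bv_tv_test", "bv_tv_control"):
        if col not in study_table.columns:
            raise ValueError(f"study table lacks column {col!r}")
    test = study_table["bv_tv_test"].to_numpy(dtype=float)
    control = study_table["bv_tv_control"].to_numpy(dtype=float)
    if test.size < 2:
        raise ValueError("need >= 2 animals (ICC and agreement undefined for a single pair)")
    if repeats is not None:
        icc, form = icc_triplicate(np.asarray(repeats, dtype=float), icc_form)
    else:
        icc, form = icc_triplicate(np.column_stack([test, control]), icc_form)
    ba = bland_altman(test, control)
    wil = wilcoxon_signed_rank(test, control)
    return AgreementReport(icc=icc, icc_form=form, ba=ba, wilcoxon=wil, n_pairs=test.size, alpha=alpha)
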