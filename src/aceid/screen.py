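"""Hit calling and screen statistics.

A treatment is a *hit* ("increase") when the mean of its technical
replicates lies more than three sample SDs above the neutral-control mean
of the (density-normalized) delivery readout; symmetric for "decrease".
Mechanistic-assay features are standardized against the neutral control
with the robust Z-score, z = (x − median_c) / (1.4826·MAD_c), and a
condition is flagged as a phenotypic outlier when any replicate exceeds
z > 3.  Group comparisons use Welch's unequal-variance t-test, Spearman
rank correlation, and Benjamini–Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HitCall",
    "call_hits",
    "robust_zscore",
    "outlier_flag",
    "welch_ttest",
    "spearman",
    "bh_adjust",
    "MAD_SCALE",
]

#: Scales the median absolute deviation to be consistent with the SD of a
#: normal distribution (1 / Phi^-1(3/4)).
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class HitCall:
    """Classification of one condition against the neutral control."""

    condition_id: str
    mean_normalized: float
    control_mean: float
    control_sd: float
    label: str  # "increase" | "no_effect" | "decrease"
    n_replicates: int = 0


def call_hits(condition_values: dict, control_values, *, n_sd: float = 3.0) -> list:
    """Classify each condition by the 3-SD rule against the neutral control.

    Parameters
    ----------
    condition_values : dict[str, array-like]
        Per-condition technical-replicate readouts (>= 2 each), on the same
        scale as ``control_values`` (raw or density-normalized).
    control_values : array-like
        Neutral-control replicate readouts (>= 8).
    n_sd : float
        Threshold width in control SDs (default 3).

    Returns
    -------
    list[HitCall]
        ``increase`` if the replicate mean exceeds mean_c + n_sd·sd_c,
        ``decrease`` if below mean_c − n_sd·sd_c, else ``no_effect``.
    """
    ctrl = np.asarray(control_values, dtype=float)
    if ctrl.size < 8:
        raise ValueError(f"need >= 8 control replicates, got {ctrl.size}")
    mu = float(ctrl.mean())
    sd = float(ctrl.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate control: zero standard deviation")
    hi, lo = mu + n_sd * sd, mu - n_sd * sd

    calls = []
    for cond, vals in condition_values.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValueError(f"condition {cond!r} has {v.size} replicate(s); need >= 2")
        m = float(v.mean())
        label = "increase" if m > hi else "decrease" if m < lo else "no_effect"
        calls.append(
            HitCall(
                condition_id=cond,
                mean_normalized=m,
                control_mean=mu,
                control_sd=sd,
                label=label,
                n_replicates=int(v.size),
            )
        )
    return calls


def robust_zscore(values, control_values):
    """Robust Z-score of ``values`` against neutral-control replicates.

    z = (x − median_c) / (1.4826 · MAD_c), where MAD_c is the median
    absolute deviation of the control replicates.  Requires >= 4 control
    replicates and a nonzero MAD.
    """
    ctrl = np.asarray(control_values, dtype=float)
    if ctrl.size < 4:
        raise ValueError(f"need >= 4 control replicates, got {ctrl.size}")
    med = float(np.median(ctrl))
    mad = float(np.median(np.abs(ctrl - med)))
    if mad == 0:
        raise ValueError("degenerate control: zero MAD")
    out = (np.asarray(values, dtype=float) - med) / (MAD_SCALE * mad)
    return out if np.ndim(out) else float(out)


def outlier_flag(z_values, *, threshold: float = 3.0) -> bool:
    """True iff any technical replicate's robust Z exceeds the threshold."""
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("need >= 1 replicate z-value")
    return bool(np.max(z) > threshold)


def welch_ttest(a, b) -> tuple:
    """Unpaired two-tailed t-test with Welch's correction.

    Returns ``(t, df, p)``.  Requires >= 3 values per group and nonzero
    variance in at least one group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            # Identical constant groups: no evidence of a difference.
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("undefined statistic: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def spearman(x, y) -> tuple:
    """Spearman rank correlation with two-tailed p-value: ``(rho, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples, n >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_adjust(p_values):
    """Benjamini–Hochberg FDR-adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
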