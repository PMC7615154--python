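"""One-phase decay model linking cell density to per-cell functional delivery.

Sparse cultures express more reporter protein per cell than dense ones, so a
raw per-cell mCherry readout confounds a treatment's effect on delivery with
its effect on proliferation.  The screen therefore seeds neutral-control
wells over a density series, fits the one-phase decay

    Y(x) = (Y0 - Plateau) * exp(-K * x) + Plateau

(x = cells per well), and divides every test well's readout by the fitted
curve at that well's cell count.  A normalized value of 1.0 means
"on-curve"; deviations above/below reflect genuine increases/decreases in
delivery, independent of density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecayParams",
    "DecayFit",
    "DecayFitError",
    "delivery_response",
    "fit_density_decay",
    "normalize_by_density",
]


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the one-phase decay Y = (Y0 - Plateau)·e^(−K·x) + Plateau.

    Attributes
    ----------
    y0 : float
        Expected per-cell reporter intensity extrapolated to zero density.
    plateau : float
        Asymptotic per-cell intensity at high density; ``0 <= plateau < y0``.
    k : float
        Rate constant per seeded cell; ``k > 0``.
    """

    y0: float
    plateau: float
    k: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.y0, self.plateau, self.k]).all():
            raise ValueError("decay parameters must be finite")
        if self.y0 <= self.plateau:
            raise ValueError(f"Y0 ({self.y0}) must exceed Plateau ({self.plateau})")
        if self.plateau < 0:
            raise ValueError(f"Plateau must be >= 0, got {self.plateau}")
        if self.k <= 0:
            raise ValueError(f"K must be > 0, got {self.k}")


class DecayFitError(RuntimeError):
    """Nonlinear fit of the density–delivery curve failed to converge.

    Carries the initial parameter guesses and the residuals at those
    guesses so the failure can be diagnosed.
    """

    def __init__(self, message: str, init: tuple[float, float, float], residuals: np.ndarray):
        super().__init__(message)
        self.init = init
        self.residuals = residuals


@dataclass(frozen=True)
class DecayFit:
    """Result of fitting the one-phase decay to control wells."""

    params: DecayParams
    stderr: dict = field(default_factory=dict)  # per-parameter standard errors
    residual_sd: float = float("nan")
    n: int = 0
    converged: bool = True
    k_identifiable: bool = True

    def predict(self, cell_count) -> np.ndarray:
        return delivery_response(cell_count, self.params)


def delivery_response(cell_count, params: DecayParams):
    """Expected per-cell delivery readout at a given cell density.

    Evaluates ``(Y0 - Plateau)·exp(-K·x) + Plateau``.  Strictly decreasing
    in ``cell_count``; equals Y0 at zero density and approaches Plateau as
    density grows.

    Parameters
    ----------
    cell_count : float or array-like
        Cells per well, >= 0.
    params : DecayParams
        Curve parameters (validated on construction).
    """
    x = np.asarray(cell_count, dtype=float)
    if np.any(x < 0):
        raise ValueError("cell_count must be >= 0")
    out = (params.y0 - params.plateau) * np.exp(-params.k * x) + params.plateau
    return out if out.ndim else float(out)


def _decay(x, y0, plateau, k):
    return (y0 - plateau) * np.exp(-k * x) + plateau


def fit_density_decay(
    cell_counts,
    delivery,
    *,
    flat_rtol: float = 1e-8,
    monotone_warn_rho: float = 0.3,
) -> DecayFit:
    """Fit the one-phase decay to neutral-control wells over a density series.

    Initialization: ``Y0 = max(Y)``, ``Plateau = min(Y)``, and K from a
    log-linear regression of ``Y - Plateau_init`` against cell count, then
    refined by nonlinear least squares (Levenberg–Marquardt via
    ``scipy.optimize.curve_fit``).

    Parameters
    ----------
    cell_counts, delivery : array-like
        Paired (cells per well, per-cell readout) for >= 6 control wells
        spanning >= 3 distinct densities.

    Returns
    -------
    DecayFit
        Parameter estimates, standard errors, residual SD and flags.  Flat
        input (no density dependence resolvable) returns a degenerate fit
        with ``k_identifiable=False`` and Plateau at the mean rather than
        raising.

    Raises
    ------
    DecayFitError
        If the optimizer does not converge; carries init and residuals.
    """
    x = np.asarray(cell_counts, dtype=float)
    y = np.asarray(delivery, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("cell_counts and delivery must be equal-length 1-D arrays")
    n = x.size
    if n < 6:
        raise ValueError(f"need >= 6 control wells, got {n}")
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct densities")

    scale = max(abs(float(np.mean(y))), 1.0)
    if np.ptp(y) <= flat_rtol * scale:
        # Flat response: K is unidentifiable; report the mean as the plateau.
        c = float(np.mean(y))
        return DecayFit(
            params=DecayParams(y0=c + max(flat_rtol * scale, 1e-12), plateau=c, k=1.0 / max(x.max(), 1.0)),
            stderr={},
            residual_sd=float(np.std(y, ddof=1)),
            n=n,
            converged=True,
            k_identifiable=False,
        )

    rho, _ = stats.spearmanr(x, y)
    if rho > monotone_warn_rho:
        warnings.warn(
            f"delivery increases with density (Spearman rho={rho:.2f}); "
            "one-phase decay may be inappropriate",
            stacklevel=2,
        )

    y0_init = float(y.max())
    plateau_init = float(y.min())
    # Log-linear K init on the points still above the plateau guess.
    excess = y - plateau_init
    ok = excess > 0
    if ok.sum() >= 2 and np.unique(x[ok]).size >= 2:
        slope = np.polyfit(x[ok], np.log(excess[ok]), 1)[0]
        k_init = -slope if slope < 0 else 1.0 / max(float(np.mean(x)), 1.0)
    else:
        k_init = 1.0 / max(float(np.mean(x)), 1.0)
    p0 = (y0_init, plateau_init, k_init)

    # Relative-error weighting: the readout's noise is multiplicative
    # (roughly constant CV), so residuals are weighted by 1/Y.
    sigma = y if np.all(y > 0) else None
    try:
        popt, pcov = optimize.curve_fit(
            _decay, x, y, p0=p0, sigma=sigma, maxfev=20000,
            bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise DecayFitError(str(exc), p0, y - _decay(x, *p0)) from exc

    y0_hat, plateau_hat, k_hat = (float(v) for v in popt)
    if not y0_hat > plateau_hat:
        raise DecayFitError(
            "fit degenerate: Y0 <= Plateau", p0, y - _decay(x, *popt)
        )
    resid = y - _decay(x, *popt)
    dof = max(n - 3, 1)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return DecayFit(
        params=DecayParams(y0=y0_hat, plateau=plateau_hat, k=k_hat),
        stderr={"y0": float(se[0]), "plateau": float(se[1]), "k": float(se[2])},
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        n=n,
        converged=True,
        k_identifiable=True,
    )


def normalize_by_density(delivery, cell_count, fit: DecayFit, *, method: str = "ratio"):
    """Normalize a well's delivery readout to the fitted density curve.

    ``method="ratio"`` (default) returns ``observed / Y_fit(cell_count)`` —
    dimensionless, 1.0 = on-curve.  ``method="residual"`` returns
    ``observed - Y_fit(cell_count)`` (0 = on-curve), in intensity units.

    Raises
    ------
    ValueError
        If the fit did not converge, a cell count is non-positive, or the
        fitted curve is non-positive at a requested density (ratio method).
    """
    if not fit.converged:
        raise ValueError("cannot normalize with a non-converged decay fit")
    x = np.asarray(cell_count, dtype=float)
    if np.any(x <= 0):
        raise ValueError("cell_count must be > 0 for normalization")
    y = np.asarray(delivery, dtype=float)
    expected = delivery_response(x, fit.params)
    if method == "ratio":
        if np.any(np.asarray(expected) <= 0):
            raise ValueError("fitted curve non-positive at requested density")
        out = y / expected
    elif method == "residual":
        out = y - expected
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return out if np.ndim(out) else float(out)
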