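"""Two-stage estimation of quenching parameters.

Stage one calibrates the Stern-Volmer constant ``Kq`` from a quencher-only
titration (:func:`fit_sv_constant`, ordinary least squares with a free
intercept). Stage two fits the protected fraction ``x`` of a
vesicle-reconstituted sample with ``Kq`` held fixed
(:func:`fit_orientation_fraction`, bounded least squares on the ratio scale).

Uncertainty comes from a case-resampling bootstrap (:func:`bootstrap_ci`);
:func:`joint_fit` fits both parameters simultaneously as an identifiability
diagnostic; :func:`aggregate_replicates` and :func:`classify_orientation`
summarise replicate experiments and turn the mean fraction into an
orientation-preference call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .models import QuenchParams, TitrationSeries, orientation_ratio, sv_ratio

__all__ = [
    "CalibrationResult",
    "OrientationFit",
    "ReplicateSummary",
    "OrientationCall",
    "N_IN_PREFERRED",
    "C_IN_PREFERRED",
    "NO_PREFERENCE",
    "NO_PREFERENCE_BAND",
    "WEAK_QUENCHING_THRESHOLD",
    "JOINT_CONDITION_THRESHOLD",
    "fit_sv_constant",
    "fit_orientation_fraction",
    "bootstrap_ci",
    "joint_fit",
    "aggregate_replicates",
    "classify_orientation",
]

#: Half-width of the |x - 0.5| band called "no preference".
NO_PREFERENCE_BAND = 0.04

#: Below Kq * max(Q) of this value, x is poorly resolved by the design.
WEAK_QUENCHING_THRESHOLD = 0.5

#: Covariance condition number above which the joint fit is flagged
#: as practically unidentifiable.
JOINT_CONDITION_THRESHOLD = 1e8

N_IN_PREFERRED = "N_IN_PREFERRED"
C_IN_PREFERRED = "C_IN_PREFERRED"
NO_PREFERENCE = "NO_PREFERENCE"


class CalibrationWarning(UserWarning):
    """Raised when a calibration diagnostic is out of its expected range."""


class IdentifiabilityWarning(UserWarning):
    """Raised when the design gives weak leverage on a parameter."""


@dataclass
class CalibrationResult:
    """Stern-Volmer calibration: slope of I0/I versus [Q]."""

    Kq_hat: float
    Kq_stderr: float
    intercept: float
    r_squared: float
    n_points: int
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.Kq_hat <= 0:
            raise ValueError("Kq_hat must be positive")
        if self.n_points < 3:
            raise ValueError("calibration needs at least 3 points")


@dataclass
class OrientationFit:
    """Protected-fraction fit with Kq held fixed."""

    x_hat: float
    x_stderr: float
    ci_low: float
    ci_high: float
    Kq_used: float
    rss: float
    converged: bool
    clipped: bool
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.x_hat <= self.ci_high <= 1.0):
            raise ValueError(
                "require 0 <= ci_low <= x_hat <= ci_high <= 1, got "
                f"({self.ci_low}, {self.x_hat}, {self.ci_high})"
            )


@dataclass
class ReplicateSummary:
    """Mean and standard error of x over replicate fits."""

    x_mean: float
    x_err: float
    n_replicates: int
    member_fits: List[OrientationFit]

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.x_err < 0:
            raise ValueError("x_err must be non-negative")


@dataclass(frozen=True)
class OrientationCall:
    """Orientation-preference label with its distance from x = 0.5."""

    label: str
    margin: float


def fit_sv_constant(series: TitrationSeries) -> CalibrationResult:
    """Estimate Kq by OLS of the observed I0/I ratio on [Q].

    The intercept is left free as a baseline-drift diagnostic; a
    :class:`CalibrationWarning` is issued when it departs from 1 by more
    than 0.05. Requires at least 3 distinct nonzero quencher concentrations.
    """
    Q, ratio = series.nonzero()
    if Q.size < 3:
        raise ValueError(
            f"calibration needs >= 3 nonzero-quencher points, got {Q.size}"
        )
    res = stats.linregress(Q, ratio)
    if res.slope <= 0:
        raise ValueError("no quenching detected (fitted slope is not positive)")
    if abs(res.intercept - 1.0) > 0.05:
        warnings.warn(
            f"calibration intercept {res.intercept:.4f} deviates from 1 by "
            f"more than 0.05; check the baseline",
            CalibrationWarning,
            stacklevel=2,
        )
    fitted = res.intercept + res.slope * Q
    return CalibrationResult(
        Kq_hat=float(res.slope),
        Kq_stderr=float(res.stderr),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(Q.size),
        residuals=ratio - fitted,
    )


def _invert_points(Kq: float, Q: np.ndarray, ratio: np.ndarray) -> np.ndarray:
    # unclipped per-point solutions for x; robust to noisy ratio < 1
    s = 1.0 + Kq * Q
    return (s / ratio - 1.0) / (Kq * Q)


def _orientation_objective(x: float, Kq: float, Q: np.ndarray, ratio: np.ndarray) -> float:
    model = orientation_ratio(QuenchParams(Kq=Kq, x=min(max(x, 0.0), 1.0)), Q)
    return float(np.sum((model - ratio) ** 2))


def fit_orientation_fraction(series: TitrationSeries, Kq: float) -> OrientationFit:
    """Fit the protected fraction x on the I0/I scale with Kq fixed.

    Unweighted least squares, x bounded to [0, 1] via scalar minimisation
    initialised at the mean of the per-point model inversions. The ``clipped``
    flag records that this unconstrained per-point average fell outside
    [0, 1]. A weak-quenching design (``Kq * max(Q) < 0.5``) attaches an
    identifiability warning rather than failing.
    """
    if not (math.isfinite(Kq) and Kq > 0):
        raise ValueError(f"Kq must be finite and positive, got {Kq}")
    Q, ratio = series.nonzero()
    if Q.size < 3:
        raise ValueError(
            f"orientation fit needs >= 3 nonzero-quencher points, got {Q.size}"
        )
    fit_warnings: List[str] = []
    if Kq * float(Q.max()) < WEAK_QUENCHING_THRESHOLD:
        msg = (
            f"Kq*max(Q) = {Kq * float(Q.max()):.3g} < {WEAK_QUENCHING_THRESHOLD}: "
            "quenching too weak to resolve x reliably"
        )
        fit_warnings.append(msg)
        warnings.warn(msg, IdentifiabilityWarning, stacklevel=2)

    inversions = _invert_points(Kq, Q, ratio)
    inv_mean = float(np.mean(inversions))
    clipped = not (0.0 <= inv_mean <= 1.0)
    x0 = min(max(inv_mean, 0.01), 0.99)

    res = optimize.minimize_scalar(
        _orientation_objective,
        bounds=(0.0, 1.0),
        args=(Kq, Q, ratio),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"orientation fit did not converge: {res.message}")
    x_hat = float(min(max(res.x, 0.0), 1.0))
    rss = float(res.fun)
    # break near-flat ties toward the inversion-based initialiser
    if _orientation_objective(x0, Kq, Q, ratio) <= rss + 1e-15:
        x_hat, rss = x0, _orientation_objective(x0, Kq, Q, ratio)

    x_stderr = _linearised_stderr(x_hat, Kq, Q, ratio, rss)
    ci_low = min(max(x_hat - 1.96 * x_stderr, 0.0), x_hat)
    ci_high = max(min(x_hat + 1.96 * x_stderr, 1.0), x_hat)
    return OrientationFit(
        x_hat=x_hat,
        x_stderr=x_stderr,
        ci_low=ci_low,
        ci_high=ci_high,
        Kq_used=float(Kq),
        rss=rss,
        converged=True,
        clipped=clipped,
        warnings=fit_warnings,
    )


def _linearised_stderr(
    x: float, Kq: float, Q: np.ndarray, ratio: np.ndarray, rss: float
) -> float:
    """Wald standard error of x from the local slope of the model."""
    s = 1.0 + Kq * Q
    denom = s * x + 1.0 - x
    grad = -s * (s - 1.0) / denom**2  # d(model)/dx
    dof = max(int(Q.size) - 1, 1)
    sigma2 = rss / dof
    gg = float(np.sum(grad**2))
    if gg == 0.0:
        return 0.0
    return math.sqrt(sigma2 / gg)


def bootstrap_ci(
    series: TitrationSeries,
    Kq: float,
    n_boot: int = 1000,
    seed: int | None = None,
) -> Tuple[float, float]:
    """Percentile 95% interval for x by case-resampling titration points.

    Nonzero-quencher points are resampled with replacement (the zero-quencher
    baseline is kept); draws with fewer than 3 distinct concentrations are
    redrawn. Deterministic for a given ``seed`` and invariant to the input
    point order (points are handled in concentration order).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for a stable percentile interval")
    if seed is None:
        raise ValueError("a seed is required for reproducible resampling")
    Q, ratio = series.nonzero()
    if Q.size < 3:
        raise ValueError("bootstrap needs >= 3 nonzero-quencher points")
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, Q.size, size=Q.size)
            if np.unique(Q[idx]).size >= 3:
                break
        qb, rb = Q[idx], ratio[idx]
        res = optimize.minimize_scalar(
            _orientation_objective,
            bounds=(0.0, 1.0),
            args=(Kq, qb, rb),
            method="bounded",
            options={"xatol": 1e-10},
        )
        estimates[b] = min(max(res.x, 0.0), 1.0)
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return float(lo), float(hi)


def joint_fit(series: TitrationSeries) -> Tuple[QuenchParams, np.ndarray]:
    """Simultaneous (Kq, x) fit — an identifiability diagnostic.

    Returns the fitted parameters and the 2x2 parameter covariance matrix
    (``numpy.inf`` entries when the Jacobian is singular, e.g. at x = 1 where
    Kq drops out of the model). The two-stage procedure is preferred in
    practice because with weak quenching (small ``Kq * max(Q)``) the two
    parameters trade off strongly and the covariance becomes ill-conditioned.
    """
    Q, ratio = series.nonzero()
    if Q.size < 3:
        raise ValueError("joint fit needs >= 3 nonzero-quencher points")

    q_max = float(Q.max())

    # fit in (kappa, x) with kappa = Kq * max(Q) so both parameters are O(1)
    # and the covariance condition number reflects intrinsic identifiability
    def resid(theta: np.ndarray) -> np.ndarray:
        kappa, x = theta
        s = 1.0 + kappa * (Q / q_max)
        return s / (s * x + 1.0 - x) - ratio

    r_max = float(ratio.max())
    kappa0 = max(2.0 * (r_max - 1.0), 0.1)  # most-quenched point, x ~ 0.5 guess
    res = optimize.least_squares(
        resid,
        x0=[kappa0, 0.5],
        bounds=([1e-12, 0.0], [np.inf, 1.0]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    if not res.success:
        raise RuntimeError(f"joint fit did not converge: {res.message}")
    kq_hat, x_hat = float(res.x[0]) / q_max, float(min(max(res.x[1], 0.0), 1.0))
    dof = max(Q.size - 2, 1)
    sigma2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    cond = float(np.linalg.cond(jtj))  # scale-free: cond(cov) == cond(JtJ)
    try:
        cov_scaled = sigma2 * np.linalg.inv(jtj)
        scale = np.diag([1.0 / q_max, 1.0])
        cov = scale @ cov_scaled @ scale
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.inf)
        cond = np.inf
    if not np.isfinite(cond) or cond > JOINT_CONDITION_THRESHOLD:
        warnings.warn(
            f"joint-fit covariance condition number {cond:.3g} exceeds "
            f"{JOINT_CONDITION_THRESHOLD:.0g}; parameters are practically "
            "unidentifiable — use the two-stage procedure",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    return QuenchParams(Kq=kq_hat, x=x_hat), cov


def aggregate_replicates(fits: Sequence[OrientationFit]) -> ReplicateSummary:
    """Arithmetic mean of x over replicates, with its standard error.

    The standard error of the mean is 0 for a single replicate.
    """
    if not fits:
        raise ValueError("no replicate fits to aggregate")
    xs = np.asarray([f.x_hat for f in fits], dtype=float)
    n = xs.size
    err = float(np.std(xs, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return ReplicateSummary(
        x_mean=float(xs.mean()),
        x_err=err,
        n_replicates=int(n),
        member_fits=list(fits),
    )


def classify_orientation(
    summary: ReplicateSummary, band: float = NO_PREFERENCE_BAND
) -> OrientationCall:
    """Call the orientation preference from the replicate mean.

    ``NO_PREFERENCE`` within ``|x_mean - 0.5| <= band``; ``N_IN_PREFERRED``
    above, ``C_IN_PREFERRED`` below.
    """
    margin = abs(summary.x_mean - 0.5)
    if margin <= band:
        label = NO_PREFERENCE
    elif summary.x_mean > 0.5:
        label = N_IN_PREFERRED
    else:
        label = C_IN_PREFERRED
    return OrientationCall(label=label, margin=margin)
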