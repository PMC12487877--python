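"""Sample-efficiency curves: power-law fits of error versus training-set size.

Keypoint-tracker error as a function of the number of training frames x is
modeled by a power-law decay

    y = a * (x + 1)**b + c          (a > 0, b < 0)

whose asymptote c is the best achievable error; saturating performance
metrics use the inverted form

    y = a * (1 - 1 / (x + 1)**b) + c    (b > 0).

The decay form is inverted analytically to answer "how many training frames
are needed to reach error t":  x = (a / (t - c))**(1 / -b) - 1, rounded up;
targets at or below the asymptote (t <= c) are unreachable.  Uncertainty
bands come from a case-resampling bootstrap over the (x, y) points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

DECAY = "decay"
SATURATING = "saturating"

#: sentinel returned by frames_required when the target is below the asymptote
UNREACHABLE = -1


@dataclass
class PowerLawFit:
    a: float
    b: float
    c: float
    form: str = DECAY
    converged: bool = True
    degenerate: bool = False
    rss: float = float("nan")

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return _evaluate(self.form, self.a, self.b, self.c, np.asarray(x, dtype=np.float64))


@dataclass
class BootstrapBand:
    x_grid: np.ndarray
    low: np.ndarray  # 2.5th percentile of fitted curves at each x
    high: np.ndarray  # 97.5th percentile
    median: np.ndarray
    fits: list[PowerLawFit] = field(default_factory=list)


def _evaluate(form: str, a: float, b: float, c: float, x: np.ndarray) -> np.ndarray:
    # wild exponents during multi-start/bootstrap exploration may overflow;
    # inf residuals are handled by the optimizer, so silence the warning
    with np.errstate(over="ignore"):
        if form == DECAY:
            return a * (x + 1.0) ** b + c
        if form == SATURATING:
            return a * (1.0 - (x + 1.0) ** (-b)) + c
    raise ValueError(f"unknown form {form!r}")


def fit_power_law(
    x: np.ndarray, y: np.ndarray, form: str = DECAY, n_starts: int = 5, seed: int = 0
) -> PowerLawFit:
    """Least-squares (a, b, c) with multi-start initialization.

    Starts jitter the exponent around -0.5 (decay) / +0.5 (saturating);
    the lowest-residual converged start wins.  Constant y-data leaves the
    exponent unidentifiable and is flagged degenerate.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter power law")
    if np.any(x < 0):
        raise ValueError("x (training frame counts) must be >= 0")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return PowerLawFit(0.0, 0.0, float(y[0]), form, converged=False, degenerate=True)

    if form == DECAY:
        c0 = float(y.min())
        b_sign = -1.0
    elif form == SATURATING:
        c0 = float(y[np.argmin(x)])
        b_sign = 1.0
    else:
        raise ValueError(f"unknown form {form!r}")
    a0 = abs(float(y[np.argmin(x)]) - c0) or max(np.ptp(y), 1.0)

    rng = np.random.default_rng(seed)
    b_starts = b_sign * np.concatenate([[0.5], np.exp(rng.normal(math.log(0.5), 0.7, n_starts - 1))])

    def residuals(p: np.ndarray) -> np.ndarray:
        return _evaluate(form, p[0], p[1], p[2], x) - y

    best = None
    for b0 in b_starts:
        p0 = np.array([max(a0, 1e-6), b0, c0])
        try:
            res = optimize.least_squares(residuals, p0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res.x)
    if best is None:
        return PowerLawFit(np.nan, np.nan, np.nan, form, converged=False)
    rss, (a, b, c) = best
    return PowerLawFit(float(a), float(b), float(c), form, converged=True, rss=rss)


def bootstrap_band(
    x: np.ndarray,
    y: np.ndarray,
    form: str = DECAY,
    n_boot: int = 1000,
    seed: int = 0,
    x_grid: np.ndarray | None = None,
    level: float = 95.0,
) -> BootstrapBand:
    """Case-resampling bootstrap band (default 95%) plus the median curve.

    (x, y) pairs are resampled with replacement ``n_boot`` times; each
    resample is refit (single start from the full-data estimate for speed)
    and evaluated on ``x_grid``.  Resamples whose x-values are all identical
    cannot identify the curve and are redrawn.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if x_grid is None:
        x_grid = np.linspace(x.min(), x.max(), 100)
    rng = np.random.default_rng(seed)
    full = fit_power_law(x, y, form=form)
    curves = np.empty((n_boot, x_grid.size))
    fits: list[PowerLawFit] = []
    for i in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, x.size, size=x.size)
            if np.ptp(x[idx]) > 0:
                break
        else:
            raise ValueError("bootstrap resamples degenerate: all x identical")
        xb, yb = x[idx], y[idx]

        def residuals(p: np.ndarray) -> np.ndarray:
            return _evaluate(form, p[0], p[1], p[2], xb) - yb

        p0 = np.array([full.a, full.b, full.c]) if full.converged else np.array([1.0, -0.5, y.min()])
        res = optimize.least_squares(residuals, p0, xtol=1e-12, ftol=1e-12)
        fit = PowerLawFit(*map(float, res.x), form=form, converged=bool(res.success))
        fits.append(fit)
        curves[i] = fit.predict(x_grid)
    half = (100.0 - level) / 2.0
    return BootstrapBand(
        x_grid=x_grid,
        low=np.percentile(curves, half, axis=0),
        high=np.percentile(curves, 100.0 - half, axis=0),
        median=np.percentile(curves, 50.0, axis=0),
        fits=fits,
    )


def frames_required(fit: PowerLawFit, error_threshold: float) -> int:
    """Training frames needed for the fitted decay curve to reach a target error.

    Closed-form inversion of y = a (x+1)^b + c, rounded *up* so the returned
    count is guaranteed to meet the threshold; returns ``UNREACHABLE`` (-1)
    when the target is at or below the asymptote c.
    """
    if fit.form != DECAY:
        raise ValueError("frames_required applies to the decay form")
    if not (fit.a > 0 and fit.b < 0):
        raise ValueError("decay inversion requires a > 0 and b < 0")
    if error_threshold <= fit.c:
        return UNREACHABLE
    x = (fit.a / (error_threshold - fit.c)) ** (1.0 / -fit.b) - 1.0
    return max(0, math.ceil(x - 1e-9))
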