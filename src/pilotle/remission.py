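"""Weekly seizure-trajectory model selection.

Whether epilepsy persists or remits is assessed by fitting weekly seizure
totals to a small candidate set — one-phase exponential decay
``Y(t) = plateau + (Y0 - plateau) e^{-k t}``, a straight line, a
horizontal line, and optionally a Gaussian transient
``Y(t) = A e^{-(t - c)^2 / (2 w^2)}`` — and selecting among them by AICc
(small-sample corrected Akaike information criterion), ties resolved
toward fewer parameters.  An extra-sum-of-squares F-test against the
horizontal line is reported alongside for each non-horizontal model.

:class:`RemissionTrajectory` is the statsmodels-style entry point:
construct from the weekly totals, call ``fit()``, inspect
``results.best`` / ``results.summary()``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .exceptions import InsufficientDataError

__all__ = [
    "RemissionModelName",
    "RemissionFit",
    "RemissionTrajectory",
    "RemissionResults",
    "fit_remission_models",
]

_TINY_RSS = 1e-12


class RemissionModelName(str, enum.Enum):
    ONE_PHASE_DECAY = "one_phase_decay"
    STRAIGHT_LINE = "straight_line"
    HORIZONTAL_LINE = "horizontal_line"
    GAUSSIAN = "gaussian"


#: number of mean-function parameters per model
_N_PARAMS = {
    RemissionModelName.ONE_PHASE_DECAY: 3,
    RemissionModelName.STRAIGHT_LINE: 2,
    RemissionModelName.HORIZONTAL_LINE: 1,
    RemissionModelName.GAUSSIAN: 3,
}


@dataclass(frozen=True)
class RemissionFit:
    """One fitted candidate model."""

    model: RemissionModelName
    params: dict[str, float]
    rss: float
    r2: float
    aicc: float
    p_vs_horizontal: float

    @property
    def n_params(self) -> int:
        return _N_PARAMS[self.model]

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.model is RemissionModelName.HORIZONTAL_LINE:
            return np.full_like(t, p["mean"])
        if self.model is RemissionModelName.STRAIGHT_LINE:
            return p["intercept"] + p["slope"] * t
        if self.model is RemissionModelName.ONE_PHASE_DECAY:
            return p["plateau"] + (p["y0"] - p["plateau"]) * np.exp(-p["k"] * t)
        return p["amplitude"] * np.exp(-0.5 * ((t - p["center"]) / p["width"]) ** 2)


def _aicc(rss: float, n: int, n_params: int) -> float:
    """AICc for Gaussian-error least squares; k counts the error variance."""
    k = n_params + 1
    if n - k - 1 <= 0:
        return float("inf")
    aic = n * math.log(max(rss, _TINY_RSS) / n) + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _f_test_vs_horizontal(rss_m: float, p_m: int, rss_h: float, n: int) -> float:
    """Extra-sum-of-squares p-value of model m against the horizontal line."""
    if rss_h <= _TINY_RSS:
        return 1.0  # horizontal already perfect; nothing to improve on
    if rss_m <= _TINY_RSS:
        return 0.0
    df_m = n - p_m
    if df_m <= 0 or rss_m >= rss_h:
        return 1.0
    f_stat = ((rss_h - rss_m) / (p_m - 1)) / (rss_m / df_m)
    return float(f_dist.sf(f_stat, p_m - 1, df_m))


class RemissionTrajectory:
    """Candidate-model comparison for a weekly seizure-count trajectory.

    Parameters
    ----------
    weekly_totals : sequence of float
        Seizures per consecutive week (week 0, 1, ...).
    include_gaussian : bool
        Also fit the Gaussian transient (needs >= 5 weeks); used for
        trajectories that rise and then remit.
    """

    def __init__(self, weekly_totals: Sequence[float], include_gaussian: bool = False):
        y = np.asarray(weekly_totals, dtype=float)
        if y.ndim != 1:
            raise InsufficientDataError("weekly totals must be 1-D")
        min_n = 5 if include_gaussian else 4
        if len(y) < min_n:
            raise InsufficientDataError(
                f"need >= {min_n} weekly bins, got {len(y)}"
            )
        self.y = y
        self.t = np.arange(len(y), dtype=float)
        self.include_gaussian = include_gaussian

    # -- per-model fits ----------------------------------------------------

    def _fit_horizontal(self) -> tuple[dict, float]:
        mean = float(self.y.mean())
        rss = float(np.sum((self.y - mean) ** 2))
        return {"mean": mean}, rss

    def _fit_line(self) -> tuple[dict, float]:
        slope, intercept = np.polyfit(self.t, self.y, 1)
        rss = float(np.sum((self.y - (intercept + slope * self.t)) ** 2))
        return {"slope": float(slope), "intercept": float(intercept)}, rss

    def _fit_decay(self) -> tuple[dict, float]:
        t, y = self.t, self.y

        def resid(theta):
            y0, plateau, k = theta
            return plateau + (y0 - plateau) * np.exp(-k * t) - y

        lb = np.array([0.0, 0.0, 0.0])
        ub = np.array([np.inf, np.inf, np.inf])
        best = None
        for k0 in (0.05, 0.2, 0.8, 2.0):
            x0 = np.array([max(y[0], 1e-6), max(y.min(), 0.0) + 1e-6, k0])
            sol = least_squares(resid, np.clip(x0, lb, 1e12), bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, max_nfev=2000)
            if best is None or sol.cost < best.cost:
                best = sol
        y0, plateau, k = best.x
        rss = float(2 * best.cost)
        return {"y0": float(y0), "plateau": float(plateau), "k": float(k)}, rss

    def _fit_gaussian(self) -> tuple[dict, float]:
        t, y = self.t, self.y

        def resid(theta):
            a, c, w = theta
            return a * np.exp(-0.5 * ((t - c) / w) ** 2) - y

        lb = np.array([0.0, -len(t), 1e-3])
        ub = np.array([np.inf, 2.0 * len(t), np.inf])
        c0 = float(t[np.argmax(y)])
        best = None
        for w0 in (1.0, len(t) / 4.0, len(t) / 2.0):
            x0 = np.clip(np.array([max(y.max(), 1e-6), c0, w0]), lb, 1e12)
            sol = least_squares(resid, x0, bounds=(lb, ub),
                                xtol=1e-12, ftol=1e-12, max_nfev=2000)
            if best is None or sol.cost < best.cost:
                best = sol
        a, c, w = best.x
        return {"amplitude": float(a), "center": float(c), "width": float(w)}, float(
            2 * best.cost
        )

    def fit(self) -> "RemissionResults":
        n = len(self.y)
        tss = float(np.sum((self.y - self.y.mean()) ** 2))
        _, rss_h = self._fit_horizontal()

        fits: list[RemissionFit] = []
        candidates = [
            (RemissionModelName.HORIZONTAL_LINE, self._fit_horizontal),
            (RemissionModelName.STRAIGHT_LINE, self._fit_line),
            (RemissionModelName.ONE_PHASE_DECAY, self._fit_decay),
        ]
        if self.include_gaussian:
            candidates.append((RemissionModelName.GAUSSIAN, self._fit_gaussian))
        for name, fitter in candidates:
            params, rss = fitter()
            p_m = _N_PARAMS[name]
            r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss <= _TINY_RSS else 0.0)
            p_vs_h = (
                1.0
                if name is RemissionModelName.HORIZONTAL_LINE
                else _f_test_vs_horizontal(rss, p_m, rss_h, n)
            )
            fits.append(
                RemissionFit(
                    model=name, params=params, rss=rss, r2=r2,
                    aicc=_aicc(rss, n, p_m), p_vs_horizontal=p_vs_h,
                )
            )
        best = min(fits, key=lambda f: (round(f.aicc, 9), f.n_params))
        return RemissionResults(trajectory=self, fits=fits, best=best)


@dataclass(frozen=True)
class RemissionResults:
    """All candidate fits plus the AICc-selected best model."""

    trajectory: RemissionTrajectory
    fits: list[RemissionFit]
    best: RemissionFit

    def __getitem__(self, model: RemissionModelName) -> RemissionFit:
        for f in self.fits:
            if f.model is model:
                return f
        raise KeyError(model)

    def summary(self) -> str:
        lines = [
            "Weekly seizure-trajectory model comparison",
            "=" * 72,
            f"{'model':<18}{'params':<8}{'RSS':>10}{'R^2':>8}{'AICc':>10}"
            f"{'p vs horiz':>12}  best",
            "-" * 72,
        ]
        for f in self.fits:
            mark = "  *" if f is self.best else ""
            lines.append(
                f"{f.model.value:<18}{f.n_params:<8d}{f.rss:>10.3g}{f.r2:>8.3f}"
                f"{f.aicc:>10.3g}{f.p_vs_horizontal:>12.3g}{mark}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, y = self.trajectory.t, self.trajectory.y
        ax.plot(t, y, "o", label="weekly totals")
        grid = np.linspace(t[0], t[-1], 200)
        ax.plot(grid, self.best.predict(grid), "-",
                label=f"best: {self.best.model.value}")
        ax.set_xlabel("week")
        ax.set_ylabel("seizures / week")
        ax.legend()
        return ax


def fit_remission_models(
    weekly: Sequence[float], include_gaussian: bool = False
) -> tuple[list[RemissionFit], RemissionFit]:
    """Fit all candidate trajectory models; returns ``(fits, best)``."""
    res = RemissionTrajectory(weekly, include_gaussian=include_gaussian).fit()
    return res.fits, res.best
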