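"""FRAP trace normalization, recovery fitting, and plateau comparison.

Fluorescence recovery after photobleaching reports the lateral mobility of
labelled molecules: after a bleach that drops the signal in a small region,
mobile molecules exchange with the surroundings and the signal recovers
towards a plateau. The normalized plateau ``y_max`` equals the mobile
fraction; ``1 - y_max`` (clipped to [0, 1]) is the immobile fraction. A
plateau near 1 outside protein clusters versus a depressed plateau inside
them indicates that lipids are partially immobilized within the clusters.

The recovery is modelled as a single exponential,

    y(t) = y_max * (1 - exp(-t / tau)),

with ``t`` re-zeroed at the first post-bleach frame (a well-mixed
approximation; the plateau, which is the quantity of interest, is robust to
the kinetic model). ``y_max`` is deliberately not constrained to be <= 1,
so complete recovery can legitimately fit to values slightly above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import MicrodomainError, ParameterError

__all__ = [
    "FRAPTrace",
    "FRAPFitResult",
    "FRAPRecoveryModel",
    "normalize_trace",
    "fit_recovery",
    "compare_plateaus",
]


@dataclass
class FRAPTrace:
    """A FRAP intensity time series.

    ``bleach_frame_index`` is the index of the first post-bleach frame;
    frames ``[0, bleach_frame_index)`` are pre-bleach. ``reference_roi``
    (an unbleached region, for acquisition-bleaching correction) and
    ``background`` are optional series of the same length.
    """

    times_s: np.ndarray
    bleach_roi: np.ndarray
    bleach_frame_index: int
    reference_roi: Optional[np.ndarray] = None
    background: Optional[np.ndarray] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=np.float64)
        n = self.times_s.size
        if self.bleach_roi.size != n:
            raise ParameterError("times_s and bleach_roi must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ParameterError("times_s must be strictly increasing")
        if not (1 <= self.bleach_frame_index < n):
            raise ParameterError("bleach_frame_index must lie inside the trace")
        for name in ("reference_roi", "background"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.float64)
                if v.size != n:
                    raise ParameterError(f"{name} must match the trace length")
                setattr(self, name, v)

    @property
    def n_prebleach(self) -> int:
        return self.bleach_frame_index

    @property
    def post_times_s(self) -> np.ndarray:
        """Post-bleach times re-zeroed at the first post-bleach frame."""
        b = self.bleach_frame_index
        return self.times_s[b:] - self.times_s[b]


@dataclass
class FRAPFitResult:
    """Result of a single-exponential recovery fit.

    ``y_max`` is the normalized plateau (the mobile fraction),
    ``immobile_fraction = clip(1 - y_max, 0, 1)``, ``tau_s`` the recovery
    time constant, ``ci95_y_max`` a 95% Wald interval from the fit
    covariance. ``degenerate`` marks flat traces with no identifiable
    kinetics (e.g. zero mobile fraction).
    """

    y_max: float
    tau_s: float
    fit_rmse: float
    ci95_y_max: tuple[float, float]
    n_frames: int
    degenerate: bool = False
    model: str = "y_max * (1 - exp(-t/tau)), t zeroed at first post-bleach frame"

    @property
    def immobile_fraction(self) -> float:
        return float(min(1.0, max(0.0, 1.0 - self.y_max)))

    def summary(self) -> str:
        lines = [
            "FRAP single-exponential recovery fit",
            "------------------------------------",
            f"frames (post-bleach)   : {self.n_frames}",
            f"y_max (plateau)        : {self.y_max:.4f}  "
            f"[95% CI {self.ci95_y_max[0]:.4f}, {self.ci95_y_max[1]:.4f}]",
            f"tau_s                  : {self.tau_s:.4f}",
            f"immobile fraction      : {self.immobile_fraction:.4f}",
            f"fit RMSE               : {self.fit_rmse:.5f}",
            f"model                  : {self.model}",
        ]
        if self.degenerate:
            lines.append("note: flat trace; kinetics not identifiable")
        return "\n".join(lines)

    def plot(self, trace: Optional[FRAPTrace] = None, ax=None):
        """Plot the fitted recovery (and the normalized data if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if trace is not None:
            ax.plot(trace.times_s, trace.bleach_roi, "k.", ms=3, label="data")
            t = trace.post_times_s
            t0 = trace.times_s[trace.bleach_frame_index]
        else:
            t = np.linspace(0, 6 * self.tau_s, 200)
            t0 = 0.0
        ax.plot(t + t0, self.y_max * (1 - np.exp(-t / self.tau_s)), "r-", label="fit")
        ax.axhline(self.y_max, color="r", ls=":", lw=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("normalized intensity")
        ax.legend()
        return ax


def normalize_trace(trace: FRAPTrace) -> FRAPTrace:
    """Double-normalize a FRAP trace.

    Steps: subtract the background series (if present); divide frame-wise
    by the reference ROI scaled to its own pre-bleach mean (correcting for
    acquisition bleaching, if present); divide by the pre-bleach mean; then
    rescale affinely so the pre-bleach level maps to 1 and the first
    post-bleach value maps to 0. Normalizing an already-normalized trace is
    a no-op.
    """
    if trace.n_prebleach < 3:
        raise ParameterError("need at least 3 pre-bleach frames to normalize")
    y = trace.bleach_roi.copy()
    if trace.background is not None:
        y = y - trace.background
    if trace.reference_roi is not None:
        ref = trace.reference_roi.copy()
        if trace.background is not None:
            ref = ref - trace.background
        ref_pre = ref[: trace.bleach_frame_index].mean()
        if ref_pre <= 0:
            raise ParameterError("reference ROI pre-bleach mean must be positive")
        y = y / (ref / ref_pre)
    pre = y[: trace.bleach_frame_index].mean()
    if pre <= 0:
        raise ParameterError("pre-bleach mean must exceed background")
    y = y / pre
    y0 = y[trace.bleach_frame_index]
    if y0 >= 1.0 - 1e-12:
        # no bleach dip: leave the scale as-is rather than divide by ~zero
        raise ParameterError("first post-bleach value is not below the pre-bleach level")
    y = (y - y0) / (1.0 - y0)
    return FRAPTrace(
        times_s=trace.times_s.copy(),
        bleach_roi=y,
        bleach_frame_index=trace.bleach_frame_index,
        normalized=True,
    )


class FRAPRecoveryModel:
    """Single-exponential recovery model for one normalized FRAP trace.

    ``FRAPRecoveryModel(trace).fit()`` returns a :class:`FRAPFitResult`.
    If the trace is not flagged as normalized it is normalized first
    (requires a bleach dip and >= 3 pre-bleach frames).
    """

    def __init__(self, trace: FRAPTrace):
        if not trace.normalized:
            trace = normalize_trace(trace)
        if trace.times_s.size - trace.bleach_frame_index < 5:
            raise ParameterError("need at least 5 post-bleach frames to fit")
        self.trace = trace

    def fit(self) -> FRAPFitResult:
        t = self.trace.post_times_s
        y = self.trace.bleach_roi[self.trace.bleach_frame_index :]
        n = t.size

        if float(np.max(np.abs(y))) < 1e-9:
            # completely flat at zero: no recovery, kinetics unidentifiable
            return FRAPFitResult(
                y_max=0.0,
                tau_s=float(t[-1]) if t[-1] > 0 else 1.0,
                fit_rmse=0.0,
                ci95_y_max=(0.0, 0.0),
                n_frames=n,
                degenerate=True,
            )

        def model(tt, y_max, tau):
            return y_max * (1.0 - np.exp(-tt / tau))

        y_guess = float(np.mean(y[max(1, n - max(3, n // 5)) :]))
        # crude tau guess: time to reach half the plateau
        half = 0.5 * y_guess
        above = np.nonzero(y >= half)[0]
        tau_guess = float(t[above[0]]) / math.log(2.0) if above.size and t[above[0]] > 0 else float(
            max(t[-1] / 5.0, 1e-3)
        )
        try:
            popt, pcov = curve_fit(
                model,
                t,
                y,
                p0=[max(y_guess, 1e-3), tau_guess],
                bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError as exc:  # pragma: no cover - hard to trigger
            raise MicrodomainError(
                f"recovery fit did not converge (p0=[{y_guess}, {tau_guess}]): {exc}"
            ) from exc
        resid = y - model(t, *popt)
        rmse = float(np.sqrt(np.mean(resid**2)))
        se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
        ci = (popt[0] - 1.96 * se, popt[0] + 1.96 * se)
        return FRAPFitResult(
            y_max=float(popt[0]),
            tau_s=float(popt[1]),
            fit_rmse=rmse,
            ci95_y_max=ci,
            n_frames=n,
        )


def fit_recovery(trace: FRAPTrace) -> FRAPFitResult:
    """Fit a single-exponential recovery to a (normalized) FRAP trace."""
    return FRAPRecoveryModel(trace).fit()


def compare_plateaus(
    fits_in: Sequence[FRAPFitResult], fits_out: Sequence[FRAPFitResult]
):
    """Two-tailed two-sample t-test on plateau (``y_max``) values.

    Returns a :class:`microdomain.stats.GroupComparisonResult` with group
    labels ``"in"`` and ``"out"``.
    """
    from .stats import compare_groups

    if len(fits_in) < 2 or len(fits_out) < 2:
        raise ParameterError("each group needs at least two fitted traces")
    return compare_groups(
        {"in": [f.y_max for f in fits_in], "out": [f.y_max for f in fits_out]},
        test="t_two_tailed",
    )
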