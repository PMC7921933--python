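"""Bioyield extraction and validation statistics for puncture force--deformation curves.

The bioyield point is the first force peak at which fruit tissue begins to
rupture: after it, the probe penetrates with a sharply reduced, fluctuating
force.  This module detects that point on measured, synthetic or simulated
curves, computes the relative-error validation statistic, runs the
material-level sensitivity study, and fits the quadratic velocity-effect
relation Delta = a*v^2 + b*v.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForceDeformationCurve",
    "PunctureMetrics",
    "VelocityEffectFit",
    "detect_bioyield",
    "relative_error",
    "sensitivity_study",
    "fit_velocity_effect",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ForceDeformationCurve:
    """Probe force (N) vs insertion depth (mm) vs time (s), equal-length and ordered."""

    times: np.ndarray
    depths: np.ndarray
    forces: np.ndarray
    source: str = "simulated"  # experimental | synthetic | simulated

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.depths, dtype=float)
        f = np.asarray(self.forces, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "forces", f)
        if not (t.shape == d.shape == f.shape) or t.ndim != 1:
            raise ValueError("times, depths, forces must be equal-length 1-D arrays")
        if np.any(np.diff(d) < -1e-12):
            raise ValueError("depths must be non-decreasing")
        if not np.all(np.isfinite(f)) or np.any(f < -1e-9):
            raise ValueError("forces must be finite and non-negative")

    @property
    def sampling_rate(self) -> float:
        """Nominal sampling rate (points/s) recovered from the time stamps."""
        dt = np.median(np.diff(self.times))
        return 1.0 / dt if dt > 0 else np.nan

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.times, "depth_mm": self.depths, "force_N": self.forces}
        )

    @classmethod
    def from_csv(cls, path, source: str = "experimental") -> "ForceDeformationCurve":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return cls(
            times=df["time_s"].to_numpy(),
            depths=df["depth_mm"].to_numpy(),
            forces=df["force_N"].to_numpy(),
            source=source,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


@dataclass(frozen=True)
class PunctureMetrics:
    """Bioyield force/deformation extracted from one curve (and peak field stress, if any)."""

    bioyield_force: float
    bioyield_deformation: float
    rupture_detected: bool
    bioyield_index: int
    peak_von_mises: float | None = None


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed curve has no edge bias
    pad = window // 2
    xp = np.pad(x, (pad, window - 1 - pad), mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def detect_bioyield(
    curve: ForceDeformationCurve,
    smooth_window: int = 5,
    drop_fraction: float = 0.05,
) -> PunctureMetrics:
    """Locate the bioyield point of a force--deformation curve.

    The curve is smoothed with a centred moving average of ``smooth_window``
    samples; the bioyield point is the first local maximum of the smoothed
    force after which the force drops by more than ``drop_fraction`` times
    that maximum without first rising above it.  The returned force and
    deformation are read off the
    *unsmoothed* curve at the local raw maximum nearest the detected peak.
    If no qualifying drop exists, ``rupture_detected`` is False and the
    metrics are taken at the global maximum.
    """
    if curve.forces.size < 10:
        raise InsufficientDataError("need at least 10 samples to detect bioyield")
    if not (0 < drop_fraction < 1):
        raise ValueError("drop_fraction must lie in (0, 1)")
    f = curve.forces
    fs = _moving_average(f, smooth_window)
    n = fs.size

    # local maxima of the smoothed force (plateaus take the first index)
    rising = np.concatenate([[True], fs[1:] > fs[:-1]])
    falling = np.concatenate([fs[:-1] > fs[1:], [False]])
    candidates = np.flatnonzero(rising & falling)

    for idx in candidates:
        peak = fs[idx]
        if peak <= 0 or idx + 1 >= n:
            continue
        # the qualifying drop must happen before the force exceeds this peak
        # again, otherwise a ripple on the rising branch would be mistaken
        # for rupture just because the eventual plateau is lower
        tail = fs[idx + 1 :]
        below = np.flatnonzero(tail < peak * (1.0 - drop_fraction))
        if below.size and np.all(tail[: below[0]] <= peak):
            raw_idx = _refine_raw_peak(f, idx, smooth_window)
            return PunctureMetrics(
                bioyield_force=float(f[raw_idx]),
                bioyield_deformation=float(curve.depths[raw_idx]),
                rupture_detected=True,
                bioyield_index=int(raw_idx),
            )

    gmax = int(np.argmax(f))
    return PunctureMetrics(
        bioyield_force=float(f[gmax]),
        bioyield_deformation=float(curve.depths[gmax]),
        rupture_detected=False,
        bioyield_index=gmax,
    )


def _refine_raw_peak(f: np.ndarray, idx: int, window: int) -> int:
    lo = max(0, idx - window)
    hi = min(f.size, idx + window + 1)
    return lo + int(np.argmax(f[lo:hi]))


def relative_error(measured: float, simulated: float) -> float:
    """Validation statistic |measured - simulated| / measured * 100 (percent)."""
    if measured == 0:
        raise ZeroDivisionError("relative error is undefined for a zero reference value")
    return abs(measured - simulated) / abs(measured) * 100.0


def sensitivity_study(
    combinations: list[tuple[str, str]],
    runner,
    smooth_window: int = 5,
    drop_fraction: float = 0.05,
) -> dict:
    """Material-level sensitivity of the simulated bioyield force.

    ``combinations`` is a list of (skin_level, flesh_level) pairs drawn from
    {"min", "avg", "max"}; ``runner(skin_level, flesh_level)`` returns either
    a ForceDeformationCurve or a bare peak force in N.  The summary reports
    the percent decrease from the all-max to the all-min combination,
    (F_max - F_min) / F_max * 100.  A failing cell is flagged and the study
    continues.
    """
    cells = {}
    for skin_level, flesh_level in combinations:
        key = (skin_level, flesh_level)
        try:
            out = runner(skin_level, flesh_level)
        except Exception as exc:  # noqa: BLE001 - cell failures must not kill the study
            cells[key] = {"ok": False, "error": repr(exc)}
            continue
        if isinstance(out, ForceDeformationCurve):
            m = detect_bioyield(out, smooth_window, drop_fraction)
            force = m.bioyield_force
        else:
            force = float(out)
        cells[key] = {"ok": True, "bioyield_force_N": force}

    summary = {"cells": cells}
    hi = cells.get(("max", "max"))
    lo = cells.get(("min", "min"))
    if hi and lo and hi.get("ok") and lo.get("ok"):
        f_hi, f_lo = hi["bioyield_force_N"], lo["bioyield_force_N"]
        summary["force_max_N"] = f_hi
        summary["force_min_N"] = f_lo
        summary["percent_decrease"] = (f_hi - f_lo) / f_hi * 100.0 if f_hi != 0 else 0.0
    return summary


@dataclass(frozen=True)
class VelocityEffectFit:
    """Least-squares fit of Delta = a*v^2 + b*v (no intercept)."""

    a: float
    b: float
    r_squared: float

    def __call__(self, v):
        return self.a * np.asarray(v) ** 2 + self.b * np.asarray(v)


def fit_velocity_effect(velocities, deltas) -> VelocityEffectFit:
    """Fit the quadratic through-origin velocity-effect relation.

    ``deltas`` are differences of bioyield force (N) or deformation (mm) at
    each probe velocity (mm/s).  R^2 is computed for the no-intercept model
    (against the uncentred total sum of squares).
    """
    v = np.asarray(velocities, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if v.size < 3 or v.size != d.size:
        raise InsufficientDataError("need at least 3 (velocity, delta) points")
    A = np.column_stack([v**2, v])
    coef, *_ = np.linalg.lstsq(A, d, rcond=None)
    resid = d - A @ coef
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(d, d))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return VelocityEffectFit(a=float(coef[0]), b=float(coef[1]), r_squared=r2)
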