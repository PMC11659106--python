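"""Mean square displacement and lateral diffusion ("tissue fluidity").

The MSD at lag τ is the time-averaged squared displacement over all start
points, with the 1/(n−τ) normalization over the available pairs, and the
ensemble average pools pairs across trajectories (each displacement pair
carries equal weight; an unweighted per-track mode is also provided).

For normal diffusion MSD(τ) = 2·d·D·τ; the diffusion coefficient is
obtained as D = m/(2d) from the slope m of an ordinary least-squares line
fitted to MSD vs τ over the first hour of lags (free intercept, τ = 0
excluded).  Lateral fluidity uses d = 2 (x, y only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import NuclearTrajectory, ValidationError

__all__ = ["MSDCurve", "DiffusionEstimate", "compute_msd", "fit_diffusion"]

DEFAULT_FIT_WINDOW = 60.0  # min


@dataclass
class MSDCurve:
    """Lag-indexed MSD. ``lags`` includes τ=0 (msd 0 by definition).

    ``track_sums``/``track_counts`` (n_tracks × n_lags) retain the
    per-trajectory squared-displacement sums and pair counts behind the
    pooled curve; they enable the jackknife standard error of the fitted
    diffusion coefficient.
    """

    lags: np.ndarray  # min
    msd: np.ndarray  # μm²
    n_pairs: np.ndarray  # displacement pairs per lag
    dimensionality: int  # 2 (lateral) or 3
    track_sums: Optional[np.ndarray] = None
    track_counts: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau_min": self.lags, "msd_um2": self.msd, "n_pairs": self.n_pairs}
        )


@dataclass
class DiffusionEstimate:
    D: float  # μm²/min
    slope: float  # μm²/min
    intercept: float  # μm²
    stderr_D: float
    fit_window: float
    dimensionality: int
    n_lags: int
    curvature_ratio: float  # mean msd(2τ)/msd(τ); ≈2 diffusive, ≈4 ballistic
    superlinear: bool


def compute_msd(
    trajectories: Sequence[NuclearTrajectory],
    max_lag: Optional[float] = None,
    dims: str = "xy",
) -> MSDCurve:
    """Pooled time- and ensemble-averaged MSD.

    All trajectories must share one sampling interval.  ``max_lag`` beyond
    the shortest trajectory is truncated with a warning.  ``dims`` selects
    lateral (``"xy"``) or full 3D (``"xyz"``) displacements.
    """
    trajs = [t for t in trajectories if t.n_samples >= 2]
    if not trajs:
        raise ValidationError("need at least one trajectory with >= 2 samples")
    if dims not in ("xy", "xyz"):
        raise ValidationError(f"dims must be 'xy' or 'xyz', got {dims!r}")
    dt = trajs[0].sampling_interval
    for t in trajs[1:]:
        if abs(t.sampling_interval - dt) > 1e-6:
            raise ValidationError(
                f"mixed sampling intervals: {dt} vs {t.sampling_interval} "
                f"(track {t.track_id!r})"
            )
    max_steps_avail = max(t.n_samples - 1 for t in trajs)
    if max_lag is None:
        k_max = max_steps_avail
    else:
        k_max = int(np.floor(max_lag / dt + 1e-9))
        if k_max > max_steps_avail:
            warnings.warn(
                f"max_lag {max_lag} min exceeds the longest trajectory; "
                f"truncating to {max_steps_avail * dt} min"
            )
            k_max = max_steps_avail
    k_max = max(k_max, 1)

    track_sums = np.zeros((len(trajs), k_max + 1))
    track_counts = np.zeros((len(trajs), k_max + 1), dtype=int)
    for i, t in enumerate(trajs):
        pos = t.positions(dims)
        n = pos.shape[0]
        track_counts[i, 0] = n
        for k in range(1, min(k_max, n - 1) + 1):
            d = pos[k:] - pos[:-k]
            track_sums[i, k] = float(np.einsum("ij,ij->", d, d))
            track_counts[i, k] = n - k
    sums = track_sums.sum(axis=0)
    counts = track_counts.sum(axis=0)
    valid = counts > 0
    msd = np.zeros(k_max + 1)
    msd[valid] = sums[valid] / counts[valid]
    lags = np.arange(k_max + 1) * dt
    return MSDCurve(
        lags=lags[valid], msd=msd[valid], n_pairs=counts[valid],
        dimensionality=2 if dims == "xy" else 3,
        track_sums=track_sums[:, valid], track_counts=track_counts[:, valid],
    )


def compute_msd_per_track(
    trajectories: Sequence[NuclearTrajectory],
    max_lag: Optional[float] = None,
    dims: str = "xy",
) -> MSDCurve:
    """Unweighted variant: average per-trajectory MSD curves across tracks."""
    curves = [compute_msd([t], max_lag, dims) for t in trajectories
              if t.n_samples >= 2]
    if not curves:
        raise ValidationError("need at least one trajectory with >= 2 samples")
    k_max = max(c.lags.size for c in curves)
    dt = curves[0].lags[1] - curves[0].lags[0] if curves[0].lags.size > 1 else 1.0
    acc = np.zeros(k_max)
    cnt = np.zeros(k_max, dtype=int)
    pairs = np.zeros(k_max, dtype=int)
    for c in curves:
        m = c.msd.size
        acc[:m] += c.msd
        cnt[:m] += 1
        pairs[:m] += c.n_pairs
    return MSDCurve(
        lags=np.arange(k_max) * dt, msd=acc / cnt, n_pairs=pairs,
        dimensionality=curves[0].dimensionality,
    )


def _jackknife_slope_se(curve: MSDCurve, sel: np.ndarray, tau: np.ndarray) -> float:
    """Delete-one-trajectory jackknife SE of the MSD slope."""
    sums = curve.track_sums[:, sel]
    counts = curve.track_counts[:, sel]
    tot_s = sums.sum(axis=0)
    tot_c = counts.sum(axis=0)
    slopes = []
    for i in range(sums.shape[0]):
        c = tot_c - counts[i]
        if np.any(c <= 0):
            continue
        m = (tot_s - sums[i]) / c
        slopes.append(sps.linregress(tau, m).slope)
    slopes = np.asarray(slopes)
    g = slopes.size
    if g < 3:
        return float("nan")
    return float(np.sqrt((g - 1) / g * np.sum((slopes - slopes.mean()) ** 2)))


def fit_diffusion(
    curve: MSDCurve, fit_window: float = DEFAULT_FIT_WINDOW
) -> DiffusionEstimate:
    """OLS fit of MSD vs τ over 0 < τ ≤ fit_window; D = slope/(2d).

    A negative fitted slope is reported as-is with a warning (not clamped).
    The curvature diagnostic is the mean of msd(2τ)/msd(τ) over lags with
    2τ inside the fit window: ≈2 for diffusive, ≈4 for ballistic motion.

    ``stderr_D`` is a delete-one-trajectory jackknife when the curve
    retains per-track sums (the default from :func:`compute_msd` with ≥ 3
    tracks): successive MSD lags share displacement pairs, so the naive
    OLS residual standard error understates the sampling variability of
    the slope by an order of magnitude.  Without per-track information the
    OLS standard error is reported instead.
    """
    sel = (curve.lags > 0) & (curve.lags <= fit_window + 1e-9)
    tau = curve.lags[sel]
    msd = curve.msd[sel]
    if tau.size < 2:
        raise ValidationError(
            f"need >= 2 lags within the {fit_window}-min fit window, "
            f"got {tau.size}"
        )
    fit = sps.linregress(tau, msd)
    d = curve.dimensionality
    D = fit.slope / (2.0 * d)
    if fit.slope < 0:
        warnings.warn(f"negative fitted MSD slope ({fit.slope:.3g} μm²/min)")

    stderr_slope = float(fit.stderr)
    if curve.track_sums is not None and curve.track_sums.shape[0] >= 3:
        stderr_slope = _jackknife_slope_se(curve, sel, tau)

    ratios = []
    for i, t1 in enumerate(tau):
        if 2 * t1 > fit_window + 1e-9 or msd[i] <= 0:
            continue
        j = np.nonzero(np.isclose(curve.lags, 2 * t1, atol=1e-9))[0]
        if j.size:
            ratios.append(curve.msd[j[0]] / msd[i])
    curvature = float(np.mean(ratios)) if ratios else float("nan")

    return DiffusionEstimate(
        D=float(D),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stderr_D=stderr_slope / (2.0 * d),
        fit_window=fit_window,
        dimensionality=d,
        n_lags=int(tau.size),
        curvature_ratio=curvature,
        superlinear=bool(curvature > 3.0) if np.isfinite(curvature) else False,
    )
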