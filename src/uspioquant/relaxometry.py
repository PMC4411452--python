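"""Voxel-wise monoexponential T2* relaxometry.

A multi-echo gradient-echo acquisition samples the signal decay
``S(t) = S(0) * exp(-t / T2*)`` at increasing echo times t.  Each voxel is
fitted by nonlinear least squares on the exponential itself (a log-linear
regression provides the starting point only), the goodness of fit is
summarised by the coefficient of determination r² in the signal domain, and
voxels with r² at or below a threshold (default 0.85) are excluded from the
valid map.  The relaxation rate R2* is the reciprocal of T2*; with T2* in
ms it is reported in s^-1 as ``R2* = 1000 / T2*``, the scale on which
iron-oxide (USPIO) uptake is quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MultiEchoStack",
    "FitSettings",
    "VoxelFit",
    "RelaxometryMaps",
    "fit_voxel",
    "fit_map",
    "r2star_from_t2star",
]


@dataclass(frozen=True)
class MultiEchoStack:
    """One spatial image per echo time.

    ``signal`` has shape (n_echoes, *spatial); ``echo_times_ms`` is strictly
    increasing and positive.  Signals are magnitude data: finite and >= 0.
    """

    echo_times_ms: np.ndarray
    signal: np.ndarray
    voxel_size_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        if te.ndim != 1 or te.size < 1:
            raise ValueError("echo_times_ms must be a 1-D sequence")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if sig.shape[0] != te.size:
            raise ValueError(
                f"stack has {sig.shape[0]} images for {te.size} echo times"
            )
        if not np.all(np.isfinite(sig)) or np.any(sig < 0):
            raise ValueError("signals must be finite and non-negative")
        object.__setattr__(self, "echo_times_ms", te)
        object.__setattr__(self, "signal", sig)

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times_ms.size)

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.signal.shape[1:]


@dataclass(frozen=True)
class FitSettings:
    """Configuration of the per-voxel fit.

    ``rsq_threshold``: validity requires r² strictly above this value.
    ``t2_bounds_ms``: admissible T2* range; a fit pinned at either bound is
    marked invalid (background and noise-only voxels land there).
    """

    rsq_threshold: float = 0.85
    t2_bounds_ms: tuple[float, float] = (0.1, 1000.0)
    max_nfev: int = 200

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class VoxelFit:
    """Result of fitting one voxel's decay curve."""

    s0: float
    t2star_ms: float
    r_squared: float
    valid: bool

    @property
    def r2star_s(self) -> float:
        """Relaxation rate in s^-1 (NaN when the fit is invalid)."""
        if not self.valid or not np.isfinite(self.t2star_ms) or self.t2star_ms <= 0:
            return float("nan")
        return 1000.0 / self.t2star_ms


INVALID_FIT = VoxelFit(s0=float("nan"), t2star_ms=float("nan"),
                       r_squared=float("nan"), valid=False)


@dataclass
class RelaxometryMaps:
    """Parallel per-voxel maps produced by :func:`fit_map`.

    Invalid voxels hold NaN in ``s0``, ``t2star_ms``, ``r2star_s`` and
    ``r_squared`` carries the (possibly sub-threshold) value when defined.
    """

    s0: np.ndarray
    t2star_ms: np.ndarray
    r2star_s: np.ndarray
    r_squared: np.ndarray
    valid: np.ndarray
    echo_times_ms: np.ndarray
    settings: FitSettings = field(default_factory=FitSettings)

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.valid.shape

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    @property
    def n_invalid(self) -> int:
        return int(self.valid.size - self.n_valid)

    def provenance(self) -> dict:
        return {
            "echo_times_ms": [float(t) for t in self.echo_times_ms],
            "fit_settings": self.settings.to_dict(),
            "n_valid": self.n_valid,
            "n_invalid": self.n_invalid,
        }


def r2star_from_t2star(t2star_ms: float | np.ndarray) -> float | np.ndarray:
    """Convert a decay constant T2* (ms) to the rate R2* (s^-1).

    ``R2* = 1000 / T2*``: a T2* of 10 ms corresponds to 100 s^-1.
    Raises for non-positive scalar input; array input propagates NaN for
    non-positive entries.
    """
    arr = np.asarray(t2star_ms, dtype=float)
    if arr.ndim == 0:
        if not arr > 0:
            raise ValueError(f"T2* must be positive, got {t2star_ms!r}")
        return float(1000.0 / arr)
    out = np.full(arr.shape, np.nan)
    pos = arr > 0
    out[pos] = 1000.0 / arr[pos]
    return out


def _loglinear_init(signals: np.ndarray, echo_times: np.ndarray,
                    t2_bounds: tuple[float, float]) -> tuple[float, float]:
    """Starting point from a log-linear regression on positive signals."""
    t2_lo, t2_hi = t2_bounds
    pos = signals > 0
    if np.count_nonzero(pos) >= 2:
        slope, intercept = np.polyfit(echo_times[pos], np.log(signals[pos]), 1)
        s0 = float(np.exp(np.clip(intercept, -50.0, 50.0)))
        t2 = -1.0 / slope if slope < 0 else t2_hi
    else:
        s0 = float(signals.max())
        t2 = float(np.sqrt(t2_lo * t2_hi))
    s0 = max(s0, np.finfo(float).tiny)
    t2 = float(np.clip(t2, t2_lo * (1 + 1e-6), t2_hi * (1 - 1e-6)))
    return s0, t2


def fit_voxel(signals: np.ndarray, echo_times_ms: np.ndarray,
              settings: FitSettings | None = None) -> VoxelFit:
    """Least-squares fit of ``s0 * exp(-t / T2*)`` to one voxel.

    Minimises the sum of squared residuals in the signal domain over
    ``s0 > 0`` and ``T2*`` within ``settings.t2_bounds_ms``.  r² is computed
    against the mean-signal null model over all echoes.  The fit is valid
    iff the optimiser converged, T2* sits strictly inside its bounds and
    r² exceeds the threshold; degenerate inputs (all-zero or constant
    signal) yield an invalid fit rather than an exception.
    """
    settings = settings or FitSettings()
    s = np.asarray(signals, dtype=float)
    t = np.asarray(echo_times_ms, dtype=float)
    if t.size < 3:
        raise ValueError("at least 3 echoes are required for a 2-parameter fit")
    if np.any(np.diff(t) <= 0) or np.any(t <= 0):
        raise ValueError("echo times must be positive and strictly increasing")
    if s.shape != t.shape:
        raise ValueError("signals and echo times differ in length")
    if not np.all(np.isfinite(s)):
        return INVALID_FIT
    if not np.any(s > 0):
        return INVALID_FIT

    t2_lo, t2_hi = settings.t2_bounds_ms
    x0 = _loglinear_init(s, t, settings.t2_bounds_ms)

    def residuals(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-t / p[1]) - s

    def jacobian(p: np.ndarray) -> np.ndarray:
        decay = np.exp(-t / p[1])
        return np.column_stack((decay, p[0] * decay * t / p[1] ** 2))

    sol = least_squares(
        residuals, x0=np.array(x0), jac=jacobian,
        bounds=([np.finfo(float).tiny, t2_lo], [np.inf, t2_hi]),
        method="trf", max_nfev=settings.max_nfev,
    )
    s0_hat, t2_hat = float(sol.x[0]), float(sol.x[1])

    ss_res = float(np.sum(residuals(sol.x) ** 2))
    ss_tot = float(np.sum((s - s.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    at_bound = t2_hat <= t2_lo * (1 + 1e-9) or t2_hat >= t2_hi * (1 - 1e-9)
    valid = (
        bool(sol.success)
        and not at_bound
        and np.isfinite(r_squared)
        and r_squared > settings.rsq_threshold
    )
    return VoxelFit(s0=s0_hat, t2star_ms=t2_hat, r_squared=r_squared, valid=valid)


def fit_map(stack: MultiEchoStack, settings: FitSettings | None = None) -> RelaxometryMaps:
    """Apply :func:`fit_voxel` to every voxel of a multi-echo stack.

    All-zero voxels (pure background before noise) are marked invalid
    without invoking the optimiser.  Returns parallel maps with the NaN
    sentinel contract of :class:`RelaxometryMaps`.
    """
    settings = settings or FitSettings()
    shape = stack.spatial_shape
    n_vox = int(np.prod(shape))
    flat = stack.signal.reshape(stack.n_echoes, n_vox)

    s0 = np.full(n_vox, np.nan)
    t2 = np.full(n_vox, np.nan)
    rsq = np.full(n_vox, np.nan)
    valid = np.zeros(n_vox, dtype=bool)

    nonzero = np.any(flat > 0, axis=0)
    for i in np.flatnonzero(nonzero):
        vf = fit_voxel(flat[:, i], stack.echo_times_ms, settings)
        rsq[i] = vf.r_squared
        if vf.valid:
            s0[i] = vf.s0
            t2[i] = vf.t2star_ms
            valid[i] = True

    r2 = np.where(valid, 1000.0 / t2, np.nan)
    return RelaxometryMaps(
        s0=s0.reshape(shape), t2star_ms=t2.reshape(shape),
        r2star_s=r2.reshape(shape), r_squared=rsq.reshape(shape),
        valid=valid.reshape(shape), echo_times_ms=stack.echo_times_ms.copy(),
        settings=settings,
    )
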