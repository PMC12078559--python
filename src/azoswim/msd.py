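"""MSD curves and signed diffusion coefficients from 2D particle tracks.

The time-averaged mean square displacement of a track r(t_0), ..., r(t_{N-1})
at lag tau_k = k * frame_interval is

    MSD(tau_k) = < |r(t_i + tau_k) - r(t_i)|^2 >_i ,

averaged over all N - k start points.  For long tracks this is computed via
the FFT/autocorrelation route (Wiener–Khinchin theorem), which is exactly
equivalent to the naive double loop but O(N log N).

The diffusion coefficient D' follows the standard tracking protocol: the MSD
curve is truncated to its first 20% of lags (the statistically reliable
part), an ordinary least-squares line is fitted to the largest 20% of the
retained lags, and D' = slope / 4 (2D: slope = 2 d D with d = 2).  Ensemble
flow direction gives the signed coefficient D* = -D' for inward-directed
flow and +D' otherwise.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Trajectory",
    "MSDCurve",
    "Direction",
    "DiffusionEstimate",
    "compute_msd_fft",
    "compute_msd_naive",
    "fit_diffusion",
    "classify_direction",
    "signed_estimates",
    "select_top",
    "curvature_index",
]

_UNIFORMITY_RTOL = 1e-6


class Direction(enum.Enum):
    INWARD = "inward"
    OUTWARD = "outward"
    UNCLASSIFIED = "unclassified"


@dataclass
class Trajectory:
    """A tracked 2D path: sample times (s) and positions (um), one per time."""

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    frame_interval: float = 0.2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def is_uniform(self) -> bool:
        if len(self) < 3:
            return True
        dts = np.diff(self.times)
        return bool(np.all(np.abs(dts - dts[0]) <= _UNIFORMITY_RTOL * dts[0]))


@dataclass
class MSDCurve:
    """Time-averaged MSD vs lag for one track (dimension fixed at 2)."""

    track_id: str
    lags: np.ndarray     # tau_k (s), strictly increasing, k = 1..N-1
    values: np.ndarray   # <r^2(tau_k)> (um^2)
    n_pairs: np.ndarray  # displacement pairs averaged per lag
    dimension: int = 2

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)

    def __len__(self) -> int:
        return len(self.lags)


@dataclass(frozen=True)
class DiffusionEstimate:
    """Fitted diffusion coefficient of one track.

    ``D_star`` is ``-D_prime`` for inward-directed ensemble flow and
    ``+D_prime`` otherwise; |D_star| == D_prime always.
    """

    track_id: str
    D_prime: float
    direction: Direction = Direction.UNCLASSIFIED
    D_star: float = None  # type: ignore[assignment]
    fit_window: tuple[float, float] = (0.0, 0.0)
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.D_star is None:
            object.__setattr__(self, "D_star", self.D_prime)
        if abs(abs(self.D_star) - self.D_prime) > 1e-12 * max(1.0, self.D_prime):
            raise ValueError("|D_star| must equal D_prime")


def _require_min_length(traj: Trajectory) -> None:
    if len(traj) < 2:
        raise ValueError(
            f"track {traj.track_id!r}: need >= 2 samples for an MSD, got {len(traj)}"
        )


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    """Unnormalized autocorrelation sum S2(k) = sum_i x_i x_{i+k}, via FFT."""
    n = len(x)
    F = np.fft.rfft(x, n=2 * n)
    acf = np.fft.irfft(F * np.conj(F), n=2 * n)[:n]
    return acf


def compute_msd_fft(traj: Trajectory) -> MSDCurve:
    """Time-averaged MSD via the FFT/autocorrelation identity.

    Requires uniform sampling (the lag grid is k * frame_interval); raises
    ``ValueError`` pointing at :func:`compute_msd_naive` otherwise.  Agrees
    with the naive double loop to floating-point rounding.
    """
    _require_min_length(traj)
    if not traj.is_uniform:
        raise ValueError(
            f"track {traj.track_id!r} is not uniformly sampled; "
            "use compute_msd_naive for irregular tracks"
        )
    r = traj.positions
    n = len(r)
    # MSD(k) = S1(k)/(n-k) - 2*S2(k)/(n-k), with
    # S1(k) = sum_i (|r_i|^2 + |r_{i+k}|^2), S2(k) = sum_i r_i . r_{i+k}
    sq = np.sum(r * r, axis=1)
    S2 = _autocorr_fft(r[:, 0]) + _autocorr_fft(r[:, 1])
    sq_pad = np.append(sq, 0.0)
    Q = 2.0 * sq.sum()
    S1 = np.empty(n)
    for k in range(n):
        Q -= sq_pad[k - 1] + sq_pad[n - k]
        S1[k] = Q
    counts = n - np.arange(n)
    msd = (S1 - 2.0 * S2) / counts
    dt = float(np.diff(traj.times)[0]) if n > 1 else traj.frame_interval
    lags = np.arange(1, n) * dt
    # rounding in the FFT round trip can leave tiny negatives at zero-MSD lags
    values = np.maximum(msd[1:], 0.0)
    return MSDCurve(traj.track_id, lags, values, counts[1:])


def compute_msd_naive(traj: Trajectory) -> MSDCurve:
    """Time-averaged MSD by the direct O(N^2) definition (oracle path).

    Works for any strictly increasing time grid; for non-uniform sampling
    the lags are indexed by sample offset k and reported as the mean time
    difference at that offset.
    """
    _require_min_length(traj)
    r = traj.positions
    n = len(r)
    values = np.empty(n - 1)
    lags = np.empty(n - 1)
    counts = np.empty(n - 1, dtype=int)
    for k in range(1, n):
        d = r[k:] - r[:-k]
        values[k - 1] = np.mean(np.sum(d * d, axis=1))
        lags[k - 1] = np.mean(traj.times[k:] - traj.times[:-k])
        counts[k - 1] = n - k
    return MSDCurve(traj.track_id, lags, values, counts)


def fit_diffusion(
    curve: MSDCurve,
    truncate_fraction: float = 0.20,
    fit_fraction: float = 0.20,
) -> DiffusionEstimate:
    """Unsigned diffusion coefficient D' from an MSD curve.

    The curve is truncated to its first ``truncate_fraction`` of lags; an
    unweighted least-squares line is fitted to the largest ``fit_fraction``
    of the retained lags; D' = slope / 4.  Lags averaging fewer than two
    displacement pairs are dropped first.  A negative fitted slope is
    clipped to D' = 0 with a warning.
    """
    if not 0 < truncate_fraction <= 1 or not 0 < fit_fraction <= 1:
        raise ValueError("fractions must lie in (0, 1]")
    usable = curve.n_pairs >= 2
    lags, values = curve.lags[usable], curve.values[usable]
    n_keep = int(np.ceil(truncate_fraction * len(lags)))
    if n_keep < 5:
        raise ValueError(
            f"track {curve.track_id!r}: only {n_keep} usable lags after "
            "truncation; need >= 5"
        )
    lags, values = lags[:n_keep], values[:n_keep]
    n_fit = max(2, int(np.ceil(fit_fraction * n_keep)))
    fit_lags, fit_values = lags[-n_fit:], values[-n_fit:]
    res = stats.linregress(fit_lags, fit_values)
    slope = res.slope
    if slope < 0:
        warnings.warn(
            f"track {curve.track_id!r}: negative MSD slope {slope:.3g}; "
            "clipping D' to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        slope = 0.0
    return DiffusionEstimate(
        track_id=curve.track_id,
        D_prime=slope / 4.0,
        fit_window=(float(fit_lags[0]), float(fit_lags[-1])),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else float("nan"),
    )


def classify_direction(
    trajectories: Sequence[Trajectory],
    roi_center: Sequence[float] | None = None,
    noise_floor: float = 0.5,
) -> dict[str, Direction]:
    """Ensemble flow direction per track from net radial displacement.

    A track is inward if its final radius w.r.t. ``roi_center`` is smaller
    than its initial radius by more than ``noise_floor`` (um), outward if
    larger, otherwise unclassified.  If no center is given, the ensemble
    centroid of the initial positions is used.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("cannot classify an empty trajectory set")
    if roi_center is None:
        roi_center = np.mean([t.positions[0] for t in trajectories], axis=0)
    center = np.asarray(roi_center, dtype=float)
    out: dict[str, Direction] = {}
    for traj in trajectories:
        r0 = np.linalg.norm(traj.positions[0] - center)
        r1 = np.linalg.norm(traj.positions[-1] - center)
        dr = r1 - r0
        if dr < -noise_floor:
            out[traj.track_id] = Direction.INWARD
        elif dr > noise_floor:
            out[traj.track_id] = Direction.OUTWARD
        else:
            out[traj.track_id] = Direction.UNCLASSIFIED
    return out


def signed_estimates(
    estimates: Sequence[DiffusionEstimate],
    directions: Mapping[str, Direction] | Sequence[Direction],
) -> list[DiffusionEstimate]:
    """Apply the sign rule D* = -D' (inward) / +D' (otherwise)."""
    if not isinstance(directions, Mapping):
        if len(directions) != len(estimates):
            raise ValueError(
                f"{len(estimates)} estimates but {len(directions)} directions"
            )
        directions = {e.track_id: d for e, d in zip(estimates, directions)}
    out = []
    for est in estimates:
        direction = directions[est.track_id]
        sign = -1.0 if direction is Direction.INWARD else 1.0
        out.append(replace(est, direction=direction, D_star=sign * est.D_prime))
    return out


def select_top(estimates: Sequence[DiffusionEstimate], k: int = 20
               ) -> list[DiffusionEstimate]:
    """Up to ``k`` estimates with the largest D' (ties broken by track id)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ranked = sorted(estimates, key=lambda e: (-e.D_prime, str(e.track_id)))
    return ranked[: min(k, len(ranked))]


def curvature_index(curve: MSDCurve, split: float = 0.5) -> float:
    """Ratio of late-lag to early-lag local MSD slope.

    > 1 indicates upward curvature (ballistic/drift-dominated motion);
    ~1 indicates a linear, purely diffusive curve.
    """
    if len(curve) < 4:
        raise ValueError("need >= 4 lags to compare local slopes")
    m = max(2, int(split * len(curve)))
    early = stats.linregress(curve.lags[:m], curve.values[:m]).slope
    late = stats.linregress(curve.lags[m:], curve.values[m:]).slope if len(curve) - m >= 2 \
        else stats.linregress(curve.lags[m - 1:], curve.values[m - 1:]).slope
    if early == 0:
        return float("inf") if late > 0 else float("nan")
    return float(late / early)
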