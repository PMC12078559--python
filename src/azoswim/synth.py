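"""Synthetic trajectory and displacement-series generators with known truth.

Everything the analysis modules consume can be generated here with ground
truth attached: Brownian ensembles with known D, ballistic drift tracks,
radially spreading/converging ensembles (the geometry of photoinduced
outward/inward microflows around an irradiated ROI), and stepwise interface
walks emulating push- and pull-swimming displacement maps.

All generators draw from ``numpy.random.default_rng(seed)`` and are
bit-reproducible under a fixed seed; the generating spec (including the
seed) is attached to each track's metadata.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np

from .msd import Trajectory

__all__ = [
    "GeneratorKind",
    "GeneratorSpec",
    "gen_brownian",
    "gen_ballistic",
    "gen_radial",
    "gen_interface_walk",
    "generate",
]


class GeneratorKind(enum.Enum):
    BROWNIAN = "brownian"
    BALLISTIC = "ballistic"
    RADIAL_SPREAD = "radial_spread"
    RADIAL_COLLAPSE = "radial_collapse"
    PUSH_WALK = "push_walk"
    PULL_WALK = "pull_walk"


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic ensemble.

    ``D_true`` is the diffusion coefficient (um^2/s) for diffusive kinds and
    ``v_true`` the drift speed (um/s) for drift kinds; ``noise_sigma`` is
    isotropic Gaussian localization noise (um) added to every recorded
    position, the standard tracking-error model.
    """

    kind: GeneratorKind
    n_particles: int = 50
    n_steps: int = 100
    frame_interval: float = 0.2
    D_true: float = 0.5
    v_true: float = 1.0
    noise_sigma: float = 0.05
    roi_center: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.kind, str):
            object.__setattr__(self, "kind", GeneratorKind(self.kind))
        if self.n_steps < 2:
            raise ValueError(f"n_steps must be >= 2, got {self.n_steps}")
        if self.n_particles < 1:
            raise ValueError(f"n_particles must be >= 1, got {self.n_particles}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.D_true < 0 or self.noise_sigma < 0:
            raise ValueError("D_true and noise_sigma must be >= 0")

    def metadata(self) -> dict:
        md = asdict(self)
        md["kind"] = self.kind.value
        return md


def _require(spec: GeneratorSpec, *kinds: GeneratorKind) -> None:
    if spec.kind not in kinds:
        raise ValueError(f"spec.kind is {spec.kind}, expected one of {kinds}")


def _package(spec: GeneratorSpec, paths: np.ndarray, rng: np.random.Generator,
             labels: Sequence[str] | None = None) -> list[Trajectory]:
    """Add localization noise and wrap raw paths (n_particles, n_steps, 2)."""
    if spec.noise_sigma > 0:
        paths = paths + rng.normal(0.0, spec.noise_sigma, size=paths.shape)
    times = np.arange(spec.n_steps) * spec.frame_interval
    out = []
    for i in range(spec.n_particles):
        meta = spec.metadata()
        if labels is not None:
            meta["true_direction"] = labels[i]
        out.append(Trajectory(
            track_id=f"{spec.kind.value}_{i:04d}",
            times=times.copy(),
            positions=paths[i],
            frame_interval=spec.frame_interval,
            meta=meta,
        ))
    return out


def gen_brownian(spec: GeneratorSpec) -> list[Trajectory]:
    """Pure 2D Brownian tracks: Gaussian increments of variance 2*D*dt per axis."""
    _require(spec, GeneratorKind.BROWNIAN)
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(2.0 * spec.D_true * spec.frame_interval)
    steps = rng.normal(0.0, sigma, size=(spec.n_particles, spec.n_steps - 1, 2)) \
        if sigma > 0 else np.zeros((spec.n_particles, spec.n_steps - 1, 2))
    start = rng.uniform(-50.0, 50.0, size=(spec.n_particles, 1, 2))
    paths = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
    return _package(spec, paths, rng)


def gen_ballistic(spec: GeneratorSpec) -> list[Trajectory]:
    """Constant-velocity drift tracks, heading random per particle."""
    _require(spec, GeneratorKind.BALLISTIC)
    rng = np.random.default_rng(spec.seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_particles)
    heading = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    t = (np.arange(spec.n_steps) * spec.frame_interval)[None, :, None]
    start = rng.uniform(-50.0, 50.0, size=(spec.n_particles, 1, 2))
    paths = start + spec.v_true * t * heading[:, None, :]
    return _package(spec, paths, rng)


def gen_radial(spec: GeneratorSpec) -> list[Trajectory]:
    """Radial drift away from (spread) or toward (collapse) the ROI center.

    Particles start on an annulus around the center, drift radially at
    ``v_true`` superposed on diffusion ``D_true``; collapsing particles stop
    shrinking at a 0.5 um core radius rather than crossing the center.
    Ground-truth direction is attached as ``meta['true_direction']``.
    """
    _require(spec, GeneratorKind.RADIAL_SPREAD, GeneratorKind.RADIAL_COLLAPSE)
    rng = np.random.default_rng(spec.seed)
    inward = spec.kind is GeneratorKind.RADIAL_COLLAPSE
    center = np.asarray(spec.roi_center, dtype=float)
    dt = spec.frame_interval
    n, m = spec.n_particles, spec.n_steps
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    radius = rng.uniform(20.0, 50.0, size=n)
    pos = center + radius[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    sigma = np.sqrt(2.0 * spec.D_true * dt)
    paths = np.empty((n, m, 2))
    paths[:, 0] = pos
    drift = -spec.v_true if inward else spec.v_true
    for k in range(1, m):
        rel = paths[:, k - 1] - center
        r = np.linalg.norm(rel, axis=1)
        unit = np.divide(rel, r[:, None], out=np.zeros_like(rel),
                         where=r[:, None] > 0)
        step = drift * dt * unit
        if inward:  # do not overshoot through the core
            step = -np.minimum(np.abs(drift) * dt, np.maximum(r - 0.5, 0.0))[:, None] * unit
        noise = rng.normal(0.0, sigma, size=(n, 2)) if sigma > 0 else 0.0
        paths[:, k] = paths[:, k - 1] + step + noise
    labels = ["inward" if inward else "outward"] * n
    return _package(spec, paths, rng, labels=labels)


@dataclass(frozen=True)
class InterfaceWalk:
    """Interface positions of a swimming condensate at switching moments."""

    positions: np.ndarray    # (n+1, 2) um
    switch_times: np.ndarray  # (n+1,) s
    spec: GeneratorSpec = field(repr=False, default=None)  # type: ignore


#: per-kind defaults emulating the observed swimming phenomenology:
#: push-swimming takes larger steps but crumbles after few operations;
#: pull-swimming takes smaller steps, lasts longer, then plateaus.
_WALK_DEFAULTS = {
    GeneratorKind.PUSH_WALK: dict(mean_step=5.0, step_sd=1.0, n_steps_eff=11,
                                  plateau_after=1.0, angle_jitter=0.3),
    GeneratorKind.PULL_WALK: dict(mean_step=1.5, step_sd=0.4, n_steps_eff=30,
                                  plateau_after=0.6, angle_jitter=0.2),
}


def gen_interface_walk(spec: GeneratorSpec, **overrides) -> InterfaceWalk:
    """Stepwise interface displacement series for push- or pull-swimming.

    A persistent heading with small angular jitter; after ``plateau_after``
    of the walk the step length decays to near zero (the pull-swimming
    displacement plateau).  ``spec.n_steps`` overrides the kind's default
    number of switching steps when it differs from the dataclass default;
    the step-length distribution (``mean_step``, ``step_sd``), the
    ``plateau_after`` fraction and the heading ``angle_jitter`` can be
    overridden by keyword.
    """
    _require(spec, GeneratorKind.PUSH_WALK, GeneratorKind.PULL_WALK)
    rng = np.random.default_rng(spec.seed)
    cfg = dict(_WALK_DEFAULTS[spec.kind])
    unknown = set(overrides) - set(cfg)
    if unknown:
        raise TypeError(f"unknown walk parameters: {sorted(unknown)}")
    cfg.update(overrides)
    n = spec.n_steps if spec.n_steps != 100 else cfg["n_steps_eff"]
    heading = rng.uniform(0.0, 2.0 * np.pi)
    pos = [np.zeros(2)]
    for i in range(n):
        frac = (i + 1) / n
        scale = 1.0 if frac <= cfg["plateau_after"] else \
            max(0.0, 1.0 - (frac - cfg["plateau_after"]) / (1.0 - cfg["plateau_after"] + 1e-12))
        step_len = max(0.0, rng.normal(cfg["mean_step"], cfg["step_sd"])) * scale
        heading += rng.normal(0.0, cfg["angle_jitter"])
        pos.append(pos[-1] + step_len * np.array([np.cos(heading), np.sin(heading)]))
    times = np.arange(n + 1) * (1.0 / (2.0 * 0.05))  # default half-cycle of f=0.05/s
    return InterfaceWalk(positions=np.array(pos), switch_times=times, spec=spec)


_DISPATCH = {
    GeneratorKind.BROWNIAN: gen_brownian,
    GeneratorKind.BALLISTIC: gen_ballistic,
    GeneratorKind.RADIAL_SPREAD: gen_radial,
    GeneratorKind.RADIAL_COLLAPSE: gen_radial,
    GeneratorKind.PUSH_WALK: gen_interface_walk,
    GeneratorKind.PULL_WALK: gen_interface_walk,
}


def generate(spec: GeneratorSpec):
    """Dispatch to the generator for ``spec.kind``."""
    return _DISPATCH[spec.kind](spec)
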