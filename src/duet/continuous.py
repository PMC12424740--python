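"""Score-based Gaussian diffusion over C-alpha coordinates.

The forward process perturbs zero-centered coordinates x0 with isotropic
Gaussian noise, ``p(x_t | x_0) = N(x_t; x_0, t^2 I)`` (variance-exploding SDE
with drift ``f = 0`` and diffusion ``g(t) = sqrt(2 t)``).  Noise levels are
handled on a warped time axis so that training and sampling spend most of
their steps near the data scale; the network output is blended into a score
estimate with a noise-level-dependent post-conditioning so that it smoothly
interpolates between predicting the score (small t) and predicting the clean
data (large t).  Sampling integrates the reverse SDE with Euler-Maruyama
under low-temperature annealing: the score drift is inflated by a factor
``(1 + beta(t))`` while the injected noise is scaled by ``sqrt(beta * gamma)``
with ``gamma < 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "SigmaSchedule",
    "AnnealingParams",
    "StructureState",
    "ScoreOutput",
    "rescale_time",
    "invert_time",
    "forward_noise",
    "score_coefficients",
    "score_from_raw",
    "loss_weight",
    "structure_loss",
    "reverse_step",
    "sample_structure",
]


@dataclass(frozen=True)
class SigmaSchedule:
    """Warped noise-level schedule.

    Parameters
    ----------
    t_min, t_max:
        Smallest / largest noise standard deviation in Angstrom.
    p:
        Warp exponent; larger p concentrates warped time near small t.
    t_data:
        Characteristic data scale in Angstrom, used by the score
        post-conditioning and the loss weighting.
    """

    t_min: float = 0.05
    t_max: float = 160.0
    p: float = 7.0
    t_data: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 < self.t_min < self.t_max):
            raise ValueError("require 0 < t_min < t_max")
        if self.p < 1.0:
            raise ValueError("warp exponent p must be >= 1")
        if self.t_data <= 0.0:
            raise ValueError("t_data must be positive")


@dataclass(frozen=True)
class AnnealingParams:
    """Low-temperature annealing of the reverse SDE.

    ``beta(t) = 1 / (1 + (t/t_data)^nu)`` mixes in Langevin-style corrections
    (stochasticity), and ``gamma`` scales the temperature of the injected
    noise.  ``nu = 0.5`` is the unconditional default, ``nu = 1`` the
    conditional one; ``beta = 1, gamma = 1`` recovers the plain reverse SDE.
    """

    nu: float = 0.5
    gamma: float = 0.5
    t_data: float = 15.0

    def __post_init__(self) -> None:
        if self.gamma <= 0.0:
            raise ValueError("gamma must be positive")

    def beta(self, t: float) -> float:
        return 1.0 / (1.0 + (t / self.t_data) ** self.nu)


@dataclass
class StructureState:
    """L x 3 C-alpha coordinates at a given noise level (Angstrom)."""

    coords: np.ndarray
    noise_level: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be L x 3")

    def centered(self) -> "StructureState":
        return StructureState(self.coords - self.coords.mean(axis=0), self.noise_level)


@dataclass
class ScoreOutput:
    raw_prediction: np.ndarray
    score: np.ndarray


def rescale_time(t, sched: SigmaSchedule = SigmaSchedule()):
    """Map a noise level t in [t_min, t_max] to warped time t' in [0, 1].

    t' = (t^(1/p) - t_min^(1/p)) / (t_max^(1/p) - t_min^(1/p)); strictly
    increasing, with t'(t_min) = 0 and t'(t_max) = 1.
    """
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < sched.t_min - 1e-12) or np.any(t > sched.t_max + 1e-12):
        raise ValueError("noise level outside [t_min, t_max]")
    a = sched.t_min ** (1.0 / sched.p)
    b = sched.t_max ** (1.0 / sched.p)
    out = (t ** (1.0 / sched.p) - a) / (b - a)
    return float(out) if out.ndim == 0 else out


def invert_time(t_prime, sched: SigmaSchedule = SigmaSchedule()):
    """Closed-form inverse of :func:`rescale_time` on [0, 1]."""
    u = np.asarray(t_prime, dtype=np.float64)
    if np.any(u < -1e-12) or np.any(u > 1.0 + 1e-12):
        raise ValueError("warped time outside [0, 1]")
    a = sched.t_min ** (1.0 / sched.p)
    b = sched.t_max ** (1.0 / sched.p)
    out = (a + u * (b - a)) ** sched.p
    return float(out) if out.ndim == 0 else out


def forward_noise(x0: StructureState, t: float, rng: np.random.Generator) -> StructureState:
    """Sample x_t ~ N(x_0, t^2 I)."""
    if t < 0.0:
        raise ValueError("noise level must be nonnegative")
    eps = rng.standard_normal(x0.coords.shape)
    return StructureState(x0.coords + t * eps, t)


def score_coefficients(t: float, sched: SigmaSchedule) -> tuple[float, float]:
    """Coefficients (c_raw, c_x) such that score = c_raw * f_theta + c_x * x.

    c_raw = t_data / (t * sqrt(t_data^2 + t^2)),  c_x = -1 / (t_data^2 + t^2).
    Small t: score ~ f/t; large t: score ~ (t_data f - x) / t^2.
    """
    if t <= 0.0:
        raise ValueError("score undefined at t <= 0")
    d2 = sched.t_data**2 + t**2
    c_raw = sched.t_data / (t * np.sqrt(d2))
    c_x = -1.0 / d2
    return c_raw, c_x


def score_from_raw(
    raw: np.ndarray, x: np.ndarray, t: float, sched: SigmaSchedule = SigmaSchedule()
) -> ScoreOutput:
    """Blend the raw network output into a score estimate (post-conditioning)."""
    raw = np.asarray(raw, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if raw.shape != x.shape:
        raise ValueError("raw and x must have matching shapes")
    c_raw, c_x = score_coefficients(t, sched)
    return ScoreOutput(raw_prediction=raw, score=c_raw * raw + c_x * x)


def input_scale(t, sched: SigmaSchedule):
    """Network input preconditioning c_in = 1/sqrt(t_data^2 + t^2).

    Normalizes the variance of noisy coordinates seen by the denoiser to
    order one across the whole noise range.
    """
    return 1.0 / np.sqrt(sched.t_data**2 + np.asarray(t, dtype=np.float64) ** 2)


def loss_weight(t: float, sched: SigmaSchedule) -> float:
    """Time weighting of the score-matching loss: t^2 (t^2 + t_data^2) / t_data^2."""
    return t**2 * (t**2 + sched.t_data**2) / sched.t_data**2


def structure_loss(
    raw: np.ndarray,
    x0: np.ndarray,
    xt: np.ndarray,
    t: float,
    sched: SigmaSchedule = SigmaSchedule(),
) -> float:
    """Weighted score-matching loss against the conditional score (x0 - xt)/t^2.

    Zero exactly when the derived score matches the target; the weighting
    makes the objective equivalent to a clean-data regression at every noise
    level.  Mean over coordinates.
    """
    raw = np.asarray(raw, dtype=np.float64)
    x0 = np.asarray(x0, dtype=np.float64)
    xt = np.asarray(xt, dtype=np.float64)
    if not (raw.shape == x0.shape == xt.shape):
        raise ValueError("raw, x0, xt must share one shape")
    score = score_from_raw(raw, xt, t, sched).score
    target = (x0 - xt) / t**2
    return float(loss_weight(t, sched) * np.mean((score - target) ** 2))


def reverse_step(
    x: StructureState,
    score: np.ndarray,
    t: float,
    dt: float,
    ann: AnnealingParams = AnnealingParams(),
    rng: Optional[np.random.Generator] = None,
    inject_noise: bool = True,
) -> StructureState:
    """One Euler-Maruyama update of the annealed reverse SDE, t -> t - dt.

    x <- x + (g^2/2)(1 + beta(t)) * score * dt + g * sqrt(beta * gamma * dt) * eps
    with g^2 = 2 t.  With beta = gamma = 1 this is the standard reverse SDE.
    """
    score = np.asarray(score, dtype=np.float64)
    if score.shape != x.coords.shape:
        raise ValueError("score shape mismatch")
    if dt <= 0.0:
        raise ValueError("dt must be positive (step toward smaller t)")
    g2 = 2.0 * t
    beta = ann.beta(t)
    drift = 0.5 * g2 * (1.0 + beta) * score * dt
    new = x.coords + drift
    if inject_noise:
        if rng is None:
            raise ValueError("rng required when injecting noise")
        new = new + np.sqrt(g2 * beta * ann.gamma * dt) * rng.standard_normal(score.shape)
    return StructureState(new, t - dt)


def sample_structure(
    score_fn: Callable[[np.ndarray, float], np.ndarray],
    L: int,
    n_steps: int,
    ann: AnnealingParams = AnnealingParams(),
    sched: SigmaSchedule = SigmaSchedule(),
    rng: Optional[np.random.Generator] = None,
    x_init: Optional[np.ndarray] = None,
    return_trajectory: bool = False,
    recenter_each_step: bool = True,
):
    """Full reverse rollout from N(0, t_max^2 I) with uniform steps in warped time.

    ``score_fn(x, t) -> score`` is called exactly once per step (L x 3 in and
    out).  The terminal step is deterministic: no noise is injected when
    landing on t_min.  The final structure is re-centered.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if x_init is None:
        x = sched.t_max * rng.standard_normal((L, 3))
    else:
        x = np.array(x_init, dtype=np.float64)
    grid_u = np.linspace(1.0, 0.0, n_steps + 1)
    grid_t = invert_time(grid_u, sched)
    traj = [x.copy()]
    for k in range(n_steps):
        t, t_next = grid_t[k], grid_t[k + 1]
        if recenter_each_step:
            x = x - x.mean(axis=0)
        score = np.asarray(score_fn(x, t), dtype=np.float64)
        if score.shape != x.shape:
            raise ValueError("score_fn returned wrong shape")
        state = reverse_step(
            StructureState(x, t),
            score,
            t,
            t - t_next,
            ann,
            rng,
            inject_noise=(k < n_steps - 1),
        )
        x = state.coords
        traj.append(x.copy())
    x = x - x.mean(axis=0)
    traj[-1] = x
    if return_trajectory:
        return traj
    return StructureState(x, grid_t[-1])
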