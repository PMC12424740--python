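"""Masked (absorbing-state) diffusion over amino-acid sequences.

Sequences live in a 21-token vocabulary: tokens 0..19 are the amino acids and
token 20 is the absorbing mask symbol.  Forward corruption independently
replaces each token with the mask with probability ``1 - alpha_t``; the exact
reverse posterior either carries unmasked tokens unchanged or fills masked
positions from the model's clean-token prediction ``x0_hat``.  Besides plain
ancestral sampling, the module implements the path-planning sampler: each
step draws Gumbel-perturbed log-confidences, unmasks the top-k most confident
positions and re-masks everything else, so the unmasking *order* itself is
chosen by the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

N_AMINO = 20
MASK = 20
VOCAB = 21

__all__ = [
    "N_AMINO",
    "MASK",
    "VOCAB",
    "SequenceState",
    "alpha_linear",
    "mask_forward",
    "reverse_posterior",
    "seq_loss",
    "path_planning_step",
    "sample_sequence",
    "inverse_fold_sample",
    "round_half_away",
]


@dataclass
class SequenceState:
    """Length-L token vector over the 21-token vocabulary at time t in [0,1]."""

    tokens: np.ndarray
    time: float

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if self.tokens.ndim != 1:
            raise ValueError("tokens must be a 1-D vector")
        if np.any(self.tokens < 0) or np.any(self.tokens >= VOCAB):
            raise ValueError("token out of vocabulary")

    @property
    def masked(self) -> np.ndarray:
        return self.tokens == MASK


def alpha_linear(t: float) -> float:
    """Linear survival probability alpha_t = 1 - t (alpha_0 = 1, alpha_1 = 0)."""
    if t < 0.0 or t > 1.0:
        raise ValueError("t must lie in [0, 1]")
    return 1.0 - t


def round_half_away(x: float) -> int:
    """Round half away from zero (fixed cross-platform semantics)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x != 0 else 0


def mask_forward(s0: SequenceState, t: float, rng: np.random.Generator) -> SequenceState:
    """Corrupt a clean sequence: keep each token w.p. alpha_t, else mask."""
    if np.any(s0.tokens == MASK):
        raise ValueError("forward corruption expects a mask-free sequence")
    alpha = alpha_linear(t)
    keep = rng.random(s0.tokens.shape) < alpha
    tokens = np.where(keep, s0.tokens, MASK)
    return SequenceState(tokens, t)


def reverse_posterior(
    xt_token: int, x0_hat: np.ndarray, alpha_s: float, alpha_t: float
) -> np.ndarray:
    """Exact one-position reverse posterior p(x_s | x_t, x0_hat), a 21-simplex row.

    Unmasked tokens are carried as a point mass.  A masked token stays masked
    with probability (1 - alpha_s)/(1 - alpha_t) and otherwise is filled from
    x0_hat with total probability (alpha_s - alpha_t)/(1 - alpha_t).
    """
    if alpha_s <= alpha_t:
        raise ValueError("require alpha_s > alpha_t (denoising moves s < t)")
    x0_hat = np.asarray(x0_hat, dtype=np.float64)
    if x0_hat.shape != (VOCAB,):
        raise ValueError("x0_hat must be a 21-vector")
    out = np.zeros(VOCAB)
    if xt_token != MASK:
        out[xt_token] = 1.0
        return out
    stay = (1.0 - alpha_s) / (1.0 - alpha_t)
    fill = (alpha_s - alpha_t) / (1.0 - alpha_t)
    out = fill * x0_hat
    out[MASK] += stay
    return out


def seq_loss(logits: np.ndarray, s0: SequenceState, st: SequenceState, t: float) -> float:
    """Masked cross-entropy with weight (1 - t).

    Only positions masked in ``st`` are supervised; the model distribution is
    the softmax of the logits restricted to the 20 amino-acid tokens (the
    clean-data prediction carries no mass on the mask symbol).
    """
    if t < 0.0 or t > 1.0:
        raise ValueError("t must lie in [0, 1]")
    logits = np.asarray(logits, dtype=np.float64)
    if logits.shape != (len(st.tokens), VOCAB):
        raise ValueError("logits must be L x 21")
    masked = st.masked
    if not masked.any():
        return 0.0
    aa = logits[:, :N_AMINO]
    logp = aa - _logsumexp(aa)
    nll = -logp[masked, s0.tokens[masked]]
    return float((1.0 - t) * nll.mean())


def _logsumexp(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(a - m).sum(axis=-1, keepdims=True))


def _log_softmax(a: np.ndarray) -> np.ndarray:
    return a - _logsumexp(a)


def path_planning_step(
    logits: np.ndarray,
    st: SequenceState,
    s: float,
    t: float,
    gamma: float,
    mode: str = "sequence",
    rng: Optional[np.random.Generator] = None,
    z: Optional[np.ndarray] = None,
    clamp: Optional[np.ndarray] = None,
) -> SequenceState:
    """One Gumbel top-k path-planning step from time t to time s < t.

    Per position, noisy log-confidences ``phi = log_softmax(logits/gamma + z)``
    give a sampled token ``y = argmax phi`` and confidence ``u = max phi``.
    The ``k = L_free - round(s * L_free)`` most confident free positions form
    the keep-set: inside it, masked positions take their sampled token and
    unmasked ones are carried; outside it, positions are re-masked.  In
    ``cogeneration`` mode, currently-unmasked positions use their own token
    and its model log-probability as (y, u).  Clamped positions are never
    masked nor resampled and do not count toward k.

    ``z`` overrides the Gumbel draws (shape L x 20), used for deterministic
    limit tests.
    """
    if not (0.0 <= s < t <= 1.0):
        raise ValueError("require 0 <= s < t <= 1")
    if mode not in ("sequence", "cogeneration"):
        raise ValueError(f"unknown mode {mode!r}")
    logits = np.asarray(logits, dtype=np.float64)
    L = len(st.tokens)
    if logits.shape != (L, VOCAB):
        raise ValueError("logits must be L x 21")
    clamp_mask = np.zeros(L, dtype=bool)
    if clamp is not None:
        clamp_mask[np.asarray(clamp, dtype=np.int64)] = True
    if z is None:
        if rng is None:
            raise ValueError("rng required when z is not supplied")
        z = rng.gumbel(size=(L, N_AMINO))
    z = np.asarray(z, dtype=np.float64)
    phi = _log_softmax(logits[:, :N_AMINO] / gamma + z)
    y = phi.argmax(axis=1)  # ties: lowest token index (argmax semantics)
    u = phi[np.arange(L), y]
    if mode == "cogeneration":
        unmasked = ~st.masked & ~clamp_mask
        if unmasked.any():
            cur = st.tokens[unmasked]
            y[unmasked] = cur
            logp = _log_softmax(logits[:, :N_AMINO])
            u[unmasked] = logp[np.flatnonzero(unmasked), cur]
    free = np.flatnonzero(~clamp_mask)
    L_free = len(free)
    k = L_free - round_half_away(s * L_free)
    # stable top-k over free positions; ties broken by lowest position index
    order = np.lexsort((free, -u[free]))
    keep = free[order[:k]]
    keep_mask = np.zeros(L, dtype=bool)
    keep_mask[keep] = True
    new = np.full(L, MASK, dtype=np.int64)
    new[keep_mask & st.masked] = y[keep_mask & st.masked]
    carried = keep_mask & ~st.masked
    new[carried] = st.tokens[carried]
    new[clamp_mask] = st.tokens[clamp_mask]
    return SequenceState(new, s)


def sample_sequence(
    model: Callable[[SequenceState], np.ndarray],
    L: int,
    n_steps: int,
    gamma_fn: Callable[[float], float] = lambda t: 0.5,
    mode: str = "path_planning",
    rng: Optional[np.random.Generator] = None,
    clamp: Optional[Sequence[int]] = None,
    clamp_tokens: Optional[Sequence[int]] = None,
) -> SequenceState:
    """Full rollout from the all-mask state with steps uniform in t.

    ``model(state) -> L x 21 logits``.  Modes: ``path_planning`` (default,
    sequence generation), ``cogeneration`` (path planning with carried-token
    confidences) and ``ancestral`` (exact per-position reverse posterior).
    ``clamp`` positions are initialized to ``clamp_tokens`` and never change.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    tokens = np.full(L, MASK, dtype=np.int64)
    clamp_idx = None
    if clamp is not None:
        clamp_idx = np.asarray(clamp, dtype=np.int64)
        if np.any(clamp_idx < 0) or np.any(clamp_idx >= L):
            raise ValueError("clamp index out of range")
        tokens[clamp_idx] = np.asarray(clamp_tokens, dtype=np.int64)
    state = SequenceState(tokens, 1.0)
    grid = np.linspace(1.0, 0.0, n_steps + 1)
    for k in range(n_steps):
        t, s = grid[k], grid[k + 1]
        logits = np.asarray(model(state), dtype=np.float64)
        if mode == "ancestral":
            state = _ancestral_step(logits, state, s, t, rng, clamp_idx)
        else:
            pp_mode = "cogeneration" if mode == "cogeneration" else "sequence"
            state = path_planning_step(
                logits, state, s, t, gamma_fn(t), pp_mode, rng, clamp=clamp_idx
            )
    return state


def _ancestral_step(
    logits: np.ndarray,
    st: SequenceState,
    s: float,
    t: float,
    rng: np.random.Generator,
    clamp_idx: Optional[np.ndarray],
) -> SequenceState:
    alpha_s, alpha_t = alpha_linear(s), alpha_linear(t)
    probs = np.exp(_log_softmax(logits[:, :N_AMINO]))
    x0_hat = np.zeros((len(st.tokens), VOCAB))
    x0_hat[:, :N_AMINO] = probs
    new = st.tokens.copy()
    for i in np.flatnonzero(st.masked):
        row = reverse_posterior(MASK, x0_hat[i], alpha_s, alpha_t)
        new[i] = rng.choice(VOCAB, p=row)
    if clamp_idx is not None:
        new[clamp_idx] = st.tokens[clamp_idx]
    return SequenceState(new, s)


def sample_sequence_batch(
    posterior_fn: Callable[[np.ndarray], np.ndarray],
    L: int,
    n_steps: int,
    n_samples: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Vectorized ancestral sampling of many independent rollouts.

    ``posterior_fn(tokens) -> (B, L, 21)`` maps a batch of partially-masked
    token arrays to clean-token posteriors ``x0_hat``.  Each rollout applies
    the exact per-position reverse posterior on a grid uniform in t.
    Returns an (n_samples, L) token array with no masks remaining.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    tokens = np.full((n_samples, L), MASK, dtype=np.int64)
    grid = np.linspace(1.0, 0.0, n_steps + 1)
    for k in range(n_steps):
        t, s = grid[k], grid[k + 1]
        alpha_s, alpha_t = alpha_linear(s), alpha_linear(t)
        masked = tokens == MASK
        if not masked.any():
            break
        x0_hat = np.asarray(posterior_fn(tokens), dtype=np.float64)
        stay = (1.0 - alpha_s) / (1.0 - alpha_t)
        fill = (alpha_s - alpha_t) / (1.0 - alpha_t)
        post = fill * x0_hat
        post[..., MASK] += stay
        cdf = np.cumsum(post, axis=-1)
        u = rng.random((n_samples, L, 1)) * cdf[..., -1:]
        draw = (u > cdf).sum(axis=-1)
        tokens = np.where(masked, draw, tokens)
    return tokens


def inverse_fold_sample(
    model: Callable[[SequenceState], np.ndarray],
    L: int,
    rng: Optional[np.random.Generator] = None,
    temperature: float = 0.1,
) -> SequenceState:
    """Inverse-folding sampler: random unmasking order, one position per step.

    The caller binds the fixed structure into ``model``; each step samples the
    next position from the model softmax at low temperature.  ``temperature=0``
    selects the argmax.
    """
    rng = np.random.default_rng() if rng is None else rng
    state = SequenceState(np.full(L, MASK, dtype=np.int64), 1.0)
    order = rng.permutation(L)
    for step, pos in enumerate(order):
        logits = np.asarray(model(state), dtype=np.float64)[pos, :N_AMINO]
        if temperature <= 0.0:
            tok = int(logits.argmax())
        else:
            p = np.exp(_log_softmax(logits[None, :] / temperature))[0]
            tok = int(rng.choice(N_AMINO, p=p))
        tokens = state.tokens.copy()
        tokens[pos] = tok
        state = SequenceState(tokens, 1.0 - (step + 1) / L)
    return state
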