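"""Classifier-free guidance and coupled two-state structure sampling.

Classifier-free guidance extrapolates between unconditional and conditional
model outputs, ``(1 - lambda) * uncond + lambda * cond``; because the score
post-conditioning is linear in the raw network output, blending raw
predictions is equivalent to blending scores.

Coupled sampling targets a single sequence that folds into two distinct
structures, each scaffolding its own motif.  Per step the model is evaluated
three times -- (s, x1 | m1), (s, x2 | m2) and (s | no conditioning) -- the
shared sequence is advanced with the product-of-experts logits
``phi1 + phi2 - phi_uncond``, and each structure is advanced with its own
branch score.  Motif residues are clamped in the sequence for the entire
trajectory; the two structure branches never exchange coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .continuous import (
    AnnealingParams,
    SigmaSchedule,
    StructureState,
    input_scale,
    invert_time,
    rescale_time,
    reverse_step,
    score_from_raw,
)
from .denoiser import Denoiser, DenoiserOutput, MotifSpec, _motif_arrays
from .discrete import MASK, SequenceState, path_planning_step
from .nn import no_grad

__all__ = [
    "GuidanceParams",
    "CoupledState",
    "cfg_combine",
    "coupled_logits",
    "coupled_sample",
    "place_effector_motif",
]


@dataclass(frozen=True)
class GuidanceParams:
    """Guidance strength lambda: 1 = conditional, 0 = unconditional."""

    strength: float = 3.0


@dataclass
class CoupledState:
    sequence: SequenceState
    structures: Tuple[StructureState, StructureState]
    motifs: Tuple[MotifSpec, MotifSpec]


def cfg_combine(uncond: DenoiserOutput, cond: DenoiserOutput, strength: float) -> DenoiserOutput:
    """Linear guidance combination of logits and raw structure predictions."""
    if uncond.logits.shape != cond.logits.shape:
        raise ValueError("shape mismatch between guidance branches")
    lam = float(strength)
    return DenoiserOutput(
        logits=(1.0 - lam) * uncond.logits + lam * cond.logits,
        structure_pred=(1.0 - lam) * uncond.structure_pred + lam * cond.structure_pred,
    )


def coupled_logits(phi1: np.ndarray, phi2: np.ndarray, phi_uncond: np.ndarray) -> np.ndarray:
    """Product-of-experts sequence logits: phi1 + phi2 - phi_uncond."""
    phi1, phi2, phi_uncond = map(np.asarray, (phi1, phi2, phi_uncond))
    if not (phi1.shape == phi2.shape == phi_uncond.shape):
        raise ValueError("logit shape mismatch")
    return phi1 + phi2 - phi_uncond


def _default_cogeneration_gamma(t: float) -> float:
    return 0.1 + 0.4 * t


def coupled_sample(
    model: Denoiser,
    m1: MotifSpec,
    m2: MotifSpec,
    L: int,
    n_steps: int,
    ann: AnnealingParams = AnnealingParams(nu=1.0),
    sched: SigmaSchedule = SigmaSchedule(),
    rng: Optional[np.random.Generator] = None,
    gamma_fn: Callable[[float], float] = _default_cogeneration_gamma,
    branch_seeds: Optional[Tuple[int, int]] = None,
    term: Optional[int] = None,
) -> CoupledState:
    """Couple two structure denoising trajectories to one sequence trajectory.

    ``branch_seeds`` fixes the noise streams of the two structure branches
    independently of the shared stream (passing equal seeds with equal motifs
    makes the branches bitwise identical, a useful diagnostic).
    """
    rng = np.random.default_rng() if rng is None else rng
    shared = set(m1.positions) & set(m2.positions)
    for p in shared:
        a = m1.identities[np.searchsorted(m1.positions, p)]
        b = m2.identities[np.searchsorted(m2.positions, p)]
        if a != b:
            raise ValueError(f"motif identity conflict at shared position {p}")
    if branch_seeds is None:
        branch_seeds = (int(rng.integers(2**31)), int(rng.integers(2**31)))
    rng1, rng2 = (np.random.default_rng(s) for s in branch_seeds)

    # clamp: union of both motifs, unmasked from step 0
    tokens = np.full(L, MASK, dtype=np.int64)
    for m in (m1, m2):
        tokens[m.positions] = m.identities
    clamp_idx = np.flatnonzero(tokens != MASK)
    seq = SequenceState(tokens, 1.0)

    x1 = sched.t_max * rng1.standard_normal((L, 3))
    x2 = sched.t_max * rng2.standard_normal((L, 3))
    mask1, mc1, mt1 = _motif_arrays(m1, L)
    mask2, mc2, mt2 = _motif_arrays(m2, L)
    none_mask, none_mc, none_mt = _motif_arrays(None, L)

    seq_grid = np.linspace(1.0, 0.0, n_steps + 1)
    struct_grid = invert_time(np.linspace(1.0, 0.0, n_steps + 1), sched)
    term_ids = None
    if model.func_emb is not None:
        t = -1 if term is None else int(term)
        term_ids = np.array([t, t, -1])
    for k in range(n_steps):
        ts, ts_next = seq_grid[k], seq_grid[k + 1]
        tx, tx_next = struct_grid[k], struct_grid[k + 1]
        x1c, x2c = x1 - x1.mean(axis=0), x2 - x2.mean(axis=0)
        x_noise = sched.t_max * rng.standard_normal((L, 3))
        batch_tokens = np.stack([seq.tokens] * 3)
        batch_coords = np.stack([x1c, x2c, x_noise])
        tp = np.array([rescale_time(tx, sched)] * 2 + [1.0])
        with no_grad():
            logits, pred = model.forward(
                batch_tokens,
                batch_coords,
                tp,
                np.concatenate([mask1, mask2, none_mask]),
                np.concatenate([mc1, mc2, none_mc]),
                np.concatenate([mt1, mt2, none_mt]),
                term_ids,
                coord_scale=input_scale(np.array([tx, tx, sched.t_max]), sched),
                motif_coord_scale=1.0 / sched.t_data,
            )
        phi = coupled_logits(logits.data[0], logits.data[1], logits.data[2])
        seq = path_planning_step(
            phi, seq, ts_next, ts, gamma_fn(ts), "cogeneration", rng, clamp=clamp_idx
        )
        last = k == n_steps - 1
        s1 = score_from_raw(pred.data[0], x1c, tx, sched).score
        s2 = score_from_raw(pred.data[1], x2c, tx, sched).score
        x1 = reverse_step(
            StructureState(x1c, tx), s1, tx, tx - tx_next, ann, rng1, inject_noise=not last
        ).coords
        x2 = reverse_step(
            StructureState(x2c, tx), s2, tx, tx - tx_next, ann, rng2, inject_noise=not last
        ).coords
    x1 -= x1.mean(axis=0)
    x2 -= x2.mean(axis=0)
    return CoupledState(
        sequence=seq,
        structures=(StructureState(x1, struct_grid[-1]), StructureState(x2, struct_grid[-1])),
        motifs=(m1, m2),
    )


def place_effector_motif(
    L: int,
    motif: MotifSpec,
    fixed_position: Optional[int] = None,
    occupied: Sequence[Tuple[int, int]] = (),
    rng: Optional[np.random.Generator] = None,
) -> MotifSpec:
    """Re-index a contiguous motif at a fixed or random non-overlapping spot.

    ``occupied`` is a list of half-open index ranges that the motif window
    [p, p + span) must not intersect.
    """
    span = int(motif.positions[-1] - motif.positions[0] + 1) if len(motif) else 0
    if span > L:
        raise ValueError("motif longer than sequence")

    def legal(p: int) -> bool:
        if p < 0 or p + span > L:
            return False
        return all(p + span <= a or p >= b for a, b in occupied)

    if fixed_position is not None:
        if not legal(fixed_position):
            raise ValueError("fixed placement is not legal")
        return motif.shifted(fixed_position)
    starts = [p for p in range(L - span + 1) if legal(p)]
    if not starts:
        raise ValueError("no legal placement for motif")
    rng = np.random.default_rng() if rng is None else rng
    return motif.shifted(int(rng.choice(starts)))
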