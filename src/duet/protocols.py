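"""End-to-end generation protocols binding the denoiser to the samplers.

All protocols take ``L`` model forward passes by default (one per step).
Sequence generation fixes a max-noise structure input while unmasking;
structure generation fixes the all-mask sequence while integrating the
reverse SDE; co-generation advances both modalities in lockstep (sequence
time uniform, structure time uniform in warped time); inverse folding keeps
the structure fixed at the data noise level and unmasks one position per
step in random order at low temperature.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Tuple

import numpy as np

from .continuous import (
    AnnealingParams,
    SigmaSchedule,
    StructureState,
    input_scale,
    invert_time,
    rescale_time,
    reverse_step,
    sample_structure,
    score_from_raw,
)
from .denoiser import Denoiser, DenoiserOutput, MotifSpec, _motif_arrays, denoise
from .discrete import (
    MASK,
    SequenceState,
    inverse_fold_sample,
    path_planning_step,
    sample_sequence,
)
from .guidance import cfg_combine
from .nn import no_grad

__all__ = [
    "generate_sequence",
    "generate_structure",
    "cogenerate",
    "inverse_fold",
]


def _guided(model, seq, struct, t_seq, t_struct, motif, term, guidance, sched) -> DenoiserOutput:
    cond = denoise(model, seq, struct, t_seq, t_struct, motif, term, sched)
    if (term is None and motif is None) or guidance == 1.0:
        return cond
    uncond = denoise(model, seq, struct, t_seq, t_struct, None, None, sched)
    return cfg_combine(uncond, cond, guidance)


def generate_sequence(
    model: Denoiser,
    L: int,
    n_steps: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    term: Optional[int] = None,
    guidance: float = 1.0,
    sched: SigmaSchedule = SigmaSchedule(),
    gamma: float = 0.5,
) -> SequenceState:
    """Unconditional/conditional sequence generation with path planning."""
    rng = np.random.default_rng() if rng is None else rng
    n_steps = L if n_steps is None else n_steps
    x_fixed = StructureState(sched.t_max * rng.standard_normal((L, 3)), sched.t_max)

    def logits_fn(state: SequenceState) -> np.ndarray:
        out = _guided(model, state, x_fixed, state.time, sched.t_max, None, term, guidance, sched)
        return out.logits

    return sample_sequence(logits_fn, L, n_steps, lambda t: gamma, "path_planning", rng)


def generate_structure(
    model: Denoiser,
    L: int,
    n_steps: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    motif: Optional[MotifSpec] = None,
    term: Optional[int] = None,
    guidance: float = 1.0,
    ann: AnnealingParams = AnnealingParams(),
    sched: SigmaSchedule = SigmaSchedule(),
    sequence: Optional[np.ndarray] = None,
) -> StructureState:
    """Structure generation with the sequence input held fixed.

    By default the sequence is the all-mask state (unconditional structure
    generation); passing ``sequence`` fixes a clean token vector instead
    (structure generation for a known sequence).
    """
    rng = np.random.default_rng() if rng is None else rng
    n_steps = L if n_steps is None else n_steps
    if sequence is None:
        seq = SequenceState(np.full(L, MASK, dtype=np.int64), 1.0)
        t_seq = 1.0
    else:
        seq = SequenceState(np.asarray(sequence, dtype=np.int64), 0.0)
        t_seq = 0.0

    def score_fn(x: np.ndarray, t: float) -> np.ndarray:
        out = _guided(model, seq, StructureState(x, t), t_seq, t, motif, term, guidance, sched)
        return score_from_raw(out.structure_pred, x, t, sched).score

    return sample_structure(score_fn, L, n_steps, ann, sched, rng)


def cogenerate(
    model: Denoiser,
    L: int,
    n_steps: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_designs: int = 1,
    motif: Optional[MotifSpec] = None,
    term: Optional[int] = None,
    ann: AnnealingParams = AnnealingParams(),
    sched: SigmaSchedule = SigmaSchedule(),
    gamma_fn: Callable[[float], float] = lambda t: 0.1 + 0.4 * t,
) -> List[Tuple[SequenceState, StructureState]]:
    """Joint sequence/structure co-generation, batched over designs.

    Motif positions (if given) are clamped in the sequence and shared by all
    designs.  Returns a list of (sequence, structure) pairs.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_steps = L if n_steps is None else n_steps
    B = n_designs
    tokens = np.full((B, L), MASK, dtype=np.int64)
    clamp_idx = None
    if motif is not None and len(motif):
        clamp_idx = motif.positions
        tokens[:, motif.positions] = motif.identities
    mask, mc, mt = _motif_arrays(motif, L)
    mask = np.repeat(mask, B, axis=0)
    mc = np.repeat(mc, B, axis=0)
    mt = np.repeat(mt, B, axis=0)
    term_ids = None
    if model.func_emb is not None:
        term_ids = np.full(B, -1 if term is None else int(term))
    coords = sched.t_max * rng.standard_normal((B, L, 3))
    seqs = [SequenceState(tokens[b], 1.0) for b in range(B)]
    seq_grid = np.linspace(1.0, 0.0, n_steps + 1)
    struct_grid = invert_time(np.linspace(1.0, 0.0, n_steps + 1), sched)
    for k in range(n_steps):
        ts, ts_next = seq_grid[k], seq_grid[k + 1]
        tx, tx_next = struct_grid[k], struct_grid[k + 1]
        coords = coords - coords.mean(axis=1, keepdims=True)
        tp = np.full(B, rescale_time(tx, sched))
        batch_tokens = np.stack([s.tokens for s in seqs])
        with no_grad():
            logits, pred = model.forward(
                batch_tokens, coords, tp, mask, mc, mt, term_ids,
                coord_scale=input_scale(tx, sched),
                motif_coord_scale=1.0 / sched.t_data,
            )
        last = k == n_steps - 1
        new_coords = np.empty_like(coords)
        for b in range(B):
            seqs[b] = path_planning_step(
                logits.data[b], seqs[b], ts_next, ts, gamma_fn(ts), "cogeneration", rng,
                clamp=clamp_idx,
            )
            score = score_from_raw(pred.data[b], coords[b], tx, sched).score
            new_coords[b] = reverse_step(
                StructureState(coords[b], tx), score, tx, tx - tx_next, ann, rng,
                inject_noise=not last,
            ).coords
        coords = new_coords
    coords = coords - coords.mean(axis=1, keepdims=True)
    return [(seqs[b], StructureState(coords[b], struct_grid[-1])) for b in range(B)]


def inverse_fold(
    model: Denoiser,
    struct: StructureState,
    rng: Optional[np.random.Generator] = None,
    temperature: float = 0.1,
    sched: SigmaSchedule = SigmaSchedule(),
) -> SequenceState:
    """Sample a sequence for a fixed backbone at the data noise level."""
    rng = np.random.default_rng() if rng is None else rng
    L = struct.coords.shape[0]
    fixed = StructureState(struct.coords, sched.t_min)

    def logits_fn(state: SequenceState) -> np.ndarray:
        return denoise(model, state, fixed, state.time, sched.t_min, sched=sched).logits

    return inverse_fold_sample(logits_fn, L, rng, temperature)
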