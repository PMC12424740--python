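"""Joint training: asynchronous modality noise, combined loss, conditioning
policy, EMA tracking, and the data-sampling policies (hierarchical cluster
sampling, inverse-frequency term sampling, ontology closure).

The two modalities are corrupted at independently drawn noise levels, so the
model learns every conditional (sequence given clean structure, structure
given clean sequence, and everything in between) from single-state training
pairs.  The combined objective is ``L_struct + 3 * L_seq``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .continuous import (
    SigmaSchedule,
    forward_noise,
    input_scale,
    invert_time,
    loss_weight,
    score_coefficients,
    structure_loss,
)
from .denoiser import Denoiser, MotifSpec
from .discrete import MASK, N_AMINO, SequenceState, mask_forward, seq_loss
from .nn import Adam, Tensor

__all__ = [
    "TrainingPolicy",
    "ClusterTable",
    "ConditionedExample",
    "combined_loss",
    "sample_noise_levels",
    "sample_motif_segments",
    "conditioning_policy",
    "hierarchical_sample",
    "propagate_terms",
    "find_roots",
    "ema_update",
    "train",
]


@dataclass(frozen=True)
class TrainingPolicy:
    motif_prob: float = 0.5
    term_use_prob: float = 0.85
    modality_drop_prob: float = 0.05
    ema_decay: float = 0.999
    crop_size: int = 512
    seq_loss_weight: float = 3.0
    motif_max_segments: int = 4
    motif_coverage: Tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        for p in (self.motif_prob, self.term_use_prob, self.modality_drop_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.ema_decay < 1.0 and self.ema_decay not in (0.0, 1.0):
            raise ValueError("ema_decay must lie in [0, 1]")


def combined_loss(l_struct: float, l_seq: float, policy: TrainingPolicy = TrainingPolicy()):
    """Weighted sum of the two modality losses (sequence weight 3)."""
    return l_struct + policy.seq_loss_weight * l_seq


def sample_noise_levels(rng: np.random.Generator) -> Tuple[float, float]:
    """Independent uniform draws: (t_seq, t_struct') on [0, 1] each."""
    return float(rng.random()), float(rng.random())


def sample_motif_segments(
    L: int,
    rng: np.random.Generator,
    max_segments: int = 4,
    coverage: Tuple[float, float] = (0.05, 0.5),
) -> np.ndarray:
    """Sample 1..max_segments disjoint contiguous segments covering 5-50% of L.

    Returns sorted residue indices.  Segment lengths are a random composition
    of the target coverage; placements are uniform over non-overlapping
    arrangements (via random gap allocation).
    """
    n_seg = int(rng.integers(1, max_segments + 1))
    frac = rng.uniform(*coverage)
    total = max(n_seg, int(round(frac * L)))
    total = min(total, L)
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_seg - 1, replace=False)) if n_seg > 1 else np.array([], dtype=int)
    lengths = np.diff(np.concatenate([[0], cuts, [total]])).astype(int)
    slack = L - total
    gaps = rng.multinomial(slack, np.ones(n_seg + 1) / (n_seg + 1))
    positions = []
    start = 0
    for i, ln in enumerate(lengths):
        start += gaps[i]
        positions.extend(range(start, start + ln))
        start += ln
    return np.asarray(positions, dtype=np.int64)


@dataclass
class ConditionedExample:
    motif: Optional[MotifSpec]
    term: Optional[int]
    drop_sequence: bool
    drop_structure: bool


def conditioning_policy(
    example: dict,
    vocab_weights: Optional[Dict[int, float]],
    policy: TrainingPolicy,
    rng: np.random.Generator,
) -> ConditionedExample:
    """Draw the conditioning configuration for one training example.

    Independently: with prob ``motif_prob`` attach a multi-segment motif cut
    from the example's own clean structure/sequence; with prob
    ``term_use_prob`` attach one of the example's terms drawn proportionally
    to its inverse global frequency; with prob ``modality_drop_prob`` each,
    drop the sequence (all-mask input) or the structure (max-noise input).
    """
    seq = np.asarray(example["sequence"], dtype=np.int64)
    struct = np.asarray(example["structure"], dtype=np.float64)
    L = len(seq)
    motif = None
    if rng.random() < policy.motif_prob:
        idx = sample_motif_segments(L, rng, policy.motif_max_segments, policy.motif_coverage)
        motif = MotifSpec(idx, struct[idx], seq[idx])
    term = None
    terms = list(example.get("terms") or [])
    if terms and rng.random() < policy.term_use_prob:
        if vocab_weights:
            w = np.array([1.0 / max(vocab_weights.get(t, 1.0), 1e-12) for t in terms])
            w = w / w.sum()
        else:
            w = np.full(len(terms), 1.0 / len(terms))
        term = int(terms[rng.choice(len(terms), p=w)])
    drop_seq = rng.random() < policy.modality_drop_prob
    drop_struct = rng.random() < policy.modality_drop_prob
    return ConditionedExample(motif, term, drop_seq, drop_struct)


@dataclass
class ClusterTable:
    """Hierarchically clustered protein records.

    ``records`` columns: id, outer_cluster, inner_cluster, quality, and any
    payload columns (sequence, structure path, ...).  Every protein belongs
    to exactly one inner cluster, every inner cluster to one outer cluster.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"id", "outer_cluster", "inner_cluster", "quality"}
        if not need.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(need)}")
        inner_outer = self.records.groupby("inner_cluster")["outer_cluster"].nunique()
        if (inner_outer > 1).any():
            raise ValueError("an inner cluster spans multiple outer clusters")


def hierarchical_sample(
    table: ClusterTable, quality_min: float, rng: np.random.Generator
) -> pd.Series:
    """Uniform over outer clusters, then inner clusters, then passing proteins."""
    df = table.records[table.records["quality"] > quality_min]
    if df.empty:
        raise ValueError("no proteins pass the quality filter")
    outers = df["outer_cluster"].unique()
    outer = outers[rng.integers(len(outers))]
    sub = df[df["outer_cluster"] == outer]
    inners = sub["inner_cluster"].unique()
    inner = inners[rng.integers(len(inners))]
    final = sub[sub["inner_cluster"] == inner]
    return final.iloc[int(rng.integers(len(final)))]


def propagate_terms(
    annotations: Dict[str, Iterable],
    ontology: Dict,
) -> Dict[str, frozenset]:
    """Transitive is_a closure of each entry's term set.

    ``ontology`` maps term -> iterable of parent terms.  Raises on cycles.
    Root terms (no parents) are retained in the closed sets; use
    :func:`find_roots` to identify and discount them.
    """
    g = nx.DiGraph()
    for term, parents in ontology.items():
        g.add_node(term)
        for p in parents:
            g.add_edge(term, p)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ontology contains an is_a cycle")
    closed = {}
    for pid, terms in annotations.items():
        out: Set = set()
        for t in terms:
            out.add(t)
            if t in g:
                out |= nx.descendants(g, t)  # edges point child -> parent
        closed[pid] = frozenset(out)
    return closed


def find_roots(ontology: Dict) -> frozenset:
    """Terms with no is_a parents (the ontology roots)."""
    all_terms = set(ontology)
    for parents in ontology.values():
        all_terms |= set(parents)
    return frozenset(t for t in all_terms if not list(ontology.get(t, ())))


def ema_update(ema: List[np.ndarray], params: List[np.ndarray], decay: float) -> None:
    """In-place EMA step: ema <- decay * ema + (1 - decay) * params."""
    for e, p in zip(ema, params):
        e *= decay
        e += (1.0 - decay) * p


# ---------------------------------------------------------------------------
# differentiable losses (Tensor versions of the numpy formulas)
# ---------------------------------------------------------------------------


def structure_loss_tensor(
    pred: Tensor, x0: np.ndarray, xt: np.ndarray, t: np.ndarray, sched: SigmaSchedule
) -> Tensor:
    """Batched differentiable score-matching loss, mean over the batch.

    ``pred`` (B, L, 3); ``t`` (B,) noise levels.  Shares its coefficients
    with :func:`duet.continuous.score_from_raw` / ``loss_weight``.
    """
    B = pred.shape[0]
    c_raw = np.empty((B, 1, 1))
    c_x = np.empty((B, 1, 1))
    w = np.empty((B, 1, 1))
    for b in range(B):
        c_raw[b], c_x[b] = score_coefficients(float(t[b]), sched)
        w[b] = loss_weight(float(t[b]), sched)
    target = (x0 - xt) / (np.asarray(t)[:, None, None] ** 2)
    err = pred * c_raw + Tensor(c_x * xt) - Tensor(target)
    return ((err**2.0) * w).mean()


def sequence_loss_tensor(
    logits: Tensor, s0: np.ndarray, st: np.ndarray, t: np.ndarray
) -> Tensor:
    """Batched differentiable masked cross-entropy with weight (1 - t).

    Per example, the mean NLL over masked positions is scaled by (1 - t);
    examples contribute the average.  Unmasked positions are excluded.
    """
    B, L, _ = logits.shape
    masked = st == MASK
    logp = logits[..., :N_AMINO].log_softmax(axis=-1)
    onehot = np.zeros((B, L, N_AMINO))
    rows, cols = np.nonzero(masked)
    onehot[rows, cols, s0[rows, cols]] = 1.0
    denom = np.maximum(masked.sum(axis=1), 1)[:, None, None].astype(float)
    weight = (1.0 - np.asarray(t))[:, None, None]
    nll = (logp * Tensor(-onehot * weight / denom)).sum(axis=(1, 2))
    return nll.mean()


def train(
    model: Denoiser,
    dataset: Callable[[np.random.Generator], dict],
    policy: TrainingPolicy,
    steps: int,
    rng: np.random.Generator,
    batch_size: int = 16,
    lr: float = 1e-3,
    warmup: int = 100,
    sched: SigmaSchedule = SigmaSchedule(),
    vocab_weights: Optional[Dict[int, float]] = None,
    log_every: int = 0,
):
    """Joint training loop; returns (model, ema_arrays, loss_history).

    ``dataset(rng)`` yields one example dict with keys ``sequence`` (length-L
    tokens), ``structure`` (L x 3 centered coords) and optionally ``terms``.
    Both modalities are corrupted at independent noise levels; conditioning
    follows :func:`conditioning_policy`.  EMA of the parameters is tracked
    with the policy's decay.  Aborts on non-finite loss.
    """
    params = model.parameters()
    ema = [p.data.copy() for p in params]
    if steps == 0:
        return model, ema, []
    opt = Adam(params, lr=lr, warmup=warmup, total_steps=steps)
    history: List[float] = []
    for step in range(steps):
        batch = [dataset(rng) for _ in range(batch_size)]
        L = len(batch[0]["sequence"])
        B = batch_size
        tokens = np.empty((B, L), dtype=np.int64)
        s0 = np.empty((B, L), dtype=np.int64)
        coords = np.empty((B, L, 3))
        x0 = np.empty((B, L, 3))
        t_seq = np.empty(B)
        t_struct = np.empty(B)
        t_prime = np.empty(B)
        motif_mask = np.zeros((B, L), dtype=bool)
        motif_coords = np.zeros((B, L, 3))
        motif_tokens = np.full((B, L), MASK, dtype=np.int64)
        term_ids = np.full(B, -1, dtype=np.int64) if model.func_emb is not None else None
        for b, ex in enumerate(batch):
            cond = conditioning_policy(ex, vocab_weights, policy, rng)
            u_seq, u_struct = sample_noise_levels(rng)
            if cond.drop_sequence:
                u_seq = 1.0
            if cond.drop_structure:
                u_struct = 1.0
            t_seq[b] = u_seq
            t_prime[b] = u_struct
            t_struct[b] = invert_time(u_struct, sched)
            clean_seq = SequenceState(np.asarray(ex["sequence"]), 0.0)
            s0[b] = clean_seq.tokens
            tokens[b] = mask_forward(clean_seq, u_seq, rng).tokens
            x0[b] = np.asarray(ex["structure"])
            coords[b] = x0[b] + t_struct[b] * rng.standard_normal((L, 3))
            if cond.motif is not None:
                motif_mask[b, cond.motif.positions] = True
                motif_coords[b, cond.motif.positions] = cond.motif.coords
                motif_tokens[b, cond.motif.positions] = cond.motif.identities
            if term_ids is not None and cond.term is not None:
                term_ids[b] = cond.term
        logits, pred = model.forward(
            tokens, coords, t_prime, motif_mask, motif_coords, motif_tokens,
            term_ids, training=True, rng=rng,
            coord_scale=input_scale(t_struct, sched),
            motif_coord_scale=1.0 / sched.t_data,
        )
        l_struct = structure_loss_tensor(pred, x0, coords, t_struct, sched)
        l_seq = sequence_loss_tensor(logits, s0, tokens, t_seq)
        loss = l_struct + l_seq * policy.seq_loss_weight
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged at step {step}: loss={value} "
                f"(l_struct={float(l_struct.data)}, l_seq={float(l_seq.data)})"
            )
        history.append(value)
        opt.zero_grad()
        loss.backward()
        opt.step()
        ema_update(ema, [p.data for p in params], policy.ema_decay)
        if log_every and (step + 1) % log_every == 0:
            recent = float(np.mean(history[-log_every:]))
            print(
                f"step {step + 1}: loss {recent:.4f} "
                f"(struct {float(l_struct.data):.4f}, seq {float(l_seq.data):.4f})"
            )
    return model, ema, history
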