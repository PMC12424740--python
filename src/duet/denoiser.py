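"""Joint sequence/structure transformer denoiser.

A plain (non-equivariant) diffusion transformer: noisy token embeddings and
linearly embedded noisy coordinates are summed into one residue-level stream,
optionally together with an embedded structural motif (coordinates + a learned
position mark + the motif's token identities) and a learned function-term
vector.  A sinusoidal embedding of the *structural* diffusion time conditions
every block through adaLN-Zero modulation (shift/scale/gate for attention and
feed-forward, six vectors per block, gates initialized to zero so each block
starts as an identity residual).  Blocks are pre-norm with QK-norm and GeLU;
two linear heads emit per-position 21-way logits and the raw structure
prediction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .continuous import SigmaSchedule, input_scale, rescale_time
from .discrete import MASK, VOCAB, SequenceState
from .continuous import StructureState
from .nn import (
    Embedding,
    Linear,
    Module,
    RMSNorm,
    Tensor,
    dropout,
    layer_norm,
    no_grad,
    sinusoidal_embedding,
)

CHECKPOINT_VERSION = 1

__all__ = [
    "DenoiserConfig",
    "DenoiserOutput",
    "MotifSpec",
    "Denoiser",
    "build_denoiser",
    "count_parameters",
    "denoise",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class DenoiserConfig:
    """Architecture hyperparameters.

    Paper-scale presets: 30 blocks with hidden 768 (unconditional) or 1024
    (conditional, with a function-term table); heads are width-64, the FFN
    expands 4x, dropout is 0.2, and the sinusoidal time embedding has 256
    frequency channels.
    """

    n_blocks: int = 30
    hidden_dim: int = 768
    ffn_ratio: int = 4
    n_heads: int = 0  # 0 -> hidden_dim // 64
    dropout: float = 0.2
    vocab_size: int = VOCAB
    n_function_terms: int = 0
    max_length: int = 512
    time_dim: int = 256

    def __post_init__(self) -> None:
        heads = self.heads
        if self.hidden_dim % heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def heads(self) -> int:
        return self.n_heads if self.n_heads > 0 else max(1, self.hidden_dim // 64)


@dataclass
class DenoiserOutput:
    logits: np.ndarray  # L x 21 (or B x L x 21)
    structure_pred: np.ndarray  # L x 3 (or B x L x 3)


@dataclass(frozen=True)
class MotifSpec:
    """Residue positions with target coordinates and amino-acid identities."""

    positions: np.ndarray
    coords: np.ndarray
    identities: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.int64))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=np.float64))
        object.__setattr__(self, "identities", np.asarray(self.identities, dtype=np.int64))
        if self.positions.ndim != 1:
            raise ValueError("positions must be 1-D")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.coords.shape != (len(self.positions), 3):
            raise ValueError("coords must be |positions| x 3")
        if self.identities.shape != (len(self.positions),):
            raise ValueError("identities must match positions")

    def __len__(self) -> int:
        return len(self.positions)

    def shifted(self, new_start: int) -> "MotifSpec":
        offs = self.positions - self.positions[0]
        return MotifSpec(new_start + offs, self.coords, self.identities)


class _Block(Module):
    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        d = cfg.hidden_dim
        self.heads = cfg.heads
        self.head_dim = d // self.heads
        self.qkv = Linear(d, 3 * d, rng)
        self.q_norm = RMSNorm(self.head_dim)
        self.k_norm = RMSNorm(self.head_dim)
        self.attn_out = Linear(d, d, rng)
        self.ffn1 = Linear(d, cfg.ffn_ratio * d, rng)
        self.ffn2 = Linear(cfg.ffn_ratio * d, d, rng)
        self.adaln = Linear(d, 6 * d, rng, zero_init=True)
        self.p_drop = cfg.dropout

    def __call__(self, h: Tensor, c: Tensor, training: bool, rng) -> Tensor:
        d = h.shape[-1]
        mod = self.adaln(c.silu())
        sh1, sc1, g1 = mod[..., :d], mod[..., d : 2 * d], mod[..., 2 * d : 3 * d]
        sh2, sc2, g2 = mod[..., 3 * d : 4 * d], mod[..., 4 * d : 5 * d], mod[..., 5 * d :]
        a = layer_norm(h) * (sc1 + 1.0) + sh1
        a = self._attention(a)
        a = dropout(a, self.p_drop, rng, training)
        h = h + g1 * a
        f = layer_norm(h) * (sc2 + 1.0) + sh2
        f = self.ffn2(self.ffn1(f).gelu())
        f = dropout(f, self.p_drop, rng, training)
        return h + g2 * f

    def _attention(self, x: Tensor) -> Tensor:
        B, L, d = x.shape
        qkv = self.qkv(x).reshape(B, L, 3, self.heads, self.head_dim)
        q = qkv[:, :, 0].transpose(0, 2, 1, 3)  # B, H, L, dh
        k = qkv[:, :, 1].transpose(0, 2, 1, 3)
        v = qkv[:, :, 2].transpose(0, 2, 1, 3)
        q, k = self.q_norm(q), self.k_norm(k)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.attn_out(out)


class Denoiser(Module):
    def __init__(self, cfg: DenoiserConfig, rng: np.random.Generator):
        d = cfg.hidden_dim
        self.cfg = cfg
        self.token_emb = Embedding(cfg.vocab_size, d, rng, scale=1.0)
        self.struct_emb = Linear(3, d, rng)
        self.motif_emb = Linear(3, d, rng)
        self.motif_mark = Embedding(1, d, rng)
        self.pos_emb = Embedding(cfg.max_length, d, rng)
        self.time_mlp1 = Linear(cfg.time_dim, d, rng)
        self.time_mlp2 = Linear(d, d, rng)
        if cfg.n_function_terms > 0:
            # one extra row serves as the null (unconditional) embedding
            self.func_emb = Embedding(cfg.n_function_terms + 1, d, rng)
        else:
            self.func_emb = None
        self.blocks = [_Block(cfg, rng) for _ in range(cfg.n_blocks)]
        self.final_adaln = Linear(d, 2 * d, rng, zero_init=True)
        self.head_logits = Linear(d, cfg.vocab_size, rng, zero_init=True)
        self.head_struct = Linear(d, 3, rng, zero_init=True)

    def forward(
        self,
        tokens: np.ndarray,
        coords: np.ndarray,
        t_prime: np.ndarray,
        motif_mask: Optional[np.ndarray] = None,
        motif_coords: Optional[np.ndarray] = None,
        motif_tokens: Optional[np.ndarray] = None,
        term_ids: Optional[np.ndarray] = None,
        training: bool = False,
        rng: Optional[np.random.Generator] = None,
        coord_scale=1.0,
        motif_coord_scale: float = 1.0,
    ):
        """Batched forward pass.

        tokens (B, L) int; coords (B, L, 3) Angstrom (re-centered internally,
        then multiplied by ``coord_scale`` -- callers pass the standard input
        preconditioning 1/sqrt(t_data^2 + t^2) so the network sees unit-scale
        features at every noise level); t_prime (B,) warped structural time in
        [0, 1]; motif arrays follow the same layout with zeros/MASK off-motif;
        term_ids (B,) with -1 for the null term.  Returns (logits,
        struct_pred) Tensors.
        """
        tokens = np.asarray(tokens, dtype=np.int64)
        B, L = tokens.shape
        if L > self.cfg.max_length:
            raise ValueError("sequence longer than max_length")
        coords = np.asarray(coords, dtype=np.float64)
        coords = coords - coords.mean(axis=1, keepdims=True)
        scale = np.broadcast_to(np.asarray(coord_scale, dtype=np.float64), (B,))
        coords = coords * scale[:, None, None]
        h = self.token_emb(tokens) + self.struct_emb(Tensor(coords))
        h = h + self.pos_emb(np.arange(L))
        mark = None
        if motif_mask is not None and np.any(motif_mask):
            m = np.asarray(motif_mask, dtype=np.float64)[..., None]  # B, L, 1
            mc = np.asarray(motif_coords, dtype=np.float64)
            n = np.maximum(m.sum(axis=1, keepdims=True), 1.0)
            mc = (mc - (mc * m).sum(axis=1, keepdims=True) / n) * m * motif_coord_scale
            mark = self.motif_mark(np.zeros(1, dtype=np.int64))  # (1, d)
            h = h + (self.motif_emb(Tensor(mc)) + self.token_emb(motif_tokens) + mark) * Tensor(m)
        c = self.time_mlp2(self.time_mlp1(Tensor(sinusoidal_embedding(t_prime, self.cfg.time_dim))).gelu())
        c = c.reshape(B, 1, -1)
        if term_ids is not None:
            if self.func_emb is None:
                raise ValueError("model built without function conditioning")
            ids = np.asarray(term_ids, dtype=np.int64)
            if np.any(ids >= self.cfg.n_function_terms):
                raise ValueError("term id out of range")
            ids = np.where(ids < 0, self.cfg.n_function_terms, ids)
            c = c + self.func_emb(ids).reshape(B, 1, -1)
        c = c + Tensor(np.zeros((B, L, 1)))  # broadcast to per-position
        if mark is not None:
            c = c + mark * Tensor(m)
        for block in self.blocks:
            h = block(h, c, training, rng)
        fmod = self.final_adaln(c.silu())
        d = self.cfg.hidden_dim
        h = layer_norm(h) * (fmod[..., d:] + 1.0) + fmod[..., :d]
        return self.head_logits(h), self.head_struct(h)


class _ZeroDraws:
    """Stand-in generator yielding zero weights; lets paper-scale models be
    built for parameter accounting without materializing gigabytes of
    random numbers (np.zeros pages stay virtual until touched)."""

    def standard_normal(self, shape):
        return np.zeros(shape)


def build_denoiser(
    config: DenoiserConfig,
    rng: Optional[np.random.Generator] = None,
    zero_weights: bool = False,
) -> Denoiser:
    if zero_weights:
        rng = _ZeroDraws()
    return Denoiser(config, np.random.default_rng(0) if rng is None else rng)


def count_parameters(model: Denoiser) -> int:
    """Total trainable scalar parameters."""
    return model.n_parameters()


def _motif_arrays(motif: Optional[MotifSpec], L: int):
    mask = np.zeros((1, L), dtype=bool)
    mc = np.zeros((1, L, 3))
    mt = np.full((1, L), MASK, dtype=np.int64)
    if motif is not None and len(motif) > 0:
        if motif.positions.max() >= L:
            raise ValueError("motif position out of range")
        mask[0, motif.positions] = True
        mc[0, motif.positions] = motif.coords
        mt[0, motif.positions] = motif.identities
    return mask, mc, mt


def denoise(
    model: Denoiser,
    seq: SequenceState,
    struct: StructureState,
    t_seq: float,
    t_struct: float,
    motif: Optional[MotifSpec] = None,
    term: Optional[int] = None,
    sched: SigmaSchedule = SigmaSchedule(),
) -> DenoiserOutput:
    """Single inference forward pass on one example (dropout disabled).

    Absent motif/term fall back to the null embeddings, as required for
    classifier-free guidance and for the unconditional branch of coupled
    sampling.  The sequence noise level ``t_seq`` is implicit in the mask
    pattern and is not separately embedded.
    """
    L = len(seq.tokens)
    if struct.coords.shape != (L, 3):
        raise ValueError("sequence/structure length mismatch")
    mask, mc, mt = _motif_arrays(motif, L)
    t_clip = float(np.clip(t_struct, sched.t_min, sched.t_max))
    tp = np.array([rescale_time(t_clip, sched)])
    term_ids = None
    if model.func_emb is not None:
        term_ids = np.array([-1 if term is None else int(term)])
    elif term is not None:
        raise ValueError("model built without function conditioning")
    with no_grad():
        logits, pred = model.forward(
            seq.tokens[None, :], struct.coords[None, :, :], tp, mask, mc, mt, term_ids,
            coord_scale=input_scale(t_clip, sched),
            motif_coord_scale=1.0 / sched.t_data,
        )
    return DenoiserOutput(logits=logits.data[0], structure_pred=pred.data[0])


def save_checkpoint(model: Denoiser, path: str) -> None:
    """Single-file archive: config + version + all parameter arrays."""
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(model.cfg)}
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> Denoiser:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg = DenoiserConfig(**meta["config"])
        model = build_denoiser(cfg, np.random.default_rng(0))
        arrays = [data[f"p{i}"] for i in range(len(model.parameters()))]
    model.load_arrays(arrays)
    return model
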