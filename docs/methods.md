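# Methods

This note records the modeling choices, defaults, numerical conventions and
known limitations of `duet`. It is written for maintainers; the README
covers usage.

## Diffusion processes

### Continuous (structure)

The structure state is an L×3 array of zero-centered Cα coordinates in
Angstrom. The forward process is variance-exploding, `x_t = x_0 + t ε`,
with drift 0 and diffusion `g(t) = √(2t)`, over noise levels
`t ∈ [0.05, 160] Å`. Training and sampling operate on the warped time
`t′(t) = (t^{1/p} − t_min^{1/p})/(t_max^{1/p} − t_min^{1/p})` with `p = 7`;
its closed-form inverse `t(t′) = (t_min^{1/p} + t′(t_max^{1/p} − t_min^{1/p}))^p`
is used to lay uniform-`t′` sampling grids. Training times are drawn
uniformly on `t′ ∈ [0, 1]` (the minimal reading where no density is
specified).

The network output is blended into the score with EDM-style
post-conditioning (data scale `t_data = 15 Å`),

```
s_θ = t_data/(t √(t_data²+t²)) · f_θ − x/(t_data²+t²),
```

and the training loss is the weighted score-matching objective

```
w(t) ‖s_θ(x_t, t) − (x_0 − x_t)/t²‖²,   w(t) = t²(t² + t_data²)/t_data²,
```

mean over coordinates. This weighting makes the objective equivalent to a
unit-weight regression on the denoised structure at every noise level; it
is the reading of the (typographically garbled) printed loss that is
consistent with the stated parameterization, and the package treats it as
such (`structure_loss` is zero iff the derived score equals the analytic
conditional score).

On the input side the network sees preconditioned coordinates
`c_in(t) · x` with `c_in = 1/√(t_data² + t²)`, so feature variance is order
one across the entire noise range. Without this scaling the coordinate
stream numerically dominates the token embeddings at high noise and the
sequence pathway trains orders of magnitude more slowly; with it the same
tiny model learns both conditionals. Motif coordinates (always clean) are
scaled by `1/t_data`.

Reverse integration is Euler–Maruyama from `t′ = 1` to `0`, uniform in
`t′`, both endpoints included. The annealed SDE uses drift
`(g²/2)(1 + β(t)) s` and noise `g √(β γ)` with
`β(t) = 1/(1 + (t/t_data)^ν)`; defaults `γ = 0.5`, `ν = 0.5`
(unconditional) or `ν = 1` (conditional); `β ≡ 1, γ = 1` recovers the
plain reverse SDE. No noise is injected on the terminal step (there is no
subsequent denoise to remove it). Inputs are re-centered before every
model call and outputs re-centered on return. Chirality is not handled:
the architecture is a plain transformer with no equivariance, so mirrored
toy structures are legal outputs.

### Discrete (sequence)

K = 21 with the 21st symbol an absorbing mask; the prior is all-mask. The
corruption schedule is linear, `α_t = 1 − t` — the schedule is otherwise
only constrained to be monotone, and the linear choice matches the stated
loss weight `λ(t) = 1 − t`. The exact reverse posterior for a masked
position keeps the mask with probability `(1−α_s)/(1−α_t)` and otherwise
fills from the predicted clean-token distribution, which carries zero mass
on the mask symbol (sampling logits are restricted to the 20 amino acids).

The path-planning step draws standard Gumbel(0,1) noise (the printed
"Gumbel(1,1)" is read as a location shift, which cancels in both the
argmax and the top-k), computes noisy log-confidences
`φ = log_softmax(logits/γ(t) + z)` — the temperature divides the logits,
since dividing after the log-softmax would be a global monotone rescale
with no effect on either ranking — and unmasks the top
`k = L_free − round(s·L_free)` free positions while re-masking the rest
(self-planning; re-masking of previously unmasked positions is permitted
and does occur on adversarial inputs). Ties: top-k by lowest position
index, argmax by lowest token index; `round` is half-away-from-zero. In
co-generation mode, currently-unmasked positions contribute their own
token and its model log-probability as (y, u); this applies to every
unmasked position, not only clamped ones. Clamped (motif) positions are
initialized unmasked, never re-masked, and excluded from the top-k
accounting. Temperatures: `γ = 0.5` for sequence generation,
`γ(t) = 0.1 + 0.4t` for co-generation. Inverse folding unmasks one
position per step in a uniformly random order at temperature 0.1.

## Denoiser

A pre-norm transformer with QK-norm (RMS over the head dimension, learned
scale), GeLU activations, FFN expansion 4, heads of width 64, dropout 0.2,
and adaLN-Zero conditioning: each block reads shift/scale/gate pairs for
its attention and FFN sub-layers (6 modulation vectors) from a linear layer
over the conditioning stream, zero-initialized so every block starts as an
identity residual. The conditioning stream is per-position: sinusoidal
embedding (256 frequency channels) of the warped structural time through a
two-layer MLP, plus the function-term embedding, plus the learned motif
mark at motif positions. The sequence noise level is not separately
embedded — it is implicit in the mask pattern. Positions use learned
absolute embeddings up to `max_length` (512 at paper scale). Motifs are
injected in the input stream as centered coordinates through a linear
layer, the position mark, and the motif residues' token embeddings (the
coupled protocol needs identity information to flow). Two zero-initialized
linear heads (21-way logits, 3-way structure) read a final adaLN-modulated
norm.

With these conventions the paper-scale builds count 321,258,264 parameters
(30 blocks, d = 768) and 579,105,560 (30 blocks, d = 1024, 8220-term table
plus one null row) — ~0.5% above the printed 576M; head counts, embedding
widths and bias placement are not fully pinned down externally, so the
count is matched approximately rather than tuned to the digit.

The model and its training loop run on a small reverse-mode autodiff
engine over numpy arrays (`duet.nn.autodiff`) — broadcasted arithmetic,
batched matmul, reductions, softmax/log-softmax, GeLU/SiLU, embedding
gather, and an Adam optimizer — keeping the package dependency-light and
every gradient inspectable. Gradients are verified against central finite
differences in the test suite.

## Training

Each step corrupts both modalities at independently drawn uniform times,
evaluates the combined loss `L_struct + 3 L_seq` (sequence cross-entropy
averaged over masked positions per example), and applies Adam with linear
warmup; parameters are tracked with an EMA (decay 0.999), and the EMA
weights are used for sampling. Conditioning is drawn independently per
example: motif with probability 0.5 (1–4 contiguous segments covering
5–50% of residues — a reduction of the multi-segment motif samplers used
at scale to their qualitative interface), a function term with probability
0.85 chosen ∝ inverse global frequency among the example's terms, and each
modality dropped with probability 0.05 (all-mask sequence / max-noise
structure, keeping tensor shapes fixed). Term and motif conditioning
co-occur independently. Optimizer settings are configuration, not part of
the method's identity. Non-finite loss aborts with a diagnostic.

Data policies are generic operations over user tables: hierarchical
sampling draws uniformly an outer (structure) cluster, then an inner
(sequence) cluster, then a protein passing the quality filter
(quality > threshold, strict); ontology closure adds all transitive is_a
parents (cycles are an error; roots are retained in the closed sets and
identifiable via `find_roots` so "non-root" counting conventions can be
applied downstream).

## Synthetic families and what they show

The toy family maps each of three residue classes (tokens mod 3:
helix-like, strand-like, coil) to an exact local geometry on a backbone of
constant 3.0 Å rise: helix-like residues wind on a 2.3 Å radius with 100°
per-residue twist, strand-like and coil residues shift ±1.2 Å along the
chain axis. The generator emits one canonical token per class so that
structure determines sequence exactly; `decode_structure` (sequence →
coordinates) and `classify_structure` (coordinates → classes) are exact
inverse oracles at zero noise. Observation noise is isotropic with
sd 0.25 Å. Two-state mode rotates the C-terminal half by 70° about the
central hinge residue — but only when the hinge residue is coil-class.
Bistability is thus a *sequence* property: flexible-hinge sequences have
two conformers, rigid-hinge sequences one, and training draws a conformer
at random per example, emulating single-state observations of (sometimes)
multistate proteins. This gating is what makes the coupled-sampling
comparison meaningful — a random sequence is usually rigid and cannot
satisfy a second-state motif, while the coupled protocol must design the
flexibility in.

Two success thresholds are used by the end-to-end checks, each calibrated
to separate its matched and mismatched distributions: full-chain
sequence–structure self-consistency (emitted structure vs. the decode of
the emitted sequence, best over states) uses 1.0 Å — above the 0.35 Å
observation-noise floor and well below the ~1.7 Å separation between
decodes of unrelated sequences, which share the backbone ramp; motif-region
scaffolding success uses 2.0 Å — realized motifs land well under it while
the wrong hinge state displaces motif residues by several Å.

These families preserve the properties the samplers rely on — a
deterministic sequence–structure coupling, multimodal conditionals, exact
enumerable posteriors — while discarding nearly everything else about real
proteins: no excluded volume, no Ramachandran statistics, no long-range
contacts, no sequence redundancy, and a 3-letter effective alphabet.
Passing end-to-end tests therefore demonstrates that the *samplers, losses
and protocols* are implemented correctly and that the architecture can
learn a sequence-structure joint; they say nothing about designability or
biophysical plausibility of real proteins, which at full scale depends on
training data and external screening tools that are documented here only
as adapter stubs.

Problem sizes for the end-to-end checks — length 32, hidden 64, 4 blocks,
5000 training steps (batch 16, Adam 3e-3 with warmup and cosine decay,
EMA weights used for sampling), a few dozen rollouts — were chosen as the
smallest configuration at which the toy family is reliably learned on one
CPU.

The continuous-sampler oracles are exact: the Gaussian-convolved mixture
score is closed-form, so integrator correctness is measured as recovery of
known terminal statistics (variance of an isotropic Gaussian within 5% at
400 steps; mixture occupancy within binomial error). The discrete oracle
enumerates a joint over ≤6^4 sequences and computes exact posteriors by
Bayesian summation, so ancestral sampling is checked in total variation.

The alignment decoys inject a known site perturbation (0.25 Å) on a
remodeled scaffold, so the pipeline's reported site RMSD has a known
ground truth; the negative decoy mutates one site residue to an identity
absent from the decoy, which must produce a matching failure rather than a
large RMSD.

## Geometry evaluation

Superposition is Kabsch (SVD with reflection correction; proper rotations
only — chirality is never silently flipped), erroring on fewer than three
or collinear points; it is cross-checked against gemmi's superposition in
the tests. Active-site alignment superposes globally on the backbone
(equal-length pairing by index; full backbone atoms where present,
degrading to Cα for Cα-only traces), then matches each annotated reference
residue to the nearest generated residue of identical type (minimum over
any atom pair; one-to-one; ties to the lower residue index). Only when all
site residues match is the site RMSD over name-paired atoms reported;
success is RMSD < 1.0 Å. Shell metrics re-superpose (on Cα) at each radius
of a spherical expansion about the site centroid — radii are inclusive
(≤), shells with fewer than three residues are undefined — and report
RMSD plus the fraction of selected residues whose nearest post-alignment
neighbor shares their identity.

## I/O conventions

Coordinates in Å; residue indices 0-based internally, 1-based author
numbering in PDB; intervals half-open internally. Generated chains are
single-chain 'A'; two-state designs are written as two MODEL blocks
sharing residue numbering, one FASTA record per design. PDB parsing is
backed by gemmi with a pre-validation pass that reports malformed ATOM
records by line number; FASTA by Biopython; the OBO dialect is parsed for
`[Term]`/`is_a` only. A run is reproducible from its archived YAML config
plus seed: every stochastic operation takes an explicit generator and no
global random state is used. Checkpoints are single-file npz archives with
an embedded JSON config and version field.

## Known limitations

- No equivariance or chirality handling anywhere in the generative core.
- The unconditional `p(s)` branch of coupled sampling feeds the shared
  noisy sequence with a max-noise structure input and no motif — the
  closest pure sequence prior the joint model offers; this is a heuristic.
- Degenerate coupled designs (both branches collapsing to one
  conformation) are measurable by comparing the branch structures but are
  not prevented.
- Euler–Maruyama only; no higher-order or probability-flow integrators.
- Cα-only structure generation; full-backbone/all-atom evaluation degrades
  to Cα where atoms are absent.
- The numpy engine is single-threaded beyond BLAS and intended for
  desk-scale models, not production training.
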