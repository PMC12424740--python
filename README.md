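# duet

Multimodal diffusion over protein sequence and Cα structure in one model:
a continuous score-based diffusion on backbone coordinates and a masked
(absorbing-state) discrete diffusion on amino-acid tokens share a single
transformer denoiser. Because the two modalities are corrupted at
independently sampled noise levels during training, one network supports
every generation workflow — sequence generation, structure generation,
joint co-generation, inverse folding, motif scaffolding, classifier-free
guidance on function labels, and a coupled two-trajectory protocol for
designing one sequence that folds into two distinct conformations.

The package is aimed at method developers who want a complete, inspectable,
CPU-scale implementation of this model family: every sampler, loss and
policy is exercised end-to-end against analytic or brute-force oracles on
synthetic protein families, with no trained weights or external tools
required.

## The model

**Structure.** Zero-centered Cα coordinates `x ∈ R^{3L}` follow a
variance-exploding diffusion `p(x_t | x_0) = N(x_0, t² I)` with `g(t) = √(2t)`.
Noise levels are warped, `t′ = (t^{1/p} − t_min^{1/p}) / (t_max^{1/p} − t_min^{1/p})`
with `t_min = 0.05 Å`, `t_max = 160 Å`, `p = 7`, and the network output
`f_θ` is blended into a score by post-conditioning

```
s_θ(x, t) = (1/t²) [ t·t_data/√(t_data² + t²) · f_θ(x, t) − t²/(t_data² + t²) · x ],   t_data = 15 Å
```

so the model interpolates between predicting the score (small `t`) and the
clean structure (large `t`). Sampling integrates the reverse SDE by
Euler–Maruyama on a uniform `t′` grid with low-temperature annealing:
drift `(g²/2)(1 + β(t)) s_θ` and noise amplitude `g √(β(t) γ)` with
`β(t) = 1/(1 + (t/t_data)^ν)`, `γ = 0.5` (`ν = 0.5` unconditional, `1`
conditional).

**Sequence.** Tokens live in a 21-symbol vocabulary (20 amino acids + mask).
Forward corruption masks each position independently with survival
probability `α_t = 1 − t`; the exact reverse posterior carries unmasked
tokens and fills masked ones from the model's clean-token prediction.
Generation uses Gumbel top-k *path planning*: each step ranks positions by
noisy model confidence, unmasks the top `k = L − round(sL)` and re-masks the
rest, so the unmasking order is chosen by the model itself. The training
loss is the masked cross-entropy weighted by `λ(t) = 1 − t`; the combined
objective is `L_struct + 3 L_seq`.

**Denoiser.** A plain pre-norm transformer (no equivariance, no pair
track): linear coordinate embedding, learned token and position embeddings,
optional motif embedding (coordinates + learned position mark + identities)
and function-term embedding, QK-norm, GeLU, and adaLN-Zero conditioning on
a sinusoidal embedding of the structural diffusion time. Two linear heads
emit 21-way logits and the raw structure prediction. At paper scale
(30 blocks, hidden 768 / 1024) the builds count ≈321M and ≈579M trainable
parameters.

**Coupled two-state design.** To find one sequence compatible with two
conformations scaffolding motifs `m₁, m₂`, the target density factorizes as
`p(s, x₁ | m₁) · p(s, x₂ | m₂) / p(s)`. Per step the denoiser is evaluated
three times; the shared sequence advances on the product-of-experts logits
`φ₁ + φ₂ − φ_∅` while each structure branch advances on its own score.

## Worked example

Train a tiny denoiser on the bundled synthetic two-state family and
co-generate sequence/structure pairs:

```bash
duet train-toy --out toy.npz --seed 7 --length 32 --steps 1000 --two-state
duet cogen --checkpoint toy.npz --length 32 --seed 11 --n 2 --out designs/
```

which prints, e.g.

```
trained 1000 steps; final loss 1.6498; saved toy.npz
wrote 2 designs to designs/
```

`designs/` then contains one Cα-trace PDB per design, `sequences.fasta`,
and the archived run config. In the toy family the three residue classes
(helix-like, strand-like, coil) each impose an exact local geometry, so
`duet.synthetic.decode_structure(sequence)` is an oracle for the structure
a sequence should fold into: comparing it against the co-generated
coordinates (Kabsch RMSD) measures sequence–structure self-consistency
without any external folding tool.

The same checkpoint drives the other protocols (`duet sample-seq`,
`duet sample-struct`, `duet invfold`, `duet couple`, `duet eval-site`);
`duet adapters` lists the documented I/O stubs for the external tools
(folding, inverse folding, function prediction, clustering, co-folding)
that full-scale screening pipelines would call.

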