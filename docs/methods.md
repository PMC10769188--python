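# Methods

This note records the modelling conventions, default parameters, numerical
choices and known limitations of the package, in the order a reader meets
them in the pipeline.

## Structure representation

A chain is stored in a fixed 14-slot heavy-atom layout per residue
(N, Cα, C, O, Cβ, then side-chain atoms in build order; tryptophan fills
all 14 slots). Missing atoms are masked, never imputed; any χ whose
defining quadruple is incomplete is masked as well. Angles live on the
half-open interval [−π, π) everywhere — backbone dihedrals, χ angles and
the bin domain all share it, so wrap-around is handled once in
`geometry.wrap_angle`.

Backbone frames follow the Gram–Schmidt convention used by structure
prediction networks: x-axis along C−Cα, the N−Cα direction completes the
xy-plane, translation at Cα. ω(i) is assigned to the peptide bond
*preceding* residue i (Cα(i−1)–C(i−1)–N(i)–Cα(i)); the undefined terminal
angles are φ and ω of the first residue and ψ of the last.

Side chains are rebuilt from χ by sequential internal-coordinate (NERF)
placement against embedded ideal bond lengths and angles. The input
backbone (including O) is kept as-is; Cβ is always placed ideally from
N/Cα/C (the same construction provides glycine's virtual Cβ for
featurization and burial counts). Ring geometries beyond the last χ-driven
atom use fixed torsions. Build and extract are exact inverses: the
round-trip error is at floating-point level (asserted at 1e−5 rad, measured
~1e−15). Proline's ring is *not* closed analytically; the ring-closing
(χ₁, χ₂) pair for the ideal geometry is found once by a Nelder–Mead search
on the Cδ–N bond-length error and cached (≈ (19.5°, −17.5°) for these
tables, giving Cδ–N within the bonded 1.3–1.6 Å range).

## Graph and features

k = 30 nearest neighbors by Cα–Cα distance, ascending, ties to the lower
residue index. Distances are rounded to 1e−6 Å before sorting so that the
exactly tied distances of ideal secondary structure cannot reorder under
the floating-point noise of a rigid motion — without this, feature
invariance would fail spuriously on symmetric fixtures.

Relative sequence positions are clipped at ±32 (65 classes). Distances are
encoded with 16 Gaussian RBFs with centers evenly spaced on [0, 20] Å and
width equal to the spacing; the 25 ordered main-chain atom pairs
(N, Cα, C, O, Cβ of both endpoints) give 400 edge channels. Masked
dihedral and χ features encode as (0, 0) rather than a learned token — the
simplest invariant choice.

Recycling features: 8 node channels (sin/cos of the four previously
decoded χ) and 3 × 16 edge channels, the RBF encodings of the *minimum*
heavy-atom distance between (side chain i, backbone j), (backbone i, side
chain j) and (side chain i, side chain j). Residues without side-chain
atoms use a sentinel distance of 1000 Å, which the RBFs map to ~0. Both
blocks are zero on the first pass; recycled features are recomputed outside
the autodiff graph, so no gradient flows through recycling (stop-gradient).

## Network

Defaults: hidden width 128, edge width 128, 3 message-passing layers,
8 invariant points per node, MLP depth 2, ~0.46 M parameters. All three
layer types share the residual mean-aggregation form, so they are drop-in
interchangeable at equal width; a layer whose MLP weights are zero is the
identity. The IPA layer follows the invariant-point-attention recipe
restricted to the k neighbors, with per-head learned point weights
(softplus γ), and emits no update for a node with no unmasked neighbor.

The five IPMP message components treat the points from node j as the
quantity mapped into node i's frame (T_i⁻¹∘T_j∘p_j^a); squared norms and
squared global-frame distances make every component invariant.

The head produces, per (residue, χ), logits over 72 bins of 5° and a
per-bin offset squashed to (−½, ½) bin widths by 0.5·tanh. The offset is
consumed only at the selected bin (argmax at decode, sampled bin when
sampling) and trained only at the target bin. Tie-breaks in argmax decoding
go to the lowest bin index. Ensembling averages logits *and* offsets
elementwise before the softmax; averaging probabilities instead is not
equivalent and is deliberately not offered.

Checkpoints are NumPy archives holding every named parameter plus a JSON
header with the full architecture configuration and a format version;
loading rejects version or shape mismatches.

## Training

Bin cross-entropy plus an offset L2 penalty at the target bin, each with
weight 1 by default, averaged over unmasked χ. Native angles are
discretized by floor binning with the signed fractional position in
[−½, ½) as the offset target; bin + offset reproduces the native angle to
1e−9 rad. Optimization is Adam under the inverse-square-root warmup
schedule (d_model^−0.5 · min(step^−0.5, step·warmup^−1.5), warmup 4000);
early stopping monitors validation χ perplexity (exp of the masked mean
NLL; 72 for a uniform predictor, 1 for a perfect one) with patience 10
evaluations. The loop contract is a random contiguous crop of 512 residues
and a batch of 32 chains; cropping shorter chains is a no-op. A config
flag discards any χ whose defining side-chain atoms (beyond N/Cα/C/O)
carry a B-factor above 40 Å².

Finetuning keeps the classification loss and adds two coordinate losses on
a Gumbel-Softmax hard sample (λ = 1, straight-through gradients) of the
predicted distributions, with a fixed learning rate of 1e−8: a clash loss
(sum of squared vdW overlaps) and a proline-closure loss (squared Cδ–N
deviation from 1.474 Å). The sampled χ feed the differentiable rebuild, so
both losses backpropagate to the logits through the sampled structure.

## Clash model

Element radii: C 1.7, N 1.55, O 1.52, S 1.8 Å. Excluded pairs: within two
covalent bonds (the proline Cδ–N ring bond counts as a bond), and
main-chain/main-chain pairs (N, Cα, C, O, Cβ) of the same or
sequence-adjacent residues, whose distances are fixed by the input
backbone. Candidate pairs come from a KD-tree at the maximum radius sum,
so the quadratic penalty and the counts are exact.

A consequence worth knowing: 1–4 intra-residue contacts (e.g. N···Cγ at
gauche χ₁, C···Oγ of serine) always overlap slightly, so the quadratic
clash loss has a small positive floor for any χ-bearing residue — only the
*serious*-clash threshold (overlap > 0.4 Å) is expected to reach zero on
well-packed structures. Clash-free test constructions therefore use either
χ-free sequences or explicitly verified rotamer assignments; note that
random rotamers on a dense helix genuinely clash, which is the packing
problem itself, not an artifact. The clashscore (serious clashes per 1000
heavy atoms) is a deliberately simplified, hydrogen-free stand-in for
MolProbity's: comparable across structures scored by this package, not
against published MolProbity numbers.

## Inference and resampling

`pack` strips any input side chains, featurizes, runs the network with the
configured recycles (3 by default), optionally ensembles, then decodes by
mode (deterministic default), by temperature sampling, or decodes by mode
and runs Metropolis resampling ("resample"). Mode decoding before
resampling is the default; low-temperature sampling is available through
the sampling mode when conformational diversity matters.

The resampler flags clashing residues and prolines whose Cδ–N distance
deviates more than 0.3 Å from ideal, then proposes new χ for one flagged
residue at a time from the predicted distributions at the current round's
temperature, accepting with probability min(1, exp(−ΔE/T)). The energy is
the clash loss plus the proline-closure loss — the same functional forms
as the finetuning penalties. The schedule starts at T = 0.1 and ramps ×1.5
per round for up to 50 rounds (one proposal per flagged residue per
round); the ramp trades probability mass for diversity when the sharp
low-temperature proposals cannot resolve a clash. Residues never flagged
keep their decoded χ bit-identically.

## Synthetic fixtures

The generator chains ideal backbone geometry from per-residue (φ, ψ, ω)
motifs (helix −57/−47/180, strand −120/120/180, or per-residue random
coil) and assigns χ either at fixed values, uniformly at random, or from
the staggered grid {−60°, 60°, 180°}; prolines always receive the
ring-closing pair. Identical spec + seed reproduces structures
bit-identically. These fixtures exercise geometry, invariance, training
and resampling code paths exactly, but they do not emulate rotamer-library
statistics, real packing density, missing atoms or experimental noise —
passing tests demonstrate correctness of the machinery, not benchmark
accuracy on crystal structures.

The adversarial clash fixture places two leucines one helical turn apart
on a short helix and picks a staggered χ assignment verified at
construction to produce a serious clash while at least one alternative
staggered assignment is verified clash-free, so resampling tests run only
on solvable instances.

## Problem sizes and test design

The test-suite and acceptance-script problem sizes — 20- to 30-residue
chains, five training chains, a reduced model (one IPMP layer, width 64),
1e5-draw sampling checks, 20 resampling fixtures — were chosen so the full
pipeline, including training to memorization, runs in well under a minute
each on a single CPU while still exercising every code path at full
numerical precision. Training to ≥95% rotamer recovery on random-coil
fixtures typically completes within a few hundred steps of the 2000-step
budget; random coils are used because their per-residue dihedrals make
every node feature distinct, which makes memorization a clean test of the
optimization path rather than of symmetry breaking.

## Known limitations

- Single chains only; no hydrogens, ligands, waters, nucleic acids or
  inter-chain context.
- Ideal-geometry reconstruction: native bond lengths/angles are replaced
  by table values, so even perfect χ recovery leaves small RMSDs on real
  structures (not on the fixtures, which are built from the same tables).
- The CPU autodiff engine is intended for the reduced models used in
  testing and for small-scale finetuning experiments, not for multi-day
  training runs on large corpora.
- χ symmetry (PHE/TYR χ₂, ASP χ₂, GLU χ₃; ARG NH relabeling for RMSD) is
  scored symmetry-minimal by default and toggleable; conventions differ
  across published evaluations, and the toggle shifts recovery and MAE.
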