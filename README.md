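# pippack

Protein side-chain packing (PSCP) with invariant point message passing:
given a fixed backbone and amino-acid sequence, predict the conformation of
every side chain. The package is aimed at protein modelling and design
workflows that need fast, idealized all-heavy-atom structures — rotamer
placement for designed backbones, pre-relaxation starting points, or
packing baselines for method development.

## The model

Each residue *i* is a node in a k-nearest-neighbor graph (k = 30, by
Cα–Cα distance). Node features are the sequence one-hot and
(sin, cos) of the backbone dihedrals φ, ψ, ω; edge features are a clipped
relative-sequence-position one-hot and Gaussian RBF encodings of the 25
main-chain atom-pair distances (N, Cα, C, O, Cβ). Every feature is
invariant under global rotations and translations; the per-residue backbone
frames T\_i = (R\_i, t\_i) (Gram–Schmidt on N/Cα/C) are the only equivariant
quantities and are consumed only through invariant contractions.

Node states are updated by one of three interchangeable residual layers:

- **MPNN** — n\_i′ = n\_i + |𝒩(i)|⁻¹ Σ\_j MLP(n\_i | n\_j | e\_ij);
- **IPA** — neighborhood-restricted invariant point attention;
- **IPMP** (default) — the MPNN update where each message additionally
  concatenates five invariant geometric components built from learned
  per-node points p\_i^a in the local frames: the receiver's points, their
  squared norms, the sender's points mapped into the receiver's frame
  (T\_i⁻¹∘T\_j∘p\_j^a), the squared norms of those, and the squared
  global-frame distances ‖T\_i∘p\_i^a − T\_j∘p\_j^a‖².

The head classifies each χ\_1..χ\_4 into 72 five-degree bins over [−π, π)
and regresses a per-bin offset in (−½, ½) bin widths, so a decoded angle is
bin center + offset. Decoded side chains are rebuilt with ideal bond
lengths and angles. Predictions are refined by recycling (default 3
extra passes conditioned on the previous decode via χ sin/cos node features
and side-chain distance RBF edge features) and can be ensembled by
averaging logits across independently trained models before the softmax.

Training minimizes masked bin cross-entropy plus an offset L2 term, with
early stopping on validation χ perplexity. A finetuning stage draws
differentiable hard samples from the predicted distributions
(Gumbel-Softmax, λ = 1) and penalizes van-der-Waals overlaps and unclosed
proline rings of the sampled structures. At inference, residual clashes
(vdW overlap > 0.4 Å) and unclosed prolines can be resolved by Metropolis
resampling of the offending residues' χ distributions under a rising
temperature schedule.

The network and its training run on a small reverse-mode autodiff engine
over NumPy float64 arrays (`pippack.ops`), which keeps the package
dependency-light and exactly reproducible on CPU; the default configuration
has ~0.46 M parameters.

## Worked example

Everything is testable without downloads: `pippack.fixtures` generates
single-chain structures with ideal geometry and known ground-truth χ. The
snippet below builds a helix in which two leucines one turn apart are
deliberately assigned clashing rotamers, then resolves them:

```python
from pippack.fixtures import make_clash_fixture, clash_fixture_prediction
from pippack.inference import resample_mcmc, ResampleSchedule
from pippack.clash import clashscore, find_clashing_residues

chain = make_clash_fixture(seed=0)
print("clashscore before:", round(clashscore(chain), 2))
print("flagged residues:", sorted(find_clashing_residues(chain)))
out = resample_mcmc(chain, clash_fixture_prediction(chain),
                    ResampleSchedule(seed=0))
print("clashscore after :", round(clashscore(out), 2))
```

```
clashscore before: 90.91
flagged residues: [2, 5, 6]
clashscore after : 0.0
```

`clashscore` counts serious steric overlaps (> 0.4 Å of vdW interpenetration)
per 1000 heavy atoms — a hydrogen-free proxy for the MolProbity clashscore.
Before resampling, the two leucines (residues 2 and 5) and a neighbor touched
by one of them are flagged; Metropolis resampling finds the clash-free
rotamers that the predicted distributions also support.

From a shell, packing and scoring a PDB chain:

```bash
pippack pack --in backbone.pdb --chain A --out packed.pdb \
    --checkpoint model.npz --recycles 3 --mode resample --seed 0
pippack evaluate --pred packed.pdb --native native.pdb --report report.json
```

`evaluate` reports rotamer recovery (all χ within 20° of native), mean
per-residue side-chain RMSD after per-residue backbone superposition, per-χ
mean absolute error, the clashscore proxy, and stratifications by residue
type and burial (core: ≥ 20 neighbors within 10 Å Cβ–Cβ; surface: ≤ 15).

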