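# phipsinet

Sequence-only prediction of protein backbone ϕ/ψ dihedral angles with a
deliberately simple, fully connected neural network.

## The problem

A protein backbone's conformation is essentially determined by two
dihedral angles per residue: ϕ (C(i−1)–N(i)–Cα(i)–C(i)) and ψ
(N(i)–Cα(i)–C(i)–N(i+1)), with the peptide-bond ω fixed at 180° (trans).
Most modern angle predictors stack evolutionary profiles, predicted
surface areas and deep recurrent/transformer ensembles. This package
implements the opposite end of the complexity spectrum: a single dense
network that sees nothing but the amino-acid sequence in a sliding
window of 21 residues (the centre residue ±10), one-hot encoded into
21 × 20 = 420 binary inputs, and regresses both angles directly in
degrees. It is a transparent baseline for studying how much local
sequence context alone says about backbone geometry, and a building
block that larger pipelines can absorb.

Because angles live on a circle, ordinary MAE/RMSE mishandle the wrap
at ±180°. Training and evaluation therefore use the periodic absolute
error

    AE = min(D, |360° − D|),   D = |P − A|,

where P is the predicted and A the measured angle; AE ∈ [0°, 180°], and
the model's loss is the mean AE over both outputs. A prediction of 245°
against a measurement of 0° costs 115°, not 245°.

## What is in the package

| module | contents |
| --- | --- |
| `phipsinet.geometry` | torsion angles (IUPAC sign convention), angle wrapping, the periodic error/loss, an ideal-geometry backbone builder and its inverse (a round-trip oracle) |
| `phipsinet.dataset` | chain quality filters (R-free < 0.25, resolution < 2.5 Å, length 40–10000, one chain per entry), PDB/mmCIF dihedral extraction via gemmi, sliding-window one-hot encoding with virtual "0" residues at the termini, seeded 80/10/10 row split |
| `phipsinet.model` | the dense dual-output regressor (default 420 → 713×4 → 2, ReLU hidden / linear output), Adadelta (lr 0.5) on the periodic-MAE loss, patience-4 early stopping with best-epoch restore |
| `phipsinet.hpo` | TPE-style Bayesian search over depth (1–5) and width (26–840) minimizing validation MAE(ϕ)+MAE(ψ), with median-rule pruning |
| `phipsinet.evaluation` | global/per-residue MAE, 1°-resolution error histograms, Ramachandran-rectangle three-state (Q3) assignment, confusion matrices, window-size sweep |
| `phipsinet.synthetic` | seeded synthetic chains (Markov conformational states with sequence-propensity coupling), ideal-geometry structure files, a zero-noise lookup task |
| `phipsinet.cli` | `phipsinet simulate / build-dataset / train / predict / evaluate / hpo / window-sweep` |

## Worked example

A complete run on synthetic data (no downloads needed):

```bash
phipsinet simulate --chains 150 --length 50:120 --seed 7 --out-dir sim --structures
phipsinet build-dataset --structures sim/structures --window 21 --out data.csv --seed 7
echo '{"hidden_widths": [128], "max_epochs": 40, "batch_size": 256}' > cfg.json
phipsinet train --dataset data.csv --config cfg.json --seed 7 --out model.npz
phipsinet predict --model model.npz --dataset data.csv --out preds.tsv
phipsinet evaluate --predictions preds.tsv --dataset data.csv --out eval
```

which prints (numbers from this exact command sequence):

```
wrote 150 chains to sim/chains.tsv
wrote 12443 rows x 422 columns to data.csv
test MAE phi=26.87 deg, psi=61.69 deg; model saved to model.npz
wrote 12443 predictions to preds.tsv
{
 "mae_phi": 24.61,
 "mae_psi": 55.78,
 "q3_overall_accuracy": 73.17,
 "q3_per_class_recall": {"helix": 85.26, "sheet": 65.57, "undesignated": 0.0},
 "n_residues": 12443
}
```

Reading the output: the held-out test MAE is 26.9° for ϕ and 61.7° for
ψ — ϕ is much easier because three of the four synthetic conformational
states put ϕ in the same negative band, whereas ψ splits into two modes
nearly 180° apart, so each mode confusion costs heavily. Converting
measured and predicted angle pairs to three-state labels via the default
Ramachandran rectangles gives 73% agreement; the "undesignated" class
(uniform-coil emissions in the generator) is intrinsically unlearnable
from sequence and the model never predicts it, mirroring how real
angle-only Q3 assignment degrades for irregular structure. The
`evaluate` step scores every dataset row, training rows included; use a
held-out dataset file for a strictly out-of-sample evaluation.

Real structures work the same way: point `build-dataset` at a directory
of PDB/mmCIF files (optionally with `--cull-list` for a PISCES-style
quality list) and the pipeline regenerates the full-scale dataset,
model and evaluation tables.

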