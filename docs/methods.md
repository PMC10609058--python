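# Methods note

This note records what the package computes, with what parameters, and
which choices were made for numerical or practical reasons. It makes no
empirical claims beyond what the shipped tests and scripts compute.

## Problem statement

Given only an amino-acid sequence, predict each residue's backbone
dihedral pair (ϕ, ψ) in degrees. ϕ is the torsion C(i−1)–N(i)–Cα(i)–C(i)
and ψ is N(i)–Cα(i)–C(i)–N(i+1); both are undefined at the corresponding
chain terminus. The peptide bond ω is treated as fixed trans (180°)
throughout.

## Geometry

* **Torsion convention.** `torsion_angle` uses the two-normal atan2
  form: with bond vectors b1=p2−p1, b2=p3−p2, b3=p4−p3, the angle is
  atan2(|b2|·b1·(b2×b3), (b1×b2)·(b2×b3)). This is the IUPAC
  convention: a right-handed rotation about p2→p3 increases the angle;
  cis is 0°, trans is ±180°. If either plane normal has norm below
  1e-10 (collinear atoms) a `DegenerateGeometryError` is raised rather
  than returning a garbage angle.
* **Wrapping.** All angles are canonicalized to the half-open interval
  [−180°, 180°) via `wrap_angle(θ) = ((θ+180) mod 360) − 180`. The
  half-open choice makes every angle have exactly one representation
  (+180 maps to −180), which keeps equality tests and histogram binning
  unambiguous.
* **Backbone builder.** `build_backbone_coordinates` places N/Cα/C
  atoms by sequential internal-coordinate (NeRF-style) construction
  with ideal geometry: bond lengths N–Cα 1.458 Å, Cα–C 1.525 Å,
  C–N 1.329 Å; bond angles N-Cα-C 111.2°, Cα-C-N 116.2°, C-N-Cα 121.7°;
  ω = 180°. Together with `extract_backbone_torsions` it forms a
  round-trip oracle: torsions → coordinates → torsions reproduces the
  inputs to ≈1e-13° in double precision, which the test suite uses to
  validate both directions at once.

## Loss and error metric

The periodic absolute error is AE = min(D, |360−D|) with D = |P−A|; it
ranges over [0°, 180°] and its maximum, 180°, is attained exactly at
antipodal pairs. The training loss is the mean AE over the batch and
both outputs. The loss is piecewise linear in the prediction, so
backpropagation uses its subgradient, the sign of the wrapped residual
wrap(P−A), scaled by 1/(batch·outputs).

## Dataset construction

* **Chain filters** (`FilterCriteria`): R-free < 0.25, resolution
  < 2.5 Å (strict inequalities; chains missing either value are
  rejected), length in [40, 10000], and at most one chain per entry
  (the first listed). A PISCES-style cull list can further restrict the
  input set.
* **Extraction.** Structures are read with gemmi (first model; first
  altloc of each backbone atom). Chains with non-canonical residues or
  missing backbone atoms are rejected with a reason.
* **Encoding.** A window of 21 residues (centre ±10) is one-hot encoded
  over the alphabet `ACDEFGHIKLMNPQRSTVWY` (alphabetical by one-letter
  code), 20 bits per position, giving 420 binary features. Positions
  that fall outside the chain are "virtual residues" encoded as all-zero
  blocks. Rows whose centre residue lacks ϕ or ψ (termini) are dropped,
  so every row has both targets defined. A dataset row is 422 columns:
  420 features plus the two target angles.
* **Split.** Rows are split 80/10/10 into train/validation/test by a
  seeded permutation; the split is over rows (windows), not chains.

## Model and training

* **Topology.** Fully connected: 420 inputs → four ReLU hidden layers
  of 713 units (defaults) → 2 linear outputs, ~1.8 M connection weights
  (`count_connection_weights` counts inter-layer products only, no
  biases). Weights are Glorot-uniform initialized from a seeded
  generator; arithmetic is float32.
* **Optimizer.** Adadelta with ρ = 0.95, ε = 1e-6 and a learning-rate
  multiplier of 0.5, implemented explicitly in numpy (the execution
  environment provides no deep-learning framework; this substitution is
  the package's own, and the explicit implementation keeps runs exactly
  reproducible on one CPU thread).
* **Stopping.** The per-epoch validation loss is MAE(ϕ)+MAE(ψ). Early
  stopping triggers after 4 consecutive non-improving epochs and the
  best epoch's weights are restored.
* **Plateau decay.** Because the loss is piecewise linear, subgradient
  magnitudes do not shrink near an optimum and a constant step can
  oscillate indefinitely. `TrainingConfig.plateau_decay` (default 0.5)
  multiplies the learning rate after every `plateau_patience`
  (default 2) consecutive non-improving epochs, a standard
  reduce-on-plateau schedule; setting the decay to 1.0 disables it.
  This is an addition relative to plain Adadelta and is needed for the
  full-size network to settle on low-noise tasks.
* **Prediction.** Raw linear outputs are wrapped to [−180°, 180°); an
  untrained model refuses to predict.

## Hyperparameter search

`phipsinet.hpo` implements a small Tree-structured-Parzen-Estimator
(TPE) style sampler over network depth (1–5 hidden layers) and shared
layer width (26–840), minimizing the validation MAE sum. The first 8
trials are uniform random; afterwards observed trials are split at the
γ = 0.25 quantile into good/bad sets, each modelled per dimension by a
Gaussian Parzen mixture (bandwidth max(1, range/√n/2)) blended with a
uniform prior, and 24 candidates are scored by log l(x) − log g(x). A
median pruner stops a trial whose running validation loss exceeds the
median of previous trials at the same epoch (active once ≥3 trials have
reported). Trial seeds are derived as seed·100003 + trial number so
trials are independent but the whole study is reproducible. The sampler
is in-package because the environment provides no HPO library.

## Evaluation

* **Per-residue statistics.** MAE per amino-acid type, with the spread
  reported as the arithmetic standard deviation of the wrapped measured
  angles (not a circular SD) — a deliberate simple convention stated
  here to avoid ambiguity.
* **Error histograms.** 180 bins of 1° over [0°, 180°], plus summary
  fractions: AE < 20°, AE < 80°, AE > 179°.
* **Three-state (Q3) assignment.** Angle pairs map to
  helix/sheet/undesignated via axis-aligned Ramachandran rectangles
  (half-open, after wrapping): helix −180 ≤ ϕ < 0 and −120 ≤ ψ < 45;
  sheet −180 ≤ ϕ < 0 and ψ ∈ [45, 180) ∪ [−180, −120); everything else
  undesignated. Sheet is tested before helix; with the default
  rectangles the regions are disjoint so the order is immaterial, but
  it fixes behaviour for user-supplied rectangles. Confusion matrices,
  overall accuracy and per-class recall are computed from these labels.
* **Window sweep.** For each window size the dataset is rebuilt, split,
  trained and tested with identical seeds and a small fixed topology,
  isolating the effect of sequence context width.

## Synthetic data generator

The generator exists so the full pipeline (structure files → dataset →
training → evaluation) can be exercised and tested offline, with known
ground truth. It emulates, crudely, the statistical structure of real
backbones; it is not a physical model.

* **Conformational states.** A first-order Markov chain over
  helix/sheet/left-handed/coil with stay probability 0.9 and jump
  probabilities (0.35, 0.30, 0.05, 0.30). Helix, sheet and left-handed
  states emit (ϕ, ψ) from isotropic Gaussians (SD 10°) centred at
  (−63, −43), (−120, 135) and (60, 45); coil emits uniformly.
* **Residue identity effects.** Proline overrides ϕ with N(−65°, 8°²);
  glycine doubles the emission SD and triples the coil jump weight —
  caricatures of real steric restriction/permissiveness.
* **Sequence–structure coupling.** Residues are drawn with a propensity
  tilt: the state of positions within ±3 residues multiplies the
  frequency of residues in that state's propensity set (helix
  "AELMQKRH", sheet "VIYCWFT", left "ND", coil "GPS") by exp(β·count)
  with β = 0.8. Without this tilt the sequence would be independent of
  the angles and a sequence-only model could learn nothing; the tilt is
  what makes window-context experiments meaningful on synthetic data.
* **What it does not model.** No side chains, no hydrogen-bond
  cooperativity, no long-range contacts, no experimental noise; coil is
  genuinely unlearnable by construction, so "undesignated" recall on
  synthetic data is expected to be near zero.
* **Lookup task.** `deterministic_toy_dataset` assigns each residue
  type a fixed (ϕ, ψ) pair (ϕ_k = wrap(−165+17k), ψ_k = wrap(150−16k)
  for the k-th alphabetical residue). Its Bayes error is exactly zero,
  which makes it a capacity/optimization oracle: a correctly
  implemented full-size network must drive test MAE low on it.

## Structure file precision

Synthetic structures can be written as PDB or mmCIF. The PDB fixed
format stores coordinates with 3 decimals (8.3 fields), which limits a
torsion round trip through a file to roughly 0.1–0.2° for these chain
lengths. Where the tests require sub-millidegree round trips, mmCIF is
used with coordinate columns rewritten at 6 decimal places; 5 decimals
was measured to just miss the 1e-3° target, 6 passes with margin.

## Problem-size conventions in tests

Heavier tests fix their budgets up front: the full-size-network lookup
test uses batch size 256 and at most 60 epochs; the window-sweep test
uses 150 chains, batch 256 and 20 epochs. These are the package's own
problem-size choices, selected for a single-CPU time budget before the
tests were first run, not tuned against outcomes.

## Limitations

* The model is sequence-window-only by design; no claim is made that it
  approaches profile- or attention-based predictors on real data.
* Synthetic results quantify pipeline correctness, not biological
  accuracy; the generator's parameters are caricatures.
* The subgradient/Adadelta/plateau combination is simple and robust but
  slow near the optimum compared to smoothed circular losses.
* Q3 rectangles are a coarse, axis-aligned partition of the
  Ramachandran plane; boundary placement materially affects class
  counts, which is why the defaults are stated exactly above.
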