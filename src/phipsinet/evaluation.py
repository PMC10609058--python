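"""Evaluation of dihedral predictions: MAE breakdowns, error histograms,
Ramachandran-region three-state assignment, and the window-size sweep.

The three-state ("Q3") assignment maps a (phi, psi) pair to helix,
sheet, or undesignated using axis-aligned half-open rectangles on the
Ramachandran torus. The default regions cover the canonical alpha and
beta basins (phi < 0 only, so the left-handed helix counts as
undesignated); they are plain data and fully configurable, since any
angle-only assignment is necessarily cruder than hydrogen-bond-based
schemes such as DSSP or STRIDE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import AA_ALPHABET, EncodedDataset, SplitSpec, WindowConfig, split_dataset
from .geometry import absolute_angular_error, wrap_angle
from .model import FCNN, ModelConfig, TrainingConfig, build_model, predict, train, validation_mae

__all__ = [
    "LABELS",
    "Q3Regions",
    "assign_q3",
    "classify_chain_fold",
    "confusion_matrix",
    "error_histogram",
    "overall_accuracy",
    "per_residue_mae",
    "row_percentages",
    "window_sweep",
]

LABELS = ("helix", "sheet", "undesignated")

#: A rectangle is (phi_min, phi_max, psi_min, psi_max), half-open in both axes.
Rect = tuple[float, float, float, float]


@dataclass(frozen=True)
class Q3Regions:
    """Half-open Ramachandran rectangles for helix and sheet.

    Any point in no rectangle is undesignated. The defaults put the
    alpha basin at {-180 <= phi < 0, -120 <= psi < 45} and the beta
    basin at {-180 <= phi < 0, psi in [45, 180) or [-180, -120)}; the
    two never overlap by construction of the psi bands.
    """

    helix: tuple[Rect, ...] = ((-180.0, 0.0, -120.0, 45.0),)
    sheet: tuple[Rect, ...] = (
        (-180.0, 0.0, 45.0, 180.0),
        (-180.0, 0.0, -180.0, -120.0),
    )


def _in_rects(phi: np.ndarray, psi: np.ndarray, rects: Sequence[Rect]) -> np.ndarray:
    hit = np.zeros(phi.shape, dtype=bool)
    for pmin, pmax, smin, smax in rects:
        hit |= (phi >= pmin) & (phi < pmax) & (psi >= smin) & (psi < smax)
    return hit


def assign_q3(phi, psi, regions: Q3Regions = Q3Regions()) -> np.ndarray:
    """Label each (phi, psi) pair helix / sheet / undesignated.

    Total and deterministic; inputs are wrapped to [-180, 180) first.
    Helix rectangles take precedence over sheet if a custom region set
    overlaps. Returns an array of label strings.
    """
    phi = np.atleast_1d(wrap_angle(phi))
    psi = np.atleast_1d(wrap_angle(psi))
    labels = np.full(phi.shape, "undesignated", dtype=object)
    labels[_in_rects(phi, psi, regions.sheet)] = "sheet"
    labels[_in_rects(phi, psi, regions.helix)] = "helix"
    return labels


def confusion_matrix(real: Sequence[str], predicted: Sequence[str]) -> pd.DataFrame:
    """3x3 count matrix; rows are real labels, columns predicted."""
    real = np.asarray(real)
    predicted = np.asarray(predicted)
    if real.shape != predicted.shape:
        raise ValueError("real and predicted label lists must have equal length")
    cm = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS), dtype=int)
    for r, p in zip(real, predicted):
        cm.loc[r, p] += 1
    return cm


def overall_accuracy(cm: pd.DataFrame) -> float:
    """Percentage of residues on the diagonal: 100 * trace / total."""
    total = int(cm.to_numpy().sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return 100.0 * float(np.trace(cm.to_numpy())) / total


def row_percentages(cm: pd.DataFrame) -> pd.DataFrame:
    """Each cell as a percentage of its row total (per-class recall on
    the diagonal)."""
    totals = cm.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every real class must have at least one residue")
    return cm.div(totals, axis=0) * 100.0


def classify_chain_fold(labels: Sequence[str], threshold: float = 0.6) -> str:
    """Class a chain as all-alpha / all-beta / mixed by measured Q3 share.

    A chain is all-alpha (all-beta) when more than ``threshold`` of its
    residues are helix (sheet).
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label list")
    if (labels == "helix").mean() > threshold:
        return "all-alpha"
    if (labels == "sheet").mean() > threshold:
        return "all-beta"
    return "mixed"


def per_residue_mae(
    residues: Sequence[str], measured: np.ndarray, predicted: np.ndarray
) -> pd.DataFrame:
    """Per-residue-type MAE and measured-angle spread.

    Returns a DataFrame indexed by one-letter code with columns
    ``mae_phi``, ``mae_psi``, ``sd_phi``, ``sd_psi``, ``count``. The SD
    is the arithmetic standard deviation of the wrapped measured angles
    (not a circular SD), which is how spreads beyond ~81° can arise for
    flexible residues like glycine.
    """
    residues = np.asarray(residues)
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if not (len(residues) == len(measured) == len(predicted)):
        raise ValueError("residues, measured and predicted must be aligned")
    err = absolute_angular_error(predicted, measured)
    rows = {}
    for code in sorted(set(residues)):
        mask = residues == code
        rows[code] = {
            "mae_phi": float(err[mask, 0].mean()),
            "mae_psi": float(err[mask, 1].mean()),
            "sd_phi": float(np.std(wrap_angle(measured[mask, 0]))),
            "sd_psi": float(np.std(wrap_angle(measured[mask, 1]))),
            "count": int(mask.sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def error_histogram(errors: np.ndarray, bin_width: float = 1.0) -> dict:
    """Histogram of absolute angular errors at the given resolution.

    Returns bin edges/counts over [0, 180] plus the fractions of errors
    below 20°, below 80°, and above 179° — the summary thresholds used
    for the phi/psi error-distribution comparison. Fractions of the
    bins sum to 1.
    """
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("no errors to histogram")
    if (errors < 0).any() or (errors > 180).any():
        raise ValueError("absolute angular errors must lie in [0, 180]")
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(errors, bins=edges)
    n = errors.size
    return {
        "bin_edges": edges,
        "counts": counts,
        "fractions": counts / n,
        "frac_under_20": float((errors < 20.0).mean()),
        "frac_under_80": float((errors < 80.0).mean()),
        "frac_over_179": float((errors > 179.0).mean()),
    }


def window_sweep(
    chains,
    sizes: Sequence[int] = (3, 7, 11, 15, 21),
    hidden_widths: tuple[int, ...] = (64,),
    tc: TrainingConfig = TrainingConfig(),
    seed: int = 0,
    max_rows: int | None = None,
) -> pd.DataFrame:
    """Re-encode, retrain and re-test the model across window sizes.

    ``chains`` is the (chain_id, records) input of
    :func:`phipsinet.dataset.build_dataset`. For each size the dataset
    is rebuilt at that window, split 80/10/10 with ``seed``, optionally
    truncated to ``max_rows``, and a fresh model (same hidden widths,
    input width following the window) is trained and scored on the test
    partition. Returns a DataFrame with columns size, mae_phi, mae_psi.
    """
    from .dataset import build_dataset  # local to avoid cycle at import time

    rows = []
    for size in sizes:
        if size % 2 == 0:
            raise ValueError(f"window sizes must be odd, got {size}")
        ds = build_dataset(chains, WindowConfig(size))
        if max_rows is not None and len(ds) > max_rows:
            ds = EncodedDataset(
                ds.features[:max_rows],
                ds.targets[:max_rows],
                ds.manifest.iloc[:max_rows].reset_index(drop=True),
                ds.window,
            )
        tr, va, te = split_dataset(ds, SplitSpec(seed=seed))
        config = ModelConfig(input_dim=size * len(AA_ALPHABET), hidden_widths=hidden_widths)
        model = build_model(config, seed=seed)
        train(model, (tr.features, tr.targets), (va.features, va.targets), tc)
        mae_phi, mae_psi = validation_mae(model, te.features.astype(np.float32), te.targets)
        rows.append({"size": size, "mae_phi": float(mae_phi), "mae_psi": float(mae_psi)})
    return pd.DataFrame(rows)
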