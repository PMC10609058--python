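"""Dataset construction: chain filtering, dihedral extraction, window encoding.

The pipeline turns protein structures into a flat regression table:

1. :func:`filter_chains` applies quality criteria (R-free, resolution,
   length, one chain per entry) to chain-level metadata, e.g. from a
   PISCES-style culling list.
2. :func:`extract_residue_records` reads a structure (PDB or mmCIF,
   first model, first altloc) and converts backbone coordinates into
   per-residue (phi, psi) pairs.
3. :func:`encode_window` one-hot encodes a sliding window of residues
   (default size 21, i.e. the centre residue plus ten on each side) into
   ``size * 20`` binary features; positions beyond the chain termini are
   "virtual residues" encoded as all-zero blocks.
4. :func:`build_dataset` assembles one row per residue with both angles
   defined, yielding ``size * 20`` feature columns plus the two targets.
5. :func:`split_dataset` performs the seeded 80/10/10 row-level random
   split into train/validation/test.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import AnglePair, torsion_angle

__all__ = [
    "AA_ALPHABET",
    "ChainMetadata",
    "ChainRejected",
    "EncodedDataset",
    "FilterCriteria",
    "ResidueRecord",
    "SplitSpec",
    "WindowConfig",
    "build_dataset",
    "encode_sequence",
    "encode_window",
    "extract_residue_records",
    "filter_chains",
    "load_dataset",
    "read_cull_list",
    "save_dataset",
    "split_dataset",
]

#: Canonical 20 one-letter codes, alphabetical; defines the one-hot column order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET)}

#: Three-letter to one-letter translation for the canonical residues.
THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}


class ChainRejected(ValueError):
    """A chain fails the dataset requirements (non-canonical residue,
    missing backbone atom, or absent chain)."""


@dataclass(frozen=True)
class ChainMetadata:
    """Quality metadata for one chain of one PDB entry."""

    pdb_id: str
    chain_id: str
    resolution: Optional[float]  # Angstrom
    r_free: Optional[float]
    length: int  # residue count


@dataclass(frozen=True)
class FilterCriteria:
    """Chain-level inclusion criteria (all inequalities strict where noted)."""

    r_free_max: float = 0.25
    resolution_max: float = 2.5
    length_min: int = 40
    length_max: int = 10000
    one_chain_per_entry: bool = True


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of one chain: code, position and its dihedral pair."""

    code: str
    position: int  # 0-based within chain
    angles: AnglePair


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: total size (odd) and the flank on each side."""

    size: int = 21

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ValueError(f"window size must be odd and positive, got {self.size}")

    @property
    def flank(self) -> int:
        return (self.size - 1) // 2

    @property
    def n_features(self) -> int:
        return self.size * len(AA_ALPHABET)


@dataclass(frozen=True)
class SplitSpec:
    """Row-level random split fractions and seed."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must be positive and sum to 1, got {self.fractions}")


@dataclass
class EncodedDataset:
    """The encoded table plus its per-row provenance manifest.

    ``features`` is an (n, size*20) uint8 matrix, ``targets`` an (n, 2)
    float array of (phi, psi) in degrees, and ``manifest`` a DataFrame
    with columns chain, position, residue aligned with the rows.
    """

    features: np.ndarray
    targets: np.ndarray
    manifest: pd.DataFrame
    window: WindowConfig = field(default_factory=WindowConfig)

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_columns(self) -> int:
        """Total table width: features plus the two angle targets."""
        return self.features.shape[1] + self.targets.shape[1]

    def to_frame(self) -> pd.DataFrame:
        ncols = self.features.shape[1]
        cols = [f"f{i:03d}" for i in range(ncols)]
        df = pd.DataFrame(self.features, columns=cols)
        df["phi"] = self.targets[:, 0]
        df["psi"] = self.targets[:, 1]
        return df


def filter_chains(
    metadata: Iterable[ChainMetadata], criteria: FilterCriteria = FilterCriteria()
) -> list[ChainMetadata]:
    """Keep chains passing all criteria; first qualifying chain per entry.

    Missing metadata values (``None``) fail the corresponding criterion.
    """
    kept: list[ChainMetadata] = []
    seen_entries: set[str] = set()
    for m in metadata:
        if m.r_free is None or not (m.r_free < criteria.r_free_max):
            continue
        if m.resolution is None or not (m.resolution < criteria.resolution_max):
            continue
        if not (criteria.length_min <= m.length <= criteria.length_max):
            continue
        key = m.pdb_id.upper()
        if criteria.one_chain_per_entry:
            if key in seen_entries:
                continue
            seen_entries.add(key)
        kept.append(m)
    return kept


def read_cull_list(path) -> list[ChainMetadata]:
    """Parse a PISCES-style whitespace-delimited culling list.

    Expected columns: chain id (e.g. ``1ABCA``), length, method,
    resolution, R-factor, R-free; a header line is skipped if present.
    """
    rows: list[ChainMetadata] = []
    text = Path(path).read_text()
    for line in io.StringIO(text):
        parts = line.split()
        if len(parts) < 6 or not parts[1].isdigit():
            continue  # header or malformed line
        ident = parts[0]
        pdb_id, chain_id = ident[:4], ident[4:] or "A"

        def _num(tok: str) -> Optional[float]:
            try:
                return float(tok)
            except ValueError:
                return None

        rows.append(
            ChainMetadata(
                pdb_id=pdb_id,
                chain_id=chain_id,
                resolution=_num(parts[3]),
                r_free=_num(parts[5]),
                length=int(parts[1]),
            )
        )
    return rows


_BACKBONE = ("N", "CA", "C")


def extract_residue_records(path, chain_id: str) -> list[ResidueRecord]:
    """Extract per-residue (phi, psi) from a PDB/mmCIF file.

    Uses the first model and, for alternate conformations, the first
    listed location. phi_i is computed from (C_{i-1}, N_i, CA_i, C_i) and
    psi_i from (N_i, CA_i, C_i, N_{i+1}); the first residue's phi and the
    last residue's psi are undefined. A missing backbone atom or a
    non-canonical residue rejects the chain (:class:`ChainRejected`).
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    if len(structure) == 0:
        raise ChainRejected(f"{path}: no models")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainRejected(f"{path}: chain {chain_id!r} not found")

    codes: list[str] = []
    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    polymer = chain.get_polymer()
    residues = list(polymer) if len(polymer) else list(chain)
    for residue in residues:
        code = THREE_TO_ONE.get(residue.name)
        if code is None:
            raise ChainRejected(f"{path}:{chain_id}: non-canonical residue {residue.name}")
        atoms = []
        for name in _BACKBONE:
            atom = residue.find_atom(name, "*")  # first altloc
            if atom is None:
                raise ChainRejected(
                    f"{path}:{chain_id}: residue {residue.seqid.num} missing backbone atom {name}"
                )
            atoms.append(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
        codes.append(code)
        backbone.append(tuple(atoms))

    records: list[ResidueRecord] = []
    n = len(codes)
    for i in range(n):
        ni, cai, ci = backbone[i]
        phi = psi = None
        if i > 0:
            phi = torsion_angle(backbone[i - 1][2], ni, cai, ci)
        if i < n - 1:
            psi = torsion_angle(ni, cai, ci, backbone[i + 1][0])
        records.append(ResidueRecord(codes[i], i, AnglePair(phi, psi)))
    return records


def encode_window(
    sequence: str, center: int, config: WindowConfig = WindowConfig()
) -> np.ndarray:
    """One-hot encode the window around ``center`` as a uint8 vector.

    Block k (20 columns, alphabetical code order) encodes the residue at
    ``center - flank + k``; offsets outside the chain are virtual
    residues and stay all-zero.
    """
    if not 0 <= center < len(sequence):
        raise IndexError(f"center {center} out of range for length {len(sequence)}")
    vec = np.zeros(config.n_features, dtype=np.uint8)
    for k in range(config.size):
        pos = center - config.flank + k
        if 0 <= pos < len(sequence):
            vec[k * 20 + _AA_INDEX[sequence[pos]]] = 1
    return vec


def encode_sequence(sequence: str, config: WindowConfig = WindowConfig()) -> np.ndarray:
    """Encode every position of a sequence; shape (len, size*20)."""
    return np.stack([encode_window(sequence, i, config) for i in range(len(sequence))])


def build_dataset(
    chains: Sequence[tuple[str, Sequence[ResidueRecord]]],
    config: WindowConfig = WindowConfig(),
) -> EncodedDataset:
    """Encode all residues with both angles defined into one flat table.

    ``chains`` is a sequence of (chain identifier, residue records).
    Chain termini (undefined phi or psi) are dropped, so a chain of
    length L >= 3 contributes L - 2 rows.
    """
    feats: list[np.ndarray] = []
    targets: list[tuple[float, float]] = []
    manifest_rows: list[tuple[str, int, str]] = []
    for chain_id, records in chains:
        sequence = "".join(r.code for r in records)
        for r in records:
            if r.angles.phi is None or r.angles.psi is None:
                continue
            feats.append(encode_window(sequence, r.position, config))
            targets.append((r.angles.phi, r.angles.psi))
            manifest_rows.append((chain_id, r.position, r.code))
    if not feats:
        import warnings

        warnings.warn("no encodable residues; dataset is empty", stacklevel=2)
        features = np.zeros((0, config.n_features), dtype=np.uint8)
        target_arr = np.zeros((0, 2), dtype=float)
    else:
        features = np.stack(feats)
        target_arr = np.asarray(targets, dtype=float)
    manifest = pd.DataFrame(manifest_rows, columns=["chain", "position", "residue"])
    return EncodedDataset(features, target_arr, manifest, config)


def split_dataset(
    dataset: EncodedDataset, spec: SplitSpec = SplitSpec()
) -> tuple[EncodedDataset, EncodedDataset, EncodedDataset]:
    """Seeded row-level random split into (train, validation, test).

    The split is uniform over rows, so windows from one chain may land in
    different partitions — appropriate for i.i.d.-style evaluation, not
    for homology-aware benchmarking.
    """
    n = len(dataset)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = round(n * spec.fractions[0])
    n_val = round(n * spec.fractions[1])
    idx = (perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :])

    def _take(i: np.ndarray) -> EncodedDataset:
        return EncodedDataset(
            dataset.features[i],
            dataset.targets[i],
            dataset.manifest.iloc[i].reset_index(drop=True),
            dataset.window,
        )

    return _take(idx[0]), _take(idx[1]), _take(idx[2])


def save_dataset(dataset: EncodedDataset, path, manifest_path=None) -> None:
    """Write the encoded table as CSV (f000..fNNN, phi, psi) and the
    manifest as TSV next to it (``<path>.manifest.tsv`` by default)."""
    path = Path(path)
    dataset.to_frame().to_csv(path, index=False)
    mpath = Path(manifest_path) if manifest_path else path.with_suffix(path.suffix + ".manifest.tsv")
    dataset.manifest.to_csv(mpath, sep="\t", index=False)


def load_dataset(path, manifest_path=None) -> EncodedDataset:
    """Read a dataset written by :func:`save_dataset`."""
    path = Path(path)
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    features = df[feat_cols].to_numpy(dtype=np.uint8)
    targets = df[["phi", "psi"]].to_numpy(dtype=float)
    mpath = Path(manifest_path) if manifest_path else path.with_suffix(path.suffix + ".manifest.tsv")
    if mpath.exists():
        manifest = pd.read_csv(mpath, sep="\t")
    else:
        manifest = pd.DataFrame({"chain": "?", "position": np.arange(len(df)), "residue": "?"})
    size = len(feat_cols) // 20
    return EncodedDataset(features, targets, manifest, WindowConfig(size))
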