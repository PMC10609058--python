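"""Chain filtering, window encoding, dataset assembly and splitting."""

import numpy as np
import pytest

from phipsinet import dataset as ds
from phipsinet import synthetic as syn
from phipsinet.geometry import AnglePair, absolute_angular_error


def make_meta(pdb="1ABC", chain="A", resolution=2.0, r_free=0.20, length=100):
    return ds.ChainMetadata(pdb, chain, resolution, r_free, length)


class TestFilterChains:
    def test_passing_chain_kept(self):
        assert ds.filter_chains([make_meta()]) == [make_meta()]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length": 39},           # below the 40-residue minimum
            {"length": 10001},
            {"resolution": 2.5},      # boundary excluded: strict < 2.5
            {"r_free": 0.25},         # strict < 0.25
            {"r_free": None},         # missing metadata fails the filter
            {"resolution": None},
        ],
    )
    def test_exclusions(self, kwargs):
        assert ds.filter_chains([make_meta(**kwargs)]) == []

    def test_length_boundaries_inclusive(self):
        assert len(ds.filter_chains([make_meta(length=40), make_meta(pdb="2XYZ", length=10000)])) == 2

    def test_one_chain_per_entry_keeps_first(self):
        first = make_meta(chain="A")
        second = make_meta(chain="B")
        assert ds.filter_chains([first, second]) == [first]


class TestCullList:
    def test_parse_pisces_style(self, tmp_path):
        text = (
            "PDBchain length method resolution rfactor rfree\n"
            "1ABCA 120 XRAY 1.90 0.18 0.21\n"
            "2DEFB 85 XRAY 2.70 0.20 0.24\n"
        )
        path = tmp_path / "cull.txt"
        path.write_text(text)
        rows = ds.read_cull_list(path)
        assert [(m.pdb_id, m.chain_id, m.length) for m in rows] == [
            ("1ABC", "A", 120),
            ("2DEF", "B", 85),
        ]
        assert rows[0].resolution == pytest.approx(1.90)
        assert rows[1].r_free == pytest.approx(0.24)


class TestEncodeWindow:
    def test_leading_virtual_positions_zero(self):
        seq = "A" * 30
        vec = ds.encode_window(seq, 0)
        assert vec.sum() == 11  # 10 virtual positions before the start
        assert len(vec) == 420

    def test_interior_window_full(self):
        vec = ds.encode_window("ACDEFGHIKLMNPQRSTVWYA" * 3, 30)
        assert vec.sum() == 21

    def test_block_structure(self):
        vec = ds.encode_window("AC", 0, ds.WindowConfig(3))
        # block 0 virtual, block 1 = A (col 0), block 2 = C (col 1)
        assert vec[:20].sum() == 0
        assert vec[20] == 1 and vec[20:40].sum() == 1
        assert vec[41] == 1 and vec[40:60].sum() == 1

    def test_center_out_of_range(self):
        with pytest.raises(IndexError):
            ds.encode_window("ACD", 3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ds.WindowConfig(20)


def synthetic_records(n_chains=10, length=52, seed=0):
    chains = syn.generate_chains(
        syn.GeneratorSpec(n_chains=n_chains, length_range=(length, length), seed=seed)
    )
    return syn.chains_to_records(chains)


class TestBuildDataset:
    def test_row_count_drops_termini(self):
        dataset = ds.build_dataset(synthetic_records(10, 52))
        assert len(dataset) == 10 * (52 - 2)

    def test_column_count(self):
        dataset = ds.build_dataset(synthetic_records(2, 10))
        assert dataset.n_columns == 422
        assert dataset.to_frame().shape[1] == 422

    def test_row_invariants_hold_everywhere(self):
        dataset = ds.build_dataset(synthetic_records(5, 30))
        blocks = dataset.features.reshape(len(dataset), 21, 20)
        per_block = blocks.sum(axis=2)
        assert (per_block <= 1).all()
        # centre block always in-chain
        assert (per_block[:, 10] == 1).all()
        assert np.isfinite(dataset.targets).all()

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            dataset = ds.build_dataset([])
        assert len(dataset) == 0


class TestSplitDataset:
    def test_fraction_sizes(self):
        dataset = syn.deterministic_toy_dataset(1000, seed=1)
        tr, va, te = ds.split_dataset(dataset, ds.SplitSpec(seed=4))
        assert (len(tr), len(va), len(te)) == (800, 100, 100)

    def test_deterministic_and_partition(self):
        dataset = syn.deterministic_toy_dataset(500, seed=1)
        a = ds.split_dataset(dataset, ds.SplitSpec(seed=9))
        b = ds.split_dataset(dataset, ds.SplitSpec(seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.features, y.features)
        # disjoint and exhaustive at the row level
        keys = [tuple(r) for part in a for r in part.manifest.itertuples(index=False)]
        all_keys = [tuple(r) for r in dataset.manifest.itertuples(index=False)]
        assert sorted(keys) == sorted(all_keys)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            ds.SplitSpec(fractions=(0.5, 0.2, 0.2))


class TestExtraction:
    def test_round_trip_through_structure_files(self, tmp_path, markov_chains):
        chains = markov_chains[:8]
        paths = syn.chains_to_structures(chains, tmp_path, fmt="cif")
        worst = 0.0
        for path, chain in zip(paths, chains):
            records = ds.extract_residue_records(path, "A")
            assert "".join(r.code for r in records) == chain.sequence
            assert records[0].angles.phi is None
            assert records[-1].angles.psi is None
            for rec, ref in zip(records, chain.angles):
                for got, want in ((rec.angles.phi, ref.phi), (rec.angles.psi, ref.psi)):
                    if want is not None:
                        worst = max(worst, float(absolute_angular_error(got, want)))
        assert worst < 1e-3

    def test_single_residue_chain_has_no_usable_row(self):
        records = [ds.ResidueRecord("A", 0, AnglePair(None, None))]
        with pytest.warns(UserWarning):
            dataset = ds.build_dataset([("X", records)])
        assert len(dataset) == 0

    def test_non_canonical_residue_rejected(self, tmp_path):
        spec = syn.GeneratorSpec(n_chains=1, length_range=(10, 10), seed=3,
                                 residue_freqs={"A": 1.0})
        (path,) = syn.chains_to_structures(syn.generate_chains(spec), tmp_path)
        mutated = path.read_text().replace("ALA A   5", "MSE A   5")
        bad = tmp_path / "bad.pdb"
        bad.write_text(mutated)
        with pytest.raises(ds.ChainRejected, match="non-canonical"):
            ds.extract_residue_records(bad, "A")

    def test_missing_backbone_atom_rejects_chain(self, tmp_path):
        spec = syn.GeneratorSpec(n_chains=1, length_range=(10, 10), seed=3)
        (path,) = syn.chains_to_structures(syn.generate_chains(spec), tmp_path)
        lines = [
            l for l in path.read_text().splitlines()
            if not (l.startswith("ATOM") and " CA " in l and " 5 " in l.ljust(80)[22:30])
        ]
        bad = tmp_path / "missing.pdb"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(ds.ChainRejected, match="missing backbone"):
            ds.extract_residue_records(bad, "A")

    def test_absent_chain_rejected(self, tmp_path, markov_chains):
        (path,) = syn.chains_to_structures(markov_chains[:1], tmp_path)
        with pytest.raises(ds.ChainRejected):
            ds.extract_residue_records(path, "Z")
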