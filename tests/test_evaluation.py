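"""Q3 assignment, confusion matrices, per-residue MAE, histograms."""

import numpy as np
import pandas as pd
import pytest

from phipsinet import evaluation as ev
from phipsinet import model as md
from phipsinet import synthetic as syn

# Published three-state confusion counts (helix/sheet/undesignated real
# rows vs predicted columns) used as fixed inputs for the arithmetic.
PUBLISHED_COUNTS = np.array(
    [
        [141380, 30837, 20908],
        [33535, 166673, 25300],
        [23151, 22905, 39335],
    ]
)


def published_cm() -> pd.DataFrame:
    return pd.DataFrame(PUBLISHED_COUNTS, index=list(ev.LABELS), columns=list(ev.LABELS))


class TestAssignQ3:
    @pytest.mark.parametrize(
        "phi,psi,label",
        [
            (-60.0, -45.0, "helix"),
            (-120.0, 135.0, "sheet"),
            (60.0, 45.0, "undesignated"),  # left-handed helix region, phi >= 0
            (-100.0, -150.0, "sheet"),     # lower beta band
            (-179.9, 44.9, "helix"),       # half-open boundary below psi = 45
            (-179.9, 45.0, "sheet"),
        ],
    )
    def test_default_region_examples(self, phi, psi, label):
        assert ev.assign_q3(phi, psi)[0] == label

    def test_total_and_single_label_on_grid(self, rng):
        phi = rng.uniform(-180, 180, 5000)
        psi = rng.uniform(-180, 180, 5000)
        labels = ev.assign_q3(phi, psi)
        assert set(labels) <= set(ev.LABELS)
        regions = ev.Q3Regions()
        helix_hit = ev._in_rects(phi, psi, regions.helix)
        sheet_hit = ev._in_rects(phi, psi, regions.sheet)
        assert not (helix_hit & sheet_hit).any()


class TestConfusionMatrix:
    def test_identical_lists_give_diagonal(self):
        labels = ["helix"] * 5 + ["sheet"] * 3 + ["undesignated"] * 2
        cm = ev.confusion_matrix(labels, labels)
        assert np.trace(cm.to_numpy()) == 10
        assert cm.to_numpy().sum() == 10

    def test_shuffling_both_lists_preserves_counts(self, rng):
        real = rng.choice(ev.LABELS, 200)
        pred = rng.choice(ev.LABELS, 200)
        perm = rng.permutation(200)
        pd.testing.assert_frame_equal(
            ev.confusion_matrix(real, pred), ev.confusion_matrix(real[perm], pred[perm])
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_matrix(["helix"], ["helix", "sheet"])


class TestPublishedTableArithmetic:
    def test_overall_accuracy(self):
        assert ev.overall_accuracy(published_cm()) == pytest.approx(68.9, abs=0.05)

    def test_total_and_trace(self):
        cm = published_cm()
        assert cm.to_numpy().sum() == 504_024
        assert np.trace(cm.to_numpy()) == 347_388

    def test_row_percentages_match_published(self):
        pct = ev.row_percentages(published_cm())
        assert pct.loc["helix", "helix"] == pytest.approx(73.2, abs=0.05)
        assert pct.loc["helix", "sheet"] == pytest.approx(16.0, abs=0.05)
        assert pct.loc["helix", "undesignated"] == pytest.approx(10.8, abs=0.05)
        assert pct.loc["sheet", "helix"] == pytest.approx(14.9, abs=0.05)
        assert pct.loc["sheet", "sheet"] == pytest.approx(73.9, abs=0.05)
        assert pct.loc["sheet", "undesignated"] == pytest.approx(11.2, abs=0.05)
        assert pct.loc["undesignated", "undesignated"] == pytest.approx(46.1, abs=0.05)

    def test_real_class_prevalences(self):
        cm = published_cm()
        total = cm.to_numpy().sum()
        assert 100 * cm.loc["sheet"].sum() / total == pytest.approx(44.7, abs=0.05)
        assert 100 * cm.loc["undesignated"].sum() / total == pytest.approx(16.9, abs=0.05)

    def test_degenerate_matrices(self):
        diag = pd.DataFrame(np.diag([5, 5, 5]), index=list(ev.LABELS), columns=list(ev.LABELS))
        assert ev.overall_accuracy(diag) == 100.0
        off = pd.DataFrame(
            [[0, 5, 0], [5, 0, 0], [0, 5, 0]], index=list(ev.LABELS), columns=list(ev.LABELS)
        )
        assert ev.overall_accuracy(off) == 0.0

    def test_uniform_row_percentages(self):
        cm = pd.DataFrame(np.full((3, 3), 7), index=list(ev.LABELS), columns=list(ev.LABELS))
        assert np.allclose(ev.row_percentages(cm).to_numpy(), 100 / 3)


class TestPerResidueMae:
    def test_constant_error_recovered(self):
        residues = np.array(["A"] * 10)
        measured = np.zeros((10, 2))
        predicted = np.full((10, 2), 25.0)
        summary = ev.per_residue_mae(residues, measured, predicted)
        assert summary.loc["A", "mae_phi"] == pytest.approx(25.0)
        assert summary.loc["A", "mae_psi"] == pytest.approx(25.0)

    def test_counts_conserved_and_proline_phi_tightest(self, markov_chains):
        residues, measured = [], []
        for chain in markov_chains:
            for code, pair in zip(chain.sequence, chain.angles):
                if pair.phi is not None and pair.psi is not None:
                    residues.append(code)
                    measured.append([pair.phi, pair.psi])
        residues = np.array(residues)
        measured = np.array(measured)
        predicted = np.zeros_like(measured)
        summary = ev.per_residue_mae(residues, measured, predicted)
        assert summary["count"].sum() == len(residues)
        assert summary["sd_phi"].idxmin() == "P"


class TestErrorHistogram:
    def test_zero_errors_fill_first_bin(self):
        hist = ev.error_histogram(np.zeros(100))
        assert hist["counts"][0] == 100
        assert hist["counts"][1:].sum() == 0
        assert hist["frac_under_20"] == 1.0

    def test_uniform_errors_fraction_under_twenty(self, rng):
        errors = rng.uniform(0, 180, 10**6)
        hist = ev.error_histogram(errors)
        assert hist["frac_under_20"] == pytest.approx(20 / 180, abs=0.002)
        assert hist["fractions"].sum() == pytest.approx(1.0)

    def test_bin_totals_equal_input_count(self, rng):
        errors = rng.uniform(0, 180, 5000)
        hist = ev.error_histogram(errors)
        assert hist["counts"].sum() == 5000
        assert len(hist["counts"]) == 180

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.error_histogram(np.array([-1.0]))


class TestChainFoldClassing:
    def test_thresholds(self):
        assert ev.classify_chain_fold(["helix"] * 7 + ["sheet"] * 3) == "all-alpha"
        assert ev.classify_chain_fold(["sheet"] * 9 + ["helix"]) == "all-beta"
        assert ev.classify_chain_fold(["helix", "sheet", "undesignated"]) == "mixed"


class TestWindowSweep:
    def _records(self):
        chains = syn.generate_chains(
            syn.GeneratorSpec(n_chains=20, length_range=(40, 60), seed=17)
        )
        return syn.chains_to_records(chains)

    def test_single_size_single_row(self):
        tc = md.TrainingConfig(batch_size=128, max_epochs=3, seed=17)
        table = ev.window_sweep(self._records(), sizes=(5,), hidden_widths=(16,), tc=tc, seed=17)
        assert list(table["size"]) == [5]
        assert table.shape == (1, 3)

    def test_deterministic_given_seed(self):
        tc = md.TrainingConfig(batch_size=128, max_epochs=3, seed=17)
        a = ev.window_sweep(self._records(), sizes=(3,), hidden_widths=(16,), tc=tc, seed=17)
        b = ev.window_sweep(self._records(), sizes=(3,), hidden_widths=(16,), tc=tc, seed=17)
        pd.testing.assert_frame_equal(a, b)

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            ev.window_sweep(self._records(), sizes=(4,))
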