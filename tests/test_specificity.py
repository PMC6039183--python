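"""Bead-panel normalization, motif scanning and bead-vs-cell regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hlabquant import cohort, specificity
from hlabquant.exceptions import InsufficientDataError, ScanError

MOTIFS = specificity.load_motif_table()
BW6_WINDOW = "SLRNLRG"
BW4_WINDOW = "NLRIALR"


def make_sequence(window, offset=0):
    return "A" * (76 + offset) + window + "Q" * 20


def brute_force_scan(sequence, motifs, offset=0):
    """Enumerate the window against every constraint (independent oracle)."""
    window = sequence[76 + offset: 83 + offset].upper()
    for name, constraints in motifs.motifs.items():
        hit = True
        for pos, residues in constraints.items():
            if window[pos - 77] not in residues:
                hit = False
                break
        if hit:
            return name
    return "none"


class TestNormalizePanel:
    def _panel(self, rows):
        return pd.DataFrame(rows)

    def test_equal_test_and_reference_gives_one(self):
        panel = self._panel([{"bead": "b1", "allele": "B*07:02",
                              "test_mfi": 500.0, "ref_mfi": 500.0,
                              "dilution": "1:50", "replicate": 1}])
        out = specificity.normalize_panel(panel)
        assert out["ratio"].iloc[0] == 1.0

    def test_zero_test_signal_gives_zero(self):
        panel = self._panel([{"bead": "b1", "allele": "A*01:01",
                              "test_mfi": 0.0, "ref_mfi": 800.0,
                              "dilution": "1:50", "replicate": 1}])
        assert specificity.normalize_panel(panel)["ratio"].iloc[0] == 0.0

    def test_replicate_mean_and_sd(self):
        rows = [{"bead": "b1", "allele": "B*07:02", "test_mfi": r * 1000.0,
                 "ref_mfi": 1000.0, "dilution": "1:50", "replicate": i}
                for i, r in enumerate([0.8, 1.0, 1.2])]
        out = specificity.normalize_panel(self._panel(rows))
        assert out["ratio"].iloc[0] == pytest.approx(1.0)
        assert out["ratio_sd"].iloc[0] == pytest.approx(
            np.std([0.8, 1.0, 1.2], ddof=1))

    def test_zero_reference_excluded_with_warning(self):
        rows = [{"bead": "b1", "allele": "x", "test_mfi": 1.0,
                 "ref_mfi": 0.0, "dilution": "1:50", "replicate": 1},
                {"bead": "b2", "allele": "y", "test_mfi": 1.0,
                 "ref_mfi": 2.0, "dilution": "1:50", "replicate": 1}]
        with pytest.warns(UserWarning):
            out = specificity.normalize_panel(self._panel(rows))
        assert out["allele"].tolist() == ["y"]

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance_per_bead(self, c):
        base = self._panel([{"bead": "b1", "allele": "B*07:02",
                             "test_mfi": 750.0, "ref_mfi": 1500.0,
                             "dilution": "1:50", "replicate": 1}])
        scaled = base.assign(test_mfi=base["test_mfi"] * c,
                             ref_mfi=base["ref_mfi"] * c)
        r0 = specificity.normalize_panel(base)["ratio"].iloc[0]
        r1 = specificity.normalize_panel(scaled)["ratio"].iloc[0]
        assert r1 == pytest.approx(r0, rel=1e-12)


class TestMotifScan:
    def test_canonical_windows(self):
        assert specificity.scan_epitope_motif(
            make_sequence(BW6_WINDOW), MOTIFS) == "Bw6"
        assert specificity.scan_epitope_motif(
            make_sequence(BW4_WINDOW), MOTIFS) == "Bw4"

    def test_single_position_violation_gives_none(self):
        # position 80: N -> K breaks Bw6, matches nothing
        window = BW6_WINDOW[:3] + "K" + BW6_WINDOW[4:]
        assert specificity.scan_epitope_motif(
            make_sequence(window), MOTIFS) == "none"

    def test_precursor_offset(self):
        seq = make_sequence(BW6_WINDOW, offset=24)
        assert specificity.scan_epitope_motif(seq, MOTIFS, offset=24) == "Bw6"

    def test_short_sequence_rejected(self):
        with pytest.raises(ScanError):
            specificity.scan_epitope_motif("ACDE", MOTIFS)

    def test_nonstandard_residue_rejected(self):
        seq = make_sequence("SLRXLRG")
        with pytest.raises(ScanError):
            specificity.scan_epitope_motif(seq, MOTIFS)

    def test_agrees_with_brute_force_on_random_sequences(self, rng):
        aa = list(cohort.AMINO_ACIDS)
        canonical = ["SLRNLRG", "NLRIALR"]
        for _ in range(2000):
            if rng.random() < 0.5:
                # mutate up to two positions of a canonical window
                w = list(canonical[rng.integers(2)])
                for pos in rng.choice(7, size=rng.integers(0, 3),
                                      replace=False):
                    w[pos] = aa[rng.integers(20)]
                window = "".join(w)
            else:
                window = "".join(rng.choice(aa, 7))
            seq = make_sequence(window)
            assert specificity.scan_epitope_motif(seq, MOTIFS) == \
                brute_force_scan(seq, MOTIFS)


class TestCrossReactivity:
    def _binding(self):
        return pd.DataFrame({"allele": ["A*23:01", "A*01:01", "A*24:02"],
                             "ratio": [0.5, 0.0, 0.2]})

    def test_threshold_inclusive_and_zero_negative(self):
        out = specificity.classify_cross_reactivity(
            ["A*23:01", "A*01:01", "A*24:02"], self._binding(),
            threshold=0.2).set_index("allele")
        assert out.loc["A*23:01", "status"] == "cross_reactive"
        assert out.loc["A*24:02", "status"] == "cross_reactive"  # == cut
        assert out.loc["A*01:01", "status"] == "negative"

    def test_absent_allele_unknown_not_negative(self):
        out = specificity.classify_cross_reactivity(
            ["A*32:01"], self._binding(), threshold=0.2)
        assert out["status"].iloc[0] == "unknown"

    def test_designed_panel_flags_exactly_the_reactive_set(self):
        ratios = {f"A*{i:02d}:01": 0.0 for i in range(1, 11)}
        reactive = ["A*23:01", "A*24:02", "A*24:03", "A*25:01", "A*32:01"]
        ratios.update({a: 0.6 for a in reactive})
        panel = cohort.simulate_luminex_panel(ratios, noise_cv=0.05, seed=3)
        binding = specificity.normalize_panel(panel)
        out = specificity.classify_cross_reactivity(
            list(ratios), binding, threshold=0.3)
        flagged = set(out[out["status"] == "cross_reactive"]["allele"])
        assert flagged == set(reactive)


class TestBeadCellRegression:
    def _tables(self, deviant=None, seed=0):
        rng = np.random.default_rng(seed)
        ratios = {"B*57:01": 1.4, "B*27:05": 1.1, "B*51:01": 0.9,
                  "B*37:01": 0.6, "B*13:02": 0.6, "B*44:02": 0.4}
        binding = pd.DataFrame({"allele": list(ratios),
                                "ratio": list(ratios.values())})
        rows = []
        for allele, r in ratios.items():
            scale = 0.6 if allele == deviant else 1.0
            for d in range(6):
                noise = rng.lognormal(0, 0.05) if deviant else 1.0
                rows.append({"donor": f"{allele}|D{d}", "allele": allele,
                             "subset": "CD4T",
                             "mean_abc": 30_000.0 * r * scale * noise})
        return binding, pd.DataFrame(rows)

    def test_proportional_data_perfect_fit_no_flags(self):
        binding, abc = self._tables()
        res = specificity.bead_vs_cell_regression(binding, abc, "CD4T")
        assert res.r == pytest.approx(1.0)
        assert res.below_line_alleles == []

    def test_shifted_allele_flagged(self):
        binding, abc = self._tables(deviant="B*51:01", seed=4)
        res = specificity.bead_vs_cell_regression(binding, abc, "CD4T")
        assert res.below_line_alleles == ["B*51:01"]

    def test_matches_closed_form_ols(self, rng):
        binding, abc = self._tables(deviant="B*51:01", seed=8)
        res = specificity.bead_vs_cell_regression(binding, abc, "CD4T")
        merged = abc.merge(binding, on="allele")
        x = merged["ratio"].to_numpy()
        y = merged["mean_abc"].to_numpy()
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        assert res.slope == pytest.approx(slope, rel=1e-9)
        assert res.intercept == pytest.approx(y.mean() - slope * x.mean(),
                                              rel=1e-9)

    def test_row_order_invariance(self):
        binding, abc = self._tables(deviant="B*51:01", seed=4)
        res1 = specificity.bead_vs_cell_regression(binding, abc, "CD4T")
        shuffled = abc.sample(frac=1.0, random_state=1)
        res2 = specificity.bead_vs_cell_regression(binding, shuffled, "CD4T")
        assert res2.below_line_alleles == res1.below_line_alleles
        assert res2.slope == pytest.approx(res1.slope)

    def test_insufficient_alleles_rejected(self):
        binding, abc = self._tables()
        two = abc[abc["allele"].isin(["B*57:01", "B*27:05"])]
        with pytest.raises(InsufficientDataError):
            specificity.bead_vs_cell_regression(binding, two, "CD4T")
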