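"""Electron ledgers, baseline correction and treatment-group statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilredox.budget import (
    BaselineError,
    ElectronLedger,
    IncubationEndpoint,
    TreatmentLabel,
    abiotic_baseline,
    compact_letter_display,
    compute_ledger,
    compute_ledgers,
    ledgers_to_frame,
    summarize_groups,
)
from soilredox.stoichiometry import BottleGeometry


def ep(group="biotic", amendment="control", rep=1, **kw):
    defaults = dict(fe2=5.0, sulfate=0.74, ch4=0.0, pcp=10.0)
    defaults.update(kw)
    return IncubationEndpoint(TreatmentLabel(group, amendment, rep), **defaults)


BASE = {"fe2": 5.0, "sulfate": 0.74}


class TestBaseline:
    def test_pooled_mean_of_sterile_extremes(self):
        eps = [
            ep("sterile_abiotic", "control", 1, fe2=4.4),
            ep("sterile_abiotic", "biochar", 1, fe2=6.8),
        ]
        assert abiotic_baseline(eps, "fe2", "pooled") == pytest.approx(5.6)

    def test_single_sterile_bottle(self):
        eps = [ep("sterile_abiotic", "control", 1, fe2=4.9)]
        assert abiotic_baseline(eps, "fe2", "matched", "control") == 4.9

    def test_matched_falls_back_to_pooled(self, caplog):
        eps = [ep("sterile_abiotic", "control", 1, fe2=4.0),
               ep("sterile_abiotic", "control", 2, fe2=6.0)]
        with caplog.at_level("WARNING"):
            v = abiotic_baseline(eps, "fe2", "matched", "biochar")
        assert v == pytest.approx(5.0)
        assert "pooled" in caplog.text

    def test_no_sterile_bottles(self):
        with pytest.raises(BaselineError):
            abiotic_baseline([ep("biotic")], "fe2", "pooled")


class TestLedger:
    def test_sulfate_drop_matches_reported_budget(self):
        # 0.74 -> 0.34 mg/g over 15 g soil at 8 e-/mol lands on ~500 umol,
        # within 0.5% of the reported 501.
        led = compute_ledger(ep(sulfate=0.34), BASE)
        assert led.e_so4 == pytest.approx(501.0, rel=0.005)

    def test_all_at_baseline_is_zero(self):
        led = compute_ledger(ep(), BASE)
        assert (led.e_fe, led.e_so4, led.e_dechlor, led.e_ch4) == (0, 0, 0, 0)
        assert led.e_total == 0

    def test_dechlorination_from_products(self):
        led = compute_ledger(ep(tecp=10.0, tcp=0.5), BASE)
        expected = 2 * (150 / 231.89) + 4 * (7.5 / 197.45)
        assert led.e_dechlor == pytest.approx(expected, rel=1e-9)
        assert led.e_dechlor == pytest.approx(1.446, abs=0.001)

    def test_missing_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            compute_ledger(ep(), {"fe2": 5.0})

    def test_negative_delta_clips_to_zero(self, caplog):
        with caplog.at_level("WARNING"):
            led = compute_ledger(ep(fe2=4.0, sulfate=0.90), BASE)
        assert led.e_fe == 0.0
        assert led.e_so4 == 0.0
        assert "clipping" in caplog.text

    def test_conservation(self):
        led = compute_ledger(ep(fe2=9.0, sulfate=0.40, ch4=150.0, tecp=8.0), BASE)
        assert led.e_total == pytest.approx(
            led.e_fe + led.e_so4 + led.e_dechlor + led.e_ch4, rel=1e-12
        )

    def test_linearity_in_deltas(self):
        one = compute_ledger(ep(fe2=6.0, sulfate=0.64, ch4=50.0, tecp=2.0), BASE)
        two = compute_ledger(ep(fe2=7.0, sulfate=0.54, ch4=100.0, tecp=4.0), BASE)
        for attr in ("e_fe", "e_so4", "e_ch4", "e_dechlor"):
            assert getattr(two, attr) == pytest.approx(
                2 * getattr(one, attr), rel=1e-9
            )

    def test_clipping_monotonicity(self):
        values = [3.0, 4.5, 5.0, 5.5, 8.0]
        efes = [compute_ledger(ep(fe2=v), BASE).e_fe for v in values]
        assert efes == sorted(efes)

    def test_compute_ledgers_uses_matched_baselines(self):
        eps = [
            ep("sterile_abiotic", "control", 1, fe2=4.4, sulfate=0.74),
            ep("sterile_abiotic", "biochar", 1, fe2=6.8, sulfate=0.74),
            ep("biotic", "control", 1, fe2=9.4),
            ep("biotic", "biochar", 1, fe2=9.4),
        ]
        ledgers = compute_ledgers(eps)
        by_am = {l.label.amendment: l for l in ledgers}
        # same measured Fe(II), different sterile baselines
        assert by_am["control"].e_fe > by_am["biochar"].e_fe


class TestGroupSummary:
    @staticmethod
    def frame(groups):
        rows = []
        for am, values in groups.items():
            for i, v in enumerate(values, 1):
                rows.append({"group": "biotic", "amendment": am,
                             "replicate": i, "y": v})
        return pd.DataFrame(rows)

    def test_identical_groups_share_one_letter(self):
        df = self.frame({"control": [5, 5, 5], "AQDS": [5, 5, 5],
                         "biochar": [5, 5, 5]})
        out = summarize_groups(df, ["y"])
        assert out["letters"].eq("a").all()
        assert out["anova_F"].isna().all()

    def test_three_separated_groups_get_three_letters(self):
        df = self.frame({"control": [1, 1.1, 0.9], "AQDS": [10, 10.1, 9.9],
                         "biochar": [20, 20.1, 19.9]})
        out = summarize_groups(df, ["y"])
        assert set(out["letters"]) == {"a", "b", "c"}
        # 'a' goes to the largest mean
        assert out.loc[out["amendment"] == "biochar", "letters"].item() == "a"

    def test_letters_agree_with_pairwise_tukey(self, rng):
        # randomized fixtures: sharing a letter <=> Tukey p >= 0.05
        for _ in range(20):
            shift = rng.choice([0.0, 3.0], size=3)
            data = {am: rng.normal(shift[k], 1.0, 4).tolist()
                    for k, am in enumerate(["control", "AQDS", "biochar"])}
            out = summarize_groups(self.frame(data), ["y"])
            letters = dict(zip(out["amendment"], out["letters"]))
            res = stats.tukey_hsd(*[np.asarray(data[a])
                                    for a in ["control", "AQDS", "biochar"]])
            for (i, a), (j, b) in itertools.combinations(
                enumerate(["control", "AQDS", "biochar"]), 2
            ):
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (res.pvalue[i, j] >= 0.05)

    def test_single_replicate_cell_suppresses_statistics(self):
        df = self.frame({"control": [1.0], "AQDS": [2.0, 2.1], "biochar": [3.0, 3.1]})
        out = summarize_groups(df, ["y"])
        assert out["anova_F"].isna().all()
        assert np.isnan(out.loc[out["amendment"] == "control", "sd"].item())


class TestCompactLetterDisplay:
    def test_chain_yields_overlapping_letters(self):
        # A~B and B~C but A!~C: classic 'a', 'ab', 'b'
        letters = compact_letter_display(
            ["A", "B", "C"],
            {"A": 3.0, "B": 2.0, "C": 1.0},
            {("A", "B"): 0.3, ("B", "C"): 0.3, ("A", "C"): 0.01},
        )
        assert letters == {"A": "a", "B": "ab", "C": "b"}

    def test_disjoint_letters_only_for_significant_pairs(self):
        letters = compact_letter_display(
            ["A", "B"], {"A": 2.0, "B": 1.0}, {("A", "B"): 0.04}
        )
        assert not set(letters["A"]) & set(letters["B"])
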