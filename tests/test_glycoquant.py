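"""Glycan classifier, microheterogeneity, differential/specific calling, FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from glycoimmune.glycomodel import (
    GlycanComposition,
    GlycoPeptideRecord,
    QuantMatrix,
    parse_composition,
)
from glycoimmune import glycoquant as gq

SAMPLES = [f"RA_{i}" for i in range(1, 5)] + [f"OA_{i}" for i in range(1, 5)]
GROUPS = pd.Series(["RA_like"] * 4 + ["OA_like"] * 4, index=SAMPLES)


def _rec(protein, site, comp, values=None, peptide="AANGTAA"):
    intens = pd.Series(values if values is not None else [1.0] * 8,
                       index=SAMPLES, dtype=float)
    return GlycoPeptideRecord(protein, peptide, site,
                              parse_composition(comp), intens)


class TestClassifyGlycan:
    @pytest.mark.parametrize(
        "comp,expected",
        [
            ("HexNAc(2)Hex(9)", "high_mannose"),
            ("HexNAc(4)Hex(5)Fuc(1)NeuAc(2)", "fucosylated_sialylated"),
            ("HexNAc(2)Hex(3)", "paucimannose"),
            ("HexNAc(2)Hex(5)Fuc(1)", "fucosylated"),
            ("HexNAc(4)Hex(5)NeuAc(1)", "sialylated"),
            ("HexNAc(5)Hex(4)", "complex_hybrid"),
            ("HexNAc(1)Hex(1)", "paucimannose"),
        ],
    )
    def test_decision_table(self, comp, expected):
        assert gq.classify_glycan(parse_composition(comp)) == expected

    def test_exhaustive_single_label(self):
        """Every composition with counts <= 8 gets exactly one class, and the
        label agrees with an independently re-coded decision table."""
        n = 0
        for hexnac, hx, fuc, neuac in itertools.product(range(9), repeat=4):
            if hexnac + hx + fuc + neuac == 0:
                continue
            n += 1
            comp = GlycanComposition(hexnac, hx, fuc, neuac)
            got = gq.classify_glycan(comp)
            assert got in gq.GLYCAN_CLASSES
            if fuc and neuac:
                want = "fucosylated_sialylated"
            elif neuac:
                want = "sialylated"
            elif fuc:
                want = "fucosylated"
            elif hexnac <= 2 and hx <= 3:
                want = "paucimannose"
            elif hexnac == 2:
                want = "high_mannose"
            else:
                want = "complex_hybrid"
            assert got == want
        assert n == 9**4 - 1

    def test_overlapping_flags_include_decorated_cores(self):
        flags = gq.glycan_class_flags(parse_composition("HexNAc(2)Hex(5)Fuc(1)"))
        assert flags["fucosylated"] and flags["high_mannose"]
        assert not flags["sialylated"]


class TestMicroheterogeneity:
    def test_single_site_three_glycans(self):
        recs = [_rec("P1", 3, c) for c in
                ["HexNAc(2)Hex(5)", "HexNAc(2)Hex(6)", "HexNAc(4)Hex(5)"]]
        res = gq.microheterogeneity(recs)
        assert res["sites_per_protein"].to_dict() == {1: 1.0}
        assert res["glycans_per_site"].to_dict() == {3: 1.0}

    def test_two_proteins(self):
        recs = [_rec("P1", 3, "Hex(5)")] + [
            _rec("P2", s, "Hex(5)") for s in (3, 10, 20)
        ]
        res = gq.microheterogeneity(recs)
        assert res["sites_per_protein"].to_dict() == {1: 0.5, 3: 0.5}

    def test_class_share_counts_sites_per_class(self):
        recs = [_rec("P1", 3, "HexNAc(2)Hex(9)"), _rec("P1", 3, "HexNAc(5)Hex(5)")]
        share = gq.microheterogeneity(recs)["class_share_per_site"]
        assert share["high_mannose"] == 1.0 and share["complex_hybrid"] == 1.0

    def test_recovers_planted_distributions(self, small_bundle):
        cfg = small_bundle.config
        res = gq.microheterogeneity(small_bundle.records)
        share = res["class_share_per_site"]
        # dominant planted classes stay dominant in the recovered shares
        assert share["fucosylated"] > share["paucimannose"]
        assert share["high_mannose"] > share["sialylated"]
        got_sites = res["sites_per_protein"]
        assert got_sites.idxmax() == 1  # single-site proteins dominate (74%)


class TestCooccurrence:
    def test_pair_counting(self):
        recs = [_rec("P1", 3, "HexNAc(2)Hex(9)"), _rec("P1", 3, "HexNAc(5)Hex(5)")]
        res = gq.class_cooccurrence(recs)
        assert res["pairs"]["complex_hybrid & high_mannose"] == 1
        assert res["pairs"].sum() == 1
        assert res["singletons"].sum() == 0

    def test_single_class_site_counts_singleton(self):
        res = gq.class_cooccurrence([_rec("P1", 3, "HexNAc(2)Hex(9)")])
        assert res["pairs"].sum() == 0
        assert res["singletons"]["high_mannose"] == 1

    def test_against_bruteforce_oracle(self, rng):
        # random multi-class sites; oracle enumerates pairs per site directly
        comps = ["HexNAc(2)Hex(9)", "HexNAc(5)Hex(5)", "HexNAc(2)Hex(3)",
                 "HexNAc(4)Hex(5)NeuAc(1)", "HexNAc(2)Hex(5)Fuc(1)",
                 "HexNAc(4)Hex(5)Fuc(1)NeuAc(2)"]
        recs, oracle = [], {}
        for site in range(100):
            chosen = rng.choice(comps, size=rng.integers(1, 5), replace=False)
            recs += [_rec("P1", 3 + 4 * site, c) for c in chosen]
            classes = {gq.classify_glycan(parse_composition(c)) for c in chosen}
            for pair in itertools.combinations(sorted(classes), 2):
                oracle[pair] = oracle.get(pair, 0) + 1
        res = gq.class_cooccurrence(recs)
        for pair in itertools.combinations(sorted(gq.GLYCAN_CLASSES), 2):
            assert res["pairs"][" & ".join(pair)] == oracle.get(pair, 0)


class TestNormalizeToProtein:
    def _proteins(self, values):
        return QuantMatrix(pd.DataFrame(values, columns=SAMPLES), GROUPS)

    def test_ratio_and_missing(self):
        prot = QuantMatrix(
            pd.DataFrame([[5.0, 5, 5, 5, np.nan, 5, 5, 5]], index=["P1"],
                         columns=SAMPLES), GROUPS)
        rec = _rec("P1", 3, "Hex(5)", values=[10.0] * 8)
        out = gq.normalize_to_protein([rec], prot)[0]
        assert out.normalized_to_protein
        assert out.normalized.iloc[0] == pytest.approx(2.0)
        assert math.isnan(out.normalized.iloc[4])  # protein missing there

    def test_protein_absent_keeps_raw_flagged(self):
        prot = QuantMatrix(pd.DataFrame([[1.0] * 8], index=["OTHER"],
                                        columns=SAMPLES), GROUPS)
        out = gq.normalize_to_protein([_rec("P1", 3, "Hex(5)")], prot)[0]
        assert not out.normalized_to_protein
        assert out.normalized.equals(out.intensities)

    def test_zero_protein_gives_missing_with_warning(self):
        prot = QuantMatrix(pd.DataFrame([[0.0] + [5.0] * 7], index=["P1"],
                                        columns=SAMPLES), GROUPS)
        with pytest.warns(UserWarning, match="zero protein"):
            out = gq.normalize_to_protein([_rec("P1", 3, "Hex(5)")], prot)[0]
        assert math.isnan(out.normalized.iloc[0])

    def test_protein_doubling_cancels(self, rng):
        """A glycopeptide that tracks its doubled protein has ratio ~1."""
        base = rng.uniform(5, 10, 8)
        shift = np.array([2.0] * 4 + [1.0] * 4)
        prot = QuantMatrix(pd.DataFrame([base * shift], index=["P1"],
                                        columns=SAMPLES), GROUPS)
        rec = _rec("P1", 3, "Hex(5)", values=list(0.1 * base * shift))
        out = gq.normalize_to_protein([rec], prot)[0]
        assert np.allclose(out.normalized, 0.1)


class TestDifferential:
    def _matrix(self, ra, oa):
        data = pd.DataFrame([list(ra) + list(oa)], index=["f1"], columns=SAMPLES)
        return QuantMatrix(data, GROUPS)

    def test_twofold_up(self, rng):
        jitter = rng.normal(0, 1e-3, 8)
        m = self._matrix(np.array([4.0] * 4) + jitter[:4],
                         np.array([2.0] * 4) + jitter[4:])
        res = gq.differential(m).iloc[0]
        assert res["fold_change"] == pytest.approx(2.0, rel=1e-2)
        assert res["category"] == "up"
        assert 0 < res["power"] <= 1

    def test_identical_groups_unchanged(self):
        m = self._matrix([3.0, 4, 5, 6], [3.0, 4, 5, 6])
        res = gq.differential(m).iloc[0]
        assert res["fold_change"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["category"] == "unchanged"

    def test_insufficient_detection(self):
        m = self._matrix([4.0, np.nan, np.nan, np.nan], [2.0] * 4)
        assert gq.differential(m).iloc[0]["category"] == "insufficient"

    def test_zero_control_median_flagged_infinite(self, rng):
        m = self._matrix(rng.uniform(3, 4, 4), [0.0, 0.0, 0.0, 2.5])
        res = gq.differential(m).iloc[0]
        assert math.isinf(res["fold_change"]) and res["degenerate"]
        # a single quantifiable control value cannot support the t test
        assert res["category"] == "insufficient"

    def test_bh_option_adds_q(self):
        m = self._matrix([3.0, 4, 5, 6], [3.1, 4.1, 5.1, 6.1])
        res = gq.differential(m, bh_correct=True)
        assert "q_value" in res.columns


class TestCallSpecific:
    def _mask_matrix(self, ra_detected, oa_detected):
        row = [1.0 if d else np.nan for d in ra_detected + oa_detected]
        return QuantMatrix(pd.DataFrame([row], index=["f1"], columns=SAMPLES),
                           GROUPS)

    @pytest.mark.parametrize(
        "ra,oa,expected",
        [
            ([1, 1, 1, 0], [0, 0, 0, 0], "case"),      # 3/4 vs 0/4
            ([1, 1, 1, 1], [1, 0, 0, 0], None),        # one control detection
            ([1, 1, 0, 0], [0, 0, 0, 0], None),        # below 75%
            ([0, 0, 0, 0], [1, 1, 1, 1], "control"),
        ],
    )
    def test_rule(self, ra, oa, expected):
        res = gq.call_specific(self._mask_matrix([bool(x) for x in ra],
                                                 [bool(x) for x in oa]))
        got = ("case" if res["case_specific"] else
               "control" if res["control_specific"] else None)
        assert got == expected

    def test_all_samples_subset(self):
        res = gq.call_specific(self._mask_matrix([True] * 4, [False] * 4))
        assert res["case_specific_all_samples"] == ["f1"]


class TestFdr:
    def test_example_and_linearity(self):
        assert gq.gpsm_fdr(1000, 5) == pytest.approx(1.0)
        assert gq.gpsm_fdr(1000, 0) == 0.0
        assert gq.gpsm_fdr(1000, 10) == pytest.approx(2 * gq.gpsm_fdr(1000, 5))

    def test_undefined_without_forward(self):
        with pytest.raises(ValueError):
            gq.gpsm_fdr(0, 5)

    def test_threshold_scan_matches_enumeration(self, rng):
        fwd = rng.normal(10, 3, size=700)
        dec = rng.normal(5, 3, size=300)
        got = gq.threshold_for_fdr(fwd, dec, target=1.0)
        # oracle: brute force over every observed cutoff
        best = None
        for cut in np.concatenate([fwd, dec]):
            nf = int((fwd >= cut).sum())
            nd = int((dec >= cut).sum())
            if nf and 2 * nd * 100 / nf <= 1.0:
                if best is None or nf > best[0]:
                    best = (nf, nd, cut)
        assert best is not None
        assert got["n_forward"] == best[0]
        assert gq.gpsm_fdr(got["n_forward"], got["n_decoy"]) <= 1.0

    def test_no_feasible_cutoff(self):
        res = gq.threshold_for_fdr([1.0, 2.0], [5.0, 6.0], target=1.0)
        assert res["threshold"] is None
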