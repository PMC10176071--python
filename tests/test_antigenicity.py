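"""Antigenicity tracks against independent naive oracles; screen semantics."""

import hashlib
import math

import numpy as np
import pytest

from glycoimmune import antigenicity as ag
from glycoimmune.glycomodel import AMINO_ACIDS

RNG = np.random.default_rng(11)


def random_peptide(rng, n=31):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


# --- independent naive oracles (no shared code with the implementation) ----

def oracle_window_mean(seq, scale, window):
    half = window // 2
    out = []
    for i in range(len(seq)):
        vals = [scale[seq[j]] for j in range(max(0, i - half),
                                             min(len(seq), i + half + 1))]
        out.append(sum(vals) / len(vals))
    return np.array(out)


def oracle_emini(seq, scale):
    out = np.full(len(seq), np.nan)
    for start in range(len(seq) - 5):
        prod = 1.0
        for j in range(start, start + 6):
            prod *= scale[seq[j]]
        out[start + 3] = prod * 0.37 ** -6
    return out


def oracle_gor(seq, table):
    n = len(seq)
    tracks = {}
    for state in ag.GOR_STATES:
        track = np.zeros(n)
        for i in range(n):
            for d in range(-8, 9):
                if 0 <= i + d < n:
                    track[i] += table[state][seq[i + d]][d + 8]
        tracks[state] = track
    return tracks


class TestTracksAgainstOracles:
    def test_hydrophilicity_is_flipped_window_mean(self):
        scale = ag.load_scale("kyte_doolittle").values
        for _ in range(20):
            seq = random_peptide(RNG)
            got = ag.hydrophilicity_kd(seq)
            want = -oracle_window_mean(seq, scale, 9)
            assert np.allclose(got, want, atol=1e-12)

    def test_surface_matches_product_formula(self):
        scale = ag.load_scale("emini").values
        for _ in range(20):
            seq = random_peptide(RNG)
            got = ag.surface_emini(seq)
            want = oracle_emini(seq, scale)
            assert np.allclose(got, want, equal_nan=True, rtol=1e-9)

    def test_flexibility_matches_window_mean(self):
        scale = ag.load_scale("karplus_schulz").values
        for _ in range(20):
            seq = random_peptide(RNG)
            got = ag.flexibility_ks(seq)
            want = oracle_window_mean(seq, scale, 7)
            assert np.allclose(got["track"], want, atol=1e-12)
            assert np.array_equal(got["flexible_region"], want > 1.0)

    def test_turns_match_argmax_oracle(self):
        table = ag.load_gor_table()
        for _ in range(20):
            seq = random_peptide(RNG)
            got = ag.turns_gr(seq)
            want = oracle_gor(seq, table)
            for state in ag.GOR_STATES:
                assert np.allclose(got["tracks"][state], want[state], atol=1e-9)
            stacked = np.vstack([want[s] for s in ag.GOR_STATES])
            flags = want["turn"] >= stacked.max(axis=0) - 1e-12
            assert np.array_equal(got["beta_turn"], flags)


class TestScaleBehaviour:
    def test_polyarginine_is_hydrophilic_polyisoleucine_not(self):
        assert np.all(ag.hydrophilicity_kd("R" * 9) > 0)
        assert np.all(ag.hydrophilicity_kd("I" * 9) < 0)

    def test_hydrophilicity_is_exact_sign_flip(self):
        seq = random_peptide(RNG)
        scale = ag.load_scale("kyte_doolittle").values
        hydropathy = oracle_window_mean(seq, scale, 9)
        assert np.allclose(ag.hydrophilicity_kd(seq), -hydropathy)

    def test_emini_buried_residue_lowers_score(self):
        base = "KRKRKK"  # highly exposed hexapeptide
        lower = "KRKRKC"  # C has the lowest surface probability
        assert ag.surface_emini(lower)[3] < ag.surface_emini(base)[3]
        assert ag.surface_emini(base)[3] > 1.0

    def test_flexibility_extremes(self):
        assert np.all(ag.flexibility_ks("G" * 7)["flexible_region"])
        assert not np.any(ag.flexibility_ks("W" * 7)["flexible_region"])

    def test_turn_rich_sequence_flags_turns(self):
        flags = ag.turns_gr("GPNGPNGPNGPNG")["beta_turn"]
        assert np.all(flags[2:-2])

    def test_short_sequence_emini_warns(self):
        with pytest.warns(UserWarning):
            track = ag.surface_emini("KRK")
        assert np.all(np.isnan(track))

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="position 2"):
            ag.hydrophilicity_kd("AAXAA")

    def test_checksum_guard(self, tmp_path, monkeypatch):
        bad = dict(ag._CHECKSUMS)
        bad["emini.tsv"] = "0" * 64
        monkeypatch.setattr(ag, "_CHECKSUMS", bad)
        with pytest.raises(RuntimeError, match="checksum"):
            ag.load_scale("emini")


class TestAntigenicIndex:
    def test_weighted_sum_bounds(self):
        n = 10
        top = {"hydrophilicity": np.full(n, 5.0), "surface": np.full(n, 3.0),
               "flexibility": np.full(n, 1.2), "turn_gr": np.full(n, 300.0),
               "turn_cf": np.full(n, 1.5)}
        ai = ag.antigenic_index_jw(**top)
        assert np.allclose(ai, 2.4)
        mid = {k: np.zeros(n) for k in top}
        mid["surface"] = np.ones(n)  # class 0 band
        mid["flexibility"] = np.ones(n)
        mid["turn_cf"] = np.ones(n)
        assert np.allclose(ag.antigenic_index_jw(**mid), 0.0)

    def test_matches_direct_weighted_sum_oracle(self):
        n = 31
        tracks = {
            "hydrophilicity": RNG.uniform(-4, 4, n),
            "surface": RNG.uniform(0, 3, n),
            "flexibility": RNG.uniform(0.9, 1.1, n),
            "turn_gr": RNG.uniform(-400, 400, n),
            "turn_cf": RNG.uniform(0.4, 1.6, n),
        }
        weights = {"hydrophilicity": 0.3, "surface": 0.15, "flexibility": 0.15,
                   "turn_gr": 0.2, "turn_cf": 0.2}
        classes = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])
        want = np.zeros(n)
        for name, track in tracks.items():
            cuts = ag.DEFAULT_CUTPOINTS[name]
            for i, v in enumerate(track):
                k = sum(v >= c for c in cuts)
                want[i] += weights[name] * classes[k]
        assert np.allclose(ag.antigenic_index_jw(**tracks), 4 * want)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ag.antigenic_index_jw(np.zeros(5), np.zeros(5), np.zeros(5),
                                  np.zeros(5), np.zeros(4))


class TestScreen:
    def _profile(self, **summary):
        base = {"max_hydrophilicity": 2.0, "max_surface_probability": 2.0,
                "max_flexibility": 1.1, "max_antigenic_index": 1.5,
                "n_flexible": 3, "n_beta_turn": 2}
        base.update(summary)
        return ag.AntigenicityProfile(
            site_id="x", window="A" * 31, center_index=15, truncated=False,
            tracks={}, turn_tracks={}, flags={}, peptide_summary=base,
        )

    def test_all_criteria_pass(self):
        v = ag.screen_peptide(self._profile())
        assert v.passes and all(v.flags.values())

    def test_single_failing_criterion_fails_conjunction(self):
        v = ag.screen_peptide(self._profile(max_surface_probability=0.5))
        assert not v.passes
        assert not v.flags["surface_probability"]
        assert v.flags["hydrophilicity"]

    @pytest.mark.parametrize("key", ["n_flexible", "n_beta_turn"])
    def test_existence_criteria(self, key):
        assert not ag.screen_peptide(self._profile(**{key: 0})).passes

    def test_monotone_in_summary(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            s = {"max_hydrophilicity": rng.uniform(-2, 3),
                 "max_surface_probability": rng.uniform(0, 3),
                 "max_flexibility": rng.uniform(0.9, 1.2),
                 "max_antigenic_index": rng.uniform(-1, 2.4),
                 "n_flexible": int(rng.integers(0, 4)),
                 "n_beta_turn": int(rng.integers(0, 4))}
            before = ag.screen_peptide(self._profile(**s)).passes
            bumped = {k: (v + abs(rng.normal())) for k, v in s.items()}
            after = ag.screen_peptide(self._profile(**bumped)).passes
            assert not (before and not after)


class TestProfileGlycosites:
    def test_one_profile_per_site_with_links(self, small_bundle):
        b = small_bundle
        profiles = ag.profile_glycosites(b.records, b.sequences)
        assert len(profiles) == len({r.site_id for r in b.records})
        linked = sum(len(p.linked_features) for p in profiles.values())
        assert linked == len(b.records)
        for p in profiles.values():
            assert p.window[p.center_index] == "N"
            assert p.verdict is not None

    def test_planted_extreme_windows(self):
        # hydrophilic/flexible/turn-prone window around the sequon
        antigenic = "KSNGSKNKSGK" + "NGS" + "KSNGSKNKSGK"
        hydrophobic = "IVLIVLIVLIV" + "NGS" + "IVLIVLIVLIV"
        good = ag.compute_profile(antigenic)
        bad = ag.compute_profile(hydrophobic)
        assert good.verdict.passes
        assert not bad.verdict.passes
        assert not bad.verdict.flags["hydrophilicity"]

    def test_truncated_window_still_screened(self):
        seq = "NGTKKKKSSKKNKK"  # glycosite at position 1
        profiles = ag.profile_glycosites(
            [_fake_record("P1", 1)], {"P1": seq})
        (profile,) = profiles.values()
        assert profile.truncated
        assert profile.verdict is not None

    def test_missing_protein_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = ag.profile_glycosites([_fake_record("GONE", 5)], {})
        assert out == {}


def _fake_record(protein, site):
    import pandas as pd
    from glycoimmune.glycomodel import GlycoPeptideRecord, parse_composition

    return GlycoPeptideRecord(protein, "NGT", site,
                              parse_composition("HexNAc(2)Hex(5)"),
                              pd.Series({"s1": 1.0}))
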