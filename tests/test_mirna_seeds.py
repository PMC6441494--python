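import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cico import mirna_seeds as ms
from cico._seq import revcomp

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


class TestScan:
    def test_8mer_site_for_let7(self):
        # CUACCUCA = complement of positions 2-8 followed by target A
        target = "GGGG" + "CUACCUCA" + "GGGG"
        matches = ms.scan(target, LET7, circular=False)
        assert len(matches) == 1
        assert matches[0].category == "8mer"

    @pytest.mark.parametrize("site,category", [
        ("CUACCUCA", "8mer"),      # m8 pair and A1
        ("CUACCUCG", "7mer-m8"),   # m8 pair, no A1
        ("GUACCUCA", "7mer-A1"),   # A1 only
        ("GUACCUCG", "6mer"),      # core only
    ])
    def test_category_assignment(self, site, category):
        target = "GGGG" + site + "GGGG"
        (match,) = ms.scan(target, LET7, circular=False)
        assert match.category == category

    def test_poly_a_target_has_no_sites(self):
        assert ms.scan("A" * 60, LET7) == []

    def test_junction_spanning_site_found_once(self):
        core = revcomp(LET7[1:7], rna=True)  # UACCUC
        seq = core[3:] + "G" * 40 + "C" + core[:3]  # core straddles the junction
        matches = ms.scan(seq, LET7, circular=True)
        starts = [m.start for m in matches]
        assert starts == [len(seq) - 3]
        # a linear scan misses it
        assert ms.scan(seq, LET7, circular=False) == []

    def test_rotation_preserves_category_multiset(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, 300))
        base = sorted(m.category for m in ms.scan(seq, LET7))
        for k in (1, 17, 150, 299):
            rot = seq[k:] + seq[:k]
            assert sorted(m.category for m in ms.scan(rot, LET7)) == base

    def test_t_and_u_equivalent(self):
        target = ("GGGG" + "CUACCUCA" + "GGGG").replace("U", "T")
        (match,) = ms.scan(target, LET7.replace("U", "T"), circular=False)
        assert match.category == "8mer"

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            ms.scan("ACGUACGU", "ACGUA")

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            ms.scan("ACGXACGU" * 4, LET7)


class TestScoring:
    def test_perfect_complement_scores_full_match(self):
        target = revcomp(LET7, rna=True)
        (match,) = [m for m in ms.scan(target, LET7, circular=False)]
        score = ms.site_score(target, match, LET7, circular=False)
        assert score == pytest.approx(len(LET7) * ms.MATCH_SCORE)  # 22 * 5 = 110

    def test_mismatched_context_scores_nonpositive(self):
        # poly-G target has no seed, so craft a match record manually
        match = ms.SeedMatch("c", "m", 10, "6mer")
        score = ms.site_score("G" * 60, match, "G" * 22, circular=False)
        assert score <= 0

    def test_perfect_duplex_energy_below_seed_only(self):
        target = revcomp(LET7, rna=True)
        (match,) = ms.scan(target, LET7, circular=False)
        full = ms.site_energy(target, match, LET7, circular=False)
        core_only = "GGGG" + revcomp(LET7[1:7], rna=True) + "GGGG"
        (m2,) = ms.scan(core_only + "A" * 20, LET7, circular=False)
        partial = ms.site_energy(core_only + "A" * 20, m2, LET7, circular=False)
        assert full < partial


class TestFilterAndCount:
    def matches(self):
        out = []
        for i in range(3):
            out.append(ms.SeedMatch("c1", "mirA", i * 10, "8mer", 160.0, -25.0))
        for i in range(5):
            out.append(ms.SeedMatch("c1", "mirB", i * 10, "6mer", 100.0, -10.0))
        return out

    def test_counts_max_and_distinct(self):
        (s,) = ms.filter_and_count(self.matches(), min_score=-math.inf,
                                   max_dg=math.inf)
        assert s.per_mirna == {"mirA": 3, "mirB": 5}
        assert s.max_single == 5 and s.n_distinct == 2

    def test_score_filter_drops_all(self):
        assert ms.filter_and_count(self.matches(), min_score=1000,
                                   max_dg=math.inf) == []

    def test_default_gates_keep_strong_sites_only(self):
        (s,) = ms.filter_and_count(self.matches())
        assert s.per_mirna == {"mirA": 3}

    @given(st.floats(-50, 200), st.floats(-50, 200))
    def test_tightening_filters_is_monotone(self, s1, s2):
        lo, hi = sorted((s1, s2))
        loose = ms.filter_and_count(self.matches(), min_score=lo, max_dg=math.inf)
        tight = ms.filter_and_count(self.matches(), min_score=hi, max_dg=math.inf)
        loose_counts = {(s.circ_id, m): n for s in loose for m, n in s.per_mirna.items()}
        for s in tight:
            for m, n in s.per_mirna.items():
                assert n <= loose_counts.get((s.circ_id, m), 0)

    def test_missing_score_with_active_filter_rejected(self):
        with pytest.raises(ValueError, match="no score"):
            ms.filter_and_count([ms.SeedMatch("c", "m", 0, "6mer")],
                                min_score=10, max_dg=math.inf)
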