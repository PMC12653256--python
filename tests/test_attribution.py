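import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import GROUP_A, GROUP_B, GROUP_C
from hoppertrace.attribution import (
    SusceptibilityInterval,
    ci_overlap,
    compact_letter_display,
    destination_groups,
    intervals_from_frame,
    letter_discrepancies,
    match_sources,
    pooled_interval,
)


def iv(pid, lo, mid, hi, ins="pymetrozine"):
    return SusceptibilityInterval(pid, ins, mid, lo, hi)


class TestOverlap:
    def test_field_pairs(self, tox_tables):
        ivs = {
            r.site_id: iv(r.site_id, r.ci_lower, r.lc50_mg_L, r.ci_upper)
            for r in tox_tables[tox_tables.insecticide == "pymetrozine"].itertuples()
        }
        assert ci_overlap(ivs["Hongjiang"], ivs["Longzhou"]) is True
        assert ci_overlap(ivs["Hongjiang"], ivs["Liujiang"]) is False

    def test_identical_intervals_overlap(self):
        a = iv("p", 1.0, 2.0, 3.0)
        b = iv("q", 1.0, 2.0, 3.0)
        assert ci_overlap(a, b) is True

    def test_cross_insecticide_comparison_rejected(self):
        with pytest.raises(ValueError):
            ci_overlap(iv("p", 1, 2, 3), iv("q", 1, 2, 3, ins="nitenpyram"))

    @given(
        bounds=st.tuples(
            st.floats(0.1, 50.0), st.floats(0.1, 10.0),
            st.floats(0.1, 50.0), st.floats(0.1, 10.0),
        )
    )
    def test_overlap_is_symmetric(self, bounds):
        lo1, w1, lo2, w2 = bounds
        a = iv("p", lo1, lo1 + w1 / 2, lo1 + w1)
        b = iv("q", lo2, lo2 + w2 / 2, lo2 + w2)
        assert ci_overlap(a, b) == ci_overlap(b, a)


interval_lists = st.lists(
    st.tuples(st.floats(0.5, 60.0), st.floats(0.2, 15.0)),
    min_size=2, max_size=10, unique=True,
)


class TestCompactLetterDisplay:
    def test_destination_rosters_for_both_insecticides(self, tox_tables):
        for ins in ("pymetrozine", "nitenpyram"):
            sub = tox_tables[(tox_tables.insecticide == ins) & (tox_tables.region == "HN")]
            cld = compact_letter_display(intervals_from_frame(sub))
            rosters = [set(m) for _, m in cld.classes]
            assert rosters == [GROUP_A, GROUP_B, GROUP_C]
            assert all(len(let) == 1 for let in cld.letters.values())

    def test_disjoint_intervals_get_distinct_single_letters(self):
        ivs = [iv("p1", 1, 1.5, 2), iv("p2", 3, 3.5, 4), iv("p3", 5, 5.5, 6)]
        cld = compact_letter_display(ivs)
        assert cld.letters == {"p1": "a", "p2": "b", "p3": "c"}

    def test_fully_overlapping_intervals_share_one_letter(self):
        ivs = [iv(f"p{k}", 1 + 0.1 * k, 2 + 0.1 * k, 3 + 0.1 * k) for k in range(4)]
        cld = compact_letter_display(ivs)
        assert set(cld.letters.values()) == {"a"}

    @given(data=interval_lists)
    def test_letters_reproduce_overlap_matrix(self, data):
        """CLD soundness: share a letter iff CIs overlap-connected the
        pairwise way (no letter for disjoint pairs, >=1 for overlapping)."""
        ivs = [iv(f"p{k}", lo, lo + w / 2, lo + w) for k, (lo, w) in enumerate(data)]
        cld = compact_letter_display(ivs)
        for a in ivs:
            for b in ivs:
                if a.population_id >= b.population_id:
                    continue
                shared = set(cld.letters[a.population_id]) & set(cld.letters[b.population_id])
                if ci_overlap(a, b):
                    assert shared, f"{a.population_id},{b.population_id} overlap but share no letter"
                else:
                    assert not shared


class TestPooledIntervals:
    def test_single_member_is_its_own_interval(self):
        assert pooled_interval([iv("p", 1.0, 2.0, 3.0)]) == (1.0, 3.0)

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_interval([])


class TestMatching:
    def test_longzhou_matches_group_a(self, tox_tables):
        dest = intervals_from_frame(tox_tables[tox_tables.region == "HN"])
        src = intervals_from_frame(tox_tables[tox_tables.region == "GX"])
        res = match_sources(dest, destination_groups(dest), src)
        assert "Longzhou" in res.matches["A"]
        assert "Liujiang" not in res.matches["A"]
        assert {"B", "C"} <= {
            g for g, s in res.matches.items() if "Fangchenggang" in s
        }

    def test_missing_insecticide_for_source_raises(self, tox_tables):
        dest = intervals_from_frame(tox_tables[tox_tables.region == "HN"])
        src = intervals_from_frame(
            tox_tables[(tox_tables.region == "GX") & (tox_tables.insecticide == "pymetrozine")]
        )
        with pytest.raises(KeyError):
            match_sources(dest, destination_groups(dest), src)

    def test_pooled_rule_is_not_stricter_than_both_all(self, tox_tables):
        dest = intervals_from_frame(tox_tables[tox_tables.region == "HN"])
        src = intervals_from_frame(tox_tables[tox_tables.region == "GX"])
        groups = destination_groups(dest)
        strict = match_sources(dest, groups, src, rule="both_all")
        pooled = match_sources(dest, groups, src, rule="both_pooled")
        either = match_sources(dest, groups, src, rule="either_all")
        for g in groups:
            assert set(strict.matches[g]) <= set(pooled.matches[g])
            assert set(strict.matches[g]) <= set(either.matches[g])

    def test_decision_matrix_covers_every_pair(self, tox_tables):
        dest = intervals_from_frame(tox_tables[tox_tables.region == "HN"])
        src = intervals_from_frame(tox_tables[tox_tables.region == "GX"])
        groups = destination_groups(dest)
        res = match_sources(dest, groups, src)
        n_members = sum(len(m) for m in groups.values())
        assert len(res.decisions) == 11 * 2 * n_members


class TestDiscrepancies:
    def test_xingbin_letter_conflict_is_surfaced(self, tox_tables):
        sub = tox_tables[tox_tables.insecticide == "nitenpyram"]
        printed = sub.set_index("site_id")["letter"].to_dict()
        rep = letter_discrepancies(intervals_from_frame(sub), printed)
        pairs = {frozenset(p) for p in zip(rep.population_a, rep.population_b)}
        assert frozenset({"Xingbin", "Youxian"}) in pairs
        assert frozenset({"Xingbin", "Babu"}) in pairs

    def test_consistent_letters_give_empty_report(self):
        ivs = [iv("p1", 1, 1.5, 2), iv("p2", 3, 3.5, 4)]
        rep = letter_discrepancies(ivs, {"p1": "a", "p2": "b"})
        assert rep.empty
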