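import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cladesig.csp import (CSPError, CSPParams, call_genome, classify_protein,
                          order_targets)
from cladesig.hits import AnnotatedHit, AnnotatedHitTable, HitRecord
from cladesig.taxa import CladeDefinitionSet, clade, parse_clade_expression

TARGET5 = CladeDefinitionSet(
    {"C": {"c1", "c2", "c3", "c4", "c5"},
     "F": {"f1", "f2", "f3"},
     "PL": {"pl"}},
    universe={"c1", "c2", "c3", "c4", "c5", "f1", "f2", "f3", "pl"})


def make_hit(taxon, evalue, slen=300, tags=(), subject=None, clades=()):
    rec = HitRecord(query_id="q", subject_id=subject or f"{taxon}_seq",
                    percent_identity=50.0, alignment_length=300, mismatches=10,
                    gap_opens=0, query_start=1, query_end=300,
                    subject_start=1, subject_end=300,
                    evalue=evalue, bitscore=100.0, subject_length=slen)
    return AnnotatedHit(hit=rec, taxon_id=taxon, group_tags=frozenset(tags),
                        clades=frozenset(clades))


def make_hits(specs):
    hits = [make_hit(*s) if isinstance(s, tuple) else s for s in specs]
    hits.sort(key=lambda h: (h.evalue, -h.hit.bitscore, h.subject_id))
    return hits


QUERY = ("q", 300)


class TestClassify:
    def test_all_members_no_foreign_is_core(self):
        hits = make_hits([("c%d" % i, 1e-30) for i in range(2, 6)])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5,
                             query_taxon="c1")
        assert d.verdict == "specific_core"
        assert d.presence_taxa == {"c1", "c2", "c3", "c4", "c5"}
        assert not d.missing_taxa

    def test_large_evalue_jump_is_core(self):
        # worst in-clade presence E = 1e-20; best foreign E = 1e-3
        hits = make_hits([("c2", 1e-30), ("c3", 1e-25), ("c4", 1e-22),
                          ("c5", 1e-20), ("f1", 1e-3)])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, query_taxon="c1")
        assert d.verdict == "specific_core"
        assert d.gap_ratio == pytest.approx(1e17, rel=1e-6)

    def test_significant_foreign_hit_blocks(self):
        hits = make_hits([("c%d" % i, 1e-30) for i in range(2, 6)] +
                         [("f1", 1e-6)])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, query_taxon="c1")
        assert d.verdict == "not_specific"
        assert ("f1", 1e-6) in d.foreign_evidence

    def test_own_taxon_only_is_orfan(self):
        hits = make_hits([("c1", 1e-80, 300, (), "c1_other")])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, query_taxon="c1")
        assert d.verdict == "orfan_excluded"

    def test_empty_hit_list_is_orfan(self):
        d = classify_protein(QUERY, [], clade("C"), TARGET5, query_taxon="c1")
        assert d.verdict == "orfan_excluded"

    def test_missing_two_is_partial(self):
        big = CladeDefinitionSet({"T": {f"t{i}" for i in range(12)}})
        hits = make_hits([(f"t{i}", 1e-30) for i in range(1, 10)])
        d = classify_protein(QUERY, hits, clade("T"), big, query_taxon="t0")
        assert d.verdict == "specific_partial"
        assert d.missing_taxa == {"t10", "t11"}

    def test_missing_three_is_rejected(self):
        big = CladeDefinitionSet({"T": {f"t{i}" for i in range(12)}})
        hits = make_hits([(f"t{i}", 1e-30) for i in range(1, 9)])
        d = classify_protein(QUERY, hits, clade("T"), big, query_taxon="t0")
        assert d.verdict == "not_specific"
        assert "missing" in d.notes

    def test_plastid_hit_retained_with_exception(self):
        hits = make_hits([("c%d" % i, 1e-30) for i in range(2, 6)] +
                         [("pl", 1e-20, 300, ("plastid_eukaryote",))])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, query_taxon="c1")
        assert d.verdict == "retained_with_exception"
        assert "pl" in d.notes
        assert d.foreign_evidence  # audit: lists the excepted taxon

    def test_isolated_foreign_allowance_when_enabled(self):
        params = CSPParams(max_isolated_foreign=1)
        hits = make_hits([("c%d" % i, 1e-30) for i in range(2, 6)] +
                         [("f1", 1e-6)])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, params,
                             query_taxon="c1")
        assert d.verdict == "retained_with_exception"
        assert "f1" in d.notes

    def test_length_mismatch_blocks_presence(self):
        # subject half the query length is not counted as presence
        hits = make_hits([("c2", 1e-30, 150), ("c3", 1e-30), ("c4", 1e-30),
                          ("c5", 1e-30)])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, query_taxon="c1")
        assert d.verdict == "specific_partial"
        assert d.missing_taxa == {"c2"}

    def test_length_check_soft_mode(self):
        params = CSPParams(length_check_hard=False)
        hits = make_hits([("c2", 1e-30, 150), ("c3", 1e-30), ("c4", 1e-30),
                          ("c5", 1e-30)])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, params,
                             query_taxon="c1")
        assert d.verdict == "specific_core"

    def test_weak_foreign_without_jump_blocks(self):
        # foreign at 2e-4 (> e_sig) but in-clade worst is 1e-5: ratio 20 < 1e3
        hits = make_hits([("c2", 1e-30), ("c3", 1e-30), ("c4", 1e-30),
                          ("c5", 1e-5), ("f1", 2e-4)])
        params = CSPParams(e_presence=1e-4)
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, params,
                             query_taxon="c1")
        assert d.verdict == "not_specific"
        assert d.foreign_evidence

    def test_evalue_zero_uses_floor_in_ratio(self):
        hits = make_hits([("c2", 0.0), ("c3", 0.0), ("c4", 0.0), ("c5", 0.0),
                          ("f1", 1e-2)])
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, query_taxon="c1")
        assert d.verdict == "specific_core"
        assert d.gap_ratio is not None and d.gap_ratio >= 1e3


class TestParams:
    def test_invariants_enforced(self):
        with pytest.raises(CSPError):
            CSPParams(e_presence=1e-3, e_sig=1e-4)
        with pytest.raises(CSPError):
            CSPParams(gap_factor=0.5)
        with pytest.raises(CSPError):
            CSPParams(min_members=1)
        with pytest.raises(CSPError):
            CSPParams(length_ratio_bounds=(1.1, 1.3))

    def test_from_dict(self):
        p = CSPParams.from_dict({"e_sig": "1e-3", "max_missing": "1",
                                 "length_ratio_bounds": "0.5,2.0",
                                 "exception_groups": "plastid_eukaryote,algae"})
        assert p.e_sig == 1e-3
        assert p.max_missing == 1
        assert p.length_ratio_bounds == (0.5, 2.0)
        assert "algae" in p.exception_groups

    def test_unknown_key_rejected(self):
        with pytest.raises(CSPError, match="unknown"):
            CSPParams.from_dict({"nope": "1"})


class TestCallGenome:
    def _table(self, mapping):
        return AnnotatedHitTable({q: make_hits(specs)
                                  for q, specs in mapping.items()})

    def test_nested_targets_smaller_wins(self):
        defs = CladeDefinitionSet({
            "Nostocales": {"n1", "n2", "n3"},
            "NOC": {"n1", "n2", "n3", "o1", "o2"}})
        table = self._table({"q": [("n2", 1e-40), ("n3", 1e-40)]})
        targets = [parse_clade_expression("NOC"),
                   parse_clade_expression("Nostocales")]
        calls = call_genome([("q", 300)], table, targets, defs,
                            query_taxa={"q": "n1"})
        assert len(calls) == 1
        assert str(calls[0].target) == "Nostocales"

    def test_empty_hit_table(self):
        calls = call_genome([("q", 300)], AnnotatedHitTable({}),
                            [clade("C")], TARGET5, query_taxa={"q": "c1"})
        assert calls == []

    def test_duplicate_query_ids_error(self):
        with pytest.raises(CSPError, match="duplicate"):
            call_genome([("q", 300), ("q", 200)], AnnotatedHitTable({}),
                        [clade("C")], TARGET5)

    def test_order_targets_by_size_then_listing(self):
        defs = CladeDefinitionSet({"Big": {"a", "b", "c"}, "S1": {"a"},
                                   "S2": {"b"}})
        ordered = order_targets([clade("Big"), clade("S2"), clade("S1")], defs)
        assert [str(t) for t in ordered] == ["S2", "S1", "Big"]

    def test_determinism(self):
        table = self._table(
            {"q": [("c2", 1e-30), ("c3", 1e-25), ("f1", 1e-2)]})
        args = ([("q", 300)], table, [clade("C")], TARGET5)
        a = call_genome(*args, query_taxa={"q": "c1"})
        b = call_genome(*args, query_taxa={"q": "c1"})
        assert a == b


@st.composite
def hit_scenario(draw):
    members = draw(st.integers(2, 5))
    specs = [(f"c{i}", draw(st.floats(min_value=1e-60, max_value=1e-7)))
             for i in range(2, members + 1)]
    n_foreign = draw(st.integers(0, 3))
    for i in range(n_foreign):
        specs.append((f"f{i + 1}",
                      draw(st.floats(min_value=1e-12, max_value=0.5))))
    return make_hits(specs)


class TestMonotonicity:
    @settings(max_examples=120, deadline=None)
    @given(hits=hit_scenario(),
           e_sig_pair=st.tuples(st.floats(1e-6, 1e-2), st.floats(1e-6, 1e-2)))
    def test_stricter_e_sig_never_loses_calls(self, hits, e_sig_pair):
        # e_presence held fixed, so only foreign significance varies
        lo, hi = sorted(e_sig_pair)
        d_loose = classify_protein(QUERY, hits, clade("C"), TARGET5,
                                   CSPParams(e_sig=hi), query_taxon="c1")
        d_strict = classify_protein(QUERY, hits, clade("C"), TARGET5,
                                    CSPParams(e_sig=lo), query_taxon="c1")
        if d_loose.verdict in ("specific_core", "specific_partial"):
            assert d_strict.verdict == d_loose.verdict

    @settings(max_examples=120, deadline=None)
    @given(hits=hit_scenario(),
           gf_pair=st.tuples(st.floats(1.5, 1e6), st.floats(1.5, 1e6)))
    def test_raising_gap_factor_never_creates_calls(self, hits, gf_pair):
        lo, hi = sorted(gf_pair)
        d_lo = classify_protein(QUERY, hits, clade("C"), TARGET5,
                                CSPParams(gap_factor=lo), query_taxon="c1")
        d_hi = classify_protein(QUERY, hits, clade("C"), TARGET5,
                                CSPParams(gap_factor=hi), query_taxon="c1")
        if d_hi.is_call:
            assert d_lo.is_call

    @settings(max_examples=100, deadline=None)
    @given(hits=hit_scenario())
    def test_blocked_decisions_carry_evidence(self, hits):
        d = classify_protein(QUERY, hits, clade("C"), TARGET5, query_taxon="c1")
        if d.verdict == "not_specific" and "foreign" in d.notes:
            assert d.foreign_evidence
        if d.verdict == "retained_with_exception":
            assert d.notes
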