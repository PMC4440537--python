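"""Family rules: dedup funnel, 80-80 decisions, copy number, membership."""

import pytest

from repeatscape import families, masking, synthetic as syn


def rec(eid, seq, **kw):
    return families.ElementRecord(eid, seq, **kw)


class TestDedup:
    def test_identical_collapse(self):
        s = syn.generate_background(2000, 0.5, 1)
        assert len(families.dedup_candidates([rec("a", s), rec("b", s)])) == 1

    def test_substring_collapse(self):
        s = syn.generate_background(2000, 0.5, 2)
        out = families.dedup_candidates([rec("a", s), rec("b", s[: int(2000 * 0.96)])])
        assert [r.element_id for r in out] == ["a"]

    def test_diverged_pair_kept(self, rng):
        s = syn.generate_background(2000, 0.5, 3)
        t = syn._mutate(s, 0.15, rng)  # ~85% identity: below 95 dedup
        assert len(families.dedup_candidates([rec("a", s), rec("b", t)])) == 2

    def test_empty_error(self):
        with pytest.raises(ValueError):
            families.dedup_candidates([])

    def test_funnel_monotonicity(self, rng):
        base = syn.generate_background(1500, 0.5, 4)
        items = [rec(f"e{i}", syn._mutate(base, 0.02 * (i % 3), rng)) for i in range(9)]
        unique = families.dedup_candidates(items)
        lib = [masking.RepeatLibraryEntry("known", ("Retroelement", None, None, None), base)]
        novel, _ = families.filter_known(unique, lib)
        assert len(novel) <= len(unique) <= len(items)


class TestSameFamily:
    def test_reflexive(self):
        s = syn.generate_background(1000, 0.5, 5)
        d = families.same_family(rec("a", s), rec("a", s))
        assert d.same_family and d.identity == 1.0

    def test_symmetric(self, rng):
        for i in range(5):
            a = syn.generate_background(800, 0.5, 10 + i)
            b = syn._mutate(a, rng.uniform(0.05, 0.4), rng)
            d1 = families.same_family(rec("a", a), rec("b", b))
            d2 = families.same_family(rec("b", b), rec("a", a))
            assert d1.same_family == d2.same_family

    def test_ltr_route_suffices(self, rng):
        ltr_a = syn.generate_background(400, 0.5, 20)
        ltr_b = syn._mutate(ltr_a, 0.15, rng)  # ~85% identical LTRs
        int_a = syn.generate_background(2000, 0.5, 21)
        int_b = syn._mutate(int_a, 0.45, rng)  # ~60% internals
        a = rec("a", ltr_a + int_a + ltr_a, ltr5=ltr_a, ltr3=ltr_a, internal=int_a)
        b = rec("b", ltr_b + int_b + ltr_b, ltr5=ltr_b, ltr3=ltr_b, internal=int_b)
        d = families.same_family(a, b)
        assert d.same_family and d.compared_region == "LTRs"

    def test_all_regions_below_threshold(self, rng):
        a = syn.generate_background(1500, 0.5, 22)
        b = syn._mutate(a, 0.35, rng)  # ~70% overall
        d = families.same_family(rec("a", a), rec("b", b))
        assert not d.same_family

    def test_whole_fallback_when_unannotated(self):
        s = syn.generate_background(500, 0.5, 23)
        d = families.same_family(rec("a", s), rec("b", s), regions=("LTRs", "internal"))
        assert d.same_family and d.compared_region == "whole"


class TestFilterKnown:
    def test_exact_copy_excluded(self):
        s = syn.generate_background(1500, 0.5, 30)
        lib = [masking.RepeatLibraryEntry("K", ("Retroelement", None, None, None), s)]
        novel, decisions = families.filter_known([rec("a", s)], lib)
        assert novel == [] and decisions[0].same_family

    def test_related_excluded_and_distant_retained(self, rng):
        s = syn.generate_background(1500, 0.5, 31)
        lib = [masking.RepeatLibraryEntry("K", ("Retroelement", None, None, None), s)]
        related = syn._mutate(s, 0.15, rng)  # ~85% identity -> excluded by 80/80
        distant = syn._mutate(s, 0.45, rng)  # ~65% identity -> novel
        novel, _ = families.filter_known([rec("rel", related), rec("dist", distant)], lib)
        assert [r.element_id for r in novel] == ["dist"]


class TestCopyNumber:
    def test_planted_copies_counted(self, rng):
        element = syn.generate_background(2000, 0.5, 40)
        bg = syn.generate_background(50_000, 0.46, 41)
        pieces, prev = [], 0
        for p in (5000, 15_000, 25_000, 35_000, 45_000):
            pieces += [bg[prev:p], syn._mutate(element, 0.10, rng)]
            prev = p
        pieces.append(bg[prev:])
        genome = "".join(pieces)
        est = families.estimate_copy_number(rec("e", element), {"chr": genome})
        assert est.count == 5
        assert all(h[3] >= 0.8 and h[4] >= 0.8 for h in est.hits)

    def test_absent_element_zero(self):
        element = syn.generate_background(1000, 0.5, 42)
        genome = syn.generate_background(20_000, 0.46, 43)
        assert families.estimate_copy_number(rec("e", element), {"chr": genome}).count == 0

    def test_half_fragment_fails_coverage(self, rng):
        element = syn.generate_background(2000, 0.5, 44)
        bg = syn.generate_background(30_000, 0.46, 45)
        genome = bg[:10_000] + element + bg[10_000:20_000] + element[:1000] + bg[20_000:]
        est = families.estimate_copy_number(rec("e", element), {"chr": genome})
        assert est.count == 1

    def test_empty_genomes_error(self):
        with pytest.raises(ValueError):
            families.estimate_copy_number(rec("e", "ACGT" * 100), {})


class TestMembership:
    @pytest.mark.parametrize(
        "target,others,expected",
        [
            (0.90, [], True),  # exclusive hit
            (0.92, [0.75], True),  # gap 17 points
            (0.85, [0.82], False),  # gap 3 points
            (0.90, [0.80], True),  # gap exactly at the 10-point margin
        ],
    )
    def test_margin_rule(self, target, others, expected):
        assert families.assign_membership(target, others) is expected


class TestThresholdEdges:
    """Inclusive semantics of the 80/80 and 95/95 rules, exactly at threshold."""

    def test_identity_exactly_080_is_same_family(self):
        a = "A" * 100
        b = "A" * 80 + "C" * 20  # glocal identity exactly 0.80
        d = families.same_family(rec("a", a), rec("b", b), regions=("whole",))
        assert d.identity == pytest.approx(0.80) and d.same_family

    def test_identity_below_080_is_not(self):
        a = "A" * 100
        b = "A" * 79 + "C" * 21
        d = families.same_family(rec("a", a), rec("b", b), regions=("whole",))
        assert not d.same_family

    def test_dedup_exactly_095(self):
        a = "A" * 100
        b = "A" * 95 + "C" * 5
        assert len(families.dedup_candidates([rec("a", a), rec("b", b)])) == 1
        c = "A" * 94 + "C" * 6
        assert len(families.dedup_candidates([rec("a", a), rec("c", c)])) == 2

    def test_copy_number_near_080_threshold(self):
        element = syn.generate_background(1000, 0.5, 50)
        # one planted copy with exactly 200 substitutions (identity ~0.80),
        # leaving an intact stretch for seeding
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        copy = list(element)
        for i in list(range(0, 400, 4)) + list(range(600, 1000, 4)):
            copy[i] = flip[copy[i]]
        bg = syn.generate_background(20_000, 0.46, 51)
        genome = bg[:10_000] + "".join(copy) + bg[10_000:]
        est = families.estimate_copy_number(rec("e", element), {"chr": genome})
        assert est.count == 1
        (_, _, _, ident, cov), = est.hits
        assert ident >= 0.80 and cov >= 0.80


class TestPartition:
    def test_two_planted_families_recovered(self, rng):
        base1 = syn.generate_background(2000, 0.5, 60)
        base2 = syn._mutate(base1, 0.35, rng)  # ~65% between families
        els = [rec(f"A{i}", syn._mutate(base1, 0.075, rng)) for i in range(6)]
        els += [rec(f"B{i}", syn._mutate(base2, 0.075, rng)) for i in range(6)]
        fams = families.single_linkage_families(els, regions=("whole",))
        parts = sorted(sorted(e.element_id for e in f) for f in fams)
        assert len(parts) == 2
        assert {p[0][0] for p in parts} == {"A", "B"}
        assert all(x[0] == p[0][0] for p in parts for x in p)

    def test_designations(self):
        assert families.make_designation("Copia", "Fam1", "acc7") == "RLC_Fam1_acc7"
        assert families.make_designation("Gypsy", "F", "a") == "RLG_F_a"
        assert families.make_designation(None, "F", "a") == "RLX_F_a"
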