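"""Structural LTR discovery: pair search, TSD/PBS/PPT, coding, tandem arrays."""

import numpy as np
import pytest

from repeatscape import ltr, synthetic as syn
from repeatscape._align import revcomp
from tests.conftest import plant_one


class TestFindPairs:
    def test_exact_element_recovered(self, autonomous_element):
        genome, rec = plant_one(*autonomous_element, age=0, tsd=5)
        cands = ltr.find_ltr_pairs(genome, seq_id="s")
        assert len(cands) == 1
        assert abs(cands[0].start - rec.start) <= 5 and abs(cands[0].end - rec.end) <= 5
        c = ltr.annotate_candidate(genome, cands[0], None, None)
        assert c.ltr5_length == 215 and c.ltr3_length == 215
        assert c.ltr_similarity == 1.0
        assert (c.start, c.end) == (rec.start, rec.end)

    def test_no_duplication_empty(self):
        genome = syn.generate_background(50_000, 0.46, 21)
        assert ltr.find_ltr_pairs(genome) == []

    def test_aged_element_detected_with_true_similarity(self, trim_element):
        entry, anatomy = trim_element
        # age chosen so the expected LTR similarity is ~0.94
        age = 0.03 / (2 * 1.36e-8)
        genome, rec = plant_one(entry, anatomy, age=age, tsd=5, seed=8)
        cands = [ltr.annotate_candidate(genome, c, None, None) for c in ltr.find_ltr_pairs(genome)]
        assert len(cands) == 1
        c = cands[0]
        l5 = genome[rec.ltr5_start : rec.ltr5_end]
        l3 = genome[rec.ltr3_start : rec.ltr3_end]
        truth_sim = sum(a == b for a, b in zip(l5, l3)) / len(l5)
        assert c.ltr_similarity >= 0.80
        assert c.ltr_similarity == pytest.approx(truth_sim, abs=0.02)

    def test_box_constraints_hold(self, trim_element, autonomous_element):
        params = ltr.DetectorParams()
        genome, _ = plant_one(*autonomous_element, age=1e6, tsd=5, seed=5)
        for c in ltr.find_ltr_pairs(genome, params):
            assert params.min_ltr <= c.ltr5_length <= params.max_ltr
            internal = c.ltr3_start - c.ltr5_end
            assert params.min_internal <= internal <= params.max_internal
            assert c.ltr_similarity >= params.min_ltr_similarity - 1e-9

    def test_determinism(self, trim_element):
        genome, _ = plant_one(*trim_element, age=1e6, tsd=4, seed=6)
        assert ltr.find_ltr_pairs(genome) == ltr.find_ltr_pairs(genome)


class TestTSD:
    def test_planted_tsd_recovered(self, autonomous_element):
        genome, rec = plant_one(*autonomous_element, age=0, tsd=5)
        c = ltr.find_ltr_pairs(genome)[0]
        c = ltr.annotate_candidate(genome, c, None, None)
        assert c.tsd == rec.tsd
        assert (c.start, c.end) == (rec.start, rec.end)

    def test_no_tsd_usually_null(self, trim_element):
        # pristine elements with random flanks: a chance anchored duplication
        # of >= 4 bp has probability ~0.005 per element
        entry, anatomy = trim_element
        false_hits = 0
        for i in range(40):
            genome, _ = plant_one(entry, anatomy, bg_len=8000, pos=4000, age=0, tsd=0, seed=i, bg_seed=100 + i)
            c = ltr.annotate_candidate(genome, ltr.find_ltr_pairs(genome)[0], None, None)
            false_hits += c.tsd is not None
        assert false_hits <= 2

    def test_longest_duplication_wins(self, trim_element):
        entry, anatomy = trim_element
        bg = syn.generate_background(8000, 0.46, 55)
        # hand-build flanks: 6-bp duplication whose last 4 bp also match
        tsd6 = "GAGGCT"
        genome = bg[:4000] + tsd6 + entry.sequence + tsd6 + bg[4000:]
        cands = ltr.find_ltr_pairs(genome)
        c = ltr.annotate_candidate(genome, cands[0], None, None)
        assert c.tsd == tsd6

    def test_element_at_edge_gives_null(self, trim_element):
        entry, anatomy = trim_element
        genome = entry.sequence + syn.generate_background(5000, 0.46, 56)
        cands = ltr.find_ltr_pairs(genome)
        if cands:
            tsd, _, _ = ltr.detect_tsd(genome, cands[0])
            assert tsd is None


class TestPBS:
    def test_planted_trna_identified(self, autonomous_element, trna_set):
        genome, rec = plant_one(*autonomous_element, age=0, tsd=5)
        c = ltr.annotate_candidate(genome, ltr.find_ltr_pairs(genome)[0], trna_set, None)
        assert c.pbs is not None and c.pbs.trna_id == "Lys"
        assert c.pbs.match_length >= 12

    def test_scrambled_internal_null(self, trim_element, trna_set, rng):
        entry, anatomy = trim_element
        # destroy the PBS by replacing the first 30 internal bases
        seq = entry.sequence
        scrambled = seq[:375] + syn._random_seq(rng, 30) + seq[405:]
        entry2 = type(entry)(entry.entry_id, entry.classification, scrambled)
        genome, _ = plant_one(entry2, anatomy, age=0, tsd=0)
        c = ltr.find_ltr_pairs(genome)[0]
        c.strand = "+"
        assert ltr.detect_pbs(genome, c, trna_set) is None

    def test_tie_breaks_to_smallest_id(self, trim_element):
        entry, anatomy = trim_element
        genome, _ = plant_one(entry, anatomy, age=0, tsd=0)
        c = ltr.find_ltr_pairs(genome)[0]
        c.strand = "+"
        tail = revcomp(c.internal_seq[:18])  # both tRNAs share the planted 3' end
        trnas = {"Zeb": "G" * 40 + tail, "Abe": "C" * 40 + tail}
        hit = ltr.detect_pbs(genome, c, trnas)
        assert hit is not None and hit.trna_id == "Abe"

    def test_empty_trna_error(self, trim_element):
        entry, anatomy = trim_element
        genome, _ = plant_one(entry, anatomy, age=0, tsd=0)
        c = ltr.find_ltr_pairs(genome)[0]
        with pytest.raises(ValueError):
            ltr.detect_pbs(genome, c, {})


class TestPPT:
    def test_planted_pure_purine(self, trim_element):
        genome, _ = plant_one(*trim_element, age=0, tsd=0)
        c = ltr.find_ltr_pairs(genome)[0]
        c.strand = "+"
        hit = ltr.detect_ppt(genome, c)
        assert hit is not None and hit.purine_fraction == 1.0

    def test_pyrimidine_junction_null(self, trim_element, rng):
        entry, anatomy = trim_element
        seq = entry.sequence
        pyr = "".join(np.array(list("CT"))[rng.integers(0, 2, 40)])
        doctored = seq[: 1898 - 375 - 40] + pyr + seq[1898 - 375 :]
        entry2 = type(entry)(entry.entry_id, entry.classification, doctored)
        genome, _ = plant_one(entry2, anatomy, age=0, tsd=0)
        cands = ltr.find_ltr_pairs(genome)
        c = cands[0]
        c.strand = "+"
        assert ltr.detect_ppt(genome, c) is None

    def test_threshold_boundary_inclusive(self, trim_element):
        entry, anatomy = trim_element
        # exactly 13 purines of 15 immediately before the 3'LTR
        window = "GAGAGAGAGAGAGCT"
        assert sum(b in "AG" for b in window) == 13
        seq = entry.sequence
        doctored = seq[: 1898 - 375 - 15] + window + seq[1898 - 375 :]
        # surround with pyrimidines so no richer window competes
        doctored = doctored[: 1898 - 375 - 30] + "CT" * 7 + "C" + doctored[1898 - 375 - 15 :]
        entry2 = type(entry)(entry.entry_id, entry.classification, doctored)
        genome, _ = plant_one(entry2, anatomy, age=0, tsd=0)
        c = ltr.find_ltr_pairs(genome)[0]
        c.strand = "+"
        hit = ltr.detect_ppt(genome, c)
        assert hit is not None and hit.purine_fraction == pytest.approx(13 / 15)


class TestCoding:
    def test_autonomous_all_domains_one_frame(self, autonomous_element, protein_library):
        genome, _ = plant_one(*autonomous_element, age=0, tsd=5)
        c = ltr.annotate_candidate(genome, ltr.find_ltr_pairs(genome)[0], None, protein_library)
        assert c.classification == "autonomous"
        frames = {h.frame for h in c.coding}
        best_frame = max(frames, key=lambda f: sum(h.frame == f for h in c.coding))
        domains_in_frame = {h.domain for h in c.coding if h.frame == best_frame}
        assert domains_in_frame == {"GAG", "AP", "INT", "RT", "RH"}

    def test_noncoding_short_element_is_trim(self, trim_element, protein_library):
        genome, _ = plant_one(*trim_element, age=0, tsd=4)
        c = ltr.annotate_candidate(genome, ltr.find_ltr_pairs(genome)[0], None, protein_library)
        assert c.classification == "TRIM"

    def test_short_fragment_not_autonomous(self, trim_element, protein_library):
        entry, anatomy = trim_element
        # plant only a short AP fragment inside the internal region
        from repeatscape.synthetic import _CODON

        frag = "".join(_CODON[a] for a in protein_library["AP"][:20])
        seq = entry.sequence
        doctored = seq[:600] + frag + seq[600 + len(frag) :]
        entry2 = type(entry)(entry.entry_id, entry.classification, doctored)
        genome, _ = plant_one(entry2, anatomy, age=0, tsd=0)
        c = ltr.annotate_candidate(genome, ltr.find_ltr_pairs(genome)[0], None, protein_library)
        assert c.classification != "autonomous"
        assert any(h.domain == "AP" for h in c.coding)

    def test_empty_library_degrades_to_length(self, trim_element):
        genome, _ = plant_one(*trim_element, age=0, tsd=0)
        c = ltr.find_ltr_pairs(genome)[0]
        hits, classification = ltr.assess_coding(genome, c, {})
        assert hits == [] and classification == "TRIM"

    def test_superfamily_from_domain_order(self):
        hits = [
            ltr.DomainHit("INT", 0, 100, 200, 50),
            ltr.DomainHit("RT", 0, 300, 400, 50),
        ]
        assert ltr.infer_superfamily(hits) == "Copia"
        hits = [
            ltr.DomainHit("RT", 1, 100, 200, 50),
            ltr.DomainHit("INT", 1, 300, 400, 50),
        ]
        assert ltr.infer_superfamily(hits) == "Gypsy"


class TestTandem:
    def _tandem_genome(self, element, n, gap_seq=""):
        bg = syn.generate_background(12_000, 0.46, 77)
        arr = gap_seq.join([element] * n)
        return bg[:6000] + arr + bg[6000:], 6000, len(arr)

    def test_four_in_tandem_flagged_as_four(self, trim_element):
        entry, _ = trim_element
        genome, start, _ = self._tandem_genome(entry.sequence, 4)
        cands = ltr.find_ltr_pairs(genome)
        cands = [ltr.annotate_candidate(genome, c, None, None) for c in cands]
        out = ltr.resolve_tandem(cands)
        assert len(out) == 4
        assert all(c.tandem for c in out)
        # within a perfect tandem the element phase is ambiguous by a few bp
        # (every flank window recurs at the array period); each call must
        # still line up with one planted unit, not a multi-unit mega-element
        for k, c in enumerate(out):
            assert abs(c.start - (start + 1898 * k)) <= 10
            assert abs(c.end - (start + 1898 * (k + 1))) <= 10

    def test_single_element_unchanged(self, trim_element):
        genome, _ = plant_one(*trim_element, age=0, tsd=5)
        cands = [ltr.annotate_candidate(genome, c, None, None) for c in ltr.find_ltr_pairs(genome)]
        out = ltr.resolve_tandem(cands)
        assert len(out) == 1 and not out[0].tandem

    def test_distant_copies_not_tandem(self, trim_element):
        entry, anatomy = trim_element
        bg = syn.generate_background(20_000, 0.46, 78)
        gap = syn.generate_background(5000, 0.46, 79)
        genome = bg[:5000] + entry.sequence + gap + entry.sequence + bg[5000:]
        cands = [ltr.annotate_candidate(genome, c, None, None) for c in ltr.find_ltr_pairs(genome)]
        out = ltr.resolve_tandem(cands)
        assert len(out) == 2 and not any(c.tandem for c in out)
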