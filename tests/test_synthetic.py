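"""Generator: background, consensus anatomy, planting, truth bookkeeping."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from repeatscape import synthetic as syn
from repeatscape._align import revcomp
from tests.conftest import plant_one


class TestBackground:
    def test_deterministic(self):
        assert syn.generate_background(100, 0.5, 0) == syn.generate_background(100, 0.5, 0)

    def test_degenerate_composition(self):
        assert set(syn.generate_background(10_000, 0.0, 5)) <= {"A", "T"}
        assert set(syn.generate_background(10_000, 1.0, 5)) <= {"C", "G"}

    def test_gc_within_binomial_ci(self):
        # 3 sigma of Binomial(n=100000, p=0.46)
        s = syn.generate_background(100_000, 0.46, 7)
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.46) < 3 * math.sqrt(0.46 * 0.54 / 100_000)

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError):
            syn.generate_background(0, 0.5, 1)
        with pytest.raises(ValueError):
            syn.generate_background(10, 1.5, 1)


class TestConsensus:
    def test_autonomous_dimensions(self, autonomous_element):
        entry, anatomy = autonomous_element
        assert len(entry.sequence) == 5132  # 215 + 4702 + 215
        assert anatomy["ltr5"] == (0, 215)
        assert anatomy["ltr3"] == (215 + 4702, 5132)
        ltr5 = entry.sequence[:215]
        ltr3 = entry.sequence[-215:]
        assert ltr5 == ltr3
        assert ltr5.startswith("TG") and ltr5.endswith("CA")

    def test_trim_dimensions_and_noncoding(self, trim_element):
        entry, anatomy = trim_element
        assert len(entry.sequence) == 1898  # 375 + 1148 + 375
        internal = entry.sequence[375:-375]
        assert syn._longest_orf_codons(internal) < 300

    def test_pbs_complementary_to_trna(self, autonomous_element, trna_set):
        entry, anatomy = autonomous_element
        internal = entry.sequence[215 : 215 + 4702]
        pbs = internal[: syn.PBS_LENGTH]
        trna = trna_set[anatomy["trna_id"]]
        assert pbs == revcomp(trna[-syn.PBS_LENGTH :])

    def test_ppt_is_purine_run(self, autonomous_element):
        entry, _ = autonomous_element
        internal = entry.sequence[215 : 215 + 4702]
        ppt = internal[-syn.PPT_LENGTH :]
        assert len(ppt) == 15 and set(ppt) <= {"A", "G"}

    def test_autonomous_orf_carries_domains(self, autonomous_element, protein_library):
        entry, anatomy = autonomous_element
        internal = entry.sequence[215 : 215 + 4702]
        s, e = anatomy["orf"]
        aa = str(Seq(internal[s:e]).translate())
        for name in ("GAG", "AP", "INT", "RT", "RH"):
            assert protein_library[name] in aa

    def test_deterministic(self):
        a = syn.build_te_consensus("ltr_rt_trim", {"ltr_length": 150, "internal_length": 1100}, seed=9)
        b = syn.build_te_consensus("ltr_rt_trim", {"ltr_length": 150, "internal_length": 1100}, seed=9)
        assert a[0].sequence == b[0].sequence

    def test_tir_and_satellite(self):
        entry, anatomy = syn.build_te_consensus("tir_dna", {"length": 2000, "tir_length": 13}, seed=1)
        assert len(entry.sequence) == 2000
        assert entry.sequence[-13:] == revcomp(entry.sequence[:13])
        sat, sanat = syn.build_te_consensus("satellite_array", {"monomer_length": 120, "copies": 8}, seed=1)
        assert len(sat.sequence) == 960
        assert sat.sequence[:120] * 8 == sat.sequence

    def test_inconsistent_lengths_error(self):
        with pytest.raises(ValueError):
            syn.build_te_consensus("ltr_rt_trim", {"ltr_length": 50, "internal_length": 1100}, seed=0)
        with pytest.raises(ValueError):
            syn.build_te_consensus(
                "ltr_rt_autonomous", {"ltr_length": 200, "internal_length": 1000}, seed=0
            )  # coding ORF cannot fit


class TestPlanting:
    def test_zero_age_identity_and_tsd(self, trim_element):
        genome, rec = plant_one(*trim_element, age=0, tsd=5)
        assert genome[rec.ltr5_start : rec.ltr5_end] == genome[rec.ltr3_start : rec.ltr3_end]
        assert genome[rec.start - 5 : rec.start] == genome[rec.end : rec.end + 5] == rec.tsd
        assert genome[rec.start : rec.end] == rec.sequence

    def test_divergence_matches_closed_form(self, trim_element):
        # per-site substitution probability m = r*age on each LTR copy:
        # P(site differs) = 2m(1-m) + (2/3)m^2; 200 replicates of a 375-bp LTR
        entry, anatomy = trim_element
        m = 1.36e-8 * 1e6
        expected = 2 * m * (1 - m) + (2 / 3) * m * m
        L, n = 375, 200
        mismatches = 0
        for i in range(n):
            genome, rec = plant_one(entry, anatomy, bg_len=4000, pos=2000, age=1e6, tsd=0, seed=i)
            l5 = genome[rec.ltr5_start : rec.ltr5_end]
            l3 = genome[rec.ltr3_start : rec.ltr3_end]
            mismatches += sum(a != b for a, b in zip(l5, l3))
        p_hat = mismatches / (n * L)
        se = math.sqrt(expected * (1 - expected) / (n * L))
        assert abs(p_hat - expected) < 3 * se

    def test_expected_divergence_field(self, trim_element):
        _, rec = plant_one(*trim_element, age=2e6)
        assert rec.expected_ltr_divergence == pytest.approx(2 * 1.36e-8 * 2e6)

    def test_nesting_grows_host_by_guest_plus_tsds(self, trim_element):
        entry, anatomy = trim_element
        bg = syn.generate_background(10_000, 0.46, 1)
        lib = {entry.entry_id: (entry, anatomy)}
        specs = [
            syn.InsertionSpec(entry.entry_id, "ltr_rt_trim", 5000, tsd_length=5, name="host"),
            syn.InsertionSpec(
                entry.entry_id, "ltr_rt_trim", 600, tsd_length=4, nested_in="host", name="guest"
            ),
        ]
        genome, truth = syn.plant_insertions(bg, lib, specs, seed=4)
        host = next(r for r in truth if r.feature_id == "host")
        guest = next(r for r in truth if r.feature_id == "guest")
        assert host.end - host.start == 1898 + 1898 + 2 * 4
        assert guest.nested_in == "host"
        assert host.start < guest.start and guest.end < host.end
        # coordinate integrity for both records
        assert genome[host.start : host.end] == host.sequence
        assert genome[guest.start : guest.end] == guest.sequence
        assert genome[guest.start - 4 : guest.start] == genome[guest.end : guest.end + 4]

    def test_errors(self, trim_element):
        entry, anatomy = trim_element
        lib = {entry.entry_id: (entry, anatomy)}
        with pytest.raises(ValueError, match="unknown element"):
            syn.plant_insertions("ACGT" * 100, lib, [syn.InsertionSpec("nope", "ltr_rt_trim", 5)], 0)
        with pytest.raises(ValueError, match="unplanted"):
            syn.plant_insertions(
                "ACGT" * 100,
                lib,
                [syn.InsertionSpec(entry.entry_id, "ltr_rt_trim", 5, nested_in="ghost")],
                0,
            )
        with pytest.raises(ValueError):
            syn.InsertionSpec(entry.entry_id, "ltr_rt_trim", 5, tsd_length=3)


class TestSSRAndLowComplexityPlanting:
    def test_tract_construction(self):
        genome, recs = syn.plant_ssrs("A" * 100, [syn.SSRSpec("GA", 12, 50)], seed=0)
        rec = recs[0]
        assert rec.end - rec.start == 24
        assert genome[rec.start : rec.end] == "GA" * 12
        assert rec.category == "simple_repeat"

    def test_motif_canonicalized_in_truth(self):
        from repeatscape.ssr import canonical_motif

        _, recs = syn.plant_ssrs("ACGT" * 50, [syn.SSRSpec("CCG", 10, 100)], seed=0)
        assert recs[0].motif == canonical_motif("CCG")

    def test_frequency_arithmetic(self):
        genome = syn.generate_background(72_000 - 10 * 24, 0.46, 3)
        specs = [syn.SSRSpec("GA", 12, 5_000 * (i + 1)) for i in range(10)]
        genome, recs = syn.plant_ssrs(genome, specs, seed=0)
        assert len(recs) == 10
        assert len(genome) / len(recs) / 1000 == pytest.approx(7.2, abs=0.01)

    def test_invalid_motif(self):
        with pytest.raises(ValueError):
            syn.plant_ssrs("ACGT" * 10, [syn.SSRSpec("AXG", 5, 0)], seed=0)

    def test_low_complexity_run(self):
        genome, recs = syn.plant_low_complexity("ACGT" * 100, [syn.LowComplexitySpec(10, 50, "AT")], 0)
        assert set(genome[recs[0].start : recs[0].end]) <= {"A", "T"}

    def test_existing_truth_shifted(self, trim_element):
        genome, rec = plant_one(*trim_element, age=0, tsd=0)
        old = (rec.start, rec.end)
        genome2, _ = syn.plant_ssrs(genome, [syn.SSRSpec("AG", 10, 5)], 0, existing_truth=[rec])
        assert (rec.start, rec.end) == (old[0] + 20, old[1] + 20)
        assert genome2[rec.start : rec.end] == rec.sequence


class TestTruthIO:
    def test_gff3_coordinate_convention(self, tmp_path):
        rec = syn.PlantedTruthRecord("x", "satellite", "chr", 0, 10, sequence="A" * 10)
        gff, _ = syn.write_truth([rec], tmp_path / "t")
        from repeatscape._io import parse_gff3

        rows = parse_gff3(gff)
        text = gff.read_text()
        assert "\t1\t10\t" in text
        assert rows[0]["start"] == 0 and rows[0]["end"] == 10

    def test_empty_truth_header_only(self, tmp_path):
        gff, tsv = syn.write_truth([], tmp_path / "e")
        assert gff.read_text().strip() == "##gff-version 3"
        assert syn.read_truth(tsv) == []

    def test_round_trip_random_records(self, tmp_path, rng):
        records = []
        for i in range(50):
            s = int(rng.integers(0, 10_000))
            ln = int(rng.integers(10, 500))
            records.append(
                syn.PlantedTruthRecord(
                    feature_id=f"f{i}",
                    category=str(rng.choice(list(syn.CATEGORIES))),
                    seq_id="chr1",
                    start=s,
                    end=s + ln,
                    age_years=float(rng.uniform(0, 3e6)) if i % 2 else None,
                    tsd="ACGTA" if i % 3 == 0 else None,
                    sequence="A" * ln,
                )
            )
        _, tsv = syn.write_truth(records, tmp_path / "r")
        assert syn.read_truth(tsv) == records


class TestSimulate:
    def test_determinism_and_integrity(self):
        cfg = syn.GeneratorConfig(
            seed=11,
            background_length=30_000,
            elements=[
                {"kind": "ltr_rt_trim", "element_id": "T", "ltr_length": 200, "internal_length": 1200}
            ],
            insertion_events=[
                syn.InsertionSpec("T", "ltr_rt_trim", 10_000, age_years=5e5, tsd_length=4)
            ],
            ssr_events=[syn.SSRSpec("AG", 10, 25_000)],
            low_complexity_events=[syn.LowComplexitySpec(28_000, 80, "A")],
        )
        r1 = syn.simulate(cfg)
        r2 = syn.simulate(cfg)
        assert r1.genome == r2.genome
        assert r1.truth == r2.truth
        for rec in r1.truth:
            assert r1.genome[rec.start : rec.end] == rec.sequence
            if rec.tsd:
                t = len(rec.tsd)
                assert r1.genome[rec.start - t : rec.start] == r1.genome[rec.end : rec.end + t]
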