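"""Ground-truth validation suites.

Each function builds a synthetic scenario with the generator, runs the
corresponding analysis stage, and returns the measured quantities together
with the problem size.  These are the package's standard self-checks: the
divergence law of the generator, masking recovery and its exhaustive-scan
oracle, the SSR caller against a brute-force tandem scan, structural LTR
recovery / false-positive / TSD rates, dating recovery, and family-partition
recovery under the 80-80 rule.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path

import numpy as np

from . import dating, families, ltr, masking, pipeline, ssr
from . import synthetic as syn
from ._align import revcomp


def _spawn(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed, k]).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# generator divergence law
# ---------------------------------------------------------------------------


def divergence_law(seed: int, replicates: int = 200, ltr_length: int = 500, age: float = 1e6) -> dict:
    """Mean LTR-pair p-distance over seeded replicates vs 2*r*age.

    Under the binomial substitution model each LTR mutates per site with
    probability m = r*age, so P(site differs) = 2m(1-m) + (2/3)m^2, slightly
    below the small-age limit 2*r*age.
    """
    r = syn.DEFAULT_RATE_R
    entry, anatomy = syn.build_te_consensus(
        "ltr_rt_trim", {"ltr_length": ltr_length, "internal_length": 1000, "element_id": "X"},
        seed=_spawn(seed, 1),
    )
    lib = {"X": (entry, anatomy)}
    bg = syn.generate_background(2 * ltr_length + 2000, 0.46, _spawn(seed, 2))
    mism = 0
    for i in range(replicates):
        genome, truth = syn.plant_insertions(
            bg, lib,
            [syn.InsertionSpec("X", "ltr_rt_trim", 500, age_years=age, tsd_length=0)],
            seed=_spawn(seed, 100 + i),
        )
        t = truth[0]
        stats = dating.align_ltr_pair(
            genome[t.ltr5_start : t.ltr5_end], genome[t.ltr3_start : t.ltr3_end]
        )
        mism += stats.mismatches
    n_sites = replicates * ltr_length
    target = 2 * r * age
    return {
        "mean_p": mism / n_sites,
        "target": target,
        "se": math.sqrt(target * (1 - target) / n_sites),
        "n": replicates,
    }


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------


def _masking_library(seed: int):
    kinds = [
        ("ltr_rt_autonomous", {"ltr_length": 215, "internal_length": 4702}),
        ("ltr_rt_trim", {"ltr_length": 375, "internal_length": 1148}),
        ("tir_dna", {"length": 3000}),
        ("satellite_array", {"monomer_length": 150, "copies": 12}),
    ]
    library = {}
    for j, (kind, pars) in enumerate(kinds):
        entry, anatomy = syn.build_te_consensus(
            kind, dict(pars, element_id=f"K{j}"), seed=_spawn(seed, 10 + j)
        )
        library[f"K{j}"] = (entry, anatomy)
    return library


def masking_recovery(seed: int, genome_length: int = 2_000_000, repeat_fraction: float = 0.6) -> dict:
    """Mask a large genome with ~repeat_fraction planted content; report the
    total masked percentage vs truth and the boundary error of exact copies."""
    rng = np.random.default_rng(_spawn(seed, 20))
    library = _masking_library(seed)
    sizes = {k: len(e.sequence) for k, (e, _) in library.items()}
    weights = {"K0": 0.55, "K1": 0.12, "K2": 0.20, "K3": 0.13}
    target_repeat = genome_length * repeat_fraction
    picks: list[str] = []
    planted = 0.0
    while planted < target_repeat:
        k = str(rng.choice(list(weights), p=list(weights.values())))
        picks.append(k)
        planted += sizes[k] + 10
    bg_len = max(50_000, genome_length - int(planted))
    bg = syn.generate_background(bg_len, 0.46, _spawn(seed, 21))
    positions = np.sort(rng.choice(np.arange(1000, bg_len - 1000), size=len(picks), replace=False))
    specs = []
    for i, (k, pos) in enumerate(zip(picks, positions)):
        age = 0.0 if i % 10 == 0 else float(rng.uniform(0, 2e6))  # every 10th copy exact
        specs.append(
            syn.InsertionSpec(k, library[k][1]["kind"], int(pos), age_years=age, tsd_length=5)
        )
    genome, truth = syn.plant_insertions(bg, library, specs, seed=_spawn(seed, 22))
    # SSR tracts and low-complexity runs planted clear of the TE intervals
    occupied = [(t.start - 200, t.end + 200) for t in truth]

    def free_positions(n, span):
        out = []
        tries = 0
        while len(out) < n and tries < 10 * n:
            tries += 1
            p = int(rng.integers(1000, len(genome) - 1000))
            if not any(s <= p <= e for s, e in occupied):
                out.append(p)
                occupied.append((p - span - 200, p + span + 200))
        return sorted(out, reverse=True)

    ssr_specs = [syn.SSRSpec("GA", 15, p) for p in free_positions(20, 30)]
    genome, ssr_truth = syn.plant_ssrs(genome, ssr_specs, seed=_spawn(seed, 23), existing_truth=truth)
    truth += ssr_truth
    entries = [e for e, _ in library.values()]
    segments = masking.mask_sequence(genome, entries)
    loci = ssr.find_ssrs(genome)
    segments += [
        masking.MaskedSegment("seq", x.start, x.end, "+", x.motif, 1.0, x.length, "Simple repeat")
        for x in loci
    ]
    segments += masking.detect_low_complexity(genome)
    resolved = masking.resolve_overlaps(segments)
    summary = masking.summarize_repeats(resolved, len(genome))
    masked_percent = float(summary.rows[summary.rows.category == "Total"].percent.iloc[0])
    truth_percent = 100.0 * sum(t.end - t.start for t in truth) / len(genome)
    # boundary error of exact (age 0) TE copies
    exact = [t for s, t in zip(specs, truth) if s.age_years == 0.0]
    errs = []
    by_start = sorted(resolved, key=lambda g: g.start)
    for t in exact:
        best = None
        for g in by_start:
            ov = min(g.end, t.end) - max(g.start, t.start)
            if ov > 0 and (best is None or ov > best[0]):
                best = (ov, g)
        if best is None:
            errs.append(len(genome))
        else:
            errs.append(max(abs(best[1].start - t.start), abs(best[1].end - t.end)))
    return {
        "masked_percent": masked_percent,
        "truth_percent": truth_percent,
        "exact_copy_max_boundary_error": max(errs) if errs else None,
        "n_exact_copies": len(exact),
        "n": len(genome),
    }


def masking_oracle_agreement(seed: int, cases: int = 20) -> dict:
    """Seeded scan vs exhaustive all-diagonals scan on small genomes."""
    rng = np.random.default_rng(_spawn(seed, 30))
    agree = 0
    for i in range(cases):
        entries = [
            masking.RepeatLibraryEntry(
                f"E{j}", ("Retroelement", None, None, None),
                syn.generate_background(int(rng.integers(150, 400)), 0.5, _spawn(seed, 300 + 10 * i + j)),
            )
            for j in range(3)
        ]
        bg = syn.generate_background(1500, 0.5, _spawn(seed, 400 + i))
        copy = syn._mutate(entries[0].sequence, float(rng.uniform(0.0, 0.15)), rng)
        genome = bg[:300] + copy + bg[300:900] + revcomp(entries[1].sequence) + bg[900:]
        a = masking.mask_sequence(genome, entries, min_score=40, min_identity=0.7)
        b = masking.mask_sequence_oracle(genome, entries, min_score=40, min_identity=0.7)
        agree += a == b
    return {"agreement": agree / cases, "n": cases}


# ---------------------------------------------------------------------------
# SSR
# ---------------------------------------------------------------------------


def ssr_oracle_agreement(seed: int, genomes: int = 10, length: int = 100_000) -> dict:
    """Vectorized caller vs brute-force maximal-perfect-tandem oracle."""
    agree = 0
    for i in range(genomes):
        g = syn.generate_background(length, 0.46, _spawn(seed, 40 + i))
        g, _ = syn.plant_ssrs(
            g,
            [
                syn.SSRSpec("GA", 12, length // 5),
                syn.SSRSpec("CCG", 10, 2 * length // 5),
                syn.SSRSpec("A", 15, 3 * length // 5),
                syn.SSRSpec("ACGTA", 7, 4 * length // 5),
            ],
            seed=_spawn(seed, 50 + i),
        )
        agree += ssr.find_ssrs(g) == ssr.find_ssrs_oracle(g)
    return {"agreement": agree / genomes, "n": genomes}


def canonicalization_exhaustive() -> dict:
    """Rotation/reverse-complement equivalence classes partition the motif
    space for all irreducible motifs of unit <= 4."""
    import itertools

    ok = True
    total = 0
    for unit in (1, 2, 3, 4):
        motifs = [
            "".join(t)
            for t in itertools.product("ACGT", repeat=unit)
            if not ssr._is_reducible("".join(t))
        ]
        total += len(motifs)
        classes: dict[str, set] = {}
        for m in motifs:
            c = ssr.canonical_motif(m)
            ok &= ssr.canonical_motif(c) == c
            ok &= ssr.canonical_motif(revcomp(m)) == c
            classes.setdefault(c, set()).add(m)
        ok &= set().union(*classes.values()) == set(motifs)
    return {"ok": float(ok), "n": total}


# ---------------------------------------------------------------------------
# LTR discovery
# ---------------------------------------------------------------------------


def ltr_recovery(seed: int, n_elements: int = 40, tolerance_bp: int = 10) -> dict:
    """Recovery and TSD rates on single-copy elements with LTRs 100-1100 bp,
    internals 1-10 kb and ages up to 3 Myr."""
    rng = np.random.default_rng(_spawn(seed, 60))
    trnas = syn.default_trna_set()
    proteins = syn.default_protein_library()
    recovered = tsd_total = tsd_exact = 0
    for i in range(n_elements):
        ltr_len = int(rng.integers(100, 1101))
        internal = int(rng.integers(1000, 10_001))
        age = float(rng.uniform(0, 3e6))
        tsd_len = int(rng.choice([4, 5, 6]))
        entry, anatomy = syn.build_te_consensus(
            "ltr_rt_trim",
            {"ltr_length": ltr_len, "internal_length": internal, "element_id": "X"},
            seed=_spawn(seed, 600 + i),
        )
        bg = syn.generate_background(2 * (2 * ltr_len + internal) + 10_000, 0.46, _spawn(seed, 700 + i))
        genome, truth = syn.plant_insertions(
            bg, {"X": (entry, anatomy)},
            [syn.InsertionSpec("X", "ltr_rt_trim", len(bg) // 2, age_years=age, tsd_length=tsd_len)],
            seed=_spawn(seed, 800 + i),
        )
        t = truth[0]
        cands = ltr.scan_genome(genome, trnas, proteins, seq_id="s")
        hit = [
            c
            for c in cands
            if max(
                abs(c.start - t.start), abs(c.end - t.end),
                abs(c.ltr5_end - t.ltr5_end), abs(c.ltr3_start - t.ltr3_start),
            )
            <= tolerance_bp
        ]
        if hit:
            recovered += 1
            tsd_total += 1
            tsd_exact += hit[0].tsd == t.tsd
    return {
        "recovery_rate": recovered / n_elements,
        "tsd_exact_rate": tsd_exact / tsd_total if tsd_total else None,
        "n": n_elements,
    }


def ltr_false_positives(seed: int, length: int = 2_000_000) -> dict:
    """Structural candidates on a repeat-free background, per Mb."""
    bg = syn.generate_background(length, 0.46, _spawn(seed, 65))
    cands = ltr.find_ltr_pairs(bg)
    return {"false_per_mb": len(cands) / (length / 1e6), "n": length}


# ---------------------------------------------------------------------------
# dating
# ---------------------------------------------------------------------------


def dating_recovery(seed: int, ages_myr=(0.5, 1.0, 2.0, 3.0), replicates: int = 100) -> dict:
    """Median estimated insertion time vs planted age, per age."""
    entry, anatomy = syn.build_te_consensus(
        "ltr_rt_trim", {"ltr_length": 500, "internal_length": 1000, "element_id": "X"},
        seed=_spawn(seed, 70),
    )
    lib = {"X": (entry, anatomy)}
    bg = syn.generate_background(4000, 0.46, _spawn(seed, 71))
    out = {}
    for age_myr in ages_myr:
        age = age_myr * 1e6
        times = []
        for i in range(replicates):
            genome, truth = syn.plant_insertions(
                bg, lib,
                [syn.InsertionSpec("X", "ltr_rt_trim", 2000, age_years=age, tsd_length=0)],
                seed=_spawn(seed, int(72_000 + 1000 * age_myr + i)),
            )
            t = truth[0]
            est = dating.date_ltr_pair(
                "x", genome[t.ltr5_start : t.ltr5_end], genome[t.ltr3_start : t.ltr3_end]
            )
            times.append(est.T)
        med = float(np.median(times))
        out[age_myr] = {"median_T_myr": med / 1e6, "median_rel_err": abs(med - age) / age, "n": replicates}
    return out


# ---------------------------------------------------------------------------
# family rules
# ---------------------------------------------------------------------------


def family_partition(seed: int, members_per_family: int = 20) -> dict:
    """Two planted families (85% within, 65% between identity): single-linkage
    over the 80-80 rule must recover the planted partition exactly, and the
    dedup -> novelty funnel must be monotone."""
    rng = np.random.default_rng(_spawn(seed, 80))
    base1 = syn.generate_background(2000, 0.5, _spawn(seed, 81))
    base2 = syn._mutate(base1, 0.35, rng)  # ~65% identity between consensi
    els = [
        families.ElementRecord(f"A{i:02d}", syn._mutate(base1, 0.075, rng))
        for i in range(members_per_family)
    ]
    els += [
        families.ElementRecord(f"B{i:02d}", syn._mutate(base2, 0.075, rng))
        for i in range(members_per_family)
    ]
    fams = families.single_linkage_families(els, regions=("whole",))
    parts = sorted(sorted(e.element_id for e in f) for f in fams)
    exact = (
        len(parts) == 2
        and all(len(p) == members_per_family for p in parts)
        and all(x[0] == p[0][0] for p in parts for x in p)
    )
    unique = families.dedup_candidates(els)
    lib = [masking.RepeatLibraryEntry("K", ("Retroelement", None, None, None), base1)]
    novel, _ = families.filter_known(unique, lib)
    monotone = len(novel) <= len(unique) <= len(els)
    return {"partition_exact": float(exact), "funnel_monotone": float(monotone), "n": len(els)}


def rule_edges() -> dict:
    """Inclusive threshold semantics of the 95/95, 80/80 and margin rules on
    constructed boundary cases."""
    r = families.ElementRecord
    checks = [
        # dedup 95/95: exactly 95% identical joins, 94% does not
        len(families.dedup_candidates([r("a", "A" * 100), r("b", "A" * 95 + "C" * 5)])) == 1,
        len(families.dedup_candidates([r("a", "A" * 100), r("c", "A" * 94 + "C" * 6)])) == 2,
        # family 80/80: exactly 80% identity is same-family, 79% is not
        families.same_family(r("a", "A" * 100), r("b", "A" * 80 + "C" * 20), ("whole",)).same_family,
        not families.same_family(r("a", "A" * 100), r("b", "A" * 79 + "C" * 21), ("whole",)).same_family,
        # membership margin: a gap of exactly 10 points is a member, 9.9 is not
        families.assign_membership(0.90, [0.80], margin=0.10),
        not families.assign_membership(0.90, [0.801], margin=0.10),
        families.assign_membership(0.5, []),
    ]
    # copy-number 80/80: full copy counted, half fragment not
    element = syn.generate_background(2000, 0.5, 90)
    bg = syn.generate_background(30_000, 0.46, 91)
    genome = bg[:10_000] + element + bg[10_000:20_000] + element[:1000] + bg[20_000:]
    checks.append(families.estimate_copy_number(r("e", element), {"chr": genome}).count == 1)
    return {"ok": float(all(checks)), "n": len(checks)}


# ---------------------------------------------------------------------------
# end-to-end determinism
# ---------------------------------------------------------------------------


def _tree_hash(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes().replace(str(root).encode(), b"OUT"))
    return h.hexdigest()


def pipeline_determinism(seed: int, workdir: str | Path) -> dict:
    """run-all twice with one seed: the output trees must be byte-identical."""
    workdir = Path(workdir)
    cfg = syn.GeneratorConfig(
        seed=_spawn(seed, 95),
        background_length=120_000,
        elements=[
            {"kind": "ltr_rt_autonomous", "element_id": "AUTO1", "ltr_length": 215,
             "internal_length": 4702, "trna_id": "Lys"},
            {"kind": "ltr_rt_trim", "element_id": "TRIM1", "ltr_length": 375,
             "internal_length": 1148, "trna_id": "Met"},
            {"kind": "tir_dna", "element_id": "TIR1", "length": 2500},
        ],
        insertion_events=[
            syn.InsertionSpec("AUTO1", "ltr_rt_autonomous", 10_000, age_years=1e6, tsd_length=5),
            syn.InsertionSpec("TRIM1", "ltr_rt_trim", 40_000, age_years=5e5, tsd_length=4),
            syn.InsertionSpec("TIR1", "tir_dna", 70_000, tsd_length=0),
        ],
        ssr_events=[syn.SSRSpec("GA", 12, 20_000)],
        low_complexity_events=[syn.LowComplexitySpec(110_000, 120, "A")],
    )
    result = syn.simulate(cfg)
    simdir = workdir / "sim"
    simdir.mkdir(parents=True, exist_ok=True)
    syn.write_simulation(result, simdir / "sim")
    hashes = []
    for run in ("a", "b"):
        out = workdir / run
        pc = pipeline.PipelineConfig(
            genome=str(simdir / "sim.fasta"),
            repeat_library=str(simdir / "sim.library.fasta"),
            trna=str(simdir / "sim.trna.fasta"),
            proteins=str(simdir / "sim.proteins.fasta"),
            truth=str(simdir / "sim.truth.tsv"),
            outdir=str(out),
            seed=seed,
        )
        pipeline.run_pipeline(pc)
        hashes.append(_tree_hash(out))
    return {"identical": float(hashes[0] == hashes[1]), "n": 2}
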