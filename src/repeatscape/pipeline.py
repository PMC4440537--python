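"""End-to-end orchestration and evaluation against generator truth.

Stage order follows the discovery funnel: homology masking -> SSR catalog ->
structural LTR scan -> redundancy removal -> novelty filter -> structural
annotation / classification -> copy number -> dating.  Every run writes a
structured JSON log of all parameters so reruns are auditable; with a truth
table the predictions are scored (precision/recall per feature class,
boundary errors, TSD exact-match rate, age errors, classification confusion).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import dating, families, ltr, masking, ssr
from ._io import GFF3_HEADER, format_gff3_line, read_fasta, write_fasta
from .synthetic import PlantedTruthRecord, read_truth

logger = logging.getLogger("repeatscape.pipeline")


@dataclass
class PipelineConfig:
    genome: str  # FASTA path
    repeat_library: str | None = None
    trna: str | None = None
    proteins: str | None = None
    truth: str | None = None  # generator truth TSV, enables evaluation
    outdir: str = "repeatscape_out"
    seed: int = 0
    mask_min_score: int = 225
    mask_min_identity: float = 0.7
    mask_k: int = 11
    lc_window: int = 64
    lc_entropy_max: float = 1.0
    ssr_min_copies: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    dedup_identity: float = 0.95
    dedup_coverage: float = 0.95
    family_identity: float = 0.80
    family_coverage: float = 0.80
    membership_margin: float = 0.10
    dating_model: str = "raw_p"
    rate_r: float = dating.DEFAULT_RATE_R
    match_tolerance_bp: int = 10

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class EvaluationReport:
    per_class: dict  # class -> {precision, recall, n_truth, n_pred, n_matched}
    boundary_errors_bp: list[int]
    tsd_exact_rate: float | None
    age_relative_errors: list[float]
    classification_confusion: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _interval_match_graph(
    predictions: list[tuple[str, int, int]],
    truth: list[tuple[str, int, int]],
    min_reciprocal_overlap: float = 0.8,
    tolerance_bp: int | None = None,
) -> list[tuple[int, int]]:
    """Maximum bipartite matching of predicted to truth intervals.

    Admissible pairs overlap reciprocally by >= min_reciprocal_overlap and,
    when a tolerance is given, have both boundaries within tolerance_bp.
    """
    g = nx.Graph()
    pred_nodes = [("p", i) for i in range(len(predictions))]
    truth_nodes = [("t", j) for j in range(len(truth))]
    g.add_nodes_from(pred_nodes, bipartite=0)
    g.add_nodes_from(truth_nodes, bipartite=1)
    for i, (ps, p0, p1) in enumerate(predictions):
        for j, (ts, t0, t1) in enumerate(truth):
            if ps != ts:
                continue
            ov = min(p1, t1) - max(p0, t0)
            if ov <= 0:
                continue
            if ov < min_reciprocal_overlap * (p1 - p0) or ov < min_reciprocal_overlap * (t1 - t0):
                continue
            if tolerance_bp is not None and (abs(p0 - t0) > tolerance_bp or abs(p1 - t1) > tolerance_bp):
                continue
            g.add_edge(("p", i), ("t", j))
    if g.number_of_edges() == 0:
        return []
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=pred_nodes)
    return sorted(
        (node[1], matching[node][1]) for node in pred_nodes if node in matching
    )


def evaluate_against_truth(
    predictions: list[dict],
    truth: list[PlantedTruthRecord],
    match_tolerance_bp: int = 10,
) -> EvaluationReport:
    """Score predictions against the generator truth table.

    Each prediction is a dict with keys seq_id, start, end, category and
    optionally tsd, age_years, classification.  A prediction matches a truth
    record of the same class when the intervals reciprocally overlap >= 80%
    and both boundaries lie within the tolerance.
    """
    truth_ids = {t.seq_id for t in truth}
    for p in predictions:
        if truth_ids and p["seq_id"] not in truth_ids:
            raise ValueError(f"prediction on unknown sequence id {p['seq_id']!r}")
    classes = sorted({t.category for t in truth} | {p["category"] for p in predictions})
    per_class = {}
    boundary_errors: list[int] = []
    tsd_total = tsd_exact = 0
    age_errors: list[float] = []
    confusion: dict[str, dict[str, int]] = {}
    for cls in classes:
        preds = [p for p in predictions if p["category"] == cls]
        trs = [t for t in truth if t.category == cls]
        pairs = _interval_match_graph(
            [(p["seq_id"], p["start"], p["end"]) for p in preds],
            [(t.seq_id, t.start, t.end) for t in trs],
            tolerance_bp=match_tolerance_bp,
        )
        n_matched = len(pairs)
        per_class[cls] = {
            "n_pred": len(preds),
            "n_truth": len(trs),
            "n_matched": n_matched,
            "precision": (n_matched / len(preds)) if preds else None,
            "recall": (n_matched / len(trs)) if trs else None,
        }
        for pi, tj in pairs:
            p, t = preds[pi], trs[tj]
            boundary_errors.append(abs(p["start"] - t.start))
            boundary_errors.append(abs(p["end"] - t.end))
            if t.tsd is not None:
                tsd_total += 1
                if p.get("tsd") == t.tsd:
                    tsd_exact += 1
            if t.age_years is not None and p.get("age_years") is not None and t.age_years > 0:
                age_errors.append(abs(p["age_years"] - t.age_years) / t.age_years)
            if p.get("classification"):
                truth_cls = "TRIM" if (t.end - t.start) <= 4000 else "autonomous"
                confusion.setdefault(truth_cls, {}).setdefault(p["classification"], 0)
                confusion[truth_cls][p["classification"]] += 1
    return EvaluationReport(
        per_class=per_class,
        boundary_errors_bp=boundary_errors,
        tsd_exact_rate=(tsd_exact / tsd_total) if tsd_total else None,
        age_relative_errors=age_errors,
        classification_confusion=confusion,
    )


def _candidates_gff3(cands: list[ltr.LTRCandidate]) -> str:
    lines = [GFF3_HEADER]
    for c in cands:
        attrs = {
            "ID": f"{c.seq_id}:{c.start}-{c.end}",
            "ltr_similarity": f"{c.ltr_similarity:.4f}",
            "classification": c.classification,
        }
        if c.tsd:
            attrs["tsd"] = c.tsd
        if c.pbs:
            attrs["pbs"] = f"{c.pbs.trna_id}:{c.pbs.match_length}"
        if c.ppt:
            attrs["ppt"] = f"{c.ppt.start}-{c.ppt.end}:{c.ppt.purine_fraction:.2f}"
        if c.tandem:
            attrs["tandem_array"] = "true"
        lines.append(
            format_gff3_line(
                c.seq_id, "repeatscape", "LTR_retrotransposon", c.start, c.end, ".", c.strand, attrs
            )
        )
    return "\n".join(lines) + "\n"


def _candidates_frame(cands: list[ltr.LTRCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": c.seq_id,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "length": c.end - c.start,
                "ltr5_size": c.ltr5_length,
                "ltr3_size": c.ltr3_length,
                "ltr_similarity": round(c.ltr_similarity, 4),
                "tsd": c.tsd or "-",
                "pbs": c.pbs.trna_id if c.pbs else "-",
                "ppt": f"{c.ppt.start}-{c.ppt.end}" if c.ppt else "-",
                "classification": c.classification,
                "tandem": c.tandem,
                "designation": c.designation,
            }
            for c in cands
        ],
        columns=[
            "seq_id", "start", "end", "strand", "length", "ltr5_size", "ltr3_size",
            "ltr_similarity", "tsd", "pbs", "ppt", "classification", "tandem", "designation",
        ],
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured genome and write the report bundle.

    Returns a dict with in-memory results and the paths written.  Any stage
    failure raises PipelineStageError naming the stage; outputs of earlier
    stages remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config": {k: v for k, v in asdict(config).items()}, "stages": []}
    results: dict = {"outdir": outdir}
    stage = "load"
    try:
        genomes = read_fasta(config.genome)
        library = masking.load_repeat_library(config.repeat_library) if config.repeat_library else []
        trna_set = read_fasta(config.trna) if config.trna else None
        proteins = read_fasta(config.proteins) if config.proteins else None
        truth = read_truth(config.truth) if config.truth else None

        stage = "mask"
        all_segments: list[masking.MaskedSegment] = []
        detector = ltr.DetectorParams(**config.detector)
        all_cands: list[ltr.LTRCandidate] = []
        all_loci: list[ssr.SSRLocus] = []
        total_len = sum(len(s) for s in genomes.values())
        for seq_id, seq in genomes.items():
            if library:
                lib = masking.deduplicate_library(library)
                all_segments.extend(
                    masking.mask_sequence(
                        seq, lib,
                        min_score=config.mask_min_score,
                        min_identity=config.mask_min_identity,
                        seq_id=seq_id, k=config.mask_k,
                    )
                )
            all_segments.extend(
                masking.detect_low_complexity(
                    seq, window=config.lc_window, entropy_max=config.lc_entropy_max, seq_id=seq_id
                )
            )
            stage = "ssr"
            loci = ssr.find_ssrs(seq, config.ssr_min_copies or None, seq_id=seq_id)
            all_loci.extend(loci)
            # SSR loci join the masking summary as Simple repeat segments
            all_segments.extend(
                masking.MaskedSegment(
                    seq_id, x.start, x.end, "+", x.motif, 1.0, x.length, "Simple repeat"
                )
                for x in loci
            )
            stage = "ltrscan"
            all_cands.extend(
                ltr.scan_genome(seq, trna_set, proteins, detector, seq_id=seq_id)
            )
        stage = "mask"
        resolved = masking.resolve_overlaps(all_segments)
        summary = masking.summarize_repeats(resolved, total_len)
        masking.segments_to_frame(resolved).to_csv(outdir / "segments.tsv", sep="\t", index=False)
        summary.to_tsv(outdir / "repeat_summary.tsv")
        masked = {
            sid: masking.apply_mask(s, [g for g in resolved if g.seq_id == sid])
            for sid, s in genomes.items()
        }
        write_fasta(masked, outdir / "masked.fasta")
        run_log["stages"].append({"stage": "mask", "segments": len(resolved)})

        stage = "ssr"
        ssr.loci_to_frame(all_loci).to_csv(outdir / "ssr.tsv", sep="\t", index=False)
        ssr.summarize_catalog(all_loci, total_len).to_csv(
            outdir / "ssr_summary.tsv", sep="\t", index=False
        )
        run_log["stages"].append({"stage": "ssr", "loci": len(all_loci)})

        stage = "classify"
        records = [families.ElementRecord.from_candidate(c) for c in all_cands]
        n_raw = len(records)
        unique = families.dedup_candidates(records, config.dedup_identity, config.dedup_coverage) if records else []
        novel, known_decisions = families.filter_known(
            unique, library, config.family_identity, config.family_coverage
        )
        fams = families.single_linkage_families(
            novel, identity_min=config.family_identity, coverage_min=config.family_coverage
        ) if novel else []
        run_log["stages"].append(
            {
                "stage": "classify",
                "funnel": {
                    "raw": n_raw,
                    "unique": len(unique),
                    "novel": len(novel),
                    "families": len(fams),
                },
            }
        )
        by_id = {families.ElementRecord.from_candidate(c).element_id: c for c in all_cands}
        for fi, fam in enumerate(fams):
            for el in fam:
                cand = by_id.get(el.element_id)
                if cand is not None:
                    sf = ltr.infer_superfamily(cand.coding)
                    cand.designation = families.make_designation(sf, f"Fam{fi+1}", el.element_id)

        stage = "copynum"
        copy_numbers = []
        for el in novel:
            est = families.estimate_copy_number(el, genomes, config.family_identity, config.family_coverage)
            copy_numbers.append({"element_id": el.element_id, "count": est.count})
        pd.DataFrame(copy_numbers, columns=["element_id", "count"]).to_csv(
            outdir / "copy_number.tsv", sep="\t", index=False
        )

        stage = "date"
        ages = [
            dating.date_ltr_pair(
                f"{c.seq_id}:{c.start}-{c.end}", c.ltr5_seq, c.ltr3_seq,
                model=config.dating_model, r=config.rate_r,
            )
            for c in all_cands
        ]
        dating.ages_to_frame(ages).to_csv(outdir / "ages.tsv", sep="\t", index=False)
        age_by_id = {a.element_id: a for a in ages}

        stage = "report"
        (outdir / "candidates.gff3").write_text(_candidates_gff3(all_cands))
        _candidates_frame(all_cands).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

        results.update(
            segments=resolved, summary=summary, loci=all_loci, candidates=all_cands,
            families=fams, ages=ages, copy_numbers=copy_numbers, novel=novel,
        )

        if truth is not None:
            stage = "evaluate"
            predictions = []
            for c in all_cands:
                aid = f"{c.seq_id}:{c.start}-{c.end}"
                predictions.append(
                    {
                        "seq_id": c.seq_id,
                        "start": c.start,
                        "end": c.end,
                        "category": "retroelement",
                        "tsd": c.tsd,
                        "age_years": age_by_id[aid].T if aid in age_by_id else None,
                        "classification": c.classification,
                    }
                )
            for g in resolved:
                cat = {
                    "Retroelement": "retroelement",
                    "DNA transposon": "dna_transposon",
                    "Satellite": "satellite",
                    "Simple repeat": "simple_repeat",
                    "Low complexity": "low_complexity",
                }.get(g.category)
                if cat and cat != "retroelement":
                    predictions.append(
                        {"seq_id": g.seq_id, "start": g.start, "end": g.end, "category": cat}
                    )
            report = evaluate_against_truth(predictions, truth, config.match_tolerance_bp)
            (outdir / "evaluation.json").write_text(json.dumps(report.to_dict(), indent=2))
            results["evaluation"] = report
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    return results


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
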