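"""Synthetic plant-genome generator with planted repeats and ground truth.

Emulates the repeat landscape the analysis pipeline assumes: an i.i.d.
background with a GC dial, into which LTR retrotransposons (two LTRs, TSD,
PBS, PPT, coding or non-coding internal domain), TIR DNA transposons,
satellite arrays, SSR tracts and low-complexity runs are planted.  Every
planted feature is recorded in a machine-readable truth table with exact
final coordinates.

Age model: an LTR retrotransposon of age A years has each of its two LTRs
(and its internal region) mutated independently with per-site substitution
probability r*A (r defaults to 1.36e-8 substitutions/site/year), so the
expected LTR-LTR divergence is ~2*r*A — the quantity the dating stage
inverts through T = K/(2r).

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np

from ._align import revcomp
from ._io import GFF3_HEADER, format_gff3_line, write_fasta
from .masking import RepeatLibraryEntry
from .ssr import canonical_motif

DEFAULT_RATE_R = 1.36e-8  # substitutions per site per year

PBS_LENGTH = 18
PPT_LENGTH = 15

CATEGORIES = ("retroelement", "dna_transposon", "satellite", "simple_repeat", "low_complexity")

_CODON = {  # fixed reverse-translation table (one codon per amino acid)
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}
_AA = "ARNDCQEGHILKMFPSTWYV"
_STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# specs and truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InsertionSpec:
    element_id: str
    kind: str  # ltr_rt_autonomous | ltr_rt_trim | tir_dna | satellite_array
    position: int  # offset into background, or into the host element if nested
    age_years: float = 0.0
    tsd_length: int = 5
    nested_in: str | None = None  # feature_id of an earlier insertion
    name: str | None = None  # feature_id override

    def __post_init__(self):
        if self.tsd_length not in (0, 4, 5, 6):
            raise ValueError("tsd_length must be 0 (absent) or 4-6")
        if self.age_years < 0:
            raise ValueError("age_years must be >= 0")


@dataclass(frozen=True)
class SSRSpec:
    motif: str
    copies: int
    position: int


@dataclass(frozen=True)
class LowComplexitySpec:
    position: int
    length: int
    alphabet: str  # subset of ACGT


@dataclass
class PlantedTruthRecord:
    feature_id: str
    category: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"
    age_years: float | None = None
    tsd: str | None = None
    ltr5_start: int | None = None
    ltr5_end: int | None = None
    ltr3_start: int | None = None
    ltr3_end: int | None = None
    expected_ltr_divergence: float | None = None
    nested_in: str | None = None
    motif: str | None = None
    sequence: str = ""

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def ltr5_interval(self) -> tuple[int, int] | None:
        if self.ltr5_start is None:
            return None
        return (self.ltr5_start, self.ltr5_end)

    @property
    def ltr3_interval(self) -> tuple[int, int] | None:
        if self.ltr3_start is None:
            return None
        return (self.ltr3_start, self.ltr3_end)


@dataclass
class GeneratorConfig:
    seed: int
    background_length: int
    gc_content: float = 0.46
    substitution_rate_r: float = DEFAULT_RATE_R
    seq_id: str = "synth1"
    elements: list[dict] = field(default_factory=list)  # build_te_consensus specs
    insertion_events: list[InsertionSpec] = field(default_factory=list)
    ssr_events: list[SSRSpec] = field(default_factory=list)
    low_complexity_events: list[LowComplexitySpec] = field(default_factory=list)

    def __post_init__(self):
        if self.background_length <= 0:
            raise ValueError("background_length must be positive")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        doc = json.loads(Path(path).read_text())
        doc["insertion_events"] = [InsertionSpec(**d) for d in doc.get("insertion_events", [])]
        doc["ssr_events"] = [SSRSpec(**d) for d in doc.get("ssr_events", [])]
        doc["low_complexity_events"] = [
            LowComplexitySpec(**d) for d in doc.get("low_complexity_events", [])
        ]
        return cls(**doc)


# ---------------------------------------------------------------------------
# background and consensus construction
# ---------------------------------------------------------------------------


def generate_background(length: int, gc_content: float = 0.46, seed: int = 0) -> str:
    """i.i.d. background sequence with the requested GC fraction."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([1 - gc_content, gc_content, gc_content, 1 - gc_content]) / 2.0
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.choice(4, size=length, p=p)].tobytes().decode()


def _random_seq(rng: np.random.Generator, length: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=length)].tobytes().decode()


def default_trna_set(seed: int = 77) -> dict[str, str]:
    """Small synthetic tRNA set (Met, Ser, Lys ids); 75-nt random bodies."""
    rng = np.random.default_rng(seed)
    return {name: _random_seq(rng, 75) for name in ("Lys", "Met", "Ser")}


def default_protein_library(seed: int = 78) -> dict[str, str]:
    """Synthetic TE protein-domain set: GAG (capsid), AP (aspartic
    proteinase), INT (integrase), RT (reverse transcriptase), RH (RNase H).
    Random amino-acid sequences of realistic lengths; these are the words the
    generator plants in autonomous elements and the detector searches for."""
    rng = np.random.default_rng(seed)
    lengths = {"GAG": 150, "AP": 100, "INT": 180, "RT": 220, "RH": 120}
    aa = np.array(list(_AA))
    return {name: "".join(aa[rng.integers(0, 20, size=n)]) for name, n in lengths.items()}


def _orf_nt(domains: dict[str, str], order: tuple[str, ...]) -> str:
    aa_seq = "".join(domains[name] for name in order)
    return "ATG" + "".join(_CODON[a] for a in aa_seq) + "TAA"


def _longest_orf_codons(seq: str) -> int:
    """Longest stop-free codon run over all six reading frames."""
    best = 0
    for s in (seq, revcomp(seq)):
        for f in range(3):
            run = 0
            for i in range(f, len(s) - 2, 3):
                if s[i : i + 3] in _STOPS:
                    run = 0
                else:
                    run += 1
                    best = max(best, run)
    return best


def _break_long_orfs(seq: str, max_codons: int = 90) -> str:
    """Plant stop codons so no reading frame (either strand) has a stop-free
    run longer than max_codons."""
    chars = list(seq)
    for _ in range(8):
        changed = False
        for strand in ("+", "-"):
            s = "".join(chars) if strand == "+" else revcomp("".join(chars))
            for f in range(3):
                run = 0
                for i in range(f, len(s) - 2, 3):
                    if s[i : i + 3] in _STOPS:
                        run = 0
                        continue
                    run += 1
                    if run > max_codons:
                        if strand == "+":
                            chars[i : i + 3] = list("TAA")
                        else:
                            j = len(s) - (i + 3)  # map back to forward strand
                            chars[j : j + 3] = list(revcomp("TAA"))
                        run = 0
                        changed = True
        if not changed:
            break
    return "".join(chars)


def build_te_consensus(
    kind: str,
    params: dict,
    seed: int = 0,
    trna_set: dict[str, str] | None = None,
    protein_library: dict[str, str] | None = None,
) -> tuple[RepeatLibraryEntry, dict]:
    """Build one consensus element plus an anatomy annotation.

    LTR retrotransposon anatomy: 5'LTR (TG...CA) + internal + identical
    3'LTR; the internal region starts with a PBS complementary to the 3' end
    of a designated tRNA and ends with a purine-rich PPT immediately before
    the 3'LTR.  The autonomous kind embeds one long ORF carrying the
    GAG-AP-INT-RT-RH domain words; the TRIM kind has a non-coding internal
    with stop codons in all frames.
    """
    rng = np.random.default_rng(seed)
    element_id = params.get("element_id", f"{kind}_{seed}")
    if kind in ("ltr_rt_autonomous", "ltr_rt_trim"):
        ltr_len = int(params["ltr_length"])
        internal_len = int(params["internal_length"])
        if ltr_len < 100 or internal_len < 1000:
            raise ValueError("ltr_length must be >= 100 and internal_length >= 1000")
        trnas = trna_set or default_trna_set()
        trna_id = params.get("trna_id", sorted(trnas)[0])
        pbs = revcomp(trnas[trna_id][-PBS_LENGTH:])
        ppt = "".join(np.array(list("AG"))[rng.integers(0, 2, size=PPT_LENGTH)])
        body_len = internal_len - PBS_LENGTH - PPT_LENGTH
        if body_len < 0:
            raise ValueError("internal_length too small for PBS and PPT")
        domains = dict(protein_library or default_protein_library())
        order = ("GAG", "AP", "INT", "RT", "RH")
        orf_interval = None
        if kind == "ltr_rt_autonomous":
            orf = _orf_nt(domains, order)
            if len(orf) + 20 > body_len:
                raise ValueError(
                    f"internal_length {internal_len} too small for the coding ORF "
                    f"({len(orf)} nt plus padding)"
                )
            pad5 = 10
            body = (
                _break_long_orfs(_random_seq(rng, pad5))
                + orf
                + _break_long_orfs(_random_seq(rng, body_len - pad5 - len(orf)))
            )
            orf_interval = (PBS_LENGTH + pad5, PBS_LENGTH + pad5 + len(orf))
        else:
            body = _break_long_orfs(_random_seq(rng, body_len))
        internal = pbs + body + ppt
        ltr = "TG" + _random_seq(rng, ltr_len - 4) + "CA"
        seq = ltr + internal + ltr
        anatomy = {
            "kind": kind,
            "ltr_length": ltr_len,
            "internal_length": internal_len,
            "ltr5": (0, ltr_len),
            "ltr3": (ltr_len + internal_len, 2 * ltr_len + internal_len),
            "pbs_offset": 0,
            "pbs_length": PBS_LENGTH,
            "trna_id": trna_id,
            "ppt": (internal_len - PPT_LENGTH, internal_len),  # internal coords
            "orf": orf_interval,  # internal coords
            "domain_order": order if kind == "ltr_rt_autonomous" else None,
        }
        superfamily = params.get("superfamily", "Copia" if kind == "ltr_rt_autonomous" else None)
        classification = ("Retroelement", "LTR", superfamily, element_id)
    elif kind == "tir_dna":
        length = int(params.get("length", 3000))
        tir_len = int(params.get("tir_length", 13))
        if length < 2 * tir_len + 10:
            raise ValueError("tir_dna length too small for its TIRs")
        tir = _random_seq(rng, tir_len)
        seq = tir + _random_seq(rng, length - 2 * tir_len) + revcomp(tir)
        anatomy = {"kind": kind, "tir_length": tir_len}
        classification = ("DNA transposon", "TIR", params.get("superfamily", "CACTA"), element_id)
    elif kind == "satellite_array":
        monomer_len = int(params.get("monomer_length", 150))
        copies = int(params.get("copies", 12))
        if monomer_len < 10 or copies < 2:
            raise ValueError("satellite_array needs monomer_length >= 10 and copies >= 2")
        monomer = _random_seq(rng, monomer_len)
        seq = monomer * copies
        anatomy = {"kind": kind, "monomer_length": monomer_len, "copies": copies}
        classification = ("Satellite", None, None, element_id)
    else:
        raise ValueError(f"unknown element kind: {kind!r}")
    return RepeatLibraryEntry(element_id, classification, seq), anatomy


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------


def _mutate(seq: str, per_site_prob: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with the given probability,
    uniformly to one of the three alternative bases."""
    if per_site_prob <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    base_idx = {65: 0, 67: 1, 71: 2, 84: 3}
    codes = np.array([base_idx.get(b, 0) for b in arr], dtype=np.int64)
    hit = rng.random(len(arr)) < per_site_prob
    shift = rng.integers(1, 4, size=len(arr))
    new_codes = (codes + shift) % 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr[hit] = lut[new_codes[hit]]
    return arr.tobytes().decode()


def plant_insertions(
    background: str,
    library: dict[str, tuple[RepeatLibraryEntry, dict]],
    specs: list[InsertionSpec],
    seed: int = 0,
    rate_r: float = DEFAULT_RATE_R,
    seq_id: str = "synth1",
) -> tuple[str, list[PlantedTruthRecord]]:
    """Insert element copies (with TSDs, mutations and nesting) into the
    background and return the final genome plus truth records with exact
    final coordinates.

    Top-level positions refer to the original background; nested positions
    are offsets into the host element sequence at insertion time.  Each
    copy's two LTRs are mutated independently with per-site probability
    rate_r * age_years.
    """
    rng = np.random.default_rng(seed)
    placed: dict[str, dict] = {}  # feature_id -> working state
    order: list[str] = []
    for idx, spec in enumerate(specs):
        if spec.element_id not in library:
            raise ValueError(f"insertion references unknown element {spec.element_id!r}")
        fid = spec.name or f"{spec.element_id}.{idx}"
        if fid in placed:
            raise ValueError(f"duplicate feature id {fid!r}")
        entry, anatomy = library[spec.element_id]
        m = rate_r * spec.age_years
        is_ltr = anatomy["kind"].startswith("ltr_rt")
        if is_ltr:
            l5s, l5e = anatomy["ltr5"]
            l3s, l3e = anatomy["ltr3"]
            seq = (
                _mutate(entry.sequence[l5s:l5e], m, rng)
                + _mutate(entry.sequence[l5e:l3s], m, rng)
                + _mutate(entry.sequence[l3s:l3e], m, rng)
            )
            ltr5, ltr3 = (l5s, l5e), (l3s, l3e)
        else:
            seq = _mutate(entry.sequence, m, rng)
            ltr5 = ltr3 = None
        tsd = _random_seq(rng, spec.tsd_length) if spec.tsd_length else ""
        placed[fid] = {
            "spec": spec,
            "seq": seq,
            "tsd": tsd,
            "ltr5": ltr5,
            "ltr3": ltr3,
            "guests": [],  # (guest_fid, local_offset_of_guest_element)
            "kind": anatomy["kind"],
        }
        order.append(fid)
        if spec.nested_in is not None:
            host = placed.get(spec.nested_in)
            if host is None:
                raise ValueError(
                    f"nested_in references unplanted element {spec.nested_in!r}"
                )
            off = spec.position
            if not 0 < off < len(host["seq"]):
                raise ValueError(f"nested position {off} outside host element")
            ins = tsd + seq + tsd
            host["seq"] = host["seq"][:off] + ins + host["seq"][off:]
            for key in ("ltr5", "ltr3"):
                iv = host[key]
                if iv is not None:
                    s, e = iv
                    host[key] = (
                        s + (len(ins) if s >= off else 0),
                        e + (len(ins) if e > off else 0),
                    )
            host["guests"] = [
                (g, loc + (len(ins) if loc >= off else 0)) for g, loc in host["guests"]
            ]
            host["guests"].append((fid, off + len(tsd)))

    # assemble: top-level insertions in ascending background position
    top = [f for f in order if placed[f]["spec"].nested_in is None]
    top.sort(key=lambda f: (placed[f]["spec"].position, order.index(f)))
    pieces: list[str] = []
    cursor = 0
    out_len = 0
    abs_start: dict[str, int] = {}
    for fid in top:
        st = placed[fid]
        pos = st["spec"].position
        if not 0 <= pos <= len(background):
            raise ValueError(f"insertion position {pos} outside background")
        pieces.append(background[cursor:pos])
        out_len += pos - cursor
        pieces.append(st["tsd"])
        out_len += len(st["tsd"])
        abs_start[fid] = out_len
        pieces.append(st["seq"])
        out_len += len(st["seq"])
        pieces.append(st["tsd"])
        out_len += len(st["tsd"])
        cursor = pos
    pieces.append(background[cursor:])
    genome = "".join(pieces)

    # absolute coordinates for nested guests (recursively via host starts)
    for fid in order:
        if fid in abs_start:
            continue
        chain_off = 0
        cur = fid
        while placed[cur]["spec"].nested_in is not None:
            host_fid = placed[cur]["spec"].nested_in
            loc = dict(placed[host_fid]["guests"])[cur]
            chain_off += loc
            cur = host_fid
        abs_start[fid] = abs_start[cur] + chain_off

    records: list[PlantedTruthRecord] = []
    category = {
        "ltr_rt_autonomous": "retroelement",
        "ltr_rt_trim": "retroelement",
        "tir_dna": "dna_transposon",
        "satellite_array": "satellite",
    }
    for fid in order:
        st = placed[fid]
        spec = st["spec"]
        s = abs_start[fid]
        e = s + len(st["seq"])
        is_ltr = st["kind"].startswith("ltr_rt")
        rec = PlantedTruthRecord(
            feature_id=fid,
            category=category[st["kind"]],
            seq_id=seq_id,
            start=s,
            end=e,
            age_years=spec.age_years if is_ltr else None,
            tsd=st["tsd"] or None,
            nested_in=spec.nested_in,
            sequence=st["seq"],
        )
        if is_ltr:
            rec.ltr5_start, rec.ltr5_end = s + st["ltr5"][0], s + st["ltr5"][1]
            rec.ltr3_start, rec.ltr3_end = s + st["ltr3"][0], s + st["ltr3"][1]
            rec.expected_ltr_divergence = 2.0 * rate_r * spec.age_years
        records.append(rec)
    return genome, records


def _insert_block(
    genome: str,
    pos: int,
    block: str,
    existing: list[PlantedTruthRecord] | None,
) -> str:
    """Insert block at pos, shifting coordinates of existing truth records
    (starts shift when >= pos, ends when > pos: an insertion strictly inside
    an interval grows it)."""
    if not 0 <= pos <= len(genome):
        raise ValueError(f"insertion position {pos} outside genome")
    n = len(block)
    if existing:
        for rec in existing:
            for s_attr, e_attr in (
                ("start", "end"),
                ("ltr5_start", "ltr5_end"),
                ("ltr3_start", "ltr3_end"),
            ):
                s, e = getattr(rec, s_attr), getattr(rec, e_attr)
                if s is None:
                    continue
                if s >= pos:
                    setattr(rec, s_attr, s + n)
                if e > pos:
                    setattr(rec, e_attr, e + n)
            if rec.start < pos < rec.end:  # block landed inside this record
                rec.sequence = rec.sequence[: pos - rec.start] + block + rec.sequence[pos - rec.start :]
    return genome[:pos] + block + genome[pos:]


def plant_ssrs(
    genome: str,
    ssr_specs: list[SSRSpec],
    seed: int = 0,
    seq_id: str = "synth1",
    existing_truth: list[PlantedTruthRecord] | None = None,
) -> tuple[str, list[PlantedTruthRecord]]:
    """Insert exact tandem tracts; positions refer to the genome as passed in.
    Coordinates of `existing_truth` records are shifted in place."""
    new: list[PlantedTruthRecord] = []
    for idx, spec in enumerate(sorted(ssr_specs, key=lambda x: -x.position)):
        if set(spec.motif.upper()) - set("ACGT"):
            raise ValueError(f"motif must be over ACGT: {spec.motif!r}")
        canon = canonical_motif(spec.motif)  # validates unit length / reducibility
        tract = spec.motif.upper() * spec.copies
        genome = _insert_block(genome, spec.position, tract, (existing_truth or []) + new)
        new.append(
            PlantedTruthRecord(
                feature_id=f"ssr.{spec.position}.{idx}",
                category="simple_repeat",
                seq_id=seq_id,
                start=spec.position,
                end=spec.position + len(tract),
                motif=canon,
                sequence=tract,
            )
        )
    new.sort(key=lambda r: r.start)
    return genome, new


def plant_low_complexity(
    genome: str,
    lc_specs: list[LowComplexitySpec],
    seed: int = 0,
    seq_id: str = "synth1",
    existing_truth: list[PlantedTruthRecord] | None = None,
) -> tuple[str, list[PlantedTruthRecord]]:
    """Insert low-complexity runs drawn from a reduced alphabet."""
    rng = np.random.default_rng(seed)
    new: list[PlantedTruthRecord] = []
    for idx, spec in enumerate(sorted(lc_specs, key=lambda x: -x.position)):
        letters = sorted(set(spec.alphabet.upper()))
        if not letters or set(letters) - set("ACGT") or len(letters) > 2:
            raise ValueError("low-complexity alphabet must be 1-2 bases from ACGT")
        run = "".join(np.array(letters)[rng.integers(0, len(letters), size=spec.length)])
        genome = _insert_block(genome, spec.position, run, (existing_truth or []) + new)
        new.append(
            PlantedTruthRecord(
                feature_id=f"lowc.{spec.position}.{idx}",
                category="low_complexity",
                seq_id=seq_id,
                start=spec.position,
                end=spec.position + spec.length,
                sequence=run,
            )
        )
    new.sort(key=lambda r: r.start)
    return genome, new


# ---------------------------------------------------------------------------
# truth I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [f.name for f in fields(PlantedTruthRecord)]


def _fmt(v) -> str:
    if v is None:
        return "."
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_truth(records: list[PlantedTruthRecord], prefix: str | Path) -> tuple[Path, Path]:
    """Write <prefix>.truth.gff3 (1-based inclusive) and <prefix>.truth.tsv
    (exact round-trip, 0-based half-open)."""
    gff_path = Path(str(prefix) + ".truth.gff3")
    tsv_path = Path(str(prefix) + ".truth.tsv")
    lines = [GFF3_HEADER]
    for rec in records:
        attrs = {"ID": rec.feature_id, "category": rec.category}
        if rec.tsd:
            attrs["tsd"] = rec.tsd
        if rec.age_years is not None:
            attrs["age_years"] = _fmt(rec.age_years)
        if rec.ltr5_interval:
            attrs["ltr5"] = f"{rec.ltr5_start}-{rec.ltr5_end}"
            attrs["ltr3"] = f"{rec.ltr3_start}-{rec.ltr3_end}"
        if rec.nested_in:
            attrs["nested_in"] = rec.nested_in
        if rec.motif:
            attrs["motif"] = rec.motif
        lines.append(
            format_gff3_line(rec.seq_id, "repeatscape", rec.category, rec.start, rec.end, ".", rec.strand, attrs)
        )
    gff_path.write_text("\n".join(lines) + "\n")
    rows = ["\t".join(_TSV_COLUMNS)]
    for rec in records:
        rows.append("\t".join(_fmt(getattr(rec, c)) for c in _TSV_COLUMNS))
    tsv_path.write_text("\n".join(rows) + "\n")
    return gff_path, tsv_path


def read_truth(tsv_path: str | Path) -> list[PlantedTruthRecord]:
    """Exact inverse of the TSV written by :func:`write_truth`."""
    text = Path(tsv_path).read_text().rstrip("\n")
    lines = text.split("\n") if text else []
    if not lines:
        return []
    header = lines[0].split("\t")
    ints = {"start", "end", "ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end"}
    floats = {"age_years", "expected_ltr_divergence"}
    records = []
    for line in lines[1:]:
        vals = line.split("\t")
        kwargs = {}
        for col, raw in zip(header, vals):
            if raw == ".":
                kwargs[col] = None
            elif col in ints:
                kwargs[col] = int(raw)
            elif col in floats:
                kwargs[col] = float(raw)
            else:
                kwargs[col] = raw
        if kwargs.get("sequence") is None:
            kwargs["sequence"] = ""
        records.append(PlantedTruthRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# end-to-end simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    genome: str
    seq_id: str
    truth: list[PlantedTruthRecord]
    library: dict[str, tuple[RepeatLibraryEntry, dict]]
    trna_set: dict[str, str]
    protein_library: dict[str, str]


def simulate(config: GeneratorConfig) -> SimulationResult:
    """Run the full generator from a config: background, consensus library,
    TE/satellite insertions, SSR tracts, low-complexity runs."""
    rng = np.random.default_rng(config.seed)
    trnas = default_trna_set()
    proteins = default_protein_library()
    library: dict[str, tuple[RepeatLibraryEntry, dict]] = {}
    for i, espec in enumerate(config.elements):
        espec = dict(espec)
        kind = espec.pop("kind")
        eseed = espec.pop("seed", int(rng.integers(0, 2**31 - 1)))
        entry, anatomy = build_te_consensus(
            kind, espec, seed=eseed, trna_set=trnas, protein_library=proteins
        )
        library[entry.entry_id] = (entry, anatomy)
    background = generate_background(
        config.background_length, config.gc_content, seed=int(rng.integers(0, 2**31 - 1))
    )
    genome, truth = plant_insertions(
        background,
        library,
        config.insertion_events,
        seed=int(rng.integers(0, 2**31 - 1)),
        rate_r=config.substitution_rate_r,
        seq_id=config.seq_id,
    )
    genome, ssr_truth = plant_ssrs(
        genome, config.ssr_events, seed=int(rng.integers(0, 2**31 - 1)),
        seq_id=config.seq_id, existing_truth=truth,
    )
    truth.extend(ssr_truth)
    genome, lc_truth = plant_low_complexity(
        genome, config.low_complexity_events, seed=int(rng.integers(0, 2**31 - 1)),
        seq_id=config.seq_id, existing_truth=truth,
    )
    truth.extend(lc_truth)
    truth.sort(key=lambda r: (r.start, r.feature_id))
    return SimulationResult(genome, config.seq_id, truth, library, trnas, proteins)


def write_simulation(result: SimulationResult, out_prefix: str | Path) -> dict[str, Path]:
    """Write <prefix>.fasta, <prefix>.truth.gff3/.tsv, <prefix>.library.fasta,
    <prefix>.trna.fasta, <prefix>.proteins.fasta."""
    out_prefix = str(out_prefix)
    paths: dict[str, Path] = {}
    fasta = Path(out_prefix + ".fasta")
    write_fasta({result.seq_id: result.genome}, fasta)
    paths["fasta"] = fasta
    gff, tsv = write_truth(result.truth, out_prefix)
    paths["truth_gff3"], paths["truth_tsv"] = gff, tsv
    lib_path = Path(out_prefix + ".library.fasta")
    headers = {
        f"{e.entry_id}#{'/'.join(x.replace(' ', '_') for x in e.classification if x)}": e.sequence
        for e, _ in result.library.values()
    }
    write_fasta(headers, lib_path)
    paths["library"] = lib_path
    trna_path = Path(out_prefix + ".trna.fasta")
    write_fasta(result.trna_set, trna_path)
    paths["trna"] = trna_path
    prot_path = Path(out_prefix + ".proteins.fasta")
    write_fasta(result.protein_library, prot_path)
    paths["proteins"] = prot_path
    return paths
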