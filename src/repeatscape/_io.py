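"""FASTA / GFF3 / TSV plumbing shared by the pipeline stages."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_HEADER = "##gff-version 3"


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence} (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    """Write 60-column wrapped FASTA."""
    records = [
        SeqRecord(Seq(s), id=name, description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def format_gff3_line(
    seq_id: str,
    source: str,
    feature_type: str,
    start0: int,
    end0: int,
    score: str,
    strand: str,
    attributes: dict[str, str],
) -> str:
    """One GFF3 line; internal 0-based half-open converted to 1-based inclusive."""
    attrs = ";".join(f"{k}={v}" for k, v in attributes.items())
    return "\t".join(
        [seq_id, source, feature_type, str(start0 + 1), str(end0), score, strand, ".", attrs]
    )


def parse_gff3(path: str | Path) -> list[dict]:
    """Read a GFF3 file into dicts with 0-based half-open coordinates."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
        rows.append(
            {
                "seq_id": f[0],
                "source": f[1],
                "type": f[2],
                "start": int(f[3]) - 1,
                "end": int(f[4]),
                "score": f[5],
                "strand": f[6],
                "attributes": attrs,
            }
        )
    return rows
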