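"""FASTA input, annotation writers (BED/TSV/JSON), config files, masking.

Coordinate conventions: BED6 output is 0-based half-open; the
human-readable TSV is 1-based inclusive; JSON carries the internal 0-based
half-open coordinates and nests subrepeats, and round-trips losslessly.
"""

from __future__ import annotations

import json
import sys
from typing import Iterator, TextIO

from Bio import SeqIO

from .annotate import RepeatRegion
from .model import DNA, ModelParams
from .split import SubRepeat

__all__ = [
    "read_fasta",
    "write_annotations",
    "regions_to_records",
    "regions_from_json",
    "write_soft_masked_fasta",
    "read_config",
]

FORMATS = ("bed", "tsv", "json")
TSV_HEADER = "seq\tstart\tend\tperiod\tscore\tpvalue\tunit\tn_subrepeats"


def read_fasta(source) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) records in file order.

    Letters are validated against the DNA/RNA alphabet (plus ambiguity N);
    case is preserved in the returned sequence (decoding uppercases
    internally).  Empty records and gap characters are rejected.
    """
    handle = open(source) if isinstance(source, (str, bytes)) else source
    try:
        seen_any = False
        for record in SeqIO.parse(handle, "fasta"):
            seen_any = True
            seq = str(record.seq)
            if not record.id:
                raise ValueError("FASTA record with empty header")
            if not seq:
                raise ValueError(f"FASTA record {record.id!r} has an empty sequence")
            DNA.encode(seq)  # validation: raises naming the offending position
            yield record.id, seq
        if not seen_any:
            raise ValueError("no FASTA records found (line 1: missing '>' header?)")
    finally:
        if isinstance(source, (str, bytes)):
            handle.close()


def regions_to_records(regions: list[RepeatRegion]) -> list[dict]:
    """Flatten regions to JSON-serializable annotation records."""
    out = []
    for r in regions:
        out.append({
            "sequence_id": r.sequence_id,
            "start": r.start,
            "end": r.end,
            "period": r.period,
            "score": r.score,
            "pvalue": r.pvalue,
            "unit": r.unit,
            "subrepeats": [
                {"start": s.start, "end": s.end, "pattern": s.pattern,
                 "canonical_unit": s.canonical_unit}
                for s in r.subrepeats
            ],
        })
    return out


def regions_from_json(stream_or_text) -> list[RepeatRegion]:
    """Inverse of the JSON writer."""
    data = json.loads(stream_or_text) if isinstance(stream_or_text, str) else json.load(stream_or_text)
    regions = []
    for d in data:
        regions.append(RepeatRegion(
            start=d["start"], end=d["end"], period=d["period"], score=d["score"],
            pvalue=d["pvalue"], unit=d["unit"], sequence_id=d["sequence_id"],
            subrepeats=[SubRepeat(s["start"], s["end"], s["pattern"], s["canonical_unit"])
                        for s in d["subrepeats"]],
        ))
    return regions


def write_annotations(regions: list[RepeatRegion], fmt: str, stream: TextIO | None = None) -> None:
    """Write sorted annotations in one of bed / tsv / json."""
    stream = stream or sys.stdout
    key = [(r.sequence_id, r.start) for r in regions]
    if key != sorted(key):
        raise ValueError("regions must be sorted by (sequence_id, start)")
    if fmt == "bed":
        for r in regions:
            score = max(0, min(1000, int(round(r.score))))
            stream.write(f"{r.sequence_id}\t{r.start}\t{r.end}\t{r.unit}\t{score}\t+\n")
    elif fmt == "tsv":
        stream.write(TSV_HEADER + "\n")
        for r in regions:
            pv = "" if r.pvalue is None else f"{r.pvalue:.3g}"
            stream.write(
                f"{r.sequence_id}\t{r.start + 1}\t{r.end}\t{r.period}\t"
                f"{r.score:.4f}\t{pv}\t{r.unit}\t{len(r.subrepeats)}\n")
    elif fmt == "json":
        json.dump(regions_to_records(regions), stream, indent=1)
        stream.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def write_soft_masked_fasta(records, regions_by_id, stream: TextIO, width: int = 60) -> None:
    """Write the input FASTA with annotated repeat spans lowercased."""
    for seq_id, seq in records:
        masked = list(seq.upper())
        for r in regions_by_id.get(seq_id, []):
            for t in range(max(0, r.start), min(len(seq), r.end)):
                masked[t] = masked[t].lower()
        stream.write(f">{seq_id}\n")
        for s in range(0, len(masked), width):
            stream.write("".join(masked[s : s + width]) + "\n")


def read_config(path: str) -> dict:
    """Parse a plain key=value model config file (comments with '#')."""
    ints = {"k", "max_insert", "max_delete", "min_unit"}
    valid = set(ModelParams.__dataclass_fields__) - {"alphabet"}
    out: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (x.strip() for x in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            out[key] = int(val) if key in ints else float(val)
    return out
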