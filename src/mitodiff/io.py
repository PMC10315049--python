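"""File I/O: FASTA, FASTQ, GFF3, the single TSV dialect, and run manifests.

One TSV dialect everywhere: tab-separated, '#'-prefixed header lines,
'.' for missing values. Every exported file that carries coordinates
declares its convention (1-based inclusive) in a header comment.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import os

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import AnnotatedGenome, Feature

COORD_HEADER = "# coordinates: 1-based inclusive"


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> list[SeqRecord]:
    """Read FASTA (optionally gzipped). Duplicate ids and empty records are
    rejected."""
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    seen = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate FASTA id {r.id!r} in {path}")
        if len(r.seq) == 0:
            raise ValueError(f"empty record {r.id!r} in {path}")
        seen.add(r.id)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            if isinstance(r, tuple):
                rid, seq = r[0], str(r[1])
                desc = r[2] if len(r) > 2 else ""
                r = SeqRecord(Seq(seq), id=rid, description=desc)
            desc = r.description
            if desc == r.id or desc.startswith(r.id + " "):
                desc = desc[len(r.id):].strip()
            fh.write(f">{r.id} {desc}".rstrip() + "\n")
            s = str(r.seq)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_genome(path, topology: str = "circular", gff3: str | None = None) -> AnnotatedGenome:
    """Load a single-record FASTA as an AnnotatedGenome, optionally with a
    GFF3 annotation file."""
    recs = read_fasta(path)
    if len(recs) != 1:
        raise ValueError(f"{path} holds {len(recs)} records; expected a single genome")
    r = recs[0]
    feats = read_gff3(gff3, len(r.seq)) if gff3 else []
    return AnnotatedGenome(r.id, str(r.seq), topology, feats, r.description)


def write_fastq(reads, path) -> None:
    """reads: iterable of (id, sequence, quality-string-or-None)."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            if qual is None:
                qual = "I" * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path, seq_length: int | None = None) -> list[Feature]:
    feats = []
    with _open_text(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise ValueError(f"{path}: missing ##gff-version pragma")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: expected 9 columns, got {len(cols)}")
            _, _, ftype, start, end, _, strand, _, attrs_s = cols
            start, end = int(start), int(end)
            if start < 1 or end < start:
                raise ValueError(f"{path}: bad interval {start}..{end}")
            if seq_length is not None and end > seq_length:
                raise ValueError(f"{path}: feature end {end} > sequence length {seq_length}")
            if strand not in "+-.":
                raise ValueError(f"{path}: unknown strand {strand!r}")
            attrs = {}
            for kv in attrs_s.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k] = v
            name = attrs.get("Name", attrs.get("ID", "."))
            feats.append(Feature(ftype, start - 1, end, strand, name, attrs))
    return feats


def write_gff3(features, seqid: str, seq_length: int, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {seq_length}\n")
        for i, f in enumerate(features):
            attrs = dict(f.attrs)
            attrs.setdefault("ID", f"{f.type}_{i + 1}")
            if f.name != ".":
                attrs.setdefault("Name", f.name)
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{seqid}\tmitodiff\t{f.type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# TSV dialect + JSON + manifest

def write_tsv(path, header: list[str], rows, comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n" if not c.startswith("#") else c + "\n")
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("." if v is None else str(v) for v in row) + "\n")


def read_tsv(path):
    """Return (header, rows) for the package's TSV dialect."""
    header, rows = None, []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line[1:].split("\t")  # last '#' line before data wins
                continue
            rows.append([None if v == "." else v for v in line.split("\t")])
    return header, rows


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, paths, path="MANIFEST.tsv") -> str:
    rows = [(os.path.relpath(p, outdir), sha256_file(p)) for p in sorted(map(str, paths))]
    out = os.path.join(outdir, path)
    write_tsv(out, ["file", "sha256"], rows)
    return out
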