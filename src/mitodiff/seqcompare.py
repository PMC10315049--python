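"""Pairwise genome comparison.

Local similarity search is delegated to NCBI BLAST+ (``blastn``), run with
low-complexity filtering disabled so that the seed-and-extend contract is
honest: any pair of intervals related by at most (1 - min_identity)
mismatch density that contains an exact word-size seed is found. Collinear
blocks are built on top of the hits by dynamic-programming anchor chaining
(monotone coordinates, uniform strand, bounded gaps), which stands in for a
locally-collinear-block decomposition; non-alignable regions are the
per-genome complement of block coverage.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

from .core import AnnotatedGenome, complement_intervals, merge_intervals

_OUTFMT = "6 qstart qend sstart send pident length mismatch gapopen bitscore qseq sseq"

DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_MIN_HIT_LEN = 90
DEFAULT_WORD_SIZE = 11
DEFAULT_MAX_GAP = 1000
DEFAULT_MIN_REGION_LEN = 90
DEFAULT_MERGE_SLACK = 50


@dataclass(frozen=True)
class AlignmentHit:
    """One local hit. Query/subject intervals are 0-based half-open on the
    forward strand of each sequence; strand '-' means the subject interval
    aligns reverse-complemented."""

    qstart: int
    qend: int
    sstart: int
    send: int
    strand: str
    length: int  # aligned columns, gap columns included
    matches: int
    identity: float  # matches / aligned columns
    score: float
    mismatches: int = 0
    gapopens: int = 0
    # gapped alignment strings (query forward orientation), when available
    qseq: str | None = None
    sseq: str | None = None

    @property
    def q_span(self) -> int:
        return self.qend - self.qstart

    @property
    def s_span(self) -> int:
        return self.send - self.sstart


def _check_alphabet(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"alphabet outside ACGTN: {sorted(bad)}")
    return seq


def local_search(
    query: str,
    subject: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
    word_size: int = DEFAULT_WORD_SIZE,
    circular_subject: bool = False,
) -> list[AlignmentHit]:
    """BLASTN local search between two sequences.

    With ``circular_subject`` the subject is concatenation-doubled and hits
    are deduplicated modulo its length, making the search rotation-tolerant.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    query = _check_alphabet(query)
    subject = _check_alphabet(subject)
    slen = len(subject)
    if circular_subject:
        subject = subject + subject

    if shutil.which("blastn") is None:  # pragma: no cover
        raise RuntimeError("blastn not found on PATH")

    with tempfile.TemporaryDirectory(prefix="mitodiff_blast_") as tmp:
        qpath = os.path.join(tmp, "q.fa")
        spath = os.path.join(tmp, "s.fa")
        with open(qpath, "w") as fh:
            fh.write(">q\n" + query + "\n")
        with open(spath, "w") as fh:
            fh.write(">s\n" + subject + "\n")
        cmd = [
            "blastn",
            "-query", qpath,
            "-subject", spath,
            "-outfmt", _OUTFMT,
            "-perc_identity", str(min_identity * 100),
            "-word_size", str(word_size),
            "-dust", "no",
            "-soft_masking", "false",
            "-evalue", "1e-3",
            "-max_target_seqs", "5000",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:  # pragma: no cover
            raise RuntimeError(f"blastn failed: {proc.stderr.strip()}")
        raw = proc.stdout

    hits, seen = [], set()
    for line in raw.splitlines():
        (qs, qe, ss, se, pident, length, mism, gapo, score,
         qseq_aln, sseq_aln) = line.split("\t")
        qs, qe, ss, se = int(qs), int(qe), int(ss), int(se)
        length, mism, gapo = int(length), int(mism), int(gapo)
        pident, score = float(pident), float(score)
        strand = "+" if ss <= se else "-"
        if strand == "-":
            ss, se = se, ss
        qs, ss = qs - 1, ss - 1  # to 0-based half-open
        if circular_subject:
            ss_mod = ss % slen
            se = ss_mod + (se - ss)
            ss = ss_mod
        if qe - qs < min_hit_len:
            continue
        key = (qs, qe, ss, se, strand)
        if key in seen:
            continue
        seen.add(key)
        matches = round(pident / 100.0 * length)
        hits.append(
            AlignmentHit(qs, qe, ss, se, strand, length, matches,
                         pident / 100.0, score, mism, gapo,
                         qseq_aln.upper(), sseq_aln.upper())
        )
    if circular_subject:
        hits = _dedup_modular(hits, slen)
    hits.sort(key=lambda h: (h.qstart, h.qend, h.sstart, h.strand))
    return hits


def _dedup_modular(hits, slen, slack=25):
    """Drop hits that are sub-alignments (modulo the subject length) of a
    larger hit: with a doubled circular subject the same locus can be
    reported both crossing the copy junction and within one copy."""
    kept = []
    for h in sorted(hits, key=lambda x: -(x.qend - x.qstart)):
        def diag(x):
            return (x.sstart - x.qstart) if x.strand == "+" else (x.send + x.qstart)

        dup = False
        for k in kept:
            if k.strand != h.strand:
                continue
            if h.qstart < k.qstart - slack or h.qend > k.qend + slack:
                continue
            d = abs(diag(h) - diag(k)) % slen
            if min(d, slen - d) <= slack:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def export_hits_tsv(hits: list[AlignmentHit], path, qid: str = "query", sid: str = "subject") -> None:
    """12-column tabular hit export (1-based inclusive; e-value column is a
    '.' placeholder)."""
    from .io import write_tsv

    rows = []
    for h in hits:
        ss, se = (h.sstart + 1, h.send) if h.strand == "+" else (h.send, h.sstart + 1)
        rows.append([qid, sid, f"{h.identity * 100:.2f}", h.length, h.mismatches,
                     h.gapopens, h.qstart + 1, h.qend, ss, se, None, h.score])
    write_tsv(path,
              ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"],
              rows, comments=["coordinates: 1-based inclusive"])


# ---------------------------------------------------------------------------
# collinear blocks

@dataclass
class CollinearBlock:
    """A maximal chain of hits with uniform strand and monotone coordinates
    in both genomes."""

    hits: list[AlignmentHit] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.hits[0].strand

    @property
    def qstart(self) -> int:
        return min(h.qstart for h in self.hits)

    @property
    def qend(self) -> int:
        return max(h.qend for h in self.hits)

    @property
    def sstart(self) -> int:
        return min(h.sstart for h in self.hits)

    @property
    def send(self) -> int:
        return max(h.send for h in self.hits)

    @property
    def q_span(self) -> int:
        return self.qend - self.qstart

    @property
    def s_span(self) -> int:
        return self.send - self.sstart

    @property
    def anchored_bp(self) -> int:
        return sum(h.q_span for h in self.hits)


def build_blocks(
    hits: list[AlignmentHit],
    max_gap: int = DEFAULT_MAX_GAP,
    gap_penalty: float = 0.05,
) -> list[CollinearBlock]:
    """Chain hits into collinear blocks.

    Chain score = anchored bp - gap_penalty * gap bp; hits in a chain must
    be strand-uniform, non-overlapping and coordinate-monotone in both
    genomes, with inter-anchor gaps <= max_gap. Chains are extracted
    best-score-first; ties break on leftmost query coordinate. Like a
    locally-collinear-block decomposition, blocks are one-to-one: a chain
    mostly covering query or subject sequence already claimed by a
    higher-scoring block is discarded, so extra copies of a duplicated
    segment stay non-alignable.
    """
    raw_blocks: list[CollinearBlock] = []
    for strand in "+-":
        sub = [h for h in hits if h.strand == strand]
        # monotone axis for the subject: ascending for '+', descending for '-'
        sub.sort(key=lambda h: (h.qstart, h.qend))
        used = [False] * len(sub)
        while True:
            n = len(sub)
            best_score = [0.0] * n
            parent = [-1] * n
            order = [i for i in range(n) if not used[i]]
            if not order:
                break
            for idx, i in enumerate(order):
                hi = sub[i]
                best_score[i] = float(hi.q_span)
                for j in order[:idx]:
                    hj = sub[j]
                    qgap = hi.qstart - hj.qend
                    if strand == "+":
                        sgap = hi.sstart - hj.send
                    else:
                        sgap = hj.sstart - hi.send
                    if qgap < 0 or sgap < 0:
                        continue
                    if qgap > max_gap or sgap > max_gap:
                        continue
                    cand = best_score[j] + hi.q_span - gap_penalty * max(qgap, sgap)
                    if cand > best_score[i]:
                        best_score[i] = cand
                        parent[i] = j
            top = max(order, key=lambda i: (best_score[i], -sub[i].qstart))
            chain = []
            k = top
            while k != -1:
                chain.append(sub[k])
                used[k] = True
                k = parent[k]
            chain.reverse()
            raw_blocks.append(CollinearBlock(chain))

    # one-to-one filter: best blocks first, drop chains that mostly re-use
    # already-claimed query or subject sequence
    raw_blocks.sort(key=lambda b: (-b.anchored_bp, b.qstart))
    kept: list[CollinearBlock] = []
    q_used: list[tuple] = []
    s_used: list[tuple] = []

    def overlap(iv, used):
        return sum(max(0, min(iv[1], e) - max(iv[0], s)) for s, e in used)

    for b in raw_blocks:
        q_iv, s_iv = (b.qstart, b.qend), (b.sstart, b.send)
        if (overlap(q_iv, q_used) > 0.5 * b.q_span
                or overlap(s_iv, s_used) > 0.5 * b.s_span):
            continue
        kept.append(b)
        q_used = merge_intervals(q_used + [q_iv])
        s_used = merge_intervals(s_used + [s_iv])
    kept.sort(key=lambda b: (b.qstart, b.qend))
    return kept


def nonalignable_regions_1d(
    blocks: list[CollinearBlock],
    genome_length: int,
    min_region_len: int = DEFAULT_MIN_REGION_LEN,
    merge_slack: int = DEFAULT_MERGE_SLACK,
    circular: bool = False,
):
    """Complement of block coverage on the *query* genome of `blocks`.

    Returns a list of (start, end) intervals, 0-based half-open; on a
    circular genome an interval may wrap (end > genome_length).

    Coverage is the union of the member hits' query intervals, not block
    spans: an unaligned insertion bridged by a chain (shorter than
    max_gap) still counts as non-alignable."""
    cov = [(h.qstart, h.qend) for b in blocks for h in b.hits]
    gaps = complement_intervals(cov, genome_length)
    # bridge sub-slack covered separations
    gaps = merge_intervals(gaps, slack=merge_slack)
    if circular and len(gaps) >= 2 and gaps[0][0] == 0 and gaps[-1][1] == genome_length:
        first, last = gaps[0], gaps[-1]
        gaps = gaps[1:-1] + [(last[0], genome_length + first[1])]
    elif circular and len(gaps) == 1 and gaps[0] == (0, genome_length):
        pass
    return [g for g in gaps if g[1] - g[0] >= min_region_len]


@dataclass(frozen=True)
class NonAlignableRegion:
    """An interval of one genome not covered by any collinear block in a
    pairwise comparison. Code example: CSC1 = pair C-S, genome C, region 1."""

    genome_id: str
    start: int
    end: int  # may exceed genome length when wrapping a circular origin
    pair: str
    code: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PairComparison:
    """Everything derived from one genome pair: hits and blocks in each
    direction, per-genome non-alignable regions, inversions."""

    a_id: str
    b_id: str
    blocks_ab: list[CollinearBlock]
    blocks_ba: list[CollinearBlock]
    regions: dict  # genome id -> list[NonAlignableRegion]
    inversions: list


def detect_inversions(blocks: list[CollinearBlock], min_len: int = 1000):
    """Minus-strand blocks above a span threshold, longest first."""
    inv = [
        ((b.qstart, b.qend), (b.sstart, b.send), b.q_span)
        for b in blocks
        if b.strand == "-" and b.q_span >= min_len
    ]
    inv.sort(key=lambda x: -x[2])
    return inv


def compare_pair(
    a: AnnotatedGenome,
    b: AnnotatedGenome,
    pair_label: str | None = None,
    letters: tuple[str, str] | None = None,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_hit_len: int = DEFAULT_MIN_HIT_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
    min_region_len: int = DEFAULT_MIN_REGION_LEN,
    merge_slack: int = DEFAULT_MERGE_SLACK,
) -> PairComparison:
    """Symmetric pairwise comparison: each genome is used as the query once,
    so role-swapping the arguments cannot change a genome's regions."""
    la, lb = letters if letters else (a.id[:1].upper(), b.id[:1].upper())
    pair = pair_label or f"{la}{lb}"
    out_regions = {}
    blocks_dir = {}
    for g, other, letter in ((a, b, la), (b, a, lb)):
        hits = local_search(
            g.sequence, other.sequence, min_identity, min_hit_len,
            circular_subject=(other.topology == "circular"),
        )
        blocks = build_blocks(hits, max_gap=max_gap)
        blocks_dir[g.id] = blocks
        ivs = nonalignable_regions_1d(
            blocks, len(g), min_region_len, merge_slack,
            circular=(g.topology == "circular"),
        )
        out_regions[g.id] = [
            NonAlignableRegion(g.id, s, e, pair, f"{pair}{letter}{i + 1}")
            for i, (s, e) in enumerate(ivs)
        ]
    inversions = detect_inversions(blocks_dir[a.id])
    return PairComparison(a.id, b.id, blocks_dir[a.id], blocks_dir[b.id],
                          out_regions, inversions)
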