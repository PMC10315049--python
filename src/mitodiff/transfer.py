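"""Chloroplast-derived DNA in a mitogenome.

Transferred regions are the merged union (on the mitochondrial axis) of
BLASTN hits between the mitogenome and its chloroplast genome at the
configured identity/length thresholds. By default one copy of the
chloroplast inverted repeat is removed before searching, so IR-borne
genes are not double-counted; pass remove_ir=False to search the
full-length plastome.

Gene copies inside transferred regions are located by projecting the
chloroplast annotation through the region's alignment, then classified
intact vs pseudogene from the lesion that first disrupts the reading
frame (frameshift indel, premature stop, or truncation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .core import AnnotatedGenome, merge_intervals, union_length
from .seqcompare import local_search
from .repeats import maximal_repeat_pairs


class UndeterminedStatusError(ValueError):
    pass


@dataclass
class GeneCopyCall:
    gene: str
    status: str  # intact | pseudogene
    cause: str  # frameshift | premature_stop | truncation | none
    mt_interval: tuple | None = None


@dataclass
class TransferredRegion:
    mt_start: int
    mt_end: int
    cp_start: int
    cp_end: int
    strand: str
    identity: float
    hits: list = field(default_factory=list)
    genes: list = field(default_factory=list)  # GeneCopyCall
    shared_with: list = field(default_factory=list)  # other species carrying it

    @property
    def length(self) -> int:
        return self.mt_end - self.mt_start


@dataclass
class TransferSummary:
    total_bp: int  # union on the mitochondrial axis
    genome_bp: int
    fraction: float
    n_regions: int
    intact_genes: int = 0
    pseudo_genes: int = 0


def remove_one_ir(cp: AnnotatedGenome, min_ir_len: int = 1000) -> AnnotatedGenome:
    """Drop the second copy of the largest inverted repeat, if one exists.
    Returns the genome unchanged when no IR >= min_ir_len is found."""
    pairs = [p for p in maximal_repeat_pairs(cp.sequence, min_ir_len, circular=False)
             if p.relation == "inverted" and p.length >= min_ir_len]
    if not pairs:
        return cp
    ir = max(pairs, key=lambda p: p.length)
    s, e = ir.copy2
    seq = cp.sequence[:s] + cp.sequence[e:]
    feats = [f for f in cp.features if f.end <= s or f.start >= e]
    import dataclasses as _dc

    feats = [(_dc.replace(f, start=f.start - (e - s), end=f.end - (e - s))
              if f.start >= e else f) for f in feats]
    return AnnotatedGenome(cp.id + "_noIR", seq, cp.topology, feats, cp.description)


def detect_idt(
    mt: AnnotatedGenome,
    cp: AnnotatedGenome,
    min_identity: float = 0.85,
    min_len: int = 90,
    remove_ir: bool = True,
    call_genes: bool = True,
):
    """Detect chloroplast-to-mitochondrion transferred regions.

    Returns (regions, summary). Regions are merged unions of qualifying
    hits on the mitochondrial axis; the summary's total is the union, so
    overlapping hits are never double-counted.
    """
    if len(cp.sequence) == 0:
        raise ValueError("empty chloroplast genome")
    cp_search = remove_one_ir(cp) if remove_ir else cp
    hits = local_search(mt.sequence, cp_search.sequence, min_identity, min_len,
                        circular_subject=(cp_search.topology == "circular"))
    merged = merge_intervals([(h.qstart, h.qend) for h in hits])
    regions = []
    for (s, e) in merged:
        sub = [h for h in hits if h.qstart < e and h.qend > s]
        top = max(sub, key=lambda h: h.q_span)
        ident = sum(h.matches for h in sub) / max(1, sum(h.length for h in sub))
        region = TransferredRegion(s, e, top.sstart, top.send, top.strand, ident, sub)
        if call_genes:
            region.genes = _project_genes(mt, cp_search, region)
        regions.append(region)
    total = union_length(merged)
    intact = sum(1 for r in regions for g in r.genes if g.status == "intact")
    pseudo = sum(1 for r in regions for g in r.genes if g.status == "pseudogene")
    summary = TransferSummary(total, len(mt), total / len(mt), len(regions),
                              intact, pseudo)
    return regions, summary


def _project_genes(mt: AnnotatedGenome, cp: AnnotatedGenome,
                   region: TransferredRegion, margin: int = 60):
    """Project chloroplast CDS annotations through the region's hits onto
    the mitogenome and call pseudogenization of each projected copy."""
    calls = []
    seen = set()
    for h in region.hits:
        for f in cp.features:
            if f.type != "CDS" or f.name in seen:
                continue
            ov = min(f.end, h.send) - max(f.start, h.sstart)
            if ov < 0.5 * f.length:
                continue
            seen.add(f.name)
            if h.strand == "+":
                m_s = h.qstart + (f.start - h.sstart)
                m_e = h.qstart + (f.end - h.sstart)
            else:
                m_s = h.qstart + (h.send - f.end)
                m_e = h.qstart + (h.send - f.start)
            m_s, m_e = max(0, m_s - margin), min(len(mt), m_e + margin)
            copy_strand = h.strand if f.strand == "+" else ("-" if h.strand == "+" else "+")
            mt_copy = mt.fetch(m_s, m_e, copy_strand)
            ref = cp.sequence[f.start:f.end]
            if f.strand == "-":
                ref = str(Seq(ref).reverse_complement())
            try:
                status, cause = call_pseudogene(mt_copy, ref)
            except UndeterminedStatusError:
                status, cause = "undetermined", "none"
            calls.append(GeneCopyCall(f.name, status, cause, (m_s, m_e)))
    return calls


_aligner = PairwiseAligner()
_aligner.mode = "local"
_aligner.match_score = 2
_aligner.mismatch_score = -3
_aligner.open_gap_score = -6
_aligner.extend_gap_score = -2


def call_pseudogene(mt_copy: str, reference_cds: str,
                    coverage_threshold: float = 0.95):
    """Classify a transferred gene copy as intact or pseudogene.

    A copy is intact iff it aligns over >= 95% of the reference CDS with no
    frame-disrupting indel and no internal stop codon. The cause reports
    the first disqualifying lesion in reference-coordinate order, with the
    precedence frameshift < premature_stop < truncation when coincident.
    """
    reference_cds = reference_cds.upper()
    mt_copy = mt_copy.upper()
    if len(reference_cds) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    if not reference_cds.startswith("ATG"):
        raise ValueError("reference CDS must begin with a start codon")
    if mt_copy and mt_copy.count("N") / len(mt_copy) > 0.05:
        raise UndeterminedStatusError("ambiguous bases exceed 5% of the copy")

    aln = _aligner.align(reference_cds, mt_copy)
    if len(aln) == 0:
        return "pseudogene", "truncation"
    best = aln[0]
    ref_blocks, tgt_blocks = best.aligned
    cov_start = int(ref_blocks[0][0])
    cov_end = int(ref_blocks[-1][1])
    covered = sum(int(e) - int(s) for s, e in ref_blocks)
    lesions = []  # (ref coordinate, precedence rank, cause)

    if covered / len(reference_cds) < coverage_threshold:
        # coordinate of the first missing stretch
        if cov_start > 0:
            lesions.append((0, 2, "truncation"))
        else:
            lesions.append((cov_end, 2, "truncation"))

    # internal indels between consecutive aligned blocks
    for k in range(1, len(ref_blocks)):
        ref_gap = int(ref_blocks[k][0]) - int(ref_blocks[k - 1][1])
        tgt_gap = int(tgt_blocks[k][0]) - int(tgt_blocks[k - 1][1])
        indel = ref_gap - tgt_gap
        if indel % 3 != 0:
            lesions.append((int(ref_blocks[k - 1][1]), 0, "frameshift"))

    # premature stops: translate target codons at in-frame, gap-free ref codons
    ref2tgt = {}
    for (rs, re_), (ts, te) in zip(ref_blocks, tgt_blocks):
        for off in range(int(re_) - int(rs)):
            ref2tgt[int(rs) + off] = int(ts) + off
    n_codons = len(reference_cds) // 3
    for ci in range(n_codons - 1):  # terminal codon is the legitimate stop
        p = 3 * ci
        if p in ref2tgt and p + 1 in ref2tgt and p + 2 in ref2tgt:
            if ref2tgt[p + 1] == ref2tgt[p] + 1 and ref2tgt[p + 2] == ref2tgt[p] + 2:
                codon = mt_copy[ref2tgt[p] : ref2tgt[p] + 3]
                if codon in ("TAA", "TAG", "TGA") and reference_cds[p : p + 3] not in (
                        "TAA", "TAG", "TGA"):
                    lesions.append((p, 1, "premature_stop"))

    if not lesions:
        return "intact", "none"
    lesions.sort()
    return "pseudogene", lesions[0][2]


def label_shared_regions(regions_by_species: dict, min_identity: float = 0.85,
                         min_len: int = 90):
    """Mark each transferred region with the other species whose mitogenome
    carries it (ancestral transfers are present in all species)."""
    from .seqcompare import local_search as _ls

    species = list(regions_by_species)
    for sp, (regions, genome) in regions_by_species.items():
        for r in regions:
            seq = genome.fetch(r.mt_start, r.mt_end)
            for other in species:
                if other == sp:
                    continue
                g2 = regions_by_species[other][1]
                hits = _ls(seq, g2.sequence, min_identity, min(min_len, len(seq)),
                           circular_subject=(g2.topology == "circular"))
                cov = union_length([(h.qstart, h.qend) for h in hits])
                if cov >= 0.5 * len(seq):
                    r.shared_with.append(other)
    return regions_by_species


def export_links(regions, path) -> None:
    """Link table for circular-diagram rendering: one row per region,
    1-based inclusive coordinates."""
    from .io import write_tsv

    rows = [[r.mt_start + 1, r.mt_end, r.cp_start + 1, r.cp_end,
             f"{r.identity:.4f}", r.strand] for r in regions]
    write_tsv(path, ["mt_start", "mt_end", "cp_start", "cp_end", "identity", "strand"],
              rows, comments=["coordinates: 1-based inclusive"])


def read_links(path):
    from .io import read_tsv

    _, rows = read_tsv(path)
    return [
        (int(r[0]) - 1, int(r[1]), int(r[2]) - 1, int(r[3]), float(r[4]), r[5])
        for r in rows
    ]
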