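"""Substitutions, indels, corrected distances and the molecular clock.

Mismatch columns and gap runs are tabulated from base-level alignments of
the collinear blocks, split by annotation context (CDS vs intron vs
intergenic). Noncoding distances use the Kimura two-parameter correction
from transition (P) and transversion (Q) proportions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Synonymous/nonsynonymous rates use pathway counting over codon pairs with
a transition/transversion weighting for site counting (the modified
Nei-Gojobori approach), followed by the same two-parameter correction
applied separately to the synonymous and nonsynonymous classes.

The clock converts a calibration distance and a calibration time into a
rate, then a query distance into a time. Its default convention divides
the pairwise distance by the pairwise calibration rate with no factor of
two; per_lineage=True switches to the 2T convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import permutations

import edlib
import numpy as np
from Bio.Seq import Seq

from .core import AnnotatedGenome, revcomp

_PURINES = {"A", "G"}
_STOP = "*"


class SaturationError(ValueError):
    pass


def is_transition(a: str, b: str) -> bool:
    return a != b and ((a in _PURINES) == (b in _PURINES))


@dataclass(frozen=True)
class SubstitutionRecord:
    pair: str
    position: int  # 0-based on the anchor genome
    a_base: str
    b_base: str
    klass: str  # transition | transversion
    context: str  # CDS | intron | intergenic
    codon_effect: str  # synonymous | nonsynonymous | n/a
    gene: str = "."
    lineage: str | None = None  # A | B | unpolarized


@dataclass(frozen=True)
class IndelRecord:
    pair: str
    position: int
    length: int
    kind: str  # ins | del, relative to the anchor genome
    context: str


@dataclass
class DistanceEstimates:
    P: float
    Q: float
    d: float
    sites: int


def _hit_alignment(a: AnnotatedGenome, b: AnnotatedGenome, hit):
    """Gapped alignment strings for one hit, query forward. Hits produced by
    the search engine carry their own affine-gap alignment; otherwise a
    unit-cost global alignment is computed as a fallback."""
    if hit.qseq is not None and hit.sseq is not None:
        return hit.qseq, hit.sseq
    qseg = a.sequence[hit.qstart:hit.qend]
    sseg = b.fetch(hit.sstart, hit.send, hit.strand)
    res = edlib.align(qseg, sseg, mode="NW", task="path")
    qa, sa = [], []
    qp = sp = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            qa.append(qseg[qp:qp + n])
            sa.append(sseg[sp:sp + n])
            qp += n
            sp += n
        elif ch == "I":
            qa.append(qseg[qp:qp + n])
            sa.append("-" * n)
            qp += n
        else:
            qa.append("-" * n)
            sa.append(sseg[sp:sp + n])
            sp += n
    return "".join(qa), "".join(sa)


def _context_of(features, pos):
    for f in features:
        if f.type in ("CDS", "intron") and f.start <= pos < f.end:
            return ("CDS" if f.type == "CDS" else "intron"), f
    return "intergenic", None


def _codon_effect(genome: AnnotatedGenome, feat, pos, b_base):
    if feat.strand == "+":
        off = pos - feat.start
        ci, k = divmod(off, 3)
        codon = genome.sequence[feat.start + 3 * ci : feat.start + 3 * ci + 3]
        alt = codon[:k] + b_base + codon[k + 1 :]
    else:
        off = feat.end - 1 - pos
        ci, k = divmod(off, 3)
        codon = revcomp(genome.sequence[feat.end - 3 * ci - 3 : feat.end - 3 * ci])
        alt = codon[:k] + revcomp(b_base) + codon[k + 1 :]
    if len(codon) != 3 or "N" in codon or "N" in alt:
        return "n/a"
    same = str(Seq(codon).translate()) == str(Seq(alt).translate())
    return "synonymous" if same else "nonsynonymous"


def tabulate_differences(a: AnnotatedGenome, b: AnnotatedGenome, blocks,
                         pair: str | None = None):
    """Walk base-level alignments of all block anchors and emit one record
    per mismatch column and one indel per gap run. Positions are on the
    anchor (query) genome; exports add 1.

    Returns (records, indels, aligned_sites) with aligned_sites a dict
    context -> number of gap-free aligned columns."""
    pair = pair or f"{a.id}-{b.id}"
    cds_feats = [f for f in a.features if f.type == "CDS"]
    for f in cds_feats:
        if f.length % 3 != 0:
            raise ValueError(f"CDS {f.name} length {f.length} not divisible by 3")
    records, indels = [], []
    sites = {"CDS": 0, "intron": 0, "intergenic": 0}
    seen_cols = set()
    for blk in blocks:
        for hit in blk.hits:
            qa, sa = _hit_alignment(a, b, hit)
            qpos = hit.qstart
            gap_run = None  # (kind, anchor position, length)
            for qc, sc in zip(qa, sa):
                if qc != "-" and sc != "-":
                    if gap_run:
                        indels.append(IndelRecord(pair, gap_run[1], gap_run[2],
                                                  gap_run[0],
                                                  _context_of(a.features, gap_run[1])[0]))
                        gap_run = None
                    if qpos not in seen_cols:
                        seen_cols.add(qpos)
                        ctx, feat = _context_of(a.features, qpos)
                        sites[ctx] += 1
                        if qc != sc:
                            eff = ("n/a" if ctx != "CDS"
                                   else _codon_effect(a, feat, qpos, sc))
                            records.append(SubstitutionRecord(
                                pair, qpos, qc, sc,
                                "transition" if is_transition(qc, sc)
                                else "transversion",
                                ctx, eff, feat.name if feat else "."))
                    qpos += 1
                elif qc != "-":  # present in the anchor only
                    if gap_run and gap_run[0] == "ins":
                        gap_run = ("ins", gap_run[1], gap_run[2] + 1)
                    else:
                        if gap_run:
                            indels.append(IndelRecord(pair, gap_run[1], gap_run[2],
                                                      gap_run[0],
                                                      _context_of(a.features,
                                                                  gap_run[1])[0]))
                        gap_run = ("ins", qpos, 1)
                    qpos += 1
                else:  # present in the partner only
                    if gap_run and gap_run[0] == "del":
                        gap_run = ("del", gap_run[1], gap_run[2] + 1)
                    else:
                        if gap_run:
                            indels.append(IndelRecord(pair, gap_run[1], gap_run[2],
                                                      gap_run[0],
                                                      _context_of(a.features,
                                                                  gap_run[1])[0]))
                        gap_run = ("del", qpos, 1)
            if gap_run:
                indels.append(IndelRecord(pair, gap_run[1], gap_run[2], gap_run[0],
                                          _context_of(a.features, gap_run[1])[0]))
    records.sort(key=lambda r: r.position)
    indels.sort(key=lambda r: r.position)
    return records, indels, sites


def aligned_base_map(a: AnnotatedGenome, b: AnnotatedGenome, blocks) -> dict:
    """anchor position -> aligned partner base (gap columns omitted)."""
    out = {}
    for blk in blocks:
        for hit in blk.hits:
            qa, sa = _hit_alignment(a, b, hit)
            qpos = hit.qstart
            for qc, sc in zip(qa, sa):
                if qc != "-":
                    if sc != "-":
                        out[qpos] = sc
                    qpos += 1
    return out


# ---------------------------------------------------------------------------
# distances

def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition/transversion
    proportions; raises SaturationError when a logarithm argument is
    non-positive."""
    if P < 0 or Q < 0 or P + Q > 1:
        raise ValueError("P and Q must be non-negative with P+Q <= 1")
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0


def distance_from_records(records, sites: int, contexts=("intergenic", "intron")):
    """K2P distance over the stated contexts (noncoding by default)."""
    sub = [r for r in records if r.context in contexts]
    ts = sum(1 for r in sub if r.klass == "transition")
    tv = len(sub) - ts
    if sites <= 0:
        raise ValueError("no aligned sites")
    P, Q = ts / sites, tv / sites
    return DistanceEstimates(P, Q, k2p_distance(P, Q), sites)


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous rates (pathway counting)

_AA_CACHE: dict = {}


def _aa(codon: str) -> str:
    aa = _AA_CACHE.get(codon)
    if aa is None:
        aa = _AA_CACHE[codon] = str(Seq(codon).translate())
    return aa


_SITE_CACHE: dict = {}
_PATH_CACHE: dict = {}


def _site_counts(codon: str, kappa: float):
    """Weighted synonymous site count of one codon; transitions weighted
    kappa against transversions. Changes that would create a stop codon
    are excluded from the site bookkeeping, mirroring the usual counting-
    method treatment of mutations to stops."""
    key = (codon, kappa)
    hit = _SITE_CACHE.get(key)
    if hit is not None:
        return hit
    s = n = 0.0
    for k in range(3):
        ws = wn = 0.0
        for b in "ACGT":
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1 :]
            if _aa(alt) == _STOP:
                continue
            w = kappa if is_transition(codon[k], b) else 1.0
            if _aa(alt) == _aa(codon):
                ws += w
            else:
                wn += w
        if ws + wn > 0:
            s += ws / (ws + wn)
            n += wn / (ws + wn)
    _SITE_CACHE[key] = (s, n)
    return _SITE_CACHE[key]


def _pathway_diffs(c1: str, c2: str):
    """Average synonymous/nonsynonymous transition/transversion differences
    over minimal substitution pathways between two codons. Pathways that
    pass through a stop codon are excluded when an alternative exists."""
    pos = [k for k in range(3) if c1[k] != c2[k]]
    if not pos:
        return np.zeros(4)
    cached = _PATH_CACHE.get((c1, c2))
    if cached is not None:
        return cached
    paths = []
    for perm in permutations(pos):
        counts = np.zeros(4)  # syn_ts, syn_tv, nonsyn_ts, nonsyn_tv
        cur = c1
        through_stop = False
        for k in perm:
            nxt = cur[:k] + c2[k] + cur[k + 1 :]
            if _aa(nxt) == _STOP and nxt != c2:
                through_stop = True
            syn = _aa(nxt) != _STOP and _aa(nxt) == _aa(cur)
            ts = is_transition(cur[k], c2[k])
            idx = (0 if syn else 2) + (0 if ts else 1)
            counts[idx] += 1
            cur = nxt
        paths.append((through_stop, counts))
    clean = [c for stop, c in paths if not stop]
    use = clean if clean else [c for _, c in paths]
    out = np.mean(use, axis=0)
    _PATH_CACHE[(c1, c2)] = out
    return out


def pathway_counts(codon_pairs, kappa: float = 1.0):
    """Weighted site counts and pathway-averaged difference counts.

    Returns (syn_sites, nonsyn_sites, diffs, n_codons) where diffs holds
    [syn_ts, syn_tv, nonsyn_ts, nonsyn_tv]; codons containing ambiguity or
    stops are skipped."""
    if (isinstance(codon_pairs, tuple) and len(codon_pairs) == 2
            and isinstance(codon_pairs[0], str)):
        a, b = codon_pairs
        if len(a) != len(b) or len(a) % 3:
            raise ValueError("sequences must be equal length multiples of 3")
        codon_pairs = [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]
    S = N = 0.0
    diffs = np.zeros(4)
    n_codons = 0
    for ca, cb in codon_pairs:
        if "N" in ca or "N" in cb or _aa(ca) == _STOP or _aa(cb) == _STOP:
            continue
        sa, na = _site_counts(ca, kappa)
        sb, nb = _site_counts(cb, kappa)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        diffs += _pathway_diffs(ca, cb)
        n_codons += 1
    return S, N, diffs, n_codons


def ks_ka(codon_pairs, kappa: float = 1.0):
    """Synonymous and nonsynonymous substitutions per site for a collection
    of aligned, gap-stripped codon pairs.

    codon_pairs: iterable of (codon_a, codon_b) 3-mers, or a pair of equal
    length coding sequences. Returns (Ks, Ka, info)."""
    S, N, diffs, n_codons = pathway_counts(codon_pairs, kappa)
    if S <= 0:
        raise ValueError("zero synonymous sites")
    Ps, Qs = diffs[0] / S, diffs[1] / S
    Pn, Qn = diffs[2] / N, diffs[3] / N
    ks = k2p_distance(Ps, Qs)
    ka = k2p_distance(Pn, Qn)
    info = {"syn_sites": S, "nonsyn_sites": N, "codons": n_codons,
            "syn_ts": diffs[0], "syn_tv": diffs[1],
            "nonsyn_ts": diffs[2], "nonsyn_tv": diffs[3]}
    return ks, ka, info


# ---------------------------------------------------------------------------
# polarization on ((A,B),outgroup)

def polarize(records, outgroup_map: dict):
    """Assign each substitution to the ingroup lineage whose base differs
    from the state shared by the outgroup and the other ingroup genome.

    outgroup_map: anchor position -> outgroup base (absent = unaligned).
    Returns (records with lineage set, counts dict); lineage counts plus
    the unpolarized count always sum to the total."""
    out_records = []
    counts = {"A": 0, "B": 0, "unpolarized": 0}
    for r in records:
        o = outgroup_map.get(r.position)
        if o is None or o not in "ACGT":
            lin = "unpolarized"
        elif o == r.b_base and o != r.a_base:
            lin = "A"
        elif o == r.a_base and o != r.b_base:
            lin = "B"
        else:
            lin = "unpolarized"
        counts[lin] += 1
        out_records.append(replace(r, lineage=lin))
    return out_records, counts


# ---------------------------------------------------------------------------
# molecular clock

def clock(query_distance: float, calibration_distance: float,
          calibration_time: float, per_lineage: bool = False):
    """Rate and divergence time from a calibrated distance.

    rate = calibration_distance / calibration_time (per site per year) and
    T = query_distance / rate. The default reproduces the pairwise
    convention with no factor of two; per_lineage=True uses T = d / (2r).
    """
    for name, v in (("query_distance", query_distance),
                    ("calibration_distance", calibration_distance),
                    ("calibration_time", calibration_time)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    r = calibration_distance / calibration_time
    T = query_distance / ((2 * r) if per_lineage else r)
    return r, T


# ---------------------------------------------------------------------------
# coding-sequence pairing through the alignment map

def codon_pairs_from_map(a: AnnotatedGenome, base_map: dict):
    """Codon pairs for every CDS of the anchor genome, using only codons
    whose three positions all have aligned partner bases."""
    pairs = []
    for f in a.features:
        if f.type != "CDS":
            continue
        for ci in range(f.length // 3):
            if f.strand == "+":
                p0 = f.start + 3 * ci
                idxs = [p0, p0 + 1, p0 + 2]
            else:
                p0 = f.end - 3 * ci - 3
                idxs = [p0 + 2, p0 + 1, p0]
            if not all(i in base_map for i in idxs):
                continue
            if f.strand == "+":
                ca = a.sequence[idxs[0] : idxs[0] + 3]
                cb = "".join(base_map[i] for i in idxs)
            else:
                ca = revcomp(a.sequence[idxs[2] : idxs[2] + 3])
                cb = revcomp("".join(base_map[i] for i in reversed(idxs)))
            pairs.append((ca, cb))
    return pairs
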