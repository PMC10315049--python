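"""Dispersed repeats and repeat-mediated recombination.

Repeats are enumerated as *exact* maximal repeated segment pairs (direct
and inverted) found by word seeding and unbounded extension, then reduced
to non-redundant repeat units by greedy longest-first selection with
coordinate tie-breaking - the masking behaviour of the classic organelle
repeat scripts. Exactness is deliberate: it makes the enumeration
checkable against a brute-force oracle.

The recombination assay follows the long-read counting approach used for
organelle repeat pairs: a read counts only if it spans one repeat copy
entirely plus a minimum of unique flanking sequence on both sides, and it
is assigned the best-matching of the four flank conformations (two
parental, two recombinant); ties are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .core import AnnotatedGenome, merge_intervals, revcomp, union_length


@dataclass(frozen=True)
class RepeatPair:
    """Two copies of a dispersed repeat (0-based half-open intervals on the
    forward strand; `relation` says whether copy2 matches copy1 directly or
    reverse-complemented)."""

    copy1: tuple
    copy2: tuple
    relation: str  # direct | inverted
    length: int
    identity: float = 1.0

    def key(self):
        return (self.copy1, self.copy2, self.relation)


def _seed_positions(seq: str, k: int) -> dict:
    d: dict[str, list] = {}
    for i in range(len(seq) - k + 1):
        d.setdefault(seq[i : i + k], []).append(i)
    return d


def maximal_repeat_pairs(seq: str, min_len: int = 30, circular: bool = False):
    """All maximal exact repeated segment pairs of length >= min_len, on
    both strand relations. On circular sequences the search runs on the
    doubled sequence and results are deduplicated modulo the length."""
    seq = seq.upper()
    n = len(seq)
    work = seq + seq if circular else seq
    k = min_len
    found: dict = {}

    def add(i1, i2, length, relation):
        if circular:
            if length > n:
                return
            i1m, i2m = i1 % n, i2 % n
            c1, c2 = (i1m, i1m + length), (i2m, i2m + length)
        else:
            c1, c2 = (i1, i1 + length), (i2, i2 + length)
        if c2 < c1:
            c1, c2 = c2, c1
        if c1 == c2:
            return
        found[(c1, c2, relation)] = RepeatPair(c1, c2, relation, length)

    # direct repeats
    seeds = _seed_positions(work, k)
    done_diag: dict[int, list] = {}
    for positions in seeds.values():
        if len(positions) < 2:
            continue
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                i, j = positions[x], positions[y]
                off = j - i
                if circular and off % n == 0:
                    continue
                covered = any(s <= i and i + k <= e for s, e in done_diag.get(off, []))
                if covered:
                    continue
                a = 0
                while i - a - 1 >= 0 and work[i - a - 1] == work[j - a - 1]:
                    a += 1
                b = k
                while j + b < len(work) and work[i + b] == work[j + b]:
                    b += 1
                s1, length = i - a, a + b
                done_diag.setdefault(off, []).append((s1, s1 + length))
                if length >= min_len:
                    add(s1, s1 + off, length, "direct")

    # inverted repeats: match against the reverse complement
    rc = revcomp(work)
    m = len(work)
    rc_seeds: dict[str, list] = {}
    for i in range(m - k + 1):
        rc_seeds.setdefault(rc[i : i + k], []).append(i)
    done_anti: dict[int, list] = {}
    for word, positions in seeds.items():
        rpos = rc_seeds.get(word)
        if not rpos:
            continue
        for i in positions:
            for p in rpos:
                # rc[p:p+L] corresponds to work interval [m-p-L, m-p)
                anti = i + (m - p)  # invariant along an extension
                covered = any(s <= i and i + k <= e for s, e in done_anti.get(anti, []))
                if covered:
                    continue
                a = 0
                while i - a - 1 >= 0 and p - a - 1 >= 0 and work[i - a - 1] == rc[p - a - 1]:
                    a += 1
                b = k
                while i + b < m and p + b < m and work[i + b] == rc[p + b]:
                    b += 1
                i0, p0, length = i - a, p - a, a + b
                done_anti.setdefault(anti, []).append((i0, i0 + length))
                if length < min_len:
                    continue
                j0 = m - p0 - length
                if j0 == i0:
                    continue  # a sequence is trivially its own reverse complement partner
                add(i0, j0, length, "inverted")

    pairs = sorted(found.values(), key=lambda r: (-r.length, r.copy1, r.copy2))
    # drop inverted self-overlaps reported twice (palindrome symmetry)
    return pairs


@dataclass
class RepeatSummary:
    unit_count: int
    largest: int
    repeat_bp: int
    content: float  # union bp of all copies / genome length
    units: list = field(default_factory=list)


def find_repeats(genome: AnnotatedGenome | str, min_len: int = 30):
    """Repeat units and content summary for one genome.

    Returns (units, summary): units are the greedy longest-first selection
    of maximal repeat pairs whose copies are not already contained in an
    accepted unit's copies; content is the union of all copies of all
    maximal pairs over the genome length.
    """
    if isinstance(genome, AnnotatedGenome):
        seq, circ, glen = genome.sequence, genome.topology == "circular", len(genome)
    else:
        seq, circ, glen = genome.upper(), False, len(genome)
    pairs = maximal_repeat_pairs(seq, min_len, circular=circ)
    units: list[RepeatPair] = []
    covered: list[tuple] = []

    def contained(iv):
        return any(s <= iv[0] and iv[1] <= e for s, e in covered)

    for p in pairs:
        if contained(p.copy1) and contained(p.copy2):
            continue
        units.append(p)
        covered.extend([p.copy1, p.copy2])
        covered = merge_intervals(covered)

    all_copies = [iv for p in pairs for iv in (p.copy1, p.copy2)]
    rep_bp = union_length([(s, min(e, glen)) for s, e in all_copies] +
                          [(0, e - glen) for s, e in all_copies if e > glen])
    summary = RepeatSummary(
        unit_count=len(units),
        largest=max((p.length for p in pairs), default=0),
        repeat_bp=rep_bp,
        content=rep_bp / glen if glen else 0.0,
        units=units,
    )
    return units, summary


# ---------------------------------------------------------------------------
# recombination assay

class AssayRefusedError(ValueError):
    pass


@dataclass
class RecombinationAssay:
    pair: RepeatPair
    flank: int
    parental_1: int = 0
    parental_2: int = 0
    recombinant_1: int = 0
    recombinant_2: int = 0
    ties: int = 0

    @property
    def total(self) -> int:
        return self.parental_1 + self.parental_2 + self.recombinant_1 + self.recombinant_2

    @property
    def frequency(self):
        t = self.total
        if t == 0:
            return None
        return (self.recombinant_1 + self.recombinant_2) / t


def recombination_frequency(
    genome: AnnotatedGenome,
    repeat: RepeatPair,
    reads,
    flank: int = 100,
    min_read_identity: float = 0.80,
) -> RecombinationAssay:
    """Count parental vs recombinant conformations among repeat-spanning
    long reads.

    With repeat copies 1 and 2 flanked by unique sequence A..B and C..D,
    the parental conformations are A-R-B and C-R-D and the recombinant
    ones A-R-D and C-R-B. A read is assigned to the conformation whose
    full sequence (repeat copy plus `flank` bp on both sides) it contains
    at >= min_read_identity; ties between a parental and a recombinant
    assignment are discarded.
    """
    (s1, e1), (s2, e2) = repeat.copy1, repeat.copy2
    if repeat.length <= 100:
        raise AssayRefusedError("assay requires repeat pairs larger than 100 bp")
    if s2 - e1 < 2 * flank:
        raise AssayRefusedError(
            f"repeat copies closer than 2x flank ({s2 - e1} < {2 * flank} bp)")

    A = genome.fetch(s1 - flank, s1) if s1 >= flank else genome.fetch(s1 - flank + len(genome), s1 + len(genome))
    B = genome.fetch(e1, e1 + flank)
    C = genome.fetch(s2 - flank, s2)
    D = genome.fetch(e2, e2 + flank)
    R1 = genome.fetch(s1, e1)
    R2 = genome.fetch(s2, e2)
    if repeat.relation == "inverted":
        # traverse copy2 on its own strand so the flank labels stay meaningful
        C, D = revcomp(D), revcomp(C)
        R2 = revcomp(R2)
    refs = {
        "parental_1": A + R1 + B,
        "parental_2": C + R2 + D,
        "recombinant_1": A + R1 + D,
        "recombinant_2": C + R2 + B,
    }
    assay = RecombinationAssay(repeat, flank)
    reads = sorted(reads, key=lambda r: getattr(r, "id", str(r)))
    for read in reads:
        seq = read.sequence if hasattr(read, "sequence") else str(read)
        best = {}
        for name, ref in refs.items():
            max_ed = int(len(ref) * (1 - min_read_identity))
            for target in (seq, revcomp(seq)):
                res = edlib.align(ref, target, mode="HW", task="distance", k=max_ed)
                if res["editDistance"] != -1:
                    best[name] = min(best.get(name, max_ed + 1), res["editDistance"])
        if not best:
            continue
        lo = min(best.values())
        winners = {n for n, d in best.items() if d == lo}
        par = {w for w in winners if w.startswith("parental")}
        rec = {w for w in winners if w.startswith("recombinant")}
        if par and rec:
            assay.ties += 1
            continue
        w = sorted(winners)[0]
        setattr(assay, w, getattr(assay, w) + 1)
    return assay
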