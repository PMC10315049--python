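"""Core containers shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; exported text
formats (GFF3, hit tables, link TSVs) use 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURE_TYPES = {
    "gene",
    "CDS",
    "tRNA",
    "rRNA",
    "intron",
    "transferred_region",
    "pseudogene",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction with ambiguous bases excluded from both numerator and
    denominator."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return 0.0
    return gc / (gc + at)


@dataclass(frozen=True)
class Feature:
    """A typed interval on a genome (0-based half-open)."""

    type: str
    start: int
    end: int
    strand: str = "+"
    name: str = "."
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad feature interval [{self.start},{self.end})")
        if self.strand not in "+-.":
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A (possibly circular-mapping) sequence plus typed features."""

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[Feature] = field(default_factory=list)
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"alphabet outside ACGTN: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n and self.topology == "linear":
                raise ValueError(f"feature {f.name} [{f.start},{f.end}) outside genome of {n} bp")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Extract [start, end); wraps the origin on circular genomes."""
        n = len(self.sequence)
        if end <= n:
            s = self.sequence[start:end]
        elif self.topology == "circular":
            s = self.sequence[start:] + self.sequence[: end - n]
        else:
            raise IndexError(f"[{start},{end}) outside linear genome of {n} bp")
        return revcomp(s) if strand == "-" else s

    def rotated(self, offset: int) -> "AnnotatedGenome":
        """Return the genome re-linearized to start at `offset` (circular only)."""
        if self.topology != "circular":
            raise ValueError("rotation only defined for circular genomes")
        n = len(self.sequence)
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            s = (f.start - offset) % n
            feats.append(replace(f, start=s, end=s + f.length))
        return AnnotatedGenome(self.id, seq, "circular", feats, self.description)


# ---------------------------------------------------------------------------
# interval arithmetic (all 0-based half-open)

def merge_intervals(ivs, slack: int = 0):
    """Union of intervals; intervals separated by < slack are bridged."""
    if not ivs:
        return []
    ivs = sorted((int(a), int(b)) for a, b in ivs if b > a)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a - out[-1][1] < slack or a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def complement_intervals(ivs, length: int):
    """Complement of a union of intervals within [0, length)."""
    out = []
    pos = 0
    for a, b in merge_intervals(ivs):
        a, b = max(0, a), min(length, b)
        if a > pos:
            out.append((pos, a))
        pos = max(pos, b)
    if pos < length:
        out.append((pos, length))
    return out


def union_length(ivs) -> int:
    return sum(b - a for a, b in merge_intervals(ivs))


def intersect_length(a, b) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))
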