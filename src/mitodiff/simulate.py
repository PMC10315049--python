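"""Synthetic three-lineage organelle genome sets with a truth ledger.

The generator emulates the comparative setting of a small tropical-shrub
genus: three mitogenomes descending from one ancestor on the rooted
topology ((C,S),D), with

* noncoding substitution rates set by branch lengths and coding sites
  evolving three-fold slower,
* short indels (1-8 bp) confined to noncoding sequence,
* chloroplast-derived insertions (ancestral and lineage-specific), with
  post-transfer divergence so old transfers carry diagnostic differences
  from the extant chloroplast,
* intragenomic duplications, segment gains and losses, foreign-donor
  (horizontal-transfer-like) insertions and nuclear-homologous segments,
* one large inversion on one branch, dispersed repeat pairs, and
* a recurrent chloroplast transfer that overwrites part of an ancestral
  transferred region in a subset of simulated individuals.

Every planted event, substitution and indel is recorded in a machine-
readable TruthLedger with final (post-mutation) coordinates per genome,
so each downstream stage can be scored against known ground truth.
Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import AnnotatedGenome, Feature, merge_intervals, revcomp

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_STOPS = {"TAA", "TAG", "TGA"}

DEFAULT_TREE = {"C": 0.0022, "S": 0.0022, "CS": 0.0004, "D": 0.0020}

DEFAULT_EVENT_COUNTS = {
    "idt_ancestral": 1,
    "idt_lineage": 1,
    "duplication": 1,
    "gain": 2,
    "loss": 2,
    "hdt": 1,
    "nuclear_homolog": 1,
    "inversion": 1,
    "repeat_pair": 2,
    "recurrent_idt": 1,
}

DEFAULT_EVENT_SIZES = {
    "idt_ancestral": 5000,
    "idt_lineage": 8000,
    "duplication": 1500,
    "gain": 2700,
    "loss": 2000,
    "hdt": 3000,
    "nuclear_homolog": 800,
    "inversion": 12000,
    "repeat_pair": 300,
    "recurrent_idt": 3300,
}

# which branch receives the k-th event of each kind (cycled)
_BRANCH_CYCLE = {
    "idt_lineage": ["D", "C", "S"],
    "duplication": ["C", "S", "D"],
    "gain": ["CS", "CS", "D"],
    "loss": ["C", "S", "D"],
    "hdt": ["D", "C", "S"],
    "nuclear_homolog": ["D", "C", "S"],
    "inversion": ["C", "S", "D"],
}


class PlacementError(RuntimeError):
    pass


# compact study profile: the full event inventory on smaller sequences, so
# search-backed stages run in seconds; used by the quick-start examples and
# the reproduction script
COMPACT_EVENT_SIZES = {
    "idt_ancestral": 1800,
    "idt_lineage": 2200,
    "duplication": 700,
    "gain": 900,
    "loss": 800,
    "hdt": 1000,
    "nuclear_homolog": 450,
    "inversion": 4000,
    "repeat_pair": 160,
    "recurrent_idt": 1100,
}


def compact_config(seed: int, **overrides) -> "SimConfig":
    kw = dict(
        seed=seed,
        mt_ancestor_len=16000,
        cp_len=10000,
        nuclear_len=8000,
        n_genes=5,
        gene_len=600,
        n_cp_genes=5,
        event_sizes=dict(COMPACT_EVENT_SIZES),
        idt_age_divergence=0.03,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass
class SimConfig:
    seed: int = 0
    mt_ancestor_len: int = 40000
    cp_len: int = 24000
    nuclear_len: int = 30000
    tree: dict = field(default_factory=lambda: dict(DEFAULT_TREE))
    coding_rate_factor: float = 1.0 / 3.0
    indel_rate: float = 4e-4
    indel_size_range: tuple = (1, 8)
    ts_weight: float = 1.0  # transition weight; 1.0 gives P(transition)=1/3
    event_counts: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_COUNTS))
    event_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_SIZES))
    idt_age_divergence: float = 0.024  # substitutions/site accrued since the old transfer
    idt_age_indel_rate: float = 0.008  # indels/site accrued since the old transfer
    recurrent_idt_carrier_fraction: float = 1.0 / 3.0
    read_len_mean: int = 8000
    read_error_rate: float = 0.08
    read_coverage: float = 20.0
    recombinant_read_fraction: float = 0.0
    n_genes: int = 10
    gene_len: int = 900
    n_cp_genes: int = 8
    rotate: bool = True
    placement_retries: int = 100

    def __post_init__(self):
        lo, hi = self.indel_size_range
        if not (1 <= lo <= hi):
            raise ValueError("indel_size_range must satisfy 1 <= min <= max")
        if not (0 <= self.recurrent_idt_carrier_fraction <= 1):
            raise ValueError("carrier fraction must be in [0,1]")
        for k, v in self.tree.items():
            if v < 0:
                raise ValueError(f"negative branch length on {k}")
        for name in ("coding_rate_factor", "indel_rate", "read_error_rate",
                     "idt_age_divergence", "idt_age_indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["indel_size_range"] = list(self.indel_size_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "indel_size_range" in d:
            d["indel_size_range"] = tuple(d["indel_size_range"])
        return cls(**d)


@dataclass
class LedgerEvent:
    id: str
    kind: str
    branch: str  # root | CS | C | S | D
    coords: dict = field(default_factory=dict)  # genome id -> [start, end, strand]
    donor: dict = field(default_factory=dict)  # source, start, end, sequence
    meta: dict = field(default_factory=dict)


@dataclass
class TruthLedger:
    events: list = field(default_factory=list)
    substitutions: list = field(default_factory=list)  # dicts, see _emit
    indels: list = field(default_factory=list)
    rotations: dict = field(default_factory=dict)
    recurrent: dict = field(default_factory=dict)

    def events_of(self, kind: str):
        return [e for e in self.events if e.kind == kind]

    def branch_substitution_counts(self) -> dict:
        out = {}
        for s in self.substitutions:
            out[s["branch"]] = out.get(s["branch"], 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "events": [dataclasses.asdict(e) for e in self.events],
            "substitutions": self.substitutions,
            "indels": self.indels,
            "rotations": self.rotations,
            "recurrent": self.recurrent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthLedger":
        led = cls(
            substitutions=d["substitutions"],
            indels=d["indels"],
            rotations=d["rotations"],
            recurrent=d["recurrent"],
        )
        led.events = [LedgerEvent(**e) for e in d["events"]]
        return led


# ---------------------------------------------------------------------------
# coordinate-tracked mutable sequence

class TrackedGenome:
    """A mutable sequence whose named intervals follow every edit."""

    def __init__(self, seq: str):
        self.seq = list(seq)
        self.tracks: dict[str, dict] = {}

    def __len__(self):
        return len(self.seq)

    @property
    def sequence(self) -> str:
        return "".join(self.seq)

    def clone(self) -> "TrackedGenome":
        tg = TrackedGenome("")
        tg.seq = list(self.seq)
        tg.tracks = copy.deepcopy(self.tracks)
        return tg

    def add_track(self, tid, start, end, strand="+", kind="event", **meta):
        self.tracks[tid] = {"start": start, "end": end, "strand": strand,
                            "kind": kind, "meta": meta}

    def insert(self, pos, s):
        n = len(s)
        self.seq[pos:pos] = list(s)
        for t in self.tracks.values():
            if t["start"] >= pos:
                t["start"] += n
                t["end"] += n
            elif t["end"] > pos:
                t["end"] += n

    def delete(self, start, end):
        d = end - start
        del self.seq[start:end]

        def remap(x):
            if x <= start:
                return x
            if x >= end:
                return x - d
            return start

        drop = []
        for tid, t in self.tracks.items():
            ns, ne = remap(t["start"]), remap(t["end"])
            if ne <= ns:
                drop.append(tid)
            else:
                t["start"], t["end"] = ns, ne
        for tid in drop:
            del self.tracks[tid]

    def invert(self, start, end):
        self.seq[start:end] = list(revcomp("".join(self.seq[start:end])))
        for tid, t in self.tracks.items():
            if t["end"] <= start or t["start"] >= end:
                continue
            if t["start"] >= start and t["end"] <= end:
                ns = start + (end - t["end"])
                ne = start + (end - t["start"])
                t["start"], t["end"] = ns, ne
                t["strand"] = "-" if t["strand"] == "+" else "+"
            else:
                raise PlacementError(f"track {tid} straddles inversion boundary")

    def substitute(self, pos, base):
        self.seq[pos] = base

    def blocked(self, min_span=2):
        return merge_intervals(
            [(t["start"], t["end"]) for t in self.tracks.values()
             if t["end"] - t["start"] >= min_span]
        )

    def rotate(self, offset):
        n = len(self.seq)
        offset %= n
        self.seq = self.seq[offset:] + self.seq[:offset]
        for t in self.tracks.values():
            span = t["end"] - t["start"]
            t["start"] = (t["start"] - offset) % n
            t["end"] = t["start"] + span


def _random_seq(rng, n) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def _random_cds(rng, n_codons) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOPS:
            codons.append(c)
    codons.append(str(rng.choice(["TAA", "TAG", "TGA"])))
    return "".join(codons)


def _free_position(rng, length, span, blocked, retries, what):
    """A start position such that [pos, pos+span) avoids all blocked
    intervals; bounded retries, then a placement error naming the event."""
    for _ in range(retries):
        pos = int(rng.integers(0, max(1, length - span)))
        if all(e <= pos or s >= pos + span for s, e in blocked):
            return pos
    raise PlacementError(f"could not place {what} ({span} bp) after {retries} attempts")


def _substitute_base(rng, old, ts_weight):
    p_ts = ts_weight / (ts_weight + 2.0)
    if rng.random() < p_ts:
        return _TRANSITION[old]
    tvs = [b for b in BASES if b != old and b != _TRANSITION[old]]
    return tvs[int(rng.integers(0, 2))]


def _coding_mask(tg: TrackedGenome) -> np.ndarray:
    mask = np.zeros(len(tg), dtype=bool)
    for t in tg.tracks.values():
        if t["kind"] == "gene":
            mask[t["start"]:t["end"]] = True
    return mask


def _mutate_branch(tg: TrackedGenome, branch: str, t_len: float, cfg: SimConfig, rng):
    """Apply substitutions (noncoding rate t_len, coding scaled) and short
    noncoding indels along one branch; record them as point tracks."""
    n = len(tg)
    if t_len > 0:
        coding = _coding_mask(tg)
        p = np.where(coding, t_len * cfg.coding_rate_factor, t_len)
        hit = np.flatnonzero(rng.random(n) < p)
        for k, pos in enumerate(hit):
            pos = int(pos)
            old = tg.seq[pos]
            if old == "N":
                continue
            new = _substitute_base(rng, old, cfg.ts_weight)
            tg.substitute(pos, new)
            tg.add_track(f"sub_{branch}_{k}_{pos}", pos, pos + 1, "+", "sub",
                         branch=branch, ref=old, alt=new, coding=bool(coding[pos]))
    if cfg.indel_rate > 0:
        n_ind = int(rng.binomial(len(tg), cfg.indel_rate))
        lo, hi = cfg.indel_size_range
        for k in range(n_ind):
            size = int(rng.integers(lo, hi + 1))
            is_ins = bool(rng.random() < 0.5)
            blocked = tg.blocked(min_span=2)
            try:
                pos = _free_position(rng, len(tg), size, blocked,
                                     cfg.placement_retries, f"indel on {branch}")
            except PlacementError:
                continue  # genome too crowded for this indel; skip it
            if is_ins:
                tg.insert(pos, _random_seq(rng, size))
            else:
                tg.delete(pos, pos + size)
            tg.add_track(f"indel_{branch}_{k}_{pos}", pos, pos + 1, "+", "indel",
                         branch=branch, size=size, type="ins" if is_ins else "del")


@dataclass
class SimResult:
    genomes: dict  # species -> AnnotatedGenome (C, S, D)
    cp: AnnotatedGenome
    nuclear: AnnotatedGenome
    external: list  # (taxon, relatedness, sequence)
    ledger: TruthLedger
    config: SimConfig


def _plant_insertion(tg, rng, cfg, eid, kind, donor_name, donor_seq, donor_iv, branch):
    blocked = tg.blocked(min_span=2)
    pos = _free_position(rng, len(tg), 1, blocked, cfg.placement_retries, eid)
    tg.insert(pos, donor_seq)
    tg.add_track(eid, pos, pos + len(donor_seq), "+", "event",
                 event_kind=kind, branch=branch)
    return LedgerEvent(eid, kind, branch, donor={
        "source": donor_name, "start": donor_iv[0], "end": donor_iv[1],
        "sequence": donor_seq,
    })


def simulate_genomes(config: SimConfig) -> SimResult:
    """Generate the three-species genome set, references and truth ledger.

    The same seed always yields byte-identical sequences and ledger."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    counts = dict(DEFAULT_EVENT_COUNTS)
    counts.update(cfg.event_counts)
    sizes = dict(DEFAULT_EVENT_SIZES)
    sizes.update(cfg.event_sizes)

    # --- references -------------------------------------------------------
    cp_tg = TrackedGenome(_random_seq(rng, cfg.cp_len))
    cp_gene_len = 900
    step = cfg.cp_len // max(1, cfg.n_cp_genes)
    for i in range(cfg.n_cp_genes):
        pos = i * step + 100
        cds = _random_cds(rng, cp_gene_len // 3)
        cp_tg.seq[pos:pos + len(cds)] = list(cds)
        cp_tg.add_track(f"cp_gene_{i + 1}", pos, pos + len(cds), "+", "gene",
                        name=f"cpg{i + 1}")

    nuclear_seq = _random_seq(rng, cfg.nuclear_len)
    distant_mito = _random_seq(rng, 20000)

    # --- ancestor ---------------------------------------------------------
    anc = TrackedGenome(_random_seq(rng, cfg.mt_ancestor_len))
    gstep = cfg.mt_ancestor_len // max(1, cfg.n_genes)
    for i in range(cfg.n_genes):
        pos = i * gstep + int(rng.integers(0, max(1, gstep // 3)))
        cds = _random_cds(rng, cfg.gene_len // 3)
        strand = "+" if rng.random() < 0.5 else "-"
        anc.seq[pos:pos + len(cds)] = list(cds if strand == "+" else revcomp(cds))
        anc.add_track(f"mt_gene_{i + 1}", pos, pos + len(cds), strand, "gene",
                      name=f"mtg{i + 1}")

    events: list[LedgerEvent] = []

    # close external mitochondrial reference: the ancestor diverged ~3%
    close_mito = list(anc.seq)
    for pos in np.flatnonzero(rng.random(len(close_mito)) < 0.03):
        close_mito[pos] = _substitute_base(rng, close_mito[pos], cfg.ts_weight)
    close_mito = "".join(close_mito)

    # ancestral chloroplast transfers, aged by post-transfer mutations
    anc_idt_ids = []
    for k in range(counts.get("idt_ancestral", 0)):
        size = sizes["idt_ancestral"]
        gene = cp_tg.tracks[f"cp_gene_{1 + k % cfg.n_cp_genes}"]
        d_start = max(0, gene["start"] - int(rng.integers(50, 300)))
        d_end = min(cfg.cp_len, d_start + size)
        donor = cp_tg.sequence[d_start:d_end]
        aged = list(donor)
        for pos in np.flatnonzero(rng.random(len(aged)) < cfg.idt_age_divergence):
            aged[pos] = _substitute_base(rng, aged[pos], cfg.ts_weight)
        n_aind = int(rng.binomial(len(aged), cfg.idt_age_indel_rate))
        for _ in range(n_aind):
            sz = int(rng.integers(cfg.indel_size_range[0], cfg.indel_size_range[1] + 1))
            pos = int(rng.integers(1, max(2, len(aged) - sz - 1)))
            if rng.random() < 0.5:
                aged[pos:pos] = list(_random_seq(rng, sz))
            else:
                del aged[pos:pos + sz]
        aged = "".join(aged)
        eid = f"idt_ancestral_{k + 1}"
        ev = _plant_insertion(anc, rng, cfg, eid, "idt_ancestral", "cp",
                              aged, (d_start, d_end), "root")
        ev.meta["cp_interval"] = [d_start, d_end]
        events.append(ev)
        anc_idt_ids.append(eid)

    # ancestral dispersed repeat pairs (direct strand)
    for k in range(counts.get("repeat_pair", 0)):
        size = sizes["repeat_pair"]
        blocked = anc.blocked(min_span=2)
        src = _free_position(rng, len(anc), size, blocked, cfg.placement_retries,
                             f"repeat_pair_{k + 1} source")
        unit = anc.sequence[src:src + size]
        anc.add_track(f"repeat_pair_{k + 1}_copy1", src, src + size, "+", "event",
                      event_kind="repeat_pair", branch="root")
        blocked = anc.blocked(min_span=2)
        dst = _free_position(rng, len(anc), 1, blocked, cfg.placement_retries,
                             f"repeat_pair_{k + 1} copy2")
        anc.insert(dst, unit)
        anc.add_track(f"repeat_pair_{k + 1}_copy2", dst, dst + size, "+", "event",
                      event_kind="repeat_pair", branch="root")
        events.append(LedgerEvent(f"repeat_pair_{k + 1}", "repeat_pair", "root",
                                  donor={"source": "self", "start": src,
                                         "end": src + size, "sequence": unit}))

    # reserve loss targets on the ancestor so losses on different branches
    # remove disjoint segments (overlapping losses would confound the truth)
    for k in range(counts.get("loss", 0)):
        size = sizes["loss"]
        blocked = anc.blocked(min_span=2)
        pos = _free_position(rng, len(anc), size, blocked, cfg.placement_retries,
                             f"loss_{k + 1} target")
        anc.add_track(f"loss_{k + 1}_target", pos, pos + size, "+", "reserved",
                      event_kind="loss_target")

    # --- evolve down the tree --------------------------------------------
    def branch_events(tg: TrackedGenome, branch: str):
        for kind in ("idt_lineage", "gain", "hdt", "nuclear_homolog",
                     "duplication", "loss", "inversion"):
            cycle = _BRANCH_CYCLE[kind]
            for k in range(counts.get(kind, 0)):
                if cycle[k % len(cycle)] != branch:
                    continue
                eid = f"{kind}_{k + 1}"
                size = sizes[kind]
                if kind == "idt_lineage":
                    gene_i = 1 + (cfg.n_cp_genes // 2 + k) % cfg.n_cp_genes
                    g = cp_tg.tracks[f"cp_gene_{gene_i}"]
                    d_start = max(0, g["start"] - 100)
                    d_end = min(cfg.cp_len, d_start + size)
                    donor = cp_tg.sequence[d_start:d_end]
                    ev = _plant_insertion(tg, rng, cfg, eid, kind, "cp",
                                          donor, (d_start, d_end), branch)
                    ev.meta["cp_interval"] = [d_start, d_end]
                    events.append(ev)
                elif kind == "gain":
                    donor = _random_seq(rng, size)
                    events.append(_plant_insertion(tg, rng, cfg, eid, kind,
                                                   "novel", donor, (0, size), branch))
                elif kind == "hdt":
                    d_start = int(rng.integers(0, len(distant_mito) - size))
                    donor = distant_mito[d_start:d_start + size]
                    events.append(_plant_insertion(tg, rng, cfg, eid, kind,
                                                   "distant_mito", donor,
                                                   (d_start, d_start + size), branch))
                elif kind == "nuclear_homolog":
                    d_start = int(rng.integers(0, cfg.nuclear_len - size))
                    donor = nuclear_seq[d_start:d_start + size]
                    events.append(_plant_insertion(tg, rng, cfg, eid, kind,
                                                   "nuclear", donor,
                                                   (d_start, d_start + size), branch))
                elif kind == "duplication":
                    blocked = tg.blocked(min_span=2)
                    src = _free_position(rng, len(tg), size, blocked,
                                         cfg.placement_retries, f"{eid} source")
                    donor = tg.sequence[src:src + size]
                    # the source interval must stay off-limits to later
                    # deletions/inversions, or events would be confounded
                    tg.add_track(f"{eid}_src", src, src + size, "+", "event",
                                 event_kind="duplication_src", branch=branch)
                    events.append(_plant_insertion(tg, rng, cfg, eid, kind,
                                                   "self", donor, (src, src + size),
                                                   branch))
                elif kind == "loss":
                    t = tg.tracks.pop(f"{eid}_target")
                    pos, end = t["start"], t["end"]
                    lost = tg.sequence[pos:end]
                    tg.delete(pos, end)
                    tg.add_track(eid, pos, pos + 1, "+", "event",
                                 event_kind="loss", branch=branch)
                    events.append(LedgerEvent(eid, kind, branch,
                                              donor={"source": "self", "start": pos,
                                                     "end": end, "sequence": lost}))
                elif kind == "inversion":
                    for _ in range(cfg.placement_retries):
                        start = int(rng.integers(0, len(tg) - size))
                        end = start + size
                        ok = all(
                            t["end"] <= start or t["start"] >= end
                            or (t["start"] >= start and t["end"] <= end)
                            for t in tg.tracks.values()
                        )
                        if ok:
                            break
                    else:
                        raise PlacementError(f"could not place {eid}")
                    tg.invert(start, end)
                    tg.add_track(eid, start, end, "-", "event",
                                 event_kind="inversion", branch=branch)
                    events.append(LedgerEvent(eid, kind, branch))

    node_cs = anc.clone()
    _mutate_branch(node_cs, "CS", cfg.tree.get("CS", 0.0), cfg, rng)
    branch_events(node_cs, "CS")

    tips = {}
    for sp, parent in (("C", node_cs), ("S", node_cs), ("D", anc)):
        tg = parent.clone()
        _mutate_branch(tg, sp, cfg.tree.get(sp, 0.0), cfg, rng)
        branch_events(tg, sp)
        tips[sp] = tg

    # --- recurrent transfer bookkeeping (applied per-individual later) ----
    recurrent = {}
    if counts.get("recurrent_idt", 0) > 0 and anc_idt_ids:
        region_id = anc_idt_ids[0]
        species = "C"
        reg = tips[species].tracks[region_id]
        reg_len = reg["end"] - reg["start"]
        bp = min(sizes["recurrent_idt"], max(1, reg_len - 500))
        ev = LedgerEvent("recurrent_idt_1", "recurrent_idt", species,
                         meta={"region_event": region_id, "species": species,
                               "breakpoint_offset": bp,
                               "carrier_fraction": cfg.recurrent_idt_carrier_fraction})
        events.append(ev)
        recurrent = {"region_event": region_id, "species": species,
                     "breakpoint_offset": bp,
                     "carrier_fraction": cfg.recurrent_idt_carrier_fraction}

    # --- rotate and emit --------------------------------------------------
    ledger = TruthLedger(recurrent=recurrent)
    genomes = {}
    for sp in ("C", "S", "D"):
        tg = tips[sp]
        if cfg.rotate:
            blocked = tg.blocked(min_span=2)
            off = _free_position(rng, len(tg), 1, blocked, 10 * cfg.placement_retries,
                                 f"rotation of {sp}")
            tg.rotate(off)
            ledger.rotations[sp] = off
        else:
            ledger.rotations[sp] = 0
        feats = []
        for tid, t in sorted(tg.tracks.items()):
            if t["kind"] == "gene":
                feats.append(Feature("CDS", t["start"], t["end"], t["strand"],
                                     t["meta"].get("name", tid), {"ID": tid}))
            elif t["kind"] == "event":
                ek = t["meta"].get("event_kind", "event")
                feats.append(Feature("transferred_region", t["start"], t["end"],
                                     t["strand"], tid, {"ID": tid, "kind": ek}))
        genomes[sp] = AnnotatedGenome(sp, tg.sequence, "circular", feats,
                                      description=f"simulated mitogenome {sp}")

    # ledger coordinates per genome
    for ev in events:
        for sp in ("C", "S", "D"):
            tg = tips[sp]
            ids = [ev.id]
            if ev.kind == "repeat_pair":
                ids = [f"{ev.id}_copy1", f"{ev.id}_copy2"]
            for tid in ids:
                t = tg.tracks.get(tid)
                if t is None:
                    continue
                key = sp if len(ids) == 1 else f"{sp}:{tid.rsplit('_', 1)[-1]}"
                ev.coords[key] = [t["start"], t["end"], t["strand"]]
    ledger.events = events

    for sp in ("C", "S", "D"):
        for tid, t in tips[sp].tracks.items():
            if t["kind"] == "sub":
                ledger.substitutions.append({
                    "genome": sp, "pos": t["start"], "branch": t["meta"]["branch"],
                    "ref": t["meta"]["ref"], "alt": t["meta"]["alt"],
                    "coding": t["meta"]["coding"],
                })
            elif t["kind"] == "indel":
                ledger.indels.append({
                    "genome": sp, "pos": t["start"], "branch": t["meta"]["branch"],
                    "size": t["meta"]["size"], "type": t["meta"]["type"],
                })

    cp_feats = [Feature("CDS", t["start"], t["end"], t["strand"],
                        t["meta"].get("name", tid), {"ID": tid})
                for tid, t in sorted(cp_tg.tracks.items()) if t["kind"] == "gene"]
    cp = AnnotatedGenome("cp", cp_tg.sequence, "circular", cp_feats,
                         description="simulated chloroplast genome")
    nuclear = AnnotatedGenome("nuclear", nuclear_seq, "linear",
                              description="simulated nuclear fragment")
    external = [("close_relative", "close", close_mito),
                ("distant_plant", "distant", distant_mito)]
    return SimResult(genomes, cp, nuclear, external, ledger, cfg)


# ---------------------------------------------------------------------------
# population sample of the recurrent-transfer region

def _map_through_alignment(a: str, b: str, pos_a: int) -> int:
    """Map a coordinate of `a` onto `b` through a global edlib alignment."""
    import edlib

    res = edlib.align(a, b, mode="NW", task="path")
    ia = ib = 0
    for n, op in _cigar_items(res["cigar"]):
        for _ in range(n):
            if ia >= pos_a:
                return ib
            if op in "=XM":
                ia += 1
                ib += 1
            elif op == "I":  # in a only
                ia += 1
            else:  # 'D': in b only
                ib += 1
    return ib


def _cigar_items(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def simulate_population(config: SimConfig, n_individuals: int,
                        sim: SimResult | None = None):
    """Per-individual sequences of the recurrent-transfer region.

    Exactly round(n_individuals x carrier_fraction) individuals carry the
    overwrite: their sequence is the extant chloroplast donor left of the
    planted breakpoint and the species' mitochondrial copy right of it.

    Returns (records, flags, truth) where records is a list of
    (individual_id, sequence), flags a parallel list of carrier booleans and
    truth a dict with the breakpoint bookkeeping.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    if sim is None:
        sim = simulate_genomes(config)
    if not sim.ledger.recurrent:
        raise ValueError("config contains no recurrent_idt event")
    rec = sim.ledger.recurrent
    sp = rec["species"]
    region_ev = next(e for e in sim.ledger.events if e.id == rec["region_event"])
    s, e, strand = region_ev.coords[sp]
    genome = sim.genomes[sp]
    mt_region = genome.fetch(s, e, strand)
    cp_s, cp_e = region_ev.meta["cp_interval"]
    cp_donor = sim.cp.sequence[cp_s:cp_e]
    bp = rec["breakpoint_offset"]
    cp_bp = _map_through_alignment(mt_region, cp_donor, bp)
    carrier_seq = cp_donor[:cp_bp] + mt_region[bp:]

    n_carriers = round(n_individuals * rec["carrier_fraction"])
    rng = np.random.default_rng([config.seed, 7])
    order = rng.permutation(n_individuals)
    flags = [False] * n_individuals
    for i in order[:n_carriers]:
        flags[int(i)] = True
    records = []
    for i in range(n_individuals):
        seq = carrier_seq if flags[i] else mt_region
        records.append((f"ind_{i + 1}", seq))
    truth = {"breakpoint_offset": bp, "cp_breakpoint": cp_bp,
             "n_carriers": n_carriers, "region": [s, e, strand],
             "mt_region": mt_region, "cp_donor": cp_donor}
    return records, flags, truth


# ---------------------------------------------------------------------------
# long reads

@dataclass
class SimRead:
    id: str
    sequence: str
    start: int
    length: int
    conformation: str  # background | parental | recombinant
    pair_id: str | None = None


def simulate_long_reads(genome: AnnotatedGenome, repeat_pairs, config: SimConfig,
                        flank: int = 100):
    """Error-bearing long reads from a circular genome, with a controlled
    fraction of repeat-spanning reads converted to the recombinant
    conformation (the read follows the other repeat copy's downstream
    flank after traversing the repeat).

    repeat_pairs: list of ((start1, end1), (start2, end2)) direct repeats.
    Returns a list of SimRead with per-read conformation truth.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 11])
    n = len(genome)
    for (s1, e1), (s2, e2) in repeat_pairs:
        if e1 - s1 <= 100:
            raise ValueError("repeat pair must be > 100 bp for the assay")
        if genome.topology == "linear" and (s1 < flank or e2 + flank > n):
            raise ValueError("repeat too close to sequence end on a linear genome")

    n_reads = max(1, int(cfg.read_coverage * n / cfg.read_len_mean))
    reads = []
    for i in range(n_reads):
        length = int(np.clip(rng.normal(cfg.read_len_mean, 0.15 * cfg.read_len_mean),
                             200, None))
        start = int(rng.integers(0, n))
        seq = genome.fetch(start, start + length)
        conf, pair_id = "background", None
        for pi, ((s1, e1), (s2, e2)) in enumerate(repeat_pairs):
            for (cs, ce), (os_, oe) in (((s1, e1), (s2, e2)), ((s2, e2), (s1, e1))):
                cs_r = (cs - start) % n
                ce_r = cs_r + (ce - cs)
                if cs_r >= flank and ce_r + flank <= length:
                    conf, pair_id = "parental", f"rp{pi}"
                    if rng.random() < cfg.recombinant_read_fraction:
                        tail_len = length - ce_r
                        seq = seq[:ce_r] + genome.fetch(oe, oe + tail_len)
                        conf = "recombinant"
                    break
            if pair_id:
                break
        if cfg.read_error_rate > 0:
            arr = list(seq)
            for pos in np.flatnonzero(rng.random(len(arr)) < cfg.read_error_rate):
                arr[pos] = _substitute_base(rng, arr[pos], 1.0)
            seq = "".join(arr)
        reads.append(SimRead(f"read_{i + 1}", seq, start, length, conf, pair_id))
    return reads
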