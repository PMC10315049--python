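"""Origin attribution for non-alignable regions.

Every base of a non-alignable region is attributed to one of six origin
categories by a fixed-precedence decision cascade:

CP  chloroplast-derived (hits the species' own plastome),
ID  intragenomic duplication (more copies in the region's own mitogenome
    than in the partner species of the pair),
GL  gain/loss of mitochondrial sequence (absent from the partner but
    present in the third species),
PH  potential horizontal transfer (best remaining hit is to a
    distant-taxon mitochondrial sequence, outscoring close-taxon hits by
    a configurable margin),
NU  nuclear-homologous (hits the species' own nuclear genome; flagged as
    a probable mitochondrion-to-nucleus transfer when mitochondrial hits
    corroborate),
ND  not determined (the residue).

Attribution is per base with precedence CP > ID > GL > PH > NU > ND, so
category totals always sum exactly to the region length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnnotatedGenome
from .seqcompare import NonAlignableRegion, local_search

CATEGORIES = ("CP", "ID", "GL", "PH", "NU", "ND")


@dataclass
class ReferencePanel:
    """Reference collection for the classifier: the species' own plastome,
    the three mitogenomes (keyed by genome id), an optional nuclear genome
    per species and an optional external mitochondrial collection tagged
    close/distant by relatedness."""

    cp: AnnotatedGenome | None
    mitogenomes: dict
    nuclear: dict | None = None  # genome id -> AnnotatedGenome
    external: list = field(default_factory=list)  # (taxon, close|distant, seq)

    def __post_init__(self):
        if len(self.mitogenomes) < 3:
            raise ValueError("panel requires the three mitogenomes")
        taxa = [t for t, _, _ in self.external]
        if len(taxa) != len(set(taxa)):
            raise ValueError("external taxon labels must be unique")


@dataclass
class OriginCall:
    region: NonAlignableRegion
    bp: dict  # category -> attributed bases
    evidence: list = field(default_factory=list)  # (category, start, end, target, identity, score)
    notes: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.region.length

    def pct(self) -> dict:
        return {c: 100.0 * self.bp[c] / self.length for c in CATEGORIES}


def _coverage_and_score(region_seq, target_seq, circular, min_identity, min_len):
    """Per-base hit count and best bitscore along the region."""
    n = len(region_seq)
    cov = np.zeros(n, dtype=np.int32)
    score = np.zeros(n, dtype=np.float64)
    if not target_seq:
        return cov, score, []
    hits = local_search(region_seq, target_seq, min_identity,
                        min(min_len, n), circular_subject=circular)
    for h in hits:
        cov[h.qstart:h.qend] += 1
        np.maximum(score[h.qstart:h.qend], h.score, out=score[h.qstart:h.qend])
    return cov, score, hits


def classify_region(
    region: NonAlignableRegion,
    panel: ReferencePanel,
    partner_id: str,
    min_identity: float = 0.85,
    min_len: int = 90,
    ph_margin: float = 1.1,
) -> OriginCall:
    """Attribute every base of one non-alignable region to an origin."""
    own_id = region.genome_id
    genome = panel.mitogenomes.get(own_id)
    if genome is None:
        raise KeyError(f"region genome {own_id!r} not in panel")
    if region.end > len(genome) and genome.topology != "circular":
        raise ValueError(f"region {region.code} not extractable from {own_id}")
    seq = genome.fetch(region.start, region.end)
    n = len(seq)
    cat = np.full(n, CATEGORIES.index("ND"), dtype=np.int8)
    unset = np.ones(n, dtype=bool)
    evidence = []
    notes = []

    def attribute(mask, code, hits, target):
        idx = CATEGORIES.index(code)
        take = mask & unset
        cat[take] = idx
        unset[take] = False
        for h in hits:
            if take[h.qstart:h.qend].any():
                evidence.append((code, h.qstart, h.qend, target,
                                 round(h.identity, 4), h.score))

    # 1) chloroplast
    if panel.cp is not None:
        cov, _, hits = _coverage_and_score(seq, panel.cp.sequence,
                                           panel.cp.topology == "circular",
                                           min_identity, min_len)
        attribute(cov > 0, "CP", hits, "cp")

    # 2) copy-count comparison across the three mitogenomes
    covs, hit_sets = {}, {}
    for gid, g in panel.mitogenomes.items():
        cov, _, hits = _coverage_and_score(seq, g.sequence,
                                           g.topology == "circular",
                                           min_identity, min_len)
        covs[gid], hit_sets[gid] = cov, hits
    third_ids = [g for g in panel.mitogenomes if g not in (own_id, partner_id)]
    third_cov = sum(covs[g] > 0 for g in third_ids) if third_ids else np.zeros(n, int)
    id_mask = (covs[own_id] > covs[partner_id]) & (covs[partner_id] >= 1)
    attribute(id_mask, "ID", hit_sets[own_id], own_id)

    # 3) gain/loss: absent from the partner, present in a third species
    gl_mask = (covs[partner_id] == 0) & (np.asarray(third_cov) > 0)
    gl_hits = [h for g in third_ids for h in hit_sets[g]]
    attribute(gl_mask, "GL", gl_hits, "+".join(third_ids))

    # 4) external mitochondrial collection and own nuclear genome
    close_score = np.zeros(n)
    distant_score = np.zeros(n)
    ext_hits = []
    for taxon, rel, eseq in panel.external:
        _, sc, hits = _coverage_and_score(seq, eseq, False, min_identity, min_len)
        ext_hits.extend((taxon, rel, h) for h in hits)
        if rel == "distant":
            np.maximum(distant_score, sc, out=distant_score)
        else:
            np.maximum(close_score, sc, out=close_score)
    ph_mask = (distant_score > 0) & (distant_score >= ph_margin * close_score)
    ph_hits = [h for _, rel, h in ext_hits if rel == "distant"]
    attribute(ph_mask, "PH", ph_hits, "distant_mito")

    nuc = (panel.nuclear or {}).get(own_id)
    if nuc is not None:
        cov, _, hits = _coverage_and_score(seq, nuc.sequence, False,
                                           min_identity, min_len)
        nu_mask = cov > 0
        if (nu_mask & unset).any() and ((distant_score + close_score) > 0)[nu_mask].any():
            notes.append("probable mt-to-nuclear transfer (nuclear bases also hit "
                         "mitochondrial sequences elsewhere)")
        attribute(nu_mask, "NU", hits, "nuclear")

    bp = {c: int((cat == i).sum()) for i, c in enumerate(CATEGORIES)}
    assert sum(bp.values()) == n, "category totals must sum to the region length"
    return OriginCall(region, bp, evidence, notes)


# ---------------------------------------------------------------------------
# Table-style pair summaries

def format_cell(bp: int, total: int) -> str:
    if total == 0:
        return "0"
    return f"{bp} bp ({100.0 * bp / total:.2f}%)"


def summarize_pair(calls: list, pair: str):
    """Per-genome accounting of one pair's non-alignable regions.

    Returns {genome id: {"n": count, "bp": {cat: bp}, "total": bp,
    "cells": {cat: 'N bp (P.PP%)'}}}."""
    if any(c.region.pair != pair for c in calls):
        raise ValueError("summarize_pair received calls from a different pair")
    out = {}
    for call in calls:
        gid = call.region.genome_id
        row = out.setdefault(gid, {"n": 0, "bp": {c: 0 for c in CATEGORIES}, "total": 0})
        row["n"] += 1
        row["total"] += call.length
        for c in CATEGORIES:
            row["bp"][c] += call.bp[c]
    for row in out.values():
        row["cells"] = {c: format_cell(row["bp"][c], row["total"]) for c in CATEGORIES}
        row["cells"]["Total"] = f"{row['total']} bp (100%)"
    return out


def export_pair_summary(summaries: dict, path) -> None:
    """Table-style TSV: one row per (pair, genome), category cells as
    'N bp (P.PP%)'."""
    from .io import write_tsv

    rows = []
    for pair, per_genome in summaries.items():
        for gid, row in per_genome.items():
            rows.append([pair, gid, row["n"]] +
                        [row["cells"][c] for c in CATEGORIES] +
                        [row["cells"]["Total"]])
    write_tsv(path, ["pair", "genome", "n_regions", *CATEGORIES, "Total"], rows,
              comments=["per-base attribution, precedence CP>ID>GL>PH>NU>ND"])


# ---------------------------------------------------------------------------
# parsimony polarity on the fixed topology ((C,S),D)

def parsimony_polarity(presence: dict, cherry: tuple | None = None):
    """Minimal gain/loss assignment of a presence/absence pattern on the
    rooted three-taxon tree ((C,S),D).

    presence maps the three taxon labels to booleans. `cherry` names the
    two ingroup taxa; by default the labels C and S form the cherry when
    present, otherwise the first two sorted labels. Returns a dict with
    verdict in {gain_in, loss_in, none, ambiguous} and the implicated
    branch."""
    taxa = sorted(presence)
    if len(taxa) != 3:
        raise ValueError("exactly three taxa required")
    if cherry is None:
        cherry = ("C", "S") if {"C", "S", "D"} == set(taxa) else tuple(taxa[:2])
    c, s = cherry
    d = next(t for t in taxa if t not in cherry)
    tips = {c: presence[c], s: presence[s], d: presence[d]}
    # edges: root->cs, root->d(tip), cs->c(tip), cs->s(tip)
    best_cost = None
    best_assignments = []
    for root in (0, 1):
        for cs in (0, 1):
            changes = []
            if root != cs:
                changes.append(("CS-stem", cs))
            if root != int(tips[d]):
                changes.append((d, int(tips[d])))
            if cs != int(tips[c]):
                changes.append((c, int(tips[c])))
            if cs != int(tips[s]):
                changes.append((s, int(tips[s])))
            cost = len(changes)
            if best_cost is None or cost < best_cost:
                best_cost = cost
                best_assignments = [changes]
            elif cost == best_cost:
                best_assignments.append(changes)

    if best_cost == 0:
        return {"verdict": "none", "branch": None, "events": 0}
    # deduplicate identical event sets
    uniq = {tuple(sorted(a)) for a in best_assignments}
    if len(uniq) > 1:
        return {"verdict": "ambiguous", "branch": None, "events": best_cost}
    events = sorted(next(iter(uniq)))
    if best_cost > 1:
        return {"verdict": "ambiguous", "branch": None, "events": best_cost}
    branch, state = events[0]
    verdict = "gain_in" if state == 1 else "loss_in"
    return {"verdict": verdict, "branch": branch, "events": best_cost}
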