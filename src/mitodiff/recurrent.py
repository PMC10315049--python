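"""Recurrent chloroplast-transfer detection: chimeric breakpoint scanning,
two-partition distance trees, and the population fixation survey.

A recurrent transfer overwrites part of an earlier transferred region
with a fresh chloroplast copy, so the region becomes chimeric: on one
side of a breakpoint the query matches the extant chloroplast, on the
other it matches the mitochondrial copies of related species. The scan
scores every inter-column boundary of a multiple alignment at the
*diagnostic* columns (where the chloroplast state differs from the
mitochondrial consensus) and keeps the boundary/orientation with the
most agreeing diagnostic sites; the verdict is "no chimera" unless the
best two-segment score beats the best single-segment explanation.
"""

from __future__ import annotations

import os
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .divergence import k2p_distance, SaturationError


class InsufficientSignalError(ValueError):
    pass


class PartitionTooShortError(ValueError):
    pass


def align_mafft(records) -> list:
    """Multiple sequence alignment via MAFFT (records: (id, seq) pairs)."""
    if shutil.which("mafft") is None:  # pragma: no cover
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory(prefix="mitodiff_mafft_") as tmp:
        inp = os.path.join(tmp, "in.fa")
        with open(inp, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        proc = subprocess.run(["mafft", "--auto", "--quiet", inp],
                              capture_output=True, text=True)
        if proc.returncode != 0:  # pragma: no cover
            raise RuntimeError(f"mafft failed: {proc.stderr.strip()}")
    out = []
    rid, chunks = None, []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if rid is not None:
                out.append((rid, "".join(chunks).upper()))
            rid, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if rid is not None:
        out.append((rid, "".join(chunks).upper()))
    return out


@dataclass
class RegionAlignmentSet:
    """Aligned copies of one transferred region: mitochondrial copies from
    several species, one or more chloroplast counterparts, and the query
    individual's copy."""

    ids: list
    seqs: list  # aligned, equal length
    query_id: str
    cp_ids: list
    mt_ids: list  # mitochondrial references, query excluded

    def __post_init__(self):
        lens = {len(s) for s in self.seqs}
        if len(lens) != 1:
            raise ValueError("aligned sequences must have equal length")
        for need in (self.query_id, *self.cp_ids, *self.mt_ids):
            if need not in self.ids:
                raise ValueError(f"{need!r} not among sequence ids")
        if self.query_id in self.mt_ids:
            raise ValueError("query must not be part of the mt consensus")

    @property
    def n_columns(self) -> int:
        return len(self.seqs[0])

    def seq(self, sid: str) -> str:
        return self.seqs[self.ids.index(sid)]

    @classmethod
    def from_unaligned(cls, records, query_id, cp_ids, mt_ids):
        aligned = align_mafft(records)
        return cls([r for r, _ in aligned], [s for _, s in aligned],
                   query_id, list(cp_ids), list(mt_ids))


def diagnostic_columns(aset: RegionAlignmentSet):
    """Columns where the chloroplast state differs from the mitochondrial
    consensus, excluding indel columns (any gap among query/cp/mt) which
    are reported separately.

    Returns (diag, indel_cols): diag is a list of (column, cp_state,
    mt_state)."""
    q = aset.seq(aset.query_id)
    cps = [aset.seq(i) for i in aset.cp_ids]
    mts = [aset.seq(i) for i in aset.mt_ids]
    diag, indel_cols = [], []
    for col in range(aset.n_columns):
        states = [s[col] for s in (q, *cps, *mts)]
        if "-" in states:
            indel_cols.append(col)
            continue
        cp_state = max(set(c[col] for c in cps),
                       key=[c[col] for c in cps].count)
        mt_states = [m[col] for m in mts]
        mt_state = max(set(mt_states), key=mt_states.count)
        if 2 * mt_states.count(mt_state) <= len(mt_states):
            continue  # no majority consensus
        if cp_state != mt_state:
            diag.append((col, cp_state, mt_state))
    return diag, indel_cols


@dataclass
class BreakpointCall:
    chimera: bool
    verdict: str  # chimera | all_cp | all_mt
    boundary_col: int | None  # alignment column of the boundary
    boundary_index: int | None  # index into the diagnostic-site list
    orientation: str | None  # cp_left | cp_right
    support_left: int = 0
    support_right: int = 0
    score: int = 0
    one_segment_score: int = 0
    n_diagnostic: int = 0
    query_position: int | None = None  # ungapped query coordinate
    indel_columns: list = field(default_factory=list)


def scan_breakpoint(aset: RegionAlignmentSet) -> BreakpointCall:
    """Exhaustive boundary/orientation scan over diagnostic sites.

    score(b, cp_left)  = #diag sites left of b where the query matches the
    chloroplast state + #sites right of b where it matches the
    mitochondrial consensus; cp_right mirrors this. The maximizing
    boundary is returned (leftmost on ties, cp_left preferred); when no
    two-segment split strictly beats the best single-segment explanation
    the verdict is all_cp or all_mt."""
    diag, indel_cols = diagnostic_columns(aset)
    if not diag:
        raise InsufficientSignalError("no diagnostic columns in the alignment")
    q = aset.seq(aset.query_id)
    m = len(diag)
    match_cp = np.array([1 if q[c] == cp else 0 for c, cp, _ in diag])
    match_mt = np.array([1 if q[c] == mt else 0 for c, _, mt in diag])
    cum_cp = np.concatenate(([0], np.cumsum(match_cp)))
    cum_mt = np.concatenate(([0], np.cumsum(match_mt)))
    total_cp, total_mt = int(cum_cp[-1]), int(cum_mt[-1])
    one_seg = max(total_cp, total_mt)

    best = (-1, 0, "")
    for b in range(m + 1):
        s_cp_left = int(cum_cp[b] + (cum_mt[m] - cum_mt[b]))
        s_cp_right = int(cum_mt[b] + (cum_cp[m] - cum_cp[b]))
        for score, orient in ((s_cp_left, "cp_left"), (s_cp_right, "cp_right")):
            if score > best[0]:
                best = (score, b, orient)
    score, b, orient = best

    if b in (0, m) or score <= one_seg:
        verdict = "all_cp" if total_cp >= total_mt else "all_mt"
        return BreakpointCall(False, verdict, None, None, None,
                              score=one_seg, one_segment_score=one_seg,
                              n_diagnostic=m, indel_columns=indel_cols)

    boundary_col = diag[b - 1][0] + 1  # just right of the last left-side site
    left = int(cum_cp[b]) if orient == "cp_left" else int(cum_mt[b])
    right = score - left
    qpos = sum(1 for ch in q[:boundary_col] if ch != "-")
    return BreakpointCall(True, "chimera", boundary_col, b, orient,
                          left, right, score, one_seg, m,
                          query_position=qpos, indel_columns=indel_cols)


# ---------------------------------------------------------------------------
# two-partition trees

def _encode(seqs):
    """Byte-encode aligned sequences: (codes, purine flag, validity)."""
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    purine = (arr == ord("A")) | (arr == ord("G"))
    return arr, purine, valid


def _k2p_matrix(arr, purine, valid) -> np.ndarray:
    k = arr.shape[0]
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = valid[i] & valid[j]
            n = int(both.sum())
            if n == 0:
                mat[i, j] = mat[j, i] = 5.0
                continue
            diff = both & (arr[i] != arr[j])
            ts = int((diff & (purine[i] == purine[j])).sum())
            tv = int(diff.sum()) - ts
            try:
                d = k2p_distance(ts / n, tv / n)
            except SaturationError:
                d = 5.0  # saturated pairs get a large finite distance
            mat[i, j] = mat[j, i] = d
    return mat


def _nj_newick(ids, seqs, cols=None) -> str:
    arr, purine, valid = _encode(seqs)
    if cols is not None:
        arr, purine, valid = arr[:, cols], purine[:, cols], valid[:, cols]
    tree = nj(DistanceMatrix(_k2p_matrix(arr, purine, valid), ids))
    return str(tree).strip()


def _splits(newick: str, taxa: frozenset):
    """Non-trivial bipartitions of an unrooted tree, each canonicalized as
    the side not containing the alphabetically first taxon."""
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    anchor = min(taxa)
    splits = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            if anchor in side:
                side = taxa - side
            splits.add(side)
    return splits


def _query_with_cp(newick: str, taxa: frozenset, query: str, cp_ids) -> bool:
    target = frozenset({query, *cp_ids})
    anchor = min(taxa)
    canon = taxa - target if anchor in target else target
    return canon in _splits(newick, taxa) or len(taxa - target) <= 1


@dataclass
class PartitionTreeResult:
    tree_recurrent: str
    tree_rest: str
    query_with_cp_recurrent: bool
    query_with_cp_rest: bool
    support_recurrent: float
    support_rest: float
    bootstrap: int


def partition_trees(aset: RegionAlignmentSet, call: BreakpointCall,
                    bootstrap: int = 1000, seed: int = 0,
                    min_columns: int = 50) -> PartitionTreeResult:
    """Neighbor-joining trees (K2P distances) for the two sides of the
    breakpoint, with nonparametric bootstrap support for the
    query-clusters-with-chloroplast bipartition in each."""
    if len(aset.ids) < 4:
        raise ValueError("at least 4 sequences required")
    if not call.chimera:
        raise ValueError("call carries no breakpoint to partition on")
    b = call.boundary_col
    parts = {}
    cp_side = (0, b) if call.orientation == "cp_left" else (b, aset.n_columns)
    rest_side = (b, aset.n_columns) if call.orientation == "cp_left" else (0, b)
    for name, (s, e) in (("recurrent", cp_side), ("rest", rest_side)):
        if e - s < min_columns:
            raise PartitionTooShortError(
                f"partition {name} has {e - s} < {min_columns} columns")
        parts[name] = [seq[s:e] for seq in aset.seqs]

    rng = np.random.default_rng(seed)
    taxa = frozenset(aset.ids)
    trees, withcp, supports = {}, {}, {}
    for name, seqs in parts.items():
        tree = _nj_newick(aset.ids, seqs)
        trees[name] = tree
        withcp[name] = _query_with_cp(tree, taxa, aset.query_id, aset.cp_ids)
        ncol = len(seqs[0])
        hitcount = 0
        for _ in range(bootstrap):
            cols = rng.integers(0, ncol, size=ncol)
            btree = _nj_newick(aset.ids, seqs, cols=cols)
            if _query_with_cp(btree, taxa, aset.query_id, aset.cp_ids) == withcp[name]:
                hitcount += 1
        supports[name] = hitcount / bootstrap if bootstrap else float("nan")
    return PartitionTreeResult(trees["recurrent"], trees["rest"],
                               withcp["recurrent"], withcp["rest"],
                               supports["recurrent"], supports["rest"], bootstrap)


# ---------------------------------------------------------------------------
# fixation survey

@dataclass
class SurveyRow:
    population: str
    carriers: int
    non_carriers: int

    @property
    def fixed(self) -> bool:
        return self.non_carriers == 0 and self.carriers > 0


def fixation_survey(populations: dict, references, query_template=None,
                    tolerance: int = 5):
    """Scan every individual's region copy for the chimeric breakpoint and
    tabulate carriers per population.

    populations: {population name: [(individual id, sequence), ...]}.
    references: (cp_records, mt_records) used to anchor each alignment.
    query_template: a BreakpointCall from a known carrier; individuals
    count as carriers only when their boundary lies within `tolerance`
    diagnostic sites of the template's. Returns (rows, per_individual,
    species_wide_fixed)."""
    cp_records, mt_records = references
    rows, per_individual = [], {}
    for pop, individuals in populations.items():
        if not individuals:
            raise ValueError(f"population {pop!r} has no individuals")
        carriers = 0
        for ind_id, seq in individuals:
            records = [*mt_records, *cp_records, (ind_id, seq)]
            aset = RegionAlignmentSet.from_unaligned(
                records, ind_id,
                [r for r, _ in cp_records], [r for r, _ in mt_records])
            try:
                call = scan_breakpoint(aset)
            except InsufficientSignalError:
                per_individual[ind_id] = None
                continue
            is_carrier = call.chimera
            if (is_carrier and query_template is not None
                    and query_template.boundary_index is not None
                    and call.boundary_index is not None):
                is_carrier = abs(call.boundary_index
                                 - query_template.boundary_index) <= tolerance
            per_individual[ind_id] = call
            carriers += int(is_carrier)
        rows.append(SurveyRow(pop, carriers, len(individuals) - carriers))
    species_fixed = all(r.fixed for r in rows) and any(r.carriers for r in rows)
    return rows, per_individual, species_fixed
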