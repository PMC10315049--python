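import numpy as np
import pytest

from conftest import random_seq, small_config
from mitodiff.recurrent import (InsufficientSignalError,
                                PartitionTooShortError, RegionAlignmentSet,
                                diagnostic_columns, fixation_survey,
                                partition_trees, scan_breakpoint)
from mitodiff.simulate import simulate_genomes, simulate_population


def _toy_set(query_seq, n_sites=60, seed=5):
    """Hand-built gapless alignment: mt consensus vs cp differ at every
    3rd column starting at 1."""
    rng = np.random.default_rng(seed)
    L = 3 * n_sites
    mt = "".join(rng.choice(list("ACGT"), L))
    cp = list(mt)
    for i in range(1, L, 3):
        cp[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[cp[i]]
    cp = "".join(cp)
    seqs = {"mt_1": mt, "mt_2": mt, "mt_3": mt, "cp": cp, "q": query_seq(mt, cp)}
    return RegionAlignmentSet(list(seqs), list(seqs.values()), "q", ["cp"],
                              ["mt_1", "mt_2", "mt_3"])


def oracle_scan(aset):
    """Independent quadratic scan over all boundaries and orientations."""
    diag, _ = diagnostic_columns(aset)
    q = aset.seq(aset.query_id)
    m = len(diag)
    best = (-1, None, None)
    for b in range(m + 1):
        for orient in ("cp_left", "cp_right"):
            score = 0
            for i, (c, cpst, mtst) in enumerate(diag):
                left = i < b
                want = (cpst if left else mtst) if orient == "cp_left" else (
                    mtst if left else cpst)
                score += q[c] == want
            if score > best[0]:
                best = (score, b, orient)
    return best


def test_query_matching_consensus_is_all_mt():
    aset = _toy_set(lambda mt, cp: mt)
    call = scan_breakpoint(aset)
    assert not call.chimera and call.verdict == "all_mt"


def test_query_matching_cp_is_all_cp():
    aset = _toy_set(lambda mt, cp: cp)
    call = scan_breakpoint(aset)
    assert not call.chimera and call.verdict == "all_cp"


def test_chimera_boundary_found_and_equals_oracle():
    aset = _toy_set(lambda mt, cp: cp[:90] + mt[90:])
    call = scan_breakpoint(aset)
    assert call.chimera and call.orientation == "cp_left"
    score, b, orient = oracle_scan(aset)
    assert (call.score, call.boundary_index, call.orientation) == (score, b, orient)
    # boundary lies between the flanking diagnostic sites of the true cut
    diag, _ = diagnostic_columns(aset)
    cols = [c for c, _, _ in diag]
    left = max(c for c in cols if c < 90)
    right = min(c for c in cols if c >= 90)
    assert left < call.boundary_col <= right + 1


def test_mirrored_chimera_uses_cp_right():
    aset = _toy_set(lambda mt, cp: mt[:90] + cp[90:])
    call = scan_breakpoint(aset)
    assert call.chimera and call.orientation == "cp_right"


def test_reversing_alignment_mirrors_boundary():
    aset = _toy_set(lambda mt, cp: cp[:90] + mt[90:])
    call = scan_breakpoint(aset)
    rev = RegionAlignmentSet(aset.ids, [s[::-1] for s in aset.seqs],
                             aset.query_id, aset.cp_ids, aset.mt_ids)
    rcall = scan_breakpoint(rev)
    assert rcall.chimera
    assert rcall.orientation == "cp_right"
    ncols = aset.n_columns
    assert rcall.n_diagnostic == call.n_diagnostic
    assert (rcall.n_diagnostic - rcall.boundary_index) == call.boundary_index


def test_no_diagnostic_columns_is_an_error():
    mt = random_seq(9, 120)
    seqs = {"mt_1": mt, "mt_2": mt, "cp": mt, "q": mt}
    aset = RegionAlignmentSet(list(seqs), list(seqs.values()), "q", ["cp"],
                              ["mt_1", "mt_2"])
    with pytest.raises(InsufficientSignalError):
        scan_breakpoint(aset)


def test_alignment_set_validation():
    with pytest.raises(ValueError, match="equal length"):
        RegionAlignmentSet(["a", "b"], ["ACGT", "ACG"], "a", [], ["b"])
    with pytest.raises(ValueError, match="not among"):
        RegionAlignmentSet(["a", "b"], ["ACGT", "ACGT"], "zzz", [], ["b"])


@pytest.fixture(scope="module")
def carrier_setup():
    cfg = small_config(4)
    sim = simulate_genomes(cfg)
    recs, flags, truth = simulate_population(cfg, 9, sim)
    ev = next(e for e in sim.ledger.events
              if e.id == sim.ledger.recurrent["region_event"])
    mt_records = [(f"mt_{sp}", sim.genomes[sp].fetch(*ev.coords[sp][:2],
                                                     ev.coords[sp][2]))
                  for sp in sorted(sim.genomes)]
    cp_records = [("cp_ref", truth["cp_donor"])]
    return sim, recs, flags, truth, mt_records, cp_records


def _aset_for(ind_id, seq, mt_records, cp_records):
    return RegionAlignmentSet.from_unaligned(
        [*mt_records, *cp_records, (ind_id, seq)], ind_id,
        [r for r, _ in cp_records], [r for r, _ in mt_records])


def test_simulated_carriers_localize_planted_breakpoint(carrier_setup):
    sim, recs, flags, truth, mt_records, cp_records = carrier_setup
    bp = truth["breakpoint_offset"]
    for (rid, seq), flag in zip(recs, flags):
        aset = _aset_for(rid, seq, mt_records, cp_records)
        call = scan_breakpoint(aset)
        assert call.chimera == flag
        assert (call.score, call.boundary_index, call.orientation)[:1] == \
            (oracle_scan(aset)[0],)
        if flag:
            # localization within the local diagnostic-site spacing
            diag, _ = diagnostic_columns(aset)
            q = aset.seq(rid)
            qpos = [sum(1 for ch in q[:c] if ch != "-") for c, _, _ in diag]
            left = max((p for p in qpos if p < len(truth["cp_donor"][:truth["cp_breakpoint"]])), default=0)
            spacing = max(np.diff(sorted(qpos))) if len(qpos) > 1 else 50
            assert abs(call.query_position - truth["cp_breakpoint"]) <= spacing + 8


def test_partition_trees_recover_clustering(carrier_setup):
    sim, recs, flags, truth, mt_records, cp_records = carrier_setup
    rid, seq = next((r, s) for (r, s), f in zip(recs, flags) if f)
    aset = _aset_for(rid, seq, mt_records, cp_records)
    call = scan_breakpoint(aset)
    res = partition_trees(aset, call, bootstrap=300, seed=11)
    assert res.query_with_cp_recurrent is True
    assert res.query_with_cp_rest is False
    assert res.support_recurrent >= 0.95
    assert res.support_rest >= 0.95
    with pytest.raises(PartitionTooShortError):
        partition_trees(aset, call, bootstrap=10, min_columns=10 ** 6)


def test_noncarrier_stays_in_mt_clade_in_both_partitions(carrier_setup):
    sim, recs, flags, truth, mt_records, cp_records = carrier_setup
    rid, seq = next((r, s) for (r, s), f in zip(recs, flags) if not f)
    aset = _aset_for(rid, seq, mt_records, cp_records)
    carrier = next((r, s) for (r, s), f in zip(recs, flags) if f)
    template = scan_breakpoint(_aset_for(*carrier, mt_records, cp_records))
    from mitodiff.recurrent import _nj_newick, _query_with_cp

    taxa = frozenset(aset.ids)
    b = template.boundary_col
    for part in ((0, b), (b, aset.n_columns)):
        seqs = [s[part[0]:part[1]] for s in aset.seqs]
        tree = _nj_newick(aset.ids, seqs)
        assert not _query_with_cp(tree, taxa, rid, ["cp_ref"])


def test_fixation_survey_population_pattern(carrier_setup):
    sim, recs, flags, truth, mt_records, cp_records = carrier_setup
    carriers = [(r, s) for (r, s), f in zip(recs, flags) if f]
    non = [(r, s) for (r, s), f in zip(recs, flags) if not f]
    template = scan_breakpoint(_aset_for(*carriers[0], mt_records, cp_records))
    pops = {"P1": carriers[:3], "P2": non[:3], "P3": non[3:6]}
    rows, per_ind, fixed = fixation_survey(pops, (cp_records, mt_records),
                                           template)
    by_pop = {r.population: r for r in rows}
    assert by_pop["P1"].carriers == 3 and by_pop["P1"].fixed
    assert by_pop["P2"].carriers == 0 and by_pop["P3"].carriers == 0
    assert fixed is False
    # all carriers everywhere -> species-wide fixation
    rows2, _, fixed2 = fixation_survey({"P1": carriers[:2], "P2": carriers[2:4]},
                                       (cp_records, mt_records), template)
    assert fixed2 is True
    rows3, _, fixed3 = fixation_survey({"P1": non[:2]},
                                       (cp_records, mt_records), template)
    assert fixed3 is False and rows3[0].carriers == 0
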