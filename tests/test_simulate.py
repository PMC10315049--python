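import edlib
import numpy as np
import pytest

from conftest import quiet_config, small_config
from mitodiff.simulate import (PlacementError, SimConfig, simulate_genomes,
                               simulate_long_reads, simulate_population)


def test_identity_case_no_events_no_branches():
    cfg = quiet_config(0, tree={"C": 0.0, "S": 0.0, "CS": 0.0, "D": 0.0},
                       indel_rate=0.0)
    sim = simulate_genomes(cfg)
    seqs = {g.sequence for g in sim.genomes.values()}
    assert len(seqs) == 1
    assert sim.ledger.events == []
    assert sim.ledger.substitutions == []


def test_same_seed_byte_identical():
    a = simulate_genomes(small_config(7))
    b = simulate_genomes(small_config(7))
    for sp in a.genomes:
        assert a.genomes[sp].sequence == b.genomes[sp].sequence
    assert a.cp.sequence == b.cp.sequence
    assert a.ledger.to_dict() == b.ledger.to_dict()


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(indel_size_range=(0, 8))
    with pytest.raises(ValueError):
        SimConfig(recurrent_idt_carrier_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(tree={"C": -0.1, "S": 0, "CS": 0, "D": 0})


def test_ledger_intervals_match_planted_sequence(trio):
    """Extracting a ledger interval returns the planted sequence, mutated
    only by the recorded branch substitutions."""
    for ev in trio.ledger.events:
        if ev.kind not in ("idt_ancestral", "idt_lineage", "gain", "hdt",
                           "nuclear_homolog"):
            continue
        donor = ev.donor["sequence"]
        for key, (s, e, strand) in ev.coords.items():
            sp = key.split(":")[0]
            got = trio.genomes[sp].fetch(s, e, strand)
            n_subs = sum(1 for sub in trio.ledger.substitutions
                         if sub["genome"] == sp and s <= sub["pos"] < e)
            dist = edlib.align(got, donor, mode="NW")["editDistance"]
            assert dist <= n_subs, (ev.id, sp, dist, n_subs)


def test_planted_insertions_do_not_overlap(trio):
    insert_kinds = {"idt_ancestral", "idt_lineage", "gain", "hdt",
                    "nuclear_homolog", "duplication", "repeat_pair"}
    for sp, g in trio.genomes.items():
        ivs = sorted(
            (f.start, f.end) for f in g.features if f.type == "transferred_region"
            and f.attrs.get("kind") in insert_kinds)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            assert b1 <= a2, (sp, (a1, b1), (a2, b2))


def test_lineage_events_only_in_their_descendants(trio):
    for ev in trio.ledger.events:
        carriers = {k.split(":")[0] for k in ev.coords}
        if ev.branch == "root":
            assert carriers == {"C", "S", "D"}
        elif ev.branch == "CS":
            assert carriers == {"C", "S"}
        elif ev.branch in ("C", "S", "D") and ev.kind != "recurrent_idt":
            assert carriers == {ev.branch}


def test_clock_consistency_pairwise_distance():
    """Observed noncoding divergence matches twice the branch length within
    three binomial standard errors; coding sites are slower by the coding
    rate factor."""
    t = 0.01
    cfg = quiet_config(13, mt_ancestor_len=60000, n_genes=10, gene_len=900,
                       indel_rate=0.0, tree={"C": t, "S": t, "CS": 0.0, "D": t})
    sim = simulate_genomes(cfg)
    C, S = sim.genomes["C"], sim.genomes["S"]
    coding = np.zeros(len(C), bool)
    for f in C.features:
        if f.type == "CDS":
            coding[f.start:f.end] = True
    diff = np.frombuffer(C.sequence.encode(), np.uint8) != np.frombuffer(
        S.sequence.encode(), np.uint8)
    n_nc = int((~coding).sum())
    p_nc = diff[~coding].mean()
    se = (2 * t * (1 - 2 * t) / n_nc) ** 0.5
    assert abs(p_nc - 2 * t) <= 3 * se
    p_c = diff[coding].mean()
    ratio = p_c / p_nc
    assert 0.15 <= ratio <= 0.55  # nominal 1/3


def test_population_carrier_counts_and_chimera_structure(trio):
    cfg = trio.config
    recs, flags, truth = simulate_population(cfg, 15, trio)
    assert sum(flags) == round(15 * cfg.recurrent_idt_carrier_fraction)
    bp, cp_bp = truth["breakpoint_offset"], truth["cp_breakpoint"]
    for (rid, seq), f in zip(recs, flags):
        if f:
            assert seq[:cp_bp] == truth["cp_donor"][:cp_bp]
            assert seq[cp_bp:] == truth["mt_region"][bp:]
        else:
            assert seq == truth["mt_region"]


@pytest.mark.parametrize("fraction,expected", [(0.0, 0), (1.0, 5)])
def test_population_fraction_extremes(fraction, expected):
    cfg = small_config(2, recurrent_idt_carrier_fraction=fraction)
    recs, flags, _ = simulate_population(cfg, 5)
    assert sum(flags) == expected
    with pytest.raises(ValueError):
        simulate_population(cfg, 0)


def test_long_reads_exact_substrings_without_error(trio):
    cfg = small_config(1, read_error_rate=0.0, read_len_mean=1500,
                       read_coverage=5.0)
    g = trio.genomes["C"]
    ev = trio.ledger.events_of("repeat_pair")[0]
    c1, c2 = ev.coords["C:copy1"], ev.coords["C:copy2"]
    rp = sorted([(c1[0], c1[1]), (c2[0], c2[1])])
    reads = simulate_long_reads(g, [rp], cfg)
    doubled = g.sequence + g.sequence
    for r in reads:
        if r.conformation != "recombinant":
            assert r.sequence in doubled


def test_long_reads_no_recombinants_at_zero_fraction(trio):
    cfg = small_config(1, recombinant_read_fraction=0.0)
    ev = trio.ledger.events_of("repeat_pair")[0]
    c1, c2 = ev.coords["C:copy1"], ev.coords["C:copy2"]
    reads = simulate_long_reads(trio.genomes["C"],
                                [sorted([(c1[0], c1[1]), (c2[0], c2[1])])], cfg)
    assert all(r.conformation != "recombinant" for r in reads)


def test_long_reads_rejects_short_repeats(trio):
    cfg = small_config(1)
    with pytest.raises(ValueError, match="100 bp"):
        simulate_long_reads(trio.genomes["C"], [((10, 80), (500, 570))], cfg)


def test_placement_error_names_the_event():
    cfg = small_config(3, mt_ancestor_len=3000, n_genes=4, gene_len=700)
    with pytest.raises(PlacementError):
        simulate_genomes(cfg)
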