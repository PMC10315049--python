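import random

import pytest
from Bio.Align import PairwiseAligner

from conftest import quiet_config, random_seq
from mitodiff.core import union_length
from mitodiff.seqcompare import (build_blocks, compare_pair, detect_inversions,
                                 local_search, nonalignable_regions_1d)
from mitodiff.simulate import simulate_genomes


def _mutate(seq, rate, seed):
    rng = random.Random(seed)
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def test_self_search_full_length_identity():
    g = random_seq(10, 10000)
    hits = local_search(g, g)
    full = [h for h in hits if h.qstart == 0 and h.qend == len(g)]
    assert full and full[0].identity == 1.0 and full[0].strand == "+"


def test_unrelated_sequences_give_no_hits():
    assert local_search(random_seq(1, 10000), random_seq(2, 10000)) == []


def test_planted_divergent_copy_is_found():
    subject = random_seq(3, 10000)
    insert = _mutate(subject[2000:2500], 0.05, 4)
    query = random_seq(5, 3000) + insert + random_seq(6, 3000)
    hits = local_search(query, subject)
    assert len(hits) >= 1
    cov = union_length([(max(h.qstart, 3000), min(h.qend, 3500)) for h in hits])
    assert cov >= 0.9 * 500


def test_alphabet_and_threshold_validation():
    with pytest.raises(ValueError, match="alphabet"):
        local_search("ACGU" * 100, "ACGT" * 100)
    with pytest.raises(ValueError):
        local_search("ACGT" * 100, "ACGT" * 100, min_identity=0.0)
    with pytest.raises(ValueError, match="empty"):
        local_search("", "ACGT")


@pytest.mark.parametrize("seed,div", [(11, 0.05), (12, 0.10), (13, 0.12)])
def test_local_search_superset_of_dp_oracle(seed, div):
    """Every optimal local alignment (quadratic Smith-Waterman oracle) that
    meets the identity/length thresholds is covered by a reported hit."""
    subject = random_seq(seed, 1500)
    planted = _mutate(subject[400:800], div, seed + 100)
    query = random_seq(seed + 200, 500) + planted + random_seq(seed + 300, 400)

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aln = aligner.align(query, subject)[0]
    qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    matches = sum(1 for a, b in zip(str(aln[0]), str(aln[1])) if a == b)
    identity = matches / aln.length
    if identity < 0.85 or qe - qs < 90:
        pytest.skip("oracle alignment below thresholds for this divergence")
    hits = local_search(query, subject)
    cov = union_length([(max(h.qstart, qs), min(h.qend, qe)) for h in hits])
    assert cov >= 0.9 * (qe - qs)


def test_identical_genomes_single_block_and_no_regions():
    g = random_seq(21, 8000)
    blocks = build_blocks(local_search(g, g))
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.qstart, b.qend, b.strand) == (0, 8000, "+")
    assert nonalignable_regions_1d(blocks, 8000) == []


def test_insertion_splits_coverage_into_flanking_blocks():
    a = random_seq(22, 12000)
    b = a[:6000] + random_seq(23, 5000) + a[6000:]
    blocks = build_blocks(local_search(b, a), max_gap=1000)
    assert len(blocks) == 2
    regions = nonalignable_regions_1d(blocks, len(b))
    assert len(regions) == 1
    s, e = regions[0]
    assert abs((e - s) - 5000) <= 50


def test_planted_gain_yields_one_region_of_planted_length():
    a = random_seq(31, 15000)
    gain = random_seq(32, 2712)
    a_gained = a[:7000] + gain + a[7000:]
    from mitodiff.core import AnnotatedGenome

    ga = AnnotatedGenome("A", a_gained, "linear")
    gb = AnnotatedGenome("B", a, "linear")
    cmp_ = compare_pair(ga, gb, letters=("A", "B"))
    assert len(cmp_.regions["A"]) == 1
    r = cmp_.regions["A"][0]
    assert abs(r.length - 2712) <= 50
    assert cmp_.regions["B"] == []


def test_role_swap_symmetry():
    a = random_seq(41, 10000)
    b = a[:3000] + random_seq(42, 1200) + a[3000:8000] + a[9000:]
    from mitodiff.core import AnnotatedGenome

    ga, gb = AnnotatedGenome("A", a, "linear"), AnnotatedGenome("B", b, "linear")
    r1 = compare_pair(ga, gb, letters=("A", "B")).regions
    r2 = compare_pair(gb, ga, letters=("B", "A")).regions
    assert [(x.start, x.end) for x in r1["A"]] == [(x.start, x.end) for x in r2["A"]]
    assert [(x.start, x.end) for x in r1["B"]] == [(x.start, x.end) for x in r2["B"]]


def test_coverage_conservation_per_genome():
    """Hit coverage + non-alignable bp + sub-threshold gap bp = genome
    length."""
    a = random_seq(51, 12000)
    b = a[:4000] + random_seq(52, 3000) + a[4000:10000]
    blocks = build_blocks(local_search(a, b))
    cov = union_length([(h.qstart, h.qend) for blk in blocks for h in blk.hits])
    regions = nonalignable_regions_1d(blocks, len(a), min_region_len=90,
                                      merge_slack=0)
    all_gaps = nonalignable_regions_1d(blocks, len(a), min_region_len=1,
                                       merge_slack=0)
    sub_threshold = union_length(all_gaps) - union_length(regions)
    assert cov + union_length(regions) + sub_threshold == len(a)


def test_inversion_recovered_within_max_gap():
    cfg = quiet_config(61)
    counts = dict(cfg.event_counts)
    counts["inversion"] = 1
    cfg = quiet_config(61, event_counts=counts)
    sim = simulate_genomes(cfg)
    ev = sim.ledger.events_of("inversion")[0]
    s, e, _ = ev.coords["C"]
    cmp_ = compare_pair(sim.genomes["C"], sim.genomes["S"], letters=("C", "S"))
    assert len(cmp_.inversions) == 1
    (qs, qe), _, length = cmp_.inversions[0]
    assert abs(qs - s) <= 1000 and abs(qe - e) <= 1000


def test_no_minus_blocks_no_inversions():
    g = random_seq(71, 6000)
    blocks = build_blocks(local_search(g, g))
    assert detect_inversions(blocks) == []


def test_two_inversions_on_different_branches(trio=None):
    """Inversions planted on two branches each show up in the pairwise
    comparisons that straddle their branch."""
    cfg = quiet_config(81)
    counts = dict(cfg.event_counts)
    counts["inversion"] = 2  # branch cycle plants them on C and S
    sizes = dict(cfg.event_sizes)
    sizes["inversion"] = 3000
    cfg = quiet_config(81, event_counts=counts, event_sizes=sizes)
    sim = simulate_genomes(cfg)
    evs = {e.id: e for e in sim.ledger.events_of("inversion")}
    assert {tuple(e.coords) for e in evs.values()} == {("C",), ("S",)}
    cmp_cs = compare_pair(sim.genomes["C"], sim.genomes["S"], letters=("C", "S"))
    assert len(cmp_cs.inversions) == 2
    cmp_cd = compare_pair(sim.genomes["C"], sim.genomes["D"], letters=("C", "D"))
    assert len(cmp_cd.inversions) == 1
    s, e, _ = evs["inversion_1"].coords["C"]
    (qs, qe), _, _ = cmp_cd.inversions[0]
    assert abs(qs - s) <= 1000 and abs(qe - e) <= 1000


def test_rotation_changes_coordinates_not_region_lengths():
    base = random_seq(91, 12000)
    other = base[:3000] + base[5000:]  # base has a 2 kb segment missing in other
    from mitodiff.core import AnnotatedGenome

    gb = AnnotatedGenome("B", other, "circular")
    lengths = {}
    for off in (0, 4000):
        ga = AnnotatedGenome("A", base[off:] + base[:off], "circular")
        cmp_ = compare_pair(ga, gb, letters=("A", "B"))
        lengths[off] = sorted(r.length for r in cmp_.regions["A"])
    assert lengths[0] == lengths[4000]
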