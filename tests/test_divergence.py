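from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import quiet_config, random_seq
from mitodiff import divergence as dv
from mitodiff.core import AnnotatedGenome
from mitodiff.seqcompare import build_blocks, local_search
from mitodiff.simulate import simulate_genomes


class TestK2P:
    def test_zero(self):
        assert dv.k2p_distance(0.0, 0.0) == 0.0

    def test_printed_example(self):
        assert dv.k2p_distance(0.1, 0.05) == pytest.approx(0.17017, abs=1e-4)

    def test_saturation(self):
        with pytest.raises(dv.SaturationError):
            dv.k2p_distance(0.3, 0.4)
        with pytest.raises(ValueError):
            dv.k2p_distance(-0.1, 0.0)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0, 0.3), st.floats(0, 0.2))
    def test_correction_never_shrinks(self, P, Q):
        if 1 - 2 * P - Q <= 0.05 or 1 - 2 * Q <= 0.05:
            return
        assert dv.k2p_distance(P, Q) >= P + Q - 1e-12


class TestClock:
    def test_identity(self):
        r, T = dv.clock(0.01, 0.01, 5e6)
        assert T == pytest.approx(5e6)

    def test_scale_invariance(self):
        _, t1 = dv.clock(1.5e-3, 6e-2, 88e6)
        _, t2 = dv.clock(1.5e-2, 6e-1, 88e6)
        assert t1 == pytest.approx(t2)

    def test_per_lineage_halves_time(self):
        _, t1 = dv.clock(1e-3, 1e-2, 1e7)
        _, t2 = dv.clock(1e-3, 1e-2, 1e7, per_lineage=True)
        assert t2 == pytest.approx(t1 / 2)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dv.clock(0, 1e-2, 1e6)
        with pytest.raises(ValueError):
            dv.clock(1e-3, -1, 1e6)


def _blocks(a, b):
    return build_blocks(local_search(a.sequence, b.sequence, min_hit_len=60))


def test_identical_sequences_give_no_records():
    g = AnnotatedGenome("a", random_seq(1, 5000), "linear")
    h = AnnotatedGenome("b", g.sequence, "linear")
    records, indels, sites = dv.tabulate_differences(g, h, _blocks(g, h))
    assert records == [] and indels == []
    assert sites["intergenic"] == 5000


def test_single_transition_column():
    s = random_seq(2, 2000)
    i = 1000
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[s[i]]
    g = AnnotatedGenome("a", s, "linear")
    h = AnnotatedGenome("b", s[:i] + alt + s[i + 1:], "linear")
    records, indels, _ = dv.tabulate_differences(g, h, _blocks(g, h))
    assert len(records) == 1 and not indels
    r = records[0]
    assert (r.position, r.klass, r.context) == (i, "transition", "intergenic")


def test_simulated_pair_counts_match_ledger_exactly():
    """With no structural events, every planted substitution and indel
    between the two ingroup genomes is tabulated."""
    cfg = quiet_config(17, tree={"C": 0.001, "S": 0.001, "CS": 0.0, "D": 0.001},
                       indel_rate=1e-4)
    sim = simulate_genomes(cfg)
    C, S = sim.genomes["C"], sim.genomes["S"]
    records, indels, _ = dv.tabulate_differences(C, S, _blocks(C, S))
    led_subs = [s for s in sim.ledger.substitutions
                if s["genome"] in "CS" and s["branch"] in "CS"]
    # positions are unique in this realization, so counts are exact
    assert len({(s["genome"], s["pos"]) for s in led_subs}) == len(led_subs)
    assert len(records) == len(led_subs)
    led_indels = [i for i in sim.ledger.indels if i["genome"] in "CS"]
    assert len(indels) == len(led_indels)


def test_codon_effect_classification():
    cds = "ATG" + "GGA" * 10 + "TAA"
    pre = random_seq(3, 300)
    post = random_seq(4, 300)
    seq = pre + cds + post
    feat_start = len(pre)
    from mitodiff.core import Feature

    g = AnnotatedGenome("a", seq, "linear",
                        [Feature("CDS", feat_start, feat_start + len(cds), "+", "x")])
    # third-position GGA->GGG is synonymous; first-position GGA->AGA is not
    i_syn = feat_start + 3 + 2
    i_non = feat_start + 3
    mut = list(seq)
    mut[i_syn] = "G"
    mut[i_non] = "A"
    h = AnnotatedGenome("b", "".join(mut), "linear")
    records, _, _ = dv.tabulate_differences(g, h, _blocks(g, h))
    effects = {r.position: r.codon_effect for r in records}
    assert effects[i_syn] == "synonymous"
    assert effects[i_non] == "nonsynonymous"


class TestKsKa:
    def test_identical(self):
        a = "ATG" + "GCT" * 50
        ks, ka, _ = dv.ks_ka((a, a))
        assert ks == 0.0 and ka == 0.0

    def test_single_synonymous_third_position(self):
        a = "ATG" + "GGA" * 299
        b = "ATG" + "GGG" + "GGA" * 298
        ks, ka, _ = dv.ks_ka((a, b))
        assert ka == 0.0 and ks > 0.0

    def test_pathway_counts_match_enumeration(self):
        """Raw difference counts equal a brute-force average over all
        substitution orderings, computed independently here."""
        from Bio.Seq import Seq

        def aa(c):
            return str(Seq(c).translate())

        def brute(c1, c2):
            pos = [k for k in range(3) if c1[k] != c2[k]]
            res = []
            for perm in permutations(pos):
                cur, counts, stop = c1, np.zeros(4), False
                for k in perm:
                    nxt = cur[:k] + c2[k] + cur[k + 1:]
                    if aa(nxt) == "*" and nxt != c2:
                        stop = True
                    syn = aa(nxt) != "*" and aa(nxt) == aa(cur)
                    ts = dv.is_transition(cur[k], c2[k])
                    counts[(0 if syn else 2) + (0 if ts else 1)] += 1
                    cur = nxt
                res.append((stop, counts))
            ok = [c for s, c in res if not s]
            return np.mean(ok if ok else [c for _, c in res], axis=0)

        for c1, c2 in [("TTT", "GTA"), ("ATG", "ACG"), ("AAA", "GGG"),
                       ("TCA", "AGT"), ("CGA", "CGG")]:
            _, _, diffs, _ = dv.pathway_counts([(c1, c2)])
            assert np.allclose(diffs, brute(c1, c2)), (c1, c2)

    def test_zero_synonymous_sites_rejected(self):
        with pytest.raises(ValueError, match="synonymous"):
            dv.ks_ka([])

    @pytest.mark.parametrize("omega", [0.3, 1.0])
    def test_omega_recovery_at_1e4_codons(self, omega):
        """Proposing random single-base changes and accepting nonsynonymous
        ones with probability omega yields Ka/Ks ~ omega."""
        from conftest import evolve_codon_pairs

        ks, ka, _ = dv.ks_ka(evolve_codon_pairs(99, omega))
        assert ka / ks == pytest.approx(omega, rel=0.10)


class TestPolarize:
    def test_definition_case(self):
        rec = dv.SubstitutionRecord("ab", 10, "G", "A", "transition",
                                    "intergenic", "n/a")
        recs, counts = dv.polarize([rec], {10: "A"})
        assert recs[0].lineage == "A" and counts == {"A": 1, "B": 0,
                                                     "unpolarized": 0}
        recs, counts = dv.polarize([rec], {10: "G"})
        assert counts["B"] == 1
        # three-state column or missing outgroup base -> unpolarized
        assert dv.polarize([rec], {10: "C"})[1]["unpolarized"] == 1
        assert dv.polarize([rec], {})[1]["unpolarized"] == 1

    def test_counts_conserve_total(self):
        recs = [dv.SubstitutionRecord("ab", i, "A", "G", "transition",
                                      "intergenic", "n/a") for i in range(20)]
        outmap = {i: "AGC"[i % 3] for i in range(15)}
        _, counts = dv.polarize(recs, outmap)
        assert sum(counts.values()) == 20

    def test_terminal_branch_recovery_on_simulation(self):
        cfg = quiet_config(23, tree={"C": 0.001, "S": 0.001, "CS": 0.0005,
                                     "D": 0.002}, indel_rate=0.0)
        sim = simulate_genomes(cfg)
        C, S, D = (sim.genomes[x] for x in "CSD")
        records, _, _ = dv.tabulate_differences(C, S, _blocks(C, S))
        out_map = dv.aligned_base_map(C, D, _blocks(C, D))
        _, counts = dv.polarize(records, out_map)
        led = {sp: sum(1 for s in sim.ledger.substitutions
                       if s["genome"] == sp and s["branch"] == sp)
               for sp in "CS"}
        assert counts["A"] == led["C"]
        assert counts["B"] == led["S"]
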