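"""End-to-end pipeline: transfer detection, pairwise comparison, origin
classification, repeats, divergence/clock, and (optionally) the recurrent
transfer assay, with every output written beside a resolved config and a
checksum manifest so a fixed seed reproduces byte-identical results.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

from . import divergence as dv
from . import io as mio
from . import provenance as pv
from . import repeats as rp
from . import transfer as tr
from .recurrent import RegionAlignmentSet, partition_trees, scan_breakpoint
from .seqcompare import compare_pair
from .simulate import SimConfig, simulate_genomes, simulate_population


@dataclass
class PipelineConfig:
    outdir: str = "mitodiff_out"
    seed: int = 0
    # inputs; when mt_paths is empty a trio is simulated from `sim`
    mt_paths: dict = field(default_factory=dict)  # species label -> FASTA path
    cp_path: str | None = None
    sim: SimConfig | None = None
    # thresholds
    min_identity: float = 0.85
    min_hit_len: int = 90
    repeat_min_len: int = 30
    assay_flank: int = 100
    min_region_len: int = 90
    max_gap: int = 1000
    merge_slack: int = 50
    bootstrap: int = 200
    remove_ir: bool = True
    # clock conventions
    clock_calibration_distance: float = 6.28e-2
    clock_calibration_time: float = 88e6
    clock_per_lineage: bool = False
    # recurrent-transfer assay
    run_breakpoint: bool = True
    n_individuals: int = 15
    # ingroup cherry for polarization / outgroup dating; None = (C,S,D) when
    # those labels are present, otherwise the first two sorted labels
    ingroup: tuple | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim"):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)


class StageFailure(RuntimeError):
    def __init__(self, stage, err):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in order and return the report dict; every file
    written is listed (with sha256) in MANIFEST.tsv under outdir."""
    cfg = config
    os.makedirs(cfg.outdir, exist_ok=True)
    written = []

    def out(name):
        p = os.path.join(cfg.outdir, name)
        written.append(p)
        return p

    report = {"seed": cfg.seed, "stages": []}
    resolved = cfg.to_dict()
    resolved["outdir"] = "."  # outputs must not depend on where they land
    mio.write_json(resolved, out("config.resolved.json"))

    # --- stage: inputs ---------------------------------------------------
    sim = None
    panel_external = []
    nuclear = {}
    if cfg.mt_paths:
        genomes = {lab: mio.read_genome(p) for lab, p in cfg.mt_paths.items()}
        cp = mio.read_genome(cfg.cp_path) if cfg.cp_path else None
    else:
        simcfg = cfg.sim or SimConfig(seed=cfg.seed)
        sim = simulate_genomes(simcfg)
        genomes, cp = sim.genomes, sim.cp
        nuclear = {sp: sim.nuclear for sp in genomes}
        panel_external = sim.external
        for sp, g in genomes.items():
            mio.write_fasta([(g.id, g.sequence, g.description)], out(f"genome_{sp}.fa"))
            mio.write_gff3(g.features, g.id, len(g), out(f"genome_{sp}.gff3"))
        mio.write_fasta([(cp.id, cp.sequence, cp.description)], out("cp.fa"))
        mio.write_json(sim.ledger.to_dict(), out("truth_ledger.json"))
    report["genomes"] = {sp: {"length": len(g), "gc": round(g.gc, 6)}
                         for sp, g in genomes.items()}
    report["stages"].append("inputs")

    # --- stage: chloroplast transfers ------------------------------------
    idt = {}
    if cp is not None:
        try:
            for sp, g in genomes.items():
                regions, summary = tr.detect_idt(
                    g, cp, cfg.min_identity, cfg.min_hit_len, remove_ir=cfg.remove_ir)
                tr.export_links(regions, out(f"idt_links_{sp}.tsv"))
                mio.write_tsv(out(f"idt_genes_{sp}.tsv"),
                              ["gene", "status", "cause", "mt_start", "mt_end"],
                              [[gc.gene, gc.status, gc.cause,
                                gc.mt_interval[0] + 1 if gc.mt_interval else None,
                                gc.mt_interval[1] if gc.mt_interval else None]
                               for r in regions for gc in r.genes],
                              comments=["coordinates: 1-based inclusive"])
                idt[sp] = (regions, summary)
            report["idt"] = {sp: {"regions": s.n_regions, "total_bp": s.total_bp,
                                  "fraction": round(s.fraction, 6),
                                  "intact_genes": s.intact_genes,
                                  "pseudo_genes": s.pseudo_genes}
                             for sp, (r, s) in idt.items()}
        except Exception as e:
            raise StageFailure("idt", e)
    else:
        report["idt"] = None
        report["notes"] = ["no chloroplast genome supplied: transfer detection "
                           "and the CP classifier arm are disabled"]
    report["stages"].append("idt")

    # --- stage: pairwise comparison --------------------------------------
    species = sorted(genomes)
    pairs = [(species[i], species[j]) for i in range(len(species))
             for j in range(i + 1, len(species))]
    comparisons = {}
    try:
        for a, b in pairs:
            cmp_ = compare_pair(genomes[a], genomes[b], letters=(a, b),
                                min_identity=cfg.min_identity,
                                min_hit_len=cfg.min_hit_len, max_gap=cfg.max_gap,
                                min_region_len=cfg.min_region_len,
                                merge_slack=cfg.merge_slack)
            comparisons[(a, b)] = cmp_
            rows = [[b_.qstart + 1, b_.qend, b_.sstart + 1, b_.send, b_.strand,
                     len(b_.hits), b_.anchored_bp] for b_ in cmp_.blocks_ab]
            mio.write_tsv(out(f"blocks_{a}{b}.tsv"),
                          ["qstart", "qend", "sstart", "send", "strand",
                           "n_anchors", "anchored_bp"], rows,
                          comments=["coordinates: 1-based inclusive",
                                    f"query={a} subject={b}"])
            mio.write_tsv(out(f"inversions_{a}{b}.tsv"),
                          ["qstart", "qend", "sstart", "send", "length"],
                          [[q[0] + 1, q[1], s[0] + 1, s[1], L]
                           for q, s, L in cmp_.inversions],
                          comments=["coordinates: 1-based inclusive"])
            mio.write_tsv(out(f"regions_{a}{b}.tsv"),
                          ["code", "genome", "start", "end", "length"],
                          [[r.code, r.genome_id, r.start + 1, r.end, r.length]
                           for gid in cmp_.regions for r in cmp_.regions[gid]],
                          comments=["coordinates: 1-based inclusive",
                                    f"min_region_len={cfg.min_region_len} "
                                    f"merge_slack={cfg.merge_slack}"])
    except Exception as e:
        raise StageFailure("compare", e)
    report["pairs"] = {f"{a}{b}": {gid: len(rs) for gid, rs in
                                   comparisons[(a, b)].regions.items()}
                       for a, b in pairs}
    report["stages"].append("compare")

    # --- stage: origin classification ------------------------------------
    try:
        panel = pv.ReferencePanel(cp, genomes, nuclear or None, panel_external)
        summaries = {}
        all_calls = []
        for a, b in pairs:
            calls = []
            for gid, regions in comparisons[(a, b)].regions.items():
                partner = b if gid == a else a
                for r in regions:
                    calls.append(pv.classify_region(
                        r, panel, partner, cfg.min_identity, cfg.min_hit_len))
            summaries[f"{a}{b}"] = pv.summarize_pair(calls, f"{a}{b}")
            all_calls.extend(calls)
        pv.export_pair_summary(summaries, out("origin_summary.tsv"))
        mio.write_tsv(out("origin_evidence.tsv"),
                      ["region", "category", "start", "end", "target",
                       "identity", "score"],
                      [[c.region.code, ev[0], ev[1] + 1, ev[2], ev[3], ev[4], ev[5]]
                       for c in all_calls for ev in c.evidence],
                      comments=["coordinates: 1-based inclusive, within the region"])
        report["origins"] = {
            pair: {gid: {"n": row["n"], "total": row["total"], "bp": row["bp"]}
                   for gid, row in per_genome.items()}
            for pair, per_genome in summaries.items()}
    except Exception as e:
        raise StageFailure("classify", e)
    report["stages"].append("classify")

    # --- stage: repeats ---------------------------------------------------
    try:
        table1 = []
        for sp, g in genomes.items():
            units, summ = rp.find_repeats(g, cfg.repeat_min_len)
            mio.write_tsv(out(f"repeats_{sp}.tsv"),
                          ["c1_start", "c1_end", "c2_start", "c2_end",
                           "relation", "length"],
                          [[u.copy1[0] + 1, u.copy1[1], u.copy2[0] + 1, u.copy2[1],
                            u.relation, u.length] for u in units],
                          comments=["coordinates: 1-based inclusive",
                                    "greedy longest-first unit selection",
                                    "content = union of all repeat copies / genome"])
            table1.append([sp, len(g), f"{100 * g.gc:.2f}%", summ.unit_count,
                           summ.largest, f"{100 * summ.content:.2f}%"])
        mio.write_tsv(out("genome_summary.tsv"),
                      ["species", "size_bp", "gc", "repeat_units",
                       "largest_repeat_bp", "repeat_content"], table1)
        report["repeats"] = {row[0]: {"units": row[3], "largest": row[4],
                                      "content": row[5]} for row in table1}
    except Exception as e:
        raise StageFailure("repeats", e)
    report["stages"].append("repeats")

    # --- stage: divergence and clock --------------------------------------
    try:
        if cfg.ingroup:
            a, b = cfg.ingroup
        elif {"C", "S", "D"} <= set(species):
            a, b = "C", "S"
        else:
            a, b = species[0], species[1]
        outg = next((s for s in species if s not in (a, b)), None)
        if (a, b) not in comparisons:
            a, b = b, a
        cmp_ab = comparisons[(a, b)]
        records, indels, sites = dv.tabulate_differences(
            genomes[a], genomes[b], cmp_ab.blocks_ab, pair=f"{a}{b}")
        mio.write_tsv(out(f"substitutions_{a}{b}.tsv"),
                      ["position", "a_base", "b_base", "class", "context",
                       "codon_effect", "gene", "lineage"],
                      [[r.position + 1, r.a_base, r.b_base, r.klass, r.context,
                        r.codon_effect, r.gene, r.lineage] for r in records],
                      comments=["coordinates: 1-based on genome " + a])
        noncoding = dv.distance_from_records(records, sites["intergenic"] + sites["intron"])
        dist = {
            "pair": f"{a}{b}",
            "n_substitutions": len(records),
            "n_indels": len(indels),
            "transitions": sum(1 for r in records if r.klass == "transition"),
            "transversions": sum(1 for r in records if r.klass == "transversion"),
            "aligned_sites": sites,
            "noncoding": {"P": noncoding.P, "Q": noncoding.Q,
                          "d_K2P": noncoding.d, "sites": noncoding.sites},
        }
        if outg:
            key = (a, outg) if (a, outg) in comparisons else (outg, a)
            cmp_ao = comparisons[key]
            blocks_a_query = cmp_ao.blocks_ab if key[0] == a else cmp_ao.blocks_ba
            out_map = dv.aligned_base_map(genomes[a], genomes[outg], blocks_a_query)
            polarized, counts = dv.polarize(records, out_map)
            dist["polarized"] = counts
            cd_map = out_map
            cpairs = dv.codon_pairs_from_map(genomes[a], cd_map)
            if cpairs:
                try:
                    ks, ka, info = dv.ks_ka(cpairs)
                    dist["ks_outgroup"] = {"Ks": ks, "Ka": ka,
                                           "codons": info["codons"]}
                    r_, T = dv.clock(ks, cfg.clock_calibration_distance,
                                     cfg.clock_calibration_time,
                                     per_lineage=cfg.clock_per_lineage)
                    dist["clock"] = {"rate_per_site_per_year": r_,
                                     "divergence_time_years": T,
                                     "calibration_distance": cfg.clock_calibration_distance,
                                     "calibration_time": cfg.clock_calibration_time,
                                     "per_lineage": cfg.clock_per_lineage}
                except (ValueError, dv.SaturationError) as e:
                    dist["ks_outgroup"] = {"error": str(e)}
        mio.write_json(dist, out("distances.json"))
        report["divergence"] = dist
    except StageFailure:
        raise
    except Exception as e:
        raise StageFailure("divergence", e)
    report["stages"].append("divergence")

    # --- stage: recurrent transfer (simulated inputs only) -----------------
    if cfg.run_breakpoint and sim is not None and sim.ledger.recurrent:
        try:
            simcfg = sim.config
            recs, flags, truth = simulate_population(simcfg, cfg.n_individuals, sim)
            ev = next(e for e in sim.ledger.events
                      if e.id == sim.ledger.recurrent["region_event"])
            mt_records = []
            for sp in sorted(genomes):
                s, e, st = ev.coords[sp]
                mt_records.append((f"mt_{sp}", genomes[sp].fetch(s, e, st)))
            cp_records = [("cp_ref", truth["cp_donor"])]
            template = None
            carrier_calls = {}
            for (rid, seq), flag in zip(recs, flags):
                aset = RegionAlignmentSet.from_unaligned(
                    [*mt_records, *cp_records, (rid, seq)], rid,
                    ["cp_ref"], [m for m, _ in mt_records])
                call = scan_breakpoint(aset)
                carrier_calls[rid] = call
                if call.chimera and template is None:
                    template = (aset, call)
            bp_report = {"n_individuals": len(recs),
                         "detected_carriers": sum(
                             1 for c in carrier_calls.values() if c.chimera)}
            if template:
                aset, call = template
                bp_report["breakpoint_query_position"] = call.query_position
                bp_report["support"] = [call.support_left, call.support_right]
                trees = partition_trees(aset, call, bootstrap=cfg.bootstrap,
                                        seed=cfg.seed)
                with open(out("partition_trees.nwk"), "w") as fh:
                    fh.write(trees.tree_recurrent + "\n" + trees.tree_rest + "\n")
                bp_report["query_with_cp_recurrent"] = trees.query_with_cp_recurrent
                bp_report["query_with_cp_rest"] = trees.query_with_cp_rest
                bp_report["bootstrap_support"] = [trees.support_recurrent,
                                                  trees.support_rest]
            mio.write_tsv(out("carrier_table.tsv"),
                          ["individual", "verdict", "boundary_query_pos"],
                          [[rid, c.verdict,
                            c.query_position + 1 if c.query_position is not None else None]
                           for rid, c in carrier_calls.items()])
            report["recurrent"] = bp_report
        except Exception as e:
            raise StageFailure("breakpoint", e)
        report["stages"].append("breakpoint")

    mio.write_json(report, out("report.json"))
    manifest = mio.write_manifest(cfg.outdir, written)
    report["manifest"] = manifest
    return report
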