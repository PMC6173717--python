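"""End-to-end orchestration: simulate/ingest -> filter -> screen ->
permutation-validate -> assign -> phylogenetic turnover analysis.

Configuration is a plain nested dict (typically parsed from YAML);
every stage gets its own sub-seed derived from the master seed so a
run is reproducible end to end.  Stage outputs are written as TSV/JSON
into the run directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from sexlinkage import assignment as asg
from sexlinkage import fixtures, genotype_io, permutation, phylo, screens, simulate

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs), < 2**31."""
    import zlib

    h = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2**31))


DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "sexlinkage_run",
    "simulate": {
        "n_males": 20,
        "n_females": 20,
        "n_loci": 2000,
        "system": "XY",
        "prop_sexlinked": 0.05,
        "prop_y_snp": 0.6,
        "prop_sex_limited": 0.2,
        "prop_x_hemizygous": 0.2,
        "n_y_haplotypes": 1,
        "error_rate": 0.005,
        "missing_rate": 0.05,
        "sex_chromosome": "Chr05",
    },
    "filter": {},
    "screen": {},
    "permutation": {"n_permutations": 1000, "percentile": 99.0},
    "assignment": {"n_random_subsets": 1000, "percentile": 99.0, "min_markers_on_chrom": 10},
    "phylo": {"n_maps": 500, "constraint": "ER", "n_starts": 5},
    "recruitment": {"n_replicates": 1000},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def run(config: dict | None = None) -> dict:
    """Run the full synthetic pipeline; returns the summary dict
    (also written to ``<outdir>/summary.json``)."""
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])
    summary: dict = {"seed": master}

    # --- simulate ---------------------------------------------------------
    sim_cfg = dict(cfg["simulate"])
    sex_chrom = sim_cfg.pop("sex_chromosome", "Chr05")
    params = simulate.PopSimParams(seed=stage_seed(master, "simulate"), **sim_cfg)
    gm, tags, truth = simulate.simulate_population(params)
    sheet = simulate.sample_sheet_for(gm)
    genotype_io.write_genotypes_tsv(gm, outdir / "genotypes.tsv")
    genotype_io.write_vcf(gm, outdir / "genotypes.vcf")
    genotype_io.write_tag_presence(tags, outdir / "tags.tsv")
    genotype_io.write_sample_sheet(sheet, outdir / "samples.tsv")
    truth.to_tsv(gm.loci, outdir / "truth.tsv")
    summary["simulate"] = {"n_loci": gm.n_loci, "n_samples": gm.n_samples, "classes": truth.class_counts()}

    # --- filter -----------------------------------------------------------
    fparams = genotype_io.FilterParams(**cfg["filter"])
    filtered = genotype_io.filter_loci(gm, sheet, fparams)
    summary["filter"] = {"retained": filtered.n_loci, "input": gm.n_loci}

    # --- screens ----------------------------------------------------------
    sparams = screens.ScreenParams(**cfg["screen"])
    report = screens.run_all_screens(filtered, tags, sheet, sparams)
    report.to_frame().to_csv(outdir / "screen_counts.tsv", sep="\t", index=False)
    summary["screens"] = {f"{a}_{o}": n for (a, o), n in report.counts().items()}

    # --- permutation validation -------------------------------------------
    pcfg = permutation.PermutationConfig(seed=stage_seed(master, "permutation"), **cfg["permutation"])
    null = permutation.build_null(filtered, tags, sheet, sparams, pcfg)
    decisions = permutation.validate(null, pcfg)
    permutation.decisions_frame(decisions).to_csv(outdir / "validation.tsv", sep="\t", index=False)
    summary["validation"] = {f"{d.approach}_{d.orientation}": d.passed for d in decisions.values()}
    passing = [k for k, d in decisions.items() if d.passed]
    summary["any_screen_passed"] = bool(passing)

    # --- chromosome assignment --------------------------------------------
    if passing:
        best_key = max(passing, key=lambda k: decisions[k].observed)
        marker_set = report.marker_sets[best_key]
        chrom_of = simulate.assign_chromosomes(truth, sex_chromosome=sex_chrom, seed=stage_seed(master, "karyotype"))
        hits, scaffold_map = simulate.simulate_alignment_hits(gm.loci, chrom_of, seed=stage_seed(master, "alignment"))
        fhits = genotype_io.filter_alignment_hits(hits)
        counts, n_unaligned, n_unplaced = asg.assign_markers(marker_set.ids, fhits, scaffold_map)
        acfg = asg.AssignmentConfig(seed=stage_seed(master, "assignment"), **cfg["assignment"])
        null_series = asg.random_subset_null(gm.loci, fhits, scaffold_map, len(marker_set), acfg)
        result = asg.identify_sex_chromosome(counts, null_series, acfg, n_unaligned, n_unplaced)
        result.to_frame().to_csv(outdir / "chromosome_assignment.tsv", sep="\t", index=False)
        summary["assignment"] = {
            "marker_set": f"{best_key[0]}_{best_key[1]}",
            "set_size": len(marker_set),
            "identified": result.identified,
            "passing": result.passing,
        }

    # --- phylogenetic turnover analysis ------------------------------------
    fix = fixtures.load_ranidae_turnovers()
    history = phylo.count_turnovers(fixture=fix.history)
    gene_counts = fixtures.load_gene_counts()
    rec_cfg = phylo.RecruitmentTestConfig(
        gene_counts,
        n_recruitments=history.total(),
        seed=stage_seed(master, "recruitment"),
        **cfg["recruitment"],
    )
    recruit = history.recruitments_per_chromosome()
    rec = phylo.recruitment_null_test(rec_cfg, recruit)
    rec.to_frame().to_csv(outdir / "recruitment_null.tsv", sep="\t", index=False)
    reg = phylo.recruitment_regression(
        [recruit.get(c, 0) for c in gene_counts],
        list(gene_counts.values()),
    )
    summary["turnover"] = {
        "total": history.total(),
        "by_scope": history.count_by_scope(),
        "preserving_heterogamety": history.n_preserving_heterogamety(),
        "recruitments": recruit,
        "species_usage": fix.species_usage_counts(),
        "heterogamety_p_equal": phylo.heterogamety_binomial(
            history.n_preserving_heterogamety(), history.total(), 0.5
        ),
        "heterogamety_p_drift": phylo.heterogamety_binomial(
            history.n_preserving_heterogamety(), history.total(), 0.75
        ),
        "recruitment_p_chr05": rec.p_upper.get("Chr05"),
        "regression": asdict(reg),
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
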