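"""End-to-end composition of the mapping and association stages.

Given a run configuration (either file inputs or a named simulation
scenario), the pipeline computes line-origin states, scans the chromosome,
estimates permutation thresholds and the bootstrap confidence interval,
builds the per-SNP association table, and — when a haplotype window is
declared — phases it and runs the haplotype regressions.  Every output file
carries the master seed, and the run log records the configuration digest,
so a run is reproducible byte for byte from (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path


from . import assoc as assoc_mod
from . import haplotypes as hap_mod
from .io import RunConfig, read_tables
from .linkage import origin_grid
from .linmod import ModelSpec, correct_phenotypes
from .scan import bootstrap_ci, permutation_threshold, scan_chromosome
from .simulate import make_fixture

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        fx = make_fixture(config.scenario, config.seed)
        return {"map": fx.gmap, "pedigree": fx.pedigree,
                "genotypes": fx.genotypes, "phenotypes": fx.phenotypes,
                "candidates": fx.candidates}
    return read_tables(config.map_path, config.pedigree_path,
                       config.genotype_path, config.phenotype_path,
                       config.candidate_path)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns {name: path} of the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    summary: dict = {"seed": config.seed, "config_digest": config.digest()}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("read inputs")
        data = _load_inputs(config)
        gmap = data["map"]
        pheno = data["phenotypes"]

        if data["pedigree"] is None:
            # outbred validation line: genotype ANCOVA only
            _stage("outbred association")
            res = assoc_mod.outbred_assoc(pheno, factors=("sex",))
            table3 = res.table
            table3.insert(0, "seed", config.seed)
            p = out / "outbred_association.tsv"
            table3.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths["outbred_association.tsv"] = p
            summary["outbred_overall_F"] = res.overall.f
            summary["outbred_overall_P"] = res.overall.p_value
            p = out / "summary.json"
            p.write_text(json.dumps(summary, indent=1, default=float))
            paths["summary.json"] = p
            return paths

        base_spec = ModelSpec()
        if "ppard_genotype" not in pheno.columns:
            base_spec = ModelSpec(factors=("batch", "sex"))

        _stage("line-origin states")
        states = origin_grid(data["pedigree"], data["genotypes"], gmap,
                             step=config.step)

        _stage("scan")
        result = scan_chromosome(pheno, states, base_spec, step=config.step)
        curve = result.to_frame()
        curve.insert(0, "seed", config.seed)
        p = out / "scan.tsv"
        curve.to_csv(p, sep="\t", index=False)
        paths["scan.tsv"] = p
        summary["peak_position_cM"] = result.peak_position
        summary["peak_F"] = result.peak_f
        summary["additive_effect"] = result.effect.a
        summary["dominance_effect"] = result.effect.d
        summary["variance_explained_pct"] = result.variance_explained

        _stage("permutation threshold")
        perm = permutation_threshold(pheno, states, base_spec,
                                     n_perm=config.n_perm, alpha=config.alpha,
                                     seed=config.seed)
        summary["permutation_threshold"] = perm.threshold
        summary["n_perm"] = perm.n_perm
        summary["alpha"] = config.alpha

        _stage("bootstrap CI")
        boot = bootstrap_ci(pheno, states, base_spec, n_boot=config.n_boot,
                            seed=config.seed + 1)
        summary["ci_95"] = list(boot.ci)
        summary["n_boot"] = boot.n_boot
        hist = boot.histogram
        hist.insert(0, "seed", config.seed)
        p = out / "bootstrap_histogram.tsv"
        hist.to_csv(p, sep="\t", index=False)
        paths["bootstrap_histogram.tsv"] = p

        candidates = data.get("candidates")
        snps = tuple(config.candidate_snps)
        if candidates is not None and not snps:
            snps = tuple(sorted({c[:-2] for c in candidates.columns
                                 if c.endswith("_1")}))
        if candidates is not None and snps:
            _stage("candidate association tests")
            table1 = assoc_mod.candidate_table(pheno, candidates, snps,
                                               states, base_spec,
                                               mode=config.fdrop_mode)
            table1.insert(0, "seed", config.seed)
            p = out / "association_tests.tsv"
            table1.to_csv(p, sep="\t", index=False,
                          float_format="%.6g")
            paths["association_tests.tsv"] = p

        window = tuple(config.haplotype_window)
        if candidates is not None and window:
            _stage("haplotype association")
            assignments = hap_mod.phase_f2(data["pedigree"], candidates, window)
            copies = hap_mod.haplotype_copy_matrix(assignments)
            resid = correct_phenotypes(pheno, data["pedigree"],
                                       config.heritability)
            table2 = hap_mod.haplotype_regression(resid, copies)
            table2.insert(0, "seed", config.seed)
            p = out / "haplotype_tests.tsv"
            table2.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths["haplotype_tests.tsv"] = p
            pct, pval = hap_mod.haplotype_variance_explained(resid, copies)
            summary["haplotype_variance_pct"] = pct
            summary["haplotype_variance_p"] = pval

        p = out / "summary.json"
        p.write_text(json.dumps(summary, indent=1, default=float))
        paths["summary.json"] = p
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    return paths
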