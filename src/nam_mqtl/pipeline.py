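"""End-to-end synthetic study pipeline.

Glues the stages together for a fully synthetic run: simulate a NAM
population and metabolite-like phenotypes, run marker QC / IBS coding /
imputation, metabolite filtering / min-imputation / Box-Cox, cross-validated
stepwise GWAS per metabolite, optional permutation threshold, mQTL grouping
with explained variance and family effects, and write the report bundle.
Used by the command-line interface and for whole-pipeline determinism
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotypes, phenotypes, regions as regions_mod, simulate
from .gwas import NAMGwas, permutation_threshold

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Desk-scale defaults for a synthetic mQTL study."""

    n_families: int = 25
    lines_per_family: int = 52
    n_snps: int = 2000
    n_chromosomes: int = 7
    chrom_length_cm: float = 150.0
    donor_polymorphism_rate: float = 0.5
    n_qtl: int = 3
    qtl_effect: float = 1.0
    h2_target: float = 0.6
    n_null_metabolites: int = 2
    phenotype_link: str = "exp"
    missing_rate: float = 0.02
    k: int = 5
    n_reps: int = 20
    p_enter: float = 0.001
    p_remove: float = 0.001
    threshold: int | None = 25  # None -> calibrate by permutation
    n_shuffles: int = 3
    percentile: float = 99.99
    gap_bp: int = 5_000_000
    date_tag: str = "1"
    min_mean_r2: float = 0.2  # screen metabolites for mQTL reporting

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    population: simulate.NAMPopulation
    truths: dict
    ibs: genotypes.IBSMatrix
    transformed: pd.DataFrame
    transform_report: pd.DataFrame
    gwas_results: dict  # metabolite -> NAMGwasResults
    threshold: int
    regions: dict  # metabolite -> list[MQTLRegion]
    family_effects: dict  # metabolite -> FamilyEffectTable
    report_paths: dict


def _spread_qtl(gmap: simulate.GeneticMap, founders, n_qtl: int) -> list:
    """Pick QTL SNPs on distinct chromosomes, mid-chromosome, polymorphic in
    most families (so they segregate broadly)."""
    tab = gmap.table
    poly_frac = founders.donor_alleles.mean(axis=0)
    chosen = []
    for i, chrom in enumerate(gmap.chromosomes[:n_qtl]):
        sub = tab[tab["chrom"] == chrom]
        mid = sub["cM"].median()
        cand = sub.assign(dist=(sub["cM"] - mid).abs()).sort_values("dist")
        idx = {s: j for j, s in enumerate(tab["snp_id"])}
        best = max(
            cand.head(25)["snp_id"], key=lambda s: poly_frac[idx[s]]
        )
        chosen.append(best)
    return chosen


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]

    gmap = simulate.default_map(
        n_snps=cfg.n_snps,
        n_chromosomes=cfg.n_chromosomes,
        chrom_length_cm=cfg.chrom_length_cm,
    )
    pop = simulate.simulate_nam(
        n_families=cfg.n_families,
        lines_per_family=cfg.lines_per_family,
        gmap=gmap,
        donor_polymorphism_rate=cfg.donor_polymorphism_rate,
        seed=seeds[0],
    )

    # phenotypes: one signal metabolite with planted QTL + null metabolites
    qtl_snps = _spread_qtl(gmap, pop.founders, cfg.n_qtl)
    qtl = simulate.QTLSpec(
        effects={s: cfg.qtl_effect for s in qtl_snps},
        h2_target=cfg.h2_target,
        link=cfg.phenotype_link,
    )
    tables, truths = [], {}
    sig_table, truth = simulate.simulate_phenotypes(
        pop, qtl, seed=seeds[1], name="met_signal"
    )
    tables.append(sig_table)
    truths["met_signal"] = truth
    for j in range(cfg.n_null_metabolites):
        null_qtl = simulate.QTLSpec(effects={}, h2_target=0.0, link=cfg.phenotype_link)
        t, tr = simulate.simulate_phenotypes(
            pop, null_qtl, seed=seeds[2] + j, name=f"met_null_{j + 1}"
        )
        tables.append(t)
        truths[f"met_null_{j + 1}"] = tr
    pheno = pd.concat(tables, axis=1)
    pheno, _controls = simulate.inject_missingness_and_controls(
        pheno, missing_rate=cfg.missing_rate, seed=seeds[3]
    )

    # genotype side
    calls = genotypes.GenotypeCalls(pop.calls_frame(), pop.family_labels)
    qc = genotypes.marker_qc(calls)
    ibs = genotypes.impute_mni(genotypes.code_ibs(calls, qc))

    # metabolite side
    filtered, _rep = phenotypes.filter_metabolites(pheno)
    imputed = phenotypes.impute_min(filtered)
    transformed, treport = phenotypes.transform_table(imputed)

    # GWAS per metabolite
    gwas_results = {}
    for col in transformed.columns:
        res = NAMGwas(
            transformed[col],
            ibs,
            gmap=gmap,
            p_enter=cfg.p_enter,
            p_remove=cfg.p_remove,
        ).fit(k=cfg.k, n_reps=cfg.n_reps, seed=seeds[4])
        gwas_results[col] = res

    if cfg.threshold is None:
        thr = permutation_threshold(
            transformed,
            ibs,
            gmap=gmap,
            n_shuffles=cfg.n_shuffles,
            k=cfg.k,
            n_reps=cfg.n_reps,
            percentile=cfg.percentile,
            seed=seeds[5],
            p_enter=cfg.p_enter,
            p_remove=cfg.p_remove,
        ).threshold
    else:
        thr = int(cfg.threshold)

    all_regions, fam_effects = {}, {}
    for col, res in gwas_results.items():
        if res.mean_r2 <= cfg.min_mean_r2:
            all_regions[col] = []
            continue
        regs = regions_mod.group_mqtl(
            res.detection_table,
            gmap,
            threshold=thr,
            gap_bp=cfg.gap_bp,
            metabolite=col,
            date_tag=cfg.date_tag,
        )
        for reg in regs:
            regions_mod.region_r2(transformed[col], reg, ibs)
        all_regions[col] = regs
        if regs:
            fam_effects[col] = regions_mod.family_effects(res.runs, regs, ibs)

    report_paths = {}
    if out_dir is not None:
        out = Path(out_dir)
        for col, res in gwas_results.items():
            regs = all_regions.get(col, [])
            report_paths[col] = regions_mod.write_report(
                out / col,
                res.detection_table,
                thr,
                regs,
                family_effect_table=fam_effects.get(col),
                metadata={
                    "seed": seed,
                    "metabolite": col,
                    "mean_r2": round(res.mean_r2, 10),
                    **cfg.to_dict(),
                },
            )
        treport.to_csv(out / "boxcox_report.tsv", sep="\t", float_format="%.6g")

    return PipelineResult(
        config=cfg,
        population=pop,
        truths=truths,
        ibs=ibs,
        transformed=transformed,
        transform_report=treport,
        gwas_results=gwas_results,
        threshold=thr,
        regions=all_regions,
        family_effects=fam_effects,
        report_paths=report_paths,
    )
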