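import numpy as np
import pandas as pd
import pytest

import nam_mqtl as nm


@pytest.fixture(scope="session")
def small_map():
    return nm.default_map(n_snps=300, n_chromosomes=3, chrom_length_cm=120.0)


@pytest.fixture(scope="session")
def medium_study(small_map):
    """A reusable small NAM study: population, IBS matrix, one QTL phenotype."""
    pop = nm.simulate_nam(
        n_families=8, lines_per_family=40, gmap=small_map, seed=11
    )
    calls = nm.GenotypeCalls(pop.calls_frame(), pop.family_labels)
    qc = nm.marker_qc(calls)
    ibs = nm.impute_mni(nm.code_ibs(calls, qc))
    qtl_snp = small_map.snp_ids[40]
    qtl = nm.QTLSpec(effects={qtl_snp: 1.0}, h2_target=0.6, link="identity")
    pheno, truth = nm.simulate_phenotypes(pop, qtl, seed=12, name="met_q")
    return {
        "map": small_map,
        "pop": pop,
        "calls": calls,
        "qc": qc,
        "ibs": ibs,
        "qtl_snp": qtl_snp,
        "pheno": pheno,
        "truth": truth,
    }


@pytest.fixture()
def toy_calls():
    """Hand-designed 6-line, 4-SNP call matrix spanning the QC rules.

    snp_mono: hom recurrent everywhere -> fails polymorphism.
    snp_miss: 1/6 missing (16.7% > 10%) -> fails failure rate.
    snp_het:  2/6 het among 6 called (33% > 12.5%) -> fails het rate.
    snp_ok:   clean polymorphic marker -> passes.
    """
    lines = [f"L{i}" for i in range(1, 7)]
    fam = pd.Series([1, 1, 1, 2, 2, 2], index=lines)
    calls = pd.DataFrame(
        {
            "snp_mono": [0, 0, 0, 0, 0, 0],
            "snp_miss": [0, np.nan, 2, 0, 2, 0],
            "snp_het": [0, 1, 2, 0, 1, 0],
            "snp_ok": [0, 2, 0, 2, 0, 2],
        },
        index=lines,
        dtype=float,
    )
    return nm.GenotypeCalls(calls=calls, families=fam)
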