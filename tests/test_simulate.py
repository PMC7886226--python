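"""Simulator contracts: founder draws, BC1S3 genetics, phenotype model."""

import numpy as np
import pandas as pd
import pytest

import nam_mqtl as nm
from _oracles import bc1s3_single_locus_distribution


@pytest.fixture(scope="module")
def big_family(small_map):
    founders = nm.simulate_founders(1, small_map, 1.0, seed=3)
    return nm.simulate_bc1s3_family(
        founders.donor_alleles[0], founders.recurrent_parent, 2000, small_map, seed=4
    )


class TestFounders:
    def test_polymorphism_rate_binomial(self, small_map):
        gmap = nm.default_map(n_snps=2000)
        fs = nm.simulate_founders(25, gmap, 0.5, seed=1)
        diffs = fs.donor_alleles.sum(axis=1).astype(int)
        sd = np.sqrt(2000 * 0.25)
        assert np.all(np.abs(diffs - 1000) <= 3 * sd)

    def test_rate_one_differs_everywhere(self, small_map):
        fs = nm.simulate_founders(3, small_map, 1.0, seed=2)
        assert fs.donor_alleles.all()

    def test_recurrent_parent_all_reference(self, small_map):
        fs = nm.simulate_founders(2, small_map, 0.5, seed=5)
        assert not fs.recurrent_parent.any()

    def test_seed_determinism(self, small_map):
        a = nm.simulate_founders(1, small_map, 0.5, seed=7).donor_alleles
        b = nm.simulate_founders(1, small_map, 0.5, seed=7).donor_alleles
        c = nm.simulate_founders(1, small_map, 0.5, seed=8).donor_alleles
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("bad", [0, -1])
    def test_rejects_nonpositive_families(self, small_map, bad):
        with pytest.raises(ValueError):
            nm.simulate_founders(bad, small_map, 0.5, seed=0)

    def test_rejects_empty_map(self):
        with pytest.raises(ValueError):
            nm.GeneticMap(pd.DataFrame(columns=["snp_id", "chrom", "bp", "cM"]))


class TestBC1S3:
    def test_heterozygosity_near_one_sixteenth(self, big_family):
        het = (big_family.origin_dosage == 1).mean()
        assert abs(het * 100 - 6.25) < 0.5

    def test_donor_genome_proportion(self, big_family):
        prop = big_family.origin_dosage.mean() / 2.0
        assert abs(prop - 0.25) < 0.02

    def test_single_locus_law_matches_enumeration(self, big_family):
        exact = bc1s3_single_locus_distribution()
        dos = big_family.origin_dosage
        emp = {
            "hom_recurrent": (dos == 0).mean(),
            "het": (dos == 1).mean(),
            "hom_donor": (dos == 2).mean(),
        }
        for state, p in exact.items():
            assert abs(emp[state] - p) < 0.02
        assert abs(exact["het"] - 1 / 16) < 1e-12

    def test_unlinked_loci_uncorrelated(self, big_family, small_map):
        # first SNP of chromosome 1 vs first SNP of chromosome 2
        chrom = small_map.table["chrom"].to_numpy()
        j1 = int(np.flatnonzero(chrom == 1)[0])
        j2 = int(np.flatnonzero(chrom == 2)[0])
        dos = big_family.origin_dosage
        r = np.corrcoef(dos[:, j1], dos[:, j2])[0, 1]
        assert abs(r) < 0.05

    def test_linkage_decay_monotone_in_binned_distance(self, big_family, small_map):
        tab = small_map.table
        sub = tab[tab["chrom"] == 1]
        idx = sub.index.to_numpy()
        cm = sub["cM"].to_numpy()
        dos = big_family.origin_dosage[:, idx].astype(float)
        anchor = 0
        dist = cm - cm[anchor]
        keep = dist > 0
        with np.errstate(invalid="ignore"):
            corr = np.array(
                [np.corrcoef(dos[:, anchor], dos[:, j])[0, 1] for j in range(len(idx))]
            )
        bins = np.digitize(dist[keep], [10, 20, 40, 80, 200])
        means = [np.nanmean(corr[keep][bins == b]) for b in np.unique(bins)]
        assert all(m2 <= m1 + 0.03 for m1, m2 in zip(means, means[1:]))

    def test_zero_length_chromosome_fully_linked(self):
        gmap = nm.GeneticMap(
            pd.DataFrame(
                {
                    "snp_id": ["a", "b", "c"],
                    "chrom": [1, 1, 1],
                    "bp": [1, 2, 3],
                    "cM": [0.0, 0.0, 0.0],
                }
            )
        )
        fam = nm.simulate_bc1s3_family(
            np.ones(3, dtype=np.uint8), np.zeros(3, dtype=np.uint8), 200, gmap, seed=1
        )
        dos = fam.origin_dosage
        assert np.all(dos[:, 0] == dos[:, 1])
        assert np.all(dos[:, 0] == dos[:, 2])

    def test_determinism_and_seed_sensitivity(self, small_map):
        donor = np.ones(small_map.n_snps, dtype=np.uint8)
        rec = np.zeros_like(donor)
        a = nm.simulate_bc1s3_family(donor, rec, 10, small_map, seed=1)
        b = nm.simulate_bc1s3_family(donor, rec, 10, small_map, seed=1)
        c = nm.simulate_bc1s3_family(donor, rec, 10, small_map, seed=2)
        assert np.array_equal(a.origins, b.origins)
        assert not np.array_equal(a.origins, c.origins)

    def test_rejects_bad_inputs(self, small_map):
        donor = np.ones(small_map.n_snps, dtype=np.uint8)
        with pytest.raises(ValueError):
            nm.simulate_bc1s3_family(donor, np.zeros(3), 10, small_map)
        with pytest.raises(ValueError):
            nm.simulate_bc1s3_family(donor, np.zeros_like(donor), 0, small_map)


class TestPhenotypes:
    def test_empty_qtl_pure_noise(self, medium_study):
        qtl = nm.QTLSpec(effects={}, h2_target=0.0)
        table, truth = nm.simulate_phenotypes(medium_study["pop"], qtl, seed=1)
        assert truth.genetic_values.var() == 0.0
        assert truth.realized_h2 == 0.0
        assert table.iloc[:, 0].std() > 0

    def test_h2_one_is_affine_in_causal_snp(self, medium_study):
        snp = medium_study["qtl_snp"]
        qtl = nm.QTLSpec(effects={snp: 2.0}, h2_target=1.0)
        table, _ = nm.simulate_phenotypes(medium_study["pop"], qtl, seed=1)
        dosage = medium_study["pop"].dosage_frame()[snp]
        resid = table.iloc[:, 0] - 2.0 * dosage
        assert np.allclose(resid, resid.iloc[0])

    def test_ols_recovers_planted_slope(self, small_map):
        pop = nm.simulate_nam(15, 100, small_map, seed=21)
        snp = small_map.snp_ids[100]
        qtl = nm.QTLSpec(effects={snp: 1.0}, h2_target=0.5)
        table, _ = nm.simulate_phenotypes(pop, qtl, seed=22)
        x = pop.dosage_frame()[snp].to_numpy(dtype=float)
        y = table.iloc[:, 0].to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert abs(slope - 1.0) < 0.1

    def test_rejects_zero_genetic_variance(self, medium_study):
        pop = medium_study["pop"]
        # donor allele absent in every family at no SNP is unlikely; force it
        qtl = nm.QTLSpec(effects={}, h2_target=0.5)
        with pytest.raises(ValueError):
            nm.simulate_phenotypes(pop, qtl, seed=1)

    def test_realized_h2_close_to_target_large_n(self, small_map):
        pop = nm.simulate_nam(25, 52, small_map, seed=30)
        snps = small_map.snp_ids[[10, 150, 250]]
        qtl = nm.QTLSpec(effects={s: 1.0 for s in snps}, h2_target=0.4)
        _, truth = nm.simulate_phenotypes(pop, qtl, seed=31)
        assert abs(truth.realized_h2 - 0.4) <= 0.05

    def test_exp_link_positive_and_skewed(self, medium_study):
        snp = medium_study["qtl_snp"]
        qtl = nm.QTLSpec(effects={snp: 1.0}, h2_target=0.5, link="exp")
        table, _ = nm.simulate_phenotypes(medium_study["pop"], qtl, seed=5)
        vals = table.iloc[:, 0]
        assert (vals > 0).all()
        assert vals.skew() > 0.5


class TestMissingnessAndControls:
    def test_zero_rate_identity(self, medium_study):
        out, _ = nm.inject_missingness_and_controls(
            medium_study["pheno"], missing_rate=0.0, seed=1
        )
        pd.testing.assert_frame_equal(out, medium_study["pheno"])

    def test_missing_count_binomial(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(100, 50)))
        out, _ = nm.inject_missingness_and_controls(table, missing_rate=0.05, seed=2)
        n_missing = int(out.isna().sum().sum())
        assert abs(n_missing - 250) <= 45  # 3 binomial SDs

    def test_zero_within_variance_gives_identical_replicates(self):
        table = pd.DataFrame({"m": np.random.default_rng(1).normal(10, 2, 50)})
        _, controls = nm.inject_missingness_and_controls(
            table, 0.0, n_controls=17, reps_per_control=4, seed=3,
            between_sd=1.0, within_sd=0.0,
        )
        assert len(controls) == 17 * 4
        assert (controls.groupby("control_id")["m"].nunique() == 1).all()

    def test_rejects_bad_rate(self, medium_study):
        with pytest.raises(ValueError):
            nm.inject_missingness_and_controls(medium_study["pheno"], 1.0)
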