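"""mQTL grouping, explained variance, family effects and report bundle."""

import json

import numpy as np
import pandas as pd
import pytest

import nam_mqtl as nm
from nam_mqtl.gwas import RunModel


def _det(gmap, dr_by_snp):
    det = pd.DataFrame(
        {"DR": [dr_by_snp.get(s, 0) for s in gmap.snp_ids]}, index=gmap.snp_ids
    )
    det["mean_beta"] = 1.0
    det.index.name = "snp_id"
    return det


@pytest.fixture()
def merge_map():
    return nm.GeneticMap(
        pd.DataFrame(
            {
                "snp_id": ["a", "b", "c", "d", "e"],
                "chrom": [1, 1, 1, 2, 2],
                "bp": [14_300_000, 16_000_000, 20_200_000, 1_000_000, 9_500_000],
                "cM": [14.3, 16.0, 20.2, 1.0, 9.5],
            }
        )
    )


class TestGrouping:
    def test_no_significant_snps_empty(self, merge_map):
        regions = nm.group_mqtl(_det(merge_map, {}), merge_map, threshold=25)
        assert regions == []

    def test_gap_merge_single_region(self, merge_map):
        regions = nm.group_mqtl(
            _det(merge_map, {"a": 30, "b": 40, "c": 28}), merge_map, threshold=25
        )
        assert len(regions) == 1
        reg = regions[0]
        assert (reg.start_bp, reg.end_bp) == (14_300_000, 20_200_000)
        assert reg.peak_snp == "b"
        assert reg.snp_ids == ["a", "b", "c"]

    def test_gap_exceeded_two_regions(self, merge_map):
        regions = nm.group_mqtl(
            _det(merge_map, {"d": 30, "e": 30}), merge_map, threshold=25
        )
        assert len(regions) == 2
        assert [r.region_id for r in regions] == ["2H-1", "2H-2"]

    def test_ids_numbered_per_chromosome_with_date_tag(self, merge_map):
        regions = nm.group_mqtl(
            _det(merge_map, {"a": 30, "d": 30, "e": 30}),
            merge_map,
            threshold=25,
            date_tag="2",
        )
        assert [r.region_id for r in regions] == ["1H-1_2", "2H-1_2", "2H-2_2"]

    def test_peak_tie_breaks_on_effect_size(self, merge_map):
        det = _det(merge_map, {"a": 30, "b": 30})
        det.loc["b", "mean_beta"] = -2.5
        regions = nm.group_mqtl(det, merge_map, threshold=25)
        assert regions[0].peak_snp == "b"

    def test_threshold_below_one_rejected(self, merge_map):
        with pytest.raises(ValueError):
            nm.group_mqtl(_det(merge_map, {}), merge_map, threshold=0)


class TestRegionR2:
    def test_exact_linear_phenotype(self, medium_study):
        ibs = medium_study["ibs"]
        snp = medium_study["qtl_snp"]
        reg = nm.MQTLRegion("1H-1", 1, 0, 1, [snp], snp)
        y = 3.0 + 2.0 * ibs.scores[snp]
        assert nm.region_r2(y, reg, ibs) == pytest.approx(1.0)
        assert reg.r_squared == pytest.approx(1.0)

    def test_null_phenotype_low_r2(self, medium_study):
        ibs = medium_study["ibs"]
        snps = list(ibs.scores.columns[:3])
        reg = nm.MQTLRegion("1H-1", 1, 0, 1, snps, snps[0])
        low = 0
        for i in range(20):
            rng = np.random.default_rng(700 + i)
            y = pd.Series(rng.normal(size=len(ibs.scores)), index=ibs.scores.index)
            low += nm.region_r2(y, reg, ibs) <= 0.05
        assert low >= 19

    def test_adding_member_never_decreases_r2(self, medium_study):
        ibs = medium_study["ibs"]
        y = medium_study["pheno"].iloc[:, 0]
        snps = list(ibs.scores.columns[:6])
        r2_small = nm.region_r2(
            y, nm.MQTLRegion("r", 1, 0, 1, snps[:3], snps[0]), ibs
        )
        r2_big = nm.region_r2(y, nm.MQTLRegion("r", 1, 0, 1, snps, snps[0]), ibs)
        assert r2_big >= r2_small - 1e-12

    def test_collinear_members_pruned_not_fatal(self, medium_study):
        ibs = medium_study["ibs"]
        dup = ibs.scores.copy()
        dup["dup_snp"] = dup.iloc[:, 0]
        ibs2 = nm.IBSMatrix(scores=dup, families=ibs.families, imputed=True)
        snps = [dup.columns[0], "dup_snp"]
        reg = nm.MQTLRegion("r", 1, 0, 1, snps, snps[0])
        y = medium_study["pheno"].iloc[:, 0]
        r2 = nm.region_r2(y, reg, ibs2)
        assert 0.0 <= r2 <= 1.0
        assert reg.rank_pruned


class TestFamilyEffects:
    def test_single_snp_region_arithmetic(self, medium_study):
        ibs = medium_study["ibs"]
        snp = medium_study["qtl_snp"]
        seg = nm.family_segregation(ibs, [snp])[snp]
        runs = [
            RunModel(rep=0, fold=f, coefficients={snp: 0.5}, intercept=0.0,
                     r2=1.0, constant_prediction=False)
            for f in range(4)
        ]
        reg = nm.MQTLRegion("1H-1", 1, 0, 1, [snp], snp)
        table = nm.family_effects(runs, [reg], ibs)
        for fam in table.mean.columns:
            expected = 1.0 if seg[fam] else 0.0
            assert table.mean.loc["1H-1", fam] == pytest.approx(expected)

    def test_half_inclusion_halves_mean(self, medium_study):
        ibs = medium_study["ibs"]
        snp = medium_study["qtl_snp"]
        runs = [
            RunModel(0, f, {snp: 1.0} if f < 2 else {}, 0.0, 0.5, False)
            for f in range(4)
        ]
        reg = nm.MQTLRegion("1H-1", 1, 0, 1, [snp], snp)
        table = nm.family_effects(runs, [reg], ibs)
        seg = nm.family_segregation(ibs, [snp])[snp]
        seg_fams = [f for f in table.mean.columns if seg[f]]
        assert len(seg_fams) > 0
        for fam in seg_fams:
            assert table.mean.loc["1H-1", fam] == pytest.approx(1.0)

    def test_nonsegregating_families_exactly_zero(self, small_map):
        # family 2's donor carries the reference allele at the QTL SNP
        founders = nm.simulate_founders(3, small_map, 0.5, seed=80)
        snp_j = 10
        founders.donor_alleles[1, snp_j] = 0
        founders.donor_alleles[0, snp_j] = 1
        fams = [
            nm.simulate_bc1s3_family(
                founders.donor_alleles[f], founders.recurrent_parent, 30,
                small_map, seed=81 + f, family_id=f + 1,
            )
            for f in range(3)
        ]
        pop = nm.NAMPopulation(small_map, founders, fams)
        calls = nm.GenotypeCalls(pop.calls_frame(), pop.family_labels)
        ibs = nm.impute_mni(nm.code_ibs(calls, nm.marker_qc(calls)))
        snp = small_map.snp_ids[snp_j]
        assert snp in ibs.scores.columns
        runs = [RunModel(0, 0, {snp: 0.7}, 0.0, 0.5, False)]
        reg = nm.MQTLRegion("r", 1, 0, 1, [snp], snp)
        table = nm.family_effects(runs, [reg], ibs)
        assert table.mean.loc["r", 2] == 0.0
        assert table.mean.loc["r", 1] != 0.0

    def test_never_selected_snp_warns(self, medium_study):
        ibs = medium_study["ibs"]
        snp = medium_study["qtl_snp"]
        reg = nm.MQTLRegion("r", 1, 0, 1, [snp], snp)
        runs = [RunModel(0, 0, {}, 0.0, 0.0, True)]
        with pytest.warns(UserWarning):
            nm.family_effects(runs, [reg], ibs)

    def test_opposite_family_private_effects_recovered(self, small_map):
        """A region whose wild alleles act in opposite directions in two
        families (via family-private QTL SNPs) yields cumulated family
        effects of opposite sign."""
        signs = []
        for i in range(6):
            founders = nm.simulate_founders(2, small_map, 0.5, seed=900 + i)
            j1, j2 = 60, 62  # adjacent SNPs, ~2.4 cM apart on chromosome 1
            founders.donor_alleles[0, j1] = 1
            founders.donor_alleles[1, j1] = 0
            founders.donor_alleles[0, j2] = 0
            founders.donor_alleles[1, j2] = 1
            fams = [
                nm.simulate_bc1s3_family(
                    founders.donor_alleles[f], founders.recurrent_parent, 130,
                    small_map, seed=910 + 2 * i + f, family_id=f + 1,
                )
                for f in range(2)
            ]
            pop = nm.NAMPopulation(small_map, founders, fams)
            snp1, snp2 = small_map.snp_ids[j1], small_map.snp_ids[j2]
            qtl = nm.QTLSpec(effects={snp1: 1.2, snp2: -1.2}, h2_target=0.7)
            pheno, _ = nm.simulate_phenotypes(pop, qtl, seed=930 + i)
            calls = nm.GenotypeCalls(pop.calls_frame(), pop.family_labels)
            ibs = nm.impute_mni(nm.code_ibs(calls, nm.marker_qc(calls)))
            res = nm.NAMGwas(pheno.iloc[:, 0], ibs, gmap=small_map).fit(
                k=5, n_reps=2, seed=940 + i
            )
            regs = nm.group_mqtl(res.detection_table, small_map, threshold=5)
            table = nm.family_effects(res.runs, regs, ibs)
            hit = [
                r for r in regs if snp1 in r.snp_ids or snp2 in r.snp_ids
            ]
            if not hit:
                signs.append(False)
                continue
            row = sum(table.mean.loc[r.region_id] for r in hit)
            signs.append(bool(row[1] > 0 and row[2] < 0))
        assert np.mean(signs) >= 0.8


class TestReport:
    def test_bundle_round_trip(self, tmp_path, medium_study, small_map):
        ibs = medium_study["ibs"]
        y = medium_study["pheno"].iloc[:, 0]
        res = nm.NAMGwas(y, ibs, gmap=small_map).fit(k=5, n_reps=2, seed=6)
        regs = nm.group_mqtl(res.detection_table, small_map, threshold=5)
        for reg in regs:
            nm.region_r2(y, reg, ibs)
        table = nm.family_effects(res.runs, regs, ibs)
        paths = nm.write_report(
            tmp_path, res.detection_table, 5, regs, table,
            metadata={"seed": 6},
        )
        man = pd.read_csv(paths["manhattan"], sep="\t", index_col=0)
        assert len(man) == ibs.scores.shape[1]
        assert man["significant"].sum() == (res.detection_table["DR"] >= 5).sum()
        summary = pd.read_csv(paths["mqtl_summary"], sep="\t")
        assert len(summary) == len(regs)
        assert set(summary["peak_snp"]) == {r.peak_snp for r in regs}
        fe = pd.read_csv(paths["family_effects"], sep="\t", index_col=0)
        assert np.allclose(fe.to_numpy(), table.mean.to_numpy(), atol=1e-6)
        meta = json.loads(paths["metadata"].read_text())
        assert meta["seed"] == 6 and "config_hash" in meta

    def test_empty_regions_valid_files(self, tmp_path, merge_map):
        det = _det(merge_map, {})
        paths = nm.write_report(tmp_path, det, 25, [])
        summary = pd.read_csv(paths["mqtl_summary"], sep="\t")
        assert summary.empty
        man = pd.read_csv(paths["manhattan"], sep="\t")
        assert not man["significant"].any()
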