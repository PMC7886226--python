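"""mQTL regions, explained variance and family-specific cumulated effects.

Significant SNPs (detection rate at or above the calibrated threshold) are
merged into regions by physical proximity: consecutive significant SNPs on
one chromosome no more than ``gap_bp`` apart (default 5 Mbp) belong to one
mQTL, numbered consecutively per chromosome (barley-style ids like
``1H-2_1``, the suffix tagging the sampling date).  A region's explained
variance is the R^2 of the joint ordinary regression of the phenotype on all
member SNPs over the whole panel.  Family-specific effects use the
cumulation method: within every cross-validation run, sum 2 x beta over the
region's member SNPs that entered that run's final model and segregate in
the family, then average over all runs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from .genotypes import IBSMatrix
from .simulate import GeneticMap

__all__ = [
    "MQTLRegion",
    "FamilyEffectTable",
    "group_mqtl",
    "region_r2",
    "family_segregation",
    "family_effects",
    "write_report",
]

_FLOAT_FMT = "%.6g"


@dataclass
class MQTLRegion:
    """A group of significant SNPs forming one mQTL."""

    region_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    snp_ids: list
    peak_snp: str
    metabolite: str | None = None
    r_squared: float | None = None
    rank_pruned: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def group_mqtl(
    detections: pd.DataFrame,
    gmap: GeneticMap,
    threshold: int,
    gap_bp: int = 5_000_000,
    metabolite: str | None = None,
    date_tag: str | None = None,
) -> list[MQTLRegion]:
    """Merge threshold-exceeding SNPs into positional regions.

    ``detections`` is indexed by snp_id with at least a ``DR`` column
    (``mean_beta`` used for peak tie-breaks when present).  The peak SNP is
    the member with maximal DR; ties break toward the largest absolute mean
    effect, then map order.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    sig = detections[detections["DR"] >= threshold]
    if len(sig) == 0:
        return []
    pos = gmap.table.set_index("snp_id")
    missing = [s for s in sig.index if s not in pos.index]
    if missing:
        raise KeyError(f"significant SNPs absent from map, e.g. {missing[:5]}")
    sig = sig.join(pos[["chrom", "bp"]], how="left", rsuffix="_map")
    chrom_col = "chrom_map" if "chrom_map" in sig.columns else "chrom"
    bp_col = "bp_map" if "bp_map" in sig.columns else "bp"
    regions: list[MQTLRegion] = []
    suffix = f"_{date_tag}" if date_tag is not None else ""
    for chrom, sub in sig.sort_values([chrom_col, bp_col]).groupby(chrom_col):
        bps = sub[bp_col].to_numpy()
        breaks = np.flatnonzero(np.diff(bps) > gap_bp)
        bounds = np.concatenate([[0], breaks + 1, [len(sub)]])
        for i in range(len(bounds) - 1):
            block = sub.iloc[bounds[i] : bounds[i + 1]]
            dr = block["DR"].to_numpy()
            best = dr == dr.max()
            if best.sum() > 1 and "mean_beta" in block.columns:
                mb = np.abs(block["mean_beta"].to_numpy())
                mb = np.where(best, np.nan_to_num(mb), -np.inf)
                peak = block.index[int(np.argmax(mb))]
            else:
                peak = block.index[int(np.argmax(dr))]
            regions.append(
                MQTLRegion(
                    region_id=f"{int(chrom)}H-{i + 1}{suffix}",
                    chromosome=int(chrom),
                    start_bp=int(block[bp_col].min()),
                    end_bp=int(block[bp_col].max()),
                    snp_ids=list(block.index),
                    peak_snp=str(peak),
                    metabolite=metabolite,
                )
            )
    return regions


def _prune_collinear(x: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a full-rank column subset (greedy, in column order)."""
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * (diag[0] if diag.size and diag[0] > 0 else 1.0)))
    return np.sort(piv[:rank])


def region_r2(y, region: MQTLRegion, ibs: IBSMatrix) -> float:
    """Explained variance: joint OLS of y on all member SNPs, whole panel."""
    missing = [s for s in region.snp_ids if s not in ibs.scores.columns]
    if missing:
        raise KeyError(f"region SNPs absent from IBS matrix: {missing[:5]}")
    x = ibs.scores[region.snp_ids].to_numpy(dtype=float)
    yv = np.asarray(y.to_numpy() if hasattr(y, "to_numpy") else y, dtype=float)
    xc = x - x.mean(axis=0)
    keep = _prune_collinear(xc)
    if len(keep) < x.shape[1]:
        region.rank_pruned = True
    fit = sm.OLS(yv, sm.add_constant(x[:, keep])).fit()
    r2 = float(fit.rsquared)
    region.r_squared = r2
    return r2


def family_segregation(ibs: IBSMatrix, snp_ids) -> pd.DataFrame:
    """family x SNP boolean table: does the SNP segregate within the family?

    Segregating means the within-family scores take at least two distinct
    values after family-wise recoding; computed on the pre-imputation
    states so fractional imputed scores do not create spurious segregation.
    """
    source = ibs.states if ibs.states is not None else ibs.scores
    sub = source[list(snp_ids)]
    nuniq = sub.groupby(ibs.families, observed=True).nunique(dropna=True)
    return nuniq >= 2


@dataclass
class FamilyEffectTable:
    """Cumulated mQTL effects per region x family (mean over CV runs)."""

    mean: pd.DataFrame  # regions x families
    per_run: np.ndarray = field(repr=False)  # (n_runs, n_regions, n_families)
    n_runs: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = self.mean.copy()
        out.index.name = "mqtl"
        out.columns = [f"family_{f}" for f in out.columns]
        return out


def family_effects(
    runs,
    regions: list,
    ibs: IBSMatrix,
) -> FamilyEffectTable:
    """Cumulation method for family-specific mQTL effects.

    For each cross-validation run and family: sum ``2 * beta`` over the
    region's member SNPs that (a) entered that run's final model and (b)
    segregate within the family (the homozygous-wild vs elite contrast
    spans two IBS units).  The reported effect is the mean over *all* runs;
    families where no member SNP segregates are exactly 0 by construction.
    """
    fam_levels = list(pd.unique(ibs.families))
    all_snps = sorted({s for reg in regions for s in reg.snp_ids})
    n_runs = len(runs)
    if all_snps:
        seg = family_segregation(ibs, all_snps)  # families x snps
    else:
        seg = pd.DataFrame(index=fam_levels)
    seen = {s for run in runs for s in run.coefficients}
    seg_vec = {
        s: seg[s].reindex(fam_levels).fillna(False).to_numpy(dtype=bool)
        for s in all_snps
    }
    per_run = np.zeros((n_runs, len(regions), len(fam_levels)))
    for ir, reg in enumerate(regions):
        never = [s for s in reg.snp_ids if s not in seen]
        if never and n_runs > 0:
            warnings.warn(
                f"region {reg.region_id}: SNPs never selected in any run "
                f"contribute 0: {never[:5]}"
            )
        for it, run in enumerate(runs):
            for s in reg.snp_ids:
                b = run.coefficients.get(s)
                if b is None:
                    continue
                per_run[it, ir, :] += np.where(seg_vec[s], 2.0 * b, 0.0)
    mean = pd.DataFrame(
        per_run.mean(axis=0) if n_runs else np.zeros((len(regions), len(fam_levels))),
        index=[reg.region_id for reg in regions],
        columns=fam_levels,
    )
    return FamilyEffectTable(mean=mean, per_run=per_run, n_runs=n_runs)


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

def _config_hash(metadata: dict) -> str:
    blob = json.dumps(metadata, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(
    out_dir,
    detections: pd.DataFrame,
    threshold: int,
    regions: list,
    family_effect_table: FamilyEffectTable | None = None,
    h2_table: pd.DataFrame | None = None,
    metadata: dict | None = None,
) -> dict:
    """Write the tabular report bundle (deterministic formatting).

    Files: ``manhattan.tsv`` (per-SNP DR with significance flag),
    ``mqtl_summary.tsv`` (one row per region), ``family_effects.tsv``,
    optional ``h2.tsv``, and ``run_metadata.json`` (config + hash).
    Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    man = detections.copy()
    man["significant"] = man["DR"] >= threshold
    man.index.name = "snp_id"
    paths["manhattan"] = out / "manhattan.tsv"
    man.to_csv(paths["manhattan"], sep="\t", na_rep="NA", float_format=_FLOAT_FMT)

    rows = []
    for reg in regions:
        rows.append(
            {
                "mqtl": reg.region_id,
                "metabolite": reg.metabolite if reg.metabolite is not None else "NA",
                "chrom": reg.chromosome,
                "start_bp": reg.start_bp,
                "end_bp": reg.end_bp,
                "n_snps": reg.n_snps,
                "peak_snp": reg.peak_snp,
                "r_squared": reg.r_squared if reg.r_squared is not None else np.nan,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "mqtl", "metabolite", "chrom", "start_bp", "end_bp",
            "n_snps", "peak_snp", "r_squared",
        ],
    )
    paths["mqtl_summary"] = out / "mqtl_summary.tsv"
    summary.to_csv(
        paths["mqtl_summary"], sep="\t", index=False, na_rep="NA",
        float_format=_FLOAT_FMT,
    )

    paths["family_effects"] = out / "family_effects.tsv"
    if family_effect_table is not None:
        family_effect_table.to_frame().to_csv(
            paths["family_effects"], sep="\t", na_rep="NA", float_format=_FLOAT_FMT
        )
    else:
        pd.DataFrame(columns=["mqtl"]).to_csv(
            paths["family_effects"], sep="\t", index=False
        )

    if h2_table is not None:
        paths["h2"] = out / "h2.tsv"
        h2_table.to_csv(paths["h2"], sep="\t", na_rep="NA", float_format=_FLOAT_FMT)

    meta = dict(metadata or {})
    meta["threshold"] = int(threshold)
    meta["config_hash"] = _config_hash(meta)
    paths["metadata"] = out / "run_metadata.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
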