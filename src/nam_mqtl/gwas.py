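"""Cross-validated stepwise GWAS with detection rates and permutation threshold.

The mapping engine runs family-stratified k-fold cross-validation (default
5 folds x 20 repetitions = 100 runs).  In each run the stepwise selector is
fitted on the training 4/5 of lines; the held-out fold is predicted from the
final model and prediction ability r^2 (squared Pearson correlation between
observed and predicted values) recorded.  A SNP's detection rate (DR) is the
number of runs whose final model included it; significance of a DR is
calibrated by permutation — the full cross-validation procedure repeated on
shuffled genotype-phenotype matrices — taking the 99.99th percentile of the
pooled null DR distribution as threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import IBSMatrix
from .simulate import GeneticMap
from .stepwise import StepwiseRegression

__all__ = [
    "FoldPlan",
    "make_folds",
    "prediction_ability",
    "RunModel",
    "NAMGwas",
    "NAMGwasResults",
    "ThresholdEstimate",
    "dr_threshold_from_pool",
    "permutation_threshold",
]


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Family-stratified fold assignments per repetition."""

    assignment: np.ndarray  # (n_reps, n_lines) int8 fold index in 0..k-1
    k: int
    seed: int
    line_ids: tuple
    families: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.assignment.shape[0]

    @property
    def n_runs(self) -> int:
        return self.n_reps * self.k


def make_folds(families, k: int = 5, n_reps: int = 20, seed: int = 0) -> FoldPlan:
    """Deal each family's lines into k folds, shuffled per repetition.

    Within every family and repetition the shuffled lines are dealt
    cyclically, so fold sizes differ by at most one.  Families smaller than
    k are still dealt round-robin (some folds then lack lines of that
    family) with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    fam = pd.Series(families)
    line_ids = tuple(fam.index)
    fam_arr = fam.to_numpy()
    n = len(fam)
    rng = np.random.default_rng(seed)
    small = sorted({f for f, c in fam.value_counts().items() if c < k})
    if small:
        warnings.warn(f"families with fewer than {k} lines dealt round-robin: {small}")
    assignment = np.empty((n_reps, n), dtype=np.int8)
    fam_indices = [np.flatnonzero(fam_arr == f) for f in pd.unique(fam_arr)]
    for rep in range(n_reps):
        for idx in fam_indices:
            perm = rng.permutation(idx)
            assignment[rep, perm] = np.arange(len(idx)) % k
    return FoldPlan(
        assignment=assignment,
        k=k,
        seed=seed,
        line_ids=line_ids,
        families=fam_arr,
    )


def prediction_ability(observed, predicted) -> float:
    """Squared Pearson correlation of observed vs predicted validation data.

    Defined as 0 when the predictions (or observations) are constant — the
    empty-model convention.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed/predicted length mismatch")
    if obs.size < 3:
        raise ValueError("need at least 3 validation pairs")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return 0.0
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# cross-validated GWAS
# ---------------------------------------------------------------------------

@dataclass
class RunModel:
    """One cross-validation run's final model."""

    rep: int
    fold: int
    coefficients: dict  # snp_id -> allele-substitution effect
    intercept: float
    r2: float
    constant_prediction: bool


@dataclass
class NAMGwasResults:
    """Detection table, per-run models and prediction abilities."""

    model: "NAMGwas" = field(repr=False)
    detection_table: pd.DataFrame
    runs: list  # list[RunModel]
    n_runs: int
    k: int
    n_reps: int
    seed: int

    @property
    def pred_abilities(self) -> np.ndarray:
        return np.array([r.r2 for r in self.runs])

    @property
    def mean_r2(self) -> float:
        return float(self.pred_abilities.mean())

    def significant(self, threshold: int) -> pd.DataFrame:
        return self.detection_table[self.detection_table["DR"] >= threshold]

    def summary(self, threshold: int | None = None) -> str:
        det = self.detection_table
        lines = [
            "Cross-validated stepwise GWAS",
            "=" * 52,
            f"{self.k}-fold x {self.n_reps} reps = {self.n_runs} runs   "
            f"SNPs: {len(det)}   lines: {len(self.model.endog)}",
            f"mean prediction ability r2: {self.mean_r2:.4f}",
            f"max detection rate: {int(det['DR'].max())}",
        ]
        if threshold is not None:
            lines.append(
                f"SNPs with DR >= {threshold}: {int((det['DR'] >= threshold).sum())}"
            )
        top = det.sort_values("DR", ascending=False).head(5)
        lines.append("-" * 52)
        lines.append(f"{'snp':<16}{'DR':>5}{'mean_beta':>12}")
        for snp, row in top.iterrows():
            mb = row["mean_beta"]
            mb_s = f"{mb:.4f}" if np.isfinite(mb) else "--"
            lines.append(f"{snp:<16}{int(row['DR']):>5}{mb_s:>12}")
        return "\n".join(lines)


class NAMGwas:
    """Cross-validated stepwise association model for one metabolite.

    Parameters
    ----------
    endog : pd.Series or array
        Transformed metabolite values aligned to the IBS matrix lines.
    ibs : IBSMatrix
        Imputed quantitative IBS genotype matrix (the design matrix).
    gmap : GeneticMap, optional
        When given, candidate columns are ordered by (chromosome, bp) so
        p-value ties break in map order, and the detection table carries
        positions.
    """

    def __init__(
        self,
        endog,
        ibs: IBSMatrix,
        gmap: GeneticMap | None = None,
        p_enter: float = 0.001,
        p_remove: float = 0.001,
        max_terms: int | None = None,
    ):
        scores = ibs.scores
        if gmap is not None:
            order = [s for s in gmap.snp_ids if s in scores.columns]
            scores = scores[order]
        y = endog.reindex(scores.index) if isinstance(endog, pd.Series) else pd.Series(
            np.asarray(endog, dtype=float), index=scores.index
        )
        if y.isna().any():
            raise ValueError("phenotype missing for some genotyped lines")
        if scores.isna().any().any():
            raise ValueError("IBS matrix must be imputed before GWAS")
        self.endog = y
        self.exog = scores
        self.families = ibs.families.reindex(scores.index)
        self.gmap = gmap
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.max_terms = max_terms

    def fit(
        self,
        k: int = 5,
        n_reps: int = 20,
        seed: int = 0,
        plan: FoldPlan | None = None,
    ) -> NAMGwasResults:
        if plan is None:
            plan = make_folds(self.families, k=k, n_reps=n_reps, seed=seed)
        x = self.exog.to_numpy(dtype=float)
        y = self.endog.to_numpy(dtype=float)
        snp_ids = list(self.exog.columns)
        n_snps = len(snp_ids)
        col_of = {s: j for j, s in enumerate(snp_ids)}
        dr = np.zeros(n_snps, dtype=int)
        beta_sum = np.zeros(n_snps)
        runs: list[RunModel] = []
        for rep in range(plan.n_reps):
            for fold in range(plan.k):
                val = plan.assignment[rep] == fold
                train = ~val
                res = StepwiseRegression(
                    y[train],
                    x[train],
                    var_names=snp_ids,
                    p_enter=self.p_enter,
                    p_remove=self.p_remove,
                    max_terms=self.max_terms,
                ).fit()
                pred = res.predict(x[val])
                constant = res.n_terms == 0 or np.ptp(pred) == 0
                r2 = prediction_ability(y[val], pred)
                coefs = {}
                for name in res.selected:
                    j = col_of[name]
                    b = float(res.params[name])
                    dr[j] += 1
                    beta_sum[j] += b
                    coefs[name] = b
                runs.append(
                    RunModel(
                        rep=rep,
                        fold=fold,
                        coefficients=coefs,
                        intercept=float(res.params.iloc[0]),
                        r2=r2,
                        constant_prediction=constant,
                    )
                )
        with np.errstate(invalid="ignore"):
            mean_beta = np.where(dr > 0, beta_sum / np.maximum(dr, 1), np.nan)
        det = pd.DataFrame(
            {"DR": dr, "mean_beta": mean_beta, "n_included": dr}, index=snp_ids
        )
        det.index.name = "snp_id"
        if self.gmap is not None:
            pos = self.gmap.table.set_index("snp_id").loc[snp_ids]
            det.insert(0, "chrom", pos["chrom"].to_numpy())
            det.insert(1, "bp", pos["bp"].to_numpy())
            det.insert(2, "cM", pos["cM"].to_numpy())
        return NAMGwasResults(
            model=self,
            detection_table=det,
            runs=runs,
            n_runs=plan.n_runs,
            k=plan.k,
            n_reps=plan.n_reps,
            seed=plan.seed,
        )


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

@dataclass
class ThresholdEstimate:
    """Detection-rate significance threshold from permuted matrices."""

    threshold: int
    percentile: float
    n_shuffles: int
    n_runs: int
    n_pooled: int
    pool_max: int
    pool_mean: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "percentile": self.percentile,
            "n_shuffles": self.n_shuffles,
            "n_runs": self.n_runs,
            "n_pooled": self.n_pooled,
            "pool_max": self.pool_max,
            "pool_mean": self.pool_mean,
        }


def dr_threshold_from_pool(
    pool, percentile: float = 99.99, n_runs: int = 100
) -> int:
    """Smallest integer t such that >= percentile% of pooled DRs are < t.

    With an all-zero pool this yields 1 (every null DR is below 1); raising
    the percentile can only raise the threshold.
    """
    pool = np.sort(np.asarray(pool))
    if pool.size == 0:
        raise ValueError("empty DR pool")
    q = percentile / 100.0
    n = pool.size
    for t in range(0, n_runs + 2):
        if np.searchsorted(pool, t, side="left") / n >= q:
            return t
    return n_runs + 1  # pragma: no cover


def permutation_threshold(
    phenotypes: pd.DataFrame,
    ibs: IBSMatrix,
    gmap: GeneticMap | None = None,
    n_shuffles: int = 3,
    k: int = 5,
    n_reps: int = 20,
    percentile: float = 99.99,
    seed: int = 0,
    p_enter: float = 0.001,
    p_remove: float = 0.001,
    max_terms: int | None = None,
) -> ThresholdEstimate:
    """Calibrate the DR significance threshold on shuffled matrices.

    Each shuffle permutes the phenotype rows as whole records relative to
    the genotypes (preserving inter-metabolite correlation), then the full
    cross-validation procedure runs for every metabolite; per-SNP DR values
    are pooled over metabolites and shuffles and the threshold is read off
    the stated percentile of the pooled null distribution.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if isinstance(phenotypes, pd.Series):
        phenotypes = phenotypes.to_frame()
    phenotypes = phenotypes.reindex(ibs.scores.index)
    rng = np.random.default_rng(seed)
    pools = []
    n = len(phenotypes)
    for _s in range(n_shuffles):
        perm = rng.permutation(n)
        shuffled = pd.DataFrame(
            phenotypes.to_numpy()[perm], index=phenotypes.index,
            columns=phenotypes.columns,
        )
        for col in shuffled.columns:
            fit_seed = int(rng.integers(0, 2**31 - 1))
            res = NAMGwas(
                shuffled[col],
                ibs,
                gmap=gmap,
                p_enter=p_enter,
                p_remove=p_remove,
                max_terms=max_terms,
            ).fit(k=k, n_reps=n_reps, seed=fit_seed)
            pools.append(res.detection_table["DR"].to_numpy())
    pool = np.concatenate(pools)
    n_runs = k * n_reps
    thr = dr_threshold_from_pool(pool, percentile=percentile, n_runs=n_runs)
    return ThresholdEstimate(
        threshold=int(thr),
        percentile=percentile,
        n_shuffles=n_shuffles,
        n_runs=n_runs,
        n_pooled=int(pool.size),
        pool_max=int(pool.max()),
        pool_mean=float(pool.mean()),
    )
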