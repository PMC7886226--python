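"""Marker QC, quantitative IBS coding and mean (MNI) imputation.

Genotype calls are held lines x SNPs with codes 0 = homozygous recurrent
(elite) allele, 1 = heterozygous, 2 = homozygous donor (wild) allele and NaN
for a failed call.  QC keeps markers that are polymorphic in at least one
family, have a failure rate strictly below 10% and a heterozygous-call rate
strictly below 12.5% (the BC1S3 expectation being 6.25%).  IBS coding maps
the retained calls to quantitative 0/1/2 scores and recodes any family that
is monomorphic at a SNP to 0 for that SNP — a within-family invariant allele
is indistinguishable from the recurrent-parent state for mapping purposes.
Missing scores are then replaced by the marker's mean score (MNI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCalls",
    "IBSMatrix",
    "marker_qc",
    "code_ibs",
    "impute_mni",
]

_TSV_CODES = {"A": 0.0, "H": 1.0, "B": 2.0, "NA": np.nan}


@dataclass
class GenotypeCalls:
    """Raw call matrix (lines x SNPs, values 0/1/2/NaN) with family labels."""

    calls: pd.DataFrame
    families: pd.Series

    def __post_init__(self) -> None:
        if self.calls.shape[0] == 0 or self.calls.shape[1] == 0:
            raise ValueError("empty genotype call matrix")
        self.families = self.families.reindex(self.calls.index)
        if self.families.isna().any():
            missing = self.families.index[self.families.isna()].tolist()[:5]
            raise ValueError(f"lines without family label, e.g. {missing}")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.unique(vals[~ok])[:5]
            raise ValueError(f"call codes outside {{0,1,2,NaN}}: {bad}")

    @classmethod
    def from_tsv(cls, calls_path, families_path=None) -> "GenotypeCalls":
        """Read a TSV of A/H/B/NA codes (or numeric 0/1/2) with a ``family``
        column or a separate two-column line/family table."""
        df = pd.read_csv(calls_path, sep="\t", index_col=0, dtype=str)
        if families_path is not None:
            fam = pd.read_csv(families_path, sep="\t", index_col=0).iloc[:, 0]
        elif "family" in df.columns:
            fam = df.pop("family").astype(int)
        else:
            raise ValueError("no family labels provided")
        calls = df.replace(_TSV_CODES).apply(pd.to_numeric, errors="coerce")
        return cls(calls=calls, families=fam.astype(int))


@dataclass
class IBSMatrix:
    """Quantitative identity-by-state scores with family labels.

    ``scores`` hold 0/1/2 (plus NaN pre-imputation, reals in [0, 2] after
    MNI).  ``states`` preserves the pre-imputation integer states, which the
    dominance kernel and family-segregation tests rely on.  ``recoded``
    flags (family, SNP) cells that the monomorphic-family rule set to 0.
    """

    scores: pd.DataFrame
    families: pd.Series
    states: pd.DataFrame | None = None
    imputed: bool = False
    recoded: pd.DataFrame | None = None

    @property
    def snp_ids(self) -> np.ndarray:
        return self.scores.columns.to_numpy()

    @property
    def line_ids(self) -> np.ndarray:
        return self.scores.index.to_numpy()

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.insert(0, "family", self.families)
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "IBSMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        fam = df.pop("family").astype(int)
        imputed = not df.isna().any().any()
        states = df.where(df.isin([0.0, 1.0, 2.0])) if imputed else df
        return cls(scores=df, families=fam, states=states, imputed=imputed)


def marker_qc(
    calls: GenotypeCalls,
    fail_max: float = 0.10,
    het_max: float = 0.125,
) -> pd.DataFrame:
    """Per-SNP quality report with the three retention rules.

    A SNP passes iff it is polymorphic (>= 2 distinct non-missing call
    states) in at least one family, its failure rate over all lines is
    strictly below ``fail_max`` and its heterozygous rate among non-missing
    calls is strictly below ``het_max``.
    """
    df = calls.calls
    vals = df.to_numpy(dtype=float)
    n_lines = vals.shape[0]
    n_called = np.sum(~np.isnan(vals), axis=0)
    failure_rate = np.sum(np.isnan(vals), axis=0) / n_lines
    with np.errstate(invalid="ignore"):
        het_rate = np.where(
            n_called > 0, np.sum(vals == 1.0, axis=0) / np.maximum(n_called, 1), 0.0
        )
    nuniq = df.groupby(calls.families, observed=True).nunique(dropna=True)
    polymorphic = (nuniq >= 2).any(axis=0).to_numpy()
    passed = polymorphic & (failure_rate < fail_max) & (het_rate < het_max)
    return pd.DataFrame(
        {
            "polymorphic_in_any_family": polymorphic,
            "failure_rate": failure_rate,
            "het_rate": het_rate,
            "passed": passed,
        },
        index=df.columns,
    )


def code_ibs(
    calls: GenotypeCalls,
    qc: pd.DataFrame | None = None,
    recode_monomorphic: bool = True,
) -> IBSMatrix:
    """Quantitative IBS coding of QC-passing SNPs.

    Calls map directly to scores (hom recurrent -> 0, het -> 1, hom donor
    -> 2, missing stays missing).  Then any family monomorphic at a SNP
    (on its non-missing calls; an all-missing family counts as monomorphic)
    has all of its lines set to 0 at that SNP.  The rule is applied for any
    within-family monomorphism, not only the all-recurrent state: an allele
    that does not segregate within a family carries no mapping information
    there, so its state is treated as not different from the elite allele.
    """
    if qc is not None:
        missing = [s for s in calls.calls.columns if s not in qc.index]
        if missing:
            raise KeyError(f"SNPs absent from QC report, e.g. {missing[:5]}")
        keep = qc.index[qc["passed"]].intersection(calls.calls.columns)
        df = calls.calls[keep].astype(float)
    else:
        df = calls.calls.astype(float)
    fam = calls.families
    recoded = pd.DataFrame(False, index=df.index, columns=df.columns)
    if recode_monomorphic and df.shape[1] > 0:
        nuniq = df.groupby(fam, observed=True).nunique(dropna=True)  # fam x snp
        mono = (nuniq <= 1).to_numpy()  # all-missing family -> 0 distinct -> mono
        fam_codes = pd.Categorical(fam, categories=nuniq.index).codes
        mono_cells = mono[fam_codes, :]  # line x snp
        vals = df.to_numpy()
        vals[mono_cells] = 0.0
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
        recoded = pd.DataFrame(mono_cells, index=df.index, columns=df.columns)
    return IBSMatrix(
        scores=df,
        families=fam,
        states=df.copy(),
        imputed=not df.isna().any().any(),
        recoded=recoded,
    )


def impute_mni(ibs: IBSMatrix, per_family: bool = False) -> IBSMatrix:
    """Mean imputation: each missing score becomes its marker's mean score.

    The population-wide column mean is the default; ``per_family=True``
    substitutes family-wise column means (falling back to the population
    mean for an all-missing family cell).
    """
    df = ibs.scores
    all_missing = df.columns[df.isna().all(axis=0)]
    if len(all_missing) > 0:
        raise ValueError(
            f"SNPs with no non-missing scores cannot be imputed: "
            f"{list(all_missing[:5])}"
        )
    if per_family:
        filled = df.groupby(ibs.families, observed=True, group_keys=False).apply(
            lambda g: g.fillna(g.mean())
        )
        filled = filled.reindex(df.index).fillna(df.mean())
    else:
        filled = df.fillna(df.mean())
    return replace(ibs, scores=filled, states=ibs.states, imputed=True)
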