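"""Metabolite table preparation and descriptive statistics.

The pipeline mirrors standard metabolomics pre-processing for QTL mapping:
metabolites with more than 10% missing values are dropped, remaining missing
values are replaced with the metabolite's minimum observed value, and each
metabolite is Box-Cox power-transformed with lambda chosen by profile
log-likelihood over the grid -3, -2.75, ..., 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BOXCOX_GRID",
    "BoxCoxResult",
    "CorrelationMatrix",
    "filter_metabolites",
    "impute_min",
    "boxcox_transform",
    "transform_table",
    "descriptive_stats",
    "correlations",
]

BOXCOX_GRID = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.25), 2)


def filter_metabolites(
    table: pd.DataFrame, max_missing: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop metabolite columns with missing fraction strictly above the cut.

    A column at exactly the cut (e.g. 10%) is retained.  Returns the filtered
    table and a per-metabolite report (missing fraction, kept flag).
    """
    frac = table.isna().mean(axis=0)
    keep = frac <= max_missing
    report = pd.DataFrame({"missing_fraction": frac, "kept": keep})
    out = table.loc[:, keep[keep].index]
    if out.shape[1] == 0:
        import warnings

        warnings.warn("all metabolite columns dropped by missingness filter")
    return out, report


def impute_min(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with the column's minimum observed value."""
    empty = table.columns[table.isna().all(axis=0)]
    if len(empty) > 0:
        raise ValueError(
            f"fully missing metabolite columns (filter first): {list(empty[:5])}"
        )
    return table.fillna(table.min())


@dataclass
class BoxCoxResult:
    """Chosen lambda, any positivity shift, and the transformed values."""

    name: str
    lam: float
    shift: float
    transformed: np.ndarray
    llf_grid: pd.Series  # profile log-likelihood per grid lambda

    def __post_init__(self) -> None:
        assert np.isclose(self.llf_grid.max(), self.llf_grid[self.lam])


def boxcox_transform(
    values,
    grid=None,
    shift: str | float = "auto",
    name: str = "metabolite",
    min_n: int = 10,
) -> BoxCoxResult:
    """Box-Cox power transform with lambda chosen on a fixed grid.

    For each grid lambda the standard Box-Cox profile log-likelihood is
    evaluated; the maximiser is applied as ``y(lam) = (y**lam - 1)/lam``
    (``log y`` at lambda 0).  Exact likelihood ties on the grid break toward
    the lambda closest to 1 (least distortion).  Non-positive inputs are
    shifted by ``1 - min(values)`` when ``shift="auto"``.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values present; impute before transforming")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    applied_shift = 0.0
    if x.min() <= 0:
        if shift == "auto":
            applied_shift = 1.0 - float(x.min())
        elif isinstance(shift, (int, float)):
            applied_shift = float(shift)
        else:
            raise ValueError("non-positive values with shifting disabled")
        x = x + applied_shift
        if x.min() <= 0:
            raise ValueError("values remain non-positive after shift")
    if np.ptp(x) == 0:
        raise ValueError("constant input: Box-Cox likelihood undefined")
    lams = BOXCOX_GRID if grid is None else np.asarray(grid, dtype=float)
    llf = np.array([stats.boxcox_llf(l, x) for l in lams])
    best = llf.max()
    tied = np.flatnonzero(np.isclose(llf, best, rtol=0.0, atol=1e-9))
    lam = float(lams[tied[np.argmin(np.abs(lams[tied] - 1.0))]])
    transformed = stats.boxcox(x, lmbda=lam)
    return BoxCoxResult(
        name=name,
        lam=lam,
        shift=applied_shift,
        transformed=transformed,
        llf_grid=pd.Series(llf, index=lams),
    )


def transform_table(
    table: pd.DataFrame, grid=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Box-Cox transform every metabolite column of an imputed table.

    Returns the transformed table and a report (lambda, shift) per
    metabolite.
    """
    cols, report = {}, []
    for col in table.columns:
        res = boxcox_transform(table[col].to_numpy(), grid=grid, name=str(col))
        cols[col] = res.transformed
        report.append({"metabolite": col, "lambda": res.lam, "shift": res.shift})
    out = pd.DataFrame(cols, index=table.index)
    return out, pd.DataFrame(report).set_index("metabolite")


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite moments: n, mean, sd, min, max, skew, excess kurtosis.

    Constant columns get skew/kurtosis 0 with ``degenerate=True``.
    """
    rows = []
    for col in table.columns:
        x = table[col].dropna()
        sd = float(x.std())
        degenerate = (len(x) < 3) or sd == 0.0 or not np.isfinite(sd)
        rows.append(
            {
                "metabolite": col,
                "n": int(len(x)),
                "mean": float(x.mean()),
                "sd": sd if np.isfinite(sd) else 0.0,
                "min": float(x.min()) if len(x) else np.nan,
                "max": float(x.max()) if len(x) else np.nan,
                "skew": 0.0 if degenerate else float(stats.skew(x, bias=False)),
                "kurtosis": 0.0
                if degenerate
                else float(stats.kurtosis(x, bias=False)),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("metabolite")


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 1e-4:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        return self.p.map(_stars)


def correlations(
    table_a: pd.DataFrame, table_b: pd.DataFrame | None = None, min_n: int = 3
) -> CorrelationMatrix:
    """Pearson correlations on pairwise-complete shared lines.

    When ``table_b`` is omitted the matrix is symmetric with unit diagonal.
    Pairs with fewer than ``min_n`` complete observations get NaN.
    """
    same = table_b is None
    b = table_a if same else table_b
    shared = table_a.index.intersection(b.index)
    a = table_a.loc[shared]
    b = b.loc[shared]
    r = pd.DataFrame(np.nan, index=a.columns, columns=b.columns)
    p = r.copy()
    n = pd.DataFrame(0, index=a.columns, columns=b.columns)
    for i, ca in enumerate(a.columns):
        for j, cb in enumerate(b.columns):
            if same and j < i:
                continue
            mask = a[ca].notna() & b[cb].notna()
            m = int(mask.sum())
            n.loc[ca, cb] = m
            if m < min_n:
                continue
            xa = a.loc[mask, ca].to_numpy()
            xb = b.loc[mask, cb].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                continue
            rr, pp = stats.pearsonr(xa, xb)
            r.loc[ca, cb] = rr
            p.loc[ca, cb] = pp
            if same:
                r.loc[cb, ca] = rr
                p.loc[cb, ca] = pp
                n.loc[cb, ca] = m
    return CorrelationMatrix(r=r, p=p, n=n)
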