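"""Stepwise forward-backward multiple-SNP regression.

The selector mirrors classical stepwise model selection on marginal F-tests:
at each forward step the candidate whose addition has the smallest marginal
F-test p-value enters if p < p_enter; backward elimination then repeatedly
removes the selected term with the largest marginal p-value (each term tested
given all others in the joint refit) while p >= p_remove.  Iteration stops
when neither direction changes the model or a term cap is reached.

Implementation notes
--------------------
Forward scans are computed by progressive orthogonalisation: candidate
columns and the response are residualised against the current design, so one
scan is a single matrix-vector product over all remaining candidates.  The
marginal F statistic for adding candidate j is F = r^2 (n-k-2) / (1-r^2)
with r the correlation between the current residual and the residualised
candidate — identical to the F-test of the new term in the joint refit.
A rank guard skips candidates whose residual column norm has collapsed
(relative squared norm below ``rank_tol``), so the design stays full rank;
among equal p-values the lowest column index wins (callers order columns by
map position).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StepwiseRegression", "StepwiseResults"]


def _ols_marginal(xs: np.ndarray, yc: np.ndarray):
    """Joint OLS of centred y on centred selected columns.

    Returns (beta, marginal two-sided p-values, sse, dof). The p-values are
    the partial (type II) tests of each term given all others; with 1 df
    they equal the marginal F-test of that term.
    """
    n, k = xs.shape
    gram = xs.T @ xs
    ginv = np.linalg.pinv(gram)
    beta = ginv @ (xs.T @ yc)
    resid = yc - xs @ beta
    dof = n - k - 1  # intercept absorbed by centring
    sse = float(resid @ resid)
    mse = sse / dof if dof > 0 else np.inf
    se = np.sqrt(np.maximum(np.diag(ginv) * mse, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof) if dof > 0 else np.ones(k)
    return beta, pvals, sse, dof


@dataclass
class StepwiseResults:
    """Final selected model: terms, joint coefficients, marginal p-values."""

    model: "StepwiseRegression" = field(repr=False)
    selected: list  # names in order of entry
    selected_idx: list
    params: pd.Series  # 'const' + selected terms, joint OLS fit
    pvalues: pd.Series  # marginal (partial F) p-values of the selected terms
    rsquared: float
    df_resid: int

    @property
    def n_terms(self) -> int:
        return len(self.selected)

    def predict(self, exog) -> np.ndarray:
        """Predict from the full candidate matrix (columns as in the model)."""
        x = np.asarray(exog, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        const = self.params.iloc[0]
        if not self.selected_idx:
            return np.full(x.shape[0], const)
        return const + x[:, self.selected_idx] @ self.params.iloc[1:].to_numpy()

    def summary(self) -> str:
        lines = [
            "Stepwise forward-backward regression",
            "=" * 52,
            f"n obs: {self.model.nobs}   candidates: {self.model.k_candidates}"
            f"   selected: {self.n_terms}",
            f"R-squared (training): {self.rsquared:.4f}",
            "-" * 52,
            f"{'term':<20}{'coef':>12}{'p (marginal F)':>18}",
            f"{'const':<20}{self.params.iloc[0]:>12.5f}{'':>18}",
        ]
        for name in self.selected:
            lines.append(
                f"{name:<20}{self.params[name]:>12.5f}{self.pvalues[name]:>18.3g}"
            )
        return "\n".join(lines)


class StepwiseRegression:
    """Stepwise marginal-F model selection over SNP candidate columns.

    Parameters
    ----------
    endog : array-like, shape (n,)
    exog : array-like, shape (n, p)
        Candidate columns, ordered by map position (ties in p-value break
        toward the earliest column).
    var_names : sequence of str, optional
    p_enter, p_remove : float
        Marginal F-test thresholds for entry and removal (default 0.001).
    max_terms : int, optional
        Cap on model size; default ``min(50, n // 10)``.
    rank_tol : float
        Relative squared-norm threshold below which a residualised candidate
        is treated as collinear with the current design and skipped.
    """

    def __init__(
        self,
        endog,
        exog,
        var_names=None,
        p_enter: float = 0.001,
        p_remove: float = 0.001,
        max_terms: int | None = None,
        rank_tol: float = 1e-10,
    ):
        y = np.asarray(
            endog.to_numpy() if hasattr(endog, "to_numpy") else endog, dtype=float
        ).ravel()
        if isinstance(exog, pd.DataFrame):
            if var_names is None:
                var_names = list(exog.columns)
            x = exog.to_numpy(dtype=float)
        else:
            x = np.asarray(exog, dtype=float)
        if x.ndim != 2 or x.shape[1] == 0:
            raise ValueError("exog must be a 2-d matrix with >= 1 column")
        if x.shape[0] != y.shape[0]:
            raise ValueError("endog/exog length mismatch")
        if np.isnan(y).any() or np.isnan(x).any():
            raise ValueError("missing values are not allowed")
        if np.ptp(y) == 0:
            raise ValueError("constant response")
        self.endog = y
        self.exog = x
        self.nobs, self.k_candidates = x.shape
        self.var_names = (
            list(var_names)
            if var_names is not None
            else [f"x{j}" for j in range(self.k_candidates)]
        )
        self.p_enter = float(p_enter)
        self.p_remove = float(p_remove)
        self.max_terms = (
            int(max_terms) if max_terms is not None else min(50, self.nobs // 10)
        )
        self.rank_tol = float(rank_tol)

    def _orthogonalize(self, selected: list):
        """Residualise candidates and response against the selected set."""
        xc = self.exog - self._xmean
        r = xc.copy()
        e = self.endog - self._ymean
        rnorm2 = self._norms0.copy()
        for j in selected:
            nj = np.sqrt(rnorm2[j])
            if nj <= 0:
                continue
            u = r[:, j] / nj
            proj = u @ r
            r -= np.outer(u, proj)
            rnorm2 = np.maximum(rnorm2 - proj**2, 0.0)
            e = e - u * (u @ e)
        return r, e, rnorm2

    def fit(self) -> StepwiseResults:
        n = self.nobs
        self._xmean = self.exog.mean(axis=0)
        self._ymean = float(self.endog.mean())
        xc = self.exog - self._xmean
        self._norms0 = np.sum(xc**2, axis=0)
        candidate_ok = self._norms0 > 0

        selected: list[int] = []
        r = xc.copy()
        e = self.endog - self._ymean
        rnorm2 = self._norms0.copy()
        in_model = np.zeros(self.k_candidates, dtype=bool)

        max_sweeps = 4 * self.max_terms + 8
        for _sweep in range(max_sweeps):
            changed = False
            # ---- forward step
            k = len(selected)
            df2 = n - k - 2
            sse = float(e @ e)
            if k < self.max_terms and df2 >= 1 and sse > 0:
                eligible = (
                    candidate_ok
                    & ~in_model
                    & (rnorm2 > self.rank_tol * np.maximum(self._norms0, 1e-300))
                )
                if eligible.any():
                    c = e @ r
                    with np.errstate(divide="ignore", invalid="ignore"):
                        r2 = np.where(
                            eligible, c * c / (sse * np.maximum(rnorm2, 1e-300)), 0.0
                        )
                    r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
                    fstat = r2 * df2 / (1.0 - r2)
                    pvals = np.where(eligible, stats.f.sf(fstat, 1, df2), np.inf)
                    j = int(np.argmin(pvals))
                    if pvals[j] < self.p_enter:
                        u = r[:, j] / np.sqrt(rnorm2[j])
                        proj = u @ r
                        r -= np.outer(u, proj)
                        rnorm2 = np.maximum(rnorm2 - proj**2, 0.0)
                        e = e - u * (u @ e)
                        selected.append(j)
                        in_model[j] = True
                        changed = True
            # ---- backward elimination to exhaustion
            removed_any = False
            while len(selected) > 1:
                xs = xc[:, selected]
                _, pvals_m, _, dof = _ols_marginal(xs, self.endog - self._ymean)
                if dof <= 0:
                    break
                worst = int(np.argmax(pvals_m))
                if pvals_m[worst] >= self.p_remove:
                    in_model[selected[worst]] = False
                    del selected[worst]
                    removed_any = True
                else:
                    break
            if len(selected) == 1:
                xs = xc[:, selected]
                _, pvals_m, _, dof = _ols_marginal(xs, self.endog - self._ymean)
                if dof > 0 and pvals_m[0] >= self.p_remove:
                    in_model[selected[0]] = False
                    selected = []
                    removed_any = True
            if removed_any:
                r, e, rnorm2 = self._orthogonalize(selected)
                changed = True
            if not changed:
                break
        else:  # pragma: no cover - cycling guard
            warnings.warn("stepwise selection hit the sweep cap; possible cycling")

        return self._finalize(selected)

    def _finalize(self, selected: list) -> StepwiseResults:
        n = self.nobs
        yc = self.endog - self._ymean
        names = [self.var_names[j] for j in selected]
        if selected:
            xs = self.exog[:, selected] - self._xmean[selected]
            beta, pvals, sse, dof = _ols_marginal(xs, yc)
            const = self._ymean - float(self._xmean[selected] @ beta)
            sst = float(yc @ yc)
            rsq = 1.0 - sse / sst if sst > 0 else 0.0
            params = pd.Series(
                np.concatenate([[const], beta]), index=["const"] + names
            )
            pvalues = pd.Series(pvals, index=names)
        else:
            params = pd.Series([self._ymean], index=["const"])
            pvalues = pd.Series(dtype=float)
            rsq = 0.0
            dof = n - 1
        return StepwiseResults(
            model=self,
            selected=names,
            selected_idx=list(selected),
            params=params,
            pvalues=pvalues,
            rsquared=float(rsq),
            df_resid=int(dof),
        )
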