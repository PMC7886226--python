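"""Genomic variance components and repeatability.

SNP-based (genomic) heritability is estimated by restricted maximum
likelihood (REML) for the model

    y = mu + g_A + g_D + g_I + e,
    Var(g_A) = sigma2_A * A,  Var(g_D) = sigma2_D * D,
    Var(g_I) = sigma2_I * I_epi,  Var(e) = sigma2_R * I_n,

with A a VanRaden-style additive kernel on the quantitative IBS scores, D a
centred heterozygosity-indicator (dominance) kernel and I_epi = A o A the
additive-by-additive epistasis kernel (Hadamard square), each scaled to mean
diagonal 1.  Heritability is

    h2_SNP = (sigma2_A + sigma2_D + sigma2_I)
             / (sigma2_A + sigma2_D + sigma2_I + sigma2_R).

The optimiser is average-information REML with EM-stabilised early steps and
non-negativity constraints on all components.

Repeatability of replicated control genotypes is the one-way random-effects
intraclass quantity rep = V_G / (V_G + V_R / r), with V_G and V_R from the
expected mean squares and r the (effective) number of replications per
genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .genotypes import IBSMatrix

__all__ = [
    "KernelSet",
    "build_kernels",
    "GenomicHeritability",
    "VarianceComponentsResults",
    "RepeatabilityEstimate",
    "repeatability",
    "repeatability_table",
]


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@dataclass
class KernelSet:
    """Additive / dominance / epistatic line x line relationship matrices."""

    additive: np.ndarray
    dominance: np.ndarray
    epistatic: np.ndarray
    line_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.additive.shape[0]

    def matrices(self) -> dict:
        return {
            "additive": self.additive,
            "dominance": self.dominance,
            "epistatic": self.epistatic,
        }

    def min_eigenvalues(self) -> dict:
        return {
            name: float(np.linalg.eigvalsh(k)[0]) for name, k in self.matrices().items()
        }


def _normalize(k: np.ndarray) -> np.ndarray:
    d = np.mean(np.diag(k))
    return k / d if d > 0 else k


def build_kernels(ibs: IBSMatrix) -> KernelSet:
    """Build the A, D and A-hadamard-A kernels from an imputed IBS matrix.

    The dominance indicator (1 for a heterozygous state, i.e. a score in
    (0.5, 1.5]) is computed from the pre-imputation integer states; imputed
    fractional scores contribute 0 to D.
    """
    z = ibs.scores.to_numpy(dtype=float)
    if np.isnan(z).any():
        raise ValueError("IBS matrix must be imputed before building kernels")
    zc = z - z.mean(axis=0)
    denom = np.mean(np.sum(zc**2, axis=1))
    if denom == 0:
        raise ValueError("zero-variance score matrix")
    a = _normalize(zc @ zc.T)

    states = ibs.states.to_numpy(dtype=float) if ibs.states is not None else z
    het = ((states > 0.5) & (states <= 1.5)).astype(float)
    het[np.isnan(states)] = 0.0
    hc = het - het.mean(axis=0)
    d = hc @ hc.T
    if np.mean(np.diag(d)) > 0:
        d = _normalize(d)
    else:
        d = np.zeros_like(a)

    epi = _normalize(a * a)
    return KernelSet(
        additive=a, dominance=d, epistatic=epi, line_ids=ibs.line_ids
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponentsResults:
    """REML variance components and the derived SNP-based heritability."""

    sigma2: dict  # additive / dominance / epistatic / residual
    llf: float
    converged: bool
    n_iter: int
    n_obs: int
    model: "GenomicHeritability | None" = field(default=None, repr=False)

    @property
    def sigma2_a(self) -> float:
        return self.sigma2["additive"]

    @property
    def sigma2_d(self) -> float:
        return self.sigma2["dominance"]

    @property
    def sigma2_i(self) -> float:
        return self.sigma2["epistatic"]

    @property
    def sigma2_r(self) -> float:
        return self.sigma2["residual"]

    @property
    def h2_snp(self) -> float:
        g = self.sigma2_a + self.sigma2_d + self.sigma2_i
        tot = g + self.sigma2_r
        return g / tot if tot > 0 else 0.0

    def summary(self) -> str:
        lines = [
            "Genomic heritability (REML variance components)",
            "=" * 48,
            f"n lines: {self.n_obs}   iterations: {self.n_iter}   "
            f"converged: {self.converged}",
            f"restricted log-likelihood: {self.llf:.4f}",
            "-" * 48,
            f"{'component':<12}{'variance':>12}{'share':>10}",
        ]
        tot = sum(self.sigma2.values())
        for name, v in self.sigma2.items():
            share = v / tot if tot > 0 else 0.0
            lines.append(f"{name:<12}{v:>12.5f}{share:>10.3f}")
        lines.append("-" * 48)
        lines.append(f"h2_SNP = {self.h2_snp:.4f}")
        return "\n".join(lines)


class GenomicHeritability:
    """REML model for SNP-based heritability from A/D/I kernels.

    Parameters
    ----------
    endog : array-like
        Phenotype vector (typically Box-Cox transformed), aligned with the
        kernel line order.
    kernels : KernelSet
        Relationship matrices from :func:`build_kernels`.
    """

    def __init__(self, endog, kernels: KernelSet):
        y = np.asarray(
            endog.to_numpy() if hasattr(endog, "to_numpy") else endog, dtype=float
        ).ravel()
        if y.shape[0] != kernels.n:
            raise ValueError("phenotype and kernels have different line counts")
        if np.isnan(y).any():
            raise ValueError("phenotype contains missing values")
        self.endog = y
        self.kernels = kernels
        self.component_names = ("additive", "dominance", "epistatic", "residual")

    # -- internals ---------------------------------------------------------

    def _varmat(self, sig: np.ndarray) -> np.ndarray:
        k = self.kernels
        n = k.n
        v = sig[0] * k.additive + sig[1] * k.dominance + sig[2] * k.epistatic
        v[np.diag_indices(n)] += sig[3]
        return v

    def _reml_pieces(self, sig: np.ndarray):
        """P matrix, Py and the restricted log-likelihood for given sigma."""
        y = self.endog
        n = y.shape[0]
        v = self._varmat(sig)
        jitter = 0.0
        for _ in range(4):
            try:
                cf = linalg.cho_factor(v + jitter * np.eye(n), lower=True)
                break
            except linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-8 * np.trace(v) / n)
        else:  # pragma: no cover - pathological
            raise linalg.LinAlgError("V not positive definite")
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        vinv = linalg.cho_solve(cf, np.eye(n))
        vinv1 = vinv.sum(axis=1)  # V^-1 X for X = 1
        xtvx = vinv1.sum()
        p = vinv - np.outer(vinv1, vinv1) / xtvx
        py = p @ y
        llf = -0.5 * (logdet_v + np.log(xtvx) + y @ py)
        return p, py, llf

    def reml_loglike(self, sig) -> float:
        """Restricted log-likelihood at the given component values."""
        return self._reml_pieces(np.asarray(sig, dtype=float))[2]

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        maxiter: int = 60,
        tol: float = 1e-6,
        start: np.ndarray | None = None,
        n_em: int = 3,
    ) -> VarianceComponentsResults:
        """AI-REML with EM-stabilised first steps and components >= 0."""
        y = self.endog
        n = y.shape[0]
        vary = float(np.var(y, ddof=1))
        if vary == 0:
            raise ValueError("constant phenotype")
        kmats = [
            self.kernels.additive,
            self.kernels.dominance,
            self.kernels.epistatic,
            np.eye(n),
        ]
        active_kernel = np.array([np.abs(k).sum() > 0 for k in kmats])
        sig = (
            np.asarray(start, dtype=float).copy()
            if start is not None
            else np.full(4, vary / 4.0)
        )
        sig[~active_kernel] = 0.0
        floor = 1e-8 * vary
        p, py, llf = self._reml_pieces(sig)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            kpy = [k @ py for k in kmats]
            tr_pk = np.array([np.sum(p * k) for k in kmats])
            quad = np.array([py @ u for u in kpy])
            grad = -0.5 * (tr_pk - quad)
            free = active_kernel & ~((sig <= floor) & (grad < 0))
            if not free.any():
                converged = True
                break
            if it <= n_em:
                new = sig + (sig**2) * (quad - tr_pk) / n
                new = np.where(free, np.maximum(new, 0.0), np.where(sig <= floor, 0.0, sig))
            else:
                pkpy = [p @ u for u in kpy]
                idx = np.flatnonzero(free)
                ai = 0.5 * np.array(
                    [[kpy[i] @ pkpy[j] for j in idx] for i in idx]
                )
                try:
                    delta = np.linalg.solve(
                        ai + 1e-10 * np.eye(len(idx)) * max(ai.max(), 1.0),
                        grad[idx],
                    )
                except np.linalg.LinAlgError:
                    delta = grad[idx] * (sig[idx] ** 2) / max(vary, 1e-12)
                new = sig.copy()
                step = 1.0
                for _ in range(12):
                    cand = sig.copy()
                    cand[idx] = np.maximum(sig[idx] + step * delta, 0.0)
                    cand[~active_kernel] = 0.0
                    try:
                        p_c, py_c, llf_c = self._reml_pieces(cand)
                    except linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if llf_c >= llf - 1e-10:
                        new = cand
                        p, py, llf_new = p_c, py_c, llf_c
                        break
                    step *= 0.5
                else:
                    converged = True
                    break
                if abs(llf_new - llf) < tol:
                    sig = new
                    llf = llf_new
                    converged = True
                    break
                sig = new
                llf = llf_new
                continue
            # EM path: re-evaluate pieces
            sig_old, llf_old = sig, llf
            sig = new
            p, py, llf = self._reml_pieces(sig)
            if abs(llf - llf_old) < tol and it > 1:
                converged = True
                break
        sig = np.where(sig <= floor, 0.0, sig)
        return VarianceComponentsResults(
            sigma2=dict(zip(self.component_names, (float(s) for s in sig))),
            llf=float(llf),
            converged=converged,
            n_iter=it,
            n_obs=n,
            model=self,
        )


def estimate_h2_snp(y, kernels: KernelSet, **fit_kws) -> VarianceComponentsResults:
    """Convenience wrapper: fit the REML model and return its results."""
    if kernels.n < 50:
        raise ValueError("need at least 50 lines for a variance-component fit")
    return GenomicHeritability(y, kernels).fit(**fit_kws)


# ---------------------------------------------------------------------------
# repeatability
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityEstimate:
    """One-way random-effects repeatability of replicated genotypes."""

    v_g: float
    v_r: float
    r: float  # effective replications per genotype (n0 for unbalanced data)
    rep: float
    n_genotypes: int
    n_obs: int


def repeatability(values, genotypes) -> RepeatabilityEstimate:
    """rep = V_G / (V_G + V_R / r) from a one-way random-effects ANOVA.

    ``values``/``genotypes`` are aligned 1-d sequences (replicate
    measurements and their genotype labels).  V_R is the within-genotype
    mean square; V_G = (MSB - MSW) / n0 with the standard unbalanced-design
    coefficient n0 = (N - sum(n_i^2)/N) / (g - 1); both are truncated at 0
    and rep is clamped to [0, 1].
    """
    y = np.asarray(values, dtype=float)
    labels = np.asarray(genotypes)
    ok = ~np.isnan(y)
    y, labels = y[ok], labels[ok]
    g = pd.Series(labels)
    groups = pd.Series(y).groupby(g)
    ni = groups.count()
    n_gen = len(ni)
    if n_gen < 2:
        raise ValueError("repeatability needs >= 2 genotypes")
    if (ni < 2).all():
        raise ValueError("repeatability needs >= 2 replicates for >= 1 genotype")
    n_tot = int(ni.sum())
    grand = y.mean()
    means = groups.mean()
    ssb = float((ni * (means - grand) ** 2).sum())
    ssw = float(((pd.Series(y) - means.reindex(g).to_numpy()) ** 2).sum())
    msb = ssb / (n_gen - 1)
    msw = ssw / (n_tot - n_gen)
    n0 = (n_tot - float((ni**2).sum()) / n_tot) / (n_gen - 1)
    v_r = max(msw, 0.0)
    v_g = max((msb - msw) / n0, 0.0)
    if v_g == 0.0:
        rep = 0.0
    elif v_r == 0.0:
        rep = 1.0
    else:
        rep = v_g / (v_g + v_r / n0)
    rep = float(np.clip(rep, 0.0, 1.0))
    return RepeatabilityEstimate(
        v_g=v_g, v_r=v_r, r=n0, rep=rep, n_genotypes=n_gen, n_obs=n_tot
    )


def repeatability_table(
    controls: pd.DataFrame, genotype_col: str = "control_id"
) -> pd.DataFrame:
    """Per-metabolite repeatability of a replicated control table."""
    meta_cols = [c for c in controls.columns if c not in (genotype_col, "rep")]
    rows = []
    for col in meta_cols:
        est = repeatability(controls[col], controls[genotype_col])
        rows.append(
            {
                "metabolite": col,
                "V_G": est.v_g,
                "V_R": est.v_r,
                "r": est.r,
                "repeatability": est.rep,
            }
        )
    return pd.DataFrame(rows).set_index("metabolite")
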