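"""Independent reference implementations used only as test oracles.

These are deliberately naive (literal loops, enumeration, library fits) and
share no code with the package's optimised implementations.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm


def bc1s3_single_locus_distribution() -> dict:
    """Exact single-locus genotype distribution after BC1 + 3 selfings.

    Brute-force enumeration of the Markov chain on genotype states
    (hom recurrent, het, hom donor).  The BC1 individual is formed from an
    F1 gamete (donor allele w.p. 1/2) and a recurrent-parent gamete; each
    selfing generation applies the Mendelian selfing transition matrix.
    """
    # state order: hom_recurrent, het, hom_donor
    start = np.array([0.5, 0.5, 0.0])
    selfing = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.25, 0.5, 0.25],
            [0.0, 0.0, 1.0],
        ]
    )
    dist = start.copy()
    for _ in range(3):
        dist = dist @ selfing
    return {"hom_recurrent": dist[0], "het": dist[1], "hom_donor": dist[2]}


def naive_stepwise(y, x, p_enter=0.001, p_remove=0.001, max_terms=None):
    """Literal forward-backward stepwise selection via repeated OLS refits.

    Forward: refit the joint model with each remaining candidate appended
    and read the new term's marginal p-value from the fit; add the smallest
    if below p_enter (first minimum wins).  Backward: repeatedly drop the
    term with the largest marginal p-value while it is >= p_remove.
    Returns (selected column indices in entry order, params with intercept
    first or None for the empty model).
    """
    n, p = x.shape
    max_terms = max_terms or min(50, n // 10)
    selected: list[int] = []
    for _ in range(4 * max_terms + 8):
        changed = False
        if len(selected) < max_terms:
            best_p, best_j = np.inf, None
            for j in range(p):
                if j in selected:
                    continue
                xs = sm.add_constant(x[:, selected + [j]])
                if np.linalg.matrix_rank(xs) < xs.shape[1]:
                    continue
                fit = sm.OLS(y, xs).fit()
                pj = fit.pvalues[-1]
                if pj < best_p:
                    best_p, best_j = pj, j
            if best_j is not None and best_p < p_enter:
                selected.append(best_j)
                changed = True
        while selected:
            fit = sm.OLS(y, sm.add_constant(x[:, selected])).fit()
            pv = fit.pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] >= p_remove:
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break
    if selected:
        fit = sm.OLS(y, sm.add_constant(x[:, selected])).fit()
        return selected, np.asarray(fit.params)
    return selected, None


def welford_moments(values):
    """Streaming (Welford) mean and sample SD, independent of the two-pass
    formulas used by the package."""
    mean, m2, count = 0.0, 0.0, 0
    for v in values:
        count += 1
        delta = v - mean
        mean += delta / count
        m2 += delta * (v - mean)
    sd = (m2 / (count - 1)) ** 0.5 if count > 1 else 0.0
    return mean, sd
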