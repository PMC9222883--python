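"""Per-site fixed-effects likelihood (FEL) scan for positive and negative
selection.

FEL is the one test in the battery that detects purifying as well as
adaptive selection.  It is two-staged: first a global M0-style fit pins down
kappa, the codon frequencies and the branch lengths; then each codon column
gets its own synonymous rate alpha and nonsynonymous rate beta, maximised
with everything else frozen, and is tested against the alpha = beta null
with a chi-squared(1) LRT.  A site is called positive when beta > alpha and
negative when beta < alpha, at p <= s (two-sided, as in FEL).

The site rate matrix is (alpha * S + beta * N) / c where S and N are the
synonymous and nonsynonymous parts of the HKY-style codon rate matrix at
the global kappa, and c is the global fit's own normalization, so that site
rates (alpha, beta) = (1, omega_hat) reproduce the global model exactly and
alpha, beta read as rate multipliers relative to it.  The nucleotide bias is
kappa-based, consistent with the rest of the package (HyPhy's own FEL
defaults to a richer GTR baseline, so counts can differ slightly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .codon_core import CodonAlignment, CodonFrequencies, GeneticCode, STANDARD_CODE
from .codon_models import (
    FitOptions,
    LikelihoodEngine,
    ModelFit,
    SpectralQ,
    _unscaled_rates,
    fit_model,
    rate_scale,
)
from .tree_topologies import PhyloTree

__all__ = ["FELSiteResult", "FELBaseline", "fit_global_baseline", "fel_site_test", "fel_scan"]

ALPHA_MIN, RATE_MAX = 1e-6, 100.0


@dataclass(frozen=True)
class FELSiteResult:
    """One codon's FEL verdict."""

    codon_index: int  # 1-based on the cleaned alignment
    alpha: float
    beta: float
    lnL_free: float
    lnL_constrained: float
    p_value: float
    direction: str  # positive | negative | none

    @property
    def statistic(self) -> float:
        return max(0.0, 2.0 * (self.lnL_free - self.lnL_constrained))


class FELBaseline:
    """Frozen global context for the per-site stage."""

    def __init__(
        self,
        tree: PhyloTree,
        alignment: CodonAlignment,
        m0_fit: ModelFit,
        code: GeneticCode = STANDARD_CODE,
    ):
        self.m0_fit = m0_fit
        self.code = code
        self.pi = m0_fit.pi
        self.kappa = m0_fit.mle["kappa"]
        self.omega_global = m0_fit.mle["omega"]
        self.engine = LikelihoodEngine(tree, alignment, code=code, pi=self.pi)
        self.branch_lengths = np.array(
            [n.length for n in m0_fit.tree.root.preorder() if n.parent is not None]
        )
        # split the unscaled rate matrix into synonymous / nonsynonymous parts
        Q1 = _unscaled_rates(self.kappa, 1.0, self.pi, code)  # S + N
        Q0 = _unscaled_rates(self.kappa, 0.0, self.pi, code)  # S only
        np.fill_diagonal(Q0, 0.0)
        np.fill_diagonal(Q1, 0.0)
        self.syn_part = Q0
        self.nonsyn_part = Q1 - Q0
        # normalize with the global fit's own scale so that site rates
        # (alpha, beta) = (1, omega_hat) reproduce the baseline model exactly
        self.scale = rate_scale(self.kappa, self.omega_global, self.pi, code)

    def site_loglik(self, site: int, alpha: float, beta: float) -> float:
        """lnL of one codon column under site rates (alpha, beta)."""
        Q = (alpha * self.syn_part + beta * self.nonsyn_part) / self.scale
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        spec = SpectralQ(Q, self.pi.pi)
        eng = self.engine
        P = {
            id(node): spec.transition(float(t))
            for node, t in zip(eng.branch_nodes, self.branch_lengths)
        }
        logscale = np.zeros(1)
        saved_codes = eng.leaf_codes
        codes = {t: arr[site : site + 1] for t, arr in saved_codes.items()}
        eng.leaf_codes = codes
        try:
            partial = eng._prune(eng.tree.root, P, logscale)
        finally:
            eng.leaf_codes = saved_codes
        lik = float(self.pi.pi @ partial[:, 0])
        return float(np.log(max(lik, 1e-300)) + logscale[0])

    def total_lnL_at_global(self) -> float:
        """Sum of site lnLs at (alpha, beta) = (1, omega_hat); equals the
        global fit's lnL (consistency check)."""
        return sum(
            self.site_loglik(s, 1.0, self.omega_global)
            for s in range(self.engine.n_sites)
        )


def fit_global_baseline(
    tree: PhyloTree,
    alignment: CodonAlignment,
    options: Optional[FitOptions] = None,
    code: GeneticCode = STANDARD_CODE,
    pi: Optional[CodonFrequencies] = None,
) -> FELBaseline:
    """Stage one: M0 fit whose kappa and branch lengths the site stage
    holds fixed."""
    m0 = fit_model(tree, alignment, "M0", options, code=code, pi=pi)
    return FELBaseline(tree, alignment, m0, code=code)


def fel_site_test(
    baseline: FELBaseline, site: int, significance: float = 0.05
) -> FELSiteResult:
    """Stage two for one codon column (0-based ``site``).

    Maximizes lnL over (alpha, beta), then over the constrained alpha = beta
    line, and reports the df=1 LRT with the direction taken from the sign of
    beta - alpha when significant.
    """

    def neg_free(x: np.ndarray) -> float:
        return -baseline.site_loglik(site, float(x[0]), float(x[1]))

    def neg_constrained(r: float) -> float:
        return -baseline.site_loglik(site, float(r), float(r))

    res_c = optimize.minimize_scalar(
        neg_constrained, bounds=(ALPHA_MIN, RATE_MAX), method="bounded",
        options={"xatol": 1e-5},
    )
    r_hat = float(res_c.x)
    lnL_c = -float(res_c.fun)

    best = None
    w = np.clip(baseline.omega_global, 0.05, RATE_MAX - 1)
    for start in ((r_hat, r_hat), (1.0, w)):
        res = optimize.minimize(
            neg_free,
            np.asarray(start, float),
            method="L-BFGS-B",
            bounds=[(ALPHA_MIN, RATE_MAX), (0.0, RATE_MAX)],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = float(best.x[0]), float(best.x[1])
    lnL_f = -float(best.fun)
    if lnL_f < lnL_c:  # the constrained optimum dominates: boundary case
        alpha = beta = r_hat
        lnL_f = lnL_c
    statistic = max(0.0, 2.0 * (lnL_f - lnL_c))
    p = float(stats.chi2.sf(statistic, 1)) if statistic > 0 else 1.0
    if p <= significance and not np.isclose(beta, alpha):
        direction = "positive" if beta > alpha else "negative"
    else:
        direction = "none"
    return FELSiteResult(
        codon_index=site + 1,
        alpha=alpha,
        beta=beta,
        lnL_free=lnL_f,
        lnL_constrained=lnL_c,
        p_value=p,
        direction=direction,
    )


def fel_scan(
    tree: PhyloTree,
    alignment: CodonAlignment,
    significance: float = 0.05,
    options: Optional[FitOptions] = None,
    code: GeneticCode = STANDARD_CODE,
    pi: Optional[CodonFrequencies] = None,
    baseline: Optional[FELBaseline] = None,
) -> list[FELSiteResult]:
    """Run the full FEL scan: one result per codon column.

    Identical columns are fitted once and the result shared.  Summary counts
    are available via :func:`fel_summary`.
    """
    if baseline is None:
        baseline = fit_global_baseline(tree, alignment, options, code=code, pi=pi)
    eng = baseline.engine
    taxa = list(eng.leaf_codes)
    columns = [tuple(eng.leaf_codes[t][s] for t in taxa) for s in range(eng.n_sites)]
    cache: dict[tuple, FELSiteResult] = {}
    results: list[FELSiteResult] = []
    for s, col in enumerate(columns):
        hit = cache.get(col)
        if hit is None:
            hit = fel_site_test(baseline, s, significance)
            cache[col] = hit
        if hit.codon_index != s + 1:
            hit = FELSiteResult(
                codon_index=s + 1,
                alpha=hit.alpha,
                beta=hit.beta,
                lnL_free=hit.lnL_free,
                lnL_constrained=hit.lnL_constrained,
                p_value=hit.p_value,
                direction=hit.direction,
            )
        results.append(hit)
    return results


def fel_summary(results: list[FELSiteResult]) -> dict[str, int]:
    return {
        "n_sites": len(results),
        "n_positive": sum(r.direction == "positive" for r in results),
        "n_negative": sum(r.direction == "negative" for r in results),
        "n_none": sum(r.direction == "none" for r in results),
    }
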