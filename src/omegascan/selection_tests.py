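"""Likelihood-ratio tests and empirical-Bayes identification of selected
sites.

Every nested model comparison is summarized as 2*(lnL_alt - lnL_null)
against a chi-squared distribution: df=2 for M1a/M2a and M7/M8, df=1 for the
branch and branch-site comparisons.  For the branch-site null the positive-
selection omega sits on the boundary (omega2 = 1), where the plain
chi-squared reference is conventional rather than exact; results carry that
caveat.

Site identification follows the empirical-Bayes route: NEB evaluates the
posterior probability of the positive-selection class at the MLEs; BEB
additionally averages over a discrete prior grid on the mixture weights and
the positive-selection omega, which accounts for their sampling error.
Site records are only produced when the companion LRT is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import special, stats

from .codon_core import CodonAlignment
from .codon_models import (
    LikelihoodEngine,
    ModelFit,
    SiteClass,
    NESTED_PAIRS,
)
from .tree_topologies import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "LRTResult",
    "SiteSelectionRecord",
    "benjamini_hochberg",
    "lrt_pvalue",
    "model_comparison",
    "site_posteriors",
    "BEB_GRID_POINTS",
]

# Prior grid resolution per integrated dimension for BEB.
BEB_GRID_POINTS = 10


@dataclass(frozen=True)
class LRTResult:
    """A chi-squared likelihood-ratio test between two nested fits."""

    comparison: str
    lnL_null: float
    lnL_alt: float
    df: int
    statistic: float
    p_value: float
    foreground_branch: Optional[str] = None

    @property
    def significant_at(self):
        return lambda s: self.p_value <= s


def lrt_pvalue(lnL_null: float, lnL_alt: float, df: int, comparison: str = "") -> LRTResult:
    """LRT statistic max(0, 2*(lnL_alt - lnL_null)) and its chi-squared
    upper-tail p-value.

    A negative difference (optimizer noise on a true null) is clamped to 0
    with a logged warning, giving p = 1.
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    if not (np.isfinite(lnL_null) and np.isfinite(lnL_alt)):
        raise ValueError(f"non-finite log-likelihoods: {lnL_null}, {lnL_alt}")
    statistic = 2.0 * (lnL_alt - lnL_null)
    if statistic < 0:
        if statistic < -1e-6:
            logger.warning(
                "alternative lnL below null (%g < %g); clamping LRT statistic to 0",
                lnL_alt,
                lnL_null,
            )
        statistic = 0.0
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return LRTResult(
        comparison=comparison,
        lnL_null=float(lnL_null),
        lnL_alt=float(lnL_alt),
        df=df,
        statistic=float(statistic),
        p_value=p,
    )


def model_comparison(pair: str, null_fit: ModelFit, alt_fit: ModelFit) -> LRTResult:
    """LRT between two fits of a declared nested pair on the same data.

    df is fixed by the pair (M1a/M2a: 2, M7/M8: 2, branch: 1, branch-site: 1)
    and the fits' data fingerprints must match.
    """
    if pair not in NESTED_PAIRS:
        raise ValueError(f"unknown comparison {pair!r}; choose from {sorted(NESTED_PAIRS)}")
    null_name, alt_name, df = NESTED_PAIRS[pair]
    if (null_fit.model_name, alt_fit.model_name) != (null_name, alt_name):
        raise ValueError(
            f"comparison {pair} expects fits ({null_name}, {alt_name}), "
            f"got ({null_fit.model_name}, {alt_fit.model_name})"
        )
    if null_fit.data_fingerprint != alt_fit.data_fingerprint:
        raise ValueError("fits were computed on different data; refusing to compare")
    if null_fit.foreground_branch != alt_fit.foreground_branch:
        raise ValueError("fits use different foreground branches")
    res = lrt_pvalue(null_fit.lnL, alt_fit.lnL, df, comparison=pair)
    return LRTResult(
        comparison=pair,
        lnL_null=res.lnL_null,
        lnL_alt=res.lnL_alt,
        df=df,
        statistic=res.statistic,
        p_value=res.p_value,
        foreground_branch=alt_fit.foreground_branch,
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1).

    Offered as an optional extension for the many parallel per-branch
    tests; the primary reports show raw per-branch p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


@dataclass(frozen=True)
class SiteSelectionRecord:
    """One codon's verdict from one site-specific test.

    ``codon_index`` is 1-based on the cleaned alignment; ``score`` is a
    posterior probability for empirical-Bayes tests (significant when
    >= 1 - s) or a p-value for FEL (significant when <= s).
    """

    codon_index: int
    reference_codon: str
    test: str
    score: float
    direction: str  # positive | negative | none
    significant: bool


def _positive_class_mask(classes: tuple[SiteClass, ...]) -> np.ndarray:
    return np.array([c.omega_foreground > 1.0 for c in classes])


def site_posteriors(
    fit: ModelFit,
    lrt: LRTResult,
    method: str = "NEB",
    significance: float = 0.05,
    alignment: Optional[CodonAlignment] = None,
    tree: Optional[PhyloTree] = None,
) -> list[SiteSelectionRecord]:
    """Per-site posterior probabilities of the positive-selection class.

    Returns one record per codon of the cleaned alignment, direction
    ``positive``, flagged significant when the posterior reaches
    ``1 - significance`` — but only when the companion LRT is itself
    significant; otherwise the list is empty, mirroring the conditional
    reporting of the empirical-Bayes tests.  ``method`` is ``NEB`` (at the
    MLEs) or ``BEB`` (grid-averaged; requires ``alignment`` and ``tree`` to
    re-evaluate site likelihoods on the prior grid).
    """
    classes = fit.mixture.classes
    pos_mask = _positive_class_mask(classes)
    if not pos_mask.any():
        return []
    if lrt.p_value > significance:
        return []
    if method == "NEB":
        posterior = _neb_posterior(fit, pos_mask)
    elif method == "BEB":
        if alignment is None or tree is None:
            raise ValueError("BEB needs the alignment and tree to evaluate the prior grid")
        posterior = _beb_posterior(fit, alignment, tree)
    else:
        raise ValueError(f"unknown empirical-Bayes method {method!r}")
    reference = fit.data_fingerprint.splitlines()[0].split("\t")[1] if fit.data_fingerprint else ""
    ref_codons = [reference[i : i + 3] for i in range(0, len(reference), 3)]
    records = []
    for site, prob in enumerate(posterior):
        records.append(
            SiteSelectionRecord(
                codon_index=site + 1,
                reference_codon=ref_codons[site] if site < len(ref_codons) else "",
                test=f"{fit.model_name}-{method}",
                score=float(prob),
                direction="positive",
                significant=bool(prob >= 1.0 - significance),
            )
        )
    return records


def _neb_posterior(fit: ModelFit, pos_mask: np.ndarray) -> np.ndarray:
    log_props = np.log(
        np.clip([c.proportion for c in fit.mixture.classes], 1e-300, None)
    )
    log_joint = fit.site_class_loglik + log_props
    log_total = special.logsumexp(log_joint, axis=1)
    log_pos = special.logsumexp(log_joint[:, pos_mask], axis=1)
    return np.exp(log_pos - log_total)


def _beb_grid(fit: ModelFit) -> list[tuple[np.ndarray, np.ndarray]]:
    """Prior grid for BEB: (class proportions, class omegas) per grid point.

    The mixture weights and the positive-selection omega are integrated over
    BEB_GRID_POINTS-point uniform grids (weights via stick-breaking
    coordinates on (0,1); omega over (1, 11)); the remaining parameters
    (kappa, branch lengths, omega0 or the beta shape) stay at their MLEs.
    """
    d = BEB_GRID_POINTS
    mids = (np.arange(d) + 0.5) / d
    name = fit.model_name
    points = []
    if name == "M2a":
        omega0 = fit.mixture.extra.get("omega0", fit.mixture.classes[0].omega_background)
        for w2 in 1.0 + 10.0 * mids:
            for q0 in mids:
                for q1 in mids:
                    props = np.array([q0, (1 - q0) * q1, (1 - q0) * (1 - q1)])
                    omegas = np.array([omega0, 1.0, w2])
                    points.append((props, omegas))
    elif name == "M8":
        K = len(fit.mixture.classes) - 1
        beta_omegas = np.array([c.omega_background for c in fit.mixture.classes[:-1]])
        for ws in 1.0 + 10.0 * mids:
            for p0 in mids:
                props = np.concatenate([np.full(K, p0 / K), [1 - p0]])
                omegas = np.concatenate([beta_omegas, [ws]])
                points.append((props, omegas))
    elif name == "branch-site-alt":
        omega0 = fit.mixture.classes[0].omega_background
        for w2 in 1.0 + 10.0 * mids:
            for q0 in mids:
                for q1 in mids:
                    props = np.array(
                        [q0 * q1, q0 * (1 - q1), (1 - q0) * q1, (1 - q0) * (1 - q1)]
                    )
                    omegas = np.array([omega0, 1.0, w2, w2])  # foreground omegas
                    points.append((props, omegas))
    else:
        raise ValueError(f"BEB is not defined for model {name!r}")
    return points


def _beb_posterior(
    fit: ModelFit, alignment: CodonAlignment, tree: PhyloTree
) -> np.ndarray:
    """Grid-averaged posterior of the positive-selection class per site.

    Each grid point g gets weight proportional to its full-data likelihood
    (uniform prior over the grid); the reported posterior is the weighted
    average of the per-point class posteriors.
    """
    engine = LikelihoodEngine(tree, alignment, code=fit.pi.code, pi=fit.pi)
    bl = np.array([n.length for n in fit.tree.root.preorder() if n.parent is not None])
    kappa = fit.mixture.kappa
    name = fit.model_name

    # site x class log-likelihood columns reusable across the grid
    distinct: dict[tuple[float, float], np.ndarray] = {}

    def col(omega_bg: float, omega_fg: float) -> np.ndarray:
        key = (omega_bg, omega_fg)
        if key not in distinct:
            distinct[key] = engine._one_class_site_logliks(kappa, omega_bg, omega_fg, bl)
        return distinct[key]

    points = _beb_grid(fit)
    n_sites = alignment.n_codons
    log_grid_lik = np.empty(len(points))
    pos_post = np.empty((len(points), n_sites))
    omega0_bg = fit.mixture.classes[0].omega_background
    for g, (props, omegas) in enumerate(points):
        if name == "branch-site-alt":
            cols = np.column_stack(
                [
                    col(omega0_bg, omega0_bg),
                    col(1.0, 1.0),
                    col(omega0_bg, omegas[2]),
                    col(1.0, omegas[3]),
                ]
            )
            pos_mask = np.array([False, False, True, True])
        else:
            cols = np.column_stack([col(w, w) for w in omegas])
            pos_mask = omegas > 1.0
        log_joint = cols + np.log(np.clip(props, 1e-300, None))
        log_site = special.logsumexp(log_joint, axis=1)
        log_grid_lik[g] = log_site.sum()
        pos_post[g] = np.exp(
            special.logsumexp(log_joint[:, pos_mask], axis=1) - log_site
        )
    weights = np.exp(log_grid_lik - special.logsumexp(log_grid_lik))
    return weights @ pos_post
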