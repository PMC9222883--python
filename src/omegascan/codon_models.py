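"""Codon substitution models and their maximum-likelihood machinery.

The likelihood core implements the Goldman–Yang-style codon model family
used for selection analysis: an HKY-type 61x61 instantaneous rate matrix in
which single-nucleotide codon changes are weighted by the target codon
frequency, by kappa for transitions, and by omega (dN/dS) for amino-acid
altering changes.  Site-to-site variation in omega is expressed as a finite
mixture of site classes; branch-to-branch variation assigns each class a
separate omega on a single marked foreground branch.

Model families
--------------
* ``M0`` — one omega for all sites and branches.
* ``M1a`` / ``M2a`` — nearly-neutral (omega0<1, omega1=1) vs the same plus a
  positive-selection class (omega2>=1).
* ``M7`` / ``M8`` — beta-distributed omega on (0,1), discretized into K
  equal-probability categories, vs beta plus an extra omega_s>=1 class.
* ``branch`` — one omega on the foreground branch, another on the rest of
  the tree; the null fixes the foreground omega at 1.
* ``branch-site`` — model A: four site classes (0, 1, 2a, 2b) whose
  foreground omega is omega2 for classes 2a/2b; the null fixes omega2 = 1.

Likelihoods are computed by Felsenstein pruning with per-node scaling, and
transition matrices come from the spectral decomposition of the reversible
rate matrix (pi^1/2-symmetrized), cached per (kappa, omega) so that repeated
evaluations during optimization only pay for the branch-length dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

from .codon_core import (
    STANDARD_CODE,
    CodonAlignment,
    CodonFrequencies,
    GeneticCode,
    equal_frequencies,
    f3x4_frequencies,
)
from .tree_topologies import PhyloTree, TreeNode, check_tree_alignment_consistency, parse_newick

__all__ = [
    "CodonRateMatrix",
    "SiteClass",
    "SiteClassMixture",
    "ModelFit",
    "FitOptions",
    "build_rate_matrix",
    "transition_matrix",
    "discretize_beta",
    "site_likelihoods",
    "fit_model",
    "fit_nested_pair",
    "make_mixture",
    "rate_scale",
    "LikelihoodEngine",
    "MODEL_NAMES",
    "NESTED_PAIRS",
]

# Practical parameter bounds (codeml-like); the optimizer never leaves them.
OMEGA_MIN, OMEGA_MAX = 1e-6, 999.0
KAPPA_MIN, KAPPA_MAX = 0.01, 100.0
BL_MIN, BL_MAX = 0.0, 50.0
PROP_EPS = 1e-6
BETA_MIN, BETA_MAX = 5e-3, 99.0
# Convergence tolerance for the bounded quasi-Newton fits (codeml Small_Diff).
SMALL_DIFF = 0.5e-6
DEFAULT_BETA_CATEGORIES = 10

MODEL_NAMES = (
    "M0",
    "M1a",
    "M2a",
    "M7",
    "M8",
    "branch-alt",
    "branch-null",
    "branch-site-alt",
    "branch-site-null",
)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# Rate matrix
# ---------------------------------------------------------------------------


class _CodeStructure:
    """Precomputed single-change pair structure of a genetic code."""

    def __init__(self, code: GeneticCode):
        sense = code.sense_codons
        self.sense = sense
        self.index = {c: i for i, c in enumerate(sense)}
        ii, jj, ts, syn = [], [], [], []
        for i, a in enumerate(sense):
            for j, b in enumerate(sense):
                if i == j:
                    continue
                diffs = [(x, y) for x, y in zip(a, b) if x != y]
                if len(diffs) != 1:
                    continue
                ii.append(i)
                jj.append(j)
                ts.append(diffs[0] in TRANSITIONS)
                syn.append(code.translate(a) == code.translate(b))
        self.i = np.array(ii)
        self.j = np.array(jj)
        self.is_transition = np.array(ts)
        self.is_synonymous = np.array(syn)


_STRUCTURE_CACHE: dict[int, _CodeStructure] = {}


def _structure(code: GeneticCode) -> _CodeStructure:
    key = id(code)
    if key not in _STRUCTURE_CACHE:
        _STRUCTURE_CACHE[key] = _CodeStructure(code)
    return _STRUCTURE_CACHE[key]


@dataclass(frozen=True)
class CodonRateMatrix:
    """A scaled reversible codon rate matrix.

    ``Q`` is 61x61 (sense codons), zero off-diagonal except for
    single-nucleotide changes, with rows summing to zero and the overall rate
    normalized to one expected substitution per codon per unit time:
    ``-sum_i pi_i Q_ii = 1``.
    """

    kappa: float
    omega: float
    pi: CodonFrequencies
    Q: np.ndarray


def build_rate_matrix(
    kappa: float,
    omega: float,
    pi: CodonFrequencies,
    code: GeneticCode = STANDARD_CODE,
) -> CodonRateMatrix:
    """HKY-style codon rate matrix: Q_ij proportional to pi_j, times kappa
    for transitions and omega for nonsynonymous changes."""
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    Q = _unscaled_rates(kappa, omega, pi, code)
    Q, _ = _normalize(Q, pi.pi)
    return CodonRateMatrix(kappa=kappa, omega=omega, pi=pi, Q=Q)


def _unscaled_rates(
    kappa: float, omega: float, pi: CodonFrequencies, code: GeneticCode
) -> np.ndarray:
    s = _structure(code)
    n = len(s.sense)
    Q = np.zeros((n, n))
    rate = pi.pi[s.j].copy()
    rate[s.is_transition] *= kappa
    rate[~s.is_synonymous] *= omega
    Q[s.i, s.j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _normalize(Q: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, float]:
    scale = -float(pi @ np.diag(Q))
    if scale <= 0:
        # omega=0 with no synonymous changes possible: degenerate but legal
        return Q, 1.0
    return Q / scale, scale


class SpectralQ:
    """Spectral form of a reversible Q enabling cheap P(t) for many t.

    With D = diag(pi), reversibility makes B = D^1/2 Q D^-1/2 symmetric, so
    B = U diag(lam) U' and P(t) = D^-1/2 U exp(lam t) U' D^1/2.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        lam, U = np.linalg.eigh(B)
        self.lam = lam
        self.left = U / sqrt_pi[:, None]   # D^-1/2 U
        self.right = (U * sqrt_pi[:, None]).T  # U' D^1/2

    def transition(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(Q: CodonRateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt): a row-stochastic matrix; P(0) is the identity."""
    return SpectralQ(Q.Q, Q.pi.pi).transition(t)


def rate_scale(
    kappa: float,
    omega: float,
    pi: CodonFrequencies,
    code: GeneticCode = STANDARD_CODE,
) -> float:
    """Normalization constant of the unscaled rate matrix at (kappa, omega):
    the expected substitutions per codon per unit time before rescaling."""
    Q = _unscaled_rates(kappa, omega, pi, code)
    return max(-float(pi.pi @ np.diag(Q)), 1e-300)


# ---------------------------------------------------------------------------
# Beta discretization (M7/M8)
# ---------------------------------------------------------------------------


def discretize_beta(p: float, q: float, K: int = DEFAULT_BETA_CATEGORIES) -> np.ndarray:
    """Discretize Beta(p, q) into K equal-probability categories.

    Returns the K category values, each the mean of the beta density within
    its quantile bin; every category has probability 1/K.
    """
    if p <= 0 or q <= 0:
        raise ValueError(f"beta parameters must be positive, got p={p}, q={q}")
    if K < 1:
        raise ValueError(f"need at least one category, got K={K}")
    edges = special.betaincinv(p, q, np.linspace(0.0, 1.0, K + 1))
    # mean within [a,b]: E[X | a<X<b] = mu * (I_b(p+1,q) - I_a(p+1,q)) / (1/K)
    mu = p / (p + q)
    inc = special.betainc(p + 1, q, edges)
    means = mu * (inc[1:] - inc[:-1]) * K
    return np.clip(means, 1e-9, 1.0 - 1e-9)


# ---------------------------------------------------------------------------
# Site classes and model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteClass:
    """One mixture component: its weight and its omega on background and
    foreground branches (identical for site-only models)."""

    proportion: float
    omega_background: float
    omega_foreground: float

    @classmethod
    def uniform_omega(cls, proportion: float, omega: float) -> "SiteClass":
        return cls(proportion, omega, omega)


@dataclass(frozen=True)
class SiteClassMixture:
    """A fully specified codon model: named family plus concrete classes."""

    model_name: str
    classes: tuple[SiteClass, ...]
    kappa: float
    extra: dict = field(default_factory=dict)  # e.g. beta p/q, omega_s

    def __post_init__(self) -> None:
        total = sum(c.proportion for c in self.classes)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(c.proportion < 0 for c in self.classes):
            raise ValueError("class proportions must be non-negative")


@dataclass
class ModelFit:
    """Result of a maximum-likelihood fit."""

    model_name: str
    lnL: float
    mle: dict[str, float]
    npar: int
    mixture: SiteClassMixture
    tree: PhyloTree
    # log per-site per-class likelihoods (n_sites x n_classes), without the
    # mixture weights; retained for empirical-Bayes site posteriors
    site_class_loglik: np.ndarray
    pi: CodonFrequencies
    foreground_branch: Optional[str] = None
    converged: bool = True
    data_fingerprint: str = ""

    @property
    def n_classes(self) -> int:
        return len(self.mixture.classes)


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------


def _deroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a basal bifurcation so branch lengths are identifiable.

    A rooted binary root makes only the sum of its two child edges
    identifiable under a reversible model; merging them gives the unrooted
    parameterization codeml uses.  Foreground marks on either merged edge are
    preserved.
    """
    tree = tree.copy()
    root = tree.root
    while len(root.children) == 2 and tree.n_leaves >= 3:
        a, b = root.children
        keep, merge = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:  # two leaves only; nothing to do
            break
        merge.length = (merge.length or 0.0) + (keep.length or 0.0)
        if keep.label is not None and merge.label is None:
            merge.label = keep.label
        root.children = list(keep.children) + [merge]
        for child in root.children:
            child.parent = root
        root.name = root.name or keep.name
    return tree


class LikelihoodEngine:
    """Pruning likelihood for one (tree, alignment) pair.

    Holds the precomputed leaf codon indices and the spectral cache; all
    model families share it.  Branch order is the preorder of non-root nodes
    of the derooted tree.
    """

    def __init__(
        self,
        tree: PhyloTree,
        alignment: CodonAlignment,
        code: GeneticCode = STANDARD_CODE,
        pi: Optional[CodonFrequencies] = None,
    ):
        check_tree_alignment_consistency(tree, alignment.taxa)
        self.code = code
        self.pi = pi if pi is not None else f3x4_frequencies(alignment, code)
        self.tree = _deroot(tree)
        self.alignment = alignment
        self.n_sites = alignment.n_codons
        index = {c: i for i, c in enumerate(code.sense_codons)}
        self.leaf_codes: dict[str, np.ndarray] = {}
        for taxon, row in zip(alignment.taxa, alignment.codons):
            try:
                self.leaf_codes[taxon] = np.array([index[c] for c in row])
            except KeyError as exc:
                raise ValueError(
                    f"sequence {taxon!r} contains a non-sense codon {exc}; clean the alignment first"
                ) from exc
        self.branch_nodes: list[TreeNode] = [
            n for n in self.tree.root.preorder() if n is not self.tree.root
        ]
        self.n_branches = len(self.branch_nodes)
        self.foreground_mask = np.array(
            [n.label == 1 for n in self.branch_nodes], dtype=bool
        )
        self._spectral_cache: dict[tuple[float, float], SpectralQ] = {}

    # -- spectral cache ----------------------------------------------------

    def spectral(self, kappa: float, omega: float) -> SpectralQ:
        key = (kappa, omega)
        hit = self._spectral_cache.get(key)
        if hit is None:
            if len(self._spectral_cache) > 512:
                self._spectral_cache.clear()
            Q = _unscaled_rates(kappa, omega, self.pi, self.code)
            Q, _ = _normalize(Q, self.pi.pi)
            hit = SpectralQ(Q, self.pi.pi)
            self._spectral_cache[key] = hit
        return hit

    def tree_branch_lengths(self) -> np.ndarray:
        """Branch lengths exactly as carried on the tree (missing -> 0.1)."""
        return np.array(
            [n.length if n.length is not None else 0.1 for n in self.branch_nodes]
        )

    def initial_branch_lengths(self) -> np.ndarray:
        """Optimizer start: tree lengths floored away from the 0 boundary."""
        return np.clip(self.tree_branch_lengths(), 1e-4, BL_MAX)

    # -- pruning -----------------------------------------------------------

    def class_site_logliks(
        self,
        kappa: float,
        classes: Sequence[SiteClass],
        branch_lengths: np.ndarray,
    ) -> np.ndarray:
        """Log-likelihood of every site under every class (sites x classes)."""
        out = np.empty((self.n_sites, len(classes)))
        for k, cls in enumerate(classes):
            out[:, k] = self._one_class_site_logliks(
                kappa, cls.omega_background, cls.omega_foreground, branch_lengths
            )
        return out

    def _one_class_site_logliks(
        self,
        kappa: float,
        omega_background: float,
        omega_foreground: float,
        branch_lengths: np.ndarray,
    ) -> np.ndarray:
        spec_bg = self.spectral(kappa, omega_background)
        spec_fg = (
            spec_bg
            if omega_foreground == omega_background
            else self.spectral(kappa, omega_foreground)
        )
        P: dict[int, np.ndarray] = {}
        for b, node in enumerate(self.branch_nodes):
            spec = spec_fg if self.foreground_mask[b] else spec_bg
            P[id(node)] = spec.transition(branch_lengths[b])
        logscale = np.zeros(self.n_sites)
        partial = self._prune(self.tree.root, P, logscale)
        site_lik = self.pi.pi @ partial
        # floor keeps the objective finite at pathological parameter corners
        return np.log(np.clip(site_lik, 1e-300, None)) + logscale

    def _prune(
        self, node: TreeNode, P: dict[int, np.ndarray], logscale: np.ndarray
    ) -> np.ndarray:
        partial: Optional[np.ndarray] = None
        for child in node.children:
            if child.is_leaf:
                contrib = P[id(child)][:, self.leaf_codes[child.name]]
            else:
                contrib = P[id(child)] @ self._prune(child, P, logscale)
            partial = contrib if partial is None else partial * contrib
        assert partial is not None
        scale = partial.max(axis=0)
        np.clip(scale, 1e-300, None, out=scale)
        partial = partial / scale
        logscale += np.log(scale)
        return partial

    def total_lnL(
        self,
        kappa: float,
        classes: Sequence[SiteClass],
        branch_lengths: np.ndarray,
    ) -> tuple[float, np.ndarray]:
        """Total log-likelihood and the site x class log-likelihood matrix."""
        scl = self.class_site_logliks(kappa, classes, branch_lengths)
        props = np.array([c.proportion for c in classes])
        total = float(_mixture_lnL(scl, props))
        return total, scl


def _mixture_lnL(site_class_loglik: np.ndarray, proportions: np.ndarray) -> float:
    active = proportions > 0
    lse = special.logsumexp(
        site_class_loglik[:, active] + np.log(proportions[active]), axis=1
    )
    return float(lse.sum())


def site_likelihoods(
    tree: PhyloTree,
    alignment: CodonAlignment,
    mixture: SiteClassMixture,
    branch_lengths: Optional[np.ndarray] = None,
    code: GeneticCode = STANDARD_CODE,
    pi: Optional[CodonFrequencies] = None,
) -> tuple[np.ndarray, float]:
    """Per-site per-class log-likelihoods and total lnL for a fixed model.

    Branch lengths default to those on the tree.  Foreground-marked branches
    (label ``#1``) use each class's foreground omega.
    """
    engine = LikelihoodEngine(tree, alignment, code=code, pi=pi)
    bl = branch_lengths if branch_lengths is not None else engine.tree_branch_lengths()
    total, scl = engine.total_lnL(mixture.kappa, mixture.classes, np.asarray(bl, float))
    return scl, total


# ---------------------------------------------------------------------------
# Model parameterizations
# ---------------------------------------------------------------------------


class _ModelParam:
    """Maps a named free-parameter vector to a concrete class list."""

    def __init__(self, name: str):
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        self.name = name

    def param_names(self) -> list[str]:
        return {
            "M0": ["omega"],
            "M1a": ["p0", "omega0"],
            "M2a": ["q0", "q1", "omega0", "omega2"],
            "M7": ["beta_p", "beta_q"],
            "M8": ["p0", "beta_p", "beta_q", "omega_s"],
            "branch-alt": ["omega_background", "omega_foreground"],
            "branch-null": ["omega_background"],
            "branch-site-alt": ["q0", "q1", "omega0", "omega2"],
            "branch-site-null": ["q0", "q1", "omega0"],
        }[self.name]

    def bounds(self) -> list[tuple[float, float]]:
        b = {
            "omega": (OMEGA_MIN, OMEGA_MAX),
            "omega0": (OMEGA_MIN, 1.0 - 1e-6),
            "omega2": (1.0, OMEGA_MAX),
            "omega_s": (1.0, OMEGA_MAX),
            "omega_background": (OMEGA_MIN, OMEGA_MAX),
            "omega_foreground": (OMEGA_MIN, OMEGA_MAX),
            "p0": (PROP_EPS, 1.0 - PROP_EPS),
            "q0": (PROP_EPS, 1.0 - PROP_EPS),
            "q1": (PROP_EPS, 1.0 - PROP_EPS),
            "beta_p": (BETA_MIN, BETA_MAX),
            "beta_q": (BETA_MIN, BETA_MAX),
        }
        return [b[n] for n in self.param_names()]

    def initial(self, init_omega: float = 1.0) -> list[float]:
        w = float(np.clip(init_omega, OMEGA_MIN, OMEGA_MAX))
        w01 = float(np.clip(init_omega, OMEGA_MIN, 0.9))
        w_up = float(np.clip(init_omega, 1.5, OMEGA_MAX))
        return {
            "M0": [w],
            "M1a": [0.7, w01],
            "M2a": [0.7, 0.8, w01, w_up],
            "M7": [1.0, 1.0],
            "M8": [0.9, 1.0, 1.0, w_up],
            "branch-alt": [w, w],
            "branch-null": [w],
            "branch-site-alt": [0.7, 0.8, w01, w_up],
            "branch-site-null": [0.7, 0.8, w01],
        }[self.name]

    def classes(self, values: Sequence[float], K: int) -> tuple[SiteClass, ...]:
        v = dict(zip(self.param_names(), values))
        U = SiteClass.uniform_omega
        if self.name == "M0":
            return (U(1.0, v["omega"]),)
        if self.name == "M1a":
            return (U(v["p0"], v["omega0"]), U(1.0 - v["p0"], 1.0))
        if self.name == "M2a":
            p0 = v["q0"]
            p1 = (1.0 - v["q0"]) * v["q1"]
            p2 = 1.0 - p0 - p1
            return (U(p0, v["omega0"]), U(p1, 1.0), U(p2, v["omega2"]))
        if self.name == "M7":
            cats = discretize_beta(v["beta_p"], v["beta_q"], K)
            return tuple(U(1.0 / K, w) for w in cats)
        if self.name == "M8":
            cats = discretize_beta(v["beta_p"], v["beta_q"], K)
            p0 = v["p0"]
            beta_classes = tuple(U(p0 / K, w) for w in cats)
            return beta_classes + (U(1.0 - p0, v["omega_s"]),)
        if self.name == "branch-alt":
            return (SiteClass(1.0, v["omega_background"], v["omega_foreground"]),)
        if self.name == "branch-null":
            return (SiteClass(1.0, v["omega_background"], 1.0),)
        if self.name in ("branch-site-alt", "branch-site-null"):
            w2 = v.get("omega2", 1.0)
            p0 = v["q0"] * v["q1"]
            p1 = v["q0"] * (1.0 - v["q1"])
            p2a = (1.0 - v["q0"]) * v["q1"]
            p2b = (1.0 - v["q0"]) * (1.0 - v["q1"])
            return (
                SiteClass(p0, v["omega0"], v["omega0"]),
                SiteClass(p1, 1.0, 1.0),
                SiteClass(p2a, v["omega0"], w2),
                SiteClass(p2b, 1.0, w2),
            )
        raise AssertionError(self.name)

    def readable_mle(self, values: Sequence[float], K: int) -> dict[str, float]:
        v = dict(zip(self.param_names(), values))
        out = dict(v)
        if self.name in ("M2a", "branch-site-alt", "branch-site-null"):
            # keep the stick-breaking coordinates and add plain proportions
            classes = self.classes(values, K)
            for k, cls in enumerate(classes):
                out[f"p{'01ab'[k] if len(classes) == 4 else k}"] = cls.proportion
        return out

    @property
    def needs_foreground(self) -> bool:
        return self.name.startswith("branch")


@dataclass
class FitOptions:
    """Knobs for :func:`fit_model`.

    ``init_omega`` mirrors the tool's ``omega`` control parameter (default
    1); ``n_restarts`` jittered restarts guard against local optima;
    ``fix_branch_lengths`` skips branch-length re-optimization and uses the
    given vector (e.g. from a previous M0 fit) for speed.
    """

    init_omega: float = 1.0
    init_kappa: float = 2.0
    n_restarts: int = 3
    beta_categories: int = DEFAULT_BETA_CATEGORIES
    fix_branch_lengths: Optional[np.ndarray] = None
    seed: int = 0
    maxiter: int = 500
    warm_start: Optional[ModelFit] = None


def fit_model(
    tree: PhyloTree,
    alignment: CodonAlignment,
    model_name: str,
    options: Optional[FitOptions] = None,
    code: GeneticCode = STANDARD_CODE,
    pi: Optional[CodonFrequencies] = None,
    engine: Optional[LikelihoodEngine] = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model family on one dataset.

    Branch lengths are re-optimized under every model unless
    ``options.fix_branch_lengths`` is provided.  Nested alternatives should
    pass the null's fit as ``options.warm_start`` so that
    ``lnL(alt) >= lnL(null)`` holds by construction; :func:`fit_nested_pair`
    does this automatically.
    """
    opts = options or FitOptions()
    param = _ModelParam(model_name)
    if engine is None:
        engine = LikelihoodEngine(tree, alignment, code=code, pi=pi)
    if param.needs_foreground and not engine.foreground_mask.any():
        raise ValueError(f"model {model_name} requires a '#1'-marked foreground branch")

    free_bl = opts.fix_branch_lengths is None
    fixed_bl = None if free_bl else np.asarray(opts.fix_branch_lengths, float)
    K = opts.beta_categories

    names = ["kappa"] + param.param_names()
    bounds = [(KAPPA_MIN, KAPPA_MAX)] + param.bounds()
    x0 = [opts.init_kappa] + param.initial(opts.init_omega)
    if free_bl:
        bl0 = engine.initial_branch_lengths()
        bounds += [(BL_MIN, BL_MAX)] * engine.n_branches
        x0 = x0 + list(bl0)
    n_model = 1 + len(param.param_names())

    def unpack(x: np.ndarray) -> tuple[float, tuple[SiteClass, ...], np.ndarray]:
        kappa = float(x[0])
        classes = param.classes(x[1:n_model], K)
        bl = x[n_model:] if free_bl else fixed_bl
        return kappa, classes, np.asarray(bl, float)

    def objective(x: np.ndarray) -> float:
        kappa, classes, bl = unpack(x)
        scl = engine.class_site_logliks(kappa, classes, bl)
        props = np.array([c.proportion for c in classes])
        return -_mixture_lnL(scl, props)

    starts: list[np.ndarray] = []
    if opts.warm_start is not None:
        starts.append(_warm_start_vector(param, opts.warm_start, np.array(x0), free_bl, n_model))
    starts.append(np.array(x0, dtype=float))
    rng = np.random.default_rng(opts.seed)
    for _ in range(max(0, opts.n_restarts - 1)):
        jitter = np.array(x0, dtype=float)
        for i, (lo, hi) in enumerate(bounds):
            span = min(hi - lo, 2.0)
            jitter[i] = float(np.clip(jitter[i] * rng.uniform(0.5, 2.0), lo + 1e-9, hi - 1e-9)) \
                if hi - lo > 1e-6 else jitter[i]
            del span
        starts.append(jitter)

    best = None
    for start in starts:
        res = optimize.minimize(
            objective,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": SMALL_DIFF, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-12 or (
            abs(res.fun - best.fun) <= 1e-12 and tuple(res.x) < tuple(best.x)
        ):
            best = res
    assert best is not None

    kappa, classes, bl = unpack(best.x)
    scl = engine.class_site_logliks(kappa, classes, bl)
    mixture = SiteClassMixture(
        model_name=model_name,
        classes=classes,
        kappa=kappa,
        extra=param.readable_mle(best.x[1:n_model], K),
    )
    fitted_tree = engine.tree.copy()
    fitted_nodes = [n for n in fitted_tree.root.preorder() if n is not fitted_tree.root]
    for node, length in zip(fitted_nodes, bl):
        node.length = float(length)
    mle = {"kappa": kappa, **param.readable_mle(best.x[1:n_model], K)}
    if free_bl:
        mle["tree_length"] = float(np.sum(bl))
    npar = n_model + (engine.n_branches if free_bl else 0)
    fg = None
    if engine.foreground_mask.any():
        from .tree_topologies import branch_id

        fg = branch_id(engine.branch_nodes[int(np.argmax(engine.foreground_mask))])
    return ModelFit(
        model_name=model_name,
        lnL=-float(best.fun),
        mle=mle,
        npar=npar,
        mixture=mixture,
        tree=fitted_tree,
        site_class_loglik=scl,
        pi=engine.pi,
        foreground_branch=fg,
        converged=bool(best.success),
        data_fingerprint=alignment.fingerprint_text(),
    )


def _warm_start_vector(
    param: _ModelParam,
    warm: ModelFit,
    default: np.ndarray,
    free_bl: bool,
    n_model: int,
) -> np.ndarray:
    """Seed a fit from a (typically nested-null) previous fit.

    The start point is mapped so that the alternative's initial likelihood
    equals the null optimum: extra classes get (near-)zero weight and
    boundary omegas, guaranteeing lnL(alt) >= lnL(null) after optimization.
    """
    x = default.astype(float).copy()
    x[0] = warm.mle.get("kappa", x[0])
    source = {**warm.mixture.extra, **warm.mle}
    if param.name == "M2a" and warm.model_name == "M1a":
        # p2 -> 0: the positive-selection class starts empty
        source = {**source, "q0": source.get("p0", 0.7), "q1": 1.0 - PROP_EPS, "omega2": 1.0}
    elif param.name == "M8" and warm.model_name == "M7":
        source = {**source, "p0": 1.0 - PROP_EPS, "omega_s": 1.0}
    elif param.name.endswith("-alt"):
        source.setdefault("omega2", 1.0)
        source.setdefault("omega_foreground", 1.0)
    for i, name in enumerate(param.param_names(), start=1):
        if name in source:
            lo, hi = param.bounds()[i - 1]
            x[i] = float(np.clip(source[name], lo, hi))
    if free_bl:
        warm_nodes = [
            n for n in warm.tree.root.preorder() if n is not warm.tree.root
        ]
        if len(warm_nodes) == len(x) - n_model:
            x[n_model:] = [n.length or 0.1 for n in warm_nodes]
    return x


def make_mixture(
    model_name: str,
    kappa: float,
    beta_categories: int = DEFAULT_BETA_CATEGORIES,
    **params: float,
) -> SiteClassMixture:
    """Build a concrete :class:`SiteClassMixture` from named parameters.

    Parameter names follow the fit parameterization of each family, e.g.
    ``make_mixture("M1a", kappa=2, p0=0.7, omega0=0.2)`` or
    ``make_mixture("M8", kappa=2, p0=0.9, beta_p=1, beta_q=2, omega_s=4)``.
    Mixture-weight parameters for M2a and the branch-site grid use the
    stick-breaking coordinates ``q0``/``q1``.
    """
    param = _ModelParam(model_name)
    names = param.param_names()
    missing = [n for n in names if n not in params]
    if missing:
        raise ValueError(f"model {model_name} needs parameters {missing}")
    values = [float(params[n]) for n in names]
    return SiteClassMixture(
        model_name=model_name,
        classes=param.classes(values, beta_categories),
        kappa=float(kappa),
        extra=param.readable_mle(values, beta_categories),
    )


NESTED_PAIRS = {
    "M1a/M2a": ("M1a", "M2a", 2),
    "M7/M8": ("M7", "M8", 2),
    "branch": ("branch-null", "branch-alt", 1),
    "branch-site": ("branch-site-null", "branch-site-alt", 1),
}


def fit_nested_pair(
    tree: PhyloTree,
    alignment: CodonAlignment,
    pair: str,
    options: Optional[FitOptions] = None,
    code: GeneticCode = STANDARD_CODE,
    pi: Optional[CodonFrequencies] = None,
    engine: Optional[LikelihoodEngine] = None,
) -> tuple[ModelFit, ModelFit, int]:
    """Fit a null/alternative pair with the alternative warm-started at the
    null's optimum, returning (null_fit, alt_fit, df)."""
    if pair not in NESTED_PAIRS:
        raise ValueError(f"unknown pair {pair!r}; choose from {sorted(NESTED_PAIRS)}")
    null_name, alt_name, df = NESTED_PAIRS[pair]
    opts = options or FitOptions()
    null_fit = fit_model(tree, alignment, null_name, opts, code=code, pi=pi, engine=engine)
    alt_opts = FitOptions(**{**opts.__dict__, "warm_start": null_fit})
    alt_fit = fit_model(tree, alignment, alt_name, alt_opts, code=code, pi=pi, engine=engine)
    return null_fit, alt_fit, df
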