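"""Phylogenetic codon-alignment simulation under the implemented models.

The simulator is the package's synthetic-data generator: it draws root
codons from the equilibrium frequencies and evolves them along the tree
with the exact transition matrices of the likelihood core, so simulate-then-
fit round trips are a direct test of the estimators.  Site classes are drawn
i.i.d. per codon from the mixture (the models' own assumption); branch-site
specs apply each class's foreground omega on ``#1``-marked branches.  Every
draw is determined by the spec's seed.

It also hosts the calibration harness (:func:`type1_power_experiment`) that
measures empirical type-I error and power of the likelihood-ratio tests on
simulated replicates, and helpers that write FASTA/Newick/ctl fixture sets
consumable by the orchestrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codon_core import (
    STANDARD_CODE,
    CodonAlignment,
    CodonFrequencies,
    GeneticCode,
    equal_frequencies,
    write_fasta_codon_alignment,
)
from .codon_models import (
    FitOptions,
    LikelihoodEngine,
    SiteClassMixture,
    fit_nested_pair,
    _deroot,
)
from .selection_tests import lrt_pvalue
from .tree_topologies import PhyloTree

__all__ = [
    "SimulationSpec",
    "simulate_alignment",
    "type1_power_experiment",
    "write_fixture_set",
    "balanced_tree",
    "three_taxon_tree",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Everything that determines one simulated alignment.

    ``tree`` must carry branch lengths (expected substitutions per codon).
    ``mixture`` is the generating model, including kappa and, for branch or
    branch-site models, per-class foreground omegas applied on branches the
    tree marks with ``#1``.  ``seed`` fully determines the output.
    """

    tree: PhyloTree
    mixture: SiteClassMixture
    n_codons: int
    seed: int
    pi: Optional[CodonFrequencies] = None
    code: GeneticCode = field(default=STANDARD_CODE)

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise ValueError(f"need at least one codon, got {self.n_codons}")
        if any(n.length is None for n in self.tree.root.preorder() if n.parent is not None):
            raise ValueError("simulation tree must have branch lengths on every branch")


def simulate_alignment(spec: SimulationSpec) -> tuple[CodonAlignment, np.ndarray]:
    """Simulate a codon alignment; returns it with the true per-site class.

    Root states are drawn from pi; each branch applies P(t) of the site's
    class (foreground omega on ``#1`` branches).  The returned label array
    gives each codon's generating mixture class index.
    """
    code = spec.code
    pi = spec.pi if spec.pi is not None else equal_frequencies(code)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_codons
    classes = spec.mixture.classes
    proportions = np.array([c.proportion for c in classes])
    labels = rng.choice(len(classes), size=n, p=proportions / proportions.sum())
    root_states = rng.choice(len(pi.pi), size=n, p=pi.pi / pi.pi.sum())

    # spectral cache shared across branches via a throwaway engine-like dict
    from .codon_models import SpectralQ, _normalize, _unscaled_rates

    spectral: dict[float, SpectralQ] = {}

    def get_spectral(omega: float) -> SpectralQ:
        if omega not in spectral:
            Q = _unscaled_rates(spec.mixture.kappa, omega, pi, code)
            Q, _ = _normalize(Q, pi.pi)
            spectral[omega] = SpectralQ(Q, pi.pi)
        return spectral[omega]

    tree = _deroot(spec.tree)
    states: dict[int, np.ndarray] = {id(tree.root): root_states}
    leaf_states: dict[str, np.ndarray] = {}
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        parent_states = states[id(node.parent)]
        child = np.empty(n, dtype=int)
        foreground = node.label == 1
        for k, cls in enumerate(classes):
            mask = labels == k
            if not mask.any():
                continue
            omega = cls.omega_foreground if foreground else cls.omega_background
            P = get_spectral(omega).transition(float(node.length))
            cum = np.cumsum(P, axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_states[mask]]
            child[mask] = (rows < u[:, None]).sum(axis=1).clip(max=len(pi.pi) - 1)
        states[id(node)] = child
        if node.is_leaf:
            leaf_states[node.name] = child

    sense = code.sense_codons
    taxa = tree.leaf_names
    codons = [[sense[s] for s in leaf_states[t]] for t in taxa]
    return CodonAlignment(taxa=taxa, codons=codons), labels


# ---------------------------------------------------------------------------
# Fixture trees
# ---------------------------------------------------------------------------


def three_taxon_tree(t: float = 0.3) -> PhyloTree:
    """The three-taxon shape of the smallest worked dataset (an outgroup and
    two ingroup species), equal branch lengths ``t``."""
    from .tree_topologies import parse_newick

    return parse_newick(f"(Out:{t},SpeciesA:{t},SpeciesB:{t});")


def balanced_tree(n_leaves: int, branch_length: float = 0.1, seed: int = 0) -> PhyloTree:
    """A random bifurcating tree with ``n_leaves`` named leaves.

    With n leaves the unrooted tree has 2n-3 branches (47 at the 25-taxon
    scale of the abalone lysin example).
    """
    from .tree_topologies import parse_newick

    rng = np.random.default_rng(seed)
    clades = [f"T{i + 1}:{branch_length:g}" for i in range(n_leaves)]
    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        b = clades.pop(j)
        a = clades.pop(i)
        clades.append(f"({a},{b}):{branch_length:g}")
    return parse_newick(clades[0] + ";")


# ---------------------------------------------------------------------------
# Calibration experiments
# ---------------------------------------------------------------------------


def type1_power_experiment(
    regimes: dict[str, SimulationSpec],
    comparisons: Sequence[str],
    replicates: int,
    significance: float = 0.05,
    seed: int = 0,
    fit_options: Optional[FitOptions] = None,
    reuse_m0_branch_lengths: bool = True,
) -> pd.DataFrame:
    """Empirical rejection rates of the LRT comparisons on simulated data.

    For every regime (a named :class:`SimulationSpec` whose seed is re-drawn
    per replicate) and every nested comparison, simulates, fits both models
    and records whether p <= significance.  Returns a table with one row per
    (regime, comparison): rejection proportion and a Wilson 95% interval.
    With ``reuse_m0_branch_lengths`` (default) branch lengths are estimated
    once per replicate under M0 and held fixed across the site-model fits —
    the documented fast path for calibration sweeps.
    """
    from .codon_models import fit_model

    columns = [
        "regime", "comparison", "replicates", "rejections",
        "rejection_rate", "ci_low", "ci_high",
    ]
    if replicates == 0:
        return pd.DataFrame(columns=columns)
    rows = []
    rng = np.random.default_rng(seed)
    base_opts = fit_options or FitOptions(n_restarts=1)
    records: dict[tuple[str, str], list[float]] = {
        (regime, cmp): [] for regime in regimes for cmp in comparisons
    }
    for regime_name, spec in regimes.items():
        for rep in range(replicates):
            rep_seed = int(rng.integers(0, 2**31 - 1))
            rep_spec = SimulationSpec(
                tree=spec.tree,
                mixture=spec.mixture,
                n_codons=spec.n_codons,
                seed=rep_seed,
                pi=spec.pi,
                code=spec.code,
            )
            alignment, _ = simulate_alignment(rep_spec)
            pi = spec.pi if spec.pi is not None else equal_frequencies(spec.code)
            engine = LikelihoodEngine(spec.tree, alignment, code=spec.code, pi=pi)
            opts = base_opts
            if reuse_m0_branch_lengths:
                m0 = fit_model(
                    spec.tree, alignment, "M0", base_opts, code=spec.code, pi=pi, engine=engine
                )
                bl = np.array(
                    [n.length for n in m0.tree.root.preorder() if n.parent is not None]
                )
                opts = FitOptions(**{**base_opts.__dict__, "fix_branch_lengths": bl})
            for cmp in comparisons:
                null_fit, alt_fit, df = fit_nested_pair(
                    spec.tree, alignment, cmp, opts, code=spec.code, pi=pi, engine=engine
                )
                res = lrt_pvalue(null_fit.lnL, alt_fit.lnL, df)
                records[(regime_name, cmp)].append(res.p_value)
    for (regime_name, cmp), pvals in records.items():
        pvals_arr = np.asarray(pvals)
        k = int((pvals_arr <= significance).sum()) if len(pvals_arr) else 0
        n = len(pvals_arr)
        lo, hi = _wilson_interval(k, n) if n else (float("nan"), float("nan"))
        rows.append(
            {
                "regime": regime_name,
                "comparison": cmp,
                "replicates": n,
                "rejections": k,
                "rejection_rate": k / n if n else float("nan"),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows, columns=columns)


def _wilson_interval(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


# ---------------------------------------------------------------------------
# Fixture emission for end-to-end runs
# ---------------------------------------------------------------------------


def write_fixture_set(
    spec: SimulationSpec,
    directory: Path | str,
    basename: str = "dataset",
    tests: str = "123h",
    extra_ctl: Optional[dict[str, str]] = None,
) -> dict[str, Path]:
    """Write a FASTA + Newick + ctl trio the orchestrator can run directly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    alignment, _ = simulate_alignment(spec)
    seq_path = directory / f"{basename}.fasta"
    tree_path = directory / f"{basename}.tre"
    ctl_path = directory / f"{basename}.ctl"
    write_fasta_codon_alignment(alignment, seq_path)
    unlabelled = spec.tree.copy()
    unlabelled.clear_labels()
    tree_path.write_text(unlabelled.to_newick() + "\n")
    lines = [f"seqfile = {seq_path.name}", f"treefile = {tree_path.name}"]
    for key, value in (extra_ctl or {}).items():
        lines.append(f"{key} = {value}")
    ctl_path.write_text("\n".join(lines) + "\n")
    return {"seqfile": seq_path, "treefile": tree_path, "ctlfile": ctl_path}
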