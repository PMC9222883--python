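"""Compile all test results into the summary file, the per-codon overview
table, the highlighted FASTA, and p-value-annotated trees.

The summary lists, per model comparison, the two log-likelihoods, the LRT
statistic, its degrees of freedom and chi-squared p-value, plus a verdict at
the configured significance threshold; branch-level tests additionally name
their foreground branch by the sorted leaf set it subtends and by the
``#1``-labelled Newick string for copy-paste reproducibility.  The codon
overview maps every cleaned-alignment codon (and its original column) to
its site-specific results across all tests; the highlighted FASTA uppercases
exactly the significant codons.  All outputs are deterministic for identical
inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .codon_core import STANDARD_CODE, CodonAlignment, CodonFrequencies
from .orchestrator import RunConfig, TaskRecord, deserialize_fit
from .selection_tests import (
    LRTResult,
    SiteSelectionRecord,
    model_comparison,
    site_posteriors,
)
from .tree_topologies import PhyloTree, enumerate_foreground_topologies

__all__ = ["CompiledResults", "compile_results", "codon_overview_table", "highlight_fasta"]


@dataclass
class BranchTestResult:
    test: str  # "branch" | "branch-site"
    topology_index: int
    foreground_branch: str
    labelled_newick: str
    lrt: LRTResult
    omega_foreground: Optional[float] = None
    sites: list[SiteSelectionRecord] = field(default_factory=list)


@dataclass
class CompiledResults:
    """Everything the reports are built from."""

    config: RunConfig
    alignment: CodonAlignment
    column_map: list[int]
    site_lrts: dict[str, LRTResult] = field(default_factory=dict)  # M1a/M2a, M7/M8
    site_records: dict[str, list[SiteSelectionRecord]] = field(default_factory=dict)
    branch_results: list[BranchTestResult] = field(default_factory=list)
    fel_sites: list[dict] = field(default_factory=list)
    fel_global: dict = field(default_factory=dict)
    failed_tasks: list[tuple[str, str]] = field(default_factory=list)

    @property
    def significance(self) -> float:
        return self.config.significance

    def significant_site_set(self) -> set[int]:
        """1-based cleaned-alignment indices significant in any site test."""
        out: set[int] = set()
        for records in self.site_records.values():
            out.update(r.codon_index for r in records if r.significant)
        for site in self.fel_sites:
            if site["direction"] != "none":
                out.add(site["codon_index"])
        for branch in self.branch_results:
            out.update(r.codon_index for r in branch.sites if r.significant)
        return out


def compile_results(
    config: RunConfig,
    tasks: list[TaskRecord],
    alignment: CodonAlignment,
    column_map: list[int],
    tree: PhyloTree,
) -> CompiledResults:
    """Aggregate persisted task results, compute the LRTs and empirical-
    Bayes posteriors, and write the four report files into the run directory.

    p-values are recomputed here from the stored lnL values (never copied),
    and failed tasks are carried into the summary rather than dropped.
    """
    pi = config.codon_frequencies(alignment)
    payloads: dict[str, dict] = {}
    compiled = CompiledResults(config=config, alignment=alignment, column_map=list(column_map))
    for task in tasks:
        path = task.result_path or (config.run_dir / "tasks" / task.task_id / "result.json")
        try:
            payload = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            compiled.failed_tasks.append((task.task_id, f"unreadable result: {exc}"))
            continue
        if payload.get("kind") == "error":
            compiled.failed_tasks.append((task.task_id, payload.get("error", "unknown error")))
            continue
        payloads[task.task_id] = payload

    s = config.significance

    def fit_of(task_id: str):
        payload = payloads.get(task_id)
        return None if payload is None else deserialize_fit(payload, alignment, pi)

    # --- test 1: site models -------------------------------------------------
    fits = {m: fit_of(f"t1-{m}") for m in ("M1a", "M2a", "M7", "M8")}
    for pair, null_name, alt_name in (("M1a/M2a", "M1a", "M2a"), ("M7/M8", "M7", "M8")):
        null_fit, alt_fit = fits[null_name], fits[alt_name]
        if null_fit is None or alt_fit is None:
            continue
        lrt = model_comparison(pair, null_fit, alt_fit)
        compiled.site_lrts[pair] = lrt
        for method in ("NEB", "BEB"):
            records = site_posteriors(
                alt_fit, lrt, method=method, significance=s,
                alignment=alignment, tree=tree,
            )
            compiled.site_records[f"{alt_name}-{method}"] = records

    # --- tests 2 & 3: per-topology branch(-site) models ----------------------
    topo_tasks: dict[tuple[str, int], dict[str, str]] = {}
    for task in tasks:
        if task.topology_index is None:
            continue
        test = "branch-site" if task.task_id.startswith("t2") else "branch"
        role = "null" if task.task_id.endswith("null") else "alt"
        topo_tasks.setdefault((test, task.topology_index), {})[role] = task.task_id
    topologies = None
    for (test, index), roles in sorted(topo_tasks.items()):
        null_fit = fit_of(roles.get("null", ""))
        alt_fit = fit_of(roles.get("alt", ""))
        if null_fit is None or alt_fit is None:
            continue
        pair = "branch-site" if test == "branch-site" else "branch"
        lrt = model_comparison(pair, null_fit, alt_fit)
        if topologies is None:
            topologies = enumerate_foreground_topologies(tree)
        topo = topologies[index]
        result = BranchTestResult(
            test=test,
            topology_index=index,
            foreground_branch=topo.foreground_branch,
            labelled_newick=topo.newick(include_lengths=False),
            lrt=lrt,
        )
        if test == "branch":
            result.omega_foreground = alt_fit.mle.get("omega_foreground")
        else:
            result.sites = site_posteriors(
                alt_fit, lrt, method="BEB", significance=s,
                alignment=alignment, tree=topo.tree,
            )
        compiled.branch_results.append(result)

    # --- test h: FEL ---------------------------------------------------------
    fel_payload = payloads.get("th-fel")
    if fel_payload is not None:
        compiled.fel_sites = fel_payload["sites"]
        compiled.fel_global = fel_payload.get("global", {})

    _write_outputs(compiled, tree)
    return compiled


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _write_outputs(compiled: CompiledResults, tree: PhyloTree) -> None:
    run_dir = compiled.config.run_dir
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "summary.txt").write_text(render_summary(compiled))
    codon_overview_table(compiled).to_csv(run_dir / "codon_overview.tsv", sep="\t", index=False)
    (run_dir / "highlighted.fasta").write_text(
        highlight_fasta(compiled.alignment, compiled.significant_site_set())
    )
    (run_dir / "annotated_trees.nwk").write_text(render_annotated_trees(compiled))


def render_summary(compiled: CompiledResults) -> str:
    s = compiled.significance
    lines = [f"# Selection analysis summary: {compiled.config.name}",
             f"# significance threshold s = {s:g}", ""]

    def verdict(p: float) -> str:
        return "SIGNIFICANT" if p <= s else "ns"

    if compiled.site_lrts:
        lines.append("## Test 1: site models")
        for pair, lrt in compiled.site_lrts.items():
            lines.append(
                f"{pair}: lnL_null={lrt.lnL_null:.6f} lnL_alt={lrt.lnL_alt:.6f} "
                f"stat={lrt.statistic:.6f} df={lrt.df} p={lrt.p_value:.6g} {verdict(lrt.p_value)}"
            )
        for test, records in sorted(compiled.site_records.items()):
            hits = [r for r in records if r.significant]
            sites = ", ".join(f"{r.codon_index}({r.score:.3f})" for r in hits) or "-"
            lines.append(f"{test} significant sites (posterior >= {1 - s:g}): {sites}")
        lines.append("")

    for test, title in (("branch-site", "Test 2: branch-site models"), ("branch", "Test 3: branch models")):
        rows = [b for b in compiled.branch_results if b.test == test]
        if not rows:
            continue
        from .selection_tests import benjamini_hochberg

        bh = benjamini_hochberg([b.lrt.p_value for b in rows])
        lines.append(f"## {title}")
        lines.append("# raw per-branch p-values; p_bh adds a Benjamini-Hochberg "
                     "adjustment across the enumerated branches (extension)")
        for b, p_adj in zip(rows, bh):
            extra = ""
            if b.omega_foreground is not None:
                extra = f" omega_fg={b.omega_foreground:.4f}"
            lines.append(
                f"[{b.topology_index:03d}] branch={b.foreground_branch} "
                f"stat={b.lrt.statistic:.6f} df={b.lrt.df} p={b.lrt.p_value:.6g} "
                f"p_bh={p_adj:.6g} {verdict(b.lrt.p_value)}{extra}"
            )
            if b.lrt.p_value <= s:
                lines.append(f"      tree: {b.labelled_newick}")
                if b.sites:
                    hits = [r for r in b.sites if r.significant]
                    sites = ", ".join(f"{r.codon_index}({r.score:.3f})" for r in hits) or "-"
                    lines.append(f"      BEB sites: {sites}")
        lines.append("")

    if compiled.fel_sites:
        lines.append("## Test h: FEL per-site scan")
        pos = [f["codon_index"] for f in compiled.fel_sites if f["direction"] == "positive"]
        neg = [f["codon_index"] for f in compiled.fel_sites if f["direction"] == "negative"]
        g = compiled.fel_global
        if g:
            lines.append(
                f"global fit: kappa={g.get('kappa', float('nan')):.4f} "
                f"omega={g.get('omega', float('nan')):.4f} lnL={g.get('lnL', float('nan')):.6f}"
            )
        lines.append(f"positively selected codons ({len(pos)}): {', '.join(map(str, pos)) or '-'}")
        lines.append(f"negatively selected codons ({len(neg)}): {', '.join(map(str, neg)) or '-'}")
        lines.append("")

    if compiled.failed_tasks:
        lines.append("## Failed tasks")
        for task_id, error in compiled.failed_tasks:
            lines.append(f"{task_id}: {error}")
        lines.append("")
    return "\n".join(lines) + "\n"


def codon_overview_table(compiled: CompiledResults) -> pd.DataFrame:
    """One row per codon of the cleaned alignment, with the per-test results
    mapped onto the reference (first) sequence."""
    aln = compiled.alignment
    ref = aln.codons[0]
    n = aln.n_codons
    colmap = compiled.column_map if compiled.column_map else list(range(n))

    def posterior_column(test: str) -> list[float]:
        records = compiled.site_records.get(test, [])
        by_index = {r.codon_index: r.score for r in records}
        return [by_index.get(i + 1, np.nan) for i in range(n)]

    data: dict[str, list] = {
        "codon": list(range(1, n + 1)),
        "original_codon": [colmap[i] + 1 for i in range(n)],
        "reference_codon": ref,
        "reference_aa": [STANDARD_CODE.translate(c) for c in ref],
    }
    for test in ("M2a-NEB", "M2a-BEB", "M8-NEB", "M8-BEB"):
        data[test] = posterior_column(test)
    fel_by_index = {f["codon_index"]: f for f in compiled.fel_sites}
    data["fel_alpha"] = [fel_by_index.get(i + 1, {}).get("alpha", np.nan) for i in range(n)]
    data["fel_beta"] = [fel_by_index.get(i + 1, {}).get("beta", np.nan) for i in range(n)]
    data["fel_p"] = [fel_by_index.get(i + 1, {}).get("p_value", np.nan) for i in range(n)]
    data["fel_direction"] = [fel_by_index.get(i + 1, {}).get("direction", "") for i in range(n)]
    hits: dict[int, list[str]] = {}
    for b in compiled.branch_results:
        if b.test != "branch-site":
            continue
        for r in b.sites:
            if r.significant:
                hits.setdefault(r.codon_index, []).append(b.foreground_branch)
    data["branch_site_hits"] = [";".join(hits.get(i + 1, [])) for i in range(n)]
    sig = compiled.significant_site_set()
    data["significant"] = [(i + 1) in sig for i in range(n)]
    return pd.DataFrame(data)


def highlight_fasta(alignment: CodonAlignment, significant_sites: set[int]) -> str:
    """FASTA text with significant codons uppercased, everything else
    lowercase; sequence content is otherwise unchanged."""
    lines = []
    for taxon, row in zip(alignment.taxa, alignment.codons):
        lines.append(f">{taxon}")
        seq = "".join(
            codon.upper() if (i + 1) in significant_sites else codon.lower()
            for i, codon in enumerate(row)
        )
        lines.append(seq)
    return "\n".join(lines) + "\n"


def render_annotated_trees(compiled: CompiledResults) -> str:
    """One Newick line per branch test: the '#1'-labelled topology with the
    LRT p-value as a bracketed branch comment."""
    lines = []
    for b in compiled.branch_results:
        marked = b.labelled_newick.replace("#1", f"#1[p={b.lrt.p_value:.4g}]", 1)
        lines.append(f"{b.test}\t{b.foreground_branch}\t{marked}")
    return "\n".join(lines) + ("\n" if lines else "")
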