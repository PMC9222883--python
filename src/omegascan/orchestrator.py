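"""Run configuration, task graph, and parallel execution with resume.

A run is driven by ctl files (``key = value`` lines naming ``seqfile`` and
``treefile``); every other key falls back to the tool defaults below.  The
scheduled work decomposes into independent tasks:

* test ``1`` — the four site-model fits (M1a, M2a, M7, M8);
* test ``2`` — branch-site null + alternative per enumerated foreground
  topology;
* test ``3`` — branch null + alternative per topology;
* test ``h`` — the FEL scan.

Tasks run in separate processes (at most ``threads`` at a time), each
persisting its result atomically (write-then-rename) into its own
subdirectory together with a fingerprint of its exact inputs.  A restarted
run skips every task whose fingerprint matches, so aborted runs continue
where they stopped and re-runs are no-ops.  Aggregation is order-independent
and seeded from the fingerprints, making output identical for any thread
count.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
from concurrent.futures import ProcessPoolExecutor, as_completed
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .codon_core import (
    STANDARD_CODE,
    CodonAlignment,
    CodonFrequencies,
    equal_frequencies,
    f3x4_frequencies,
    read_fasta_codon_alignment,
    remove_gap_codons,
    validate_cds_alignment,
)
from .codon_models import (
    DEFAULT_BETA_CATEGORIES,
    FitOptions,
    LikelihoodEngine,
    ModelFit,
    fit_model,
)
from .tree_topologies import (
    PhyloTree,
    check_tree_alignment_consistency,
    enumerate_foreground_topologies,
    parse_newick,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "TaskRecord",
    "DEFAULT_PARAMS",
    "parse_config",
    "build_task_queue",
    "run_pipeline",
    "run_many",
    "status_and_cleanup",
]

# Default control parameters (codeml-compatible keys).  Keys marked no-op are
# accepted and recorded but have no effect on the native likelihood core.
DEFAULT_PARAMS: dict[str, str] = {
    "CodonFreq": "2",
    "Malpha": "0",
    "Mgene": "0",
    "RateAncestor": "0",
    "Small_Diff": "0.5e-6",
    "aaDist": "0",
    "alpha": "0",
    "cleandata": "1",
    "clock": "0",
    "fix_alpha": "1",
    "fix_blength": "-1",
    "fix_rho": "1",
    "getSE": "0",
    "icode": "0",
    "method": "0",
    "ndata": "1",
    "omega": "1",
    "outfile": "mlc",
    "rho": "0",
    "runmode": "0",
    "seqtype": "1",
}

_NOOP_KEYS = {
    "Malpha", "Mgene", "RateAncestor", "aaDist", "alpha", "clock", "fix_alpha",
    "fix_rho", "getSE", "method", "ndata", "outfile", "rho", "runmode",
    "seqtype", "fix_blength",
}

VALID_TESTS = set("123h")


@dataclass
class RunConfig:
    """One dataset's configuration: input files, tests, and parameters."""

    name: str
    seqfile: Path
    treefile: Path
    workdir: Path
    tests: str = "123h"
    threads: int = 1
    significance: float = 0.05
    keep_dirs: bool = False
    seed: Optional[int] = None
    params: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PARAMS))

    def __post_init__(self) -> None:
        self.tests = "".join(sorted(set(self.tests)))
        if not self.tests or set(self.tests) - VALID_TESTS:
            raise ValueError(f"tests must be a non-empty subset of 123h, got {self.tests!r}")
        if self.threads < 1:
            raise ValueError(f"threads must be >= 1, got {self.threads}")
        if not 0 < self.significance < 1:
            raise ValueError(f"significance must be in (0,1), got {self.significance}")
        unknown = set(self.params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown control parameters: {sorted(unknown)}")
        if self.params.get("icode", "0") != "0":
            raise ValueError("only the standard genetic code (icode 0) is supported")

    @property
    def run_dir(self) -> Path:
        return self.workdir / f"{self.name}.run"

    @property
    def init_omega(self) -> float:
        return float(self.params.get("omega", "1"))

    def codon_frequencies(self, alignment: CodonAlignment) -> CodonFrequencies:
        cf = self.params.get("CodonFreq", "2")
        if cf == "0":
            return equal_frequencies(STANDARD_CODE)
        if cf == "1":
            from .codon_core import f1x4_frequencies

            return f1x4_frequencies(alignment, STANDARD_CODE)
        if cf == "2":
            return f3x4_frequencies(alignment, STANDARD_CODE)
        raise ValueError(f"unsupported CodonFreq {cf!r} (use 0, 1 or 2)")

    def relevant_param_items(self) -> list[tuple[str, str]]:
        """Parameters that actually influence results (for fingerprints)."""
        keys = sorted(set(DEFAULT_PARAMS) - _NOOP_KEYS)
        return [(k, self.params.get(k, DEFAULT_PARAMS[k])) for k in keys]


def parse_config(
    ctl_files: Optional[list[Path | str]] = None,
    overrides: Optional[dict[str, str]] = None,
    workdir: Path | str = ".",
    tests: str = "123h",
    threads: int = 1,
    significance: float = 0.05,
    keep_dirs: bool = False,
    seed: Optional[int] = None,
) -> list[RunConfig]:
    """Parse ctl files (all ``*.ctl`` in ``workdir`` when none are named)
    plus command-line overrides into one :class:`RunConfig` per dataset.

    Lines are ``key = value``, case-insensitive in the key, whitespace
    tolerant; ``seqfile`` and ``treefile`` are mandatory.  Unspecified keys
    take the package defaults; no-op codeml keys are accepted and logged.
    """
    workdir = Path(workdir)
    if ctl_files is None:
        ctl_files = sorted(workdir.glob("*.ctl"))
        if not ctl_files:
            raise FileNotFoundError(f"no .ctl files found in {workdir}")
    configs = []
    canonical = {k.lower(): k for k in DEFAULT_PARAMS}
    for ctl in ctl_files:
        ctl = Path(ctl)
        if not ctl.exists() and not ctl.is_absolute():
            ctl = workdir / ctl
        entries: dict[str, str] = {}
        for raw in ctl.read_text().splitlines():
            line = raw.split("*")[0].strip()  # '*' starts a comment, as in codeml
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{ctl}: cannot parse line {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            entries[key.lower()] = value
        merged = dict(entries)
        for key, value in (overrides or {}).items():
            merged[key.lower()] = value
        if "seqfile" not in merged or "treefile" not in merged:
            raise ValueError(f"{ctl}: ctl file must name both seqfile and treefile")
        seqfile = workdir / merged.pop("seqfile")
        treefile = workdir / merged.pop("treefile")
        params = dict(DEFAULT_PARAMS)
        for key, value in merged.items():
            if key not in canonical:
                raise ValueError(f"{ctl}: unknown control parameter {key!r}")
            name = canonical[key]
            if name in _NOOP_KEYS and value != DEFAULT_PARAMS[name]:
                logger.info("%s: parameter %s=%s accepted but has no effect here", ctl, name, value)
            params[name] = value
        configs.append(
            RunConfig(
                name=ctl.stem,
                seqfile=seqfile,
                treefile=treefile,
                workdir=workdir,
                tests=tests,
                threads=threads,
                significance=significance,
                keep_dirs=keep_dirs,
                seed=seed,
                params=params,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------


def load_inputs(config: RunConfig) -> tuple[CodonAlignment, list[int], PhyloTree]:
    """Read, validate and clean the dataset named by a config.

    Returns the cleaned alignment, the column map to original codon indices,
    and the parsed tree (consistency-checked against the alignment).
    """
    alignment = read_fasta_codon_alignment(config.seqfile)
    cleaned, column_map = remove_gap_codons(alignment)
    violations = validate_cds_alignment(cleaned)
    if violations:
        raise ValueError(
            f"{config.seqfile}: alignment is not analysis-ready:\n  " + "\n  ".join(violations)
        )
    tree = parse_newick(config.treefile.read_text())
    check_tree_alignment_consistency(tree, cleaned.taxa)
    return cleaned, column_map, tree


# ---------------------------------------------------------------------------
# Task queue
# ---------------------------------------------------------------------------


@dataclass
class TaskRecord:
    """One schedulable unit of work."""

    task_id: str
    kind: str  # fit | fel
    model_name: Optional[str] = None  # for fit tasks
    topology_index: Optional[int] = None  # for branch / branch-site tasks
    foreground_branch: Optional[str] = None
    state: str = "pending"  # pending | running | done | failed
    fingerprint: str = ""
    result_path: Optional[Path] = None


def _fingerprint(config: RunConfig, alignment: CodonAlignment, tree_text: str, task_id: str, model: str) -> str:
    h = hashlib.sha256()
    h.update(alignment.fingerprint_text().encode())
    h.update(tree_text.encode())
    h.update(task_id.encode())
    h.update(model.encode())
    for key, value in config.relevant_param_items():
        h.update(f"{key}={value};".encode())
    h.update(f"s={config.significance}".encode())
    return h.hexdigest()


def build_task_queue(
    config: RunConfig, tree: PhyloTree, alignment: CodonAlignment
) -> list[TaskRecord]:
    """Deterministic task list for one dataset.

    |tasks| = 4*[1 in tests] + 2B*[2 in tests] + 2B*[3 in tests] + [h in
    tests], with B the number of enumerable branches of the (unrooted) tree.
    """
    check_tree_alignment_consistency(tree, alignment.taxa)
    tasks: list[TaskRecord] = []
    base_tree_text = tree.to_newick()

    def add(task_id: str, kind: str, model: Optional[str], topo_idx=None, fg=None, tree_text=None):
        tasks.append(
            TaskRecord(
                task_id=task_id,
                kind=kind,
                model_name=model,
                topology_index=topo_idx,
                foreground_branch=fg,
                fingerprint=_fingerprint(
                    config, alignment, tree_text or base_tree_text, task_id, model or kind
                ),
            )
        )

    if "1" in config.tests:
        for model in ("M1a", "M2a", "M7", "M8"):
            add(f"t1-{model}", "fit", model)
    needs_topologies = "2" in config.tests or "3" in config.tests
    topologies = enumerate_foreground_topologies(tree) if needs_topologies else []
    if "2" in config.tests:
        for topo in topologies:
            text = topo.newick()
            add(f"t2-{topo.index:03d}-null", "fit", "branch-site-null", topo.index, topo.foreground_branch, text)
            add(f"t2-{topo.index:03d}-alt", "fit", "branch-site-alt", topo.index, topo.foreground_branch, text)
    if "3" in config.tests:
        for topo in topologies:
            text = topo.newick()
            add(f"t3-{topo.index:03d}-null", "fit", "branch-null", topo.index, topo.foreground_branch, text)
            add(f"t3-{topo.index:03d}-alt", "fit", "branch-alt", topo.index, topo.foreground_branch, text)
    if "h" in config.tests:
        add("th-fel", "fel", None)
    return tasks


# ---------------------------------------------------------------------------
# Task execution (worker side)
# ---------------------------------------------------------------------------


def _task_seed(fingerprint: str, user_seed: Optional[int]) -> int:
    base = int(fingerprint[:8], 16)
    if user_seed is not None:
        base ^= user_seed
    return base % (2**31 - 1)


def _serialize_fit(fit: ModelFit) -> dict:
    return {
        "model_name": fit.model_name,
        "lnL": fit.lnL,
        "mle": {k: float(v) for k, v in fit.mle.items()},
        "npar": fit.npar,
        "kappa": fit.mixture.kappa,
        "classes": [
            [c.proportion, c.omega_background, c.omega_foreground]
            for c in fit.mixture.classes
        ],
        "extra": {k: float(v) for k, v in fit.mixture.extra.items()},
        "tree": fit.tree.to_newick(),
        "site_class_loglik": fit.site_class_loglik.tolist(),
        "foreground_branch": fit.foreground_branch,
        "converged": fit.converged,
    }


def deserialize_fit(payload: dict, alignment: CodonAlignment, pi: CodonFrequencies) -> ModelFit:
    """Rebuild a :class:`ModelFit` from its persisted JSON form."""
    from .codon_models import SiteClass, SiteClassMixture

    mixture = SiteClassMixture(
        model_name=payload["model_name"],
        classes=tuple(SiteClass(p, wb, wf) for p, wb, wf in payload["classes"]),
        kappa=payload["kappa"],
        extra=payload.get("extra", {}),
    )
    return ModelFit(
        model_name=payload["model_name"],
        lnL=payload["lnL"],
        mle=payload["mle"],
        npar=payload["npar"],
        mixture=mixture,
        tree=parse_newick(payload["tree"]),
        site_class_loglik=np.asarray(payload["site_class_loglik"]),
        pi=pi,
        foreground_branch=payload.get("foreground_branch"),
        converged=payload.get("converged", True),
        data_fingerprint=alignment.fingerprint_text(),
    )


def _execute_task(args: tuple[dict, dict]) -> tuple[str, str]:
    """Worker entry point: run one task and persist its result atomically."""
    task, config_state = args
    config = RunConfig(**{**config_state, "seqfile": Path(config_state["seqfile"]),
                          "treefile": Path(config_state["treefile"]),
                          "workdir": Path(config_state["workdir"])})
    try:
        alignment, _, tree = load_inputs(config)
        pi = config.codon_frequencies(alignment)
        seed = _task_seed(task["fingerprint"], config.seed)
        if task["kind"] == "fel":
            from .fel import fel_scan, fit_global_baseline

            baseline = fit_global_baseline(
                tree, alignment, FitOptions(init_omega=config.init_omega, seed=seed),
                pi=pi,
            )
            results = fel_scan(
                tree, alignment, config.significance, pi=pi, baseline=baseline
            )
            payload = {
                "kind": "fel",
                "global": {
                    "kappa": baseline.kappa,
                    "omega": baseline.omega_global,
                    "lnL": baseline.m0_fit.lnL,
                },
                "sites": [
                    {
                        "codon_index": r.codon_index,
                        "alpha": r.alpha,
                        "beta": r.beta,
                        "lnL_free": r.lnL_free,
                        "lnL_constrained": r.lnL_constrained,
                        "p_value": r.p_value,
                        "direction": r.direction,
                    }
                    for r in results
                ],
            }
        else:
            fit_tree = tree
            if task["topology_index"] is not None:
                topo = enumerate_foreground_topologies(tree)[task["topology_index"]]
                fit_tree = topo.tree
            opts = FitOptions(init_omega=config.init_omega, seed=seed)
            alt_pairs = {
                "M2a": "M1a/M2a",
                "M8": "M7/M8",
                "branch-alt": "branch",
                "branch-site-alt": "branch-site",
            }
            if task["model_name"] in alt_pairs:
                # alternative models refit their null in-task and warm-start
                # from it, so nesting holds without cross-task coupling
                from .codon_models import fit_nested_pair

                _, fit, _ = fit_nested_pair(
                    fit_tree, alignment, alt_pairs[task["model_name"]], opts, pi=pi
                )
            else:
                fit = fit_model(fit_tree, alignment, task["model_name"], opts, pi=pi)
            payload = {"kind": "fit", **_serialize_fit(fit)}
            payload["foreground_branch"] = task.get("foreground_branch") or payload["foreground_branch"]
        payload["task_id"] = task["task_id"]
        payload["fingerprint"] = task["fingerprint"]
        _atomic_write_json(Path(task["result_path"]), payload)
        return task["task_id"], "done"
    except Exception as exc:  # failures become content, never silent drops
        payload = {
            "task_id": task["task_id"],
            "fingerprint": task["fingerprint"],
            "kind": "error",
            "error": f"{type(exc).__name__}: {exc}",
        }
        _atomic_write_json(Path(task["result_path"]), payload)
        return task["task_id"], "failed"


def _atomic_write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(".tmp")
    tmp.write_text(json.dumps(payload, indent=1))
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _config_state(config: RunConfig) -> dict:
    state = asdict(config)
    state["seqfile"] = str(config.seqfile)
    state["treefile"] = str(config.treefile)
    state["workdir"] = str(config.workdir)
    return state


def run_pipeline(config: RunConfig, compile_report: bool = True):
    """Execute all scheduled tasks for one dataset and compile the outputs.

    Completed tasks whose stored fingerprint matches are skipped (resume).
    Returns the :class:`~omegascan.report.CompiledResults` (or the task list
    when ``compile_report`` is false).
    """
    alignment, column_map, tree = load_inputs(config)
    tasks = build_task_queue(config, tree, alignment)
    task_dir = config.run_dir / "tasks"
    pending: list[TaskRecord] = []
    for task in tasks:
        task.result_path = task_dir / task.task_id / "result.json"
        if task.result_path.exists():
            try:
                stored = json.loads(task.result_path.read_text())
            except json.JSONDecodeError:
                stored = {}
            if stored.get("fingerprint") == task.fingerprint and stored.get("kind") != "error":
                task.state = "done"
                continue
        pending.append(task)

    job_args = [
        (
            {
                "task_id": t.task_id,
                "kind": t.kind,
                "model_name": t.model_name,
                "topology_index": t.topology_index,
                "foreground_branch": t.foreground_branch,
                "fingerprint": t.fingerprint,
                "result_path": str(t.result_path),
            },
            _config_state(config),
        )
        for t in pending
    ]
    by_id = {t.task_id: t for t in tasks}
    if config.threads == 1 or len(job_args) <= 1:
        for args in job_args:
            task_id, state = _execute_task(args)
            by_id[task_id].state = state
    else:
        with ProcessPoolExecutor(max_workers=config.threads) as pool:
            futures = {pool.submit(_execute_task, args): args[0]["task_id"] for args in job_args}
            for fut in as_completed(futures):
                task_id, state = fut.result()
                by_id[task_id].state = state

    for task in tasks:
        if task.state == "pending":
            task.state = "done"
    if not compile_report:
        return tasks
    from .report import compile_results

    compiled = compile_results(config, tasks, alignment, column_map, tree)
    if not config.keep_dirs:
        pass  # task dirs are removed only by explicit cleanup (-c)
    return compiled


def run_many(configs: list[RunConfig], threads: Optional[int] = None) -> list:
    """Run several datasets through one shared worker pool.

    All datasets' pending tasks feed a single rolling queue, so the first
    task of the next dataset starts as soon as a worker frees up — the
    multi-ctl behaviour of the original workflow.  Reports are compiled per
    dataset once its tasks are done.  Returns the compiled results in
    config order.
    """
    if not configs:
        return []
    threads = threads or max(c.threads for c in configs)
    prepared = []  # (config, alignment, column_map, tree, tasks, pending)
    for config in configs:
        alignment, column_map, tree = load_inputs(config)
        tasks = build_task_queue(config, tree, alignment)
        task_dir = config.run_dir / "tasks"
        pending = []
        for task in tasks:
            task.result_path = task_dir / task.task_id / "result.json"
            if task.result_path.exists():
                try:
                    stored = json.loads(task.result_path.read_text())
                except json.JSONDecodeError:
                    stored = {}
                if stored.get("fingerprint") == task.fingerprint and stored.get("kind") != "error":
                    task.state = "done"
                    continue
            pending.append(task)
        prepared.append((config, alignment, column_map, tree, tasks, pending))

    jobs = []
    for config, _, _, _, tasks, pending in prepared:
        state = _config_state(config)
        for t in pending:
            jobs.append(
                (
                    {
                        "task_id": t.task_id,
                        "kind": t.kind,
                        "model_name": t.model_name,
                        "topology_index": t.topology_index,
                        "foreground_branch": t.foreground_branch,
                        "fingerprint": t.fingerprint,
                        "result_path": str(t.result_path),
                    },
                    state,
                )
            )
    states: dict[tuple[str, str], str] = {}
    if threads == 1 or len(jobs) <= 1:
        for args in jobs:
            task_id, st = _execute_task(args)
            states[(args[1]["name"], task_id)] = st
    else:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            futures = {
                pool.submit(_execute_task, args): (args[1]["name"], args[0]["task_id"])
                for args in jobs
            }
            for fut in as_completed(futures):
                task_id, st = fut.result()
                states[(futures[fut][0], task_id)] = st

    from .report import compile_results

    compiled_all = []
    for config, alignment, column_map, tree, tasks, pending in prepared:
        for t in pending:
            t.state = states.get((config.name, t.task_id), t.state)
        compiled_all.append(compile_results(config, tasks, alignment, column_map, tree))
    return compiled_all


def status_and_cleanup(config: RunConfig, mode: str = "info") -> dict:
    """``info``: count task states from persisted results; ``clean``: remove
    the temporary task directories (kept when the run used ``-d``).

    Both modes are idempotent.
    """
    task_dir = config.run_dir / "tasks"
    if mode == "info":
        counts = {"done": 0, "failed": 0, "pending": 0}
        try:
            alignment, _, tree = load_inputs(config)
            tasks = build_task_queue(config, tree, alignment)
        except (OSError, ValueError):
            return {"error": "inputs unreadable", **counts}
        for task in tasks:
            path = task_dir / task.task_id / "result.json"
            if not path.exists():
                counts["pending"] += 1
                continue
            try:
                stored = json.loads(path.read_text())
            except json.JSONDecodeError:
                counts["pending"] += 1
                continue
            if stored.get("fingerprint") != task.fingerprint:
                counts["pending"] += 1
            elif stored.get("kind") == "error":
                counts["failed"] += 1
            else:
                counts["done"] += 1
        counts["total"] = len(tasks)
        return counts
    if mode == "clean":
        if config.keep_dirs:
            return {"removed": False, "reason": "keep_dirs set"}
        if task_dir.exists():
            shutil.rmtree(task_dir)
            return {"removed": True}
        return {"removed": False, "reason": "nothing to remove"}
    raise ValueError(f"unknown mode {mode!r}")
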