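import json

import numpy as np
import pytest

from omegascan.codon_models import make_mixture
from omegascan.orchestrator import (
    DEFAULT_PARAMS,
    build_task_queue,
    load_inputs,
    parse_config,
    run_pipeline,
    status_and_cleanup,
)
from omegascan.simulator import SimulationSpec, balanced_tree, three_taxon_tree, write_fixture_set


@pytest.fixture
def fixture_dir(tmp_path, star_tree):
    spec = SimulationSpec(
        tree=star_tree,
        mixture=make_mixture("M0", kappa=2.0, omega=0.5),
        n_codons=30,
        seed=8,
    )
    write_fixture_set(spec, tmp_path, basename="toy")
    return tmp_path


class TestParseConfig:
    def test_defaults_applied(self, fixture_dir):
        config = parse_config(workdir=fixture_dir)[0]
        assert config.tests == "123h"
        assert config.significance == 0.05
        assert config.params["CodonFreq"] == "2"
        assert config.params["omega"] == "1"
        assert config.seqfile.name == "toy.fasta"

    def test_override_initial_omega(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, overrides={"omega": "0.5"})[0]
        assert config.init_omega == 0.5

    def test_test_subset_and_case_insensitive_keys(self, fixture_dir):
        ctl = fixture_dir / "toy.ctl"
        ctl.write_text(ctl.read_text() + "CODONFREQ = 0\n")
        config = parse_config(workdir=fixture_dir, tests="1h")[0]
        assert config.tests == "1h"
        assert config.params["CodonFreq"] == "0"

    def test_unknown_key_rejected(self, fixture_dir):
        (fixture_dir / "toy.ctl").write_text(
            "seqfile = toy.fasta\ntreefile = toy.tre\nbogus = 1\n"
        )
        with pytest.raises(ValueError, match="unknown control parameter"):
            parse_config(workdir=fixture_dir)

    def test_noop_codeml_keys_accepted(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, overrides={"Mgene": "9", "rho": "34"})[0]
        assert config.params["Mgene"] == "9"

    def test_missing_seqfile_entry_rejected(self, fixture_dir):
        (fixture_dir / "toy.ctl").write_text("treefile = toy.tre\n")
        with pytest.raises(ValueError, match="seqfile"):
            parse_config(workdir=fixture_dir)

    def test_missing_ctl_files_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_config(workdir=tmp_path)

    def test_invalid_tests_rejected(self, fixture_dir):
        with pytest.raises(ValueError, match="subset"):
            parse_config(workdir=fixture_dir, tests="9")


class TestTaskQueue:
    def test_three_taxon_full_battery_has_17_tasks(self, fixture_dir):
        config = parse_config(workdir=fixture_dir)[0]
        aln, _, tree = load_inputs(config)
        assert len(build_task_queue(config, tree, aln)) == 4 + 3 * 2 + 3 * 2 + 1

    def test_site_models_only_has_4_tasks(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, tests="1")[0]
        aln, _, tree = load_inputs(config)
        assert len(build_task_queue(config, tree, aln)) == 4

    def test_25_taxon_branch_site_test_has_94_tasks(self, tmp_path):
        tree = balanced_tree(25, 0.1, seed=6)
        spec = SimulationSpec(
            tree=tree, mixture=make_mixture("M0", kappa=2, omega=1), n_codons=10, seed=1
        )
        write_fixture_set(spec, tmp_path, basename="big")
        config = parse_config(workdir=tmp_path, tests="2")[0]
        aln, _, t = load_inputs(config)
        assert len(build_task_queue(config, t, aln)) == 47 * 2

    def test_fingerprints_stable_and_input_sensitive(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, tests="1")[0]
        aln, _, tree = load_inputs(config)
        q1 = build_task_queue(config, tree, aln)
        q2 = build_task_queue(config, tree, aln)
        assert [t.fingerprint for t in q1] == [t.fingerprint for t in q2]
        # editing the alignment must invalidate every fingerprint
        mutated = aln.subset_columns(range(aln.n_codons - 1))
        q3 = build_task_queue(config, tree, mutated)
        assert all(a.fingerprint != b.fingerprint for a, b in zip(q1, q3))


class TestPipeline:
    def test_resume_after_interruption_matches_uninterrupted_run(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, tests="1", threads=1)[0]
        run_pipeline(config)
        summary_once = (config.run_dir / "summary.txt").read_text()
        # simulate an aborted run: one result lost, one truncated mid-write
        results = sorted((config.run_dir / "tasks").glob("*/result.json"))
        results[0].unlink()
        results[1].write_text(results[1].read_text()[:40])
        run_pipeline(config)
        assert (config.run_dir / "summary.txt").read_text() == summary_once

    def test_completed_tasks_are_not_recomputed(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, tests="1", threads=1)[0]
        run_pipeline(config)
        stamps = {
            p: p.stat().st_mtime_ns
            for p in (config.run_dir / "tasks").glob("*/result.json")
        }
        run_pipeline(config)
        assert {
            p: p.stat().st_mtime_ns
            for p in (config.run_dir / "tasks").glob("*/result.json")
        } == stamps

    def test_failed_task_is_reported_not_dropped(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, tests="1", threads=1)[0]
        aln, _, tree = load_inputs(config)
        tasks = build_task_queue(config, tree, aln)
        # poison one task result with a matching fingerprint and error kind
        bad = config.run_dir / "tasks" / tasks[0].task_id / "result.json"
        bad.parent.mkdir(parents=True)
        bad.write_text(
            json.dumps(
                {"task_id": tasks[0].task_id, "fingerprint": "stale", "kind": "error", "error": "boom"}
            )
        )
        compiled = run_pipeline(config)  # recomputes: fingerprint mismatch
        assert compiled.failed_tasks == []
        summary = (config.run_dir / "summary.txt").read_text()
        assert "M1a/M2a" in summary

    def test_status_counts_and_cleanup(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, tests="1", threads=1)[0]
        info = status_and_cleanup(config, "info")
        assert info["pending"] == 4 and info["done"] == 0
        run_pipeline(config)
        info = status_and_cleanup(config, "info")
        assert info["done"] == 4 and info["total"] == 4
        assert status_and_cleanup(config, "clean") == {"removed": True}
        assert status_and_cleanup(config, "clean")["removed"] is False

    def test_keep_dirs_blocks_cleanup(self, fixture_dir):
        config = parse_config(workdir=fixture_dir, tests="1", threads=1, keep_dirs=True)[0]
        run_pipeline(config)
        assert status_and_cleanup(config, "clean")["removed"] is False
        assert (config.run_dir / "tasks").exists()


def test_run_many_rolls_multiple_datasets_through_one_pool(tmp_path, star_tree):
    from omegascan.orchestrator import run_many

    for name, seed in (("ds1", 8), ("ds2", 9)):
        spec = SimulationSpec(
            tree=star_tree,
            mixture=make_mixture("M0", kappa=2.0, omega=0.5),
            n_codons=20,
            seed=seed,
        )
        write_fixture_set(spec, tmp_path, basename=name)
    configs = parse_config(workdir=tmp_path, tests="1", threads=2)
    compiled = run_many(configs, threads=2)
    assert len(compiled) == 2
    for config in configs:
        assert (config.run_dir / "summary.txt").exists()
        assert status_and_cleanup(config, "info")["done"] == 4


def test_cli_info_and_run(fixture_dir, capsys):
    from omegascan.cli import main

    rc = main(["-p", "1", "-t", "1", "--workdir", str(fixture_dir)])
    assert rc == 0
    assert "summary.txt" in capsys.readouterr().out
    rc = main(["-i", "--workdir", str(fixture_dir), "-t", "1"])
    assert rc == 0
    assert "'done': 4" in capsys.readouterr().out
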