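"""Module discovery, job expansion, dependency DAG, persistence, execution."""

import json

import numpy as np
import pytest

from voxpipe import engine
from voxpipe.engine import (Pipeline, add_module, build_dependency_graph,
                            discover_modules, execute, load_pipeline,
                            save_pipeline)
from voxpipe.fixtures import CohortSpec, make_cohort
from voxpipe.project import ProjectError, load_project

FAIL_MODULE_SRC = '''
from voxpipe.engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    if context["timepoint"] == params["fail_timepoint"]:
        raise RuntimeError("injected failure")
    return {"copy": inputs["sequence"]}


MODULE = ModuleSpec(
    id="Module_FlakyCopy",
    category="testing",
    params=[
        Param("sequence", "sequence_selector"),
        Param("fail_timepoint", "string", default="-"),
        Param("extension", "string", default="copy"),
    ],
    outputs=[OutputSpec("copy", "Scan", extension_param="extension")],
    run=run,
)
'''


@pytest.fixture
def specs_by_id():
    specs, broken = discover_modules()
    assert not broken
    return {s.id: s for s in specs}


@pytest.fixture
def cohort(tmp_path):
    return make_cohort(CohortSpec(seed=21, roi_per_session=True,
                                  shape=(10, 10, 8)), tmp_path / "cohort")


def two_module_chain(project, specs_by_id):
    pipe = Pipeline(project, "chain")
    add_module(pipe, specs_by_id["Module_Smooth"], {"sequence": "T2w"})
    add_module(pipe, specs_by_id["Module_Smooth"],
               {"sequence": "T2w_smooth", "extension": "s2"})
    return pipe


class TestDiscovery:
    def test_builtin_library_has_at_least_twelve_modules(self):
        specs, broken = discover_modules()
        assert len(specs) >= 12
        assert broken == []
        assert all(s.id.startswith("Module_") for s in specs)

    def test_empty_directory_yields_nothing_extra(self, tmp_path):
        base, _ = discover_modules()
        with_empty, _ = discover_modules([tmp_path])
        assert len(with_empty) == len(base)

    def test_broken_file_reported_not_fatal(self, tmp_path):
        (tmp_path / "module_broken.py").write_text("MODULE = 42\n")
        specs, broken = discover_modules([tmp_path], include_builtin=False)
        assert specs == []
        assert len(broken) == 1
        assert "module_broken" in broken[0][0]

    def test_adding_a_file_changes_next_discovery(self, tmp_path):
        before, _ = discover_modules([tmp_path], include_builtin=False)
        (tmp_path / "module_flaky.py").write_text(FAIL_MODULE_SRC)
        after, _ = discover_modules([tmp_path], include_builtin=False)
        assert [s.id for s in after] == ["Module_FlakyCopy"]
        assert len(after) == len(before) + 1


class TestAddModule:
    def test_one_job_per_session_with_virtual_outputs(self, cohort, specs_by_id):
        pipe = Pipeline(cohort, "p")
        inst = add_module(pipe, specs_by_id["Module_Smooth"],
                          {"sequence": "T2w"})
        assert len(inst.jobs) == 6          # 2 subjects x 3 timepoints
        assert inst.state == "green"
        virtuals = [e for e in cohort.entries
                    if e.sequence_name == "T2w_smooth"]
        assert len(virtuals) == 6
        assert all(e.status == "virtual" for e in virtuals)

    def test_second_module_consumes_virtual_entries(self, cohort, specs_by_id):
        pipe = two_module_chain(cohort, specs_by_id)
        assert len(pipe.modules[1].jobs) == 6
        g = build_dependency_graph(pipe)
        assert g.number_of_edges() == 6

    def test_missing_selector_makes_module_red(self, cohort, specs_by_id):
        pipe = Pipeline(cohort, "p")
        inst = add_module(pipe, specs_by_id["Module_Smooth"],
                          {"sequence": "does_not_exist"})
        assert inst.state == "red"
        assert inst.jobs == []

    def test_invalid_params_rejected(self, cohort, specs_by_id):
        pipe = Pipeline(cohort, "p")
        with pytest.raises(ValueError, match="dimension"):
            add_module(pipe, specs_by_id["Module_Smooth"],
                       {"sequence": "T2w", "dimension": "4D"})
        with pytest.raises(ValueError, match="unknown parameter"):
            add_module(pipe, specs_by_id["Module_Smooth"],
                       {"sequence": "T2w", "zweep": 1})

    def test_insertion_filter_restricts_jobs(self, cohort, specs_by_id):
        pipe = Pipeline(cohort, "p")
        inst = add_module(pipe, specs_by_id["Module_Smooth"],
                          {"sequence": "T2w"}, criteria={"subject": "S01"})
        assert len(inst.jobs) == 3

    def test_job_count_matches_bruteforce_group_oracle(self, cohort, specs_by_id):
        """Jobs == distinct (subject, timepoint) groups holding the inputs."""
        rng = np.random.default_rng(33)
        df = cohort.database
        for _ in range(100):
            seq = str(rng.choice(df["sequence_name"].unique()))
            subjects = list(rng.choice(["S01", "S02"],
                                       size=rng.integers(1, 3), replace=False))
            crit = {"subject": set(subjects)}
            pipe = Pipeline(cohort, "p")
            inst = add_module(pipe, specs_by_id["Module_Smooth"],
                              {"sequence": seq, "extension":
                               f"x{rng.integers(1e9)}"}, criteria=crit)
            expected = {
                (r.subject, r.timepoint)
                for r in df.itertuples()
                if r.sequence_name == seq and r.type == "Scan"
                and r.subject in crit["subject"]
            }
            assert len(inst.jobs) == len(expected)


class TestDependencyGraph:
    def test_single_module_has_no_edges(self, cohort, specs_by_id):
        pipe = Pipeline(cohort, "p")
        add_module(pipe, specs_by_id["Module_Smooth"], {"sequence": "T2w"})
        assert build_dependency_graph(pipe).number_of_edges() == 0

    def test_chain_has_no_cross_subject_edges(self, cohort, specs_by_id):
        pipe = two_module_chain(cohort, specs_by_id)
        g = build_dependency_graph(pipe)
        for a, b in g.edges:
            ja, jb = pipe.job_by_id(a), pipe.job_by_id(b)
            assert (ja.subject, ja.timepoint) == (jb.subject, jb.timepoint)

    def test_fan_in_jobs_have_two_parents(self, cohort, specs_by_id):
        pipe = Pipeline(cohort, "p")
        add_module(pipe, specs_by_id["Module_BrainExtract"], {"sequence": "T2w"})
        add_module(pipe, specs_by_id["Module_Smooth"], {"sequence": "T2w"})
        add_module(pipe, specs_by_id["Module_MaskWithROI"],
                   {"sequence": "T2w_smooth", "roi": "T2w_brain"})
        g = build_dependency_graph(pipe)
        for job in pipe.modules[2].jobs:
            assert g.in_degree(job.id) == 2

    def test_matches_bruteforce_pairwise_io_intersection(self, cohort,
                                                         specs_by_id):
        pipe = Pipeline(cohort, "p")
        add_module(pipe, specs_by_id["Module_BrainExtract"], {"sequence": "T2w"})
        add_module(pipe, specs_by_id["Module_MaskWithROI"],
                   {"sequence": "T2w", "roi": "T2w_brain"})
        g = build_dependency_graph(pipe)
        expected = set()
        for j1 in pipe.jobs:
            for j2 in pipe.jobs:
                if j1 is not j2 and set(j1.outputs.values()) & set(j2.inputs.values()):
                    expected.add((j1.id, j2.id))
        assert set(g.edges) == expected


class TestPersistence:
    def test_save_load_reproduces_job_multiset(self, cohort, specs_by_id,
                                               tmp_path):
        pipe = two_module_chain(cohort, specs_by_id)
        path = save_pipeline(pipe)
        assert path.parent.name == "Saved_Pipelines"
        payload = json.loads(path.read_text())
        assert "jobs" not in json.dumps(payload)  # only modules are stored
        again = load_pipeline(path, cohort)
        assert [m.state for m in again.modules] == ["green", "green"]
        orig = sorted((j.module_id, j.subject, j.timepoint) for j in pipe.jobs)
        back = sorted((j.module_id, j.subject, j.timepoint) for j in again.jobs)
        assert orig == back

    def test_load_on_incompatible_project_propagates_red(self, cohort,
                                                         specs_by_id, tmp_path):
        pipe = two_module_chain(cohort, specs_by_id)
        path = save_pipeline(pipe)
        other = make_cohort(CohortSpec(n_subjects=1, timepoints=("T0",),
                                       sequences=("FLAIR",), shape=(8, 8, 6),
                                       seed=5), tmp_path / "other")
        loaded = load_pipeline(path, other)
        assert [m.state for m in loaded.modules] == ["red", "red"]

    def test_load_after_execution_is_orange(self, cohort, specs_by_id):
        pipe = two_module_chain(cohort, specs_by_id)
        path = save_pipeline(pipe)
        execute(pipe, timestamp="2022-01-01T00:00:00Z")
        reopened = load_project(cohort.root)
        loaded = load_pipeline(path, reopened)
        assert [m.state for m in loaded.modules] == ["orange", "orange"]

    def test_version_incompatible_file_rejected(self, cohort, tmp_path):
        bad = tmp_path / "old.json"
        bad.write_text(json.dumps({"format_version": 99, "modules": []}))
        with pytest.raises(ValueError, match="incompatible"):
            load_pipeline(bad, cohort)


class TestExecution:
    def test_single_and_multi_outputs_byte_identical(self, tmp_path,
                                                     specs_by_id):
        import hashlib

        def run(mode, workers, seed_dir):
            p = make_cohort(CohortSpec(seed=21, roi_per_session=True,
                                       shape=(10, 10, 8)),
                            tmp_path / seed_dir)
            pipe = two_module_chain(p, specs_by_id)
            rep = execute(pipe, mode=mode, workers=workers,
                          timestamp="2022-02-02T00:00:00Z")
            digests = {}
            for f in sorted((p.root / "Derived_data").iterdir()):
                digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
            return rep, digests

        rep_s, d_s = run("single", 1, "a")
        rep_m, d_m = run("multi", 4, "b")
        assert rep_s.counts["done"] == rep_m.counts["done"] == 12
        assert d_s == d_m

    def test_failed_job_skips_descendants_only(self, cohort, tmp_path):
        ext_dir = tmp_path / "ext"
        ext_dir.mkdir()
        (ext_dir / "module_flaky.py").write_text(FAIL_MODULE_SRC)
        specs, _ = discover_modules([ext_dir])
        by = {s.id: s for s in specs}
        pipe = Pipeline(cohort, "p")
        add_module(pipe, by["Module_FlakyCopy"],
                   {"sequence": "T2w", "fail_timepoint": "T1"})
        add_module(pipe, by["Module_Smooth"], {"sequence": "T2w_copy"})
        report = execute(pipe, timestamp="2022-01-01T00:00:00Z")
        assert report.counts == {"done": 8, "failed": 2, "skipped": 2}
        skipped = [r for r in report.job_records if r["state"] == "skipped"]
        assert all("T1" in r["job_id"] for r in skipped)
        # failed jobs leave no partial files in the final folders
        derived = {f.name for f in (cohort.root / "Derived_data").iterdir()}
        assert not any("T1" in name for name in derived)
        assert "injected failure" in [r for r in report.job_records
                                      if r["state"] == "failed"][0]["log"]

    def test_multi_mode_failure_semantics_match(self, cohort, tmp_path):
        ext_dir = tmp_path / "ext"
        ext_dir.mkdir()
        (ext_dir / "module_flaky.py").write_text(FAIL_MODULE_SRC)
        specs, _ = discover_modules([ext_dir])
        by = {s.id: s for s in specs}
        pipe = Pipeline(cohort, "p")
        add_module(pipe, by["Module_FlakyCopy"],
                   {"sequence": "T2w", "fail_timepoint": "T2"})
        add_module(pipe, by["Module_Smooth"], {"sequence": "T2w_copy"})
        report = execute(pipe, mode="multi", workers=2,
                         timestamp="2022-01-01T00:00:00Z")
        assert report.counts == {"done": 8, "failed": 2, "skipped": 2}

    def test_reexecution_without_overwrite_skips_everything(self, cohort,
                                                            specs_by_id):
        pipe = two_module_chain(cohort, specs_by_id)
        execute(pipe, timestamp="2022-03-01T00:00:00Z")
        mtimes = {f: f.stat().st_mtime_ns
                  for f in (cohort.root / "Derived_data").iterdir()}
        report = execute(pipe, timestamp="2022-03-02T00:00:00Z")
        assert report.counts == {"done": 0, "failed": 0, "skipped": 12}
        assert all(f.stat().st_mtime_ns == t for f, t in mtimes.items())

    def test_reexecution_with_overwrite_reruns(self, cohort, specs_by_id):
        pipe = two_module_chain(cohort, specs_by_id)
        execute(pipe, timestamp="2022-03-01T00:00:00Z")
        report = execute(pipe, timestamp="2022-03-03T00:00:00Z",
                         overwrite=True)
        assert report.counts["done"] == 12

    def test_red_only_pipeline_refuses_to_run(self, cohort, specs_by_id):
        pipe = Pipeline(cohort, "p")
        add_module(pipe, specs_by_id["Module_Smooth"], {"sequence": "nope"})
        with pytest.raises(ProjectError, match="non-red"):
            execute(pipe)

    def test_done_jobs_flip_entries_to_derived(self, cohort, specs_by_id):
        pipe = two_module_chain(cohort, specs_by_id)
        execute(pipe, timestamp="2022-01-01T00:00:00Z")
        for e in cohort.entries:
            if e.sequence_name.startswith("T2w_smooth"):
                assert e.status == "derived"
                assert e.image_path(cohort.root).exists()
        assert not any((cohort.root / "Tmp" / "jobs").iterdir())

    def test_tmp_residue_never_enters_database(self, cohort, specs_by_id):
        pipe = two_module_chain(cohort, specs_by_id)
        execute(pipe, timestamp="2022-01-01T00:00:00Z")
        assert not any(e.path.startswith("Tmp") for e in cohort.entries)


class TestScheduleEquivalence:
    def test_random_pipelines_identical_across_worker_counts(self, tmp_path,
                                                             specs_by_id):
        """Multi-worker output equals single-mode output, workers in {1,2,4}."""
        import hashlib
        rng = np.random.default_rng(99)
        for trial in range(3):
            steps = [("Module_Smooth", {"sequence": "T2w", "extension": "a"}),
                     ("Module_Threshold", {"sequence": "T2w_a", "cutoff": 50.0,
                                           "extension": "m"})]
            if trial % 2:
                steps.append(("Module_MaskWithROI",
                              {"sequence": "T2w_a", "roi": "T2w_a_m",
                               "extension": "msk"}))
            digests = []
            for mode, workers in (("single", 1), ("multi", 2), ("multi", 4)):
                p = make_cohort(CohortSpec(seed=trial, shape=(8, 8, 6),
                                           timepoints=("T0", "T1")),
                                tmp_path / f"t{trial}_{mode}{workers}")
                pipe = Pipeline(p, "rnd")
                for mid, params in steps:
                    add_module(pipe, specs_by_id[mid], params)
                execute(pipe, mode=mode, workers=workers,
                        timestamp="2022-05-05T00:00:00Z")
                h = hashlib.sha256()
                for sub in ("Derived_data", "ROI_data"):
                    for f in sorted((p.root / sub).iterdir()):
                        h.update(f.name.encode())
                        h.update(f.read_bytes())
                digests.append(h.hexdigest())
            assert len(set(digests)) == 1
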