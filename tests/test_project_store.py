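"""Project skeleton, tag database, filtering, renames, deletion, BIDS import."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from voxpipe import convert
from voxpipe.fixtures import CohortSpec, make_cohort, make_volume
from voxpipe.project import (SUBDIRS, FilterCriteria, ProjectError,
                             audit_project, create_project, delete_entries,
                             entry_status_color, filter_database, import_bids,
                             load_project, register_entry, rename_tag_value)
from voxpipe.volume import ScanVolume


def _write_phantom(tmp_path, name="scan.nii.gz", shape=(8, 8, 6), value=1.0):
    vol = ScanVolume(array=np.full(shape, value), affine=np.eye(4),
                     sidecar={"Modality": "MR"})
    img, _ = convert.write_scan(vol, tmp_path / name)
    return img


class TestCreation:
    def test_skeleton_and_empty_database(self, tmp_path):
        p = create_project(tmp_path / "p1")
        assert all((p.root / sub).is_dir() for sub in SUBDIRS)
        assert len(p.entries) == 0

    def test_refuses_existing_project(self, tmp_path):
        create_project(tmp_path / "p1")
        with pytest.raises(ProjectError, match="project exists"):
            create_project(tmp_path / "p1")

    def test_save_load_round_trip(self, small_cohort):
        reloaded = load_project(small_cohort.root)
        orig = small_cohort.database.drop(columns="missing")
        back = reloaded.database.drop(columns="missing")
        assert orig.equals(back)
        assert not reloaded.database["missing"].any()

    def test_load_flags_missing_file_without_failing(self, small_cohort):
        victim = small_cohort.entries[0]
        victim.image_path(small_cohort.root).unlink()
        reloaded = load_project(small_cohort.root)
        flags = reloaded.database["missing"]
        assert flags.sum() == 1
        assert (~flags).sum() == len(small_cohort.entries) - 1

    def test_load_empty_project(self, tmp_path):
        create_project(tmp_path / "p")
        assert len(load_project(tmp_path / "p").entries) == 0

    def test_corrupt_database_reports_line(self, tmp_path):
        p = create_project(tmp_path / "p")
        with open(p.db_path(), "a") as fh:
            fh.write("only\tthree\tfields\n")
        with pytest.raises(ProjectError, match="line 2"):
            load_project(p.root)


class TestRegistration:
    def test_register_single_scan(self, empty_project, tmp_path):
        img = _write_phantom(tmp_path)
        entry = register_entry(empty_project, img,
                               tags={"subject": "S01", "timepoint": "T0",
                                     "sequence_name": "T2w"})
        assert entry.status == "raw"
        assert entry.image_path(empty_project.root).exists()
        assert entry.image_path(empty_project.root).parent.name == "Raw_data"
        assert entry.sidecar_path(empty_project.root).exists()

    def test_duplicate_key_is_collision(self, empty_project, tmp_path):
        img = _write_phantom(tmp_path)
        tags = {"subject": "S01", "timepoint": "T0", "sequence_name": "T2w"}
        register_entry(empty_project, img, tags=tags)
        with pytest.raises(ProjectError, match="T2w"):
            register_entry(empty_project, img, tags=tags)

    def test_non_nifti_rejected(self, empty_project, tmp_path):
        bogus = tmp_path / "x.nii"
        bogus.write_bytes(b"not a nifti")
        with pytest.raises(ValueError, match="readable NIfTI"):
            register_entry(empty_project, bogus,
                           tags={"subject": "S", "timepoint": "T",
                                 "sequence_name": "Q"})

    def test_cohort_of_60_scans_and_per_subject_filter(self, small_cohort):
        df = small_cohort.database
        scans = df[df["type"] == "Scan"]
        assert len(scans) == 60
        per_subject = filter_database(scans, {"subject": "S01"})
        assert len(per_subject) == 30

    def test_compressed_transparency(self, empty_project, tmp_path):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 1000, size=(6, 6, 4)).astype(np.int16)
        vol = ScanVolume(array=arr, affine=np.eye(4))
        convert.write_scan(vol, tmp_path / "a.nii")
        convert.write_scan(vol, tmp_path / "b.nii.gz")
        e1 = register_entry(empty_project, tmp_path / "a.nii",
                            tags={"subject": "S", "timepoint": "T",
                                  "sequence_name": "plain"})
        e2 = register_entry(empty_project, tmp_path / "b.nii.gz",
                            tags={"subject": "S", "timepoint": "T",
                                  "sequence_name": "gz"})
        a = convert.read_scan(e1.image_path(empty_project.root)).array
        b = convert.read_scan(e2.image_path(empty_project.root)).array
        assert np.array_equal(a, b)


class TestFiltering:
    def test_empty_criteria_selects_all(self, small_cohort):
        assert len(filter_database(small_cohort, None)) == len(small_cohort.entries)
        assert len(filter_database(small_cohort, {})) == len(small_cohort.entries)

    def test_session_filter_returns_ten_scans(self, small_cohort):
        sub = filter_database(small_cohort, {"subject": "S01", "timepoint": "T0",
                                             "type": "Scan"})
        assert len(sub) == 10

    def test_roi_filter_on_scan_only_rows(self, small_cohort):
        scans_only = filter_database(small_cohort, {"type": "Scan"})
        assert len(filter_database(scans_only, {"type": "ROI"})) == 0

    def test_unknown_tag_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown filter tag"):
            filter_database(small_cohort, {"flavor": "x"})

    def test_filter_is_idempotent(self, small_cohort):
        crit = {"subject": "S02", "sequence_name": {"T2w", "ADC"}}
        once = filter_database(small_cohort, crit)
        twice = filter_database(once, crit)
        assert once.equals(twice)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=hst.integers(min_value=0, max_value=2**31 - 1))
    def test_filter_equals_bruteforce_row_scan(self, seed):
        """Oracle equivalence: filtering matches a per-row predicate loop."""
        import pandas as pd
        rng = np.random.default_rng(seed)
        pools = {
            "type": ["Scan", "ROI"],
            "subject": [f"S{i}" for i in range(6)],
            "timepoint": [f"T{i}" for i in range(4)],
            "sequence_name": [f"Q{i}" for i in range(8)],
            "group": ["", "ctrl", "treated"],
            "status": ["raw", "derived", "roi", "virtual"],
        }
        n = int(rng.integers(200, 260))
        df = pd.DataFrame({tag: rng.choice(pool, size=n)
                           for tag, pool in pools.items()})
        df = df.assign(path="", filename="", missing=False)
        crit_dict = {}
        for tag in ("subject", "timepoint", "sequence_name", "type", "status"):
            if rng.random() < 0.5:
                k = int(rng.integers(0, 4))
                crit_dict[tag] = set(rng.choice(pools[tag], size=k)) if k else set()
        crit = FilterCriteria.from_dict(crit_dict)
        got = filter_database(df, crit)
        expected_idx = [
            i for i, row in df.iterrows()
            if all(row[tag] in values for tag, values in crit_dict.items())
        ]
        assert list(got.index) == expected_idx


class TestRename:
    def test_rename_timepoint_across_rows(self, small_cohort):
        n_t0 = len(filter_database(small_cohort, {"timepoint": "T0"}))
        count = rename_tag_value(small_cohort, "timepoint", "T0", "J0")
        assert count == n_t0
        assert len(filter_database(small_cohort, {"timepoint": "T0"})) == 0
        assert len(filter_database(small_cohort, {"timepoint": "J0"})) == n_t0
        # files follow the tags
        for e in small_cohort.entries:
            if not e.is_virtual():
                assert e.image_path(small_cohort.root).exists()

    def test_colliding_rename_rejected_atomically(self, small_cohort):
        before = small_cohort.database
        with pytest.raises(ProjectError, match="collide"):
            rename_tag_value(small_cohort, "timepoint", "T0", "T1")
        assert small_cohort.database.equals(before)

    def test_rename_absent_value_returns_zero(self, small_cohort):
        assert rename_tag_value(small_cohort, "subject", "nobody", "someone") == 0

    def test_rename_persists_through_reload(self, small_cohort):
        rename_tag_value(small_cohort, "sequence_name", "T2w", "T2weighted")
        reloaded = load_project(small_cohort.root)
        assert len(filter_database(reloaded, {"sequence_name": "T2weighted"})) == 6
        assert not reloaded.database["missing"].any()


class TestDeletion:
    def test_delete_nothing(self, small_cohort):
        empty = filter_database(small_cohort, {"subject": "nope"})
        assert delete_entries(small_cohort, empty) == 0

    def test_delete_with_files(self, small_cohort):
        sel = filter_database(small_cohort, {"subject": "S01", "timepoint": "T0",
                                             "type": "Scan"})
        paths = [small_cohort.root / r.path / r.filename for r in sel.itertuples()]
        assert delete_entries(small_cohort, sel, remove_files=True) == 10
        assert not any(p.exists() for p in paths)
        assert len(filter_database(small_cohort, {"subject": "S01",
                                                  "timepoint": "T0",
                                                  "type": "Scan"})) == 0

    def test_delete_rows_keep_files(self, small_cohort):
        sel = filter_database(small_cohort, {"subject": "S02", "timepoint": "T1",
                                             "type": "Scan"})
        paths = [small_cohort.root / r.path / r.filename for r in sel.itertuples()]
        assert delete_entries(small_cohort, sel, remove_files=False) == 10
        assert all(p.exists() for p in paths)


class TestBidsImport:
    @staticmethod
    def _bids_tree(root, subjects, sessions, suffixes):
        for s in subjects:
            for ses in sessions or [None]:
                base = root / f"sub-{s}"
                if ses:
                    base = base / f"ses-{ses}"
                anat = base / "anat"
                anat.mkdir(parents=True, exist_ok=True)
                for suffix in suffixes:
                    stem = f"sub-{s}" + (f"_ses-{ses}" if ses else "") + f"_{suffix}"
                    vol = ScanVolume(array=np.zeros((4, 4, 3)), affine=np.eye(4))
                    convert.write_scan(vol, anat / f"{stem}.nii.gz",
                                       sidecar={"Modality": "MR"})
        return root

    def test_single_subject_session(self, empty_project, tmp_path):
        tree = self._bids_tree(tmp_path / "bids", ["01"], ["01"], ["T1w"])
        entries = import_bids(empty_project, tree)
        assert len(entries) == 1
        e = entries[0]
        assert (e.subject, e.timepoint, e.sequence_name) == ("01", "ses-01", "T1w")

    def test_missing_session_level_gets_default(self, empty_project, tmp_path):
        tree = self._bids_tree(tmp_path / "bids", ["01"], [], ["T1w"])
        entries = import_bids(empty_project, tree)
        assert entries[0].timepoint == "ses-01"

    def test_full_grid_enumeration(self, empty_project, tmp_path):
        tree = self._bids_tree(tmp_path / "bids", ["01", "02", "03"],
                               ["01", "02"], ["T1w", "T2w"])
        entries = import_bids(empty_project, tree)
        assert len(entries) == 12

    def test_not_a_bids_tree(self, empty_project, tmp_path):
        (tmp_path / "plain").mkdir()
        with pytest.raises(ProjectError, match="not a BIDS tree"):
            import_bids(empty_project, tmp_path / "plain")

    def test_bids_sidecar_carried_over(self, empty_project, tmp_path):
        tree = self._bids_tree(tmp_path / "bids", ["01"], ["01"], ["T1w"])
        sc = next(tree.rglob("*.json"))
        sc.write_text(json.dumps({"Modality": "MR", "EchoTime": 12.5}))
        entries = import_bids(empty_project, tree)
        stored = json.loads(entries[0].sidecar_path(empty_project.root).read_text())
        assert stored["EchoTime"] == 12.5


class TestStatusColors:
    @pytest.mark.parametrize("status,color", [
        ("raw", "blue"), ("derived", "green"), ("roi", "pink"),
        ("virtual", "yellow"),
    ])
    def test_color_convention(self, status, color):
        assert entry_status_color(status) == color

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError):
            entry_status_color("odd")


class TestReferentialIntegrity:
    def test_audit_after_random_operation_sequence(self, tmp_path):
        """fsck audit stays clean across 100 random register/rename/deletes."""
        rng = np.random.default_rng(7)
        spec = CohortSpec(n_subjects=2, timepoints=("T0",), sequences=("A", "B"),
                          shape=(4, 4, 3), seed=5)
        project = make_cohort(spec, tmp_path / "p")
        counter = 0
        for step in range(100):
            op = rng.choice(["register", "rename", "delete"])
            try:
                if op == "register":
                    counter += 1
                    vol, _ = make_volume("ramp", shape=(4, 4, 3))
                    src = tmp_path / f"new{counter}.nii.gz"
                    convert.write_scan(vol, src)
                    register_entry(project, src, tags={
                        "subject": f"S{rng.integers(1, 4):02d}",
                        "timepoint": f"T{rng.integers(0, 3)}",
                        "sequence_name": f"Q{rng.integers(0, 5)}"})
                elif op == "rename" and project.entries:
                    e = project.entries[rng.integers(len(project.entries))]
                    tag = rng.choice(["subject", "timepoint", "sequence_name"])
                    rename_tag_value(project, tag, getattr(e, tag),
                                     f"{getattr(e, tag)}x")
                elif op == "delete" and project.entries:
                    e = project.entries[rng.integers(len(project.entries))]
                    sel = filter_database(project, {
                        "subject": e.subject, "timepoint": e.timepoint,
                        "sequence_name": e.sequence_name})
                    delete_entries(project, sel, remove_files=True)
            except ProjectError:
                pass  # collisions are legal outcomes, integrity must still hold
            if step % 10 == 9:
                report = audit_project(project)
                assert report["clean"], report
        assert audit_project(project)["clean"]
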