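"""Create a project, register scans, filter and edit the tag database.

Builds a small synthetic cohort (2 subjects x 3 timepoints x 10 MR
sequences plus one brain ROI per session), then shows the database
operations every other capability builds on: filtering, renaming a tag
value (which renames files on disk too) and an integrity audit.
"""

import tempfile
from pathlib import Path

from voxpipe import audit_project, filter_database, rename_tag_value
from voxpipe.fixtures import CohortSpec, make_cohort

root = Path(tempfile.mkdtemp()) / "demo_project"
project = make_cohort(CohortSpec(seed=1, roi_per_session=True), root)

df = project.database
print(f"project at {project.root}")
print(f"database rows: {len(df)} "
      f"({(df['type'] == 'Scan').sum()} scans, {(df['type'] == 'ROI').sum()} ROIs)")
# 66 rows: 60 scans + 6 session ROIs, one row per NIfTI+JSON pair on disk

session = filter_database(project, {"subject": "S01", "timepoint": "T0"})
print(f"rows for subject S01 at timepoint T0: {len(session)}")
# 11 = the session's 10 sequences + its brain ROI

n = rename_tag_value(project, "timepoint", "T0", "D0")
print(f"renamed timepoint T0 -> D0 on {n} rows (files renamed with them)")

report = audit_project(project)
print(f"integrity audit clean: {report['clean']} "
      f"(missing={len(report['missing_files'])}, orphans={len(report['orphan_files'])})")
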