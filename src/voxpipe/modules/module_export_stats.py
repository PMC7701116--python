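"""Per-session first-order ROI statistics exported as a CSV fragment.

Each job writes a one-row CSV for its session; fragments from all
sessions can be merged into one cohort table with
:func:`voxpipe.ops.merge_stats_csv`.
"""

import io

import pandas as pd

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    row = ops._stats_row(
        context["subject"], context["timepoint"],
        context["input_names"]["sequence"], context["input_names"]["roi"],
        inputs["sequence"], inputs["roi"],
    )
    buf = io.StringIO()
    pd.DataFrame([row]).to_csv(buf, index=False, lineterminator="\n")
    return {"stats": buf.getvalue()}


MODULE = ModuleSpec(
    id="Module_ExportStats",
    category="reporting",
    description="CSV of mean/std/median/min/max/n_voxels/volume within a ROI.",
    params=[
        Param("sequence", "sequence_selector"),
        Param("roi", "roi_selector"),
        Param("extension", "string", default="stats"),
    ],
    outputs=[OutputSpec("stats", "File", extension_param="extension",
                        file_suffix=".csv")],
    run=run,
)
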