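"""Reslice a scan onto the grid of a reference scan.

The reference is another sequence of the same session by default; set
``reference_timepoint`` to pin the reference to one timepoint of the
same subject (e.g. align every visit onto the first one).
"""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    out = ops.reslice_to_reference(inputs["sequence"], inputs["reference"],
                                   interpolation=params["interpolation"])
    return {"resliced": out}


MODULE = ModuleSpec(
    id="Module_Reslice",
    category="basic",
    description="Resample onto a reference grid (nearest or trilinear).",
    params=[
        Param("sequence", "sequence_selector"),
        Param("reference", "sequence_selector"),
        Param("reference_timepoint", "string", default=""),
        Param("interpolation", "choice", default="trilinear",
              choices=("nearest", "trilinear")),
        Param("extension", "string", default="resliced"),
    ],
    outputs=[OutputSpec("resliced", "Scan", extension_param="extension")],
    run=run,
)
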