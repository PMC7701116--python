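"""Strict intensity threshold producing a binary ROI mask."""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    mask = ops.threshold(inputs["sequence"], cutoff=params["cutoff"],
                         direction=params["direction"], output="mask")
    return {"mask": mask}


MODULE = ModuleSpec(
    id="Module_Threshold",
    category="basic",
    description="Binary mask of voxels strictly above/below a cutoff.",
    params=[
        Param("sequence", "sequence_selector"),
        Param("cutoff", "number", default=0.0),
        Param("direction", "choice", default="above", choices=("above", "below")),
        Param("extension", "string", default="mask"),
    ],
    outputs=[OutputSpec("mask", "ROI", extension_param="extension")],
    run=run,
)
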