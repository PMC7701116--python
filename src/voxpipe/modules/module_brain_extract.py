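"""Simplified brain extraction: Otsu threshold, largest 26-connected
component, morphological closing and hole filling."""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    roi = ops.brain_extract(inputs["sequence"],
                            closing_radius_mm=params["closing_radius_mm"])
    return {"brain": roi}


MODULE = ModuleSpec(
    id="Module_BrainExtract",
    category="segmentation",
    description="Intensity/morphology brain mask (simplified algorithm).",
    params=[
        Param("sequence", "sequence_selector"),
        Param("closing_radius_mm", "number", default=2.0),
        Param("extension", "string", default="brain"),
    ],
    outputs=[OutputSpec("brain", "ROI", extension_param="extension")],
    run=run,
)
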