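"""Gaussian smoothing module (2D per-slice or 3D volumetric)."""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    out = ops.smooth(inputs["sequence"], dimension=params["dimension"],
                     size=params["size"], unit=params["unit"])
    return {"smoothed": out}


MODULE = ModuleSpec(
    id="Module_Smooth",
    category="basic",
    description="Gaussian filter; size is the standard deviation (mm or voxels).",
    params=[
        Param("sequence", "sequence_selector"),
        Param("dimension", "choice", default="3D", choices=("2D", "3D")),
        Param("size", "number", default=2.0),
        Param("unit", "choice", default="mm", choices=("mm", "voxel")),
        Param("extension", "string", default="smooth"),
    ],
    outputs=[OutputSpec("smoothed", "Scan", extension_param="extension")],
    run=run,
)
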