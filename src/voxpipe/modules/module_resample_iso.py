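"""Resample a scan onto an isotropic grid of a chosen voxel size."""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    out = ops.resample_isotropic(inputs["sequence"], voxel_mm=params["voxel_mm"],
                                 interpolation=params["interpolation"])
    return {"resampled": out}


MODULE = ModuleSpec(
    id="Module_ResampleIso",
    category="basic",
    description="Isotropic resampling preserving the field of view.",
    params=[
        Param("sequence", "sequence_selector"),
        Param("voxel_mm", "number", default=1.0),
        Param("interpolation", "choice", default="trilinear",
              choices=("nearest", "trilinear")),
        Param("extension", "string", default="iso"),
    ],
    outputs=[OutputSpec("resampled", "Scan", extension_param="extension")],
    run=run,
)
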