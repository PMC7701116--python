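"""Mask a scan with a binary ROI (outside voxels set to 0 or NaN)."""

import numpy as np

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    fill = np.nan if params["fill"] == "NaN" else 0
    out = ops.mask_with_roi(inputs["sequence"], inputs["roi"], fill=fill)
    return {"masked": out}


MODULE = ModuleSpec(
    id="Module_MaskWithROI",
    category="basic",
    description="Zero (or NaN) out every voxel outside the ROI.",
    params=[
        Param("sequence", "sequence_selector"),
        Param("roi", "roi_selector"),
        Param("fill", "choice", default="0", choices=("0", "NaN")),
        Param("extension", "string", default="masked"),
    ],
    outputs=[OutputSpec("masked", "Scan", extension_param="extension")],
    run=run,
)
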