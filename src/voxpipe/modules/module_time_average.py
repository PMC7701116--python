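"""Average a 4D scan along its fourth (time) dimension."""

import numpy as np

from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    scan = inputs["sequence"]
    if scan.array.ndim < 4:
        raise ValueError("time average requires a 4D scan")
    out = scan.copy_with(array=np.nanmean(scan.array.astype(np.float64), axis=3))
    return {"mean": out}


MODULE = ModuleSpec(
    id="Module_TimeAverage",
    category="basic",
    description="Voxelwise mean over the 4th dimension (NaN-aware).",
    params=[
        Param("sequence", "sequence_selector"),
        Param("extension", "string", default="tmean"),
    ],
    outputs=[OutputSpec("mean", "Scan", extension_param="extension")],
    run=run,
)
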