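"""Local Shannon entropy texture map (bits)."""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    out = ops.entropy_map(inputs["sequence"], radius=int(params["radius"]),
                          bins=int(params["bins"]), window=params["window"])
    return {"entropy": out}


MODULE = ModuleSpec(
    id="Module_EntropyMap",
    category="texture",
    description="Per-voxel histogram entropy in a sliding square/cube window.",
    params=[
        Param("sequence", "sequence_selector"),
        Param("radius", "number", default=3),
        Param("bins", "number", default=32),
        Param("window", "choice", default="2D", choices=("2D", "3D")),
        Param("extension", "string", default="entropy"),
    ],
    outputs=[OutputSpec("entropy", "Scan", extension_param="extension")],
    run=run,
)
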