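"""Seeded region growth ROI (active-contour style growth)."""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    seed = (int(params["seed_x"]), int(params["seed_y"]), int(params["seed_z"]))
    roi = ops.active_contour_roi(
        inputs["sequence"], seed=seed,
        tolerance_k=params["tolerance_k"],
        smoothness_m=int(params["smoothness_m"]),
        max_iter=int(params["max_iter"]),
    )
    return {"roi": roi}


MODULE = ModuleSpec(
    id="Module_ActiveContourROI",
    category="segmentation",
    description="Grow a connected ROI from a seed by intensity similarity.",
    params=[
        Param("sequence", "sequence_selector"),
        Param("seed_x", "number", default=0),
        Param("seed_y", "number", default=0),
        Param("seed_z", "number", default=0),
        Param("tolerance_k", "number", default=2.5),
        Param("smoothness_m", "number", default=2),
        Param("max_iter", "number", default=500),
        Param("extension", "string", default="grown"),
    ],
    outputs=[OutputSpec("roi", "ROI", extension_param="extension")],
    run=run,
)
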