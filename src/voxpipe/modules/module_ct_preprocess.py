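"""CT preparation: resize, clip to a Hounsfield window, filter and
extract the brain. Defaults follow the published CT recipe (0-100 HU
soft-tissue window, 1 mm Gaussian)."""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    resample = params["resample_mm"] if params["resample_mm"] > 0 else None
    clipped, roi = ops.ct_preprocess(
        inputs["sequence"],
        hu_window=(params["hu_low"], params["hu_high"]),
        smooth_sigma=params["smooth_sigma"],
        resample_mm=resample,
    )
    return {"clipped": clipped, "brain": roi}


MODULE = ModuleSpec(
    id="Module_CTPreprocess",
    category="ct",
    description="Clip to HU window, smooth, threshold and keep the brain.",
    params=[
        Param("sequence", "sequence_selector"),
        Param("hu_low", "number", default=0.0),
        Param("hu_high", "number", default=100.0),
        Param("smooth_sigma", "number", default=1.0),
        Param("resample_mm", "number", default=0.0),   # 0 disables resizing
        Param("extension_clip", "string", default="clip"),
        Param("extension_roi", "string", default="brainmask"),
    ],
    outputs=[
        OutputSpec("clipped", "Scan", extension_param="extension_clip"),
        OutputSpec("brain", "ROI", extension_param="extension_roi"),
    ],
    run=run,
)
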