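"""Self-contained HTML report (thumbnail + stats) for one session."""

from .. import ops
from ..engine import ModuleSpec, OutputSpec, Param


def run(inputs, params, context):
    item = (context["subject"], context["timepoint"],
            context["input_names"]["sequence"], context["input_names"]["roi"],
            inputs["sequence"], inputs["roi"])
    return {"report": ops.html_report_string([item], timestamp=params["timestamp"])}


MODULE = ModuleSpec(
    id="Module_HTMLReport",
    category="reporting",
    description="Static HTML with embedded mid-slice thumbnail and ROI stats.",
    params=[
        Param("sequence", "sequence_selector"),
        Param("roi", "roi_selector"),
        Param("timestamp", "string", default=""),
        Param("extension", "string", default="report"),
    ],
    outputs=[OutputSpec("report", "File", extension_param="extension",
                        file_suffix=".html")],
    run=run,
)
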