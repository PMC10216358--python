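"""Feature generalization to a third, intermediate group.

Screens features on the patient-vs-control comparison only, then reuses
that mask unchanged to classify a prodromal group (whose planted effects
are halfway between the two) against the controls.
"""

from vgerp import EvalProtocol, PipelineConfig, run_generalization
from vgerp.cohorts import STUDY_BANDS, generalization_study

config = PipelineConfig(
    out_dir="scratch_generalization",
    synth=generalization_study(),
    bands=STUDY_BANDS,
    select_pair=("AD", "RNE"),
    protocol=EvalProtocol(n_repeats=100, pca_k=11),
    seed=7,
)

bundle = run_generalization(config, select_pair=("AD", "RNE"), eval_pair=("pAD", "RNE"))
print(f"mask screened on AD vs RNE: {bundle.selection.n_selected} features")
print()
print(bundle.report.render_table())
# The prodromal group is classified well above chance using only features
# discovered on the patient/control contrast, and never better than that
# two-extreme comparison — the transfer pattern expected of a group whose
# ERP components sit between the extremes.
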