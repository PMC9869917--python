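"""Run the complete grid: 6 conditioning methods x 2 references over a
seeded phantom cohort, producing the cohort summary tables.

Each case is generated, stitched, scored with RX under every conditioning
variant, and evaluated against the ACE and CIELAB reference masks; AUC and
Youden-index means (with standard errors in the long-form CSV) summarize
the cohort, one row per reference and one column per method.
"""

import mpmri_anomaly as mp
from mpmri_anomaly import pipeline

cfg = mp.RunConfig(
    methods=pipeline.METHODS,
    references=("ace", "cielab"),
    n_cases=6,
    seed=2024,
    out_dir="scratch/example_run",
    save_maps=False,
)
report = mp.run(cfg)

print("mean AUC over 6 phantom cases (rows=reference, cols=conditioning):")
print(report.auc_table.round(3).to_string())
print()
print("mean Youden index (max balanced accuracy):")
print(report.yi_table.round(3).to_string())
print()
print(f"per-case ROC curves and summaries written under {report.out_dir}/")
print("higher AUC against a reference means RX ranks that reference's "
      "tumor voxels above normal tissue more consistently.")
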