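"""The full study workflow on a synthetic 127-subject cohort.

simulate_study writes RR files (one per subject and posture), a
manifest and the cohort table; run_pipeline cleans each series,
computes the 11 indices per posture, forms the deltas, builds the
group-comparison tables, pre-selects predictors per Δ index and runs
the hierarchical partitioning.  Rerunning with the same config and
seed reproduces every output byte for byte.
"""

import tempfile
import warnings
from pathlib import Path

from hrvpart.pipeline import PipelineConfig, run_pipeline, simulate_study

with tempfile.TemporaryDirectory() as tmp:
    study = Path(tmp) / "study"
    simulate_study(study, n_per_group=(22, 73, 32), seed=0)
    cfg = PipelineConfig(input_dir=str(study), output_dir=str(Path(tmp) / "out"),
                         seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(cfg)

print(f"usable subjects: {res['run_log']['n_usable']} / "
      f"{res['run_log']['n_subjects']}")
print(f"{'delta':>12} {'valve':>8} {'I(abs%)':>8} {'R²':>7}  covariables")
for r in res["partition_rows"]:
    i_abs = "--" if r["valve_i_pct_absolute"] is None else f"{r['valve_i_pct_absolute']:.2f}"
    r2 = "--" if r["r2_combined"] is None else f"{r['r2_combined']:.3f}"
    print(f"{r['delta']:>12} {str(r['valve_parameter']):>8} {i_abs:>8} {r2:>7}  "
          f"{len(r.get('covariables', []))} covariables")
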