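"""The whole study in one run: cohort -> features -> selection -> SVM -> importance.

Simulates the default 28-participant weekly-quality cohort, runs the full
pipeline (LSTM + statistical features, GA/PSO-union selection, linear SVM
with participant-grouped 10-fold CV, permutation importance on the held-out
folds) and prints the evaluation metrics and the top-ranked features.

Takes a minute or two on a laptop CPU (the LSTM trains from scratch).
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from actisleep.config import PipelineConfig
from actisleep.pipeline import make_demo_dataset, run_pipeline

with tempfile.TemporaryDirectory() as td:
    data = Path(td) / "cohort"
    out = Path(td) / "run"
    make_demo_dataset("SleepQualWeek", data, seed=7)
    manifest = run_pipeline(PipelineConfig(seed=7), data, out)

    print("evaluation (window-level unless noted):")
    for k, v in manifest["metrics"].items():
        print(f"  {k:>24}: {v:.3f}")

    table = pd.read_csv(out / "importance.csv").sort_values("rank")
    print("\ntop 5 features by permutation importance:")
    print(table.head(5).to_string(index=False))

    selected = json.loads((out / "selected_features.json").read_text())
    print(f"\nunion subset: {selected['union']['indices']}")

print("\nAccuracy near 0.9 and participant-level accuracy near 1.0 mean the")
print("pipeline separates Good/Average/Poor sleepers generated with distinct")
print("sleep-architecture profiles; importance tags show whether deep (LSTM)")
print("or statistical columns drive the decision.")
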