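"""Enumerate (and optionally execute) the factorial experiment grid.

Each classification task crosses 4 classifiers x 2 feature sets x 2
dataset variants x 2 selectors x 2 regularization modes = 64 cells.
A dry run enumerates the cells; executing one cell writes a JSON report
with its manifest embedded.
"""

import tempfile
from pathlib import Path

from manavoc import features, preprocess, synth
from manavoc.grid import enumerate_grid, run_grid

configs = enumerate_grid("sex")
print(f"sex task grid: {len(configs)} configurations, e.g.")
for cfg in configs[:4]:
    print(" ", cfg.to_dict())

catalog = synth.reference_cohort(seed=1, n_calls_override=8)
vocs, meta = synth.generate_dataset(catalog, seed=1)
table = features.extract_table([preprocess.highpass(v) for v in vocs], meta, "SET2")

out = Path(tempfile.mkdtemp())
paths = run_grid(
    table, "sex", out,
    classifier="lda", feature_set="SET2", dataset_variant="complete",
    selector="kbest", tau_mode="fixed",
)
print(f"\nexecuted {len(paths)} cell(s); summary at {out / 'sex_summary.csv'}")
print((out / "sex_summary.csv").read_text())
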