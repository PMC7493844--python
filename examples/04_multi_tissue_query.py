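"""Run two tissues and query a ceRNA pair across them.

Mirrors the batch/query workflow: each tissue gets its own run directory;
the store then answers "in which tissues is this pair supported, and where
was it filtered out?"
"""

import tempfile
from pathlib import Path

from cerna import (
    GeneratorSpec,
    ResultStore,
    RunConfig,
    generate_dataset,
    query_pair,
    run_pipeline,
)

root = Path(tempfile.mkdtemp())
for tissue, seed in (("breast", 7), ("colon", 8)):
    dataset, truth = generate_dataset(GeneratorSpec(seed=seed))
    dataset.tissue_label = tissue
    config = RunConfig(seed=11, null_draws=500, tissue_label=tissue)
    run_pipeline(dataset, config, out_dir=root / tissue)

store = ResultStore.load(root)
print("tissues:", store.tissues)

first = store.runs[("breast", "normal")]["interactions"].iloc[0]
res = query_pair(store, first["ceRNA-A"], first["ceRNA-B"])
print(res.to_string(index=False))
# one row per tissue: present pairs carry their mscor and p-value; absent
# ones are annotated with the pipeline stage that removed them, and
# cross_tissue_count tallies the tissues supporting the pair.
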