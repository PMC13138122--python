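"""Run the whole pipeline — simulate, preprocess, gate, test — from one
config, writing tidy TSV tables with full provenance.

This is what the `naivegate run` CLI wraps. Sizes here are scaled down so
the example finishes in about a minute.
"""

import pandas as pd

from naivegate.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    out_dir="pipeline_demo",
    seed=42,
    n_donors=10,
    group_sizes=[2, 2, 2, 2, 2],
    events_per_donor=8000,
    subsample_n=7000,
    min_naive_cd8=50,
)
manifest = run_pipeline(config)

processed = [d for d, s in manifest.donors.items() if s["status"] == "processed"]
print(f"processed {len(processed)}/{len(manifest.donors)} donors; "
      f"config hash {manifest.config_hash}")

prop = pd.read_csv("pipeline_demo/proportions.tsv", sep="\t")
summary = (prop.groupby(["parent", "subset"])["proportion"].mean() * 100)
print("\nmean subset proportions (% of naive):")
print(summary.round(1).to_string())

tests = pd.read_csv("pipeline_demo/tests.tsv", sep="\t")
print("\nsmallest corrected pairwise p per subset:")
print(tests.groupby(["parent", "subset"])["p_final"].min().round(3).to_string())
# Re-running with the same config and seed reproduces these tables byte for
# byte; the config hash in every table ties outputs to their parameters.
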