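"""Full pipeline run: derepression detection with FDR control.

Runs simulate → build-ref → assign → quantify → differential as one
reproducible pipeline and prints the per-family differential table. With two
replicates per condition the Baggerly-style weighted t-test is selected; the
fold change is the ratio of mean treated to mean control proportions of
quantified (repeat-assigned) reads.
"""

import pandas as pd

from repeatrain import default_config, run_pipeline, validate_config

sim = default_config(seed=11, reads_per_sample=10_000,
                     condition_fold_changes={"SATMIN-like": 4.0})
cfg = validate_config({"seed": 11, "outdir": "example_out/run",
                       "simulation": sim.to_dict()})
manifest = run_pipeline(cfg)

c = manifest["counts"]["control_1"]
print(f"control_1 accounting: {c['input']} reads in, {c['assigned']} assigned, "
      f"{sum(c['discarded'].values())} discarded, {c['quantified']} quantified")

d = pd.read_csv("example_out/run/differential.tsv", sep="\t")
print("\ndifferential table (treated vs control):")
print(d.round(6).to_string(index=False))
print("\nSATMIN-like shows a fold change near the configured 4 with q << 0.05; "
      "the other families' modest apparent decrease is the compositional "
      "shadow of SATMIN's increase (proportions sum to 1 within the repeat "
      "compartment).")
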