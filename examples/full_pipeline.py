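"""Run the whole workflow from one config: QC -> association -> mapping ->
four GWAS tests -> expression arm -> Fisher combination -> overlap report.

Equivalent to `pathuniter run --config pipeline.yaml` from a shell.
"""

import pathlib

import pathuniter as pu

config = pu.PipelineConfig(
    out_dir="scratch/example_run",
    seed=17,
    synthetic={
        "n_case": 150, "n_control": 150, "n_genes": 80,
        "snps_per_gene": 3, "n_sets": 10, "genes_per_set": 8,
    },
    methods={m: {"n_perm": 200} for m in
             ("gsea", "aligator", "srt", "setbased", "gsea_expr")},
)
out = pu.run_pipeline(config)
print(f"outputs in {out}:")
for f in sorted(pathlib.Path(out).iterdir()):
    print(f"  {f.name}")
import pandas as pd  # noqa: E402

combined = pd.read_csv(out / "combined.tsv", sep="\t")
print("\ntop of combined.tsv (sorted by combined P):")
print(combined.head(3).to_string(index=False))
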