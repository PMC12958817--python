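"""Run the full seven-stage pipeline on a reduced cohort and print the
report tables.  The same thing is available from the shell:

    stressqtl pipeline run --config run.yaml
    stressqtl pipeline report <run-dir>

Run: python examples/05_full_pipeline.py   (~1 minute)
"""
from stressqtl.pipeline import PipelineConfig, report, run_pipeline

cfg = PipelineConfig(
    preset="cl_bivar",
    out_dir="example_run",
    seed=1,
    n_individuals=150,          # reduced from the preset's 600 for speed
    n_markers=500,
    gwas_opts={"chain_length": 1500, "burn_in": 300, "thin": 2, "pi": 0.99},
    enrichment_opts={"n_genes": 200, "n_sets": 20,
                     "set_size_range": [5, 30], "n_perm": 150},
)
manifest = run_pipeline(cfg)
for stage, rec in manifest["stages"].items():
    print(f"{stage:12s} {rec['status']:10s} {rec['wall_seconds']:7.1f}s")

tables = report("example_run")
print("\ngenetic parameters:")
print(tables["genetic_parameters"].to_string(index=False))
print("\nQTL calls:")
print(tables["qtl"].head(5).to_string(index=False))
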