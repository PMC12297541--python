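"""Run the whole simulate -> analyze -> report pipeline from one config.

Writes every result table (richness, pairing tests, contact maps, TVD
matrices) plus a JSON manifest with parameter echo and file digests under
./pipeline_demo/; rerunning with the same seed reproduces every byte.
"""

from pairedab import PipelineConfig, RepertoireConfig, StructureConfig, run_pipeline

config = PipelineConfig(
    out_dir="pipeline_demo",
    seed=17,
    repertoire=RepertoireConfig(n_cells=5000, seed=17),
    structures=StructureConfig(n_structures=5, seed=17),
)
manifest = run_pipeline(config)
print("stages completed:", ", ".join(manifest["stages_completed"]))
print("outputs written under", config.out_dir, ":")
for name in sorted(manifest["outputs"]):
    print(" ", name)
print("\nmanifest.json records the seed, every parameter and the SHA-256 of each file;")
print("rerunning this script reproduces identical digests.")
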