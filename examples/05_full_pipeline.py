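"""End-to-end synthetic analysis: simulate → reconstruct → model → decode.

Runs the complete pipeline on a generated dataset and prints the headline
outputs of each stage. Artifacts (meshes, tables, manifest) are written to
the run directory.
"""

from cortevo.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(out_dir="cortevo_demo_run", seed=1,
                        n_tips=8, icosphere_level=2,
                        n_surrogates=300, n_terms=100)
manifest, state = run_pipeline(config, return_state=True)

print("stages completed:", ", ".join(manifest["stages"]))
print("config hash:", manifest["config_hash"])

print("\nselected evolutionary model:", state["best_fit"].family)

rm = state["region_rm"]
print("\nhabitat repeated-measures correlations (top rows):")
print(rm.head(4).to_string(index=False))

print("\ntop decoded terms for the arboreal expansion map:")
print(state["decoded"].to_string(index=False))
# Each region's r_rm measures how consistently that region expands or
# contracts along the habitat-complexity ordering (arboreal > terrestrial >
# fossorial); the decoded terms are the synthetic term-library maps most
# correlated with the expansion pattern.
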