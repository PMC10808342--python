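"""Run the complete analysis pipeline on a synthetic study.

Simulates a small cohort, preprocesses the pupil data, applies the
behavioural exclusion rules, fits the mixture model per participant and
condition, classifies trials with the aggregate density-ratio threshold,
and computes the condition contrasts with Bayes factors.
"""

from pathlib import Path

from pupilmem import SimConfig, run_pipeline

out = Path("example_output/pipeline")
config = SimConfig(n_participants=10, seed=5)
manifest = run_pipeline(config, out)

print(f"completed stages: {manifest.completed_stages}")
print(f"exclusions: {manifest.exclusions}")
print(
    f"aggregate fit: p_t = {manifest.fit_summary['aggregate_p_t']:.3f}, "
    f"kappa = {manifest.fit_summary['aggregate_kappa']:.2f}, "
    f"threshold = {manifest.fit_summary['threshold_deg']:.1f} deg"
)
print("\n" + (out / "report.txt").read_text())
print(
    "Outputs (trials, epochs, fits, contrasts, manifest) are in "
    f"{out}/ and are byte-identical across reruns with the same seed."
)
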