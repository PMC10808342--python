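"""Generate a small synthetic reward-memory experiment and write it to CSV.

Builds the trial design (6 blocks x 14 trials, half reward / half neutral,
targets on a 4-degree circular grid), simulates mixture-model recall
responses, 40-Hz pupil traces and deadline-titrated reaction times, and
writes the tables that the analysis stages consume.
"""

from pathlib import Path

from pupilmem import SimConfig, simulate_dataset, traces_to_long, markers_to_table

out = Path("example_output/simulated")
out.mkdir(parents=True, exist_ok=True)

config = SimConfig(n_participants=3, seed=42)
dataset = simulate_dataset(config)

dataset.trials.to_csv(out / "trials.csv", index=False)
traces_to_long(dataset.traces).to_csv(out / "traces.csv", index=False)
markers_to_table(dataset.traces).to_csv(out / "markers.csv", index=False)

trials = dataset.trials
print(f"participants: {trials['participant'].nunique()}")
print(f"trials per participant: {len(trials) // trials['participant'].nunique()}")
print(trials.groupby("condition")[["rt_ms", "error_deg"]].agg(["mean", "std"]).round(2))
reward = trials[trials["condition"] == "reward"]
print(f"positive feedback on reward trials: {reward['positive_feedback'].mean():.1%}")
print(
    "\nEach participant gets 84 trials; reward trials should show faster RTs "
    "(~378 vs ~422 ms) and the staircase should put positive feedback near 70%."
)
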