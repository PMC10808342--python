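"""End-to-end orchestration: simulate -> pupil -> QC -> mixture -> stats.

:func:`run_pipeline` reproduces the full analysis on a synthetic dataset
(or on tables a caller supplies) and writes every intermediate product to
disk: the trial table, epoch table, per-participant mixture fits, the
aggregate fit with its trial-classification threshold, condition contrasts
with Bayes factors, a two-stage RT~pupil summary, a human-readable report
and a manifest.  All outputs are deterministic for a given config + seed
(fixed float formatting, sorted JSON keys, no timestamps outside the log).

The rule that only correctly classified study trials enter the analyses is
enforced once, centrally, at the behavioural-QC stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .behavior import (
    exclude_chance_participants,
    filter_classified_trials,
)
from .config import CONDITIONS, REWARD, SimConfig
from .mixture import (
    classify_trials,
    fit_mixture,
    threshold_from_fit,
    trial_precision,
)
from .pupil import epochs_table
from .simulate import markers_to_table, simulate_dataset, traces_to_long
from .stats import paired_ttest, per_participant_slopes

_FLOAT_FMT = "%.6f"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    versions: dict
    paths: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    fit_summary: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _condition_summaries(trials: pd.DataFrame, epochs: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition means of RT and anticipatory pupil change."""
    merged = trials.merge(
        epochs[["participant", "trial_index", "anticip_change_mm"]],
        on=["participant", "trial_index"],
        how="left",
    )
    g = merged.groupby(["participant", "condition"])
    return g.agg(
        rt_ms=("rt_ms", "mean"),
        anticip_change_mm=("anticip_change_mm", "mean"),
    ).reset_index()


def _paired_table(summary: pd.DataFrame, value: str) -> tuple[np.ndarray, np.ndarray]:
    wide = summary.pivot(index="participant", columns="condition", values=value)
    wide = wide.dropna()
    return wide[REWARD].to_numpy(), wide["neutral"].to_numpy()


def run_pipeline(
    config: SimConfig,
    out_dir: str | Path,
    write_traces: bool = False,
) -> RunManifest:
    """Run the whole analysis on a freshly simulated dataset.

    Stages: (1) simulate, (2) pupil preprocessing + epoching,
    (3) behavioural QC and exclusions, (4) mixture fits, aggregate
    threshold and trial classification, (5) condition contrasts and
    two-stage pupil–behaviour summaries.  Any stage failure aborts with
    :class:`PipelineError` naming the stage, after writing a partial
    manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("pupilmem.pipeline")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        versions={
            "pupilmem": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    )

    def finish_stage(name: str) -> None:
        manifest.completed_stages.append(name)
        log.info("stage %s complete", name)

    def fail(name: str, exc: BaseException):
        log.error("stage %s failed: %s", name, exc)
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
        log.removeHandler(handler)
        handler.close()
        raise PipelineError(name, exc) from exc

    try:
        # ---- stage 1: simulate ------------------------------------------
        stage = "simulate"
        dataset = simulate_dataset(config)
        trials = dataset.trials
        trials.to_csv(out / "trials.csv", index=False, float_format=_FLOAT_FMT)
        manifest.paths["trials"] = "trials.csv"
        if write_traces:
            traces_to_long(dataset.traces).to_csv(
                out / "traces.csv", index=False, float_format=_FLOAT_FMT
            )
            markers_to_table(dataset.traces).to_csv(
                out / "markers.csv", index=False, float_format=_FLOAT_FMT
            )
            manifest.paths["traces"] = "traces.csv"
            manifest.paths["markers"] = "markers.csv"
        finish_stage(stage)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - converted to PipelineError
        fail(stage, exc)

    try:
        # ---- stage 2: pupil preprocessing + epochs ----------------------
        stage = "pupil"
        log.info(
            "pupil pipeline order: foreshortening hook -> blink interpolation "
            "-> zero-phase low-pass -> epoching -> QC -> baseline correction"
        )
        epochs = epochs_table(dataset.traces, trial_meta=trials)
        epochs.to_csv(out / "epochs.csv", index=False, float_format=_FLOAT_FMT)
        manifest.paths["epochs"] = "epochs.csv"
        finish_stage(stage)
    except Exception as exc:
        fail(stage, exc)

    try:
        # ---- stage 3: behavioural QC ------------------------------------
        stage = "behavior_qc"
        retained, chance_report = exclude_chance_participants(trials)
        analysed, too_few = filter_classified_trials(retained)
        log.info(
            "central filter: %d of %d trials correctly classified and retained",
            len(analysed),
            len(trials),
        )
        manifest.exclusions = {
            "chance_level": chance_report["excluded"],
            "too_few_trials": too_few,
            "n_participants_analysed": int(analysed["participant"].nunique()),
        }
        _write_json(
            out / "exclusions.json",
            {**manifest.exclusions, "chance_report": chance_report},
        )
        manifest.paths["exclusions"] = "exclusions.json"
        finish_stage(stage)
    except Exception as exc:
        fail(stage, exc)

    try:
        # ---- stage 4: mixture fits + trial classification ---------------
        stage = "mixture"
        errors_rad = np.deg2rad(analysed["error_deg"].to_numpy())
        aggregate = fit_mixture(errors_rad)
        threshold = threshold_from_fit(aggregate)
        fits = []
        for (pid, cond), sub in analysed.groupby(["participant", "condition"]):
            f = fit_mixture(np.deg2rad(sub["error_deg"].to_numpy()))
            fits.append({"participant": int(pid), "condition": cond, **f.to_dict()})
        _write_json(
            out / "fits.json",
            {
                "aggregate": aggregate.to_dict(),
                "threshold_deg": threshold,
                "participants": fits,
            },
        )
        manifest.paths["fits"] = "fits.json"
        manifest.fit_summary = {
            "aggregate_p_t": aggregate.p_t,
            "aggregate_kappa": aggregate.kappa,
            "threshold_deg": threshold,
        }
        classified = analysed.copy()
        classified["correct"] = classify_trials(
            classified["error_deg"].to_numpy(), threshold
        )
        classified["precision_inv_deg"] = trial_precision(
            classified["error_deg"].to_numpy(), classified["correct"].to_numpy()
        )
        classified.to_csv(
            out / "trials_classified.csv", index=False, float_format=_FLOAT_FMT
        )
        manifest.paths["trials_classified"] = "trials_classified.csv"
        finish_stage(stage)
    except Exception as exc:
        fail(stage, exc)

    try:
        # ---- stage 5: statistics ----------------------------------------
        stage = "stats"
        summary = _condition_summaries(analysed, epochs)
        fit_df = pd.DataFrame(fits)
        contrasts = {}
        for name, x, y in [
            ("rt_ms", *_paired_table(summary, "rt_ms")),
            ("anticip_change_mm", *_paired_table(summary, "anticip_change_mm")),
            (
                "p_t",
                *_paired_table(fit_df.rename(columns={"p_t": "value"}), "value"),
            ),
            (
                "kappa",
                *_paired_table(fit_df.rename(columns={"kappa": "value"}), "value"),
            ),
        ]:
            contrasts[name] = paired_ttest(x, y, with_bf=True).to_dict()

        trial_level = classified.merge(
            epochs[["participant", "trial_index", "anticip_change_mm"]],
            on=["participant", "trial_index"],
            how="left",
        )
        trial_level["is_reward"] = (trial_level["condition"] == REWARD).astype(float)
        rt_slopes = per_participant_slopes(
            trial_level, "rt_ms", ["anticip_change_mm", "is_reward"]
        )
        trial_level["correct_f"] = trial_level["correct"].astype(float)
        mem_slopes = per_participant_slopes(
            trial_level, "correct_f", ["anticip_change_mm"]
        )
        slopes_out = {
            "rt_vs_anticip": {
                k: v.to_dict() for k, v in rt_slopes.group.items()
            },
            "memory_success_vs_anticip": {
                k: v.to_dict() for k, v in mem_slopes.group.items()
            },
        }
        _write_json(out / "contrasts.json", {"paired": contrasts, "slopes": slopes_out})
        manifest.paths["contrasts"] = "contrasts.json"

        report_lines = ["Condition contrasts (reward - neutral):"]
        for name, x, y in [
            ("RT (ms)", *_paired_table(summary, "rt_ms")),
            ("anticipatory pupil change (mm)", *_paired_table(summary, "anticip_change_mm")),
            ("memory success p_t", *_paired_table(fit_df.rename(columns={"p_t": "value"}), "value")),
            ("memory precision kappa", *_paired_table(fit_df.rename(columns={"kappa": "value"}), "value")),
        ]:
            report_lines.append("  " + paired_ttest(x, y, with_bf=True).describe(name))
        report_lines.append(
            f"Aggregate mixture fit: p_t = {aggregate.p_t:.3f}, "
            f"kappa = {aggregate.kappa:.2f}, "
            f"trial-classification threshold = {threshold:.1f} deg"
        )
        rt_g = rt_slopes.group["anticip_change_mm"]
        report_lines.append(
            "Two-stage RT ~ anticipatory pupil change (with condition covariate): "
            + rt_g.describe("group slope (ms per mm)")
        )
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        manifest.paths["report"] = "report.txt"
        finish_stage(stage)
    except Exception as exc:
        fail(stage, exc)

    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    manifest.paths["manifest"] = "manifest.json"
    log.removeHandler(handler)
    handler.close()
    return manifest
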