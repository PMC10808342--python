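"""Synthetic generator for the reward–memory task.

Emulates the full experiment the analysis pipeline expects, so that every
downstream stage is testable without any data download:

* a study design of ``n_blocks x trials_per_block`` trials per participant
  (default 6 x 14 = 84), half reward / half neutral within each block, with
  target locations on a circle discretised in 4-degree steps and the two
  choice dots always 180 degrees apart;
* recall responses drawn from the uniform + von Mises mixture with
  condition-wise success probability and concentration;
* 40-Hz pupil traces spanning each trial, with a participant-specific
  baseline, slow drift, an event-locked anticipatory dilation ramp whose
  amplitude differs by condition, reward carry-over into the next trial's
  baseline, white measurement noise and blink gaps (invalid samples set to
  NaN);
* number-classification reaction times negatively coupled to the trial's
  anticipatory dilation, and an adaptive response deadline (weighted
  up–down staircase) targeting a ~70% positive-feedback rate on reward
  trials (+15c / -10c; neutral trials always 0c).

All randomness flows through numpy Generators seeded from
``SimConfig.seed``, so identical configurations reproduce identical tables
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import wrap_positive_deg, wrap_signed_deg
from .config import CONDITIONS, NEUTRAL, REWARD, SimConfig
from .pupil import PupilTrace

# trial timeline constants (seconds): item alone, choice display window,
# post-anticipation tail (number + response + blank + feedback)
ITEM_S = 3.0
CHOICE_S = 6.0
TAIL_S = 2.6

TARGET_NUMBERS = (1, 4, 6, 9)

FEEDBACK_WIN_C = 15
FEEDBACK_LOSS_C = -10


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_design(config: SimConfig) -> pd.DataFrame:
    """Generate the trial table for every participant.

    Per participant: ``n_blocks * trials_per_block`` trials; conditions
    balanced (half reward, half neutral) within each block in randomised
    order; target angles are distinct multiples of 4 degrees in (0, 360],
    and the paired (incorrect) dot sits exactly 180 degrees away.
    """
    if config.total_trials > 90:
        raise ValueError(
            "cannot place more than 90 trials on distinct 4-degree angles"
        )
    rng = _rng(config, 0)
    half = config.trials_per_block // 2
    all_angles = np.arange(4.0, 364.0, 4.0)
    rows = []
    for p in range(1, config.n_participants + 1):
        angles = rng.permutation(all_angles)[: config.total_trials]
        idx = 0
        for block in range(1, config.n_blocks + 1):
            conds = np.array([REWARD] * half + [NEUTRAL] * half)
            rng.shuffle(conds)
            for cond in conds:
                target = float(angles[idx])
                rows.append(
                    {
                        "participant": p,
                        "block": block,
                        "trial_index": idx,
                        "condition": cond,
                        "target_angle_deg": target,
                        "paired_angle_deg": wrap_positive_deg(target + 180.0),
                        "fixation_s": rng.uniform(3.0, 6.0),
                        "anticipation_s": rng.uniform(2.0, 4.0),
                        "target_number": int(rng.choice(TARGET_NUMBERS)),
                    }
                )
                idx += 1
    return pd.DataFrame(rows)


def simulate_recall(
    design: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Add mixture-model recall responses to a design table.

    With probability ``p_t(condition)`` the signed error is von Mises with
    ``kappa(condition)``; otherwise the response is uniform on the circle.
    Study-phase item classification is an independent Bernoulli with the
    configured accuracy.  Adds columns ``retrieved`` (latent generative
    truth), ``response_deg``, ``error_deg``, ``classified_correct``.
    """
    out = design.copy()
    n = len(out)
    is_reward = (out["condition"] == REWARD).to_numpy()
    p_t = np.where(is_reward, config.p_t_reward, config.p_t_neutral)
    kappa = np.where(is_reward, config.kappa_reward, config.kappa_neutral)
    if np.any(kappa < 0) or np.any((p_t < 0) | (p_t > 1)):
        raise ValueError("invalid mixture parameters in config")

    retrieved = rng.random(n) < p_t
    vm_err = np.rad2deg(rng.vonmises(0.0, np.maximum(kappa, 1e-12)))
    uni_err = rng.uniform(-180.0, 180.0, n)
    error = np.where(retrieved, vm_err, uni_err)
    error = wrap_signed_deg(error)

    out["retrieved"] = retrieved
    out["error_deg"] = error
    out["response_deg"] = wrap_positive_deg(
        out["target_angle_deg"].to_numpy() + error
    )
    out["classified_correct"] = rng.random(n) < config.classification_accuracy
    return out


def _trial_trace(
    fixation_s: float,
    anticipation_s: float,
    baseline_mm: float,
    amplitude_mm: float,
    carryover_mm: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> PupilTrace:
    fs = config.sample_rate_hz
    t_item = fixation_s
    t_choice = t_item + ITEM_S
    t_anticip = t_choice + CHOICE_S
    t_anticip_off = t_anticip + anticipation_s
    duration = t_anticip_off + TAIL_S
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    w = 0.2  # flat shoulders so the measured first/last-window difference
    # equals the generative amplitude exactly
    xp = [t_anticip + w, t_anticip_off - w, t_anticip_off, t_anticip_off + 1.0]
    fp = [0.0, amplitude_mm, amplitude_mm, 0.0]
    dilation = np.interp(t, xp, fp, left=0.0, right=0.0)

    drift = config.drift_amplitude_mm * np.sin(
        2.0 * np.pi * config.drift_freq_hz * t + rng.uniform(0.0, 2.0 * np.pi)
    )
    noise = rng.normal(0.0, config.pupil_noise_mm, n)
    decay = carryover_mm * np.exp(-t / 2.0)
    diameter = baseline_mm + drift + dilation + decay + noise

    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(config.blink_rate_hz * duration)
    for _ in range(n_blinks):
        onset = rng.uniform(0.0, duration)
        dur = rng.uniform(config.blink_min_ms, config.blink_max_ms) / 1000.0
        valid &= ~((t >= onset) & (t < onset + dur))
    diameter = np.where(valid, diameter, np.nan)

    markers = {
        "item_onset": t_item,
        "choice_onset": t_choice,
        "anticip_onset": t_anticip,
        "anticip_offset": t_anticip_off,
    }
    return PupilTrace(t_s=t, diameter_mm=diameter, valid=valid, markers=markers)


def simulate_pupil(
    design: pd.DataFrame, config: SimConfig, rng: np.random.Generator
):
    """Simulate one 40-Hz pupil trace per trial.

    The anticipatory dilation amplitude of each trial is
    ``effect(condition) + participant-by-condition offset + trial noise``;
    it is held flat over the first and last 0.2 s of the anticipation
    window so the epoching change measure recovers it exactly in the
    noise-free limit.

    Returns ``(traces, anticip_true_mm)``: a list of
    ``(participant, trial_index, PupilTrace)`` in design row order, and the
    realized amplitude per trial (the generative truth the RT model uses).
    """
    traces = []
    anticip_true = np.full(len(design), np.nan)
    design = design.reset_index(drop=True)
    for p, sub in design.groupby("participant", sort=True):
        baseline = config.pupil_baseline_mm + rng.normal(
            0.0, config.pupil_baseline_sd_mm
        )
        effect_offsets = {
            c: rng.normal(0.0, config.anticip_participant_sd_mm) for c in CONDITIONS
        }
        prev_reward = False
        for row in sub.sort_values("trial_index").itertuples():
            amp = (
                config.anticip_effect_mm(row.condition)
                + effect_offsets[row.condition]
                + rng.normal(0.0, config.anticip_trial_sd_mm)
            )
            carry = config.carryover_reward_mm if prev_reward else 0.0
            trace = _trial_trace(
                row.fixation_s,
                row.anticipation_s,
                baseline,
                amp,
                carry,
                config,
                rng,
            )
            traces.append((p, row.trial_index, trace))
            anticip_true[row.Index] = amp
            prev_reward = row.condition == REWARD
    return traces, anticip_true


def run_titration(
    rts_ms: np.ndarray,
    config: SimConfig,
    correct: np.ndarray | None = None,
):
    """Run the adaptive-deadline staircase over a sequence of reward trials.

    A weighted up–down rule: after positive feedback (RT at or below the
    deadline, and a correct response if ``correct`` is given) the deadline
    tightens by ``deadline_step_down_ms``; after negative feedback it
    relaxes by ``deadline_step_up_ms = step_down * p/(1-p)``, whose
    equilibrium hit rate is the target positive-feedback rate ``p``.

    Returns ``(deadlines_ms, positive)``: the deadline in effect on each
    trial and the per-trial positive-feedback flags.
    """
    rts = np.asarray(rts_ms, dtype=float)
    ok = np.ones(rts.size, dtype=bool) if correct is None else np.asarray(correct, bool)
    deadlines = np.empty(rts.size)
    positive = np.empty(rts.size, dtype=bool)
    d = config.deadline_init_ms
    up = config.deadline_step_up_ms
    down = config.deadline_step_down_ms
    for i in range(rts.size):
        deadlines[i] = d
        hit = ok[i] and rts[i] <= d
        positive[i] = hit
        d = d - down if hit else d + up
        d = min(max(d, config.deadline_min_ms), config.deadline_max_ms)
    return deadlines, positive


def simulate_rt_and_titration(
    design: pd.DataFrame,
    anticip_change_mm: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate number-classification RTs, feedback and the deadline staircase.

    ``RT = rt_mean + reward offset + slope * anticipatory change + noise``,
    truncated at ``rt_floor_ms``.  Trials with a missing anticipatory
    change get no coupling term and are flagged
    (``rt_pupil_coupled = False``).  The deadline staircase runs over each
    participant's reward trials in presentation order; neutral trials give
    0c feedback and leave the deadline untouched.

    Adds columns ``rt_ms``, ``rt_pupil_coupled``, ``deadline_ms``,
    ``number_correct``, ``positive_feedback``, ``feedback_cents``.
    """
    out = design.reset_index(drop=True).copy()
    n = len(out)
    anticip = np.asarray(anticip_change_mm, dtype=float)
    if anticip.size != n:
        raise ValueError("anticip_change_mm must align with the design rows")
    is_reward = (out["condition"] == REWARD).to_numpy()
    coupled = np.isfinite(anticip)
    coupling = np.where(coupled, anticip, 0.0) * config.rt_pupil_slope_ms_per_mm
    rt = (
        config.rt_mean_ms
        + np.where(is_reward, config.rt_reward_offset_ms, 0.0)
        + coupling
        + rng.normal(0.0, config.rt_sd_ms, n)
    )
    rt = np.maximum(rt, config.rt_floor_ms)
    number_correct = rng.random(n) < config.number_accuracy

    deadline = np.full(n, np.nan)
    positive = np.zeros(n, dtype=bool)
    feedback = np.zeros(n, dtype=int)
    for _, sub in out.groupby("participant", sort=True):
        sub = sub.sort_values("trial_index")
        ridx = sub.index[is_reward[sub.index]]
        dls, pos = run_titration(rt[ridx], config, correct=number_correct[ridx])
        deadline[ridx] = dls
        positive[ridx] = pos
        feedback[ridx] = np.where(pos, FEEDBACK_WIN_C, FEEDBACK_LOSS_C)

    out["rt_ms"] = rt
    out["rt_pupil_coupled"] = coupled
    out["deadline_ms"] = deadline
    out["number_correct"] = number_correct
    out["positive_feedback"] = positive
    out["feedback_cents"] = feedback
    return out


@dataclass
class SimulatedDataset:
    """A complete simulated experiment: trial table + per-trial pupil traces."""

    config: SimConfig
    trials: pd.DataFrame
    traces: list


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: design -> recall -> pupil -> RT/titration.

    The trial table carries the generative truth columns (``retrieved``,
    ``anticip_true_mm``) alongside everything an analysis would observe.
    """
    design = generate_design(config)
    trials = simulate_recall(design, config, _rng(config, 1))
    traces, anticip_true = simulate_pupil(trials, config, _rng(config, 2))
    trials["anticip_true_mm"] = anticip_true
    trials = simulate_rt_and_titration(trials, anticip_true, config, _rng(config, 3))
    return SimulatedDataset(config=config, trials=trials, traces=traces)


def traces_to_long(traces) -> pd.DataFrame:
    """Long-format pupil table: participant, trial_index, t_s, diameter_mm, valid."""
    frames = []
    for p, ti, tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "participant": p,
                    "trial_index": ti,
                    "t_s": tr.t_s,
                    "diameter_mm": tr.diameter_mm,
                    "valid": tr.valid,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def markers_to_table(traces) -> pd.DataFrame:
    """Event-marker table: participant, trial_index, label, t_s."""
    rows = [
        {"participant": p, "trial_index": ti, "label": label, "t_s": t}
        for p, ti, tr in traces
        for label, t in tr.markers.items()
    ]
    return pd.DataFrame(rows)


def traces_from_long(
    long: pd.DataFrame, markers: pd.DataFrame | None = None
) -> list:
    """Rebuild ``(participant, trial_index, PupilTrace)`` from long CSV tables."""
    marker_map: dict = {}
    if markers is not None:
        for row in markers.itertuples():
            marker_map.setdefault((row.participant, row.trial_index), {})[
                row.label
            ] = float(row.t_s)
    out = []
    for (p, ti), sub in long.groupby(["participant", "trial_index"], sort=True):
        sub = sub.sort_values("t_s")
        out.append(
            (
                p,
                ti,
                PupilTrace(
                    t_s=sub["t_s"].to_numpy(),
                    diameter_mm=sub["diameter_mm"].to_numpy(),
                    valid=sub["valid"].to_numpy(dtype=bool),
                    markers=marker_map.get((p, ti), {}),
                ),
            )
        )
    return out
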