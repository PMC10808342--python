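"""Generative configuration for the synthetic reward–memory experiment.

:class:`SimConfig` holds every parameter of the simulated study: task design
counts, the condition-wise mixture parameters of the recall-error model
(success probability ``p_t`` and von Mises concentration ``kappa``), the
pupil signal model, the RT model with its pupil coupling, and the adaptive
response-deadline staircase.  Defaults reproduce the study conditions the
analysis is designed for: 36 participants, 84 trials in 6 blocks, half
reward / half neutral, 40-Hz pupillometry, a ~70% positive-feedback target
on reward trials, and condition parameters equal to the participant-level
means the task is known to produce (reward: p_t = 0.58, kappa = 13.67;
neutral: p_t = 0.55, kappa = 17.02; anticipatory dilation 0.10 vs 0.03 mm;
RT 378 vs 422 ms; -30 ms RT per mm of anticipatory dilation).
"""

from __future__ import annotations

import hashlib

from pydantic import BaseModel, Field, model_validator

REWARD = "reward"
NEUTRAL = "neutral"
CONDITIONS = (REWARD, NEUTRAL)


class SimConfig(BaseModel):
    """All generative parameters of the simulated experiment.

    Units are embedded in field names (``_mm``, ``_ms``, ``_hz``, ``_s``).
    Probabilities are proportions in [0, 1]; concentrations are unitless
    and non-negative.
    """

    # -- design -------------------------------------------------------------
    n_participants: int = Field(default=36, gt=0)
    n_blocks: int = Field(default=6, gt=0)
    trials_per_block: int = Field(default=14, gt=0)

    # -- recall (mixture) model --------------------------------------------
    p_t_reward: float = Field(default=0.58, ge=0.0, le=1.0)
    p_t_neutral: float = Field(default=0.55, ge=0.0, le=1.0)
    kappa_reward: float = Field(default=13.67, ge=0.0)
    kappa_neutral: float = Field(default=17.02, ge=0.0)

    # -- study-phase classification performance ----------------------------
    classification_accuracy: float = Field(default=0.93, ge=0.0, le=1.0)
    number_accuracy: float = Field(default=0.90, ge=0.0, le=1.0)

    # -- pupil signal model -------------------------------------------------
    pupil_baseline_mm: float = Field(default=5.7, gt=0.0)
    pupil_baseline_sd_mm: float = Field(default=0.3, ge=0.0)
    anticip_effect_reward_mm: float = 0.10
    anticip_effect_neutral_mm: float = 0.03
    anticip_participant_sd_mm: float = Field(default=0.06, ge=0.0)
    anticip_trial_sd_mm: float = Field(default=0.10, ge=0.0)
    pupil_noise_mm: float = Field(default=0.02, ge=0.0)
    drift_amplitude_mm: float = Field(default=0.05, ge=0.0)
    drift_freq_hz: float = Field(default=0.05, gt=0.0)
    carryover_reward_mm: float = Field(default=0.02, ge=0.0)
    blink_rate_hz: float = Field(default=0.1, ge=0.0)
    blink_min_ms: float = Field(default=100.0, gt=0.0)
    blink_max_ms: float = Field(default=400.0, gt=0.0)
    sample_rate_hz: float = Field(default=40.0, gt=0.0)

    # -- reaction-time model -----------------------------------------------
    rt_mean_ms: float = Field(default=422.0, gt=0.0)
    rt_reward_offset_ms: float = -44.0
    rt_sd_ms: float = Field(default=50.0, ge=0.0)
    rt_floor_ms: float = Field(default=150.0, gt=0.0)
    rt_pupil_slope_ms_per_mm: float = -30.0

    # -- deadline staircase -------------------------------------------------
    target_reward_rate: float = Field(default=0.70, gt=0.0, lt=1.0)
    deadline_init_ms: float = Field(default=500.0, gt=0.0)
    deadline_step_down_ms: float = Field(default=10.0, gt=0.0)
    deadline_min_ms: float = Field(default=150.0, gt=0.0)
    deadline_max_ms: float = Field(default=1500.0, gt=0.0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.blink_max_ms < self.blink_min_ms:
            raise ValueError("blink_max_ms must be >= blink_min_ms")
        if self.deadline_max_ms < self.deadline_min_ms:
            raise ValueError("deadline_max_ms must be >= deadline_min_ms")
        if self.trials_per_block % 2 != 0:
            raise ValueError(
                "trials_per_block must be even so reward/neutral can be "
                "balanced within each block"
            )
        return self

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def deadline_step_up_ms(self) -> float:
        """Up-step of the weighted up–down staircase.

        The equilibrium hit rate of a weighted up–down rule is
        ``up / (up + down)``; choosing ``up = down * p / (1 - p)`` makes the
        staircase converge to the target positive-feedback rate ``p``.
        """
        p = self.target_reward_rate
        return self.deadline_step_down_ms * p / (1.0 - p)

    def p_t(self, condition: str) -> float:
        return self.p_t_reward if condition == REWARD else self.p_t_neutral

    def kappa(self, condition: str) -> float:
        return self.kappa_reward if condition == REWARD else self.kappa_neutral

    def anticip_effect_mm(self, condition: str) -> float:
        if condition == REWARD:
            return self.anticip_effect_reward_mm
        return self.anticip_effect_neutral_mm

    def config_hash(self) -> str:
        """Stable SHA-256 of the serialized configuration (for manifests)."""
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()
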