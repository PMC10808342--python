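"""Pupillometry preprocessing and event epoching.

The preprocessing chain, in fixed order:

1. optional pupil-foreshortening correction (pass-through hook for an
   externally corrected trace; the geometric correction itself is applied
   upstream of this package),
2. blink interpolation — samples from 100 ms before each blink onset to
   400 ms after its offset are replaced by linear interpolation between the
   nearest valid neighbours,
3. zero-phase low-pass filtering (10-Hz fourth-order Butterworth applied
   forward and backward).

Epoching then extracts three event measures per trial on the 40-Hz grid,
each from a 0.2-s half-open window [start, start + 0.2):

* ``pre_item_mm`` — mean diameter over the 0.2 s before item onset,
* ``choice_mm`` — mean over 0–0.2 s after the choice display, minus the
  trial's pre-item mean (baseline correction),
* ``anticip_change_mm`` — mean of the final 0.2 s of the anticipation
  period minus the mean of its first 0.2 s (phasic arousal proxy).

Epoch QC: an epoch with > 50% device-invalid raw samples is excluded
(strictly greater: exactly half survives); surviving epochs have samples
more than 3 SDs from the epoch mean removed in a single pass before
averaging (SDs computed on the interpolated, filtered samples).  Flagged
epochs carry NaN, never a silently degraded value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import signal

#: Marker labels every trial trace is expected to carry.
MARKER_LABELS = ("item_onset", "choice_onset", "anticip_onset", "anticip_offset")

EPOCH_WINDOW_S = 0.2


@dataclass
class PupilTrace:
    """A uniformly sampled pupil-diameter trace for one trial.

    ``valid`` is the device validity mask (False during blinks/dropouts);
    ``markers`` maps event labels to within-trial times in seconds;
    ``interpolated`` marks samples replaced by blink interpolation.
    """

    t_s: np.ndarray
    diameter_mm: np.ndarray
    valid: np.ndarray
    markers: dict = field(default_factory=dict)
    interpolated: np.ndarray | None = None

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t_s.size == self.diameter_mm.size == self.valid.size):
            raise ValueError("t_s, diameter_mm and valid must have equal length")
        if self.t_s.size >= 2:
            dt = np.diff(self.t_s)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(dt) > 1e-6:
                raise ValueError("sampling interval must be uniform")

    @property
    def fs_hz(self) -> float:
        if self.t_s.size < 2:
            raise ValueError("cannot infer sample rate from < 2 samples")
        return 1.0 / float(self.t_s[1] - self.t_s[0])


def interpolate_blinks(
    trace: PupilTrace, pre_ms: float = 100.0, post_ms: float = 400.0
) -> PupilTrace:
    """Linearly interpolate blink gaps, widened by ``pre_ms``/``post_ms``.

    Every contiguous run of invalid samples is widened by ``pre_ms`` before
    its onset and ``post_ms`` after its offset; samples inside the widened
    windows are replaced by linear interpolation between the nearest valid
    samples outside them.  Samples outside every window are bit-identical
    to the input.  Gaps touching a trace edge are filled with the nearest
    valid value.  The returned trace keeps the original validity mask and
    records the replaced samples in ``interpolated``.
    """
    valid = trace.valid
    if valid.all():
        return replace(
            trace,
            diameter_mm=trace.diameter_mm.copy(),
            interpolated=np.zeros(valid.size, dtype=bool),
        )
    if not valid.any():
        raise ValueError("trace has no valid samples to interpolate from")

    fs = trace.fs_hz
    n_pre = math.ceil(pre_ms / 1000.0 * fs)
    n_post = math.ceil(post_ms / 1000.0 * fs)

    to_fill = np.zeros(valid.size, dtype=bool)
    inv = ~valid
    # widen each invalid run
    starts = np.flatnonzero(inv & ~np.r_[False, inv[:-1]])
    ends = np.flatnonzero(inv & ~np.r_[inv[1:], False])
    for s, e in zip(starts, ends):
        to_fill[max(0, s - n_pre) : min(valid.size, e + n_post + 1)] = True

    anchors = np.flatnonzero(~to_fill & valid)
    if anchors.size == 0:
        raise ValueError("blink windows cover every valid sample")
    idx = np.arange(valid.size)
    diam = trace.diameter_mm.copy()
    diam[to_fill] = np.interp(idx[to_fill], anchors, trace.diameter_mm[anchors])
    return replace(trace, diameter_mm=diam, interpolated=to_fill)


def _butter_sos(cutoff_hz: float, fs_hz: float, order: int):
    return signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")


def lowpass(trace: PupilTrace, cutoff_hz: float = 10.0, order: int = 4) -> PupilTrace:
    """Zero-phase Butterworth low-pass (forward-backward filtering).

    DC is preserved exactly up to numerical precision; the effective
    magnitude response is the filter's squared.  The trace must be gap-free
    (run :func:`interpolate_blinks` first); NaNs raise.
    """
    x = trace.diameter_mm
    if np.any(~np.isfinite(x)):
        raise ValueError("trace contains non-finite samples; interpolate blinks first")
    sos = _butter_sos(cutoff_hz, trace.fs_hz, order)
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if x.size <= padlen:
        raise ValueError(
            f"trace too short for zero-phase filtering: need > {padlen} samples, "
            f"got {x.size}"
        )
    y = signal.sosfiltfilt(sos, x)
    return replace(trace, diameter_mm=y)


def preprocess_trace(
    trace: PupilTrace,
    foreshortening: Callable[[PupilTrace], PupilTrace] | None = None,
    pre_ms: float = 100.0,
    post_ms: float = 400.0,
    cutoff_hz: float = 10.0,
    order: int = 4,
) -> PupilTrace:
    """Full preprocessing chain in fixed order: hook -> blinks -> filter."""
    if foreshortening is not None:
        trace = foreshortening(trace)
    trace = interpolate_blinks(trace, pre_ms=pre_ms, post_ms=post_ms)
    return lowpass(trace, cutoff_hz=cutoff_hz, order=order)


def qc_epoch(
    values,
    valid,
    max_invalid_frac: float = 0.5,
    z_thresh: float = 3.0,
):
    """QC'd mean of one epoch's samples.

    Returns ``(mean, flag)``; ``flag`` is ``None`` when the epoch passes,
    otherwise one of ``"no_samples"``, ``"too_many_invalid"``,
    ``"all_removed"`` and the mean is NaN.
    """
    v = np.asarray(values, dtype=float)
    ok = np.asarray(valid, dtype=bool)
    if v.size == 0:
        return np.nan, "no_samples"
    if (~ok).mean() > max_invalid_frac:
        return np.nan, "too_many_invalid"
    m = v.mean()
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd > 0:
        keep = np.abs(v - m) <= z_thresh * sd
    else:
        keep = np.ones(v.size, dtype=bool)
    if not keep.any():
        return np.nan, "all_removed"
    return float(v[keep].mean()), None


def _window(trace: PupilTrace, start: float, width: float = EPOCH_WINDOW_S):
    mask = (trace.t_s >= start) & (trace.t_s < start + width)
    return trace.diameter_mm[mask], trace.valid[mask]


def extract_epochs(trace: PupilTrace) -> dict:
    """Three event measures for one preprocessed trial trace.

    Requires markers ``item_onset``, ``choice_onset``, ``anticip_onset``,
    ``anticip_offset``.  A missing marker flags the affected measures
    (``"missing_marker"``) rather than dropping the trial.

    Returns a dict with ``pre_item_mm``, ``choice_mm`` (baseline-corrected),
    ``anticip_change_mm`` and per-measure QC flags (None = pass).
    """
    out: dict = {}
    flags: dict = {}
    mk = trace.markers

    def measure(name, start):
        if start is None:
            return np.nan, "missing_marker"
        return qc_epoch(*_window(trace, start))

    pre, f_pre = measure(
        "pre_item",
        mk["item_onset"] - EPOCH_WINDOW_S if "item_onset" in mk else None,
    )
    choice_raw, f_choice = measure(
        "choice", mk.get("choice_onset", None)
    )
    a_first, f_a1 = measure("anticip_first", mk.get("anticip_onset", None))
    a_last, f_a2 = (
        measure("anticip_last", mk["anticip_offset"] - EPOCH_WINDOW_S)
        if "anticip_offset" in mk
        else (np.nan, "missing_marker")
    )

    flags["pre_item"] = f_pre
    # baseline-corrected choice needs both windows
    flags["choice"] = f_choice or f_pre
    flags["anticip"] = f_a1 or f_a2

    out["pre_item_mm"] = pre if f_pre is None else np.nan
    out["choice_mm"] = (
        choice_raw - pre if flags["choice"] is None else np.nan
    )
    out["anticip_change_mm"] = (
        a_last - a_first if flags["anticip"] is None else np.nan
    )
    out["qc_pre_item"] = f_pre
    out["qc_choice"] = flags["choice"]
    out["qc_anticip"] = flags["anticip"]
    return out


def epochs_table(
    traces: Iterable[tuple],
    trial_meta: pd.DataFrame | None = None,
    foreshortening: Callable[[PupilTrace], PupilTrace] | None = None,
    preprocess: bool = True,
) -> pd.DataFrame:
    """Epoch measures for many trials, with carry-over covariates.

    Parameters
    ----------
    traces
        Iterable of ``(participant, trial_index, PupilTrace)``.
    trial_meta
        Optional table with columns ``participant``, ``trial_index``,
        ``condition`` and ``fixation_s``; used to attach the carry-over
        covariates ``prev_condition`` (condition of the preceding trial
        within participant) and ``iti_s`` (current fixation duration).
    preprocess
        Run :func:`preprocess_trace` on each trace first (default).
    """
    rows = []
    for participant, trial_index, trace in traces:
        if preprocess:
            trace = preprocess_trace(trace, foreshortening=foreshortening)
        rec = {"participant": participant, "trial_index": trial_index}
        rec.update(extract_epochs(trace))
        rows.append(rec)
    epochs = pd.DataFrame(rows)
    if trial_meta is not None:
        meta = trial_meta.sort_values(["participant", "trial_index"]).copy()
        meta["prev_condition"] = meta.groupby("participant")["condition"].shift(1)
        cov = meta[["participant", "trial_index", "prev_condition", "fixation_s"]]
        cov = cov.rename(columns={"fixation_s": "iti_s"})
        epochs = epochs.merge(cov, on=["participant", "trial_index"], how="left")
    return epochs
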