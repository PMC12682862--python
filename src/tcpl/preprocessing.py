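"""Motor-imagery EEG preprocessing.

The pipeline turns a cued raw recording into normalised fixed-length epochs:

1. zero-phase band-pass (default 8-30 Hz, the mu/beta range carrying ERD/ERS),
2. 4-s epochs after each cue, baseline-corrected with the 1-s pre-cue mean,
3. peak-to-peak amplitude rejection of artefactual trials,
4. polyphase resampling to 128 Hz, common average reference, and per-subject
   per-channel z-scoring pooled over all of the subject's surviving trials.

All filters are 4th-order Butterworth applied forward-backward (``sosfiltfilt``)
so cue latencies are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochedTrial, RawRecording

__all__ = [
    "PreprocessConfig",
    "bandpass_filter",
    "epoch_and_baseline",
    "reject_artifacts",
    "resample_car_zscore",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_FILTER_ORDER = 4
_STD_FLOOR = 1e-8


@dataclass
class PreprocessConfig:
    band: tuple[float, float] = (8.0, 30.0)
    epoch_s: float = 4.0
    baseline_s: float = 1.0
    target_fs: float = 128.0
    amplitude_thresh: float = 150.0  # uV peak-to-peak
    car: bool = True
    bad_channels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        low, high = self.band
        if not (0 < low < high):
            raise ValueError(f"invalid band {self.band}: need 0 < low < high")
        if high >= self.target_fs / 2:
            raise ValueError(
                f"band edge {high} Hz >= Nyquist of target rate {self.target_fs / 2} Hz")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        if self.baseline_s < 0:
            raise ValueError("baseline_s must be non-negative")
        if self.amplitude_thresh <= 0:
            raise ValueError("amplitude threshold must be positive")


def _design_bandpass(band: tuple[float, float], fs: float) -> np.ndarray:
    low, high = band
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz >= Nyquist {fs / 2} Hz")
    if low <= 0:
        raise ValueError("band low edge must be positive")
    return signal.butter(_FILTER_ORDER, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def bandpass_filter(rec: RawRecording, band: tuple[float, float]) -> RawRecording:
    """Zero-phase band-pass of a whole recording (forward-backward Butterworth)."""
    sos = _design_bandpass(band, rec.fs)
    filtered = signal.sosfiltfilt(sos, rec.signal, axis=-1)
    return RawRecording(filtered, rec.fs, list(rec.channel_names),
                        list(rec.events), rec.subject_id)


def epoch_and_baseline(rec: RawRecording,
                       cfg: PreprocessConfig) -> list[EpochedTrial]:
    """Cut one epoch per cue and subtract the per-channel pre-cue baseline mean.

    Events whose window falls outside the recording are skipped with a log
    message rather than raising.
    """
    n_epoch = int(round(cfg.epoch_s * rec.fs))
    n_base = int(round(cfg.baseline_s * rec.fs))
    n_samples = rec.signal.shape[1]
    trials: list[EpochedTrial] = []
    skipped = 0
    for cue, label in rec.events:
        if cue - n_base < 0 or cue + n_epoch > n_samples:
            skipped += 1
            log.warning("skipping event at sample %d (window out of range)", cue)
            continue
        epoch = rec.signal[:, cue:cue + n_epoch].copy()
        if n_base > 0:
            epoch -= rec.signal[:, cue - n_base:cue].mean(axis=1, keepdims=True)
        trials.append(EpochedTrial(epoch, int(label), rec.subject_id, rec.fs))
    if skipped:
        log.info("epoching: %d events skipped, %d trials kept", skipped, len(trials))
    return trials


def reject_artifacts(trials: list[EpochedTrial],
                     amplitude_thresh: float) -> list[EpochedTrial]:
    """Drop trials whose largest per-channel peak-to-peak exceeds the threshold."""
    if amplitude_thresh <= 0:
        raise ValueError("amplitude threshold must be positive")
    kept = []
    for t in trials:
        ptp = (t.data.max(axis=1) - t.data.min(axis=1)).max() if t.data.size else 0.0
        if ptp <= amplitude_thresh:
            kept.append(t)
    removed = len(trials) - len(kept)
    if removed:
        log.info("artifact rejection: removed %d of %d trials", removed, len(trials))
    if trials and not kept:
        log.warning("artifact rejection removed every trial")
    return kept


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels (idempotent)."""
    return data - data.mean(axis=-2, keepdims=True)


def resample_car_zscore(trials: list[EpochedTrial],
                        cfg: PreprocessConfig) -> list[EpochedTrial]:
    """Resample to the target rate, re-reference (CAR), and z-score.

    Z-scoring uses per-channel mean/std pooled over *all* given trials of the
    subject, so statistics never mix across subjects. A zero-variance channel
    is guarded with a small floor and logged.
    """
    if not trials:
        return []
    fs_set = {t.fs for t in trials}
    sid_set = {t.subject_id for t in trials}
    if len(fs_set) > 1 or len(sid_set) > 1:
        raise ValueError("all trials must share sampling rate and subject")
    fs = trials[0].fs
    n_target = int(round(cfg.epoch_s * cfg.target_fs))

    frac = Fraction(cfg.target_fs / fs).limit_denominator(1000)
    resampled = []
    for t in trials:
        if frac != 1:
            data = signal.resample_poly(t.data, frac.numerator, frac.denominator,
                                        axis=-1)
        else:
            data = t.data.copy()
        data = data[:, :n_target]
        if cfg.car:
            data = common_average_reference(data)
        resampled.append(data)

    stacked = np.stack(resampled)  # n x C x T
    mean = stacked.mean(axis=(0, 2), keepdims=True)
    std = stacked.std(axis=(0, 2), keepdims=True)
    degenerate = std < _STD_FLOOR
    if degenerate.any():
        log.warning("z-score: %d degenerate (zero-variance) channels",
                    int(degenerate.sum()))
    stacked = (stacked - mean) / (std + _STD_FLOOR)
    return [EpochedTrial(d, t.label, t.subject_id, cfg.target_fs)
            for d, t in zip(stacked, trials)]


def run_pipeline(rec: RawRecording, cfg: PreprocessConfig) -> list[EpochedTrial]:
    """Full pipeline: band-pass -> epoch+baseline -> reject -> resample/CAR/z-score."""
    if cfg.bad_channels:
        keep = [i for i, name in enumerate(rec.channel_names)
                if name not in cfg.bad_channels]
        if not keep:
            raise ValueError("all channels listed as bad")
        rec = RawRecording(rec.signal[keep], rec.fs,
                           [rec.channel_names[i] for i in keep],
                           list(rec.events), rec.subject_id)
    filtered = bandpass_filter(rec, cfg.band)
    epochs = epoch_and_baseline(filtered, cfg)
    log.info("pipeline: %d events -> %d epochs", len(rec.events), len(epochs))
    kept = reject_artifacts(epochs, cfg.amplitude_thresh)
    out = resample_car_zscore(kept, cfg)
    log.info("pipeline: %d epochs survive rejection, %d normalised", len(kept),
             len(out))
    return out
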