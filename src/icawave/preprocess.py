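"""Filtering, R-wave detection and beat segmentation.

All filters are applied forward-backward (zero phase): any phase lag would
shift the detected R apex away from the window centre and corrupt the
phase-shift coefficient alpha, to which the feature extractor is sensitive.

Conventions: 0-based sample indices, half-open windows ``[start, start + d)``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from icawave.records import ECGRecord, Heartbeat

logger = logging.getLogger(__name__)

REFRACTORY_S = 0.200  # minimum R-R separation enforced by the detector
SEARCHBACK_FACTOR = 0.5  # search-back threshold relative to the signal threshold


def bandpass_filter(record: ECGRecord, low: float = 5.0, high: float = 15.0,
                    order: int = 2) -> ECGRecord:
    """Zero-phase Butterworth band-pass (default 5-15 Hz, the QRS band)."""
    nyq = record.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"invalid band ({low}, {high}) for fs={record.sampling_rate}")
    sos = sps.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return record.replace_samples(sps.sosfiltfilt(sos, record.samples))


def remove_baseline(record: ECGRecord, cutoff: float = 0.5) -> ECGRecord:
    """Subtract a low-frequency (< ``cutoff`` Hz) baseline-wander estimate.

    The estimate is a zero-phase low-pass of the signal, so QRS amplitudes are
    preserved while respiration-scale drift is removed.
    """
    if len(record) <= int(2 * record.sampling_rate / cutoff):
        raise ValueError("record too short for baseline estimation")
    nyq = record.sampling_rate / 2.0
    sos = sps.butter(2, cutoff / nyq, btype="lowpass", output="sos")
    baseline = sps.sosfiltfilt(sos, record.samples)
    return record.replace_samples(record.samples - baseline)


def detect_r_peaks(record: ECGRecord) -> list[int]:
    """Pan-Tompkins QRS detection.

    Band-pass (5-15 Hz) -> derivative -> squaring -> moving-window integration
    (150 ms) -> adaptive dual thresholds with search-back.  Detections are
    refined to the apex of the baseline-removed raw signal within +/-50 ms, so
    the returned indices mark the R peak itself.  Thresholds adapt
    multiplicatively, making the output invariant to amplitude scaling.
    """
    fs = record.sampling_rate
    if len(record) < 2 * fs:
        raise ValueError("record must be at least 2 s long")
    x = record.samples
    filt = bandpass_filter(record).samples
    deriv = np.gradient(filt)
    squared = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0 or mwi.max() <= 0:
        return []

    # raw signal with wander removed, for apex refinement
    try:
        raw = remove_baseline(record).samples
    except ValueError:
        raw = x - np.mean(x)
    refine_half = int(round(0.050 * fs))

    # threshold initialization from the first 2 s
    head = mwi[: int(2 * fs)]
    spki = 0.5 * float(head.max())
    npki = float(np.mean(head)) * 0.5
    thr1 = npki + 0.25 * (spki - npki)

    accepted: list[int] = []
    rr_history: list[int] = []
    last = None
    i = 0
    while i < len(cand):
        p = int(cand[i])
        if mwi[p] > thr1:
            accepted.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
            if last is not None:
                rr_history.append(p - last)
                rr_history = rr_history[-8:]
            last = p
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            # search-back: if a beat is overdue, accept the best candidate
            # above the lower threshold since the last detection
            if rr_history and last is not None and (p - last) > 1.66 * np.mean(rr_history):
                window = [c for c in cand if last + refractory <= c <= p]
                window = [c for c in window if mwi[c] > SEARCHBACK_FACTOR * thr1]
                if window:
                    best = int(max(window, key=lambda c: mwi[c]))
                    accepted.append(best)
                    spki = 0.25 * mwi[best] + 0.75 * spki
                    rr_history.append(best - last)
                    rr_history = rr_history[-8:]
                    last = best
        thr1 = npki + 0.25 * (spki - npki)
        i += 1

    # refine each detection to the raw-signal apex
    refined = []
    for p in accepted:
        lo = max(0, p - refine_half)
        hi = min(len(raw), p + refine_half + 1)
        refined.append(lo + int(np.argmax(raw[lo:hi])))
    refined = sorted(set(refined))
    # enforce the refractory period after refinement
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refractory:
            if raw[p] > raw[out[-1]]:
                out[-1] = p
            continue
        out.append(p)
    return out


def segment_beats(
    record: ECGRecord,
    r_indices: list[int],
    d: int,
    label_tolerance_s: float = 0.150,
) -> list[Heartbeat]:
    """Cut fixed-width windows ``[r - d//2, r - d//2 + d)`` around each R index.

    Windows exceeding the record bounds are dropped, as are beats with no
    annotation within ``label_tolerance_s`` of the R index; both counts are
    logged.  Each window is an exact slice of the record samples.
    """
    half = d // 2
    tol = int(round(label_tolerance_s * record.sampling_rate))
    ann = sorted(record.annotations)
    ann_idx = np.array([a[0] for a in ann], dtype=int)
    beats: list[Heartbeat] = []
    dropped_bounds = dropped_label = 0
    for r in r_indices:
        start = r - half
        if start < 0 or start + d > len(record):
            dropped_bounds += 1
            continue
        if len(ann_idx) == 0:
            dropped_label += 1
            continue
        j = int(np.argmin(np.abs(ann_idx - r)))
        if abs(int(ann_idx[j]) - r) > tol:
            dropped_label += 1
            continue
        beats.append(
            Heartbeat(
                window=record.samples[start : start + d].copy(),
                r_index=r - start,
                class_label=ann[j][1],
                subject_id=record.subject_id,
            )
        )
    if dropped_bounds or dropped_label:
        logger.info(
            "segment_beats: dropped %d out-of-bounds and %d unlabeled beats",
            dropped_bounds, dropped_label,
        )
    return beats


def phase_shift(t1: int, td: int, tR: int) -> float:
    """Phase-shift coefficient between the R index and the window middle.

    ``alpha = |tR - (t1 + (td - t1)//2)| / ((td - t1)//2)``; 0 when the R wave
    sits exactly at the middle, ~1 at the window edge.
    """
    if td <= t1:
        raise ValueError("window end must exceed window start")
    if not t1 <= tR <= td:
        raise ValueError("tR outside window")
    half = (td - t1) // 2
    mid = t1 + half
    return abs(tR - mid) / half


def apply_shift(beat: Heartbeat, alpha_target: float, direction: int = 1) -> Heartbeat:
    """Re-crop a beat so its phase shift equals ``alpha_target``.

    ``direction`` (+1/-1) selects a late or early R wave.  Samples shifted in
    from outside the original window are filled by edge replication; the
    achieved alpha matches the target up to one-sample quantization.
    """
    if not 0 <= alpha_target <= 1:
        raise ValueError("alpha_target must be in [0, 1]")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    d = beat.d
    half = d // 2
    shift = int(round(alpha_target * half)) * direction
    if shift == 0:
        return Heartbeat(beat.window.copy(), beat.r_index, beat.class_label, beat.subject_id)
    out = np.empty(d)
    if shift > 0:  # R moves right; content shifts right, left edge replicated
        out[shift:] = beat.window[:-shift]
        out[:shift] = beat.window[0]
    else:
        out[:shift] = beat.window[-shift:]
        out[shift:] = beat.window[-1]
    r_new = int(np.clip(beat.r_index + shift, 0, d - 1))
    return Heartbeat(out, r_new, beat.class_label, beat.subject_id)
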