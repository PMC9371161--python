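"""Channel-specific preprocessing for PSG signals.

SaO2 artifact rejection, airflow/effort baseline correction and filtering,
ECG band-pass, Pan-Tompkins R-peak detection, RR interval correction, QRS
window extraction, and ECG-derived respiration (EDR).

All Butterworth filters are applied zero-phase (forward-backward), so event
boundaries are not shifted by filter group delay. Running medians replicate
edge values over the first/last half-window.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "RrSeries",
    "zero_phase_butter",
    "running_median",
    "clean_sao2",
    "preprocess_airflow",
    "preprocess_effort",
    "preprocess_ecg",
    "detect_r_peaks",
    "correct_rr",
    "extract_qrs",
    "derive_edr",
]


@dataclass
class PreprocessConfig:
    """Tunables for the preprocessing stage (all units SI)."""

    sao2_jump_pts: float = 8.0          # point-to-point artifact threshold (% pts)
    airflow_lowpass_hz: float = 3.0
    airflow_baseline_s: float = 10.0
    airflow_out_fs: float = 1.0
    effort_band_hz: tuple = (0.05, 4.0)
    effort_baseline_s: float = 60.0
    ecg_band_hz: tuple = (0.05, 40.0)
    butter_order: int = 3
    pt_band_hz: tuple = (5.0, 15.0)     # Pan-Tompkins internal band-pass
    pt_integration_s: float = 0.150
    pt_refractory_s: float = 0.200
    pt_learning_s: float = 2.0
    rr_range_s: tuple = (0.3, 2.0)
    rr_deviation_frac: float = 0.20
    rr_neighbours: int = 5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RrSeries:
    """R-peak times and the successive RR intervals between them."""

    times_s: np.ndarray
    intervals_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intervals_s = np.asarray(self.intervals_s, dtype=float)
        if self.times_s.size and self.intervals_s.size != self.times_s.size - 1:
            raise ValueError("need len(intervals_s) == len(times_s) - 1")

    @classmethod
    def from_peaks(cls, peak_indices: np.ndarray, fs: float) -> "RrSeries":
        t = np.asarray(peak_indices, dtype=float) / fs
        return cls(t, np.diff(t))


# ---------------------------------------------------------------------------
# shared filter helpers
# ---------------------------------------------------------------------------

def zero_phase_butter(x: np.ndarray, fs: float, btype: str, cutoff, order: int = 3) -> np.ndarray:
    """Forward-backward Butterworth filter (zero net phase)."""
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise ValueError(f"series of {x.size} samples too short for filter warm-up ({padlen})")
    return sps.sosfiltfilt(sos, x)


def running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running median with edge replication, O(n log w)."""
    x = np.asarray(x, dtype=float)
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1  # keep the window centred
    half = window // 2
    padded = np.concatenate([np.repeat(x[0], half), x, np.repeat(x[-1], half)])
    med = pd.Series(padded).rolling(window, center=True).median().to_numpy()
    return med[half:half + x.size]


# ---------------------------------------------------------------------------
# per-channel preprocessing
# ---------------------------------------------------------------------------

def clean_sao2(x: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Replace non-physiological SaO2 jumps by an early-record reference.

    Scanning left to right, any sample differing from its (cleaned)
    predecessor by strictly more than 8 percentage points is replaced by
    the median of the first 10 s of the original series. Comparing against
    the cleaned predecessor makes the operation idempotent.
    """
    cfg = config or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("clean_sao2 needs at least 10 samples (10 s at 1 Hz)")
    ref = float(np.median(x[:10]))
    y = x.copy()
    for i in range(1, y.size):
        if abs(y[i] - y[i - 1]) > cfg.sao2_jump_pts:
            y[i] = ref
    return y


def preprocess_airflow(x: np.ndarray, fs: float = 10.0,
                       config: PreprocessConfig | None = None) -> np.ndarray:
    """Airflow: 10-s running-median baseline removal, 3rd-order Butterworth
    low-pass at 3 Hz (zero-phase), then decimation to 1 Hz."""
    cfg = config or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    baseline = running_median(x, int(round(cfg.airflow_baseline_s * fs)))
    y = zero_phase_butter(x - baseline, fs, "lowpass", cfg.airflow_lowpass_hz, cfg.butter_order)
    step = int(round(fs / cfg.airflow_out_fs))
    return y[::step]


def preprocess_effort(x: np.ndarray, fs: float = 10.0,
                      config: PreprocessConfig | None = None) -> np.ndarray:
    """Thoracic/abdominal effort: 60-s running-median baseline removal and a
    zero-phase 0.05-4 Hz Butterworth band-pass; rate unchanged."""
    cfg = config or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    baseline = running_median(x, int(round(cfg.effort_baseline_s * fs)))
    return zero_phase_butter(x - baseline, fs, "bandpass", cfg.effort_band_hz, cfg.butter_order)


def preprocess_ecg(x: np.ndarray, fs: float = 125.0,
                   config: PreprocessConfig | None = None) -> np.ndarray:
    """ECG: zero-phase 3rd-order Butterworth band-pass 0.05-40 Hz."""
    cfg = config or PreprocessConfig()
    return zero_phase_butter(np.asarray(x, dtype=float), fs, "bandpass",
                             cfg.ecg_band_hz, cfg.butter_order)


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float,
                   config: PreprocessConfig | None = None) -> np.ndarray:
    """Pan-Tompkins QRS detection returning R-peak sample indices.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, then adaptive signal/noise thresholds with a
    200 ms refractory period and search-back at half threshold when the gap
    since the last detection exceeds 1.66x the running RR average. Thresholds
    are initialized on the first 2 s. Detected integration peaks are refined
    to the local maximum of the band-passed ECG.
    """
    cfg = config or PreprocessConfig()
    x = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError("detect_r_peaks expects fs >= 100 Hz")
    if x.size < 2 * fs:
        raise ValueError("record shorter than 2 s")
    if np.ptp(x) < 1e-12:
        return np.array([], dtype=int)

    bp = zero_phase_butter(x, fs, "bandpass", cfg.pt_band_hz, order=2)
    # five-point derivative, same length
    der = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    sq = der ** 2
    win = max(1, int(round(cfg.pt_integration_s * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(cfg.pt_refractory_s * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    learn = mwi[: int(cfg.pt_learning_s * fs)]
    spki = float(np.max(learn)) * 0.5 if learn.size else float(np.max(mwi)) * 0.5
    npki = float(np.mean(learn)) * 0.5 if learn.size else 0.0

    detections: list[int] = []
    rr_history: list[float] = []
    last_missed: list[int] = []

    def accept(idx: int) -> None:
        nonlocal spki
        spki = 0.125 * mwi[idx] + 0.875 * spki
        detections.append(idx)

    for idx in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[idx] > thr:
            if detections and rr_history:
                gap = idx - detections[-1]
                avg_rr = float(np.mean(rr_history[-8:]))
                if gap > 1.66 * avg_rr and last_missed:
                    # search-back: best missed candidate above half threshold
                    back = [j for j in last_missed if mwi[j] > 0.5 * thr]
                    if back:
                        accept(max(back, key=lambda j: mwi[j]))
                        rr_history.append(detections[-1] - detections[-2])
            if detections:
                rr_history.append(idx - detections[-1])
            accept(idx)
            last_missed = []
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki
            last_missed.append(idx)

    if not detections:
        return np.array([], dtype=int)

    # refine to the band-passed ECG local maximum near each integration peak
    half = int(round(0.10 * fs))
    refined = []
    for idx in sorted(set(detections)):
        lo, hi = max(0, idx - half), min(x.size, idx + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=int)

    # enforce the refractory contract on the final indices
    keep = [int(refined[0])]
    for idx in refined[1:]:
        if idx - keep[-1] >= refractory:
            keep.append(int(idx))
        elif bp[idx] > bp[keep[-1]]:
            keep[-1] = int(idx)
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# RR correction, QRS matrix, EDR
# ---------------------------------------------------------------------------

def correct_rr(rr: RrSeries, config: PreprocessConfig | None = None) -> RrSeries:
    """Replace implausible RR intervals by a local median.

    An interval is implausible when it falls outside [0.3, 2.0] s or
    deviates by more than 20% from the median of its 5 nearest neighbouring
    intervals. Replacements use that local median, clipped into the
    physiological range; length is preserved and R times are left untouched.
    """
    cfg = config or PreprocessConfig()
    lo, hi = cfg.rr_range_s
    iv = rr.intervals_s.copy()
    n = iv.size
    if n == 0:
        return RrSeries(rr.times_s.copy(), iv)
    half = cfg.rr_neighbours // 2
    out = iv.copy()
    for i in range(n):
        nb = np.concatenate([iv[max(0, i - half):i], iv[i + 1:i + half + 1]])
        local = float(np.median(nb)) if nb.size else float(iv[i])
        bad = iv[i] < lo or iv[i] > hi
        if not bad and local > 0:
            bad = abs(iv[i] - local) > cfg.rr_deviation_frac * local
        if bad:
            out[i] = float(np.clip(local, lo, hi))
    return RrSeries(rr.times_s.copy(), np.clip(out, lo, hi))


def qrs_window_samples(fs: float) -> int:
    """Samples in a symmetric 120 ms QRS window (15 at 125 Hz), forced odd."""
    n = int(round(0.120 * fs))
    return n + 1 if n % 2 == 0 else n


def extract_qrs(ecg: np.ndarray, rpeaks: np.ndarray, fs: float = 125.0) -> np.ndarray:
    """Stack symmetric 120 ms windows around R-peaks (rows ordered by time).

    Peaks too close to a record edge for a full window are dropped.
    """
    ecg = np.asarray(ecg, dtype=float)
    rpeaks = np.asarray(rpeaks, dtype=int)
    width = qrs_window_samples(fs)
    half = width // 2
    rows = [
        ecg[p - half:p + half + 1]
        for p in rpeaks
        if p - half >= 0 and p + half + 1 <= ecg.size
    ]
    if not rows:
        return np.empty((0, width))
    return np.vstack(rows)


def derive_edr(ecg: np.ndarray, rpeaks: np.ndarray, fs: float = 125.0) -> np.ndarray:
    """ECG-derived respiration at 1 Hz via the R-wave-area method.

    Per beat, the 120 ms QRS window has the straight line through its first
    and last samples subtracted and the residual averaged (an area measure
    of R-wave morphology, which respiration modulates). The per-beat series
    is then linearly interpolated onto a 1 Hz grid spanning the record.
    """
    ecg = np.asarray(ecg, dtype=float)
    rpeaks = np.asarray(rpeaks, dtype=int)
    if rpeaks.size == 0:
        raise ValueError("derive_edr needs at least one R-peak")
    width = qrs_window_samples(fs)
    half = width // 2
    ramp = np.linspace(0.0, 1.0, width)
    times, values = [], []
    for p in rpeaks:
        if p - half < 0 or p + half + 1 > ecg.size:
            continue
        w = ecg[p - half:p + half + 1]
        baseline = w[0] + (w[-1] - w[0]) * ramp
        times.append(p / fs)
        values.append(float(np.mean(w - baseline)))
    if not times:
        raise ValueError("no complete QRS window available for EDR")
    grid = np.arange(0.0, ecg.size / fs, 1.0)
    return np.interp(grid, np.asarray(times), np.asarray(values))
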