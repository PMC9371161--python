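"""The 66-feature multi-domain battery computed per segment.

Five families share one code path regardless of how segments were produced
(event-duration or fixed 60-s windows): 12 SaO2 features, 10 airflow, 6
abdominal, 6 thoracic, and 32 ECG features. Feature names carry a family
prefix (``sao2.``, ``airflow.``, ``abd.``, ``thor.``, ``ecg.``) followed by
the canonical short name, and their order is fixed and versioned in
:data:`FEATURE_NAMES`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from . import dsp
from . import preprocess as pp
from .psg import PsgRecord, Segment, segment_by_events, segment_by_windows

logger = logging.getLogger(__name__)

SAO2_NAMES = [
    "sao2.med", "sao2.MM2", "sao2.kur", "sao2.var", "sao2.min", "sao2.mean",
    "sao2.NumZC", "sao2.comp", "sao2.SD1", "sao2.Bel98", "sao2.Abo98",
    "sao2.mean_PSD0.016/0.05",
]
AIRFLOW_NAMES = [
    "airflow.mean", "airflow.med", "airflow.std", "airflow.mean_PSD0/0.1",
    "airflow.mean_PSD0.4/0.5", "airflow.mean_D1", "airflow.mean_D2",
    "airflow.mean_D3", "airflow.mean_A3", "airflow.comp",
]
ABDOMINAL_NAMES = [
    "abd.sum_abs", "abd.std_abs", "abd.mean", "abd.mean_PSD80/100",
    "abd.mean_D2", "abd.mean_D1",
]
THORACIC_NAMES = [
    "thor.sum", "thor.med", "thor.std", "thor.mean", "thor.var",
    "thor.sum_PSD80/100",
]
ECG_NAMES = [
    "ecg.NN50_RR", "ecg.SDSD_RR", "ecg.tSD_RR", "ecg.std_RR", "ecg.var",
    "ecg.kur", "ecg.mean_RR", "ecg.CV_EDR", "ecg.SS", "ecg.SD",
    "ecg.entropy_D1", "ecg.entropy_D2", "ecg.entropy_D3", "ecg.entropy_D4",
    "ecg.entropy_D5", "ecg.entropy_D6", "ecg.entropy_D7",
    "ecg.var_D1", "ecg.var_D2", "ecg.var_D3", "ecg.var_D4", "ecg.var_D5",
    "ecg.var_D6", "ecg.var_D7",
    "ecg.WSD_RR", "ecg.max_PSD0.03/0.5", "ecg.mean_PSD10/20",
    "ecg.mean_PSD80/100", "ecg.SCrC_3_RR", "ecg.SCrC_4_RR",
    "ecg.max_dia_kPCA", "ecg.RP_2_PC",
]

#: the fixed 66-name schema, in canonical (family-block) order
FEATURE_NAMES: list[str] = (
    SAO2_NAMES + AIRFLOW_NAMES + ABDOMINAL_NAMES + THORACIC_NAMES + ECG_NAMES
)
assert len(FEATURE_NAMES) == 66


@dataclass
class FeatureConfig:
    """Tunables of the feature battery."""

    mm2_threshold_pts: float = 2.0      # SaO2 extremum-to-extremum excursion
    bel98_fraction: float = 0.98        # threshold relative to window max
    nn50_ms: float = 50.0
    ar_order: int = 5
    nfft: int = 256
    effort_yw_segment: int = 40         # samples per Yule-Walker segment
    ecg_welch_s: float = 2.0            # Hann segment length for ECG PSDs
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)


def _kurtosis(x: np.ndarray) -> float:
    """Pearson kurtosis (normal -> 3); degenerate (constant) windows -> 0."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) < 1e-15:
        return 0.0
    return float(spstats.kurtosis(x, fisher=False, bias=True))


# ---------------------------------------------------------------------------
# SaO2 family
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray) -> np.ndarray:
    """Alternating local-extrema sequence including the window endpoints.

    Runs of equal values are compressed first, so plateaus count once.
    """
    keep = np.concatenate([[True], np.diff(x) != 0])
    z = x[keep]
    if z.size <= 2:
        return z
    interior = np.sign(np.diff(z))
    turning = np.concatenate([[True], interior[1:] != interior[:-1], [True]])
    return z[turning]


def mm2_count(x: np.ndarray, threshold: float = 2.0) -> int:
    """Count maximum-to-minimum swings larger than ``threshold`` points:
    adjacent pairs in the alternating local-extrema sequence whose absolute
    difference exceeds the threshold."""
    e = _local_extrema(np.asarray(x, dtype=float))
    if e.size < 2:
        return 0
    return int(np.sum(np.abs(np.diff(e)) > threshold))


def sao2_features(w: np.ndarray, config: FeatureConfig | None = None) -> dict[str, float]:
    """12 oximetry features of a cleaned SaO2 window at 1 Hz."""
    cfg = config or FeatureConfig()
    w = np.asarray(w, dtype=float)
    if w.size < 10:
        raise ValueError("sao2_features needs at least 10 samples")
    if not np.all(np.isfinite(w)):
        raise ValueError("sao2_features: non-finite input")
    thr = cfg.bel98_fraction * float(np.max(w))
    bel = int(np.sum(w < thr))
    psd = dsp.yule_walker_psd(w, order=cfg.ar_order, fs=1.0, nfft=cfg.nfft)
    return {
        "sao2.med": float(np.median(w)),
        "sao2.MM2": float(mm2_count(w, cfg.mm2_threshold_pts)),
        "sao2.kur": _kurtosis(w),
        "sao2.var": float(np.var(w)),
        "sao2.min": float(np.min(w)),
        "sao2.mean": float(np.mean(w)),
        "sao2.NumZC": float(dsp.zero_crossings(w)),
        "sao2.comp": dsp.lz_complexity(w),
        "sao2.SD1": dsp.poincare_sd1(w),
        "sao2.Bel98": float(bel),
        "sao2.Abo98": float(w.size - bel),
        "sao2.mean_PSD0.016/0.05": dsp.band_stat(psd, 0.016, 0.05, "mean"),
    }


# ---------------------------------------------------------------------------
# airflow family
# ---------------------------------------------------------------------------

def airflow_features(w: np.ndarray, config: FeatureConfig | None = None) -> dict[str, float]:
    """10 features of a preprocessed airflow window at 1 Hz."""
    cfg = config or FeatureConfig()
    w = np.asarray(w, dtype=float)
    psd = dsp.welch_psd(w, segment_len=5, overlap=2, fs=1.0, nfft=cfg.nfft)
    wstats, _ = dsp.wavelet_stats(w, "db3", 3)
    return {
        "airflow.mean": float(np.mean(w)),
        "airflow.med": float(np.median(w)),
        "airflow.std": float(np.std(w)),
        "airflow.mean_PSD0/0.1": dsp.band_stat(psd, 0.0, 0.1, "mean"),
        "airflow.mean_PSD0.4/0.5": dsp.band_stat(psd, 0.4, 0.5, "mean"),
        "airflow.mean_D1": wstats["D1"]["mean"],
        "airflow.mean_D2": wstats["D2"]["mean"],
        "airflow.mean_D3": wstats["D3"]["mean"],
        "airflow.mean_A3": wstats["A3"]["mean"],
        "airflow.comp": dsp.lz_complexity(w),
    }


# ---------------------------------------------------------------------------
# effort families
# ---------------------------------------------------------------------------

def _effort_psd(w: np.ndarray, fs: float, cfg: FeatureConfig) -> dsp.PsdEstimate:
    return dsp.yule_walker_psd(w, order=cfg.ar_order, fs=fs, nfft=cfg.nfft,
                               segment_len=cfg.effort_yw_segment)


def abdominal_features(w: np.ndarray, fs: float = 10.0,
                       config: FeatureConfig | None = None) -> dict[str, float]:
    """6 features of a preprocessed abdominal-effort window at 10 Hz."""
    cfg = config or FeatureConfig()
    w = np.asarray(w, dtype=float)
    psd = _effort_psd(w, fs, cfg)
    wstats, _ = dsp.wavelet_stats(w, "db2", 2)
    return {
        "abd.sum_abs": float(np.sum(np.abs(w))),
        "abd.std_abs": float(np.std(np.abs(w))),
        "abd.mean": float(np.mean(w)),
        # 80-100 band read under the normalized-band convention (4-5 Hz here)
        "abd.mean_PSD80/100": dsp.band_stat(psd, 80.0, 100.0, "mean"),
        "abd.mean_D2": wstats["D2"]["mean"],
        "abd.mean_D1": wstats["D1"]["mean"],
    }


def thoracic_features(w: np.ndarray, fs: float = 10.0,
                      config: FeatureConfig | None = None) -> dict[str, float]:
    """6 features of a preprocessed thoracic-effort window at 10 Hz."""
    cfg = config or FeatureConfig()
    w = np.asarray(w, dtype=float)
    psd = _effort_psd(w, fs, cfg)
    return {
        "thor.sum": float(np.sum(w)),
        "thor.med": float(np.median(w)),
        "thor.std": float(np.std(w)),
        "thor.mean": float(np.mean(w)),
        "thor.var": float(np.var(w)),
        "thor.sum_PSD80/100": dsp.band_stat(psd, 80.0, 100.0, "sum"),
    }


# ---------------------------------------------------------------------------
# ECG family
# ---------------------------------------------------------------------------

def nn50_count(intervals_s: np.ndarray, threshold_ms: float = 50.0) -> int:
    """One-sided NN50: adjacent RR pairs where the later interval exceeds
    the earlier one by more than the threshold."""
    iv = np.asarray(intervals_s, dtype=float)
    if iv.size < 2:
        return 0
    return int(np.sum(np.diff(iv) > threshold_ms / 1000.0))


def _tsd_rr(intervals_s: np.ndarray, times_s: np.ndarray, duration_s: float) -> float:
    """Absolute difference of the RR standard deviations in the two halves
    of the segment (30 s + 30 s for a 60-s window). Intervals are assigned
    to halves by their midpoint time; a half with <2 intervals contributes 0."""
    mid = duration_s / 2.0
    midpoints = (times_s[:-1] + times_s[1:]) / 2.0
    first = intervals_s[midpoints < mid]
    second = intervals_s[midpoints >= mid]
    sd1 = float(np.std(first)) if first.size >= 2 else 0.0
    sd2 = float(np.std(second)) if second.size >= 2 else 0.0
    return abs(sd1 - sd2)


def ecg_features(
    ecg: np.ndarray,
    fs: float = 125.0,
    rr: pp.RrSeries | None = None,
    edr: np.ndarray | None = None,
    qrs: np.ndarray | None = None,
    duration_s: float | None = None,
    config: FeatureConfig | None = None,
) -> dict[str, float]:
    """32 ECG-block features of a preprocessed ECG window.

    ``rr``/``edr``/``qrs`` may be precomputed (times relative to the window
    start); when omitted they are derived from the window itself via
    Pan-Tompkins detection, RR correction, the R-wave-area EDR, and 120 ms
    QRS extraction. Degenerate windows (too few beats) yield zeroed
    RR/kPCA features with a logged warning instead of failing.
    """
    cfg = config or FeatureConfig()
    ecg = np.asarray(ecg, dtype=float)
    if duration_s is None:
        duration_s = ecg.size / fs

    if rr is None or qrs is None or edr is None:
        peaks = pp.detect_r_peaks(ecg, fs, cfg.preprocess)
        if rr is None:
            rr = pp.correct_rr(pp.RrSeries.from_peaks(peaks, fs), cfg.preprocess)
        if qrs is None:
            qrs = pp.extract_qrs(ecg, peaks, fs)
        if edr is None:
            if peaks.size >= 2:
                edr = pp.derive_edr(ecg, peaks, fs)
            else:
                logger.warning("ecg_features: <2 R-peaks, EDR features set to 0")
                edr = np.zeros(max(2, int(duration_s)))

    iv, tt = rr.intervals_s, rr.times_s
    out: dict[str, float] = {}

    if iv.size >= 2:
        out["ecg.NN50_RR"] = float(nn50_count(iv, cfg.nn50_ms))
        out["ecg.SDSD_RR"] = float(np.std(np.diff(iv)))
        out["ecg.tSD_RR"] = _tsd_rr(iv, tt, duration_s)
        out["ecg.std_RR"] = float(np.std(iv))
        out["ecg.mean_RR"] = float(np.mean(iv))
        out["ecg.SCrC_3_RR"] = dsp.serial_corr(iv, 3)
        out["ecg.SCrC_4_RR"] = dsp.serial_corr(iv, 4)
        # RR interval sequence treated as sampled at the mean beat rate
        rr_fs = 1.0 / float(np.mean(iv))
        if iv.size > cfg.ar_order:
            rr_psd = dsp.yule_walker_psd(iv, order=cfg.ar_order, fs=rr_fs, nfft=cfg.nfft)
            out["ecg.max_PSD0.03/0.5"] = dsp.band_stat(rr_psd, 0.03, 0.5, "argmax_freq")
        else:
            out["ecg.max_PSD0.03/0.5"] = 0.0
        rr_level = min(7, pywt_max_level(iv.size))
        if rr_level >= 1:
            rr_stats, _ = dsp.wavelet_stats(iv, "sym3", rr_level)
            detail_energy = sum(rr_stats[f"D{i}"]["energy"] for i in range(1, rr_level + 1))
            out["ecg.WSD_RR"] = detail_energy / iv.size
        else:
            out["ecg.WSD_RR"] = 0.0
    else:
        logger.warning("ecg_features: <2 RR intervals, RR features set to 0")
        for name in ("ecg.NN50_RR", "ecg.SDSD_RR", "ecg.tSD_RR", "ecg.std_RR",
                     "ecg.mean_RR", "ecg.SCrC_3_RR", "ecg.SCrC_4_RR",
                     "ecg.max_PSD0.03/0.5", "ecg.WSD_RR"):
            out[name] = 0.0

    out["ecg.var"] = float(np.var(ecg))
    out["ecg.kur"] = _kurtosis(ecg)

    edr = np.asarray(edr, dtype=float)
    edr_mean = float(np.mean(edr)) if edr.size else 0.0
    out["ecg.CV_EDR"] = float(np.std(edr) / edr_mean) if abs(edr_mean) > 1e-12 else 0.0

    nperseg = min(ecg.size, int(round(cfg.ecg_welch_s * fs)))
    ecg_psd = dsp.welch_psd(ecg, segment_len=nperseg, overlap=nperseg // 2,
                            fs=fs, nfft=max(cfg.nfft, nperseg))
    out["ecg.SS"] = dsp.spectral_spread(ecg_psd)
    out["ecg.SD"] = dsp.spectral_decrease(ecg_psd)
    out["ecg.mean_PSD10/20"] = dsp.band_stat(ecg_psd, 10.0, 20.0, "mean")
    out["ecg.mean_PSD80/100"] = dsp.band_stat(ecg_psd, 80.0, 100.0, "mean")

    wstats, wdec = dsp.wavelet_stats(ecg, "sym3", 7)
    for i in range(1, 8):
        out[f"ecg.entropy_D{i}"] = dsp.shannon_entropy_coeffs(wdec.details[i - 1])
        out[f"ecg.var_D{i}"] = wstats[f"D{i}"]["var"]

    qrs = np.asarray(qrs, dtype=float)
    if qrs.ndim == 2 and qrs.shape[0] >= 3:
        max_dia, rp2 = dsp.kpca_qrs(qrs)
    else:
        logger.warning("ecg_features: <3 QRS complexes, kPCA features set to 0")
        max_dia, rp2 = 0.0, 0.0
    out["ecg.max_dia_kPCA"] = max_dia
    out["ecg.RP_2_PC"] = rp2

    return {name: out[name] for name in ECG_NAMES}


def pywt_max_level(n: int, wavelet: str = "sym3") -> int:
    """Deepest DWT level with at least one full filter support."""
    import pywt
    try:
        return pywt.dwt_max_level(n, wavelet)
    except Exception:
        return 0


# ---------------------------------------------------------------------------
# whole-segment extraction
# ---------------------------------------------------------------------------

def extract_all(seg: Segment, config: FeatureConfig | None = None) -> dict:
    """Compute the full 66-feature vector of one preprocessed segment.

    The segment's five channels must already be preprocessed (see
    :func:`preprocess_record`). Returns a dict with ``patient_id``,
    ``label``, and the 66 features in schema order.
    """
    cfg = config or FeatureConfig()
    for name in ("sao2", "airflow", "thoracic", "abdominal", "ecg"):
        if name not in seg.channels:
            raise ValueError(f"segment lacks channel {name!r}")
    values: dict[str, float] = {}
    values.update(sao2_features(seg.channels["sao2"].samples, cfg))
    values.update(airflow_features(seg.channels["airflow"].samples, cfg))
    values.update(abdominal_features(seg.channels["abdominal"].samples,
                                     seg.channels["abdominal"].fs, cfg))
    values.update(thoracic_features(seg.channels["thoracic"].samples,
                                    seg.channels["thoracic"].fs, cfg))
    values.update(ecg_features(seg.channels["ecg"].samples,
                               seg.channels["ecg"].fs,
                               duration_s=seg.duration_s, config=cfg))
    row = {"patient_id": seg.patient_id, "label": seg.label}
    row.update({name: values[name] for name in FEATURE_NAMES})
    return row


def preprocess_record(record: PsgRecord, config: FeatureConfig | None = None) -> PsgRecord:
    """Apply the per-channel preprocessing chain to a raw record.

    SaO2 is artifact-cleaned (1 Hz), airflow is baseline-corrected,
    low-passed and resampled to 1 Hz, both effort bands are
    baseline-corrected and band-passed (10 Hz), and ECG is band-passed
    (125 Hz). The returned record feeds segmentation + extraction.
    """
    cfg = config or FeatureConfig()
    pcfg = cfg.preprocess
    from .psg import ChannelSeries
    ch = record.channels
    out = {
        "sao2": ChannelSeries("sao2", ch["sao2"].fs,
                              pp.clean_sao2(ch["sao2"].samples, pcfg), ch["sao2"].units),
        "airflow": ChannelSeries("airflow", pcfg.airflow_out_fs,
                                 pp.preprocess_airflow(ch["airflow"].samples,
                                                       ch["airflow"].fs, pcfg)),
        "thoracic": ChannelSeries("thoracic", ch["thoracic"].fs,
                                  pp.preprocess_effort(ch["thoracic"].samples,
                                                       ch["thoracic"].fs, pcfg)),
        "abdominal": ChannelSeries("abdominal", ch["abdominal"].fs,
                                   pp.preprocess_effort(ch["abdominal"].samples,
                                                        ch["abdominal"].fs, pcfg)),
        "ecg": ChannelSeries("ecg", ch["ecg"].fs,
                             pp.preprocess_ecg(ch["ecg"].samples, ch["ecg"].fs, pcfg)),
    }
    return PsgRecord(record.patient_id, out)


def extract_table(
    records_with_annotations,
    mode: str = "windows",
    window_s: float = 60.0,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Run preprocessing, segmentation and extraction over a cohort.

    ``records_with_annotations`` is an iterable of ``(PsgRecord,
    list[EventAnnotation])`` pairs; ``mode`` selects event-duration or
    fixed-window segmentation. Returns the feature table (one row per
    segment).
    """
    cfg = config or FeatureConfig()
    rows = []
    for record, annotations in records_with_annotations:
        prepped = preprocess_record(record, cfg)
        if mode == "events":
            segments = segment_by_events(prepped, annotations)
        elif mode == "windows":
            segments = segment_by_windows(prepped, annotations, window_s=window_s)
        else:
            raise ValueError(f"unknown segmentation mode {mode!r}")
        for seg in segments:
            rows.append(extract_all(seg, cfg))
    return pd.DataFrame(rows, columns=["patient_id", "label"] + FEATURE_NAMES)
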