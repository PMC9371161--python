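"""Seeded synthetic PSG generator with ground truth.

Emulates the physiological signatures of obstructive apnea that the feature
battery targets: airflow amplitude collapsing to <= 10% of its basal value
for >= 10 s, respiratory effort persisting but attenuated and counter-phased
(obstructive character; a central mode collapses effort too), a delayed SaO2
desaturation dip with exponential resaturation, cyclic RR lengthening during
events with post-event shortening, and an ECG built by placing a fixed
QRS-T template at the cumulative RR times with respiratory amplitude
modulation (so EDR recovery is testable), baseline wander and white noise.

Every record also carries occasional single-sample SaO2 dropout spikes
(> 8-point jumps) so the artifact cleaner is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psg import APNEA, NORMAL, ChannelSeries, EventAnnotation, PsgRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_record",
    "generate_cohort",
    "synthetic_feature_table",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort."""

    n_patients: int = 40
    record_s: float = 3600.0
    apnea_rate_per_h: float = 15.0          # moderate-to-severe OSA
    apnea_duration_s: tuple = (10.0, 60.0)
    desat_depth_pts: tuple = (3.0, 10.0)
    desat_delay_s: float = 15.0
    airflow_reduction: float = 0.9          # collapse to <= 10% of basal
    breathing_freq_hz: float = 0.25
    rr_base_s: float = 1.0
    noise: dict = field(default_factory=lambda: {
        "sao2": 0.15, "airflow": 0.03, "effort": 0.03, "ecg": 0.02,
    })
    sao2_spikes_per_h: float = 5.0
    central: bool = False                   # central apnea: effort collapses too
    seed: int = 0

    def __post_init__(self) -> None:
        if self.record_s <= 0:
            raise ValueError("record_s must be positive")
        if not (0.0 < self.airflow_reduction <= 1.0):
            raise ValueError("airflow_reduction must lie in (0, 1]")
        if self.apnea_duration_s[0] < 10.0:
            raise ValueError("apnea events must last at least 10 s")


@dataclass
class GroundTruth:
    """Hidden generator state for oracle-based testing."""

    r_times_s: np.ndarray
    events: list                      # (start_s, end_s) of apnea events
    breathing_freq_hz: float
    airflow_envelope: np.ndarray      # at 10 Hz, in units of the basal amplitude
    basal_airflow_amp: float
    sao2_baseline: float


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------

def _draw_events(rng: np.random.Generator, cfg: SyntheticConfig) -> list:
    hours = cfg.record_s / 3600.0
    rate = cfg.apnea_rate_per_h * float(rng.uniform(0.75, 1.25))
    n_events = int(round(rate * hours))
    if cfg.apnea_rate_per_h <= 0 or n_events == 0:
        return []
    lo, hi = cfg.apnea_duration_s
    events: list[tuple[float, float]] = []
    min_gap = 45.0  # lets SaO2 recover between events
    attempts = 0
    while len(events) < n_events and attempts < 200 * n_events:
        attempts += 1
        dur = float(rng.uniform(lo, hi))
        start = float(rng.uniform(60.0, cfg.record_s - dur - 90.0))
        if all(start > e + min_gap or start + dur < s - min_gap for s, e in events):
            events.append((start, start + dur))
    return sorted(events)


def _smooth_event_indicator(t: np.ndarray, events: list, ramp_s: float = 2.0) -> np.ndarray:
    """1 inside events, 0 outside, cosine ramps of ``ramp_s`` at the edges."""
    ind = np.zeros_like(t)
    for s, e in events:
        rise = np.clip((t - s) / ramp_s, 0.0, 1.0)
        fall = np.clip((e - t) / ramp_s, 0.0, 1.0)
        level = np.minimum(rise, fall)
        ind = np.maximum(ind, 0.5 - 0.5 * np.cos(np.pi * level))
    return ind


# ---------------------------------------------------------------------------
# record synthesis
# ---------------------------------------------------------------------------

def generate_record(config: SyntheticConfig, patient_index: int = 0):
    """Synthesize one five-channel record.

    Returns ``(PsgRecord, annotations, GroundTruth)``. The annotations list
    contains the apnea events plus explicit normal annotations covering the
    inter-event stretches (30 s after the previous event is excluded so the
    desaturation recovery is not marked normal), mimicking physiologist
    scoring for the event-duration protocol.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, patient_index])
    dur = cfg.record_s
    events = _draw_events(rng, cfg)

    # per-patient physiology
    f_breath = cfg.breathing_freq_hz * float(rng.uniform(0.9, 1.1))
    basal_amp = float(rng.uniform(0.8, 1.2))
    sao2_base = float(rng.uniform(96.0, 98.0))
    depth_scale = float(rng.uniform(0.8, 1.2))
    rr_base = cfg.rr_base_s * float(rng.uniform(0.9, 1.1))

    # --- airflow (10 Hz) -------------------------------------------------
    fs_af = 10.0
    t10 = np.arange(int(dur * fs_af)) / fs_af
    phase = 2 * np.pi * f_breath * t10 + rng.uniform(0, 2 * np.pi)
    ind10 = _smooth_event_indicator(t10, events)
    envelope = 1.0 - cfg.airflow_reduction * ind10
    airflow = basal_amp * envelope * np.sin(phase)
    airflow = airflow + rng.normal(0.0, cfg.noise["airflow"], t10.size)

    # --- respiratory effort (10 Hz) --------------------------------------
    # obstructive: effort persists (attenuated) and abdomen counter-phases;
    # central: effort collapses with the airflow
    effort_floor = cfg.airflow_reduction if cfg.central else 0.5
    env_eff = 1.0 - effort_floor * ind10
    thor = 0.9 * basal_amp * env_eff * np.sin(phase + 0.4)
    abd_phase = phase + 0.2 + np.pi * ind10 * (0.0 if cfg.central else 1.0)
    abd = 0.8 * basal_amp * env_eff * np.sin(abd_phase)
    thor = thor + rng.normal(0.0, cfg.noise["effort"], t10.size)
    abd = abd + rng.normal(0.0, cfg.noise["effort"], t10.size)

    # --- SaO2 (1 Hz) ------------------------------------------------------
    t1 = np.arange(int(dur))
    sao2 = sao2_base + 0.3 * np.sin(2 * np.pi * t1 / 900.0 + rng.uniform(0, 2 * np.pi))
    for s, e in events:
        depth = depth_scale * float(rng.uniform(*cfg.desat_depth_pts))
        t_fall0 = s + cfg.desat_delay_s
        fall_dur = min(e - s, 20.0)
        t_min = t_fall0 + fall_dur
        falling = (t1 >= t_fall0) & (t1 < t_min)
        sao2[falling] -= depth * (t1[falling] - t_fall0) / fall_dur
        recovering = t1 >= t_min
        sao2[recovering] -= depth * np.exp(-(t1[recovering] - t_min) / 8.0)
    sao2 = sao2 + rng.normal(0.0, cfg.noise["sao2"], t1.size)
    n_spikes = rng.poisson(cfg.sao2_spikes_per_h * dur / 3600.0)
    if n_spikes > 0:
        spike_at = rng.choice(np.arange(10, t1.size), size=min(n_spikes, t1.size - 10),
                              replace=False)
        sao2[spike_at] -= rng.uniform(10.0, 30.0, spike_at.size)
    sao2 = np.clip(sao2, 50.0, 100.0)
    sao2 = np.round(sao2, 1)  # oximeter output quantized to 0.1

    # --- RR tachogram and ECG (125 Hz) ------------------------------------
    def rr_at(t: float) -> float:
        rr = rr_base * (1.0 + 0.04 * np.sin(2 * np.pi * f_breath * t))
        for s, e in events:
            if s <= t < e:  # progressive bradycardia during the event
                rr *= 1.0 + 0.15 * min(1.0, (t - s) / 10.0)
                break
            if e <= t < e + 5.0:  # post-event tachycardia
                rr *= 1.0 - 0.10 * (1.0 - (t - e) / 5.0)
                break
        rr *= 1.0 + 0.01 * float(rng.standard_normal())
        return float(np.clip(rr, 0.4, 1.8))

    beats = []
    t = float(rng.uniform(0.2, 1.0))
    while t < dur - 0.3:
        beats.append(t)
        t += rr_at(t)
    r_times = np.array(beats)

    fs_ecg = 125.0
    n_ecg = int(dur * fs_ecg)
    ecg = np.zeros(n_ecg)
    template = _qrs_template(fs_ecg)
    center = np.argmax(template)
    ind_at = _smooth_event_indicator(r_times, events)
    resp_mod = 1.0 + 0.10 * np.sin(2 * np.pi * f_breath * r_times) * (1.0 - 0.5 * ind_at)
    for tk, amp in zip(r_times, resp_mod):
        i = int(round(tk * fs_ecg))
        lo, hi = i - center, i - center + template.size
        if lo < 0 or hi > n_ecg:
            continue
        ecg[lo:hi] += amp * template
    t125 = np.arange(n_ecg) / fs_ecg
    ecg += 0.1 * np.sin(2 * np.pi * 0.15 * t125 + rng.uniform(0, 2 * np.pi))
    ecg += rng.normal(0.0, cfg.noise["ecg"], n_ecg)

    record = PsgRecord(f"synthetic-{patient_index:03d}", {
        "sao2": ChannelSeries("sao2", 1.0, sao2, "%"),
        "airflow": ChannelSeries("airflow", 10.0, airflow, "a.u."),
        "thoracic": ChannelSeries("thoracic", 10.0, thor, "a.u."),
        "abdominal": ChannelSeries("abdominal", 10.0, abd, "a.u."),
        "ecg": ChannelSeries("ecg", 125.0, ecg, "mV"),
    })

    annotations = [EventAnnotation(APNEA, s, e) for s, e in events]
    annotations += _normal_gaps(events, dur)
    annotations.sort(key=lambda a: a.start_s)

    truth = GroundTruth(r_times, events, f_breath, envelope, basal_amp, sao2_base)
    return record, annotations, truth


def _qrs_template(fs: float) -> np.ndarray:
    """Fixed QRS-T morphology template (~0.5 s support, R amplitude 1)."""
    t = (np.arange(int(0.5 * fs)) - int(0.25 * fs)) / fs
    r = np.exp(-(t / 0.012) ** 2)
    q = -0.12 * np.exp(-((t + 0.030) / 0.010) ** 2)
    s = -0.20 * np.exp(-((t - 0.030) / 0.010) ** 2)
    t_wave = 0.25 * np.exp(-((t - 0.20) / 0.05) ** 2)
    return r + q + s + t_wave


def _normal_gaps(events: list, duration_s: float,
                 recovery_s: float = 30.0, min_len_s: float = 20.0) -> list:
    """Explicit normal annotations over inter-event gaps, skipping the
    desaturation recovery after each event."""
    out = []
    cursor = 0.0
    for s, e in events + [(duration_s, duration_s)]:
        if cursor > 0:
            cursor += recovery_s  # skip post-event recovery
        if s - cursor >= min_len_s:
            out.append(EventAnnotation(NORMAL, cursor, s))
        cursor = e
    return out


def generate_cohort(config: SyntheticConfig):
    """Generate ``config.n_patients`` records with per-patient child seeds
    derived deterministically from ``config.seed``."""
    return [generate_record(config, i) for i in range(config.n_patients)]


# ---------------------------------------------------------------------------
# feature-table generator for selection experiments
# ---------------------------------------------------------------------------

def synthetic_feature_table(
    n_patients: int = 40,
    segments_per_class: int = 15,
    n_informative: int = 10,
    n_noise: int = 56,
    separation_sd: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list, list]:
    """A feature table with known signal structure, for testing Stage 1.

    The first ``n_informative`` features shift their within-patient mean by
    ``separation_sd`` standard deviations between classes; the rest are pure
    noise, identically distributed in both classes. Returns
    ``(table, informative_names, noise_names)``.
    """
    rng = np.random.default_rng(seed)
    informative = [f"inf_{i:02d}" for i in range(n_informative)]
    noise = [f"noise_{i:02d}" for i in range(n_noise)]
    rows = []
    for p in range(n_patients):
        offsets = rng.normal(0.0, 1.0, n_informative + n_noise)
        for label in (APNEA, NORMAL):
            shift = separation_sd if label == APNEA else 0.0
            for _ in range(segments_per_class):
                x = offsets + rng.standard_normal(n_informative + n_noise)
                x[:n_informative] += shift if label == APNEA else 0.0
                row = {"patient_id": f"p{p:03d}", "label": label}
                row.update(dict(zip(informative + noise, x)))
                rows.append(row)
    table = pd.DataFrame(rows)
    return table, informative, noise
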