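"""Numerical primitives underlying the apnea feature battery.

Pure, deterministic operators: Lempel-Ziv complexity, autoregressive and
Welch power spectral densities, band statistics, wavelet statistics,
coefficient entropy, Poincare SD1, spectral shape descriptors, serial
correlation, kernel PCA on QRS matrices, and zero-crossing counting.
No operator here holds hidden random state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.spatial.distance import pdist
from statsmodels.regression.linear_model import yule_walker

logger = logging.getLogger(__name__)

__all__ = [
    "PsdEstimate",
    "WaveletDecomposition",
    "lz_complexity",
    "lz76_phrase_count",
    "yule_walker_psd",
    "welch_psd",
    "band_stat",
    "wavelet_stats",
    "shannon_entropy_coeffs",
    "poincare_sd1",
    "spectral_spread",
    "spectral_decrease",
    "serial_corr",
    "kpca_qrs",
    "zero_crossings",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PsdEstimate:
    """One-sided power spectral density on an ascending frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("frequency grid and power must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        # tiny negative values from numerical round-off are clipped
        self.power = np.clip(self.power, 0.0, None)

    @property
    def nyquist_hz(self) -> float:
        return float(self.freqs_hz[-1])


@dataclass
class WaveletDecomposition:
    """Multilevel DWT result: approximation at the deepest level + details.

    ``details[i]`` is level i+1 (D1 = finest). Periodization padding keeps
    orthogonal wavelets energy-preserving (Parseval) at every depth.
    """

    wavelet: str
    level: int
    approximation: np.ndarray
    details: list[np.ndarray]

    def energy(self) -> float:
        e = float(np.sum(self.approximation ** 2))
        for d in self.details:
            e += float(np.sum(d ** 2))
        return e


# ---------------------------------------------------------------------------
# Lempel-Ziv complexity (LZ76)
# ---------------------------------------------------------------------------

def lz76_phrase_count(bits: str) -> int:
    """Number of phrases in the LZ76 left-to-right exhaustive parse.

    Each phrase is the shortest prefix of the remaining string that does not
    occur as a substring of everything produced so far (self-overlap up to
    one position before the phrase end is allowed). A trailing fragment that
    is still reproducible from the past when the string ends does not open a
    new phrase, so a constant string has count 1.
    """
    n = len(bits)
    if n == 0:
        return 0
    c = 0
    i = 0
    while i < n:
        l = 1
        # grow the candidate phrase while it is reproducible from the past
        while i + l <= n and bits.find(bits[i:i + l], 0, i + l - 1) != -1:
            l += 1
        if i + l <= n:          # innovation found: phrase terminates
            c += 1
        elif l == 1:            # single trailing novel symbol
            c += 1
        i += l
    return max(c, 1)


def lz_complexity(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity of a real series.

    The series is binarized at its median (>= median maps to 1), parsed with
    LZ76, and the phrase count c(n) is returned as c(n) * log2(n) / n so that
    windows of different lengths are comparable.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("lz_complexity needs at least 2 samples")
    med = np.median(x)
    bits = "".join("1" if v >= med else "0" for v in x)
    c = lz76_phrase_count(bits)
    return c * np.log2(n) / n


# ---------------------------------------------------------------------------
# power spectral density estimators
# ---------------------------------------------------------------------------

def _ar_psd(x: np.ndarray, order: int, fs: float, freqs: np.ndarray) -> np.ndarray:
    """One-sided AR PSD of a single segment via Yule-Walker."""
    rho, sigma = yule_walker(x, order=order, method="mle")
    # A(e^{-iw}) = 1 - sum_k rho_k e^{-iwk}
    a = np.concatenate(([1.0], -rho))
    _, h = sps.freqz(1.0, a, worN=freqs, fs=fs)
    psd = (sigma ** 2 / fs) * np.abs(h) ** 2
    psd = psd.copy()
    psd[1:-1] *= 2.0  # fold negative frequencies, keep DC and Nyquist
    return psd


def yule_walker_psd(
    x: np.ndarray,
    order: int = 5,
    fs: float = 1.0,
    nfft: int = 256,
    segment_len: int | None = None,
) -> PsdEstimate:
    """Autoregressive PSD via the Yule-Walker autocorrelation method.

    With ``segment_len`` set, the series is cut into consecutive
    non-overlapping segments of that many samples and the returned PSD is
    the mean of the per-segment estimates (trailing partial segment
    dropped). Constant input yields a flat near-zero PSD with a logged
    warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= order:
        raise ValueError(f"series length {x.size} must exceed AR order {order}")
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)

    if np.ptp(x) < 1e-12 or np.var(x) < 1e-24:
        logger.warning("yule_walker_psd: (near-)constant input, returning flat zero PSD")
        return PsdEstimate(freqs, np.zeros(freqs.shape), "yule_walker",
                           {"order": order, "nfft": nfft, "segment_len": segment_len})

    if segment_len is not None and x.size >= 2 * segment_len:
        nseg = x.size // segment_len
        psds = []
        for k in range(nseg):
            seg = x[k * segment_len:(k + 1) * segment_len]
            if np.ptp(seg) < 1e-12:
                continue
            psds.append(_ar_psd(seg, order, fs, freqs))
        psd = np.mean(psds, axis=0) if psds else np.zeros(freqs.shape)
    else:
        psd = _ar_psd(x, order, fs, freqs)

    return PsdEstimate(freqs, psd, "yule_walker",
                       {"order": order, "nfft": nfft, "segment_len": segment_len})


def welch_psd(
    x: np.ndarray,
    segment_len: int = 5,
    overlap: int = 2,
    fs: float = 1.0,
    nfft: int = 256,
) -> PsdEstimate:
    """Hann-windowed averaged periodogram, zero-padded to ``nfft`` bins."""
    x = np.asarray(x, dtype=float)
    if x.size < segment_len:
        raise ValueError("series shorter than one Welch segment")
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=segment_len,
        noverlap=overlap,
        nfft=max(nfft, segment_len),
        detrend=False,
        scaling="density",
    )
    return PsdEstimate(freqs, psd, "welch",
                       {"segment_len": segment_len, "overlap": overlap, "nfft": nfft})


def band_stat(psd: PsdEstimate, lo_hz: float, hi_hz: float, stat: str = "mean") -> float:
    """Statistic of a PSD over a frequency band.

    If the whole requested band lies above the grid's Nyquist frequency it
    is reinterpreted under the normalized-band convention: the printed edges
    are read as percentages of Nyquist, e.g. an 80-100 band on a 10 Hz
    channel becomes [0.80, 1.00] * fs/2 = 4-5 Hz (the uppermost fifth of the
    spectrum). A band that merely straddles Nyquist is clipped to it.
    ``stat`` is one of mean, sum, argmax_freq.
    """
    nyq = psd.nyquist_hz
    if lo_hz > nyq + 1e-12:
        lo_hz, hi_hz = lo_hz / 100.0 * nyq, hi_hz / 100.0 * nyq
    elif hi_hz > nyq + 1e-12:
        hi_hz = nyq
    mask = (psd.freqs_hz >= lo_hz - 1e-12) & (psd.freqs_hz <= hi_hz + 1e-12)
    if not np.any(mask):
        raise ValueError(f"band [{lo_hz}, {hi_hz}] Hz contains no grid points")
    p = psd.power[mask]
    if stat == "mean":
        return float(np.mean(p))
    if stat == "sum":
        return float(np.sum(p))
    if stat == "argmax_freq":
        return float(psd.freqs_hz[mask][int(np.argmax(p))])
    raise ValueError(f"unknown band statistic {stat!r}")


# ---------------------------------------------------------------------------
# wavelets
# ---------------------------------------------------------------------------

def wavelet_stats(x: np.ndarray, wavelet: str, level: int):
    """Multilevel DWT (periodization padding) + per-level mean/variance/energy.

    Returns ``(stats, decomposition)`` where ``stats`` maps coefficient-array
    names (``D1``.. ``D<level>``, ``A<level>``) to dicts with keys
    ``mean``, ``var``, ``energy``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("wavelet_stats needs at least 2 samples")
    with warnings.catch_warnings():
        # depths beyond the dyadic maximum are legitimate under periodization
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    approx, details_deep_first = coeffs[0], coeffs[1:]
    details = list(reversed(details_deep_first))  # D1 = finest
    dec = WaveletDecomposition(wavelet, level, approx, details)
    stats: dict[str, dict[str, float]] = {}
    for i, d in enumerate(details, start=1):
        stats[f"D{i}"] = {
            "mean": float(np.mean(d)),
            "var": float(np.var(d)),
            "energy": float(np.sum(d ** 2)),
        }
    stats[f"A{level}"] = {
        "mean": float(np.mean(approx)),
        "var": float(np.var(approx)),
        "energy": float(np.sum(approx ** 2)),
    }
    return stats, dec


def shannon_entropy_coeffs(c: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalized squared-coefficient mass.

    p_i = c_i^2 / sum c_j^2, H = -sum p_i log2 p_i with 0*log 0 = 0. An
    all-zero array carries no mass and returns 0 bits.
    """
    c = np.asarray(c, dtype=float)
    e = c ** 2
    total = e.sum()
    if total <= 0:
        return 0.0
    p = e / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# time-domain descriptors
# ---------------------------------------------------------------------------

def poincare_sd1(x: np.ndarray) -> float:
    """Poincare SD1: dispersion perpendicular to the identity line of the
    lag-1 return map, sqrt(Var(d)/2) for successive differences d
    (population variance)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("poincare_sd1 needs at least 2 samples")
    d = np.diff(x)
    return float(np.sqrt(np.var(d) / 2.0))


def serial_corr(x: np.ndarray, lag: int) -> float:
    """Pearson correlation of (x_t, x_{t+lag}); degenerate cases return 0."""
    x = np.asarray(x, dtype=float)
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    if lag == 0:
        return 1.0
    if x.size - lag < 2:
        logger.warning("serial_corr: too few pairs at lag %d, returning 0", lag)
        return 0.0
    a, b = x[:-lag], x[lag:]
    sa, sb = np.std(a), np.std(b)
    if sa < 1e-15 or sb < 1e-15:
        logger.warning("serial_corr: degenerate (constant) series, returning 0")
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def zero_crossings(x: np.ndarray) -> int:
    """Count strict sign changes of x - mean(x); zeros inherit the previous
    sign (leading zeros are ignored)."""
    x = np.asarray(x, dtype=float)
    y = x - np.mean(x)
    s = np.sign(y)
    s = s[s != 0]  # dropping zeros == inheriting the previous sign
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


# ---------------------------------------------------------------------------
# spectral shape
# ---------------------------------------------------------------------------

def spectral_spread(psd: PsdEstimate) -> float:
    """Spectral spread: sqrt of the power-weighted variance of frequency
    about the spectral centroid. Zero-power spectra return 0 Hz."""
    total = psd.power.sum()
    if total <= 0:
        return 0.0
    centroid = float(np.sum(psd.freqs_hz * psd.power) / total)
    return float(np.sqrt(np.sum((psd.freqs_hz - centroid) ** 2 * psd.power) / total))


def spectral_decrease(psd: PsdEstimate) -> float:
    """Spectral decrease: average slope of the spectrum relative to its
    first bin, sum_{k>=1}[(P_k - P_0)/k] / sum_{k>=1} P_k. Flat spectra give
    0; zero tail power gives 0."""
    p = psd.power
    if p.size < 2:
        return 0.0
    tail = p[1:]
    denom = tail.sum()
    if denom <= 0:
        return 0.0
    k = np.arange(1, p.size)
    return float(np.sum((tail - p[0]) / k) / denom)


# ---------------------------------------------------------------------------
# kernel PCA of QRS morphology
# ---------------------------------------------------------------------------

def kpca_qrs(q: np.ndarray) -> tuple[float, float]:
    """Kernel PCA spectrum summary of a QRS matrix (rows = beats).

    RBF kernel with bandwidth set by the median heuristic (median pairwise
    Euclidean distance); the kernel matrix is double-centred and its
    eigenvalues sorted descending with negatives clipped at 0. Returns
    (lambda_1, lambda_2 / sum lambda). Identical rows are degenerate: the
    centred kernel vanishes and (0, 0) is returned.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] < 3:
        raise ValueError("kpca_qrs needs a matrix with at least 3 rows")
    n = q.shape[0]
    d = pdist(q)
    h = np.median(d)
    if h < 1e-12:
        return 0.0, 0.0
    d2 = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d2[iu] = d ** 2
    d2 += d2.T
    k_mat = np.exp(-d2 / (2.0 * h ** 2))
    one = np.full((n, n), 1.0 / n)
    kc = k_mat - one @ k_mat - k_mat @ one + one @ k_mat @ one
    eigvals = np.linalg.eigvalsh(kc)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    total = eigvals.sum()
    if total <= 1e-15:
        return 0.0, 0.0
    return float(eigvals[0]), float(eigvals[1] / total)
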