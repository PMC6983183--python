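"""Whole-night HRV features: six time-domain, five frequency-domain.

Time domain (whole recording):

* SDNN    — population standard deviation of the RR intervals, ms
* pNN50   — percentage of successive-difference magnitudes > 50 ms
* rMSSD   — root mean square of successive differences, ms
* IRRR    — inter-quartile range of the RR series (linear-interpolation
            quantiles), ms
* MADRR   — median absolute successive difference, ms
* HRVi    — triangular index: total beat count divided by the modal count of
            the RR histogram (bin width 1/128 s = 7.8125 ms, anchored at 0)

Frequency domain: the unevenly-sampled tachogram is linearly interpolated to
a regular grid (4 Hz), short-time Fourier spectrograms are computed over
sliding windows (300 s wide, 10 s displacement, mean-detrended, Hamming
taper), and per-window band powers are integrated over the ULF / VLF / LF /
HF bands.  Whole-night band powers are the arithmetic means of the
per-window values; LF/HF is the ratio of the aggregated means.  Powers are
density-integrated so a sinusoid of amplitude A inside a band contributes
~A^2/2 ms^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal import get_window

from .rr_io import RRSeries

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "ulf": (0.0, 0.03),
    "vlf": (0.03, 0.05),
    "lf": (0.05, 0.15),
    "hf": (0.15, 0.40),
}

TIME_FEATURES = ("sdnn", "pnn50", "rmssd", "irrr", "madrr", "hrvi")
FREQ_FEATURES = ("ulf", "vlf", "lf", "hf", "lfhf")
FEATURE_NAMES = TIME_FEATURES + FREQ_FEATURES


@dataclass
class SpectralConfig:
    window_s: float = 300.0
    displacement_s: float = 10.0
    resample_hz: float = 4.0
    taper: str = "hamming"  # hamming | hann | none
    bands_hz: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        if not self.window_s > self.displacement_s > 0:
            raise ValueError("need window_s > displacement_s > 0")
        if self.resample_hz <= 0:
            raise ValueError("resample_hz must be > 0")
        if self.taper not in ("hamming", "hann", "none"):
            raise ValueError(f"unknown taper {self.taper!r}")
        edges = sorted(self.bands_hz.values())
        nyq = self.resample_hz / 2
        prev_hi = 0.0
        for lo, hi in edges:
            if lo < prev_hi or hi <= lo or hi > nyq:
                raise ValueError(
                    "bands must be non-overlapping, ordered and within "
                    f"[0, {nyq}] Hz; got {self.bands_hz}"
                )
            prev_hi = hi


@dataclass
class HRVFeatureVector:
    """The eleven whole-night scalar HRV features of one recording."""

    sdnn: float
    pnn50: float
    rmssd: float
    irrr: float
    madrr: float
    hrvi: float
    ulf: float
    vlf: float
    lf: float
    hf: float
    lfhf: float

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def time_domain_features(series: RRSeries, madrr_verbatim: bool = False
                         ) -> dict[str, float]:
    """SDNN, pNN50, rMSSD, IRRR and MADRR over the whole recording.

    ``madrr_verbatim=True`` switches MADRR to the literal reading "median of
    the absolute values of the RR series" instead of the conventional median
    absolute successive difference.
    """
    rr = series.rr_ms
    if rr.size < 2:
        raise ValueError("time-domain features require at least 2 beats")
    diffs = np.diff(rr)
    q1, q3 = np.percentile(rr, [25, 75])  # linear-interpolation quantiles
    madrr = float(np.median(np.abs(rr if madrr_verbatim else diffs)))
    return {
        "sdnn": float(np.std(rr)),
        "pnn50": float(100.0 * np.mean(np.abs(diffs) > 50.0)),
        "rmssd": float(np.sqrt(np.mean(diffs**2))),
        "irrr": float(q3 - q1),
        "madrr": madrr,
    }


def hrv_triangular_index(series: RRSeries, bin_width_ms: float = 7.8125) -> float:
    """Triangular index: beat count over the modal RR-histogram bin count.

    The histogram uses fixed-width bins anchored at 0 ms (the conventional
    1/128 s width by default).
    """
    rr = series.rr_ms
    if rr.size < 1:
        raise ValueError("HRVi requires at least 1 beat")
    idx = np.floor(rr / bin_width_ms).astype(np.int64)
    counts = np.bincount(idx - idx.min())
    return float(rr.size / counts.max())


def resample_tachogram(series: RRSeries, config: SpectralConfig | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Evenly resample the RR tachogram by linear interpolation.

    Returns ``(times_s, rr_ms)`` sampled at ``config.resample_hz`` over the
    span between the first and last beat; gaps left by filtering are
    interpolated across.  Errors if the span is shorter than one spectral
    window.
    """
    config = config or SpectralConfig()
    if series.n_beats < 2:
        raise ValueError("resampling requires at least 2 beats")
    span = series.span_s
    if span < config.window_s:
        raise ValueError(
            f"recording span {span:.1f} s is shorter than one {config.window_s:.0f} s window"
        )
    fs = config.resample_hz
    n = int(np.floor(span * fs)) + 1
    t = series.onsets_s[0] + np.arange(n) / fs
    return t, np.interp(t, series.onsets_s, series.rr_ms)


def stft_band_powers(signal: np.ndarray, config: SpectralConfig | None = None
                     ) -> pd.DataFrame:
    """Per-window band powers of an evenly sampled tachogram signal.

    Each window (stride ``displacement_s``) is mean-detrended, tapered and
    turned into a one-sided periodogram (density scaling); band powers are
    the density integrals over the configured bands, in ms^2.
    """
    config = config or SpectralConfig()
    fs = config.resample_hz
    wlen = int(round(config.window_s * fs))
    hop = max(1, int(round(config.displacement_s * fs)))
    signal = np.asarray(signal, dtype=float)
    if signal.size < wlen:
        raise ValueError("signal spans less than one window")
    segs = np.lib.stride_tricks.sliding_window_view(signal, wlen)[::hop]
    segs = segs - segs.mean(axis=1, keepdims=True)
    if config.taper == "none":
        w = np.ones(wlen)
    else:
        w = get_window(config.taper, wlen)
    spec = rfft(segs * w, axis=1)
    # one-sided power spectral density; interior bins doubled
    pxx = (np.abs(spec) ** 2) * (2.0 / (fs * np.sum(w**2)))
    pxx[:, 0] *= 0.5
    if wlen % 2 == 0:
        pxx[:, -1] *= 0.5
    freqs = rfftfreq(wlen, d=1.0 / fs)
    df = fs / wlen
    out = {}
    for name, (lo, hi) in config.bands_hz.items():
        mask = (freqs >= lo) & (freqs < hi)
        out[name] = pxx[:, mask].sum(axis=1) * df
    return pd.DataFrame(out)


def extract_features(series: RRSeries, config: SpectralConfig | None = None,
                     madrr_verbatim: bool = False) -> HRVFeatureVector:
    """All eleven whole-night HRV features of one recording."""
    config = config or SpectralConfig()
    td = time_domain_features(series, madrr_verbatim=madrr_verbatim)
    hrvi = hrv_triangular_index(series)
    _, sig = resample_tachogram(series, config)
    bands = stft_band_powers(sig, config).mean(axis=0)
    hf = float(bands["hf"])
    lf = float(bands["lf"])
    return HRVFeatureVector(
        **td,
        hrvi=hrvi,
        ulf=float(bands["ulf"]),
        vlf=float(bands["vlf"]),
        lf=lf,
        hf=hf,
        lfhf=lf / hf if hf > 0 else float("nan"),
    )


def cohort_feature_table(records, sensor: str, filtered: bool,
                         filter_config=None, spectral_config: SpectralConfig | None = None,
                         ) -> pd.DataFrame:
    """Feature table (one row per subject) for one sensor x filter condition.

    ``records`` is a list of :class:`~apneahrv.synthetic_cohort.SubjectRecord`
    (or anything with ``subject_id`` and ``recordings``).  When ``filtered``
    is True the two-rule RR pre-filter is applied before feature extraction.
    """
    from .rr_filter import filter_rr

    rows = []
    for rec in records:
        series = rec.recordings[sensor]
        if filtered:
            series, _ = filter_rr(series, filter_config)
        fv = extract_features(series, spectral_config)
        rows.append({"subject_id": rec.subject_id, **fv.to_dict()})
    return pd.DataFrame(rows).set_index("subject_id")
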