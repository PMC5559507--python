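"""Band-pass filtering, sliding-window Hilbert phase, and relative band power.

The connectivity pipeline works on narrow-band instantaneous phase.  Recordings
are filtered into the four analysis bands (theta 4-8, alpha1 8-10, alpha2
10-13, beta 13-30 Hz) with a zero-phase Butterworth filter, and instantaneous
phase is extracted with a sliding-window Hilbert transform: 4-s Hann-tapered
windows with 50% overlap, each window contributing the central half of its
analytic signal, so the recording is tiled exactly once away from the edges.
Zero-phase filtering matters here because the downstream phase lag index is a
pure phase statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

#: Amplitude (µV) below which instantaneous phase is treated as undefined.
_AMP_EPS = 1e-12

#: Default Butterworth order (applied forward-backward, i.e. effective order 8).
DEFAULT_FILTER_ORDER = 4


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )


#: The four analysis bands of the connectivity pipeline.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

#: Delta band used by the band-power analysis (conventional 1-4 Hz).
DELTA_BAND = BandDefinition("delta", 1.0, 4.0)

#: Band set for relative power (delta + the four analysis bands, tiling 1-30 Hz).
POWER_BANDS: tuple[BandDefinition, ...] = (DELTA_BAND,) + DEFAULT_BANDS

#: Default denominator range for relative power, spanning all analysed bands.
DEFAULT_TOTAL_RANGE: tuple[float, float] = (1.0, 30.0)


@dataclass
class EEGRecording:
    """A channel x time voltage matrix with sampling rate and channel labels.

    data is in µV.  positions (optional) are 2-D or 3-D sensor coordinates,
    one row per channel, used only for plotting/debugging.
    """

    data: np.ndarray
    rate: float
    labels: list[str]
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channel x time matrix")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != self.data.shape[0]:
                raise ValueError("positions must have one row per channel")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        return EEGRecording(
            data=np.array(data, dtype=float),
            rate=self.rate,
            labels=list(self.labels),
            positions=None if self.positions is None else self.positions.copy(),
        )


@dataclass
class PhaseTensor:
    """Instantaneous phase per channel/sample for one band.

    phase is wrapped to (-pi, pi]; entries outside valid_mask (window-edge
    samples) and near-zero-amplitude samples (phase undefined, stored NaN)
    must not enter phase statistics.
    """

    phase: np.ndarray
    band: BandDefinition
    valid_mask: np.ndarray
    rate: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.phase.shape[1],):
            raise ValueError("valid_mask must be per-sample (1-D, length n_samples)")

    @property
    def n_channels(self) -> int:
        return self.phase.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phase.shape[1]


def bandpass(
    rec: EEGRecording,
    band: BandDefinition,
    order: int = DEFAULT_FILTER_ORDER,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass filter into one band.

    The filter is applied forward and backward (``sosfiltfilt``) so it
    introduces no phase shift — a prerequisite for lag-based connectivity.
    """
    nyq = rec.rate / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high} Hz >= Nyquist {nyq} Hz"
        )
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=rec.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(filtered)


def hilbert_phase(
    rec: EEGRecording,
    window_s: float = 4.0,
    overlap: float = 0.5,
) -> PhaseTensor:
    """Instantaneous phase via Hann-tapered, overlapping Hilbert windows.

    Each window of ``window_s`` seconds is Hann-tapered, its analytic signal
    computed, and only the central half kept; with 50% overlap the central
    halves tile the recording exactly once.  Samples never covered by a
    central half (the first and last quarter window) are flagged invalid.
    Samples whose analytic amplitude is ~0 get NaN phase (undefined).
    """
    if overlap != 0.5:
        raise NotImplementedError("only 50% overlap is supported")
    win_len = int(round(window_s * rec.rate))
    win_len -= win_len % 4  # need clean quarters
    if win_len < 8:
        raise ValueError("window too short for this sampling rate")
    n = rec.n_samples
    if n < win_len:
        raise ValueError(
            f"recording of {n} samples shorter than one {win_len}-sample window"
        )
    quarter = win_len // 4
    step = win_len // 2
    taper = sps.windows.hann(win_len, sym=False)

    phase = np.full_like(rec.data, np.nan)
    valid = np.zeros(n, dtype=bool)
    for start in range(0, n - win_len + 1, step):
        seg = rec.data[:, start : start + win_len] * taper
        analytic = sps.hilbert(seg, axis=1)
        centre = analytic[:, quarter : 3 * quarter]
        amp = np.abs(centre)
        ph = np.angle(centre)
        ph[amp < _AMP_EPS] = np.nan
        sl = slice(start + quarter, start + 3 * quarter)
        phase[:, sl] = ph
        valid[sl] = True
    return PhaseTensor(phase=phase, band=getattr(rec, "band", None) or BandDefinition("broadband", 1e-9, rec.rate), valid_mask=valid, rate=rec.rate)


def band_phase(
    rec: EEGRecording,
    band: BandDefinition,
    window_s: float = 4.0,
    order: int = DEFAULT_FILTER_ORDER,
) -> PhaseTensor:
    """Band-pass filter then sliding-window Hilbert phase.

    Besides the window-edge samples, the valid mask excludes a filter
    transient margin at both recording ends (a few cycles of the band's low
    edge, where the forward-backward filter's start-up response lives).
    """
    pt = hilbert_phase(bandpass(rec, band, order=order), window_s=window_s)
    valid = pt.valid_mask.copy()
    margin = int(round(max(3.0, 6.0 / band.low) * rec.rate))
    valid[:margin] = False
    if margin > 0:
        valid[-margin:] = False
    return PhaseTensor(phase=pt.phase, band=band, valid_mask=valid, rate=rec.rate)


def relative_band_power(
    rec: EEGRecording,
    bands: Sequence[BandDefinition] = POWER_BANDS,
    total_range: tuple[float, float] = DEFAULT_TOTAL_RANGE,
    roi_map: "dict[str, str] | None" = None,
    nperseg_s: float = 4.0,
) -> pd.DataFrame:
    """Relative spectral power per channel (or ROI) and band.

    Power spectra are estimated with Welch's method (Hann windows of
    ``nperseg_s`` seconds, 50% overlap); the fraction for each band is its
    power divided by the power inside ``total_range``.  Frequency bins are
    assigned half-open, ``low <= f < high``, so a band set tiling the total
    range yields fractions that sum to exactly 1.  Channels that are all zero
    yield NaN fractions (documented degenerate contract).

    Returns a DataFrame indexed by channel (or ROI) with one column per band.
    """
    if len(bands) == 0:
        raise ValueError("empty band set")
    lo, hi = total_range
    for b in bands:
        if b.low < lo or b.high > hi:
            raise ValueError(f"band {b.name!r} outside total_range {total_range}")
    nperseg = min(int(round(nperseg_s * rec.rate)), rec.n_samples)
    freqs, psd = sps.welch(rec.data, fs=rec.rate, nperseg=nperseg, axis=1)
    total_mask = (freqs >= lo) & (freqs < hi)
    total = psd[:, total_mask].sum(axis=1)
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for b in bands:
            m = (freqs >= b.low) & (freqs < b.high)
            out[b.name] = np.where(total > 0, psd[:, m].sum(axis=1) / total, np.nan)
    table = pd.DataFrame(out, index=pd.Index(rec.labels, name="channel"))
    if roi_map is not None:
        mapped = table.loc[[c for c in rec.labels if c in roi_map]]
        table = mapped.groupby([roi_map[c] for c in mapped.index]).mean()
        table.index.name = "roi"
    return table
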