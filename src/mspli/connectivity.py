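"""Phase lag index and its microstate-segmented variant (msPLI).

The phase lag index (PLI) of a channel pair is |mean_t sign(dphi_t)| over the
instantaneous phase difference series dphi: it measures the asymmetry of the
phase-difference distribution around zero and is therefore blind to zero-lag
(volume-conduction) coupling.  msPLI computes PLI on phase samples stitched
together *within* each microstate class — for every class the labelled samples
are concatenated in temporal order and cut into epochs (default 4,000 phase
differences each, the first ``n_epochs`` of them), giving up to
n_epochs x k matrices per band that are averaged into one connectivity matrix
per subject.  Electrode matrices are finally grouped into 22 regions of
interest (11 per hemisphere) by averaging cross-region electrode pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .microstates import LabelVector
from .preprocessing import BandDefinition, EEGRecording, PhaseTensor, band_phase

DEFAULT_EPOCH_LEN = 4000
DEFAULT_N_EPOCHS = 4


@dataclass
class PhaseDifferenceSeries:
    """Phase differences (radians) for one channel pair, with provenance."""

    dphi: np.ndarray
    pair: tuple[str, str] = ("", "")
    microstate: int | None = None

    def __post_init__(self) -> None:
        self.dphi = np.asarray(self.dphi, dtype=float)
        if self.dphi.ndim != 1:
            raise ValueError("dphi must be 1-D")


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node PLI matrix with zero diagonal, values in [0, 1]."""

    W: np.ndarray
    nodes: list[str]
    band: BandDefinition | None = None
    coverage: dict = field(default_factory=dict)  # microstate -> epochs used

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        if len(self.nodes) != n:
            raise ValueError("node labels must match matrix size")
        if not np.allclose(self.W, self.W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal must be zero")
        if np.nanmin(self.W) < -1e-12 or np.nanmax(self.W) > 1 + 1e-12:
            raise ValueError("PLI values must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def edge_names(self) -> list[str]:
        n = self.n_nodes
        return [f"{self.nodes[i]}--{self.nodes[j]}" for i in range(n) for j in range(i + 1, n)]

    def edge_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.W[iu]


class ROIMap:
    """Channel -> region-of-interest assignment.

    Each mapped channel belongs to exactly one ROI; channels absent from the
    map (midline/neck/face in the reference montage) are excluded from ROI
    aggregation.  ``rois`` preserves a stable region order.
    """

    def __init__(self, mapping: dict[str, str]):
        self.mapping = dict(mapping)
        seen: list[str] = []
        for roi in self.mapping.values():
            if roi not in seen:
                seen.append(roi)
        self.rois = seen

    def channels_for(self, roi: str) -> list[str]:
        return [c for c, r in self.mapping.items() if r == roi]

    def __contains__(self, channel: str) -> bool:
        return channel in self.mapping

    def __len__(self) -> int:
        return len(self.rois)


def pli(series: PhaseDifferenceSeries | np.ndarray) -> float:
    """Phase lag index |mean sign(dphi)| of one phase-difference series.

    sign(0) contributes 0; NaN entries (undefined phase) are excluded.
    """
    dphi = series.dphi if isinstance(series, PhaseDifferenceSeries) else np.asarray(series, float)
    if dphi.size == 0:
        raise ValueError("empty phase-difference series")
    finite = dphi[np.isfinite(dphi)]
    if finite.size == 0:
        raise ValueError("phase-difference series has no finite entries")
    return float(abs(np.mean(np.sign(finite))))


def extract_ms_epochs(
    phases: PhaseTensor,
    labels: LabelVector,
    epoch_len: int = DEFAULT_EPOCH_LEN,
    n_epochs: int = DEFAULT_N_EPOCHS,
) -> dict[int, list[np.ndarray]]:
    """Stitch labelled samples per microstate class and cut them into epochs.

    For each class, valid samples carrying that label are concatenated in
    temporal order and the first ``n_epochs`` consecutive stretches of
    ``epoch_len`` samples are kept (classes with fewer labelled samples yield
    as many full epochs as available, possibly zero).

    Returns {class: [sample-index arrays, one per epoch]}; pair phase
    differences for an epoch are formed from ``phases.phase[:, indices]``.
    """
    if epoch_len <= 0:
        raise ValueError("epoch_len must be positive")
    if n_epochs <= 0:
        raise ValueError("n_epochs must be positive")
    if labels.n_samples != phases.n_samples:
        raise ValueError("labels not aligned to phase samples")
    out: dict[int, list[np.ndarray]] = {}
    for cls in range(labels.k):
        idx = np.flatnonzero(
            (labels.labels == cls) & phases.valid_mask
        )
        n_full = min(idx.size // epoch_len, n_epochs)
        out[cls] = [idx[e * epoch_len : (e + 1) * epoch_len] for e in range(n_full)]
    return out


def _wrap(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences circularly to (-pi, pi]."""
    return np.pi - np.mod(np.pi - d, 2.0 * np.pi)


def pair_series(
    phases: PhaseTensor, indices: np.ndarray, i: int, j: int, microstate: int | None = None
) -> PhaseDifferenceSeries:
    """Phase-difference series of channel pair (i, j) over the given samples,
    wrapped to (-pi, pi]."""
    dphi = _wrap(phases.phase[i, indices] - phases.phase[j, indices])
    return PhaseDifferenceSeries(dphi=dphi, microstate=microstate)


def _epoch_pli_matrix(phase: np.ndarray) -> np.ndarray:
    """PLI matrix from a channel x sample phase block (NaN-aware)."""
    d = _wrap(phase[:, None, :] - phase[None, :, :])
    signs = np.sign(d)
    finite = np.isfinite(signs)
    count = finite.sum(axis=2)
    total = np.where(finite, signs, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.abs(np.where(count > 0, total / np.maximum(count, 1), 0.0))
    np.fill_diagonal(W, 0.0)
    return W


def ms_pli(
    rec: EEGRecording,
    labels: LabelVector,
    band: BandDefinition,
    epoch_len: int | None = None,
    n_epochs: int = DEFAULT_N_EPOCHS,
    window_s: float = 4.0,
) -> ConnectivityMatrix:
    """Microstate-segmented PLI matrix for one band.

    The recording is band-pass filtered, instantaneous phase extracted, epochs
    stitched per microstate class, a PLI matrix computed per epoch, and all
    available matrices (target ``n_epochs`` x k) averaged elementwise.
    ``epoch_len`` defaults to 4 s worth of samples at the recording's rate.
    """
    if epoch_len is None:
        epoch_len = int(round(4.0 * rec.rate))
    phases = band_phase(rec, band, window_s=window_s)
    return ms_pli_from_phases(phases, labels, rec.labels, epoch_len, n_epochs)


def ms_pli_from_phases(
    phases: PhaseTensor,
    labels: LabelVector,
    node_labels: list[str],
    epoch_len: int = DEFAULT_EPOCH_LEN,
    n_epochs: int = DEFAULT_N_EPOCHS,
) -> ConnectivityMatrix:
    """msPLI from a precomputed phase tensor (see :func:`ms_pli`)."""
    epochs = extract_ms_epochs(phases, labels, epoch_len=epoch_len, n_epochs=n_epochs)
    mats = []
    coverage = {}
    for cls, idx_list in epochs.items():
        coverage[cls] = len(idx_list)
        for idx in idx_list:
            mats.append(_epoch_pli_matrix(phases.phase[:, idx]))
    if not mats:
        raise ValueError(
            "no full epochs in any microstate class "
            f"(epoch_len={epoch_len}, labelled-sample counts insufficient)"
        )
    W = np.mean(mats, axis=0)
    W = (W + W.T) / 2.0
    return ConnectivityMatrix(W=W, nodes=list(node_labels), band=phases.band, coverage=coverage)


def roi_aggregate(W: ConnectivityMatrix, roi_map: ROIMap) -> ConnectivityMatrix:
    """Aggregate an electrode matrix into ROI space.

    The value for an ROI pair is the mean PLI over all electrode pairs
    spanning the two regions; within-ROI pairs never enter off-diagonal
    entries and the diagonal stays zero.  Channels absent from the map are
    ignored; an ROI with no channel present in W is an error.
    """
    chan_idx: dict[str, list[int]] = {}
    for roi in roi_map.rois:
        idx = [W.nodes.index(c) for c in roi_map.channels_for(roi) if c in W.nodes]
        if not idx:
            raise ValueError(f"ROI {roi!r} has no channels present in the matrix")
        chan_idx[roi] = idx
    n = len(roi_map.rois)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ia = chan_idx[roi_map.rois[a]]
            ib = chan_idx[roi_map.rois[b]]
            out[a, b] = out[b, a] = W.W[np.ix_(ia, ib)].mean()
    return ConnectivityMatrix(W=out, nodes=list(roi_map.rois), band=W.band, coverage=dict(W.coverage))
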