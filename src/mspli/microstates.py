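"""EEG microstate segmentation.

Resting EEG passes through a sequence of quasi-stable scalp topographies
("microstates", ~50-100 ms each).  Segmentation fits k template maps by
polarity-invariant (modified) k-means on the topographies at local maxima of
the global field power (GFP), selects k with the Krzanowski-Lai (KL) index,
and back-fits the templates to every sample to produce the label vector that
gates connectivity epoch extraction.

Polarity is ignored throughout (a map and its negation are the same state),
which is the microstate convention: assignment uses the squared spatial
correlation, and template updates use the leading eigenvector of the cluster's
outer-product sum rather than a plain mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocessing import EEGRecording

#: Label value for samples that cannot be assigned (zero spatial variance).
UNASSIGNED = -1

#: Default minimum microstate segment duration (seconds) for label smoothing.
DEFAULT_SMOOTH_S = 0.03

#: KL peak threshold: interior maxima below this are treated as "no peak"
#: and the smallest candidate k is returned instead.  Data with real k-fold
#: topographic structure produce KL peaks an order of magnitude above the
#: ~1-2 range that featureless (single-topography) data meander in.
KL_PEAK_MIN = 5.0


@dataclass
class MicrostateModel:
    """k unit-norm template topographies plus goodness of fit (GEV)."""

    templates: np.ndarray  # k x n_channels, average-referenced, unit-norm
    k: int
    gev: float

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.templates.shape[0] != self.k:
            raise ValueError("template count must equal k")
        norms = np.linalg.norm(self.templates, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("templates must be unit-norm")
        if not (0.0 <= self.gev <= 1.0):
            raise ValueError("gev must lie in [0, 1]")


@dataclass
class LabelVector:
    """Per-sample microstate class in {0..k-1}, or UNASSIGNED."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        bad = (self.labels != UNASSIGNED) & ((self.labels < 0) | (self.labels >= self.k))
        if bad.any():
            raise ValueError("labels outside {0..k-1} / UNASSIGNED")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]


def gfp(rec: EEGRecording) -> np.ndarray:
    """Global field power: spatial standard deviation across channels per sample."""
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    return rec.data.std(axis=0)


def _center(maps: np.ndarray) -> np.ndarray:
    """Average-reference maps (subtract the spatial mean of each map)."""
    return maps - maps.mean(axis=1, keepdims=True)


def _unit(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    out = np.zeros_like(maps)
    np.divide(maps, norms, out=out, where=norms > 0)
    return out


def gfp_peak_maps(rec: EEGRecording) -> np.ndarray:
    """Topographies at local GFP maxima (n_peaks x n_channels)."""
    g = gfp(rec)
    peaks, _ = sps.find_peaks(g)
    return rec.data[:, peaks].T


def _kmeans_once(
    maps: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray, float]:
    """One run of polarity-invariant k-means on centered maps.

    Returns (templates k x m unit-norm, assignment, within-cluster dispersion).
    Dispersion is the summed squared residual after projecting each map on its
    template: sum_i ||x_i||^2 - (x_i . t_a(i))^2.
    """
    n, m = maps.shape
    idx = rng.choice(n, size=k, replace=False)
    templates = _unit(maps[idx])
    assign = np.full(n, -1)
    for _ in range(max_iter):
        proj = maps @ templates.T  # n x k
        new_assign = np.argmax(proj**2, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            member = maps[assign == j]
            if member.shape[0] == 0:
                # re-seed an empty cluster from the worst-fitting map
                resid = (maps**2).sum(axis=1) - np.max(proj**2, axis=1)
                templates[j] = _unit(maps[np.argmax(resid)][None, :])[0]
                continue
            # leading eigenvector of the cluster scatter (polarity-proof mean)
            scatter = member.T @ member
            w, v = np.linalg.eigh(scatter)
            templates[j] = v[:, -1]
    proj = maps @ templates.T
    assign = np.argmax(proj**2, axis=1)
    dispersion = float(((maps**2).sum() - (np.take_along_axis(proj, assign[:, None], 1) ** 2).sum()))
    return templates, assign, dispersion


def _fit_on_maps(
    maps: np.ndarray, k: int, n_restarts: int, seed: int
) -> tuple[MicrostateModel, float]:
    """Fit templates on pre-extracted GFP-peak maps; returns (model, dispersion)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if maps.shape[0] < 10 * k:
        raise ValueError(
            f"only {maps.shape[0]} GFP-peak maps for k={k}; need at least {10 * k}"
        )
    maps = _center(maps)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        templates, assign, disp = _kmeans_once(maps, k, rng)
        if best is None or disp < best[2]:
            best = (templates, assign, disp)
    templates, assign, disp = best
    total = float((maps**2).sum())
    gev = 0.0 if total == 0 else 1.0 - disp / total
    model = MicrostateModel(templates=templates, k=k, gev=gev)
    return model, disp


def fit_microstates(
    rec: EEGRecording, k: int, n_restarts: int = 10, seed: int = 0
) -> MicrostateModel:
    """Polarity-invariant k-means on GFP-peak topographies, best of n_restarts.

    The restart with the smallest within-cluster dispersion (equivalently the
    largest explained variance on the peak maps) wins.  Deterministic for a
    given seed.
    """
    maps = gfp_peak_maps(rec)
    model, _ = _fit_on_maps(maps, k, n_restarts, seed)
    return model


def krzanowski_lai(dispersions: dict[int, float], m: int) -> dict[int, float]:
    """KL index per interior k from a {k: within-dispersion} curve.

    DIFF(k) = (k-1)^(2/m) W_{k-1} - k^(2/m) W_k with m the map dimensionality
    (channel count); KL(k) = |DIFF(k)| / |DIFF(k+1)|.
    """
    ks = sorted(dispersions)
    diff = {
        k: (k - 1) ** (2.0 / m) * dispersions[k - 1] - k ** (2.0 / m) * dispersions[k]
        for k in ks[1:]
    }
    out = {}
    for k in ks[1:-1]:
        denom = abs(diff[k + 1])
        out[k] = np.inf if denom == 0 else abs(diff[k]) / denom
    return out


def select_k(
    rec: EEGRecording, k_range: "list[int]", n_restarts: int = 10, seed: int = 0
) -> int:
    """Choose the number of microstates by maximizing the Krzanowski-Lai index.

    Models are fitted for every k in the contiguous ``k_range``; KL(k) is
    defined for interior k only, so the range must hold at least 3 values.
    A flat KL curve (maximum below ``KL_PEAK_MIN``, as for data generated by
    a single topography plus noise) triggers the documented fallback of the
    smallest candidate k.
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values (KL needs neighbors)")
    if any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("k_range must be contiguous")
    maps = gfp_peak_maps(rec)
    dispersions = {}
    for k in ks:
        _, disp = _fit_on_maps(maps, k, n_restarts, seed + k)
        dispersions[k] = disp
    kl = krzanowski_lai(dispersions, m=rec.n_channels)
    finite = {k: v for k, v in kl.items() if np.isfinite(v)}
    if not finite:
        return ks[0]
    k_best, v_best = max(finite.items(), key=lambda kv: (kv[1], -kv[0]))
    if v_best < KL_PEAK_MIN:
        return ks[0]
    return k_best


def _smooth_labels(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Merge segments shorter than min_len into their neighbours.

    Short runs are relabelled to the preceding segment's label (the following
    one at the start).  Iterates until no short run remains or labels stop
    changing; UNASSIGNED runs are left untouched.
    """
    if min_len <= 1:
        return labels
    lab = labels.copy()
    for _ in range(100):
        # run-length encode
        change = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [lab.size]))
        short = [
            (s, e)
            for s, e in zip(starts, ends)
            if (e - s) < min_len and lab[s] != UNASSIGNED
        ]
        if not short:
            break
        prev = lab.copy()
        for s, e in short:
            if s > 0 and lab[s - 1] != UNASSIGNED:
                lab[s:e] = lab[s - 1]
            elif e < lab.size:
                lab[s:e] = lab[e]
        if np.array_equal(prev, lab):
            break
    return lab


def backfit(
    rec: EEGRecording,
    model: MicrostateModel,
    smooth_s: float = DEFAULT_SMOOTH_S,
) -> LabelVector:
    """Label every sample by its best-correlated template (either polarity).

    Samples with zero spatial variance (undefined correlation) are left
    UNASSIGNED.  Segments shorter than ``smooth_s`` are merged into their
    neighbours so 1-2 sample flickers do not fragment epoch stitching.
    """
    if model.templates.shape[1] != rec.n_channels:
        raise ValueError(
            f"model has {model.templates.shape[1]} channels, recording {rec.n_channels}"
        )
    maps = _center(rec.data.T)  # n_samples x n_channels
    proj = maps @ model.templates.T
    labels = np.argmax(proj**2, axis=1)
    labels[np.linalg.norm(maps, axis=1) < 1e-12] = UNASSIGNED
    min_len = int(round(smooth_s * rec.rate))
    labels = _smooth_labels(labels, min_len)
    return LabelVector(labels=labels, k=model.k)
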