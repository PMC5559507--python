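"""Synthetic resting-EEG cohorts with known ground truth.

The generator emulates the three features of real resting EEG that the
analysis pipeline depends on, at desk scale (32 channels, 250 Hz, 3 min by
default; the study-scale 256 channels / 1,000 Hz / 12 min remain
configurable):

* **microstate structure** — a first-order Markov chain switches between k
  unit-norm template topographies (mean dwell ~80 ms); the active template is
  scaled by a band-limited carrier, producing GFP peaks with quasi-stable
  maps;
* **phase-lag coupling** — selected channel pairs share a band-limited
  analytic carrier with a fixed phase offset; the second channel mixes the
  shared lagged carrier with an independent one in proportion to the coupling
  strength, so strength 1 yields a perfectly constant lag (expected PLI 1)
  and strength 0 independent phases (expected PLI ~ 0);
* **a planted covariate association** — for designated edges, coupling
  strength depends linearly on the subject's standardized apathy score, with
  confounds (age, sex, education, MMS, LED) correlated to apathy through a
  Gaussian copula.

Covariate marginals follow the study population they emulate: AES scores are
right-skewed integers in [18, 39] (gamma-shaped, median ~24.5), age ~68 ± 8 y,
education ~14.6 ± 3 y, MMS 24-30, LED log-normal around 600 mg/day.

For calibration experiments that need hundreds of replicate cohorts (FWER
under the global null, power of the permutation correction), a cohort-level
fast path (:func:`simulate_cohort_connectivity`) draws per-subject edge
connectivity directly from the same covariate model plus measurement noise,
skipping the time-series layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import DEFAULT_BANDS, BandDefinition, EEGRecording

# Study-population covariate parameters (mean/spread the cohort emulates).
AES_MEAN, AES_SD = 26.2, 6.2
AES_RANGE = (18, 39)
_AES_GAMMA_SHAPE, _AES_GAMMA_SCALE = 1.8, 4.5
_AGE = (68.0, 7.7)
_EDUCATION = (14.6, 3.0)
_MMS = (28.8, 1.0)
_LED_LOG = (6.34, 0.425)  # log-normal: median ~569, mean ~623 mg/day
_BDI = (7.4, 4.3)
_UPDRS = (15.4, 11.2)
_FEMALE_FRACTION = 0.35

#: Default copula correlations of each confound's latent with the apathy latent.
DEFAULT_CONFOUND_SPEC: dict[str, float] = {
    "age": 0.30,
    "sex": 0.10,
    "education": -0.20,
    "MMS": -0.30,
    "LED": 0.20,
    "BDI": 0.25,
    "UPDRS_III": 0.20,
}

#: Loading of the initiation factor on the apathy latent (negative: apathetic
#: subjects initiate worse) and of each cognitive test on that factor.
_INITIATION_APATHY_LOADING = -0.45
_INITIATION_ITEM_LOADING = 0.7
#: Test variables where smaller raw values mean better performance are stored
#: sign-flipped, mirroring how such tests arrive in a real covariate table.
_COGNITIVE_TESTS = {
    "phonemic_fluency": False,
    "semantic_fluency": False,
    "five_point": False,
    "tmt_a": True,
    "stroop_naming": True,
}

#: Default 32-channel montage (matches the packaged 22-ROI map; the four
#: midline channels are unmapped there, mirroring the midline exclusion).
DEFAULT_MONTAGE_32: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC1", "FC5", "C3", "T7",
    "CP1", "CP5", "P3", "P7", "PO3", "O1",
    "Fp2", "AF4", "F4", "F8", "FC2", "FC6", "C4", "T8",
    "CP2", "CP6", "P4", "P8", "PO4", "O2",
    "Fz", "Cz", "Pz", "Oz",
)

#: Frozen effect size of the planted association for cohort-level power
#: studies, in log-connectivity units per SD of apathy (connectivity is
#: analysed on the log scale, so planted effects are multiplicative:
#: -0.4 means ~33% lower connectivity per SD of apathy).
DEFAULT_EFFECT_SLOPE = -0.4
DEFAULT_MEASUREMENT_SD = 0.02


@dataclass(frozen=True)
class CouplingSpec:
    """One phase-coupled channel pair in one band."""

    pair: tuple[int, int]
    band: str
    lag: float  # radians; phase of channel pair[0] leads pair[1] by lag
    strength: float  # in [0, 1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("coupling strength must lie in [0, 1]")


@dataclass(frozen=True)
class EffectSpec:
    """Linear dependence of one coupling's strength on standardized apathy."""

    pair: tuple[int, int]
    band: str
    slope: float  # strength units per SD of AES


@dataclass
class SimConfig:
    """Full description of a simulated cohort (see module docstring)."""

    n_subjects: int = 40
    n_channels: int = 32
    rate: float = 250.0
    duration: float = 180.0
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    templates: np.ndarray | None = None  # k x n_channels unit-norm; None = derive
    k: int = 4
    markov_transition: np.ndarray | None = None  # None = uniform switching
    mean_dwell: float = 0.08  # seconds
    coupling_spec: tuple[CouplingSpec, ...] = ()
    effect_spec: tuple[EffectSpec, ...] = ()
    confound_spec: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUND_SPEC)
    )
    noise_sd: float = 1.0  # µV white noise
    ms_amplitude: float = 3.0  # µV scale of the microstate component
    ms_carrier_band: tuple[float, float] = (8.0, 10.0)
    coupling_amplitude: float = 2.0  # µV scale of each coupled carrier
    channel_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.templates is not None:
            self.templates = np.asarray(self.templates, dtype=float)
            if self.templates.shape != (self.k, self.n_channels):
                raise ValueError("templates must be k x n_channels")
            if not np.allclose(np.linalg.norm(self.templates, axis=1), 1.0, atol=1e-8):
                raise ValueError("templates must be unit-norm")
        if self.markov_transition is not None:
            T = np.asarray(self.markov_transition, dtype=float)
            if T.shape != (self.k, self.k):
                raise ValueError("transition matrix must be k x k")
            if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("transition matrix rows must sum to 1")
            self.markov_transition = T
        band_names = {b.name for b in self.bands}
        for c in tuple(self.coupling_spec) + tuple(self.effect_spec):
            for ch in c.pair:
                if not (0 <= ch < self.n_channels):
                    raise ValueError(f"coupling references nonexistent channel {ch}")
            if c.band not in band_names:
                raise ValueError(f"coupling references unknown band {c.band!r}")
        for e in self.effect_spec:
            if not any(
                set(c.pair) == set(e.pair) and c.band == e.band
                for c in self.coupling_spec
            ):
                raise ValueError(
                    f"effect on {e.pair}/{e.band} has no matching coupling baseline"
                )
        if self.channel_labels is not None and len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))

    def labels(self) -> list[str]:
        if self.channel_labels is not None:
            return list(self.channel_labels)
        if self.n_channels == len(DEFAULT_MONTAGE_32):
            return list(DEFAULT_MONTAGE_32)
        return [f"ch{i:02d}" for i in range(self.n_channels)]

    def band_by_name(self, name: str) -> BandDefinition:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(name)


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    microstate_labels: np.ndarray | None  # per-sample true state
    coupling_strengths: dict[tuple[int, int, str], float]  # per edge/band
    effect_slopes: dict[tuple[int, int, str], float]
    templates: np.ndarray | None = None
    per_subject_strengths: "dict[int, dict] | None" = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "coupling_strengths": {
                    f"{i}-{j}-{b}": v for (i, j, b), v in self.coupling_strengths.items()
                },
                "effect_slopes": {
                    f"{i}-{j}-{b}": v for (i, j, b), v in self.effect_slopes.items()
                },
            }
        )


def default_templates(k: int, n_channels: int, seed: int = 0) -> np.ndarray:
    """k orthonormal, average-referenced topographies (deterministic per seed)."""
    rng = np.random.default_rng([seed, 7])
    raw = rng.standard_normal((n_channels, k))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    return q.T[:k]


def default_transition(k: int, mean_dwell: float, rate: float) -> np.ndarray:
    """Row-stochastic matrix with geometric dwell of ``mean_dwell`` seconds."""
    stay = 1.0 - 1.0 / max(mean_dwell * rate, 1.0)
    off = (1.0 - stay) / (k - 1)
    T = np.full((k, k), off)
    np.fill_diagonal(T, stay)
    return T


def sample_markov_labels(
    T: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample a state sequence of length n_samples from the chain."""
    k = T.shape[0]
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(k))
    t = 0
    while t < n_samples:
        stay = T[state, state]
        # geometric dwell, then a jump drawn from the renormalized off-row
        dwell = int(rng.geometric(1.0 - stay)) if stay < 1.0 else n_samples - t
        dwell = min(dwell, n_samples - t)
        labels[t : t + dwell] = state
        t += dwell
        if t >= n_samples:
            break
        off = T[state].copy()
        off[state] = 0.0
        off /= off.sum()
        state = int(rng.choice(k, p=off))
    return labels


def analytic_band_noise(
    rng: np.random.Generator, n_samples: int, rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Complex analytic Gaussian noise band-limited to ``band`` (unit-RMS real part).

    Built in the frequency domain with support only on positive frequencies
    inside the band, so the exact analytic signal of its real part is the
    series itself (no negative-frequency image).
    """
    freqs = np.fft.fftfreq(n_samples, d=1.0 / rate)
    sel = (freqs >= band[0]) & (freqs < band[1])
    if not sel.any():
        raise ValueError(f"band {band} contains no FFT bins at n={n_samples}")
    spec = np.zeros(n_samples, dtype=complex)
    spec[sel] = rng.standard_normal(sel.sum()) + 1j * rng.standard_normal(sel.sum())
    a = np.fft.ifft(spec)
    rms = np.sqrt(np.mean(a.real**2))
    return a / rms


def _apathy_z(aes_score: float) -> float:
    return (float(aes_score) - AES_MEAN) / AES_SD


def effective_strengths(
    config: SimConfig, apathy_score: float
) -> dict[tuple[int, int, str], float]:
    """Per-edge/band coupling strength after applying planted apathy effects."""
    z = _apathy_z(apathy_score)
    out = {}
    for c in config.coupling_spec:
        s = c.strength
        for e in config.effect_spec:
            if set(e.pair) == set(c.pair) and e.band == c.band:
                s = s + e.slope * z
        out[(c.pair[0], c.pair[1], c.band)] = float(np.clip(s, 0.0, 1.0))
    return out


def generate_subject_eeg(
    config: SimConfig, subject_index: int, apathy_score: float
) -> tuple[EEGRecording, GroundTruth]:
    """One subject's recording: microstates + couplings + white noise.

    Deterministic given (config.seed, subject_index).  Coupled pairs share a
    band-limited analytic carrier: channel i carries Re(A), channel j carries
    s * Re(A e^{-i lag}) + (1 - s) * Re(B) with B independent, so at strength
    s = 1 the pair's instantaneous phase difference is the constant lag.
    """
    rng = np.random.default_rng([config.seed, 11, subject_index])
    n = config.n_samples
    T = (
        config.markov_transition
        if config.markov_transition is not None
        else default_transition(config.k, config.mean_dwell, config.rate)
    )
    templates = (
        config.templates
        if config.templates is not None
        else default_templates(config.k, config.n_channels, config.seed)
    )
    labels = sample_markov_labels(T, n, rng)
    data = np.zeros((config.n_channels, n))
    if config.ms_amplitude > 0:
        carrier = analytic_band_noise(rng, n, config.rate, config.ms_carrier_band).real
        data += config.ms_amplitude * templates[labels].T * carrier
    else:
        # keep the stream position independent of the amplitude setting
        analytic_band_noise(rng, n, config.rate, config.ms_carrier_band)
    strengths = effective_strengths(config, apathy_score)
    for c in config.coupling_spec:
        band = config.band_by_name(c.band)
        s = strengths[(c.pair[0], c.pair[1], c.band)]
        A = analytic_band_noise(rng, n, config.rate, (band.low, band.high))
        B = analytic_band_noise(rng, n, config.rate, (band.low, band.high))
        i, j = c.pair
        data[i] += config.coupling_amplitude * A.real
        data[j] += config.coupling_amplitude * (
            s * (A * np.exp(-1j * c.lag)).real + (1.0 - s) * B.real
        )
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
    rec = EEGRecording(data=data, rate=config.rate, labels=config.labels())
    truth = GroundTruth(
        microstate_labels=labels,
        coupling_strengths=strengths,
        effect_slopes={(e.pair[0], e.pair[1], e.band): e.slope for e in config.effect_spec},
        templates=templates,
    )
    return rec, truth


def _covariate_table(
    n_subjects: int,
    confound_spec: dict[str, float],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cohort covariates via a Gaussian copula on the apathy latent."""
    z_apathy = rng.standard_normal(n_subjects)

    def latent(rho: float) -> np.ndarray:
        return rho * z_apathy + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_subjects)

    from scipy import stats as ss

    u = ss.norm.cdf(z_apathy)
    aes = 18.0 + ss.gamma.ppf(u, a=_AES_GAMMA_SHAPE, scale=_AES_GAMMA_SCALE)
    aes = np.clip(np.round(aes), *AES_RANGE)

    rho = {**DEFAULT_CONFOUND_SPEC, **confound_spec}
    age = _AGE[0] + _AGE[1] * latent(rho["age"])
    education = np.clip(_EDUCATION[0] + _EDUCATION[1] * latent(rho["education"]), 5, 25)
    mms = np.clip(np.round(_MMS[0] + _MMS[1] * latent(rho["MMS"])), 25, 30)
    led = np.exp(_LED_LOG[0] + _LED_LOG[1] * latent(rho["LED"]))
    sex = (ss.norm.cdf(latent(rho["sex"])) < _FEMALE_FRACTION).astype(int)
    bdi = np.clip(np.round(_BDI[0] + _BDI[1] * latent(rho["BDI"])), 0, 63)
    updrs = np.clip(np.round(_UPDRS[0] + _UPDRS[1] * latent(rho["UPDRS_III"])), 0, 80)

    g = _INITIATION_APATHY_LOADING * z_apathy + np.sqrt(
        1.0 - _INITIATION_APATHY_LOADING**2
    ) * rng.standard_normal(n_subjects)
    cognition = {}
    lam = _INITIATION_ITEM_LOADING
    for name, reversed_ in _COGNITIVE_TESTS.items():
        item = lam * g + np.sqrt(1.0 - lam**2) * rng.standard_normal(n_subjects)
        cognition[name] = -item if reversed_ else item

    table = pd.DataFrame(
        {
            "id": [f"subj{i:03d}" for i in range(n_subjects)],
            "AES": aes,
            "BDI": bdi,
            "age": age,
            "sex": sex,
            "education": education,
            "MMS": mms,
            "LED": led,
            "UPDRS_III": updrs,
            **cognition,
        }
    )
    return table, z_apathy


def generate_cohort(
    config: SimConfig,
) -> tuple[list[EEGRecording], pd.DataFrame, GroundTruth]:
    """Full cohort: recordings, covariate table, and planted ground truth."""
    if config.n_subjects < 4:
        raise ValueError(
            "need at least 4 subjects (residualization on 5 confounds is undefined)"
        )
    rng = np.random.default_rng([config.seed, 13])
    cohort, _ = _covariate_table(config.n_subjects, config.confound_spec, rng)
    recordings = []
    per_subject = {}
    for i in range(config.n_subjects):
        rec, truth_i = generate_subject_eeg(config, i, float(cohort["AES"].iloc[i]))
        recordings.append(rec)
        per_subject[i] = truth_i.coupling_strengths
    truth = GroundTruth(
        microstate_labels=None,
        coupling_strengths={},
        effect_slopes={(e.pair[0], e.pair[1], e.band): e.slope for e in config.effect_spec},
        templates=None,
        per_subject_strengths=per_subject,
    )
    return recordings, cohort, truth


# ---------------------------------------------------------------------------
# Cohort-level fast path: per-subject edge connectivity without time series.
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityCohort:
    """Per-subject edge connectivity with its covariate table and truth."""

    values: pd.DataFrame  # subjects x edges
    cohort: pd.DataFrame
    effect_edges: dict[str, float]  # edge name -> slope (per SD of apathy)


def simulate_cohort_connectivity(
    n_subjects: int = 40,
    edge_names: "list[str] | None" = None,
    n_edges: int = 231,
    effect_edges: "dict[str, float] | None" = None,
    measurement_sd: float = DEFAULT_MEASUREMENT_SD,
    confound_spec: "dict[str, float] | None" = None,
    seed: int = 0,
) -> ConnectivityCohort:
    """Draw a cohort of per-subject ROI-edge connectivity values directly.

    Each edge e has a cohort-level baseline b_e ~ U(0.05, 0.25) (typical
    averaged-PLI magnitudes), a small age loading g_e ~ N(0, 0.01) (so
    confound residualization has real work to do), i.i.d. measurement noise,
    and an optional planted apathy effect that acts multiplicatively —
    connectivity is analysed on the log scale, so planted slopes are in
    log-connectivity units per SD of the apathy latent:

        value[s, e] = clip(b_e + g_e z_age[s] + eps, 0.01, 1) * exp(slope_e z_AES[s])

    With all slopes zero the outcome is, after residualization on the
    confounds, exchangeable against the edge values — the global null used
    for family-wise error calibration.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    rng = np.random.default_rng([seed, 17])
    cohort, z_apathy = _covariate_table(n_subjects, confound_spec or {}, rng)
    if edge_names is None:
        edge_names = [f"edge{e:03d}" for e in range(n_edges)]
    n_edges = len(edge_names)
    effect_edges = dict(effect_edges or {})
    unknown = set(effect_edges) - set(edge_names)
    if unknown:
        raise ValueError(f"effect edges not in edge set: {sorted(unknown)}")
    base = rng.uniform(0.05, 0.25, size=n_edges)
    age_load = rng.normal(0.0, 0.01, size=n_edges)
    z_age = (cohort["age"].to_numpy(float) - _AGE[0]) / _AGE[1]
    slopes = np.array([effect_edges.get(name, 0.0) for name in edge_names])
    raw = (
        base[None, :]
        + age_load[None, :] * z_age[:, None]
        + rng.normal(0.0, measurement_sd, size=(n_subjects, n_edges))
    )
    vals = np.clip(raw, 0.01, 1.0) * np.exp(slopes[None, :] * z_apathy[:, None])
    vals = np.clip(vals, 1e-4, 1.0)
    values = pd.DataFrame(vals, columns=edge_names, index=cohort["id"])
    return ConnectivityCohort(values=values, cohort=cohort, effect_edges=effect_edges)
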