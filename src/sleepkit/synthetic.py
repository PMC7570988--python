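"""Synthetic hypnograms, EEG, actigraphy and whole study cohorts.

The generator reproduces the statistical structure the staging pipeline
assumes, with ground truth retained at every level so each downstream stage
has an exact reference:

* hypnograms are samples of the four-state stage Markov chain (defaulting to
  the stager's prior transition matrix, i.e. a 7-h night of 840 30-s epochs
  starting awake);
* EEG is, per epoch, a sum of four band-limited noise components whose
  relative powers are Gaussian draws around the stage's emission mean
  (clipped to >= 0 and renormalized), scaled to unit total variance —
  band-power structure only, no physiological waveform morphology, and no
  continuity guarantee across epoch boundaries;
* actigraphy counts are Poisson per minute, with a higher rate during Wake
  minutes than sleep minutes;
* cohorts follow the crossover design: each subject contributes one night per
  mattress condition (A = fully inflated baseline, S = shoulder-customized,
  SH = shoulder+hip-customized), with a condition effect injected by
  converting Light epochs of the sampled hypnogram to REM (or Light<->Deep)
  until a known boost in minutes is reached — the injected effect is exact by
  construction, so recovery is testable.

Every artifact is a deterministic function of its spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .actigraphy import ActivitySeries
from .features import DEFAULT_BANDS, BandSet
from .hmm import HMMParameters, init_params
from .indices import hypnogram_indices
from .stages import Hypnogram, Stage

__all__ = [
    "GeneratorSpec",
    "CohortSpec",
    "sample_hypnogram",
    "sample_features",
    "synthesize_eeg",
    "synthesize_actigraphy",
    "generate_cohort",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth parameters for one synthetic night.

    Defaults mirror the stager's prior chain (pi0, Q0, mu0) over 840 30-s
    epochs (a 7-h night at 100 Hz). The emission spread defaults to 0.15 so
    adjacent stage means (0.7 vs 0.1 on the discriminating band) sit 4
    standard deviations apart — the separability regime the end-to-end
    accuracy contract assumes.
    """

    pi_true: np.ndarray = None
    q_true: np.ndarray = None
    mu_true: np.ndarray = None
    sigma_true: np.ndarray = None
    sampling_rate_hz: float = 100.0
    epoch_seconds: float = 30.0
    n_epochs: int = 840
    seed: int = 0

    def __post_init__(self) -> None:
        prior = init_params()
        object.__setattr__(
            self, "pi_true",
            np.asarray(self.pi_true if self.pi_true is not None else prior.initial_probs,
                       dtype=float))
        object.__setattr__(
            self, "q_true",
            np.asarray(self.q_true if self.q_true is not None else prior.transition,
                       dtype=float))
        object.__setattr__(
            self, "mu_true",
            np.asarray(self.mu_true if self.mu_true is not None else prior.emission_means,
                       dtype=float))
        object.__setattr__(
            self, "sigma_true",
            np.asarray(self.sigma_true if self.sigma_true is not None
                       else np.full((4, 4), 0.15), dtype=float))
        # reuse the parameter container's validation
        HMMParameters(self.pi_true, self.q_true, self.mu_true, self.sigma_true)
        if self.n_epochs < 2:
            raise ValueError("n_epochs must be >= 2")
        if self.seed is None:
            raise ValueError("seed is mandatory (reproducibility contract)")

    def params(self) -> HMMParameters:
        return HMMParameters(self.pi_true, self.q_true, self.mu_true, self.sigma_true)


def sample_hypnogram(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> Hypnogram:
    """Markov-chain stage sequence of length ``n_epochs``; first state ~ pi."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    states = np.empty(spec.n_epochs, dtype=np.int8)
    states[0] = rng.choice(4, p=spec.pi_true)
    for t in range(1, spec.n_epochs):
        states[t] = rng.choice(4, p=spec.q_true[states[t - 1]])
    return Hypnogram(states, epoch_seconds=spec.epoch_seconds)


def sample_features(
    hyp: Hypnogram, spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Raw Gaussian emission draws for each epoch, shape (n_epochs, 4).

    Emissions are N(mu_true[stage], sigma_true[stage]) per band, unclipped —
    exactly the observation model the HMM assumes, for parameter-recovery
    checks.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    mu = spec.mu_true[hyp.stages]
    sd = spec.sigma_true[hyp.stages]
    return rng.normal(mu, sd)


def _band_noise(n: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise exactly limited to ``band`` (FFT brickwall).

    Sharp spectral edges keep the injected relative band powers exact, so the
    feature extractor's loop-back error reflects only the analysis filter.
    """
    lo, hi = band
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    return x / max(x.std(), 1e-12)


def synthesize_eeg(
    hyp: Hypnogram,
    spec: GeneratorSpec,
    band_set: BandSet | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Band-structured EEG realizing the hypnogram's stage sequence.

    Per epoch, four band-limited noise components are mixed with relative
    powers drawn around ``mu_true[stage]`` (clipped to >= 0, renormalized)
    and the epoch is scaled to unit total variance.
    """
    if spec.sampling_rate_hz < 100:
        raise ValueError("EEG synthesis needs a sampling rate of at least 100 Hz")
    bands = band_set if band_set is not None else DEFAULT_BANDS
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    n = int(round(spec.sampling_rate_hz * hyp.epoch_seconds))
    out = np.empty(len(hyp) * n)
    for e, stage in enumerate(hyp.stages):
        weights = rng.normal(spec.mu_true[stage], spec.sigma_true[stage])
        weights = np.clip(weights, 0.0, None)
        if weights.sum() <= 0:
            weights = np.asarray(spec.mu_true[stage], dtype=float).copy()
        weights = weights / weights.sum()
        epoch = np.zeros(n)
        for b, (_, lo, hi) in enumerate(bands.bands):
            if weights[b] > 0:
                epoch += np.sqrt(weights[b]) * _band_noise(n, (lo, hi),
                                                           spec.sampling_rate_hz, rng)
        epoch /= max(epoch.std(), 1e-12)
        out[e * n : (e + 1) * n] = epoch
    return out


def synthesize_actigraphy(
    hyp: Hypnogram,
    wake_rate: float = 200.0,
    sleep_rate: float = 5.0,
    seed: int = 0,
) -> ActivitySeries:
    """Per-minute Poisson activity counts driven by the hypnogram.

    Counts average ``wake_rate`` during Wake minutes and ``sleep_rate``
    otherwise. The series length equals the hypnogram duration in whole
    minutes.
    """
    if sleep_rate < 0 or wake_rate < sleep_rate:
        raise ValueError("need wake_rate >= sleep_rate >= 0")
    rng = np.random.default_rng(seed)
    n_min = int(hyp.duration_minutes)
    if n_min < 1:
        raise ValueError("hypnogram shorter than one minute")
    # per-minute wake fraction from epoch-resolution sleep/wake
    epochs_per_min = max(1, int(round(60.0 / hyp.epoch_seconds)))
    sw = hyp.sleep_wake()[: n_min * epochs_per_min].reshape(n_min, epochs_per_min)
    is_wake_min = sw.mean(axis=1) < 0.5
    rates = np.where(is_wake_min, wake_rate, sleep_rate)
    return ActivitySeries(rng.poisson(rates).astype(float))


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Crossover study design with exactly known condition effects.

    ``rem_boost_min`` / ``deep_shift_min`` give, per condition, the minutes
    of Light sleep converted to REM / Deep on top of the base chain; the
    injected deltas are exact, so downstream recovery is testable.

    Each subject has a stable base night (one chain sample) shared across
    conditions — the within-subject correlation a paired crossover design
    relies on — and each condition-night independently re-scores a fraction
    ``night_noise`` of epochs from the subject's own stage distribution,
    emulating night-to-night variability. PSQI defaults to a fixed
    ten-subject profile with mean 5.6, range 2–10 and a 5/5 poor/good split
    at the PSQI > 5 cutoff. Subjective depth/length ratings (1–7) are drawn
    around per-condition means.
    """

    n_subjects: int = 10
    conditions: tuple[str, ...] = ("A", "S", "SH")
    rem_boost_min: dict = field(
        default_factory=lambda: {"A": 0.0, "S": 10.0, "SH": 20.0})
    deep_shift_min: dict = field(
        default_factory=lambda: {"A": 0.0, "S": 0.0, "SH": 0.0})
    psqi: tuple[int, ...] = (2, 3, 4, 5, 5, 6, 7, 8, 9, 10)
    subjective_means: dict = field(
        default_factory=lambda: {"A": (5.0, 5.2), "S": (4.7, 4.8), "SH": (4.1, 3.6)})
    subjective_sd: float = 1.3
    night: GeneratorSpec = field(default_factory=GeneratorSpec)
    night_noise: float = 0.10
    wake_rate: float = 200.0
    sleep_rate: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        unknown = set(self.conditions) - {"A", "S", "SH"}
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if len(self.psqi) < self.n_subjects:
            raise ValueError("psqi profile shorter than n_subjects")


def _inject_rem_boost(hyp: Hypnogram, boost_min: float,
                      rng: np.random.Generator, target: Stage = Stage.REM) -> Hypnogram:
    """Convert randomly chosen Light epochs to ``target`` for an exact boost."""
    n_convert = int(round(boost_min * 60.0 / hyp.epoch_seconds))
    if n_convert == 0:
        return hyp
    light_pos = np.flatnonzero(hyp.stages == int(Stage.LIGHT))
    if light_pos.size < n_convert:
        raise ValueError(
            f"cannot inject {boost_min} min: only {light_pos.size} Light epochs"
        )
    chosen = rng.choice(light_pos, size=n_convert, replace=False)
    stages = hyp.stages.copy()
    stages[chosen] = int(target)
    return Hypnogram(stages, epoch_seconds=hyp.epoch_seconds)


def generate_cohort(
    spec: CohortSpec, include_signals: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Full synthetic study: per subject × condition, a night with known truth.

    Returns ``(records, nights)``. ``records`` has one row per subject ×
    condition with subject metadata, subjective ratings and the ground-truth
    hypnogram indices (columns match the study-table layout). ``nights`` maps
    ``(subject_id, condition)`` to a dict with the ground-truth ``hypnogram``,
    the ``activity`` series, and (if ``include_signals``) the synthesized
    ``eeg`` signal.
    """
    root = np.random.SeedSequence(spec.seed)
    rows = []
    nights: dict = {}
    for s_idx in range(spec.n_subjects):
        subject_id = f"S{s_idx + 1:02d}"
        psqi = int(spec.psqi[s_idx])
        subj_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(s_idx,)))
        base_seed = int(subj_rng.integers(0, 2**31 - 1))
        base_night = replace(spec.night, seed=base_seed)
        base_hyp = sample_hypnogram(base_night, rng=subj_rng)
        stage_probs = np.bincount(base_hyp.stages, minlength=4) / len(base_hyp)
        for c_idx, cond in enumerate(spec.conditions):
            child = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(s_idx, c_idx))
            rng = np.random.default_rng(child)
            night_seed = int(rng.integers(0, 2**31 - 1))
            night = replace(spec.night, seed=night_seed)
            # night-to-night variability: re-score a fraction of epochs from
            # the subject's own stage distribution
            stages = base_hyp.stages.copy()
            flip = rng.random(len(base_hyp)) < spec.night_noise
            stages[flip] = rng.choice(4, size=int(flip.sum()), p=stage_probs)
            hyp = Hypnogram(stages, epoch_seconds=base_hyp.epoch_seconds)
            hyp = _inject_rem_boost(
                hyp, spec.rem_boost_min.get(cond, 0.0), rng, target=Stage.REM)
            deep_shift = spec.deep_shift_min.get(cond, 0.0)
            if deep_shift:
                hyp = _inject_rem_boost(hyp, deep_shift, rng, target=Stage.DEEP)
            activity = synthesize_actigraphy(
                hyp, wake_rate=spec.wake_rate, sleep_rate=spec.sleep_rate,
                seed=int(rng.integers(0, 2**31 - 1)))
            idx = hypnogram_indices(hyp)
            depth_mu, length_mu = spec.subjective_means.get(cond, (4.5, 4.5))
            depth = int(np.clip(round(rng.normal(depth_mu, spec.subjective_sd)), 1, 7))
            length = int(np.clip(round(rng.normal(length_mu, spec.subjective_sd)), 1, 7))
            rows.append(
                {
                    "subject_id": subject_id,
                    "condition": cond,
                    "psqi": psqi,
                    "depth": depth,
                    "length": length,
                    **idx.as_dict(),
                }
            )
            entry = {"hypnogram": hyp, "activity": activity, "spec": night}
            if include_signals:
                entry["eeg"] = synthesize_eeg(hyp, night, rng=rng)
            nights[(subject_id, cond)] = entry
    return pd.DataFrame(rows), nights
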