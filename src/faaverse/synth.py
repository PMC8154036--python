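"""Synthetic multi-study resting-EEG generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without the original recordings: five studies with
heterogeneous group designs, 1/f background plus alpha-band oscillations with
subject-varying peak frequency, an injectable right-minus-left frontal
asymmetry effect tied to diagnosis or questionnaire score, confounds
correlated with depression status, per-study scale differences, and
bad-segment masks.

The injection contract: with ``asymmetry_effect_d = d`` the population
Cohen's d of pipeline-measured FAA (log right minus log left alpha power)
between diagnosed and healthy subjects equals ``d`` in expectation (negative
d = relatively more left alpha power in the diagnosed group, the classical
pattern); with ``score_faa_r = r`` the FAA-score correlation equals ``r``.
The effect is injected as an alpha-amplitude gain imbalance on frontal
channels only; alpha must therefore dominate frontal band power for the
contract to hold, which the defaults ensure (see docs/methods.md).

Each channel's alpha oscillator has its own random phase and amplitude
envelope.  This deliberately omits volume-conduction coherence: with
incoherent channels, common-average re-referencing leaks only O(1/N^2) of the
other channels' alpha power into a given channel, so the injected asymmetry
survives re-referencing essentially unchanged.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cluster import grid_adjacency
from .datasets import (
    GROUPS,
    RawStudy,
    SourceDataset,
    SpectralDataset,
    validate_meta,
)
from .layouts import ChannelLayout, channel_side, make_standard_layout

__all__ = [
    "ConfoundModel",
    "StudyConfig",
    "generate_metadata",
    "generate_study",
    "generate_multistudy",
    "generate_band_power",
    "generate_source_surrogate",
    "default_study_configs",
]

# Broadband range over which the 1/f background is normalized to unit power;
# shared by the time-series and band-power generators so both dilute the
# injected alpha asymmetry identically.
_BROADBAND = (0.5, 125.0)

# Alpha amplitude topography by channel-label row (posterior-dominant).
_TOPO_BY_PREFIX = {
    "Fp": 0.45, "AF": 0.48, "F": 0.5,
    "T": 0.6, "C": 0.7,
    "P": 1.0, "O": 1.0,
}


def _topo_weight(name: str) -> float:
    for prefix in ("Fp", "AF", "F", "T", "C", "P", "O"):
        if name.startswith(prefix):
            return _TOPO_BY_PREFIX[prefix]
    return 0.6


@dataclass(frozen=True)
class ConfoundModel:
    """Group-dependent confound distributions (age/gender/education).

    Defaults loosely match the age gap between diagnosed and control groups
    in Study I and the lower education of the diagnosed group in Study V.
    ``missing_rate`` nulls out all confounds for that fraction of subjects to
    exercise listwise-drop rules downstream.
    """

    age_mean: dict = field(default_factory=lambda: {
        "diagnosed": 28.0, "subclinical": 25.0, "healthy": 24.0, "unclassified": 25.0})
    age_sd: float = 6.0
    male_prob: dict = field(default_factory=lambda: {
        "diagnosed": 0.33, "subclinical": 0.30, "healthy": 0.45, "unclassified": 0.40})
    education_mean: dict = field(default_factory=lambda: {
        "diagnosed": 13.5, "subclinical": 14.5, "healthy": 15.0, "unclassified": 14.5})
    education_sd: float = 2.5
    missing_rate: float = 0.0


@dataclass(frozen=True)
class StudyConfig:
    """Full recipe for one synthetic study.

    asymmetry_effect_d : target Cohen's d of FAA between diagnosed and
        healthy (negative = classical left-sided FAA).
    score_faa_r : target FAA-score Pearson correlation (linear design).
    faa_sd : between-subject SD of the latent FAA (log-power units); varies
        across the default studies so the cross-study Levene scale gate has
        something to detect.
    symmetric_effect : inject the latent effect as a bilateral frontal alpha
        power modulation instead of a left/right imbalance (exercises the
        standardized analysis and the chi-square asymmetry follow-up).
    alpha_channel_jitter : SD (Hz) of the per-channel offset around the
        subject's alpha peak.  Besides being realistic, the jitter keeps the
        channel oscillators mutually incoherent, so the alpha component of
        the common average does not interfere coherently with any single
        channel's alpha and the injected asymmetry survives re-referencing.
    """

    study_id: str
    n_per_group: dict
    sfreq: float = 250.0
    duration: float = 300.0
    channel_layout: ChannelLayout | None = None
    asymmetry_effect_d: float = 0.0
    score_faa_r: float = 0.0
    alpha_peak_mean: float = 10.5
    alpha_peak_sd: float = 0.8
    alpha_channel_jitter: float = 0.25
    alpha_amp_mean: float = 2.5
    alpha_amp_sd: float = 0.5
    noise_exponent: float = 1.0
    power_scale: float = 1.0
    faa_sd: float = 0.4
    confound_model: ConfoundModel = field(default_factory=ConfoundModel)
    bad_segment_rate: float = 0.05
    symmetric_effect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {g: int(self.n_per_group.get(g, 0)) for g in GROUPS}
        if any(v < 0 for v in counts.values()):
            raise ValueError("group counts must be >= 0")
        if sum(counts.values()) == 0:
            raise ValueError("empty study: zero subjects in every group")
        object.__setattr__(self, "n_per_group", counts)
        n_samp = self.duration * self.sfreq
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration * sfreq must be an integer sample count")
        lo = self.alpha_peak_mean - 3 * self.alpha_peak_sd
        hi = self.alpha_peak_mean + 3 * self.alpha_peak_sd
        if not (8.0 < lo and hi < 13.0):
            raise ValueError("alpha peak mean +/- 3 sd must lie inside (8, 13) Hz")
        if self.power_scale <= 0:
            raise ValueError("power_scale must be > 0")
        if not (0.0 <= self.bad_segment_rate < 1.0):
            raise ValueError("bad_segment_rate must be in [0, 1)")
        if self.channel_layout is None:
            object.__setattr__(self, "channel_layout", make_standard_layout())

    @property
    def n_subjects(self) -> int:
        return sum(self.n_per_group.values())


def _study_rng(config: StudyConfig, stream: str) -> np.random.Generator:
    """Deterministic, study- and purpose-specific random stream."""
    tag = hashlib.blake2s(f"{config.study_id}/{stream}".encode()).digest()[:4]
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int.from_bytes(tag, "little")])
    )


def generate_metadata(config: StudyConfig) -> pd.DataFrame:
    """Draw the subject table: groups, questionnaire scores, confounds.

    Scores respect the group definitions (healthy <= 5, subclinical >= 10,
    unclassified in between); confounds follow the group-dependent
    distributions of ``config.confound_model``.
    """
    rng = _study_rng(config, "meta")
    cm = config.confound_model
    rows = []
    i = 0
    for group in GROUPS:
        for _ in range(config.n_per_group[group]):
            if group == "healthy":
                score = min(5, rng.poisson(2.0))
            elif group == "subclinical":
                score = 10 + rng.poisson(8.0)
            elif group == "diagnosed":
                score = int(np.clip(round(rng.normal(21.0, 8.0)), 0, 60))
            else:
                score = int(rng.integers(6, 10))
            age = float(np.clip(rng.normal(cm.age_mean[group], cm.age_sd), 16, 75))
            gender = "male" if rng.random() < cm.male_prob[group] else "female"
            education = float(
                np.clip(rng.normal(cm.education_mean[group], cm.education_sd), 6, 22)
            )
            rows.append({
                "subject_id": f"{config.study_id}-{i:03d}",
                "study_id": config.study_id,
                "group": group,
                "score": int(score),
                "age": round(age, 1),
                "gender": gender,
                "education": round(education, 1),
            })
            i += 1
    meta = pd.DataFrame(rows)
    if cm.missing_rate > 0:
        drop = rng.random(len(meta)) < cm.missing_rate
        meta.loc[drop, ["age", "education"]] = np.nan
        meta.loc[drop, "gender"] = None
    return validate_meta(meta)


def _latent_faa(config: StudyConfig, meta: pd.DataFrame,
                rng: np.random.Generator) -> np.ndarray:
    """Per-subject latent FAA (log-power units) realizing the injection targets."""
    d, r, sd = config.asymmetry_effect_d, config.score_faa_r, config.faa_sd
    score = meta["score"].to_numpy(float)
    z = np.zeros_like(score)
    if score.std() > 0:
        z = (score - score.mean()) / score.std()
    is_diag = (meta["group"] == "diagnosed").to_numpy(float)
    eps = rng.standard_normal(len(meta))
    return sd * (d * is_diag + r * z + math.sqrt(max(0.0, 1.0 - r * r)) * eps)


def _frontal_gains(config: StudyConfig, layout: ChannelLayout,
                   latent: np.ndarray) -> np.ndarray:
    """(n_subjects, n_channels) alpha-amplitude gains implementing the effect.

    Lateral asymmetric injection: right frontal x exp(+a/4), left frontal
    x exp(-a/4); power ratio R/L then equals exp(a) when alpha dominates the
    band, so measured FAA tracks the latent ``a``.  Symmetric mode scales all
    frontal channels (midline included) by exp(a/4) instead.
    """
    gains = np.ones((len(latent), layout.n_channels))
    frontal = set(layout.frontal_subset)
    for c, name in enumerate(layout.names):
        if name not in frontal:
            continue
        side = channel_side(name)
        if config.symmetric_effect:
            gains[:, c] = np.exp(latent / 4.0)
        elif side == "right":
            gains[:, c] = np.exp(latent / 4.0)
        elif side == "left":
            gains[:, c] = np.exp(-latent / 4.0)
    return gains


def _one_over_f_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                      sfreq: float, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise per channel."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    scale = np.empty_like(freqs)
    scale[0] = 0.0  # no DC
    with np.errstate(divide="ignore"):
        scale[1:] = np.maximum(freqs[1:], _BROADBAND[0]) ** (-exponent / 2.0)
    noise = np.fft.irfft(spec * scale, n=n_samp, axis=-1)
    noise /= noise.std(axis=-1, keepdims=True)
    return noise


def _slow_envelope(rng: np.random.Generator, n_ch: int, n_samp: int,
                   sfreq: float, cutoff: float = 2.0, depth: float = 0.5) -> np.ndarray:
    """Positive slow amplitude envelopes, mean ~1 (sets the alpha peak width)."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    spec[:, freqs > cutoff] = 0.0
    slow = np.fft.irfft(spec, n=n_samp, axis=-1)
    sd = slow.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    slow /= sd
    return np.clip(1.0 + depth * slow, 0.05, None)


def _draw_bad_mask(rng: np.random.Generator, n_subjects: int, n_seg: int,
                   rate: float) -> np.ndarray:
    mask = rng.random((n_subjects, n_seg)) < rate
    # keep every subject analyzable: redraw rows that lost more than half
    for s in range(n_subjects):
        for _ in range(100):
            if mask[s].mean() <= 0.5:
                break
            mask[s] = rng.random(n_seg) < rate
    return mask


def generate_study(config: StudyConfig) -> RawStudy:
    """Synthesize one study's continuous multichannel recording.

    Per subject: 1/f background noise plus per-channel alpha oscillators
    (subject-specific peak frequency and amplitude, posterior-dominant
    topography, independent phases and slow envelopes), frontal gain
    imbalance injecting the configured FAA effect, everything scaled by
    sqrt(power_scale).  Deterministic given the config (including seed).
    """
    layout = config.channel_layout
    meta = generate_metadata(config)
    rng = _study_rng(config, "signal")
    latent = _latent_faa(config, meta, rng)
    gains = _frontal_gains(config, layout, latent)

    n_sub = config.n_subjects
    n_ch = layout.n_channels
    n_samp = int(round(config.duration * config.sfreq))
    topo = np.array([_topo_weight(n) for n in layout.names])

    lo = max(8.0 + 1e-6, config.alpha_peak_mean - 3 * config.alpha_peak_sd)
    hi = min(13.0 - 1e-6, config.alpha_peak_mean + 3 * config.alpha_peak_sd)
    t = np.arange(n_samp) / config.sfreq

    data = np.empty((n_sub, n_ch, n_samp))
    amp_floor = 0.2 * config.alpha_amp_mean
    for s in range(n_sub):
        f_peak = float(np.clip(
            rng.normal(config.alpha_peak_mean, config.alpha_peak_sd), lo, hi))
        amp_s = max(amp_floor, rng.normal(config.alpha_amp_mean, config.alpha_amp_sd))
        bg = _one_over_f_noise(rng, n_ch, n_samp, config.sfreq, config.noise_exponent)
        env = _slow_envelope(rng, n_ch, n_samp, config.sfreq)
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        f_chan = np.clip(f_peak + config.alpha_channel_jitter
                         * rng.standard_normal(n_ch), 8.05, 12.95)
        carrier = np.sin(2 * np.pi * f_chan[:, None] * t[None, :] + phases[:, None])
        amps = amp_s * topo * gains[s]
        data[s] = bg + amps[:, None] * env * carrier
    data *= math.sqrt(config.power_scale)

    n_seg = int(math.floor(config.duration))
    mask = _draw_bad_mask(_study_rng(config, "mask"), n_sub, n_seg,
                          config.bad_segment_rate)
    return RawStudy(data=data, sfreq=config.sfreq, layout=layout,
                    bad_mask=mask, meta=meta, study_id=config.study_id)


def generate_multistudy(configs: list[StudyConfig]) -> list[RawStudy]:
    """Generate several studies with independent random streams.

    Study ids must be distinct; streams are keyed by (seed, study_id) so two
    configs sharing a seed still produce different data.
    """
    ids = [c.study_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study_id in configs")
    return [generate_study(c) for c in configs]


def _spectral_model_power(config: StudyConfig, meta: pd.DataFrame,
                          latent: np.ndarray, freqs: np.ndarray,
                          rng: np.random.Generator,
                          ln_noise_sd: float = 0.15) -> np.ndarray:
    """Draw (subjects, channels, freqs) power directly from the spectral model."""
    layout = config.channel_layout
    gains = _frontal_gains(config, layout, latent)
    topo = np.array([_topo_weight(n) for n in layout.names])
    n_sub, n_ch, n_f = len(meta), layout.n_channels, len(freqs)

    # background density: unit total power over the broadband range
    exp = config.noise_exponent
    f0, f1 = _BROADBAND
    if abs(exp - 1.0) < 1e-12:
        total = math.log(f1 / f0)
    else:
        total = (f1 ** (1 - exp) - f0 ** (1 - exp)) / (1 - exp)
    bg_density = np.maximum(freqs, f0) ** (-exp) / total

    lo = max(8.0 + 1e-6, config.alpha_peak_mean - 3 * config.alpha_peak_sd)
    hi = min(13.0 - 1e-6, config.alpha_peak_mean + 3 * config.alpha_peak_sd)
    f_peak = np.clip(rng.normal(config.alpha_peak_mean, config.alpha_peak_sd, n_sub),
                     lo, hi)
    amp_floor = 0.2 * config.alpha_amp_mean
    amp = np.maximum(amp_floor,
                     rng.normal(config.alpha_amp_mean, config.alpha_amp_sd, n_sub))

    width = 0.8  # Hz, matches the slow-envelope spectral broadening
    bump = np.exp(-0.5 * ((freqs[None, :] - f_peak[:, None]) / width) ** 2)
    bump /= bump.sum(axis=1, keepdims=True) * (freqs[1] - freqs[0])
    # total alpha power per channel: (amp * topo * gain)^2 * E[env^2] / 2
    alpha_total = (amp[:, None] * topo[None, :] * gains) ** 2 * 1.25 / 2.0
    power = bg_density[None, None, :] + alpha_total[:, :, None] * bump[:, None, :]
    power *= config.power_scale
    power *= np.exp(ln_noise_sd * rng.standard_normal((n_sub, n_ch, n_f)))
    return power


def generate_band_power(config: StudyConfig, space: str = "avg",
                        freqs: np.ndarray | None = None) -> SpectralDataset:
    """Shortcut generator: draw spectral power directly, skipping time series.

    Same effect-injection contract as :func:`generate_study`; used for
    statistics-layer tests and as a surrogate for externally supplied signal
    spaces (``space='csd'`` or similar), where it is labelled accordingly.
    """
    if freqs is None:
        freqs = np.arange(1.0, 30.0 + 1e-9, 0.5)
    meta = generate_metadata(config)
    rng = _study_rng(config, f"bandpower/{space}")
    latent = _latent_faa(config, meta, rng)
    power = _spectral_model_power(config, meta, latent, np.asarray(freqs, float), rng)
    return SpectralDataset(power=power, freqs=np.asarray(freqs, float),
                           layout=config.channel_layout, meta=meta, space=space,
                           study_id=config.study_id)


def generate_source_surrogate(config: StudyConfig, n_rows: int = 6,
                              n_cols: int = 5) -> SourceDataset:
    """Synthetic stand-in for hemisphere-differenced source-space FAA values.

    A beamformer pipeline would produce right-minus-left log alpha power per
    mirrored cortical vertex; this surrogate places the latent FAA effect on a
    small frontal lattice (stronger on an anterior patch) plus vertex noise.
    """
    meta = generate_metadata(config)
    rng = _study_rng(config, "source")
    latent = _latent_faa(config, meta, rng)
    graph = grid_adjacency(n_rows, n_cols)
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    profile = 0.3 + 0.7 * np.exp(-0.5 * ((rows - 1) ** 2 + (cols - (n_cols - 1) / 2) ** 2) / 2.0)
    values = latent[:, None] * profile[None, :] + rng.normal(
        0.0, config.faa_sd, (len(meta), n_rows * n_cols))
    node_ids = tuple(f"v{r}_{c}" for r, c in zip(rows, cols))
    return SourceDataset(values=values, node_ids=node_ids, adjacency=graph,
                         meta=meta, space="src", study_id=config.study_id)


def default_study_configs(seed: int = 0) -> list[StudyConfig]:
    """The five default studies: group designs mirror the published cohorts.

    Study I: 29 diagnosed vs 22 healthy; Study II: 28 healthy / 25
    subclinical / 23 unclassified; Study III: 27 / 21 / 34 / 9; Study IV:
    22 / 72 / 21 / 2; Study V: 24 diagnosed vs 29 healthy.  Sampling rates
    and eyes-closed rest durations follow each study's acquisition; FAA
    dispersion varies across studies so the pooling scale gate is non-trivial.
    Injected effects default to zero (the null world).
    """
    specs = [
        ("I", {"diagnosed": 29, "healthy": 22}, 512.0, 300.0, 0.30),
        ("II", {"healthy": 28, "subclinical": 25, "unclassified": 23}, 200.0, 300.0, 0.50),
        ("III", {"diagnosed": 27, "healthy": 21, "subclinical": 34, "unclassified": 9},
         250.0, 180.0, 0.35),
        ("IV", {"diagnosed": 22, "healthy": 72, "subclinical": 21, "unclassified": 2},
         512.0, 180.0, 0.45),
        ("V", {"diagnosed": 24, "healthy": 29}, 250.0, 300.0, 0.60),
    ]
    return [
        StudyConfig(study_id=sid, n_per_group=groups, sfreq=sf, duration=dur,
                    faa_sd=faa_sd, seed=seed)
        for sid, groups, sf, dur, faa_sd in specs
    ]


def scaled_configs(configs: list[StudyConfig], subject_scale: float = 1.0,
                   duration: float | None = None,
                   sfreq: float | None = None) -> list[StudyConfig]:
    """Shrink studies for desk-scale runs (at least 2 kept per nonempty group)."""
    out = []
    for c in configs:
        groups = {g: (max(2, round(n * subject_scale)) if n else 0)
                  for g, n in c.n_per_group.items()}
        kwargs: dict = {"n_per_group": groups}
        if duration is not None:
            kwargs["duration"] = duration
        if sfreq is not None:
            kwargs["sfreq"] = sfreq
        out.append(replace(c, **kwargs))
    return out
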