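"""Synthetic SEEG session generator.

Emulates the data model the decoding pipeline assumes: a continuous
multichannel recording at 2 kHz with an instructed-speed reaching task
(two instructed speeds, ~20% perturbed trials, variable movement durations),
where the log band power of chosen channel×band pairs varies linearly with
the trial's normalized speed.

Signal model
------------
Every (channel, band) pair carries an independent band-limited Gaussian
carrier (spectrally flat inside the band's half-open range, zero outside)
riding on broadband white noise.  The carrier's log amplitude follows a
piecewise envelope process ``z(t)``:

* for non-informative pairs, ``z`` is piecewise-constant over short
  segments drawn i.i.d. normal through the whole session — ongoing power
  fluctuations with no relation to the task (see ``_envelope_z`` for why
  null envelopes are deliberately not trial-locked);
* for informative pairs the same segment process runs between movements,
  but during each trial's movement window (MoveOnset − 100 ms to
  HitTarget, so that every spectrogram bin labelled inside the window is
  covered) ``z = y_t + jitter_t``, with ``y_t`` the trial's normalized
  speed.

Instantaneous carrier power is proportional to ``exp(γ·z(t))``, so the
natural-log band power is linear in ``z`` with modulation depth γ.  Because
the spectrogram z-scores log power per frequency over the whole session, the
slope of the resulting z-power feature against ``y`` equals
``γ / sd_session(γ·z)`` — the generator therefore sets the rest-segment
variance so that the session-wide variance of ``z`` is ``1/effect²``, which
realizes a configured effect size in z-power units per unit normalized speed
(up to a small spectral-estimation attenuation; see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy.ndimage import uniform_filter1d

from . import behavior
from .bands import BAND_ORDER, BANDS

# Empirical slope-calibration factors: the ratio of the realized z-power
# slope to the configured effect under the default envelope parameters,
# estimated by regression over repeated 200-trial sessions.  The shortfall
# comes from spectral-estimation noise and neighbour-band carrier leakage
# inflating the session z-score denominator; the generator divides the design
# effect by these factors so the realized slope matches the configured one.
_BAND_SLOPE_CAL = {
    "theta": 0.93,
    "alpha": 0.70,
    "beta": 0.76,
    "low_gamma": 0.86,
    "high_gamma": 0.89,
    "hyper_gamma": 0.86,
}

# region vocabulary: (label, hemisphere); cycled over channels
REGION_VOCAB = (
    ("hippocampus", "R"),
    ("middle temporal gyrus", "L"),
    ("intraparietal sulcus", "L"),
    ("intraparietal sulcus", "R"),
    ("fusiform gyrus", "L"),
    ("superior temporal gyrus", "R"),
    ("insula", "L"),
    ("amygdala", "R"),
    ("posterior cingulate", "L"),
    ("orbitofrontal cortex", "R"),
    ("supramarginal gyrus", "L"),
    ("parahippocampal gyrus", "R"),
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_channels: int = 40
    n_trials: int = 120
    fs: float = 2000.0
    informative_pairs: tuple = ()  # (channel index, band name, effect size)
    noise_sd: float = 1.0
    speed_logmean: float = -0.7
    speed_logsd: float = 0.5
    perturbed_fraction: float = 0.20
    incomplete_fraction: float = 0.05
    movement_duration_range: tuple = (0.4, 2.5)
    inter_trial_gap_range: tuple = (0.9, 1.3)
    target_distance: float = 0.15  # m
    calibration_speed: float = 0.35  # m/s
    trial_power_jitter_sd: float = 1.85  # sd of per-trial log-power excursions / γ
    log_power_depth: float = 1.2  # γ: ln-power units per unit envelope z
    carrier_snr: float = 400.0  # carrier-to-broadband in-band power ratio at z=0
    rest_segment_s: float = 0.2
    pad_s: float = 3.0
    handedness: str = "R"
    n_artifact_channels: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_trials < 10:
            raise ConfigError("n_trials must be at least 10")
        if not self.fs > 2 * 200.0:
            raise ConfigError("fs must exceed twice the 200 Hz analysis ceiling")
        if not (0 <= self.perturbed_fraction < 1):
            raise ConfigError("perturbed_fraction must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.handedness not in ("L", "R"):
            raise ConfigError("handedness must be 'L' or 'R'")
        for pair in self.informative_pairs:
            ch, band, eff = pair
            if not (0 <= int(ch) < self.n_channels):
                raise ConfigError(f"informative pair references invalid channel {ch}")
            if band not in BANDS:
                raise ConfigError(f"informative pair references unknown band {band!r}")
            if not np.isfinite(eff) or eff == 0:
                raise ConfigError(f"effect size {eff!r} must be finite and nonzero")


@dataclass
class SessionBundle:
    """One recording session: signal + channel metadata + trial table."""

    signal: np.ndarray  # channels × samples, float32
    fs: float
    channel_table: pd.DataFrame  # name, region_label, hemisphere, artifact_flag
    trial_table: pd.DataFrame  # trial_id, instruction, perturbed, completed, ...
    handedness: str
    ground_truth: dict | None = None  # synthetic only

    @property
    def duration(self) -> float:
        return self.signal.shape[1] / self.fs

    def validate(self) -> None:
        tt = self.trial_table
        if tt["trial_id"].duplicated().any():
            dup = tt.loc[tt["trial_id"].duplicated(), "trial_id"].iloc[0]
            raise ValueError(f"duplicate trial_id {dup}")
        bad = tt[tt["hit_target"] <= tt["move_onset"]]
        if len(bad):
            raise ValueError(
                f"trial {bad['trial_id'].iloc[0]}: HitTarget <= MoveOnset")
        if (tt["move_onset"].min() < 0) or (tt["hit_target"].max() > self.duration):
            raise ValueError("event times fall outside the recorded signal")
        if len(self.channel_table) != self.signal.shape[0]:
            raise ValueError("channel table does not match signal channel count")


def make_channel_table(n_channels: int, n_artifact: int = 0) -> pd.DataFrame:
    rows = []
    for c in range(n_channels):
        region, hemi = REGION_VOCAB[c % len(REGION_VOCAB)]
        rows.append({
            "name": f"ch{c:02d}",
            "region_label": region,
            "hemisphere": hemi,
            "artifact_flag": c >= n_channels - n_artifact,
        })
    return pd.DataFrame(rows)


def _draw_trials(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_trials
    raw_ratio = np.minimum(
        np.exp(rng.normal(config.speed_logmean, config.speed_logsd, size=n)), 1.0)
    gaps = rng.uniform(*config.inter_trial_gap_range, size=n)
    perturbed = rng.random(n) < config.perturbed_fraction
    completed = rng.random(n) >= config.incomplete_fraction
    # movement time follows from the intended speed, clipped to plausible range
    natural = config.target_distance / config.calibration_speed
    duration = np.clip(natural / raw_ratio, *config.movement_duration_range)
    ratio = np.minimum(natural / duration, 1.0)
    onset = np.empty(n)
    t = config.pad_s
    for i in range(n):
        t += gaps[i]
        onset[i] = t
        t += duration[i]
    instruction = np.where(ratio >= math.exp(config.speed_logmean), "fast", "slow")
    return pd.DataFrame({
        "trial_id": np.arange(n),
        "instruction": instruction,
        "perturbed": perturbed,
        "completed": completed,
        "calibration_speed": config.calibration_speed,
        "target_distance": config.target_distance,
        "move_onset": onset,
        "hit_target": onset + duration,
    })


# carriers occupy the central portion of each band (inset by this fraction of
# the band's log-width per side) so that wavelets centred in one band respond
# only weakly to the neighbouring bands' carriers
_CARRIER_EDGE_INSET = 0.15


def _band_carrier(band, n: int, fs: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise spectrally flat on the band's inset core, variance sd²."""
    # synthesize at a 5-smooth length and truncate (plain n can be a slow FFT size)
    nf = _next_smooth(n)
    nbins = nf // 2 + 1
    fgrid = np.arange(nbins) * fs / nf
    ratio = (band.hi / band.lo) ** _CARRIER_EDGE_INSET
    sel = (fgrid >= band.lo * ratio) & (fgrid < band.hi / ratio)
    spec = np.zeros(nbins, dtype=np.complex128)
    k = int(sel.sum())
    spec[sel] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = sfft.irfft(spec, nf)[:n]
    return x * (sd / x.std())


def _next_smooth(n: int) -> int:
    k = n
    while True:
        r = k
        for p in (2, 3, 5):
            while r % p == 0:
                r //= p
        if r == 1:
            return k
        k += 1


def _envelope_z(config: SimulationConfig, trials: pd.DataFrame, n: int,
                mov_values: np.ndarray | None, rest_sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """Piecewise envelope process z(t).

    With ``mov_values`` (informative pairs): i.i.d. segment values between
    movements and one trial-locked value per movement window.  Without
    (null pairs): the segment process runs through the whole session, so the
    envelope's step-boundary density — and with it the small convexity bias
    of log power near amplitude steps — is uniform in time instead of tied
    to the y-dependent movement durations.
    """
    fs = config.fs
    seg = max(int(round(config.rest_segment_s * fs)), 1)
    nseg = -(-n // seg)
    z = np.repeat(rng.normal(0.0, rest_sd, size=nseg), seg)[:n]
    if mov_values is not None:
        pre = 0.1  # envelope leads MoveOnset so every in-window bin is covered
        for i, row in enumerate(trials.itertuples()):
            a = max(int(round((row.move_onset - pre) * fs)), 0)
            b = min(int(round(row.hit_target * fs)) + 1, n)
            z[a:b] = mov_values[i]
    # short smoothing avoids step discontinuities in the log-amplitude
    return uniform_filter1d(z, size=41, mode="nearest")


def generate_session(config: SimulationConfig) -> SessionBundle:
    """Deterministically generate a SessionBundle from a SimulationConfig."""
    rng = np.random.default_rng(config.rng_seed)
    trials = _draw_trials(config, rng)
    fs = config.fs
    n = int(math.ceil((trials["hit_target"].iloc[-1] + config.pad_s) * fs))

    # ground-truth normalized speeds: constants from the modeled subset,
    # applied to every trial
    modeled = trials[trials["completed"] & ~trials["perturbed"]]
    if len(modeled) < 10:
        raise ConfigError("fewer than 10 completed, unperturbed trials")
    _, norm = behavior.normalize_speeds(_ratios(modeled, config))
    y_all = (np.log(_ratios(trials, config)) - norm.log_mean) / norm.log_sd

    # movement-window fraction of the session (envelope lead included)
    durations = (trials["hit_target"] - trials["move_onset"]).to_numpy() + 0.1
    m_frac = float(durations.sum() * fs / n)
    jit2 = config.trial_power_jitter_sd ** 2

    informative = {(int(c), b): float(e) for c, b, e in config.informative_pairs}
    gamma = config.log_power_depth
    sig = np.empty((config.n_channels, n), dtype=np.float32)
    for c in range(config.n_channels):
        x = rng.standard_normal(n) * config.noise_sd
        for bname in BAND_ORDER:
            band = BANDS[bname]
            carrier_sd = math.sqrt(config.carrier_snr * config.noise_sd ** 2
                                   * (band.hi - band.lo) / (fs / 2))
            carrier = _band_carrier(band, n, fs, carrier_sd, rng)
            eff = informative.get((c, bname))
            if eff is None:
                mov = None
                rest_sd = math.sqrt(1.0 + jit2)
            else:
                eff_design = eff / _BAND_SLOPE_CAL[bname]
                target_var = 1.0 / eff_design ** 2
                rest_var = (target_var - m_frac * (1.0 + jit2)) / (1.0 - m_frac)
                if rest_var <= 0.01:
                    raise ConfigError(
                        f"effect size {eff:g} for channel {c} band {bname} is too "
                        f"large to realize (movement fraction {m_frac:.2f}, "
                        f"jitter sd {config.trial_power_jitter_sd:g})")
                jitter = rng.normal(0.0, config.trial_power_jitter_sd,
                                    size=len(trials))
                mov = np.sign(eff) * (y_all + jitter)
                rest_sd = math.sqrt(rest_var)
            z = _envelope_z(config, trials, n, mov, rest_sd, rng)
            x += carrier * np.exp(0.5 * gamma * z)
        sig[c] = x.astype(np.float32)

    bundle = SessionBundle(
        signal=sig,
        fs=fs,
        channel_table=make_channel_table(config.n_channels,
                                         config.n_artifact_channels),
        trial_table=trials,
        handedness=config.handedness,
        ground_truth={
            "informative_pairs": [
                {"channel": f"ch{int(c):02d}", "band": b, "effect": float(e)}
                for c, b, e in config.informative_pairs
            ],
            "normalized_speed": y_all.tolist(),
            "speed_norm": {"log_mean": norm.log_mean, "log_sd": norm.log_sd},
            "modeled_trial_ids": modeled["trial_id"].tolist(),
        },
    )
    bundle.validate()
    return bundle


def _ratios(trials: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    return np.array([
        behavior.compute_trial_speed(config.target_distance, row.move_onset,
                                     row.hit_target, config.calibration_speed)
        for row in trials.itertuples()
    ])
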