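"""Synthetic populations, trials, traces and channel signals.

Emulates the statistical structure of a two-photon sound-level experiment:
each neuron is monotonic (sigmoid tuning) or nonmonotonic (Gaussian tuning)
with parameters drawn around the mean fitted parameters of the recorded
populations; optogenetic activation of SST or VIP interneurons shifts those
parameters the way the recorded means shift between no and high laser power
(SST: sigmoid midpoints move up, Gaussian amplitudes shrink; VIP: amplitudes
grow and Gaussian tuning broadens).  Trial responses are tuning-curve means
plus Gaussian noise; frame-level traces wrap each trial response in a
calcium-like kernel on top of baseline noise; channel signals emulate
GCaMP-to-red bleedthrough with elevated red fluorescence in opsin-tagged
interneurons.

Every stage draws from per-neuron seeded substreams, so outputs are
bit-reproducible and stable under population subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import evaluate_model
from .tables import LASERS, validate_response_table
from .traces import TraceSet
from .twocell import TwoCellConfig

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "ChannelSignals",
    "generate_population",
    "generate_traces",
    "generate_channel_signals",
]

_DEFAULT_LEVELS = (0.0, 30.0, 50.0, 60.0, 70.0, 80.0, 90.0)

# substream tags
_PARAMS, _TRIALS, _TRACES, _CHANNELS = 0, 1, 2, 3


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic experiment.

    activated selects which interneuron class the laser drives: "sst" or
    "vip" apply the corresponding parameter shifts at medium (half) and high
    (full) laser power; "control" applies no laser effect.  noise_sd is the
    per-trial additive response noise in dF/Fstd units; param_sd_frac the
    population dispersion of tuning parameters as a fraction of each mean.
    """

    n_neurons: int = 100
    frac_monotonic: float = 0.5
    levels: tuple[float, ...] = _DEFAULT_LEVELS
    lasers: tuple[str, ...] = LASERS
    n_trials: int = 10
    noise_sd: float = 0.15
    heteroscedastic: bool = False
    frac_tagged: float = 0.1
    bleedthrough_coef: float = 0.3
    frame_rate: float = 30.0
    onset_delay_s: float = 0.3
    activated: str = "sst"
    param_sd_frac: float = 0.2
    channel_noise_sd: float = 2.0
    tag_elevation_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        for name in ("frac_monotonic", "frac_tagged"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.levels) == 0 or 0.0 not in self.levels:
            raise ValueError("levels must be non-empty and contain 0 dB")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be sorted ascending")
        if self.activated not in ("sst", "vip", "control"):
            raise ValueError(f"activated must be sst|vip|control, got {self.activated}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters behind a synthetic population.

    kinds[i] is "sigmoid" or "gaussian"; params[i][laser] the 4-tuple for
    neuron i under that laser condition; tagged[i] flags opsin-expressing
    interneurons.
    """

    kinds: tuple[str, ...]
    params: tuple[dict[str, tuple[float, float, float, float]], ...]
    tagged: np.ndarray = field(compare=False)


def _rng(seed: int, tag: int, neuron: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag, neuron])


def _condition_shift(kind: str, activated: str) -> np.ndarray:
    """Full-power parameter shift (high laser minus none) for one tuning kind."""
    if activated == "control":
        return np.zeros(4)
    cond = activated.upper()
    tc = TwoCellConfig()
    base = tc.sigmoid if kind == "sigmoid" else tc.gaussian
    return np.array(base[cond].as_tuple()) - np.array(base["none"].as_tuple())


def _laser_scale(laser: str) -> float:
    # medium laser power produces roughly half the high-power parameter shift
    return {"none": 0.0, "medium": 0.5, "high": 1.0}[laser]


def _draw_base_params(kind: str, rng: np.random.Generator, sd_frac: float) -> np.ndarray:
    tc = TwoCellConfig()
    mean = np.array(
        (tc.sigmoid if kind == "sigmoid" else tc.gaussian)["none"].as_tuple()
    )
    p = rng.normal(mean, sd_frac * np.abs(mean))
    p[3] = max(p[3], 1.0)  # width stays positive and resolvable
    if kind == "gaussian":
        p[2] = float(np.clip(p[2], 10.0, 80.0))
    return p


def _neuron_params(config: SynthConfig, kind: str, neuron: int) -> dict[str, tuple]:
    base = _draw_base_params(kind, _rng(config.seed, _PARAMS, neuron), config.param_sd_frac)
    shift = _condition_shift(kind, config.activated)
    out = {}
    for laser in config.lasers:
        p = base + _laser_scale(laser) * shift
        p[3] = max(p[3], 1.0)
        if kind == "gaussian":
            p[2] = float(np.clip(p[2], 10.0, 80.0))
        out[laser] = tuple(float(v) for v in p)
    return out


def generate_population(config: SynthConfig) -> tuple[GroundTruth, pd.DataFrame]:
    """Draw a population and its trial-level response table.

    Each neuron's mean response at every (level, laser) is its tuning curve
    evaluated at that level; trials add independent Gaussian noise of sd
    ``noise_sd`` (optionally scaled with the mean response magnitude when
    ``heteroscedastic``).  Deterministic given the config seed.
    """
    n_mono = int(round(config.frac_monotonic * config.n_neurons))
    kinds = tuple(
        "sigmoid" if i < n_mono else "gaussian" for i in range(config.n_neurons)
    )
    params = tuple(_neuron_params(config, kinds[i], i) for i in range(config.n_neurons))
    tag_rng = np.random.default_rng([config.seed, _CHANNELS, 2**20])
    tagged = tag_rng.random(config.n_neurons) < config.frac_tagged
    truth = GroundTruth(kinds=kinds, params=params, tagged=tagged)

    levels = np.asarray(config.levels, dtype=float)
    rows = []
    for i in range(config.n_neurons):
        rng = _rng(config.seed, _TRIALS, i)
        for laser in config.lasers:
            mean = evaluate_model(kinds[i], params[i][laser], levels)
            sd = config.noise_sd * (
                0.5 + np.abs(mean) if config.heteroscedastic else np.ones_like(mean)
            )
            resp = mean[None, :] + rng.normal(0.0, 1.0, (config.n_trials, levels.size)) * sd
            for j, lv in enumerate(levels):
                for t in range(config.n_trials):
                    rows.append((i, float(lv), laser, t, float(resp[t, j])))
    table = pd.DataFrame(rows, columns=["neuron_id", "level_db", "laser", "trial", "response"])
    return truth, validate_response_table(table)


# --- frame-level traces -----------------------------------------------------

_BASELINE_F = 100.0  # raw fluorescence baseline (a.u.)
_BASELINE_NOISE_F = 10.0  # per-frame baseline noise sd (a.u.)
_TAU_RISE_S = 0.05
_TAU_DECAY_S = 1.0
_PRE_S = 1.0  # baseline seconds before stimulus onset
_POST_S = 5.0  # seconds after onset


def _calcium_kernel(t: np.ndarray, delay: float) -> np.ndarray:
    """Difference-of-exponentials kernel starting `delay` s after onset."""
    s = np.clip(t - delay, 0.0, None)
    k = np.exp(-s / _TAU_DECAY_S) - np.exp(-s / _TAU_RISE_S)
    k[t < delay] = 0.0
    return k


def generate_traces(
    truth: GroundTruth, config: SynthConfig, table: pd.DataFrame | None = None
) -> TraceSet:
    """Frame-level fluorescence traces realizing the trial table.

    Each trial trace is 1 s of baseline noise followed by a calcium-like
    transient (fast rise, ~1 s decay, onset delayed by ``onset_delay_s``)
    scaled so that the mean dF/Fstd over the first post-onset second equals
    the trial's tabled response.  If no table is passed the trial table is
    regenerated from the same seeded substreams, so traces and table agree.
    """
    if config.frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    if table is None:
        _, table = generate_population(config)
    fr = config.frame_rate
    onset = int(round(_PRE_S * fr))
    n_frames = onset + int(round(_POST_S * fr))
    t_post = (np.arange(n_frames) - onset) / fr
    kernel = _calcium_kernel(t_post, config.onset_delay_s)
    win = slice(onset, onset + int(round(fr)))
    kmean = kernel[win].mean()

    labels = (
        table[["laser", "level_db", "trial"]]
        .drop_duplicates()
        .sort_values(["laser", "level_db", "trial"], kind="stable")
        .reset_index(drop=True)
    )
    resp = table.pivot_table(
        index=["laser", "level_db", "trial"], columns="neuron_id", values="response"
    ).loc[list(labels.itertuples(index=False, name=None))]
    n_neurons = resp.shape[1]
    F = np.empty((n_neurons, len(labels), n_frames))
    for i in range(n_neurons):
        rng = _rng(config.seed, _TRACES, i)
        noise = rng.normal(0.0, _BASELINE_NOISE_F, (len(labels), n_frames))
        amp = resp.iloc[:, i].to_numpy() * _BASELINE_NOISE_F / kmean
        F[i] = _BASELINE_F + noise + amp[:, None] * kernel[None, :]
    return TraceSet(
        F=F,
        frame_rate=fr,
        onset_frame=onset,
        labels=labels[["level_db", "laser"]].copy(),
    )


@dataclass(frozen=True)
class ChannelSignals:
    """Green/red channel summary signals per cell, frames along the last axis."""

    green: np.ndarray
    red: np.ndarray
    background_sd: float
    background_mean: float = 0.0


def generate_channel_signals(
    truth: GroundTruth, config: SynthConfig, n_frames: int = 600
) -> ChannelSignals:
    """Two-channel signals with bleedthrough and tag-elevated red fluorescence.

    red = bleedthrough_coef * green + baseline + elevation (tagged cells
    only, ``tag_elevation_sigma`` background sds) + background noise.
    """
    n = len(truth.kinds)
    rng = np.random.default_rng([config.seed, _CHANNELS, 0])
    g_base = rng.uniform(50.0, 150.0, n)
    green = g_base[:, None] + rng.normal(0.0, 10.0, (n, n_frames))
    elevation = config.tag_elevation_sigma * config.channel_noise_sd
    red_background = 20.0
    red = (
        config.bleedthrough_coef * green
        + red_background
        + elevation * truth.tagged.astype(float)[:, None]
        + rng.normal(0.0, config.channel_noise_sd, (n, n_frames))
    )
    return ChannelSignals(
        green=green,
        red=red,
        background_sd=config.channel_noise_sd,
        background_mean=red_background,
    )
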