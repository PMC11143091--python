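"""Synthetic oddball-paradigm EEG generator.

Produces labeled 8 x 201 epochs with the statistical structure the downstream
analysis assumes: a 1:7 target/standard ratio, a parietal-maximal P300 whose
latency can drift across sessions, a frontocentral P200 whose amplitude depends
on scenario, 1/f background noise, and per-subject latency/amplitude jitter.
Every draw descends from a single integer seed through a spawn tree, so a
dataset is a pure function of its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .continuous import ContinuousRecording
from .epochs import EPOCH_TMAX_MS, EPOCH_TMIN_MS, META_COLUMNS, SFREQ, EpochSet, epoch_times
from .layout import ChannelLayout

SCENARIOS = ("social", "non-social")


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: a Gaussian bump in time, rank-1 in space.

    ``topography`` holds one weight in [0, 1] per channel, with weight 1 at the
    component's focal electrode (Pz for the P300).
    """

    name: str
    peak_latency: float  # ms post-stimulus
    width: float  # ms, Gaussian sigma of the bump
    amplitude: float  # µV at the focal electrode
    topography: np.ndarray

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("component width must be positive")
        topo = np.asarray(self.topography, dtype=float)
        if not np.isclose(topo.max(), 1.0):
            raise ValueError("topography must peak at 1 at the focal electrode")
        object.__setattr__(self, "topography", topo)


@dataclass(frozen=True)
class ScenarioSpec:
    """Scenario-level effect structure (social vs non-social)."""

    label: str
    p200_gain: float = 1.0
    p300_latency_by_session: tuple[float, ...] = (400.0,) * 7
    discriminability: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in SCENARIOS:
            raise ValueError(f"scenario label must be one of {SCENARIOS}, got {self.label!r}")
        if len(self.p300_latency_by_session) != 7:
            raise ValueError("p300_latency_by_session needs exactly 7 entries")


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise model: 1/f^alpha spectrum with optional common source."""

    spectral_exponent: float = 1.0
    sigma: float = 4.0  # µV
    channel_correlation: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0.0 <= self.channel_correlation <= 1.0:
            raise ValueError("channel_correlation must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Full generator configuration; the dataset is a pure function of it."""

    seed: int = 0
    n_subjects: int = 15
    n_sessions: int = 7
    blocks_per_session: int = 20
    runs_per_block: int = 10
    trials_per_run: int = 8
    targets_per_run: int = 1
    soa_ms: float = 200.0
    flash_ms: float = 100.0
    sfreq: float = SFREQ
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    scenarios: tuple[ScenarioSpec, ...] = ()
    components: tuple[ComponentSpec, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    subject_latency_jitter_ms: float = 10.0
    subject_amplitude_jitter: float = 0.10
    nontarget_gain: float = 0.0  # component gain on standard trials (0 = pure noise)

    def __post_init__(self) -> None:
        if not self.scenarios:
            object.__setattr__(self, "scenarios", default_scenarios())
        if not self.components:
            object.__setattr__(self, "components", default_components(self.layout))
        if self.targets_per_run != 1:
            raise ValueError("paradigm requires exactly one target per run")
        for comp in self.components:
            if len(comp.topography) != self.layout.n_channels:
                raise ValueError(f"topography of {comp.name} does not match layout")

    @property
    def trials_per_session(self) -> int:
        return self.trials_per_run * self.runs_per_block * self.blocks_per_session

    def scenario(self, label: str) -> ScenarioSpec:
        for s in self.scenarios:
            if s.label == label:
                return s
        raise ValueError(f"unknown scenario {label!r}")


def default_components(layout: ChannelLayout | None = None) -> tuple[ComponentSpec, ...]:
    """Default P200 (frontocentral, Cz-max) and P300 (parietal, Pz-max)."""
    layout = layout or ChannelLayout()
    return (
        ComponentSpec(
            name="P200",
            peak_latency=200.0,
            width=30.0,
            amplitude=2.0,
            topography=layout.gaussian_topography("Cz", spread=0.5),
        ),
        ComponentSpec(
            name="P300",
            peak_latency=400.0,
            width=30.0,
            amplitude=5.0,
            topography=layout.gaussian_topography("Pz", spread=0.30),
        ),
    )


def default_scenarios() -> tuple[ScenarioSpec, ...]:
    """Social: stronger P200, P300 latency 400 -> 340 ms over sessions 1-7.

    Non-social: flat 400 ms latency, unit P200 gain.
    """
    social_lat = tuple(np.linspace(400.0, 340.0, 7))
    return (
        ScenarioSpec(label="social", p200_gain=1.5, p300_latency_by_session=social_lat),
        ScenarioSpec(label="non-social", p200_gain=1.0, p300_latency_by_session=(400.0,) * 7),
    )


# ------------------------------------------------------------------ presets --
def default_config(seed: int = 0) -> SimConfig:
    """Full paradigm scale: 15 subjects, 7 sessions, 20 blocks x 10 runs x 8."""
    return SimConfig(seed=seed)


def reduced_config(seed: int = 0, n_subjects: int = 4, blocks_per_session: int = 2) -> SimConfig:
    """Reduced preset for CPU-budget recovery tests (keeps all 7 sessions)."""
    return SimConfig(seed=seed, n_subjects=n_subjects, blocks_per_session=blocks_per_session)


def demo_config(seed: int = 0) -> SimConfig:
    """Tiny end-to-end smoke preset: 2 subjects, 2 sessions, 2 blocks."""
    return SimConfig(seed=seed, n_subjects=2, n_sessions=2, blocks_per_session=2)


# ----------------------------------------------------------------- waveform --
def component_waveform(spec: ComponentSpec, times_ms: np.ndarray) -> np.ndarray:
    """Evaluate the component's temporal bump on a time axis (ms).

    A Gaussian centred at ``spec.peak_latency`` with sigma ``spec.width``,
    truncated to exactly zero beyond +-3 widths so the bump has compact
    support.
    """
    if spec.width <= 0:
        raise ValueError("component width must be positive")
    t = np.asarray(times_ms, dtype=float)
    z = (t - spec.peak_latency) / spec.width
    wave = spec.amplitude * np.exp(-0.5 * z**2)
    wave[np.abs(z) > 3.0] = 0.0
    return wave


def colored_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, spec: NoiseSpec, sfreq: float
) -> np.ndarray:
    """1/f^alpha noise, unit-free std = sigma, with inter-channel correlation.

    Each channel is sqrt(1-c) * own source + sqrt(c) * one shared source, which
    yields pairwise correlation c for unit-variance sources.
    """
    if spec.sigma == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels + 1, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.empty_like(freqs)
    scale[0] = 0.0  # no DC
    scale[1:] = freqs[1:] ** (-spec.spectral_exponent / 2.0)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * scale, n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    c = spec.channel_correlation
    mixed = np.sqrt(1.0 - c) * shaped[:-1] + np.sqrt(c) * shaped[-1]
    return spec.sigma * mixed


# -------------------------------------------------------------- trial level --
@dataclass(frozen=True)
class TrialRecord:
    """One scheduled stimulus presentation."""

    subject: int
    session: int  # 1-based
    scenario: str
    block: int
    run: int
    trial_in_run: int
    label: int  # 1 = target, 0 = standard
    true_p300_latency: float  # ms; NaN for standards

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class SubjectEffects:
    """Per-subject deviations, constant across that subject's trials."""

    latency_shift_ms: dict[str, float]
    amplitude_factor: dict[str, float]


def draw_subject_effects(config: SimConfig, rng: np.random.Generator) -> SubjectEffects:
    shifts = {}
    factors = {}
    for comp in config.components:
        shifts[comp.name] = rng.normal(0.0, config.subject_latency_jitter_ms)
        factors[comp.name] = 1.0 + rng.normal(0.0, config.subject_amplitude_jitter)
    return SubjectEffects(latency_shift_ms=shifts, amplitude_factor=factors)


def _resolve_component(
    comp: ComponentSpec,
    scenario: ScenarioSpec,
    session: int,
    effects: SubjectEffects | None,
) -> ComponentSpec:
    """Apply scenario/session rules and subject jitter to one component."""
    latency = comp.peak_latency
    amplitude = comp.amplitude
    if comp.name == "P300":
        latency = scenario.p300_latency_by_session[session - 1]
    if comp.name == "P200":
        amplitude *= scenario.p200_gain
    if effects is not None:
        latency += effects.latency_shift_ms.get(comp.name, 0.0)
        amplitude *= effects.amplitude_factor.get(comp.name, 1.0)
    return replace(comp, peak_latency=latency, amplitude=amplitude)


def generate_epoch(
    record: TrialRecord,
    config: SimConfig,
    rng: np.random.Generator,
    effects: SubjectEffects | None = None,
) -> np.ndarray:
    """Simulate one 8 x 201 epoch (µV) for a scheduled trial.

    Targets receive every component scaled by the scenario/session rules and
    projected through its topography; standards receive ``nontarget_gain``
    times the same components (0 by default). Identical rng state gives
    identical output.
    """
    scenario = config.scenario(record.scenario)
    times = epoch_times(EPOCH_TMIN_MS, EPOCH_TMAX_MS, config.sfreq)
    epoch = colored_noise(rng, config.layout.n_channels, len(times), config.noise, config.sfreq)
    gain = scenario.discriminability if record.label == 1 else config.nontarget_gain
    if gain != 0.0:
        for comp in config.components:
            resolved = _resolve_component(comp, scenario, record.session, effects)
            epoch += gain * resolved.topography[:, None] * component_waveform(resolved, times)[None, :]
    return epoch


def make_schedule(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial schedule for one subject: all sessions x scenarios x blocks x runs.

    Exactly one target per run, at a uniformly random position, so every run
    contributes 1 target and trials_per_run - 1 standards (1:7 by default).
    """
    rows = []
    for session in range(1, config.n_sessions + 1):
        for scenario in config.scenarios:
            for block in range(1, config.blocks_per_session + 1):
                for run in range(1, config.runs_per_block + 1):
                    target_pos = int(rng.integers(config.trials_per_run))
                    for trial in range(config.trials_per_run):
                        rows.append(
                            (session, scenario.label, block, run, trial, int(trial == target_pos))
                        )
    return pd.DataFrame(
        rows, columns=["session", "scenario", "block", "run", "trial_in_run", "label"]
    )


def generate_dataset(config: SimConfig) -> EpochSet:
    """Generate the full dataset: epochs + trial-record metadata table.

    Randomness descends from ``config.seed`` through a SeedSequence spawn tree
    (one branch per subject: schedule, subject effects, then one stream per
    trial), so the result is bit-reproducible and subjects are independent.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    all_data: list[np.ndarray] = []
    all_meta: list[pd.DataFrame] = []
    times = epoch_times(EPOCH_TMIN_MS, EPOCH_TMAX_MS, config.sfreq)
    for subj_idx, subj_ss in enumerate(subject_seeds, start=1):
        sched_ss, fx_ss, trials_ss = subj_ss.spawn(3)
        schedule = make_schedule(config, np.random.default_rng(sched_ss))
        effects = draw_subject_effects(config, np.random.default_rng(fx_ss))
        trial_rng = np.random.default_rng(trials_ss)
        data = np.empty((len(schedule), config.layout.n_channels, len(times)))
        latencies = np.full(len(schedule), np.nan)
        for i, row in enumerate(schedule.itertuples(index=False)):
            record = TrialRecord(
                subject=subj_idx,
                session=row.session,
                scenario=row.scenario,
                block=row.block,
                run=row.run,
                trial_in_run=row.trial_in_run,
                label=row.label,
                true_p300_latency=np.nan,
            )
            data[i] = generate_epoch(record, config, trial_rng, effects)
            if row.label == 1:
                scen = config.scenario(row.scenario)
                latencies[i] = (
                    scen.p300_latency_by_session[row.session - 1]
                    + effects.latency_shift_ms.get("P300", 0.0)
                )
        meta = schedule.copy()
        meta.insert(0, "subject", subj_idx)
        meta["true_p300_latency"] = latencies
        all_data.append(data)
        all_meta.append(meta)
    meta = pd.concat(all_meta, ignore_index=True)
    labels = meta.pop("label").to_numpy()
    meta = meta[list(META_COLUMNS)]
    return EpochSet(
        data=np.concatenate(all_data, axis=0),
        labels=labels,
        meta=meta,
        layout=config.layout,
        sfreq=config.sfreq,
        tmin_ms=EPOCH_TMIN_MS,
    )


# ------------------------------------------------------ continuous export ---
def export_continuous(
    epochs: EpochSet, spacing_ms: float = 1600.0, pad_ms: float = 1500.0
) -> ContinuousRecording:
    """Lay epochs onto a zero-background continuous recording with markers.

    Stimulus onsets are spaced ``spacing_ms`` apart (default wide enough that
    -200..+1200 ms segmentation windows never collide), enabling round-trip
    tests of the preprocessing chain. Event codes carry the trial labels and
    the event table keeps the full epoch metadata.
    """
    sfreq = epochs.sfreq
    step = int(round(spacing_ms / 1000.0 * sfreq))
    pad = int(round(pad_ms / 1000.0 * sfreq))
    pre = int(round(-epochs.tmin_ms / 1000.0 * sfreq))
    n_ep, n_ch, n_samp = epochs.data.shape
    total = 2 * pad + (n_ep - 1) * step + n_samp
    signal = np.zeros((n_ch, total))
    onsets = pad + pre + np.arange(n_ep) * step
    for i, onset in enumerate(onsets):
        signal[:, onset - pre : onset - pre + n_samp] += epochs.data[i]
    events = epochs.meta.copy()
    events.insert(0, "code", epochs.labels)
    events.insert(0, "sample", onsets)
    return ContinuousRecording(signal=signal, sfreq=sfreq, events=events, layout=epochs.layout)
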