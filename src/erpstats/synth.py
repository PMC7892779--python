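"""Synthetic multi-subject single-trial EEG generator.

Generates epoch sets with the study's factorial design (4 sentence types x
2 lengths, 48 trials each, 61 electrodes, 500 Hz RSVP with 600 ms SOA) and a
controllable background-noise + injected-component structure, so that every
downstream analysis stage can be exercised without access to real data.

Background noise is spatially correlated Gaussian with a power-law (1/f)
spectrum plus an alpha-band bump; ERP-like components are added as windowed
constant (boxcar or ramped-plateau) deflections with subject-level amplitude
variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epochs import EpochSet
from .montage import ElectrodeLayout, build_default_layout, build_region_map

__all__ = [
    "ComponentSpec",
    "NoiseSpec",
    "StudyDesign",
    "simulate_noise_epochs",
    "add_component",
    "simulate_study",
    "preset_components",
]

SENTENCE_TYPES = ("indirectQ", "directQ", "declarative", "whetherQ")
LENGTHS = ("short", "long")


@dataclass(frozen=True)
class NoiseSpec:
    """Background-noise parameters.

    ``sd_broadband`` is the per-sample standard deviation (microvolts) of the
    shaped noise at each electrode; ``spectral_exponent`` the 1/f slope of
    the power spectrum; ``alpha_power_fraction`` the share of variance placed
    in a 10 Hz bump; ``spatial_correlation_length`` the e-folding distance of
    between-electrode correlation in units of the median inter-electrode
    (nearest-neighbor) distance; ``trial_sd_scale`` and ``subject_gain_sd``
    multiplicative (lognormal) amplitude variability per trial / subject.
    """

    sd_broadband: float = 15.0
    spectral_exponent: float = 1.0
    alpha_power_fraction: float = 0.2
    spatial_correlation_length: float = 2.0
    trial_sd_scale: float = 0.1
    subject_gain_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.sd_broadband < 0 or self.spectral_exponent < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.alpha_power_fraction <= 1.0:
            raise ValueError("alpha_power_fraction must lie in [0, 1]")
        if self.spatial_correlation_length < 0 or self.trial_sd_scale < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class ComponentSpec:
    """An injectable ERP-like component.

    ``amplitude`` is the mean subject-level amplitude in microvolts (negative
    for negativities); the component is added, multiplied by a temporal
    envelope over ``time_window`` (seconds, in epoch time), to
    ``electrode_set`` in the listed ``conditions`` only.
    """

    name: str
    amplitude: float
    time_window: tuple[float, float]
    electrode_set: tuple[int, ...]
    conditions: tuple[str, ...]
    envelope: str = "half_cosine"
    amplitude_sd_across_subjects: float = 0.0
    ramp_s: float = 0.05

    def __post_init__(self) -> None:
        if self.envelope not in ("boxcar", "half_cosine"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.time_window[0] >= self.time_window[1]:
            raise ValueError("time_window start must precede end")
        if self.amplitude_sd_across_subjects < 0:
            raise ValueError("amplitude SD must be non-negative")
        object.__setattr__(self, "electrode_set", tuple(int(e) for e in self.electrode_set))
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def envelope_on(self, times: np.ndarray) -> np.ndarray:
        """Temporal envelope sampled on ``times`` (0 outside the window)."""
        t0, t1 = self.time_window
        env = ((times >= t0 - 1e-12) & (times <= t1 + 1e-12)).astype(float)
        if self.envelope == "half_cosine":
            ramp = min(self.ramp_s, (t1 - t0) / 2)
            if ramp > 0:
                rising = (times >= t0) & (times < t0 + ramp)
                falling = (times > t1 - ramp) & (times <= t1)
                env[rising] = 0.5 * (1 - np.cos(np.pi * (times[rising] - t0) / ramp))
                env[falling] = 0.5 * (1 - np.cos(np.pi * (t1 - times[falling]) / ramp))
        return env


def _word_onsets(length: str, soa: float) -> tuple[float, ...]:
    """Word onsets relative to the main verb: verb, intervening words, target."""
    n_intervening = 3 if length == "short" else 5
    return tuple(round(soa * i, 10) for i in range(n_intervening + 2))


@dataclass(frozen=True)
class StudyDesign:
    """Factorial design of the emulated study.

    The default epoch is locked to the main-verb onset and spans -0.3 to
    4.6 s, long enough to contain the verb-to-target interval plus 1 s after
    the target word in both the short (target at 2.4 s) and long (target at
    3.6 s) conditions; analysis windows are cropped out of it.
    """

    n_subjects: int = 37
    trials_per_condition: int = 48
    sfreq: float = 500.0
    soa: float = 0.6
    epoch_window: tuple[float, float] = (-0.3, 4.6)
    conditions: tuple[str, ...] = tuple(
        f"{t}_{l}" for t in SENTENCE_TYPES for l in LENGTHS
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_condition < 1:
            raise ValueError("need at least one subject and one trial")
        if self.sfreq <= 0 or self.soa <= 0:
            raise ValueError("sfreq and soa must be positive")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch window start must precede end")
        object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def times(self) -> np.ndarray:
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) * self.sfreq)) + 1
        return t0 + np.arange(n) / self.sfreq

    def length_of(self, condition: str) -> str:
        for l in LENGTHS:
            if condition.endswith("_" + l):
                return l
        raise KeyError(f"condition {condition!r} carries no length suffix")

    def word_onsets(self, condition: str) -> tuple[float, ...]:
        """Onsets of verb, intervening words, and target, in epoch time."""
        return _word_onsets(self.length_of(condition), self.soa)

    def target_onset(self, condition: str) -> float:
        return self.word_onsets(condition)[-1]

    def intervening_onsets(self, condition: str) -> tuple[float, ...]:
        ons = self.word_onsets(condition)
        return ons[1:-1]

    def interval_window(self, condition: str) -> tuple[float, float]:
        """Verb-to-target analysis interval: 2.2 s (short) or 3.0 s (long)."""
        return (0.0, 2.2 if self.length_of(condition) == "short" else 3.0)

    @classmethod
    def default(cls) -> "StudyDesign":
        return cls()

    @classmethod
    def demo(cls) -> "StudyDesign":
        """Miniature design for smoke tests: 6 subjects, 8 trials, 100 Hz."""
        return cls(n_subjects=6, trials_per_condition=8, sfreq=100.0)


def _spectral_amplitude(n_times: int, sfreq: float, noise: NoiseSpec) -> np.ndarray:
    """rfft-bin amplitude shaping for unit-variance output from white input."""
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    p_pink = np.zeros_like(freqs)
    if n_times > 1:
        p_pink[1:] = freqs[1:] ** (-noise.spectral_exponent)
    p_alpha = np.exp(-0.5 * ((freqs - 10.0) / 1.5) ** 2)
    p_alpha[0] = 0.0
    p = np.zeros_like(freqs)
    if p_pink.sum() > 0:
        p += (1.0 - noise.alpha_power_fraction) * p_pink / p_pink.sum()
    if p_alpha.sum() > 0:
        p += noise.alpha_power_fraction * p_alpha / p_alpha.sum()
    amp = np.sqrt(p)
    # normalize so filtering unit white noise yields unit per-sample variance
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n_times % 2 == 0:
        weights[-1] = 1.0
    var = float((weights * amp**2).sum()) / n_times
    if var > 0:
        amp /= np.sqrt(var)
    return amp


def simulate_noise_epochs(
    design: StudyDesign,
    noise: NoiseSpec,
    layout: ElectrodeLayout,
    seed: int,
) -> EpochSet:
    """Zero-mean spatially correlated 1/f + alpha background, per trial.

    Each trial's noise is independent across trials; spatial correlation
    decays exponentially with chord distance; a lognormal gain is applied per
    subject and per trial.  Deterministic given ``seed``.
    """
    times = design.times()
    n_t = times.size
    n_e = layout.n_electrodes
    shape = (design.n_subjects, design.n_conditions, design.trials_per_condition, n_e, n_t)
    prov = {
        "seed": int(seed),
        "design": {
            "n_subjects": design.n_subjects,
            "conditions": list(design.conditions),
            "trials_per_condition": design.trials_per_condition,
            "sfreq": design.sfreq,
            "epoch_window": list(design.epoch_window),
        },
        "noise": vars(noise).copy() if hasattr(noise, "__dict__") else {
            f: getattr(noise, f) for f in noise.__dataclass_fields__
        },
        "components": [],
    }
    if noise.sd_broadband == 0.0:
        return EpochSet(np.zeros(shape), times, design.sfreq, design.conditions, layout, prov)

    rng = np.random.default_rng(seed)
    amp = _spectral_amplitude(n_t, design.sfreq, noise) * noise.sd_broadband

    if n_e > 1 and noise.spatial_correlation_length > 0:
        d = layout.chord_distances()
        rho = noise.spatial_correlation_length * layout.median_nn_distance()
        cov = np.exp(-d / rho)
        mix = np.linalg.cholesky(cov + 1e-10 * np.eye(n_e))
    else:
        mix = None

    data = np.empty(shape)
    n_cond, n_trials = design.n_conditions, design.trials_per_condition
    for s in range(design.n_subjects):
        white = rng.standard_normal((n_cond, n_trials, n_e, n_t))
        spec = np.fft.rfft(white, axis=-1) * amp
        x = np.fft.irfft(spec, n=n_t, axis=-1)
        if mix is not None:
            x = np.einsum("ab,ctbn->ctan", mix, x)
        gain_s = (
            np.exp(noise.subject_gain_sd * rng.standard_normal() - 0.5 * noise.subject_gain_sd**2)
            if noise.subject_gain_sd > 0
            else 1.0
        )
        if noise.trial_sd_scale > 0:
            z = rng.standard_normal((n_cond, n_trials, 1, 1))
            gain_t = np.exp(noise.trial_sd_scale * z - 0.5 * noise.trial_sd_scale**2)
        else:
            gain_t = 1.0
        data[s] = gain_s * gain_t * x
    return EpochSet(data, times, design.sfreq, design.conditions, layout, prov)


def add_component(epochs: EpochSet, spec: ComponentSpec, seed: int) -> EpochSet:
    """Add an ERP-like component to the named conditions; other data untouched.

    Per subject an amplitude is drawn from
    ``Normal(spec.amplitude, spec.amplitude_sd_across_subjects)`` and applied,
    multiplied by the temporal envelope, to every trial of the listed
    conditions on ``spec.electrode_set``.
    """
    t0, t1 = spec.time_window
    if t0 < epochs.times[0] - 1e-9 or t1 > epochs.times[-1] + 1e-9:
        raise ValueError(
            f"component window {spec.time_window} outside epoch "
            f"[{epochs.times[0]}, {epochs.times[-1]}] s"
        )
    cond_idx = [epochs.condition_index(c) for c in spec.conditions]  # KeyError if unknown
    e_idx = epochs.layout.indices_of(spec.electrode_set)

    rng = np.random.default_rng(seed)
    amps = spec.amplitude + spec.amplitude_sd_across_subjects * rng.standard_normal(
        epochs.n_subjects
    )
    env = spec.envelope_on(epochs.times)

    out = epochs.copy()
    for s in range(epochs.n_subjects):
        bump = amps[s] * env
        for ci in cond_idx:
            out.data[s, ci][:, e_idx, :] += bump
    out.provenance.setdefault("components", []).append(
        {
            "name": spec.name,
            "amplitude": spec.amplitude,
            "sd": spec.amplitude_sd_across_subjects,
            "time_window": list(spec.time_window),
            "electrodes": list(spec.electrode_set),
            "conditions": list(spec.conditions),
            "envelope": spec.envelope,
            "seed": int(seed),
        }
    )
    return out


def preset_components(
    preset: str,
    design: StudyDesign,
    san_uv: float = 0.0,
    p600_uv: float = 0.0,
    p2_uv: float = 2.0,
    subject_sd_uv: float = 0.5,
) -> list[ComponentSpec]:
    """Component lists for the study presets.

    ``null``: no components.  ``paper``: a P2 (positivity ~0.15-0.25 s after
    the target word) in the question conditions, plus optional SAN
    (sustained anterior negativity over the verb-to-target interval in
    indirect questions) and P600 (posterior positivity 0.5-0.7 s after the
    target word in indirect questions) of configurable size.
    """
    if preset == "null":
        return []
    if preset != "paper":
        raise ValueError(f"unknown preset {preset!r}")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        rm = build_region_map()
    anterior = tuple(sorted(rm.anterior))
    posterior = tuple(sorted(rm.posterior))
    comps: list[ComponentSpec] = []
    for length in LENGTHS:
        target = design.target_onset(f"indirectQ_{length}")
        if p2_uv != 0.0:
            comps.append(
                ComponentSpec(
                    name=f"P2_{length}",
                    amplitude=abs(p2_uv),
                    time_window=(target + 0.15, target + 0.25),
                    electrode_set=anterior,
                    conditions=(f"indirectQ_{length}", f"directQ_{length}"),
                    amplitude_sd_across_subjects=subject_sd_uv,
                )
            )
        if san_uv != 0.0:
            comps.append(
                ComponentSpec(
                    name=f"SAN_{length}",
                    amplitude=-abs(san_uv),
                    time_window=design.interval_window(f"indirectQ_{length}"),
                    electrode_set=anterior,
                    conditions=(f"indirectQ_{length}",),
                    amplitude_sd_across_subjects=subject_sd_uv,
                )
            )
        if p600_uv != 0.0:
            comps.append(
                ComponentSpec(
                    name=f"P600_{length}",
                    amplitude=abs(p600_uv),
                    time_window=(target + 0.5, target + 0.7),
                    electrode_set=posterior,
                    conditions=(f"indirectQ_{length}",),
                    amplitude_sd_across_subjects=subject_sd_uv,
                )
            )
    return comps


def simulate_study(
    design: StudyDesign,
    noise: NoiseSpec,
    components: list[ComponentSpec],
    seed: int,
    layout: ElectrodeLayout | None = None,
) -> EpochSet:
    """Noise background plus the given components; deterministic given seed."""
    if layout is None:
        layout = build_default_layout()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(1 + len(components))
    epochs = simulate_noise_epochs(
        design, noise, layout, seed=children[0].generate_state(1)[0]
    )
    for comp, child in zip(components, children[1:]):
        epochs = add_component(epochs, comp, seed=child.generate_state(1)[0])
    epochs.provenance["master_seed"] = int(seed)
    return epochs
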