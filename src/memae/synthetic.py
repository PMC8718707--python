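"""Seeded synthetic heartbeat generator.

Beats are sums of Gaussian bumps, one per ECG wave (P, Q, R, S, T), plus an
optional very narrow pacemaker stimulus spike before the QRS, sinusoidal
baseline wander and white Gaussian noise. Three stock morphologies ship with
the package:

``routine``
    Narrow QRS, upright T — an unremarkable sinus beat.
``paced``
    Ventricular-paced morphology: a 1–2-sample stimulus spike immediately
    before a widened QRS with a discordant (inverted) T wave.
``wide_qrs``
    The confounder: the same widened-QRS morphology *without* the stimulus
    spike, mimicking a left-bundle-branch-block beat that is clinically
    confused with pacing.

The analytic (noise-free) waveform is available in closed form, which makes
every downstream module testable without any recorded data. The generator
does not attempt physiological realism (no heart-rate variability,
respiration coupling or realistic 12-lead vector projections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .autoencoder import ECGBeat

__all__ = ["MorphologySpec", "default_specs", "generate_beat",
           "generate_dataset", "generate_pacing_record", "analytic_waveform"]


@dataclass
class MorphologySpec:
    """Parametric description of one beat class.

    ``waves`` maps wave name -> (amplitude, center, width), with center and
    width as fractions of the window. ``paced_spike`` is (amplitude,
    width_in_samples, center_fraction) or None. ``qrs_width_multiplier``
    scales the Q/R/S widths (>= 1; >1 models bundle-branch-block-like or
    paced widening). ``baseline_wander`` is (amplitude, cycles_per_window).
    """

    waves: dict
    paced_spike: tuple | None = None
    qrs_width_multiplier: float = 1.0
    noise_sd: float = 0.0
    baseline_wander: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name, (amp, center, width) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name}: width must be positive")
            if not 0.0 < center < 1.0:
                raise ValueError(f"wave {name}: center must be in (0, 1)")
        if self.qrs_width_multiplier < 1.0:
            raise ValueError("qrs_width_multiplier must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.paced_spike is not None:
            amp, width, center = self.paced_spike
            if width <= 0 or width > 2.0:
                raise ValueError("spike width must be in (0, 2] samples")
            if not 0.0 < center < 1.0:
                raise ValueError("spike center must be in (0, 1)")


def default_specs() -> dict:
    """The stock morphology classes, loaded from the shipped config."""
    text = resources.files("memae").joinpath("morphologies.yaml").read_text()
    raw = yaml.safe_load(text)
    specs = {}
    for label, cfg in raw["classes"].items():
        specs[label] = MorphologySpec(
            waves={k: tuple(v) for k, v in cfg["waves"].items()},
            paced_spike=tuple(cfg["paced_spike"]) if cfg.get("paced_spike") else None,
            qrs_width_multiplier=cfg.get("qrs_width_multiplier", 1.0),
            noise_sd=cfg.get("noise_sd", 0.0),
            baseline_wander=tuple(cfg.get("baseline_wander", (0.0, 0.0))),
        )
    return specs


def analytic_waveform(spec: MorphologySpec, t_len: int) -> np.ndarray:
    """Noise-free closed form: Gaussian wave sum plus the stimulus spike."""
    if t_len < 8:
        raise ValueError("beat length too short")
    t = np.arange(t_len) / t_len
    beat = np.zeros(t_len)
    for name, (amp, center, width) in spec.waves.items():
        w = width * spec.qrs_width_multiplier if name in ("Q", "R", "S") else width
        beat += amp * np.exp(-((t - center) ** 2) / (2.0 * w ** 2))
    if spec.paced_spike is not None:
        amp, width_samples, center = spec.paced_spike
        sigma = width_samples / t_len
        beat += amp * np.exp(-((t - center) ** 2) / (2.0 * sigma ** 2))
    return beat


def generate_beat(spec: MorphologySpec, t_len: int = 235,
                  seed: int | np.random.SeedSequence = 0,
                  label: str | None = None,
                  source_id: str | None = None) -> ECGBeat:
    """One noisy beat: analytic waveform + baseline wander + Gaussian noise."""
    rng = np.random.default_rng(seed)
    beat = analytic_waveform(spec, t_len)
    amp, cycles = spec.baseline_wander
    if amp != 0.0:
        phase = rng.uniform(0, 2 * np.pi)
        beat = beat + amp * np.sin(2 * np.pi * cycles * np.arange(t_len) / t_len + phase)
    if spec.noise_sd > 0:
        beat = beat + rng.normal(0.0, spec.noise_sd, size=t_len)
    return ECGBeat(samples=beat[None, :], label=label, source_id=source_id)


def generate_dataset(class_specs: dict, n_per_class: int, t_len: int = 235,
                     seed: int = 0) -> list:
    """Exactly ``n_per_class`` beats per label, deterministically shuffled.

    Per-beat randomness is spawned from the master seed, so changing the
    seed changes the noise but never the class structure.
    """
    if not class_specs:
        raise ValueError("need at least one class spec")
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    master = np.random.SeedSequence(seed)
    labels = sorted(class_specs)
    children = master.spawn(len(labels) * n_per_class + 1)
    beats = []
    i = 0
    for label in labels:
        spec = class_specs[label]
        for j in range(n_per_class):
            beats.append(generate_beat(spec, t_len=t_len, seed=children[i],
                                       label=label, source_id=f"synth-{label}-{j:04d}"))
            i += 1
    shuffle_rng = np.random.default_rng(children[-1])
    order = shuffle_rng.permutation(len(beats))
    return [beats[k] for k in order]


# Fixed relative lead gains used for multi-lead emulation; index 1 (lead II)
# carries the reference amplitude.
_LEAD_GAINS = np.array([0.6, 1.0, 0.8, -0.5, 0.4, 0.9,
                        -0.3, 0.5, 0.7, 0.9, 1.0, 0.8])


def generate_pacing_record(n_beats: int = 12, heart_rate_bpm: float = 75.0,
                           fs: int = 500, duration_s: float = 10.0,
                           leads: int = 12, seed: int = 0,
                           spec: MorphologySpec | None = None,
                           symbol: str = "/"):
    """A multi-lead record of concatenated beats with R-position annotations.

    Defaults emulate a 12-lead, 10-s, 500-Hz paced recording. Returns an
    :class:`memae.ecg_io.ECGRecord`.
    """
    from .ecg_io import ECGRecord

    if n_beats < 1 or heart_rate_bpm <= 0 or fs <= 0 or duration_s <= 0:
        raise ValueError("invalid rate/duration parameters")
    if leads < 1 or leads > len(_LEAD_GAINS):
        raise ValueError(f"leads must be in [1, {len(_LEAD_GAINS)}]")
    total = int(round(fs * duration_s))
    rr = int(round(60.0 / heart_rate_bpm * fs))
    beat_len = min(rr, total)
    if (n_beats - 1) * rr + beat_len > total:
        raise ValueError(
            f"{n_beats} beats at {heart_rate_bpm} bpm do not fit in {duration_s} s")
    spec = spec if spec is not None else default_specs()["paced"]

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_beats)
    signal = np.zeros((leads, total))
    annotations = []
    r_center = 0.47  # R-wave center fraction used by the stock morphologies
    for i in range(n_beats):
        beat = generate_beat(spec, t_len=beat_len, seed=children[i]).samples[0]
        start = i * rr
        signal[:, start:start + beat_len] += np.outer(_LEAD_GAINS[:leads], beat)
        annotations.append((start + int(round(r_center * beat_len)), symbol))
    lead_names = [f"lead{i + 1}" for i in range(leads)]
    lead_names[:2] = ["I", "II"][: min(2, leads)]
    return ECGRecord(signal=signal, sampling_rate=float(fs),
                     lead_names=lead_names, annotations=annotations)
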