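"""Seeded synthetic EEG datasets and game instances with known ground truth.

Class structure is carried by band-limited oscillatory power (alpha-band
contrast by default), on top of broadband background and white sensor noise.
Ocular contamination is injected as a raised-cosine blink train with a known
mixing coefficient so recovery can be verified exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .eeg_io import EEGRecording
from .stackelberg import Equilibrium, GameSpec, solve_stackelberg

__all__ = [
    "SynthConfig",
    "BANDS",
    "generate_eeg_dataset",
    "inject_artifacts",
    "generate_game_instance",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass
class SynthConfig:
    n_subjects: int = 32  # per class
    n_classes: int = 2
    fs: float = 128.0
    duration_s: float = 12.0
    n_channels: int = 3
    # per-class relative band power (variance units); one dict per class
    band_power: list[dict[str, float]] = field(
        default_factory=lambda: [
            {"delta": 1.0, "theta": 0.8, "alpha": 1.0, "beta": 0.6},
            {"delta": 1.0, "theta": 0.8, "alpha": 2.0, "beta": 0.6},
        ]
    )
    amplitude_uV: float = 10.0  # RMS scale of the unit-power band mixture
    tonal_fraction: float = 0.95  # share of band power carried by a sustained oscillation
    # bands carrying a sustained-rhythm component (others are pure band noise)
    tonal_bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    noise_sd: float = 0.5
    eog_beta: float = 0.25
    eog_rate_per_min: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 128 <= self.fs <= 512:
            raise ValueError(f"fs {self.fs} outside the supported 128-512 Hz range")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if len(self.band_power) != self.n_classes:
            raise ValueError("band_power needs one mapping per class")
        for bp in self.band_power:
            if any(v < 0 for v in bp.values()):
                raise ValueError("band powers must be nonnegative")


def _band_noise(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance noise confined to ``band`` Hz (last axis is time)."""
    white = rng.standard_normal(shape)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _band_oscillation(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs: float,
    band: tuple[float, float],
    tonal_fraction: float,
) -> np.ndarray:
    """Unit-variance band component: sustained tone plus band-limited noise.

    Cortical rhythms hold their amplitude over seconds, so a share of the
    band power rides on a constant-amplitude sinusoid (random in-band
    frequency and phase per channel); the rest is stochastic band noise.
    """
    noise = _band_noise(rng, shape, fs, band)
    if tonal_fraction <= 0:
        return noise
    n = shape[-1]
    lead = shape[:-1] + (1,)
    # individual rhythm peaks cluster mid-band, so draw from the central half
    width = band[1] - band[0]
    freq = rng.uniform(band[0] + 0.25 * width, band[1] - 0.25 * width, size=lead)
    phase = rng.uniform(0, 2 * np.pi, size=lead)
    t = np.arange(n) / fs
    tone = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t + phase)  # unit variance
    return np.sqrt(tonal_fraction) * tone + np.sqrt(1.0 - tonal_fraction) * noise


def _default_labels(n_channels: int) -> list[str]:
    if n_channels == 3:
        return ["Fp1", "Fp2", "Fpz"]
    from .eeg_io import load_montage

    if n_channels == 128:
        return list(load_montage("cap128").channel_labels)
    return [f"CH{i + 1}" for i in range(n_channels)]


def generate_eeg_dataset(cfg: SynthConfig) -> tuple[list[tuple[EEGRecording, int]], dict]:
    """Generate labelled recordings; fully reproducible from ``cfg.seed``.

    Returns ``(pairs, manifest)`` where each pair is ``(recording, class
    label)`` and the manifest records the seed, parameters, and per-recording
    metadata.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samp = int(round(cfg.duration_s * cfg.fs))
    labels = _default_labels(cfg.n_channels)
    pairs: list[tuple[EEGRecording, int]] = []
    entries = []
    for cls in range(cfg.n_classes):
        weights = np.array([np.sqrt(cfg.band_power[cls].get(b, 0.0)) for b in BANDS])
        for subj in range(cfg.n_subjects):
            mix = sum(
                w
                * _band_oscillation(
                    rng,
                    (cfg.n_channels, n_samp),
                    cfg.fs,
                    BANDS[b],
                    cfg.tonal_fraction if b in cfg.tonal_bands else 0.0,
                )
                for w, b in zip(weights, BANDS)
            )
            data = cfg.amplitude_uV * mix + cfg.noise_sd * rng.standard_normal(
                (cfg.n_channels, n_samp)
            )
            sid = f"c{cls}s{subj:03d}"
            pairs.append(
                (EEGRecording(data=data, fs=cfg.fs, channel_labels=list(labels), session_id=sid), cls)
            )
            entries.append({"session_id": sid, "label": cls})
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "recordings": entries,
        "n_recordings": len(pairs),
    }
    return pairs, manifest


def _blink_train(
    rng: np.random.Generator, n: int, fs: float, rate_per_min: float, amp_uV: float = 100.0
) -> np.ndarray:
    """Poisson train of 300 ms raised-cosine blink transients."""
    width = int(round(0.3 * fs))
    template = amp_uV * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
    eog = np.zeros(n)
    rate_per_sample = rate_per_min / 60.0 / fs
    starts = np.flatnonzero(rng.random(n) < rate_per_sample)
    if starts.size == 0 and n > width:  # guarantee a usable regression target
        starts = np.array([int(rng.integers(0, n - width))])
    for s in starts:
        stop = min(s + width, n)
        eog[s:stop] += template[: stop - s]
    return eog


def inject_artifacts(
    rec: EEGRecording, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[EEGRecording, EEGRecording, float]:
    """Contaminate ``rec`` with a known ocular artifact.

    Returns ``(contaminated, clean, beta)``: the contaminated recording has
    ``clean + beta * EOG`` on every EEG channel and the EOG trace appended as
    a labelled channel (``eog_index`` set); the exact mixing coefficient is
    returned.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 7)
    eog = _blink_train(rng, rec.n_samples, rec.fs, cfg.eog_rate_per_min)
    beta = float(cfg.eog_beta)
    contaminated_data = np.vstack([rec.data + beta * eog[None, :], eog[None, :]])
    contaminated = rec.copy_with(
        data=contaminated_data,
        channel_labels=list(rec.channel_labels) + ["EOG"],
        eog_index=rec.n_channels,
    )
    return contaminated, rec.copy_with(), beta


def generate_game_instance(
    n_followers: int, seed: int = 0, max_draws: int = 1000
) -> tuple[GameSpec, Equilibrium]:
    """Draw a default-family game with an interior equilibrium.

    Parameters are resampled until the analytic solution has the leader
    strictly inside its bounds and every follower response strictly inside
    its box, so the reference equilibrium satisfies the first-order
    condition of the reduced leader objective.
    """
    if n_followers < 1:
        raise ValueError("n_followers must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_draws):
        game = GameSpec(
            leader_bounds=(0.0, float(rng.uniform(2.0, 4.0))),
            n_followers=n_followers,
            follower_bounds=[(0.0, float(rng.uniform(3.0, 6.0))) for _ in range(n_followers)],
            lambda1=float(rng.uniform(0.5, 2.0)),
            lambda2=float(rng.uniform(0.2, 1.0)),
            accuracy_params=[
                (float(rng.uniform(1.0, 3.0)), float(rng.uniform(0.5, 2.0)))
                for _ in range(n_followers)
            ],
            cost_params=[
                (float(rng.uniform(0.02, 0.2)), float(rng.uniform(0.02, 0.2)))
                for _ in range(n_followers)
            ],
            follower_utility_params=[
                (
                    float(rng.uniform(0.5, 2.0)),  # p
                    float(rng.uniform(0.5, 2.0)),  # q
                    float(rng.uniform(0.0, 0.3)),  # r
                )
                for _ in range(n_followers)
            ],
        )
        eq = solve_stackelberg(game, solver="closed_form", tol=1e-10)
        xlo, xhi = game.leader_bounds
        margin = 1e-3 * (xhi - xlo)
        if not (xlo + margin < eq.x_star < xhi - margin):
            continue
        interior = all(
            game.follower_bounds[i][0] + 1e-6 < eq.y_star[i] < game.follower_bounds[i][1] - 1e-6
            for i in range(n_followers)
        )
        if interior:
            return game, eq
    raise RuntimeError("failed to draw an interior-equilibrium instance")


def save_dataset(pairs, manifest, out_dir, format: str = "matrix") -> dict:
    """Write a generated dataset to ``out_dir`` and return the manifest."""
    from pathlib import Path

    from .eeg_io import write_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".edf" if format == "edf" else ".tsv"
    for entry, (rec, _) in zip(manifest["recordings"], pairs):
        entry["path"] = str(out / (rec.session_id + suffix))
        write_recording(rec, entry["path"], format=format)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
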