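"""EEG cleaning, filtering, alignment, segmentation, and quality scoring.

The canonical chain is: ocular-artifact regression -> per-channel
standardization -> zero-phase band-pass (+ optional notch) -> spatial
filtering -> montage alignment -> windowed segmentation.  Every stage
preserves the ``(channels, samples)`` shape except the ocular regression,
which drops the EOG channel from the EEG set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .eeg_io import EEGRecording, Montage

__all__ = [
    "PreprocessConfig",
    "ChannelStats",
    "SegmentSet",
    "QualityReport",
    "remove_eog",
    "standardize",
    "bandpass_filter",
    "spatial_filter",
    "align_montage",
    "segment",
    "consistency_score",
    "session_consistency_flags",
    "quality_score",
    "run_chain",
]


@dataclass
class PreprocessConfig:
    """Knobs for the preprocessing chain; defaults follow common EEG practice."""

    beta_mode: str = "least_squares"  # {"fixed", "least_squares"}
    beta_value: float = 0.0
    band: tuple[float, float] = (0.5, 40.0)
    notch: float | None = None
    spatial_method: str = "common_average"  # {"common_average", "laplacian", "none"}
    window_s: float = 2.0
    hop_s: float = 1.0
    sigma_zero_policy: str = "error"  # {"error", "zero_output"}
    validity_amp_uV: float = 100.0
    validity_flat_eps: float = 1e-6
    consistency_z: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValueError(f"invalid band {self.band}")
        if self.window_s <= 0 or self.hop_s <= 0:
            raise ValueError("window_s and hop_s must be positive")
        if not np.isfinite(self.beta_value):
            raise ValueError("beta_value must be finite")


@dataclass
class ChannelStats:
    mu: np.ndarray
    sigma: np.ndarray


@dataclass
class SegmentSet:
    """Windowed epochs: ``segments`` is (n_segments, n_channels, n_window)."""

    segments: np.ndarray
    labels: np.ndarray | None = None
    valid: np.ndarray | None = None
    session_ids: list[str] = field(default_factory=list)
    fs: float | None = None

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


@dataclass
class QualityReport:
    consistency_score: float | None
    quality_score: float
    n_consistent_sessions: int | None
    n_sessions: int | None
    n_valid_segments: int
    n_segments: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def remove_eog(rec: EEGRecording, cfg: PreprocessConfig) -> tuple[EEGRecording, np.ndarray]:
    """Regress the EOG channel out of every EEG channel.

    Returns the cleaned recording (EOG channel removed) and the per-channel
    regression coefficients.  In ``fixed`` mode every channel uses
    ``cfg.beta_value``; in ``least_squares`` mode each coefficient is the
    ordinary least-squares slope of the EEG channel on the EOG channel.
    """
    if rec.eog_index is None:
        if cfg.beta_mode == "fixed":
            # No reference channel: the fixed coefficient has nothing to scale.
            return rec.copy_with(), np.full(rec.n_channels, cfg.beta_value)
        raise ValueError("least_squares EOG removal requires an EOG channel")
    eog = rec.data[rec.eog_index]
    keep = [i for i in range(rec.n_channels) if i != rec.eog_index]
    eeg = rec.data[keep]
    if cfg.beta_mode == "fixed":
        beta = np.full(len(keep), cfg.beta_value)
    elif cfg.beta_mode == "least_squares":
        eog_c = eog - eog.mean()
        denom = float(eog_c @ eog_c)
        if denom <= 0:
            raise ValueError("EOG channel has zero variance; regression slope undefined")
        beta = (eeg - eeg.mean(axis=1, keepdims=True)) @ eog_c / denom
    else:
        raise ValueError(f"unknown beta_mode {cfg.beta_mode!r}")
    clean = eeg - beta[:, None] * eog[None, :]
    labels = [rec.channel_labels[i] for i in keep]
    return rec.copy_with(data=clean, channel_labels=labels, eog_index=None), beta


def standardize(rec: EEGRecording, cfg: PreprocessConfig) -> tuple[EEGRecording, ChannelStats]:
    """Per-channel z-score using population statistics over the full record."""
    mu = rec.data.mean(axis=1)
    sigma = rec.data.std(axis=1)  # population (ddof=0) by convention
    zero = sigma == 0
    if np.any(zero):
        if cfg.sigma_zero_policy == "error":
            bad = [rec.channel_labels[i] for i in np.flatnonzero(zero)]
            raise ValueError(f"zero-variance channels {bad} (sigma_zero_policy='error')")
        sigma = np.where(zero, 1.0, sigma)
    out = (rec.data - mu[:, None]) / sigma[:, None]
    if np.any(zero):
        out[zero] = 0.0
    return rec.copy_with(data=out), ChannelStats(mu=mu, sigma=rec.data.std(axis=1))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def bandpass_filter(rec: EEGRecording, cfg: PreprocessConfig) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass, plus optional notch."""
    lo, hi = cfg.band
    nyq = rec.fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    if cfg.notch is not None:
        if cfg.notch >= nyq:
            raise ValueError(f"notch {cfg.notch} Hz >= Nyquist {nyq} Hz")
        b, a = signal.iirnotch(cfg.notch, Q=30.0, fs=rec.fs)
        out = signal.filtfilt(b, a, out, axis=1)
    return rec.copy_with(data=out)


def spatial_filter(
    rec: EEGRecording, cfg: PreprocessConfig, montage: Montage | None = None
) -> EEGRecording:
    """Apply the configured spatial reference.

    ``common_average`` subtracts the instantaneous cross-channel mean;
    ``laplacian`` subtracts the mean of each channel's 4 nearest neighbours
    (needs montage positions); ``none`` is the identity.
    """
    method = cfg.spatial_method
    if method == "none":
        return rec.copy_with()
    if method == "common_average":
        if rec.n_channels < 2:
            raise ValueError("common_average needs at least 2 channels")
        return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))
    if method == "laplacian":
        if montage is None or montage.positions is None:
            raise ValueError("laplacian spatial filtering requires montage positions")
        if rec.n_channels < 4:
            raise ValueError("laplacian needs at least 4 channels")
        lab_to_pos = {l.lower(): montage.positions[i] for i, l in enumerate(montage.channel_labels)}
        try:
            pos = np.array([lab_to_pos[l.lower()] for l in rec.channel_labels])
        except KeyError as exc:
            raise ValueError(f"channel {exc} has no montage position") from exc
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        k = min(4, rec.n_channels - 1)
        neigh = np.argsort(d, axis=1)[:, :k]
        out = rec.data - rec.data[neigh].mean(axis=1)
        return rec.copy_with(data=out)
    raise ValueError(f"unknown spatial_method {method!r}")


def align_montage(rec: EEGRecording, montage: Montage) -> EEGRecording:
    """Reorder channels to montage order (case-insensitive label match).

    Channels absent from the montage are dropped with a warning; a montage
    label missing from the recording is an error.
    """
    lookup = {lab.lower(): i for i, lab in enumerate(rec.channel_labels)}
    order = []
    for lab in montage.channel_labels:
        if lab.lower() not in lookup:
            raise ValueError(f"montage label {lab!r} missing from recording")
        order.append(lookup[lab.lower()])
    dropped = set(range(rec.n_channels)) - set(order)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} channel(s) not in montage {montage.name!r}",
            stacklevel=2,
        )
    new_eog = None
    if rec.eog_index is not None and rec.eog_index in order:
        new_eog = order.index(rec.eog_index)
    return rec.copy_with(
        data=rec.data[order],
        channel_labels=[rec.channel_labels[i] for i in order],
        eog_index=new_eog,
    )


# ---------------------------------------------------------------------------
# Segmentation and quality
# ---------------------------------------------------------------------------


def segment(rec: EEGRecording, cfg: PreprocessConfig) -> SegmentSet:
    """Cut sliding windows of ``window_s`` seconds at ``hop_s`` stride."""
    win = int(round(cfg.window_s * rec.fs))
    hop = int(round(cfg.hop_s * rec.fs))
    if win < 1:
        raise ValueError("window shorter than one sample")
    if rec.n_samples < win:
        warnings.warn(
            f"record of {rec.n_samples} samples shorter than window of {win}; 0 segments",
            stacklevel=2,
        )
        segs = np.empty((0, rec.n_channels, win))
        return SegmentSet(segments=segs, session_ids=[], fs=rec.fs)
    n = (rec.n_samples - win) // hop + 1
    starts = np.arange(n) * hop
    segs = np.stack([rec.data[:, s : s + win] for s in starts])
    return SegmentSet(segments=segs, session_ids=[rec.session_id] * n, fs=rec.fs)


def consistency_score(session_flags: np.ndarray | list[bool]) -> float:
    """Fraction of sessions flagged consistent."""
    flags = np.asarray(session_flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("no sessions to score")
    return float(flags.sum() / flags.size)


def _band_power_vector(rec: EEGRecording, bands=((1, 4), (4, 8), (8, 13), (13, 30))) -> np.ndarray:
    freqs, psd = signal.welch(rec.data, fs=rec.fs, nperseg=min(rec.n_samples, 512), axis=1)
    out = []
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs < hi)
        out.append(psd[:, mask].sum(axis=1))
    return np.concatenate(out)


def session_consistency_flags(
    recordings: list[EEGRecording], cfg: PreprocessConfig
) -> np.ndarray:
    """Flag sessions whose band-power profile sits near the cohort median.

    A session is consistent when every element of its per-channel band-power
    vector lies within ``cfg.consistency_z`` robust z-units (median/MAD across
    sessions) of the across-session median.
    """
    if not recordings:
        raise ValueError("no sessions to score")
    vectors = np.stack([_band_power_vector(r) for r in recordings])
    med = np.median(vectors, axis=0)
    mad = np.median(np.abs(vectors - med), axis=0)
    scale = np.where(mad > 0, 1.4826 * mad, 1.0)
    z = np.abs(vectors - med) / scale
    return np.all(z <= cfg.consistency_z, axis=1)


def quality_score(
    segs: SegmentSet,
    cfg: PreprocessConfig,
    session_flags: np.ndarray | list[bool] | None = None,
) -> QualityReport:
    """Score segment validity: amplitude ceiling plus flatline floor.

    A segment is valid iff its peak absolute amplitude is at most
    ``cfg.validity_amp_uV`` and every channel's standard deviation is at
    least ``cfg.validity_flat_eps``.
    """
    if segs.n_segments == 0:
        raise ValueError("no segments to score")
    amp_ok = np.abs(segs.segments).max(axis=(1, 2)) <= cfg.validity_amp_uV
    flat_ok = segs.segments.std(axis=2).min(axis=1) >= cfg.validity_flat_eps
    valid = amp_ok & flat_ok
    segs.valid = valid
    cons = None
    n_cons = None
    n_sess = None
    if session_flags is not None:
        flags = np.asarray(session_flags, dtype=bool)
        cons = consistency_score(flags)
        n_cons = int(flags.sum())
        n_sess = int(flags.size)
    return QualityReport(
        consistency_score=cons,
        quality_score=float(valid.sum() / valid.size),
        n_consistent_sessions=n_cons,
        n_sessions=n_sess,
        n_valid_segments=int(valid.sum()),
        n_segments=int(valid.size),
    )


def run_chain(
    rec: EEGRecording,
    cfg: PreprocessConfig,
    montage: Montage | None = None,
) -> tuple[SegmentSet, dict]:
    """Run the full chain on one recording and return segments plus metadata."""
    meta: dict = {}
    if rec.eog_index is not None or cfg.beta_mode == "fixed":
        rec, beta = remove_eog(rec, cfg)
        meta["beta"] = beta.tolist()
    rec, stats = standardize(rec, cfg)
    meta["mu"] = stats.mu.tolist()
    meta["sigma"] = stats.sigma.tolist()
    rec = bandpass_filter(rec, cfg)
    rec = spatial_filter(rec, cfg, montage)
    if montage is not None:
        rec = align_montage(rec, montage)
    return segment(rec, cfg), meta
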