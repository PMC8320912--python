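"""Audio loading and short-time Fourier analysis for speech signals.

Speech energy is distributed across frequency differently for each phoneme;
windowed Fourier transforms expose this either as a single spectrum over a
phoneme-sized window or as a spectrogram (time on the horizontal axis,
frequency on the vertical axis, magnitude as brightness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window

__all__ = ["AudioSignal", "Spectrogram", "read_audio", "window_spectrum", "spectrogram"]

_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


@dataclass
class AudioSignal:
    """A mono audio signal with amplitudes normalised to [-1, 1].

    Attributes
    ----------
    samples : ndarray of float
        Amplitude sequence (dimensionless).
    sample_rate : float
        Sampling rate in Hz.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal requires a 1-D sample array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.n_samples / self.sample_rate

    @property
    def amp_min(self) -> float:
        return float(self.samples.min()) if self.n_samples else 0.0

    @property
    def amp_max(self) -> float:
        return float(self.samples.max()) if self.n_samples else 0.0


@dataclass
class Spectrogram:
    """Short-time Fourier magnitudes on a time-frequency grid.

    ``magnitudes`` has shape ``(n_freq_bins, n_windows)`` with
    ``n_freq_bins == window_length // 2 + 1``; values are either linear
    magnitudes or dB relative to the global maximum (``db`` flag).
    ``time_axis`` holds the centre time of each window in seconds.
    """

    magnitudes: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    window_length: int
    hop: int
    window_fn: str
    db: bool
    floor_db: float | None = None

    def plot(self, ax=None, timeline=None):
        """Render the spectrogram; optionally overlay phoneme boundaries.

        Parameters
        ----------
        ax : matplotlib axes, optional
        timeline : PhonemeTimeline, optional
            When given, phoneme boundaries are drawn as dashed vertical
            lines with labels alternating high/low for legibility.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        extent = (
            float(self.time_axis[0]),
            float(self.time_axis[-1]),
            float(self.freq_axis[0]),
            float(self.freq_axis[-1]),
        )
        ax.imshow(
            self.magnitudes,
            origin="lower",
            aspect="auto",
            extent=extent,
            cmap="magma",
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        if timeline is not None:
            top = self.freq_axis[-1]
            for k, iv in enumerate(timeline.phonemes):
                ax.axvline(iv.start, color="w", ls="--", lw=0.6, alpha=0.7)
                y = top * (0.92 if k % 2 == 0 else 0.84)
                ax.text(
                    (iv.start + iv.end) / 2, y, iv.label,
                    color="w", ha="center", fontsize=7,
                )
        return ax


def read_audio(path: str | Path) -> AudioSignal:
    """Read a PCM or float WAV file into a normalised :class:`AudioSignal`.

    Integer PCM samples are scaled to [-1, 1] by the type's full scale
    (16-bit by 2^15, 32-bit by 2^31, unsigned 8-bit recentred).  Stereo
    files are collapsed to mono by averaging the channels, with a warning.
    """
    rate, data = wavfile.read(Path(path))
    if data.ndim == 2:
        warnings.warn("stereo WAV collapsed to mono by channel averaging", stacklevel=2)
        data = data.mean(axis=1).astype(np.float64) if data.dtype.kind == "f" else data
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, sample_rate=float(rate))


def window_spectrum(
    signal: AudioSignal, t_start: float, t_end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum of the extract ``[t_start, t_end)``.

    Useful for inspecting the frequency content of a single phoneme by
    transforming a window spanning its whole duration.

    Returns
    -------
    freqs, mags : ndarray
        Frequency axis (0 .. sample_rate/2, Hz) and linear magnitudes.
    """
    if not (0 <= t_start < t_end <= signal.duration + 1e-9):
        raise ValueError(
            f"window [{t_start}, {t_end}) outside signal of duration {signal.duration:.6f} s"
        )
    i0 = int(round(t_start * signal.sample_rate))
    i1 = min(int(round(t_end * signal.sample_rate)), signal.n_samples)
    chunk = signal.samples[i0:i1]
    if chunk.size < 2:
        raise ValueError("analysis window shorter than 2 samples")
    mags = np.abs(np.fft.rfft(chunk))
    freqs = np.fft.rfftfreq(chunk.size, d=1.0 / signal.sample_rate)
    return freqs, mags


def spectrogram(
    signal: AudioSignal,
    window_length: int = 512,
    hop: int = 256,
    window_fn: str = "hann",
    db: bool = True,
    floor_db: float = -80.0,
) -> Spectrogram:
    """Compute a short-time Fourier spectrogram.

    The signal is partitioned into windows of ``window_length`` samples
    advancing by ``hop``; each window is tapered by ``window_fn`` and
    transformed, giving ``floor((n_samples - window_length)/hop) + 1``
    columns.  Defaults (512-sample window, 50% overlap, Hann) are
    conventional for 16 kHz speech.

    Parameters
    ----------
    db : bool
        When True (default) magnitudes are converted to dB relative to the
        global maximum and clipped at ``floor_db``; when False linear
        magnitudes are returned (in which case the transform is exactly
        linear in the input amplitude).
    """
    if window_length < 4:
        raise ValueError("window_length must be >= 4 samples")
    if not 1 <= hop <= window_length:
        raise ValueError("hop must satisfy 1 <= hop <= window_length")
    n = signal.n_samples
    if n < window_length:
        raise ValueError(
            f"signal of {n} samples shorter than one window ({window_length})"
        )
    win = get_window(window_fn, window_length, fftbins=True)
    n_windows = (n - window_length) // hop + 1
    idx = hop * np.arange(n_windows)[:, None] + np.arange(window_length)[None, :]
    frames = signal.samples[idx] * win
    mags = np.abs(np.fft.rfft(frames, axis=1)).T  # (n_bins, n_windows)
    if db:
        ref = mags.max()
        if ref == 0:
            mags = np.full_like(mags, floor_db)
        else:
            with np.errstate(divide="ignore"):
                mags = 20.0 * np.log10(mags / ref)
            mags = np.maximum(mags, floor_db)
    freq_axis = np.fft.rfftfreq(window_length, d=1.0 / signal.sample_rate)
    time_axis = (hop * np.arange(n_windows) + window_length / 2.0) / signal.sample_rate
    return Spectrogram(
        magnitudes=mags,
        freq_axis=freq_axis,
        time_axis=time_axis,
        window_length=window_length,
        hop=hop,
        window_fn=window_fn,
        db=db,
        floor_db=floor_db if db else None,
    )
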