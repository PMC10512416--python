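"""Audio preparation: speech power, additive white-noise masking at a fixed
SNR, duration trimming, and dichotic headphone-screening stimuli.

The masking convention mirrors classic additive-white-Gaussian-noise
utilities: the clean clip's mean-square power P is measured first, then
zero-mean Gaussian noise with *theoretical* variance P / 10^(SNR/10) is
added.  The realized (sample) SNR of any given masked clip therefore
fluctuates around the target; ``realized_snr`` measures it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

DEFAULT_SNR_DB = 10.0
TRIM_MS = 3000


@dataclass(frozen=True)
class AudioClip:
    """Mono (n,) or stereo (n, 2) float samples at ``sample_rate`` Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim not in (1, 2) or (arr.ndim == 2 and arr.shape[1] != 2):
            raise ValueError("samples must be shape (n,) or (n, 2)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else 2

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sample_rate


@dataclass(frozen=True)
class SnrSpec:
    snr_db: float = DEFAULT_SNR_DB
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def measure_power(clip: AudioClip) -> float:
    """Mean-square power (1/N)·Σ s², pooled over channels."""
    if clip.n_samples == 0:
        raise ValueError("cannot measure power of an empty clip")
    p = float(np.mean(np.square(clip.samples)))
    if p == 0.0:
        raise ValueError("clip is silent; power-based SNR scaling is undefined")
    return p


def mix_noise_at_snr(clip: AudioClip, spec: SnrSpec) -> AudioClip:
    """Add seeded Gaussian white noise with variance P_signal / 10^(SNR/10)."""
    power = measure_power(clip)  # raises on silent/empty input
    sigma = math.sqrt(power / 10.0 ** (spec.snr_db / 10.0))
    rng = np.random.default_rng(spec.noise_seed)
    noise = rng.normal(0.0, sigma, size=clip.samples.shape)
    return AudioClip(clip.samples + noise, clip.sample_rate)


def realized_snr(signal: AudioClip, noisy: AudioClip) -> float:
    """Measured SNR in dB: 10·log10(P_signal / P_noise), noise = noisy − signal.

    Returns ``math.inf`` when the two clips are identical (zero noise).
    """
    if signal.samples.shape != noisy.samples.shape or signal.sample_rate != noisy.sample_rate:
        raise ValueError("signal and noisy clips must share shape and sample rate")
    p_signal = measure_power(signal)
    residual = noisy.samples - signal.samples
    p_noise = float(np.mean(np.square(residual)))
    if p_noise == 0.0:
        return math.inf
    return 10.0 * math.log10(p_signal / p_noise)


def trim_clip(clip: AudioClip, duration_ms: float = TRIM_MS, pad: bool = False) -> AudioClip:
    """Keep the first ⌊duration·rate/1000⌋ samples; optionally zero-pad short clips."""
    n_keep = int(duration_ms * clip.sample_rate // 1000)
    if clip.n_samples < n_keep:
        if not pad:
            raise ValueError(
                f"clip is {clip.duration_ms:.0f} ms, shorter than {duration_ms:.0f} ms (set pad=True to zero-pad)"
            )
        pad_shape = (n_keep - clip.n_samples,) + clip.samples.shape[1:]
        return AudioClip(np.concatenate([clip.samples, np.zeros(pad_shape)]), clip.sample_rate)
    return AudioClip(clip.samples[:n_keep].copy(), clip.sample_rate)


def synth_speech_like(
    duration_ms: float = 3000,
    sample_rate: int = 44100,
    f0: float = 120.0,
    seed: int = 0,
) -> AudioClip:
    """Synthetic speech-like clip: a harmonic complex with a syllabic envelope.

    A stand-in for recorded emotional speech — it reproduces the coarse
    spectro-temporal statistics that matter for SNR bookkeeping (harmonic
    structure, ~3 Hz amplitude modulation, aperiodic component), nothing
    perceptual.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_ms * sample_rate / 1000)
    t = np.arange(n) / sample_rate
    voiced = np.zeros(n)
    for k in range(1, 13):
        voiced += (1.0 / k) * np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi))
    envelope = 0.55 + 0.45 * np.sin(2 * np.pi * 3.1 * t + rng.uniform(0, 2 * np.pi))
    aperiodic = 0.05 * rng.standard_normal(n)
    samples = envelope * voiced + aperiodic
    samples *= 0.1 / np.sqrt(np.mean(np.square(samples)))
    return AudioClip(samples, sample_rate)


def make_screening_pair(
    kind: str,
    sample_rate: int = 44100,
    duration_ms: float = 1000,
    frequency: float = 200.0,
    hp_center: float = 600.0,
    hp_width_frac: float = 0.06,
    amplitude: float = 0.1,
    seed: int = 0,
) -> AudioClip:
    """Two-channel stimulus for dichotic headphone screening.

    ``antiphase_tone``: a pure tone with the right channel sign-inverted, so
    the two channels cancel exactly when summed (as over loudspeakers).
    ``huggins_pitch``: one white-noise realization in both ears except for a
    narrow band around ``hp_center`` whose phase is shifted by π in the right
    ear — audible as a faint pitch only under true dichotic presentation.
    """
    n = int(duration_ms * sample_rate / 1000)
    if kind == "antiphase_tone":
        if not 0 < frequency < sample_rate / 2:
            raise ValueError(f"tone frequency {frequency} Hz outside (0, Nyquist)")
        t = np.arange(n) / sample_rate
        left = amplitude * np.sin(2 * np.pi * frequency * t)
        return AudioClip(np.stack([left, -left], axis=1), sample_rate)
    if kind == "huggins_pitch":
        if not 0 < hp_center < sample_rate / 2:
            raise ValueError(f"Huggins center {hp_center} Hz outside (0, Nyquist)")
        rng = np.random.default_rng(seed)
        left = rng.standard_normal(n)
        spectrum = np.fft.rfft(left)
        freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        band = (freqs >= hp_center * (1 - hp_width_frac)) & (freqs <= hp_center * (1 + hp_width_frac))
        right = np.fft.irfft(spectrum * np.where(band, -1.0, 1.0), n=n)
        scale = amplitude / np.sqrt(np.mean(np.square(left)))
        return AudioClip(np.stack([left * scale, right * scale], axis=1), sample_rate)
    raise ValueError(f"unknown screening kind {kind!r}")


def read_wav(path) -> AudioClip:
    """Read PCM16/PCM32/float32/float64 WAV into float samples in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        samples = data.astype(np.float64)
    return AudioClip(samples, int(rate))


def write_wav(path, clip: AudioClip, subtype: str = "float32") -> None:
    """Write a clip as float32 or PCM16 WAV."""
    if subtype == "float32":
        wavfile.write(path, clip.sample_rate, clip.samples.astype(np.float32))
    elif subtype == "pcm16":
        scaled = np.clip(clip.samples, -1.0, 1.0) * 32767.0
        wavfile.write(path, clip.sample_rate, scaled.astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")
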