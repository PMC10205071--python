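"""Stimulus predictor time series on a shared clock.

Speech-evoked encoding models predict a continuous neural response from
continuous stimulus descriptors.  This module builds those descriptors:

* an auditory **envelope spectrogram** -- a gammatone filterbank magnitude
  representation, ERB-spaced, binned into a few broad frequency bands;
* an **onset spectrogram** -- half-wave-rectified temporal edges of the
  (log) envelope, a transparent stand-in for neural edge-extraction models;
* **impulse predictors** -- word onsets, non-initial phoneme onsets, and
  phoneme-onset impulses scaled by cohort-model surprisal and entropy.

All channels live on one master clock (default 100 Hz) in a
:class:`PredictorSet`; event times map to the nearest sample (round half up).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .lexicon import Lexicon, annotate_word

__all__ = [
    "AlignedWord",
    "AlignedStimulus",
    "PredictorSet",
    "erb_number",
    "erb_to_hz",
    "gammatone_bands",
    "onset_bands",
    "impulse_series",
    "build_predictor_set",
    "standardize",
    "event_sample",
]

#: master sampling rate for predictors and responses (Hz)
DEFAULT_RATE = 100.0


@dataclass(frozen=True)
class AlignedWord:
    """One word of a forced-aligned session."""

    wordform: str
    onset: float  # s
    phonemes: tuple[str, ...]
    phoneme_onsets: tuple[float, ...]  # s, absolute

    def __post_init__(self) -> None:
        if len(self.phonemes) != len(self.phoneme_onsets):
            raise ValueError(f"{self.wordform!r}: phoneme/onset count mismatch")
        on = np.asarray(self.phoneme_onsets)
        if len(on) and (np.diff(on) <= 0).any():
            raise ValueError(f"{self.wordform!r}: phoneme onsets not increasing")


@dataclass(frozen=True)
class AlignedStimulus:
    """An ordered sequence of aligned words plus the session duration (s)."""

    words: tuple[AlignedWord, ...]
    duration: float

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for w in self.words:
            if w.phoneme_onsets and w.phoneme_onsets[0] != w.onset:
                raise ValueError(f"{w.wordform!r}: first phoneme onset != word onset")
            if w.onset <= prev_end:
                raise ValueError("word onsets not strictly increasing across words")
            prev_end = w.phoneme_onsets[-1] if w.phoneme_onsets else w.onset
        if self.words and prev_end >= self.duration:
            raise ValueError("events extend beyond the session duration")

    @property
    def n_phonemes(self) -> int:
        return sum(len(w.phonemes) for w in self.words)

    def shifted(self, offset: float) -> "AlignedStimulus":
        """A copy with all times moved by ``offset`` seconds."""
        return AlignedStimulus(
            tuple(
                AlignedWord(
                    w.wordform,
                    w.onset + offset,
                    w.phonemes,
                    tuple(t + offset for t in w.phoneme_onsets),
                )
                for w in self.words
            ),
            self.duration + offset,
        )


class PredictorSet:
    """Named predictor channels sharing one sampling rate and length.

    Channels are 1-D ``(n_samples,)`` or banded 2-D ``(n_bands, n_samples)``
    arrays.  Iteration order is insertion order and defines the feature
    expansion used by the estimation code.
    """

    def __init__(self, channels: Mapping[str, np.ndarray], rate: float = DEFAULT_RATE):
        self.rate = float(rate)
        self.channels: dict[str, np.ndarray] = {}
        n = None
        for name, arr in channels.items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                arr = arr[None, :]
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} must be 1-D or 2-D")
            if n is None:
                n = arr.shape[1]
            elif arr.shape[1] != n:
                raise ValueError(f"channel {name!r} length mismatch")
            self.channels[name] = arr
        if n is None:
            raise ValueError("predictor set has no channels")
        self.n_samples = n

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    @property
    def feature_names(self) -> list[str]:
        out = []
        for name, arr in self.channels.items():
            if arr.shape[0] == 1:
                out.append(name)
            else:
                out.extend(f"{name}[{b}]" for b in range(arr.shape[0]))
        return out

    @property
    def n_features(self) -> int:
        return sum(arr.shape[0] for arr in self.channels.values())

    def to_array(self) -> np.ndarray:
        """Stack all channels/bands into a ``(n_features, n_samples)`` array."""
        return np.concatenate(list(self.channels.values()), axis=0)

    def feature_channel_index(self) -> np.ndarray:
        """Channel index of each expanded feature (bands share their channel)."""
        idx = []
        for i, arr in enumerate(self.channels.values()):
            idx.extend([i] * arr.shape[0])
        return np.asarray(idx, np.int64)

    def subset(self, names: Iterable[str]) -> "PredictorSet":
        names = list(names)
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"unknown channels: {missing}")
        return PredictorSet({n: self.channels[n] for n in names}, self.rate)

    def drop(self, names: Iterable[str]) -> "PredictorSet":
        drop = set(names)
        keep = {n: a for n, a in self.channels.items() if n not in drop}
        return PredictorSet(keep, self.rate)

    def concatenate(self, other: "PredictorSet") -> "PredictorSet":
        """Append ``other`` in time (channels must match)."""
        if self.names != other.names or self.rate != other.rate:
            raise ValueError("predictor sets are not compatible")
        return PredictorSet(
            {
                n: np.concatenate([self.channels[n], other.channels[n]], axis=1)
                for n in self.channels
            },
            self.rate,
        )

    def __repr__(self) -> str:
        return (
            f"<PredictorSet: {len(self.channels)} channels, "
            f"{self.n_features} features, {self.n_samples} samples @ {self.rate} Hz>"
        )


# ---------------------------------------------------------------------------
# acoustic predictors


def erb_number(f_hz):
    """ERB-number (Cam) of a frequency in Hz (Glasberg & Moore scale)."""
    return 21.4 * np.log10(1.0 + 4.37 * np.asarray(f_hz, float) / 1000.0)


def erb_to_hz(erb):
    """Inverse of :func:`erb_number`."""
    return (10.0 ** (np.asarray(erb, float) / 21.4) - 1.0) * 1000.0 / 4.37


def gammatone_bands(
    waveform: np.ndarray,
    fs: float,
    n_channels: int = 256,
    n_bands: int = 8,
    fmin: float = 20.0,
    fmax: float = 5000.0,
    out_rate: float = DEFAULT_RATE,
) -> np.ndarray:
    """Banded gammatone magnitude spectrogram of an audio waveform.

    ``n_channels`` fourth-order gammatone filters with center frequencies
    regularly spaced on the ERB-number scale between ``fmin`` and ``fmax``
    are applied to the waveform; the rectified outputs are averaged within
    non-overlapping windows of ``1/out_rate`` s and the channels averaged
    into ``n_bands`` contiguous equal ERB-index bins.

    Returns a nonnegative ``(n_bands, ceil(duration*out_rate))`` array.
    """
    waveform = np.asarray(waveform, float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be 1-D")
    if fs < 2 * fmax:
        raise ValueError(f"fmax={fmax} Hz above Nyquist for fs={fs} Hz")
    if n_channels % n_bands:
        raise ValueError("n_channels must be a multiple of n_bands")
    # FIR gammatone impulse response length (scipy default: 15 ms)
    numtaps = int(0.015 * fs)
    if len(waveform) < numtaps:
        raise ValueError("audio shorter than the gammatone filter ringing")
    centers = erb_to_hz(np.linspace(erb_number(fmin), erb_number(fmax), n_channels))
    n_out = int(np.ceil(len(waveform) / fs * out_rate - 1e-9))
    edges = np.floor(np.arange(n_out) * fs / out_rate).astype(np.intp)
    bands = np.zeros((n_bands, n_out))
    per_band = n_channels // n_bands
    for c, fc in enumerate(centers):
        b, _ = _signal.gammatone(fc, "fir", fs=fs)
        env = np.abs(_signal.fftconvolve(waveform, b, mode="full")[: len(waveform)])
        # average within output-rate windows
        sums = np.add.reduceat(env, edges)
        counts = np.diff(np.append(edges, len(env)))
        bands[c // per_band] += sums / counts
    bands /= per_band
    return bands


def onset_bands(
    envelope_bands: np.ndarray,
    smooth_samples: int = 3,
    floor_ratio: float = 1e-4,
) -> np.ndarray:
    """Acoustic-edge (onset) signal for each envelope band.

    Computed as the half-wave-rectified first difference of the floored log
    envelope after a short moving-average smoothing.  This is a transparent
    stand-in for neural edge-extraction models cited in the auditory
    literature, exposed behind this named interface so such a model can be
    swapped in; it shares the properties that matter here: zero response on
    steady-state and decaying segments, a localized peak at energy onsets.
    """
    env = np.asarray(envelope_bands, float)
    if env.ndim == 1:
        env = env[None, :]
    if (env < 0).any():
        raise ValueError("envelope bands must be nonnegative")
    peak = env.max()
    floor = peak * floor_ratio if peak > 0 else 1.0
    logenv = np.log(np.maximum(env, floor))
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        pad = smooth_samples // 2
        # edge-replicate padding avoids spurious onsets at the array ends
        padded = np.pad(logenv, ((0, 0), (pad, pad)), mode="edge")
        logenv = np.apply_along_axis(
            lambda x: np.convolve(x, kernel, mode="valid"), 1, padded
        )[:, : logenv.shape[1]]
    d = np.diff(logenv, axis=1, prepend=logenv[:, :1])
    return np.maximum(d, 0.0)


# ---------------------------------------------------------------------------
# impulse predictors


def event_sample(time_s: float, rate: float) -> int:
    """Nearest sample to an event time, rounding half up."""
    return int(np.floor(time_s * rate + 0.5))


def impulse_series(
    events: Sequence[tuple[float, float]],
    rate: float,
    n_samples: int,
) -> np.ndarray:
    """Impulse time series: each event's value added at its nearest sample.

    Coincident events sum.  An event at the extreme end of the last sampling
    interval is assigned to the last sample; events at or beyond the series
    duration are errors.
    """
    x = np.zeros(n_samples)
    duration = n_samples / rate
    for t, v in events:
        if not np.isfinite(v):
            raise ValueError(f"non-finite event value at t={t}")
        if t < 0 or t >= duration:
            raise ValueError(f"event at t={t}s outside [0, {duration}s)")
        s = event_sample(t, rate)
        if s == n_samples:  # rounded up past the end; keep within the series
            s = n_samples - 1
        x[s] += v
    return x


def build_predictor_set(
    session: AlignedStimulus,
    lexicon: Lexicon,
    audio: tuple[np.ndarray, float] | None = None,
    split_initial: bool = False,
    split_syllabic: Mapping[str, str] | None = None,
    rate: float = DEFAULT_RATE,
    strict: bool = True,
    n_acoustic_bands: int = 8,
) -> PredictorSet:
    """Assemble the full predictor set for one session.

    Linguistic channels (always present): ``word_onset`` (unit impulse at
    every word onset), ``phoneme_onset`` (unit impulses at non-initial
    phoneme onsets), and surprisal/entropy impulse channels carrying the
    cohort-model quantities at *all* phoneme onsets.  With ``split_initial``
    the surprisal/entropy channels are split into word-initial and
    non-initial variants; with ``split_syllabic`` they are split by the given
    word-class map (e.g. mono- vs multisyllabic).  If ``audio`` (waveform,
    fs) is supplied, 8-band ``envelope`` and ``onset`` spectrogram channels
    are added.  Silence between events is all-zero in every channel.
    """
    if split_initial and split_syllabic is not None:
        raise ValueError("split_initial and split_syllabic are mutually exclusive")
    n_samples = int(np.ceil(session.duration * rate - 1e-9))

    word_events: list[tuple[float, float]] = []
    phon_events: list[tuple[float, float]] = []
    info_events: dict[str, list[tuple[float, float]]] = {}

    def _info_channels() -> list[str]:
        if split_initial:
            return [
                "surprisal_initial",
                "surprisal_noninitial",
                "entropy_initial",
                "entropy_noninitial",
            ]
        if split_syllabic is not None:
            classes = sorted(set(split_syllabic.values()))
            return [f"{q}_{c}" for q in ("surprisal", "entropy") for c in classes]
        return ["surprisal", "entropy"]

    for name in _info_channels():
        info_events[name] = []

    for word in session.words:
        if word.wordform not in lexicon:
            raise KeyError(f"word {word.wordform!r} not resolvable in the lexicon")
        ann = annotate_word(lexicon, word.phonemes, word.wordform, strict=strict)
        word_events.append((word.onset, 1.0))
        for i, t in enumerate(word.phoneme_onsets):
            if i > 0:
                phon_events.append((t, 1.0))
            if split_initial:
                tag = "initial" if i == 0 else "noninitial"
                info_events[f"surprisal_{tag}"].append((t, ann.surprisal[i]))
                info_events[f"entropy_{tag}"].append((t, ann.entropy[i]))
            elif split_syllabic is not None:
                cls = split_syllabic[word.wordform]
                info_events[f"surprisal_{cls}"].append((t, ann.surprisal[i]))
                info_events[f"entropy_{cls}"].append((t, ann.entropy[i]))
            else:
                info_events["surprisal"].append((t, ann.surprisal[i]))
                info_events["entropy"].append((t, ann.entropy[i]))

    channels: dict[str, np.ndarray] = {}
    if audio is not None:
        waveform, fs = audio
        env = gammatone_bands(
            waveform, fs, n_bands=n_acoustic_bands, out_rate=rate
        )
        # pad/trim the acoustic channels to the session clock
        env = _fit_length(env, n_samples)
        channels["envelope"] = env
        channels["onset"] = onset_bands(env)
    channels["word_onset"] = impulse_series(word_events, rate, n_samples)
    channels["phoneme_onset"] = impulse_series(phon_events, rate, n_samples)
    for name, events in info_events.items():
        channels[name] = impulse_series(events, rate, n_samples)
    return PredictorSet(channels, rate)


def _fit_length(arr: np.ndarray, n: int) -> np.ndarray:
    if arr.shape[1] >= n:
        return arr[:, :n]
    pad = np.zeros((arr.shape[0], n - arr.shape[1]))
    return np.concatenate([arr, pad], axis=1)


# ---------------------------------------------------------------------------
# standardization


def standardize(data, return_params: bool = False):
    """Center each channel and divide by its mean absolute value.

    Accepts a :class:`PredictorSet` (returns a new one) or an array whose
    last axis is time (returns an array).  After standardization every
    channel has mean 0 and mean absolute value 1.  A channel that is
    constant (zero after centering) is an error, identified by name where
    available.
    """
    if isinstance(data, PredictorSet):
        out = {}
        params = {}
        for name, arr in data.channels.items():
            centered = arr - arr.mean(axis=1, keepdims=True)
            scale = np.abs(centered).mean(axis=1, keepdims=True)
            if (scale == 0).any():
                raise ValueError(f"channel {name!r} is constant; cannot standardize")
            out[name] = centered / scale
            params[name] = (arr.mean(axis=1), scale[:, 0])
        ps = PredictorSet(out, data.rate)
        return (ps, params) if return_params else ps
    arr = np.asarray(data, float)
    centered = arr - arr.mean(axis=-1, keepdims=True)
    scale = np.abs(centered).mean(axis=-1, keepdims=True)
    if (scale == 0).any():
        raise ValueError("constant series cannot be standardized")
    result = centered / scale
    if return_params:
        return result, (arr.mean(axis=-1), scale[..., 0])
    return result
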