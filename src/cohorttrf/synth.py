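"""Synthetic listening studies with a known entropy/surprisal dissociation.

Generates everything a desk-scale re-analysis needs without neuroimaging
data: a toy pronunciation lexicon with Zipf-distributed frequencies,
forced-alignment-style sessions (isolated words separated by a 267 ms
interstimulus interval, or pause-free continuous speech), ground-truth
temporal response functions with the characteristic two-peak shape
(positive lobe near 100 ms, negative lobe near 350 ms), and multi-source
recordings built by convolving the predictor impulse trains with those
kernels and adding Gaussian noise at a configurable SNR.

The dissociation of interest is encoded in the per-group kernel gains: the
default study gives the entropy predictor zero gain in the single-word
group and full gain in the continuous group, while surprisal drives both,
so recovery of the interaction can be scored against the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .lexicon import LexEntry, Lexicon
from .mtrf import TRFBasis, TRFModel, predict
from .predictors import AlignedStimulus, AlignedWord, PredictorSet, build_predictor_set
from .stats import SourceGeometry

__all__ = [
    "GroupSpec",
    "SimConfig",
    "SimStudy",
    "GroupData",
    "generate_lexicon",
    "generate_session",
    "two_peak_kernel",
    "ground_truth_trfs",
    "simulate_recording",
    "simulate_study",
    "match_phoneme_count",
]

#: compact ARPABET-style inventory for toy lexicons.  Deliberately small:
#: heavy prefix-sharing between wordforms (as English phonotactics produces
#: in real lexicons) is what keeps cohorts large and entropy informative.
DEFAULT_INVENTORY = ("P", "T", "K", "S", "M", "N", "L", "R", "AA", "IY")


@dataclass(frozen=True)
class GroupSpec:
    """One participant group: session style, size, and true kernel gains."""

    name: str
    session_mode: str  # "single_word" | "continuous"
    n_subjects: int
    gains: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.session_mode not in ("single_word", "continuous"):
            raise ValueError(f"unknown session mode {self.session_mode!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for k, v in self.gains.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite gain for {k!r}")


def _default_groups() -> tuple[GroupSpec, GroupSpec]:
    # the dissociation design: surprisal everywhere, entropy only in
    # continuous speech; onset covariates in both
    base = {"word_onset": 0.5, "phoneme_onset": 0.5, "surprisal": 1.0}
    return (
        GroupSpec("single_word", "single_word", 18, {**base, "entropy": 0.0}),
        GroupSpec("continuous", "continuous", 12, {**base, "entropy": 1.0}),
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic two-group listening study.

    Defaults mirror the structure of a single-word MEG study compared with
    an audiobook study: 1,000 words per session, a 267 ms interstimulus
    interval in the single-word condition and none in continuous speech,
    and groups of 18 and 12 participants.  Kernel gains are per predictor
    channel and per group; SNR is RMS(signal) / RMS(noise) at sources
    carrying signal.
    """

    seed: int = 0
    # lexicon
    lexicon_size: int = 1000
    inventory: tuple[str, ...] = DEFAULT_INVENTORY
    word_length_range: tuple[int, int] = (2, 5)
    zipf_exponent: float = 1.0
    # sessions
    n_words: int = 1000
    isi: float = 0.267  # s, single-word mode only
    speech_rate: float = 8.0  # phonemes / s
    rate: float = 100.0  # master clock, Hz
    # responses
    snr: float = 2.0
    subject_jitter_sd: float = 0.2  # lognormal sigma on per-subject gain
    # source space
    grid_shape: tuple[int, int] = (6, 6)
    grid_spacing: float = 5.0  # mm
    roi_box: tuple[int, int, int, int] = (1, 4, 1, 4)
    # delay basis for ground-truth kernels
    basis_tmin: float = -0.1
    basis_tmax: float = 1.0
    groups: tuple[GroupSpec, ...] = field(default_factory=_default_groups)

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive (np.inf for noise-free)")
        if self.isi < 0:
            raise ValueError("ISI must be nonnegative")
        if len(self.inventory) < 4:
            raise ValueError("inventory needs at least 4 symbols")
        if self.lexicon_size < 2:
            raise ValueError("lexicon needs at least 2 words")

    def basis(self) -> TRFBasis:
        return TRFBasis(self.basis_tmin, self.basis_tmax, self.rate)

    def geometry(self) -> SourceGeometry:
        return SourceGeometry.grid(
            *self.grid_shape,
            spacing=self.grid_spacing,
            roi=self.roi_box,
            split_hemispheres=True,
        )


# ---------------------------------------------------------------------------
# generators


def generate_lexicon(config: SimConfig, rng: np.random.Generator | None = None) -> Lexicon:
    """Random toy lexicon with unique pronunciations and Zipf frequencies.

    Frequencies follow the law ``f(rank) = size / rank**s`` exactly, with
    ranks assigned to wordforms in random order, so the top-rank to rank-r
    frequency ratio is ``r**s``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lmin, lmax = config.word_length_range
    if lmin < 1 or lmax < lmin:
        raise ValueError("invalid word length range")
    n_inv = len(config.inventory)
    capacity = sum(n_inv**l for l in range(lmin, lmax + 1))
    if config.lexicon_size > capacity:
        raise ValueError(
            f"lexicon size {config.lexicon_size} exceeds the "
            f"{capacity} distinct pronunciations available"
        )
    prons: set[tuple[str, ...]] = set()
    ordered: list[tuple[str, ...]] = []
    attempts = 0
    while len(ordered) < config.lexicon_size:
        attempts += 1
        if attempts > 1000 * config.lexicon_size:
            raise RuntimeError("pronunciation sampling failed to find unique forms")
        length = int(rng.integers(lmin, lmax + 1))
        pron = tuple(
            config.inventory[i] for i in rng.integers(0, n_inv, size=length)
        )
        if pron not in prons:
            prons.add(pron)
            ordered.append(pron)
    ranks = rng.permutation(config.lexicon_size) + 1
    entries = [
        LexEntry(
            f"w{i:05d}",
            pron,
            config.lexicon_size / ranks[i] ** config.zipf_exponent,
        )
        for i, pron in enumerate(ordered)
    ]
    return Lexicon(entries, config.inventory)


def generate_session(
    lexicon: Lexicon,
    config: SimConfig,
    mode: str | None = None,
    rng: np.random.Generator | None = None,
    n_words: int | None = None,
) -> AlignedStimulus:
    """A simulated aligned session of frequency-sampled words.

    Phoneme onsets within a word are spaced by ``1 / speech_rate``; in
    single-word mode each word is followed by the ISI in addition to the
    final phoneme's slot, while continuous mode runs words back to back
    (inter-word onset gap exactly ``1 / speech_rate``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mode = mode or "single_word"
    if mode not in ("single_word", "continuous"):
        raise ValueError(f"unknown session mode {mode!r}")
    n_words = n_words if n_words is not None else config.n_words
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    weights = np.array([lexicon.weight(e.wordform) for e in lexicon.entries])
    weights = weights / weights.sum()
    idx = rng.choice(len(lexicon.entries), size=n_words, p=weights)
    dt = 1.0 / config.speech_rate
    words = []
    cursor = dt  # lead-in silence of one phoneme slot
    for i in idx:
        entry = lexicon.entries[i]
        onsets = tuple(cursor + j * dt for j in range(len(entry.pronunciation)))
        words.append(
            AlignedWord(entry.wordform, onsets[0], entry.pronunciation, onsets)
        )
        cursor = onsets[-1] + dt
        if mode == "single_word":
            cursor += config.isi
    duration = cursor + dt  # trailing silence covers TRF delays
    return AlignedStimulus(tuple(words), duration)


def match_phoneme_count(session: AlignedStimulus, target: int) -> AlignedStimulus:
    """Truncate a session to approximately ``target`` phonemes (whole words).

    Words are kept in order until the phoneme count reaches the target; the
    result is within one word of the target count.
    """
    if target < 1:
        raise ValueError("target phoneme count must be >= 1")
    kept = []
    count = 0
    for w in session.words:
        if count >= target:
            break
        kept.append(w)
        count += len(w.phonemes)
    if not kept:
        raise ValueError("session has no words")
    duration = min(session.duration, kept[-1].phoneme_onsets[-1] + 1.0)
    return AlignedStimulus(tuple(kept), duration)


# ---------------------------------------------------------------------------
# ground-truth kernels and recordings


def two_peak_kernel(
    basis: TRFBasis,
    peak1: float = 0.100,
    peak2: float = 0.350,
    width: float = 0.050,
    ratio: float = -0.7,
) -> np.ndarray:
    """The canonical two-peak TRF template, exactly within the basis span.

    A positive Gaussian lobe at ``peak1`` and an opposite lobe scaled by
    ``ratio`` at ``peak2``; ``width`` is the FWHM of each lobe.  The
    template is projected onto the Hamming basis and re-expanded, so it
    lies exactly in the span used by the estimator.

    Returns basis weights ``(n_basis,)``.
    """
    sigma = width / 2.355
    t = basis.delay_times
    kern = np.exp(-((t - peak1) ** 2) / (2 * sigma**2)) + ratio * np.exp(
        -((t - peak2) ** 2) / (2 * sigma**2)
    )
    return basis.project(kern)


def ground_truth_trfs(
    gains: Mapping[str, float],
    basis: TRFBasis,
    feature_names: list[str] | None = None,
) -> TRFModel:
    """Ground-truth kernels: ``gain x two-peak template`` per channel."""
    template = two_peak_kernel(basis)
    names = feature_names if feature_names is not None else list(gains)
    weights = np.array([gains.get(n, 0.0) * template for n in names])
    return TRFModel(basis, list(names), weights)


def simulate_recording(
    predictors: PredictorSet,
    truth: TRFModel,
    geometry: SourceGeometry,
    snr: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-source recording: spatially weighted convolution signal + noise.

    Each ROI source carries the full convolution of the predictors with the
    ground-truth kernels (spatial weight 1); sources outside the ROI carry
    pure noise (weight 0).  Noise is white Gaussian with standard deviation
    ``RMS(signal) / snr`` at every source.

    Returns ``(recording, noiseless)`` with shape ``(n_sources, n_time)``.
    """
    if predictors.rate != truth.basis.rate:
        raise ValueError("predictor and kernel sampling rates differ")
    signal = predict(truth, predictors)
    weights = (
        geometry.roi_mask.astype(float)
        if geometry.roi_mask is not None
        else np.ones(geometry.n_sources)
    )
    noiseless = weights[:, None] * signal[None, :]
    if np.isinf(snr):
        return noiseless.copy(), noiseless
    sig_rms = np.sqrt(np.mean(signal**2))
    if sig_rms == 0:
        raise ValueError("ground-truth signal is identically zero")
    noise_sd = sig_rms / snr
    noise = rng.normal(0.0, noise_sd, size=noiseless.shape)
    return noiseless + noise, noiseless


@dataclass
class GroupData:
    """Per-group simulated sessions, predictors, truths and recordings."""

    spec: GroupSpec
    sessions: list[AlignedStimulus]
    predictor_sets: list[PredictorSet]
    truths: list[TRFModel]  # per subject (jittered gains)
    recordings: np.ndarray  # (n_subjects, n_sources, n_time_max)
    noiseless: np.ndarray
    n_times: np.ndarray  # valid length per subject


@dataclass
class SimStudy:
    """A complete synthetic study: inputs, ground truth, and recordings."""

    config: SimConfig
    lexicon: Lexicon
    geometry: SourceGeometry
    basis: TRFBasis
    groups: list[GroupData]
    truth_table: pd.DataFrame


def simulate_study(config: SimConfig) -> SimStudy:
    """Simulate the full two-group study described by ``config``.

    Deterministic given ``config.seed``.  Each subject receives an
    independently sampled session, per-subject lognormal gain jitter
    (applied jointly to all channels, so within-subject gain ratios are
    preserved), and an independent noise realization.
    """
    if len(config.groups) < 2:
        raise ValueError("study needs two groups")
    rng = np.random.default_rng(config.seed)
    lexicon = generate_lexicon(config, rng)
    geometry = config.geometry()
    basis = config.basis()

    groups = []
    truth_rows = []
    for spec in config.groups:
        sessions, psets, truths, recs, clean = [], [], [], [], []
        for subj in range(spec.n_subjects):
            session = generate_session(lexicon, config, spec.session_mode, rng)
            ps = build_predictor_set(session, lexicon, rate=config.rate)
            jitter = float(np.exp(rng.normal(0.0, config.subject_jitter_sd)))
            gains = {k: v * jitter for k, v in spec.gains.items()}
            truth = ground_truth_trfs(gains, basis, ps.feature_names)
            rec, noiseless = simulate_recording(
                ps, truth, geometry, config.snr, rng
            )
            sessions.append(session)
            psets.append(ps)
            truths.append(truth)
            recs.append(rec)
            clean.append(noiseless)
            for ch, g in gains.items():
                truth_rows.append(
                    {"group": spec.name, "subject": subj, "channel": ch, "gain": g}
                )
        n_times = np.array([r.shape[1] for r in recs])
        n_max = n_times.max()
        rec_arr = np.zeros((spec.n_subjects, geometry.n_sources, n_max))
        clean_arr = np.zeros_like(rec_arr)
        for i, (r, c) in enumerate(zip(recs, clean)):
            rec_arr[i, :, : r.shape[1]] = r
            clean_arr[i, :, : c.shape[1]] = c
        groups.append(
            GroupData(spec, sessions, psets, truths, rec_arr, clean_arr, n_times)
        )

    return SimStudy(
        config=config,
        lexicon=lexicon,
        geometry=geometry,
        basis=basis,
        groups=groups,
        truth_table=pd.DataFrame(truth_rows),
    )
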