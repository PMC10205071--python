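"""File formats: WAV audio, Praat TextGrids, alignment tables, HDF5 containers.

Forced alignments arrive either as Praat TextGrid files (a word tier plus a
phone tier) or as long-format delimited tables with one row per phoneme.
Predictor sets, multi-subject recordings, fit results and statistic maps are
serialized to HDF5 with shape and rate attributes so a study can be split
across processes or archived.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .predictors import AlignedStimulus, AlignedWord, PredictorSet

__all__ = [
    "read_wav",
    "write_wav",
    "read_textgrid",
    "read_alignment_table",
    "write_alignment_table",
    "save_predictor_set",
    "load_predictor_set",
    "save_recordings",
    "load_recordings",
    "save_stat_map",
    "load_stat_map",
    "save_test_result",
    "load_test_result",
    "write_lexicon_tsv",
]


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file as (float waveform in [-1, 1], sampling rate)."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(fs)


def write_wav(path, waveform: np.ndarray, fs: float) -> None:
    scaled = np.clip(np.asarray(waveform, float), -1.0, 1.0)
    wavfile.write(path, int(fs), (scaled * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Praat TextGrid (long text format)

_TG_INTERVAL = re.compile(
    r"intervals\s*\[\d+\]\s*:\s*"
    r"xmin\s*=\s*([\d.eE+-]+)\s*"
    r"xmax\s*=\s*([\d.eE+-]+)\s*"
    r'text\s*=\s*"([^"]*)"',
)


def _parse_tiers(text: str) -> dict[str, list[tuple[float, float, str]]]:
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    # split on tier item headers
    chunks = re.split(r"item\s*\[\d+\]\s*:", text)
    for chunk in chunks[1:]:
        name_m = re.search(r'name\s*=\s*"([^"]*)"', chunk)
        if name_m is None:
            continue
        intervals = [
            (float(a), float(b), t.strip())
            for a, b, t in _TG_INTERVAL.findall(chunk)
        ]
        tiers[name_m.group(1).lower()] = intervals
    return tiers


def read_textgrid(
    path,
    word_tier: str = "words",
    phone_tier: str = "phones",
    silence_labels: Iterable[str] = ("", "sil", "sp", "spn", "<p:>"),
) -> AlignedStimulus:
    """Parse a long-format Praat TextGrid into an :class:`AlignedStimulus`.

    Phones are assigned to the word interval containing their onset; empty
    or silence-labelled intervals are skipped.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    tiers = _parse_tiers(text)
    wt = word_tier.lower()
    pt = phone_tier.lower()
    if wt not in tiers or pt not in tiers:
        raise ValueError(
            f"TextGrid tiers {sorted(tiers)} lack {word_tier!r}/{phone_tier!r}"
        )
    sil = {s.lower() for s in silence_labels}
    words_raw = [(a, b, t) for a, b, t in tiers[wt] if t.lower() not in sil]
    phones_raw = [(a, b, t) for a, b, t in tiers[pt] if t.lower() not in sil]
    duration = max(b for _, b, _ in tiers[wt]) if tiers[wt] else 0.0

    words = []
    for a, b, label in words_raw:
        inside = [(pa, pl) for pa, pb, pl in phones_raw if a - 1e-9 <= pa < b - 1e-9]
        if not inside:
            continue
        inside.sort()
        words.append(
            AlignedWord(
                wordform=label,
                onset=inside[0][0],
                phonemes=tuple(pl for _, pl in inside),
                phoneme_onsets=tuple(pa for pa, _ in inside),
            )
        )
    return AlignedStimulus(tuple(words), duration)


# ---------------------------------------------------------------------------
# delimited alignment tables


def read_alignment_table(path_or_buf, duration: float | None = None) -> AlignedStimulus:
    """Long-format alignment: columns word, word_onset_s, phone, phone_onset_s.

    Rows belonging to one word share its ``word_onset_s``; phone rows must be
    in temporal order.  ``duration`` defaults to the last phone onset plus
    one second.
    """
    df = pd.read_csv(path_or_buf, sep=r"[\t,]", engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"word", "word_onset_s", "phone", "phone_onset_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"alignment table needs columns {sorted(required)}")
    words = []
    for (w, onset), grp in df.groupby(["word", "word_onset_s"], sort=False):
        grp = grp.sort_values("phone_onset_s")
        words.append(
            AlignedWord(
                wordform=str(w),
                onset=float(onset),
                phonemes=tuple(str(p) for p in grp["phone"]),
                phoneme_onsets=tuple(float(t) for t in grp["phone_onset_s"]),
            )
        )
    words.sort(key=lambda w: w.onset)
    if duration is None:
        duration = (words[-1].phoneme_onsets[-1] + 1.0) if words else 0.0
    return AlignedStimulus(tuple(words), duration)


def write_alignment_table(path, session: AlignedStimulus) -> None:
    rows = []
    for w in session.words:
        for ph, t in zip(w.phonemes, w.phoneme_onsets):
            rows.append(
                {
                    "word": w.wordform,
                    "word_onset_s": w.onset,
                    "phone": ph,
                    "phone_onset_s": t,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_lexicon_tsv(path, lexicon) -> None:
    rows = [
        {
            "wordform": e.wordform,
            "pronunciation": " ".join(e.pronunciation),
            "frequency": e.frequency,
        }
        for e in lexicon.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HDF5 containers


def save_predictor_set(path, ps: PredictorSet, provenance: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.attrs["rate"] = ps.rate
        f.attrs["n_samples"] = ps.n_samples
        f.attrs["provenance"] = provenance
        f.attrs["channel_order"] = np.array(ps.names, dtype=h5py.string_dtype())
        g = f.create_group("channels")
        for name, arr in ps.channels.items():
            g.create_dataset(name, data=arr)


def load_predictor_set(path) -> PredictorSet:
    with h5py.File(path, "r") as f:
        order = [
            s.decode() if isinstance(s, bytes) else s
            for s in f.attrs["channel_order"]
        ]
        channels = {name: f["channels"][name][()] for name in order}
        return PredictorSet(channels, float(f.attrs["rate"]))


def save_stat_map(path, stat_map) -> None:
    """Serialize a StatMap (values + geometry, if any) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=stat_map.values)
        g = stat_map.geometry
        if g is not None:
            geo = f.create_group("geometry")
            geo.create_dataset("coordinates", data=g.coordinates)
            geo.create_dataset("edges", data=g.edges)
            for name in ("orientations", "roi_mask", "hemisphere"):
                arr = getattr(g, name)
                if arr is not None:
                    geo.create_dataset(name, data=arr)


def load_stat_map(path):
    from .stats import SourceGeometry, StatMap

    with h5py.File(path, "r") as f:
        values = f["values"][()]
        geometry = None
        if "geometry" in f:
            geo = f["geometry"]
            geometry = SourceGeometry(
                geo["coordinates"][()],
                geo["edges"][()],
                geo["orientations"][()] if "orientations" in geo else None,
                geo["roi_mask"][()].astype(bool) if "roi_mask" in geo else None,
                geo["hemisphere"][()] if "hemisphere" in geo else None,
            )
    return StatMap(values, geometry)


def save_test_result(path, result) -> None:
    """Serialize a TestResult (statistic, TFCE, p, null summary) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["n_permutations"] = result.n_permutations
        f.attrs["tail"] = result.tail
        if result.seed is not None:
            f.attrs["seed"] = result.seed
        f.create_dataset("statistic", data=result.statistic)
        f.create_dataset("tfce_map", data=result.tfce_map)
        f.create_dataset("p", data=result.p)
        f.create_dataset("null_max", data=result.null_max)


def load_test_result(path):
    from .stats import TestResult

    with h5py.File(path, "r") as f:
        return TestResult(
            statistic=f["statistic"][()],
            tfce_map=f["tfce_map"][()],
            p=f["p"][()],
            null_max=f["null_max"][()],
            n_permutations=int(f.attrs["n_permutations"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            tail=str(f.attrs["tail"]),
        )


def save_recordings(path, data: np.ndarray, rate: float, subjects=None) -> None:
    """Save a (subjects, sources, time) response array with its rate."""
    data = np.asarray(data, float)
    if data.ndim != 3:
        raise ValueError("recordings must be (subjects, sources, time)")
    with h5py.File(path, "w") as f:
        f.attrs["rate"] = rate
        f.create_dataset("recordings", data=data)
        if subjects is not None:
            f.create_dataset(
                "subjects",
                data=np.array([str(s) for s in subjects], dtype=h5py.string_dtype()),
            )


def load_recordings(path) -> tuple[np.ndarray, float, list[str] | None]:
    with h5py.File(path, "r") as f:
        data = f["recordings"][()]
        rate = float(f.attrs["rate"])
        subjects = None
        if "subjects" in f:
            subjects = [
                s.decode() if isinstance(s, bytes) else s for s in f["subjects"][()]
            ]
    return data, rate, subjects
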