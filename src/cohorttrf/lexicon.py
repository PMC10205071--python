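"""Cohort model of spoken-word recognition.

A listener hearing a word phoneme by phoneme can, at each position, entertain
exactly the set of wordforms whose pronunciations begin with the phonemes heard
so far -- the *cohort*.  Weighting each cohort member by its corpus frequency
yields a posterior distribution over wordforms, from which two
information-theoretic quantities follow:

* **phoneme surprisal** at position ``i``: ``-log2 p(k_i | k_1..k_{i-1})``,
  the negative log probability of the incoming phoneme given the previous
  cohort -- how much the new phoneme updates the listener's beliefs;
* **cohort entropy** at position ``i``: the Shannon entropy (bits) of the
  posterior over wordforms compatible with ``k_1..k_i`` -- how much
  uncertainty remains about the word's identity.

Both are computed from the same frequency-weighted lexicon, with the whole
lexicon serving as the prior cohort for the first phoneme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LexEntry",
    "Lexicon",
    "Cohort",
    "InfoAnnotation",
    "load_lexicon",
    "read_lexicon_table",
    "cohort_sequence",
    "phoneme_surprisal",
    "cohort_entropy",
    "annotate_word",
    "annotation_table",
]

#: probability-sum tolerance for cohort validation
_PROB_TOL = 1e-12


class CohortError(ValueError):
    """Raised when a phoneme prefix cannot be resolved in the lexicon."""


@dataclass(frozen=True)
class LexEntry:
    """A wordform with its pronunciation and frequency count."""

    wordform: str
    pronunciation: tuple[str, ...]
    frequency: float

    def __post_init__(self) -> None:
        if len(self.pronunciation) < 1:
            raise ValueError(f"empty pronunciation for {self.wordform!r}")
        if not self.frequency > 0:
            raise ValueError(
                f"non-positive frequency {self.frequency} for {self.wordform!r}"
            )


class Lexicon:
    """A frequency-weighted pronunciation lexicon.

    Parameters
    ----------
    entries
        Lexical entries; wordforms must be unique.
    inventory
        Phoneme inventory.  Defaults to the union of symbols appearing in the
        entries; if given explicitly, every pronunciation must draw from it.
    frequency_transform
        Optional hook mapping raw counts to the weights used for cohort
        probabilities (e.g. ``math.log1p``).  Identity (raw counts) by default.
    """

    def __init__(
        self,
        entries: Iterable[LexEntry],
        inventory: Iterable[str] | None = None,
        frequency_transform: Callable[[float], float] | None = None,
    ) -> None:
        entries = list(entries)
        if not entries:
            raise ValueError("lexicon has no entries")
        seen: dict[str, LexEntry] = {}
        for e in entries:
            if e.wordform in seen:
                raise ValueError(f"duplicate wordform {e.wordform!r}")
            seen[e.wordform] = e
        self.entries: tuple[LexEntry, ...] = tuple(entries)
        used = {p for e in entries for p in e.pronunciation}
        if inventory is None:
            self.inventory = frozenset(used)
        else:
            self.inventory = frozenset(inventory)
            extra = used - self.inventory
            if extra:
                raise ValueError(f"phonemes outside inventory: {sorted(extra)}")
        self._transform = frequency_transform
        self._weights = {
            e.wordform: (
                e.frequency if frequency_transform is None
                else float(frequency_transform(e.frequency))
            )
            for e in entries
        }
        if any(w <= 0 for w in self._weights.values()):
            raise ValueError("frequency transform produced non-positive weight")
        self._by_word = seen

    @property
    def total_frequency(self) -> float:
        return sum(e.frequency for e in self.entries)

    @property
    def total_weight(self) -> float:
        return sum(self._weights.values())

    def weight(self, wordform: str) -> float:
        return self._weights[wordform]

    def pronunciation(self, wordform: str) -> tuple[str, ...]:
        return self._by_word[wordform].pronunciation

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, wordform: str) -> bool:
        return wordform in self._by_word

    def __repr__(self) -> str:
        return f"<Lexicon: {len(self)} words, {len(self.inventory)} phonemes>"

    def prior(self) -> "Cohort":
        """The whole-lexicon prior distribution (cohort at position 0)."""
        z = self.total_weight
        members = {e.wordform: self._weights[e.wordform] / z for e in self.entries}
        return Cohort(position=0, prefix=(), members=members, lexicon=self)

    def merge_homophones(self) -> "Lexicon":
        """Return a lexicon in which identical pronunciations are merged.

        Frequencies of homophones are summed; the surviving wordform is the
        one with the highest count (ties broken alphabetically).
        """
        groups: dict[tuple[str, ...], list[LexEntry]] = {}
        for e in self.entries:
            groups.setdefault(e.pronunciation, []).append(e)
        merged = []
        for pron, grp in groups.items():
            grp = sorted(grp, key=lambda e: (-e.frequency, e.wordform))
            merged.append(
                LexEntry(grp[0].wordform, pron, sum(e.frequency for e in grp))
            )
        return Lexicon(merged, self.inventory, self._transform)


@dataclass
class Cohort:
    """Posterior distribution over wordforms compatible with a phoneme prefix.

    ``position`` is 1-based; position 0 denotes the whole-lexicon prior.
    """

    position: int
    prefix: tuple[str, ...]
    members: Mapping[str, float]
    lexicon: Lexicon | None = None
    backed_off: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise CohortError(
                f"empty cohort for prefix {' '.join(self.prefix) or '(prior)'}"
            )
        total = math.fsum(self.members.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cohort probabilities sum to {total}, not 1")
        if self.lexicon is not None and self.prefix:
            for w in self.members:
                pron = self.lexicon.pronunciation(w)
                if pron[: len(self.prefix)] != self.prefix:
                    raise ValueError(f"{w!r} does not begin with the cohort prefix")

    def __len__(self) -> int:
        return len(self.members)

    def next_phoneme_probability(self, phoneme: str) -> float:
        """Total posterior mass of members whose next phoneme is ``phoneme``."""
        if self.lexicon is None:
            raise ValueError("cohort has no backing lexicon")
        i = len(self.prefix)
        return math.fsum(
            p
            for w, p in self.members.items()
            if len(self.lexicon.pronunciation(w)) > i
            and self.lexicon.pronunciation(w)[i] == phoneme
        )


@dataclass
class InfoAnnotation:
    """Per-phoneme-position surprisal and entropy for one word."""

    wordform: str
    phonemes: tuple[str, ...]
    surprisal: np.ndarray  # bits, one per position
    entropy: np.ndarray  # bits, one per position
    cohort_size: np.ndarray  # members after each position
    word_initial: np.ndarray  # bool, True at position 1
    backed_off: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.phonemes)
        self.surprisal = np.asarray(self.surprisal, float)
        self.entropy = np.asarray(self.entropy, float)
        self.cohort_size = np.asarray(self.cohort_size, int)
        self.word_initial = np.asarray(self.word_initial, bool)
        if self.backed_off is None:
            self.backed_off = np.zeros(n, bool)
        for arr in (self.surprisal, self.entropy, self.cohort_size, self.word_initial):
            if arr.shape != (n,):
                raise ValueError("annotation arrays must match phoneme count")
        if (self.surprisal < 0).any() or (self.entropy < 0).any():
            raise ValueError("surprisal and entropy must be nonnegative")
        with np.errstate(divide="ignore"):
            cap = np.log2(self.cohort_size)
        if (self.entropy > cap + 1e-9).any():
            raise ValueError("entropy exceeds log2(cohort size)")


# ---------------------------------------------------------------------------
# I/O


def read_lexicon_table(path_or_buf, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited lexicon table with columns wordform/pronunciation[/frequency]."""
    if sep is None:
        sep = r"[\t,]"
    df = pd.read_csv(path_or_buf, sep=sep, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "wordform" not in df.columns or "pronunciation" not in df.columns:
        raise ValueError("table must have 'wordform' and 'pronunciation' columns")
    return df


def load_lexicon(
    pronunciation_table,
    frequency_table=None,
    frequency_floor: float = 1.0,
    inventory: Iterable[str] | None = None,
    frequency_transform: Callable[[float], float] | None = None,
) -> Lexicon:
    """Build a :class:`Lexicon` from delimited tables.

    ``pronunciation_table`` maps wordform to a space-separated phoneme string
    (and optionally a frequency column); ``frequency_table``, if given
    separately, maps wordform to a count.  Words missing a frequency, or with
    a zero count, receive ``frequency_floor``.  Duplicate rows for a wordform
    are merged when their pronunciations agree (frequencies summed) and
    rejected otherwise.

    Accepts file paths, file-like objects, or pandas DataFrames.
    """
    if isinstance(pronunciation_table, pd.DataFrame):
        pron_df = pronunciation_table.copy()
        pron_df.columns = [c.strip().lower() for c in pron_df.columns]
    else:
        pron_df = read_lexicon_table(pronunciation_table)
    if len(pron_df) == 0:
        raise ValueError("empty pronunciation table")

    table_freqs: dict[str, float] | None = None
    if frequency_table is not None:
        if isinstance(frequency_table, pd.DataFrame):
            fdf = frequency_table.copy()
            fdf.columns = [c.strip().lower() for c in fdf.columns]
        else:
            fdf = pd.read_csv(frequency_table, sep=r"[\t,]", engine="python", dtype=str)
            fdf.columns = [c.strip().lower() for c in fdf.columns]
        if "wordform" not in fdf.columns or "frequency" not in fdf.columns:
            raise ValueError("frequency table must have 'wordform' and 'frequency'")
        table_freqs = {
            str(row["wordform"]).strip(): float(row["frequency"])
            for _, row in fdf.iterrows()
        }

    prons: dict[str, tuple[str, ...]] = {}
    row_freqs: dict[str, float] = {}  # summed over duplicate identical rows
    conflicts = []
    for _, row in pron_df.iterrows():
        w = str(row["wordform"]).strip()
        pron = tuple(str(row["pronunciation"]).split())
        if not pron:
            raise ValueError(f"empty pronunciation for {w!r}")
        if w in prons and prons[w] != pron:
            conflicts.append(w)
            continue
        prons[w] = pron
        if table_freqs is None and "frequency" in pron_df.columns:
            f = row["frequency"]
            if not pd.isna(f):
                row_freqs[w] = row_freqs.get(w, 0.0) + float(f)
    if conflicts:
        raise ValueError(
            f"duplicate wordforms with conflicting pronunciations: {sorted(set(conflicts))}"
        )

    entries = []
    for w, pron in prons.items():
        if table_freqs is not None:
            f = table_freqs.get(w, float("nan"))
        else:
            f = row_freqs.get(w, float("nan"))
        if math.isnan(f) or f <= 0:
            f = frequency_floor
        entries.append(LexEntry(w, pron, f))
    return Lexicon(entries, inventory, frequency_transform)


def annotation_table(annotations: Iterable[InfoAnnotation]) -> pd.DataFrame:
    """Long-format per-word annotation table (one row per phoneme position)."""
    rows = []
    for ann in annotations:
        for i, ph in enumerate(ann.phonemes):
            rows.append(
                {
                    "wordform": ann.wordform,
                    "position": i + 1,
                    "phoneme": ph,
                    "surprisal_bits": ann.surprisal[i],
                    "entropy_bits": ann.entropy[i],
                    "word_initial": bool(ann.word_initial[i]),
                    "cohort_size": int(ann.cohort_size[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort computation


def cohort_sequence(
    lexicon: Lexicon,
    pronunciation: Sequence[str],
    strict: bool = True,
) -> list[Cohort]:
    """Cohorts at every position of ``pronunciation`` (positions 1..n).

    The implicit position-0 prior is the whole lexicon weighted by frequency;
    the cohort at position ``i`` restricts to entries whose pronunciation
    begins with ``k_1..k_i``, renormalized.  In strict mode an empty cohort is
    an error naming the offending prefix; in lenient mode the previous
    cohort's members are retained with a uniform epsilon back-off and the
    position is flagged ``backed_off``.
    """
    pronunciation = tuple(pronunciation)
    if not pronunciation:
        raise ValueError("empty pronunciation")
    cohorts: list[Cohort] = []
    # incremental winnowing: start from all entries, drop mismatches
    current = list(lexicon.entries)
    prev_members: Mapping[str, float] = lexicon.prior().members
    for i, ph in enumerate(pronunciation, start=1):
        current = [
            e
            for e in current
            if len(e.pronunciation) >= i and e.pronunciation[i - 1] == ph
        ]
        prefix = pronunciation[:i]
        if current:
            z = math.fsum(lexicon.weight(e.wordform) for e in current)
            members = {e.wordform: lexicon.weight(e.wordform) / z for e in current}
            cohort = Cohort(i, prefix, members, lexicon)
        elif strict:
            raise CohortError(
                f"no lexicon entry matches prefix {' '.join(prefix)!r}"
            )
        else:
            # epsilon back-off: keep the previous distribution, flag it
            cohort = Cohort(i, prefix, dict(prev_members), None, backed_off=True)
        cohorts.append(cohort)
        prev_members = cohort.members
    return cohorts


def phoneme_surprisal(
    prev_cohort: Cohort,
    phoneme: str,
    strict: bool = True,
    epsilon: float | None = None,
) -> float:
    """Surprisal (bits) of ``phoneme`` given the preceding cohort.

    ``-log2`` of the summed posterior probability of cohort members whose
    next phoneme is ``phoneme``.  For the first phoneme pass the lexicon
    prior (:meth:`Lexicon.prior`).
    """
    p = prev_cohort.next_phoneme_probability(phoneme)
    if p <= 0:
        if strict:
            raise CohortError(
                f"phoneme {phoneme!r} has zero probability after "
                f"prefix {' '.join(prev_cohort.prefix) or '(prior)'}"
            )
        if epsilon is None:
            lex = prev_cohort.lexicon
            epsilon = 1.0 / lex.total_weight if lex is not None else 1e-12
        return -math.log2(epsilon)
    return max(0.0, -math.log2(p))


def cohort_entropy(cohort: Cohort) -> float:
    """Shannon entropy (bits) of the cohort's posterior over wordforms."""
    total = math.fsum(cohort.members.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"cohort probabilities sum to {total}")
    h = -math.fsum(p * math.log2(p) for p in cohort.members.values() if p > 0)
    return max(0.0, h)


def annotate_word(
    lexicon: Lexicon,
    pronunciation: Sequence[str],
    wordform: str = "",
    strict: bool = True,
) -> InfoAnnotation:
    """Surprisal and entropy at every phoneme position of one word."""
    pronunciation = tuple(pronunciation)
    cohorts = cohort_sequence(lexicon, pronunciation, strict=strict)
    prev: Cohort = lexicon.prior()
    surprisal = np.empty(len(pronunciation))
    entropy = np.empty(len(pronunciation))
    sizes = np.empty(len(pronunciation), int)
    backed = np.zeros(len(pronunciation), bool)
    for i, (ph, cohort) in enumerate(zip(pronunciation, cohorts)):
        if cohort.backed_off:
            surprisal[i] = phoneme_surprisal(prev, ph, strict=False) if prev.lexicon else 0.0
            backed[i] = True
        else:
            surprisal[i] = phoneme_surprisal(prev, ph, strict=strict)
        entropy[i] = cohort_entropy(cohort)
        sizes[i] = len(cohort)
        prev = cohort
    initial = np.zeros(len(pronunciation), bool)
    initial[0] = True
    return InfoAnnotation(
        wordform=wordform or " ".join(pronunciation),
        phonemes=pronunciation,
        surprisal=surprisal,
        entropy=entropy,
        cohort_size=sizes,
        word_initial=initial,
        backed_off=backed,
    )
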