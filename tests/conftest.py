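import numpy as np
import pandas as pd
import pytest

from cohorttrf.lexicon import LexEntry, Lexicon, load_lexicon


@pytest.fixture
def toy_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wordform": ["cat", "cab", "dog"],
            "pronunciation": ["K AE T", "K AE B", "D AO G"],
            "frequency": [3, 1, 4],
        }
    )


@pytest.fixture
def toy_lexicon(toy_table) -> Lexicon:
    return load_lexicon(toy_table)


def random_lexicon(rng: np.random.Generator, n_words=20, n_phonemes=5, max_len=4):
    """A random small lexicon with positive integer frequencies."""
    inventory = [chr(ord("A") + i) for i in range(n_phonemes)]
    entries = []
    seen = set()
    while len(entries) < n_words:
        length = int(rng.integers(1, max_len + 1))
        pron = tuple(inventory[i] for i in rng.integers(0, n_phonemes, length))
        name = f"w{len(entries)}"
        if (name, pron) in seen:
            continue
        seen.add((name, pron))
        entries.append(LexEntry(name, pron, int(rng.integers(1, 50))))
    return Lexicon(entries)
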