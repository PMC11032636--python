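"""ARPAbet phoneme classification and surface-form feature extraction.

Words are described by 60 numeric surface-form variables built from their
ARPAbet transcription and orthography:

* whole-word measures: length in letters, in phonemes, and in syllables
  (syllable count = number of vowel phonemes);
* phoneme-category counts: vowel height (high/mid/low) and frontness
  (front/central/back), consonant place (bilabial, labiodental,
  linguodental, alveolar, palatal, velar, glottal) and manner (stop,
  fricative, affricate, nasal, liquid, glide), and voicing
  (voiced/voiceless over all phonemes);
* first- and final-phoneme indicators: is-vowel, the seven places, the six
  manners, and voiced/voiceless (16 each);
* primary-stress position: initial, final, medial, or multiple.

The phoneme -> category decision table ships as a CSV resource
(``data/arpabet_features.csv``) and can be overridden, e.g. to move the
diphthongs to different height classes.  Diphthongs are classified by their
nucleus; AO is grouped with the low vowels (the /a/ of "tall").

Monosyllables are coded ``stress_initial=1``: treating the single syllable
as initial avoids exact collinearity between the initial- and final-stress
indicators in monosyllable-heavy samples, so the final-stress variable
measures multisyllabic final stress.  Multisyllabic words with no
primary-stress digit (rare; CMUdict marks one on virtually every word)
carry 0 on all four stress indicators.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon_io import NormsRecord, PronunciationEntry

__all__ = [
    "PhonemeFeatures",
    "FEATURE_NAMES",
    "ARPABET_VOWELS",
    "ARPABET_CONSONANTS",
    "ARPABET_INVENTORY",
    "PLACES",
    "MANNERS",
    "load_feature_table",
    "classify_phoneme",
    "extract_features",
    "build_feature_matrix",
]

PLACES = (
    "bilabial",
    "labiodental",
    "linguodental",
    "alveolar",
    "palatal",
    "velar",
    "glottal",
)
MANNERS = ("stop", "fricative", "affricate", "nasal", "liquid", "glide")
HEIGHTS = ("high", "mid", "low")
FRONTNESS = ("front", "central", "back")


@dataclass(frozen=True)
class PhonemeFeatures:
    """Phonetic classification of one ARPAbet base symbol."""

    symbol: str
    klass: str  # "consonant" | "vowel"
    place: str  # consonants only, else "none"
    manner: str  # consonants only, else "none"
    voicing: str  # "voiced" | "voiceless"
    height: str  # vowels only, else "none"
    frontness: str  # vowels only, else "none"

    def __post_init__(self) -> None:
        if self.klass == "vowel":
            if self.place != "none" or self.manner != "none":
                raise ValueError(f"vowel {self.symbol} must have place=manner=none")
            if self.voicing != "voiced":
                raise ValueError(f"vowel {self.symbol} must be voiced")
            if self.height not in HEIGHTS or self.frontness not in FRONTNESS:
                raise ValueError(f"vowel {self.symbol} needs height and frontness")
        elif self.klass == "consonant":
            if self.place not in PLACES or self.manner not in MANNERS:
                raise ValueError(f"consonant {self.symbol} needs place and manner")
            if self.height != "none" or self.frontness != "none":
                raise ValueError(f"consonant {self.symbol} must have height=frontness=none")
        else:
            raise ValueError(f"unknown class {self.klass!r} for {self.symbol}")


def load_feature_table(path=None) -> dict[str, PhonemeFeatures]:
    """Load a phoneme decision table (the packaged one by default)."""
    if path is None:
        source = resources.files("formtyp.data").joinpath("arpabet_features.csv")
        text = source.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    table: dict[str, PhonemeFeatures] = {}
    for row in rows:
        symbol = row["symbol"].strip().upper()
        if symbol in table:
            raise ValueError(f"phoneme {symbol} classified more than once")
        table[symbol] = PhonemeFeatures(
            symbol=symbol,
            klass=row["klass"],
            place=row["place"],
            manner=row["manner"],
            voicing=row["voicing"],
            height=row["height"],
            frontness=row["frontness"],
        )
    return table


_DEFAULT_TABLE = load_feature_table()

ARPABET_VOWELS = frozenset(s for s, f in _DEFAULT_TABLE.items() if f.klass == "vowel")
ARPABET_CONSONANTS = frozenset(s for s, f in _DEFAULT_TABLE.items() if f.klass == "consonant")
ARPABET_INVENTORY = ARPABET_VOWELS | ARPABET_CONSONANTS

# Canonical 60-variable order.  Pruning scans columns left to right, so this
# order is part of the published interface and must not be reordered.
FEATURE_NAMES: tuple[str, ...] = (
    ("length_letters", "length_phonemes", "n_syllables")
    + tuple(f"n_{h}" for h in HEIGHTS)
    + tuple(f"n_{f}" for f in FRONTNESS)
    + tuple(f"n_{p}" for p in PLACES)
    + tuple(f"n_{m}" for m in MANNERS)
    + ("n_voiced", "n_voiceless")
    + ("first_is_vowel",)
    + tuple(f"first_{p}" for p in PLACES)
    + tuple(f"first_{m}" for m in MANNERS)
    + ("first_voiced", "first_voiceless")
    + ("final_is_vowel",)
    + tuple(f"final_{p}" for p in PLACES)
    + tuple(f"final_{m}" for m in MANNERS)
    + ("final_voiced", "final_voiceless")
    + ("stress_initial", "stress_final", "stress_medial", "stress_multiple")
)
assert len(FEATURE_NAMES) == 60


def strip_stress(symbol: str) -> str:
    """Remove a trailing stress digit from an ARPAbet symbol."""
    return symbol[:-1] if symbol and symbol[-1] in "012" else symbol


def classify_phoneme(symbol: str, table: Mapping[str, PhonemeFeatures] | None = None) -> PhonemeFeatures:
    """Classify one ARPAbet symbol (stress digit allowed) by the decision table.

    Raises ``KeyError`` naming the symbol when it is not in the inventory.
    """
    table = _DEFAULT_TABLE if table is None else table
    base = strip_stress(symbol).upper()
    try:
        return table[base]
    except KeyError:
        raise KeyError(f"unknown ARPAbet symbol {symbol!r}") from None


def _edge_indicators(feats: PhonemeFeatures, prefix: str, out: dict[str, int]) -> None:
    out[f"{prefix}_is_vowel"] = int(feats.klass == "vowel")
    for p in PLACES:
        out[f"{prefix}_{p}"] = int(feats.place == p)
    for m in MANNERS:
        out[f"{prefix}_{m}"] = int(feats.manner == m)
    out[f"{prefix}_voiced"] = int(feats.voicing == "voiced")
    out[f"{prefix}_voiceless"] = int(feats.voicing == "voiceless")


def extract_features(
    entry: "PronunciationEntry",
    letters: int | None = None,
    table: Mapping[str, PhonemeFeatures] | None = None,
    stress_pattern: Iterable[int] | None = None,
) -> dict[str, float]:
    """Compute the 60 surface-form variables for one pronunciation.

    Parameters
    ----------
    entry
        Pronunciation with ARPAbet symbols; vowels may carry stress digits.
    letters
        Orthographic length; defaults to ``len(entry.orthography)``.
    table
        Alternative phoneme decision table.
    stress_pattern
        Optional external stress codes, one int per syllable (1 = primary),
        overriding the dictionary's stress digits, for callers that prefer a
        dedicated stress database over CMUdict's own digits.

    Raises
    ------
    ValueError
        If the transcription contains no vowel (syllable count undefined).
    """
    phonemes = list(entry.phonemes)
    if not phonemes:
        raise ValueError(f"{entry.orthography!r}: empty phoneme list")
    feats = [classify_phoneme(p, table) for p in phonemes]
    n_vowels = sum(f.klass == "vowel" for f in feats)
    if n_vowels == 0:
        raise ValueError(
            f"{entry.orthography!r}: no vowel phoneme, syllable count undefined"
        )

    out: dict[str, float] = {
        "length_letters": len(entry.orthography) if letters is None else int(letters),
        "length_phonemes": len(phonemes),
        "n_syllables": n_vowels,
    }
    for h in HEIGHTS:
        out[f"n_{h}"] = sum(f.height == h for f in feats)
    for fr in FRONTNESS:
        out[f"n_{fr}"] = sum(f.frontness == fr for f in feats)
    for p in PLACES:
        out[f"n_{p}"] = sum(f.place == p for f in feats)
    for m in MANNERS:
        out[f"n_{m}"] = sum(f.manner == m for f in feats)
    out["n_voiced"] = sum(f.voicing == "voiced" for f in feats)
    out["n_voiceless"] = sum(f.voicing == "voiceless" for f in feats)

    _edge_indicators(feats[0], "first", out)
    _edge_indicators(feats[-1], "final", out)

    # Primary-stress position from the digits on vowel symbols (digit 1 is
    # primary; secondary stress, digit 2, never matters here).
    if stress_pattern is not None:
        codes = list(stress_pattern)
        if len(codes) != n_vowels:
            raise ValueError(
                f"{entry.orthography!r}: stress pattern length {len(codes)} "
                f"!= syllable count {n_vowels}"
            )
        primary = [i for i, c in enumerate(codes) if c == 1]
    else:
        digits = [
            sym[-1] for sym in phonemes
            if classify_phoneme(sym, table).klass == "vowel" and sym[-1] in "012"
        ]
        primary = [i for i, d in enumerate(digits) if d == "1"]

    out["stress_initial"] = out["stress_final"] = 0
    out["stress_medial"] = out["stress_multiple"] = 0
    if n_vowels == 1:
        out["stress_initial"] = 1
    elif len(primary) >= 2:
        out["stress_multiple"] = 1
    elif len(primary) == 1:
        pos = primary[0]
        if pos == 0:
            out["stress_initial"] = 1
        elif pos == n_vowels - 1:
            out["stress_final"] = 1
        else:
            out["stress_medial"] = 1
    return out


def build_feature_matrix(
    entries: Iterable["PronunciationEntry"],
    norms: Iterable["NormsRecord"] | None = None,
    table: Mapping[str, PhonemeFeatures] | None = None,
) -> pd.DataFrame:
    """Build the word-by-feature matrix in canonical column order.

    With ``norms`` given, rows are restricted and aligned to the retained
    norm words; every retained word must have a pronunciation.
    """
    by_word: dict[str, "PronunciationEntry"] = {}
    for e in entries:
        by_word.setdefault(e.orthography, e)

    if norms is None:
        words = list(by_word)
    else:
        words = [r.orthography for r in norms]
        missing = [w for w in words if w not in by_word]
        if missing:
            raise KeyError(
                "no pronunciation for retained word(s): " + ", ".join(sorted(missing))
            )

    rows = [extract_features(by_word[w], table=table) for w in words]
    matrix = pd.DataFrame(rows, index=pd.Index(words, name="word"), dtype=float)
    matrix = matrix[list(FEATURE_NAMES)]
    if matrix.isna().any().any():  # defensive; extract_features fills all 60
        raise ValueError("feature matrix has missing cells")
    return matrix
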