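"""Readers, writers and word-exclusion filters for the pipeline's inputs.

Three external formats are handled:

* pronunciation lexicons in the CMUdict plain-text dialect
  (``WORD  PH1 PH2 ...``, ``;;;`` comment lines, ``WORD(2)`` alternate
  pronunciations, stress digits 0/1/2 on vowel symbols);
* CSV norms tables (word, mean 1-7 size rating, rating SD, part of speech,
  optional homograph-alternate flag);
* generic CSV covariate / outcome tables with a declared required-column
  schema.

Exclusions follow the rating-norm curation recipe: drop alternate meanings
of homographs first, then words whose raters disagreed (rating SD strictly
greater than a cutoff, default 1.5 — a word at exactly 1.5 is retained),
then proper names by part-of-speech label.  Homography cannot be inferred
from orthography, so the norms CSV must carry an explicit
``is_homograph_alternate`` flag when that stage is wanted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .form_features import ARPABET_INVENTORY, ARPABET_VOWELS, strip_stress

logger = logging.getLogger(__name__)

__all__ = [
    "PronunciationEntry",
    "NormsRecord",
    "ExclusionConfig",
    "ExclusionReport",
    "LexiconParseError",
    "SchemaError",
    "read_pronunciations",
    "write_pronunciations",
    "read_norms",
    "write_norms",
    "read_table",
    "apply_exclusions",
    "match_pronunciations",
]


class LexiconParseError(ValueError):
    """Malformed line or unknown symbol in a pronunciation lexicon."""


class SchemaError(ValueError):
    """CSV table missing required columns."""


@dataclass(frozen=True)
class PronunciationEntry:
    """One dictionary entry: a word and its ARPAbet transcription."""

    orthography: str
    phonemes: tuple[str, ...]
    variant_index: int = 1

    def __post_init__(self) -> None:
        if not self.phonemes:
            raise ValueError(f"{self.orthography!r}: empty phoneme list")
        if self.variant_index < 1:
            raise ValueError("variant_index must be >= 1")
        for sym in self.phonemes:
            base = strip_stress(sym)
            if base not in ARPABET_INVENTORY:
                raise LexiconParseError(f"unknown ARPAbet symbol {sym!r}")
            if sym != base and base not in ARPABET_VOWELS:
                raise LexiconParseError(f"stress digit on non-vowel symbol {sym!r}")


@dataclass(frozen=True)
class NormsRecord:
    """One word's semantic-size rating summary (1-7 Likert scale)."""

    orthography: str
    rating_mean: float
    rating_sd: float
    pos: str
    is_homograph_alternate: bool = False

    def __post_init__(self) -> None:
        if not 1.0 <= self.rating_mean <= 7.0:
            raise ValueError(
                f"{self.orthography!r}: rating_mean {self.rating_mean} outside [1, 7]"
            )
        if self.rating_sd < 0:
            raise ValueError(f"{self.orthography!r}: negative rating_sd")


@dataclass(frozen=True)
class ExclusionConfig:
    sd_threshold: float = 1.5
    drop_homograph_alternates: bool = True
    drop_proper_names: bool = True
    name_labels: frozenset[str] = frozenset({"name"})

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")


@dataclass
class ExclusionReport:
    """Counts surviving each exclusion stage, in application order."""

    n_input: int
    n_after_homographs: int
    n_after_sd: int
    n_after_names: int

    def __post_init__(self) -> None:
        stages = (self.n_input, self.n_after_homographs, self.n_after_sd, self.n_after_names)
        if any(a < b for a, b in zip(stages, stages[1:])):
            raise ValueError("stage counts must be monotone non-increasing")

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_after_names

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _parse_word(token: str) -> tuple[str, int]:
    variant = 1
    if token.endswith(")") and "(" in token:
        head, _, tail = token.rpartition("(")
        digits = tail[:-1]
        if digits.isdigit():
            token, variant = head, int(digits)
    return token.lower(), variant


def read_pronunciations(path, on_duplicate: str = "first") -> list[PronunciationEntry]:
    """Parse a CMUdict-dialect lexicon.

    ``on_duplicate`` is ``"first"`` (keep only the primary entry per word,
    the common choice) or ``"all"`` (keep every alternate with its variant
    index).
    """
    if on_duplicate not in {"first", "all"}:
        raise ValueError("on_duplicate must be 'first' or 'all'")
    entries: list[PronunciationEntry] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(";;;"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise LexiconParseError(f"{path}:{lineno}: malformed line {line!r}")
            word, variant = _parse_word(fields[0])
            try:
                entry = PronunciationEntry(word, tuple(s.upper() for s in fields[1:]), variant)
            except LexiconParseError as err:
                raise LexiconParseError(f"{path}:{lineno}: {err}") from None
            if on_duplicate == "first":
                if word in seen:
                    continue
                seen.add(word)
            entries.append(entry)
    return entries


def write_pronunciations(entries: Iterable[PronunciationEntry], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(";;; generated by formtyp\n")
        for e in entries:
            word = e.orthography.upper()
            if e.variant_index > 1:
                word = f"{word}({e.variant_index})"
            fh.write(f"{word}  {' '.join(e.phonemes)}\n")


NORMS_COLUMNS = ("word", "size_mean", "size_sd", "pos")


def read_norms(path) -> list[NormsRecord]:
    """Read a norms CSV (word, size_mean, size_sd, pos[, is_homograph_alternate])."""
    frame = read_table(path, required=NORMS_COLUMNS)
    has_flag = "is_homograph_alternate" in frame.columns
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            NormsRecord(
                orthography=str(row.word).lower(),
                rating_mean=float(row.size_mean),
                rating_sd=float(row.size_sd),
                pos=str(row.pos),
                is_homograph_alternate=bool(getattr(row, "is_homograph_alternate"))
                if has_flag
                else False,
            )
        )
    return records


def write_norms(records: Iterable[NormsRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "word": [r.orthography for r in records],
            "size_mean": [r.rating_mean for r in records],
            "size_sd": [r.rating_sd for r in records],
            "pos": [r.pos for r in records],
            "is_homograph_alternate": [int(r.is_homograph_alternate) for r in records],
        }
    )
    frame.to_csv(path, index=False)


def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a CSV with a header row, checking required columns.

    Missing values stay as NaN; they are never silently dropped here (the
    modelling layer decides about listwise deletion and logs counts).
    """
    frame = pd.read_csv(path)
    absent = [c for c in required if c not in frame.columns]
    if absent:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(absent)}")
    return frame


def apply_exclusions(
    norms: Sequence[NormsRecord], config: ExclusionConfig | None = None
) -> tuple[list[NormsRecord], ExclusionReport]:
    """Apply the three exclusion stages in their canonical order.

    Stages: homograph alternates -> rating-SD filter (strict ``>``) ->
    proper names.  Idempotent; an empty result is legal.
    """
    config = config or ExclusionConfig()
    stage0 = list(norms)
    stage1 = (
        [r for r in stage0 if not r.is_homograph_alternate]
        if config.drop_homograph_alternates
        else stage0
    )
    stage2 = [r for r in stage1 if r.rating_sd <= config.sd_threshold]
    stage3 = (
        [r for r in stage2 if r.pos not in config.name_labels]
        if config.drop_proper_names
        else stage2
    )
    report = ExclusionReport(len(stage0), len(stage1), len(stage2), len(stage3))
    logger.info(
        "exclusions: %d input -> %d after homographs -> %d after SD filter (>%g) -> %d after names",
        report.n_input, report.n_after_homographs, report.n_after_sd,
        config.sd_threshold, report.n_after_names,
    )
    return stage3, report


def match_pronunciations(
    norms: Sequence[NormsRecord], entries: Sequence[PronunciationEntry]
) -> tuple[list[NormsRecord], int]:
    """Drop norm words with no pronunciation, returning the dropped count."""
    have = {e.orthography for e in entries}
    kept = [r for r in norms if r.orthography in have]
    dropped = len(norms) - len(kept)
    if dropped:
        logger.info("dropped %d norm word(s) absent from the pronunciation lexicon", dropped)
    return kept, dropped
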