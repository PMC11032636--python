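"""Synthetic lexicons, ratings, covariates and outcomes with known truth.

The generator emulates the *structure* of the real inputs — a pronunciation
dictionary, a 1-7 Likert size-norms table with per-word rater variability,
a covariate table of lexical/semantic controls, and item-level behavioural
outcome tables — while planting every effect, so each pipeline stage can be
checked against ground truth without downloading anything.

What is emulated and what is not
--------------------------------
Word forms come from simple (onset)(vowel)(coda) syllable templates over
the full ARPAbet inventory.  This spans every phonetic category (a coverage
test asserts it) but is *not* English phonotactics: real cluster
constraints, positional frequencies and morphology are absent, so passing
recovery tests demonstrates the estimators work, not that English looks
like this.  Size ratings follow a linear model in the form features — by
default the 18-variable coefficient set of the published size model
(intercept 3.017, e.g. +0.361 per syllable) — plus word-level noise
calibrated so the refit adjusted R² lands near the observed ~0.20, then
per-rater noise, rounding to the 1-7 scale, and averaging over raters.
Covariates are independent normals matched to the reported means/SDs (an
optional correlation matrix adds realistic collinearity).  Outcomes are
linear in standardized controls plus *orthogonalized* size and typicality
components whose planted unique-variance shares (ΔR²) are therefore exact
by construction.

A single global seed fans out to per-stage child seeds, so stages can be
regenerated independently and byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import form_features as ff
from .lexicon_io import NormsRecord, PronunciationEntry

__all__ = [
    "DEFAULT_SIZE_COEFFICIENTS",
    "DEFAULT_SIZE_INTERCEPT",
    "OutcomeSpec",
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_lexicon",
    "generate_size_ratings",
    "generate_covariates",
    "generate_outcomes",
    "generate_study",
    "write_study",
]

# Default planted size-model coefficients (Likert units per feature unit).
DEFAULT_SIZE_INTERCEPT = 3.017
DEFAULT_SIZE_COEFFICIENTS: dict[str, float] = {
    "length_letters": 0.071,
    "n_high": -0.113,
    "n_mid": -0.066,
    "n_labiodental": 0.209,
    "n_linguodental": 0.232,
    "n_alveolar": 0.076,
    "n_palatal": 0.230,
    "n_stop": -0.096,
    "n_liquid": -0.066,
    "first_bilabial": -0.154,
    "first_labiodental": -0.199,
    "first_alveolar": -0.199,
    "first_palatal": -0.425,
    "first_voiced": 0.126,
    "final_velar": 0.126,
    "final_stop": 0.086,
    "n_syllables": 0.361,
    "stress_final": 0.239,
}

DEFAULT_SYLLABLE_DIST: dict[int, float] = {1: 0.33, 2: 0.42, 3: 0.18, 4: 0.06, 5: 0.01}
DEFAULT_POS_DIST: dict[str, float] = {
    "noun": 0.60, "adjective": 0.19, "verb": 0.17,
    "adverb": 0.01, "function": 0.01, "name": 0.02,
}

# Control-covariate means/SDs in the units of the real predictor tables.
DEFAULT_COVARIATE_STATS: dict[str, tuple[float, float]] = {
    "old": (2.23, 0.76),
    "pld": (2.11, 0.88),
    "bigram_frequency": (1043.35, 965.72),
    "zipf_frequency": (3.94, 0.73),
    "phonographic_neighbours": (2.13, 3.76),
    "feedforward_consistency": (0.87, 0.17),
    "feedback_consistency": (0.84, 0.18),
    "aoa": (4.10, 1.19),
    "prevalence": (2.32, 0.20),
    "concreteness": (4.41, 1.39),
    "arousal": (4.71, 1.12),
    "valence": (5.20, 1.57),
}

# Directions/relative magnitudes of control effects, in per-SD units; the
# vector is rescaled to hit each outcome's planted control R².
DEFAULT_CONTROL_SLOPES: dict[str, float] = {
    "length": 0.35,
    "old": 0.05,
    "pld": 0.05,
    "bigram_frequency": 0.05,
    "zipf_frequency": -0.40,
    "phonographic_neighbours": 0.08,
    "feedforward_consistency": -0.05,
    "feedback_consistency": 0.01,
    "aoa": 0.20,
    "prevalence": -0.30,
    "concreteness": 0.02,
    "arousal": -0.03,
    "valence": -0.05,
}

_ORTHOGRAPHY = {
    "AA": "o", "AE": "a", "AH": "u", "AO": "aw", "AW": "ow", "AY": "i",
    "EH": "e", "ER": "er", "EY": "ay", "IH": "i", "IY": "ee", "OW": "o",
    "OY": "oy", "UH": "oo", "UW": "u",
    "B": "b", "CH": "ch", "D": "d", "DH": "th", "F": "f", "G": "g",
    "HH": "h", "JH": "j", "K": "k", "L": "l", "M": "m", "N": "n",
    "NG": "ng", "P": "p", "R": "r", "S": "s", "SH": "sh", "T": "t",
    "TH": "th", "V": "v", "W": "w", "Y": "y", "Z": "z", "ZH": "zh",
}


@dataclass
class OutcomeSpec:
    """Planted structure of one behavioural outcome.

    ``control_r2``, ``size_delta_r2`` and ``typicality_delta_r2`` are the
    variance shares (of a unit-variance latent outcome) claimed by the
    scaled control block and by the orthogonalized size and typicality
    components; the signs carry the planted effect directions.  ``kind``
    selects the output mapping: ``"zrt"`` standardizes across items,
    ``"proportion"`` / ``"corrected_hit"`` apply a clamped affine map into
    [0, 1] / [-1, 1] with the given mean and SD.
    """

    name: str
    kind: str = "zrt"
    control_r2: float = 0.43
    size_delta_r2: float = 0.001
    size_sign: float = -1.0
    typicality_delta_r2: float = 0.005
    typicality_sign: float = -1.0
    out_mean: float = 0.0
    out_sd: float = 1.0
    control_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_SLOPES)
    )

    def __post_init__(self) -> None:
        if self.kind not in {"zrt", "proportion", "corrected_hit"}:
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        total = self.control_r2 + self.size_delta_r2 + self.typicality_delta_r2
        if not 0 <= total < 1:
            raise ValueError("planted variance shares must sum to < 1")


def _default_outcomes() -> dict[str, OutcomeSpec]:
    return {
        "zrt": OutcomeSpec("zrt", "zrt", 0.43, 0.001, -1.0, 0.005, -1.0),
        "accuracy": OutcomeSpec(
            "accuracy", "proportion", 0.36, 0.0, 1.0, 0.0, 1.0,
            out_mean=0.96, out_sd=0.06,
        ),
        "corrected_hit": OutcomeSpec(
            "corrected_hit", "corrected_hit", 0.30, 0.004, -1.0, 0.001, -1.0,
            out_mean=0.50, out_sd=0.13,
        ),
    }


@dataclass
class SyntheticConfig:
    """All knobs of the generator, with study-scale defaults."""

    n_words: int = 2924
    seed: int = 0
    syllable_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SYLLABLE_DIST)
    )
    pos_dist: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POS_DIST)
    )
    onset_prob: float = 0.85
    coda_prob: float = 0.60
    secondary_stress_prob: float = 0.15
    homograph_alternate_rate: float = 0.02
    # rating model
    rating_intercept: float = DEFAULT_SIZE_INTERCEPT
    rating_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_COEFFICIENTS)
    )
    n_raters: int = 30
    rater_sd: float = 1.2
    word_noise_sd: float | None = None  # None -> calibrated to target_adj_r2
    target_adj_r2: float = 0.201
    # covariate model
    covariate_stats: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_STATS)
    )
    covariate_corr: pd.DataFrame | None = None
    # outcome model
    outcomes: Mapping[str, OutcomeSpec] = field(default_factory=_default_outcomes)

    def __post_init__(self) -> None:
        if self.n_words < 1:
            raise ValueError("n_words must be >= 1")
        if self.n_raters < 2:
            raise ValueError("n_raters must be >= 2")
        for dist, what in ((self.syllable_dist, "syllable"), (self.pos_dist, "pos")):
            if not dist:
                raise ValueError(f"empty {what} distribution")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{what} distribution must sum to 1")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Child generator for a named stage (independent, reproducible)."""
        offsets = {"lexicon": 0, "ratings": 1, "covariates": 2, "outcomes": 3}
        root = np.random.SeedSequence(self.seed)
        return np.random.default_rng(root.spawn(4)[offsets[stage]])


@dataclass
class SyntheticStudy:
    """Bundle of everything one seeded run generates."""

    entries: list[PronunciationEntry]
    norms: list[NormsRecord]
    features: pd.DataFrame  # word x 60, all generated words
    predictors: pd.DataFrame  # word, length, covariates, category
    outcomes: pd.DataFrame  # word, one column per outcome
    truth: dict


def _make_word(rng: np.random.Generator, syllables: int, onset_p: float,
               coda_p: float, secondary_p: float) -> tuple[str, ...]:
    vowels = sorted(ff.ARPABET_VOWELS)
    consonants = sorted(ff.ARPABET_CONSONANTS)
    primary = int(rng.integers(syllables))
    phonemes: list[str] = []
    for s in range(syllables):
        if rng.random() < onset_p:
            phonemes.append(str(rng.choice(consonants)))
        if s == primary:
            digit = "1"
        elif rng.random() < secondary_p:
            digit = "2"
        else:
            digit = "0"
        phonemes.append(str(rng.choice(vowels)) + digit)
        if rng.random() < coda_p:
            phonemes.append(str(rng.choice(consonants)))
    return tuple(phonemes)


def generate_lexicon(config: SyntheticConfig) -> tuple[list[PronunciationEntry], list[str], list[bool]]:
    """Generate words, pronunciations, part-of-speech labels and homograph
    flags.  Deterministic under the config seed; every word has >= 1 vowel
    and a unique orthography derived from its phonemes."""
    rng = config.stage_rng("lexicon")
    syl_counts = sorted(config.syllable_dist)
    syl_probs = [config.syllable_dist[c] for c in syl_counts]
    pos_labels = sorted(config.pos_dist)
    pos_probs = [config.pos_dist[p] for p in pos_labels]

    entries: list[PronunciationEntry] = []
    pos: list[str] = []
    homograph: list[bool] = []
    used: set[str] = set()
    for _ in range(config.n_words):
        syllables = int(rng.choice(syl_counts, p=syl_probs))
        phonemes = _make_word(
            rng, syllables, config.onset_prob, config.coda_prob,
            config.secondary_stress_prob,
        )
        word = "".join(_ORTHOGRAPHY[ff.strip_stress(p)] for p in phonemes)
        while word in used:  # deterministic disambiguation
            word += "x"
        used.add(word)
        entries.append(PronunciationEntry(word, phonemes))
        pos.append(str(rng.choice(pos_labels, p=pos_probs)))
        homograph.append(bool(rng.random() < config.homograph_alternate_rate))
    return entries, pos, homograph


def _linear_predictor(features: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    s = np.full(len(features), float(config.rating_intercept))
    for name, beta in config.rating_coefficients.items():
        if name not in features.columns:
            raise KeyError(f"rating coefficient on unknown feature {name!r}")
        s += beta * features[name].to_numpy(dtype=float)
    return s


def calibrate_word_noise(features: pd.DataFrame, config: SyntheticConfig) -> float:
    """Word-level noise SD such that a refit of the rating model reaches
    the target adjusted R², accounting for rater noise and 1-7 rounding."""
    s0 = _linear_predictor(features, config)
    v_signal = float(np.var(s0))
    t = config.target_adj_r2
    v_noise_needed = v_signal * (1.0 - t) / t
    # variance contributed to the across-rater mean by rater noise + rounding
    v_rater = (config.rater_sd**2 + 1.0 / 12.0) / config.n_raters
    return float(np.sqrt(max(v_noise_needed - v_rater, 1e-4)))


def generate_size_ratings(
    features: pd.DataFrame, config: SyntheticConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Per-word rating mean and SD from a planted linear model plus rater
    noise, rounded to the 1-7 Likert scale and clamped.

    Returns ``(rating_mean, rating_sd, true_size, word_noise_sd)``.
    """
    rng = config.stage_rng("ratings")
    s0 = _linear_predictor(features, config)
    word_sd = (
        calibrate_word_noise(features, config)
        if config.word_noise_sd is None
        else float(config.word_noise_sd)
    )
    true_size = s0 + word_sd * rng.standard_normal(len(s0))
    responses = true_size[None, :] + config.rater_sd * rng.standard_normal(
        (config.n_raters, len(s0))
    )
    responses = np.clip(np.rint(responses), 1.0, 7.0)
    return responses.mean(axis=0), responses.std(axis=0, ddof=1), true_size, word_sd


def generate_covariates(n: int, config: SyntheticConfig) -> pd.DataFrame:
    """Control covariates: normals with the configured means/SDs, optionally
    correlated via a Cholesky factor of ``covariate_corr``."""
    rng = config.stage_rng("covariates")
    names = list(config.covariate_stats)
    z = rng.standard_normal((n, len(names)))
    if config.covariate_corr is not None:
        corr = config.covariate_corr.loc[names, names].to_numpy(dtype=float)
        z = z @ np.linalg.cholesky(corr).T
    data = {}
    for j, name in enumerate(names):
        mean, sd = config.covariate_stats[name]
        data[name] = mean + sd * z[:, j]
    return pd.DataFrame(data)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _residualize(x: np.ndarray, others: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), others])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


def generate_outcomes(
    predictors: pd.DataFrame,
    size: np.ndarray,
    typicality: np.ndarray,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict]:
    """Latent outcome = scaled controls + orthogonalized size and typicality
    components + noise; planted ΔR² shares are exact by construction.

    Controls are every ``predictors`` column named in the outcome's
    ``control_slopes`` (standardized internally).  Returns the outcome
    table and the planted ground truth per outcome.
    """
    rng = config.stage_rng("outcomes")
    out: dict[str, np.ndarray] = {}
    truth: dict[str, dict] = {}
    size_z = _standardize(np.asarray(size, dtype=float))
    ft_z = _standardize(np.asarray(typicality, dtype=float))
    for name, spec in config.outcomes.items():
        controls = [c for c in spec.control_slopes if c in predictors.columns]
        C = np.column_stack([_standardize(predictors[c].to_numpy(float)) for c in controls])
        gamma0 = np.array([spec.control_slopes[c] for c in controls])
        u = C @ gamma0
        scale = np.sqrt(spec.control_r2 / np.var(u)) if np.var(u) > 0 else 0.0
        u *= scale

        r_size = _residualize(size_z, C)
        beta_size = (
            spec.size_sign * np.sqrt(spec.size_delta_r2 / np.var(r_size))
            if spec.size_delta_r2 > 0 else 0.0
        )
        r_ft = _residualize(ft_z, np.column_stack([C, size_z]))
        beta_ft = (
            spec.typicality_sign * np.sqrt(spec.typicality_delta_r2 / np.var(r_ft))
            if spec.typicality_delta_r2 > 0 else 0.0
        )
        resid_sd = np.sqrt(
            1.0 - spec.control_r2 - spec.size_delta_r2 - spec.typicality_delta_r2
        )
        y = u + beta_size * r_size + beta_ft * r_ft + resid_sd * rng.standard_normal(len(u))
        if spec.kind == "zrt":
            y = _standardize(y)
        elif spec.kind == "proportion":
            y = np.clip(spec.out_mean + spec.out_sd * y, 0.0, 1.0)
        else:  # corrected_hit
            y = np.clip(spec.out_mean + spec.out_sd * y, -1.0, 1.0)
        out[name] = y
        truth[name] = {
            "control_r2": spec.control_r2,
            "size_delta_r2": spec.size_delta_r2,
            "size_sign": spec.size_sign,
            "typicality_delta_r2": spec.typicality_delta_r2,
            "typicality_sign": spec.typicality_sign,
            "beta_size": float(beta_size),
            "beta_typicality": float(beta_ft),
            "residual_sd": float(resid_sd),
        }
    frame = pd.DataFrame(out, index=predictors.index)
    return frame, truth


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Run the whole generator: lexicon, features, ratings, covariates and
    outcomes, with the planted truth recorded."""
    config = config or SyntheticConfig()
    entries, pos, homograph = generate_lexicon(config)
    features = ff.build_feature_matrix(entries)
    features = features.loc[[e.orthography for e in entries]]

    rating_mean, rating_sd, true_size, word_sd = generate_size_ratings(features, config)
    norms = [
        NormsRecord(
            orthography=e.orthography,
            rating_mean=float(np.clip(m, 1.0, 7.0)),
            rating_sd=float(s),
            pos=p,
            is_homograph_alternate=h,
        )
        for e, m, s, p, h in zip(entries, rating_mean, rating_sd, pos, homograph)
    ]

    covariates = generate_covariates(config.n_words, config)
    covariates.index = features.index
    predictors = covariates.copy()
    predictors.insert(0, "length", features["length_letters"])
    predictors["category"] = np.where(
        predictors["concreteness"] >= 4.41, "concrete", "abstract"
    )

    # ground-truth form typicality: the z-scored noiseless form signal
    s0 = _linear_predictor(features, config)
    ft_true = _standardize(s0)

    control_cols = predictors.drop(columns="category")
    outcomes, outcome_truth = generate_outcomes(
        control_cols, rating_mean, ft_true, config
    )

    truth = {
        "seed": config.seed,
        "n_words": config.n_words,
        "rating_intercept": config.rating_intercept,
        "rating_coefficients": dict(config.rating_coefficients),
        "word_noise_sd": word_sd,
        "rater_sd": config.rater_sd,
        "n_raters": config.n_raters,
        "target_adj_r2": config.target_adj_r2,
        "true_size": true_size.tolist(),
        "typicality_true": ft_true.tolist(),
        "outcomes": outcome_truth,
    }
    return SyntheticStudy(entries, norms, features, predictors, outcomes, truth)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write the exact input formats the pipeline reads, plus truth JSON."""
    from pathlib import Path

    from .lexicon_io import write_norms, write_pronunciations

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pronunciations": outdir / "lexicon.dict",
        "norms": outdir / "norms.csv",
        "predictors": outdir / "predictors.csv",
        "outcomes": outdir / "outcomes.csv",
        "truth": outdir / "truth.json",
    }
    write_pronunciations(study.entries, paths["pronunciations"])
    write_norms(study.norms, paths["norms"])
    study.predictors.rename_axis("word").to_csv(paths["predictors"])
    study.outcomes.rename_axis("word").to_csv(paths["outcomes"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(study.truth, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
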