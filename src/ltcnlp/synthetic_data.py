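"""Synthetic corpus generation with known ground truth, plus simulated annotators.

Real death-investigation narrative corpora are restricted-access, so every
stage of the pipeline is exercised against generated corpora whose
category assignments are known.  Narratives are assembled from fixed phrase
banks (:mod:`ltcnlp.phrases`): each positive record carries one or two
category-specific signature phrases, a fraction of negative records carry
keyword-bearing distractor phrases, and neutral filler clauses pad every
narrative to a length drawn from a floored normal distribution.

Independent random streams are used for each generation concern (category
assignment, lengths, location codes, covariates, narrative assembly, blanks)
so changing one configuration knob does not perturb the others.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .corpus_io import NarrativeRecord
from .phrases import DISTRACTOR_PHRASES, FILLER_CLAUSES, PHRASE_BANKS
from .types import CaseCategory, ConfigError, UnknownIdError

__all__ = [
    "CovariateProfile",
    "GeneratorConfig",
    "SyntheticCorpus",
    "OracleConfig",
    "generate_corpus",
    "oracle_annotate",
    "oracle_categorize",
    "expected_rater_kappa",
    "error_rate_for_kappa",
    "default_config",
]

NARRATIVE_LENGTH_FLOOR = 40

DEATH_LOCATION_CODES = (
    "inpatient",
    "outpatient/ED",
    "LTC/nursing home",
    "decedent's home",
    "other",
)

INJURY_LOCATION_SRF = "SRF"
_INJURY_LOCATION_OTHER = ("house or apartment", "other")

_MARITAL_LEVELS = (
    "married/in a relationship",
    "single/never married",
    "widowed",
    "divorced/separated",
    "unknown",
    "missing",
)

_MEANS_LEVELS = (
    "firearm",
    "sharp_blunt",
    "poisoning",
    "fall",
    "other",
    "unknown",
    "missing",
)

_MANNER_LEVELS = ("suicide", "undetermined", "accidental_firearm")

FLAG_NAMES = (
    "depressed_mood",
    "physical_health_problem",
    "suicidal_ideation_history",
    "recent_crisis",
    "any_crisis",
    "crisis_eviction_loss_of_home",
    "crisis_death_of_friend_or_relative",
    "crisis_financial",
    "crisis_family_relationship",
)


@dataclass
class CovariateProfile:
    """Per-category marginal distributions for structured covariates."""

    male_p: float
    white_p: float
    age_median: float
    age_sd: float
    marital: Mapping[str, float]
    manner: Mapping[str, float]
    means: Mapping[str, float]
    flags: Mapping[str, float]
    deathloc: Mapping[str, float]


def _norm_dist(d: Mapping[str, float]) -> Dict[str, float]:
    total = float(sum(d.values()))
    if total <= 0:
        raise ConfigError("distribution has nonpositive mass")
    return {k: v / total for k, v in d.items()}


def _default_profiles() -> Dict[CaseCategory, CovariateProfile]:
    """Calibration defaults chosen to match national surveillance marginals."""
    C = CaseCategory
    common_neg_deathloc = {
        "inpatient": 0.12,
        "outpatient/ED": 0.08,
        "LTC/nursing home": 0.010,
        "decedent's home": 0.70,
        "other": 0.09,
    }
    return {
        C.NOT_ASSOCIATED: CovariateProfile(
            male_p=0.776, white_p=0.898, age_median=64, age_sd=11,
            marital={"married/in a relationship": 0.443, "single/never married": 0.108,
                     "widowed": 0.152, "divorced/separated": 0.279,
                     "unknown": 0.016, "missing": 0.002},
            manner={"suicide": 0.890, "undetermined": 0.104, "accidental_firearm": 0.006},
            means={"firearm": 0.573, "sharp_blunt": 0.026, "poisoning": 0.204,
                   "fall": 0.017, "other": 0.033, "unknown": 0.019, "missing": 0.128},
            flags={"depressed_mood": 0.359, "physical_health_problem": 0.377,
                   "suicidal_ideation_history": 0.120, "recent_crisis": 0.113,
                   "any_crisis": 0.202, "crisis_eviction_loss_of_home": 0.023,
                   "crisis_death_of_friend_or_relative": 0.077,
                   "crisis_financial": 0.093, "crisis_family_relationship": 0.041},
            deathloc=common_neg_deathloc,
        ),
        C.IN_LTC: CovariateProfile(
            male_p=0.647, white_p=0.925, age_median=79, age_sd=12,
            marital={"married/in a relationship": 0.234, "single/never married": 0.136,
                     "widowed": 0.393, "divorced/separated": 0.231,
                     "unknown": 0.005, "missing": 0.001},
            manner={"suicide": 0.897, "undetermined": 0.103, "accidental_firearm": 0.0},
            means={"firearm": 0.243, "sharp_blunt": 0.05, "poisoning": 0.227,
                   "fall": 0.08, "other": 0.05, "unknown": 0.046, "missing": 0.304},
            flags={"depressed_mood": 0.393, "physical_health_problem": 0.507,
                   "suicidal_ideation_history": 0.093, "recent_crisis": 0.119,
                   "any_crisis": 0.196, "crisis_eviction_loss_of_home": 0.023,
                   "crisis_death_of_friend_or_relative": 0.100,
                   "crisis_financial": 0.035, "crisis_family_relationship": 0.019},
            deathloc={"inpatient": 0.133, "outpatient/ED": 0.100,
                      "LTC/nursing home": 0.206, "decedent's home": 0.357,
                      "other": 0.204},
        ),
        C.TRANSITIONING: CovariateProfile(
            male_p=0.802, white_p=0.953, age_median=80, age_sd=10,
            marital={"married/in a relationship": 0.261, "single/never married": 0.062,
                     "widowed": 0.454, "divorced/separated": 0.218,
                     "unknown": 0.004, "missing": 0.001},
            manner={"suicide": 0.978, "undetermined": 0.022, "accidental_firearm": 0.0},
            means={"firearm": 0.710, "sharp_blunt": 0.02, "poisoning": 0.138,
                   "fall": 0.02, "other": 0.012, "unknown": 0.006, "missing": 0.094},
            flags={"depressed_mood": 0.450, "physical_health_problem": 0.782,
                   "suicidal_ideation_history": 0.169, "recent_crisis": 0.269,
                   "any_crisis": 0.361, "crisis_eviction_loss_of_home": 0.091,
                   "crisis_death_of_friend_or_relative": 0.127,
                   "crisis_financial": 0.031, "crisis_family_relationship": 0.085},
            deathloc=common_neg_deathloc,
        ),
        C.OTHERWISE_ASSOCIATED: CovariateProfile(
            male_p=0.800, white_p=0.962, age_median=75, age_sd=13,
            marital={"married/in a relationship": 0.725, "single/never married": 0.075,
                     "widowed": 0.088, "divorced/separated": 0.106,
                     "unknown": 0.005, "missing": 0.001},
            manner={"suicide": 0.960, "undetermined": 0.040, "accidental_firearm": 0.0},
            means={"firearm": 0.662, "sharp_blunt": 0.02, "poisoning": 0.169,
                   "fall": 0.02, "other": 0.015, "unknown": 0.008, "missing": 0.106},
            flags={"depressed_mood": 0.613, "physical_health_problem": 0.400,
                   "suicidal_ideation_history": 0.088, "recent_crisis": 0.206,
                   "any_crisis": 0.281, "crisis_eviction_loss_of_home": 0.062,
                   "crisis_death_of_friend_or_relative": 0.062,
                   "crisis_financial": 0.150, "crisis_family_relationship": 0.244},
            deathloc=common_neg_deathloc,
        ),
    }


def _default_states() -> Tuple[Tuple[str, int], ...]:
    """27 synthetic states; the first 13 begin reporting in 2003 or 2004."""
    early = tuple((f"S{i:02d}", 2003 if i <= 7 else 2004) for i in range(1, 14))
    late_years = (2005, 2005, 2006, 2006, 2007, 2008, 2009, 2010, 2010,
                  2011, 2012, 2013, 2013, 2014)
    late = tuple((f"S{i:02d}", y) for i, y in zip(range(14, 28), late_years))
    return early + late


def _default_prevalence() -> Dict[CaseCategory, float]:
    n = 47759.0
    p = {
        CaseCategory.IN_LTC: 428 / n,
        CaseCategory.TRANSITIONING: 449 / n,
        CaseCategory.OTHERWISE_ASSOCIATED: 160 / n,
    }
    p[CaseCategory.NOT_ASSOCIATED] = 1.0 - sum(p.values())
    return p


@dataclass
class GeneratorConfig:
    """Configuration for :func:`generate_corpus`.

    Defaults are calibrated so that a corpus of 47 759 records reproduces, in
    expectation, the marginal structure of the national analytic sample this
    generator stands in for: ~2.2% LTC-associated prevalence split 428/449/160
    across subtypes, narrative lengths with mean 513.8 and SD 344.2
    characters, an SRF injury-location code with 25% sensitivity for
    in-facility cases, and covariate marginals per category.
    """

    n_records: int = 47759
    prevalence: Dict[CaseCategory, float] = field(default_factory=_default_prevalence)
    narrative_length_mean: float = 513.8
    narrative_length_sd: float = 344.2
    srf_sensitivity: float = 0.25
    srf_false_positive_rate: float = 157.0 / 47331.0
    blank_narrative_fraction: float = 2578.0 / 50337.0
    distractor_fraction: float = 0.145
    covariate_marginals: Dict[CaseCategory, CovariateProfile] = field(
        default_factory=_default_profiles
    )
    states: Tuple[Tuple[str, int], ...] = field(default_factory=_default_states)
    year_range: Tuple[int, int] = (2003, 2015)
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 0:
            raise ConfigError("n_records must be nonnegative")
        vals = list(self.prevalence.values())
        if any(v < 0 for v in vals):
            raise ConfigError("prevalence values must be nonnegative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigError(f"prevalence must sum to 1, got {sum(vals)!r}")
        for name in ("srf_sensitivity", "srf_false_positive_rate",
                     "blank_narrative_fraction", "distractor_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.narrative_length_mean <= 0:
            raise ConfigError("narrative_length_mean must be positive")
        if self.narrative_length_sd < 0:
            raise ConfigError("narrative_length_sd must be nonnegative")
        y0, y1 = self.year_range
        if y0 > y1:
            raise ConfigError("year_range must be (first, last) with first <= last")


def default_config(**overrides) -> GeneratorConfig:
    """Calibrated default configuration, with keyword overrides applied."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class SyntheticCorpus:
    """Generated records plus the hidden ground-truth category map."""

    records: List[NarrativeRecord]
    truth: Dict[str, CaseCategory]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate record ids in corpus")
        missing = set(ids) - set(self.truth)
        if missing:
            raise ConfigError(f"{len(missing)} record ids missing from truth map")

    def __len__(self) -> int:
        return len(self.records)

    def narratives(self) -> Dict[str, str]:
        return {r.id: r.narrative for r in self.records}

    def binary_truth(self, record_id: str) -> int:
        try:
            return int(self.truth[record_id].is_ltc)
        except KeyError:
            raise UnknownIdError(record_id) from None


@dataclass
class OracleConfig:
    """Simulated annotator: flips the true binary label with ``error_rate``."""

    error_rate: float = 0.0
    n_raters: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must be in [0, 0.5)")
        if self.n_raters < 1:
            raise ConfigError("n_raters must be >= 1")


def _length_model_params(mean: float, sd: float) -> Tuple[float, float]:
    """Internal normal parameters such that flooring at 40 chars recovers
    the configured mean/SD of generated lengths."""
    if sd == 0:
        return max(mean, NARRATIVE_LENGTH_FLOOR), 0.0
    L = float(NARRATIVE_LENGTH_FLOOR)

    def moments(p):
        mu, sigma = p
        sigma = abs(sigma)
        a = (L - mu) / sigma
        Phi, phi = norm.cdf(a), norm.pdf(a)
        m1 = L * Phi + mu * (1 - Phi) + sigma * phi
        m2 = L * L * Phi + (mu * mu + sigma * sigma) * (1 - Phi) + sigma * (L + mu) * phi
        return m1, math.sqrt(max(m2 - m1 * m1, 0.0))

    def eqs(p):
        m1, s1 = moments(p)
        return [m1 - mean, s1 - sd]

    sol, info, ier, _ = optimize.fsolve(eqs, [mean, sd], full_output=True)
    if ier != 1 or max(abs(v) for v in info["fvec"]) > 1e-6:
        # Fall back to raw parameters; the floor then biases the moments.
        return mean, sd
    return float(sol[0]), abs(float(sol[1]))


# Phrases starting with these words take "The decedent" as their subject.
_VERB_STARTS = frozenset(
    "was had lived resided spoke visited told said dreaded stated reported "
    "completed described worked".split()
)


def _phrase_sentence(phrase: str) -> str:
    first = phrase.split(" ", 1)[0]
    if first in _VERB_STARTS:
        return "The decedent " + phrase + "."
    return phrase[0].upper() + phrase[1:] + "."


def _assemble_narrative(
    rng: np.random.Generator,
    category: CaseCategory,
    target_len: int,
    use_distractor: bool,
) -> str:
    parts: List[str] = []
    if category.is_ltc:
        bank = PHRASE_BANKS[category.value]
        n_sig = 2 + int(rng.random() < 0.25)
        idx = rng.choice(len(bank), size=min(n_sig, len(bank)), replace=False)
        for i in idx:
            parts.append(_phrase_sentence(bank[int(i)]))
    elif use_distractor:
        i = int(rng.integers(len(DISTRACTOR_PHRASES)))
        parts.append(_phrase_sentence(DISTRACTOR_PHRASES[i]))
    text = " ".join(parts)
    # Signature content is never cut: only filler is trimmed to hit the
    # target, so short positive narratives still carry their phrases.
    min_len = max(target_len, len(text))
    while len(text) < min_len:
        clause = FILLER_CLAUSES[int(rng.integers(len(FILLER_CLAUSES)))]
        text = clause if not text else text + " " + clause
    return text[:min_len]


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a corpus of ``config.n_records`` records with known truth.

    Fully deterministic for a fixed ``config.seed``.
    """
    config.validate()
    n = config.n_records
    if n == 0:
        return SyntheticCorpus(records=[], truth={})

    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_cat, rng_len, rng_code, rng_cov, rng_text, rng_blank = (
        np.random.default_rng(s) for s in streams
    )

    categories_order = list(CaseCategory)
    probs = np.array([config.prevalence.get(c, 0.0) for c in categories_order])
    cat_idx = rng_cat.choice(len(categories_order), size=n, p=probs)

    mu, sigma = _length_model_params(
        config.narrative_length_mean, config.narrative_length_sd
    )
    lengths = np.maximum(
        rng_len.normal(mu, sigma, size=n), NARRATIVE_LENGTH_FLOOR
    ).astype(int)
    blanks = rng_blank.random(n) < config.blank_narrative_fraction
    distract = rng_text.random(n) < config.distractor_fraction

    y0, y1 = config.year_range
    states = [s for s, first in config.states if first <= y1]
    first_year = dict(config.states)
    state_pick = rng_cov.integers(len(states), size=n) if states else None

    records: List[NarrativeRecord] = []
    truth: Dict[str, CaseCategory] = {}
    for i in range(n):
        cat = categories_order[int(cat_idx[i])]
        prof = config.covariate_marginals[cat]
        rid = f"D{i:06d}"

        state = states[int(state_pick[i])] if states else "S00"
        lo = max(y0, first_year.get(state, y0))
        year = int(rng_cov.integers(lo, y1 + 1))

        age = int(np.clip(round(rng_cov.normal(prof.age_median, prof.age_sd)), 55, 105))
        sex = "male" if rng_cov.random() < prof.male_p else "female"
        race = "non-Hispanic white" if rng_cov.random() < prof.white_p else "other"
        marital_d = _norm_dist(prof.marital)
        marital = str(rng_cov.choice(list(marital_d), p=list(marital_d.values())))
        manner_d = _norm_dist(prof.manner)
        manner = str(rng_cov.choice(list(manner_d), p=list(manner_d.values())))
        means_d = _norm_dist(prof.means)
        means = str(rng_cov.choice(list(means_d), p=list(means_d.values())))

        flags: Dict[str, bool] = {}
        p_recent = prof.flags.get("recent_crisis", 0.0)
        p_any = max(prof.flags.get("any_crisis", p_recent), p_recent)
        recent = rng_cov.random() < p_recent
        extra = 0.0 if p_recent >= 1.0 else (p_any - p_recent) / (1.0 - p_recent)
        any_crisis = recent or (rng_cov.random() < extra)
        for name in FLAG_NAMES:
            if name == "recent_crisis":
                flags[name] = bool(recent)
            elif name == "any_crisis":
                flags[name] = bool(any_crisis)
            else:
                flags[name] = bool(rng_cov.random() < prof.flags.get(name, 0.0))

        srf_p = (
            config.srf_sensitivity
            if cat is CaseCategory.IN_LTC
            else config.srf_false_positive_rate
        )
        if rng_code.random() < srf_p:
            injury_loc = INJURY_LOCATION_SRF
        else:
            injury_loc = _INJURY_LOCATION_OTHER[int(rng_code.random() > 0.65)]
        deathloc_d = _norm_dist(prof.deathloc)
        death_loc = str(rng_code.choice(list(deathloc_d), p=list(deathloc_d.values())))

        if blanks[i]:
            narrative = ""
        else:
            narrative = _assemble_narrative(
                rng_text, cat, int(lengths[i]), bool(distract[i])
            )

        records.append(
            NarrativeRecord(
                id=rid, state=state, year=year, age=age, sex=sex,
                race_eth=race, marital=marital, manner=manner, means=means,
                injury_location_code=injury_loc, death_location_code=death_loc,
                flags=flags, narrative=narrative,
            )
        )
        truth[rid] = cat

    return SyntheticCorpus(records=records, truth=truth)


def oracle_annotate(
    corpus: SyntheticCorpus,
    ids: Sequence[str],
    oracle: OracleConfig,
) -> Dict[str, Dict[str, int]]:
    """Simulate ``oracle.n_raters`` independent binary annotations of ``ids``.

    Each rater returns the true LTC-associated label, independently flipped
    with probability ``oracle.error_rate``.  Reproducible from ``oracle.seed``.

    Returns a map rater name -> (id -> 0/1).
    """
    oracle.validate()
    unknown = [i for i in ids if i not in corpus.truth]
    if unknown:
        raise UnknownIdError(f"unknown ids: {unknown[:5]}{'...' if len(unknown) > 5 else ''}")
    out: Dict[str, Dict[str, int]] = {}
    for r in range(oracle.n_raters):
        rng = np.random.default_rng(np.random.SeedSequence([oracle.seed, r]))
        flips = rng.random(len(ids)) < oracle.error_rate
        out[f"rater{r}"] = {
            rid: int(corpus.binary_truth(rid)) ^ int(flip)
            for rid, flip in zip(ids, flips)
        }
    return out


def oracle_categorize(
    corpus: SyntheticCorpus, ids: Iterable[str]
) -> Dict[str, CaseCategory]:
    """Return ground-truth categories for ``ids`` (simulated 4-way annotation)."""
    out: Dict[str, CaseCategory] = {}
    for rid in ids:
        if rid not in corpus.truth:
            raise UnknownIdError(rid)
        out[rid] = corpus.truth[rid]
    return out


def make_oracle_annotator(
    corpus: SyntheticCorpus, oracle: OracleConfig
) -> Callable[[Sequence[str]], Dict[str, Dict[str, int]]]:
    """Bind a corpus + oracle config into an ``ids -> rater labels`` callable."""
    counter = {"round": 0}

    def annotate(ids: Sequence[str]) -> Dict[str, Dict[str, int]]:
        # Vary the stream per call so repeated rounds are independent.
        counter["round"] += 1
        cfg = dataclasses.replace(oracle, seed=oracle.seed + counter["round"])
        return oracle_annotate(corpus, ids, cfg)

    return annotate


def expected_rater_kappa(error_rate: float, prevalence: float = 0.5) -> float:
    """Closed-form expected Cohen's kappa between two independent raters who
    each flip the true binary label with probability ``error_rate``.

    Observed agreement is ``1 - 2e(1-e)`` regardless of prevalence; chance
    agreement comes from the common marginal ``q = p(1-2e) + e``.  At
    ``prevalence=0.5`` this reduces to ``1 - 4e(1-e)``.
    """
    e, p = error_rate, prevalence
    po = 1.0 - 2.0 * e * (1.0 - e)
    q = p * (1.0 - 2.0 * e) + e
    pe = q * q + (1.0 - q) * (1.0 - q)
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def error_rate_for_kappa(kappa: float) -> float:
    """Invert :func:`expected_rater_kappa` at balanced prevalence.

    From ``kappa = 1 - 4e(1-e)``: ``e = (1 - sqrt(kappa)) / 2``.
    """
    if not 0.0 < kappa <= 1.0:
        raise ConfigError("kappa must be in (0, 1]")
    return (1.0 - math.sqrt(kappa)) / 2.0
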