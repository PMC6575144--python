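"""Keyword-based candidate discovery and labeled-set management.

The initial training set is seeded by searching narratives for a small set
of care-related keywords, sampling candidates for annotation, and recording
rater labels.  Unanimous items enter the labeled set directly; discordant
items are adjudicated by majority vote with a designated tie-breaking rater.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .corpus_io import AnalyticSample
from .types import ConfigError

__all__ = [
    "KeywordSet",
    "LabelEntry",
    "LabeledSet",
    "AnnotationOutcome",
    "DEFAULT_KEYWORDS",
    "keyword_search",
    "sample_for_annotation",
    "record_annotations",
]

#: Default seed keywords; the published lists for this kind of triage are
#: short and extensible, so these live in config rather than code paths.
DEFAULT_KEYWORDS = (
    "long-term",
    "convalescent",
    "residential",
    "nursing home",
    "assisted living",
    "care facility",
    "rehab",
)

SOURCE_KEYWORD_SEED = "keyword-seed"
SOURCE_BAND_SAMPLE = "band-sample"
SOURCE_ADJUDICATION = "adjudication"
_VALID_SOURCES = {SOURCE_KEYWORD_SEED, SOURCE_BAND_SAMPLE, SOURCE_ADJUDICATION}


@dataclass(frozen=True)
class KeywordSet:
    terms: Tuple[str, ...] = DEFAULT_KEYWORDS
    match_mode: str = "substring"  # or "word-boundary"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigError("keyword set must be nonempty")
        lowered = [t.lower() for t in self.terms]
        if len(set(lowered)) != len(lowered):
            raise ConfigError("duplicate keywords")
        if self.match_mode not in ("substring", "word-boundary"):
            raise ConfigError(f"unknown match_mode {self.match_mode!r}")
        object.__setattr__(self, "terms", tuple(lowered))

    def matches(self, text: str) -> bool:
        low = text.lower()
        if self.match_mode == "substring":
            return any(t in low for t in self.terms)
        import re

        return any(
            re.search(r"\b" + re.escape(t) + r"\b", low) for t in self.terms
        )


@dataclass(frozen=True)
class LabelEntry:
    label: int
    round: int
    source: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ConfigError("labels must be binary")
        if self.source not in _VALID_SOURCES:
            raise ConfigError(f"unknown label source {self.source!r}")


@dataclass
class LabeledSet:
    """Append-only map of record id -> binary label with provenance."""

    entries: Dict[str, LabelEntry] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.entries

    def add(self, record_id: str, label: int, round: int, source: str) -> None:
        entry = LabelEntry(label=label, round=round, source=source)
        existing = self.entries.get(record_id)
        if existing is not None:
            if existing.label != label:
                raise ConfigError(
                    f"conflicting re-annotation of {record_id!r}: "
                    f"{existing.label} vs {label}"
                )
            return  # idempotent re-add with the same label
        self.entries[record_id] = entry

    def labels(self) -> Dict[str, int]:
        return {k: v.label for k, v in self.entries.items()}

    def ids(self) -> List[str]:
        return sorted(self.entries)

    def positives(self) -> List[str]:
        return sorted(k for k, v in self.entries.items() if v.label == 1)

    def negatives(self) -> List[str]:
        return sorted(k for k, v in self.entries.items() if v.label == 0)

    def copy(self) -> "LabeledSet":
        return LabeledSet(entries=dict(self.entries))

    def class_counts(self) -> Tuple[int, int]:
        pos = sum(v.label for v in self.entries.values())
        return len(self.entries) - pos, pos

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "label", "round", "source"])
            for rid in sorted(self.entries):
                e = self.entries[rid]
                w.writerow([rid, e.label, e.round, e.source])

    @classmethod
    def read_csv(cls, path: str | Path) -> "LabeledSet":
        out = cls()
        with Path(path).open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                out.add(row["id"], int(row["label"]), int(row["round"]), row["source"])
        return out


@dataclass
class AnnotationOutcome:
    """Result of folding one round of rater labels into a labeled set."""

    labeled: LabeledSet
    unanimous_ids: List[str]
    discordant_ids: List[str]
    adjudicated: Dict[str, int]

    @property
    def n_entered(self) -> int:
        return len(self.unanimous_ids) + len(self.adjudicated)


def keyword_search(sample: AnalyticSample, keywords: KeywordSet) -> List[str]:
    """Return ids (sorted) of narratives matching at least one keyword."""
    return sorted(r.id for r in sample.records if keywords.matches(r.narrative))


def sample_for_annotation(
    candidates: Sequence[str], n: int, seed: int
) -> List[str]:
    """Simple random sample of ``n`` candidate ids without replacement."""
    if n > len(candidates):
        raise ValueError(f"requested {n} from a pool of {len(candidates)}")
    rng = np.random.default_rng(seed)
    # Sort first so the draw depends only on the candidate *set* and seed.
    pool = sorted(candidates)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[int(i)] for i in idx]


def record_annotations(
    labeled: LabeledSet,
    rater_labels: Mapping[str, Mapping[str, int]],
    round: int,
    source: str = SOURCE_KEYWORD_SEED,
    tiebreak_rater: str | None = None,
) -> AnnotationOutcome:
    """Fold per-rater binary labels into a new labeled set.

    All raters must have labeled the same id set.  Unanimous items enter with
    the given ``source``; discordant items are adjudicated by majority vote
    (ties resolved by ``tiebreak_rater``, default the first rater name in
    sorted order) and enter with source ``adjudication``.  The input
    ``labeled`` set is not mutated.
    """
    if not rater_labels:
        raise ValueError("need at least one rater")
    raters = sorted(rater_labels)
    id_sets = [set(rater_labels[r]) for r in raters]
    if any(s != id_sets[0] for s in id_sets[1:]):
        raise ValueError("raters labeled different id sets")
    if tiebreak_rater is None:
        tiebreak_rater = raters[0]
    if tiebreak_rater not in rater_labels:
        raise ValueError(f"unknown tiebreak rater {tiebreak_rater!r}")

    out = labeled.copy()
    unanimous: List[str] = []
    discordant: List[str] = []
    adjudicated: Dict[str, int] = {}
    for rid in sorted(id_sets[0]):
        votes = [int(rater_labels[r][rid]) for r in raters]
        if len(set(votes)) == 1:
            out.add(rid, votes[0], round, source)
            unanimous.append(rid)
        else:
            discordant.append(rid)
            ones = sum(votes)
            if ones * 2 == len(votes):
                final = int(rater_labels[tiebreak_rater][rid])
            else:
                final = int(ones * 2 > len(votes))
            out.add(rid, final, round, SOURCE_ADJUDICATION)
            adjudicated[rid] = final
    return AnnotationOutcome(
        labeled=out,
        unanimous_ids=unanimous,
        discordant_ids=discordant,
        adjudicated=adjudicated,
    )
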