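"""Four-way categorization of classifier positives and final label assembly.

Classifier positives are resolved to one of the four case categories (the
fourth, NOT_ASSOCIATED, marks false positives); everything at or below the
probability threshold is NOT_ASSOCIATED by definition.  The merge step
combines positives discovered at the keyword-seed stage, the band-annotation
stage, and the final annotation pass into a single full-corpus assignment
with an exact accounting report.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Sequence, Union

from .types import CaseCategory, UnknownIdError

__all__ = [
    "CategorizeError",
    "FinalLabeling",
    "assign_categories",
    "merge_final_labels",
]

Resolver = Union[
    Mapping[str, CaseCategory],
    Callable[[Sequence[str]], Mapping[str, CaseCategory]],
]


class CategorizeError(ValueError):
    pass


def assign_categories(
    positive_ids: Sequence[str], resolver: Resolver
) -> Dict[str, CaseCategory]:
    """Resolve every classifier-positive id to a case category.

    ``resolver`` is either a mapping or a callable (e.g. the synthetic
    categorization oracle, or a loaded annotation file).  Every positive id
    must resolve; unresolved ids raise :class:`CategorizeError`.
    """
    ids = list(positive_ids)
    if callable(resolver):
        try:
            resolved = dict(resolver(ids))
        except UnknownIdError as exc:
            raise CategorizeError(f"unresolvable id: {exc}") from exc
    else:
        resolved = {i: resolver[i] for i in ids if i in resolver}
    missing = [i for i in ids if i not in resolved]
    if missing:
        raise CategorizeError(
            f"{len(missing)} positive ids unresolved: {missing[:5]}"
        )
    return {i: CaseCategory(resolved[i]) for i in ids}


@dataclass
class FinalLabeling:
    """Full-corpus category assignment plus stage accounting."""

    assignment: Dict[str, CaseCategory]
    stage_of: Dict[str, str]
    report: Dict[str, object] = field(default_factory=dict)

    @property
    def total_ltc(self) -> int:
        return sum(1 for c in self.assignment.values() if c.is_ltc)

    def subgroup_counts(self) -> Dict[CaseCategory, int]:
        counts = {c: 0 for c in CaseCategory}
        for c in self.assignment.values():
            counts[c] += 1
        return counts


def merge_final_labels(
    stage_maps: Mapping[str, Mapping[str, CaseCategory]],
    all_ids: Iterable[str],
) -> FinalLabeling:
    """Combine per-stage category maps into one full-corpus assignment.

    ``stage_maps`` maps a stage name (e.g. ``keyword-seed``, ``band-sample``,
    ``final``) to the categories assigned at that stage.  Stages are applied
    in insertion order; an id categorized differently by two stages is a
    reconciliation failure and raises :class:`CategorizeError` listing the
    conflicting ids.  Ids in ``all_ids`` not covered by any stage are
    NOT_ASSOCIATED.  The report reconciles per-stage counts against the final
    totals exactly.
    """
    assignment: Dict[str, CaseCategory] = {}
    stage_of: Dict[str, str] = {}
    conflicts: List[str] = []
    for stage, mapping in stage_maps.items():
        for rid, cat in mapping.items():
            cat = CaseCategory(cat)
            if rid in assignment and assignment[rid] != cat:
                conflicts.append(rid)
                continue
            if rid not in assignment:
                assignment[rid] = cat
                stage_of[rid] = stage
    if conflicts:
        raise CategorizeError(
            f"{len(conflicts)} ids categorized inconsistently across stages: "
            f"{sorted(conflicts)[:10]}"
        )

    covered = set(assignment)
    for rid in all_ids:
        if rid not in covered:
            assignment[rid] = CaseCategory.NOT_ASSOCIATED
            stage_of[rid] = "unlabeled"

    per_stage_ltc = {
        stage: sum(
            1 for rid in mapping if assignment.get(rid, CaseCategory.NOT_ASSOCIATED).is_ltc
            and stage_of.get(rid) == stage
        )
        for stage, mapping in stage_maps.items()
    }
    subgroup_totals = {c.value: 0 for c in CaseCategory}
    for c in assignment.values():
        subgroup_totals[c.value] += 1
    total_ltc = sum(
        v for k, v in subgroup_totals.items()
        if k != CaseCategory.NOT_ASSOCIATED.value
    )
    if sum(per_stage_ltc.values()) != total_ltc:
        raise CategorizeError(
            "stage accounting does not reconcile: "
            f"{per_stage_ltc} vs total {total_ltc}"
        )
    report = {
        "per_stage_ltc": per_stage_ltc,
        "subgroup_totals": subgroup_totals,
        "total_ltc": total_ltc,
        "n_records": len(assignment),
    }
    return FinalLabeling(assignment=assignment, stage_of=stage_of, report=report)
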