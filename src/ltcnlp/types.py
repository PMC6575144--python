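"""Shared domain types."""
from __future__ import annotations

import enum


class CaseCategory(str, enum.Enum):
    """Four-way classification of a death with respect to residential long-term care.

    ``IN_LTC``: the decedent was living in a residential LTC facility when injured.
    ``TRANSITIONING``: the decedent was moving into (or out of) LTC.
    ``OTHERWISE_ASSOCIATED``: LTC was a salient circumstance (caregiver strain,
    fear of placement, financial burden) without residence or transition.
    ``NOT_ASSOCIATED``: everything else, including classifier false positives.
    """

    IN_LTC = "in_ltc"
    TRANSITIONING = "transitioning"
    OTHERWISE_ASSOCIATED = "otherwise_associated"
    NOT_ASSOCIATED = "not_associated"

    @property
    def is_ltc(self) -> bool:
        return self is not CaseCategory.NOT_ASSOCIATED


#: The three LTC-associated subgroups, in canonical display order.
LTC_SUBGROUPS = (
    CaseCategory.IN_LTC,
    CaseCategory.TRANSITIONING,
    CaseCategory.OTHERWISE_ASSOCIATED,
)


class ConfigError(ValueError):
    """Raised when a configuration object violates its invariants."""


class UnknownIdError(KeyError):
    """Raised when an id cannot be resolved against a corpus or labeling."""
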