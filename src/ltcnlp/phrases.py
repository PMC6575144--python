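"""Versioned phrase banks for the synthetic narrative generator.

The vocabulary is fixed so that generated corpora are stable across releases;
bump ``PHRASES_VERSION`` whenever any bank changes.
"""
from __future__ import annotations

PHRASES_VERSION = "1.0"

# Signature phrases for decedents living in a residential care facility.
FACILITY_PHRASES = (
    "was a resident of a nursing home",
    "lived at an assisted living facility",
    "was found in his room at the convalescent center",
    "staff at the long-term care facility found the decedent unresponsive",
    "was a resident of the skilled nursing and care facility",
    "the nursing home staff discovered the decedent during morning rounds",
    "was living at a continuing care residential community",
    "a nursing aide at the care facility found him unresponsive",
    "resided in the memory care unit of an assisted living facility",
    "was a resident of the care facility for the past two years",
    "was found by long-term care staff during evening checks",
    "was in the dining hall of the assisted living center earlier that day",
    "the convalescent home reported the decedent missing from his room",
    "the long-term care facility where the decedent resided notified police",
    "was living in the nursing unit of a veterans care facility",
    "was a resident at the rehabilitation and nursing center",
)

# Signature phrases for decedents transitioning into or out of care.
TRANSITION_PHRASES = (
    "was to be placed in a nursing home the following week",
    "had recently been discharged from the rehabilitation facility",
    "was scheduled to move into assisted living",
    "was being admitted to a long-term care facility",
    "the family planned to place her in a care facility",
    "had toured an assisted living facility the prior week",
    "was on a waiting list for the nursing home",
    "discharge paperwork for placement in a skilled nursing facility was found",
    "had recently moved out of the convalescent home",
    "was in the process of transitioning to residential care",
    "placement in a long-term care facility was pending",
    "had just been released from the nursing facility to his home",
    "had been told he could no longer live at home and needed residential care",
    "admission paperwork for the nursing home was found on the table",
    "the move to the continuing care residential community was scheduled",
    "the family had arranged nursing home placement for the decedent",
)

# Signature phrases for deaths otherwise associated with care settings
# (caregivers, fear of placement, financial strain).
OTHERWISE_PHRASES = (
    "his wife had recently been placed in a nursing home",
    "was the primary caregiver for a spouse living in long-term care",
    "had told family he feared he would end up in a nursing home",
    "was worried about the cost of long-term care",
    "stated she could not afford the assisted living fees",
    "told friends he would never go to a nursing home",
    "was distressed over her mother's nursing home bills",
    "was anxious about possibly needing residential care after the fall",
    "visited his brother at the care facility every day",
    "spoke often about the financial burden of the convalescent home",
    "dreaded becoming a burden and being put in a care facility",
    "was despondent after visiting his wife at the nursing home",
    "said he refused to be put in a home by his children",
    "was concerned that his long-term care insurance had lapsed",
    "her husband resides in a memory care facility across town",
    "was under strain paying for the nursing facility for her mother",
)

# Phrases that share surface vocabulary with the keyword seeds but describe
# deaths with no residential-care association; sprinkled into a fraction of
# negative narratives so keyword search has imperfect precision.
DISTRACTOR_PHRASES = (
    "lived in a group home for adults with disabilities years earlier",
    "had a history of long-term unemployment",
    "reported long-term use of prescription pain medication",
    "had a long-term dispute with a neighbor over the property line",
    "resided on a quiet residential street",
    "officers canvassed the residential neighborhood",
    "a long-term relationship had recently ended",
    "had been convalescing at home after a surgery",
    "completed residential treatment for alcohol abuse in his twenties",
    "described the long-term effects of the medication to his doctor",
    "worked the night shift at a rehab clinic many years ago",
    "was struggling with a long-term illness managed at home",
)

# Neutral clauses used to pad every narrative to its target length.  These
# must stay free of the default seed keywords.
FILLER_CLAUSES = (
    "The decedent was found unresponsive at the scene.",
    "A handwritten note was located near the decedent.",
    "He had a documented history of depression.",
    "The medical examiner ruled the death a suicide.",
    "Family reported a recent decline in health.",
    "No signs of foul play were observed.",
    "Toxicology results were pending at the time of the report.",
    "She had been treated for chronic pain for several years.",
    "The decedent had recently lost a spouse.",
    "A firearm was recovered at the scene.",
    "Police responded to a report of an unresponsive person.",
    "He had expressed feelings of hopelessness in recent weeks.",
    "The decedent lived alone.",
    "Neighbors reported nothing unusual in the preceding days.",
    "EMS pronounced the decedent at the scene.",
    "The decedent had recently been hospitalized.",
    "Family members were notified by the investigator.",
    "There was no known history of prior attempts.",
    "The decedent had stopped taking prescribed medication.",
    "A relative performed a welfare check at the residence.",
)

PHRASE_BANKS = {
    "in_ltc": FACILITY_PHRASES,
    "transitioning": TRANSITION_PHRASES,
    "otherwise_associated": OTHERWISE_PHRASES,
}
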