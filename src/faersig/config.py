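"""Editable vocabulary shared across the pipeline.

Everything here is a convention of spontaneous-report databases rather than
of any particular analysis: FAERS role codes, outcome codes and their
severity ranking, the default adverse-event term set, and the salt suffixes
stripped during drug-name normalization.
"""

from __future__ import annotations

# FAERS drug role codes -> canonical role names
ROLE_CODES = {
    "PS": "primary-suspect",
    "SS": "secondary-suspect",
    "C": "concomitant",
    "I": "interacting",
}
ROLE_NAMES = {v: k for k, v in ROLE_CODES.items()}

# FAERS outcome codes -> canonical outcome names
OUTCOME_CODES = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "congenital-anomaly",
    "RI": "required-intervention",
    "OT": "other-serious",
}
OUTCOME_NAMES = {v: k for k, v in OUTCOME_CODES.items()}

# Most-serious-first ordering used when a report must contribute a single
# outcome category to a baseline table.
OUTCOME_SEVERITY_ORDER = [
    "death",
    "life-threatening",
    "disability",
    "congenital-anomaly",
    "required-intervention",
    "hospitalization",
    "other-serious",
    "missing",
]

SEXES = ("female", "male", "unknown")

# Default MedDRA preferred-term set defining the event of interest.  A
# broader family (e.g. subcapsular variants) can be supplied per run.
DEFAULT_EVENT_TERMS = frozenset({"CATARACT"})

# Trailing salt/ester tokens stripped when normalizing drug names to an
# active-ingredient string.  The list is deliberately editable: brand-name
# consolidation maps differ between extractions.
SALT_SUFFIXES = frozenset({
    "CALCIUM",
    "SODIUM",
    "POTASSIUM",
    "MAGNESIUM",
    "HCL",
    "HYDROCHLORIDE",
    "HYDROBROMIDE",
    "MESYLATE",
    "BESYLATE",
    "MALEATE",
    "TARTRATE",
    "BITARTRATE",
    "CITRATE",
    "SULFATE",
    "SUCCINATE",
    "FUMARATE",
    "ACETATE",
    "PHOSPHATE",
    "DIHYDRATE",
    "MONOHYDRATE",
})

# Demographic plausibility bounds: values strictly above these are treated
# as data-entry errors; the boundary values themselves are retained.
MAX_PLAUSIBLE_AGE_YEARS = 120.0
MAX_PLAUSIBLE_WEIGHT_KG = 400.0
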