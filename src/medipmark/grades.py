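"""Cervical-neoplasia diagnosis grades and case/control dichotomization schemes.

Grades form a total order Normal < CIN1 < CIN2 < CIN3/CIS < SCC. Parsing is
case-insensitive; ``CIS`` and ``CIN3`` map onto the combined ``CIN3/CIS``
category.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError

GRADE_ORDER: tuple[str, ...] = ("Normal", "CIN1", "CIN2", "CIN3/CIS", "SCC")

_SYNONYMS = {
    "normal": "Normal",
    "cin1": "CIN1",
    "cin 1": "CIN1",
    "cin2": "CIN2",
    "cin 2": "CIN2",
    "cin3": "CIN3/CIS",
    "cin 3": "CIN3/CIS",
    "cin3/cis": "CIN3/CIS",
    "cis": "CIN3/CIS",
    "scc": "SCC",
}


def parse_grade(value: str) -> str:
    """Return the canonical grade label, or raise :class:`InputError`."""
    key = str(value).strip().lower()
    try:
        return _SYNONYMS[key]
    except KeyError:
        raise InputError(
            f"unparseable diagnosis grade {value!r}; expected one of {GRADE_ORDER}"
        ) from None


def grade_categorical(values) -> pd.Categorical:
    """Parse an iterable of grade labels into an ordered pandas Categorical."""
    parsed = [parse_grade(v) for v in values]
    return pd.Categorical(parsed, categories=list(GRADE_ORDER), ordered=True)


@dataclass(frozen=True)
class DichotomyScheme:
    """A case/control split of the grade spectrum.

    Cases must be the upper segment of the grade order and, together with
    controls, partition the five grades.
    """

    name: str
    case_grades: frozenset[str]
    control_grades: frozenset[str]

    def __post_init__(self) -> None:
        all_grades = set(GRADE_ORDER)
        if set(self.case_grades) | set(self.control_grades) != all_grades or (
            set(self.case_grades) & set(self.control_grades)
        ):
            raise InputError(
                f"scheme {self.name!r}: case and control grades must partition {GRADE_ORDER}"
            )
        # cases are an upper order segment
        k = len(self.case_grades)
        if set(GRADE_ORDER[-k:]) != set(self.case_grades):
            raise InputError(
                f"scheme {self.name!r}: case grades must be the upper segment of the grade order"
            )


def _scheme(name: str, n_cases: int) -> DichotomyScheme:
    return DichotomyScheme(
        name=name,
        case_grades=frozenset(GRADE_ORDER[-n_cases:]),
        control_grades=frozenset(GRADE_ORDER[:-n_cases]),
    )


CIN2_PLUS = _scheme("CIN2+/CIN1-", 3)
CIN3_PLUS = _scheme("CIN3+/CIN2-", 2)
SCC_ONLY = _scheme("SCC/SCC-", 1)

STANDARD_SCHEMES: tuple[DichotomyScheme, ...] = (CIN2_PLUS, CIN3_PLUS, SCC_ONLY)

SCHEMES_BY_NAME = {s.name: s for s in STANDARD_SCHEMES}
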