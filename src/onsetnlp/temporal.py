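"""Rule-based temporal expression extraction and normalisation.

Finds temporal expressions in clinical free text and assigns each a
normalised value anchored to the document date: absolute dates
(``since Nov 2015`` -> 2015-11), relative dates (``three years ago`` at
anchor 2020-08 -> 2017-08), ages (``at the age of 16`` -> AGE16Y) and
durations (``for the past six months`` -> 180 days).  The normalised
granularity follows the specificity of the surface form: a bare year
normalises to YEAR, a month-year to MONTH, a full date to DAY; relative
year/month offsets normalise to MONTH (the anchor day is not trusted).

The rule inventory is a declarative table of regular expressions with
per-category normalisers.  Overlapping matches are resolved
leftmost-longest.  Two-digit years are deliberately not resolved
(ambiguous in clinical text) and ages above a configurable cap are
rejected.  Fuzzy expressions ("a long time ago") yield nothing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from typing import List, Optional, Sequence

from dateutil.relativedelta import relativedelta

from .corpus import Granularity, NormValue

logger = logging.getLogger("onsetnlp")

ABSOLUTE_DATE = "ABSOLUTE_DATE"
RELATIVE_DATE = "RELATIVE_DATE"
AGE = "AGE"
DURATION = "DURATION"


@dataclass(frozen=True)
class TemporalExpression:
    span: tuple  # (start, end) 0-based half-open
    surface: str
    category: str
    value: Optional[NormValue] = None
    duration_days: Optional[int] = None


@dataclass(frozen=True)
class TaggerConfig:
    """Switches for the rule set.

    ``resolve_history``: normalise "N year history of" to a relative date
    (anchor minus N years); when off the pattern is emitted as a plain
    duration only.  ``max_age``: ages above this are rejected as
    implausible.
    """

    resolve_history: bool = True
    max_age: int = 120


_NUM_WORDS = {
    "a": 1, "an": 1, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "thirteen": 13, "fourteen": 14, "fifteen": 15,
    "sixteen": 16, "seventeen": 17, "eighteen": 18, "nineteen": 19,
    "twenty": 20, "thirty": 30, "forty": 40, "fifty": 50,
}
_NUM = r"(?:\d{1,3}|" + "|".join(w for w in _NUM_WORDS if w not in ("a", "an")) + r"|an?)"

_MONTHS = {
    "jan": 1, "january": 1, "feb": 2, "february": 2, "mar": 3, "march": 3,
    "apr": 4, "april": 4, "may": 5, "jun": 6, "june": 6, "jul": 7, "july": 7,
    "aug": 8, "august": 8, "sep": 9, "sept": 9, "september": 9,
    "oct": 10, "october": 10, "nov": 11, "november": 11,
    "dec": 12, "december": 12,
}
_MONTH = r"(?:" + "|".join(sorted(_MONTHS, key=len, reverse=True)) + r")"

_UNIT_DAYS = {"day": 1, "week": 7, "month": 30, "year": 365}


def _num(token: str) -> int:
    token = token.lower()
    return int(token) if token.isdigit() else _NUM_WORDS[token]


def _year_ok(y: int) -> bool:
    return 1900 <= y <= 2099


# Each rule: (category, compiled regex, normaliser name).  Normalisers map a
# regex match + anchor + config to (NormValue | None, duration_days | None)
# and may veto the match by raising ValueError.

def _norm_dmy(m, anchor, cfg):
    day, month, year = int(m["d"]), m["m"], int(m["y"])
    mnum = int(month) if month.isdigit() else _MONTHS[month.lower()]
    if not _year_ok(year):
        raise ValueError("year out of range")
    date(year, mnum, day)  # raises on an invalid day/month combination
    return NormValue.date(year, mnum, day), None


def _norm_iso(m, anchor, cfg):
    y, mo, d = int(m["y"]), int(m["m"]), int(m["d"])
    date(y, mo, d)  # raises on invalid
    if not _year_ok(y):
        raise ValueError("year out of range")
    return NormValue.date(y, mo, d), None


def _norm_month_year(m, anchor, cfg):
    year = int(m["y"])
    if not _year_ok(year):
        raise ValueError("year out of range")
    return NormValue.date(year, _MONTHS[m["m"].lower()]), None


def _norm_year(m, anchor, cfg):
    return NormValue.date(int(m["y"])), None


def _norm_ago(m, anchor, cfg):
    n, unit = _num(m["n"]), m["u"].lower()
    if unit == "year":
        then = anchor - relativedelta(years=n)
        return NormValue.date(then.year, then.month), None
    if unit == "month":
        then = anchor - relativedelta(months=n)
        return NormValue.date(then.year, then.month), None
    days = n * _UNIT_DAYS[unit]
    then = anchor - relativedelta(days=days)
    return NormValue.date(then.year, then.month, then.day), None


def _norm_age(m, anchor, cfg):
    n = _num(m["n"])
    if n > cfg.max_age:
        raise ValueError(f"age {n} above cap")
    return NormValue.age(n), None


def _norm_duration(m, anchor, cfg):
    n, unit = _num(m["n"]), m["u"].lower()
    return None, n * _UNIT_DAYS[unit]


def _norm_history(m, anchor, cfg):
    n, unit = _num(m["n"]), m["u"].lower()
    if not cfg.resolve_history:
        return None, n * _UNIT_DAYS[unit]
    then = anchor - relativedelta(**{unit + "s": n})
    return NormValue.date(then.year, then.month), None


_RULES = [
    # day month year, UK ordering: "12 March 2015", "3rd of Nov 2015"
    (ABSOLUTE_DATE,
     rf"\b(?P<d>\d{{1,2}})(?:st|nd|rd|th)?\s+(?:of\s+)?(?P<m>{_MONTH})\.?,?\s+(?P<y>\d{{4}})\b",
     _norm_dmy),
    # numeric day-first: 12/03/2015, 12.03.2015
    (ABSOLUTE_DATE,
     r"\b(?P<d>\d{1,2})[/.](?P<m>\d{1,2})[/.](?P<y>\d{4})\b",
     _norm_dmy),
    # ISO: 2015-03-12
    (ABSOLUTE_DATE,
     r"\b(?P<y>\d{4})-(?P<m>\d{2})-(?P<d>\d{2})\b",
     _norm_iso),
    # month year: "Nov 2015", "November, 2015"
    (ABSOLUTE_DATE,
     rf"\b(?P<m>{_MONTH})\.?,?\s+(?P<y>\d{{4}})\b",
     _norm_month_year),
    # bare year 1900-2099: "in 2012"
    (ABSOLUTE_DATE, r"\b(?P<y>19\d{2}|20\d{2})\b", _norm_year),
    # relative: "three years ago"
    (RELATIVE_DATE,
     rf"\b(?P<n>{_NUM})\s+(?P<u>year|month|week|day)s?\s+(?:ago|previously|earlier)\b",
     _norm_ago),
    # ages: "at the age of 16", "aged 16", "when he was 16", "since she was 19"
    (AGE, rf"\b(?:at\s+)?the\s+age\s+of\s+(?P<n>{_NUM})\b", _norm_age),
    (AGE, rf"\bat\s+age\s+(?P<n>{_NUM})\b", _norm_age),
    (AGE, rf"\baged\s+(?P<n>{_NUM})\b", _norm_age),
    (AGE,
     rf"\b(?:when|since)\s+(?:he|she|they)\s+(?:was|were)\s+(?:about\s+)?(?P<n>{_NUM})"
     r"(?:\s+years?\s+old)?\b",
     _norm_age),
    # durations: "for the past six months", "for 3 years"
    (DURATION,
     rf"\b(?:for|over|during)\s+the\s+(?:past|last)\s+(?P<n>{_NUM})\s+(?P<u>day|week|month|year)s?\b",
     _norm_duration),
    (DURATION,
     rf"\bfor\s+(?P<n>{_NUM})\s+(?P<u>day|week|month|year)s?\b",
     _norm_duration),
    # "3 year history of" — resolvable to anchor minus N (config switch)
    ("HISTORY",
     rf"\b(?P<n>{_NUM})[\s-](?P<u>month|year)s?\s+history\s+of\b",
     _norm_history),
]

_COMPILED = [(cat, re.compile(pat, re.IGNORECASE), fn) for cat, pat, fn in _RULES]

DEFAULT_CONFIG = TaggerConfig()


def tag(text: str, anchor: date, config: TaggerConfig = DEFAULT_CONFIG) -> List[TemporalExpression]:
    """Extract and normalise all temporal expressions from ``text``.

    ``anchor`` (the document date) resolves relative expressions.  Returns
    non-overlapping expressions sorted by start offset; overlap conflicts
    are resolved leftmost-longest.  Deterministic for identical inputs.
    """
    candidates = []
    for cat, rx, fn in _COMPILED:
        for m in rx.finditer(text):
            try:
                value, dur = fn(m, anchor, config)
            except (ValueError, KeyError) as exc:
                logger.debug("skipped candidate %r: %s", m.group(0), exc)
                continue
            if cat == "HISTORY":
                real_cat = RELATIVE_DATE if value is not None else DURATION
            else:
                real_cat = cat
            candidates.append(
                TemporalExpression(
                    span=(m.start(), m.end()),
                    surface=m.group(0),
                    category=real_cat,
                    value=value,
                    duration_days=dur,
                )
            )
    # leftmost-longest: prefer earlier start, then longer match
    candidates.sort(key=lambda e: (e.span[0], -(e.span[1] - e.span[0])))
    chosen: List[TemporalExpression] = []
    last_end = -1
    for expr in candidates:
        if expr.span[0] >= last_end:
            chosen.append(expr)
            last_end = expr.span[1]
    return chosen


def count_expressions(text: str, anchor: date, config: TaggerConfig = DEFAULT_CONFIG) -> int:
    return len(tag(text, anchor, config))


def earliest_date(expressions: Sequence[TemporalExpression]) -> Optional[NormValue]:
    """Earliest DATE value among the expressions, reduced to year granularity."""
    years = [e.value.year for e in expressions
             if e.value is not None and e.value.kind == "DATE"]
    return NormValue.date(min(years)) if years else None


def earliest_age(expressions: Sequence[TemporalExpression]) -> Optional[NormValue]:
    ages = [e.value.age_years for e in expressions
            if e.value is not None and e.value.kind == "AGE"]
    return NormValue.age(min(ages)) if ages else None


def longest_duration(expressions: Sequence[TemporalExpression]) -> Optional[int]:
    durations = [e.duration_days for e in expressions if e.duration_days is not None]
    return max(durations) if durations else None
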