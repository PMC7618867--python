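"""Bilingual-experience metrics and eligibility screening.

Language exposure arrives as weekly hours per language (aggregated from a
parental day-by-day interview, which itself is out of scope) and is reduced
to percentages. Two summary metrics follow:

* **degree of bilingualism** — exposure percentage of the less dominant
  language divided by that of the more dominant one; 1.0 is a balanced
  50/50 split, 0.25 a 20/80 split.
* **mixing score** — the sum of parent-report ratings (0 = Never ... 6 =
  Always per item, six items, 36-point maximum) of within-utterance
  language mixing and borrowing.

Eligibility screening for the bilingual group requires both main languages
within the 20-80 % exposure band (inclusive), no more than 5 % combined
exposure to third/fourth languages (strictly more than 5 % excludes), and
neither main language on a supplied exclusion list of languages containing
retroflex consonants (a static list derived from a phonological-inventory
database; querying such a database is not done here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, DataError

log = logging.getLogger(__name__)

MIXING_ITEMS = 6
MIXING_MAX = 36  # 6 items x 6 points


def exposure_percentages(hours_by_language: Mapping[str, float]) -> dict[str, float]:
    """Normalize per-language hours to percentages summing to 100."""
    if not hours_by_language:
        raise DataError("no exposure hours given")
    for lang, h in hours_by_language.items():
        if h < 0:
            raise DataError(f"negative exposure hours for {lang}")
    total = sum(hours_by_language.values())
    if total <= 0:
        raise DataError("all exposure hours are zero")
    return {lang: 100.0 * h / total for lang, h in hours_by_language.items()}


def degree_of_bilingualism(pct_mapping: Mapping[str, float]) -> float | None:
    """min/max ratio of the two main exposure percentages; None if monolingual."""
    pcts = sorted(pct_mapping.values(), reverse=True)
    pcts = [p for p in pcts if p > 0]
    if len(pcts) < 2:
        return None  # monolingual marker
    hi, lo = pcts[0], pcts[1]
    return lo / hi


def mixing_score(item_ratings: Sequence[float], n_items: int = MIXING_ITEMS) -> float:
    """Sum of mixing-scale item ratings.

    Fractional ratings (e.g. 4.5) are accepted; each item must lie in
    [0, 6] and the item count must match the scale (default six items,
    36-point maximum).
    """
    if len(item_ratings) != n_items:
        raise DataError(f"expected {n_items} mixing items, got {len(item_ratings)}")
    for r in item_ratings:
        if not 0 <= r <= 6:
            raise DataError(f"mixing rating {r} outside [0, 6]")
    return float(sum(item_ratings))


@dataclass(frozen=True)
class EligibilityBounds:
    min_main_pct: float = 20.0  # minimum exposure to the minority language
    max_main_pct: float = 80.0  # maximum exposure to the majority language
    max_other_pct: float = 5.0  # combined third/fourth language cap (strict >)


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reasons: tuple[str, ...] = ()


def check_eligibility(
    exposure_pct: Mapping[str, float],
    retroflex_languages: Iterable[str] = (),
    bounds: EligibilityBounds = EligibilityBounds(),
) -> EligibilityResult:
    """Screen a bilingual exposure profile for inclusion.

    Bilingual-eligible iff the two main languages both fall within the
    [min, max] exposure band (inclusive), neither is on the retroflex
    exclusion list, and remaining languages total at most ``max_other_pct``
    (strictly more excludes). An empty exclusion list skips that check with
    a warning.
    """
    retroflex = {l.strip().lower() for l in retroflex_languages}
    if not retroflex:
        log.warning("empty retroflex-language exclusion list; skipping that check")
    ranked = sorted(exposure_pct.items(), key=lambda kv: kv[1], reverse=True)
    reasons: list[str] = []
    if len(ranked) < 2:
        return EligibilityResult(False, ("monolingual",))
    (lang1, p1), (lang2, p2) = ranked[0], ranked[1]
    if not (bounds.min_main_pct <= p2 and p1 <= bounds.max_main_pct):
        reasons.append("exposure_bounds")
    other = sum(p for _, p in ranked[2:])
    if other > bounds.max_other_pct:
        reasons.append("third_language_exposure")
    if retroflex and any(l.lower() in retroflex for l in (lang1, lang2)):
        reasons.append("retroflex_language")
    return EligibilityResult(eligible=not reasons, reasons=tuple(reasons))


def read_retroflex_list(path) -> set[str]:
    """Read a newline-delimited retroflex-language exclusion list."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}
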