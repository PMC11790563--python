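"""Emotion-term vocabulary and the four situation types.

The rating instrument crosses valence (positive/negative) with interpersonal
motive (relationship-/autonomy-promoting), giving four situation types and four
matching three-term emotion subscales.  A handful of additional terms are used
only for screening: ``good``/``bad`` anchor the valence prompt check, and
``happy``/``angry`` break ties when both primary valence criteria are neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

from .exceptions import ValidationError

#: Fixed situation-type vocabulary: valence x interpersonal motive.
SITUATIONS: Tuple[str, ...] = ("pos_rel", "pos_auto", "neg_rel", "neg_auto")

#: Valence of each situation type ("positive" / "negative").
SITUATION_VALENCE: Mapping[str, str] = {
    "pos_rel": "positive",
    "pos_auto": "positive",
    "neg_rel": "negative",
    "neg_auto": "negative",
}

_DEFAULT_SUBSCALES: Mapping[str, Tuple[str, str, str]] = {
    "pos_rel": ("respectful", "close", "helpful"),
    "pos_auto": ("proud", "happy", "elated"),
    "neg_rel": ("guilty", "ashamed", "indebted"),
    "neg_auto": ("frustrated", "angry", "resentful"),
}

_DEFAULT_TERMS: Tuple[str, ...] = (
    "respectful", "close", "helpful",
    "proud", "happy", "elated",
    "guilty", "ashamed", "indebted",
    "frustrated", "angry", "resentful",
    "good", "bad",
    "calm", "worried", "nervous", "fearful", "sad", "surprised",
)

#: The 15 terms that survive the cross-cultural equivalence screen by default
#: (``frustrated``, ``calm`` and ``surprised`` dropped; ``good``/``bad`` are
#: valence-check-only and never active).
_DEFAULT_ACTIVE: Tuple[str, ...] = (
    "respectful", "close", "helpful",
    "proud", "happy", "elated",
    "guilty", "ashamed", "indebted",
    "angry", "resentful",
    "worried", "nervous", "fearful", "sad",
)


@dataclass(frozen=True)
class EmotionTermSet:
    """The rated emotion vocabulary, its subscale structure and active subset.

    Parameters
    ----------
    terms
        All rated term labels, in instrument order.
    subscales
        Mapping of the four emotion types (keyed by situation type) to their
        three constituent terms.
    check_terms
        Terms used only by the screening rules (valence anchors + tiebreak).
    active_terms
        Terms entering fit profiles; must exclude ``good`` and ``bad``.
    """

    terms: Tuple[str, ...] = _DEFAULT_TERMS
    subscales: Mapping[str, Tuple[str, str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_SUBSCALES)
    )
    check_terms: Tuple[str, ...] = ("good", "bad", "happy", "angry")
    active_terms: Tuple[str, ...] = _DEFAULT_ACTIVE

    def __post_init__(self) -> None:
        terms = set(self.terms)
        if len(terms) != len(self.terms):
            raise ValidationError("duplicate term labels")
        seen: set = set()
        for sit, sub in self.subscales.items():
            if sit not in SITUATIONS:
                raise ValidationError(f"unknown subscale key {sit!r}")
            overlap = seen & set(sub)
            if overlap:
                raise ValidationError(f"subscale terms not disjoint: {sorted(overlap)}")
            seen |= set(sub)
            missing = set(sub) - terms
            if missing:
                raise ValidationError(f"subscale term(s) not in terms: {sorted(missing)}")
        if not set(self.active_terms) <= terms:
            extra = sorted(set(self.active_terms) - terms)
            raise ValidationError(f"active term(s) not in terms: {extra}")
        if {"good", "bad"} & set(self.active_terms):
            raise ValidationError("'good'/'bad' are valence-check-only terms and "
                                  "cannot be active")
        missing_checks = set(self.check_terms) - terms
        if missing_checks:
            raise ValidationError(f"check term(s) not in terms: {sorted(missing_checks)}")

    def subscale_of(self, term: str) -> str | None:
        """Return the situation type whose subscale contains ``term``, if any."""
        for sit, sub in self.subscales.items():
            if term in sub:
                return sit
        return None


def default_term_set() -> EmotionTermSet:
    """The standard 20-term instrument with its 15-term active subset."""
    return EmotionTermSet()


def validate_situations(values: Sequence[str]) -> None:
    """Raise :class:`ValidationError` if any value is not a known situation type."""
    bad = sorted(set(values) - set(SITUATIONS))
    if bad:
        raise ValidationError(
            f"unknown situation type(s) {bad}; expected one of {list(SITUATIONS)}"
        )
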