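"""Data-screening rules applied before any fit is computed.

Two checks are implemented.  The *valence prompt check* decides, per reported
situation, whether the recalled event matches the valence the prompt asked for,
combining a consensus coder label with the participant's own ``good``/``bad``
ratings and, when both are neutral, a ``happy``/``angry`` tiebreak.  The
*manipulation check* verifies at the group level that the emotion subscale
matching each prompt is rated most intensely, using Bonferroni-corrected paired
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError
from .io import RatingDataset
from .terms import SITUATIONS, SITUATION_VALENCE, EmotionTermSet


@dataclass(frozen=True)
class PromptRecord:
    """One participant-situation entry of the valence prompt check."""

    participant: str
    situation: str
    coder_label: str                   # 'positive' | 'negative' | 'unclear'
    rating_good: int
    rating_bad: int
    rating_happy: int
    rating_angry: int
    culture: Optional[str] = None

    def __post_init__(self) -> None:
        if self.situation not in SITUATIONS:
            raise ValidationError(f"unknown situation {self.situation!r}")
        if self.coder_label not in ("positive", "negative", "unclear"):
            raise ValidationError(f"invalid coder label {self.coder_label!r}")
        for name in ("rating_good", "rating_bad", "rating_happy", "rating_angry"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 5):
                raise ValidationError(f"{name}={v!r} outside Likert range 1-5")

    @property
    def expected_valence(self) -> str:
        return SITUATION_VALENCE[self.situation]


@dataclass(frozen=True)
class ScreeningDecision:
    keep: bool
    basis: str       # 'coder' | 'rating' | 'tiebreak_happy_angry'
    reason: str


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def valence_check(record: PromptRecord) -> ScreeningDecision:
    """Decide keep/exclude for one situation report.

    Criterion A is the coder label against the prompted valence; criterion B is
    the sign of ``good - bad``.  Any contradiction excludes; otherwise a single
    match keeps; if both are neutral, the strict sign of ``happy - angry`` must
    match the prompted valence, with a tie excluding.
    """
    expected = +1 if record.expected_valence == "positive" else -1

    coder = {"positive": +1, "negative": -1, "unclear": 0}[record.coder_label]
    a = 0 if coder == 0 else (1 if coder == expected else -1)       # match/neutral/contra
    rating_sign = _sign(record.rating_good - record.rating_bad)
    b = 0 if rating_sign == 0 else (1 if rating_sign == expected else -1)

    if a == -1 or b == -1:
        basis = "coder" if a == -1 else "rating"
        return ScreeningDecision(False, basis,
                                 f"{basis} criterion contradicts prompted "
                                 f"{record.expected_valence} valence")
    if a == 1 or b == 1:
        basis = "coder" if a == 1 else "rating"
        return ScreeningDecision(True, basis,
                                 f"{basis} criterion matches prompted valence")
    tiebreak = _sign(record.rating_happy - record.rating_angry)
    if tiebreak == expected:
        return ScreeningDecision(True, "tiebreak_happy_angry",
                                 "happy/angry ordering matches prompted valence")
    reason = ("happy/angry tie" if tiebreak == 0
              else "happy/angry ordering contradicts prompted valence")
    return ScreeningDecision(False, "tiebreak_happy_angry", reason)


@dataclass
class ScreeningReport:
    """Outcome of screening a record collection."""

    decisions: pd.DataFrame      # participant, situation, culture, keep, basis, reason
    kept: List[PromptRecord]
    excluded: List[PromptRecord]

    @property
    def per_situation_counts(self) -> pd.DataFrame:
        return (self.decisions.groupby(["situation", "keep"])
                .size().unstack(fill_value=0))

    @property
    def keep_rate(self) -> float:
        return float(self.decisions["keep"].mean())


def screen_dataset(records: Iterable[PromptRecord]) -> ScreeningReport:
    """Apply :func:`valence_check` to every record, reporting each decision."""
    records = list(records)
    keys = [(r.participant, r.situation) for r in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(f"duplicate participant-situation record(s): {dupes[:3]}")
    rows, kept, excluded = [], [], []
    for r in records:
        decision = valence_check(r)
        (kept if decision.keep else excluded).append(r)
        rows.append({"participant": r.participant, "situation": r.situation,
                     "culture": r.culture, "keep": decision.keep,
                     "basis": decision.basis, "reason": decision.reason})
    decisions = pd.DataFrame(
        rows, columns=["participant", "situation", "culture", "keep", "basis", "reason"]
    )
    return ScreeningReport(decisions=decisions, kept=kept, excluded=excluded)


def prompt_records(dataset: RatingDataset,
                   coder_labels: pd.DataFrame | None = None) -> List[PromptRecord]:
    """Build prompt-check records from a ratings table plus coder labels.

    Rows without a coder label get ``'unclear'`` (a neutral criterion A).
    """
    labels: Dict[Tuple[str, str], str] = {}
    source = coder_labels if coder_labels is not None else dataset.coder_labels
    if source is not None:
        labels = {(row.participant, row.situation): row.coder_label
                  for row in source.itertuples()}
    out = []
    for row in dataset.table.itertuples():
        key = (row.participant_id, row.situation_type)
        out.append(PromptRecord(
            participant=row.participant_id, situation=row.situation_type,
            coder_label=labels.get(key, "unclear"),
            rating_good=int(getattr(row, "good")),
            rating_bad=int(getattr(row, "bad")),
            rating_happy=int(getattr(row, "happy")),
            rating_angry=int(getattr(row, "angry")),
            culture=row.culture,
        ))
    return out


def apply_screening(dataset: RatingDataset, report: ScreeningReport) -> RatingDataset:
    """Drop the excluded participant-situations from a ratings dataset."""
    drop = {(r.participant, r.situation) for r in report.excluded}
    keep_mask = [
        (row.participant_id, row.situation_type) not in drop
        for row in dataset.table.itertuples()
    ]
    return RatingDataset(table=dataset.table.loc[keep_mask].reset_index(drop=True),
                         terms=dataset.terms, coder_labels=dataset.coder_labels)


def manipulation_check(dataset: RatingDataset,
                       terms: EmotionTermSet | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per culture x situation: is the prompt-matching subscale rated highest?

    For every culture and situation type the four subscale means are computed
    over participants, and the matching subscale is compared with each of the
    other three by paired t tests (two-sided, Bonferroni x3).  ``maximal`` is
    True when the matching subscale's mean strictly exceeds every other and all
    corrected comparisons are significant at ``alpha``; False when some other
    subscale significantly exceeds the matching one; otherwise the check is
    indeterminate (pandas NA) — the data do not separate the subscales.
    """
    terms = terms or dataset.terms
    sub = dataset.subscale_means()
    rows = []
    for culture, group in sub.groupby("culture"):
        for situation in SITUATIONS:
            cell = group[group["situation"] == situation]
            if len(cell) < 2:
                raise InsufficientDataError(
                    f"manipulation_check: fewer than 2 participants for "
                    f"{culture}/{situation}"
                )
            means = {s: float(cell[s].mean()) for s in SITUATIONS}
            row: Dict[str, object] = {"culture": culture, "situation": situation,
                                      **{f"mean_{s}": means[s] for s in SITUATIONS}}
            all_signif_above = True
            any_signif_below = False
            for other in SITUATIONS:
                if other == situation:
                    continue
                diff = cell[situation].to_numpy() - cell[other].to_numpy()
                if np.all(diff == 0):
                    t, p = np.nan, np.nan
                else:
                    t, p = stats.ttest_rel(cell[situation], cell[other])
                p_bonf = float(min(1.0, 3.0 * p)) if np.isfinite(p) else np.nan
                row[f"t_vs_{other}"] = float(t)
                row[f"p_vs_{other}"] = float(p)
                row[f"p_bonf_vs_{other}"] = p_bonf
                signif = np.isfinite(p_bonf) and p_bonf < alpha
                if not (means[situation] > means[other] and signif):
                    all_signif_above = False
                if means[situation] < means[other] and signif:
                    any_signif_below = True
            row["maximal"] = (True if all_signif_above
                              else (False if any_signif_below else pd.NA))
            rows.append(row)
    return pd.DataFrame(rows)
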