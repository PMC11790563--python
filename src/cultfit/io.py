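"""Core data containers and file I/O.

Three external formats are handled here: the participant ratings table (CSV,
one row per participant x situation with integer Likert 1-5 intensities), the
per-participant-per-situation transcript directory (plain text files named
``<participant>__<situation>.txt``) and the long-format fit-score table (CSV).
Lexicon files are handled in :mod:`cultfit.lexicon`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ParameterError, ValidationError
from .terms import SITUATIONS, EmotionTermSet, default_term_set, validate_situations

ID_COLUMNS = ("participant_id", "culture", "situation_type")

FIT_COLUMNS = ("participant", "culture", "situation", "measure", "target_culture",
               "r", "z")


@dataclass
class RatingDataset:
    """Participants x situation types x emotion terms, Likert 1-5.

    ``table`` is a long-ish frame: one row per reported participant-situation,
    columns ``participant_id``, ``culture``, ``situation_type`` plus one column
    per term.  A situation a participant did not report is simply absent (no
    imputation anywhere downstream).  ``coder_labels`` optionally carries the
    consensus valence codes used by the prompt check.
    """

    table: pd.DataFrame
    terms: EmotionTermSet = field(default_factory=default_term_set)
    coder_labels: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"ratings table missing required column(s) {missing}")
        term_cols = [c for c in self.table.columns if c not in ID_COLUMNS]
        unknown = sorted(set(term_cols) - set(self.terms.terms))
        if unknown:
            raise FormatError(f"ratings table has non-term column(s) {unknown}")
        absent = sorted(set(self.terms.terms) - set(term_cols))
        if absent:
            raise FormatError(f"ratings table missing term column(s) {absent}")
        validate_situations(self.table["situation_type"].unique())
        dup = self.table.duplicated(subset=["participant_id", "situation_type"])
        if dup.any():
            first = self.table.loc[dup, ["participant_id", "situation_type"]].iloc[0]
            raise ValidationError(
                f"participant {first['participant_id']!r} has more than one record "
                f"for situation {first['situation_type']!r}"
            )
        for col in self.terms.terms:
            values = self.table[col]
            as_float = pd.to_numeric(values, errors="coerce")
            bad = as_float.isna() | (as_float != as_float.round()) | \
                (as_float < 1) | (as_float > 5)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"rating out of range or non-integer at row {row}, column "
                    f"{col!r}: {values.iloc[row]!r} (expected integer 1-5)"
                )
        # normalise dtype so round-trips are exact
        self.table = self.table.copy()
        self.table[list(self.terms.terms)] = (
            self.table[list(self.terms.terms)].astype(np.int64)
        )

    @property
    def participants(self) -> pd.DataFrame:
        """Unique (participant_id, culture) pairs."""
        return (self.table[["participant_id", "culture"]]
                .drop_duplicates().reset_index(drop=True))

    @property
    def cultures(self) -> Tuple[str, ...]:
        return tuple(sorted(self.table["culture"].unique()))

    def profiles(self, terms: Sequence[str] | None = None) -> pd.DataFrame:
        """Long profile frame: participant, culture, situation + term columns."""
        cols = list(terms) if terms is not None else list(self.terms.active_terms)
        missing = sorted(set(cols) - set(self.table.columns))
        if missing:
            raise ValidationError(f"unknown term(s) {missing}")
        out = self.table[[*ID_COLUMNS, *cols]].copy()
        return out.rename(columns={"participant_id": "participant",
                                   "situation_type": "situation"})

    def subscale_means(self) -> pd.DataFrame:
        """Per participant-situation mean of each three-term subscale."""
        rows = self.table[list(ID_COLUMNS)].copy()
        for sit, sub in self.terms.subscales.items():
            rows[sit] = self.table[list(sub)].mean(axis=1).to_numpy()
        return rows.rename(columns={"participant_id": "participant",
                                    "situation_type": "situation"})


def read_ratings(path: str | Path, terms: EmotionTermSet | None = None) -> RatingDataset:
    """Read and validate a ratings CSV (see :class:`RatingDataset`)."""
    table = pd.read_csv(path, dtype={"participant_id": str, "culture": str,
                                     "situation_type": str})
    return RatingDataset(table=table, terms=terms or default_term_set())


def write_ratings(dataset: RatingDataset, path: str | Path) -> None:
    dataset.table.to_csv(path, index=False)


def read_coder_labels(path: str | Path) -> pd.DataFrame:
    """Read the consensus coder-label CSV (participant, situation, coder_label)."""
    df = pd.read_csv(path, dtype=str)
    required = {"participant", "situation", "coder_label"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise FormatError(f"coder table missing column(s) {missing}")
    validate_situations(df["situation"].unique())
    bad = ~df["coder_label"].isin(["positive", "negative", "unclear"])
    if bad.any():
        raise ValidationError(
            f"invalid coder_label {df.loc[bad, 'coder_label'].iloc[0]!r} "
            f"(row {int(np.flatnonzero(bad.to_numpy())[0])})"
        )
    return df


@dataclass
class TranscriptCorpus:
    """Plain-text documents keyed by (participant, situation type)."""

    documents: Dict[Tuple[str, str], str]
    language: Optional[str] = None

    def __post_init__(self) -> None:
        validate_situations([sit for _, sit in self.documents])
        for key, text in self.documents.items():
            if not isinstance(text, str) or not text.strip():
                raise ValidationError(f"empty transcript for {key}")

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def participants(self) -> Tuple[str, ...]:
        return tuple(sorted({pid for pid, _ in self.documents}))


_TRANSCRIPT_NAME = re.compile(
    r"^(?P<pid>.+)__(?P<sit>" + "|".join(SITUATIONS) + r")\.txt$"
)


def read_transcripts(directory: str | Path, language: str | None = None) -> TranscriptCorpus:
    """Load a transcript directory (``<participant>__<situation>.txt`` files)."""
    directory = Path(directory)
    documents: Dict[Tuple[str, str], str] = {}
    for path in sorted(directory.glob("*.txt")):
        m = _TRANSCRIPT_NAME.match(path.name)
        if not m or "__" in m.group("pid"):
            # allow participant ids without the separator only
            m = None
        if m is None:
            raise FormatError(
                f"transcript filename {path.name!r} does not match "
                f"'<participant>__<situation>.txt'"
            )
        pid, sit = m.group("pid"), m.group("sit")
        if sit not in SITUATIONS:
            raise FormatError(f"transcript {path.name!r}: unknown situation {sit!r}")
        key = (pid, sit)
        if key in documents:
            raise ValidationError(f"duplicate transcript for {key}")
        documents[key] = path.read_text(encoding="utf-8")
    return TranscriptCorpus(documents=documents, language=language)


def write_transcripts(corpus: TranscriptCorpus, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (pid, sit), text in corpus.documents.items():
        (directory / f"{pid}__{sit}.txt").write_text(text, encoding="utf-8")


def write_fit_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format fit table, floats at 12 significant digits."""
    missing = [c for c in FIT_COLUMNS if c not in scores.columns]
    if missing:
        raise FormatError(f"fit table missing column(s) {missing}")
    scores[list(FIT_COLUMNS)].to_csv(path, index=False, float_format="%.12g")


def read_fit_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant": str, "culture": str,
                                  "situation": str, "measure": str,
                                  "target_culture": str})
    missing = [c for c in FIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fit table missing column(s) {missing}")
    validate_situations(df["situation"].unique())
    return df


@dataclass
class RunConfig:
    """Run configuration mirrored by the YAML config file."""

    ratings_path: Optional[str] = None
    transcripts_dir: Optional[str] = None
    lexicon_path: Optional[str] = None
    coders_path: Optional[str] = None
    category_subset: str = "all"
    apply_valence_screen: bool = True
    clip_epsilon: float = 1e-6
    alpha: float = 0.05
    loading_threshold: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.clip_epsilon <= 0.01):
            raise ParameterError("clip_epsilon must lie in (0, 0.01]")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.category_subset not in ("all", "psychological_processes", "psych"):
            raise ParameterError(f"unknown category_subset {self.category_subset!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False),
                              encoding="utf-8")
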