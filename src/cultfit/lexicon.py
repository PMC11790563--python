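"""Dictionary-based word-category counting (LIWC2007 ``.dic`` dialect).

A lexicon maps lowercase words — literal entries and wildcard stems such as
``happ*`` — to one or more numeric category ids.  Documents are scored as the
percentage of tokens that belong to each category; a token increments a given
category at most once even when several entries fire on it.  Coverage is the
percentage of tokens matched by at least one entry.

File dialect
------------
A header block delimited by lines containing only ``%`` declares the
categories, one per line as ``id<TAB>name`` (an optional third field gives a
parent category id, used to express sub-category trees).  Entry lines follow as
``word<TAB>id [id ...]``; a trailing ``*`` on the word marks a prefix stem.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FormatError, InsufficientDataError, ParameterError, ValidationError

_TOKEN_RE = re.compile(r"[^\W_]+(?:'[^\W_]+)*", re.UNICODE)


def tokenize(text: str) -> List[str]:
    """Split text into lowercase word tokens.

    A token is a maximal run of letters/digits, possibly containing internal
    apostrophes (``don't`` is one token); everything else separates tokens.
    The length of the returned list is the denominator of all category scores.
    """
    return _TOKEN_RE.findall(text.replace("’", "'").lower())


@dataclass(frozen=True)
class Category:
    id: int
    name: str
    parent: Optional[int] = None


@dataclass(frozen=True)
class LexiconEntry:
    surface: str          # lowercase, wildcard stems stored without the '*'
    wildcard: bool
    category_ids: FrozenSet[int]

    def __post_init__(self) -> None:
        if self.wildcard and not self.surface:
            raise ValidationError("wildcard entry with empty prefix")
        if not self.surface:
            raise ValidationError("empty entry surface")

    def matches(self, token: str) -> bool:
        if self.wildcard:
            return token.startswith(self.surface)
        return token == self.surface


@dataclass
class Lexicon:
    """A word-category dictionary: category table plus entry list."""

    categories: Dict[int, Category]
    entries: List[LexiconEntry]
    _matcher: "_Matcher | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        declared = set(self.categories)
        for cat in self.categories.values():
            if cat.parent is not None and cat.parent not in declared:
                raise FormatError(
                    f"category {cat.id} ({cat.name}) references undeclared parent "
                    f"{cat.parent}"
                )
        for entry in self.entries:
            undeclared = entry.category_ids - declared
            if undeclared:
                raise FormatError(
                    f"entry {entry.surface!r} references undeclared category "
                    f"id(s) {sorted(undeclared)}"
                )

    @property
    def category_ids(self) -> List[int]:
        return sorted(self.categories)

    def name_of(self, cid: int) -> str:
        return self.categories[cid].name

    def id_of(self, name: str) -> int:
        for cid, cat in self.categories.items():
            if cat.name == name:
                return cid
        raise ValidationError(f"no category named {name!r}")

    def subtree(self, root: int | str) -> List[int]:
        """Ids of ``root`` and all its descendants (depth-first, sorted)."""
        root_id = root if isinstance(root, int) else self.id_of(root)
        if root_id not in self.categories:
            raise ValidationError(f"no category with id {root_id}")
        children: Dict[int, List[int]] = {}
        for cat in self.categories.values():
            if cat.parent is not None:
                children.setdefault(cat.parent, []).append(cat.id)
        out, stack = [], [root_id]
        while stack:
            cid = stack.pop()
            out.append(cid)
            stack.extend(children.get(cid, []))
        return sorted(out)

    def matcher(self) -> "_Matcher":
        if self._matcher is None:
            self._matcher = _Matcher(self.entries)
        return self._matcher


class _Matcher:
    """Token -> category-id lookup with literal dict + length-bucketed stems.

    Wildcard prefixes are grouped by length so matching a token costs one dict
    probe per distinct stem length instead of a scan over all stems.  Results
    are memoised per surface form, which makes repeated counting over a shared
    vocabulary (the common case for interview corpora) close to dict-speed.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._literal: Dict[str, FrozenSet[int]] = {}
        by_len: Dict[int, Dict[str, set]] = {}
        for e in entries:
            if e.wildcard:
                bucket = by_len.setdefault(len(e.surface), {})
                bucket.setdefault(e.surface, set()).update(e.category_ids)
            else:
                prev = self._literal.get(e.surface, frozenset())
                self._literal[e.surface] = prev | e.category_ids
        self._stem_lengths: List[int] = sorted(by_len)
        self._stems: Dict[int, Dict[str, FrozenSet[int]]] = {
            ln: {s: frozenset(ids) for s, ids in bucket.items()}
            for ln, bucket in by_len.items()
        }
        self._cache: Dict[str, FrozenSet[int]] = {}

    def match(self, token: str) -> FrozenSet[int]:
        hit = self._cache.get(token)
        if hit is not None:
            return hit
        ids: set = set(self._literal.get(token, ()))
        tlen = len(token)
        for ln in self._stem_lengths:
            if ln > tlen:
                break
            got = self._stems[ln].get(token[:ln])
            if got:
                ids |= got
        out = frozenset(ids)
        self._cache[token] = out
        return out


def read_lexicon(path: str | Path) -> Lexicon:
    """Parse a ``.dic``-dialect lexicon file."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    # locate the %-delimited header block
    marks = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(marks) < 2:
        raise FormatError(f"{path}: missing %%-delimited category header block")
    header = lines[marks[0] + 1 : marks[1]]
    body = lines[marks[1] + 1 :]
    categories: Dict[int, Category] = {}
    for i, raw in enumerate(header):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) not in (2, 3):
            raise FormatError(f"{path}: malformed header line {marks[0] + 2 + i}: {raw!r}")
        try:
            cid = int(parts[0])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer category id on header line "
                              f"{marks[0] + 2 + i}: {parts[0]!r}") from exc
        parent = None
        if len(parts) == 3 and parts[2].strip():
            parent = int(parts[2])
        if cid in categories:
            raise FormatError(f"{path}: duplicate category id {cid}")
        categories[cid] = Category(cid, parts[1].strip(), parent)
    if not categories:
        raise FormatError(f"{path}: empty category header block")

    merged: Dict[Tuple[str, bool], set] = {}
    for j, raw in enumerate(body):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        word = parts[0].strip().lower()
        ids_text = " ".join(parts[1:]).split()
        if not word or not ids_text:
            raise FormatError(f"{path}: malformed entry line {marks[1] + 2 + j}: {raw!r}")
        wildcard = word.endswith("*")
        surface = word[:-1] if wildcard else word
        try:
            ids = {int(tok) for tok in ids_text}
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer category id on entry line "
                              f"{marks[1] + 2 + j}: {raw!r}") from exc
        merged.setdefault((surface, wildcard), set()).update(ids)

    entries = [
        LexiconEntry(surface, wildcard, frozenset(ids))
        for (surface, wildcard), ids in merged.items()
    ]
    entries.sort(key=lambda e: (e.surface, e.wildcard))
    return Lexicon(categories=categories, entries=entries)


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    """Serialise a lexicon back to the ``.dic`` dialect."""
    out = ["%"]
    for cid in sorted(lexicon.categories):
        cat = lexicon.categories[cid]
        if cat.parent is None:
            out.append(f"{cid}\t{cat.name}")
        else:
            out.append(f"{cid}\t{cat.name}\t{cat.parent}")
    out.append("%")
    for e in sorted(lexicon.entries, key=lambda e: (e.surface, e.wildcard)):
        word = e.surface + ("*" if e.wildcard else "")
        out.append(word + "\t" + " ".join(str(i) for i in sorted(e.category_ids)))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


@dataclass
class CategoryProfile:
    """Per-document category scores (percent of tokens) and coverage.

    ``scores`` is ``None`` for an empty document: a document with no tokens has
    an undefined profile, which must not masquerade as "0% on everything".
    """

    key: Tuple[str, str]
    word_count: int
    scores: Optional[Dict[int, float]]
    coverage: Optional[float]

    @property
    def missing(self) -> bool:
        return self.scores is None


def count_categories(tokens: Sequence[str], lexicon: Lexicon) -> CategoryProfile:
    """Score one tokenised document against every lexicon category.

    Each token contributes to a category if any literal or prefix-stem entry of
    that category matches it; multiple matching entries of the same category
    still count the token once.  Scores are ``100 * matched / word_count``.
    """
    n = len(tokens)
    if n == 0:
        return CategoryProfile(key=("", ""), word_count=0, scores=None, coverage=None)
    matcher = lexicon.matcher()
    counts: Dict[int, int] = dict.fromkeys(lexicon.categories, 0)
    matched = 0
    for token, mult in Counter(tokens).items():
        ids = matcher.match(token)
        if ids:
            matched += mult
            for cid in ids:
                counts[cid] += mult
    scores = {cid: 100.0 * c / n for cid, c in counts.items()}
    return CategoryProfile(key=("", ""), word_count=n,
                           scores=scores, coverage=100.0 * matched / n)


def select_categories(lexicon: Lexicon, subset: str | Sequence[int],
                      psych_root: str = "psychproc") -> List[int]:
    """Resolve a category-subset selector to sorted category ids.

    ``"all"`` keeps every category; ``"psychological_processes"`` keeps the
    subtree rooted at the category named ``psych_root``; an explicit id list is
    validated against the declared categories.
    """
    if isinstance(subset, str):
        if subset == "all":
            return lexicon.category_ids
        if subset in ("psychological_processes", "psych"):
            return lexicon.subtree(psych_root)
        raise ValidationError(f"unknown category subset {subset!r}")
    ids = sorted(set(int(i) for i in subset))
    undeclared = set(ids) - set(lexicon.categories)
    if undeclared:
        raise ValidationError(f"subset names absent categories: {sorted(undeclared)}")
    if not ids:
        raise ValidationError("empty category subset")
    return ids


def corpus_profiles(corpus, lexicon: Lexicon,
                    subset: str | Sequence[int] = "all",
                    psych_root: str = "psychproc") -> pd.DataFrame:
    """Score every document of a corpus; one row per (participant, situation).

    Returns a DataFrame with ``participant``, ``situation``, ``word_count``,
    ``coverage`` and one column per selected category (named by category name).
    Scores always use the document's full token count as denominator; the
    subset only restricts which score columns are reported.
    """
    ids = select_categories(lexicon, subset, psych_root)
    names = [lexicon.name_of(cid) for cid in ids]
    if len(set(names)) != len(names):
        names = [f"{lexicon.name_of(cid)}_{cid}" for cid in ids]
    rows = []
    for (pid, situation) in sorted(corpus.documents):
        text = corpus.documents[(pid, situation)]
        profile = count_categories(tokenize(text), lexicon)
        row: Dict[str, object] = {"participant": pid, "situation": situation,
                                  "word_count": profile.word_count,
                                  "coverage": profile.coverage
                                  if profile.coverage is not None else np.nan}
        if profile.missing:
            row.update({name: np.nan for name in names})
        else:
            row.update({name: profile.scores[cid] for name, cid in zip(names, ids)})
        rows.append(row)
    return pd.DataFrame(rows, columns=["participant", "situation", "word_count",
                                       "coverage", *names])


@dataclass(frozen=True)
class CoverageComparison:
    mean_a: float
    mean_b: float
    t: float
    df: int
    p: float
    degenerate: bool = False


def coverage_compare(coverage_a: Sequence[float],
                     coverage_b: Sequence[float]) -> CoverageComparison:
    """Pooled-variance two-sample t comparison of dictionary coverage."""
    a = np.asarray(coverage_a, dtype=float)
    b = np.asarray(coverage_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("coverage_compare needs >= 2 documents per group")
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return CoverageComparison(float(np.mean(a)), float(np.mean(b)),
                                      0.0, df, np.nan, degenerate=True)
        return CoverageComparison(float(np.mean(a)), float(np.mean(b)),
                                  np.nan, df, np.nan, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=True)
    return CoverageComparison(float(np.mean(a)), float(np.mean(b)),
                              float(res.statistic), df, float(res.pvalue))
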