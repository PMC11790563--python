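"""Profile-correlation fit: the package's central statistic.

A participant's *profile* for a situation is their vector of emotion-intensity
ratings over the active terms (emotional fit) or of word-category percentages
(language fit).  Fit toward a culture is the Pearson correlation between the
participant's profile and that culture's average profile for the same
situation type, Fisher-transformed (arctanh) for averaging and testing.  When
a participant is scored against their *own* culture, their profile is left out
of the reference average, otherwise the shared component would inflate
own-culture fit.

The model/results pair follows the statsmodels convention:
``ProfileFitModel(profiles, ...).fit()`` returns a :class:`FitResults` holding
the long fit table, with comparison, composite and summary methods hanging off
the results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, ParameterError, ValidationError
from .io import FIT_COLUMNS, RatingDataset
from .terms import SITUATIONS

DEFAULT_EPS = 1e-6


def fisher_z(r, eps: float = DEFAULT_EPS):
    """Fisher transformation z = arctanh(r), with |r| clipped to 1 - eps.

    Accepts scalars or arrays; NaN passes through (missing stays missing).
    Raises on |r| > 1, which can only arise from a computation error upstream.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(arr) > 1 + 1e-12):
            raise ParameterError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -(1 - eps), 1 - eps))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def reference_profile(members: pd.DataFrame | np.ndarray,
                      exclude: Optional[str] = None) -> pd.Series | np.ndarray:
    """Element-wise mean profile of a group, optionally leaving one member out.

    ``members`` has one row per participant (index = participant id when a
    DataFrame).  With ``exclude`` set, that member's row is omitted; excluding
    may not leave fewer than two members.
    """
    if isinstance(members, pd.DataFrame):
        if exclude is not None:
            if exclude in members.index:
                members = members.drop(index=exclude)
            if len(members) < 2:
                raise InsufficientDataError(
                    "reference profile needs >= 2 members after exclusion"
                )
        elif len(members) < 2:
            raise InsufficientDataError("reference profile needs >= 2 members")
        return members.mean(axis=0)
    arr = np.asarray(members, dtype=float)
    if exclude is not None:
        raise ParameterError("exclusion by id requires a DataFrame with an id index")
    if len(arr) < 2:
        raise InsufficientDataError("reference profile needs >= 2 members")
    return arr.mean(axis=0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def profile_fit(profile: Sequence[float], reference: Sequence[float],
                eps: float = DEFAULT_EPS) -> Tuple[float, float]:
    """Correlate one profile with a reference profile; return ``(r, z)``.

    A zero-variance vector (e.g. a participant who rated every term
    identically) has no defined correlation: the result is ``(nan, nan)`` with
    a warning, never a silent 0.
    """
    x = np.asarray(profile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape:
        raise ParameterError(f"profile length {x.shape} != reference {y.shape}")
    r = _pearson(x, y)
    if np.isnan(r):
        warnings.warn("zero-variance profile: fit is undefined (missing)",
                      stacklevel=2)
        return np.nan, np.nan
    return r, fisher_z(r, eps)


class ProfileFitModel:
    """Compute all four fit directions from a long profile table.

    Parameters
    ----------
    profiles
        Frame with columns ``participant``, ``culture``, ``situation`` plus the
        feature columns; one row per participant-situation.
    measure
        Label recorded in the output (``"emotion"`` or ``"language"``).
    feature_columns
        The profile vector, in order.  Defaults to every non-id column.
    eps
        Clipping margin for the Fisher transformation.
    min_group
        Minimum group size per situation for a usable reference (leave-one-out
        still leaves ``min_group - 1 >= 2`` members).  Cells below this yield
        missing scores with a warning rather than an error.
    """

    ID_COLS = ("participant", "culture", "situation")

    def __init__(self, profiles: pd.DataFrame, measure: str = "emotion",
                 feature_columns: Sequence[str] | None = None,
                 eps: float = DEFAULT_EPS, min_group: int = 3):
        missing = [c for c in self.ID_COLS if c not in profiles.columns]
        if missing:
            raise ValidationError(f"profile table missing column(s) {missing}")
        if feature_columns is None:
            feature_columns = [c for c in profiles.columns if c not in self.ID_COLS]
        if len(feature_columns) < 3:
            raise ParameterError("profiles need at least 3 features to correlate")
        if not (0 < eps <= 0.01):
            raise ParameterError("eps must lie in (0, 0.01]")
        if min_group < 3:
            raise ParameterError("min_group must be >= 3 (leave-one-out needs 2 left)")
        dup = profiles.duplicated(subset=["participant", "situation"])
        if dup.any():
            raise ValidationError("duplicate participant-situation profile rows")
        self.profiles = profiles.reset_index(drop=True)
        self.measure = measure
        self.feature_columns = list(feature_columns)
        self.eps = eps
        self.min_group = min_group
        self.cultures = tuple(sorted(profiles["culture"].unique()))

    @classmethod
    def from_ratings(cls, dataset: RatingDataset,
                     terms: Sequence[str] | None = None,
                     eps: float = DEFAULT_EPS, min_group: int = 3,
                     ) -> "ProfileFitModel":
        """Emotional-fit model over the active emotion terms."""
        cols = list(terms) if terms is not None else list(dataset.terms.active_terms)
        return cls(dataset.profiles(cols), measure="emotion",
                   feature_columns=cols, eps=eps, min_group=min_group)

    @classmethod
    def from_category_profiles(cls, profiles: pd.DataFrame,
                               cultures: Mapping[str, str] | None = None,
                               feature_columns: Sequence[str] | None = None,
                               eps: float = DEFAULT_EPS, min_group: int = 3,
                               ) -> "ProfileFitModel":
        """Language-fit model over word-category score columns.

        ``profiles`` is the output of :func:`cultfit.lexicon.corpus_profiles`;
        a ``culture`` column may be supplied directly or via the
        ``cultures`` participant->culture mapping.  Documents with missing
        (empty-document) profiles are dropped: they cannot be correlated.
        """
        frame = profiles.copy()
        if "culture" not in frame.columns:
            if cultures is None:
                raise ParameterError("provide a culture column or mapping")
            frame["culture"] = frame["participant"].map(dict(cultures))
            if frame["culture"].isna().any():
                orphan = frame.loc[frame["culture"].isna(), "participant"].iloc[0]
                raise ValidationError(f"no culture for participant {orphan!r}")
        if feature_columns is None:
            feature_columns = [c for c in frame.columns
                               if c not in (*cls.ID_COLS, "word_count", "coverage")]
        keep = ~frame[list(feature_columns)].isna().any(axis=1)
        return cls(frame.loc[keep], measure="language",
                   feature_columns=feature_columns, eps=eps, min_group=min_group)

    def fit(self) -> "FitResults":
        """Compute fit scores for every participant x situation x target culture.

        References are built per situation type from the target culture's
        member profiles; leave-one-out applies exactly when the scored
        participant belongs to the target culture.  Situation cells where the
        target culture has fewer than ``min_group`` members produce missing
        scores (with a warning), as do zero-variance profiles or references.
        """
        feats = self.feature_columns
        rows: List[dict] = []
        n_zero_variance = 0
        small_cells: List[Tuple[str, str]] = []
        for situation, cell in self.profiles.groupby("situation", sort=True):
            mats = {c: sub for c, sub in cell.groupby("culture")}
            for target in self.cultures:
                members = mats.get(target)
                ok = members is not None and len(members) >= self.min_group
                if not ok:
                    small_cells.append((situation, target))
                if ok:
                    M = members[feats].to_numpy(dtype=float)
                    total = M.sum(axis=0)
                    m = len(M)
                    id_to_row = {pid: i
                                 for i, pid in enumerate(members["participant"])}
                for sub in mats.values():
                    X = sub[feats].to_numpy(dtype=float)
                    pids = sub["participant"].to_numpy()
                    for i, pid in enumerate(pids):
                        if not ok:
                            r = z = np.nan
                        else:
                            j = id_to_row.get(pid)
                            if j is None:
                                ref = total / m
                            else:
                                ref = (total - M[j]) / (m - 1)
                            r = _pearson(X[i], ref)
                            if np.isnan(r):
                                n_zero_variance += 1
                                z = np.nan
                            else:
                                z = fisher_z(r, self.eps)
                        rows.append({"participant": pid,
                                     "culture": sub["culture"].iloc[0],
                                     "situation": situation, "measure": self.measure,
                                     "target_culture": target,
                                     "r": r, "z": z})
        if small_cells:
            warnings.warn(
                f"situation cells with < {self.min_group} members produce missing "
                f"scores: {small_cells}", stacklevel=2)
        if n_zero_variance:
            warnings.warn(
                f"{n_zero_variance} zero-variance profile(s): fit undefined, "
                f"left missing", stacklevel=2)
        table = pd.DataFrame(rows, columns=list(FIT_COLUMNS))
        table = table.sort_values(["situation", "target_culture", "culture",
                                   "participant"]).reset_index(drop=True)
        return FitResults(model=self, table=table)


@dataclass
class FitResults:
    """Fit table plus the comparison/composite methods that consume it."""

    model: ProfileFitModel
    table: pd.DataFrame

    def scores(self, culture: str | None = None, target: str | None = None,
               situation: str | None = None) -> pd.DataFrame:
        out = self.table
        if culture is not None:
            out = out[out["culture"] == culture]
        if target is not None:
            out = out[out["target_culture"] == target]
        if situation is not None:
            out = out[out["situation"] == situation]
        return out

    def z_matrix(self, culture: str, target: str) -> pd.DataFrame:
        """Participants x situations matrix of z for one culture-target pair."""
        sub = self.scores(culture=culture, target=target)
        return sub.pivot(index="participant", columns="situation", values="z")

    def composite(self, culture: str, target: str,
                  min_situations: int = 2) -> "CompositeFit":
        """Mean z across situation types, with its reliability (Cronbach alpha).

        Situation-level fit is the primary quantity; composites are averages of
        the available situation scores (participants with fewer than
        ``min_situations`` scores get a missing composite) and are shipped with
        the alpha of the situation columns so poor-reliability composites can
        be rejected.
        """
        from .inference import cronbach_alpha
        mat = self.z_matrix(culture, target)
        n_avail = mat.notna().sum(axis=1)
        composite = mat.mean(axis=1, skipna=True)
        composite[n_avail < min_situations] = np.nan
        frame = pd.DataFrame({
            "participant": mat.index,
            "culture": culture,
            "target_culture": target,
            "composite_z": composite.to_numpy(),
            "n_situations": n_avail.to_numpy(),
            "incomplete": (n_avail < mat.shape[1]).to_numpy(),
        }).reset_index(drop=True)
        try:
            alpha = cronbach_alpha(mat)
        except InsufficientDataError:
            alpha = np.nan
        return CompositeFit(table=frame, alpha=alpha,
                            measure=self.model.measure)

    def within_compare(self, culture: str, situation: str):
        from .inference import fit_within_compare
        return fit_within_compare(self.table, culture, situation)

    def between_compare(self, target: str, situation: str):
        from .inference import fit_between_compare
        return fit_between_compare(self.table, target, situation)

    def summary(self) -> str:
        """Mean (SD) of z per situation x culture x target, plus paired tests."""
        lines = [f"Profile-correlation fit ({self.model.measure}), "
                 f"{len(self.model.feature_columns)} features",
                 f"cultures: {', '.join(self.model.cultures)}", ""]
        desc = (self.table.groupby(["situation", "culture", "target_culture"])["z"]
                .agg(["mean", "std", "count"]).round(3))
        lines.append(desc.to_string())
        lines.append("")
        lines.append("Within-culture paired comparisons (fit-to-own vs fit-to-other):")
        for situation in sorted(self.table["situation"].unique()):
            for culture in self.model.cultures:
                try:
                    res = self.within_compare(culture, situation)
                except (InsufficientDataError, ValidationError):
                    continue
                stars = ("***" if res.p < 0.001 else "**" if res.p < 0.01
                         else "*" if res.p < 0.05 else "")
                lines.append(
                    f"  {situation:9s} {culture:10s} "
                    f"diff={res.estimate:+.3f}  t({res.df})={res.t:.2f}{stars}"
                )
        return "\n".join(lines)


@dataclass
class CompositeFit:
    table: pd.DataFrame
    alpha: float
    measure: str


def compute_fit_scores(profiles: pd.DataFrame, measure: str = "emotion",
                       feature_columns: Sequence[str] | None = None,
                       eps: float = DEFAULT_EPS, min_group: int = 3) -> pd.DataFrame:
    """Functional wrapper: profile table in, long fit table out."""
    model = ProfileFitModel(profiles, measure=measure,
                            feature_columns=feature_columns,
                            eps=eps, min_group=min_group)
    return model.fit().table
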