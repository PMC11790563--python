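"""Simultaneous component analysis for cross-group measurement equivalence.

The SCA-P variant is implemented: each cultural block is column-standardised
within block, the blocks are stacked row-wise, and the components are the
leading principal axes of the stacked matrix, i.e. loadings are *common* across
blocks while component scores (and hence per-block term-component correlations)
may differ.  A term whose strongest per-block loading sits on different
components in different blocks measures something non-equivalent across groups
and is flagged for exclusion from fit profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError


class SimultaneousComponents:
    """SCA-P model over two or more blocks sharing the same term columns.

    Parameters
    ----------
    blocks
        Mapping of block label (e.g. culture) to a participants-x-terms frame.
        All blocks must share an identical term-column set.
    """

    def __init__(self, blocks: Mapping[str, pd.DataFrame]):
        if len(blocks) < 2:
            raise ParameterError("SCA needs at least two blocks")
        labels = list(blocks)
        cols = list(blocks[labels[0]].columns)
        for label in labels[1:]:
            if set(blocks[label].columns) != set(cols):
                raise ValidationError(f"block {label!r} has different term columns")
        # store with a canonical column order (the first block's order)
        self.blocks: Dict[str, pd.DataFrame] = {
            label: blocks[label][cols].astype(float) for label in labels
        }
        self.terms: List[str] = cols

    def _standardised(self) -> Dict[str, np.ndarray]:
        out = {}
        for label, frame in self.blocks.items():
            X = frame.to_numpy()
            if len(X) < 2:
                raise ValidationError(f"block {label!r} has fewer than 2 rows")
            sd = X.std(axis=0, ddof=0)
            zero = np.flatnonzero(sd == 0)
            if zero.size:
                raise ValidationError(
                    f"zero-variance term {self.terms[zero[0]]!r} in block {label!r}"
                )
            out[label] = (X - X.mean(axis=0)) / sd
        return out

    def fit(self, k: int) -> "SCAResults":
        """Fit a ``k``-component SCA-P solution."""
        if not (1 <= k <= len(self.terms)):
            raise ParameterError(
                f"k={k} outside 1..{len(self.terms)} (number of terms)"
            )
        standardised = self._standardised()
        stacked = np.vstack([standardised[label] for label in self.blocks])
        # principal axes of the stacked standardised data
        _, svals, vt = np.linalg.svd(stacked, full_matrices=False)
        eigvals = svals**2
        loadings = vt[:k].T.copy()
        # deterministic sign: largest-|loading| element of each component positive
        for j in range(k):
            pivot = np.argmax(np.abs(loadings[:, j]))
            if loadings[pivot, j] < 0:
                loadings[:, j] *= -1
        comp_names = [f"comp{j + 1}" for j in range(k)]
        common = pd.DataFrame(loadings, index=self.terms, columns=comp_names)

        per_block: Dict[str, pd.DataFrame] = {}
        for label in self.blocks:
            Z = standardised[label]
            scores = Z @ loadings
            score_sd = scores.std(axis=0, ddof=0)
            corr = np.full((len(self.terms), k), np.nan)
            ok = score_sd > 0
            corr[:, ok] = (Z.T @ scores[:, ok]) / (len(Z) * score_sd[ok])
            per_block[label] = pd.DataFrame(corr, index=self.terms, columns=comp_names)

        variance_explained = 100.0 * eigvals[:k].sum() / eigvals.sum()
        return SCAResults(model=self, k=k, loadings=common,
                          per_block_loadings=per_block,
                          variance_explained=float(variance_explained),
                          eigenvalues=eigvals)

    def variance_curve(self, k_max: int | None = None) -> pd.Series:
        """Cumulative percent of variance explained for k = 1..k_max."""
        k_max = k_max or len(self.terms)
        if not (1 <= k_max <= len(self.terms)):
            raise ParameterError(f"k_max={k_max} outside 1..{len(self.terms)}")
        stacked = np.vstack(list(self._standardised().values()))
        eigvals = np.linalg.svd(stacked, compute_uv=False)**2
        cum = 100.0 * np.cumsum(eigvals) / eigvals.sum()
        return pd.Series(cum[:k_max], index=range(1, k_max + 1),
                         name="variance_explained_pct")


@dataclass
class SCAResults:
    """Fitted SCA-P solution."""

    model: SimultaneousComponents
    k: int
    loadings: pd.DataFrame                       # terms x components, common
    per_block_loadings: Dict[str, pd.DataFrame]  # term-component correlations
    variance_explained: float                    # percent of total variance
    eigenvalues: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Simultaneous Component Analysis (SCA-P)",
            f"blocks: {', '.join(self.model.blocks)}   terms: {len(self.model.terms)}"
            f"   components: {self.k}",
            f"variance explained: {self.variance_explained:.2f}%",
            "",
            "Common loadings:",
            self.loadings.round(3).to_string(),
        ]
        for label, frame in self.per_block_loadings.items():
            lines += ["", f"Block {label!r} term-component correlations:",
                      frame.round(3).to_string()]
        return "\n".join(lines)


@dataclass(frozen=True)
class TermFlag:
    term: str
    reason: str          # 'cross-loading' | 'theory-misplaced'
    detail: str


def flag_nonequivalent_terms(results: SCAResults,
                             loading_threshold: float = 0.30,
                             expected_components: Mapping[str, int] | None = None,
                             ) -> List[TermFlag]:
    """Flag terms whose component allocation differs across blocks.

    A term is flagged ``cross-loading`` when its maximal-|loading| component
    differs between blocks, provided the maximal loading reaches
    ``loading_threshold`` in every block (weak loadings carry no allocation
    evidence).  ``theory-misplaced`` flags require an explicit
    ``expected_components`` map (term -> 1-based component index) and fire when
    the common-loading allocation deviates from it.
    """
    if not (0 < loading_threshold < 1):
        raise ParameterError("loading_threshold must lie in (0, 1)")
    flags: List[TermFlag] = []
    blocks = list(results.per_block_loadings)
    for term in results.model.terms:
        allocations = []
        salient = True
        for label in blocks:
            row = results.per_block_loadings[label].loc[term].to_numpy()
            j = int(np.nanargmax(np.abs(row)))
            if not np.abs(row[j]) >= loading_threshold:
                salient = False
                break
            allocations.append(j)
        if salient and len(set(allocations)) > 1:
            detail = ", ".join(
                f"{label}: comp{j + 1}" for label, j in zip(blocks, allocations)
            )
            flags.append(TermFlag(term, "cross-loading", detail))
    if expected_components:
        unknown = sorted(set(expected_components) - set(results.model.terms))
        if unknown:
            raise ValidationError(f"expected_components names unknown term(s) {unknown}")
        for term, expected in expected_components.items():
            row = results.loadings.loc[term].to_numpy()
            j = int(np.argmax(np.abs(row)))
            if j + 1 != expected:
                flags.append(TermFlag(
                    term, "theory-misplaced",
                    f"loads on comp{j + 1}, expected comp{expected}",
                ))
    return flags
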