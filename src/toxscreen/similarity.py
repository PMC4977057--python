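"""Chemical-chemical similarity over binned bioactivity fingerprints.

Each chemical's profile across the assay panel is reduced to six categories:

    untested                        -> NA
    inactive / presumed inactive    -> 0
    active, z <= 3                  -> 1
    active, 3 < z <= 6              -> 2
    active, 6 < z <= 9              -> 3
    active, z > 9                   -> 4

with the last four grades expressing increasing specificity of the activity.
Pearson correlations between chemical fingerprints are computed on complete
pairwise observations (assays tested in both chemicals), which makes the
profile comparison robust to sparse testing coverage; a coverage filter can
further restrict the analysis to the densely tested part of the library.

Note the z <= 2 burst exclusion used for ToxPi scoring is *not* applied
here: the binning itself assigns active pairs with z <= 3 to category 1, so
the two stages intentionally handle specificity differently.

An AC50-based variant correlates negative-log-molar potencies instead of
binned z-scores; it tracks potency rather than specificity and can order
similar chemicals differently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .hts import HitCall, HTSMatrix, PairResult
from .toxpi import neglog_molar

__all__ = [
    "SimilarityEntry",
    "ZScoreBinner",
    "bin_z",
    "build_binned_matrix",
    "pairwise_pearson",
    "pairwise_pearson_ac50",
    "top_similar",
    "entries_frame",
]

#: default minimum pairwise overlap for a defined correlation; r on a
#: handful of shared assays is noise, but the floor is configurable down to 2
DEFAULT_MIN_OVERLAP = 10

_BIN_UPPER = (3.0, 6.0, 9.0)


def bin_z(pair: PairResult) -> Optional[int]:
    """Six-category bin of one pair (None = untested/NA)."""
    if pair.status is HitCall.UNTESTED:
        return None
    if pair.status is not HitCall.ACTIVE:
        return 0
    z = pair.z_score
    for category, upper in enumerate(_BIN_UPPER, start=1):
        if z <= upper:
            return category
    return 4


class ZScoreBinner(TransformerMixin, BaseEstimator):
    """Stateless transformer: HTSMatrix -> binned fingerprint matrix.

    Parameters
    ----------
    coverage_filter : float, optional
        Minimum fraction of the panel a chemical must have been tested on;
        chemicals below it are dropped before binning (mirrors restricting a
        correlation analysis to the densely covered part of a library).
    """

    def __init__(self, coverage_filter: Optional[float] = None):
        self.coverage_filter = coverage_filter

    def fit(self, X: HTSMatrix, y=None) -> "ZScoreBinner":
        return self

    def transform(self, X: HTSMatrix) -> pd.DataFrame:
        return build_binned_matrix(X, self.coverage_filter)


def build_binned_matrix(
    matrix: HTSMatrix, coverage_filter: Optional[float] = None
) -> pd.DataFrame:
    """Chemical x assay binned matrix; NaN encodes untested."""
    if coverage_filter is not None:
        coverage = matrix.coverage_stats().per_chemical
        keep = coverage[coverage >= coverage_filter].index.tolist()
        if not keep:
            raise ValueError(
                f"coverage filter {coverage_filter} removed every chemical"
            )
        matrix = matrix.subset(chemicals=keep)
    frame = pd.DataFrame(
        np.nan, index=matrix.chemical_ids, columns=matrix.assay_ids, dtype=float
    )
    for (cid, aid), res in matrix.results.items():
        frame.at[cid, aid] = bin_z(res)
    frame.index.name = "chemical_id"
    frame.columns.name = "assay_id"
    return frame


@dataclass(frozen=True)
class SimilarityEntry:
    """One unordered chemical pair: Pearson r (None if undefined) and overlap."""

    chem_a: str
    chem_b: str
    pearson_r: Optional[float]
    n_overlap: int


def _pairwise_from_frame(values: pd.DataFrame, min_overlap: int) -> list[SimilarityEntry]:
    if min_overlap < 2:
        raise ValueError("min_overlap must be >= 2")
    # pairwise-complete Pearson; pandas returns NaN when the overlap is below
    # min_periods or either restricted vector is constant (r undefined there)
    corr = values.T.corr(min_periods=min_overlap)
    tested = values.notna().to_numpy().astype(np.int64)
    overlap = tested @ tested.T
    ids = list(values.index)
    entries = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = corr.iat[i, j]
            entries.append(
                SimilarityEntry(
                    ids[i], ids[j], None if math.isnan(r) else float(r), int(overlap[i, j])
                )
            )
    return entries


def pairwise_pearson(
    binned: pd.DataFrame, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> list[SimilarityEntry]:
    """All unordered pairwise correlations of a binned fingerprint matrix."""
    return _pairwise_from_frame(binned, min_overlap)


def pairwise_pearson_ac50(
    matrix: HTSMatrix, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> list[SimilarityEntry]:
    """AC50-based variant: correlate negative log molar potencies.

    Active pairs contribute ``neglog_molar(ac50)``, tested-inactive pairs 0,
    untested pairs NA.
    """
    frame = pd.DataFrame(
        np.nan, index=matrix.chemical_ids, columns=matrix.assay_ids, dtype=float
    )
    for (cid, aid), res in matrix.results.items():
        frame.at[cid, aid] = (
            neglog_molar(res.ac50_uM) if res.status is HitCall.ACTIVE else 0.0
        )
    return _pairwise_from_frame(frame, min_overlap)


def entries_frame(entries: Iterable[SimilarityEntry]) -> pd.DataFrame:
    """Long-format view of similarity entries (one row per unordered pair)."""
    return pd.DataFrame(
        [(e.chem_a, e.chem_b, e.pearson_r, e.n_overlap) for e in entries],
        columns=["chem_a", "chem_b", "pearson_r", "n_overlap"],
    )


def top_similar(
    entries: Sequence[SimilarityEntry],
    chemical_id: str,
    k: int,
    exclude: Optional[Callable[[str], bool]] = None,
) -> list[SimilarityEntry]:
    """The k most similar chemicals to a query, by descending Pearson r.

    Undefined correlations are skipped; ties break lexicographically by the
    candidate's id so the output is deterministic.  ``exclude`` is a
    predicate over candidate ids (e.g. dropping pharmaceuticals via an
    annotation lookup).
    """
    known = False
    candidates: list[tuple[str, SimilarityEntry]] = []
    for entry in entries:
        if chemical_id not in (entry.chem_a, entry.chem_b):
            continue
        known = True
        other = entry.chem_b if entry.chem_a == chemical_id else entry.chem_a
        if entry.pearson_r is None:
            continue
        if exclude is not None and exclude(other):
            continue
        candidates.append((other, entry))
    if not known:
        raise KeyError(f"chemical {chemical_id!r} has no similarity entries")
    candidates.sort(key=lambda item: (-item[1].pearson_r, item[0]))
    return [entry for _, entry in candidates[:k]]
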