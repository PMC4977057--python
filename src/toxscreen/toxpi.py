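"""ToxPi scoring core: potency+specificity input values, slice scores, ranks.

The transform from one chemical-assay measurement to a scoring input value is

    input_value = 0                                   if not active or z <= 2
    input_value = max(0, -log10(AC50 * 1e-6) + z)     otherwise

i.e. the AC50 is converted to negative log molar units (1 uM -> 6) and the
cytotoxicity z-score is added so that more specific responses weigh more.
Hits with z <= 2 are excluded outright: near the cytotoxic concentration
range many assays light up nonspecifically (the "cytotoxic signal burst"),
and a cutoff of 2 removes the bulk of those false positives while keeping
marginal hits.

Per model slice, input values are summed across the slice's assays, the sums
are range-normalized across chemicals ((x - min) / (max - min)), multiplied
by the slice weight, and the component scores summed into an overall score in
[0, 1].  A score of 1 means the chemical is the most potent chemical in every
slice of the model.  Because normalization is population-relative, scoring is
exposed as a scikit-learn style estimator: :class:`ToxPiScorer.fit` learns
the per-slice min/range from a population and ``transform`` applies them.

Untested pairs contribute 0: sparse coverage means the approach finds
candidate positives but can miss chemicals that simply were not tested.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .hts import HitCall, HTSMatrix, PairResult
from .models import ProcessModel

__all__ = [
    "Z_CUTOFF",
    "Band",
    "ToxPiResult",
    "ToxPiScorer",
    "neglog_molar",
    "input_value",
    "build_input_matrix",
    "slice_raw_sums",
    "toxpi_scores",
    "rank_and_band",
    "prioritize",
    "rar_scores",
]

#: specificity cutoff: active pairs with z-score <= 2 are scored 0
Z_CUTOFF = 2.0


class Band(str, enum.Enum):
    """Percentile band of a ranked chemical (star notation in reports)."""

    TOP5 = "top5"  # top ~5th percentile, "***"
    TOP10 = "top10"  # top ~10th percentile, "**"
    TOP15 = "top15"  # top ~15th percentile, "*"
    NONE = "none"
    NOT_ACTIVE = "not_active"  # score exactly 0, "-"


def neglog_molar(ac50_uM: float) -> float:
    """AC50 in micromolar -> negative log molar units (1 uM -> 6)."""
    if not (isinstance(ac50_uM, (int, float)) and math.isfinite(ac50_uM)) or ac50_uM <= 0:
        raise ValueError(f"ac50_uM must be positive and finite, got {ac50_uM!r}")
    return -math.log10(ac50_uM * 1e-6)


def input_value(pair: PairResult) -> float:
    """Scoring input value of one pair (0 unless active with z > 2)."""
    if pair.status is not HitCall.ACTIVE:
        return 0.0
    if pair.z_score <= Z_CUTOFF:
        return 0.0
    # negative sums are conceivable only for AC50 > 1 M; floored at 0 since
    # the value represents nonnegative potency evidence
    return max(0.0, neglog_molar(pair.ac50_uM) + pair.z_score)


def build_input_matrix(matrix: HTSMatrix) -> pd.DataFrame:
    """Chemical x assay input-value matrix (untested pairs scored 0)."""
    frame = pd.DataFrame(
        0.0, index=matrix.chemical_ids, columns=matrix.assay_ids, dtype=float
    )
    for (cid, aid), res in matrix.results.items():
        value = input_value(res)
        if value:
            frame.at[cid, aid] = value
    frame.index.name = "chemical_id"
    frame.columns.name = "assay_id"
    return frame


def slice_raw_sums(iv: pd.DataFrame, model: ProcessModel) -> pd.DataFrame:
    """Per (chemical, slice) sum of input values; absent model assays add 0."""
    columns = {}
    for s in model.slices:
        present = [a for a in s.assay_ids if a in iv.columns]
        columns[s.slice_name] = (
            iv[present].sum(axis=1) if present else pd.Series(0.0, index=iv.index)
        )
    sums = pd.DataFrame(columns, index=iv.index)
    sums.index.name = "chemical_id"
    sums.columns.name = "slice"
    return sums


@dataclass
class ToxPiResult:
    """Scored chemical: per-slice component scores, overall score, rank, band."""

    chemical_id: str
    slice_scores: Mapping[str, float]
    overall_score: float
    rank: Optional[int] = None
    band: Optional[Band] = None


class ToxPiScorer(TransformerMixin, BaseEstimator):
    """Range-normalizing, weighted slice scorer for one process model.

    Parameters
    ----------
    model : ProcessModel
        Slice definitions and weights.
    denominator_policy : {"active_only", "full_library"}
        Population used as the percentile-band denominator: chemicals with a
        nonzero score only, or the whole library.  The published band tables
        are not fully reconcilable with either choice, so both are offered;
        ``active_only`` is the default.

    Attributes
    ----------
    slice_names_ : list of str
    weights_ : ndarray, per-slice proportional weights
    slice_min_, slice_range_ : ndarray
        Per-slice minimum raw sum and range across the fitted population.
        A degenerate slice (range 0) scores 0 for every chemical, because
        range normalization is undefined and a constant slice carries no
        ranking information.
    """

    def __init__(self, model: ProcessModel, denominator_policy: str = "active_only"):
        self.model = model
        self.denominator_policy = denominator_policy

    def fit(self, X: pd.DataFrame, y=None) -> "ToxPiScorer":
        """Learn per-slice min/range from the population input-value matrix."""
        if len(X) < 2:
            raise ValueError(
                "ToxPi normalization is population-relative: need at least 2 chemicals"
            )
        if self.denominator_policy not in ("active_only", "full_library"):
            raise ValueError(f"unknown denominator_policy {self.denominator_policy!r}")
        sums = slice_raw_sums(X, self.model)
        self.slice_names_ = list(sums.columns)
        self.weights_ = np.array([s.weight for s in self.model.slices])
        self.slice_min_ = sums.min(axis=0).to_numpy()
        self.slice_range_ = (sums.max(axis=0) - sums.min(axis=0)).to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Component-score matrix (chemical x slice), each column in [0, weight].

        Chemicals outside the fitted population are clipped into [0, 1] per
        slice before weighting, keeping the score bounds.
        """
        sums = slice_raw_sums(X, self.model).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = (sums - self.slice_min_) / self.slice_range_
        norm = np.where(self.slice_range_ > 0, norm, 0.0)
        norm = np.clip(norm, 0.0, 1.0)
        return pd.DataFrame(
            norm * self.weights_, index=X.index, columns=self.slice_names_
        )

    def score_results(self, X: pd.DataFrame) -> list[ToxPiResult]:
        """Full per-chemical results, sorted by score and rank/band annotated."""
        components = self.transform(X)
        results = [
            ToxPiResult(
                chemical_id=str(cid),
                slice_scores=dict(row),
                overall_score=float(row.sum()),
            )
            for cid, row in components.iterrows()
        ]
        return rank_and_band(results, self.denominator_policy)


def toxpi_scores(
    iv: pd.DataFrame, model: ProcessModel, denominator_policy: str = "active_only"
) -> list[ToxPiResult]:
    """Score a population: fit + transform + rank on the same matrix."""
    return ToxPiScorer(model, denominator_policy).fit(iv).score_results(iv)


def rank_and_band(
    results: Sequence[ToxPiResult], denominator_policy: str = "active_only"
) -> list[ToxPiResult]:
    """Sort by score, assign competition ranks and percentile bands.

    Ties share the minimum rank (preserving "top N%" semantics).  Chemicals
    with score exactly 0 are banded ``not_active`` and excluded from the
    ``active_only`` denominator.
    """
    if denominator_policy not in ("active_only", "full_library"):
        raise ValueError(f"unknown denominator_policy {denominator_policy!r}")
    scores = np.array([r.overall_score for r in results])
    ranks = rankdata(-scores, method="min").astype(int)
    n_active = int((scores > 0).sum())
    denom = n_active if denominator_policy == "active_only" else len(results)
    out = []
    for res, rank in zip(results, ranks):
        if res.overall_score == 0:
            band = Band.NOT_ACTIVE
        elif denom and rank / denom <= 0.05:
            band = Band.TOP5
        elif denom and rank / denom <= 0.10:
            band = Band.TOP10
        elif denom and rank / denom <= 0.15:
            band = Band.TOP15
        else:
            band = Band.NONE
        out.append(replace(res, rank=int(rank), band=band))
    out.sort(key=lambda r: (r.rank, r.chemical_id))
    return out


def prioritize(results_by_model: Mapping[str, Sequence[ToxPiResult]]) -> set[str]:
    """Chemicals in the top ~10% (band top5 or top10) of >= 1 model."""
    if not results_by_model:
        raise ValueError("at least one scored model is required")
    flagged: set[str] = set()
    for results in results_by_model.values():
        for res in results:
            if res.band in (Band.TOP5, Band.TOP10):
                flagged.add(res.chemical_id)
    return flagged


def rar_scores(iv: pd.DataFrame, rar_model: ProcessModel) -> pd.Series:
    """Companion per-chemical RAR score: identical math on a one-slice model."""
    results = toxpi_scores(iv, rar_model)
    series = pd.Series(
        {r.chemical_id: r.overall_score for r in results}, name="RAR_score"
    )
    return series.reindex(iv.index.astype(str))
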