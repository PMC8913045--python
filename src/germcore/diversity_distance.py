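"""Gower distance over mixed traits, core-distance summaries, Shannon-Weaver.

Gower's coefficient handles the mixed quantitative/qualitative descriptor
panel directly: a quantitative trait contributes the range-scaled absolute
difference |xi - xj| / range, a qualitative trait contributes a 0/1
mismatch, and the distance is the mean contribution over traits observed in
both accessions (pairwise deletion of missing values).  Trait ranges are
always taken from the whole collection so a pair's distance is identical in
every context.

The three core-quality distance summaries follow the entry/accession
nearest-neighbour scheme:

    E-NE : mean distance from each core entry to its nearest other entry
           (high = diverse, low redundancy)
    A-NE : mean distance from each collection accession to its nearest core
           entry (low = representative; core members contribute 0)
    E-E  : mean pairwise distance among core entries

Shannon-Weaver diversity H' = -sum p ln p uses observed class frequencies
but a *declared* class count for H'max = ln(k), so evenness is comparable
between a core and the whole collection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .trait_schema_io import PhenotypeMatrix

__all__ = [
    "DistanceSummary",
    "DiversityIndex",
    "GowerDistance",
    "gower_matrix",
    "distance_summaries",
    "shannon_weaver",
]


@dataclass(frozen=True)
class DistanceSummary:
    ENE: float  # entry-to-nearest-entry
    ANE: float  # accession-to-nearest-entry
    EE: float  # mean entry-entry


@dataclass(frozen=True)
class DiversityIndex:
    Hprime: float
    Hmax: float
    evenness: float


class GowerDistance(BaseEstimator, TransformerMixin):
    """Pairwise Gower distances for a mixed-trait phenotype matrix.

    ``fit`` records trait ranges/classes from the reference (whole)
    collection; ``transform`` computes the square distance matrix for any
    subset scored on the same schema.  Zero-range quantitative traits are
    excluded from the average (with a warning flag in ``dropped_traits_``).
    """

    def __init__(self, standardize_first: bool = False):
        self.standardize_first = standardize_first

    def fit(self, X: PhenotypeMatrix, y=None):
        if X.n_accessions < 2:
            raise ValueError("need >= 2 accessions")
        if self.standardize_first:
            from .trait_schema_io import standardize

            X = standardize(X)
        self.schema_ = X.schema
        self.ranges_ = {}
        self.dropped_traits_ = []
        for name in X.schema.quantitative:
            col = X.values[name].astype(float)
            rng = float(col.max() - col.min())
            if rng == 0 or np.isnan(rng):
                self.dropped_traits_.append(name)
            else:
                self.ranges_[name] = rng
        self._fit_X = X
        return self

    def transform(self, X: PhenotypeMatrix | None = None) -> np.ndarray:
        if X is None:
            X = self._fit_X
        elif self.standardize_first:
            # apply the reference scaling so ranges stay consistent
            df = X.values.copy()
            for name, (mu, sd) in self._fit_X.scaling_.items():
                df[name] = df[name].astype(float).sub(mu).div(sd)
            X = PhenotypeMatrix(df, X.schema)
        n = X.n_accessions
        num = np.zeros((n, n))
        cnt = np.zeros((n, n))
        for name in X.schema.quantitative:
            if name not in self.ranges_:
                continue
            v = X.values[name].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            both = np.outer(ok, ok)
            diff = np.abs(np.subtract.outer(v, v)) / self.ranges_[name]
            num += np.where(both, np.nan_to_num(diff), 0.0)
            cnt += both
        for name in X.schema.qualitative:
            v = X.values[name].to_numpy(dtype=object)
            ok = np.array([x == x and x is not None for x in v])  # not NaN
            both = np.outer(ok, ok)
            mismatch = (v[:, None] != v[None, :]).astype(float)
            num += np.where(both, mismatch, 0.0)
            cnt += both
        with np.errstate(invalid="ignore"):
            d = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
        np.fill_diagonal(d, 0.0)
        return d

    def fit_transform(self, X: PhenotypeMatrix, y=None) -> np.ndarray:
        return self.fit(X).transform(None)


def gower_matrix(
    m: PhenotypeMatrix, standardize_first: bool = False
) -> np.ndarray:
    """Square symmetric Gower distance matrix in [0, 1] (accession order)."""
    return GowerDistance(standardize_first=standardize_first).fit_transform(m)


def distance_summaries(d: np.ndarray, core: Sequence[int]) -> DistanceSummary:
    """E-NE / A-NE / E-E summaries of a core (row indices into ``d``)."""
    core_idx = np.asarray(sorted(set(core)), dtype=int)
    n = d.shape[0]
    if core_idx.size == 0:
        raise ValueError("core must be non-empty")
    if core_idx.min() < 0 or core_idx.max() >= n:
        raise ValueError("core indices out of range")

    sub = d[np.ix_(core_idx, core_idx)]
    k = core_idx.size
    if k > 1:
        offdiag = sub + np.diag(np.full(k, np.inf))
        ene = float(offdiag.min(axis=1).mean())
        iu = np.triu_indices(k, 1)
        ee = float(sub[iu].mean())
    else:
        ene = float("nan")
        ee = float("nan")
    ane = float(d[:, core_idx].min(axis=1).mean())
    return DistanceSummary(ENE=ene, ANE=ane, EE=ee)


def shannon_weaver(
    labels: Sequence, declared_k: int | None = None
) -> DiversityIndex:
    """Shannon-Weaver H' (natural log) and evenness for one descriptor.

    ``declared_k`` is the number of declared classes used for
    H'max = ln(k); defaults to the number of observed classes.
    """
    s = pd.Series(list(labels)).dropna()
    if s.empty:
        raise ValueError("need >= 1 observation")
    counts = s.value_counts()
    if declared_k is None:
        declared_k = len(counts)
    if declared_k < 2:
        raise ValueError("declared class count must be >= 2")
    if len(counts) > declared_k:
        raise ValueError("observed more classes than declared")
    p = counts.to_numpy(dtype=float) / counts.sum()
    h = float(-(p * np.log(p)).sum())
    hmax = float(np.log(declared_k))
    return DiversityIndex(Hprime=h, Hmax=hmax, evenness=h / hmax)
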