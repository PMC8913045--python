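"""Core-set construction: distance optimization, richness, class coverage.

Three strategy families build candidate cores of a fixed size (about 10% of
the collection, never smaller than the forced-inclusion kernel):

``DistanceOptCoreSampler``
    Maximizes ``w_ene * E-NE - w_ane * A-NE`` over Gower distances by seeded
    simulated annealing on the single-swap neighbourhood.  E-NE (entry to
    nearest entry) rewards diversity; A-NE (accession to nearest entry) is a
    representativeness *cost*, so it enters with a negative sign.  Weight
    pairs like (1,0), (0,1), (1,1), (0.3,0.7), (0.7,0.3) reproduce the
    classic five-strategy battery.

``MaxRichnessCoreSampler``
    Greedy + swap refinement maximizing the total number of distinct trait
    classes captured (quantitative traits binned per schema rule), ties
    broken by summed Shannon H'.

``ClassCoverageCoreSampler``
    Phase 1: greedy set cover of all observed trait classes; phase 2: fill
    to the target size by maximal-minimum-distance addition.

All samplers honour a fixed kernel of accession ids, are deterministic
given ``random_state``, and report an objective trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .diversity_distance import distance_summaries, gower_matrix
from .trait_schema_io import PhenotypeMatrix, bin_quantitative

__all__ = [
    "CoreSet",
    "core_size",
    "DistanceOptCoreSampler",
    "MaxRichnessCoreSampler",
    "ClassCoverageCoreSampler",
    "sample_distance_opt",
    "sample_max_richness",
    "sample_class_coverage",
]


@dataclass
class CoreSet:
    """A candidate core with provenance."""

    members: list  # accession ids, sorted by id for determinism
    strategy: str
    weights: tuple[float, float] | None
    seed: int | None
    objective: float
    trace: list[float] = field(default_factory=list)
    size_violation: bool = False

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("core members must be unique")

    def to_json_dict(self) -> dict:
        return {
            "members": list(self.members),
            "strategy": self.strategy,
            "weights": list(self.weights) if self.weights else None,
            "seed": self.seed,
            "objective": self.objective,
            "trace_head": self.trace[:5],
            "trace_final": self.trace[-1] if self.trace else None,
            "n": len(self.members),
            "size_violation": self.size_violation,
        }


def core_size(n: int, fraction: float, kernel_size: int = 0) -> int:
    """Target core size: round-half-up of n*fraction, at least the kernel."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    size = int(math.floor(n * fraction + 0.5))
    size = max(size, kernel_size, 1)
    if size >= n:
        raise ValueError(f"core size {size} must be smaller than collection {n}")
    return size


def _resolve_kernel(ids: list, kernel: Sequence | None) -> list[int]:
    if not kernel:
        return []
    pos = {a: i for i, a in enumerate(ids)}
    missing = [a for a in kernel if a not in pos]
    if missing:
        raise ValueError(f"kernel ids not in collection: {missing[:5]}")
    return [pos[a] for a in kernel]


# ---------------------------------------------------------------------------
# Distance-optimizing sampler


class DistanceOptCoreSampler(BaseEstimator):
    """Simulated-annealing subset search on the weighted E-NE/A-NE objective.

    Parameters
    ----------
    fraction : float
        Target core fraction of the collection (default 0.10).
    w_ene, w_ane : float
        Non-negative objective weights (not both zero).  The objective
        maximized is ``w_ene * ENE - w_ane * ANE``.
    kernel : sequence of accession ids forced into the core.
    max_iter : int
        Swap proposals per restart.
    patience : int
        Proposals without best-ever improvement before a restart.
    n_restarts : int
    random_state : int

    Attributes
    ----------
    members_ : list of accession ids in the fitted core
    support_ : boolean mask over the collection
    objective_ : best objective value found
    trace_ : best-ever objective after each accepted improvement
    coreset_ : :class:`CoreSet`
    """

    def __init__(
        self,
        fraction: float = 0.10,
        w_ene: float = 1.0,
        w_ane: float = 1.0,
        kernel: Sequence | None = None,
        max_iter: int = 3000,
        patience: int = 600,
        n_restarts: int = 4,
        temp0: float | None = None,
        cooling: float = 0.995,
        random_state: int = 0,
    ):
        self.fraction = fraction
        self.w_ene = w_ene
        self.w_ane = w_ane
        self.kernel = kernel
        self.max_iter = max_iter
        self.patience = patience
        self.n_restarts = n_restarts
        self.temp0 = temp0
        self.cooling = cooling
        self.random_state = random_state

    # objective ------------------------------------------------------------

    def _objective(self, d: np.ndarray, idx: np.ndarray) -> float:
        s = distance_summaries(d, idx)
        obj = 0.0
        if self.w_ene:
            obj += self.w_ene * s.ENE
        if self.w_ane:
            obj -= self.w_ane * s.ANE
        return obj

    def fit(self, X, y=None, ids: Sequence | None = None):
        """X: square distance matrix (ndarray) or PhenotypeMatrix."""
        if self.w_ene < 0 or self.w_ane < 0 or (self.w_ene == self.w_ane == 0):
            raise ValueError("weights must be >= 0 and not both zero")
        if self.max_iter < 1:
            raise ValueError("search budget must be >= 1")
        if isinstance(X, PhenotypeMatrix):
            ids = X.accession_ids
            d = gower_matrix(X)
        else:
            d = np.asarray(X, dtype=float)
            if ids is None:
                ids = list(range(d.shape[0]))
        n = d.shape[0]
        kernel_idx = _resolve_kernel(list(ids), self.kernel)
        size = core_size(n, self.fraction, kernel_size=len(kernel_idx))
        rng = np.random.default_rng(self.random_state)

        kernel_set = set(kernel_idx)
        free_pool = np.array([i for i in range(n) if i not in kernel_set])
        n_fill = size - len(kernel_idx)

        best_idx: np.ndarray | None = None
        best_obj = -np.inf
        trace: list[float] = []

        for _restart in range(max(self.n_restarts, 1)):
            fill = rng.choice(free_pool, size=n_fill, replace=False)
            current = np.concatenate([np.array(kernel_idx, dtype=int), fill]).astype(int)
            cur_obj = self._objective(d, current)
            if cur_obj > best_obj:
                best_obj, best_idx = cur_obj, current.copy()
                trace.append(best_obj)
            # temperature from the objective scale (distances are in [0,1])
            temp = self.temp0 if self.temp0 is not None else 0.02 * (
                self.w_ene + self.w_ane
            )
            stall = 0
            member_mask = np.zeros(n, dtype=bool)
            member_mask[current] = True
            swappable = [i for i in current if i not in kernel_set]
            for _ in range(self.max_iter):
                if not swappable:
                    break
                out_i = swappable[rng.integers(len(swappable))]
                outside = np.flatnonzero(~member_mask)
                in_i = outside[rng.integers(outside.size)]
                proposal = current.copy()
                proposal[np.where(proposal == out_i)[0][0]] = in_i
                prop_obj = self._objective(d, proposal)
                delta = prop_obj - cur_obj
                if delta > 0 or rng.random() < math.exp(min(delta / max(temp, 1e-12), 0)):
                    current = proposal
                    cur_obj = prop_obj
                    member_mask[out_i] = False
                    member_mask[in_i] = True
                    swappable = [i for i in current if i not in kernel_set]
                if cur_obj > best_obj + 1e-15:
                    best_obj, best_idx = cur_obj, current.copy()
                    trace.append(best_obj)
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
                temp *= self.cooling
        assert best_idx is not None

        # exhaustive hill climb from the best solution; only on small
        # instances where the full swap neighbourhood is affordable (the
        # single-swap landscape has shallow traps, so tiny instances also
        # get a two-swap pass)
        n_free = size - len(kernel_idx)
        if n_free * (n - size) <= 5000:
            import itertools as _it

            use_double = (
                math.comb(n_free, 2) * math.comb(n - size, 2) <= 20000
                if n_free >= 2 and n - size >= 2
                else False
            )
            improved = True
            while improved:
                improved = False
                member_mask = np.zeros(n, dtype=bool)
                member_mask[best_idx] = True
                outside = np.flatnonzero(~member_mask)
                free_pos = [
                    p for p, i in enumerate(best_idx) if i not in kernel_set
                ]
                moves = [((p,), (i,)) for p in free_pos for i in outside]
                if use_double:
                    moves += [
                        (pp, ii)
                        for pp in _it.combinations(free_pos, 2)
                        for ii in _it.combinations(outside, 2)
                    ]
                for positions, incoming in moves:
                    trial = best_idx.copy()
                    for p, i in zip(positions, incoming):
                        trial[p] = i
                    obj = self._objective(d, trial)
                    if obj > best_obj + 1e-15:
                        best_obj, best_idx = obj, trial
                        trace.append(best_obj)
                        improved = True
                        break

        ids = list(ids)
        self.members_ = sorted((ids[i] for i in best_idx), key=str)
        self.support_ = np.zeros(n, dtype=bool)
        self.support_[best_idx] = True
        self.objective_ = float(best_obj)
        self.trace_ = trace
        self.coreset_ = CoreSet(
            members=self.members_,
            strategy="distance_opt",
            weights=(self.w_ene, self.w_ane),
            seed=self.random_state,
            objective=self.objective_,
            trace=trace,
        )
        return self


# ---------------------------------------------------------------------------
# Class tables shared by the richness / coverage samplers


def _class_table(m: PhenotypeMatrix) -> pd.DataFrame:
    """Accession x trait table of class labels (quantitative traits binned)."""
    cols = {}
    for t in m.schema:
        if t.is_quantitative:
            if t.bin_rule == "none":
                continue
            labels, _ = bin_quantitative(
                m.values[t.name].to_numpy(dtype=float), t.bin_rule
            )
            cols[t.name] = labels
        else:
            cols[t.name] = m.values[t.name].to_numpy(dtype=object)
    return pd.DataFrame(cols, index=m.values.index)


def _class_sets(table: pd.DataFrame) -> list[set]:
    """Per-accession set of (trait, class) tokens."""
    out = []
    for _, row in table.iterrows():
        out.append(
            {(c, v) for c, v in row.items() if v is not None and v == v}
        )
    return out


def _richness(table: pd.DataFrame, idx: Sequence[int]) -> int:
    sub = table.iloc[list(idx)]
    return int(sum(sub[c].dropna().nunique() for c in sub.columns))


def _hprime_sum(table: pd.DataFrame, idx: Sequence[int]) -> float:
    sub = table.iloc[list(idx)]
    total = 0.0
    for c in sub.columns:
        counts = sub[c].dropna().value_counts().to_numpy(dtype=float)
        if counts.size == 0:
            continue
        p = counts / counts.sum()
        total += float(-(p * np.log(p)).sum())
    return total


class MaxRichnessCoreSampler(BaseEstimator):
    """Greedy-plus-swaps maximization of captured trait-class richness."""

    def __init__(
        self,
        fraction: float = 0.10,
        kernel: Sequence | None = None,
        max_swap_rounds: int = 2,
        random_state: int = 0,
    ):
        self.fraction = fraction
        self.kernel = kernel
        self.max_swap_rounds = max_swap_rounds
        self.random_state = random_state

    def fit(self, X: PhenotypeMatrix, y=None):
        ids = X.accession_ids
        n = len(ids)
        kernel_idx = _resolve_kernel(ids, self.kernel)
        size = core_size(n, self.fraction, kernel_size=len(kernel_idx))
        rng = np.random.default_rng(self.random_state)

        table = _class_table(X)
        acc_sets = _class_sets(table)

        from collections import Counter

        order = rng.permutation(n)  # seeded shuffle, ties then by id order
        order = sorted(order, key=lambda i: (str(ids[i])))
        cover: Counter = Counter()
        members: list[int] = []
        for i in kernel_idx:
            members.append(i)
            cover.update(acc_sets[i])
        member_set = set(members)
        while len(members) < size:
            best_gain, pool = -1, []
            for i in order:
                if i in member_set:
                    continue
                gain = sum(1 for t in acc_sets[i] if cover[t] == 0)
                if gain > best_gain:
                    best_gain, pool = gain, [i]
                elif gain == best_gain:
                    pool.append(i)
            if not pool:
                break
            if 1 < len(pool) <= 25:
                # richness tie: prefer the candidate giving higher summed H'
                pool.sort(
                    key=lambda i: -_hprime_sum(table, members + [i])
                )
            best_pick = pool[0]
            members.append(best_pick)
            member_set.add(best_pick)
            cover.update(acc_sets[best_pick])

        # swap refinement with incremental richness deltas: removing member m
        # loses its uniquely-covered tokens, adding candidate c gains tokens
        # not covered after the removal; ties in richness broken by summed H'
        kernel_set = set(kernel_idx)
        trace = [float(sum(1 for v in cover.values() if v > 0))]
        for _ in range(self.max_swap_rounds):
            improved = False
            for mi, out_i in enumerate(list(members)):
                if out_i in kernel_set:
                    continue
                out_tokens = acc_sets[out_i]
                lost = {t for t in out_tokens if cover[t] == 1}
                best = None  # (delta, candidate)
                for in_i in order:
                    if in_i in member_set:
                        continue
                    in_tokens = acc_sets[in_i]
                    gained = sum(
                        1
                        for t in in_tokens
                        if cover[t] == 0 or (cover[t] == 1 and t in out_tokens)
                    )
                    delta = gained - len(lost - in_tokens)
                    if best is None or delta > best[0]:
                        best = (delta, in_i)
                if best is not None and best[0] > 0:
                    delta, in_i = best
                    members[mi] = in_i
                    member_set.discard(out_i)
                    member_set.add(in_i)
                    cover.subtract(out_tokens)
                    cover.update(acc_sets[in_i])
                    improved = True
            trace.append(float(sum(1 for v in cover.values() if v > 0)))
            if not improved:
                break

        self.members_ = sorted((ids[i] for i in members), key=str)
        self.support_ = np.zeros(n, dtype=bool)
        self.support_[list(members)] = True
        self.objective_ = float(_richness(table, members))
        self.trace_ = trace
        self.coreset_ = CoreSet(
            members=self.members_,
            strategy="max_richness",
            weights=None,
            seed=self.random_state,
            objective=self.objective_,
            trace=trace,
        )
        return self


class ClassCoverageCoreSampler(BaseEstimator):
    """Greedy class cover, then maximal-minimum-distance fill to size."""

    def __init__(
        self,
        fraction: float = 0.10,
        kernel: Sequence | None = None,
        random_state: int = 0,
    ):
        self.fraction = fraction
        self.kernel = kernel
        self.random_state = random_state

    def fit(self, X: PhenotypeMatrix, y=None, d: np.ndarray | None = None):
        ids = X.accession_ids
        n = len(ids)
        kernel_idx = _resolve_kernel(ids, self.kernel)
        size = core_size(n, self.fraction, kernel_size=len(kernel_idx))
        rng = np.random.default_rng(self.random_state)

        table = _class_table(X)
        acc_sets = _class_sets(table)
        universe = set().union(*acc_sets) if acc_sets else set()

        order = rng.permutation(n)
        order = sorted(order, key=lambda i: str(ids[i]))
        members: list[int] = list(kernel_idx)
        covered = set().union(*(acc_sets[i] for i in members)) if members else set()
        # phase 1: greedy set cover of every observed class
        while covered != universe:
            gains = [
                (len(acc_sets[i] - covered), i)
                for i in order
                if i not in set(members)
            ]
            best_gain = max(g for g, _ in gains)
            if best_gain == 0:
                break
            pick = next(i for g, i in gains if g == best_gain)
            members.append(pick)
            covered |= acc_sets[pick]

        size_violation = len(members) > size
        # phase 2: fill by maximal minimum distance to the current core
        if len(members) < size:
            if d is None:
                d = gower_matrix(X)
            member_arr = np.array(members, dtype=int)
            min_d = d[:, member_arr].min(axis=1)
            member_mask = np.zeros(n, dtype=bool)
            member_mask[member_arr] = True
            while len(members) < size:
                cand = np.where(~member_mask, min_d, -np.inf)
                pick = int(np.argmax(cand))  # ties: lowest index
                members.append(pick)
                member_mask[pick] = True
                min_d = np.minimum(min_d, d[:, pick])

        self.members_ = sorted((ids[i] for i in members), key=str)
        self.support_ = np.zeros(n, dtype=bool)
        self.support_[list(members)] = True
        self.objective_ = float(len(covered))
        self.trace_ = [self.objective_]
        self.coreset_ = CoreSet(
            members=self.members_,
            strategy="class_coverage",
            weights=None,
            seed=self.random_state,
            objective=self.objective_,
            trace=self.trace_,
            size_violation=size_violation,
        )
        return self


# ---------------------------------------------------------------------------
# Thin function wrappers


def sample_distance_opt(
    d: np.ndarray,
    ids: Sequence,
    fraction: float = 0.10,
    w_ene: float = 1.0,
    w_ane: float = 1.0,
    kernel: Sequence | None = None,
    seed: int = 0,
    **kwargs,
) -> CoreSet:
    est = DistanceOptCoreSampler(
        fraction=fraction, w_ene=w_ene, w_ane=w_ane, kernel=kernel,
        random_state=seed, **kwargs,
    ).fit(d, ids=ids)
    return est.coreset_


def sample_max_richness(
    m: PhenotypeMatrix, fraction: float = 0.10, kernel=None, seed: int = 0
) -> CoreSet:
    return (
        MaxRichnessCoreSampler(fraction=fraction, kernel=kernel, random_state=seed)
        .fit(m)
        .coreset_
    )


def sample_class_coverage(
    m: PhenotypeMatrix,
    fraction: float = 0.10,
    kernel=None,
    seed: int = 0,
    d: np.ndarray | None = None,
) -> CoreSet:
    return (
        ClassCoverageCoreSampler(fraction=fraction, kernel=kernel, random_state=seed)
        .fit(m, d=d)
        .coreset_
    )
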