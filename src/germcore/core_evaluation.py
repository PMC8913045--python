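"""Core-vs-whole quality evaluation battery and core ranking.

Indices compared against the conventional acceptance thresholds for a good
core collection (MD% < 20, VD% > 80, CR% > 80, VR% > 100):

    MD% : percent of quantitative traits whose core and whole-collection
          means differ significantly (Welch t-test)
    VD% : percent of traits with significantly different variances
          (Levene's test, median-centred / Brown-Forsythe)
    CR% : mean over traits of 100 * core range / whole range
          (coincidence rate of range)
    VR% : mean over traits of 100 * core CV / whole CV
          (variable rate of the coefficient of variation)

plus qualitative class coverage, per-trait Shannon-Weaver H', a shared-bin
histogram Kullback-Leibler divergence of the core from the whole, a Mantel
permutation test between the two trait correlation matrices, and a PCA
comparison of the first five components of each correlation matrix.

The core is treated as an independent sample even though it is a subset of
the whole collection; the resulting tests are descriptive indices, not
calibrated inference (the positive dependence makes them conservative for
mean differences).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity_distance import (
    DistanceSummary,
    distance_summaries,
    shannon_weaver,
)
from .trait_schema_io import PhenotypeMatrix

__all__ = [
    "Thresholds",
    "TraitTestResult",
    "EvaluationReport",
    "md_vd_cr_vr",
    "class_coverage",
    "kl_distance",
    "compare_moments",
    "mantel",
    "pca_compare",
    "evaluate_core",
    "rank_cores",
]


@dataclass(frozen=True)
class Thresholds:
    """Acceptance thresholds for a good core (MD advisory, rest mandatory)."""

    MD_max: float = 20.0
    VD_min: float = 80.0
    CR_min: float = 80.0
    VR_min: float = 100.0
    alpha: float = 0.05


@dataclass
class TraitTestResult:
    trait: str
    t_stat: float
    t_p: float
    snk_q: float
    snk_p: float
    levene_stat: float
    levene_p: float
    wilcoxon_stat: float
    wilcoxon_p: float


@dataclass
class EvaluationReport:
    strategy: str
    n_core: int
    n_whole: int
    distances: dict  # ENE/ANE/EE
    MD_pct: float
    VD_pct: float
    CR_pct: float
    VR_pct: float
    class_coverage_pct: float
    mean_hprime_core: float
    mean_hprime_whole: float
    hprime: dict  # trait -> {core, whole, hmax, evenness_core, evenness_whole}
    kl: dict  # trait -> nats
    tests: list[dict]
    mantel_r: float
    mantel_p: float
    pca: dict  # {"whole": table records, "core": table records}
    verdict: dict  # per-threshold pass flags + overall

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=float)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Index computations


def md_vd_cr_vr(
    whole: PhenotypeMatrix, core: PhenotypeMatrix, alpha: float = 0.05
) -> dict:
    """MD%, VD%, CR%, VR% over the shared quantitative traits."""
    traits = whole.schema.quantitative
    n_sig_mean = n_sig_var = 0
    cr_parts, vr_parts = [], []
    used = 0
    for t in traits:
        w = whole.values[t].dropna().to_numpy(dtype=float)
        c = core.values[t].dropna().to_numpy(dtype=float)
        w_range = w.max() - w.min()
        w_cv = 100.0 * w.std(ddof=1) / w.mean() if w.mean() != 0 else 0.0
        if w_range == 0 or w_cv == 0:
            continue  # excluded with no contribution
        used += 1
        if stats.ttest_ind(c, w, equal_var=False).pvalue < alpha:
            n_sig_mean += 1
        if stats.levene(c, w, center="median").pvalue < alpha:
            n_sig_var += 1
        cr_parts.append(100.0 * (c.max() - c.min()) / w_range)
        c_cv = 100.0 * c.std(ddof=1) / c.mean()
        vr_parts.append(100.0 * c_cv / w_cv)
    if used == 0:
        raise ValueError("no usable quantitative traits")
    return {
        "MD_pct": 100.0 * n_sig_mean / used,
        "VD_pct": 100.0 * n_sig_var / used,
        "CR_pct": float(np.mean(cr_parts)),
        "VR_pct": float(np.mean(vr_parts)),
        "n_traits": used,
    }


def class_coverage(whole: PhenotypeMatrix, core: PhenotypeMatrix) -> float:
    """Mean % of whole-collection observed classes captured, per trait."""
    parts = []
    for t in whole.schema.qualitative:
        w_classes = set(whole.values[t].dropna().unique())
        c_classes = set(core.values[t].dropna().unique())
        if not w_classes:
            continue
        parts.append(100.0 * len(c_classes & w_classes) / len(w_classes))
    return float(np.mean(parts)) if parts else float("nan")


def kl_distance(
    whole_vals: Sequence[float],
    core_vals: Sequence[float],
    min_bins: int = 5,
) -> float:
    """Histogram KL divergence (nats) of the core from the whole.

    Both samples are discretized on shared Freedman-Diaconis bins computed
    from the pooled data (at least ``min_bins``); each bin receives 1/(2n)
    pseudo-mass before normalization so the divergence is finite.
    """
    w = np.asarray(whole_vals, dtype=float)
    c = np.asarray(core_vals, dtype=float)
    w, c = w[~np.isnan(w)], c[~np.isnan(c)]
    if w.size < 10 or c.size < 10:
        raise ValueError("need >= 10 observations in each sample")
    pooled = np.concatenate([w, c])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        return 0.0
    iqr = np.subtract(*np.percentile(pooled, [75, 25]))
    if iqr > 0:
        width = 2.0 * iqr / pooled.size ** (1.0 / 3.0)
        k = max(int(np.ceil((hi - lo) / width)), min_bins)
    else:
        k = min_bins
    edges = np.linspace(lo, hi, k + 1)

    def _probs(x: np.ndarray) -> np.ndarray:
        counts, _ = np.histogram(x, bins=edges)
        # 1/(2n) pseudo-mass per bin = half a pseudo-count before normalizing
        smoothed = counts + 0.5
        return smoothed / smoothed.sum()

    p, q = _probs(c), _probs(w)  # divergence of core from whole
    return float(np.sum(p * np.log(p / q)))


def compare_moments(
    whole: PhenotypeMatrix | Sequence[float],
    core: PhenotypeMatrix | Sequence[float],
    trait: str | None = None,
    n_qq: int = 101,
) -> tuple[TraitTestResult, pd.DataFrame]:
    """Mean/variance/distribution test battery for one quantitative trait.

    Returns the test results (Welch t, two-group Student-Newman-Keuls,
    Brown-Forsythe Levene, Wilcoxon rank-sum) and a QQ table pairing core
    quantiles with whole-collection quantiles.
    """
    if isinstance(whole, PhenotypeMatrix):
        if trait is None:
            raise ValueError("trait name required with PhenotypeMatrix inputs")
        w = whole.values[trait].dropna().to_numpy(dtype=float)
        c = core.values[trait].dropna().to_numpy(dtype=float)
    else:
        w = np.asarray(whole, dtype=float)
        c = np.asarray(core, dtype=float)
        w, c = w[~np.isnan(w)], c[~np.isnan(c)]
        trait = trait or ""
    if min(w.size, c.size) < 3:
        raise ValueError("need >= 3 observations per group")

    t_res = stats.ttest_ind(c, w, equal_var=False)

    # SNK with two groups: studentized range q = sqrt(2) |t_pooled|,
    # reference distribution = studentized range with k = 2 means
    n1, n2 = c.size, w.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * c.var(ddof=1) + (n2 - 1) * w.var(ddof=1)) / df
    if sp2 > 0:
        t_pooled = (c.mean() - w.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        q = np.sqrt(2.0) * abs(t_pooled)
        snk_p = float(stats.studentized_range.sf(q, 2, df))
    else:
        q, snk_p = 0.0, 1.0

    lev = stats.levene(c, w, center="median")
    wil = stats.mannwhitneyu(c, w, alternative="two-sided")

    probs = np.linspace(0, 1, n_qq)
    qq = pd.DataFrame(
        {
            "prob": probs,
            "whole_quantile": np.quantile(w, probs),
            "core_quantile": np.quantile(c, probs),
        }
    )
    res = TraitTestResult(
        trait=trait,
        t_stat=float(t_res.statistic),
        t_p=float(t_res.pvalue),
        snk_q=float(q),
        snk_p=snk_p,
        levene_stat=float(lev.statistic),
        levene_p=float(lev.pvalue),
        wilcoxon_stat=float(wil.statistic),
        wilcoxon_p=float(wil.pvalue),
    )
    return res, qq


def mantel(
    corr_a: np.ndarray | pd.DataFrame,
    corr_b: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel test between two trait correlation matrices.

    r is the Pearson correlation of the upper off-diagonal triangles; the
    two-sided p-value comes from ``n_perm`` seeded simultaneous row/column
    permutations of the second matrix.
    """
    a = np.asarray(corr_a, dtype=float)
    b = np.asarray(corr_b, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    if n_perm < 99:
        raise ValueError("need >= 99 permutations")
    iu = np.triu_indices(a.shape[0], 1)
    r_obs = float(np.corrcoef(a[iu], b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.shape[0])
        bp = b[np.ix_(perm, perm)]
        r = np.corrcoef(a[iu], bp[iu])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)


def pca_compare(
    whole: PhenotypeMatrix, core: PhenotypeMatrix, n_components: int = 5
) -> dict[str, pd.DataFrame]:
    """First components of the trait correlation matrices of both sets.

    Component SDs are the square roots of the eigenvalues of the trait
    correlation matrix (PCA of standardized traits); proportions of
    variance sum to 1 over all components.
    """

    def _one(m: PhenotypeMatrix) -> pd.DataFrame:
        X = m.quantitative_frame().dropna()
        if len(X) < 6:
            raise ValueError("need >= 6 accessions")
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        w = np.linalg.eigvalsh(corr)[::-1]
        w = np.clip(w, 0, None)
        rank = int(np.sum(w > 1e-10 * w.max()))
        k = min(n_components, rank)
        props = w / w.sum()
        return pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(k)],
                "sd": np.sqrt(w[:k]),
                "proportion": props[:k],
                "cumulative": np.cumsum(props)[:k],
            }
        )

    return {"whole": _one(whole), "core": _one(core)}


# ---------------------------------------------------------------------------
# Assembly and ranking


def evaluate_core(
    whole: PhenotypeMatrix,
    core_ids: Sequence,
    d: np.ndarray,
    thresholds: Thresholds = Thresholds(),
    strategy: str = "",
    mantel_permutations: int = 999,
    seed: int = 0,
) -> EvaluationReport:
    """Assemble the full evaluation report for one candidate core."""
    ids = whole.accession_ids
    pos = {a: i for i, a in enumerate(ids)}
    core_idx = [pos[a] for a in core_ids]
    core = whole.subset(list(core_ids))

    ds = distance_summaries(d, core_idx)
    idx = md_vd_cr_vr(whole, core, alpha=thresholds.alpha)
    cov = class_coverage(whole, core)

    hprime: dict[str, dict] = {}
    h_core, h_whole = [], []
    for t in whole.schema.qualitative:
        k = len(whole.schema[t].classes)
        dw = shannon_weaver(whole.values[t], declared_k=k)
        dc = shannon_weaver(core.values[t], declared_k=k)
        hprime[t] = {
            "whole": dw.Hprime,
            "core": dc.Hprime,
            "hmax": dw.Hmax,
            "evenness_whole": dw.evenness,
            "evenness_core": dc.evenness,
        }
        h_core.append(dc.Hprime)
        h_whole.append(dw.Hprime)

    kl = {
        t: kl_distance(whole.values[t], core.values[t])
        for t in whole.schema.quantitative
    }

    tests = []
    for t in whole.schema.quantitative:
        res, _ = compare_moments(whole, core, t)
        tests.append(asdict(res))

    cw = whole.quantitative_frame().corr().to_numpy()
    cc = core.quantitative_frame().corr().to_numpy()
    r, p = mantel(cw, cc, n_perm=mantel_permutations, seed=seed)

    pca = pca_compare(whole, core)

    verdict = {
        "MD_ok": idx["MD_pct"] < thresholds.MD_max,  # advisory
        "VD_ok": idx["VD_pct"] >= thresholds.VD_min,
        "CR_ok": idx["CR_pct"] >= thresholds.CR_min,
        "VR_ok": idx["VR_pct"] >= thresholds.VR_min,
    }
    verdict["overall"] = verdict["VD_ok"] and verdict["CR_ok"] and verdict["VR_ok"]

    return EvaluationReport(
        strategy=strategy,
        n_core=len(core_idx),
        n_whole=whole.n_accessions,
        distances={"ENE": ds.ENE, "ANE": ds.ANE, "EE": ds.EE},
        MD_pct=idx["MD_pct"],
        VD_pct=idx["VD_pct"],
        CR_pct=idx["CR_pct"],
        VR_pct=idx["VR_pct"],
        class_coverage_pct=cov,
        mean_hprime_core=float(np.mean(h_core)) if h_core else float("nan"),
        mean_hprime_whole=float(np.mean(h_whole)) if h_whole else float("nan"),
        hprime=hprime,
        kl=kl,
        tests=tests,
        mantel_r=r,
        mantel_p=p,
        pca={k: v.to_dict(orient="records") for k, v in pca.items()},
        verdict=verdict,
    )


def rank_cores(
    reports: Sequence[EvaluationReport],
) -> tuple[list[EvaluationReport], EvaluationReport]:
    """Rank candidate cores; return (ordered reports, selected core).

    Cores passing all mandatory thresholds (VD, CR, VR) are ranked ahead of
    failing ones; within each group the order is lexicographic on
    (higher ENE, lower ANE, higher EE, higher mean core H'), ties broken by
    strategy tag.  MD% is advisory and does not gate selection.
    """
    if not reports:
        raise ValueError("need at least one report")

    def key(r: EvaluationReport):
        return (
            0 if r.verdict["overall"] else 1,
            -r.distances["ENE"],
            r.distances["ANE"],
            -r.distances["EE"],
            -r.mean_hprime_core,
            r.strategy,
        )

    ordered = sorted(reports, key=key)
    return ordered, ordered[0]
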