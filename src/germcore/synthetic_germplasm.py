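"""Synthetic germplasm collections and augmented-design fieldbooks.

The generator emulates a large cereal genebank characterization: a few
thousand accessions scored for 8 quantitative traits (days to spike
emergence DSE, days to maturity DPM, plant height PH, spike length SL,
spikelet triplet groups STG, grains per spike GNS, hundred-grain weight HGW,
grain yield per row GY) and 9 qualitative descriptors (growth class GC,
early plant vigor EPV, growth habit GH, spike row type SR, awn type AT,
spike density SD, grain type GT, grain pericarp color GPC, lodging
tendency LT).

Quantitative traits are drawn through a Gaussian copula so target pairwise
correlations are reproduced, with truncated-normal marginals matched to the
target mean, CV% and [min, max].  Qualitative descriptors are multinomial at
the target class frequencies, independent of the quantitative block except
an optional row-type linkage hook (two-rowed spikes carry fewer grains).

Fieldbooks follow an augmented randomized complete block design: test
entries unreplicated, a small panel of check varieties replicated in every
block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trait_schema_io import (
    PhenotypeMatrix,
    QUALITATIVE,
    QUANTITATIVE,
    Trait,
    TraitSchema,
)

__all__ = [
    "QuantTraitSpec",
    "QualTraitSpec",
    "CollectionSpec",
    "DesignSpec",
    "default_collection_spec",
    "generate_collection",
    "generate_fieldbook",
    "nearest_psd",
]


@dataclass(frozen=True)
class QuantTraitSpec:
    """Target marginal for one quantitative trait."""

    mean: float
    cv_pct: float
    min: float
    max: float
    units: str = ""
    non_negative: bool = False


@dataclass(frozen=True)
class QualTraitSpec:
    """Declared classes and target frequencies for one qualitative trait."""

    classes: tuple[str, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.freqs):
            raise ValueError("classes and freqs must have equal length")
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError(f"class frequencies must sum to 1, got {sum(self.freqs)}")


@dataclass
class CollectionSpec:
    """Full recipe for a synthetic collection."""

    n_accessions: int
    quantitative: Mapping[str, QuantTraitSpec]
    qualitative: Mapping[str, QualTraitSpec]
    correlation: pd.DataFrame  # target correlations, quantitative trait order
    seed: int = 0
    row_type_linkage: bool = False  # two-rowed accessions get a lower GNS mean

    def schema(self) -> TraitSchema:
        traits = [
            Trait(name, QUANTITATIVE, units=q.units, non_negative=q.non_negative)
            for name, q in self.quantitative.items()
        ]
        traits += [
            Trait(name, QUALITATIVE, classes=q.classes)
            for name, q in self.qualitative.items()
        ]
        return TraitSchema(traits)


# ---------------------------------------------------------------------------
# Study-scale defaults.  Means/CV%/ranges for the 8 quantitative traits and
# the qualitative class frequencies mirror a large hulled/hulless barley
# genebank collection; correlations include the strong maturity pair
# (DSE-DPM 0.58) and height-yield (PH-GY 0.53) plus weaker positives among
# the yield components.

_QUANT_DEFAULTS: dict[str, QuantTraitSpec] = {
    "DSE": QuantTraitSpec(91.46, 11.88, 50.02, 134.82, "days"),
    "DPM": QuantTraitSpec(130.64, 5.66, 99.97, 152.57, "days"),
    "PH": QuantTraitSpec(115.88, 14.64, 45.96, 171.32, "cm"),
    "SL": QuantTraitSpec(8.43, 16.69, 3.44, 13.73, "cm"),
    "STG": QuantTraitSpec(21.95, 19.55, 7.71, 41.64, "count"),
    "GNS": QuantTraitSpec(45.55, 30.82, 10.48, 82.35, "count"),
    "HGW": QuantTraitSpec(3.99, 21.54, 1.20, 6.86, "g"),
    "GY": QuantTraitSpec(104.46, 55.18, 0.0, 333.17, "g", non_negative=True),
}

_QUAL_DEFAULTS: dict[str, QualTraitSpec] = {
    "GC": QualTraitSpec(("spring", "winter", "facultative"), (0.96, 0.03, 0.01)),
    "EPV": QualTraitSpec(("good", "medium", "poor"), (0.92, 0.06, 0.02)),
    "GH": QualTraitSpec(("semi-spreading", "erect", "spreading"), (0.79, 0.12, 0.09)),
    "SR": QualTraitSpec(("six-rowed", "two-rowed", "irregular"), (0.89, 0.105, 0.005)),
    "AT": QualTraitSpec(
        ("awned", "awnleted", "scurs", "awnless", "hooded-sessile", "hooded-elevated"),
        (0.96, 0.024, 0.008, 0.003, 0.001, 0.004),
    ),
    "SD": QualTraitSpec(("dense", "intermediate", "lax"), (0.36, 0.41, 0.23)),
    "GT": QualTraitSpec(("hulled", "hulless", "intermediate"), (0.87, 0.13, 0.0)),
    "GPC": QualTraitSpec(
        ("white", "black", "blue", "purple", "red"),
        (0.9672, 0.0198, 0.0108, 0.0015, 0.0007),
    ),
    "LT": QualTraitSpec(("none", "low", "medium", "high"), (0.35, 0.20, 0.21, 0.24)),
}

_CORR_PAIRS: dict[tuple[str, str], float] = {
    ("DSE", "DPM"): 0.58,
    ("PH", "GY"): 0.53,
    ("PH", "SL"): 0.35,
    ("PH", "STG"): 0.30,
    ("PH", "GNS"): 0.30,
    ("SL", "STG"): 0.40,
    ("SL", "GNS"): 0.20,
    ("SL", "HGW"): 0.20,
    ("SL", "GY"): 0.20,
    ("STG", "GNS"): 0.50,
    ("STG", "GY"): 0.25,
    ("GNS", "GY"): 0.30,
    ("GNS", "HGW"): 0.10,
    ("HGW", "GY"): 0.25,
}


def _default_correlation() -> pd.DataFrame:
    names = list(_QUANT_DEFAULTS)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for (a, b), v in _CORR_PAIRS.items():
        r.loc[a, b] = r.loc[b, a] = v
    return r


def default_collection_spec(n_accessions: int = 6778, seed: int = 0) -> CollectionSpec:
    """Spec matching the whole-collection summary statistics of the study system."""
    return CollectionSpec(
        n_accessions=n_accessions,
        quantitative=dict(_QUANT_DEFAULTS),
        qualitative=dict(_QUAL_DEFAULTS),
        correlation=_default_correlation(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Correlation matrix repair


def nearest_psd(r: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalue clipping followed by re-normalization of the diagonal.
    """
    sym = (r + r.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= eps:
        return sym
    w = np.clip(w, eps, None)
    fixed = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _matched_truncnorm(q: QuantTraitSpec) -> stats.rv_continuous:
    """Truncated normal whose *truncated* mean and sd hit the targets.

    Newton-style fixed-point on (loc, scale): truncation to [min, max]
    shifts the moments, so the untruncated parameters are adjusted until
    the truncated mean/sd match the spec within 1e-6 relative.
    """
    target_mu = q.mean
    target_sd = q.cv_pct / 100.0 * q.mean
    if target_sd == 0:
        raise ValueError("CV=0 handled by caller")
    loc, scale = target_mu, target_sd
    for _ in range(50):
        a, b = (q.min - loc) / scale, (q.max - loc) / scale
        if a >= b:
            raise ValueError(f"infeasible truncation: [{q.min}, {q.max}]")
        dist = stats.truncnorm(a, b, loc=loc, scale=scale)
        m, s = dist.mean(), dist.std()
        if abs(m - target_mu) < 1e-6 * max(1, abs(target_mu)) and abs(
            s - target_sd
        ) < 1e-6 * max(1, target_sd):
            break
        loc += target_mu - m
        scale *= target_sd / s
    a, b = (q.min - loc) / scale, (q.max - loc) / scale
    return stats.truncnorm(a, b, loc=loc, scale=scale)


def generate_collection(spec: CollectionSpec) -> PhenotypeMatrix:
    """Draw a synthetic collection reproducibly from ``spec.seed``.

    Quantitative block: Gaussian copula at the (PSD-repaired) target
    correlation, marginals mapped through moment-matched truncated normals.
    Qualitative block: independent multinomial draws.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_accessions
    qnames = list(spec.quantitative)
    ids = [f"ACC{i + 1:05d}" for i in range(n)]

    corr = spec.correlation.loc[qnames, qnames].to_numpy(dtype=float)
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must be symmetric with unit diagonal")
    corr = nearest_psd(corr)

    # jitter keeps Cholesky defined when the repaired matrix is singular
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(qnames)))
    z = rng.standard_normal((n, len(qnames))) @ chol.T
    u = stats.norm.cdf(z)

    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(qnames):
        q = spec.quantitative[name]
        if q.cv_pct == 0:
            if q.min != q.max and not (q.min <= q.mean <= q.max):
                raise ValueError(f"{name}: mean outside [min, max] with CV=0")
            data[name] = np.full(n, q.mean)
            continue
        if q.min == q.max:
            raise ValueError(f"{name}: min=max with CV>0 is infeasible")
        dist = _matched_truncnorm(q)
        # clip away exact 0/1 quantiles produced by floating-point cdf
        data[name] = dist.ppf(np.clip(u[:, j], 1e-12, 1 - 1e-12))

    for name, qual in spec.qualitative.items():
        data[name] = rng.choice(qual.classes, size=n, p=qual.freqs)

    df = pd.DataFrame(data, index=pd.Index(ids, name="accession_id"))

    if spec.row_type_linkage and "SR" in df.columns and "GNS" in df.columns:
        # two-rowed spikes carry a single fertile spikelet per node: shift
        # their grain count down toward the 25-30 grains typical of the type
        two = df["SR"] == "two-rowed"
        gns = spec.quantitative["GNS"]
        df.loc[two, "GNS"] = np.clip(
            df.loc[two, "GNS"] * 0.6, gns.min, gns.max
        )

    return PhenotypeMatrix(df, spec.schema())


# ---------------------------------------------------------------------------
# Augmented-design fieldbook


@dataclass
class DesignSpec:
    """Augmented RCBD layout and true effects for one trait.

    ``entries_per_block`` counts test entries only; every check is added to
    every block on top of that.  The last block may be incomplete.
    """

    n_entries: int
    n_blocks: int = 40
    check_names: Sequence[str] = ("CHK1", "CHK2", "CHK3", "CHK4", "CHK5")
    grand_mean: float = 100.0
    block_sd: float = 5.0
    genotype_sd: float = 10.0
    residual_sd: float = 3.0
    seed: int = 0


def generate_fieldbook(
    dspec: DesignSpec, trait: str = "Y"
) -> tuple[pd.DataFrame, dict]:
    """Simulate plot observations plus the true effects that produced them.

    Returns ``(fieldbook, truth)`` where the fieldbook has columns
    ``plot, block, entry, is_check, <trait>`` and ``truth`` records the
    block effects, genotype effects and grand mean for recovery testing.
    """
    if dspec.n_entries < dspec.n_blocks:
        raise ValueError("need at least one test entry per block")
    rng = np.random.default_rng(dspec.seed)
    checks = list(dspec.check_names)

    block_eff = rng.normal(0, dspec.block_sd, dspec.n_blocks)
    block_eff -= block_eff.mean()  # identifiable: effects sum to zero
    entries = [f"G{i + 1:05d}" for i in range(dspec.n_entries)]
    geno_eff = dict(
        zip(entries, rng.normal(0, dspec.genotype_sd, dspec.n_entries))
    )
    for c in checks:
        geno_eff[c] = rng.normal(0, dspec.genotype_sd)

    # deal test entries into blocks as evenly as possible (last block may be
    # smaller); checks in every block
    split = np.array_split(np.array(entries, dtype=object), dspec.n_blocks)
    rows = []
    plot = 0
    for b in range(dspec.n_blocks):
        block_entries = list(split[b])
        for name in checks + block_entries:
            plot += 1
            y = (
                dspec.grand_mean
                + block_eff[b]
                + geno_eff[name]
                + (rng.normal(0, dspec.residual_sd) if dspec.residual_sd > 0 else 0.0)
            )
            rows.append(
                {
                    "plot": plot,
                    "block": b + 1,
                    "entry": name,
                    "is_check": name in checks,
                    trait: y,
                }
            )
    fb = pd.DataFrame(rows)
    truth = {
        "grand_mean": dspec.grand_mean,
        "block_effects": dict(enumerate(block_eff, start=1)),
        "genotype_effects": geno_eff,
        "trait": trait,
    }
    return fb, truth
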