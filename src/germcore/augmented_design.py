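"""Adjusted means and genetic-variability statistics for augmented RCBDs.

In an augmented randomized complete block design, unreplicated test entries
are corrected using a panel of check varieties replicated in every block:
the estimated effect of block *j* is the mean of the checks in block *j*
minus the grand mean of all check plots, and a test entry's adjusted value
is its observation minus its block's effect.  The replicated checks also
supply the error variance (the block x check interaction mean square of the
check sub-table), which feeds the genetic-variability decomposition:

    VP = var(adjusted means),   VG = max(VP - error MS, 0)
    h2 (broad sense) = VG / VP
    GCV% = 100 sqrt(VG) / mean,   PCV% = 100 sqrt(VP) / mean
    EGA  = k sqrt(VP) h2          (expected genetic advance)
    GAM% = 100 EGA / mean

with k the standardized selection differential of truncation selection
(2.06 at a 5% selected fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignError",
    "VariabilityRecord",
    "adjust_means",
    "variability_stats",
    "selection_intensity",
    "classify_variability",
]


class DesignError(ValueError):
    """Fieldbook violates the augmented-design layout."""


@dataclass
class VariabilityRecord:
    """Genetic-variability summary for one trait."""

    trait: str
    mean: float
    se_mean: float
    min: float
    max: float
    VG: float
    VP: float
    GCV: float  # percent
    PCV: float  # percent
    h2: float  # proportion in [0, 1]
    EGA: float
    GAM: float  # percent
    k: float
    vg_truncated: bool = False  # error MS exceeded VP
    degenerate: bool = False  # VP == 0, ratios undefined

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Adjusted means


def adjust_means(
    fb: pd.DataFrame,
    trait: str,
    floor_at_zero: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Federer adjustment of an augmented-design fieldbook for one trait.

    Parameters
    ----------
    fb : DataFrame
        Columns ``block``, ``entry``, ``is_check`` and the trait.
    trait : str
        Trait column to adjust.
    floor_at_zero : bool
        Floor negative adjusted values at 0 (for traits that cannot be
        negative, e.g. yields).

    Returns
    -------
    adjusted : Series
        Adjusted value per entry (checks: across-block mean; tests:
        observation minus block effect), indexed by entry id.
    anova : DataFrame
        Source / df / SS / MS table partitioning blocks, treatments
        (checks, tests, checks-vs-tests) and the check-based error.
    """
    if trait not in fb.columns:
        raise KeyError(f"trait {trait!r} not in fieldbook")
    for col in ("block", "entry", "is_check"):
        if col not in fb.columns:
            raise DesignError(f"fieldbook missing column {col!r}")

    checks = fb.loc[fb["is_check"], "entry"].unique()
    blocks = fb["block"].unique()
    if len(checks) == 0:
        raise DesignError("no check plots in fieldbook")

    chk = fb[fb["is_check"]]
    counts = chk.pivot_table(index="block", columns="entry", values=trait, aggfunc="size")
    if counts.reindex(index=blocks, columns=checks).isna().any().any():
        missing = counts.reindex(index=blocks, columns=checks)
        where = [
            (b, c)
            for b in blocks
            for c in checks
            if pd.isna(missing.loc[b, c])
        ]
        raise DesignError(f"checks missing from blocks: {where[:5]}")

    tests = fb[~fb["is_check"]]
    per_entry_blocks = tests.groupby("entry")["block"].nunique()
    if (per_entry_blocks > 1).any():
        bad = per_entry_blocks[per_entry_blocks > 1].index.tolist()
        raise DesignError(f"test entries replicated across blocks: {bad[:5]}")

    check_block_mean = chk.groupby("block")[trait].mean()
    check_grand = chk[trait].mean()
    block_eff = check_block_mean - check_block_mean.mean()

    adj_tests = tests[trait].to_numpy() - block_eff.loc[tests["block"]].to_numpy()
    adjusted = pd.Series(adj_tests, index=tests["entry"].to_numpy(), dtype=float)
    adj_checks = chk.groupby("entry")[trait].mean()
    adjusted = pd.concat([adjusted, adj_checks])
    if floor_at_zero:
        adjusted = adjusted.clip(lower=0.0)

    anova = _augmented_anova(fb, trait, checks)
    return adjusted, anova


def _augmented_anova(fb: pd.DataFrame, trait: str, checks) -> pd.DataFrame:
    """ANOVA with the error estimated from the replicated check sub-table."""
    chk = fb[fb["is_check"]]
    tst = fb[~fb["is_check"]]
    b = chk["block"].nunique()
    c = len(checks)

    # check sub-table: blocks x checks two-way layout, error = interaction
    grand = chk[trait].mean()
    block_means = chk.groupby("block")[trait].mean()
    check_means = chk.groupby("entry")[trait].mean()
    ss_block = (c * (block_means - grand) ** 2).sum()
    ss_check = (b * (check_means - grand) ** 2).sum()
    resid = (
        chk[trait]
        - block_means.loc[chk["block"]].to_numpy()
        - check_means.loc[chk["entry"]].to_numpy()
        + grand
    )
    ss_err = float((resid**2).sum())
    df_err = (b - 1) * (c - 1)

    # treatment partition on adjusted-scale observations
    n_tests = tst["entry"].nunique()
    block_eff = block_means - block_means.mean()
    adj_test_vals = tst[trait].to_numpy() - block_eff.loc[tst["block"]].to_numpy()
    ss_tests = (
        float(((adj_test_vals - adj_test_vals.mean()) ** 2).sum())
        if n_tests > 1
        else 0.0
    )
    mean_checks = check_means.mean()
    mean_tests = adj_test_vals.mean() if n_tests else np.nan
    n_chk_plots = len(chk)
    n_tst_plots = len(tst)
    if n_tests:
        pooled = (n_chk_plots * mean_checks + n_tst_plots * mean_tests) / (
            n_chk_plots + n_tst_plots
        )
        ss_cvt = n_chk_plots * (mean_checks - pooled) ** 2 + n_tst_plots * (
            mean_tests - pooled
        ) ** 2
    else:
        ss_cvt = 0.0

    rows = [
        ("blocks (checks)", b - 1, ss_block),
        ("checks", c - 1, ss_check),
        ("tests (adjusted)", max(n_tests - 1, 0), ss_tests),
        ("checks vs tests", 1 if n_tests else 0, ss_cvt),
        ("error (check reps)", df_err, ss_err),
    ]
    tab = pd.DataFrame(rows, columns=["source", "df", "SS"])
    tab["MS"] = np.where(tab["df"] > 0, tab["SS"] / tab["df"].replace(0, np.nan), np.nan)
    return tab


def error_mean_square(anova: pd.DataFrame) -> float:
    row = anova.loc[anova["source"] == "error (check reps)"]
    return float(row["MS"].iloc[0])


# ---------------------------------------------------------------------------
# Variability statistics


def variability_stats(
    adjusted: pd.Series | np.ndarray,
    error_ms: float,
    k: float = 2.06,
    trait: str = "",
) -> VariabilityRecord:
    """Variance decomposition and selection-response statistics.

    ``adjusted`` are the per-entry adjusted means; ``error_ms`` the check
    error mean square; ``k`` the standardized selection differential.
    """
    vals = np.asarray(adjusted, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("need >= 2 adjusted values")
    if error_ms < 0:
        raise ValueError("error mean square must be >= 0")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("trait mean must be positive for CV-scale statistics")
    vp = float(vals.var(ddof=1))
    se = float(np.sqrt(vp / vals.size))
    if vp == 0:
        return VariabilityRecord(
            trait, mean, 0.0, float(vals.min()), float(vals.max()),
            0.0, 0.0, 0.0, 0.0, float("nan"), 0.0, 0.0, k, degenerate=True,
        )
    vg = vp - error_ms
    truncated = vg < 0
    vg = max(vg, 0.0)
    h2 = vg / vp
    gcv = 100.0 * np.sqrt(vg) / mean
    pcv = 100.0 * np.sqrt(vp) / mean
    ega = k * np.sqrt(vp) * h2
    gam = 100.0 * ega / mean
    return VariabilityRecord(
        trait, mean, se, float(vals.min()), float(vals.max()),
        vg, vp, float(gcv), float(pcv), float(h2), float(ega), float(gam),
        k, vg_truncated=truncated,
    )


def selection_intensity(p: float) -> float:
    """Standardized selection differential of truncation selection.

    k = phi(Phi^-1(1 - p)) / p for selected fraction p in (0, 1];
    k(0.05) ~= 2.06, k(1) = 0.
    """
    if not 0 < p <= 1:
        raise ValueError(f"selected fraction must be in (0, 1], got {p}")
    if p == 1:
        return 0.0
    z = stats.norm.ppf(1 - p)
    return float(stats.norm.pdf(z) / p)


# thresholds: lower bound of the upper class is inclusive
_CV_SCALE = ((10.0, "low"), (20.0, "medium"), (np.inf, "high"))
_H2_SCALE = ((30.0, "low"), (60.0, "medium"), (np.inf, "high"))
_GAM_SCALE = ((10.0, "low"), (20.0, "moderate"), (np.inf, "high"))


def _classify(value: float, scale) -> str:
    for upper, label in scale:
        if value < upper:
            return label
    return scale[-1][1]


def classify_variability(rec: VariabilityRecord) -> dict[str, str]:
    """Categorical labels for GCV/PCV (<10 low, 10-20 medium, >20 high),
    heritability percent (<30 low, 30-60 medium, >60 high) and GAM
    (<10 low, 10-20 moderate, >20 high)."""
    return {
        "GCV": _classify(rec.GCV, _CV_SCALE),
        "PCV": _classify(rec.PCV, _CV_SCALE),
        "h2": _classify(rec.h2 * 100.0, _H2_SCALE),
        "GAM": _classify(rec.GAM, _GAM_SCALE),
    }
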