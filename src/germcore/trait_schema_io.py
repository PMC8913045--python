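"""Trait schema, phenotype matrix container, and delimited-text I/O.

Phenotype collections mix quantitative traits (real-valued, with units) and
qualitative descriptors (nominal class labels).  The :class:`TraitSchema`
declares which is which; :class:`PhenotypeMatrix` couples a validated pandas
DataFrame (rows = accessions, columns = traits) with its schema.

File dialect: comma-separated UTF-8, ``.`` decimal, empty cell = missing.
The first column of a phenotype CSV is the accession identifier.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trait",
    "TraitSchema",
    "PhenotypeMatrix",
    "StandardizedMatrix",
    "SchemaError",
    "IntegrityError",
    "load_phenotypes",
    "save_phenotypes",
    "standardize",
    "bin_quantitative",
]


class SchemaError(ValueError):
    """A trait declaration or a column/schema mismatch is invalid."""


class IntegrityError(ValueError):
    """Data violate a structural invariant (duplicate ids, bad labels)."""


QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"


@dataclass(frozen=True)
class Trait:
    """Declaration of a single trait.

    Parameters
    ----------
    name : str
        Unique trait identifier (CSV column name).
    kind : {"quantitative", "qualitative"}
    units : str, optional
        Measurement units; quantitative traits only.
    classes : tuple of str, optional
        Ordered allowed class labels; qualitative traits only (>= 2).
    bin_rule : str
        How to discretize a quantitative trait for class-based sampling:
        ``"sturges"`` (default), ``"fixed:k"`` or ``"none"``.
    non_negative : bool
        Trait cannot biologically be negative (e.g. a yield); adjusted
        means below zero may be floored at 0 for such traits.
    """

    name: str
    kind: str
    units: str = ""
    classes: tuple[str, ...] = ()
    bin_rule: str = "sturges"
    non_negative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (QUANTITATIVE, QUALITATIVE):
            raise SchemaError(f"trait {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == QUALITATIVE:
            if len(self.classes) < 2:
                raise SchemaError(
                    f"qualitative trait {self.name!r} needs >= 2 declared classes"
                )
            if len(set(self.classes)) != len(self.classes):
                raise SchemaError(f"trait {self.name!r}: duplicate class labels")
        elif self.classes:
            raise SchemaError(
                f"quantitative trait {self.name!r} must not declare classes"
            )

    @property
    def is_quantitative(self) -> bool:
        return self.kind == QUANTITATIVE


class TraitSchema:
    """Ordered collection of :class:`Trait` declarations with unique names."""

    def __init__(self, traits: Iterable[Trait]):
        traits = list(traits)
        names = [t.name for t in traits]
        if len(set(names)) != len(names):
            raise SchemaError("trait names must be unique within a schema")
        self.traits: list[Trait] = traits
        self._by_name = {t.name: t for t in traits}

    def __iter__(self):
        return iter(self.traits)

    def __len__(self) -> int:
        return len(self.traits)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Trait:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"trait {name!r} not in schema") from None

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    @property
    def quantitative(self) -> list[str]:
        return [t.name for t in self.traits if t.is_quantitative]

    @property
    def qualitative(self) -> list[str]:
        return [t.name for t in self.traits if not t.is_quantitative]

    # -- (de)serialization ------------------------------------------------

    def to_dict(self) -> list[dict]:
        out = []
        for t in self.traits:
            d: dict = {"name": t.name, "kind": t.kind}
            if t.kind == QUANTITATIVE:
                if t.units:
                    d["units"] = t.units
                d["bin_rule"] = t.bin_rule
                if t.non_negative:
                    d["non_negative"] = True
            else:
                d["classes"] = list(t.classes)
            out.append(d)
        return out

    @classmethod
    def from_dict(cls, items: Sequence[dict]) -> "TraitSchema":
        traits = []
        for d in items:
            traits.append(
                Trait(
                    name=d["name"],
                    kind=d["kind"],
                    units=d.get("units", ""),
                    classes=tuple(d.get("classes", ())),
                    bin_rule=d.get("bin_rule", "sturges"),
                    non_negative=bool(d.get("non_negative", False)),
                )
            )
        return cls(traits)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"traits": self.to_dict()}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitSchema":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc["traits"])


class PhenotypeMatrix:
    """Accessions x traits table validated against a :class:`TraitSchema`.

    ``values`` is a pandas DataFrame indexed by accession id.  Quantitative
    columns are float (NaN = missing); qualitative columns hold class labels
    (NaN = missing).  Validation rejects out-of-class labels with row-level
    diagnostics and duplicate accession ids.
    """

    def __init__(self, values: pd.DataFrame, schema: TraitSchema):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate accession ids: {dups[:5]}")
        missing_cols = [n for n in schema.names if n not in values.columns]
        if missing_cols:
            raise SchemaError(f"missing required columns: {missing_cols}")
        values = values[schema.names].copy()
        problems: list[str] = []
        for name in schema.quantitative:
            values[name] = pd.to_numeric(values[name], errors="raise")
        for name in schema.qualitative:
            col = values[name]
            allowed = set(schema[name].classes)
            bad = col.dropna()[~col.dropna().isin(allowed)]
            for acc, val in bad.items():
                problems.append(
                    f"accession {acc!r}, trait {name!r}: label {val!r} "
                    f"not among declared classes {sorted(allowed)}"
                )
        if problems:
            raise IntegrityError(
                "out-of-class qualitative values:\n  " + "\n  ".join(problems)
            )
        self.values = values
        self.schema = schema

    @property
    def accession_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_accessions(self) -> int:
        return len(self.values)

    def subset(self, ids: Sequence) -> "PhenotypeMatrix":
        """Row subset (e.g. a core set) preserving schema and id order."""
        return PhenotypeMatrix(self.values.loc[list(ids)], self.schema)

    def quantitative_frame(self) -> pd.DataFrame:
        return self.values[self.schema.quantitative].astype(float)

    def qualitative_frame(self) -> pd.DataFrame:
        return self.values[self.schema.qualitative]


class StandardizedMatrix(PhenotypeMatrix):
    """PhenotypeMatrix with z-scored quantitative columns.

    ``scaling_`` maps trait name -> (mean, sd) of the original column
    (sample sd, n-1 denominator), enabling the inverse transform.
    """

    def __init__(self, values, schema, scaling: dict[str, tuple[float, float]]):
        super().__init__(values, schema)
        self.scaling_ = dict(scaling)

    def inverse_transform(self) -> PhenotypeMatrix:
        df = self.values.copy()
        for name, (mu, sd) in self.scaling_.items():
            df[name] = df[name] * sd + mu
        return PhenotypeMatrix(df, self.schema)

    def save_scaling(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.scaling_, indent=2))


# ---------------------------------------------------------------------------
# I/O


def load_phenotypes(path: str | Path, schema: TraitSchema) -> PhenotypeMatrix:
    """Read a phenotype CSV (first column = accession id) against a schema."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=True)
    for name in schema.quantitative:
        if name in df.columns:
            df[name] = pd.to_numeric(df[name], errors="raise")
    return PhenotypeMatrix(df, schema)


def save_phenotypes(m: PhenotypeMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = df.index.name or "accession_id"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Standardization


def standardize(m: PhenotypeMatrix) -> StandardizedMatrix:
    """Z-score quantitative columns (sample sd); qualitative untouched.

    Raises
    ------
    ValueError
        If a quantitative trait is constant (degenerate trait) or has
        fewer than two distinct non-missing values.
    """
    df = m.values.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for name in m.schema.quantitative:
        col = df[name].astype(float)
        obs = col.dropna()
        if obs.nunique() < 2:
            raise ValueError(f"degenerate quantitative trait {name!r}: constant")
        mu = float(obs.mean())
        sd = float(obs.std(ddof=1))
        df[name] = (col - mu) / sd
        scaling[name] = (mu, sd)
    return StandardizedMatrix(df, m.schema, scaling)


# ---------------------------------------------------------------------------
# Binning


def bin_quantitative(
    values: Sequence[float] | np.ndarray, rule: str = "sturges"
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically bin quantitative values into class labels.

    ``rule`` is ``"sturges"`` (ceil(log2(n)+1) equal-width bins over
    [min, max]) or ``"fixed:k"`` (k equal-width bins).  Missing values map
    to the label ``None``.  Returns ``(labels, edges)``.
    """
    arr = np.asarray(values, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size < 1:
        raise ValueError("need at least one non-missing value")
    lo, hi = float(obs.min()), float(obs.max())

    if rule == "sturges":
        k = int(math.ceil(math.log2(obs.size) + 1)) if obs.size > 1 else 1
    elif rule.startswith("fixed:"):
        k = int(rule.split(":", 1)[1])
        if k < 2:
            raise ValueError(f"fixed:k requires k >= 2, got {k}")
    elif rule == "none":
        raise ValueError("bin rule 'none' declares the trait unbinnable")
    else:
        raise ValueError(f"unknown bin rule {rule!r}")

    if lo == hi:  # degenerate: every value in one bin
        edges = np.array([lo, hi])
        labels = np.where(np.isnan(arr), None, "bin1")
        return labels, edges

    edges = np.linspace(lo, hi, k + 1)
    idx = np.digitize(arr, edges[1:-1], right=False)  # 0..k-1
    labels = np.empty(arr.shape, dtype=object)
    for i, (v, b) in enumerate(zip(arr, idx)):
        labels[i] = None if np.isnan(v) else f"bin{b + 1}"
    return labels, edges
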