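"""One-command orchestration: data -> cores -> evaluation -> ranking.

``run_pipeline`` executes the whole analysis: synthesize (or load) a
collection, compute the Gower distance matrix once, build the
seven-candidate core battery (five E-NE/A-NE weightings, richness,
class coverage), evaluate every candidate against the whole collection,
rank them, and write all artifacts with a checksum manifest.

``identify_promising`` screens the collection for trait-specific promising
accessions against direction/cutoff criteria (e.g. days to spike emergence
< 65 d, hundred-grain weight > 5.5 g).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_evaluation import EvaluationReport, Thresholds, evaluate_core, rank_cores
from .core_samplers import (
    ClassCoverageCoreSampler,
    DistanceOptCoreSampler,
    MaxRichnessCoreSampler,
)
from .diversity_distance import gower_matrix
from .synthetic_germplasm import CollectionSpec, default_collection_spec, generate_collection
from .trait_schema_io import PhenotypeMatrix, load_phenotypes, save_phenotypes, TraitSchema

__all__ = [
    "PipelineConfig",
    "Criterion",
    "default_promising_criteria",
    "identify_promising",
    "run_pipeline",
    "DEFAULT_BATTERY",
]

log = logging.getLogger("germcore")

# the classic five distance-based weightings plus richness and coverage
DEFAULT_BATTERY: list[dict] = [
    {"strategy": "distance_opt", "w_ene": 1.0, "w_ane": 0.0, "name": "ENE"},
    {"strategy": "distance_opt", "w_ene": 0.0, "w_ane": 1.0, "name": "ANE"},
    {"strategy": "distance_opt", "w_ene": 1.0, "w_ane": 1.0, "name": "ENE-ANE-1:1"},
    {"strategy": "distance_opt", "w_ene": 0.3, "w_ane": 0.7, "name": "ENE-ANE-0.3:0.7"},
    {"strategy": "distance_opt", "w_ene": 0.7, "w_ane": 0.3, "name": "ENE-ANE-0.7:0.3"},
    {"strategy": "max_richness", "name": "richness"},
    {"strategy": "class_coverage", "name": "coverage"},
]


@dataclass
class PipelineConfig:
    out_dir: str | Path = "germcore_out"
    seed: int = 0
    n_accessions: int = 1000  # used when synthesizing
    phenotypes_path: str | Path | None = None  # load instead of synthesize
    schema_path: str | Path | None = None
    fraction: float = 0.10
    kernel: Sequence = ()
    battery: list[dict] = field(default_factory=lambda: [dict(b) for b in DEFAULT_BATTERY])
    thresholds: Thresholds = field(default_factory=Thresholds)
    sampler_max_iter: int = 3000
    mantel_permutations: int = 199

    def __post_init__(self) -> None:
        if not self.battery:
            raise ValueError("sampler battery must be non-empty")
        if self.phenotypes_path is not None and self.schema_path is None:
            raise ValueError("schema_path required when loading phenotypes")


@dataclass(frozen=True)
class Criterion:
    """Promising-germplasm predicate on one quantitative trait."""

    trait: str
    direction: str  # "<" or ">"
    cutoff: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("<", ">"):
            raise ValueError("direction must be '<' or '>'")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


def default_promising_criteria() -> list[Criterion]:
    """Trait-specific cutoffs for promising barley germplasm."""
    return [
        Criterion("DSE", "<", 65.0, "days"),
        Criterion("DPM", "<", 115.0, "days"),
        Criterion("PH", ">", 150.0, "cm"),
        Criterion("PH", "<", 80.0, "cm"),
        Criterion("SL", ">", 12.0, "cm"),
        Criterion("GNS", ">", 75.0),
        Criterion("HGW", ">", 5.5, "g"),
    ]


def identify_promising(
    m: PhenotypeMatrix, criteria: Sequence[Criterion] | None = None
) -> dict:
    """Accession lists per criterion plus the multi-trait intersection.

    The "multi_trait" entry lists accessions satisfying criteria on more
    than one distinct trait.
    """
    if criteria is None:
        criteria = default_promising_criteria()
    out: dict[str, list] = {}
    per_acc_traits: dict = {}
    for cr in criteria:
        if cr.trait not in m.schema:
            raise KeyError(f"criterion trait {cr.trait!r} not in schema")
        if not m.schema[cr.trait].is_quantitative:
            raise TypeError(f"criterion on qualitative trait {cr.trait!r}")
        col = m.values[cr.trait].astype(float)
        hit = col < cr.cutoff if cr.direction == "<" else col > cr.cutoff
        ids = list(m.values.index[hit.fillna(False)])
        out[f"{cr.trait}{cr.direction}{cr.cutoff:g}"] = ids
        for a in ids:
            per_acc_traits.setdefault(a, set()).add(cr.trait)
    out["multi_trait"] = sorted(
        (a for a, ts in per_acc_traits.items() if len(ts) > 1), key=str
    )
    return out


# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_core(cfg: PipelineConfig, entry: dict, m: PhenotypeMatrix, d: np.ndarray, seed: int):
    strategy = entry["strategy"]
    if strategy == "distance_opt":
        est = DistanceOptCoreSampler(
            fraction=cfg.fraction,
            w_ene=entry.get("w_ene", 1.0),
            w_ane=entry.get("w_ane", 1.0),
            kernel=list(cfg.kernel) or None,
            max_iter=cfg.sampler_max_iter,
            random_state=seed,
        ).fit(d, ids=m.accession_ids)
    elif strategy == "max_richness":
        est = MaxRichnessCoreSampler(
            fraction=cfg.fraction, kernel=list(cfg.kernel) or None, random_state=seed
        ).fit(m)
    elif strategy == "class_coverage":
        est = ClassCoverageCoreSampler(
            fraction=cfg.fraction, kernel=list(cfg.kernel) or None, random_state=seed
        ).fit(m, d=d)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return est.coreset_


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full battery; return the artifact manifest (also written).

    Stages: ingest/synthesize -> distance matrix -> sampler battery ->
    per-core evaluation -> ranking -> comparison table.  Every random stage
    derives its own substream from the global seed; reruns at a fixed seed
    write byte-identical core membership files.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "files": {}, "stages": []}

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    # stage: data
    if cfg.phenotypes_path is not None:
        schema = TraitSchema.from_yaml(cfg.schema_path)
        m = load_phenotypes(cfg.phenotypes_path, schema)
        log.info("loaded %d accessions from %s", m.n_accessions, cfg.phenotypes_path)
    else:
        spec = default_collection_spec(n_accessions=cfg.n_accessions, seed=cfg.seed)
        m = generate_collection(spec)
        log.info("synthesized %d accessions (seed %d)", m.n_accessions, cfg.seed)
    pheno_path = out / "phenotypes.csv"
    save_phenotypes(m, pheno_path)
    record(pheno_path)
    manifest["stages"].append({"stage": "data", "n_accessions": m.n_accessions})

    # stage: distance matrix (computed once, reused by every sampler)
    d = gower_matrix(m)
    manifest["stages"].append({"stage": "distance", "shape": list(d.shape)})

    # stage: sampler battery
    reports: list[EvaluationReport] = []
    rows = []
    for j, entry in enumerate(cfg.battery):
        sub_seed = (cfg.seed * 1000 + j) % (2**31 - 1)
        core = _build_core(cfg, entry, m, d, sub_seed)
        name = entry.get("name", f"core{j + 1}")
        core_path = out / f"core_{name}.txt"
        core_path.write_text("\n".join(str(a) for a in core.members) + "\n")
        record(core_path)
        prov_path = out / f"core_{name}.json"
        prov_path.write_text(json.dumps(core.to_json_dict(), indent=2))
        record(prov_path)
        log.info("built core %s (%d members)", name, len(core.members))

        rep = evaluate_core(
            m,
            core.members,
            d,
            thresholds=cfg.thresholds,
            strategy=name,
            mantel_permutations=cfg.mantel_permutations,
            seed=sub_seed,
        )
        rep_path = out / f"report_{name}.json"
        rep_path.write_text(rep.to_json())
        record(rep_path)
        reports.append(rep)
        rows.append(
            {
                "core": name,
                "n": rep.n_core,
                "E-NE": rep.distances["ENE"],
                "A-NE": rep.distances["ANE"],
                "E-E": rep.distances["EE"],
                "MD%": rep.MD_pct,
                "VD%": rep.VD_pct,
                "CR%": rep.CR_pct,
                "VR%": rep.VR_pct,
                "Average H'": rep.mean_hprime_core,
                "Class Coverage": rep.class_coverage_pct,
                "Mantel r": rep.mantel_r,
                "passes": rep.verdict["overall"],
            }
        )
    manifest["stages"].append({"stage": "battery", "n_cores": len(reports)})

    # stage: ranking + comparison table
    ordered, best = rank_cores(reports)
    comparison = pd.DataFrame(rows).set_index("core")
    comp_path = out / "comparison.csv"
    comparison.to_csv(comp_path)
    record(comp_path)
    ranking_path = out / "ranking.json"
    ranking_path.write_text(
        json.dumps(
            {
                "order": [r.strategy for r in ordered],
                "selected": best.strategy,
                "selected_verdict": best.verdict,
            },
            indent=2,
        )
    )
    record(ranking_path)
    manifest["stages"].append({"stage": "ranking", "selected": best.strategy})

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    log.info("pipeline finished in %.1fs; selected core: %s", manifest["elapsed_s"], best.strategy)
    return manifest
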