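"""End-to-end orchestration: read/simulate -> classify -> diversity -> model.

The pipeline mirrors the survey's analysis chain.  Input is either the four
CSV tables (stations, community, video, sieves) or a synthetic-survey
block; stages run in a fixed order with a manifest that reconciles row
counts across every filter, and all randomness (replicate subsampling,
permutation rarefaction, simulation) flows from one seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_data, diversity, granulometry, heterogeneity, richness_model
from .core_data import CommunityMatrix
from .diversity import RareSpeciesCriteria
from .richness_model import ModelSpec
from .synthetic_data import GeneratorConfig, generate_dataset

__all__ = ["PipelineConfig", "ReportBundle", "exclusion_filters", "subsample_replicates", "run_pipeline"]

DEFAULT_MODEL_TERMS = (
    "geoclass",
    "sediment_type",
    "season",
    "depth_m",
    "salinity_psu",
    "year_c",
    "year_c:sediment_type",
    "season:sediment_type",
)


@dataclass
class PipelineConfig:
    """Configuration of a full run; exactly one of inputs/simulate is used."""

    inputs: dict | None = None  # paths: stations, community, video, sieves
    simulate: GeneratorConfig | None = None
    rare_criteria: RareSpeciesCriteria = field(default_factory=RareSpeciesCriteria)
    rarefaction_nperm: int = 999
    model_terms: tuple[str, ...] = DEFAULT_MODEL_TERMS
    model_family: str = "negative_binomial"
    backward_selection: bool = True
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("provide exactly one of inputs= or simulate=")

    def digest(self) -> str:
        payload = {
            "inputs": {k: str(v) for k, v in (self.inputs or {}).items()},
            "simulate": None if self.simulate is None else sorted(
                (k, repr(v)) for k, v in vars(self.simulate).items()
            ),
            "rare": vars(self.rare_criteria),
            "nperm": self.rarefaction_nperm,
            "terms": self.model_terms,
            "family": self.model_family,
            "selection": self.backward_selection,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All per-stage outputs plus the run manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict
    model_fit: richness_model.RichnessModelFit | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2, default=str))


def exclusion_filters(
    stations: pd.DataFrame,
    community: CommunityMatrix,
    sample_flags: pd.DataFrame | None = None,
    taxon_flags: pd.DataFrame | None = None,
    genus_whitelist: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, CommunityMatrix, list[dict]]:
    """Apply the survey's sample- and taxon-level exclusions.

    ``sample_flags`` (index station) may carry boolean columns
    ``hard_substrate`` and ``kelp``: flagged samples are removed.
    ``taxon_flags`` (index taxon) may carry ``unattached_sessile`` and
    ``genus_only``: flagged taxa are dropped, except genus-only taxa on the
    whitelist (genera never identified further but known to be a single
    regional species).  Every removal is logged with its reason; with no
    flags the data pass through unchanged.
    """
    log: list[dict] = []
    keep_stations = list(stations.index)
    if sample_flags is not None:
        for col in ("hard_substrate", "kelp"):
            if col in sample_flags.columns:
                flagged = sample_flags.index[sample_flags[col].astype(bool)]
                for sid in flagged:
                    if sid in keep_stations:
                        keep_stations.remove(sid)
                        log.append({"kind": "sample", "id": sid, "reason": col})
    counts = community.counts.loc[[s for s in community.stations if s in keep_stations]]

    drop_taxa: list[str] = []
    if taxon_flags is not None:
        for col in ("unattached_sessile", "genus_only"):
            if col in taxon_flags.columns:
                for taxon in taxon_flags.index[taxon_flags[col].astype(bool)]:
                    if col == "genus_only" and taxon in genus_whitelist:
                        continue
                    if taxon in counts.columns and taxon not in drop_taxa:
                        drop_taxa.append(taxon)
                        log.append({"kind": "taxon", "id": taxon, "reason": col})
    counts = counts.drop(columns=drop_taxa)
    groups = community.taxon_groups
    if groups is not None:
        groups = {t: g for t, g in groups.items() if t not in drop_taxa}
    return (
        stations.loc[keep_stations],
        CommunityMatrix(counts=counts, taxon_groups=groups),
        log,
    )


def subsample_replicates(
    stations: pd.DataFrame, rng: np.random.Generator, location_col: str = "location"
) -> tuple[pd.DataFrame, list[dict]]:
    """Keep one randomly selected sample per location (spatial independence).

    Applies only when a ``location`` column marks replicate samples;
    otherwise the table passes through unchanged.  Reproducible under seed.
    """
    if location_col not in stations.columns:
        return stations, []
    log: list[dict] = []
    keep: list[str] = []
    for loc, grp in stations.groupby(location_col, sort=True):
        ids = sorted(grp.index)
        chosen = ids[int(rng.integers(len(ids)))]
        keep.append(chosen)
        for sid in ids:
            if sid != chosen:
                log.append({"kind": "replicate", "id": sid, "reason": f"replicate at {loc}"})
    return stations.loc[sorted(keep)], log


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and return the collected tables and manifest."""
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "config_hash": config.digest(), "stages": {}}
    tables: dict[str, pd.DataFrame] = {}

    # --- load or simulate -------------------------------------------------
    if config.simulate is not None:
        data = generate_dataset(config.simulate, seed=rng)
        stations = data["stations_frame"]
        community: CommunityMatrix = data["community"]
        profiles = data["profiles"]
        sieves = data["sieves"]
    else:
        station_records = core_data.read_station_table(config.inputs["stations"])
        stations = core_data.stations_frame(station_records)
        community = core_data.read_community_csv(config.inputs["community"])
        profiles = core_data.read_video_csv(config.inputs["video"])
        sieves = core_data.read_sieve_csv(config.inputs["sieves"])
        report = core_data.validate_dataset(station_records, community, profiles, sieves)
        manifest["stages"]["validate"] = {
            "warnings": len(report.warnings),
            "errors": len(report.errors),
        }
        if not report.ok:
            raise RuntimeError(
                "stage validate: fatal cross-table issues: "
                + "; ".join(i.message for i in report.errors)
            )
    manifest["stages"]["load"] = {"stations_in": len(stations)}

    # --- exclusions and replicate subsampling -----------------------------
    stations, community, excl_log = exclusion_filters(stations, community)
    stations, repl_log = subsample_replicates(stations, rng)
    community = CommunityMatrix(
        counts=community.counts.loc[[s for s in community.stations if s in stations.index]],
        taxon_groups=community.taxon_groups,
    )
    manifest["stages"]["filter"] = {
        "excluded": len(excl_log) + len(repl_log),
        "stations_kept": len(stations),
        "log": excl_log + repl_log,
    }

    # --- granulometry ------------------------------------------------------
    granulo = granulometry.summarize_stations(sieves[sieves["station"].isin(stations.index)])
    granulo = granulo.set_index("station")
    tables["granulometry"] = granulo
    stations = stations.copy()
    derived_sed = granulo["sediment_type"].reindex(stations.index)
    if "sediment_type" in stations.columns:
        stations["sediment_type"] = stations["sediment_type"].fillna(derived_sed)
    else:
        stations["sediment_type"] = derived_sed

    # --- heterogeneity ------------------------------------------------------
    geo = heterogeneity.classify_profiles([p for p in profiles if p.station in stations.index])
    geo = geo.set_index("station")
    tables["geoclass"] = geo
    if "geoclass" in stations.columns:
        stations["geoclass"] = stations["geoclass"].fillna(geo["geoclass"].reindex(stations.index))
    else:
        stations["geoclass"] = geo["geoclass"].reindex(stations.index)
    tables["stations_resolved"] = stations

    # --- diversity ----------------------------------------------------------
    rich = diversity.richness_per_sample(community)
    tables["richness"] = rich.to_frame()
    tables["frequencies"] = diversity.occupancy_and_frequency(community)
    rare = diversity.identify_rare(community, config.rare_criteria)
    tables["rare_species"] = pd.DataFrame({"taxon": rare}).set_index("taxon")
    rate_table = diversity.rare_rate_table(
        community, stations, config.rare_criteria, rare_taxa=rare
    )
    tables["rare_rate_table"] = rate_table.with_margins(decimals=2)
    for sed in sorted(stations["sediment_type"].dropna().unique()):
        ids = stations.index[stations["sediment_type"] == sed]
        sub = CommunityMatrix(counts=community.counts.loc[ids])
        curve = diversity.rarefaction_permutation(
            sub, n_perm=config.rarefaction_nperm, rng=rng
        )
        tables[f"rarefaction_{sed}"] = pd.DataFrame(
            {"k": curve.k, "expected_richness": curve.expected_richness, "sd": curve.sd}
        ).set_index("k")
    manifest["stages"]["diversity"] = {
        "n_rare_species": len(rare),
        "n_rare_records": rate_table.total_records,
    }

    # --- modelling ----------------------------------------------------------
    model_data = stations.join(rich)
    model_data["year_c"] = model_data["year"] - model_data["year"].mean()
    spec = ModelSpec(
        response="richness",
        terms=config.model_terms,
        family=config.model_family,
    )
    if config.backward_selection:
        spec, fit, path = richness_model.backward_aic(spec, model_data)
        manifest["stages"]["model"] = {"selection_path": path}
    else:
        fit = richness_model.fit_model(spec, model_data)
        manifest["stages"]["model"] = {"selection_path": []}
    tables["model_coefficients"] = fit.table
    manifest["stages"]["model"].update(
        {
            "family": fit.family,
            "terms": list(spec.terms),
            "aic": fit.aic,
            "theta": fit.theta,
            "pearson_dispersion": richness_model.pearson_dispersion(fit),
            "n_modelled": int(len(fit.y)),
        }
    )

    X, _, info, _ = richness_model.build_design(spec, model_data)
    try:
        tables["gvif"] = richness_model.gvif(X, info.term_columns).table
    except ValueError:
        pass  # single-term model after selection

    nonpar = richness_model.nonparametric_suite(rich, stations["geoclass"])
    tables["nonparametric_geoclass"] = nonpar["pairwise"]
    manifest["stages"]["nonparametric"] = {
        "kruskal_geoclass": nonpar["kruskal"],
    }

    # manifest reconciliation: every loaded station is either kept or logged
    manifest["reconciled"] = (
        manifest["stages"]["load"]["stations_in"]
        == manifest["stages"]["filter"]["stations_kept"]
        + manifest["stages"]["filter"]["excluded"]
    )

    bundle = ReportBundle(tables=tables, manifest=manifest, model_fit=fit)
    if config.outdir is not None:
        bundle.write(config.outdir)
    return bundle
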