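"""Synthetic benthic survey generator with known ground truth.

Emulates a grab-sample + video survey of a heterogeneous sublittoral area:
162 stations spread over four sediment types (mud 53, fine sand 27, medium
sand 53, coarse 29) crossed with four substrate-heterogeneity classes in an
unbalanced joint design (the observed confounding of coarse substrate with
high heterogeneity is preserved on purpose), a 199-taxon species pool with
a long-tailed occupancy distribution and a designated rare tail, and
per-station species richness drawn from a negative-binomial log-linear
model whose coefficients are the recoverable ground truth.

Richness is generated directly from the count model (the estimand) and
species identities are sampled conditional on the realized richness; the
abundance marginal (zero-truncated geometric) is a modelling convenience.
Every draw is reproducible from a single seed, and a :class:`TruthRecord`
carries the latent values for oracle-style testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    HETEROGENEITY_CLASSES,
    SEDIMENT_TYPES,
    CommunityMatrix,
    FeatureProfile,
    StationCovariates,
)
from .granulometry import to_phi
from .heterogeneity import sample_profile_for_class

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "DEFAULT_CELL_COUNTS",
    "DEFAULT_BETA",
    "generate_pool",
    "generate_stations",
    "expected_log_richness",
    "generate_community",
    "generate_dataset",
]

#: Joint sediment x heterogeneity sample counts (rows: none/low/medium/high;
#: columns: mud/fine_sand/medium_sand/coarse).  The default reproduces the
#: unbalanced field design, including its empty cells.
DEFAULT_CELL_COUNTS = pd.DataFrame(
    [[22, 0, 1, 0], [18, 7, 12, 6], [8, 14, 25, 2], [5, 6, 15, 21]],
    index=list(HETEROGENEITY_CLASSES),
    columns=list(SEDIMENT_TYPES),
)

#: True coefficients of the richness model on the log scale.  Keys follow the
#: design-matrix column naming of :mod:`benthet.richness_model`; ``year_c`` is
#: calendar year centered at the study midpoint.  Reference levels: geoclass
#: high, sediment coarse, season spring.
DEFAULT_BETA: dict[str, float] = {
    "Intercept": 3.65,
    "geoclass(low)": -0.37,
    "geoclass(medium)": -0.05,
    "geoclass(none)": -0.62,
    "depth_m": -0.03,
    "salinity_psu": 0.04,
    "year_c": -0.15,
    "sediment_type(fine_sand)": 0.10,
    "sediment_type(medium_sand)": 0.15,
    "sediment_type(mud)": -0.45,
    "season(summer)": 0.29,
    "year_c:sediment_type(fine_sand)": 0.07,
    "year_c:sediment_type(medium_sand)": 0.16,
    "year_c:sediment_type(mud)": 0.19,
    "season(summer):sediment_type(fine_sand)": -0.26,
    "season(summer):sediment_type(medium_sand)": -0.15,
    "season(summer):sediment_type(mud)": -0.55,
}

#: Interior d50 draw ranges per sediment type (um), kept clear of the
#: 63/250/500 um class boundaries so granulometry always classifies back.
_D50_RANGES = {
    "mud": (15.0, 45.0),
    "fine_sand": (80.0, 200.0),
    "medium_sand": (280.0, 450.0),
    "coarse": (600.0, 1400.0),
}

#: Depth ranges per sediment type (m): muds accumulate in the deep channel,
#: coarse lag deposits cap the shallow abrasion platform.
_DEPTH_RANGES = {
    "mud": (25.0, 40.0),
    "fine_sand": (15.0, 30.0),
    "medium_sand": (12.0, 28.0),
    "coarse": (10.0, 22.0),
}

_SAND_MESHES_UM = (2000.0, 1000.0, 710.0, 500.0, 355.0, 250.0, 180.0, 125.0, 90.0, 63.0, 1.0)
_MUD_MESHES_UM = (500.0, 250.0, 125.0, 63.0, 31.0, 16.0, 8.0, 4.0, 2.0, 0.5)


@dataclass(frozen=True, eq=False)
class GeneratorConfig:
    """All knobs of the synthetic survey, with field-realistic defaults."""

    n_stations: int = 162
    pool_size: int = 199
    group_counts: dict = field(
        default_factory=lambda: {"polychaete": 79, "mollusc": 54, "crustacean": 39, "other": 27}
    )
    cell_counts: pd.DataFrame = field(default_factory=lambda: DEFAULT_CELL_COUNTS.copy())
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    theta: float = 3.0
    rare_tail: int = 48
    expected_rare_records_per_taxon: float = 80 / 48
    abundance_mean: float = 6.0
    years: tuple[int, int] = (2012, 2018)
    p_spring: float = 36 / 162
    sediment_affinity_sd: float = 0.7

    def __post_init__(self) -> None:
        if self.rare_tail >= self.pool_size:
            raise ValueError("rare tail must be smaller than the pool")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if sum(self.group_counts.values()) != self.pool_size:
            raise ValueError("group counts must sum to pool_size")
        if int(self.cell_counts.to_numpy().sum()) != 162:
            raise ValueError("cell_counts must sum to 162 (proportions are rescaled "
                             "when n_stations differs)")

    @property
    def year_mid(self) -> float:
        return 0.5 * (self.years[0] + self.years[1])


@dataclass
class TruthRecord:
    """Latent generator state: the oracle against which analyses are checked."""

    stations: pd.DataFrame  # station, lambda, richness_drawn
    pool: pd.DataFrame
    config: GeneratorConfig


def generate_pool(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Taxon pool: group labels, occupancy weights, sediment affinities.

    Occupancy weights of the common pool follow a log-normal rank-abundance
    form; the designated rare tail gets a weight small enough that its
    expected occupancy stays below 2% of stations.  Sediment affinities are
    independent log-normal multipliers, giving overlapping but
    differentiated sediment preferences.
    """
    n = config.pool_size
    groups = [g for g, k in config.group_counts.items() for _ in range(k)]
    rng.shuffle(groups)
    weights = np.exp(rng.normal(0.0, 1.0, size=n))
    rare = np.zeros(n, dtype=bool)
    rare_idx = rng.choice(n, size=config.rare_tail, replace=False)
    rare[rare_idx] = True
    # calibrate rare weights: expected picks per rare taxon ~ target when the
    # whole survey draws ~ n_stations * E[S] species incidences
    approx_total_picks = config.n_stations * 27.0
    common_total = weights[~rare].sum()
    target_share = config.expected_rare_records_per_taxon / approx_total_picks
    # share w_r / (common_total + n_rare * w_r) = target  ->  solve for w_r
    w_r = target_share * common_total / (1.0 - target_share * config.rare_tail)
    weights[rare] = w_r
    affinity = np.exp(
        rng.normal(0.0, config.sediment_affinity_sd, size=(n, len(SEDIMENT_TYPES)))
    )
    pool = pd.DataFrame(
        {
            "taxon": [f"taxon_{i + 1:03d}" for i in range(n)],
            "group": groups,
            "weight": weights,
            "rare_by_design": rare,
        }
    )
    for j, sed in enumerate(SEDIMENT_TYPES):
        pool[f"affinity_{sed}"] = affinity[:, j]
    return pool.set_index("taxon")


def _sieve_stack(
    station: str, sediment: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, float]:
    """Sieve (or laser-diffraction pseudo-sieve) stack for one station.

    Grain phi follows a logistic distribution centred on the target d50;
    retained masses are the CDF increments between adjacent meshes, with the
    finest entry acting as the pan.  Muddy stations use laser-diffraction
    bins reaching below 63 um, recorded through the same table.
    """
    lo, hi = _D50_RANGES[sediment]
    d50 = float(rng.uniform(lo, hi))
    mu = to_phi(d50)
    s = float(rng.uniform(0.3, 0.8))
    meshes = np.array(_MUD_MESHES_UM if sediment == "mud" else _SAND_MESHES_UM)
    phi = to_phi(meshes)  # ascending (coarse -> fine)
    cdf = 1.0 / (1.0 + np.exp(-(phi - mu) / s))  # P(grain phi <= mesh phi)
    retained = np.diff(np.concatenate([[0.0], cdf]))
    total = float(rng.uniform(150.0, 400.0))
    df = pd.DataFrame(
        {"station": station, "mesh_um": meshes, "retained_g": retained * total}
    )
    return df, d50


def generate_stations(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[StationCovariates], list[FeatureProfile], pd.DataFrame]:
    """Stations with covariates, matching video profiles and sieve stacks.

    Sediment x heterogeneity labels follow the configured joint design
    (exactly at n = 162, multinomially rescaled otherwise); depth depends on
    sediment type, salinity increases with depth (halocline) plus noise;
    profiles are drawn by inverse sampling so the classifier recovers the
    intended class, and sieve stacks are drawn so granulometry recovers the
    intended sediment type.
    """
    cells = [
        (geo, sed)
        for geo in HETEROGENEITY_CLASSES
        for sed in SEDIMENT_TYPES
        for _ in range(int(config.cell_counts.loc[geo, sed]))
    ]
    if config.n_stations == len(cells):
        idx = rng.permutation(len(cells))
        assigned = [cells[i] for i in idx]
    else:
        probs = np.full(len(cells), 1.0 / len(cells))
        draws = rng.choice(len(cells), size=config.n_stations, p=probs)
        assigned = [cells[i] for i in draws]

    stations: list[StationCovariates] = []
    profiles: list[FeatureProfile] = []
    sieve_frames: list[pd.DataFrame] = []
    for i, (geo, sed) in enumerate(assigned):
        sid = f"st{i + 1:04d}"
        dlo, dhi = _DEPTH_RANGES[sed]
        depth = float(rng.uniform(dlo, dhi))
        salinity = float(np.clip(15.0 + 0.25 * (depth - 10.0) + rng.normal(0.0, 1.5), 8.0, 30.0))
        year = int(rng.integers(config.years[0], config.years[1] + 1))
        season = "spring" if rng.random() < config.p_spring else "summer"
        stations.append(
            StationCovariates(
                station=sid,
                depth_m=depth,
                salinity_psu=salinity,
                year=year,
                season=season,
                sediment_type=sed,
                geoclass=geo,
            )
        )
        profiles.append(sample_profile_for_class(geo, rng, station=sid))
        stack, _ = _sieve_stack(sid, sed, rng)
        sieve_frames.append(stack)
    return stations, profiles, pd.concat(sieve_frames, ignore_index=True)


_LEVEL_RE = re.compile(r"^(\w+)\(([^)]+)\)$")


def _beta_column(key: str, df: pd.DataFrame) -> np.ndarray:
    """Evaluate one coefficient's design column on a covariate frame."""
    out = np.ones(len(df))
    for part in key.split(":"):
        m = _LEVEL_RE.match(part)
        if m:
            var, level = m.groups()
            if var not in df.columns:
                raise KeyError(f"covariate {var!r} missing for coefficient {key!r}")
            out = out * (df[var].astype(str) == level).to_numpy(dtype=float)
        else:
            if part not in df.columns:
                raise KeyError(f"covariate {part!r} missing for coefficient {key!r}")
            out = out * df[part].to_numpy(dtype=float)
    return out


def expected_log_richness(covariates: pd.DataFrame, beta: dict[str, float]) -> np.ndarray:
    """Per-station expected richness lambda = exp(linear predictor).

    ``covariates`` must contain every variable named in ``beta`` (with
    ``year_c`` already centered); factor coefficients are keyed
    "var(level)" and interactions "a(x):b" / "a:b(y)".
    """
    lp = np.zeros(len(covariates))
    for key, value in beta.items():
        if key == "Intercept":
            lp = lp + value
        else:
            lp = lp + value * _beta_column(key, covariates)
    return np.exp(lp)


def _truncated_nb(
    lam: np.ndarray, theta: float, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    p = theta / (theta + lam)
    draws = rng.negative_binomial(theta, p)
    return np.clip(draws, lo, hi)


def generate_community(
    stations: pd.DataFrame,
    pool: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[CommunityMatrix, TruthRecord]:
    """Community matrix conditioned on model-drawn richness.

    Per station, richness S ~ NB(lambda, theta) truncated to [1, pool size];
    S distinct taxa are drawn without replacement with probability
    proportional to occupancy weight x sediment affinity; abundances are
    zero-truncated geometric with the configured mean, capped at 3
    individuals for rare-by-design taxa.
    """
    cov = stations.copy()
    cov["year_c"] = cov["year"] - config.year_mid
    lam = expected_log_richness(cov, config.beta)
    S = _truncated_nb(lam, config.theta, 1, config.pool_size, rng)

    taxa = list(pool.index)
    weight = pool["weight"].to_numpy()
    counts = np.zeros((len(cov), len(taxa)), dtype=int)
    rare_mask = pool["rare_by_design"].to_numpy()
    p_geom = 1.0 / config.abundance_mean
    for i, (sid, row) in enumerate(cov.iterrows()):
        aff = pool[f"affinity_{row['sediment_type']}"].to_numpy()
        w = weight * aff
        w = w / w.sum()
        chosen = rng.choice(len(taxa), size=int(S[i]), replace=False, p=w)
        abund = rng.geometric(p_geom, size=len(chosen))
        abund = np.where(rare_mask[chosen], np.minimum(abund, 3), abund)
        counts[i, chosen] = abund
    matrix = CommunityMatrix(
        counts=pd.DataFrame(counts, index=list(cov.index), columns=taxa),
        taxon_groups=pool["group"].to_dict(),
    )
    truth = TruthRecord(
        stations=pd.DataFrame(
            {"lambda": lam, "richness_drawn": S}, index=list(cov.index)
        ),
        pool=pool,
        config=config,
    )
    return matrix, truth


def community_for_rare_records(
    records: pd.DataFrame,
    n_samples: pd.DataFrame,
    n_rare_species: int,
    rng: np.random.Generator,
    n_common: int = 12,
) -> tuple[CommunityMatrix, pd.DataFrame]:
    """Minimal survey realizing exact per-cell rare-record counts.

    Builds a station table following the ``n_samples`` layout
    (heterogeneity rows x sediment columns) and a community matrix in which
    a set of ``n_rare_species`` taxa — each at one to three stations, never
    above 3 individuals — produces exactly ``records`` rare incidences per
    cell, on top of ``n_common`` widespread background taxa.  Used to test
    the rate-table machinery against a published layout without the
    original data.
    """
    total_records = int(records.to_numpy().sum())
    if not n_rare_species <= total_records <= 3 * n_rare_species:
        raise ValueError("records cannot be split into species with 1-3 records each")

    stations = []
    slots = []  # one entry per rare record: the station carrying it
    i = 0
    for geo in records.index:
        for sed in records.columns:
            n_cell = int(n_samples.loc[geo, sed])
            ids = []
            for _ in range(n_cell):
                sid = f"r{i + 1:04d}"
                stations.append({"station": sid, "sediment_type": sed, "geoclass": geo})
                ids.append(sid)
                i += 1
            r = int(records.loc[geo, sed])
            for j in range(r):
                slots.append(ids[j % n_cell])
    frame = pd.DataFrame(stations).set_index("station")

    # species sizes: as many 2-record species as needed, the rest singletons,
    # upgraded to 3 where the record surplus demands it
    sizes = [1] * n_rare_species
    surplus = total_records - n_rare_species
    j = 0
    while surplus > 0:
        if sizes[j % n_rare_species] < 3:
            sizes[j % n_rare_species] += 1
            surplus -= 1
        j += 1
    rng.shuffle(slots)
    counts = pd.DataFrame(
        0, index=list(frame.index), columns=[f"rare_{k + 1:02d}" for k in range(n_rare_species)]
    )
    remaining = list(slots)
    # large species first so distinct stations are always available
    for k, size in sorted(enumerate(sizes), key=lambda t: -t[1]):
        assigned: list[str] = []
        for sid in list(remaining):
            if len(assigned) == size:
                break
            if sid not in assigned:
                assigned.append(sid)
                remaining.remove(sid)
        if len(assigned) < size:
            raise RuntimeError("could not place rare records at distinct stations")
        for sid in assigned:
            counts.loc[sid, f"rare_{k + 1:02d}"] = int(rng.integers(1, 4))
    # widespread background taxa (high occupancy -> never rare)
    for c in range(n_common):
        present = rng.random(len(frame)) < 0.6
        counts[f"common_{c + 1:02d}"] = np.where(present, rng.integers(1, 20, len(frame)), 0)
    return CommunityMatrix(counts=counts), frame


def generate_dataset(
    config: GeneratorConfig | None = None, seed: int | np.random.Generator = 0
):
    """End-to-end draw: stations, profiles, sieves, community and truth.

    Returns a dict with keys ``stations`` (list of StationCovariates),
    ``stations_frame``, ``profiles``, ``sieves``, ``community``, ``truth``.
    Identical seed and config give identical output.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    pool = generate_pool(config, rng)
    stations, profiles, sieves = generate_stations(config, rng)
    frame = pd.DataFrame([vars(s) for s in stations]).set_index("station")
    community, truth = generate_community(frame, pool, config, rng)
    return {
        "stations": stations,
        "stations_frame": frame,
        "profiles": profiles,
        "sieves": sieves,
        "community": community,
        "truth": truth,
        "config": config,
    }
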