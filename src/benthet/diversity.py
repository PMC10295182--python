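"""Species richness, occupancy, rare species, and sample-based rarefaction.

The sampling unit throughout is one 0.1 m2 grab sample per station.  A
taxon's *occupancy* is the number of stations where it occurs; its
*frequency* is occupancy as a percentage of stations.  A taxon is *rare*
when its frequency is below 2% of stations (strict inequality on the
fraction) and it never exceeds 3 individuals in any single sample.

Sample-based rarefaction uses the exact hypergeometric estimator

    E[S(k)] = sum_i [ 1 - C(N - n_i, k) / C(N, k) ]

(the mean richness over all k-subsets of the N samples, with n_i the
occupancy of taxon i), with binomial coefficients evaluated in log space;
a seeded permutation estimator provides the accompanying SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core_data import CommunityMatrix

__all__ = [
    "RareSpeciesCriteria",
    "RarefactionCurve",
    "RareRateTable",
    "richness_per_sample",
    "occupancy_and_frequency",
    "identify_rare",
    "rare_rate_table",
    "rarefaction_exact",
    "rarefaction_permutation",
    "taxon_group_tally",
]

#: Decimal convention used in printed reports: round-half-up.
def round_half_up(x: float | np.ndarray, decimals: int) -> float | np.ndarray:
    factor = 10.0**decimals
    return np.floor(np.asarray(x) * factor + 0.5) / factor


@dataclass(frozen=True)
class RareSpeciesCriteria:
    """Definition of a rare taxon.

    ``max_frequency`` is an exclusive upper bound on the fraction of
    stations occupied (default 0.02, i.e. "< 2%"); ``max_abundance`` is an
    inclusive cap on the per-sample count (default 3 individuals).
    """

    max_frequency: float = 0.02
    max_abundance: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.max_frequency < 1:
            raise ValueError("max_frequency must lie in (0, 1)")
        if self.max_abundance < 1:
            raise ValueError("max_abundance must be >= 1")


@dataclass
class RarefactionCurve:
    """Expected cumulative richness when pooling k of N samples."""

    k: np.ndarray
    expected_richness: np.ndarray
    sd: np.ndarray | None
    method: str  # "exact" | "permutation"


def richness_per_sample(matrix: CommunityMatrix) -> pd.Series:
    """Number of taxa with abundance > 0 per station."""
    return (matrix.counts > 0).sum(axis=1).rename("richness")


def occupancy_and_frequency(matrix: CommunityMatrix) -> pd.DataFrame:
    """Per-taxon occupancy (stations occupied) and frequency (% of stations).

    Frequency is reported rounded half-up to one decimal, matching the
    survey-report convention (147 of 162 stations -> 90.7%).
    """
    n = len(matrix.stations)
    occ = (matrix.counts > 0).sum(axis=0)
    freq = round_half_up(100.0 * occ.to_numpy() / n, 1)
    return pd.DataFrame(
        {"occupancy": occ, "frequency_pct": freq}, index=matrix.counts.columns
    ).rename_axis("taxon")


def identify_rare(
    matrix: CommunityMatrix, criteria: RareSpeciesCriteria = RareSpeciesCriteria()
) -> list[str]:
    """Taxa meeting the rare-species definition, in column order.

    Tightening either criterion can only shrink the returned set.
    """
    n = len(matrix.stations)
    occ = (matrix.counts > 0).sum(axis=0)
    peak = matrix.counts.max(axis=0)
    mask = (occ / n < criteria.max_frequency) & (occ > 0) & (
        peak <= criteria.max_abundance
    )
    return [t for t, m in mask.items() if m]


@dataclass
class RareRateTable:
    """Rare-species records per sample, by sediment type x heterogeneity class.

    ``records`` and ``n_samples`` hold the interior cells (heterogeneity
    rows x sediment columns); rates are records / samples with empty cells
    as NaN (printed NA).  Margins are pooled sums, so the overall rate
    times N equals the total record count.
    """

    records: pd.DataFrame
    n_samples: pd.DataFrame

    @property
    def rates(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.records / self.n_samples.where(self.n_samples > 0)

    def with_margins(self, decimals: int | None = 2) -> pd.DataFrame:
        """Rates table with pooled row/column/overall margins.

        ``decimals`` rounds half-up for report output; pass None for full
        precision.
        """
        rec = self.records.copy()
        ns = self.n_samples.copy()
        rec["Overall"] = rec.sum(axis=1)
        ns["Overall"] = ns.sum(axis=1)
        rec.loc["Overall"] = rec.sum(axis=0)
        ns.loc["Overall"] = ns.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = rec / ns.where(ns > 0)
        if decimals is not None:
            rates = rates.apply(lambda col: round_half_up(col, decimals))
        return rates

    @property
    def total_records(self) -> int:
        return int(self.records.sum().sum())


def reconstruct_records(rates: pd.DataFrame, n_samples: pd.DataFrame) -> pd.DataFrame:
    """Invert a printed rate table (2-decimal rates, known n) to record counts.

    Because rates are records/samples rounded to two decimals, the integer
    cell count is recovered as round(rate * n) whenever n < 200 or so.
    Empty cells (NaN rate) yield 0 records.
    """
    rec = round_half_up((rates * n_samples).to_numpy(), 0)
    rec = np.where(np.isnan(rec), 0, rec).astype(int)
    return pd.DataFrame(rec, index=rates.index, columns=rates.columns)


def rare_rate_table(
    matrix: CommunityMatrix,
    stations: pd.DataFrame,
    criteria: RareSpeciesCriteria = RareSpeciesCriteria(),
    rare_taxa: list[str] | None = None,
) -> RareRateTable:
    """Tabulate rare-species records per sample over sediment x heterogeneity.

    ``stations`` must carry ``sediment_type`` and ``geoclass`` for every
    station in the matrix; a record is one (station, rare taxon) incidence.
    """
    from .core_data import HETEROGENEITY_CLASSES, SEDIMENT_TYPES

    meta = stations.loc[:, ["sediment_type", "geoclass"]]
    missing = [
        s
        for s in matrix.stations
        if s not in meta.index or meta.loc[s].isna().any()
    ]
    if missing:
        raise ValueError(f"stations missing sediment/heterogeneity labels: {missing}")
    if rare_taxa is None:
        rare_taxa = identify_rare(matrix, criteria)
    rare_records = (matrix.counts[rare_taxa] > 0).sum(axis=1)

    rec = pd.DataFrame(0, index=list(HETEROGENEITY_CLASSES), columns=list(SEDIMENT_TYPES))
    ns = rec.copy()
    for station in matrix.stations:
        g = meta.loc[station, "geoclass"]
        s = meta.loc[station, "sediment_type"]
        ns.loc[g, s] += 1
        rec.loc[g, s] += int(rare_records.loc[station])
    return RareRateTable(records=rec, n_samples=ns)


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_exact(matrix: CommunityMatrix, kmax: int | None = None) -> RarefactionCurve:
    """Exact sample-based rarefaction curve for a set of samples.

    At k = 1 the estimator reduces to the mean per-sample richness; at
    k = N it equals the total observed richness.  The curve is
    non-decreasing and concave in k.
    """
    n_stations = len(matrix.stations)
    kmax = n_stations if kmax is None else kmax
    if kmax > n_stations or kmax < 1:
        raise ValueError(f"kmax must lie in [1, {n_stations}], got {kmax}")
    occ = (matrix.counts > 0).sum(axis=0).to_numpy()
    occ = occ[occ > 0]
    ks = np.arange(1, kmax + 1)
    expected = np.empty(len(ks))
    for j, k in enumerate(ks):
        # P(taxon i absent from all k samples) = C(N - n_i, k) / C(N, k)
        valid = n_stations - occ >= k
        p_absent = np.zeros(len(occ))
        p_absent[valid] = np.exp(
            _log_comb(n_stations - occ[valid], k) - _log_comb(n_stations, k)
        )
        expected[j] = np.sum(1.0 - p_absent)
    return RarefactionCurve(k=ks, expected_richness=expected, sd=None, method="exact")


def rarefaction_permutation(
    matrix: CommunityMatrix,
    kmax: int | None = None,
    n_perm: int = 999,
    rng: np.random.Generator | int = 0,
) -> RarefactionCurve:
    """Permutation rarefaction: mean and SD over random sample orderings.

    The mean converges to the exact estimator; the SD is the empirical
    spread of the accumulation curve over ``n_perm`` seeded orderings
    (0 at k = N, where every ordering pools all samples).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    incidence = (matrix.counts.to_numpy() > 0)
    n_stations = incidence.shape[0]
    kmax = n_stations if kmax is None else kmax
    richness = np.empty((n_perm, kmax))
    for p in range(n_perm):
        order = rng.permutation(n_stations)
        seen = np.cumsum(incidence[order], axis=0) > 0
        richness[p] = seen.sum(axis=1)[:kmax]
    return RarefactionCurve(
        k=np.arange(1, kmax + 1),
        expected_richness=richness.mean(axis=0),
        sd=richness.std(axis=0, ddof=1),
        method="permutation",
    )


def taxon_group_tally(matrix: CommunityMatrix) -> dict[str, int]:
    """Number of observed taxa (>= 1 record) per taxonomic group."""
    if matrix.taxon_groups is None:
        raise ValueError("community matrix carries no taxon group labels")
    present = matrix.counts.sum(axis=0) > 0
    unlabeled = [t for t in matrix.taxa if t not in matrix.taxon_groups]
    if unlabeled:
        raise ValueError(f"taxa without group label: {unlabeled[:5]}")
    tally: dict[str, int] = {}
    for taxon in matrix.taxa:
        if present[taxon]:
            g = matrix.taxon_groups[taxon]
            tally[g] = tally.get(g, 0) + 1
    return tally
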