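"""Grain-size analysis: cumulative curves, phi-scale summaries, sediment typing.

A station's sieve stack (retained mass per mesh) is turned into a cumulative
grain-size curve on the phi scale (phi = -log2(diameter in mm)), summarised by
an asymmetric logistic fit, and classified into one of four sediment types by
the median grain size d50:

    mud          d50 <  63 um
    fine sand    63 um <= d50 < 250 um
    medium sand  250 um <= d50 < 500 um
    coarse       d50 >= 500 um

Class boundaries are half-open with the boundary value assigned to the
coarser class.  Pre-binned laser-diffraction output for muddy stations is
ingested through the same :class:`CumulativeCurve` container (each bin edge
acting as a pseudo-mesh), bypassing sieve-mass conversion.

The summary statistics are graphic (Folk-Ward-style) measures computed from
percentiles of the fitted curve: sorting = (phi84 - phi16) / 2 and skewness
= (phi16 + phi84 - 2*phi50) / (phi84 - phi16).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core_data import SchemaError

__all__ = [
    "SieveRecord",
    "CumulativeCurve",
    "GranulometrySummary",
    "to_phi",
    "from_phi",
    "cumulative_curve",
    "interpolate_percentiles",
    "fit_sshape",
    "classify_sediment",
    "summarize_stations",
]


@dataclass
class SieveRecord:
    """Mass retained on one sieve of a station's stack."""

    station: str
    mesh_um: float
    retained_g: float

    def __post_init__(self) -> None:
        if self.mesh_um <= 0:
            raise ValueError(f"station {self.station}: mesh must be positive")
        if self.retained_g < 0:
            raise ValueError(f"station {self.station}: retained mass must be >= 0")


@dataclass
class CumulativeCurve:
    """Cumulative grain-size curve of one station on the phi scale.

    ``phi`` is strictly ascending (coarse to fine); ``cum_coarser`` is the
    cumulative mass fraction of grains coarser than (retained on or above)
    each mesh, non-decreasing from ~0 to 1.  The complementary "fraction
    finer" is ``1 - cum_coarser``.
    """

    station: str
    phi: np.ndarray
    cum_coarser: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.cum_coarser = np.asarray(self.cum_coarser, dtype=float)
        if self.phi.size < 2:
            raise ValueError("curve needs at least two knots")
        if np.any(np.diff(self.phi) <= 0):
            raise ValueError("phi knots must be strictly ascending")
        if np.any(np.diff(self.cum_coarser) < 0):
            raise ValueError("cumulative fractions must be non-decreasing")
        if self.cum_coarser.min() < 0 or self.cum_coarser.max() > 1 + 1e-9:
            raise ValueError("cumulative fractions must lie in [0, 1]")

    @property
    def fraction_finer(self) -> np.ndarray:
        return 1.0 - self.cum_coarser


@dataclass
class GranulometrySummary:
    """Graphic grain-size statistics and derived sediment type for a station."""

    station: str
    d50_um: float
    d50_phi: float
    sorting_phi: float
    skewness: float
    sediment_type: str
    fit_method: str  # "sshape" | "interpolation"
    loi_pct: float | None = None


def to_phi(size_um: float | np.ndarray) -> float | np.ndarray:
    """Phi transform: phi = -log2(size in mm); strictly decreasing in size."""
    size_um = np.asarray(size_um, dtype=float)
    if np.any(size_um <= 0):
        raise ValueError("grain size must be positive")
    out = -np.log2(size_um / 1000.0)
    return float(out) if out.ndim == 0 else out


def from_phi(phi: float | np.ndarray) -> float | np.ndarray:
    """Inverse phi transform, returning size in um."""
    out = 1000.0 * np.exp2(-np.asarray(phi, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def cumulative_curve(records: pd.DataFrame | list[SieveRecord]) -> CumulativeCurve:
    """Build the cumulative curve for one station's sieve stack.

    The fraction coarser at a mesh is the mass retained on this and all
    coarser sieves divided by total mass.  Requires >= 3 sieves and a
    positive total mass; duplicate meshes are rejected.
    """
    if isinstance(records, list):
        records = pd.DataFrame(
            [{"station": r.station, "mesh_um": r.mesh_um, "retained_g": r.retained_g} for r in records]
        )
    stations = records["station"].unique()
    if len(stations) != 1:
        raise ValueError(f"expected a single station, got {list(stations)}")
    station = str(stations[0])
    mesh = records["mesh_um"].to_numpy(dtype=float)
    mass = records["retained_g"].to_numpy(dtype=float)
    if len(np.unique(mesh)) != len(mesh):
        raise ValueError(f"station {station}: duplicate mesh sizes")
    if len(mesh) < 3:
        raise ValueError(f"station {station}: >= 3 sieves required, got {len(mesh)}")
    total = mass.sum()
    if total <= 0:
        raise ValueError(f"station {station}: zero total mass")
    order = np.argsort(mesh)[::-1]  # coarsest first = ascending phi
    cum = np.cumsum(mass[order]) / total
    return CumulativeCurve(station=station, phi=to_phi(mesh[order]), cum_coarser=cum)


def interpolate_percentiles(
    curve: CumulativeCurve, p: float | list[float] | np.ndarray
) -> np.ndarray:
    """Phi values at cumulative fractions ``p`` by piecewise-linear inversion.

    Inverts the (phi, cumulative fraction coarser) knots monotonically.
    Fractions outside the observed range cannot be inverted and raise.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("percentile fractions must lie strictly in (0, 1)")
    lo, hi = curve.cum_coarser[0], curve.cum_coarser[-1]
    if np.any(p < lo - 1e-12) or np.any(p > hi + 1e-12):
        raise ValueError(
            f"station {curve.station}: fraction outside observed range "
            f"[{lo:.3f}, {hi:.3f}]; refusing to extrapolate"
        )
    # np.interp needs strictly increasing x; collapse exact plateaus so each
    # cumulative level maps to a single representative phi (midpoint of the
    # plateau), keeping the inversion monotone.
    cum, phi = curve.cum_coarser, curve.phi
    xs: list[float] = []
    ys: list[float] = []
    i = 0
    while i < len(cum):
        j = i
        while j + 1 < len(cum) and cum[j + 1] == cum[i]:
            j += 1
        xs.append(cum[i])
        ys.append(0.5 * (phi[i] + phi[j]))
        i = j + 1
    return np.interp(p, xs, ys)


def _richards_cdf(phi: np.ndarray, mu: float, s: float, nu: float) -> np.ndarray:
    """Asymmetric (Richards-type) logistic CDF on the phi scale."""
    z = np.clip(-(phi - mu) / s, -500, 500)
    return (1.0 + np.exp(z)) ** (-nu)


def _richards_ppf(p: float, mu: float, s: float, nu: float) -> float:
    return mu - s * np.log(p ** (-1.0 / nu) - 1.0)


def fit_sshape(curve: CumulativeCurve, loi_pct: float | None = None) -> GranulometrySummary:
    """Summarise a cumulative curve via an asymmetric logistic least-squares fit.

    Fits F(phi) = [1 + exp(-(phi - mu)/s)]^(-nu) to the knots, then reads
    d50, sorting and skewness off the fitted curve.  If the fit does not
    converge or the curve is degenerate (a single 0-to-1 jump between
    adjacent knots), falls back to direct percentile interpolation and
    flags the record with ``fit_method="interpolation"``.

    The true s-shape used for the survey's granulometry is not published;
    the Richards-type logistic is this package's declared approximation.
    """
    phi, cum = curve.phi, curve.cum_coarser

    # Degenerate step: all mass between two adjacent meshes.  The only
    # defensible point estimate is the mesh that retained the mass.
    jumps = np.flatnonzero(np.diff(cum) > 0)
    if len(jumps) == 1 and cum[jumps[0]] < 1e-12 and cum[jumps[0] + 1] > 1 - 1e-12:
        d50_phi = float(phi[jumps[0] + 1])
        d50 = float(from_phi(d50_phi))
        return GranulometrySummary(
            station=curve.station,
            d50_um=d50,
            d50_phi=d50_phi,
            sorting_phi=0.0,
            skewness=0.0,
            sediment_type=classify_sediment(d50),
            fit_method="interpolation",
            loi_pct=loi_pct,
        )

    interior = (cum > 1e-9) & (cum < 1 - 1e-9)
    mu0 = float(np.interp(0.5, cum, phi)) if cum[-1] > 0.5 > cum[0] else float(np.median(phi))
    s0 = max(float(np.ptp(phi[interior])) / 4 if interior.sum() >= 2 else 0.5, 0.05)
    ok = False
    if interior.sum() >= 3:
        try:
            res = least_squares(
                lambda th: _richards_cdf(phi, th[0], th[1], th[2]) - cum,
                x0=[mu0, s0, 1.0],
                bounds=([-20.0, 1e-3, 1e-2], [20.0, 10.0, 100.0]),
                max_nfev=2000,
            )
            ok = res.success and np.sqrt(np.mean(res.fun**2)) < 0.05
        except Exception:
            ok = False
    if ok:
        mu, s, nu = res.x
        p16, p50, p84 = (_richards_ppf(q, mu, s, nu) for q in (0.16, 0.50, 0.84))
        method = "sshape"
    else:
        # percentile fallback requires the observed fractions to bracket them
        lo, hi = cum[0], cum[-1]
        ps = np.clip([0.16, 0.50, 0.84], max(lo, 1e-9), min(hi, 1 - 1e-9))
        p16, p50, p84 = interpolate_percentiles(curve, ps)
        method = "interpolation"
    d50 = float(from_phi(p50))
    spread = p84 - p16
    return GranulometrySummary(
        station=curve.station,
        d50_um=d50,
        d50_phi=float(p50),
        sorting_phi=float(spread / 2.0),
        skewness=float((p16 + p84 - 2 * p50) / spread) if spread > 1e-12 else 0.0,
        sediment_type=classify_sediment(d50),
        fit_method=method,
        loi_pct=loi_pct,
    )


def classify_sediment(d50_um: float) -> str:
    """Sediment type from median grain size, half-open class boundaries."""
    if d50_um <= 0 or not np.isfinite(d50_um):
        raise ValueError(f"d50 must be positive and finite, got {d50_um}")
    if d50_um < 63:
        return "mud"
    if d50_um < 250:
        return "fine_sand"
    if d50_um < 500:
        return "medium_sand"
    return "coarse"


def summarize_stations(sieves: pd.DataFrame) -> pd.DataFrame:
    """Per-station granulometry summary table from a long sieve table.

    Returns a DataFrame (station, d50_um, d50_phi, sorting_phi, skewness,
    sediment_type, fit_method) with one row per station.
    """
    rows = []
    for station, grp in sieves.groupby("station", sort=True):
        summary = fit_sshape(cumulative_curve(grp))
        rows.append(vars(summary))
    return pd.DataFrame(rows).drop(columns=["loi_pct"])
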