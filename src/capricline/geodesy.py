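"""Ellipsoidal geodesic distances and diversity-vs-distance cline regression.

The dispersal analysis asks a single question of each continental breed set:
does a diversity statistic (Ho, He, Fst against a near-origin reference, or
F_ROH) decrease or increase linearly with the geodesic distance between a
breed's sampling site and the putative domestication-era origin?  Distances
are computed on the WGS84 ellipsoid with Vincenty's inverse method, and the
association is summarized by the Pearson product-moment correlation with a
two-sided p-value from the exact t transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

__all__ = [
    "Origin",
    "GANJ_DAREH",
    "ClineResult",
    "vincenty_km",
    "distances_to_origin",
    "subset_breeds",
    "pearson_cline",
    "cline_report",
    "SUBSET_PRESETS",
]

# WGS84 ellipsoid
_WGS84_A = 6378137.0  # semi-major axis, metres
_WGS84_F = 1.0 / 298.257223563  # flattening
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)

_CONVERGENCE_RAD = 1e-12
_MAX_ITERATIONS = 200


@dataclass(frozen=True)
class Origin:
    """A named geographic origin point (decimal degrees, N/E positive)."""

    name: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"invalid origin coordinates ({self.lat}, {self.lon})")


#: Neolithic settlement in the central Zagros mountains (western Iran) with
#: early evidence of goat management; the default dispersal origin.
GANJ_DAREH = Origin("Ganj Dareh", lat=34.27, lon=47.47)


class GeodesicError(ValueError):
    """Raised when the inverse geodesic iteration fails to converge."""


def vincenty_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Inverse geodesic distance between two points on the WGS84 ellipsoid.

    Implements Vincenty's iterative inverse formula (accurate to well below a
    millimetre for non-antipodal pairs).  Near-antipodal point pairs, for
    which the classical iteration is known to stall, raise ``GeodesicError``.

    Parameters
    ----------
    lat1, lon1, lat2, lon2:
        Coordinates in decimal degrees, north/east positive.

    Returns
    -------
    float
        Distance in kilometres.
    """
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} out of range [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} out of range [-180, 180]")

    if lat1 == lat2 and lon1 == lon2:
        return 0.0

    a, b, f = _WGS84_A, _WGS84_B, _WGS84_F
    # reduced latitudes
    u1 = math.atan((1.0 - f) * math.tan(math.radians(lat1)))
    u2 = math.atan((1.0 - f) * math.tan(math.radians(lat2)))
    big_l = math.radians(lon2 - lon1)

    sin_u1, cos_u1 = math.sin(u1), math.cos(u1)
    sin_u2, cos_u2 = math.sin(u2), math.cos(u2)

    lam = big_l
    for _ in range(_MAX_ITERATIONS):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cos_u2 * sin_lam, cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0  # coincident points
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sin_u1 * sin_u2 / cos2_alpha
        big_c = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = big_l + (1.0 - big_c) * f * sin_alpha * (
            sigma
            + big_c
            * sin_sigma
            * (
                cos_2sigma_m
                + big_c * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m * cos_2sigma_m)
            )
        )
        if abs(lam - lam_prev) < _CONVERGENCE_RAD:
            break
    else:
        raise GeodesicError(
            "Vincenty iteration did not converge (near-antipodal points); "
            "consider a great-circle fallback"
        )

    u_sq = cos2_alpha * (a * a - b * b) / (b * b)
    big_a = 1.0 + u_sq / 16384.0 * (
        4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq))
    )
    big_b = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = (
        big_b
        * sin_sigma
        * (
            cos_2sigma_m
            + big_b
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
                - big_b
                / 6.0
                * cos_2sigma_m
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sigma_m**2)
            )
        )
    )
    return b * big_a * (sigma - delta_sigma) / 1000.0


def distances_to_origin(
    breeds: pd.DataFrame, origin: Origin = GANJ_DAREH
) -> pd.Series:
    """Vincenty distance (km) from every breed's sampling site to ``origin``.

    ``breeds`` must carry ``breed_id``, ``lon`` and ``lat`` columns.  Returns
    a Series indexed by ``breed_id``.
    """
    out = {}
    for row in breeds.itertuples(index=False):
        try:
            out[row.breed_id] = vincenty_km(origin.lat, origin.lon, row.lat, row.lon)
        except ValueError as exc:
            raise ValueError(f"breed {row.breed_id}: {exc}") from exc
    return pd.Series(out, name="distance_km")


# ---------------------------------------------------------------------------
# Breed subsets

#: Named breed subsets used by the continental cline analyses.  The African
#: presets always drop the three South African commercial breeds (Boer,
#: Savanna, Kalahari Red), whose partially Asian ancestry makes them
#: unrepresentative of indigenous dispersal; the African insular breeds are
#: the two Malagasy populations and the Canary-Islands Palmera.  The default
#: European "no islands" preset removes only the British and Irish
#: populations; an extended variant also drops breeds sampled on
#: Mediterranean islands.
SUBSET_PRESETS: Mapping[str, Mapping[str, Sequence[str]]] = {
    "europe_all": {"exclude": ()},
    "europe_no_british_irish": {"exclude": ("ENG", "IRL")},
    "europe_no_all_islands": {
        "exclude": ("ENG", "IRL", "MAL", "MLT", "SAR", "CRS")
    },
    "africa_with_islands": {"exclude": ("BOE", "SAV", "KHAR")},
    "africa_no_islands": {"exclude": ("BOE", "SAV", "KHAR", "MEN", "SOF", "PAL")},
    "asia_all": {"exclude": ()},
}


def subset_breeds(
    table: pd.DataFrame,
    spec: str | Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Filter a diversity table by a named preset or include/exclude spec.

    ``spec`` is either a key of :data:`SUBSET_PRESETS` or a mapping with
    optional ``include`` and ``exclude`` iterables of breed ids.  Unknown
    breed ids raise ``KeyError``.
    """
    if isinstance(spec, str):
        try:
            spec = SUBSET_PRESETS[spec]
        except KeyError:
            raise KeyError(f"unknown subset preset {spec!r}") from None
    known = set(table["breed_id"])
    include = list(spec.get("include", ()))
    exclude = list(spec.get("exclude", ()))
    for bid in (*include, *exclude):
        if bid not in known:
            raise KeyError(f"unknown breed_id {bid!r} in subset spec")
    out = table
    if include:
        out = out[out["breed_id"].isin(include)]
    if exclude:
        out = out[~out["breed_id"].isin(exclude)]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cline regression


@dataclass(frozen=True)
class ClineResult:
    """Pearson correlation of one diversity statistic against distance."""

    statistic_name: str
    subset_label: str
    n_breeds: int
    r: float
    p_two_sided: float
    slope: float  # per km
    intercept: float
    n_dropped: int = 0  # rows dropped for a missing statistic or distance

    def __post_init__(self) -> None:
        if self.n_breeds < 3:
            raise ValueError("cline regression needs at least 3 breeds")


def pearson_cline(
    table: pd.DataFrame,
    statistic_name: str,
    subset_label: str = "",
    distance_col: str = "distance_km",
) -> ClineResult:
    """Correlate a diversity statistic with distance to the origin.

    Rows where either the statistic or the distance is absent are dropped
    pairwise and counted in ``n_dropped``.  The p-value is the exact
    two-sided t transform with n-2 degrees of freedom; slope and intercept
    are the ordinary least-squares fit used for plotting.
    """
    if statistic_name not in table.columns:
        raise KeyError(f"no column {statistic_name!r} in table")
    pair = table[[statistic_name, distance_col]].astype(float)
    kept = pair.dropna()
    n = len(kept)
    if n < 3:
        raise ValueError(
            f"need >= 3 breeds with both {statistic_name} and distance; got {n}"
        )
    y = kept[statistic_name].to_numpy()
    x = kept[distance_col].to_numpy()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("degenerate: zero variance in statistic or distance")
    r, p = _scistats.pearsonr(x, y)
    fit = _scistats.linregress(x, y)
    return ClineResult(
        statistic_name=statistic_name,
        subset_label=subset_label,
        n_breeds=n,
        r=float(r),
        p_two_sided=float(p),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_dropped=len(pair) - n,
    )


#: The continent -> presets map the standard report iterates over.
_REPORT_PLAN: Mapping[str, Sequence[str]] = {
    "europe": ("europe_all", "europe_no_british_irish"),
    "africa": ("africa_with_islands", "africa_no_islands"),
    "asia": ("asia_all",),
}

_REPORT_STATS = ("ho", "he", "fst_vs_ref", "f_roh")


def cline_report(
    tables: Mapping[str, pd.DataFrame],
    statistics: Sequence[str] = _REPORT_STATS,
) -> pd.DataFrame:
    """All standard continent x subset x statistic cline regressions.

    ``tables`` maps continent name (europe/africa/asia) to a diversity table
    that already carries a ``distance_km`` column.  Statistics entirely
    absent from a table are skipped.
    """
    rows = []
    for continent, presets in _REPORT_PLAN.items():
        if continent not in tables:
            continue
        table = tables[continent]
        for preset in presets:
            sub = subset_breeds(table, preset)
            for stat in statistics:
                if stat not in sub.columns or sub[stat].isna().all():
                    continue
                res = pearson_cline(sub, stat, subset_label=preset)
                rows.append(
                    {
                        "continent": continent,
                        "subset": preset,
                        "statistic": res.statistic_name,
                        "n_breeds": res.n_breeds,
                        "r": res.r,
                        "p_two_sided": res.p_two_sided,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "n_dropped": res.n_dropped,
                    }
                )
    return pd.DataFrame(rows)
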