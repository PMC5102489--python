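"""Closed-population capture–recapture density estimation from camera traps.

Encounter histories (individuals × occasions) feed two classical
closed-population estimators: M0 (constant detection probability, joint
maximum likelihood over N and p) and Mh (individual heterogeneity, the
Burnham–Overton jackknife on capture frequencies f_1..f_t). The effective
survey area is the minimum convex polygon of the camera stations dilated by
a buffer of ½MMDM or MMDM — (half) the mean maximum distance moved among
individuals photographed at more than one station — and density is
100·N̂/area in animals per 100 km². All coordinates are projected km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm

from .errors import (DegenerateGeometryError, InconsistentInputError,
                     InvalidArgumentError, NoDataError, UndefinedMMDMError)


@dataclass
class EncounterHistory:
    """Binary detection matrix plus the station geometry behind it."""

    matrix: np.ndarray                 # individuals x occasions, 0/1
    individuals: tuple[str, ...]
    occasions: int
    occasion_nights: list[tuple[int, int]]   # inclusive night ranges
    stations: pd.DataFrame             # station, x_km, y_km
    detections: pd.DataFrame           # the records the matrix was built from

    @property
    def m_t1(self) -> int:
        """Number of distinct individuals ever captured."""
        return self.matrix.shape[0]

    def capture_frequencies(self) -> np.ndarray:
        """f_k = number of individuals captured on exactly k occasions, k=1..t."""
        caps = self.matrix.sum(axis=1).astype(int)
        f = np.zeros(self.occasions, dtype=int)
        for c in caps:
            if c >= 1:
                f[c - 1] += 1
        return f


@dataclass
class PopulationEstimate:
    """Abundance estimate with its uncertainty and capture summary."""

    estimator: str
    n_hat: float
    se: float
    m_t1: int
    occasions: int
    capture_frequencies: np.ndarray
    p_hat: float | None = None
    boundary: bool = False
    details: dict | None = None


@dataclass
class DensityEstimate:
    """Density from an abundance estimate over a buffered station polygon."""

    buffer_kind: str          # "half-mmdm" | "mmdm" | "custom"
    mmdm_km: float | None
    buffer_km: float
    area_km2: float
    density: float            # animals per 100 km2
    interval: tuple[float, float]

    @property
    def density_1dp(self) -> float:
        """Density rounded half-away-from-zero to one decimal (report format)."""
        return round_half_away(self.density, 1)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (5.15 -> 5.2), unlike banker's rounding."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def build_encounter_history(detections: pd.DataFrame,
                            occasion_length_nights: int,
                            stations: pd.DataFrame | None = None,
                            ) -> EncounterHistory:
    """Group detection nights into occasions and build the 0/1 matrix.

    ``detections`` needs columns individual, station, night (1-based) and,
    unless ``stations`` is given, x_km/y_km per record. Nights are grouped
    into consecutive occasions of the requested length starting at night 1;
    the last occasion may be short. X[i, o] = 1 iff individual i was
    detected during occasion o.
    """
    if occasion_length_nights < 1:
        raise InvalidArgumentError("occasion length must be >= 1 night")
    det = detections.copy()
    if stations is None:
        stations = (det[["station", "x_km", "y_km"]]
                    .drop_duplicates("station").reset_index(drop=True))
    unknown = set(det["station"]) - set(stations["station"])
    if unknown:
        raise InconsistentInputError(f"detections reference unknown stations: "
                                     f"{sorted(unknown)}")
    last_night = int(det["night"].max()) if len(det) else occasion_length_nights
    n_occ = int(np.ceil(last_night / occasion_length_nights))
    ranges = [(o * occasion_length_nights + 1,
               min((o + 1) * occasion_length_nights, last_night))
              for o in range(n_occ)]
    individuals = tuple(sorted(det["individual"].unique()))
    mat = np.zeros((len(individuals), n_occ), dtype=int)
    idx = {ind: i for i, ind in enumerate(individuals)}
    occ_of_night = (det["night"].to_numpy(dtype=int) - 1) // occasion_length_nights
    for ind, o in zip(det["individual"], occ_of_night):
        mat[idx[ind], o] = 1
    return EncounterHistory(matrix=mat, individuals=individuals,
                            occasions=n_occ, occasion_nights=ranges,
                            stations=stations, detections=det)


def _m0_loglik(n: float, mt1: int, total_caps: int, t: int) -> float:
    """M0 log-likelihood profiled over p (p̂ = total/(t·N))."""
    p = total_caps / (t * n)
    if p >= 1.0:
        p = 1.0 - 1e-12
    ll = (gammaln(n + 1) - gammaln(n - mt1 + 1)
          + total_caps * np.log(p) + (t * n - total_caps) * np.log1p(-p))
    return float(ll)


def estimate_m0(history: EncounterHistory | np.ndarray) -> PopulationEstimate:
    """Null-model (M0) abundance: constant capture probability.

    Maximizes the integer-relaxed joint likelihood over N (continuous,
    profiled p̂ = total captures/(t·N̂)); SE from the observed information of
    the (N, p) likelihood at the optimum.
    """
    X = history.matrix if isinstance(history, EncounterHistory) else np.asarray(history)
    mt1, t = X.shape
    if t < 2:
        raise InvalidArgumentError("need at least 2 occasions")
    if mt1 < 1:
        raise NoDataError("no individuals captured")
    total = int(X.sum())
    f = _freqs(X)

    if total == mt1 * t:
        # every individual captured on every occasion: boundary N̂ = M_{t+1}
        return PopulationEstimate("M0", float(mt1), 0.0, mt1, t, f,
                                  p_hat=1.0, boundary=True)
    if total == mt1:
        # no recaptures: the likelihood increases in N without bound,
        # so no finite MLE exists
        return PopulationEstimate("M0", float("inf"), float("inf"), mt1, t, f,
                                  p_hat=0.0, boundary=True)

    upper = max(10.0 * mt1, mt1 + 100.0)
    while True:
        res = minimize_scalar(lambda n: -_m0_loglik(n, mt1, total, t),
                              bounds=(mt1, upper), method="bounded",
                              options={"xatol": 1e-8})
        if res.x < upper - 1e-3 or upper > 1e7:
            break
        upper *= 10.0
    n_hat = float(res.x)
    boundary = n_hat <= mt1 + 1e-6
    if boundary:
        n_hat = float(mt1)
    p_hat = total / (t * n_hat)
    se = _m0_se(n_hat, p_hat, mt1, total, t)
    return PopulationEstimate("M0", n_hat, se, mt1, t, f, p_hat=p_hat,
                              boundary=boundary)


def _m0_se(n_hat: float, p_hat: float, mt1: int, total: int, t: int) -> float:
    """Asymptotic SE of N̂ from the observed information of (N, p)."""
    h = max(1e-4 * n_hat, 1e-4)

    def prof(n):
        return _m0_loglik(n, mt1, total, t)

    d2 = (prof(n_hat + h) - 2.0 * prof(n_hat) + prof(n_hat - h)) / h ** 2
    if d2 >= 0:
        # flat or boundary likelihood: fall back to the standard closed form
        q = (1.0 - p_hat) ** t
        denom = (1.0 - q) ** 2 - t * p_hat * (1 - p_hat) ** (t - 1) * (1 - q)
        if denom <= 0:
            return 0.0
        return float(np.sqrt(n_hat * q * (1 - q) / denom))
    return float(np.sqrt(-1.0 / d2))


def _freqs(X: np.ndarray) -> np.ndarray:
    t = X.shape[1]
    caps = X.sum(axis=1).astype(int)
    f = np.zeros(t, dtype=int)
    for c in caps:
        if c >= 1:
            f[c - 1] += 1
    return f


def jackknife_coefficients(t: int, k: int) -> np.ndarray:
    """Burnham–Overton jackknife coefficients a_ik, i = 1..t, for order k.

    N̂_Jk = Σ_i a_ik f_i. The a_ik equal 1 + adjustment for i <= k and 1 for
    i > k, from the published coefficient table (orders 1–5).
    """
    if not 1 <= k <= 5:
        raise InvalidArgumentError("jackknife order must be in 1..5")
    if t < k + 1:
        raise InvalidArgumentError(f"order {k} needs at least {k + 1} occasions")
    a = np.ones(t)
    T = float(t)
    if k == 1:
        a[0] += (T - 1) / T
    elif k == 2:
        a[0] += (2 * T - 3) / T
        a[1] -= (T - 2) ** 2 / (T * (T - 1))
    elif k == 3:
        a[0] += (3 * T - 6) / T
        a[1] -= (3 * T ** 2 - 15 * T + 19) / (T * (T - 1))
        a[2] += (T - 3) ** 3 / (T * (T - 1) * (T - 2))
    elif k == 4:
        a[0] += (4 * T - 10) / T
        a[1] -= (6 * T ** 2 - 36 * T + 55) / (T * (T - 1))
        a[2] += (4 * T ** 3 - 42 * T ** 2 + 148 * T - 175) / (T * (T - 1) * (T - 2))
        a[3] -= (T - 4) ** 4 / (T * (T - 1) * (T - 2) * (T - 3))
    else:
        a[0] += (5 * T - 15) / T
        a[1] -= (10 * T ** 2 - 70 * T + 125) / (T * (T - 1))
        a[2] += (10 * T ** 3 - 120 * T ** 2 + 485 * T - 660) / (T * (T - 1) * (T - 2))
        a[3] -= ((T - 4) ** 5 - (T - 5) ** 5) / (T * (T - 1) * (T - 2) * (T - 3))
        a[4] += (T - 5) ** 5 / (T * (T - 1) * (T - 2) * (T - 3) * (T - 4))
    return a


def estimate_mh_jackknife(history: EncounterHistory | np.ndarray,
                          max_order: int = 5, alpha: float = 0.05,
                          ) -> PopulationEstimate:
    """Heterogeneity-model (Mh) abundance by the Burnham–Overton jackknife.

    Computes N̂_Jk for k = 1..min(max_order, t−1) from capture frequencies.
    Order selection is the standard sequential test on successive
    differences: the first order whose increment to the next is not
    significant at ``alpha`` is selected; if every increment is significant
    the highest computed order is used. Var(N̂_Jk) = Σ a_ik² f_i − N̂_Jk.
    """
    X = history.matrix if isinstance(history, EncounterHistory) else np.asarray(history)
    mt1, t = X.shape
    if t < 2:
        raise InvalidArgumentError("need at least 2 occasions")
    f = _freqs(X)
    if f.sum() == 0:
        raise NoDataError("capture-frequency vector is all zeros")

    orders = list(range(1, min(max_order, t - 1) + 1))
    coeffs = {k: jackknife_coefficients(t, k) for k in orders}
    # raw combinations can dip below M_{t+1} on pathological frequency
    # vectors; the reported estimate is clamped to the observed count
    n_hats = {k: max(float(coeffs[k] @ f), float(mt1)) for k in orders}
    variances = {k: max(float(coeffs[k] ** 2 @ f) - n_hats[k], 0.0)
                 for k in orders}

    selected = orders[-1]
    tests = {}
    for k in orders[:-1]:
        d = coeffs[k + 1] - coeffs[k]
        diff = n_hats[k + 1] - n_hats[k]
        var_diff = float(d ** 2 @ f) - diff ** 2 / mt1 if mt1 > 0 else 0.0
        var_diff = max(var_diff, 0.0) * (mt1 / max(mt1 - 1, 1))
        z = diff / np.sqrt(var_diff) if var_diff > 0 else 0.0
        p = 2.0 * (1.0 - norm.cdf(abs(z)))
        tests[k] = (z, p)
        if p > alpha:
            selected = k
            break
    n_hat = n_hats[selected]
    se = float(np.sqrt(variances[selected]))
    return PopulationEstimate(f"Mh-jackknife-{selected}", n_hat, se, mt1, t, f,
                              details={"orders": n_hats, "variances": variances,
                                       "tests": tests, "selected": selected})


def compute_mmdm(detections: pd.DataFrame) -> float:
    """Mean maximum distance moved among multi-station individuals (km).

    For each individual detected at >= 2 distinct stations, take the maximum
    pairwise Euclidean distance among its stations; MMDM is the mean over
    those individuals. Individuals seen at a single station are excluded;
    if none qualifies the MMDM (and hence density) is undefined.
    """
    maxima = []
    for _, grp in detections.groupby("individual"):
        pts = grp[["station", "x_km", "y_km"]].drop_duplicates("station")
        if len(pts) < 2:
            continue
        xy = pts[["x_km", "y_km"]].to_numpy()
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        maxima.append(float(d.max()))
    if not maxima:
        raise UndefinedMMDMError(
            "no individual was detected at more than one station")
    return float(np.mean(maxima))


def station_hull(stations: pd.DataFrame):
    """Minimum convex polygon of the stations (shapely Polygon)."""
    pts = shapely.multipoints(np.column_stack([stations["x_km"], stations["y_km"]]))
    hull = shapely.convex_hull(pts)
    if hull.geom_type != "Polygon" or hull.area == 0.0:
        raise DegenerateGeometryError(
            "need at least 3 non-collinear stations for a convex polygon")
    return hull


def effective_area(stations: pd.DataFrame, buffer_km: float) -> float:
    """Area (km²) of the station MCP dilated by ``buffer_km``.

    Uses the exact Steiner formula for the dilation of a convex polygon:
    area + perimeter·b + πb² — no discretized circle approximation.
    """
    if buffer_km < 0:
        raise InvalidArgumentError("buffer must be >= 0")
    hull = station_hull(stations)
    return float(hull.area + hull.length * buffer_km + np.pi * buffer_km ** 2)


def density(est: PopulationEstimate, area_km2: float,
            buffer_kind: str = "custom", mmdm_km: float | None = None,
            buffer_km: float = 0.0) -> DensityEstimate:
    """Density D = 100·N̂/area (animals per 100 km²) with an SE interval.

    The interval is 100·(N̂ ± SE)/area, mirroring the asymmetric ranges of
    field report tables; ``density_1dp`` applies one-decimal
    half-away-from-zero rounding for reporting.
    """
    if area_km2 <= 0:
        raise InvalidArgumentError("area must be positive")
    d = 100.0 * est.n_hat / area_km2
    lo = 100.0 * max(est.n_hat - est.se, 0.0) / area_km2
    hi = 100.0 * (est.n_hat + est.se) / area_km2
    return DensityEstimate(buffer_kind=buffer_kind, mmdm_km=mmdm_km,
                           buffer_km=buffer_km, area_km2=float(area_km2),
                           density=float(d), interval=(float(lo), float(hi)))


def density_from_detections(detections: pd.DataFrame, est: PopulationEstimate,
                            stations: pd.DataFrame,
                            buffers: tuple[str, ...] = ("half-mmdm", "mmdm"),
                            ) -> list[DensityEstimate]:
    """½MMDM/MMDM-buffered densities for one survey."""
    mmdm = compute_mmdm(detections)
    out = []
    for kind in buffers:
        b = mmdm / 2.0 if kind == "half-mmdm" else mmdm
        area = effective_area(stations, b)
        out.append(density(est, area, buffer_kind=kind, mmdm_km=mmdm,
                           buffer_km=b))
    return out


def accumulation_curve(detections: pd.DataFrame,
                       n_stations: int | None = None) -> pd.DataFrame:
    """Cumulative distinct individuals vs cumulative trap-nights.

    Returns a night-indexed step series (night, trap_nights, individuals),
    non-decreasing in individuals, plus a ``stabilized_night`` attribute:
    the first night after which no new individual appears.
    """
    if len(detections) == 0:
        out = pd.DataFrame(columns=["night", "trap_nights", "individuals"])
        out.attrs["stabilized_night"] = None
        return out
    if n_stations is None:
        n_stations = detections["station"].nunique()
    first_seen = detections.groupby("individual")["night"].min()
    last_night = int(detections["night"].max())
    nights = np.arange(1, last_night + 1)
    counts = np.array([(first_seen <= n).sum() for n in nights])
    out = pd.DataFrame({"night": nights,
                        "trap_nights": nights * n_stations,
                        "individuals": counts})
    out.attrs["stabilized_night"] = int(first_seen.max())
    return out
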