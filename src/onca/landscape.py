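"""Synthetic landscapes with known ground truth.

Emulates the data context of a predator–prey–habitat study in a Guiana-Shield
type forest block: a stack of gridded environmental layers on 0.5-km cells,
presence-only sightings of a large felid, camera-trap capture–recapture
surveys on station grids, and line-transect prey surveys whose encounter
rates decline with the human footprint index (HFI). Every generator is
deterministic given its seed, and the generating parameters are exposed as a
:class:`TruthModel` so recovery tests can compare estimates against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit
import shapely

from .errors import InfeasibleSampleError, InvalidArgumentError

N_GEOLOGY_CLASSES = 5
N_VEGETATION_CLASSES = 5
N_BIOGEO_CLASSES = 4


@dataclass
class LayerStack:
    """Aligned gridded environmental variables plus validity/sampling masks.

    Continuous layers: rainfall (mm/yr), altitude (m), dem (m), agb (Mg/ha),
    footprint (unitless HFI >= 0). Categorical layers: vegetation, biogeo,
    geology (class ids). The sampling mask marks cells with observer effort
    and is a subset of the validity mask.
    """

    rows: int
    cols: int
    continuous: dict[str, np.ndarray]
    categorical: dict[str, np.ndarray]
    validity: np.ndarray
    sampling: np.ndarray
    cell_km: float = 0.5

    def __post_init__(self) -> None:
        shape = (self.rows, self.cols)
        for name, arr in {**self.continuous, **self.categorical}.items():
            if arr.shape != shape:
                raise InvalidArgumentError(f"layer {name!r} shape {arr.shape} != {shape}")
        if self.validity.shape != shape or self.sampling.shape != shape:
            raise InvalidArgumentError("mask shape mismatch")
        if np.any(self.sampling & ~self.validity):
            raise InvalidArgumentError("sampling mask must be a subset of the validity mask")
        fp = self.continuous.get("footprint")
        if fp is not None and np.any(fp[self.validity] < 0):
            raise InvalidArgumentError("footprint must be >= 0 on valid cells")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def cell_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates (km) of cells; y grows northward from row rows-1."""
        x = (np.asarray(col) + 0.5) * self.cell_km
        y = (self.rows - np.asarray(row) - 0.5) * self.cell_km
        return x, y


@dataclass
class TruthModel:
    """Generating parameters behind a synthetic landscape.

    ``weights`` are the coefficients of the linear+quadratic suitability
    surface on [0,1]-rescaled layers; ``suitability`` is the resulting
    probability-scale surface. ``species`` carries per-species transect
    log-rate intercepts (contacts/km at HFI 0, log scale) and HFI slopes.
    Camera-trap truth: population size per site, half-normal detection scale
    sigma (km), baseline per-occasion detection g0 and the s.d. of the
    individual logit-scale heterogeneity.
    """

    weights: dict[str, float]
    suitability: np.ndarray
    species: pd.DataFrame
    n_population: int = 60
    sigma_km: float = 2.0
    g0: float = 0.3
    het_sd: float = 0.75

    def __post_init__(self) -> None:
        s = self.suitability
        if np.any((s < 0) | (s > 1)):
            raise InvalidArgumentError("suitability must lie in [0, 1]")
        if not (0.0 <= self.g0 < 1.0):
            raise InvalidArgumentError("g0 must lie in [0, 1)")
        if self.sigma_km <= 0:
            raise InvalidArgumentError("sigma_km must be positive")
        if self.n_population < 0:
            raise InvalidArgumentError("population size must be >= 0")


#: Default prey community: two large rodents, three artiodactyls and two
#: large terrestrial frugivorous birds, with adult masses (kg) from the
#: regional mammal/bird literature, baseline kilometric encounter rates
#: (contacts/km at HFI 0, log scale) and negative HFI slopes — birds respond
#: more steeply than mammals, mirroring the field pattern.
DEFAULT_SPECIES = pd.DataFrame(
    [
        # species, group, gregarious, mass_kg, log_rate, hfi_slope, group_size_mean
        ("Myoprocta_acouchy", "mammal", False, 1.0, np.log(0.20), -0.02, 1.0),
        ("Dasyprocta_leporina", "mammal", False, 4.5, np.log(0.45), -0.02, 1.0),
        ("Mazama_nemorivaga", "mammal", False, 15.0, np.log(0.08), -0.03, 1.0),
        ("Mazama_americana", "mammal", False, 30.0, np.log(0.10), -0.03, 1.0),
        ("Pecari_tajacu", "mammal", True, 20.0, np.log(0.06), -0.03, 3.5),
        ("Crax_alector", "bird", False, 3.2, np.log(0.25), -0.08, 1.0),
        ("Psophia_crepitans", "bird", True, 1.3, np.log(0.15), -0.08, 4.0),
    ],
    columns=["species", "group", "gregarious", "mass_kg",
             "log_rate", "hfi_slope", "group_size_mean"],
)


def _smooth_field(rng: np.random.Generator, rows: int, cols: int,
                  sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise (spatially autocorrelated)."""
    z = gaussian_filter(rng.standard_normal((rows, cols)), sigma, mode="reflect")
    return (z - z.mean()) / z.std()


def generate_layers(seed: int, rows: int, cols: int, cell_km: float = 0.5,
                    n_access_lines: int = 3, sampling_frac: float = 0.4) -> LayerStack:
    """Generate a spatially autocorrelated environmental layer stack.

    Continuous layers are affine transforms of Gaussian-smoothed white noise;
    categorical layers are quantile-binned smooth fields; the human footprint
    decays exponentially with distance from randomly placed access lines
    (roads/rivers), and the sampling mask covers the ``sampling_frac`` of
    cells closest to those lines — observer effort concentrates near access.
    """
    if rows < 16 or cols < 16:
        raise InvalidArgumentError("rows and cols must both be >= 16")
    rng = np.random.default_rng(seed)

    rainfall = np.clip(3000 + 600 * _smooth_field(rng, rows, cols, 3.0), 1500, 4500)
    altitude = np.clip(250 + 160 * _smooth_field(rng, rows, cols, 4.0), 0, 800)
    dem = np.clip(altitude + 25 * _smooth_field(rng, rows, cols, 1.2), 0, None)
    agb = np.clip(350 + 60 * _smooth_field(rng, rows, cols, 3.0), 120, 550)

    # Access lines: random point + direction; distance of each cell centre to
    # the nearest line drives both the footprint and the sampling mask.
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    x = (jj + 0.5) * cell_km
    y = (rows - ii - 0.5) * cell_km
    dist = np.full((rows, cols), np.inf)
    for _ in range(max(1, n_access_lines)):
        px, py = rng.uniform(0, cols * cell_km), rng.uniform(0, rows * cell_km)
        theta = rng.uniform(0, np.pi)
        nx, ny = -np.sin(theta), np.cos(theta)  # unit normal of the line
        dist = np.minimum(dist, np.abs((x - px) * nx + (y - py) * ny))
    footprint = np.clip(
        30.0 * np.exp(-dist / 5.0) + 1.5 * _smooth_field(rng, rows, cols, 2.0),
        0.0, None)

    def _classes(sigma: float, k: int) -> np.ndarray:
        f = _smooth_field(rng, rows, cols, sigma)
        edges = np.quantile(f, np.linspace(0, 1, k + 1)[1:-1])
        return np.digitize(f, edges)

    vegetation = _classes(4.0, N_VEGETATION_CLASSES)
    biogeo = _classes(max(rows, cols) / 5.0, N_BIOGEO_CLASSES)
    geology = _classes(6.0, N_GEOLOGY_CLASSES)

    validity = np.ones((rows, cols), dtype=bool)
    cutoff = np.quantile(dist, sampling_frac)
    sampling = (dist <= cutoff) & validity

    return LayerStack(
        rows=rows, cols=cols, cell_km=cell_km,
        continuous={"rainfall": rainfall, "altitude": altitude, "dem": dem,
                    "agb": agb, "footprint": footprint},
        categorical={"vegetation": vegetation, "biogeo": biogeo,
                     "geology": geology},
        validity=validity, sampling=sampling,
    )


def rescale01(arr: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Min–max rescale to [0,1] over the masked cells (constant -> zeros)."""
    vals = arr[mask] if mask is not None else arr
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if hi == lo:
        return np.zeros_like(arr, dtype=float)
    return (arr - lo) / (hi - lo)


#: Coefficients of the default true suitability surface: a linear+quadratic
#: response to rainfall and altitude plus a negative footprint term, on
#: [0,1]-rescaled layers, passed through a logistic link.
DEFAULT_TRUTH_WEIGHTS = {
    "intercept": -1.0,
    "rainfall": 4.0, "rainfall2": -2.0,
    "altitude": 2.0, "altitude2": -2.5,
    "footprint": -3.0,
}


def default_truth(stack: LayerStack, weights: dict[str, float] | None = None,
                  species: pd.DataFrame | None = None, **kwargs) -> TruthModel:
    """Build the TruthModel for a stack from linear+quadratic weights."""
    w = dict(DEFAULT_TRUTH_WEIGHTS if weights is None else weights)
    zr = rescale01(stack.continuous["rainfall"], stack.validity)
    za = rescale01(stack.continuous["altitude"], stack.validity)
    zf = rescale01(stack.continuous["footprint"], stack.validity)
    eta = (w.get("intercept", 0.0)
           + w.get("rainfall", 0.0) * zr + w.get("rainfall2", 0.0) * zr ** 2
           + w.get("altitude", 0.0) * za + w.get("altitude2", 0.0) * za ** 2
           + w.get("footprint", 0.0) * zf)
    suit = expit(eta)
    sp = DEFAULT_SPECIES.copy() if species is None else species.copy()
    return TruthModel(weights=w, suitability=suit, species=sp, **kwargs)


def generate_sightings(stack: LayerStack, truth: TruthModel, n: int,
                       bias: bool = True, seed: int = 0) -> pd.DataFrame:
    """Sample ``n`` distinct presence cells with probability ∝ suitability.

    One record per grid unit. With ``bias=True`` sampling is restricted to
    the sampling mask, emulating the geographic bias of opportunistic
    sighting collation near accessible areas.
    """
    if n < 10:
        raise InvalidArgumentError("n must be >= 10")
    mask = stack.sampling if bias else stack.validity
    weights = np.where(mask, truth.suitability, 0.0).ravel()
    avail = int(np.count_nonzero(weights > 0))
    if n > avail:
        raise InfeasibleSampleError(
            f"requested {n} distinct cells but only {avail} have positive weight")
    rng = np.random.default_rng(seed)
    idx = rng.choice(weights.size, size=n, replace=False, p=weights / weights.sum())
    row, col = np.unravel_index(idx, stack.shape)
    x, y = stack.cell_xy(row, col)
    return pd.DataFrame({"row": row, "col": col, "x_km": x, "y_km": y})


def station_grid(n_side: int = 4, spacing_km: float = 2.5, origin_km: float = 0.0,
                 jitter_km: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Regular camera-station grid (n_side², 2–3 km spacing by default)."""
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
    x = origin_km + xs.ravel() * spacing_km
    y = origin_km + ys.ravel() * spacing_km
    if jitter_km > 0:
        x = x + rng.uniform(-jitter_km, jitter_km, x.size)
        y = y + rng.uniform(-jitter_km, jitter_km, y.size)
    return pd.DataFrame({"station": [f"S{i:02d}" for i in range(x.size)],
                         "x_km": x, "y_km": y})


def _station_region(stations: pd.DataFrame, sigma_km: float):
    pts = shapely.multipoints(np.column_stack([stations["x_km"], stations["y_km"]]))
    return shapely.convex_hull(pts).buffer(2.0 * sigma_km)


def sample_activity_centers(stations: pd.DataFrame, n: int, sigma_km: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Uniform activity centres over the station hull buffered by 2·sigma."""
    region = _station_region(stations, sigma_km)
    minx, miny, maxx, maxy = region.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 64)
        cand = np.column_stack([rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)])
        inside = shapely.contains_xy(region, cand[:, 0], cand[:, 1])
        take = cand[inside][: n - got]
        out[got: got + take.shape[0]] = take
        got += take.shape[0]
    return out


def detection_probabilities(centers: np.ndarray, stations: pd.DataFrame,
                            g0: float, sigma_km: float,
                            eta: np.ndarray | None = None) -> np.ndarray:
    """Per (individual, station) per-occasion detection probabilities.

    Baseline p = g0·exp(−d²/(2σ²)); an individual's heterogeneity term
    ``eta`` shifts that baseline on the logit scale.
    """
    sx = stations["x_km"].to_numpy()
    sy = stations["y_km"].to_numpy()
    d2 = ((centers[:, 0, None] - sx[None, :]) ** 2
          + (centers[:, 1, None] - sy[None, :]) ** 2)
    base = g0 * np.exp(-d2 / (2.0 * sigma_km ** 2))
    if eta is None or np.all(eta == 0):
        return base
    with np.errstate(divide="ignore"):
        lo = logit(np.clip(base, 0.0, 1.0 - 1e-12))
    return expit(lo + eta[:, None])


def simulate_cmr(truth: TruthModel, stations: pd.DataFrame, occasions: int,
                 seed: int = 0, n_individuals: int | None = None,
                 centers: np.ndarray | None = None) -> pd.DataFrame:
    """Simulate closed-population camera-trap detections.

    Activity centres are uniform over the station minimum convex polygon
    buffered by 2σ; detection of individual i at station s on each occasion
    is Bernoulli with probability g0·exp(−d²/2σ²) shifted by the individual's
    logit-normal heterogeneity term. Returns one record per (individual,
    station, occasion) detection, with station coordinates and a ``night``
    column equal to the occasion index.
    """
    if len(stations) < 4:
        raise InvalidArgumentError("need at least 4 stations")
    if occasions < 2:
        raise InvalidArgumentError("need at least 2 occasions")
    n = truth.n_population if n_individuals is None else n_individuals
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = sample_activity_centers(stations, n, truth.sigma_km, rng)
    else:
        centers = np.asarray(centers, dtype=float)
        n = centers.shape[0]
    eta = (rng.normal(0.0, truth.het_sd, n) if truth.het_sd > 0
           else np.zeros(n))
    p = detection_probabilities(centers, stations, truth.g0, truth.sigma_km, eta)
    det = rng.random((n, len(stations), occasions)) < p[:, :, None]
    ind, st, occ = np.nonzero(det)
    out = pd.DataFrame({
        "individual": [f"J{i:03d}" for i in ind],
        "station": stations["station"].to_numpy()[st],
        "occasion": occ + 1,
        "night": occ + 1,
        "x_km": stations["x_km"].to_numpy()[st],
        "y_km": stations["y_km"].to_numpy()[st],
    })
    return out.sort_values(["individual", "occasion", "station"], ignore_index=True)


def simulate_transects(stack: LayerStack, truth: TruthModel, sites: int = 30,
                       km_per_site: float = 97.0, seed: int = 0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate line-transect surveys at random valid cells.

    Per species, contacts ~ Poisson(L·exp(a + b·HFI_site)); gregarious
    species draw a group size >= 1 per contact (1 + Poisson). Contact
    positions are uniform along the cumulative transect, enabling
    effort-truncation analyses. Returns ``(contacts, site_table)``.
    """
    if km_per_site < 0:
        raise InvalidArgumentError("km_per_site must be >= 0")
    rng = np.random.default_rng(seed)
    valid_idx = np.flatnonzero(stack.validity.ravel())
    cells = rng.choice(valid_idx, size=sites, replace=False)
    row, col = np.unravel_index(cells, stack.shape)
    hfi = stack.continuous["footprint"][row, col]
    suit = truth.suitability[row, col]
    site_ids = [f"T{i:02d}" for i in range(sites)]
    site_table = pd.DataFrame({
        "site": site_ids, "row": row, "col": col,
        "total_km": km_per_site, "hfi": hfi, "suitability": suit,
    })
    records = []
    for _, sp in truth.species.iterrows():
        lam = km_per_site * np.exp(sp.log_rate + sp.hfi_slope * hfi)
        counts = rng.poisson(lam)
        for s, c in zip(site_ids, counts):
            if c == 0:
                continue
            pos = np.sort(rng.uniform(0.0, km_per_site, c))
            if sp.gregarious:
                gs = 1 + rng.poisson(max(sp.group_size_mean - 1.0, 0.0), c)
            else:
                gs = np.ones(c, dtype=int)
            records.append(pd.DataFrame({
                "site": s, "species": sp.species, "group_size": gs,
                "km_position": pos, "total_km": km_per_site,
            }))
    contacts = (pd.concat(records, ignore_index=True) if records else
                pd.DataFrame(columns=["site", "species", "group_size",
                                      "km_position", "total_km"]))
    return contacts, site_table


def synthetic_waveform(canopy_height_m: float, slope_spread_m: float = 0.0,
                       step_m: float = 0.3, noise_sd: float = 1.0,
                       amplitude: float = 60.0, seed: int = 0,
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Synthetic full-waveform LiDAR return over a forest footprint.

    The signal occupies elevations [−s/2, h + s/2] (h = canopy height,
    s = slope-induced spread) with a canopy peak near the top and a ground
    peak near the bottom, over Gaussian sensor noise. Returns
    ``(elevation, intensity, true_extent)`` with true_extent = h + s.
    """
    if canopy_height_m < 0 or slope_spread_m < 0:
        raise InvalidArgumentError("height and spread must be >= 0")
    rng = np.random.default_rng(seed)
    top = canopy_height_m + slope_spread_m / 2.0
    bottom = -slope_spread_m / 2.0
    elev = np.arange(bottom - 15.0, top + 15.0 + step_m, step_m)
    inside = (elev >= bottom) & (elev <= top)
    span = max(top - bottom, step_m)
    canopy_peak = np.exp(-0.5 * ((elev - (top - 0.15 * span)) / (0.12 * span)) ** 2)
    ground_peak = np.exp(-0.5 * ((elev - (bottom + 0.08 * span)) / (0.06 * span)) ** 2)
    intensity = amplitude * inside * (0.35 + canopy_peak + 0.8 * ground_peak)
    intensity = intensity + rng.normal(0.0, noise_sd, elev.size)
    return elev, intensity, top - bottom
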