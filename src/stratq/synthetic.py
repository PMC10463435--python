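"""Synthetic study generator with known ground truth.

Emulates the study's inputs — a lattice of ~122 Chinese cities split into
north/south at 33°N, city-level annual-mean pollutant fields (PM2.5, PM10,
SO2, O3, NO2) with region-specific marginals, and ~16,000 individual
anthropometric records — so the whole prevalence → autocorrelation →
Geodetector pipeline can be exercised against analytically known targets:

* pollutant fields are log-Gaussian with exponential distance-decay
  correlation exp(-d/range), moment-matched per region, so they are
  positive, spatially autocorrelated, and hit the configured mean;
* stratified responses are drawn as stratum mean + iid noise, so the
  theoretical q = Var_between / (Var_between + sigma_w^2) is exact;
* individual BMI is Gaussian per age group (optionally shifted by region
  and by a pollutant-stratum coupling), so city prevalences inherit a
  known spatial and stratified structure.

All draws come from named substreams of one integer seed: identical
(config, seed) reproduces identical tables byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import substream
from .weights import great_circle_km
from .geodetector import StrataAssignment, discretize

__all__ = [
    "PollutantSpec",
    "StrataEffect",
    "BMIGroupModel",
    "Coupling",
    "SyntheticConfig",
    "generate_city_lattice",
    "generate_pollutants",
    "generate_response",
    "generate_individuals",
    "strata_means_for_q",
    "DEFAULT_POLLUTANT_SPECS",
]

POLLUTANTS = ("pm25", "pm10", "so2", "o3", "no2")


@dataclass
class PollutantSpec:
    """Target marginal moments (µg/m³) per region and a spatial range (km)."""

    mean_north: float
    mean_south: float
    sd_north: float
    sd_south: float
    corr_range_km: float = 500.0

    def validate(self, name: str) -> None:
        if self.mean_north <= 0 or self.mean_south <= 0:
            raise ValueError(f"{name}: target means must be positive")
        if self.sd_north < 0 or self.sd_south < 0 or self.corr_range_km < 0:
            raise ValueError(f"{name}: dispersions and range must be nonnegative")


# Region-wise annual-mean concentrations of the five monitored pollutants,
# with dispersions back-solved from 5%-95% spans under normality
# ((q95 - q5) / 3.29).
DEFAULT_POLLUTANT_SPECS: dict[str, PollutantSpec] = {
    "pm25": PollutantSpec(56.21, 43.50, 18.1, 11.7),
    "pm10": PollutantSpec(104.52, 69.77, 30.2, 17.7),
    "so2": PollutantSpec(31.56, 18.84, 12.3, 7.9),
    "o3": PollutantSpec(62.09, 57.50, 9.6, 10.5),
    "no2": PollutantSpec(33.86, 26.72, 8.3, 8.3),
}


@dataclass
class StrataEffect:
    """Per-stratum response means and a common within-stratum sd."""

    means: list
    within_sd: float

    def validate(self) -> None:
        if self.within_sd < 0:
            raise ValueError("within-stratum sd must be nonnegative")
        if len(self.means) < 1:
            raise ValueError("at least one stratum mean is required")


@dataclass
class BMIGroupModel:
    mean: float
    sd: float

    def validate(self, name: str) -> None:
        if self.sd < 0:
            raise ValueError(f"bmi_model[{name}]: sd must be nonnegative")


@dataclass
class Coupling:
    """Optional exposure→response coupling: the chosen pollutant is cut
    into quantile strata and each stratum shifts the city's BMI mean."""

    pollutant: str = "so2"
    n_strata: int = 5
    bmi_shifts: list = field(default_factory=lambda: [-1.0, -0.5, 0.0, 0.5, 1.0])

    def validate(self) -> None:
        if self.pollutant not in POLLUTANTS:
            raise ValueError(f"unknown pollutant {self.pollutant!r}")
        if len(self.bmi_shifts) != self.n_strata:
            raise ValueError("bmi_shifts must have one entry per stratum")


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic study.

    Defaults reproduce the study's scale: 122 cities over mainland-China
    extents split at 33°N (a flat-latitude proxy for the Qinling–Huaihe
    line), 16,171 individuals, 49.1% middle-aged, 53.7% female, and the
    published region-wise pollutant marginals.
    """

    n_cities: int = 122
    n_individuals: int = 16171
    allocation: str = "equal"  # or "multinomial"
    bbox: tuple = (74.0, 18.0, 134.0, 53.0)  # lon_min, lat_min, lon_max, lat_max
    region_split_latitude: float = 33.0
    pollutant_specs: dict = field(
        default_factory=lambda: {k: PollutantSpec(**asdict(v))
                                 for k, v in DEFAULT_POLLUTANT_SPECS.items()})
    strata_effect: StrataEffect | None = None
    bmi_model: dict = field(default_factory=lambda: {
        "middle_aged": BMIGroupModel(24.0, 3.5),
        "elderly": BMIGroupModel(23.4, 3.5),
    })
    region_bmi_shift: dict = field(default_factory=lambda: {"north": 0.7, "south": -0.7})
    coupling: Coupling | None = None
    prop_middle_aged: float = 0.491
    prop_female: float = 0.537
    seed: int = 0

    def validate(self) -> None:
        if self.n_cities < 0:
            raise ValueError("n_cities must be nonnegative")
        lon0, lat0, lon1, lat1 = self.bbox
        if lon0 >= lon1 or lat0 >= lat1:
            raise ValueError(f"invalid bbox {self.bbox}: min must be < max")
        if not (lat0 <= self.region_split_latitude <= lat1):
            raise ValueError("region_split_latitude must lie inside the bbox")
        if self.allocation not in ("equal", "multinomial"):
            raise ValueError(f"unknown allocation {self.allocation!r}")
        if not (0 <= self.prop_middle_aged <= 1 and 0 <= self.prop_female <= 1):
            raise ValueError("group proportions must lie in [0, 1]")
        for name, spec in self.pollutant_specs.items():
            spec.validate(name)
        for name, m in self.bmi_model.items():
            m.validate(name)
        if self.strata_effect is not None:
            self.strata_effect.validate()
        if self.coupling is not None:
            self.coupling.validate()

    # --- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["bbox"] = list(self.bbox)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "bbox" in d:
            d["bbox"] = tuple(d["bbox"])
        if "pollutant_specs" in d:
            d["pollutant_specs"] = {k: PollutantSpec(**v) if isinstance(v, dict) else v
                                    for k, v in d["pollutant_specs"].items()}
        if d.get("strata_effect") is not None and isinstance(d["strata_effect"], dict):
            d["strata_effect"] = StrataEffect(**d["strata_effect"])
        if "bmi_model" in d:
            d["bmi_model"] = {k: BMIGroupModel(**v) if isinstance(v, dict) else v
                              for k, v in d["bmi_model"].items()}
        if d.get("coupling") is not None and isinstance(d["coupling"], dict):
            d["coupling"] = Coupling(**d["coupling"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_city_lattice(config: SyntheticConfig) -> pd.DataFrame:
    """City centroids uniform over the bbox; region = north iff
    latitude >= the split latitude."""
    config.validate()
    rng = substream(config.seed, "cities")
    n = config.n_cities
    lon0, lat0, lon1, lat1 = config.bbox
    lon = rng.uniform(lon0, lon1, n)
    lat = rng.uniform(lat0, lat1, n)
    region = np.where(lat >= config.region_split_latitude, "north", "south")
    return pd.DataFrame({
        "city_id": [f"C{i:04d}" for i in range(n)],
        "lon": lon, "lat": lat, "region": region.astype(object) if n else region,
    })


def _log_gaussian_field(dist_km: np.ndarray, mean: np.ndarray, sd: np.ndarray,
                        corr_range: float, rng: np.random.Generator) -> np.ndarray:
    """Positive field with target mean/sd and exp(-d/range) correlation.

    A standard Gaussian field z with the exponential correlogram is mapped
    through a moment-matched lognormal: mu and s solve
    E exp(mu + s z) = mean, Var = sd^2.
    """
    n = dist_km.shape[0]
    if corr_range > 0:
        corr = np.exp(-dist_km / corr_range)
        corr[np.diag_indices(n)] = 1.0 + 1e-9  # jitter for Cholesky
        z = np.linalg.cholesky(corr) @ rng.standard_normal(n)
    else:
        z = rng.standard_normal(n)
    s2 = np.log1p(sd ** 2 / mean ** 2)
    mu = np.log(mean) - s2 / 2.0
    return np.exp(mu + np.sqrt(s2) * z)


def generate_pollutants(cities: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Attach the five pollutant columns to a city table.

    Each pollutant is one spatially correlated field over all cities with
    region-specific target mean/sd, so the north/south marginal contrast
    and the spatial autocorrelation are both present.
    """
    config.validate()
    if cities.empty:
        raise ValueError("city table is empty")
    out = cities.copy()
    coords = out[["lon", "lat"]].to_numpy()
    dist = great_circle_km(coords)
    north = (out["region"] == "north").to_numpy()
    for name in POLLUTANTS:
        spec = config.pollutant_specs[name]
        rng = substream(config.seed, f"pollutant:{name}")
        mean = np.where(north, spec.mean_north, spec.mean_south)
        sd = np.where(north, spec.sd_north, spec.sd_south)
        out[name] = _log_gaussian_field(dist, mean, sd, spec.corr_range_km, rng)
    return out


@dataclass
class ResponseDraw:
    """A stratified response draw with its analytically known q."""

    values: np.ndarray
    theoretical_q: float
    clipped: bool
    n_clipped: int


def strata_means_for_q(target_q: float, within_sd: float, L: int = 5,
                       center: float = 0.5) -> list:
    """Equally spaced stratum means achieving a target theoretical q
    (for equal-size strata): Var_between = q/(1-q) * within_sd^2."""
    if not (0 <= target_q < 1):
        raise ValueError("target q must lie in [0, 1)")
    pattern = np.arange(L) - (L - 1) / 2.0
    var_b = target_q / (1.0 - target_q) * within_sd ** 2
    scale = np.sqrt(var_b / pattern.var()) if pattern.var() > 0 else 0.0
    return list(center + scale * pattern)


def generate_response(cities: pd.DataFrame, strata: StrataAssignment,
                      strata_effect: StrataEffect, seed: int,
                      clip_to_unit: bool = False) -> ResponseDraw:
    """Stratified response: stratum mean + iid Gaussian noise.

    The attached theoretical q is Var_between / (Var_between + sigma_w^2)
    with Var_between the stratum-size-weighted population variance of the
    configured means.  Clipping to [0, 1] (prevalence mode) is off by
    default because it biases q; when on, the flag and count are recorded.
    """
    strata_effect.validate()
    n = len(cities)
    if len(strata) != n:
        raise ValueError("every city needs a stratum assignment")
    means = np.asarray(strata_effect.means, dtype=float)
    if strata.L > len(means):
        raise ValueError(f"stratum {strata.L} referenced but only "
                         f"{len(means)} means configured")
    rng = substream(seed, "response")
    mu = means[strata.labels - 1]
    values = mu + rng.normal(0.0, strata_effect.within_sd, n)

    n_h = strata.counts
    m_used = means[:strata.L]
    mbar = np.average(m_used, weights=n_h)
    var_b = np.average((m_used - mbar) ** 2, weights=n_h)
    denom = var_b + strata_effect.within_sd ** 2
    q_theo = 1.0 if denom == 0 else float(var_b / denom)
    if var_b == 0:
        q_theo = 0.0

    n_clipped = 0
    if clip_to_unit:
        n_clipped = int(((values < 0) | (values > 1)).sum())
        values = np.clip(values, 0.0, 1.0)
    return ResponseDraw(values=values, theoretical_q=q_theo,
                        clipped=clip_to_unit, n_clipped=n_clipped)


def _allocate(n_total: int, n_cities: int, allocation: str,
              rng: np.random.Generator) -> np.ndarray:
    if allocation == "multinomial":
        return rng.multinomial(n_total, np.full(n_cities, 1.0 / n_cities))
    counts = np.full(n_cities, n_total // n_cities)
    counts[: n_total % n_cities] += 1
    return counts


def generate_individuals(cities: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Individual records (id, city_id, age, sex, height_cm, weight_kg).

    Age group and sex are Bernoulli with the configured proportions; ages
    are uniform within [45, 60) / [60, 85); height is Gaussian by sex and
    weight is derived from a Gaussian BMI, whose mean may be shifted by
    the city's region and by the pollutant-stratum coupling.
    """
    config.validate()
    if cities.empty:
        raise ValueError("city table is empty")
    rng = substream(config.seed, "individuals")
    n = config.n_individuals
    counts = _allocate(n, len(cities), config.allocation, rng)

    city_shift = np.zeros(len(cities))
    if config.region_bmi_shift:
        city_shift += np.array([config.region_bmi_shift.get(r, 0.0)
                                for r in cities["region"]])
    if config.coupling is not None:
        c = config.coupling
        if c.pollutant not in cities.columns:
            raise ValueError(f"coupling pollutant {c.pollutant!r} not in city table; "
                             "run generate_pollutants first")
        strata = discretize(cities[c.pollutant].to_numpy(), "quantile", c.n_strata)
        shifts = np.asarray(c.bmi_shifts, dtype=float)[:strata.L]
        city_shift += shifts[strata.labels - 1]

    city_idx = np.repeat(np.arange(len(cities)), counts)
    rng.shuffle(city_idx)

    is_middle = rng.random(n) < config.prop_middle_aged
    age = np.where(is_middle, rng.uniform(45.0, 60.0, n), rng.uniform(60.0, 85.0, n))
    sex = np.where(rng.random(n) < config.prop_female, "female", "male")
    height = np.where(sex == "female", rng.normal(157.0, 6.0, n),
                      rng.normal(168.0, 6.5, n))
    height = np.clip(height, 120.0, 210.0)

    bmi = np.empty(n)
    for group, mask in (("middle_aged", is_middle), ("elderly", ~is_middle)):
        m = config.bmi_model[group]
        bmi[mask] = rng.normal(m.mean, m.sd, int(mask.sum()))
    bmi += city_shift[city_idx]
    bmi = np.clip(bmi, 12.0, 60.0)
    weight = bmi * (height / 100.0) ** 2

    return pd.DataFrame({
        "id": [f"I{i:06d}" for i in range(n)],
        "city_id": cities["city_id"].to_numpy()[city_idx],
        "age": np.round(age, 1),
        "sex": sex.astype(object),
        "height_cm": np.round(height, 1),
        "weight_kg": np.round(weight, 2),
    })
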