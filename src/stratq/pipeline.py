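"""End-to-end orchestration: simulate → prevalence → autocorrelation →
Geodetector, with a reproducible report bundle.

`run_full` emits, per region × age group, the study's table shapes:

* ``prevalence_summary.csv`` — 5%/50%/95% quantiles and city-unweighted
  mean of overweight prevalence;
* ``moran.csv`` — global Moran's I, Z and p per age group;
* ``gistar.geojson`` / ``gistar.csv`` — per-city Gi* z-scores and
  hot/cold-spot classes;
* ``factor_q.csv`` — q per pollutant with a/b significance markers at
  0.05/0.01;
* ``interactions.csv`` and per-cell interaction matrices;
* ``manifest.json`` — config, seed, library versions and warnings, enough
  to reproduce every number in the bundle.
"""

from __future__ import annotations

import json
import logging
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .autocorr import Moran, GiStar
from .geodetector import GeoDetector
from .io import write_geojson_points
from .prevalence import aggregate_prevalence
from .synthetic import (SyntheticConfig, generate_city_lattice,
                        generate_pollutants, generate_individuals, POLLUTANTS)
from .weights import build_weights

__all__ = ["RunConfig", "ReportBundle", "run_full", "summarize_prevalence"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable recipe for one pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    individuals_csv: str | None = None   # measured-data mode
    cities_csv: str | None = None
    weights_scheme: str = "knn"
    knn_k: int = 5
    distance_threshold_km: float | None = None
    discretize_method: str = "quantile"
    n_strata: int = 5
    moran_inference: str = "randomization"
    n_perm: int = 999
    significance_levels: tuple = (0.05, 0.01)
    include_obese: bool = True
    seed: int = 0
    out_dir: str = "stratq_out"

    def validate(self) -> None:
        for lvl in self.significance_levels:
            if not (0.0 < lvl < 1.0):
                raise ValueError("significance levels must lie strictly in (0, 1)")
        for p in (self.individuals_csv, self.cities_csv):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        self.synthetic.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        d["significance_levels"] = list(self.significance_levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        if "significance_levels" in d:
            d["significance_levels"] = tuple(d["significance_levels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def summarize_prevalence(city_prev: pd.DataFrame) -> pd.DataFrame:
    """Quantile summary of city-level prevalence per region × age group.

    Returns columns region, age_group, n_cities, p5, p50, p95, mean with
    linear-interpolation percentiles and the city-unweighted mean; empty
    cells are omitted with a warning.
    """
    if city_prev.empty:
        raise ValueError("no city prevalence rows to summarize")
    rows = []
    for (region, group), sub in city_prev.groupby(["region", "age_group"]):
        if sub.empty:  # pragma: no cover - groupby never yields empty groups
            _warnings.warn(f"empty cell {region}/{group} omitted")
            continue
        p = sub["prevalence"].to_numpy()
        rows.append({"region": region, "age_group": group, "n_cities": len(p),
                     "p5": np.percentile(p, 5), "p50": np.percentile(p, 50),
                     "p95": np.percentile(p, 95), "mean": p.mean()})
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """In-memory results of a full run (everything also lands on disk)."""

    cities: pd.DataFrame
    individuals: pd.DataFrame | None
    city_prevalence: pd.DataFrame
    prevalence_summary: pd.DataFrame
    moran: pd.DataFrame
    gistar: pd.DataFrame
    factor_q: pd.DataFrame
    interactions: pd.DataFrame
    manifest: dict


def _library_versions() -> dict:
    import scipy

    return {"stratq": _pkg_version, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


def _stage(manifest: dict, name: str, **info) -> None:
    logger.info("stage %s: %s", name, info)
    manifest["stages"].append({"stage": name, **info})


def run_full(config: RunConfig) -> ReportBundle:
    """Run the whole pipeline and write the report bundle to
    ``config.out_dir``.  Deterministic for a fixed config."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed,
                      "library_versions": _library_versions(),
                      "stages": [], "warnings": []}

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")

        # --- stage 1: inputs ---------------------------------------------
        if config.cities_csv is not None:
            cities = pd.read_csv(config.cities_csv)
            _stage(manifest, "load_cities", n=len(cities), path=config.cities_csv)
        else:
            syn = config.synthetic
            cities = generate_pollutants(generate_city_lattice(syn), syn)
            _stage(manifest, "simulate_cities", n=len(cities))
        if config.individuals_csv is not None:
            individuals = pd.read_csv(config.individuals_csv)
            _stage(manifest, "load_individuals", n=len(individuals))
        else:
            individuals = generate_individuals(cities, config.synthetic)
            _stage(manifest, "simulate_individuals", n=len(individuals))

        # --- stage 2: prevalence -------------------------------------------
        prev = aggregate_prevalence(individuals, include_obese=config.include_obese)
        prev = prev.merge(cities[["city_id", "region"]], on="city_id", how="left")
        summary = summarize_prevalence(prev)
        _stage(manifest, "prevalence", cells=len(prev))

        # wide prevalence per city for the spatial stages
        wide = prev.pivot(index="city_id", columns="age_group",
                          values="prevalence").reset_index()
        wide.columns.name = None
        city_table = cities.merge(wide, on="city_id", how="left")
        for col in ("middle_aged", "elderly"):
            if col not in city_table.columns:
                city_table[col] = np.nan

        # --- stage 3: spatial autocorrelation ------------------------------
        w = build_weights(city_table[["lon", "lat"]].to_numpy(),
                          scheme=config.weights_scheme, k=config.knn_k,
                          threshold=config.distance_threshold_km,
                          ids=list(city_table["city_id"]))
        w.to_gal(out / "weights.gal")
        moran_rows, gi_frames = [], []
        for group in ("middle_aged", "elderly"):
            y = city_table[group].to_numpy()
            ok = np.isfinite(y)
            if ok.sum() < 4:
                _warnings.warn(f"too few cities with {group} prevalence; skipped")
                continue
            sub = city_table[ok].reset_index(drop=True)
            w_g = (w if ok.all() else
                   build_weights(sub[["lon", "lat"]].to_numpy(),
                                 scheme=config.weights_scheme, k=config.knn_k,
                                 threshold=config.distance_threshold_km,
                                 ids=list(sub["city_id"])))
            mres = Moran(y[ok], w_g).fit(inference=config.moran_inference,
                                         n_perm=config.n_perm, seed=config.seed)
            moran_rows.append({"age_group": group, "I": mres.I,
                               "expected": mres.expected, "z": mres.z,
                               "p": mres.p, "n": mres.n})
            g = GiStar(y[ok], w_g).fit()
            gi = sub[["city_id", "lon", "lat", "region"]].copy()
            gi["age_group"] = group
            gi["prevalence"] = y[ok]
            gi["G"] = g.raw
            gi["z"] = g.z
            gi["hotspot"] = g.classes
            gi_frames.append(gi)
        moran = pd.DataFrame(moran_rows)
        gistar = pd.concat(gi_frames, ignore_index=True)
        _stage(manifest, "autocorrelation", groups=len(moran_rows))

        # --- stage 4: Geodetector ------------------------------------------
        fq_rows, int_frames = [], []
        for (region, group), sub in gistar.groupby(["region", "age_group"]):
            merged = sub.merge(cities[["city_id", *POLLUTANTS]], on="city_id")
            if len(merged) <= config.n_strata * 2:
                _warnings.warn(f"cell {region}/{group} too small for the detector; skipped")
                continue
            gd = GeoDetector.from_dataframe(merged, response="prevalence",
                                            factors=list(POLLUTANTS))
            res = gd.fit(method=config.discretize_method, n_strata=config.n_strata,
                         seed=config.seed)
            ft = res.factor_table(levels=config.significance_levels)
            for _, r in ft.iterrows():
                fq_rows.append({"region": region, "age_group": group, **r.to_dict()})
            it = res.interaction_table()
            it.insert(0, "region", region)
            it.insert(1, "age_group", group)
            int_frames.append(it)
            res.interaction_matrix().to_csv(
                out / f"interaction_matrix_{region}_{group}.csv")
        factor_q_table = pd.DataFrame(fq_rows)
        interactions = (pd.concat(int_frames, ignore_index=True)
                        if int_frames else pd.DataFrame())
        _stage(manifest, "geodetector", cells=len(int_frames))

        manifest["warnings"] = [str(c.message) for c in caught]

    # --- stage 5: artifacts ------------------------------------------------
    cities.to_csv(out / "cities.csv", index=False)
    write_geojson_points(city_table, out / "cities.geojson")
    if individuals is not None:
        individuals.to_csv(out / "individuals.csv", index=False)
    prev.to_csv(out / "city_prevalence.csv", index=False)
    summary.to_csv(out / "prevalence_summary.csv", index=False)
    moran.to_csv(out / "moran.csv", index=False)
    gistar.to_csv(out / "gistar.csv", index=False)
    write_geojson_points(gistar, out / "gistar.geojson")
    factor_q_table.to_csv(out / "factor_q.csv", index=False)
    interactions.to_csv(out / "interactions.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")

    return ReportBundle(cities=cities, individuals=individuals,
                        city_prevalence=prev, prevalence_summary=summary,
                        moran=moran, gistar=gistar, factor_q=factor_q_table,
                        interactions=interactions, manifest=manifest)
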