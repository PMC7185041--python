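"""Synthetic constant-effort capture data with known ground truth.

Generates the three inputs the pipeline consumes — a capture CSV, an EVI
cell CSV and a station habitat CSV — by running the analysis model forward:
station greenness follows a reclamation trajectory, each species gets a true
intercept and EVI slope drawn from the community hyperdistribution, each
simulated adult's true age class is a Bernoulli draw from the logit model,
and the observation layer adds symmetric SY/ASY misclassification,
masking to the indeterminate AHY class, and within- and between-year
recaptures with independent re-determinations. The realised truth (species
effects, every bird's true age, every determination's error flag, true
station-year EVI) is returned alongside, so any estimator in the pipeline
can be scored against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults are the "paper-like" scenario: a 35-station (15 natural, 15
    disturbed, 5 reclaimed), 6-year, 29-species community producing on the
    order of 13,000 adult bird-years, community mean yearling proportion
    around 0.4 (``mu_alpha`` = logit 0.407 ~ -0.38), EVI slope
    hyperdistribution Normal(-1.29, 1), an AHY-masking rate matching an
    11.8% indeterminate share, and a per-determination misclassification
    rate of 0.0423, the rate at which two independent determinations of the
    same bird disagree 2e(1-e) = 8.1% of the time.
    """

    name: str = "paper-like"
    # stations and years
    n_natural: int = 15
    n_disturbed: int = 15
    n_reclaimed: int = 5
    first_year: int = 2011
    last_year: int = 2016
    # community
    n_species: int = 29
    mu_alpha: float = -0.38
    sigma_alpha: float = 0.5
    mu_beta: float = -1.29
    sigma_beta: float = 1.0
    # abundance: per-species base Poisson mean per station-year is
    # lognormal(capture_log_mean, capture_log_sd); the log-linear tilt in
    # centered EVI gives species a habitat preference (sign = preferred end)
    capture_log_mean: float = 0.40
    capture_log_sd: float = 0.8
    abundance_tilt_sd: float = 2.0
    # observation process
    misclass_rate: float = 0.0423
    ahy_mask_rate: float = 0.118
    hy_rate: float = 0.3
    recapture_within: float = 0.35
    recapture_between: float = 0.085
    # EVI trajectory
    evi_natural_mean: float = 0.55
    evi_station_sd: float = 0.03
    evi_disturbed_min: float = 0.30
    parity_years: float = 20.0
    evi_obs_sd: float = 0.015
    evi_cell_sd: float = 0.05
    seed: int | None = None

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.last_year + 1))

    @property
    def n_stations(self) -> int:
        return self.n_natural + self.n_disturbed + self.n_reclaimed

    def validate(self) -> None:
        probs = {"misclass_rate": self.misclass_rate,
                 "ahy_mask_rate": self.ahy_mask_rate,
                 "recapture_between": self.recapture_between}
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must be a probability, got {v}")
        rates = {"recapture_within": self.recapture_within,
                 "hy_rate": self.hy_rate,
                 "abundance_tilt_sd": self.abundance_tilt_sd,
                 "evi_station_sd": self.evi_station_sd,
                 "evi_obs_sd": self.evi_obs_sd,
                 "evi_cell_sd": self.evi_cell_sd,
                 "sigma_alpha": self.sigma_alpha,
                 "sigma_beta": self.sigma_beta}
        for k, v in rates.items():
            if v < 0:
                raise ValueError(f"{k} must be >= 0, got {v}")
        if self.last_year < self.first_year:
            raise ValueError("last_year before first_year")
        if min(self.n_species, self.n_natural, self.n_reclaimed) < 1:
            raise ValueError("need >= 1 species, natural and reclaimed "
                             "station")
        if self.parity_years <= 0:
            raise ValueError("parity_years must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def scenario_presets() -> dict[str, SimConfig]:
    """Named study conditions.

    - ``paper-like``: the defaults above.
    - ``null``: no habitat effect on age structure (mu_beta = 0 and
      sigma_beta = 0, so every species slope is exactly zero).
    - ``error-free``: perfect aging (no misclassification, no AHY masking).
    - ``high-missingness``: a third of bird-years left indeterminate.
    - ``smoke``: a miniature community (6 species, 10 stations, 2 years)
      for fast end-to-end checks.
    """
    presets = {
        "paper-like": SimConfig(),
        "null": SimConfig(name="null", mu_beta=0.0, sigma_beta=0.0),
        "error-free": SimConfig(name="error-free", misclass_rate=0.0,
                                ahy_mask_rate=0.0),
        "high-missingness": SimConfig(name="high-missingness",
                                      ahy_mask_rate=0.35),
        "smoke": SimConfig(name="smoke", n_natural=4, n_disturbed=4,
                           n_reclaimed=2, n_species=6, first_year=2012,
                           last_year=2013, capture_log_mean=0.3),
    }
    for cfg in presets.values():
        cfg.validate()
    return presets


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    config: SimConfig
    species_codes: list[str]
    alpha: np.ndarray
    beta: np.ndarray
    lambda0: np.ndarray
    tilt: np.ndarray
    stations: pd.DataFrame      #: station_id, station_class, pct_natural, ...
    evi: pd.DataFrame           #: station_id, year, evi_true, evi_centered
    evi_center: float = np.nan
    birds: pd.DataFrame | None = None   #: one row per adult bird-year
    determinations: pd.DataFrame | None = None  #: one row per handling

    @property
    def n_adult_bird_years(self) -> int:
        return 0 if self.birds is None else len(self.birds)

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "species_codes": self.species_codes,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "lambda0": self.lambda0.tolist(),
            "tilt": self.tilt.tolist(),
            "evi_center": self.evi_center,
            "stations": self.stations.to_dict(orient="records"),
            "evi": self.evi.to_dict(orient="records"),
            "n_adult_bird_years": self.n_adult_bird_years,
            "birds": (None if self.birds is None
                      else self.birds.to_dict(orient="records")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _station_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_natural):
        rows.append({"station_id": f"N{i+1:02d}", "station_class": "natural",
                     "pct_natural": float(rng.uniform(91, 99)),
                     "reclamation_start_year": np.nan})
    for i in range(cfg.n_disturbed):
        rows.append({"station_id": f"D{i+1:02d}",
                     "station_class": "disturbed",
                     "pct_natural": float(rng.uniform(0, 89)),
                     "reclamation_start_year": np.nan})
    # reclamation ages spread so the study window sees young through mature
    ages_at_last = np.linspace(2, 34, cfg.n_reclaimed)
    for i in range(cfg.n_reclaimed):
        rows.append({"station_id": f"R{i+1:02d}",
                     "station_class": "reclaimed",
                     "pct_natural": float(rng.uniform(5, 40)),
                     "reclamation_start_year":
                         float(cfg.last_year - round(ages_at_last[i]))})
    return pd.DataFrame(rows)


def _true_evi(cfg: SimConfig, stations: pd.DataFrame,
              rng: np.random.Generator) -> pd.DataFrame:
    """Per station-year true EVI: a ramp from a station floor up to the
    natural-station mean, reaching parity at ``parity_years`` after
    reclamation; disturbed stations sit at a floor set by their natural
    share; natural stations sit at the natural mean."""
    nat = cfg.evi_natural_mean
    lo = cfg.evi_disturbed_min
    rows = []
    for _, st in stations.iterrows():
        offset = float(rng.normal(0, cfg.evi_station_sd))
        if st["station_class"] == "natural":
            floor = nat + offset
        elif st["station_class"] == "disturbed":
            floor = lo + (nat - lo) * st["pct_natural"] / 100.0 + offset
        else:
            floor = lo + offset
        for year in cfg.years:
            if st["station_class"] == "reclaimed":
                age = max(0.0, year - st["reclamation_start_year"])
                frac = min(age / cfg.parity_years, 1.0)
            else:
                frac = 0.0 if st["station_class"] == "disturbed" else 1.0
            evi_true = nat - (nat - floor) * (1.0 - frac)
            rows.append({"station_id": st["station_id"], "year": year,
                         "evi_true": evi_true})
    return pd.DataFrame(rows)


def _habitat_csv(cfg: SimConfig, stations: pd.DataFrame,
                 evi_truth: pd.DataFrame,
                 rng: np.random.Generator) -> pd.DataFrame:
    """In-situ habitat table: 1-3 habitat types per station with proportions
    and three-strata cover. Midstory cover tracks greenness (the stratum
    EVI mostly sees); upperstory is developed only at natural stations."""
    first_evi = (evi_truth.sort_values("year")
                 .groupby("station_id")["evi_true"].last())
    rows = []
    for _, st in stations.iterrows():
        n_types = int(rng.integers(1, 4))
        props = rng.dirichlet(np.full(n_types, 2.0))
        props = np.round(props, 6)
        props[-1] = round(1.0 - props[:-1].sum(), 6)
        evi = first_evi[st["station_id"]]
        mid_base = 100.0 * np.clip((evi - 0.25) / 0.35, 0.0, 1.0)
        upper_base = (50.0 if st["station_class"] == "natural"
                      else 8.0)
        for h in range(n_types):
            rows.append({
                "station_id": st["station_id"],
                "station_class": st["station_class"],
                "pct_natural": round(st["pct_natural"], 2),
                "reclamation_start_year": st["reclamation_start_year"],
                "habitat_type": f"type{h+1}",
                "proportion": props[h],
                "understory_cover": round(float(rng.uniform(20, 60)), 1),
                "midstory_cover": round(float(np.clip(
                    mid_base + rng.normal(0, 8), 0, 100)), 1),
                "upperstory_cover": round(float(np.clip(
                    upper_base + rng.normal(0, 6), 0, 100)), 1),
            })
    return pd.DataFrame(rows)


def _evi_cells(cfg: SimConfig, evi_truth: pd.DataFrame,
               rng: np.random.Generator) -> pd.DataFrame:
    grid = 9
    cell_row, cell_col = np.meshgrid(np.arange(grid), np.arange(grid),
                                     indexing="ij")
    frames = []
    for _, row in evi_truth.iterrows():
        for date in (f"{row['year']}-06-10", f"{row['year']}-06-26"):
            composite_mean = row["evi_true"] + rng.normal(0, cfg.evi_obs_sd)
            values = composite_mean + rng.normal(0, cfg.evi_cell_sd,
                                                 grid * grid)
            values = np.clip(values, -0.2, 1.0)
            frames.append(pd.DataFrame({
                "station_id": row["station_id"], "year": int(row["year"]),
                "composite_date": date,
                "cell_row": cell_row.ravel(), "cell_col": cell_col.ravel(),
                "value": np.round(values, 4)}))
    return pd.concat(frames, ignore_index=True)


def simulate_evi(config: SimConfig, seed: int):
    """Generate the EVI cell table, the habitat table and the truth tables.

    Returns ``(evi_cells, habitat, stations, evi_truth)``; the last holds
    the noiseless per-station-year EVI the capture model conditions on.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    stations = _station_table(config, rng)
    evi_truth = _true_evi(config, stations, rng)
    habitat = _habitat_csv(config, stations, evi_truth, rng)
    cells = _evi_cells(config, evi_truth, rng)
    return cells, habitat, stations, evi_truth


def _flip(recorded: np.ndarray) -> np.ndarray:
    return np.where(recorded == "SY", "ASY", "SY")


def simulate_captures(config: SimConfig, evi_truth: pd.DataFrame,
                      stations: pd.DataFrame, seed: int):
    """Run the capture and observation model forward.

    Returns ``(captures, truth)`` where ``captures`` conforms to the capture
    CSV schema (band_id, species_code, station_id, date, age) and ``truth``
    is a fully populated :class:`SimTruth`.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    J = config.n_species
    codes = [f"SP{j+1:02d}" for j in range(J)]

    alpha = rng.normal(config.mu_alpha, config.sigma_alpha, J)
    beta = (rng.normal(config.mu_beta, config.sigma_beta, J)
            if config.sigma_beta > 0
            else np.full(J, config.mu_beta))
    lambda0 = rng.lognormal(config.capture_log_mean, config.capture_log_sd, J)
    tilt = rng.normal(0.0, config.abundance_tilt_sd, J)

    evi = evi_truth.copy()
    center = float(evi["evi_true"].mean())
    evi["evi_centered"] = evi["evi_true"] - center
    evi_c_map = {(r.station_id, r.year): r.evi_centered
                 for r in evi.itertuples()}

    # --- new adult birds per species x station-year ---
    sy_keys = list(evi_c_map)
    n_cells = len(sy_keys)
    evi_c_cell = np.array([evi_c_map[k] for k in sy_keys])
    lam = (np.repeat(lambda0, n_cells)
           * np.exp(np.repeat(tilt, n_cells) * np.tile(evi_c_cell, J)))
    counts = rng.poisson(lam)
    sp_of_cell = np.repeat(np.arange(J), n_cells)
    cell_idx = np.tile(np.arange(n_cells), J)
    reps = np.repeat(np.arange(counts.size), counts)
    bird_sp = sp_of_cell[reps]
    bird_cell = cell_idx[reps]
    bird_station = np.array([sy_keys[c][0] for c in bird_cell])
    bird_year = np.array([sy_keys[c][1] for c in bird_cell], dtype=int)
    bird_evi = evi_c_cell[bird_cell]
    n_new = bird_sp.size
    bird_id = np.arange(n_new)

    p_sy = expit(alpha[bird_sp] + beta[bird_sp] * bird_evi)
    true_sy = rng.random(n_new) < p_sy

    birds = pd.DataFrame({
        "bird": bird_id, "species_idx": bird_sp, "station_id": bird_station,
        "year": bird_year, "true_age": np.where(true_sy, "SY", "ASY"),
        "origin": "new",
    })

    # --- between-year returns (true age ASY thereafter) ---
    all_years = config.years
    rows = [birds]
    current = birds
    for y in all_years[:-1]:
        cohort = pd.concat([df[df["year"] == y] for df in rows],
                           ignore_index=True)
        if cohort.empty:
            continue
        back = cohort[rng.random(len(cohort)) < config.recapture_between]
        if back.empty:
            continue
        nxt = back.copy()
        nxt["year"] = y + 1
        nxt["true_age"] = "ASY"
        nxt["origin"] = "return"
        rows.append(nxt)
    bird_years = pd.concat(rows, ignore_index=True)
    bird_years = bird_years.sort_values(["bird", "year"],
                                        kind="stable").reset_index(drop=True)

    nby = len(bird_years)
    masked = rng.random(nby) < config.ahy_mask_rate
    n_caps = 1 + rng.poisson(config.recapture_within, nby)
    bird_years["masked"] = masked
    bird_years["n_captures"] = n_caps

    # --- expand bird-years into handlings with independent determinations ---
    reps = np.repeat(np.arange(nby), n_caps)
    cap_true = bird_years["true_age"].to_numpy()[reps]
    cap_masked = bird_years["masked"].to_numpy()[reps]
    err = rng.random(reps.size) < config.misclass_rate
    recorded = np.where(err, _flip(cap_true), cap_true)
    recorded = np.where(cap_masked, "AHY", recorded)
    day = rng.integers(0, 60, reps.size)
    years = bird_years["year"].to_numpy()[reps]
    dates = (pd.to_datetime(pd.DataFrame({"year": years, "month": 6,
                                          "day": 5}))
             + pd.to_timedelta(day, unit="D"))

    captures = pd.DataFrame({
        "band_id": np.char.add("A", np.char.zfill(
            bird_years["bird"].to_numpy()[reps].astype(str), 6)),
        "species_code": np.array(codes)[bird_years["species_idx"]
                                        .to_numpy()[reps]],
        "station_id": bird_years["station_id"].to_numpy()[reps],
        "date": dates.dt.strftime("%Y-%m-%d"),
        "age": recorded,
    })
    determinations = pd.DataFrame({
        "band_id": captures["band_id"], "year": years,
        "true_age": cap_true, "recorded_age": recorded,
        "masked": cap_masked, "error": err & ~cap_masked,
    })

    # --- juveniles (single capture each; excluded downstream at resolve) ---
    n_hy = rng.poisson(config.hy_rate * np.repeat(lambda0, n_cells))
    hy_reps = np.repeat(np.arange(n_hy.size), n_hy)
    if hy_reps.size:
        hy_sp = sp_of_cell[hy_reps]
        hy_cell = cell_idx[hy_reps]
        hy_year = np.array([sy_keys[c][1] for c in hy_cell], dtype=int)
        hy_day = rng.integers(20, 60, hy_reps.size)
        hy_dates = (pd.to_datetime(pd.DataFrame({"year": hy_year, "month": 6,
                                                 "day": 5}))
                    + pd.to_timedelta(hy_day, unit="D"))
        hy = pd.DataFrame({
            "band_id": np.char.add("H", np.char.zfill(
                np.arange(hy_reps.size).astype(str), 6)),
            "species_code": np.array(codes)[hy_sp],
            "station_id": np.array([sy_keys[c][0] for c in hy_cell]),
            "date": hy_dates.dt.strftime("%Y-%m-%d"),
            "age": "HY",
        })
        captures = pd.concat([captures, hy], ignore_index=True)

    captures = captures.sort_values(["band_id", "date"],
                                    kind="stable").reset_index(drop=True)

    birds_out = bird_years.assign(
        band_id=np.char.add("A", np.char.zfill(
            bird_years["bird"].to_numpy().astype(str), 6)),
        species_code=np.array(codes)[bird_years["species_idx"]],
    )[["band_id", "species_code", "station_id", "year", "true_age",
       "origin", "masked", "n_captures"]]

    truth = SimTruth(config=config, species_codes=codes, alpha=alpha,
                     beta=beta, lambda0=lambda0, tilt=tilt,
                     stations=stations, evi=evi, evi_center=center,
                     birds=birds_out, determinations=determinations)
    return captures, truth


def simulate(config: SimConfig, seed: int):
    """Full forward simulation.

    Returns a dict with ``captures``, ``evi_cells``, ``habitat`` DataFrames
    (the pipeline's three input files) and the :class:`SimTruth`. The EVI
    and capture stages consume independent child streams of ``seed``, and
    identical (config, seed) gives identical output byte for byte.
    """
    ss = np.random.SeedSequence(seed)
    s_evi, s_cap = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    cells, habitat, stations, evi_truth = simulate_evi(config, s_evi)
    captures, truth = simulate_captures(config, evi_truth, stations, s_cap)
    return {"captures": captures, "evi_cells": cells, "habitat": habitat,
            "truth": truth}
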