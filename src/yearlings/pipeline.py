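"""End-to-end orchestration: capture curation through model post-processing.

A run consumes either real input files (capture CSV, EVI cell CSV, habitat
CSV), a simulation preset, or a packaged counts-only community table, and
produces a directory of artifacts plus a report and a manifest sufficient to
reproduce the run (config hash, seed, input digests, per-stage row counts
and warnings).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, age_quality, capture_data, evi_habitat, \
    hier_model, table1, yearling_stats
from .synthetic import SimConfig, scenario_presets, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def add_stage(self, name: str, rows: int, warnings: list[str]) -> None:
        self.stages.append({"name": name, "rows": int(rows),
                            "warnings": list(warnings)})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _versions() -> dict:
    import scipy
    return {"yearlings": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__}


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setLevel(logging.INFO)
    logging.getLogger("yearlings").addHandler(handler)
    return handler


def community_report_from_counts(summary: pd.DataFrame,
                                 error_rates: pd.DataFrame | None = None
                                 ) -> dict:
    """Community-level derived statistics from a per-species count table.

    ``summary`` needs ``species_code, n_SY, n_ASY, n_AHY`` (and optionally
    ``n_year_inds``); ``error_rates`` needs ``species_code, rate,
    n_eligible`` when available.
    """
    props = yearling_stats.yearling_proportion(summary["n_SY"],
                                               summary["n_ASY"])
    n_sy = int(summary["n_SY"].sum())
    n_asy = int(summary["n_ASY"].sum())
    n_ahy = int(summary["n_AHY"].sum())
    total = n_sy + n_asy + n_ahy
    defined = props[~np.isnan(props)]
    report = {
        "n_species": int(len(summary)),
        "total_year_individuals": total,
        "total_SY": n_sy, "total_ASY": n_asy, "total_AHY": n_ahy,
        "mean_yearling_proportion":
            yearling_stats.community_mean_proportion(props),
        "pooled_yearling_proportion":
            yearling_stats.pooled_proportion(summary),
        "min_yearling_proportion": float(defined.min()),
        "max_yearling_proportion": float(defined.max()),
        "percent_aged": age_quality.percent_aged(n_sy, n_asy, n_ahy),
        "ahy_share": n_ahy / total if total else float("nan"),
    }
    if error_rates is not None:
        report["mean_age_error_rate"] = \
            age_quality.community_mean_error(error_rates)
    return report


def run_table1(out_dir) -> dict:
    """Counts-only run on the packaged 29-species community table: derived
    columns and community statistics, no model stage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t1 = table1.load_table1()
    summary = t1.rename(columns={"error_rate": "rate"})
    derived = yearling_stats.species_table(
        t1, error_rates=summary[["species_code", "rate", "n_eligible"]])
    derived.to_csv(out_dir / "yearling_table.csv", index=False)
    report = community_report_from_counts(
        t1, error_rates=summary[["species_code", "rate", "n_eligible"]])
    report["percent_initial_ahy"] = (table1.INITIAL_AHY_CAPTURES
                                     / table1.TOTAL_ADULT_CAPTURES)
    report["percent_ahy_redetermined"] = (table1.REDETERMINED_AHY_CAPTURES
                                          / table1.INITIAL_AHY_CAPTURES)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    manifest = RunManifest(config_hash="table1", seed=0,
                           versions=_versions())
    manifest.add_stage("table1", len(t1), [])
    manifest.outputs = [str(out_dir / "yearling_table.csv"),
                        str(out_dir / "report.json")]
    manifest.to_json(out_dir / "manifest.json")
    return report


def run_all(out_dir, seed: int = 0, preset: str | None = None,
            config: SimConfig | None = None,
            captures_path=None, evi_cells_path=None, habitat_path=None,
            schema: dict | None = None, skip_fit: bool = False,
            chains: int = 3, iterations: int = 2000, warmup: int = 2000,
            min_mean_per_year: float = 20.0, plots: bool = False) -> dict:
    """Execute every pipeline stage and write a report plus manifest.

    Inputs are either a simulation preset/config (files are generated into
    the run directory first) or real file paths. Stage outputs are pure
    functions of (inputs, config, seed), so the manifest reproduces the run.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir)
    try:
        return _run_all(out_dir, seed, preset, config, captures_path,
                        evi_cells_path, habitat_path, schema, skip_fit,
                        chains, iterations, warmup, min_mean_per_year, plots)
    finally:
        logging.getLogger("yearlings").removeHandler(handler)
        handler.close()


def _run_all(out_dir, seed, preset, config, captures_path, evi_cells_path,
             habitat_path, schema, skip_fit, chains, iterations, warmup,
             min_mean_per_year, plots) -> dict:
    report: dict = {"seed": seed}
    warnings_all: list[str] = []

    if preset is not None or config is not None:
        cfg = config or scenario_presets()[preset]
        sim = simulate(cfg, seed)
        captures_path = out_dir / "captures.csv"
        evi_cells_path = out_dir / "evi_cells.csv"
        habitat_path = out_dir / "habitat.csv"
        sim["captures"].to_csv(captures_path, index=False)
        sim["evi_cells"].to_csv(evi_cells_path, index=False)
        sim["habitat"].to_csv(habitat_path, index=False)
        sim["truth"].to_json(out_dir / "truth.json")
        config_hash = hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True,
                       default=str).encode()).hexdigest()
        report["preset"] = cfg.name
    elif captures_path is None:
        raise ValueError("run_all needs a preset, a config, or input files")
    else:
        config_hash = "external-inputs"

    manifest = RunManifest(config_hash=config_hash, seed=seed,
                           versions=_versions())
    for p in (captures_path, evi_cells_path, habitat_path):
        if p is not None:
            manifest.inputs[str(p)] = _sha256(p)

    # --- capture curation ---
    try:
        captures = capture_data.read_captures(captures_path, schema=schema)
    except ValueError as exc:
        raise RuntimeError(f"stage read_captures failed: {exc}") from exc
    pr = captures.attrs["parse_report"]
    manifest.add_stage("read_captures", pr.n_kept,
                       [f"dropped {pr.n_dropped}"] if pr.n_dropped else [])

    individuals = capture_data.resolve_year_unique(captures)
    cr = individuals.attrs["conflict_report"]
    manifest.add_stage(
        "resolve_year_unique", len(individuals),
        [f"{cr.n_sy_asy_conflicts} within-year SY/ASY conflict(s)"]
        if cr.n_sy_asy_conflicts else [])

    years = sorted(individuals["year"].unique())
    n_years = years[-1] - years[0] + 1
    targets = capture_data.filter_target_species(
        individuals, n_years, min_mean_per_year=min_mean_per_year)
    manifest.add_stage("filter_target_species", len(targets), [])
    report["n_target_species"] = len(targets)

    summary = capture_data.summarize_species(
        individuals[individuals["species_code"].isin(targets)])
    capture_data.write_species_summary(summary,
                                       out_dir / "species_summary.csv")
    manifest.add_stage("summarize_species", len(summary), [])

    # --- age quality ---
    target_caps = captures[captures["species_code"].isin(targets)]
    err = age_quality.age_error_rates(target_caps)
    age_quality.error_table(err).to_csv(out_dir / "error_rates.csv",
                                        index=False)
    undef = err["rate"].isna().sum()
    manifest.add_stage("age_error_rates", len(err),
                       [f"{int(undef)} species with undefined rate"]
                       if undef else [])

    derived = yearling_stats.species_table(summary, error_rates=err)
    derived.to_csv(out_dir / "yearling_table.csv", index=False)
    report["community"] = community_report_from_counts(summary,
                                                       error_rates=err)

    # --- habitat covariates ---
    station_year = None
    if evi_cells_path is not None:
        cells = evi_habitat.read_evi_cells(evi_cells_path)
        station_year = evi_habitat.station_year_evi(cells)
        centered, mean = evi_habitat.center_covariate(station_year["evi"])
        station_year["evi_centered"] = centered
        station_year.to_csv(out_dir / "station_year_covariates.csv",
                            index=False)
        manifest.add_stage("station_year_evi", len(station_year), [])
        report["evi_center"] = mean

        if habitat_path is not None:
            habitat = pd.read_csv(habitat_path,
                                  dtype={"station_id": str})
            cover = evi_habitat.weighted_station_cover(habitat)
            cover.to_csv(out_dir / "station_cover.csv", index=False)
            st = habitat.drop_duplicates("station_id")[
                ["station_id", "station_class", "pct_natural",
                 "reclamation_start_year"]]
            rows = station_year.merge(st, on="station_id")
            rows = rows[rows["station_class"] != "natural"].copy()
            rows["years_reclaimed"] = evi_habitat.years_since_reclamation(
                rows["year"], rows["reclamation_start_year"])
            fit_reg = evi_habitat.evi_regression(rows)
            with open(out_dir / "evi_regression.json", "w") as fh:
                json.dump(fit_reg.to_dict(), fh, indent=2)
            manifest.add_stage("evi_regression", len(rows),
                              fit_reg.warnings)
            report["evi_regression"] = fit_reg.to_dict()
            warnings_all += fit_reg.warnings

    # --- hierarchical model ---
    if not skip_fit and station_year is not None:
        data = hier_model.build_model_data(individuals, station_year,
                                           target_species=targets)
        post = hier_model.fit(data, chains=chains, iterations=iterations,
                              warmup=warmup, seed=seed)
        warnings_all += post.warnings
        post.draws_frame().to_csv(out_dir / "draws.csv", index=False)
        summ = post.summary()
        summ.to_csv(out_dir / "posterior_summary.csv", index=False)
        with open(out_dir / "posterior_summary.json", "w") as fh:
            json.dump(summ.to_dict(orient="records"), fh, indent=2)
        manifest.add_stage("fit", summ.shape[0], post.warnings)

        profiles = hier_model.species_evi_profiles(
            individuals[individuals["species_code"].isin(targets)],
            station_year)
        profiles.to_csv(out_dir / "species_profiles.csv", index=False)
        groups = hier_model.group_coefficient_summary(post, profiles)
        with open(out_dir / "group_summary.json", "w") as fh:
            json.dump(groups.to_dict(orient="records"), fh, indent=2)
        try:
            meta = hier_model.coefficient_meta_regression(
                post.beta_point_estimates(), profiles)
        except ValueError as exc:
            meta = None
            warnings_all.append(f"meta-regression skipped: {exc}")
            logger.warning("meta-regression skipped: %s", exc)
        if meta is not None:
            with open(out_dir / "meta_regression.json", "w") as fh:
                json.dump(meta.to_dict(), fh, indent=2)
            warnings_all += meta.warnings
            report["meta_regression"] = meta.to_dict()
        report["model"] = {
            name: {"mean": float(post.draws[name].mean()),
                   "ci_95": list(post.hyper_interval(name))}
            for name in hier_model.HYPER_NAMES}
        report["group_summary"] = groups.to_dict(orient="records")

        if plots:
            from . import plots as _plots
            _plots.plot_species_coefficients(post,
                                             out_dir / "coefficients.png")

    report["warnings"] = warnings_all
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    manifest.outputs = sorted(str(p) for p in out_dir.iterdir()
                              if p.name != "manifest.json")
    manifest.to_json(out_dir / "manifest.json")
    return report
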