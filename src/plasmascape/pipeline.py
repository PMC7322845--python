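"""End-to-end orchestration: fix tables + plasma table -> isoscape bundle.

Stage order (fixed): trip segmentation -> speed filter -> regular
resampling -> colony buffer -> behavioral labelling -> lipid normalization
-> 7-day window -> time-spent gridding -> weighted mean foraging locations
-> correlations -> species surfaces -> guild bootstrap surfaces ->
differences -> front/zone summaries. Every stage logs individuals in/out;
all randomness is funnelled through one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, chem, fronts as fronts_mod, isoscape, locate, tracks
from .errors import NoDataError, NoForagingError, PlasmascapeError
from .geo import haversine_km
from .grids import GridSpec
from .synth import COLONY, SshField

log = logging.getLogger(__name__)

#: published default parameters per guild
GUILD_DEFAULTS = {
    "flying": {"vmax_kmh": 135.0, "buffer_km": 15.0, "dt_s": 3600.0,
               "interp": "linear", "hull_buffer_deg": 0.5},
    "diving": {"vmax_kmh": 10.0, "buffer_km": 2.0, "dt_s": 120.0,
               "interp": "ctcrw", "hull_buffer_deg": 0.05},
}


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters (defaults are the study's values)."""

    colony: tuple = COLONY
    land_radius_km: float = 0.5
    window_days: float = 7.0
    guild_of_species: dict = dc_field(default_factory=dict)  # species -> guild
    guild_params: dict = dc_field(default_factory=lambda: {
        g: dict(p) for g, p in GUILD_DEFAULTS.items()})
    cell_size_override: dict = dc_field(default_factory=dict)  # guild -> deg
    bootstrap_B: int = 1000
    bootstrap_k: Optional[int] = None  # None -> min individuals per species
    norm_form: str = "direct"
    variogram_bins: int = 12
    max_lag_fraction: float = 2.0 / 3.0
    min_samples_kriging: int = 5
    seed: int = 0

    def __post_init__(self):
        for g, p in self.guild_params.items():
            for key in ("vmax_kmh", "buffer_km", "dt_s"):
                if p[key] <= 0:
                    raise ValueError(f"{g}.{key} must be positive")
        if self.window_days <= 0 or self.land_radius_km < 0:
            raise ValueError("bad window/land radius")

    def guild_of(self, species: str) -> str:
        return self.guild_of_species.get(species, "flying")


@dataclass
class PipelineResult:
    locations: pd.DataFrame
    regressions: dict                  # (label, isotope, predictor) -> RegressionResult
    surfaces: dict                     # (species, isotope) -> IsoscapeSurface
    guild_surfaces: dict               # (guild, isotope) -> IsoscapeSurface
    differences: dict                  # (spA, spB, isotope) -> IsoscapeSurface
    norm_models: dict                  # species -> NormalizationModel
    front_lines: dict                  # name -> FrontLine
    feature_summaries: pd.DataFrame
    back_calculations: pd.DataFrame
    manifest: dict


def _clean_individual(fixes: pd.DataFrame, cfg: PipelineConfig, species: str,
                      individual_id: str) -> list[tracks.Trip]:
    guild = cfg.guild_of(species)
    p = cfg.guild_params[guild]
    trips = tracks.segment_trips(fixes, cfg.colony, cfg.land_radius_km,
                                 individual_id=individual_id, species=species,
                                 guild=guild, interval_s=p["dt_s"])
    out = []
    for trip in trips:
        try:
            trip = tracks.speed_filter(trip, p["vmax_kmh"])
            trip = tracks.interpolate_regular(trip, p["dt_s"], p["interp"])
            trip = tracks.apply_colony_buffer(trip, p["buffer_km"], cfg.colony)
        except PlasmascapeError as exc:
            log.info("%s: trip dropped (%s)", individual_id, exc)
            continue
        if not trip.excluded and len(trip) >= 3:
            out.append(trip)
    return out


def _label_behavior(by_species: dict, cfg: PipelineConfig, seed: int) -> None:
    """Attach foraging labels in place, pooling steps per species."""
    for species, per_ind in by_species.items():
        guild = cfg.guild_of(species)
        all_trips = [t for trips_ in per_ind.values() for t in trips_]
        metrics = [behavior.step_metrics(t) for t in all_trips]
        if guild == "flying":
            pooled = pd.concat(metrics, ignore_index=True)
            valid = pooled["speed_kmh"].notna() & pooled["turn_rad"].notna()
            X = np.column_stack([pooled.loc[valid, "speed_kmh"],
                                 np.abs(pooled.loc[valid, "turn_rad"])])
            clf = behavior.EmbcClassifier(random_state=seed).fit(X)
            for trip, m in zip(all_trips, metrics):
                v = m["speed_kmh"].notna() & m["turn_rad"].notna()
                lab = pd.Series(pd.NA, index=m.index, dtype=object)
                Xi = np.column_stack([m.loc[v, "speed_kmh"],
                                      np.abs(m.loc[v, "turn_rad"])])
                lab.loc[v] = clf.predict(Xi)
                trip.df["label"] = lab.to_numpy()
                trip.df["foraging"] = (lab == behavior.FORAGING_LABEL).to_numpy()
        else:
            labels = behavior.speed_threshold_foraging(metrics)
            for trip, lab in zip(all_trips, labels):
                trip.df["label"] = lab.to_numpy()
                trip.df["foraging"] = (lab == "FORAGE").to_numpy()


def _resolve_isotopes(plasma: pd.DataFrame, cfg: PipelineConfig):
    """Per-species normalization models + final per-individual d13c/d15n."""
    models = {}
    rows = {}
    for species, grp in plasma.groupby("species"):
        pairs = grp.dropna(subset=["d13c_del", "cn_del"])
        model = None
        if len(pairs) >= 3:
            try:
                model = chem.fit_normalization(pairs, form=cfg.norm_form,
                                               species=str(species))
                models[str(species)] = model
            except PlasmascapeError as exc:
                log.warning("%s: normalization fit failed (%s)", species, exc)
        for _, r in grp.iterrows():
            if not pd.isna(r.get("d13c_del")):
                d13c = float(r["d13c_del"])
            elif model is not None:
                sample = chem.PlasmaSample(str(r["id"]), str(species),
                                           float(r["d13c_raw"]), float(r["d15n"]),
                                           float(r["cn_raw"]))
                d13c = chem.correct_delta13c(sample, model)
            else:
                log.warning("%s: no delipidated value and no model; raw d13c used",
                            r["id"])
                d13c = float(r["d13c_raw"])
            rows[str(r["id"])] = {"d13c": d13c, "d15n": float(r["d15n"]),
                                  "blood_time": r["blood_time"]}
    return models, rows


def run_pipeline(config: PipelineConfig, fix_table: pd.DataFrame,
                 plasma_table: pd.DataFrame,
                 ssh: Optional[SshField] = None) -> PipelineResult:
    """Run the full analysis; see module docstring for the stage order.

    ``fix_table`` columns: id, species, time, lon, lat. ``plasma_table``
    columns: id, species, d13c_raw, d13c_del, d15n, cn_raw, cn_del,
    blood_time. Individuals present in only one input are excluded with a
    logged reason.
    """
    if len(plasma_table) == 0:
        raise NoDataError("empty isotope table: nothing to join against tracks")
    if len(fix_table) == 0:
        raise NoDataError("empty fix table: nothing to join against isotopes")
    tracked = set(fix_table["id"].astype(str))
    sampled = set(plasma_table["id"].astype(str))
    for missing in sorted(tracked - sampled):
        log.info("%s: tracked but no isotope record; excluded", missing)
    for missing in sorted(sampled - tracked):
        log.info("%s: isotope record but no track; excluded", missing)
    ids = sorted(tracked & sampled)
    if not ids:
        raise NoDataError("track/isotope join is empty")

    ss = np.random.SeedSequence(config.seed)
    seed_behavior, seed_boot = (int(s) % (2 ** 31) for s in ss.generate_state(2))

    # --- track cleaning ---------------------------------------------------
    by_species: dict[str, dict[str, list[tracks.Trip]]] = {}
    species_of: dict[str, str] = {}
    for ind, grp in fix_table.groupby("id"):
        ind = str(ind)
        if ind not in ids:
            continue
        species = str(grp["species"].iloc[0])
        species_of[ind] = species
        trips = _clean_individual(grp.sort_values("time").reset_index(drop=True),
                                  config, species, ind)
        if trips:
            by_species.setdefault(species, {})[ind] = trips
        else:
            log.info("%s: no usable trips after cleaning; excluded", ind)

    # --- behavior ---------------------------------------------------------
    _label_behavior(by_species, config, seed_behavior)

    # --- isotopes ---------------------------------------------------------
    norm_models, iso_by_id = _resolve_isotopes(plasma_table, config)

    # --- per-guild grids --------------------------------------------------
    guilds = sorted({config.guild_of(s) for s in by_species})
    cell_size = {}
    grid_by_guild = {}
    for g in guilds:
        g_trips = [t for s, per in by_species.items()
                   if config.guild_of(s) == g
                   for trips_ in per.values() for t in trips_]
        cell_size[g] = config.cell_size_override.get(g) or locate.grid_cell_size(g_trips)
        lons = np.concatenate([t.df["lon"].to_numpy() for t in g_trips])
        lats = np.concatenate([t.df["lat"].to_numpy() for t in g_trips])
        grid_by_guild[g] = GridSpec.from_extent(
            lons.min() - cell_size[g], lons.max() + cell_size[g],
            lats.min() - cell_size[g], lats.max() + cell_size[g], cell_size[g])

    # --- mean foraging locations -----------------------------------------
    loc_rows = []
    for species, per_ind in by_species.items():
        guild = config.guild_of(species)
        for ind, trips_ in per_ind.items():
            if ind not in iso_by_id:
                continue
            iso = iso_by_id[ind]
            try:
                res = locate.mean_foraging_location(
                    trips_, iso["blood_time"], grid_by_guild[guild],
                    config.window_days)
            except (NoForagingError, NoDataError) as exc:
                log.info("%s: excluded (%s)", ind, exc)
                continue
            loc_rows.append({"id": ind, "species": species, "guild": guild,
                             "lon": res["lon"], "lat": res["lat"],
                             "n_trips": res["n_trips"],
                             "d13c": iso["d13c"], "d15n": iso["d15n"]})
    locations = pd.DataFrame(loc_rows)
    if len(locations) == 0:
        raise NoDataError("no individuals survived the pipeline")

    # --- correlations -----------------------------------------------------
    regressions = {}

    def _corr(label, sub, predictor):
        if predictor == "dist_to_coast":
            x = haversine_km(sub["lon"].to_numpy(), sub["lat"].to_numpy(),
                             config.colony[0], config.colony[1])
        else:
            x = sub[predictor].to_numpy()
        for iso in ("d13c", "d15n"):
            try:
                regressions[(label, iso, predictor)] = isoscape.correlate(
                    sub[iso].to_numpy(), x, predictor)
            except PlasmascapeError as exc:
                log.info("correlation %s/%s/%s skipped (%s)", label, iso,
                         predictor, exc)

    for species, sub in locations.groupby("species"):
        preds = (("lat", "lon") if config.guild_of(str(species)) == "flying"
                 else ("dist_to_coast",))
        for p in preds:
            _corr(str(species), sub, p)
    for guild, sub in locations.groupby("guild"):
        preds = ("lat", "lon") if guild == "flying" else ("dist_to_coast",)
        for p in preds:
            _corr(f"{guild}:pooled", sub, p)

    # --- species surfaces -------------------------------------------------
    surfaces = {}
    for species, sub in locations.groupby("species"):
        guild = config.guild_of(str(species))
        if len(sub) < config.min_samples_kriging:
            log.info("%s: %d locations < %d, no kriged surface", species,
                     len(sub), config.min_samples_kriging)
            continue
        for iso in ("d13c", "d15n"):
            try:
                surfaces[(str(species), iso)] = isoscape.species_isoscape(
                    sub, iso, cell_size[guild],
                    config.guild_params[guild]["hull_buffer_deg"],
                    provenance={"species": str(species), "guild": guild})
            except PlasmascapeError as exc:
                log.warning("%s/%s surface failed (%s)", species, iso, exc)

    # --- differences ------------------------------------------------------
    differences = {}
    by_guild_sp = {}
    for (sp, iso), surf in surfaces.items():
        by_guild_sp.setdefault((surf.provenance.get("guild"), iso), []).append(sp)
    for (g, iso), sps in by_guild_sp.items():
        for i, a in enumerate(sps):
            for b in sps[i + 1:]:
                try:
                    differences[(a, b, iso)] = isoscape.difference_surface(
                        surfaces[(a, iso)], surfaces[(b, iso)])
                except PlasmascapeError as exc:
                    log.info("difference %s-%s/%s not shown (%s)", a, b, iso, exc)

    # --- guild bootstrap --------------------------------------------------
    guild_surfaces = {}
    for guild, sub in locations.groupby("guild"):
        per_species = {str(s): g.reset_index(drop=True)
                       for s, g in sub.groupby("species")}
        if len(per_species) < 1:
            continue
        k = config.bootstrap_k or min(len(g) for g in per_species.values())
        if k < 1 or any(len(g) < k for g in per_species.values()):
            log.info("%s guild: bootstrap skipped (k=%d infeasible)", guild, k)
            continue
        for iso in ("d13c", "d15n"):
            try:
                surf, _env = isoscape.bootstrap_guild_isoscape(
                    per_species, iso, k, B=config.bootstrap_B, seed=seed_boot,
                    cell_size=cell_size[str(guild)],
                    buffer_deg=config.guild_params[str(guild)]["hull_buffer_deg"])
                guild_surfaces[(str(guild), iso)] = surf
            except PlasmascapeError as exc:
                log.warning("%s guild %s bootstrap failed (%s)", guild, iso, exc)

    # --- fronts and zones -------------------------------------------------
    front_lines = {}
    summaries = []
    backcalc = []
    if ssh is not None:
        for name, level in fronts_mod.FRONT_LEVELS.items():
            try:
                front_lines[name] = fronts_mod.extract_front(ssh, level, name)
            except PlasmascapeError as exc:
                log.info("front %s not present (%s)", name, exc)
        if set(front_lines) == {"STF", "SAF", "APF"}:
            for (sp, iso), surf in surfaces.items():
                for name, fl in front_lines.items():
                    try:
                        s = fronts_mod.summarize_by_feature(surf, fl, isotope=iso)
                        summaries.append({"species": sp, "feature": name,
                                          "isotope": iso, "mean": s.mean,
                                          "sd": s.sd, "n": s.n_cells})
                    except PlasmascapeError:
                        pass
                for zone in fronts_mod.ZONES:
                    try:
                        s = fronts_mod.summarize_by_feature(
                            surf, zone, fronts=front_lines, isotope=iso)
                        summaries.append({"species": sp, "feature": zone,
                                          "isotope": iso, "mean": s.mean,
                                          "sd": s.sd, "n": s.n_cells})
                    except PlasmascapeError:
                        pass
    for (label, iso, pred), reg in regressions.items():
        if pred != "lat":
            continue
        for fname, flat in fronts_mod.FRONT_LATITUDES.items():
            value, rounded = fronts_mod.back_calculate_front_value(reg, flat)
            backcalc.append({"species": label, "front": fname, "isotope": iso,
                             "value": value, "rounded": rounded})

    manifest = {
        "seed": config.seed,
        "window_days": config.window_days,
        "cell_size": cell_size,
        "guild_params": config.guild_params,
        "norm_form": config.norm_form,
        "bootstrap": {"B": config.bootstrap_B, "k": config.bootstrap_k},
        "n_individuals": {"in": len(ids), "located": len(locations)},
        "species": sorted(by_species),
    }
    return PipelineResult(locations, regressions, surfaces, guild_surfaces,
                          differences, norm_models, front_lines,
                          pd.DataFrame(summaries), pd.DataFrame(backcalc),
                          manifest)
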