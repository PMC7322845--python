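"""Synthetic study-system generator.

Emulates the statistical structure the downstream analysis assumes, so every
stage is testable without field data: correlated-random-walk foraging trips
from a colony (hourly fixes spanning tens of degrees for flying birds;
2-minute fixes within ~0.5 degrees for penguins), baseline isotope fields
with a latitudinal gradient plus front steps and inshore enrichment, plasma
values as time-weighted field averages over the week before blood sampling
plus a trophic offset and Gaussian noise, lipid contamination linear in C:N
excess, and a monotone sea-surface-height field with fronts planted at known
latitudes. Ground truth (weighted foraging location, baseline value, per-fix
behavioral state) is always emitted alongside the samples so parameter
recovery can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import chem
from .errors import (EmptyTrackError, InvalidContaminationError,
                     InvalidFieldError, InvalidSpecError, NoDataError)
from .geo import destination, haversine_km, initial_bearing_rad
from .grids import GridSpec
from .tracks import Trip

log = logging.getLogger(__name__)

# Default study conditions ------------------------------------------------
#: colony position (sub-Antarctic island in the SW Indian Ocean sector)
COLONY = (37.75, -46.9)
#: default trophic offsets consumer-minus-baseline, permil (d13c, d15n)
TROPHIC_OFFSET = (1.0, 3.5)
#: default plasma measurement/integration noise SD, permil
PLASMA_NOISE_SD = (0.3, 0.3)


@dataclass(frozen=True)
class FieldSpec:
    """Generating law of one isotope's baseline surface.

    value(lon, lat) = slope*lat + intercept
                      + sum(step for fronts south of lat)
                      + inshore_amplitude * exp(-dist_to(coast_point)/scale)
                      + N(0, noise_sd) per cell
    """

    slope: float            # permil per degree latitude
    intercept: float        # permil
    front_steps: tuple = ()  # ((front_lat, step_permil), ...)
    inshore_amplitude: float = 0.0
    inshore_scale_km: float = 200.0
    noise_sd: float = 0.0
    coast_point: tuple = COLONY

    def __post_init__(self):
        vals = [self.slope, self.intercept, self.inshore_amplitude,
                self.inshore_scale_km, self.noise_sd]
        vals += [v for pair in self.front_steps for v in pair]
        if not np.all(np.isfinite(vals)):
            raise InvalidSpecError("non-finite field spec value")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")

    def mean_value(self, lon, lat):
        """Noise-free expectation of the field."""
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        v = self.slope * lat + self.intercept
        for front_lat, step in self.front_steps:
            v = v + step * (lat > front_lat)
        if self.inshore_amplitude != 0.0:
            d = haversine_km(lon, lat, self.coast_point[0], self.coast_point[1])
            v = v + self.inshore_amplitude * np.exp(-np.asarray(d) / self.inshore_scale_km)
        return v


# plasma-level Table-2-like gradients minus the default trophic offsets
DEFAULT_D13C_SPEC = FieldSpec(slope=0.21, intercept=-11.25 - TROPHIC_OFFSET[0])
DEFAULT_D15N_SPEC = FieldSpec(slope=0.12, intercept=18.29 - TROPHIC_OFFSET[1])


@dataclass
class BaselineField:
    """Gridded baseline δ13C/δ15N surfaces plus their generating specs."""

    grid: GridSpec
    d13c: np.ndarray  # (n_lat, n_lon)
    d15n: np.ndarray
    spec: dict        # {"d13c": FieldSpec, "d15n": FieldSpec}

    def value_at(self, lon, lat, isotope: str) -> np.ndarray:
        """Bilinear interpolation of the gridded field at points.

        Exact for fields linear in lon/lat (zero noise, no steps), which is
        what the parameter-recovery tests rely on.
        """
        values = {"d13c": self.d13c, "d15n": self.d15n}[isotope]
        lonc, latc = self.grid.lon_centers(), self.grid.lat_centers()
        lon = np.clip(np.asarray(lon, float), lonc[0], lonc[-1])
        lat = np.clip(np.asarray(lat, float), latc[0], latc[-1])
        ix = np.clip(np.searchsorted(lonc, lon) - 1, 0, len(lonc) - 2)
        iy = np.clip(np.searchsorted(latc, lat) - 1, 0, len(latc) - 2)
        fx = (lon - lonc[ix]) / (lonc[ix + 1] - lonc[ix])
        fy = (lat - latc[iy]) / (latc[iy + 1] - latc[iy])
        v = (values[iy, ix] * (1 - fx) * (1 - fy)
             + values[iy, ix + 1] * fx * (1 - fy)
             + values[iy + 1, ix] * (1 - fx) * fy
             + values[iy + 1, ix + 1] * fx * fy)
        return v


def generate_baseline_field(spec_d13c: FieldSpec = DEFAULT_D13C_SPEC,
                            spec_d15n: FieldSpec = DEFAULT_D15N_SPEC,
                            grid: GridSpec | None = None,
                            seed: int = 0) -> BaselineField:
    """Realise both isotope surfaces on a grid (i.i.d. Gaussian cell noise)."""
    if grid is None:
        grid = GridSpec.from_extent(10.0, 65.0, -72.0, -22.0, 0.5)
    rng = np.random.default_rng(seed)
    lon2d, lat2d = grid.meshgrid_centers()
    layers = {}
    for name, spec in (("d13c", spec_d13c), ("d15n", spec_d15n)):
        v = np.asarray(spec.mean_value(lon2d, lat2d), float)
        if spec.noise_sd > 0:
            v = v + rng.normal(0.0, spec.noise_sd, v.shape)
        layers[name] = v
    return BaselineField(grid, layers["d13c"], layers["d15n"],
                         {"d13c": spec_d13c, "d15n": spec_d15n})


# ------------------------------------------------------------------ tracks

@dataclass(frozen=True)
class SimulationConfig:
    """Correlated-random-walk trip generator settings for one guild."""

    mode: str = "flying"              # "flying" | "diving"
    fix_interval_s: float = 3600.0
    mean_speed_kmh: float = 35.0
    speed_sd_kmh: float = 10.0
    transit_turn_sd_rad: float = 0.15   # heading-change SD while commuting
    forage_turn_sd_rad: float = 1.5     # while foraging (high sinuosity)
    forage_speed_factor: float = 0.25   # forage speed = factor * transit speed
    trip_duration_h: float = 120.0
    colony: tuple = COLONY
    p_switch: float = 0.05            # per-step chance of changing state
    forage_start_frac: float = 0.3    # foraging only after this trip fraction
    return_to_colony: bool = True

    def __post_init__(self):
        if self.fix_interval_s <= 0:
            raise InvalidSpecError("fix interval must be > 0")
        if self.mean_speed_kmh < 0 or self.speed_sd_kmh < 0:
            raise InvalidSpecError("speeds must be >= 0")
        if self.trip_duration_h <= 0:
            raise EmptyTrackError("zero-duration trip")


#: study-condition defaults per guild
FLYING_CONFIG = SimulationConfig()
DIVING_CONFIG = SimulationConfig(mode="diving", fix_interval_s=120.0,
                                 mean_speed_kmh=4.0, speed_sd_kmh=1.5,
                                 transit_turn_sd_rad=0.25,
                                 trip_duration_h=48.0, p_switch=0.02)


def _draw_speed(rng, mean, sd):
    if sd == 0:
        return mean
    return max(0.0, rng.normal(mean, sd))


def simulate_track(config: SimulationConfig, seed: int, *,
                   individual_id: str = "bird", species: str = "sp",
                   initial_heading_rad: float | None = None) -> Trip:
    """Simulate one colony-based foraging trip.

    First-order correlated random walk on the sphere: wrapped-normal heading
    increments, truncated-normal speeds; a two-state Markov chain switches
    between fast/straight transit and slow/tortuous foraging (per-fix truth
    in column ``true_state``). With ``return_to_colony`` the walk turns
    homeward once the remaining time budget requires it, and the first and
    last fixes sit exactly at the colony.
    """
    rng = np.random.default_rng(seed)
    dt_h = config.fix_interval_s / 3600.0
    n_steps = int(round(config.trip_duration_h / dt_h))
    if n_steps < 1:
        raise EmptyTrackError("trip shorter than one fix interval")
    lon = np.empty(n_steps + 1)
    lat = np.empty(n_steps + 1)
    state = np.empty(n_steps + 1, dtype=object)
    lon[0], lat[0] = config.colony
    state[0] = "transit"
    heading = (rng.uniform(-np.pi, np.pi) if initial_heading_rad is None
               else initial_heading_rad)
    cur = "transit"
    arrived = False
    for k in range(1, n_steps + 1):
        if arrived:
            lon[k], lat[k] = config.colony
            state[k] = "transit"
            continue
        frac = k / n_steps
        dist_home = haversine_km(lon[k - 1], lat[k - 1], *config.colony)
        time_left_h = (n_steps - k) * dt_h
        homing = (config.return_to_colony
                  and dist_home >= 0.9 * max(config.mean_speed_kmh, 1e-9) * time_left_h)
        if homing:
            cur = "transit"
            heading = (initial_bearing_rad(lon[k - 1], lat[k - 1], *config.colony)
                       + rng.normal(0.0, 0.1))
            speed = _draw_speed(rng, config.mean_speed_kmh, config.speed_sd_kmh)
            step_km = min(speed * dt_h, dist_home)
        else:
            if frac > config.forage_start_frac and rng.random() < config.p_switch:
                cur = "forage" if cur == "transit" else "transit"
            turn_sd = (config.forage_turn_sd_rad if cur == "forage"
                       else config.transit_turn_sd_rad)
            heading = heading + rng.normal(0.0, turn_sd)
            mean_v = config.mean_speed_kmh * (config.forage_speed_factor
                                              if cur == "forage" else 1.0)
            speed = _draw_speed(rng, mean_v, config.speed_sd_kmh
                                * (config.forage_speed_factor if cur == "forage" else 1.0))
            step_km = speed * dt_h
        lon[k], lat[k] = destination(lon[k - 1], lat[k - 1], heading, step_km)
        state[k] = cur
        if config.return_to_colony and haversine_km(lon[k], lat[k], *config.colony) < 1e-6:
            arrived = True
    if config.return_to_colony:
        lon[-1], lat[-1] = config.colony
        state[-1] = "transit"
    t0 = np.datetime64("2016-12-01T00:00:00")
    times = t0 + (np.arange(n_steps + 1) * config.fix_interval_s * 1e9).astype("timedelta64[ns]")
    df = pd.DataFrame({"time": times, "lon": lon, "lat": lat,
                       "true_state": state})
    guild = "diving" if config.mode == "diving" else "flying"
    return Trip(individual_id, species, guild, df, config.fix_interval_s)


# ------------------------------------------------------------------ plasma

def sample_plasma(track: Trip, bfield: BaselineField, window_days: float = 7.0,
                  trophic_offset=TROPHIC_OFFSET, noise_sd=PLASMA_NOISE_SD,
                  seed: int = 0, blood_time=None,
                  delipidated: bool = True) -> chem.PlasmaSample:
    """Draw a plasma sample as the time-weighted field mean along the track.

    Uses fixes within ``window_days`` before ``blood_time`` (default: the
    final fix). If the track carries ``true_state`` labels only foraging
    fixes contribute, mirroring the downstream weighting; each contributing
    fix gets its sampling interval as weight. The ground-truth weighted
    location and baseline values are stored on ``sample.truth``.
    """
    rng = np.random.default_rng(seed)
    df = track.df
    blood_time = pd.Timestamp(df["time"].iloc[-1]) if blood_time is None else pd.Timestamp(blood_time)
    start = blood_time - pd.Timedelta(days=window_days)
    sel = (df["time"] >= start) & (df["time"] <= blood_time)
    if "true_state" in df.columns and (df.loc[sel, "true_state"] == "forage").any():
        sel &= df["true_state"] == "forage"
    sub = df.loc[sel]
    inside = bfield.grid.contains(sub["lon"].to_numpy(float), sub["lat"].to_numpy(float))
    sub = sub.loc[np.asarray(inside, bool)]
    if len(sub) == 0:
        raise NoDataError(f"{track.individual_id}: no usable fixes in window")
    w = np.full(len(sub), track.interval_s)
    w = w / w.sum()
    lon = sub["lon"].to_numpy(float)
    lat = sub["lat"].to_numpy(float)
    truth_lon = float(np.sum(w * lon))
    truth_lat = float(np.sum(w * lat))
    base = {}
    plasma = {}
    for iso, off, nsd in zip(("d13c", "d15n"), trophic_offset, noise_sd):
        vals = np.asarray(bfield.value_at(lon, lat, iso), float)
        base[iso] = float(np.sum(w * vals))
        plasma[iso] = base[iso] + off + (rng.normal(0.0, nsd) if nsd > 0 else 0.0)
    sample = chem.PlasmaSample(
        individual_id=track.individual_id, species=track.species,
        d13c_raw=plasma["d13c"], d15n=plasma["d15n"],
        cn_raw=3.2, d13c_del=plasma["d13c"] if delipidated else None,
        cn_del=3.2 if delipidated else None, blood_time=blood_time)
    sample.truth = {"lon": truth_lon, "lat": truth_lat,
                    "d13c_base": base["d13c"], "d15n_base": base["d15n"],
                    "d13c_plasma": plasma["d13c"], "d15n_plasma": plasma["d15n"]}
    return sample


def add_lipid_contamination(sample: chem.PlasmaSample, m: float, c: float,
                            delta_cn: float, mean_cn_del: float = 3.2,
                            form: str = "direct") -> chem.PlasmaSample:
    """Emit a raw (lipid-contaminated) counterpart of a clean sample.

    The raw C:N exceeds ``mean_cn_del`` by ``delta_cn`` and the raw δ13C is
    depressed by exactly the correction the chosen normalization form would
    add back at that C:N, so contaminate -> correct is the identity.
    """
    if delta_cn < 0:
        raise InvalidContaminationError("delta_cn must be >= 0")
    if form not in chem.FORMS:
        raise InvalidSpecError(f"unknown normalization form {form!r}")
    truth = sample.d13c_del if sample.has_delipidated else sample.d13c_raw
    cn_raw = mean_cn_del + delta_cn
    dcn_star = mean_cn_del - cn_raw  # = -delta_cn
    if form == "direct":
        correction = m * dcn_star + c
    else:
        if m == 0:
            raise InvalidSpecError("inverse form needs m != 0")
        correction = (dcn_star + c) / m
    out = replace(sample, d13c_raw=float(truth - correction),
                  cn_raw=float(cn_raw), d13c_del=None, cn_del=None)
    out.truth = dict(sample.truth, d13c_true=float(truth))
    return out


# --------------------------------------------------------------------- SSH

@dataclass
class SshField:
    """Gridded sea-surface height (m), monotone increasing northward."""

    grid: GridSpec
    values: np.ndarray  # (n_lat, n_lon)


#: the front SSH levels used throughout (sub-tropical, sub-Antarctic, polar)
FRONT_LEVELS = {"STF": 0.92, "SAF": 0.03, "APF": -0.48}


def generate_ssh_field(front_lats, levels, grid: GridSpec | None = None,
                       end_slope: float | None = None) -> SshField:
    """SSH field monotone in latitude, exact at each (front_lat, level) pair.

    ``front_lats`` strictly south-to-north with strictly increasing
    ``levels``; between anchors SSH is linear in latitude, and beyond the
    outermost anchors it continues with the nearest segment's slope (or
    ``end_slope``).
    """
    front_lats = np.asarray(front_lats, float)
    levels = np.asarray(levels, float)
    if len(front_lats) != len(levels) or len(front_lats) < 1:
        raise InvalidFieldError("front_lats and levels must match, non-empty")
    if np.any(np.diff(front_lats) <= 0):
        raise InvalidFieldError("front latitudes must increase south->north")
    if len(levels) > 1 and np.any(np.diff(levels) <= 0):
        raise InvalidFieldError("levels must increase with latitude")
    if grid is None:
        grid = GridSpec.from_extent(10.0, 65.0, -72.0, -22.0, 0.5)
    lat = grid.lat_centers()
    if len(front_lats) == 1:
        slope = end_slope if end_slope is not None else 0.1
        prof = levels[0] + slope * (lat - front_lats[0])
    elif len(front_lats) == 2:
        s = (levels[1] - levels[0]) / (front_lats[1] - front_lats[0])
        prof = levels[0] + s * (lat - front_lats[0])
    else:
        # monotone C1 spline through the anchors keeps the profile smooth so
        # gridded sampling and contour extraction stay accurate near anchors
        from scipy.interpolate import PchipInterpolator
        # pseudo-anchors continuing the end secant slopes make the real
        # anchors interior points of the monotone spline, so the profile is
        # smooth and strictly increasing right through them
        s_lo = (levels[1] - levels[0]) / (front_lats[1] - front_lats[0])
        s_hi = (levels[-1] - levels[-2]) / (front_lats[-1] - front_lats[-2])
        span = 2.0 * (front_lats[-1] - front_lats[0])
        ext_lats = np.concatenate([[front_lats[0] - span], front_lats,
                                   [front_lats[-1] + span]])
        ext_levels = np.concatenate([[levels[0] - s_lo * span], levels,
                                     [levels[-1] + s_hi * span]])
        pchip = PchipInterpolator(ext_lats, ext_levels)
        prof = np.asarray(pchip(lat), float)
        below = lat < ext_lats[0]
        above = lat > ext_lats[-1]
        prof[below] = ext_levels[0] + s_lo * (lat[below] - ext_lats[0])
        prof[above] = ext_levels[-1] + s_hi * (lat[above] - ext_lats[-1])
    values = np.repeat(prof[:, None], grid.n_lon, axis=1)
    return SshField(grid, values)


# ------------------------------------------------------------- full bundle

SPECIES_DEFAULTS = {
    "flying": ("albatross_a", "albatross_b", "petrel_a"),
    "diving": ("penguin_a", "penguin_b", "penguin_c"),
}


def make_study_bundle(n_per_species: int = 25, guild: str = "flying",
                      species: tuple | None = None,
                      config: SimulationConfig | None = None,
                      field_spec_d13c: FieldSpec = DEFAULT_D13C_SPEC,
                      field_spec_d15n: FieldSpec = DEFAULT_D15N_SPEC,
                      noise_sd=PLASMA_NOISE_SD, window_days: float = 7.0,
                      lipid_fraction: float = 0.3,
                      lipid_model=(-0.6, 0.1), seed: int = 0):
    """Generate a full synthetic study: tracks, plasma table, field, truth.

    Returns ``(tracks_df, plasma_df, field, truth_df)`` in the standard CSV
    dialects. A ``lipid_fraction`` of individuals get raw-only contaminated
    samples (contamination drawn uniformly on [0.2, 1.0] C:N excess); the
    rest carry both raw and delipidated aliquots.
    """
    species = species or SPECIES_DEFAULTS[guild]
    config = config or (FLYING_CONFIG if guild == "flying" else DIVING_CONFIG)
    ss = np.random.SeedSequence(seed)
    field_seed, *ind_seeds = [int(s) for s in
                              ss.generate_state(1 + len(species) * n_per_species)]
    bfield = generate_baseline_field(field_spec_d13c, field_spec_d15n,
                                     seed=field_seed)
    m_lip, c_lip = lipid_model
    track_rows, plasma_rows, truth_rows = [], [], []
    i_seed = iter(ind_seeds)
    for sp_i, sp in enumerate(species):
        for j in range(n_per_species):
            sd = next(i_seed) % (2 ** 31)
            rng = np.random.default_rng(sd)
            bird = f"{sp}_{j:02d}"
            # spread individuals over latitude by giving each a persistent
            # initial heading (birds radiate from the colony)
            head = rng.uniform(-np.pi, np.pi)
            trip = simulate_track(config, seed=sd, individual_id=bird,
                                  species=sp, initial_heading_rad=head)
            samp = sample_plasma(trip, bfield, window_days=window_days,
                                 noise_sd=noise_sd, seed=sd + 1)
            contaminated = rng.random() < lipid_fraction
            if contaminated:
                samp = add_lipid_contamination(
                    samp, m_lip, c_lip, delta_cn=rng.uniform(0.2, 1.0))
            else:
                # paired aliquots: raw aliquot carries mild contamination
                raw = add_lipid_contamination(
                    samp, m_lip, c_lip, delta_cn=rng.uniform(0.0, 0.8))
                samp = replace(raw, d13c_del=samp.d13c_del, cn_del=samp.cn_del)
                samp.truth = raw.truth
            tdf = trip.df.copy()
            tdf.insert(0, "id", bird)
            tdf.insert(1, "species", sp)
            track_rows.append(tdf)
            plasma_rows.append({
                "id": bird, "species": sp,
                "d13c_raw": samp.d13c_raw, "d13c_del": samp.d13c_del,
                "d15n": samp.d15n, "cn_raw": samp.cn_raw,
                "cn_del": samp.cn_del, "blood_time": samp.blood_time})
            truth_rows.append(dict(samp.truth, id=bird, species=sp))
    tracks_df = pd.concat(track_rows, ignore_index=True)
    plasma_df = pd.DataFrame(plasma_rows)
    truth_df = pd.DataFrame(truth_rows)
    return tracks_df, plasma_df, bfield, truth_df
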