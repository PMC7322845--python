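"""Oceanographic fronts, water zones, and front-value back-calculation.

The three Southern Ocean fronts are fixed sea-surface-height contours
(sub-tropical 0.92 m, sub-Antarctic 0.03 m, Antarctic polar −0.48 m); the
four water zones they delimit partition the domain from sub-tropical (north
of the STF) to Antarctic (south of the APF). Isoscape surfaces are
summarised within a latitude band along each front and within each zone,
and species latitude regressions are evaluated at the nominal front
latitudes (Antarctic polar 51°S, sub-tropical 42°S) to back-calculate
front plasma values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from skimage import measure

from .errors import (AmbiguousZoneError, EmptyFeatureError,
                     FrontNotPresentError, InsufficientDataError,
                     WrongPredictorError)
from .isoscape import IsoscapeSurface, RegressionResult
from .synth import SshField

log = logging.getLogger(__name__)

#: canonical SSH levels (m) of the named fronts
FRONT_LEVELS = {"STF": 0.92, "SAF": 0.03, "APF": -0.48}
#: nominal evaluation latitudes (degrees south) for back-calculation
FRONT_LATITUDES = {"APF": 51.0, "STF": 42.0}
ZONES = ("STZ", "SAZ", "PFZ", "AZ")


@dataclass
class FrontLine:
    """A front as a polyline of (lon, lat) vertices at one SSH level."""

    name: str
    level: float
    vertices: np.ndarray  # (n, 2) lon, lat

    def latitude_at(self, lon) -> np.ndarray:
        """Front latitude at given longitudes (linear interpolation)."""
        v = self.vertices[np.argsort(self.vertices[:, 0])]
        return np.interp(np.asarray(lon, float), v[:, 0], v[:, 1])


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given number of decimals.

    Float fuzz is removed first (round to 9 decimals) so printed-precision
    arithmetic like 0.17*(−42) − 12.71 = −19.85 rounds to −19.9.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(round(float(x), 9))).quantize(q, rounding=ROUND_HALF_UP))


def extract_front(ssh: SshField, level: float, name: str = "") -> FrontLine:
    """Marching-squares contour of the SSH field at the given level.

    With several disjoint contours the longest (by path length) is taken and
    a note logged.
    """
    vmin, vmax = float(np.nanmin(ssh.values)), float(np.nanmax(ssh.values))
    if not (vmin <= level <= vmax):
        raise FrontNotPresentError(
            f"level {level} m outside SSH range [{vmin:.3f}, {vmax:.3f}]")
    contours = measure.find_contours(ssh.values, level)
    if not contours:
        raise FrontNotPresentError(f"no contour at {level} m")
    if len(contours) > 1:
        log.info("front %s: %d disjoint contours, keeping the longest",
                 name, len(contours))
    lengths = [np.sum(np.linalg.norm(np.diff(c, axis=0), axis=1)) for c in contours]
    c = contours[int(np.argmax(lengths))]
    lonc = ssh.grid.lon_centers()
    latc = ssh.grid.lat_centers()
    lon = np.interp(c[:, 1], np.arange(len(lonc)), lonc)
    lat = np.interp(c[:, 0], np.arange(len(latc)), latc)
    return FrontLine(name, level, np.column_stack([lon, lat]))


def classify_zone(point, fronts: dict) -> str:
    """Water zone of a (lon, lat) point given the three named fronts.

    Zones: STZ north of the STF, SAZ between STF and SAF, PFZ between SAF
    and APF, AZ south of the APF. A point exactly on a front is assigned to
    the zone north of it.
    """
    lon, lat = float(point[0]), float(point[1])
    stf = float(fronts["STF"].latitude_at(lon))
    saf = float(fronts["SAF"].latitude_at(lon))
    apf = float(fronts["APF"].latitude_at(lon))
    if not (apf < saf < stf):
        raise AmbiguousZoneError(
            f"fronts out of order at lon={lon}: APF={apf}, SAF={saf}, STF={stf}")
    if lat >= stf:
        return "STZ"
    if lat >= saf:
        return "SAZ"
    if lat >= apf:
        return "PFZ"
    return "AZ"


@dataclass
class FeatureSummary:
    """Mean ± SD of an isoscape over a front band or water zone."""

    feature: str
    isotope: str
    mean: float
    sd: float
    n_cells: int


def summarize_by_feature(surface: IsoscapeSurface, feature, *,
                         fronts: dict | None = None, band_deg: float = 1.0,
                         isotope: str = "") -> FeatureSummary:
    """Mean and sample SD of defined cells along a front or inside a zone.

    ``feature`` is a :class:`FrontLine` (cells whose centre latitude is
    within ``band_deg`` of the front's latitude at the cell's longitude) or
    a zone label string (cells classified into that zone; requires
    ``fronts``).
    """
    lon2d, lat2d = surface.grid.meshgrid_centers()
    defined = surface.defined()
    if isinstance(feature, FrontLine):
        fl = feature.latitude_at(lon2d)
        inband = np.abs(lat2d - fl) <= band_deg
        sel = defined & inband
        name = feature.name or f"front@{feature.level}m"
    else:
        if fronts is None:
            raise ValueError("zone summaries need the fronts dict")
        if feature not in ZONES:
            raise ValueError(f"unknown zone {feature!r}")
        stf = fronts["STF"].latitude_at(lon2d)
        saf = fronts["SAF"].latitude_at(lon2d)
        apf = fronts["APF"].latitude_at(lon2d)
        if not np.all((apf < saf) & (saf < stf)):
            raise AmbiguousZoneError("fronts out of order inside the surface extent")
        zone_sel = {"STZ": lat2d >= stf,
                    "SAZ": (lat2d >= saf) & (lat2d < stf),
                    "PFZ": (lat2d >= apf) & (lat2d < saf),
                    "AZ": lat2d < apf}[feature]
        sel = defined & zone_sel
        name = feature
    vals = surface.values[sel]
    if vals.size == 0:
        raise EmptyFeatureError(f"no defined cells in {name}")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return FeatureSummary(name, isotope or surface.provenance.get("isotope", ""),
                          float(vals.mean()), sd, int(vals.size))


def back_calculate_front_value(reg: RegressionResult, front_lat: float):
    """Evaluate a latitude regression at a front latitude (degrees south).

    Returns ``(value, rounded)`` where ``rounded`` is half-away-from-zero at
    one decimal — the convention that reproduces the published per-species
    front values from the printed regression coefficients.
    """
    if reg.predictor != "lat":
        raise WrongPredictorError(
            f"need a latitude regression, got {reg.predictor!r}")
    value = reg.slope * (-abs(front_lat)) + reg.intercept
    return float(value), round_half_away(value, 1)


def aggregate_across_species(values) -> tuple[float, float]:
    """Cross-species mean and sample SD (n−1), both reported at one decimal.

    Returns ``(mean, sd)`` rounded half away from zero; raises if fewer
    than two species values are supplied (SD undefined).
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise InsufficientDataError("need >= 2 species values for an SD")
    return (round_half_away(float(v.mean()), 1),
            round_half_away(float(v.std(ddof=1)), 1))
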