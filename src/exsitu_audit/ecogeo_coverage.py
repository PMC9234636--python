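"""Buffered geographic coverage and ecoregion coverage of ex situ sources.

Every known wild occurrence and every ex situ seed-source locality gets a
circular buffer (10/50/100 km by default); the buffers of each role are
dissolved into one polygon.  Geographic coverage is the dissolved ex-situ
area intersected with the dissolved in-situ area, as a percent of the
in-situ area.  Ecoregion coverage counts the distinct Level-III (coarse) and
Level-IV (fine) ecoregion polygons each dissolved buffer overlaps.

Points arrive as longitude/latitude degrees and are projected to an Albers
equal-area conic on the authalic sphere before buffering, so buffers are
planar circles and areas come out in km^2.  The projection's standard
parallels default to the 1/6 rule on the data's latitude span, which keeps
scale distortion well under the percent-level tolerances of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon, shape
from shapely.ops import unary_union

#: Authalic (equal-area) Earth radius, km.
EARTH_RADIUS_KM = 6371.0072

ROLES = ("in_situ", "ex_situ_source")
BUFFER_QUAD_SEGS = 64


@dataclass
class OccurrenceSet:
    """Occurrence points: lon, lat, role (in_situ / ex_situ_source), region."""

    points: pd.DataFrame  # columns lon, lat, role, region

    def __post_init__(self) -> None:
        df = self.points
        required = {"lon", "lat", "role", "region"}
        if not required.issubset(df.columns):
            raise ValueError(f"points need columns {sorted(required)}")
        bad = df[(df["lon"].abs() > 180) | (df["lat"].abs() > 90)]
        if len(bad):
            raise ValueError(f"invalid coordinates at rows {list(bad.index)[:5]}")
        bad_role = df[~df["role"].isin(ROLES)]
        if len(bad_role):
            raise ValueError(f"role must be one of {ROLES}")

    def coords(self, role: str | None = None, scope: str = "overall") -> np.ndarray:
        """Deduplicated (lon, lat) array for a role within a scope."""
        df = self.points
        if role is not None:
            df = df[df["role"] == role]
        if scope != "overall":
            df = df[df["region"] == scope]
        return df[["lon", "lat"]].drop_duplicates().to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


@dataclass
class EcoregionLayer:
    """Polygon layer with Level-III and Level-IV ecoregion identifiers."""

    features: pd.DataFrame  # columns level3, level4, geometry (shapely)

    def ids(self, level: str) -> pd.Series:
        col = {"III": "level3", "IV": "level4"}[level]
        return self.features[col]

    @classmethod
    def from_geojson(cls, path, level3_field: str = "level3",
                     level4_field: str = "level4") -> "EcoregionLayer":
        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj["features"]:
            props = feat["properties"]
            rows.append(
                {"level3": props[level3_field], "level4": props[level4_field],
                 "geometry": shape(feat["geometry"])}
            )
        if not rows:
            raise ValueError("ecoregion layer has no features")
        return cls(pd.DataFrame(rows))

    def to_geojson(self, path) -> None:
        feats = [
            {"type": "Feature",
             "properties": {"level3": r.level3, "level4": r.level4},
             "geometry": r.geometry.__geo_interface__}
            for r in self.features.itertuples()
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


@dataclass
class CoverageReport:
    """Geographic and ecoregion coverage per buffer radius and scope."""

    rows: pd.DataFrame
    # columns: method (geographic | ecoregion_III | ecoregion_IV), radius_km,
    # scope, conserved, total, percent

    def cell(self, method: str, radius_km: float, scope: str = "overall"):
        df = self.rows
        row = df[(df["method"] == method) & (df["radius_km"] == radius_km)
                 & (df["scope"] == scope)]
        if row.empty:
            raise KeyError((method, radius_km, scope))
        r = row.iloc[0]
        return float(r["percent"]), r["conserved"], r["total"]


# ---------------------------------------------------------------------------
# Equal-area projection
# ---------------------------------------------------------------------------


class AlbersEqualArea:
    """Spherical Albers equal-area conic projection, coordinates in km.

    Maps lon/lat degrees to planar x/y such that areas on the authalic sphere
    are preserved exactly; distances near the standard parallels are close to
    true, so a planar circle of radius r approximates a geodesic disc.
    """

    def __init__(self, lat1: float, lat2: float, lon0: float, lat0: float,
                 radius_km: float = EARTH_RADIUS_KM):
        phi1, phi2 = np.radians([lat1, lat2])
        self.R = radius_km
        self.lon0 = np.radians(lon0)
        self.n = (np.sin(phi1) + np.sin(phi2)) / 2.0
        if abs(self.n) < 1e-12:
            raise ValueError("standard parallels symmetric about the equator "
                             "degenerate the cone; shift them")
        self.C = np.cos(phi1) ** 2 + 2.0 * self.n * np.sin(phi1)
        self.rho0 = self._rho(np.radians(lat0))

    def _rho(self, phi):
        return self.R * np.sqrt(np.maximum(self.C - 2.0 * self.n * np.sin(phi), 0.0)) / self.n

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        theta = self.n * (lon - self.lon0)
        rho = self._rho(phi)
        return rho * np.sin(theta), self.rho0 - rho * np.cos(theta)

    @classmethod
    def for_points(cls, coords: np.ndarray) -> "AlbersEqualArea":
        """Projection fitted to a point cloud via the 1/6-rule parallels."""
        lat_min, lat_max = coords[:, 1].min(), coords[:, 1].max()
        span = max(lat_max - lat_min, 1.0)
        return cls(
            lat1=lat_min + span / 6.0, lat2=lat_max - span / 6.0,
            lon0=float(np.mean(coords[:, 0])), lat0=(lat_min + lat_max) / 2.0,
        )


# ---------------------------------------------------------------------------
# Coverage computations
# ---------------------------------------------------------------------------


def buffer_and_dissolve(
    occ: OccurrenceSet,
    radius_km: float,
    role: str,
    scope: str = "overall",
    projection: AlbersEqualArea | None = None,
):
    """Dissolved union of planar circular buffers around one role's points.

    Returns ``(polygon, area_km2)``.  Duplicate coordinates are deduplicated
    first and geometry validity is repaired (zero-width buffer) before the
    union.  Pass a shared ``projection`` when several polygons must live in
    the same plane (any coverage ratio does).
    """
    coords = occ.coords(role=role, scope=scope)
    if coords.shape[0] == 0:
        raise ValueError(f"no {role} points in scope {scope!r}")
    if projection is None:
        projection = AlbersEqualArea.for_points(occ.coords())
    x, y = projection.forward(coords[:, 0], coords[:, 1])
    discs = [Point(xi, yi).buffer(radius_km, quad_segs=BUFFER_QUAD_SEGS)
             for xi, yi in zip(x, y)]
    dissolved = unary_union(discs)
    if not dissolved.is_valid:
        dissolved = dissolved.buffer(0)
    return dissolved, float(dissolved.area)


def geographic_coverage(
    occ: OccurrenceSet,
    radius_km: float,
    scope: str = "overall",
    projection: AlbersEqualArea | None = None,
) -> tuple[float, float, float]:
    """Percent of the buffered wild range overlapped by ex situ source buffers.

    Returns ``(percent, conserved_km2, total_km2)`` where total is the
    dissolved in-situ buffer area and conserved is its intersection with the
    dissolved ex-situ-source buffer.
    """
    if projection is None:
        projection = AlbersEqualArea.for_points(occ.coords())
    insitu, total = buffer_and_dissolve(occ, radius_km, "in_situ", scope, projection)
    exsitu, _ = buffer_and_dissolve(occ, radius_km, "ex_situ_source", scope, projection)
    if total <= 0:
        raise ValueError("zero in situ buffered area")
    conserved = float(insitu.intersection(exsitu).area)
    return 100.0 * conserved / total, conserved, total


def ecoregion_coverage(
    occ: OccurrenceSet,
    radius_km: float,
    level: str,
    layer: EcoregionLayer,
    scope: str = "overall",
    projection: AlbersEqualArea | None = None,
) -> tuple[float, int, int]:
    """Coverage of overlapped ecoregions: percent, conserved count, total count.

    Total counts distinct ecoregion IDs at the level whose polygons intersect
    the dissolved in-situ buffer; conserved counts those also intersecting the
    dissolved ex-situ buffer.  Any nonzero-area overlap counts.
    """
    if projection is None:
        projection = AlbersEqualArea.for_points(occ.coords())
    insitu, _ = buffer_and_dissolve(occ, radius_km, "in_situ", scope, projection)
    exsitu, _ = buffer_and_dissolve(occ, radius_km, "ex_situ_source", scope, projection)

    ids = layer.ids(level)
    geoms = []
    for g in layer.features["geometry"]:
        lons, lats = np.array(g.exterior.coords).T if isinstance(g, Polygon) else (None, None)
        if lons is None:
            parts = []
            for part in g.geoms:
                px, py = projection.forward(*np.array(part.exterior.coords).T)
                parts.append(Polygon(np.column_stack([px, py])))
            proj_geom = MultiPolygon(parts)
        else:
            px, py = projection.forward(lons, lats)
            proj_geom = Polygon(np.column_stack([px, py]))
        if not proj_geom.is_valid:
            proj_geom = proj_geom.buffer(0)
        geoms.append(proj_geom)

    total_ids: set = set()
    conserved_ids: set = set()
    for rid, geom in zip(ids, geoms):
        inter_in = geom.intersection(insitu)
        if not inter_in.is_empty and inter_in.area > 0:
            total_ids.add(rid)
            inter_ex = geom.intersection(exsitu)
            if not inter_ex.is_empty and inter_ex.area > 0:
                conserved_ids.add(rid)
    if not total_ids:
        raise ValueError("no ecoregions intersect the in situ buffer")
    return (100.0 * len(conserved_ids) / len(total_ids),
            len(conserved_ids), len(total_ids))


def coverage_report(
    occ: OccurrenceSet,
    layer: EcoregionLayer | None = None,
    radii_km: tuple[float, ...] = (10.0, 50.0, 100.0),
    levels: tuple[str, ...] = ("III", "IV"),
    scopes: tuple[str, ...] = ("overall", "East", "West"),
) -> CoverageReport:
    """Full coverage table across radii, scopes, and ecoregion levels."""
    projection = AlbersEqualArea.for_points(occ.coords())
    rows = []
    for radius in radii_km:
        for scope in scopes:
            pct, cons, tot = geographic_coverage(occ, radius, scope, projection)
            rows.append({"method": "geographic", "radius_km": radius,
                         "scope": scope, "conserved": cons, "total": tot,
                         "percent": pct})
            if layer is not None:
                for level in levels:
                    pct, cons, tot = ecoregion_coverage(
                        occ, radius, level, layer, scope, projection
                    )
                    rows.append({"method": f"ecoregion_{level}",
                                 "radius_km": radius, "scope": scope,
                                 "conserved": cons, "total": tot,
                                 "percent": pct})
    return CoverageReport(rows=pd.DataFrame(rows))
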