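"""Haplogroup frequency surfaces: HV-I motif classification and IDW maps.

Hypervariable-segment-I haplotypes are assigned to U6 subclades by their
diagnostic control-region transition motifs (positions relative to rCRS):

====== ==========================================
U6a    16172, 16219, 16278
U6a1   U6a plus 16189
U6b    16172, 16219, 16311
U6b1   U6b plus 16163
U6c    16169, 16172, 16189
U6c1   U6c plus 16129
====== ==========================================

The most-derived matching class wins (U6b1 over U6b and so on). For mapping,
U6b and U6d are pooled as "U6bd" (U6d is rare and indistinguishable from U6b
at HV-I resolution). Per-population frequencies at sampling centroids are
interpolated onto a grid by inverse distance weighting with power two: every
site contributes with weight d^-2, a cell coincident with a site takes that
site's value exactly, and no search-radius cutoff is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .variants import SequenceProfile

HV1_RANGE = (16024, 16365)

#: diagnostic HV-I transition motifs, most derived first within each lineage
MOTIFS: dict[str, frozenset[int]] = {
    "U6a1": frozenset({16172, 16219, 16278, 16189}),
    "U6a": frozenset({16172, 16219, 16278}),
    "U6b1": frozenset({16172, 16219, 16311, 16163}),
    "U6b": frozenset({16172, 16219, 16311}),
    "U6c1": frozenset({16169, 16172, 16189, 16129}),
    "U6c": frozenset({16169, 16172, 16189}),
}

#: classes used for mapping; U6b and U6d pool as U6bd at HV-I resolution
MAP_CLASSES = ("U6", "U6a", "U6bd")


def classify_hv1(positions: Iterable[int],
                 allow_16189_back: bool = False) -> str:
    """Assign an HV-I haplotype (set of variant positions) to a subclade.

    The most-derived fully matching motif wins. With ``allow_16189_back``
    the notoriously unstable position 16189 is treated as a wildcard in
    motifs that require it (it back-mutates so often that its absence is
    weak evidence). Returns "U6-other" for haplotypes carrying the U6-like
    core (16172 with 16219 or 16169) without a complete motif, else
    "non-U6".
    """
    pos = frozenset(int(p) for p in positions)
    for cls, motif in MOTIFS.items():
        required = motif - {16189} if allow_16189_back else motif
        if required <= pos:
            return cls
    if 16172 in pos and (16219 in pos or 16169 in pos):
        return "U6-other"
    return "non-U6"


def map_class(cls: str) -> str:
    """Collapse a classification to its mapping class (U6b/U6d -> U6bd)."""
    if cls in ("U6b", "U6b1", "U6d"):
        return "U6bd"
    if cls.startswith("U6"):
        return {"U6a": "U6a", "U6a1": "U6a"}.get(cls, "U6")
    return cls


@dataclass
class SampleSite:
    """A population sampling centroid with per-class counts."""

    name: str
    lon: float
    lat: float
    n: int
    counts: dict[str, int] = field(default_factory=dict)
    flagged_small: bool = False

    def frequency(self, cls: str) -> float:
        if self.n == 0:
            raise ValueError(f"site {self.name!r} has no samples")
        c = self.counts.get(cls, 0)
        if c > self.n:
            raise ValueError(f"site {self.name!r}: count exceeds n")
        return c / self.n


def hv1_positions(profile: SequenceProfile) -> frozenset[int]:
    """Substituted HV-I positions of a whole-molecule profile."""
    return frozenset(v.position for v in profile.substitutions
                     if HV1_RANGE[0] <= v.position <= HV1_RANGE[1])


def site_frequencies(profiles: Sequence[SequenceProfile],
                     min_n: int = 5,
                     allow_16189_back: bool = False) -> list[SampleSite]:
    """Group classified profiles by population into sampling sites.

    The site coordinate is the centroid (mean) of the member samples'
    coordinates. Populations without coordinates or samples are dropped
    with a warning; sites with fewer than ``min_n`` samples are flagged.
    """
    import logging
    log = logging.getLogger("mthaplo")
    groups: dict[str, list[SequenceProfile]] = {}
    for p in profiles:
        if p.population is None:
            log.warning("profile %s has no population; skipped", p.sample_id)
            continue
        groups.setdefault(p.population, []).append(p)
    sites = []
    for popname in sorted(groups):
        members = groups[popname]
        coords = [(p.lon, p.lat) for p in members
                  if p.lon is not None and p.lat is not None]
        if not coords:
            log.warning("population %s has no coordinates; excluded", popname)
            continue
        lon = float(np.mean([c[0] for c in coords]))
        lat = float(np.mean([c[1] for c in coords]))
        counts: dict[str, int] = {}
        for p in members:
            cls = classify_hv1(hv1_positions(p), allow_16189_back)
            counts[cls] = counts.get(cls, 0) + 1
            mc = map_class(cls)
            if mc != cls and mc.startswith("U6"):
                counts[mc] = counts.get(mc, 0) + 1
            if cls.startswith("U6"):
                counts["U6"] = counts.get("U6", 0) + 1
        n = len(members)
        sites.append(SampleSite(popname, lon, lat, n, counts,
                                flagged_small=n < min_n))
    return sites


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid (plate carree); cell (0, 0) is the NW corner."""

    xllcorner: float
    yllcorner: float
    cellsize: float
    nrows: int
    ncols: int

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yllcorner + (self.nrows - 1 - np.arange(self.nrows) + 0.5) \
            * self.cellsize
        return np.meshgrid(xs, ys)

    @classmethod
    def covering(cls, lons, lats, cellsize: float, pad: float = 1.0):
        x0 = np.floor(min(lons) - pad)
        y0 = np.floor(min(lats) - pad)
        ncols = int(np.ceil((max(lons) + pad - x0) / cellsize))
        nrows = int(np.ceil((max(lats) + pad - y0) / cellsize))
        return cls(float(x0), float(y0), cellsize, nrows, ncols)


@dataclass
class FrequencySurface:
    """Gridded haplogroup frequency raster."""

    values: np.ndarray
    grid: GridSpec
    haplogroup: str = ""

    def write(self, path, nodata: float = -9999.0) -> None:
        from .io import write_ascii_grid
        write_ascii_grid(path, self.values, self.grid.xllcorner,
                         self.grid.yllcorner, self.grid.cellsize, nodata)


def _haversine(lon1, lat1, lon2, lat2):
    """Great-circle distance in kilometres (broadcasting)."""
    r = 6371.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) \
        * np.sin(dlmb / 2.0) ** 2
    return 2.0 * r * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def idw_interpolate(points: Sequence[tuple[float, float, float]] | Sequence[SampleSite],
                    grid: GridSpec,
                    power: float = 2.0,
                    haplogroup: str = "",
                    metric: str = "haversine") -> FrequencySurface:
    """Inverse-distance-weighted surface from (lon, lat, value) points.

    value(cell) = sum(w_i f_i) / sum(w_i) with w_i = d_i^-power; a cell
    whose centre coincides with a site takes that site's value exactly.
    All sites contribute (no neighbourhood cutoff). ``metric`` is
    "haversine" (great-circle, default) or "euclidean" (planar degrees).
    Duplicate coordinates with conflicting values raise.
    """
    if points and isinstance(points[0], SampleSite):
        if not haplogroup:
            raise ValueError("need a haplogroup to map SampleSites")
        pts = [(s.lon, s.lat, s.frequency(haplogroup)) for s in points]
    else:
        pts = [(float(a), float(b), float(c)) for a, b, c in points]
    if not pts:
        raise ValueError("need at least one site")
    seen: dict[tuple[float, float], float] = {}
    for lon, lat, val in pts:
        key = (lon, lat)
        if key in seen and seen[key] != val:
            raise ValueError(f"duplicate site at {key} with conflicting values")
        seen[key] = val
    lons = np.array([p[0] for p in pts])
    lats = np.array([p[1] for p in pts])
    vals = np.array([p[2] for p in pts])

    gx, gy = grid.cell_centers()
    if metric == "haversine":
        d = _haversine(gx[..., None], gy[..., None],
                       lons[None, None, :], lats[None, None, :])
    elif metric == "euclidean":
        d = np.sqrt((gx[..., None] - lons) ** 2 + (gy[..., None] - lats) ** 2)
    else:
        raise ValueError("metric must be 'haversine' or 'euclidean'")
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    out = np.empty(gx.shape)
    exact = d == 0.0
    any_exact = exact.any(axis=-1)
    w_masked = np.where(np.isinf(w), 0.0, w)
    num = (w_masked * vals).sum(axis=-1)
    den = w_masked.sum(axis=-1)
    out = num / den
    if any_exact.any():
        first_exact = exact.argmax(axis=-1)
        out = np.where(any_exact, vals[first_exact], out)
    return FrequencySurface(out, grid, haplogroup)
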