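"""Reading and validation of traps, captures and genotypes, and 3-D distances.

Trap coordinates are WGS84 longitude/latitude plus a height above ground in
meters.  Geographic distance between two sampled mosquitoes is the straight
(Euclidean) 3-D distance between their trap positions: horizontal distance on
a local metric plane centered on the trap centroid, combined with the height
difference.  Study areas span well under 5 km, where the local-plane error
relative to a true geodesic is far below 0.1%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_E2 = _WGS84_F * (2.0 - _WGS84_F)


class SpatialParseError(ValueError):
    """Malformed or inconsistent trap/capture/genotype input."""


@dataclass(frozen=True)
class TrapRecord:
    trap_id: str
    lon: float
    lat: float
    height: float  # meters above ground
    building_id: str
    floor: int

    def __post_init__(self):
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise SpatialParseError(
                f"trap {self.trap_id!r}: non-finite coordinate "
                f"(lon={self.lon}, lat={self.lat})"
            )
        if not math.isfinite(self.height) or self.height < 0:
            raise SpatialParseError(
                f"trap {self.trap_id!r}: height must be >= 0 m, got {self.height}"
            )


@dataclass(frozen=True)
class CaptureRecord:
    individual_id: str
    trap_id: str
    date: date


@dataclass
class GenotypeTable:
    """Individuals x biallelic SNPs, alt-allele dosage calls.

    ``calls`` is an int8 matrix with entries in {0, 1, 2} and -1 for missing.
    """

    individual_ids: list[str]
    site_ids: list[str]
    calls: np.ndarray
    n_multiallelic_skipped: int = 0

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individual_ids), len(self.site_ids)):
            raise SpatialParseError(
                "genotype matrix shape does not match id lists: "
                f"{self.calls.shape} vs ({len(self.individual_ids)}, {len(self.site_ids)})"
            )
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise SpatialParseError("genotype calls must be in {0,1,2} or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def missingness(self) -> np.ndarray:
        """Per-individual fraction of missing calls."""
        return (self.calls == -1).mean(axis=1)

    def subset(self, individual_ids) -> "GenotypeTable":
        index = {iid: k for k, iid in enumerate(self.individual_ids)}
        rows = [index[i] for i in individual_ids]
        return GenotypeTable(list(individual_ids), list(self.site_ids),
                             self.calls[rows], self.n_multiallelic_skipped)


def load_traps(path) -> dict[str, TrapRecord]:
    """Load a trap table CSV with columns trap_id,lon,lat,height,building,floor."""
    df = pd.read_csv(path, dtype={"trap_id": str, "building": str})
    required = ["trap_id", "lon", "lat", "height", "building", "floor"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpatialParseError(f"trap table missing column(s): {', '.join(missing)}")
    dupes = df["trap_id"][df["trap_id"].duplicated()].unique()
    if len(dupes):
        raise SpatialParseError(f"duplicate trap_id: {', '.join(map(str, dupes))}")
    traps: dict[str, TrapRecord] = {}
    for row in df.itertuples(index=False):
        try:
            lon, lat, height = float(row.lon), float(row.lat), float(row.height)
            floor = int(row.floor)
        except (TypeError, ValueError) as exc:
            raise SpatialParseError(
                f"trap {row.trap_id!r}: non-numeric coordinate/floor ({exc})"
            ) from exc
        traps[row.trap_id] = TrapRecord(row.trap_id, lon, lat, height,
                                        str(row.building), floor)
    return traps


def load_captures(path, traps: dict[str, TrapRecord]) -> list[CaptureRecord]:
    """Load a capture table CSV with columns individual_id,trap_id,date (ISO-8601)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "trap_id": str})
    required = ["individual_id", "trap_id", "date"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SpatialParseError(f"capture table missing column(s): {', '.join(missing)}")
    dupes = df["individual_id"][df["individual_id"].duplicated()].unique()
    if len(dupes):
        raise SpatialParseError(f"duplicate individual_id: {', '.join(map(str, dupes))}")
    records = []
    for row in df.itertuples(index=False):
        if row.trap_id not in traps:
            raise SpatialParseError(
                f"capture {row.individual_id!r} references unknown trap {row.trap_id!r}"
            )
        try:
            d = datetime.strptime(str(row.date), "%Y-%m-%d").date()
        except ValueError as exc:
            raise SpatialParseError(
                f"capture {row.individual_id!r}: unparseable date {row.date!r}"
            ) from exc
        records.append(CaptureRecord(row.individual_id, row.trap_id, d))
    return records


def load_genotypes(path) -> GenotypeTable:
    """Read diploid GT calls from a VCF into a dosage matrix.

    Multiallelic sites are skipped (count recorded); ``./.`` maps to missing.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise SpatialParseError(f"unreadable VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, site_ids = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        gts = variant.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        dosage = np.array([0, 1, -1, 2], dtype=np.int8)[gts]
        rows.append(dosage)
        site_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    vcf.close()
    if not rows:
        raise SpatialParseError(f"no biallelic sites in {path}")
    if n_multi:
        logger.info("skipped %d multiallelic site(s) in %s", n_multi, path)
    calls = np.stack(rows, axis=1)  # individuals x sites
    return GenotypeTable(samples, site_ids, calls, n_multiallelic_skipped=n_multi)


def _geodetic_to_ecef(lon_deg, lat_deg, h=0.0):
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    n = _WGS84_A / np.sqrt(1.0 - _WGS84_E2 * np.sin(lat) ** 2)
    x = (n + h) * np.cos(lat) * np.cos(lon)
    y = (n + h) * np.cos(lat) * np.sin(lon)
    z = (n * (1.0 - _WGS84_E2) + h) * np.sin(lat)
    return np.stack([x, y, z], axis=-1)


def local_plane_coordinates(lons, lats) -> np.ndarray:
    """Project lon/lat to east/north meters on a local plane at the centroid.

    WGS84 ECEF coordinates are rotated into the east-north-up frame of the
    point centroid; the east/north components are returned.  For extents under
    a few km the planar distances agree with geodesics to well below 0.1%.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lon0, lat0 = np.radians(lons.mean()), np.radians(lats.mean())
    ecef = _geodetic_to_ecef(lons, lats)
    origin = _geodetic_to_ecef(np.degrees(lon0), np.degrees(lat0))
    east = np.array([-np.sin(lon0), np.cos(lon0), 0.0])
    north = np.array([-np.sin(lat0) * np.cos(lon0),
                      -np.sin(lat0) * np.sin(lon0),
                      np.cos(lat0)])
    rel = ecef - origin
    return np.stack([rel @ east, rel @ north], axis=-1)


def trap_positions_3d(traps: dict[str, TrapRecord]) -> dict[str, np.ndarray]:
    """(east, north, height) meters for every trap, on a shared local plane."""
    ids = list(traps)
    en = local_plane_coordinates([traps[t].lon for t in ids],
                                 [traps[t].lat for t in ids])
    return {t: np.array([en[k, 0], en[k, 1], traps[t].height])
            for k, t in enumerate(ids)}


def distance_3d(a: TrapRecord, b: TrapRecord) -> float:
    """Euclidean 3-D distance in meters between two trap positions."""
    en = local_plane_coordinates([a.lon, b.lon], [a.lat, b.lat])
    horiz = float(np.hypot(*(en[0] - en[1])))
    return float(math.hypot(horiz, a.height - b.height))


@dataclass
class PairwiseDistances:
    """Per-individual 3-D distance matrix plus its ln-transformed copy.

    ``ln_meters`` is NaN where the distance is zero (same trap); such pairs
    are flagged in ``zero_pairs`` and must be excluded from ln-distance work.
    """

    individual_ids: list[str]
    meters: np.ndarray
    ln_meters: np.ndarray = field(repr=False)
    zero_pairs: list[tuple[str, str]] = field(default_factory=list)


def pairwise_distances(captures: list[CaptureRecord],
                       traps: dict[str, TrapRecord]) -> PairwiseDistances:
    """Symmetric matrix of 3-D trap distances between captured individuals."""
    for c in captures:
        if c.trap_id not in traps:
            raise SpatialParseError(
                f"capture {c.individual_id!r} references unknown trap {c.trap_id!r}"
            )
    pos = trap_positions_3d(traps)
    xyz = np.array([pos[c.trap_id] for c in captures])
    diff = xyz[:, None, :] - xyz[None, :, :]
    meters = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(meters, 0.0)
    ids = [c.individual_id for c in captures]
    with np.errstate(divide="ignore"):
        ln = np.where(meters > 0, np.log(np.where(meters > 0, meters, 1.0)), np.nan)
    iu, ju = np.triu_indices(len(ids), k=1)
    zero = [(ids[i], ids[j]) for i, j in zip(iu, ju) if meters[i, j] == 0.0]
    return PairwiseDistances(ids, meters, ln, zero)


def temporal_distances(captures: list[CaptureRecord]) -> tuple[list[str], np.ndarray]:
    """|date_i - date_j| in whole days for every pair of captures."""
    ordinals = np.array([c.date.toordinal() for c in captures], dtype=float)
    days = np.abs(ordinals[:, None] - ordinals[None, :])
    return [c.individual_id for c in captures], days
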