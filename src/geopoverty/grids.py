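"""Georeferenced grid layers: container, plain-text raster I/O, alignment, validation.

A :class:`GridLayer` is a single-band raster on a uniform north-up lattice:
row 0 is the northernmost row, cells are addressed ``(row, col)`` 0-based,
``origin`` is the (x, y) coordinate of the top-left corner of cell (0, 0),
and cell area is treated as uniform (no latitude correction).

Rasters are stored as a small plain-text format: a one-line header
``nrows,ncols,cell_size,origin_x,origin_y,nodata`` followed by the cell
values in row-major order, one grid row per line.
"""

from __future__ import annotations

import csv
import hashlib
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Semantic kinds a layer can carry; used by validation.
LAYER_KINDS = ("npp_trend", "mask", "travel_time", "population", "zone")

#: Layer names a complete analysis stack must provide.
STACK_LAYERS = (
    "npp_trend",
    "agri_mask",
    "urban_mask",
    "travel_time",
    "population_2000",
    "population_2010",
    "country_zone",
)

_LAYER_KIND = {
    "npp_trend": "npp_trend",
    "agri_mask": "mask",
    "urban_mask": "mask",
    "travel_time": "travel_time",
    "population_2000": "population",
    "population_2010": "population",
    "country_zone": "zone",
}

#: Region codes: the six developing regions plus the developed-country group.
REGION_CODES = ("EAP", "ECA", "LAC", "MENA", "SA", "SSA", "DEV")


class ConfigurationError(ValueError):
    """A required input (layer name, region mapping entry) is missing."""


class AlignmentError(ValueError):
    """Layers cannot be brought onto a common grid."""


class GridValidationError(ValueError):
    """A layer violates its domain invariants."""


@dataclass
class GridLayer:
    """One georeferenced 2-D variable (NPP trend, mask, travel time, population, zone ids)."""

    values: np.ndarray
    kind: str = "npp_trend"
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridValidationError("layer values must be a 2-D array")
        if self.kind not in LAYER_KINDS:
            raise GridValidationError(f"unknown layer kind {self.kind!r}")
        if self.cell_size <= 0:
            raise GridValidationError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data (not the nodata sentinel, not NaN).

        ``+inf`` travel times (unreachable cells) count as valid data.
        """
        with np.errstate(invalid="ignore"):
            return ~np.isnan(self.values) & (self.values != self.nodata)

    def same_geometry(self, other: "GridLayer") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "GridLayer":
        return replace(self, values=self.values.copy())


@dataclass
class LayerStack:
    """All layers of one analysis, mutually aligned, plus the zone->region mapping."""

    npp_trend: GridLayer
    agri_mask: GridLayer
    urban_mask: GridLayer
    travel_time: GridLayer
    population_2000: GridLayer
    population_2010: GridLayer
    country_zone: GridLayer
    region_map: dict[int, str] = field(default_factory=dict)
    country_names: dict[int, str] = field(default_factory=dict)

    def layers(self) -> dict[str, GridLayer]:
        return {name: getattr(self, name) for name in STACK_LAYERS}

    def zone_ids(self) -> np.ndarray:
        zl = self.country_zone
        vals = zl.values[zl.valid_mask()]
        return np.unique(vals.astype(int))


# ---------------------------------------------------------------------------
# plain-text raster I/O


def write_grid_csv(layer: GridLayer, path: str | Path) -> None:
    path = Path(path)
    nrows, ncols = layer.shape
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([nrows, ncols, layer.cell_size, layer.origin[0], layer.origin[1], layer.nodata])
        for row in layer.values:
            w.writerow([_fmt(v) for v in row])


def _fmt(v: float) -> str:
    if np.isposinf(v):
        return "inf"
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def read_grid_csv(path: str | Path, kind: str = "npp_trend") -> GridLayer:
    path = Path(path)
    try:
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            header = next(r)
            nrows, ncols = int(header[0]), int(header[1])
            cell_size = float(header[2])
            origin = (float(header[3]), float(header[4]))
            nodata = float(header[5])
            values = np.array([[float(v) for v in row] for row in r if row], dtype=float)
    except OSError as exc:
        raise OSError(f"cannot read raster file {path}: {exc}") from exc
    except (ValueError, StopIteration, IndexError) as exc:
        raise OSError(f"file {path} does not parse as a grid raster: {exc}") from exc
    if values.shape != (nrows, ncols):
        raise OSError(
            f"file {path}: header declares {nrows}x{ncols} but body has shape {values.shape}"
        )
    return GridLayer(values, kind=kind, cell_size=cell_size, origin=origin, nodata=nodata)


def read_region_map(path: str | Path) -> tuple[dict[int, str], dict[int, str]]:
    """Read a zone_id -> (country name, region code) mapping from CSV or YAML."""
    path = Path(path)
    regions: dict[int, str] = {}
    names: dict[int, str] = {}
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        for zid, entry in data.items():
            if isinstance(entry, dict):
                regions[int(zid)] = str(entry["region"])
                names[int(zid)] = str(entry.get("country_name", zid))
            else:
                regions[int(zid)] = str(entry)
                names[int(zid)] = str(zid)
    else:
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                zid = int(rec["zone_id"])
                regions[zid] = rec["region"].strip()
                names[zid] = rec.get("country_name", str(zid)).strip()
    bad = sorted(set(regions.values()) - set(REGION_CODES))
    if bad:
        raise ConfigurationError(f"unknown region codes in {path}: {bad}")
    return regions, names


def write_region_map(region_map: Mapping[int, str], names: Mapping[int, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["zone_id", "country_name", "region"])
        for zid in sorted(region_map):
            w.writerow([zid, names.get(zid, str(zid)), region_map[zid]])


# ---------------------------------------------------------------------------
# alignment


def align_to_reference(layer: GridLayer, reference: GridLayer) -> GridLayer:
    """Resample ``layer`` onto the geometry of ``reference`` by nearest neighbour.

    Each reference cell centre is mapped to the source cell containing it;
    reference cells falling outside the source extent become nodata.
    Nearest-neighbour is used for every layer kind, including population,
    to preserve mask/zone semantics; a change in the global population sum
    under resampling is logged as a warning.
    """
    if layer.same_geometry(reference):
        return layer.copy()

    rr, rc = reference.shape
    # reference cell-centre coordinates
    xs = reference.origin[0] + (np.arange(rc) + 0.5) * reference.cell_size
    ys = reference.origin[1] - (np.arange(rr) + 0.5) * reference.cell_size
    # source indices containing those centres
    col = np.floor((xs - layer.origin[0]) / layer.cell_size).astype(int)
    row = np.floor((layer.origin[1] - ys) / layer.cell_size).astype(int)
    ok_c = (col >= 0) & (col < layer.shape[1])
    ok_r = (row >= 0) & (row < layer.shape[0])
    if not ok_c.any() or not ok_r.any():
        raise AlignmentError("layer extent does not overlap the reference extent")
    out = np.full((rr, rc), layer.nodata, dtype=float)
    rgrid, cgrid = np.meshgrid(row, col, indexing="ij")
    inside = ok_r[:, None] & ok_c[None, :]
    out[inside] = layer.values[rgrid[inside], cgrid[inside]]

    if layer.kind == "population":
        src_sum = float(layer.values[layer.valid_mask()].sum())
        res = GridLayer(out, kind=layer.kind, cell_size=reference.cell_size,
                        origin=reference.origin, nodata=layer.nodata)
        new_sum = float(res.values[res.valid_mask()].sum())
        if abs(new_sum - src_sum) > 0:
            logger.warning(
                "population resampling changed the global sum: %.6g -> %.6g", src_sum, new_sum
            )
        return res
    return GridLayer(out, kind=layer.kind, cell_size=reference.cell_size,
                     origin=reference.origin, nodata=layer.nodata)


# ---------------------------------------------------------------------------
# stack loading and validation


def load_stack(
    paths: Mapping[str, str | Path],
    reference: str = "npp_trend",
    align: bool = True,
) -> LayerStack:
    """Read all stack layers (and the region map) from disk and align them.

    ``paths`` maps each name in :data:`STACK_LAYERS` plus ``"region_map"``
    to a file path. ``reference`` names the layer whose grid defines the
    common analysis geometry. Provenance (file names and SHA-256 checksums)
    is logged.
    """
    missing = [n for n in (*STACK_LAYERS, "region_map") if n not in paths]
    if missing:
        raise ConfigurationError(f"missing layer paths: {missing}")
    layers: dict[str, GridLayer] = {}
    for name in STACK_LAYERS:
        p = Path(paths[name])
        layers[name] = read_grid_csv(p, kind=_LAYER_KIND[name])
        logger.info("loaded %s from %s sha256=%s", name, p, _sha256(p))
    region_map, names = read_region_map(Path(paths["region_map"]))
    if align:
        ref = layers[reference]
        layers = {n: align_to_reference(l, ref) for n, l in layers.items()}
    stack = LayerStack(**layers, region_map=region_map, country_names=names)
    report = validate_stack(stack)
    if report.fatal:
        raise GridValidationError("stack fails validation:\n" + report.summary())
    return stack


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class Finding:
    layer: str
    fatal: bool
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)
    nodata_counts: dict[str, int] = field(default_factory=dict)

    @property
    def fatal(self) -> bool:
        return any(f.fatal for f in self.findings)

    def summary(self) -> str:
        buf = io.StringIO()
        for name, n in self.nodata_counts.items():
            buf.write(f"{name}: {n} nodata cells\n")
        for f in self.findings:
            buf.write(f"[{'FATAL' if f.fatal else 'warn'}] {f.layer}: {f.message}\n")
        if not self.findings:
            buf.write("no findings\n")
        return buf.getvalue()


def validate_stack(stack: LayerStack) -> ValidationReport:
    """Check alignment and per-layer domain invariants; never raises."""
    rep = ValidationReport()
    ref = stack.npp_trend
    for name, layer in stack.layers().items():
        rep.nodata_counts[name] = int((~layer.valid_mask()).sum())
        if not layer.same_geometry(ref):
            rep.findings.append(Finding(name, True, "not aligned with the reference geometry"))
        valid = layer.valid_mask()
        vals = layer.values[valid]
        if layer.kind == "mask":
            bad = ~np.isin(vals, (0.0, 1.0))
            if bad.any():
                idx = tuple(int(i) for i in np.argwhere(valid)[bad][0])
                rep.findings.append(
                    Finding(name, True, f"mask value outside {{0,1}} at cell {idx}")
                )
        elif layer.kind == "population":
            neg = vals < 0
            if neg.any():
                idx = tuple(int(i) for i in np.argwhere(valid)[neg][0])
                rep.findings.append(Finding(name, True, f"negative population at cell {idx}"))
        elif layer.kind == "travel_time":
            neg = vals < 0
            if neg.any():
                idx = tuple(int(i) for i in np.argwhere(valid)[neg][0])
                rep.findings.append(Finding(name, True, f"negative travel time at cell {idx}"))
        elif layer.kind == "zone":
            if vals.size and not np.allclose(vals, np.round(vals)):
                rep.findings.append(Finding(name, True, "non-integer zone id"))
    # region-map coverage
    present = set(stack.zone_ids().tolist())
    unmapped = sorted(present - set(stack.region_map))
    if unmapped:
        rep.findings.append(
            Finding("country_zone", True, f"zone ids missing from region_map: {unmapped}")
        )
    return rep


def analysis_mask(stack: LayerStack) -> np.ndarray:
    """Cells usable by the classifier: every needed layer carries data there.

    A nodata cell in any required layer excludes that cell from all
    tabulations (countries with missing coverage simply contribute less).
    """
    needed: Iterable[GridLayer] = (
        stack.npp_trend,
        stack.agri_mask,
        stack.travel_time,
        stack.country_zone,
    )
    m = np.ones(stack.npp_trend.shape, dtype=bool)
    for layer in needed:
        m &= layer.valid_mask()
    return m
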