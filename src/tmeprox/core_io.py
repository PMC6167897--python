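"""Domain types and readers/writers for cell tables, annotations and metrics.

Conventions
-----------
* Coordinates are continuous Cartesian microns; y increases downward (image
  convention); origin at the slide scan origin.
* Marker positivity is consumed as precomputed binary flags (0/1).  Calling
  flags from raw intensity is available as :func:`call_positivity` with a
  fixed per-marker cutoff.
* All areas are reported in mm^2; the micron/mm conversion lives in
  :data:`UM2_PER_MM2`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, shape, mapping

#: square microns per square millimetre — the single unit-conversion constant
UM2_PER_MM2 = 1.0e6

#: admissible values of the per-cell region label
REGION_LABELS = ("IT", "PT", "OUTSIDE", "EXCLUDED", "UNASSIGNED")

#: reserved (non-marker) column names in a cell-table CSV
RESERVED_COLUMNS = ("cell_id", "x_um", "y_um", "radius_um", "region", "lineage")

#: admissible annotation roles in a region GeoJSON
ANNOTATION_ROLES = ("tumor", "exclusion", "tissue")

RESPONSE_LABELS = ("CR", "PR", "SD", "PD", "NE")


class FormatError(ValueError):
    """A file does not conform to the expected tabular/GeoJSON layout."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class SpecimenMeta:
    """Specimen-level clinical metadata.

    ``responder`` is derived: objective response means complete (CR) or
    partial (PR) response.
    """

    specimen_id: str
    response: str = "NE"
    viral_status: str = "unknown"  # MCPyV+ | MCPyV- | unknown
    lesion: str = "primary"  # primary | metastasis

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_LABELS:
            raise ValidationError(
                f"response {self.response!r} not one of {RESPONSE_LABELS}"
            )

    @property
    def responder(self) -> bool:
        return self.response in ("CR", "PR")


class CellTable:
    """One section's segmented cells as a column-oriented table.

    Wraps a :class:`pandas.DataFrame` with the reserved columns ``cell_id``,
    ``x_um``, ``y_um``, ``radius_um`` plus one binary 0/1 column per marker.
    Row order is preserved through every operation; cell ids are unique
    within a section.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        markers: Sequence[str],
        specimen_id: str = "",
        section_id: str = "",
        validate: bool = True,
    ) -> None:
        data = data.copy()
        for col in ("x_um", "y_um"):
            if col not in data.columns:
                raise FormatError(f"cell table missing coordinate column {col!r}")
        if "cell_id" not in data.columns:
            data.insert(0, "cell_id", np.arange(len(data)))
        if "radius_um" not in data.columns:
            data["radius_um"] = 0.0
        if "region" not in data.columns:
            data["region"] = "UNASSIGNED"
        self.data = data
        self.markers = tuple(markers)
        self.specimen_id = specimen_id
        self.section_id = section_id
        self.attrs: dict = {}
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.data
        xy = df[["x_um", "y_um"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValidationError("non-finite cell coordinates")
        if np.any(df["radius_um"].to_numpy(float) < 0):
            raise ValidationError("negative cell radius")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValidationError(f"duplicate cell id {dup!r}")
        for m in self.markers:
            if m not in df.columns:
                raise FormatError(f"marker column {m!r} absent")
            vals = df[m].to_numpy()
            if len(vals) and not np.isin(vals, (0, 1)).all():
                raise ValidationError(f"marker {m!r} has non-binary values")
            df[m] = df[m].astype(np.int8)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of centroid coordinates in microns."""
        return self.data[["x_um", "y_um"]].to_numpy(float)

    @property
    def radii(self) -> np.ndarray:
        return self.data["radius_um"].to_numpy(float)

    def positive(self, marker: str) -> np.ndarray:
        """Boolean mask of cells positive for ``marker``."""
        if marker not in self.markers:
            raise KeyError(f"unknown marker {marker!r}; have {self.markers}")
        return self.data[marker].to_numpy() == 1

    def subset(self, mask: np.ndarray) -> "CellTable":
        """Row subset preserving order, ids and metadata."""
        out = CellTable(
            self.data.loc[mask].reset_index(drop=True),
            self.markers,
            self.specimen_id,
            self.section_id,
            validate=False,
        )
        out.attrs = dict(self.attrs)
        return out

    def copy(self) -> "CellTable":
        out = CellTable(
            self.data, self.markers, self.specimen_id, self.section_id, validate=False
        )
        out.attrs = dict(self.attrs)
        return out


@dataclass
class AnnotationSet:
    """Pathologist-style region annotations: tumor border polygons, exclusion
    polygons (acellular/necrotic areas removed from all analyses) and an
    optional outer tissue boundary.  All coordinates in microns."""

    tumor_polygons: list = field(default_factory=list)
    exclusion_polygons: list = field(default_factory=list)
    tissue_polygon: Polygon | None = None

    def __post_init__(self) -> None:
        for role, polys in (
            ("tumor", self.tumor_polygons),
            ("exclusion", self.exclusion_polygons),
            ("tissue", [self.tissue_polygon] if self.tissue_polygon else []),
        ):
            for p in polys:
                if not p.is_valid:
                    raise ValidationError(f"invalid (self-intersecting?) {role} polygon")
                coords = np.asarray(p.exterior.coords)
                if not np.all(np.isfinite(coords)):
                    raise ValidationError(f"non-finite vertex in {role} polygon")


def call_positivity(
    intensity: np.ndarray | pd.Series, cutoff: float
) -> np.ndarray:
    """Threshold a raw intensity vector into binary positivity flags
    (``intensity >= cutoff``)."""
    return (np.asarray(intensity, float) >= cutoff).astype(np.int8)


def read_cell_table(
    path: str | Path,
    markers: Sequence[str] | None = None,
    specimen_id: str = "",
    section_id: str = "",
    strict: bool = True,
) -> CellTable:
    """Read a per-cell CSV (columns ``cell_id, x_um, y_um[, radius_um]`` plus
    one 0/1 column per marker).

    When ``markers`` is omitted, every non-reserved column whose values are
    all in {0, 1} is taken as a marker; other columns are preserved untouched.
    Under ``strict`` a non-binary value in a declared marker column raises
    :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing coordinate column {col!r}")
    if markers is None:
        markers = [
            c
            for c in df.columns
            if c not in RESERVED_COLUMNS
            and (len(df) == 0 or np.isin(df[c].to_numpy(), (0, 1)).all())
        ]
    return CellTable(
        df, markers, specimen_id=specimen_id, section_id=section_id, validate=strict
    )


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a cell table back to CSV; exact round-trip of coordinates and
    flags (coordinates serialised with full float precision)."""
    df = table.data
    cols = [c for c in RESERVED_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection of region annotations.

    Each feature must carry a ``role`` property in {tumor, exclusion,
    tissue}; MultiPolygon features are split into their parts.  Coordinates
    are interpreted as microns.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path.name}: expected a GeoJSON FeatureCollection")
    out = AnnotationSet()
    for i, feat in enumerate(gj.get("features", [])):
        role = (feat.get("properties") or {}).get("role")
        if role not in ANNOTATION_ROLES:
            raise FormatError(
                f"{path.name}: feature {i} has role {role!r}; "
                f"allowed roles are {ANNOTATION_ROLES}"
            )
        geom = shape(feat["geometry"])
        parts = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
        for p in parts:
            if p.geom_type != "Polygon":
                raise FormatError(
                    f"{path.name}: feature {i} is {p.geom_type}, expected Polygon"
                )
            if not p.is_valid:
                raise ValidationError(
                    f"{path.name}: feature {i} ({role}) is self-intersecting"
                )
            if role == "tumor":
                out.tumor_polygons.append(p)
            elif role == "exclusion":
                out.exclusion_polygons.append(p)
            else:
                if out.tissue_polygon is not None:
                    raise ValidationError(f"{path.name}: multiple tissue features")
                out.tissue_polygon = p
    return out


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Serialise an :class:`AnnotationSet` as GeoJSON (role property set)."""
    feats = []
    for role, polys in (
        ("tumor", annotations.tumor_polygons),
        ("exclusion", annotations.exclusion_polygons),
        ("tissue", [annotations.tissue_polygon] if annotations.tissue_polygon else []),
    ):
        for p in polys:
            feats.append(
                {"type": "Feature", "properties": {"role": role}, "geometry": mapping(p)}
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary staining mask (single-channel TIFF or PNG; nonzero =
    positive).  The pixel size in microns is supplied separately by the
    caller — it is never inferred from image headers."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a single-channel mask")
    return arr


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as single-channel TIFF or PNG (by extension)."""
    path = Path(path)
    arr = (np.asarray(mask) != 0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr * 255).save(path)


def write_metrics(
    records: Iterable[Mapping] | pd.DataFrame, path: str | Path
) -> pd.DataFrame:
    """Write derived per-specimen metrics to CSV with a deterministic column
    order (first-appearance order across records) and return the frame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        records = list(records)
        cols: list[str] = []
        for rec in records:
            for k in rec:
                if k not in cols:
                    cols.append(k)
        df = pd.DataFrame(records, columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return df
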