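"""Point-annotation data model and I/O.

The counting method this package supports is click-based: a pathologist
places one marker per tumor nucleus on a calibrated ×40 microscope field,
first on Ki-67-positive (brown) nuclei, then on negative (blue) ones.  A
field is therefore a set of labelled points plus its physical geometry.

Coordinates use the image convention: origin at the field's top-left corner,
x rightward along the width, y downward along the height.  Internally all
coordinates are micrometres; pixel-unit files are converted on read using
the ``um_per_px`` calibration.  A marker exactly on the field border is
in-bounds (clicked nuclei may straddle edges).

Two interchange dialects are supported:

* CSV with columns ``case_id, field_id, x, y, label`` plus a YAML/JSON
  calibration sidecar (``width_um``, ``height_um``, optional ``um_per_px``);
  an optional leading ``# unit: um|px`` comment declares the unit.
* GeoJSON ``FeatureCollection`` of Point features with properties
  ``case_id``, ``field_id``, ``label``; the collection carries ``unit`` and
  ``calibration`` members, so GeoJSON files are self-contained.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.spatial import cKDTree

from .errors import (
    AnnotationFormatError,
    AnnotationValidationError,
    CalibrationError,
)

Unit = Literal["px", "um"]

CSV_COLUMNS = ("case_id", "field_id", "x", "y", "label")


class MarkerLabel(str, Enum):
    """Nucleus label: Ki-67 immunopositive or negative."""

    positive = "positive"
    negative = "negative"


class PointMarker(BaseModel):
    """One clicked nucleus, in micrometres from the field's top-left corner."""

    model_config = ConfigDict(frozen=True)

    x: float = Field(ge=0, allow_inf_nan=False)
    y: float = Field(ge=0, allow_inf_nan=False)
    label: MarkerLabel


class FieldGeometry(BaseModel):
    """Physical dimensions and pixel calibration of a microscope field."""

    model_config = ConfigDict(frozen=True)

    width_um: float = Field(gt=0, allow_inf_nan=False)
    height_um: float = Field(gt=0, allow_inf_nan=False)
    um_per_px: Optional[float] = Field(default=None, gt=0)
    objective_label: Optional[str] = None


#: The ×40 field of the reference acquisition setup: 310.3 × 232.72 μm.
PAPER_FIELD = FieldGeometry(width_um=310.3, height_um=232.72, objective_label="x40")


class FieldAnnotation(BaseModel):
    """A field's marker set plus its geometry.

    Marker order is the click order and is preserved through I/O round
    trips.  Every marker must lie inside the closed rectangle
    ``[0, width_um] x [0, height_um]``.
    """

    model_config = ConfigDict(frozen=True)

    field_id: str
    case_id: str
    geometry: FieldGeometry
    markers: tuple[PointMarker, ...] = ()

    @model_validator(mode="after")
    def _markers_in_bounds(self) -> "FieldAnnotation":
        w, h = self.geometry.width_um, self.geometry.height_um
        for i, m in enumerate(self.markers):
            if not (0.0 <= m.x <= w and 0.0 <= m.y <= h):
                raise ValueError(
                    f"marker {i} at ({m.x}, {m.y}) um is outside the "
                    f"{w} x {h} um field"
                )
        return self

    @property
    def n_positive(self) -> int:
        return sum(1 for m in self.markers if m.label is MarkerLabel.positive)

    @property
    def n_negative(self) -> int:
        return sum(1 for m in self.markers if m.label is MarkerLabel.negative)

    @property
    def n_total(self) -> int:
        return len(self.markers)


# ---------------------------------------------------------------------------
# calibration sidecars
# ---------------------------------------------------------------------------


def read_calibration(path: Path | str) -> FieldGeometry:
    """Read a YAML or JSON calibration sidecar into a :class:`FieldGeometry`."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise CalibrationError(f"cannot read calibration file {path}: {exc}") from exc
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise CalibrationError(f"calibration file {path} is not a mapping")
    try:
        return FieldGeometry(**data)
    except Exception as exc:
        raise CalibrationError(f"invalid calibration in {path}: {exc}") from exc


def write_calibration(geometry: FieldGeometry, path: Path | str) -> None:
    """Write a calibration sidecar (YAML for .yaml/.yml, JSON otherwise)."""
    path = Path(path)
    data = {k: v for k, v in geometry.model_dump().items() if v is not None}
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


def _find_sidecar(path: Path) -> Optional[Path]:
    candidates = [
        path.with_suffix(path.suffix + ext) for ext in (".yaml", ".yml", ".json")
    ] + [path.with_suffix(ext) for ext in (".yaml", ".yml", ".json")]
    for cand in candidates:
        if cand != path and cand.exists():
            return cand
    return None


def _to_um(x: float, y: float, unit: Unit, geometry: FieldGeometry) -> tuple[float, float]:
    if unit == "um":
        return x, y
    if geometry.um_per_px is None:
        raise CalibrationError(
            "markers are in pixels but the calibration has no um_per_px scale"
        )
    return x * geometry.um_per_px, y * geometry.um_per_px


def _from_um(x: float, y: float, unit: Unit, geometry: FieldGeometry) -> tuple[float, float]:
    if unit == "um":
        return x, y
    if geometry.um_per_px is None:
        raise CalibrationError(
            "cannot write pixel coordinates: calibration has no um_per_px scale"
        )
    return x / geometry.um_per_px, y / geometry.um_per_px


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _parse_label(value: object, where: str) -> MarkerLabel:
    try:
        return MarkerLabel(str(value))
    except ValueError:
        raise AnnotationValidationError(
            f"unknown label {value!r} at {where}; expected one of "
            f"{[m.value for m in MarkerLabel]}"
        ) from None


def _build_field(
    case_id: str,
    field_id: str,
    rows: Iterable[tuple[float, float, MarkerLabel, str]],
    unit: Unit,
    geometry: FieldGeometry,
) -> FieldAnnotation:
    markers = []
    w, h = geometry.width_um, geometry.height_um
    for x, y, label, where in rows:
        xu, yu = _to_um(x, y, unit, geometry)
        if not (0.0 <= xu <= w and 0.0 <= yu <= h):
            raise AnnotationValidationError(
                f"marker at {where} with coordinates ({xu:g}, {yu:g}) um lies "
                f"outside the {w} x {h} um field"
            )
        markers.append(PointMarker(x=xu, y=yu, label=label))
    return FieldAnnotation(
        field_id=field_id, case_id=case_id, geometry=geometry, markers=tuple(markers)
    )


def read_field_annotations(
    path: Path | str,
    unit: Optional[Unit] = None,
    geometry: Optional[FieldGeometry] = None,
) -> list[FieldAnnotation]:
    """Read per-field point annotations from CSV or GeoJSON.

    Parameters
    ----------
    path
        Annotation file.  ``.geojson``/``.json`` files are read as GeoJSON;
        anything else as CSV.
    unit
        Coordinate unit of the file.  For CSV, defaults to a leading
        ``# unit:`` comment if present, else pixels.  For GeoJSON, defaults
        to the collection's ``unit`` member.
    geometry
        Field calibration.  For CSV, defaults to a sidecar next to the file
        (``<name>.csv.yaml`` etc.); for GeoJSON, to the embedded
        ``calibration`` member.

    Returns
    -------
    list of :class:`FieldAnnotation`, grouped by (case_id, field_id) in
    first-appearance order, marker order preserved within each field.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationFormatError(f"annotation file not found: {path}")
    if path.suffix.lower() in {".geojson", ".json"}:
        return _read_geojson(path, unit=unit, geometry=geometry)
    return _read_csv(path, unit=unit, geometry=geometry)


def _read_csv(
    path: Path,
    unit: Optional[Unit],
    geometry: Optional[FieldGeometry],
) -> list[FieldAnnotation]:
    header_unit: Optional[Unit] = None
    n_comment_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.lstrip().startswith("#"):
                break
            n_comment_lines += 1
            decl = line.lstrip("# \t").strip().lower()
            if decl.startswith("unit:"):
                value = decl.split(":", 1)[1].strip()
                if value not in ("px", "um"):
                    raise AnnotationFormatError(
                        f"unrecognized unit {value!r} in header comment of {path}"
                    )
                header_unit = value  # type: ignore[assignment]
    if unit is None:
        unit = header_unit if header_unit is not None else "px"

    if geometry is None:
        sidecar = _find_sidecar(path)
        if sidecar is None:
            raise CalibrationError(
                f"no calibration given and no sidecar found next to {path}"
            )
        geometry = read_calibration(sidecar)

    df = pd.read_csv(path, comment="#", dtype={"case_id": str, "field_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationFormatError(
            f"{path} is missing required column(s): {', '.join(missing)}"
        )

    fields: list[FieldAnnotation] = []
    for (case_id, field_id), group in df.groupby(
        ["case_id", "field_id"], sort=False
    ):
        rows = []
        for idx, row in group.iterrows():
            # 1-based file line: data index + leading comments + header line
            where = f"row {idx + n_comment_lines + 2}"
            label = _parse_label(row["label"], where)
            try:
                x, y = float(row["x"]), float(row["y"])
            except (TypeError, ValueError):
                raise AnnotationValidationError(
                    f"non-numeric coordinates at {where}: "
                    f"({row['x']!r}, {row['y']!r})"
                ) from None
            if not (math.isfinite(x) and math.isfinite(y)):
                raise AnnotationValidationError(
                    f"non-finite coordinates at {where}: ({x}, {y})"
                )
            rows.append((x, y, label, where))
        fields.append(_build_field(str(case_id), str(field_id), rows, unit, geometry))
    return fields


def _read_geojson(
    path: Path,
    unit: Optional[Unit],
    geometry: Optional[FieldGeometry],
) -> list[FieldAnnotation]:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise AnnotationFormatError(f"{path} is not valid JSON: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise AnnotationFormatError(f"{path} is not a GeoJSON FeatureCollection")

    if unit is None:
        unit = doc.get("unit", "px")
        if unit not in ("px", "um"):
            raise AnnotationFormatError(f"unrecognized unit {unit!r} in {path}")
    if geometry is None:
        cal = doc.get("calibration")
        if cal is None:
            sidecar = _find_sidecar(path)
            if sidecar is None:
                raise CalibrationError(
                    f"{path} has no calibration member and no sidecar was found"
                )
            geometry = read_calibration(sidecar)
        else:
            try:
                geometry = FieldGeometry(**cal)
            except Exception as exc:
                raise CalibrationError(f"invalid calibration in {path}: {exc}") from exc

    grouped: dict[tuple[str, str], list] = {}
    for i, feat in enumerate(doc.get("features", [])):
        where = f"feature {i}"
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise AnnotationFormatError(f"{where} in {path} is not a Point feature")
        props = feat.get("properties") or {}
        for key in ("case_id", "field_id", "label"):
            if key not in props:
                raise AnnotationFormatError(
                    f"{where} in {path} is missing property {key!r}"
                )
        label = _parse_label(props["label"], where)
        x, y = geom["coordinates"][:2]
        grouped.setdefault((str(props["case_id"]), str(props["field_id"])), []).append(
            (float(x), float(y), label, where)
        )
    return [
        _build_field(case_id, field_id, rows, unit, geometry)
        for (case_id, field_id), rows in grouped.items()
    ]


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _common_geometry(fields: Sequence[FieldAnnotation]) -> Optional[FieldGeometry]:
    geoms = {f.geometry.model_dump_json() for f in fields}
    if len(geoms) > 1:
        raise CalibrationError(
            "fields with differing calibrations cannot share one annotation file"
        )
    return fields[0].geometry if fields else None


def write_field_annotations(
    fields: Sequence[FieldAnnotation],
    path: Path | str,
    unit: Unit = "um",
    write_sidecar: bool = True,
) -> None:
    """Write annotations to CSV or GeoJSON (re-readable by the reader).

    All fields in one file must share a calibration.  For CSV a calibration
    sidecar ``<path>.yaml`` is written unless ``write_sidecar`` is false;
    GeoJSON embeds the calibration.  Writing in pixels requires
    ``um_per_px``.
    """
    path = Path(path)
    geometry = _common_geometry(list(fields))
    if path.suffix.lower() in {".geojson", ".json"}:
        _write_geojson(fields, path, unit, geometry)
        return

    records = []
    for f in fields:
        for m in f.markers:
            x, y = _from_um(m.x, m.y, unit, f.geometry)
            records.append(
                {
                    "case_id": f.case_id,
                    "field_id": f.field_id,
                    "x": x,
                    "y": y,
                    "label": m.label.value,
                }
            )
    df = pd.DataFrame.from_records(records, columns=list(CSV_COLUMNS))
    try:
        with path.open("w", encoding="utf-8", newline="") as fh:
            fh.write(f"# unit: {unit}\n")
            df.to_csv(fh, index=False)
    except OSError as exc:
        raise AnnotationFormatError(f"cannot write {path}: {exc}") from exc
    if write_sidecar and geometry is not None:
        write_calibration(geometry, path.with_suffix(path.suffix + ".yaml"))


def _write_geojson(
    fields: Sequence[FieldAnnotation],
    path: Path,
    unit: Unit,
    geometry: Optional[FieldGeometry],
) -> None:
    features = []
    for f in fields:
        for m in f.markers:
            x, y = _from_um(m.x, m.y, unit, f.geometry)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [x, y]},
                    "properties": {
                        "case_id": f.case_id,
                        "field_id": f.field_id,
                        "label": m.label.value,
                    },
                }
            )
    doc: dict = {"type": "FeatureCollection", "unit": unit, "features": features}
    if geometry is not None:
        doc["calibration"] = {
            k: v for k, v in geometry.model_dump().items() if v is not None
        }
    try:
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
    except OSError as exc:
        raise AnnotationFormatError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def flag_near_duplicates(
    field: FieldAnnotation, min_separation_um: float
) -> list[tuple[int, int]]:
    """Flag marker pairs closer than ``min_separation_um`` (strictly).

    Returns sorted, unordered index pairs into ``field.markers``.  Pairs are
    flagged, never merged: the human click is ground truth in this method,
    so suspected double-clicks are surfaced for review only.  A threshold of
    zero flags nothing.
    """
    if min_separation_um < 0:
        raise ValueError("min_separation_um must be non-negative")
    n = len(field.markers)
    if min_separation_um == 0 or n < 2:
        return []
    pts = [(m.x, m.y) for m in field.markers]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=min_separation_um, output_type="ndarray")
    out = []
    for i, j in pairs:
        i, j = int(i), int(j)
        d = math.dist(pts[i], pts[j])
        if d < min_separation_um:  # query_pairs is <=; the contract is strict <
            out.append((min(i, j), max(i, j)))
    return sorted(out)
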