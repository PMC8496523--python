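"""Health-facility points and their GeoJSON representation."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError


@dataclass(frozen=True)
class Facility:
    """A candidate health-campaign point of care, in planar meters."""

    facility_id: str
    x: float
    y: float
    name: str = ""
    group: str = ""


def read_facilities(path) -> list[Facility]:
    """Read facilities from a GeoJSON FeatureCollection of Points."""
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for feat in fc.get("features", []):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(f"{path}: facility features must be Points")
        props = feat.get("properties") or {}
        x, y = geom["coordinates"][:2]
        out.append(Facility(facility_id=str(props.get("id")), x=float(x), y=float(y),
                            name=str(props.get("name", "")), group=str(props.get("group", ""))))
    ids = [f.facility_id for f in out]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate facility ids")
    return out


def write_facilities(facilities, path) -> None:
    feats = [{
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [f.x, f.y]},
        "properties": {"id": f.facility_id, "name": f.name, "group": f.group},
    } for f in facilities]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
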