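"""Parsing and labelling of local-expert disturbance reports.

Each report describes one monitored plot: geo-location, timestamp,
current canopy cover, evidence of disturbance and overall forest
status.  Provisional change-class labels follow a canopy-cover decision
rule — a disturbed plot whose canopy fell below the forest-definition
threshold (20% cover) is deforestation regardless of area cleared; a
disturbed plot still above the threshold is degradation; an undisturbed
forest plot is no-change and a non-forest plot is non-forest.  Final
labels are provisional labels optionally overridden by a human verifier
(photo/narrative review), with every override recorded in an audit log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import ALL_LABELS


@dataclass(frozen=True)
class DisturbanceReport:
    """One local-expert disturbance form."""

    report_id: str
    lon: float
    lat: float
    timestamp: float
    canopy_cover_pct: float | None
    disturbance_evidence: bool
    forest_status: str = "FOREST"
    photos: tuple[str, ...] = ()
    narrative: str = ""
    pixel: tuple[int, int] | None = None
    provisional_label: str | None = None
    final_label: str | None = None

    def __post_init__(self) -> None:
        if self.canopy_cover_pct is not None and not (
            0.0 <= self.canopy_cover_pct <= 100.0
        ):
            raise ValueError("canopy_cover_pct must lie in [0, 100]")
        if self.forest_status not in ("FOREST", "NONFOREST"):
            raise ValueError(f"invalid forest_status {self.forest_status!r}")
        for label in (self.provisional_label, self.final_label):
            if label is not None and label not in ALL_LABELS:
                raise ValueError(f"invalid label {label!r}")


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds of the change-class decision rule.

    ``canopy_threshold_pct`` is the forest-definition canopy cover
    below which a disturbed plot counts as deforested (default 20).
    The area-based degradation criterion (clearings smaller than an
    area threshold counted as degradation) is off by default.
    """

    canopy_threshold_pct: float = 20.0
    area_rule_enabled: bool = False
    area_threshold_ha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.canopy_threshold_pct < 100.0:
            raise ValueError("canopy threshold must lie in (0, 100)")


def assign_provisional_label(
    report: DisturbanceReport, rules: ClassificationRules | None = None
) -> DisturbanceReport:
    """Assign the automatic provisional change-class label.

    Decision rule: non-forest status -> NONFOREST; forest with
    disturbance evidence -> DEF if canopy < threshold else DEG; forest
    without evidence -> NOCH.
    """
    if rules is None:
        rules = ClassificationRules()
    if report.forest_status == "NONFOREST":
        return replace(report, provisional_label="NONFOREST")
    if report.canopy_cover_pct is None:
        raise ValueError(
            f"report {report.report_id}: canopy cover required for forest plots"
        )
    if report.disturbance_evidence:
        if report.canopy_cover_pct < rules.canopy_threshold_pct:
            label = "DEF"
        else:
            label = "DEG"
        if (
            rules.area_rule_enabled
            and label == "DEF"
            and getattr(report, "area_ha", None) is not None
        ):  # pragma: no cover - optional rule, off by default
            if report.area_ha < rules.area_threshold_ha:
                label = "DEG"
    else:
        label = "NOCH"
    return replace(report, provisional_label=label)


def finalize_labels(
    reports: Iterable[DisturbanceReport],
    overrides: Mapping[str, str] | None = None,
) -> tuple[list[DisturbanceReport], list[dict]]:
    """Apply verification overrides and return (reports, audit log).

    The final label equals the override where one is given, otherwise
    the provisional label.  Every override is recorded as an audit
    entry ``{report_id, from, to}``.
    """
    overrides = dict(overrides or {})
    reports = list(reports)
    known = {r.report_id for r in reports}
    for rid, label in overrides.items():
        if rid not in known:
            raise KeyError(f"override for unknown report id {rid!r}")
        if label not in ALL_LABELS:
            raise ValueError(f"invalid override label {label!r}")
    out = []
    audit: list[dict] = []
    for r in reports:
        if r.report_id in overrides:
            new = overrides[r.report_id]
            audit.append(
                {"report_id": r.report_id, "from": r.provisional_label, "to": new}
            )
            out.append(replace(r, final_label=new))
        else:
            out.append(replace(r, final_label=r.provisional_label))
    return out, audit


def filter_for_training(
    reports: Iterable[DisturbanceReport],
    supplements: Iterable[DisturbanceReport] = (),
) -> pd.DataFrame:
    """Build the labelled-location table used to train change models.

    Keeps deforestation and degradation reports, drops no-change and
    non-forest reports, then appends the supplied no-change supplement
    points (independently validated stable-forest locations) labelled
    NOCH.  Returns a DataFrame with columns
    ``report_id, lon, lat, timestamp, label, pixel_row, pixel_col``.
    """
    rows = []
    for r in reports:
        if r.final_label is None:
            raise ValueError(f"report {r.report_id} has no final label")
        if r.final_label in ("DEF", "DEG"):
            rows.append(_row(r, r.final_label))
    for s in supplements:
        rows.append(_row(s, "NOCH"))
    table = pd.DataFrame(
        rows,
        columns=[
            "report_id", "lon", "lat", "timestamp", "label",
            "pixel_row", "pixel_col",
        ],
    )
    if table.empty or table["label"].nunique() < 2:
        raise ValueError("training requires at least two classes of labelled points")
    return table


def _row(r: DisturbanceReport, label: str) -> dict:
    pr, pc = (r.pixel if r.pixel is not None else (np.nan, np.nan))
    return {
        "report_id": r.report_id,
        "lon": r.lon,
        "lat": r.lat,
        "timestamp": r.timestamp,
        "label": label,
        "pixel_row": pr,
        "pixel_col": pc,
    }


# ---------------------------------------------------------------------------
# I/O: GeoJSON points and CSV

def reports_to_geojson(reports: Iterable[DisturbanceReport], path) -> None:
    features = []
    for r in reports:
        props = {
            "report_id": r.report_id,
            "timestamp": r.timestamp,
            "canopy_cover_pct": r.canopy_cover_pct,
            "disturbance_evidence": r.disturbance_evidence,
            "forest_status": r.forest_status,
            "narrative": r.narrative,
            "provisional_label": r.provisional_label,
            "final_label": r.final_label,
        }
        if r.pixel is not None:
            props["pixel_row"], props["pixel_col"] = r.pixel
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r.lon, r.lat]},
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def reports_from_geojson(path) -> list[DisturbanceReport]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        lon, lat = feat["geometry"]["coordinates"]
        p = feat["properties"]
        pixel = None
        if "pixel_row" in p and p["pixel_row"] is not None:
            pixel = (int(p["pixel_row"]), int(p["pixel_col"]))
        out.append(
            DisturbanceReport(
                report_id=str(p["report_id"]),
                lon=float(lon),
                lat=float(lat),
                timestamp=float(p["timestamp"]),
                canopy_cover_pct=p.get("canopy_cover_pct"),
                disturbance_evidence=bool(p.get("disturbance_evidence", False)),
                forest_status=p.get("forest_status", "FOREST"),
                narrative=p.get("narrative", ""),
                pixel=pixel,
                provisional_label=p.get("provisional_label"),
                final_label=p.get("final_label"),
            )
        )
    return out


def write_audit_log(audit: list[dict], path) -> None:
    """Write override audit entries as line-delimited JSON."""
    with open(path, "w") as fh:
        for entry in audit:
            fh.write(json.dumps(entry) + "\n")


__all__ = [
    "DisturbanceReport",
    "ClassificationRules",
    "assign_provisional_label",
    "finalize_labels",
    "filter_for_training",
    "reports_to_geojson",
    "reports_from_geojson",
    "write_audit_log",
]
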