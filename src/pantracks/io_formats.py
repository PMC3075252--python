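"""Occurrence-table input and KML / TSV report output.

Input is a plain-text table, one record per line: taxon name, latitude,
longitude in decimal degrees.  NOTE the order: the input format is
lat, lon (the convention of field occurrence tables), while KML output is
lon,lat (the KML specification).  This inversion is deliberate, documented
and tested — silently swapping it is the classic bug of this format pair.

The delimiter (comma, tab, or whitespace) is auto-detected per file.
Malformed lines never abort the parse; they are collected, with line
numbers, into a validation report.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .geometry import GeoPoint, InputError
from .pipeline import AnalysisResult
from .tracks import SpeciesRecordSet, Track

__all__ = [
    "OccurrenceRecord",
    "ValidationReport",
    "read_records",
    "write_kml",
    "write_report",
    "read_kml_vertices",
]

KML_NS = "http://www.opengis.net/kml/2.2"


@dataclass(frozen=True)
class OccurrenceRecord:
    taxon: str
    lat: float
    lon: float
    line_no: int


@dataclass
class ValidationReport:
    """Per-file parse diagnostics: rejected lines and suspicious names."""

    n_lines: int = 0
    n_accepted: int = 0
    rejected: List[Tuple[int, str]] = field(default_factory=list)  # (line_no, reason)
    near_duplicate_names: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _detect_delimiter(lines: List[str]) -> str:
    """Pick the per-file delimiter: comma, tab, or whitespace."""
    n_comma = sum(1 for ln in lines if "," in ln)
    n_tab = sum(1 for ln in lines if "\t" in ln)
    if n_comma >= max(1, len(lines) // 2):
        return ","
    if n_tab >= max(1, len(lines) // 2):
        return "\t"
    return ""  # generic whitespace


def _parse_line(line: str, delim: str):
    if delim:
        fields = [f.strip() for f in line.split(delim)]
    else:
        fields = line.split()
    fields = [f for f in fields if f != ""]
    if len(fields) < 3:
        raise ValueError("expected taxon, latitude, longitude")
    taxon = fields[0]
    lat = float(fields[1])
    lon = float(fields[2])
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError("non-finite coordinate")
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} out of range [-90, 90]")
    if not -180.0 <= lon <= 180.0:
        raise ValueError(f"longitude {lon} out of range [-180, 180]")
    return taxon, lat, lon


def read_records(path) -> Tuple[List[SpeciesRecordSet], ValidationReport]:
    """Parse an occurrence table into per-species record sets.

    Records are grouped by exact taxon string (no case/underscore
    normalisation — near-identical names are only *warned* about in the
    report), preserving first-appearance order; points keep file order
    within each species.  Duplicate identical lines are kept: removing
    spatial duplicates is the cut value's job.

    Raises :class:`~pantracks.geometry.InputError` if the file is empty or
    every line is rejected; otherwise bad lines go into the report.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = fh.readlines()
    lines = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(raw)]
    content = [(no, ln) for no, ln in lines
               if ln.strip() and not ln.lstrip().startswith("#")]
    report = ValidationReport(n_lines=len(content))
    if not content:
        raise InputError(f"{path}: no occurrence records found")
    delim = _detect_delimiter([ln for _, ln in content])

    by_taxon: Dict[str, List[GeoPoint]] = {}
    for line_no, line in content:
        try:
            taxon, lat, lon = _parse_line(line, delim)
        except ValueError as exc:
            report.rejected.append((line_no, str(exc)))
            continue
        by_taxon.setdefault(taxon, []).append(GeoPoint(lon=lon, lat=lat))
        report.n_accepted += 1
    if report.n_accepted == 0:
        raise InputError(f"{path}: all {report.n_lines} lines rejected")

    # warn (never merge) on names identical up to case/underscore/space
    normalised: Dict[str, str] = {}
    for name in by_taxon:
        key = name.casefold().replace("_", " ").strip()
        if key in normalised and normalised[key] != name:
            report.near_duplicate_names.append((normalised[key], name))
        else:
            normalised[key] = name
    species = [SpeciesRecordSet(taxon=t, points=pts) for t, pts in by_taxon.items()]
    return species, report


# ---------------------------------------------------------------------------
# KML output
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _track_geometry(parent: ET.Element, track: Track) -> None:
    """Emit a track as a MultiGeometry of 2-point LineStrings.

    An MST generally branches, so a single LineString cannot represent it;
    each edge becomes its own LineString.  A 0-edge track is a Point.
    """
    multi = ET.SubElement(parent, "MultiGeometry")
    if not track.edges:
        p = track.vertices[0]
        pt = ET.SubElement(multi, "Point")
        ET.SubElement(pt, "coordinates").text = f"{_fmt(p.lon)},{_fmt(p.lat)},0"
        return
    for i, j in track.edges:
        a, b = track.vertices[i], track.vertices[j]
        ls = ET.SubElement(multi, "LineString")
        ET.SubElement(ls, "coordinates").text = (
            f"{_fmt(a.lon)},{_fmt(a.lat)},0 {_fmt(b.lon)},{_fmt(b.lat)},0"
        )


def _style(doc: ET.Element, style_id: str, color: str, width: str) -> None:
    st = ET.SubElement(doc, "Style", id=style_id)
    line = ET.SubElement(st, "LineStyle")
    ET.SubElement(line, "color").text = color  # KML aabbggrr
    ET.SubElement(line, "width").text = width


def write_kml(result: AnalysisResult, path) -> None:
    """Write the analysis as a KML 2.2 document.

    Two folders: "Individual tracks" (one placemark per species, named by
    taxon) and "Generalized tracks" (placemarks GT-1, GT-2, ... whose
    descriptions list the member taxa), with distinct line styles.
    Coordinates are lon,lat,0 to six decimals; output is byte-deterministic
    for a given result.
    """
    kml = ET.Element("kml", xmlns=KML_NS)
    doc = ET.SubElement(kml, "Document")
    ET.SubElement(doc, "name").text = "pantracks analysis"
    _style(doc, "individualTrack", "ff999999", "1")
    _style(doc, "generalizedTrack", "ff0000ff", "3")

    folder_ind = ET.SubElement(doc, "Folder")
    ET.SubElement(folder_ind, "name").text = "Individual tracks"
    for track in result.individual_tracks:
        pm = ET.SubElement(folder_ind, "Placemark")
        ET.SubElement(pm, "name").text = "+".join(sorted(track.taxa))
        ET.SubElement(pm, "styleUrl").text = "#individualTrack"
        _track_geometry(pm, track)

    folder_gen = ET.SubElement(doc, "Folder")
    ET.SubElement(folder_gen, "name").text = "Generalized tracks"
    for k, track in enumerate(result.generalized_tracks, start=1):
        pm = ET.SubElement(folder_gen, "Placemark")
        ET.SubElement(pm, "name").text = f"GT-{k}"
        ET.SubElement(pm, "description").text = ", ".join(sorted(track.taxa))
        ET.SubElement(pm, "styleUrl").text = "#generalizedTrack"
        _track_geometry(pm, track)

    data = ET.tostring(kml, encoding="UTF-8", xml_declaration=True)
    with open(path, "wb") as fh:
        fh.write(data)
        fh.write(b"\n")


def read_kml_vertices(path) -> List[Tuple[float, float]]:
    """All (lon, lat) coordinates in a KML file, in document order.

    Round-trip helper: parses the files produced by :func:`write_kml` (or
    any KML with <coordinates> elements) with a generic XML reader.
    """
    tree = ET.parse(path)
    out: List[Tuple[float, float]] = []
    for el in tree.getroot().iter(f"{{{KML_NS}}}coordinates"):
        for token in el.text.split():
            lon, lat = token.split(",")[:2]
            out.append((float(lon), float(lat)))
    return out


def write_report(result: AnalysisResult, path) -> None:
    """TSV track report: id, kind, taxa, vertex count, total length (degrees)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("track_id\tkind\ttaxa\tn_vertices\ttotal_length_deg\n")
        for track in result.individual_tracks:
            fh.write(f"{'+'.join(sorted(track.taxa))}\tindividual\t"
                     f"{';'.join(sorted(track.taxa))}\t{len(track.vertices)}\t"
                     f"{track.total_length:.6f}\n")
        for k, track in enumerate(result.generalized_tracks, start=1):
            fh.write(f"GT-{k}\tgeneralized\t{';'.join(sorted(track.taxa))}\t"
                     f"{len(track.vertices)}\t{track.total_length:.6f}\n")
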