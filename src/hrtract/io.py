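"""Plain-text readers and writers for marker maps and clone tables.

Marker maps use a small key/value config with a ``[markers]`` section, one
marker per line (``id  arm  distance  kind``).  Clone tables are wide TSV:
one row per clone with metadata columns followed by one column per
genotyped marker, in map order, holding calls from {V, C, S, N}.  Both
writers emit a canonical form so a write/read/write round trip is
byte-identical.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Union

from .markers import (
    CALLS,
    CloneRecord,
    CloneTable,
    Marker,
    MarkerMap,
    MECHANISMS,
    validate_map,
)

__all__ = [
    "read_marker_map",
    "write_marker_map",
    "read_clone_table",
    "write_clone_table",
    "MapFormatError",
    "TableFormatError",
]

PathLike = Union[str, Path]


class MapFormatError(ValueError):
    """A marker-map config could not be parsed or validated."""


class TableFormatError(ValueError):
    """A clone-table TSV could not be parsed or validated."""


_HEADER_KEYS = ("arm_length_left", "arm_length_right", "cassette_id")
_META_COLS = ("clone_id", "parent_id", "half_site", "selected", "truth_mechanism")


def write_marker_map(marker_map: MarkerMap, path: PathLike) -> None:
    lines = [
        f"arm_length_left = {marker_map.arm_length_left}",
        f"arm_length_right = {marker_map.arm_length_right}",
        f"cassette_id = {marker_map.cassette_id}",
        "[markers]",
        "# id\tarm\tdistance\tkind",
    ]
    for m in marker_map.markers:
        lines.append(f"{m.id}\t{m.arm}\t{m.distance}\t{m.kind}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_marker_map(path: PathLike) -> MarkerMap:
    """Parse a marker-map config; errors carry the offending line number."""
    header: dict[str, str] = {}
    markers: list[Marker] = []
    in_markers = False
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[markers]":
            in_markers = True
            continue
        if not in_markers:
            if "=" not in line:
                raise MapFormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
        else:
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 4:
                raise MapFormatError(
                    f"{path}:{lineno}: expected 4 fields (id, arm, distance, kind), "
                    f"got {len(fields)}"
                )
            mid, arm, dist_s, kind = fields
            if arm not in ("LEFT", "RIGHT"):
                raise MapFormatError(f"{path}:{lineno}: unknown arm {arm!r}")
            if kind not in ("SNP", "HAIRPIN", "HALF_SITE"):
                raise MapFormatError(f"{path}:{lineno}: unknown marker kind {kind!r}")
            try:
                dist = int(dist_s)
            except ValueError:
                raise MapFormatError(
                    f"{path}:{lineno}: distance must be an integer, got {dist_s!r}"
                ) from None
            if any(m.id == mid for m in markers):
                raise MapFormatError(f"{path}:{lineno}: duplicate marker id {mid!r}")
            markers.append(Marker(mid, arm, dist, kind))  # type: ignore[arg-type]

    for key in ("arm_length_left", "arm_length_right"):
        if key not in header:
            raise MapFormatError(f"{path}: missing header key {key!r}")
        try:
            header[key] = int(header[key])  # type: ignore[assignment]
        except ValueError:
            raise MapFormatError(f"{path}: {key} must be an integer") from None
    mm = MarkerMap(
        markers=markers,
        arm_length_left=int(header["arm_length_left"]),
        arm_length_right=int(header["arm_length_right"]),
        cassette_id=header.get("cassette_id", "NEO"),
    )
    problems = validate_map(mm)
    if problems:
        raise MapFormatError(f"{path}: invalid map: " + "; ".join(problems))
    return mm


def write_clone_table(table: CloneTable, path: PathLike) -> None:
    marker_ids = [m.id for m in table.map.genotyped_markers]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(list(_META_COLS) + marker_ids)
        for c in table.clones:
            w.writerow(
                [
                    c.clone_id,
                    c.parent_id or "",
                    "1" if c.half_site_present else "0",
                    "1" if c.selected else "0",
                    c.truth_mechanism or "",
                ]
                + [c.calls[m] for m in marker_ids]
            )


def read_clone_table(path: PathLike, marker_map: MarkerMap) -> CloneTable:
    """Read a wide clone-table TSV against a known marker map."""
    marker_ids = [m.id for m in marker_map.genotyped_markers]
    clones: list[CloneRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}: empty file") from None
        expected = list(_META_COLS) + marker_ids
        if header != expected:
            missing = [c for c in expected if c not in header]
            extra = [c for c in header if c not in expected]
            detail = []
            if missing:
                detail.append(f"missing columns {missing}")
            if extra:
                detail.append(f"unknown columns {extra}")
            raise TableFormatError(
                f"{path}: header does not match the marker map"
                + (": " + "; ".join(detail) if detail else " (column order)")
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(expected)} fields, got {len(row)}"
                )
            meta, callvals = row[: len(_META_COLS)], row[len(_META_COLS) :]
            clone_id, parent_id, half, selected, truth = meta
            calls = {}
            for mid, call in zip(marker_ids, callvals):
                if call not in CALLS:
                    raise TableFormatError(
                        f"{path}:{lineno}: clone {clone_id!r}, marker {mid!r}: "
                        f"invalid call {call!r} (expected one of {'/'.join(CALLS)})"
                    )
                calls[mid] = call
            if truth and truth not in MECHANISMS:
                raise TableFormatError(
                    f"{path}:{lineno}: unknown truth mechanism {truth!r}"
                )
            clones.append(
                CloneRecord(
                    clone_id=clone_id,
                    calls=calls,
                    half_site_present=half == "1",
                    selected=selected == "1",
                    truth_mechanism=truth or None,  # type: ignore[arg-type]
                    parent_id=parent_id or None,
                )
            )
    table = CloneTable(map=marker_map, clones=clones, provenance=str(path))
    problems = table.validate()
    if problems:
        raise TableFormatError(f"{path}: invalid table: " + "; ".join(problems))
    return table
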