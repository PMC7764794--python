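"""Point-cloud file I/O: PLY (ASCII and binary little-endian) and CSV.

The PLY dialect is the plain vertex-element one used by most point-cloud
tooling: ``x``/``y``/``z`` float properties, optional ``red``/``green``/
``blue`` uchar colour, and NIR intensity carried as a custom scalar
vertex property named ``nir`` (ushort); ``intensity`` is accepted as an
alias on read.  When only part of a cloud carries colour (the RGB and
depth imagers have different fields of view) a ``has_rgb`` uchar flag
property is written alongside the colour columns.

CSV files are comma-delimited UTF-8 with a header row
``x,y,z[,r,g,b][,nir]``; points lacking colour leave the r,g,b fields
empty.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cloud import PointCloud, ValidationError


class FormatError(ValueError):
    """Raised when a file does not parse as the expected format."""


_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}

_NIR_ALIASES = ("nir", "intensity")


def read_point_cloud(path: Union[str, Path], format: Optional[str] = None) -> PointCloud:
    """Read a point cloud from a PLY or CSV file.

    ``format`` is ``"ply"`` or ``"csv"``; when omitted it is inferred
    from the file suffix.  Point order is preserved; channels absent
    from the file are absent from the result (never zero-filled).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValidationError(f"unsupported format {fmt!r} (expected 'ply' or 'csv')")


def write_point_cloud(
    cloud: PointCloud,
    path: Union[str, Path],
    format: Optional[str] = None,
    binary: bool = True,
) -> None:
    """Write a point cloud to PLY or CSV, readable back losslessly
    (PLY coordinates are stored as float32)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "csv":
        _write_csv(cloud, path)
    else:
        raise ValidationError(f"unsupported format {fmt!r} (expected 'ply' or 'csv')")


# ---------------------------------------------------------------- PLY

def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise FormatError("missing 'ply' magic line")
        fmt = None
        n_vertices = None
        props: list[tuple[str, str]] = []  # (name, numpy dtype code)
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise FormatError("unterminated header (no 'end_header')")
            tokens = line.decode("ascii", errors="replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                if len(tokens) < 2 or tokens[1] not in (
                    "ascii", "binary_little_endian"
                ):
                    raise FormatError(f"unsupported format line: {line!r}")
                fmt = tokens[1]
            elif tokens[0] == "element":
                if len(tokens) != 3:
                    raise FormatError(f"malformed element line: {line!r}")
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    try:
                        n_vertices = int(tokens[2])
                    except ValueError:
                        raise FormatError(
                            f"non-integer vertex count: {tokens[2]!r}"
                        ) from None
                elif n_vertices is None:
                    raise FormatError(
                        f"unsupported leading element {tokens[1]!r} (vertex expected)"
                    )
            elif tokens[0] == "property":
                if not in_vertex:
                    continue  # properties of trailing elements are ignored
                if len(tokens) != 3 or tokens[1] == "list":
                    raise FormatError(f"unsupported property line: {line!r}")
                ptype, pname = tokens[1], tokens[2]
                if ptype not in _PLY_DTYPES:
                    raise FormatError(f"unknown property type {ptype!r}")
                props.append((pname, _PLY_DTYPES[ptype]))
            elif tokens[0] == "end_header":
                break
            else:
                raise FormatError(f"unrecognised header keyword {tokens[0]!r}")
        if fmt is None:
            raise FormatError("header has no 'format' line")
        if n_vertices is None:
            raise FormatError("header has no 'element vertex' line")
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise FormatError(f"vertex element lacks property {axis!r}")
        if fmt == "ascii":
            text = fh.read().decode("ascii")
            data = np.loadtxt(
                _io.StringIO(text), ndmin=2, max_rows=n_vertices or None
            )
            if n_vertices == 0:
                data = np.empty((0, len(props)))
            if data.shape != (n_vertices, len(props)):
                raise FormatError(
                    f"expected {n_vertices} x {len(props)} vertex values, "
                    f"got {data.shape}"
                )
            # honour the declared storage type (e.g. float32 coords)
            columns = {
                name: data[:, k].astype(code)
                for k, (name, code) in enumerate(props)
            }
        else:
            dtype = np.dtype([(name, "<" + code) for name, code in props])
            raw = fh.read(dtype.itemsize * n_vertices)
            if len(raw) != dtype.itemsize * n_vertices:
                raise FormatError("truncated binary vertex data")
            rec = np.frombuffer(raw, dtype=dtype)
            columns = {name: rec[name] for name, _ in props}

    coords = np.column_stack(
        [np.asarray(columns[a], dtype=np.float64) for a in ("x", "y", "z")]
    )
    rgb = None
    has_rgb = None
    if all(c in columns for c in ("red", "green", "blue")):
        rgb = np.column_stack(
            [columns["red"], columns["green"], columns["blue"]]
        ).astype(np.uint8)
        if "has_rgb" in columns:
            has_rgb = np.asarray(columns["has_rgb"]).astype(bool)
    nir = None
    for alias in _NIR_ALIASES:
        if alias in columns:
            nir = np.asarray(columns[alias]).astype(np.uint16)
            break
    return PointCloud(coords=coords, rgb=rgb, nir=nir, has_rgb=has_rgb)


def _write_ply(cloud: PointCloud, path: Path, binary: bool = True) -> None:
    parts: list[tuple[str, str, np.ndarray]] = [
        ("x", "float", cloud.coords[:, 0].astype("<f4")),
        ("y", "float", cloud.coords[:, 1].astype("<f4")),
        ("z", "float", cloud.coords[:, 2].astype("<f4")),
    ]
    partial_rgb = cloud.has_rgb is not None and not cloud.has_rgb.all()
    if cloud.rgb is not None:
        rgb = cloud.rgb.copy()
        if partial_rgb:
            rgb[~cloud.has_rgb] = 0
        parts += [
            ("red", "uchar", rgb[:, 0]),
            ("green", "uchar", rgb[:, 1]),
            ("blue", "uchar", rgb[:, 2]),
        ]
        if partial_rgb:
            parts.append(("has_rgb", "uchar", cloud.has_rgb.astype(np.uint8)))
    if cloud.nir is not None:
        parts.append(("nir", "ushort", cloud.nir.astype("<u2")))

    header = ["ply"]
    header.append(
        "format binary_little_endian 1.0" if binary else "format ascii 1.0"
    )
    header.append(f"element vertex {cloud.n_points}")
    header += [f"property {ptype} {name}" for name, ptype, _ in parts]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = np.empty(
                cloud.n_points,
                dtype=[(name, arr.dtype) for name, _, arr in parts],
            )
            for name, _, arr in parts:
                rec[name] = arr
            fh.write(rec.tobytes())
        else:
            cols = [arr for _, _, arr in parts]
            for row in zip(*cols):
                fh.write(
                    (" ".join(_ascii_value(v) for v in row) + "\n").encode("ascii")
                )


def _ascii_value(v) -> str:
    if np.issubdtype(np.asarray(v).dtype, np.integer):
        return str(int(v))
    return np.format_float_positional(np.float32(v), unique=True, trim="0")


# ---------------------------------------------------------------- CSV

def _read_csv(path: Path) -> PointCloud:
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    for axis in ("x", "y", "z"):
        if axis not in df.columns:
            raise FormatError(f"CSV header lacks column {axis!r}")
    coords = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    rgb = None
    has_rgb = None
    if all(c in df.columns for c in ("r", "g", "b")):
        cols = df[["r", "g", "b"]]
        present = cols.notna().all(axis=1).to_numpy()
        rgb = np.zeros((len(df), 3), dtype=np.uint8)
        rgb[present] = cols.to_numpy(dtype=float)[present].astype(np.uint8)
        has_rgb = present
    nir = None
    for alias in _NIR_ALIASES:
        if alias in df.columns:
            nir = df[alias].to_numpy(dtype=np.uint16)
            break
    return PointCloud(coords=coords, rgb=rgb, nir=nir, has_rgb=has_rgb)


def _write_csv(cloud: PointCloud, path: Path) -> None:
    data: dict = {
        "x": cloud.coords[:, 0],
        "y": cloud.coords[:, 1],
        "z": cloud.coords[:, 2],
    }
    if cloud.rgb is not None:
        mask = (
            cloud.has_rgb
            if cloud.has_rgb is not None
            else np.ones(cloud.n_points, dtype=bool)
        )
        for k, name in enumerate("rgb"):
            col = cloud.rgb[:, k].astype(object)
            col[~mask] = None  # empty field for colourless points
            data[name] = col
    if cloud.nir is not None:
        data["nir"] = cloud.nir
    # %.17g round-trips float64 exactly
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
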