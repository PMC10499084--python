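"""Reading experimental load-displacement files.

The expected format is plain text with two numeric columns (displacement,
force), comma or whitespace separated.  Metadata lives in leading ``#``
comment lines as ``key: value`` (or ``key = value``) pairs::

    # R: 25e-6
    # W_over_R: 20
    # H_over_R: 10
    # depth_unit: um
    # force_unit: uN
    0.0   0.0
    0.5   0.012
    ...

``R`` is given in metres (or in ``depth_unit`` via ``R_unit``).  Anything
in the metadata can instead be supplied by the caller, which wins over
the file.  Output is an :class:`~indentml.curves.IndentationCurve` in
canonical SI units (m, N), sorted and strictly increasing in depth, with
an optional leading pre-contact baseline trimmed and re-zeroed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .curves import IndentationCurve, SampleGeometry

__all__ = ["read_curve_file", "UNIT_FACTORS"]

logger = logging.getLogger(__name__)

UNIT_FACTORS = {
    "m": 1.0, "mm": 1.0e-3, "um": 1.0e-6, "nm": 1.0e-9,
    "N": 1.0, "mN": 1.0e-3, "uN": 1.0e-6, "nN": 1.0e-9,
}


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body:
            continue
        for sep in (":", "="):
            if sep in body:
                key, _, val = body.partition(sep)
                meta[key.strip()] = val.strip()
                break
    return meta


def read_curve_file(
    path,
    units: dict | None = None,
    geometry: SampleGeometry | None = None,
    *,
    trim_baseline: float | None = None,
) -> IndentationCurve:
    """Read a two-column (displacement, force) text file to SI units.

    Parameters
    ----------
    units:
        Optional ``{"depth": ..., "force": ...}`` unit names (see
        ``UNIT_FACTORS``); overrides the file's ``depth_unit`` /
        ``force_unit`` metadata.  Defaults to SI.
    geometry:
        Overrides ``R`` / ``W_over_R`` / ``H_over_R`` metadata.
    trim_baseline:
        If set, leading points whose force is at or below this fraction
        of the maximum force are treated as pre-contact baseline: they
        are dropped and the depth axis is re-zeroed at the first retained
        point.  Default assumes the file starts at contact.

    Raises
    ------
    ValueError
        On malformed rows (with the line number), missing geometry
        metadata, or non-monotone displacement after cleaning.
    """
    path = Path(path)
    header: list[str] = []
    rows: list[tuple[float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            header.append(stripped)
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected two columns (displacement, force), "
                f"got {len(parts)}"
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    if len(rows) < 2:
        raise ValueError(f"{path}: need at least two data rows")
    meta = _parse_meta(header)

    units = units or {}
    depth_unit = units.get("depth", meta.get("depth_unit", "m"))
    force_unit = units.get("force", meta.get("force_unit", "N"))
    try:
        d_fac, f_fac = UNIT_FACTORS[depth_unit], UNIT_FACTORS[force_unit]
    except KeyError as exc:
        raise ValueError(f"unknown unit {exc.args[0]!r}") from None

    data = np.asarray(rows, dtype=float)
    depth = data[:, 0] * d_fac
    force = data[:, 1] * f_fac

    if geometry is None:
        try:
            R = float(meta["R"]) * UNIT_FACTORS[meta.get("R_unit", "m")]
            if "W_over_R" in meta:
                w, h = float(meta["W_over_R"]), float(meta["H_over_R"])
            else:
                w = float(meta["W"]) * d_fac / R
                h = float(meta["H"]) * d_fac / R
            geometry = SampleGeometry(R, w, h)
        except KeyError as exc:
            raise ValueError(
                f"{path}: missing geometry metadata {exc.args[0]!r} "
                "(pass geometry= or add '# key: value' header lines)"
            ) from None

    order = np.argsort(depth, kind="stable")
    depth, force = depth[order], force[order]
    keep = np.concatenate([[True], np.diff(depth) > 0])
    if not keep.all():
        logger.info("%s: dropped %d duplicate-depth rows", path, int((~keep).sum()))
        depth, force = depth[keep], force[keep]
    if np.any(np.diff(depth) <= 0):
        raise ValueError(f"{path}: displacement not strictly increasing after cleaning")

    if trim_baseline is not None:
        threshold = trim_baseline * force.max()
        start = 0
        while start < len(force) - 1 and force[start] <= threshold:
            start += 1
        depth, force = depth[start:] - depth[start], force[start:]
        force = force - force[0]

    force = np.clip(force, 0.0, None)
    if len(depth) < 2:
        raise ValueError(f"{path}: fewer than two points remain after trimming")
    return IndentationCurve(depth, force, geometry.R, geometry)
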