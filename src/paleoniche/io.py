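"""Standard-format I/O: ESRI ASCII grids, scenario directories, occurrence CSV.

Scenarios are stored as one ESRI ASCII grid (``.asc``) per variable plus a
``scenario.json`` sidecar recording the label and band order; nodata cells
encode the validity mask.  Occurrences travel as CSV with the header
``id,x,y,period``.  All writers are deterministic (no timestamps), so
identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .scenario import EnvScenario, GridTransform, OccurrenceSet

NODATA = -9999.0


def write_ascii_grid(path: str | Path, array: np.ndarray, transform: GridTransform,
                     mask: np.ndarray | None = None, nodata: float = NODATA) -> None:
    """Write a single band as an ESRI ASCII grid (north-up, row-major)."""
    array = np.asarray(array, dtype=float)
    out = array.copy()
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = nodata
    n_rows, n_cols = out.shape
    lines = [
        f"ncols {n_cols}",
        f"nrows {n_rows}",
        f"xllcorner {transform.xll!r}",
        f"yllcorner {transform.yll!r}",
        f"cellsize {transform.cellsize!r}",
        f"NODATA_value {nodata!r}",
    ]
    lines += [" ".join(f"{v:.12g}" for v in row) for row in out]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, GridTransform]:
    """Read an ESRI ASCII grid; returns (values, valid_mask, transform)."""
    text = Path(path).read_text().strip().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise InvalidParameterError(f"{path}: missing header field {key}")
    nodata = header.get("nodata_value", NODATA)
    values = np.array([[float(v) for v in line.split()] for line in text[i:]])
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise InvalidParameterError(
            f"{path}: data shape {values.shape} does not match header")
    mask = values != nodata
    transform = GridTransform(header["xllcorner"], header["yllcorner"],
                              header["cellsize"])
    return values, mask, transform


def write_scenario(scenario: EnvScenario, directory: str | Path) -> list[Path]:
    """One .asc per variable plus a scenario.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, var in enumerate(scenario.variables):
        p = directory / f"{var}.asc"
        write_ascii_grid(p, scenario.values[i], scenario.transform, scenario.mask)
        written.append(p)
    sidecar = directory / "scenario.json"
    sidecar.write_text(json.dumps(
        {"label": scenario.label, "variables": list(scenario.variables),
         "format_version": 1}, indent=1, sort_keys=True))
    written.append(sidecar)
    return written


def read_scenario(directory: str | Path) -> EnvScenario:
    directory = Path(directory)
    sidecar = json.loads((directory / "scenario.json").read_text())
    bands, masks, transforms = [], [], []
    for var in sidecar["variables"]:
        values, mask, tfm = read_ascii_grid(directory / f"{var}.asc")
        bands.append(values)
        masks.append(mask)
        transforms.append(tfm)
    if any(t != transforms[0] for t in transforms):
        raise InvalidParameterError(f"{directory}: bands have mismatched transforms")
    if any(m.shape != masks[0].shape or not np.array_equal(m, masks[0]) for m in masks):
        raise InvalidParameterError(f"{directory}: bands have mismatched masks")
    values = np.stack(bands)
    values[:, ~masks[0]] = 0.0  # nodata placeholder off-mask
    return EnvScenario(sidecar["label"], tuple(sidecar["variables"]), values,
                       masks[0], transforms[0])


def write_occurrences(occ_sets: list[OccurrenceSet], path: str | Path) -> None:
    rows = [{"id": sid, "x": x, "y": y, "period": occ.period}
            for occ in occ_sets for sid, x, y in occ.sites]
    pd.DataFrame(rows, columns=["id", "x", "y", "period"]).to_csv(path, index=False)


def read_occurrences(path: str | Path,
                     allowed_periods: list[str] | None = None
                     ) -> dict[str, OccurrenceSet]:
    """Read occurrences CSV; returns one OccurrenceSet per period label.

    Malformed rows are reported with their line numbers; duplicate ids and
    period labels outside the allowed vocabulary are errors.
    """
    df = pd.read_csv(path, dtype={"id": str, "period": str})
    required = ["id", "x", "y", "period"]
    if list(df.columns[:4]) != required:
        raise InvalidParameterError(
            f"{path}: header must be id,x,y,period, got {list(df.columns)}")
    bad_lines = [int(i) + 2 for i in  # +2: header line and 1-based numbering
                 df.index[df[["id", "x", "y", "period"]].isna().any(axis=1)
                          | ~df["x"].apply(np.isreal) | ~df["y"].apply(np.isreal)]]
    if bad_lines:
        raise InvalidParameterError(f"{path}: malformed rows at lines {bad_lines}")
    dupes = df["id"][df["id"].duplicated()].unique().tolist()
    if dupes:
        raise InvalidParameterError(f"{path}: duplicate ids {dupes}")
    if allowed_periods is not None:
        unknown = sorted(set(df["period"]) - set(allowed_periods))
        if unknown:
            raise InvalidParameterError(
                f"{path}: period labels {unknown} not in {sorted(allowed_periods)}")
    out: dict[str, OccurrenceSet] = {}
    for period, grp in df.groupby("period", sort=True):
        sites = [(str(r.id), float(r.x), float(r.y)) for r in grp.itertuples()]
        out[str(period)] = OccurrenceSet(str(period), sites)
    return out


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))
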