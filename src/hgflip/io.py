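"""Text formats: COLVAR-style time series, FES tables, window metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fes import FESGrid
from .geometry import TorsionSeries
from .umbrella import UmbrellaWindow, WindowGrid


class FormatError(ValueError):
    pass


def write_colvar(path, series):
    """Write a (time, cpdb, chi) series in COLVAR-style whitespace text."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cpdb chi\n")
        for t, c, x in zip(series.times, series.cpdb, series.chi):
            fh.write(f"{t:.6f} {c:.10g} {x:.10g}\n")


def read_colvar(path):
    """Parse a COLVAR-style file into a TorsionSeries.

    The header line ``#! FIELDS ...`` names the columns; ``cpdb`` and
    ``chi`` are required (``time`` defaults to the row index).  Comment
    lines and extra columns are ignored; angles are wrapped.
    """
    path = Path(path)
    fields = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                tokens = line[2:].split()
                if tokens and tokens[0] == "FIELDS":
                    fields = tokens[1:]
                continue
            if line.startswith("#"):
                continue
            rows.append(line.split())
    if fields is None:
        raise FormatError(f"{path}: missing '#! FIELDS' header line")
    for req in ("cpdb", "chi"):
        if req not in fields:
            raise FormatError(f"{path}: required field {req!r} missing "
                              f"from header {fields}")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    ncol = len(fields)
    data = np.array([[float(v) for v in r[:ncol]] for r in rows])
    if data.shape[1] < ncol:
        raise FormatError(f"{path}: rows have fewer columns than the header")
    cpdb = data[:, fields.index("cpdb")]
    chi = data[:, fields.index("chi")]
    times = (data[:, fields.index("time")] if "time" in fields
             else np.arange(len(rows), dtype=float))
    return TorsionSeries(times, cpdb, chi)


def write_fes(fes, path):
    """Write an FESGrid as TSV plus a JSON sidecar with grid metadata."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# cpdb_center\tchi_center\tF_kcal_mol\tsampled\n")
        cc, xc = fes.cpdb_centers, fes.chi_centers
        for i in range(len(cc)):
            for j in range(len(xc)):
                f = fes.F[i, j]
                fstr = f"{f:.17g}" if np.isfinite(f) else "nan"
                fh.write(f"{cc[i]:.17g}\t{xc[j]:.17g}\t{fstr}\t"
                         f"{int(fes.sampled_mask[i, j])}\n")
    sidecar = {
        "temperature": fes.temperature,
        "cpdb_edges": fes.cpdb_edges.tolist(),
        "chi_edges": fes.chi_edges.tolist(),
        "reference": "min sampled bin = 0",
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_fes(path):
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    cpdb_edges = np.array(meta["cpdb_edges"])
    chi_edges = np.array(meta["chi_edges"])
    nc, nx = len(cpdb_edges) - 1, len(chi_edges) - 1
    F = np.full((nc, nx), np.nan)
    mask = np.zeros((nc, nx), dtype=bool)
    k = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _, _, fval, sampled = line.split("\t")
            i, j = divmod(k, nx)
            F[i, j] = float(fval)
            mask[i, j] = bool(int(sampled))
            k += 1
    if k != nc * nx:
        raise FormatError(f"{path}: expected {nc * nx} rows, found {k}")
    return FESGrid(cpdb_edges, chi_edges, F, mask, meta["temperature"])


def write_windows(grid, path):
    payload = {
        "n_cpdb": grid.n_cpdb, "n_chi": grid.n_chi,
        "cpdb_range": list(grid.cpdb_range), "chi_range": list(grid.chi_range),
        "windows": [
            {"id": w.id, "cpdb0": w.cpdb0, "chi0": w.chi0,
             "k_cpdb": w.k_cpdb, "k_chi": w.k_chi}
            for w in grid
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_windows(path):
    with open(path) as fh:
        payload = json.load(fh)
    windows = tuple(UmbrellaWindow(**w) for w in payload["windows"])
    return WindowGrid(windows, payload["n_cpdb"], payload["n_chi"],
                      tuple(payload["cpdb_range"]),
                      tuple(payload["chi_range"]))
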