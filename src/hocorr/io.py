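"""File formats, manifests and run configuration.

Timeseries travel as comma-delimited text (rows = timepoints, columns =
features, optional single header row, period decimal) or as HDF5 for large
runs.  Vectorized correlation streams use the same two containers plus a JSON
sidecar recording K, the vectorization ordering, and the kernel spec and
estimator mode that produced them.  Every pipeline stage writes a manifest
echoing its fully resolved configuration and the package version, so outputs
are reproducible bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .dyncorr import Timeseries
from .kernels import KernelSpec

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_manifest",
    "read_manifest",
    "write_sidecar",
    "parse_kernel",
    "load_config",
    "read_group",
]


def parse_kernel(text: str) -> KernelSpec:
    """Parse ``"family"`` or ``"family:width"`` (e.g. ``laplace:20``)."""
    if ":" in text:
        family, width = text.split(":", 1)
        return KernelSpec(family.strip(), float(width))
    return KernelSpec(text.strip())


def _parse_delimited(path: Path) -> tuple[np.ndarray, list[str] | None]:
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    rows: list[list[float]] = []
    labels: list[str] | None = None
    ncol: int | None = None
    for i, line in enumerate(lines, start=1):
        cells = [c.strip() for c in line.split(",")]
        if ncol is None:
            ncol = len(cells)
        elif len(cells) != ncol:
            raise ValueError(
                f"{path}: ragged row {i} has {len(cells)} cells, expected {ncol}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            if i == 1 and not rows:
                labels = cells  # single optional header row
                continue
            bad = next(
                j for j, c in enumerate(cells, start=1) if not _is_float(c)
            )
            raise ValueError(
                f"{path}: non-numeric cell at row {i}, column {bad}"
            ) from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float), labels


def _is_float(c: str) -> bool:
    try:
        float(c)
        return True
    except ValueError:
        return False


def read_timeseries(path, format: str = "delimited", order: int = 0) -> Timeseries:
    """Read a T × K timeseries from delimited text or HDF5."""
    path = Path(path)
    if format == "delimited":
        values, labels = _parse_delimited(path)
        return Timeseries(values, order=order, feature_labels=labels)
    if format == "binary":
        with h5py.File(path, "r") as f:
            values = f["values"][...]
            order = int(f["values"].attrs.get("order", order))
            labels = f["values"].attrs.get("feature_labels", None)
            if labels is not None:
                labels = [str(x) for x in labels]
        return Timeseries(values, order=order, feature_labels=labels)
    raise ValueError(f"unknown format {format!r}")


def write_timeseries(ts: Timeseries | np.ndarray, path, format: str = "delimited") -> None:
    """Write a timeseries (or bare matrix) in the chosen container."""
    if not isinstance(ts, Timeseries):
        ts = Timeseries(np.asarray(ts, dtype=float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "delimited":
        with path.open("w") as f:
            if ts.feature_labels is not None:
                f.write(",".join(ts.feature_labels) + "\n")
            for row in ts.values:
                f.write(",".join(repr(float(v)) for v in row) + "\n")
        return
    if format == "binary":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("values", data=ts.values)
            d.attrs["order"] = ts.order
            if ts.feature_labels is not None:
                d.attrs["feature_labels"] = [str(x) for x in ts.feature_labels]
        return
    raise ValueError(f"unknown format {format!r}")


def write_sidecar(path, K: int, kernel: KernelSpec | None, mode: str | None, **extra) -> None:
    """JSON sidecar describing a vectorized correlation stream."""
    record = {
        "K": K,
        "ordering": "row-major upper triangle including diagonal",
        "kernel": None if kernel is None else {"family": kernel.family, "width": kernel.width},
        "mode": mode,
        **extra,
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def write_manifest(directory, stage: str, config: dict) -> Path:
    """Write ``manifest.json`` echoing the resolved config and package version."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "manifest.json"
    out.write_text(
        json.dumps(
            {"stage": stage, "version": __version__, "config": config},
            indent=2,
            default=str,
        )
        + "\n"
    )
    return out


def read_manifest(directory) -> dict:
    return json.loads((Path(directory) / "manifest.json").read_text())


def load_config(path) -> dict:
    """Load a declarative YAML run configuration."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def read_group(directory, pattern: str = "*.csv") -> list[Timeseries]:
    """Read a participant group: one delimited matrix per file, sorted by name."""
    directory = Path(directory)
    files = sorted(p for p in directory.glob(pattern) if p.name != "manifest.json")
    if len(files) < 2:
        raise ValueError(f"{directory}: need at least 2 participant files")
    return [read_timeseries(p) for p in files]
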