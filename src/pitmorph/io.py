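"""Readers and writers for landmark data and derived artefacts.

Formats: ``.pts`` point files (a tolerant superset of Landmark-Editor-style
exports: optional count header, ``#`` comments, ``label x y z`` rows with
whitespace or comma separation), long/wide CSV panels of observer datasets,
CSV distance matrices and newick trees.  All text is UTF-8; coordinates are
millimetres; line numbers in errors are 0-based.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import DistanceMatrix, LandmarkConfiguration, ObserverDataset

_COORD_FMT = "%.9g"  # lossless well past 6 significant digits


class ParseError(ValueError):
    """Malformed input file; carries a 0-based line number where relevant."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# .pts point files

def read_pts(path) -> LandmarkConfiguration:
    path = Path(path)
    meta: dict[str, str] = {}
    labels: list[str] = []
    coords: list[list[float]] = []
    declared: int | None = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines()):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        tokens = line.replace(",", " ").split()
        if len(tokens) == 1 and declared is None and not labels:
            try:
                declared = int(tokens[0])
                continue
            except ValueError:
                pass
        if len(tokens) != 4:
            raise ParseError(
                f"expected 'label x y z', got {len(tokens)} fields", line=lineno
            )
        label = tokens[0]
        if label in labels:
            raise FormatError(f"duplicate landmark label {label!r}")
        try:
            xyz = [float(t) for t in tokens[1:]]
        except ValueError:
            raise ParseError(f"non-numeric coordinate in {line!r}", line=lineno) from None
        labels.append(label)
        coords.append(xyz)
    if not labels:
        raise ParseError("no landmark rows found", line=0)
    if declared is not None and declared != len(labels):
        raise FormatError(
            f"header declares {declared} points but file contains {len(labels)}"
        )
    return LandmarkConfiguration(
        pit_id=meta.get("pit_id", path.stem),
        labels=tuple(labels),
        coords=np.asarray(coords),
        analyst_id=meta.get("analyst_id") or None,
        carnivore_label=meta.get("carnivore_label") or None,
    )


def write_pts(config: LandmarkConfiguration, path) -> None:
    path = Path(path)
    lines = [f"# pit_id: {config.pit_id}"]
    if config.analyst_id is not None:
        lines.append(f"# analyst_id: {config.analyst_id}")
    if config.carnivore_label is not None:
        lines.append(f"# carnivore_label: {config.carnivore_label}")
    lines.append(str(len(config)))
    for label, xyz in config.landmarks:
        lines.append(label + " " + " ".join(_COORD_FMT % v for v in xyz))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV observer datasets

_LONG_COLUMNS = ["pit_id", "analyst_id", "carnivore_label", "landmark", "x", "y", "z"]


def write_landmark_csv(dataset: ObserverDataset, path, dialect: str = "long") -> None:
    path = Path(path)
    if dialect == "long":
        rows = []
        for cfg in dataset.configurations:
            for label, xyz in cfg.landmarks:
                rows.append(
                    (cfg.pit_id, cfg.analyst_id or "", cfg.carnivore_label or "",
                     label, *(_COORD_FMT % v for v in xyz))
                )
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_LONG_COLUMNS)
            writer.writerows(rows)
    elif dialect == "wide":
        scheme = dataset.scheme
        header = ["pit_id", "analyst_id", "carnivore_label"]
        for lab in scheme:
            header += [f"{lab}_x", f"{lab}_y", f"{lab}_z"]
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for cfg in dataset.configurations:
                row = [cfg.pit_id, cfg.analyst_id or "", cfg.carnivore_label or ""]
                row += [_COORD_FMT % v for v in cfg.coords.ravel()]
                writer.writerow(row)
    else:
        raise FormatError(f"unknown CSV dialect {dialect!r}")


def read_landmark_csv(path, dialect: str = "long") -> ObserverDataset:
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path, keep_default_na=False, dtype={"pit_id": str})
        missing = set(_LONG_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"long CSV is missing columns {sorted(missing)}")
        configs = []
        for (pit, analyst, carnivore), grp in df.groupby(
            ["pit_id", "analyst_id", "carnivore_label"], sort=False
        ):
            configs.append(
                LandmarkConfiguration(
                    pit_id=pit,
                    labels=tuple(grp["landmark"]),
                    coords=grp[["x", "y", "z"]].to_numpy(float),
                    analyst_id=analyst or None,
                    carnivore_label=carnivore or None,
                )
            )
        return ObserverDataset(configurations=configs)
    if dialect == "wide":
        df = pd.read_csv(path, keep_default_na=False, dtype={"pit_id": str})
        coord_cols = [c for c in df.columns if c.endswith(("_x", "_y", "_z"))]
        labels = []
        for c in coord_cols:
            lab = c[:-2]
            if lab not in labels:
                labels.append(lab)
        if len(coord_cols) != 3 * len(labels):
            raise FormatError("wide CSV has incomplete coordinate triplets")
        configs = []
        for i, row in df.iterrows():
            values = [row[f"{lab}_{ax}"] for lab in labels for ax in "xyz"]
            try:
                coords = np.asarray(values, dtype=float).reshape(-1, 3)
            except ValueError:
                raise FormatError(
                    f"row {i}: inconsistent or non-numeric landmark coordinates"
                ) from None
            if not np.all(np.isfinite(coords)):
                raise FormatError(f"row {i}: inconsistent landmark counts across rows")
            configs.append(
                LandmarkConfiguration(
                    pit_id=str(row["pit_id"]),
                    labels=tuple(labels),
                    coords=coords,
                    analyst_id=str(row["analyst_id"]) or None,
                    carnivore_label=str(row["carnivore_label"]) or None,
                )
            )
        return ObserverDataset(configurations=configs)
    raise FormatError(f"unknown CSV dialect {dialect!r}")


# ---------------------------------------------------------------------------
# newick trees and distance matrices

def write_newick(tree, path) -> None:
    """Serialise a UPGMA tree (see :mod:`pitmorph.morphospace`) to newick."""
    leaves = tree.leaf_labels
    if len(set(leaves)) != len(leaves):
        raise FormatError("duplicate leaf names in tree")
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def write_distance_csv(dist: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dist.values, index=dist.labels, columns=dist.labels)
    df.to_csv(path, float_format="%.9g")


def read_distance_csv(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(float)
    values = 0.5 * (values + values.T)  # remove round-trip asymmetry
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels=tuple(df.index.astype(str)), values=values)
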