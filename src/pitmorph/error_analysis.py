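"""The four observer-error assessments on an observer dataset.

1. *Raw* inter-analyst Euclidean distances per landmark, computed before
   any superimposition — metrically meaningful in mm because all analysts
   digitise the same 3D model in the same model frame (a documented
   precondition; configurations are not re-registered here).
2. *Centroid-deviation* errors: each analyst's distance to the mean of all
   analysts' placements of the same landmark on the same pit.
3. Robust summaries of Procrustes distances from each configuration to a
   reference (the mean of all individuals, by default) in shape or form
   space.
4. The repeatability measure RM: each analyst's share of the total squared
   Procrustes distance to the reference.  Under the ratio reading the
   common 1/(n - I) factor cancels and the analysts' RMs sum to one.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .robust import RobustSummary
from .superimposition import AlignedEnsemble, procrustes_distance
from .types import ObserverDataset

logger = logging.getLogger(__name__)

#: Standard landmark subsets of the 17-landmark scheme.
DEFAULT_SUBSETS: dict[str, tuple[str, ...]] = {
    "LM1-17": tuple(f"LM{i}" for i in range(1, 18)),
    "LM1-13": tuple(f"LM{i}" for i in range(1, 14)),
    "LM1-5": tuple(f"LM{i}" for i in range(1, 6)),
}


def _panel(dataset: ObserverDataset) -> dict[str, dict[str, object]]:
    """pit -> {analyst -> configuration}, skipping pits with < 2 analysts."""
    by_pit: dict[str, dict[str, object]] = {}
    for cfg in dataset.configurations:
        by_pit.setdefault(cfg.pit_id, {})[cfg.analyst_id] = cfg
    skipped = [pit for pit, entry in by_pit.items() if len(entry) < 2]
    if skipped:
        logger.warning("skipping %d pits with fewer than 2 analysts", len(skipped))
    return {pit: entry for pit, entry in by_pit.items() if len(entry) >= 2}


def raw_pairwise_errors(dataset: ObserverDataset) -> pd.DataFrame:
    """All pairwise inter-analyst distances per pit and landmark, in raw
    (unsuperimposed) coordinates.  Columns: pit_id, carnivore_label,
    landmark, analyst_a, analyst_b, error_mm."""
    rows = []
    for pit, entry in _panel(dataset).items():
        analysts = sorted(entry, key=lambda a: dataset.analysts.index(a))
        labels = next(iter(entry.values())).labels
        carnivore = next(iter(entry.values())).carnivore_label
        for a, b in combinations(analysts, 2):
            d = np.linalg.norm(entry[a].coords - entry[b].coords, axis=1)
            for lab, err in zip(labels, d):
                rows.append((pit, carnivore, lab, a, b, float(err)))
    return pd.DataFrame(
        rows,
        columns=["pit_id", "carnivore_label", "landmark", "analyst_a", "analyst_b", "error_mm"],
    )


def centroid_deviation_errors(dataset: ObserverDataset) -> pd.DataFrame:
    """Distance from each analyst's point to the cross-analyst centroid of
    that landmark on that pit.  Columns: pit_id, carnivore_label, landmark,
    analyst_id, error_mm."""
    rows = []
    for pit, entry in _panel(dataset).items():
        stack = np.stack([cfg.coords for cfg in entry.values()])
        centroid = stack.mean(axis=0)
        labels = next(iter(entry.values())).labels
        carnivore = next(iter(entry.values())).carnivore_label
        for analyst, cfg in entry.items():
            d = np.linalg.norm(cfg.coords - centroid, axis=1)
            for lab, err in zip(labels, d):
                rows.append((pit, carnivore, lab, analyst, float(err)))
    return pd.DataFrame(
        rows, columns=["pit_id", "carnivore_label", "landmark", "analyst_id", "error_mm"]
    )


def _stratum_mask(errors: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "Absolute":
        return pd.Series(True, index=errors.index)
    carnivores = set(errors["carnivore_label"].dropna())
    if stratum.lower() in {str(c).lower() for c in carnivores}:
        return errors["carnivore_label"].str.lower() == stratum.lower()
    for col in ("analyst_id", "analyst_a", "analyst_b"):
        if col in errors.columns and (errors[col] == stratum).any():
            if col == "analyst_a":
                return (errors["analyst_a"] == stratum) | (errors["analyst_b"] == stratum)
            return errors[col] == stratum
    raise KeyError(f"stratum {stratum!r} matches no carnivore or analyst")


def error_summary(
    errors: pd.DataFrame,
    subsets: Mapping[str, Sequence[str]] | None = None,
    strata: Sequence[str] = ("Absolute", "wolf", "dog"),
    value_col: str = "error_mm",
) -> pd.DataFrame:
    """Robust dispersion table per (landmark subset x stratum).

    ``subsets`` maps subset name -> landmark labels; defaults to the
    LM1-17 / LM1-13 / LM1-5 families restricted to the labels present.
    Empty cells are kept and flagged rather than dropped.
    """
    if errors.empty:
        raise ValueError("error collection is empty")
    present = set(errors["landmark"])
    if subsets is None:
        subsets = {
            name: labs
            for name, labs in DEFAULT_SUBSETS.items()
            if set(labs) <= present
        } or {"all": tuple(sorted(present))}
    rows = []
    for name, labs in subsets.items():
        sub = errors[errors["landmark"].isin(set(labs))]
        for stratum in strata:
            cell = sub[_stratum_mask(sub, stratum)] if not sub.empty else sub
            if cell.empty:
                logger.warning("empty cell for subset %s, stratum %s", name, stratum)
                rows.append({"subset": name, "stratum": stratum, "empty": True})
                continue
            summary = RobustSummary.from_values(cell[value_col].to_numpy())
            rows.append(
                {"subset": name, "stratum": stratum, "empty": False, **summary.__dict__}
            )
    return pd.DataFrame(rows).set_index(["subset", "stratum"])


def per_landmark_summary(errors: pd.DataFrame, value_col: str = "error_mm") -> pd.DataFrame:
    """Median / NMAD / sqrt-BWMV per landmark (the per-landmark error table)."""
    rows = []
    for lab, grp in errors.groupby("landmark", sort=False):
        s = RobustSummary.from_values(grp[value_col].to_numpy())
        rows.append({"landmark": lab, "median": s.median, "nmad": s.nmad,
                     "sqrt_bwmv": s.sqrt_bwmv, "n": s.n})
    return pd.DataFrame(rows).set_index("landmark")


def procrustes_distances_to_reference(
    ensemble: AlignedEnsemble, reference: str = "overall"
) -> pd.DataFrame:
    """Procrustes distance of every configuration to a mean reference shape.

    ``reference``: ``overall`` (the ensemble mean), ``analyst`` or
    ``carnivore`` (subgroup means).  Distances use the ensemble's space.
    """
    configs = ensemble.configurations
    space = ensemble.space

    def group_mean(members):
        coords = np.mean([c.coords for c in members], axis=0)
        return ensemble.mean_shape.replace(coords=coords)

    if reference == "overall":
        ref_for = {None: ensemble.mean_shape}
        key = lambda c: None
    elif reference == "analyst":
        key = lambda c: c.analyst_id
        ref_for = {
            k: group_mean([c for c in configs if c.analyst_id == k])
            for k in {c.analyst_id for c in configs}
        }
    elif reference == "carnivore":
        key = lambda c: c.carnivore_label
        ref_for = {
            k: group_mean([c for c in configs if c.carnivore_label == k])
            for k in {c.carnivore_label for c in configs}
        }
    else:
        raise ValueError(f"unknown reference {reference!r}")

    rows = [
        (
            c.pit_id,
            c.analyst_id,
            c.carnivore_label,
            procrustes_distance(c, ref_for[key(c)], space=space),
        )
        for c in configs
    ]
    return pd.DataFrame(rows, columns=["pit_id", "analyst_id", "carnivore_label", "distance"])


def repeatability_measures(distances: pd.DataFrame) -> dict[str, float]:
    """Per-analyst repeatability measure from distances to the reference.

    RM_j = sum_i d_ij^2 / sum_ij d_ij^2 over a *balanced* design (equal
    individual counts per analyst; unbalanced input is refused).  The RMs
    sum to one; the analyst contributing the most measurement variance has
    the largest RM.
    """
    counts = distances.groupby("analyst_id")["distance"].count()
    if counts.nunique() != 1:
        raise ValueError("repeatability requires a balanced design")
    if len(counts) < 2:
        raise ValueError("repeatability requires at least two analysts")
    total = float((distances["distance"] ** 2).sum())
    if total == 0.0:
        raise ValueError("all distances are zero; RM undefined")
    sums = distances.groupby("analyst_id")["distance"].apply(lambda d: float((d**2).sum()))
    return {analyst: float(v / total) for analyst, v in sums.items()}


def kruskal_wallis_matrix(distances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Kruskal-Wallis H and p between analysts' distance samples."""
    from .robust import kruskal_wallis

    analysts = sorted(distances["analyst_id"].unique())
    rows = []
    for a, b in combinations(analysts, 2):
        h, p = kruskal_wallis(
            distances.loc[distances["analyst_id"] == a, "distance"],
            distances.loc[distances["analyst_id"] == b, "distance"],
        )
        rows.append({"analyst_a": a, "analyst_b": b, "H": h, "p": p})
    return pd.DataFrame(rows)


def centroid_deviation_vectors(ensemble: AlignedEnsemble) -> dict[str, np.ndarray]:
    """Per-analyst arrow field: analyst landmark centroid minus the overall
    landmark centroid, in the superimposed space.  The analyst-count
    weighted sum of the vectors is zero at every landmark."""
    coords = ensemble.coords_array()
    overall = coords.mean(axis=0)
    out: dict[str, np.ndarray] = {}
    analysts = [c.analyst_id for c in ensemble.configurations]
    for analyst in dict.fromkeys(analysts):
        mask = np.array([a == analyst for a in analysts])
        out[analyst] = coords[mask].mean(axis=0) - overall
    return out
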