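"""Study orchestration: observer-error assessment and model revision.

Runs the two headline workflows end to end from a single configuration and
writes CSV report tables (with generation metadata as comment headers),
newick trees and a JSON run manifest.  Every number in the outputs comes
from the module-level operations; the pipeline only sequences them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .error_analysis import (
    centroid_deviation_errors,
    error_summary,
    kruskal_wallis_matrix,
    per_landmark_summary,
    procrustes_distances_to_reference,
    raw_pairwise_errors,
    repeatability_measures,
)
from .identifiability import landmark_identifiability
from .io import read_landmark_csv, read_pts, write_landmark_csv, write_newick
from .morphospace import manova, model_comparison_report, pca, truncate_scores, upgma
from .semilandmarks import patch_size_sweep
from .superimposition import full_gpa, pairwise_procrustes_distances, partial_gpa
from .synthetic import ObserverStudyConfig, generate_observer_study
from .types import DistanceMatrix, ObserverDataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class StudyConfig:
    """Configuration of one pipeline run.

    Exactly one input source: a synthetic study config, or paths to
    landmark files (.pts per configuration, or one long-format CSV).
    """

    mode: str = "observer_error"  # observer_error | model_revision | both
    synthetic: ObserverStudyConfig | None = None
    input_paths: tuple[str, ...] | None = None
    output_dir: str = "pitmorph_out"
    seed: int = 0
    include_raw: bool = True
    include_full_gpa: bool = True
    include_partial_gpa: bool = True
    include_clustering: bool = True
    include_sweep: bool = False
    schemes: tuple[str, ...] = ("LM17", "LM5", "hybrid30")
    grid_sizes: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    n_permutations: int = 999

    def validate(self) -> None:
        if self.mode not in ("observer_error", "model_revision", "both"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if (self.synthetic is None) == (self.input_paths is None):
            raise ConfigError("exactly one of synthetic config or input paths required")


def _load_dataset(cfg: StudyConfig) -> ObserverDataset:
    if cfg.synthetic is not None:
        return generate_observer_study(replace(cfg.synthetic, seed=cfg.seed))
    paths = [Path(p) for p in cfg.input_paths]
    try:
        if len(paths) == 1 and paths[0].suffix.lower() == ".csv":
            return read_landmark_csv(paths[0], dialect="long")
        return ObserverDataset(configurations=[read_pts(p) for p in paths])
    except (OSError, ValueError) as exc:
        raise DataError(str(exc)) from exc


def _write_table(df: pd.DataFrame, path: Path, cfg: StudyConfig, index: bool = True) -> None:
    header = (
        f"# generated by pitmorph v{__version__}\n"
        f"# seed = {cfg.seed}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=index, float_format="%.9g")


def _space_reports(
    dataset: ObserverDataset, space: str, cfg: StudyConfig, outdir: Path, bundle: dict
) -> None:
    gpa = full_gpa if space == "shape" else partial_gpa
    ensemble = gpa(dataset.configurations)
    distances = procrustes_distances_to_reference(ensemble, reference="overall")

    summary_rows = []
    for analyst, grp in distances.groupby("analyst_id"):
        from .robust import RobustSummary

        for stratum, sub in (
            ("Overall", grp),
            *(
                (str(c), grp[grp["carnivore_label"] == c])
                for c in sorted(set(grp["carnivore_label"].dropna()))
            ),
        ):
            if sub.empty:
                continue
            s = RobustSummary.from_values(sub["distance"].to_numpy())
            summary_rows.append(
                {"stratum": stratum, "analyst": analyst, "median": s.median,
                 "nmad": s.nmad, "sqrt_bwmv": s.sqrt_bwmv}
            )
    _write_table(
        pd.DataFrame(summary_rows), outdir / f"procrustes_summary_{space}.csv", cfg, index=False
    )
    bundle["tables"].append(f"procrustes_summary_{space}.csv")

    _write_table(
        kruskal_wallis_matrix(distances), outdir / f"kruskal_wallis_{space}.csv", cfg, index=False
    )
    bundle["tables"].append(f"kruskal_wallis_{space}.csv")

    rm = repeatability_measures(distances)
    _write_table(
        pd.DataFrame(sorted(rm.items()), columns=["analyst", "RM"]),
        outdir / f"repeatability_{space}.csv",
        cfg,
        index=False,
    )
    bundle["tables"].append(f"repeatability_{space}.csv")

    res = pca(ensemble)
    analyst_labels = [c.analyst_id for c in ensemble.configurations]
    carnivore_labels = [c.carnivore_label for c in ensemble.configurations]
    rows = [{
        "space": space,
        "dimensionality": res.dimensionality,
        "pc1_2_pct": res.cumulative_percent(2),
        "pc1_10_pct": res.cumulative_percent(10),
    }]
    for name, labels in (("analyst", analyst_labels), ("carnivore", carnivore_labels)):
        try:
            man = manova(truncate_scores(res, labels), labels)
            rows[0][f"manova_p_{name}"] = man.p
            rows[0][f"manova_statistic_{name}"] = man.statistic_name
        except ValueError as exc:
            logger.warning("MANOVA (%s, %s) failed: %s", name, space, exc)
            bundle["incomplete"] = True
    _write_table(pd.DataFrame(rows), outdir / f"pca_manova_{space}.csv", cfg, index=False)
    bundle["tables"].append(f"pca_manova_{space}.csv")

    dmat = pairwise_procrustes_distances(ensemble.configurations, space=space)
    leaf_labels = [f"{c.pit_id}_{c.analyst_id}" for c in ensemble.configurations]
    tree = upgma(DistanceMatrix(labels=tuple(leaf_labels), values=dmat))
    tree_path = outdir / f"upgma_{space}.nwk"
    write_newick(tree, tree_path)
    bundle["trees"].append(tree_path.name)


def run_observer_error_study(cfg: StudyConfig) -> dict:
    """Run the observer-error workflow; returns the report bundle manifest."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = _load_dataset(cfg)
    bundle: dict = {"mode": "observer_error", "seed": cfg.seed, "incomplete": False,
                    "tables": [], "trees": [], "cluster_reports": []}

    if cfg.include_raw:
        raw = raw_pairwise_errors(dataset)
        _write_table(error_summary(raw), outdir / "raw_error_summary.csv", cfg)
        _write_table(per_landmark_summary(raw), outdir / "raw_error_per_landmark.csv", cfg)
        centro = centroid_deviation_errors(dataset)
        _write_table(
            per_landmark_summary(centro), outdir / "centroid_deviation_per_landmark.csv", cfg
        )
        bundle["tables"] += [
            "raw_error_summary.csv",
            "raw_error_per_landmark.csv",
            "centroid_deviation_per_landmark.csv",
        ]

    for space, enabled in (("shape", cfg.include_full_gpa), ("form", cfg.include_partial_gpa)):
        if not enabled:
            continue
        try:
            _space_reports(dataset, space, cfg, outdir, bundle)
        except ValueError as exc:
            logger.warning("%s-space analysis failed: %s", space, exc)
            bundle["incomplete"] = True

    if cfg.include_clustering:
        rows = []
        for method in ("dbscan", "meanshift"):
            try:
                reports = landmark_identifiability(dataset, method=method)
            except ValueError as exc:
                logger.warning("clustering (%s) failed: %s", method, exc)
                bundle["incomplete"] = True
                continue
            for subset, report in reports.items():
                rows.append({"method": method, "subset": subset, **report.to_row()})
        if rows:
            _write_table(pd.DataFrame(rows), outdir / "cluster_reports.csv", cfg, index=False)
            bundle["cluster_reports"].append("cluster_reports.csv")

    bundle["n_configurations"] = len(dataset.configurations)
    _write_manifest(bundle, cfg, outdir)
    return bundle


def run_model_revision_study(cfg: StudyConfig) -> dict:
    """Run the landmark-model comparison workflow (and optional patch sweep)."""
    cfg.validate()
    if cfg.synthetic is None:
        raise ConfigError("model revision requires a synthetic study config")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"mode": "model_revision", "seed": cfg.seed, "incomplete": False,
                    "tables": [], "trees": [], "cluster_reports": []}

    datasets = {}
    for scheme in cfg.schemes:
        synth = replace(cfg.synthetic, landmark_scheme=scheme, seed=cfg.seed)
        datasets[scheme] = generate_observer_study(synth)
    report = model_comparison_report(
        datasets, n_permutations=cfg.n_permutations, seed=cfg.seed
    )
    _write_table(report, outdir / "model_comparison.csv", cfg, index=False)
    bundle["tables"].append("model_comparison.csv")

    if cfg.include_sweep:
        sweep = patch_size_sweep(
            replace(cfg.synthetic, seed=cfg.seed),
            grid_sizes=cfg.grid_sizes,
            n_permutations=cfg.n_permutations,
        )
        _write_table(sweep, outdir / "patch_size_sweep.csv", cfg, index=False)
        bundle["tables"].append("patch_size_sweep.csv")

    _write_manifest(bundle, cfg, outdir)
    return bundle


def simulate_to_csv(cfg: ObserverStudyConfig, path) -> ObserverDataset:
    """Generate a synthetic study and write it as a long-format CSV."""
    dataset = generate_observer_study(cfg)
    write_landmark_csv(dataset, path, dialect="long")
    return dataset


def _write_manifest(bundle: dict, cfg: StudyConfig, outdir: Path) -> None:
    manifest = dict(bundle)
    manifest["pitmorph_version"] = __version__
    versions = {}
    for mod in ("numpy", "scipy", "pandas", "sklearn", "statsmodels"):
        try:
            versions[mod] = __import__(mod).__version__
        except Exception:  # pragma: no cover
            pass
    manifest["library_versions"] = versions
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
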