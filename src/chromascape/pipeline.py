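"""End-to-end orchestration: images + ratings -> metrics -> factors ->
clusters -> correlation tables, with a reproducibility manifest.

All tabular outputs use a fixed CSV dialect (UTF-8, comma separator,
'.' decimal, ``NA`` for undefined cells) so identical inputs, config and
seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .metrics import compute_color_metrics
from .palette import COLOR_NAMES, load_image, segment_image
from .psych import (CorrelationTable, FactorSolution, correlate_metrics_factors,
                    factor_scores, image_factor_scores,
                    item_correlation_matrix, kaiser_n_factors,
                    principal_axis_factor, rotate_solution, screen_loadings,
                    select_samples, summarize_healing_ratings, ward_cluster)

__all__ = [
    "RunManifest",
    "segment_images",
    "metrics_table",
    "select_images",
    "analyze",
    "write_csv",
]

logger = logging.getLogger(__name__)

CSV_KW = dict(float_format="%.6f", na_rep="NA", lineterminator="\n")


@dataclasses.dataclass
class RunManifest:
    """Snapshot of one pipeline run: config, input digests, row counts."""

    config: dict
    version: str
    input_checksums: dict[str, str]
    stage_counts: dict[str, int]
    warnings: list[str]

    def digest(self) -> str:
        body = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(body.encode()).hexdigest()[:16]

    def write(self, path: str | Path) -> None:
        body = dataclasses.asdict(self)
        body["manifest_hash"] = self.digest()
        Path(path).write_text(json.dumps(body, indent=2, sort_keys=True)
                              + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, **CSV_KW)


def segment_images(paths: Sequence[str | Path],
                   config: PipelineConfig) -> pd.DataFrame:
    """Composition table: one row per image, the six exclusive-mode area
    proportions plus the unclassified fraction."""
    rows = []
    for p in paths:
        img = load_image(p)
        ms = segment_image(img, config.palette, mode="exclusive",
                           precedence=config.precedence)
        row = {"image_id": Path(p).stem}
        row.update(ms.proportions)
        row["unclassified_fraction"] = ms.unclassified_fraction
        rows.append(row)
    df = pd.DataFrame(rows).set_index("image_id")
    return df[list(COLOR_NAMES) + ["unclassified_fraction"]]


def metrics_table(paths: Sequence[str | Path],
                  config: PipelineConfig) -> pd.DataFrame:
    """Tidy per-(image, color) metric table with columns image_id, color,
    D, r_squared, H_color, C, unclassified_fraction."""
    mcfg = config.metrics_config()
    rows = []
    for p in paths:
        img = load_image(p)
        ms = segment_image(img, config.palette, config.segmentation_mode,
                           precedence=config.precedence)
        for rec in compute_color_metrics(ms, image_id=Path(p).stem,
                                         config=mcfg):
            rows.append({
                "image_id": rec.image_id, "color": rec.color,
                "D": rec.dimension, "r_squared": rec.r_squared,
                "H_color": rec.h_color, "C": rec.concentration,
                "unclassified_fraction": ms.unclassified_fraction,
            })
    return pd.DataFrame(rows)


def metrics_wide(tidy: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy metric table to images x 18 columns named
    ``<color>_<D|H|C>`` (the correlation-table row layout)."""
    out = {}
    for metric, col in (("D", "D"), ("H", "H_color"), ("C", "C")):
        piv = tidy.pivot(index="image_id", columns="color", values=col)
        for color in COLOR_NAMES:
            out[f"{color}_{metric}"] = piv[color]
    wide = pd.DataFrame(out)
    wide.index.name = "image_id"
    return wide[[f"{c}_{m}" for c in COLOR_NAMES for m in ("D", "H", "C")]]


def select_images(ratings: Mapping[str, Sequence[int]],
                  config: PipelineConfig) -> pd.DataFrame:
    """Healing-rating summary table with a ``selected`` flag."""
    summaries = summarize_healing_ratings(ratings)
    chosen = set(select_samples(summaries, config.mean_min,
                                config.median_min, config.sd_max))
    df = pd.DataFrame([dataclasses.asdict(s) for s in summaries]
                      ).set_index("image_id")
    df["selected"] = [i in chosen for i in df.index]
    return df


@dataclasses.dataclass
class AnalysisResult:
    solution: FactorSolution
    loading_table: pd.DataFrame
    retained_items: list[str]
    item_assignments: dict[str, int]
    image_scores: pd.DataFrame
    cluster_profile: pd.DataFrame
    cluster_assignments: dict[str, int]
    correlation: CorrelationTable | None


def _loading_table(solution: FactorSolution) -> pd.DataFrame:
    """Items x factors loading table with eigenvalue / contribution /
    cumulative footer rows and a communality column."""
    k = solution.n_factors
    cols = [f"factor{j + 1}" for j in range(k)]
    body = pd.DataFrame(solution.loadings, index=solution.item_labels,
                        columns=cols)
    body["communality"] = solution.communalities
    footer = pd.DataFrame(
        [list(solution.eigenvalues) + [np.nan],
         list(solution.contribution_rate_pct) + [np.nan],
         list(solution.cumulative_pct) + [np.nan]],
        index=["eigenvalue", "contribution_rate_pct", "cumulative_pct"],
        columns=cols + ["communality"])
    return pd.concat([body, footer])


def analyze(sd_long: pd.DataFrame,
            metrics: pd.DataFrame | None,
            config: PipelineConfig) -> AnalysisResult:
    """Factor the SD ratings, cluster image scores, correlate with metrics.

    ``sd_long`` is long-format (participant, image, item, score);
    ``metrics`` is the tidy metric table (or None to skip correlation).
    Observation rows for the correlation matrix are participant-by-image
    responses by default, or per-image item means in ``image_mean`` mode.
    """
    needed = {"participant", "image", "item", "score"}
    if not needed <= set(sd_long.columns):
        raise ValueError(f"SD ratings need columns {sorted(needed)}")

    wide = sd_long.pivot_table(index=["participant", "image"],
                               columns="item", values="score",
                               sort=False)
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing SD cells for items {missing}")
    item_labels = [c for c in sd_long["item"].unique()]
    wide = wide[item_labels]

    if config.observation_mode == "image_mean":
        obs = wide.groupby(level="image", sort=False).mean()
    else:
        obs = wide

    corr = item_correlation_matrix(obs, item_labels)
    n_factors = (config.n_factors if config.retention == "fixed"
                 else kaiser_n_factors(corr))
    solution = principal_axis_factor(corr, n_factors=n_factors,
                                     item_labels=item_labels)
    solution.n_obs = obs.shape[0]
    solution = rotate_solution(solution)
    retained, assignments = screen_loadings(solution, config.load_min,
                                            config.crossload_gap)

    scores = factor_scores(obs.to_numpy(dtype=float), solution,
                           method=config.scoring_method)
    if config.observation_mode == "image_mean":
        image_ids = list(obs.index)
    else:
        image_ids = list(obs.index.get_level_values("image"))
    img_scores = image_factor_scores(scores, image_ids)

    cluster = ward_cluster(img_scores, k=config.cluster_k)

    correlation = None
    if metrics is not None:
        wide_metrics = metrics_wide(metrics)
        shared = wide_metrics.index.intersection(img_scores.index)
        missing = set(wide_metrics.index) ^ set(img_scores.index)
        if not len(shared):
            raise ValueError(
                f"no shared image ids between metrics and ratings; "
                f"offending ids: {sorted(missing)[:10]}")
        correlation = correlate_metrics_factors(wide_metrics.loc[shared],
                                                img_scores.loc[shared])

    return AnalysisResult(
        solution=solution, loading_table=_loading_table(solution),
        retained_items=retained, item_assignments=assignments,
        image_scores=img_scores, cluster_profile=cluster.profile,
        cluster_assignments=cluster.assignments, correlation=correlation)


def run_all(image_paths: Sequence[str | Path],
            healing_ratings: Mapping[str, Sequence[int]] | None,
            sd_long: pd.DataFrame,
            config: PipelineConfig,
            out_dir: str | Path) -> RunManifest:
    """Full pipeline to disk: composition, metrics, selection, factor,
    cluster and correlation tables plus a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    composition = segment_images(image_paths, config)
    write_csv(composition, out / "composition.csv")

    tidy = metrics_table(image_paths, config)
    write_csv(tidy, out / "metrics.csv", index=False)
    n_undefined = int(tidy["D"].isna().sum())
    if n_undefined:
        warnings_log.append(f"{n_undefined} (image,color) cells undefined")

    counts = {"images": len(list(image_paths)),
              "metric_rows": len(tidy)}

    if healing_ratings is not None:
        selection = select_images(healing_ratings, config)
        write_csv(selection, out / "selection.csv")
        counts["selected_images"] = int(selection["selected"].sum())

    result = analyze(sd_long, tidy, config)
    write_csv(result.loading_table, out / "factor_loadings.csv")
    write_csv(result.image_scores, out / "image_factor_scores.csv")
    write_csv(result.cluster_profile, out / "cluster_profile.csv")
    assignments = pd.DataFrame(
        {"cluster": pd.Series(result.cluster_assignments)})
    assignments.index.name = "image_id"
    write_csv(assignments, out / "cluster_assignments.csv")
    if result.correlation is not None:
        write_csv(result.correlation.formatted(),
                  out / "metric_factor_correlations.csv")
        write_csv(result.correlation.r,
                  out / "metric_factor_correlations_r.csv")
        write_csv(result.correlation.p,
                  out / "metric_factor_correlations_p.csv")
    counts["factors_retained"] = result.solution.n_factors
    counts["clusters"] = len(set(result.cluster_assignments.values()))

    manifest = RunManifest(
        config=config.to_dict(), version=__version__,
        input_checksums={str(p): _checksum(Path(p)) for p in image_paths},
        stage_counts=counts, warnings=warnings_log)
    manifest.write(out / "manifest.json")
    return manifest
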