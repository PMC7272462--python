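"""End-to-end analysis pipeline: simulate/load -> build -> measure -> hubs -> stats.

Mirrors the structure of a severity dose-response connectome study: global
network measures compared across groups with one-way ANOVA + LSD post-hoc and
Benjamini-Hochberg FDR within each analysis family, betweenness-rank hub
identification per group with overlap reporting, per-region ("local")
comparisons, and Pearson correlations between cognitive change scores and
network measures in hub regions.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .build import GROUPS, WeightedNetwork, build_network
from .cohort import Cohort, CohortSpec, generate_cohort, make_labels
from .hubs import DEFAULT_HUB_FRACTION, HubOverlap, HubRanking, hub_overlap
from .io import (
    cohort_metadata_frame,
    read_cohort_dir,
    write_cohort,
    write_json,
)
from .measures import measure_table, normalize_measures
from .stats import anova_oneway, bh_fdr, lsd_posthoc, pearson_correlation

GLOBAL_FAMILY = ("strength", "global_efficiency", "clustering")
NODE_FAMILY = ("strength", "nodal_efficiency", "clustering")
LOCAL_FAMILY = ("strength", "local_efficiency", "clustering")

# Group comparisons of "strength" use the pre-normalization streamline
# strength: total-fiber normalization fixes the summed weight at 1 per
# subject, which removes exactly the diffuse severity signal strength is
# meant to capture (and tabulated strengths in this literature are raw
# counts, ~1e4). Efficiency and clustering are computed on normalized weights.
_STAT_KEY = {"strength": "raw_strength"}


def _table_key(measure: str) -> str:
    return _STAT_KEY.get(measure, measure)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline; serialized alongside outputs."""

    input_dir: str | None = None
    simulate: CohortSpec | None = None
    threshold: float = 10.0
    hub_fraction: float = DEFAULT_HUB_FRACTION
    fdr_alpha: float = 0.05
    weight_length_map: str = "inverse"
    normalize: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_dir is None and self.simulate is None:
            self.simulate = CohortSpec(seed=self.seed)
        if self.simulate is not None:
            self.simulate.seed = self.seed

    def to_dict(self) -> dict:
        return {
            "input_dir": self.input_dir,
            "simulate": None if self.simulate is None else self.simulate.to_dict(),
            "threshold": self.threshold,
            "hub_fraction": self.hub_fraction,
            "fdr_alpha": self.fdr_alpha,
            "weight_length_map": self.weight_length_map,
            "normalize": self.normalize,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


@dataclass
class AnalysisReport:
    config: PipelineConfig
    measures: pd.DataFrame
    normalized: pd.DataFrame | None
    hub_rankings: pd.DataFrame
    overlap: HubOverlap
    global_stats: pd.DataFrame
    hub_region_stats: pd.DataFrame
    local_stats: pd.DataFrame
    correlations: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        sig_local = self.local_stats[self.local_stats["significant"]]
        return {
            "n_subjects": int(self.measures["subject_id"].nunique()),
            "global_significant": sorted(
                self.global_stats.loc[self.global_stats["significant"], "measure"]
            ),
            "hub_sets": {
                g: sorted(
                    self.hub_rankings.loc[
                        (self.hub_rankings["group"] == g) & self.hub_rankings["is_hub"],
                        "node_label",
                    ]
                )
                for g in GROUPS
            },
            "hubs_shared": len(self.overlap.shared),
            "hubs_union": len(self.overlap.union),
            "local_significant_counts": {
                m: int((sig_local["measure"] == m).sum()) for m in LOCAL_FAMILY
            },
            "provenance": self.provenance,
        }

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.measures.to_csv(outdir / "measures.csv", index=False)
        if self.normalized is not None:
            self.normalized.to_csv(outdir / "measures_normalized.csv", index=False)
        self.hub_rankings.to_csv(outdir / "hub_report.tsv", sep="\t", index=False)
        write_json(
            {
                "shared": self.overlap.shared,
                "unique": self.overlap.unique,
                "union": self.overlap.union,
            },
            outdir / "hub_overlap.json",
        )
        self.global_stats.to_csv(outdir / "stats_global.tsv", sep="\t", index=False)
        self.hub_region_stats.to_csv(outdir / "stats_hub_regions.tsv", sep="\t", index=False)
        self.local_stats.to_csv(outdir / "stats_local.tsv", sep="\t", index=False)
        self.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        write_json(self.summary(), outdir / "summary.json")
        return outdir


def _config_hash(config: PipelineConfig) -> str:
    payload = config.to_dict()
    payload.pop("output_dir", None)  # analysis identity, not artifact location
    blob = yaml.safe_dump(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(
    config: PipelineConfig,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, list[str], Cohort | None]:
    if config.input_dir is not None:
        matrices, meta, labels = read_cohort_dir(config.input_dir)
        return matrices, meta, labels, None
    cohort = generate_cohort(config.simulate)
    matrices = {s.id: s.matrix for s in cohort.subjects}
    meta = cohort_metadata_frame(cohort)
    labels = make_labels(cohort.spec.n_nodes)
    return matrices, meta, labels, cohort


def _pivot(table: pd.DataFrame, scope: str, measure: str) -> pd.DataFrame:
    sub = table[(table["scope"] == scope) & (table["measure"] == measure)]
    if scope == "global":
        return sub.set_index("subject_id")[["value"]]
    return sub.pivot(index="subject_id", columns="node_label", values="value")


def _groups_of(meta: pd.DataFrame) -> dict[str, list[str]]:
    return {
        g: meta.loc[meta["group"] == g, "subject_id"].astype(str).tolist()
        for g in GROUPS
    }


def _anova_row(values_by_group: list[np.ndarray]) -> dict:
    res = anova_oneway(values_by_group)
    post = lsd_posthoc(values_by_group)
    row = {
        "F": res.F,
        "df_between": res.df_between,
        "df_within": res.df_within,
        "p": res.p,
    }
    for (a, b), p in post.p.items():
        row[f"p_{GROUPS[a]}_vs_{GROUPS[b]}"] = p
    for g, mean in zip(GROUPS, res.group_means):
        row[f"mean_{g}"] = mean
    for g, sd in zip(GROUPS, res.group_sds):
        row[f"sd_{g}"] = sd
    return row


def compare_global_measures(
    table: pd.DataFrame, meta: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """ANOVA + LSD on the global measures, FDR within the 3-test family."""
    groups = _groups_of(meta)
    rows = []
    for measure in GLOBAL_FAMILY:
        pivot = _pivot(table, "global", _table_key(measure))
        values = [pivot.loc[groups[g], "value"].to_numpy() for g in GROUPS]
        rows.append({"measure": measure, **_anova_row(values)})
    out = pd.DataFrame(rows)
    fdr = bh_fdr(out["p"].to_numpy(), alpha=alpha)
    out["q"] = fdr.q
    out["significant"] = fdr.significant
    out["family_m"] = fdr.m
    return out


def compare_node_measures(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    regions: Sequence[str],
    measures: Sequence[str],
    alpha: float = 0.05,
    family: str = "joint",
) -> pd.DataFrame:
    """Per-region ANOVAs; FDR either jointly (regions x measures) or per measure.

    ``family='joint'`` matches the hub-region analysis (one family of
    len(regions) * len(measures) tests); ``family='per-measure'`` matches the
    whole-brain local analysis (each measure corrected over its regions).
    """
    groups = _groups_of(meta)
    rows = []
    for measure in measures:
        pivot = _pivot(table, "node", _table_key(measure))
        for region in regions:
            values = [pivot.loc[groups[g], region].to_numpy() for g in GROUPS]
            if all(np.ptp(v) == 0 for v in values) and len({v[0] for v in values}) == 1:
                warnings.warn(
                    f"region {region!r} measure {measure!r} constant; skipped",
                    stacklevel=2,
                )
                continue
            rows.append({"measure": measure, "region": region, **_anova_row(values)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    out["significant"] = False
    if family == "joint":
        fdr = bh_fdr(out["p"].to_numpy(), alpha=alpha)
        out["q"] = fdr.q
        out["significant"] = fdr.significant
        out["family_m"] = fdr.m
    else:
        out["family_m"] = 0
        for measure in out["measure"].unique():
            mask = out["measure"] == measure
            fdr = bh_fdr(out.loc[mask, "p"].to_numpy(), alpha=alpha)
            out.loc[mask, "q"] = fdr.q
            out.loc[mask, "significant"] = fdr.significant
            out.loc[mask, "family_m"] = fdr.m
    return out


def rank_hubs(
    table: pd.DataFrame, meta: pd.DataFrame, labels: Sequence[str],
    fraction: float = DEFAULT_HUB_FRACTION,
) -> tuple[pd.DataFrame, HubOverlap, dict[str, HubRanking]]:
    """Per-group betweenness ranking, hub sets, and cross-group overlap."""
    groups = _groups_of(meta)
    pivot = _pivot(table, "node", "betweenness")[list(labels)]
    rankings: dict[str, HubRanking] = {}
    rows = []
    for g in GROUPS:
        vectors = [pivot.loc[sid].to_numpy() for sid in groups[g]]
        ranking = HubRanking.from_group(g, vectors, fraction=fraction)
        rankings[g] = ranking
        for i, label in enumerate(labels):
            rows.append(
                {
                    "group": g,
                    "node_label": label,
                    "mean_betweenness": ranking.mean_betweenness[i],
                    "rank": int(ranking.rank[i]),
                    "is_hub": i in ranking.hub_set,
                }
            )
    overlap = hub_overlap({g: r.hub_set for g, r in rankings.items()})
    return pd.DataFrame(rows), overlap, rankings


def correlate_cognition(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    target_regions: Sequence[str],
    measures: Sequence[str] = NODE_FAMILY,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between RPM change scores and nodal measures.

    Change scores (post minus pre) are computed per subject; subjects missing
    either score are dropped listwise within this analysis only. Correlations
    are reported pooled across all scored subjects and per group (groups with
    fewer than 3 scored subjects are skipped with a warning); FDR is applied
    within the pooled family.
    """
    meta = meta.copy()
    meta["subject_id"] = meta["subject_id"].astype(str)
    change = (meta["rpm_post"] - meta["rpm_pre"]).to_numpy(dtype=float)
    scored = np.isfinite(change)
    rows = []
    for measure in measures:
        pivot = _pivot(table, "node", _table_key(measure))
        for region in target_regions:
            values = pivot.loc[meta["subject_id"], region].to_numpy(dtype=float)
            for scope_name, mask in [("all", scored)] + [
                (g, scored & (meta["group"] == g).to_numpy()) for g in GROUPS
            ]:
                x, y = values[mask], change[mask]
                if x.size < 3:
                    warnings.warn(
                        f"correlation {scope_name}/{region}/{measure}: n={x.size} < 3; skipped",
                        stacklevel=2,
                    )
                    continue
                if np.std(x) == 0 or np.std(y) == 0:
                    warnings.warn(
                        f"correlation {scope_name}/{region}/{measure}: constant input; skipped",
                        stacklevel=2,
                    )
                    continue
                res = pearson_correlation(x, y)
                rows.append(
                    {
                        "region": region,
                        "measure": measure,
                        "group": scope_name,
                        "n": res.n,
                        "r": res.r,
                        "p": res.p,
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = np.nan
    out["significant"] = False
    pooled = out["group"] == "all"
    if pooled.any():
        fdr = bh_fdr(out.loc[pooled, "p"].to_numpy(), alpha=alpha)
        out.loc[pooled, "q"] = fdr.q
        out.loc[pooled, "significant"] = fdr.significant
    return out


logger = logging.getLogger("tbiconn.pipeline")


class _StageTimer:
    """Collects per-stage wall times and mirrors them to the package logger."""

    def __init__(self) -> None:
        self.lines: list[str] = []
        self._t0 = time.perf_counter()

    def done(self, stage: str) -> None:
        elapsed = time.perf_counter() - self._t0
        line = f"stage {stage}: {elapsed:.2f}s"
        logger.info(line)
        self.lines.append(line)
        self._t0 = time.perf_counter()


def _input_hash(matrices: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for sid in sorted(matrices):
        h.update(sid.encode())
        h.update(np.ascontiguousarray(matrices[sid]).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage and (optionally) write all artifacts.

    Deterministic: re-running with the same config and seed reproduces every
    table exactly. Stage timings and input hashes are logged and, when an
    output directory is set, written to ``run.log`` alongside the reports.
    """
    timer = _StageTimer()
    matrices, meta, labels, cohort = _load_inputs(config)
    meta = meta.copy()
    meta["subject_id"] = meta["subject_id"].astype(str)
    input_hash = _input_hash(matrices)
    timer.done("load/simulate")

    networks: dict[str, WeightedNetwork] = {}
    for sid, matrix in matrices.items():
        try:
            networks[sid] = build_network(
                matrix, min_streamlines=config.threshold, node_labels=labels
            )
        except ValueError as exc:
            raise RuntimeError(f"network construction failed for subject {sid!r}: {exc}") from exc
    timer.done("build")

    table = measure_table(networks.items(), mapping=config.weight_length_map)
    normalized = normalize_measures(table) if config.normalize else None
    stats_table = table  # min-max scaling leaves F and r unchanged; raw kept for reports
    timer.done("measures")

    hub_frame, overlap, rankings = rank_hubs(
        table, meta, labels, fraction=config.hub_fraction
    )
    timer.done("hubs")
    global_stats = compare_global_measures(stats_table, meta, alpha=config.fdr_alpha)
    hub_regions = sorted(labels[i] for i in overlap.union)
    hub_region_stats = compare_node_measures(
        stats_table, meta, hub_regions, NODE_FAMILY,
        alpha=config.fdr_alpha, family="joint",
    )
    local_stats = compare_node_measures(
        stats_table, meta, list(labels), LOCAL_FAMILY,
        alpha=config.fdr_alpha, family="per-measure",
    )
    timer.done("stats")
    # cognition correlations target the hubs that are not shared by all groups
    differing = sorted(labels[i] for i in overlap.union - overlap.shared)
    corr_regions = differing if differing else hub_regions
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        correlations = correlate_cognition(
            stats_table, meta, corr_regions, NODE_FAMILY, alpha=config.fdr_alpha
        )
    timer.done("correlate")

    report = AnalysisReport(
        config=config,
        measures=table,
        normalized=normalized,
        hub_rankings=hub_frame,
        overlap=overlap,
        global_stats=global_stats,
        hub_region_stats=hub_region_stats,
        local_stats=local_stats,
        correlations=correlations,
        provenance={
            "config_hash": _config_hash(config),
            "input_hash": input_hash,
            "seed": config.seed,
            "version": _pkg_version,
            "n_subjects": len(networks),
            "n_nodes": len(labels),
        },
    )
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        report.write(outdir)
        if cohort is not None:
            write_cohort(cohort, outdir / "cohort")
        timer.done("write")
        log_lines = [
            f"config_hash {report.provenance['config_hash']}",
            f"input_hash {input_hash}",
            f"seed {config.seed}",
            *timer.lines,
        ]
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
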