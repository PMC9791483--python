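"""Cohort-level orchestration: run every statistic over a set of dyads.

``run_pipeline`` takes a small config (an events file or a simulation
block, a seed, and the permutation count), runs the full chain — event
model, frequency statistics and Topic/Comment partition, cluster and
quartile statistics against the permutation baseline, cross-recurrence
lags, observed and Random networks with node measures — and collects
per-dyad tables, group summaries (mean, s.d., range) and the
within-subject 2x2 (and 2x4 quartile) ANOVA contrasts into a
:class:`CohortReport`.  The run is deterministic given the config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .anova import AnovaResult, rm_anova_2x2, rm_anova_two_way
from .events import BEHAVIOURS, DyadSeries, read_events
from .frequency import compare_streams, partition_topics
from .events import behaviour_stream
from .network import MEASURES, network_from_series, node_measures, random_network
from .simulate import GeneratorParams, simulate_cohort
from .temporal import (
    CATEGORIES,
    cluster_stats,
    cross_recurrence,
    permutation_baseline,
    quartile_profile,
)

logger = logging.getLogger(__name__)

STREAM_PAIRS = (
    ("toddler_handle", "parent_handle"),
    ("parent_handle", "parent_talk"),
    ("parent_talk", "toddler_handle"),
)


@dataclass
class CohortReport:
    """All per-dyad tables, group summaries and ANOVA contrasts of one run."""

    dyads: pd.DataFrame
    comparisons: pd.DataFrame
    clusters: pd.DataFrame
    quartiles: pd.DataFrame
    networks: pd.DataFrame
    anovas: dict[str, list[AnovaResult]]
    group_summary: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def anova_table(self) -> pd.DataFrame:
        rows = [
            {"design": design, "effect": r.effect, "F": r.F,
             "df1": r.df1, "df2": r.df2, "p": r.p}
            for design, results in self.anovas.items()
            for r in results
        ]
        return pd.DataFrame(rows, columns=["design", "effect", "F", "df1", "df2", "p"])

    def check_consistency(self) -> None:
        """Every reported group mean must be recomputable from its per-dyad table."""
        recomputed = _summarize(self.dyads)
        if not np.allclose(
            recomputed["mean"].to_numpy(dtype=float),
            self.group_summary["mean"].to_numpy(dtype=float),
            equal_nan=True,
        ):
            raise AssertionError("group summary inconsistent with per-dyad table")

    def write(self, out_dir: str | Path) -> None:
        self.check_consistency()
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("dyads", "comparisons", "clusters", "quartiles", "networks"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False,
                                       lineterminator="\n")
        self.group_summary.to_csv(out / "group_summary.csv", index=False,
                                  lineterminator="\n")
        self.anova_table().to_csv(out / "anovas.csv", index=False, lineterminator="\n")
        (out / "report.json").write_text(
            json.dumps(
                {
                    "metadata": self.metadata,
                    "group_summary": self.group_summary.to_dict(orient="records"),
                    "anovas": self.anova_table().to_dict(orient="records"),
                },
                indent=2,
                sort_keys=True,
                default=float,
            )
            + "\n",
            encoding="utf-8",
        )


def _summarize(dyads: pd.DataFrame) -> pd.DataFrame:
    numeric = dyads.select_dtypes(include=[np.number]).drop(columns=[], errors="ignore")
    rows = []
    for col in numeric.columns:
        v = numeric[col].to_numpy(dtype=float)
        rows.append(
            {
                "metric": col,
                "mean": np.nanmean(v),
                "sd": np.nanstd(v, ddof=1) if np.isfinite(v).sum() > 1 else np.nan,
                "min": np.nanmin(v),
                "max": np.nanmax(v),
            }
        )
    return pd.DataFrame(rows, columns=["metric", "mean", "sd", "min", "max"])


def _load_cohort(config: Mapping[str, Any]) -> list[DyadSeries]:
    if "input" in config and config["input"]:
        return read_events(
            config["input"],
            n_segments=int(config.get("n_segments", 121)),
            universe_size=int(config.get("universe_size", 32)),
        )
    sim = dict(config.get("simulate") or {})
    n_dyads = int(sim.pop("n_dyads", 32))
    param_names = {f.name for f in dataclass_fields(GeneratorParams)}
    unknown = set(sim) - param_names
    if unknown:
        raise ValueError(f"unknown simulate parameter(s): {sorted(unknown)}")
    if "behaviour_mix" in sim:
        sim["behaviour_mix"] = tuple(sim["behaviour_mix"])
    params = GeneratorParams(**sim)
    return simulate_cohort(n_dyads, params, seed=int(config.get("seed", 0)))


def analyze_dyad(
    series: DyadSeries,
    *,
    n_perms: int,
    seed: int,
    k_topics: int = 5,
    min_run: int = 2,
) -> dict[str, Any]:
    """Run every per-dyad statistic; returns a dict of tables and objects."""
    partition = partition_topics(series, k=k_topics)
    observed = cluster_stats(series, partition, min_run=min_run)
    ensemble = permutation_baseline(
        series,
        "cluster_and_run",
        n_perms=n_perms,
        seed=seed,
        partition=partition,
        min_run=min_run,
        include_transitions=True,
    )
    profile = quartile_profile(series, partition)
    lags = cross_recurrence(series, partition)
    obs_net = node_measures(network_from_series(series, partition))
    rand_net = node_measures(random_network(series, ensemble, partition=partition))
    comparisons = {
        pair: compare_streams(behaviour_stream(series, pair[0]),
                              behaviour_stream(series, pair[1]))
        for pair in STREAM_PAIRS
    }
    return {
        "series": series,
        "partition": partition,
        "observed_clusters": observed,
        "ensemble": ensemble,
        "quartiles": profile,
        "lags": lags,
        "observed_network": obs_net,
        "random_network": rand_net,
        "comparisons": comparisons,
    }


def _network_cells(net_measures: pd.DataFrame, measure: str) -> dict[str, float]:
    out = {}
    for cat in CATEGORIES:
        sub = net_measures[net_measures["category"] == cat]
        out[cat] = float(sub[measure].mean()) if len(sub) else float("nan")
    return out


def run_pipeline(config: Mapping[str, Any]) -> CohortReport:
    """Execute the full analysis for a cohort of dyads.

    Config keys: ``input`` (events CSV/TSV) or ``simulate`` (generator
    parameters plus ``n_dyads``), ``seed``, ``n_perms`` (default 10000),
    ``k_topics`` (default 5), ``min_run`` (default 2), ``out_dir``
    (optional; write tables there).
    """
    t0 = time.perf_counter()
    seed = int(config.get("seed", 0))
    n_perms = int(config.get("n_perms", 10_000))
    k_topics = int(config.get("k_topics", 5))
    min_run = int(config.get("min_run", 2))
    cohort = _load_cohort(config)
    if not cohort:
        raise ValueError("no dyads found in the input")
    logger.info("loaded %d dyad(s)", len(cohort))

    ss = np.random.SeedSequence(seed)
    dyad_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(cohort))]

    dyad_rows, comp_rows, cluster_rows, quartile_rows, network_rows = [], [], [], [], []
    cc_cells, rl_cells, q_cells = [], [], []
    net_cells: dict[str, list[np.ndarray]] = {m: [] for m in MEASURES}

    for series, dseed in zip(cohort, dyad_seeds):
        t_dyad = time.perf_counter()
        try:
            res = analyze_dyad(
                series, n_perms=n_perms, seed=dseed, k_topics=k_topics, min_run=min_run
            )
        except Exception as exc:  # annotate failures with dyad id and stage
            raise RuntimeError(f"dyad {series.dyad_id!r}: {exc}") from exc
        partition = res["partition"]
        obs = res["observed_clusters"]
        ens = res["ensemble"]
        prof = res["quartiles"]
        lags = res["lags"]
        perm_mean = dict(zip(ens.components, ens.mean))

        streams = {b: behaviour_stream(series, b) for b in BEHAVIOURS}
        dyad_rows.append(
            {
                "dyad": series.dyad_id,
                "total_events": series.total_events,
                "pct_segments_occupied": 100.0 * series.segments_occupied(),
                "unique_toys_toddler_handle": sum(
                    1 for c in streams["toddler_handle"].counts.values() if c
                ),
                "unique_toys_parent_handle": sum(
                    1 for c in streams["parent_handle"].counts.values() if c
                ),
                "unique_toys_parent_talk": sum(
                    1 for c in streams["parent_talk"].counts.values() if c
                ),
                "topic_share_pct": 100.0 * partition.topic_share,
                "prop_positive_lags": lags.proportion_positive,
                "mean_lag_topic_s": lags.mean_lag("topic"),
                "mean_lag_comment_s": lags.mean_lag("comment"),
            }
        )
        for (a, b), comp in res["comparisons"].items():
            comp_rows.append(
                {
                    "dyad": series.dyad_id,
                    "stream_a": a,
                    "stream_b": b,
                    "wilcoxon_V": comp.wilcoxon_V,
                    "wilcoxon_p": comp.wilcoxon_p,
                    "spearman_rho": comp.spearman_rho,
                    "spearman_p": comp.spearman_p,
                }
            )
        for cat in CATEGORIES:
            cluster_rows.append(
                {
                    "dyad": series.dyad_id,
                    "category": cat,
                    "observed_clusters_per_toy": obs[cat].clusters_per_toy,
                    "observed_total_clusters": obs[cat].n_clusters,
                    "observed_mean_run_length": obs[cat].mean_run_length,
                    "random_clusters_per_toy": perm_mean[f"clusters_{cat}"],
                    "random_mean_run_length": perm_mean[f"run_{cat}"],
                }
            )
            quartile_rows.append(
                {
                    "dyad": series.dyad_id,
                    "category": cat,
                    **{
                        f"q{q + 1}": float(prof.as_cells()[CATEGORIES.index(cat), q])
                        for q in range(4)
                    },
                }
            )
        for kind in ("observed", "random"):
            m = res[f"{kind}_network"].measures.reset_index()
            m.insert(0, "kind", kind)
            m.insert(0, "dyad", series.dyad_id)
            network_rows.append(m)

        cc_cells.append(
            [
                [obs["topic"].clusters_per_toy, obs["comment"].clusters_per_toy],
                [perm_mean["clusters_topic"], perm_mean["clusters_comment"]],
            ]
        )
        rl_cells.append(
            [
                [obs["topic"].mean_run_length, obs["comment"].mean_run_length],
                [perm_mean["run_topic"], perm_mean["run_comment"]],
            ]
        )
        q_cells.append(prof.as_cells())
        for measure in MEASURES:
            obs_m = _network_cells(res["observed_network"].measures, measure)
            rand_m = _network_cells(res["random_network"].measures, measure)
            net_cells[measure].append(
                np.array(
                    [
                        [obs_m["topic"], obs_m["comment"]],
                        [rand_m["topic"], rand_m["comment"]],
                    ]
                )
            )
        logger.info(
            "dyad %s: %d events, %d perms in %.2fs",
            series.dyad_id, series.total_events, n_perms,
            time.perf_counter() - t_dyad,
        )

    anovas: dict[str, list[AnovaResult]] = {}

    def _add_2x2(name: str, cells: list) -> None:
        Y = np.asarray(cells, dtype=float)
        ok = ~np.isnan(Y).any(axis=(1, 2))
        if ok.sum() >= 2:
            if (~ok).any():
                logger.warning(
                    "%s: dropped %d dyad(s) with incomplete cells", name, int((~ok).sum())
                )
            anovas[name] = rm_anova_2x2(Y[ok])

    _add_2x2("cluster_count", cc_cells)
    _add_2x2("run_length", rl_cells)
    for measure in MEASURES:
        _add_2x2(f"network_{measure}", net_cells[measure])
    Yq = np.asarray(q_cells, dtype=float)
    if len(Yq) >= 2 and not np.isnan(Yq).any():
        anovas["quartile"] = rm_anova_two_way(Yq, ("node_category", "quartile"))

    dyads = pd.DataFrame(dyad_rows)
    report = CohortReport(
        dyads=dyads,
        comparisons=pd.DataFrame(comp_rows),
        clusters=pd.DataFrame(cluster_rows),
        quartiles=pd.DataFrame(quartile_rows),
        networks=pd.concat(network_rows, ignore_index=True),
        anovas=anovas,
        group_summary=_summarize(dyads),
        metadata={
            "playnet_version": __version__,
            "seed": seed,
            "n_perms": n_perms,
            "k_topics": k_topics,
            "min_run": min_run,
            "n_dyads": len(cohort),
            "n_segments": cohort[0].n_segments,
            "total_coded_segments": len(cohort) * cohort[0].n_segments,
            "source": "input" if config.get("input") else "simulate",
            "runtime_s": round(time.perf_counter() - t0, 3),
        },
    )
    if config.get("out_dir"):
        report.write(config["out_dir"])
    return report
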