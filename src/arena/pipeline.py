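"""End-to-end orchestration: simulate -> classify -> network -> coaccess -> train.

``run_pipeline`` executes the enabled stages in dependency order against
an output directory, writes every artifact with a manifest (size + sha256)
and returns a :class:`RunReport`. Stages are deterministic given the
configuration seed, so a rerun with the same config is byte-identical for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from arena import __version__, io, simulate
from arena.config import SimulationConfig
from arena.deltacon import build_coaccess_graph, class_impact_summary, compare_graphs
from arena.network import anchor_overlap, build_graph, centrality, interaction_frequency, tss_node_table
from arena.occupancy import (
    binding_energy,
    build_occupancy_table,
    evaluate,
    fit_bagged_multinomial_lasso,
    make_training_set,
)
from arena.starr import ClassificationThresholds, activity_stats, classify_enhancers

log = logging.getLogger("arena")

STAGES = ("simulate", "classify", "network", "coaccess", "train")
_DEPENDS = {"classify": ("simulate",), "network": ("simulate", "classify"),
            "coaccess": ("simulate", "classify"), "train": ("simulate", "classify")}


@dataclass
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    stages: tuple[str, ...] = STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    coaccess_threshold: float = 0.1
    tss_window: int = 5000
    n_estimators: int = 2000
    max_samples: int = 50
    max_features: int = 5
    l1_penalty: float = 0.1
    n_noninducible: int = 500
    train_frac: float = 0.8
    seed: int = 0
    out_dir: str = "results/run"
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_json(self) -> str:
        doc = asdict(self)
        doc["stages"] = list(self.stages)
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        doc = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "simulation" in doc:
            sim = doc["simulation"]
            for key in ("class_proportions", "tss_direction_fractions"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            doc["simulation"] = SimulationConfig(**sim)
        if "thresholds" in doc:
            doc["thresholds"] = ClassificationThresholds(**doc["thresholds"])
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_classes(calls: pd.Series, decimals: int = 1) -> pd.DataFrame:
    """Counts and percentages per enhancer class (half-up rounding).

    Percentages are count / total over all supplied calls, so including
    the ambiguous class they sum to 100 up to rounding.
    """
    if len(calls) == 0:
        raise ValueError("no calls to summarize")
    counts = calls.value_counts()
    total = int(counts.sum())
    out = pd.DataFrame({
        "count": counts,
        "percent": [round_half_up(100.0 * c / total, decimals) for c in counts],
    })
    out.index.name = "enhancer_class"
    out["total"] = total
    return out


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    stages_run: list[str] = field(default_factory=list)
    row_counts: dict = field(default_factory=dict)
    class_summary: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    deltacon: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    elapsed_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _manifest(out: Path) -> list[dict]:
    entries = []
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            data = path.read_bytes()
            entries.append({"path": str(path.relative_to(out)),
                            "bytes": len(data),
                            "sha256": hashlib.sha256(data).hexdigest()})
    return entries


def _require(out: Path, names: list[str], stage: str, needed_by: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise FileNotFoundError(
                f"stage {needed_by!r} needs artifact {name!r} from "
                f"disabled/unrun stage {stage!r}")


def run_pipeline(config: PipelineConfig) -> RunReport:
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in config.stages:
        for dep in _DEPENDS.get(stage, ()):
            if dep not in config.stages:
                # allow resuming from artifacts of an earlier run
                marker = {"simulate": "regions.bed", "classify": "calls.tsv"}[dep]
                _require(out, [marker], dep, stage)
    sim = config.simulation.replace(seed=config.seed)
    report = RunReport(version=__version__, config_hash=config.config_hash(),
                       seed=config.seed)
    (out / "config.json").write_text(config.to_json() + "\n")

    truth = None
    if "simulate" in config.stages:
        t0 = time.perf_counter()
        regions, truth = simulate.simulate_regions(sim)
        counts, roles = simulate.simulate_starr_counts(regions, truth, sim)
        raw_occ, ctrl_occ = simulate.simulate_occupancy(regions, truth, sim)
        tss = simulate.simulate_tss(sim)
        loops = simulate.simulate_interactions(regions, truth, tss, sim)
        co_etoh, co_dht = simulate.simulate_coaccessibility(regions, truth, sim)
        io.write_bed(regions, out / "regions.bed")
        io.write_table(regions, out / "regions.tsv")
        io.write_counts(counts, roles, out / "starr_counts.tsv", out / "sample_roles.tsv")
        io.write_table(raw_occ.reset_index(), out / "occupancy_raw.tsv")
        io.write_table(ctrl_occ.reset_index(), out / "occupancy_control.tsv")
        io.write_table(tss, out / "tss.tsv")
        io.write_bedpe(loops, out / "loops.bedpe")
        io.write_table(co_etoh, out / "coaccess_etoh.tsv")
        io.write_table(co_dht, out / "coaccess_dht.tsv")
        io.write_table(truth.class_series().rename_axis("region_id").reset_index(),
                       out / "truth_classes.tsv")
        report.row_counts["simulate"] = {
            "regions": len(regions), "counts": int(counts.size),
            "loops": len(loops), "coaccess_pairs": len(co_etoh)}
        report.stages_run.append("simulate")
        report.elapsed_s["simulate"] = round(time.perf_counter() - t0, 3)
        log.info("simulate: %d regions, %d loops (%.1fs)", len(regions),
                 len(loops), report.elapsed_s["simulate"])

    if "classify" in config.stages:
        t0 = time.perf_counter()
        counts, roles = io.read_counts(out / "starr_counts.tsv", out / "sample_roles.tsv")
        regions = io.read_table(out / "regions.tsv")
        clinical = regions.loc[regions["group"] == "clinical", "region_id"]
        stats = activity_stats(counts.loc[clinical], roles)
        calls = classify_enhancers(stats, config.thresholds)
        io.write_table(stats.rename_axis("region_id").reset_index(), out / "activity_stats.tsv")
        io.write_table(calls.rename_axis("region_id").reset_index(), out / "calls.tsv")
        summary = summarize_classes(calls["enhancer_class"])
        io.write_table(summary.reset_index(), out / "class_summary.tsv")
        report.class_summary = {
            cls: {"count": int(row["count"]), "percent": row["percent"]}
            for cls, row in summary.iterrows()}
        report.row_counts["classify"] = {"regions_tested": len(stats)}
        report.stages_run.append("classify")
        report.elapsed_s["classify"] = round(time.perf_counter() - t0, 3)
        log.info("classify: %s", report.class_summary)

    calls = None
    if {"network", "coaccess", "train"} & set(config.stages):
        calls_df = io.read_table(out / "calls.tsv", index_col="region_id")
        calls = calls_df["enhancer_class"]
        regions = io.read_table(out / "regions.tsv")

    if "network" in config.stages:
        t0 = time.perf_counter()
        loops = io.read_bedpe(out / "loops.bedpe")
        tss = io.read_table(out / "tss.tsv")
        node_table = _node_table(regions, calls, tss)
        edges = anchor_overlap(loops, regions, tss, window=config.tss_window)
        graph = build_graph(edges, node_table)
        import networkx as nx
        n_comp = nx.number_connected_components(graph)
        stats_rows = []
        present = {d["node_class"] for _, d in graph.nodes(data=True)}
        for cls in ("inducible", "constitutive", "inactive"):
            for other in ("TSS_up", "TSS_down", cls):
                if cls in present and other in present:
                    s = interaction_frequency(graph, cls, other)
                    stats_rows.append(asdict(s))
        io.write_table(pd.DataFrame(stats_rows), out / "interaction_frequency.tsv")
        cent = centrality(graph)
        cent_df = pd.DataFrame({"node_id": list(cent.degree),
                                "degree_centrality": list(cent.degree.values()),
                                "betweenness": [cent.betweenness[n] for n in cent.degree]})
        io.write_table(cent_df, out / "centrality.tsv")
        report.network = {"nodes": graph.number_of_nodes(),
                          "edges": graph.number_of_edges(),
                          "components": n_comp}
        report.stages_run.append("network")
        report.elapsed_s["network"] = round(time.perf_counter() - t0, 3)
        log.info("network: %s", report.network)

    if "coaccess" in config.stages:
        t0 = time.perf_counter()
        co_etoh = io.read_table(out / "coaccess_etoh.tsv")
        co_dht = io.read_table(out / "coaccess_dht.tsv")
        node_table = pd.DataFrame({
            "node_id": regions["region_id"],
            "node_class": calls.reindex(regions["region_id"]).fillna("untested_ARBS").to_numpy(),
        })
        g1 = build_coaccess_graph(co_etoh, node_table, config.coaccess_threshold)
        g2 = build_coaccess_graph(co_dht, node_table, config.coaccess_threshold)
        order = sorted(node_table["node_id"])
        result = compare_graphs(g1, g2, order)
        io.write_table(result.impact.reset_index(), out / "node_impact.tsv")
        summary, tests = class_impact_summary(
            result.impact, calls, classes=["inducible", "constitutive", "inactive"])
        io.write_table(tests, out / "impact_tests.tsv")
        report.deltacon = {"distance": result.distance, "epsilon": result.epsilon,
                           "n_nodes": result.n_nodes}
        report.stages_run.append("coaccess")
        report.elapsed_s["coaccess"] = round(time.perf_counter() - t0, 3)
        log.info("coaccess: d=%.4f", result.distance)

    if "train" in config.stages:
        t0 = time.perf_counter()
        raw = io.read_table(out / "occupancy_raw.tsv", index_col="region_id")
        ctrl = io.read_table(out / "occupancy_control.tsv", index_col="region_id")
        table = build_occupancy_table(raw, ctrl)
        occ = table.occupancy.loc[calls.index]
        split = make_training_set(occ, calls, n_noninducible=config.n_noninducible,
                                  train_frac=config.train_frac, seed=config.seed)
        model = fit_bagged_multinomial_lasso(
            split.x_train, split.y_train, n_estimators=config.n_estimators,
            max_samples=config.max_samples, max_features=config.max_features,
            l1_penalty=config.l1_penalty, seed=config.seed, record_metadata=False)
        metrics = evaluate(model, split.x_test, split.y_test)
        energy = binding_energy(model, occ, calls)
        io.write_table(model.weights.rename_axis("enhancer_class").reset_index(),
                       out / "model_weights.tsv")
        io.write_table(energy.rename_axis("factor").reset_index(),
                       out / "binding_energy.tsv")
        io.write_json(metrics, out / "classifier_metrics.json")
        report.metrics = metrics
        report.stages_run.append("train")
        report.elapsed_s["train"] = round(time.perf_counter() - t0, 3)
        log.info("train: accuracy=%.3f", metrics["accuracy"])

    io.write_json(report.to_dict(), out / "run_report.json")
    io.write_json(_manifest(out), out / "manifest.json")
    return report


def _node_table(regions: pd.DataFrame, calls: pd.Series, tss: pd.DataFrame) -> pd.DataFrame:
    """Node table: called CREs, untested ARBS, and DEG TSSs."""
    classes = calls.reindex(regions["region_id"])
    node_class = classes.fillna("untested_ARBS").to_numpy()
    region_nodes = pd.DataFrame({"node_id": regions["region_id"].to_numpy(),
                                 "node_class": node_class})
    tss_nodes = tss_node_table(tss)[["node_id", "node_class"]]
    return pd.concat([region_nodes, tss_nodes], ignore_index=True)
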