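"""End-to-end study pipeline: clean, screen, estimate, compare, bootstrap.

Runs the full multi-group workflow on a :class:`SurveyDataset` (read
from CSV or generated synthetically) and writes a reproducible report
bundle: cleaning report, per-group pruned networks with fit indices,
centrality tables, all pairwise comparisons, case-drop bootstrap
summaries, the cross-group variability network, and a run manifest.

Sub-stage randomness is derived from the single master seed through a
fixed spawn order (one child stream per group bootstrap, then one per
sorted group pair), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import SurveyDataset, default_community_map
from .preprocess import clean, CleaningReport
from .ggm import estimate_network, PrunedNetwork
from .centrality import centrality_table, CentralityTable, expected_influence
from .comparison import compare_groups, PairwiseComparison
from .stability import casedrop_bootstrap, variability_network, top_varying_edges, BootstrapResult, VariabilityNetwork

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of the study pipeline; ``seed`` governs every stochastic stage."""

    seed: int
    input_csv: str | None = None
    community: dict[str, str] | None = None   # default: R1..R10 / A1..A17 map
    categories: int = 5
    alpha: float = 0.05
    correlation_method: str = "pearson"
    min_age: int = 20
    max_age: int = 29
    goldbricker_r: float = 0.7
    goldbricker_unique_frac: float = 0.2
    n_permutations: int = 5000
    n_ppc_draws: int = 1000
    n_boot: int = 1000
    drop_fraction: float = 0.25
    min_n_per_item: int = 10
    allow_small_groups: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("n_permutations", "n_ppc_draws", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if not 0 <= self.drop_fraction < 1:
            raise ValueError("drop_fraction must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class ReportBundle:
    """Everything the pipeline produces, plus a manifest for reproduction."""

    cleaning: CleaningReport
    networks: dict[str, PrunedNetwork]
    centralities: dict[str, CentralityTable]
    comparisons: list[PairwiseComparison]
    bootstraps: dict[str, BootstrapResult]
    variability: VariabilityNetwork | None
    manifest: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cleaning.to_json(out / "cleaning_report.json")
        fits = {}
        for g, net in self.networks.items():
            fits[g] = {
                "n": net.n,
                "alpha": net.alpha,
                "iterations": net.iterations,
                "n_edges": len(net.edges()),
                **{k: v for k, v in asdict(net.fit).items()},
            }
            _write_edge_csv(net, self.manifest["community"], out / f"network_{g}.csv")
            _write_graphml(net, self.manifest["community"], out / f"network_{g}.graphml")
        with open(out / "fit_indices.json", "w") as fh:
            json.dump(fits, fh, indent=2)
        for g, cent in self.centralities.items():
            cent.to_csv(out / f"centrality_{g}.csv")
        with open(out / "comparisons.json", "w") as fh:
            json.dump([c.summary() for c in self.comparisons], fh, indent=2)
        if self.comparisons:
            counts = pd.DataFrame(
                [
                    {
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "edge_diff_count": c.edge_diff_count,
                        "bridge_edge_diff_count": c.bridge_edge_diff_count,
                        "nonbridge_edge_diff_count": c.nonbridge_edge_diff_count,
                        "node_ei_diff_count": c.node_ei_diff_count,
                        "node_bridge_ei_diff_count": c.node_bridge_ei_diff_count,
                    }
                    for c in self.comparisons
                ]
            )
            counts.to_csv(out / "comparison_counts.csv", index=False)
            glob = pd.DataFrame(
                [
                    {
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "kl_observed": c.kl_observed,
                        "kl_p": c.kl_p,
                        "global_ei_diff": c.global_ei_diff,
                        "global_ei_p": c.global_ei_p,
                        "global_bridge_ei_diff": c.global_bridge_ei_diff,
                        "global_bridge_ei_p": c.global_bridge_ei_p,
                    }
                    for c in self.comparisons
                ]
            )
            glob.to_csv(out / "comparison_global.csv", index=False)
        for g, boot in self.bootstraps.items():
            boot.summary_table(self.networks[g].items).to_csv(
                out / f"bootstrap_{g}.csv", index=False
            )
        if self.variability is not None:
            self.variability.edge_table(self.manifest["community"]).to_csv(
                out / "variability_edges.csv", index=False
            )
            _write_variability_graphml(
                self.variability, self.manifest["community"], out / "variability.graphml"
            )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _write_edge_csv(net: PrunedNetwork, community: dict, path) -> None:
    items = net.items or [str(i) for i in range(net.p)]
    rows = [
        {
            "item_i": items[i],
            "item_j": items[j],
            "weight": net.weights[i, j],
            "is_bridge": community[items[i]] != community[items[j]],
        }
        for (i, j) in net.edges()
    ]
    pd.DataFrame(rows, columns=["item_i", "item_j", "weight", "is_bridge"]).to_csv(
        path, index=False
    )


def _write_graphml(net: PrunedNetwork, community: dict, path) -> None:
    import networkx as nx

    items = net.items or [str(i) for i in range(net.p)]
    G = nx.Graph()
    for it in items:
        G.add_node(it, community=community[it])
    for (i, j) in net.edges():
        G.add_edge(
            items[i], items[j],
            weight=float(net.weights[i, j]),
            is_bridge=community[items[i]] != community[items[j]],
        )
    nx.write_graphml(G, path)


def _write_variability_graphml(var: VariabilityNetwork, community: dict, path) -> None:
    import networkx as nx

    p = var.edge_sd.shape[0]
    items = var.items or [str(i) for i in range(p)]
    G = nx.Graph()
    for k, it in enumerate(items):
        G.add_node(it, community=community[it], ei_sd=float(var.node_ei_sd[k]))
    for i in range(p):
        for j in range(i + 1, p):
            if var.edge_sd[i, j] > 0:
                G.add_edge(items[i], items[j], sd=float(var.edge_sd[i, j]))
    nx.write_graphml(G, path)


def run_pipeline(config: PipelineConfig, data: SurveyDataset | None = None) -> ReportBundle:
    """Execute the full workflow: clean -> screen -> estimate -> centrality ->
    pairwise comparisons -> bootstrap -> variability.

    ``data`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is read from ``config.input_csv``. Comparison stages
    are skipped when fewer than two groups survive cleaning.
    """
    t0 = time.time()
    if data is None:
        if config.input_csv is None:
            raise ValueError("either data or config.input_csv is required")
        community = config.community or default_community_map()
        data = SurveyDataset.from_csv(config.input_csv, community, config.categories)
    community = data.community
    items = data.items

    logger.info("stage clean: %d respondents in", data.n)
    cleaned, report = clean(
        data,
        min_age=config.min_age,
        max_age=config.max_age,
        goldbricker_r=config.goldbricker_r,
        goldbricker_unique_frac=config.goldbricker_unique_frac,
    )
    logger.info("stage clean done: %d retained", cleaned.n)

    groups = cleaned.groups
    p = len(items)
    networks: dict[str, PrunedNetwork] = {}
    centralities: dict[str, CentralityTable] = {}
    for g in groups:
        sub = cleaned.group_data(g)
        if sub.n < config.min_n_per_item * p and not config.allow_small_groups:
            raise ValueError(
                f"group {g!r} has n={sub.n} < {config.min_n_per_item} x {p} items; "
                "pruning is unstable at this size (set allow_small_groups to override)"
            )
        net = estimate_network(
            sub.response_matrix(), alpha=config.alpha,
            method=config.correlation_method, items=items,
        )
        networks[g] = net
        centralities[g] = centrality_table(net, community)
        logger.info("stage estimate(%s): %d edges, %d pruning rounds", g, len(net.edges()), net.iterations)

    master = np.random.SeedSequence(config.seed)
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    boot_streams = master.spawn(len(groups))
    pair_streams = master.spawn(len(pairs))

    comparisons: list[PairwiseComparison] = []
    for (a, b), ss in zip(pairs, pair_streams):
        t = time.time()
        cmpres = compare_groups(
            cleaned.group_data(a).response_matrix(),
            cleaned.group_data(b).response_matrix(),
            community, items,
            label_a=a, label_b=b,
            n_permutations=config.n_permutations,
            n_ppc_draws=config.n_ppc_draws,
            alpha=config.alpha,
            method=config.correlation_method,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        comparisons.append(cmpres)
        logger.info("stage compare(%s,%s): %.1fs", a, b, time.time() - t)

    bootstraps: dict[str, BootstrapResult] = {}
    for g, ss in zip(groups, boot_streams):
        t = time.time()
        bootstraps[g] = casedrop_bootstrap(
            cleaned.group_data(g).response_matrix(),
            n_boot=config.n_boot,
            drop_fraction=config.drop_fraction,
            alpha=config.alpha,
            method=config.correlation_method,
            seed=np.random.default_rng(ss),
        )
        logger.info("stage bootstrap(%s): %.1fs", g, time.time() - t)

    variability = None
    if len(groups) >= 2:
        variability = variability_network(
            [networks[g] for g in groups],
            centralities=[expected_influence(networks[g]) for g in groups],
            groups=groups,
        )

    manifest = {
        "config": asdict(config),
        "community": community,
        "items": items,
        "groups": groups,
        "resilnet_version": __version__,
        "numpy_version": np.__version__,
        "wall_clock_s": round(time.time() - t0, 2),
    }
    bundle = ReportBundle(
        cleaning=report,
        networks=networks,
        centralities=centralities,
        comparisons=comparisons,
        bootstraps=bootstraps,
        variability=variability,
        manifest=manifest,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
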