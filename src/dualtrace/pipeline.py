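"""One-config orchestration of the statistics pipeline and figure rendering.

A run starts from per-group regional count tables (CSV paths or a simulation
block), applies outlier cleaning and the shared-region rule, computes
correlation matrices, thresholded networks, topology metrics, threshold
sweeps, permutation differences, optional KS region comparisons and
communities, and writes a deterministic directory layout::

    <output_dir>/tables/    counts, correlations, edges, metrics, permutations
    <output_dir>/figures/   requested figure kinds (PNG + SVG)
    <output_dir>/logs/      parameter echo

Re-running with an identical config (and seed) reproduces the tables
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import networks, viz
from .fixtures.counts import CountSimSpec, simulate_region_counts
from .model import RegionCountTable, remove_outliers, shared_regions_filter


class ConfigError(ValueError):
    pass


DEFAULT_SWEEP_ALPHAS = [0.001, 0.005, 0.01, 0.05, 0.1, 0.5]


@dataclass
class RunConfig:
    groups: tuple[str, str]
    output_dir: Path
    counts: dict[str, str] | None = None          # group -> CSV path
    simulate: dict | None = None                  # CountSimSpec kwargs
    channel: str | None = None
    r_min: float = 0.9
    alpha: float | None = None
    use_absolute: bool = True
    outlier_sd: float = 2.0
    permutation_n: int = 1000
    permutation_seed: int = 0
    sweep_alphas: list[float] = field(default_factory=lambda: list(DEFAULT_SWEEP_ALPHAS))
    ks_regions: list[str] = field(default_factory=list)
    volcano_d_threshold: float = 1.0
    volcano_alpha: float = 0.01
    figures: list[str] = field(default_factory=lambda: ["heatmap", "network", "volcano"])
    min_mice: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        try:
            groups = tuple(raw["groups"])
            network = raw.get("network", {})
            if "alpha" not in network:
                raise KeyError("network.alpha")
            perm = raw.get("permutation", {})
            cfg = cls(
                groups=groups,  # type: ignore[arg-type]
                output_dir=base / raw["output_dir"],
                counts=raw.get("counts"),
                simulate=raw.get("simulate"),
                channel=raw.get("channel"),
                r_min=float(network.get("r_min", 0.9)),
                alpha=float(network["alpha"]),
                use_absolute=bool(network.get("use_absolute", True)),
                outlier_sd=float(raw.get("outlier_sd", 2.0)),
                permutation_n=int(perm.get("n", 1000)),
                permutation_seed=int(perm.get("seed", 0)),
                sweep_alphas=list(raw.get("sweep_alphas", DEFAULT_SWEEP_ALPHAS)),
                ks_regions=list(raw.get("ks_regions", [])),
                volcano_d_threshold=float(raw.get("volcano", {}).get("d_threshold", 1.0)),
                volcano_alpha=float(raw.get("volcano", {}).get("alpha", 0.01)),
                figures=list(raw.get("figures", ["heatmap", "network", "volcano"])),
                min_mice=raw.get("min_mice"),
            )
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from exc
        cfg.validate(base)
        return cfg

    def validate(self, base: Path = Path(".")) -> None:
        if len(self.groups) != 2:
            raise ConfigError("exactly two group labels are required")
        if not 0 < (self.alpha or 0) < 1:
            raise ConfigError("network.alpha must lie in (0, 1)")
        if not 0 <= self.r_min < 1:
            raise ConfigError("network.r_min must lie in [0, 1)")
        if (self.counts is None) == (self.simulate is None):
            raise ConfigError("give exactly one of 'counts' or 'simulate'")
        if self.counts is not None:
            for g in self.groups:
                if g not in self.counts:
                    raise ConfigError(f"counts path missing for group {g!r}")
                p = base / self.counts[g]
                if not p.exists():
                    raise ConfigError(f"counts file does not exist: {p}")
            self.counts = {g: str(base / self.counts[g]) for g in self.groups}
        unknown = set(self.figures) - set(viz.FIGURE_KINDS)
        if unknown:
            raise ConfigError(f"unknown figure kind(s): {sorted(unknown)}")


def _load_counts(config: RunConfig) -> tuple[RegionCountTable, RegionCountTable]:
    if config.counts is not None:
        return (
            RegionCountTable.from_csv(config.counts[config.groups[0]]),
            RegionCountTable.from_csv(config.counts[config.groups[1]]),
        )
    sim = dict(config.simulate or {})
    sim.setdefault("groups", config.groups)
    sim["target_corr"] = {
        tuple(k.split("~")): v for k, v in sim.get("target_corr", {}).items()
    }
    sim["planted_diffs"] = {
        tuple(k.split("~")): tuple(v) for k, v in sim.get("planted_diffs", {}).items()
    }
    if "groups" in sim:
        sim["groups"] = tuple(sim["groups"])
    table_a, table_b, _ = simulate_region_counts(CountSimSpec(**sim))
    return table_a, table_b


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and return the paths of the written artifacts."""
    out = Path(config.output_dir)
    tables_dir = out / "tables"
    figures_dir = out / "figures"
    logs_dir = out / "logs"
    for d in (tables_dir, figures_dir, logs_dir):
        d.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    ga, gb = config.groups
    table_a, table_b = _stage("load_counts", lambda: _load_counts(config))
    table_a = _stage("outliers", lambda: remove_outliers(table_a, config.outlier_sd))
    table_b = _stage("outliers", lambda: remove_outliers(table_b, config.outlier_sd))
    table_a, table_b = _stage(
        "shared_regions",
        lambda: shared_regions_filter(table_a, table_b, min_mice=config.min_mice),
    )
    for g, t in ((ga, table_a), (gb, table_b)):
        p = tables_dir / f"counts_{g}.csv"
        t.to_csv(p)
        written[f"counts_{g}"] = p

    corrs = {
        ga: _stage("correlate", lambda: networks.pairwise_correlations(table_a, config.channel)),
        gb: _stage("correlate", lambda: networks.pairwise_correlations(table_b, config.channel)),
    }
    nets = {}
    metric_rows = []
    community_rows = []
    for g, corr in corrs.items():
        p = tables_dir / f"correlations_{g}.csv"
        corr.to_csv(p)
        written[f"correlations_{g}"] = p
        net = _stage(
            "network",
            lambda c=corr: networks.build_network(
                c, r_min=config.r_min, alpha=config.alpha, use_absolute=config.use_absolute
            ),
        )
        nets[g] = net
        p = tables_dir / f"edges_{g}.csv"
        net.edge_frame().to_csv(p, index=False)
        written[f"edges_{g}"] = p
        m = _stage("metrics", lambda n=net: networks.node_metrics(n))
        df = m.per_node.copy()
        df.insert(0, "group", g)
        metric_rows.append(df)
        if net.graph.number_of_edges() > 0:
            membership = _stage(
                "communities", lambda n=net: networks.leading_eigenvector_partition(n)
            )
            community_rows.append(
                pd.DataFrame(
                    {"group": g, "node": list(membership), "community": list(membership.values())}
                )
            )
    p = tables_dir / "node_metrics.csv"
    pd.concat(metric_rows, ignore_index=True).to_csv(p, index=False)
    written["node_metrics"] = p
    if community_rows:
        p = tables_dir / "communities.csv"
        pd.concat(community_rows, ignore_index=True).to_csv(p, index=False)
        written["communities"] = p

    sweep = _stage(
        "sweep",
        lambda: networks.threshold_sweep(
            corrs, sorted(config.sweep_alphas), r_min=config.r_min,
            use_absolute=config.use_absolute,
        ),
    )
    p = tables_dir / "threshold_sweep.csv"
    sweep.to_csv(p, index=False)
    written["threshold_sweep"] = p

    perm = _stage(
        "permutation",
        lambda: networks.permutation_correlation_diff(
            table_a, table_b, n_permutations=config.permutation_n,
            seed=config.permutation_seed, channel=config.channel,
        ),
    )
    p = tables_dir / "permutation.csv"
    perm.to_frame().to_csv(p, index=False)
    written["permutation"] = p

    if config.ks_regions:
        rows = []
        for region in config.ks_regions:
            d, pv = _stage(
                "ks", lambda r=region: networks.ks_region_distributions(corrs[ga], corrs[gb], r)
            )
            rows.append({"region": region, "D": d, "p": pv})
        p = tables_dir / "ks_regions.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written["ks_regions"] = p

    with open(logs_dir / "params.yaml", "w") as fh:
        echo = {k: (str(v) if isinstance(v, Path) else v) for k, v in vars(config).items()}
        yaml.safe_dump(echo, fh)

    written.update(
        render_figures(
            figures_dir, config.figures, corrs=corrs, nets=nets, perm=perm, config=config
        )
    )
    return written


def render_figures(
    figures_dir: str | Path,
    kinds: list[str],
    corrs: dict[str, networks.CorrelationMatrix],
    nets: dict[str, networks.FunctionalNetwork],
    perm: networks.PermutationResult,
    config: RunConfig,
) -> dict[str, Path]:
    """Render the requested figure kinds; one PNG and one SVG per kind."""
    figures_dir = Path(figures_dir)
    out: dict[str, Path] = {}
    groups = list(corrs)
    for kind in kinds:
        if kind not in viz.FIGURE_KINDS:
            raise ConfigError(f"unknown figure kind {kind!r}")
        for ext in ("png", "svg"):
            if kind == "heatmap":
                for g in groups:
                    out[f"heatmap_{g}_{ext}"] = viz.plot_heatmap(
                        corrs[g], figures_dir / f"heatmap_{g}.{ext}", title=g
                    )
            elif kind == "network":
                for g in groups:
                    out[f"network_{g}_{ext}"] = viz.plot_network(
                        nets[g], figures_dir / f"network_{g}.{ext}", title=g
                    )
            elif kind == "volcano":
                out[f"volcano_{ext}"] = viz.plot_volcano(
                    perm, figures_dir / f"volcano.{ext}",
                    d_threshold=config.volcano_d_threshold,
                    alpha=config.volcano_alpha,
                )
            elif kind == "parallel":
                out[f"parallel_{ext}"] = viz.plot_parallel(
                    perm, corrs[groups[0]], corrs[groups[1]],
                    figures_dir / f"parallel.{ext}",
                    d_threshold=config.volcano_d_threshold,
                    alpha=config.volcano_alpha,
                )
            elif kind == "distribution":
                for region in config.ks_regions:
                    out[f"distribution_{region}_{ext}"] = viz.plot_region_distribution(
                        corrs[groups[0]], corrs[groups[1]], region,
                        figures_dir / f"distribution_{region}.{ext}",
                        labels=(groups[0], groups[1]),
                    )
    return out
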