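"""One-command end-to-end analysis run.

A :class:`RunConfig` names the inputs (a mineral table + crustal table, or
the synthetic generator), the exclusion and outlier settings, and the
networks to build; :func:`run_pipeline` executes every stage, writes all
tables and exports under one output directory, and returns a run report.

Outputs of a run directory::

    element_stats.tsv     per-element summary table (post-exclusion)
    regressions.tsv       the four trend fits
    outliers.tsv          flagged trend outliers per fit
    rejects.tsv           minerals dropped for ambiguous/unparseable formulas
    network_<label>.graphml / communities_<label>.tsv   per requested network
    run_report.json       counts, seeds and a config echo
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .elements import (
    DEFAULT_EXCLUDED_ELEMENTS,
    DEFAULT_MIN_MINERALS,
    MineralRecord,
    apply_exclusions,
    compute_element_stats,
)
from .network import (
    DEFAULT_LOUVAIN_RESOLUTION,
    DEFAULT_LOUVAIN_SEED,
    build_network,
    detect_communities,
    export_network,
)
from .synthetic import SyntheticConfig, generate_minerals, generate_universe
from .trends import DEFAULT_OUTLIER_THRESHOLD, flag_outliers, run_paper_regressions

__all__ = ["NetworkRequest", "RunConfig", "run_pipeline", "paper_preset_networks"]

logger = logging.getLogger("mineralnet.pipeline")


@dataclass(frozen=True)
class NetworkRequest:
    """One requested network slice: a label, focal elements, age threshold."""

    label: str
    focal_elements: frozenset[str] | None = None
    min_age_ga: float | None = None


def paper_preset_networks() -> list[NetworkRequest]:
    """The named focal-element / era slices of the published analysis:
    the S network, the Sc-Ga-Br-Yb network at >1.7/>0.6/>0 Ga, and the
    C-H-N network at >3.5/>2.3/>0 Ga."""
    sgby = frozenset({"Sc", "Ga", "Br", "Yb"})
    chn = frozenset({"C", "H", "N"})
    return [
        NetworkRequest("S_all", frozenset({"S"}), None),
        NetworkRequest("ScGaBrYb_ge1.7", sgby, 1.7),
        NetworkRequest("ScGaBrYb_ge0.6", sgby, 0.6),
        NetworkRequest("ScGaBrYb_ge0", sgby, 0.0),
        NetworkRequest("CHN_ge3.5", chn, 3.5),
        NetworkRequest("CHN_ge2.3", chn, 2.3),
        NetworkRequest("CHN_ge0", chn, 0.0),
    ]


@dataclass
class RunConfig:
    """Full configuration of one pipeline run.

    Exactly one input mode is active: file paths (``mineral_table`` and
    optionally ``crustal_table``) or the synthetic generator
    (``synthetic=True``).
    """

    outdir: str | Path = "mineralnet_run"
    mineral_table: str | Path | None = None
    crustal_table: str | Path | None = None
    synthetic: bool = False
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    column_map: dict[str, str] | None = None
    excluded_symbols: frozenset[str] = DEFAULT_EXCLUDED_ELEMENTS
    min_minerals: int = DEFAULT_MIN_MINERALS
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD
    networks: list[NetworkRequest] = field(default_factory=list)
    community_seed: int = DEFAULT_LOUVAIN_SEED
    community_resolution: float = DEFAULT_LOUVAIN_RESOLUTION

    def __post_init__(self) -> None:
        if self.synthetic == (self.mineral_table is not None):
            raise ValueError("exactly one of mineral_table / synthetic must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic_config" in raw and raw["synthetic_config"] is not None:
            sc = dict(raw["synthetic_config"])
            for key in ("abundance_log10_range", "age_levels", "age_weights"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            if "outlier_spec" in sc:
                sc["outlier_spec"] = tuple((s, float(m)) for s, m in sc["outlier_spec"])
            raw["synthetic_config"] = SyntheticConfig(**sc)
        if "networks" in raw:
            raw["networks"] = [
                NetworkRequest(
                    label=n["label"],
                    focal_elements=frozenset(n["focal_elements"]) if n.get("focal_elements") else None,
                    min_age_ga=n.get("min_age_ga"),
                )
                for n in raw["networks"]
            ]
        if "excluded_symbols" in raw:
            raw["excluded_symbols"] = frozenset(raw["excluded_symbols"])
        return cls(**raw)


def _config_echo(config: RunConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["outdir"] = str(echo["outdir"])
    for key in ("mineral_table", "crustal_table"):
        if echo[key] is not None:
            echo[key] = str(echo[key])
    echo["excluded_symbols"] = sorted(config.excluded_symbols)
    echo["networks"] = [
        {
            "label": n.label,
            "focal_elements": sorted(n.focal_elements) if n.focal_elements else None,
            "min_age_ga": n.min_age_ga,
        }
        for n in config.networks
    ]
    return echo


def _load_inputs(config: RunConfig) -> tuple[list[MineralRecord], dict[str, float], int]:
    """Return (records, crustal map, n_rejected); also writes rejects.tsv."""
    outdir = Path(config.outdir)
    if config.synthetic:
        logger.info("stage=generate synthetic universe (seed=%d)", config.synthetic_config.seed)
        universe, _ = generate_universe(config.synthetic_config)
        records = generate_minerals(config.synthetic_config, universe)
        crustal = dict(zip(universe["element"], universe["weight_percent"]))
        # synthetic formulas are unambiguous by construction; write an empty rejects file
        pd.DataFrame(columns=["mineral_name", "formula", "reason"]).to_csv(
            outdir / "rejects.tsv", sep="\t", index=False
        )
        return records, crustal, 0
    logger.info("stage=read mineral table %s", config.mineral_table)
    records, rejects = mio.read_mineral_table(config.mineral_table, config.column_map)
    rejects.to_csv(outdir / "rejects.tsv", sep="\t", index=False)
    crustal: dict[str, float] = {}
    if config.crustal_table is not None:
        logger.info("stage=read crustal table %s", config.crustal_table)
        crustal = mio.read_crustal_table(config.crustal_table)
    return records, crustal, len(rejects)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle; returns the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not logging.getLogger().handlers:
        logging.basicConfig(
            level=logging.INFO, format="%(asctime)s %(name)s %(message)s", force=False
        )

    records, crustal, n_rejected = _load_inputs(config)
    if not records:
        raise ValueError("no usable mineral records after parsing")

    logger.info("stage=element_stats %d minerals", len(records))
    stats = compute_element_stats(records, crustal)
    kept, exclusion_log = apply_exclusions(stats, config.excluded_symbols, config.min_minerals)
    mio.write_element_stats(kept, outdir / "element_stats.tsv")

    logger.info("stage=regressions %d elements", len(kept))
    fits = run_paper_regressions(kept)
    mio.write_regression_summary(fits, outdir / "regressions.tsv")
    # outlier calling needs >=4 points; tiny fits just report no outliers
    outlier_calls = {
        name: (flag_outliers(r, config.outlier_threshold) if r.n >= 4 else [])
        for name, r in fits.items()
    }
    mio.write_outliers(outlier_calls, outdir / "outliers.tsv")

    network_summaries = {}
    for request in config.networks:
        logger.info("stage=network label=%s", request.label)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = build_network(records, request.focal_elements, request.min_age_ga)
        summary = {
            "n_minerals": len(net.mineral_nodes),
            "n_elements": len(net.element_nodes),
            "n_edges": net.n_edges,
        }
        if net.n_nodes >= 2:
            partition = detect_communities(net, config.community_seed, config.community_resolution)
            mio.write_communities(net, partition, outdir / f"communities_{request.label}.tsv")
            summary["n_communities"] = partition.n_communities
            summary["modularity"] = partition.modularity
        export_network(net, outdir / f"network_{request.label}.graphml", format="graphml")
        network_summaries[request.label] = summary

    report = {
        "n_minerals_used": len(records),
        "n_minerals_rejected": n_rejected,
        "n_elements_total": len(stats),
        "n_elements_after_exclusions": len(kept),
        "excluded_by_symbol": exclusion_log.excluded_by_symbol,
        "excluded_by_min_minerals": exclusion_log.excluded_by_min_minerals,
        "community_seed": config.community_seed,
        "regressions": {
            name: {"n": r.n, "slope": r.slope, "r_squared": r.r_squared, "p_value": r.p_value}
            for name, r in fits.items()
        },
        "outliers": {
            name: [[c.symbol, c.direction] for c in calls]
            for name, calls in outlier_calls.items()
        },
        "networks": network_summaries,
        "config": _config_echo(config),
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    logger.info("stage=done outdir=%s", outdir)
    return report
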