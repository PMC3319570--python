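"""Pipeline orchestration: from a run config to tables, networks and logs.

A run reads (or simulates) expression matrices plus sample metadata, builds
the per-setting coexpression networks, tallies cross-setting conservation,
profiles gatekeeper concordance, runs the moderated-t contrasts where a
setting has both conditions, and writes every artifact under one output
directory. Outputs are deterministically ordered, so identical inputs and
config give byte-identical tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .coexpression import CorrelationEdge, Thresholds, build_network, edges_to_frame
from .conservation import conserved_edges, conservation_to_frame, occurrence_table
from .diffexpr import de_filter, moderated_de, results_to_frame
from .expression_io import (
    read_matrix,
    read_metadata,
    read_probe_map,
    select_probe_per_gene,
    subset_to_geneset,
)
from .gatekeeper import classify_phenotype_gene, concordance_summary, profiles_to_frame
from .geneset import GATEKEEPER_SET, load_geneset
from .synthetic import generate, scenario

__all__ = ["RunConfig", "run_pipeline", "simulate_to_dir", "export_network", "read_edges_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Either ``scenario`` (a named synthetic design) or ``matrix_path`` +
    ``metadata_path`` must be given. ``methods`` maps setting id to
    "pearson" or "partial"; settings with a non-empty ``subgroup`` column
    default to partial correlation, matching how grouped samples are handled.
    """

    matrix_path: str | None = None
    metadata_path: str | None = None
    probe_map_path: str | None = None
    geneset_path: str | None = None
    scenario: str | None = None
    methods: dict[str, str] = field(default_factory=dict)
    r_min: float = 0.75
    alpha: float = 0.05
    approach_max: float = 0.10
    fc_min: float = 1.5
    min_settings: int = 3
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = Thresholds(
            r_min=self.r_min, alpha=self.alpha, approach_max=self.approach_max
        )
        if self.fc_min < 1.0:
            raise ValueError(f"fc_min must be >= 1, got {self.fc_min}")
        if self.min_settings < 1:
            raise ValueError("min_settings must be >= 1")
        if self.scenario is None and (self.matrix_path is None or self.metadata_path is None):
            raise ValueError("config needs either a scenario or matrix + metadata paths")
        for setting, method in self.methods.items():
            if method not in ("pearson", "partial"):
                raise ValueError(f"setting {setting!r}: unknown method {method!r}")
        for name in ("matrix_path", "metadata_path", "probe_map_path", "geneset_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "out_dir" not in raw:
            raw["out_dir"] = str(Path(path).with_suffix("")) + "_results"
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


def _write_tsv(frame: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def simulate_to_dir(name: str, seed: int, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate a named scenario and write matrix + metadata TSVs.

    All settings of the scenario are concatenated column-wise into one
    matrix (shared gene universe) with a combined metadata table; ground
    truth goes to ``ground_truth.tsv``. Returns (matrix path, metadata path).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configs = scenario(name, seed)
    matrices, metas, truth_rows = [], [], []
    for setting, cfg in configs.items():
        matrix, meta, truth = generate(cfg)
        matrices.append(matrix)
        metas.append(meta)
        for cond, edges in truth.true_edges.items():
            for a, b, sign, rho in edges:
                truth_rows.append([setting, cond, a, b, sign, rho])
    combined = pd.concat(matrices, axis=1)
    combined.insert(0, "gene", combined.index)
    matrix_path = out / "matrix.tsv"
    combined.to_csv(matrix_path, sep="\t", index=False, float_format="%.6f")
    meta_path = out / "metadata.tsv"
    pd.concat(metas, ignore_index=True).to_csv(meta_path, sep="\t", index=False)
    _write_tsv(
        pd.DataFrame(
            truth_rows,
            columns=["setting_id", "condition", "gene_a", "gene_b", "sign", "rho"],
        ),
        out / "ground_truth.tsv",
    )
    return matrix_path, meta_path


def _setting_networks(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: RunConfig,
) -> dict[str, list[CorrelationEdge]]:
    """One network per (setting, condition-present) with the configured method."""
    networks: dict[str, list[CorrelationEdge]] = {}
    for setting in sorted(metadata["setting_id"].unique()):
        sub_meta = metadata[metadata["setting_id"] == setting]
        for condition in sorted(sub_meta["condition"].unique()):
            rows = sub_meta[sub_meta["condition"] == condition]
            samples = [s for s in rows["sample_id"] if s in matrix.columns]
            key = (
                setting
                if len(sub_meta["condition"].unique()) == 1
                else f"{setting}:{condition}"
            )
            if len(samples) < 3:
                logger.warning("setting %s skipped: %d usable sample(s)", key, len(samples))
                continue
            groups = rows.set_index("sample_id").loc[samples, "subgroup"].tolist()
            has_groups = len(set(groups)) > 1
            method = config.methods.get(setting, "partial" if has_groups else "pearson")
            networks[key] = build_network(
                matrix[samples],
                method=method,
                groups=groups if method == "partial" else None,
                setting_id=key,
                thresholds=config.thresholds,
            )
    if not networks:
        raise ValueError("no setting had >= 3 usable samples")
    return networks


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write artifacts under ``config.out_dir``.

    Returns a mapping of artifact name to path. Stages: input (or
    simulation), probe collapse and geneset restriction when a probe map /
    geneset is configured, per-setting networks, conservation report,
    occurrence counts, gatekeeper profiles, and per-setting DE tables for
    settings with both conditions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines = [
        f"coexprofiler {__version__}",
        f"seed: {config.seed}",
        f"thresholds: |r|>={config.thresholds.r_min}, p<{config.thresholds.alpha}, "
        f"approaching<{config.thresholds.approach_max}, fc>={config.fc_min}",
        f"min_settings: {config.min_settings}",
    ]

    if config.scenario is not None:
        sim_dir = out / "simulated"
        matrix_path, metadata_path = simulate_to_dir(config.scenario, config.seed, sim_dir)
        artifacts["ground_truth"] = sim_dir / "ground_truth.tsv"
        log_lines.append(f"scenario: {config.scenario}")
    else:
        matrix_path, metadata_path = Path(config.matrix_path), Path(config.metadata_path)
    log_lines += [f"matrix: {matrix_path}", f"metadata: {metadata_path}"]

    matrix = read_matrix(matrix_path)
    metadata = read_metadata(metadata_path)

    if config.probe_map_path is not None:
        probe_map = read_probe_map(config.probe_map_path)
        matrix, report = select_probe_per_gene(matrix, probe_map, metadata)
        log_lines.append(
            f"probe collapse: kept {len(report.kept)} gene(s); dropped "
            f"{len(report.dropped_probes)} probe(s); unmapped {len(report.unmapped_probes)}"
        )
    if config.geneset_path is not None or config.probe_map_path is not None:
        gs = load_geneset(config.geneset_path)
        matrix, absent = subset_to_geneset(matrix, gs)
        log_lines.append(f"geneset restriction: {matrix.shape[0]} present, {len(absent)} absent")

    networks = _setting_networks(matrix, metadata, config)
    for key, edges in networks.items():
        path = out / f"edges_{key.replace(':', '_')}.tsv"
        _write_tsv(edges_to_frame(edges), path)
        artifacts[f"edges:{key}"] = path
        strong = sum(1 for e in edges if e.sig_class == "strong")
        log_lines.append(f"setting {key}: {len(edges)} pair(s), {strong} strong")

    result = conserved_edges(networks, config.min_settings)
    cons_path = out / "conservation.tsv"
    _write_tsv(conservation_to_frame(result), cons_path)
    artifacts["conservation"] = cons_path
    log_lines.append(
        f"conservation: {len(result.conserved)} pair(s) in >= {config.min_settings} "
        f"setting(s); {len(result.sign_discordant)} sign-discordant"
    )

    occ = occurrence_table(networks)
    occ_path = out / "occurrences.tsv"
    occ.rename("strong_edges").rename_axis("gene").reset_index().to_csv(
        occ_path, sep="\t", index=False
    )
    artifacts["occurrences"] = occ_path

    # gatekeeper concordance, per setting, where enough of the set is measured
    gk_present = [g for g in GATEKEEPER_SET if g in matrix.index]
    if len(gk_present) >= 2:
        gs_all = load_geneset(config.geneset_path)
        phenotype_genes = [g for g in gs_all.symbols("phenotype") if g in matrix.index]
        profiles_frames = []
        for setting in sorted(metadata["setting_id"].unique()):
            rows = metadata[metadata["setting_id"] == setting]
            samples = [s for s in rows["sample_id"] if s in matrix.columns]
            if len(samples) < 3 or not phenotype_genes:
                continue
            groups = rows.set_index("sample_id").loc[samples, "subgroup"].tolist()
            groups = groups if len(set(groups)) > 1 else None
            profiles = [
                classify_phenotype_gene(
                    matrix[samples], pheno, groups=groups, thresholds=config.thresholds
                )
                for pheno in phenotype_genes
            ]
            frame = profiles_to_frame(profiles)
            frame.insert(0, "setting_id", setting)
            profiles_frames.append(frame)
            log_lines.append(
                f"gatekeeper concordance {setting}: {concordance_summary(profiles)}"
            )
        if profiles_frames:
            gk_path = out / "gatekeeper_profiles.tsv"
            _write_tsv(pd.concat(profiles_frames, ignore_index=True), gk_path)
            artifacts["gatekeeper_profiles"] = gk_path

    # DE contrasts for settings with both conditions
    for setting in sorted(metadata["setting_id"].unique()):
        rows = metadata[metadata["setting_id"] == setting]
        conds = set(rows["condition"])
        if not {"control", "exposed"} <= conds:
            continue
        samples = [s for s in rows["sample_id"] if s in matrix.columns]
        labels = rows.set_index("sample_id").loc[samples, "condition"].tolist()
        if labels.count("control") < 2 or labels.count("exposed") < 2:
            logger.warning("setting %s: too few samples for a DE contrast", setting)
            continue
        results = moderated_de(matrix[samples], labels)
        de_path = out / f"de_{setting}.tsv"
        _write_tsv(
            results_to_frame(results, config.fc_min, config.thresholds.alpha), de_path
        )
        artifacts[f"de:{setting}"] = de_path
        passing, near = de_filter(results, config.fc_min, config.thresholds.alpha)
        log_lines.append(
            f"de {setting}: {len(passing)} gene(s) pass, {len(near)} near-miss(es)"
        )

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    artifacts["run_log"] = log_path
    return artifacts


_EDGE_COLUMNS = ["gene_a", "gene_b", "r", "p", "n", "k_groups", "method", "setting_id", "sig_class"]


def export_network(
    edges: Sequence[CorrelationEdge],
    path: str | Path,
    format: str = "tsv",
    node_categories: Mapping[str, str] | None = None,
) -> Path:
    """Write an edge list as TSV, SIF or GraphML.

    GraphML carries r as a numeric edge attribute (plus p and sig_class) and
    the optional ``node_categories`` mapping as a node attribute, for
    network viewers. SIF uses the interaction type ``corr``.
    """
    edges = list(edges)
    if not edges:
        raise ValueError("refusing to export an empty edge list")
    path = Path(path)
    if format == "tsv":
        _write_tsv(edges_to_frame(edges), path, float_format="%.10g")
    elif format == "sif":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.gene_a}\tcorr\t{e.gene_b}\n")
    elif format == "graphml":
        graph = nx.Graph()
        for e in edges:
            graph.add_edge(
                e.gene_a, e.gene_b, r=float(e.r), p=float(e.p), sig_class=e.sig_class
            )
        if node_categories:
            for node in graph.nodes:
                graph.nodes[node]["category"] = node_categories.get(node, "")
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def read_edges_tsv(path: str | Path) -> list[CorrelationEdge]:
    """Read back an edge TSV written by :func:`export_network` / the pipeline."""
    frame = pd.read_csv(path, sep="\t", dtype={"setting_id": str}, keep_default_na=False)
    missing = [c for c in _EDGE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing edge column(s) {missing}")
    return [
        CorrelationEdge(
            gene_a=row.gene_a, gene_b=row.gene_b, r=float(row.r), p=float(row.p),
            n=int(row.n), k_groups=int(row.k_groups), method=row.method,
            setting_id=str(row.setting_id), sig_class=row.sig_class,
        )
        for row in frame.itertuples()
    ]
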