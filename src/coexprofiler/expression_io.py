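"""Reading expression matrices and sample metadata; probe-to-gene collapse.

Input matrices are RMA-style log2 intensities (rows = probes or genes,
columns = samples) in tab-delimited text. Probe-level matrices are collapsed
to one row per gene by keeping, for each gene, the probe with the highest
mean expression over the normal (control) samples of the setting at hand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geneset import Geneset

__all__ = [
    "ExpressionIOError",
    "CONDITIONS",
    "METADATA_COLUMNS",
    "read_matrix",
    "read_metadata",
    "read_probe_map",
    "select_probe_per_gene",
    "subset_to_geneset",
    "ProbeCollapseReport",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "exposed")
METADATA_COLUMNS = ("sample_id", "setting_id", "condition", "subgroup", "species", "compound")

#: plausibility window for RMA-scale log2 intensities
_LOG2_RANGE = (0.0, 20.0)


class ExpressionIOError(ValueError):
    """Raised for malformed matrix / metadata / probe-map inputs."""


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Parse a tab-delimited expression matrix.

    First row holds sample ids, first column row (probe/gene) ids. Returns a
    float DataFrame (rows x samples). Duplicate sample ids, ragged rows,
    duplicate row ids and non-numeric cells (including ``NA``) are reported
    with their location.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ExpressionIOError(f"{path}: expected at least one sample column")
        samples = header[1:]
        dupes = [s for s in set(samples) if samples.count(s) > 1]
        if dupes:
            raise ExpressionIOError(
                f"{path}: duplicated sample id(s) in header: {sorted(dupes)}"
            )
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(samples) + 1:
                raise ExpressionIOError(
                    f"{path}: line {lineno} has {len(fields) - 1} value(s), "
                    f"expected {len(samples)}"
                )
            rid = fields[0]
            if rid in row_ids:
                raise ExpressionIOError(f"{path}: duplicated row id {rid!r} at line {lineno}")
            values = []
            for col, cell in zip(samples, fields[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise ExpressionIOError(
                        f"{path}: non-numeric cell {cell!r} at row {rid!r}, column {col!r}"
                    ) from None
                if not np.isfinite(v):
                    raise ExpressionIOError(
                        f"{path}: non-finite cell {cell!r} at row {rid!r}, column {col!r}"
                    )
                values.append(v)
            row_ids.append(rid)
            rows.append(values)
    if not rows:
        raise ExpressionIOError(f"{path}: matrix has no data rows")
    matrix = pd.DataFrame(rows, index=row_ids, columns=samples, dtype=float)
    lo, hi = _LOG2_RANGE
    if (matrix.values < lo).any() or (matrix.values > hi).any():
        warnings.warn(
            f"{path}: values outside the plausible log2 range [{lo}, {hi}]; "
            "is the matrix RMA/log2 normalized?",
            stacklevel=2,
        )
    return matrix


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Parse the per-sample metadata TSV.

    Expected header: ``sample_id setting_id condition subgroup species
    compound`` (tab-separated); ``subgroup`` and ``compound`` may be empty.
    """
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS[:3] if c not in meta.columns]
    if missing:
        raise ExpressionIOError(f"{path}: missing metadata column(s) {missing}")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = ""
    if meta["sample_id"].duplicated().any():
        dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ExpressionIOError(f"{path}: duplicated sample_id(s) {dupes}")
    bad = sorted(set(meta["condition"]) - set(CONDITIONS))
    if bad:
        raise ExpressionIOError(
            f"{path}: condition must be one of {CONDITIONS}, got {bad}"
        )
    return meta[list(METADATA_COLUMNS)]


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Parse a two-column ``probe_id <tab> symbol`` TSV into a dict."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ExpressionIOError(f"{path}: line {lineno}: expected 2 columns")
            probe, symbol = fields
            if lineno == 1 and probe.lower() in ("probe_id", "probe"):
                continue
            if probe in mapping:
                raise ExpressionIOError(f"{path}: duplicated probe id {probe!r}")
            mapping[probe] = symbol
    return mapping


@dataclass
class ProbeCollapseReport:
    """Audit trail of the probe -> gene collapse."""

    kept: dict[str, str] = field(default_factory=dict)  # gene -> winning probe
    dropped_probes: list[str] = field(default_factory=list)
    unmapped_probes: list[str] = field(default_factory=list)
    used_all_samples_fallback: bool = False


def _normal_samples(matrix: pd.DataFrame, metadata: pd.DataFrame | None) -> tuple[list[str], bool]:
    if metadata is None:
        return list(matrix.columns), True
    meta = metadata.set_index("sample_id")
    controls = [s for s in matrix.columns if s in meta.index and meta.at[s, "condition"] == "control"]
    if controls:
        return controls, False
    return list(matrix.columns), True


def select_probe_per_gene(
    matrix: pd.DataFrame,
    probe_map: Mapping[str, str],
    metadata: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ProbeCollapseReport]:
    """Collapse a probe-level matrix to one row per gene.

    For a gene measured by several probes, the probe with the highest mean
    over the normal (``condition == control``) samples wins; ties break on
    lexicographic probe id, which makes the collapse deterministic and
    independent of column order. Settings without control samples fall back
    to the mean over all samples (warned, recorded in the report). Probes
    absent from ``probe_map`` are dropped and listed.
    """
    normal, fallback = _normal_samples(matrix, metadata)
    if fallback and metadata is not None:
        warnings.warn(
            "no control samples found; probe selection uses the mean over all samples",
            stacklevel=2,
        )
    report = ProbeCollapseReport(used_all_samples_fallback=fallback)

    by_gene: dict[str, list[str]] = {}
    for probe in matrix.index:
        gene = probe_map.get(probe)
        if gene is None:
            report.unmapped_probes.append(probe)
            continue
        by_gene.setdefault(gene, []).append(probe)

    if not by_gene:
        raise ExpressionIOError("no matrix row maps to a gene via the probe map")

    normal_means = matrix[normal].mean(axis=1)
    genes, winners = [], []
    for gene, probes in by_gene.items():
        # max mean; ties resolved by lexicographically first probe id
        best = min(probes, key=lambda p: (-normal_means.at[p], p))
        genes.append(gene)
        winners.append(best)
        report.kept[gene] = best
        report.dropped_probes.extend(p for p in probes if p != best)

    collapsed = matrix.loc[winners]
    collapsed.index = genes
    if report.dropped_probes:
        logger.info(
            "probe collapse dropped %d probe(s): %s",
            len(report.dropped_probes), ", ".join(sorted(report.dropped_probes)),
        )
    if report.unmapped_probes:
        logger.info(
            "%d probe(s) absent from the probe map were dropped", len(report.unmapped_probes)
        )
    return collapsed, report


def subset_to_geneset(
    matrix: pd.DataFrame, geneset: Geneset
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict a gene-level matrix to the analysis geneset.

    Row ids are first canonicalized through the geneset alias table (so a
    platform row labelled ``Utx`` matches the entry ``Kdm6a``). Returns the
    restricted matrix and the list of geneset genes absent from the platform.
    """
    canonical = []
    for rid in matrix.index:
        symbol, _known = geneset.resolve(rid)
        canonical.append(symbol)
    renamed = matrix.copy()
    renamed.index = canonical
    present = [s for s in renamed.index if s in geneset]
    if not present:
        raise ExpressionIOError("no geneset gene is present in the matrix")
    sub = renamed.loc[renamed.index.isin(list(geneset.symbols()))]
    # stable order: keep matrix order, drop duplicate symbols (first wins)
    sub = sub[~sub.index.duplicated(keep="first")]
    absent = [s for s in geneset.symbols() if s not in set(sub.index)]
    if absent:
        logger.info("%d geneset gene(s) absent from the platform", len(absent))
    return sub, absent
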