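"""Gatekeeper-set network profiling and phenotype-gene concordance.

The gatekeeper mechanism (Garcia-Bassets and colleagues) holds that
repressive H3K9 methylation marks written by Ehmt1, Prdm2 and Setdb1 gate
promoter access for liganded nuclear receptors, with the demethylase Kdm1
removing the marks on activation. Its coregulatory gene set here is
{Esr2, Ehmt2, Ehmt1, Kdm1, Prdm2, Setdb1}.

A phenotype gene is concordant with the mechanism when its coexpression
pattern with the gatekeeper genes mirrors its link to the receptor(s):
``full`` — strong with a receptor and strong with every gatekeeper modifier;
``approaching`` — at least approaching on both counts; ``none`` otherwise.
Pattern agreement is judged on significance class, not sign: the observed
consistent patterns mix correlation and anti-correlation, so the signed
pattern vector is reported for users who want a stricter criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .coexpression import (
    DEFAULT_THRESHOLDS,
    CorrelationEdge,
    Thresholds,
    UndefinedCorrelationError,
    build_network,
    classify_edge,
    partial_with_p,
    pearson_with_p,
)
from .geneset import GATEKEEPER_SET

__all__ = [
    "DEFAULT_RECEPTOR_SUBSET",
    "ConcordanceProfile",
    "gatekeeper_network",
    "classify_phenotype_gene",
    "concordance_summary",
    "profiles_to_frame",
]

logger = logging.getLogger(__name__)

#: Receptors against which phenotype genes are profiled (restricted to
#: platform availability at call time).
DEFAULT_RECEPTOR_SUBSET = ("Esr1", "Esr2", "Ar")

_CLASS_RANK = {"strong": 2, "approaching": 1, "absent": 0}


@dataclass(frozen=True)
class ConcordanceProfile:
    """Concordance of one phenotype gene with the gatekeeper set.

    ``pattern`` holds one (gatekeeper gene, r, sig_class) triple per
    gatekeeper-set member present on the platform; ``receptor_link`` is the
    best significance class over the receptor subset.
    """

    phenotype_gene: str
    receptor_link: str  # {strong, approaching, none}
    pattern: tuple[tuple[str, float, str], ...]
    concordance_class: str  # {full, approaching, none}


def gatekeeper_network(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    gatekeeper_genes: Sequence[str] = GATEKEEPER_SET,
    *,
    method: str = "pearson",
    groups: Sequence | None = None,
    setting_id: str = "",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[CorrelationEdge]:
    """All pairwise classified edges among the gatekeeper genes present."""
    present = [g for g in gatekeeper_genes if g in matrix.index]
    absent = [g for g in gatekeeper_genes if g not in matrix.index]
    if absent:
        logger.info("gatekeeper gene(s) absent from the platform: %s", ", ".join(absent))
    if len(present) < 2:
        raise ValueError(
            f"need at least 2 gatekeeper genes on the platform, found {len(present)}"
        )
    return build_network(
        matrix.loc[present], metadata, method=method, groups=groups,
        setting_id=setting_id, thresholds=thresholds,
    )


def _corr_class(
    matrix: pd.DataFrame,
    a: str,
    b: str,
    groups: Sequence | None,
    thresholds: Thresholds,
) -> tuple[float, str]:
    x, y = matrix.loc[a].values, matrix.loc[b].values
    try:
        if groups is None:
            r, p, _ = pearson_with_p(x, y)
        else:
            r, p, _, _ = partial_with_p(x, y, groups)
    except UndefinedCorrelationError:
        return float("nan"), "absent"
    return r, classify_edge(r, p, thresholds)


def classify_phenotype_gene(
    matrix: pd.DataFrame,
    phenotype_gene: str,
    gatekeeper_genes: Sequence[str] = GATEKEEPER_SET,
    receptor_subset: Sequence[str] = DEFAULT_RECEPTOR_SUBSET,
    *,
    groups: Sequence | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> ConcordanceProfile:
    """Profile one phenotype gene against receptors and the gatekeeper set.

    ``receptor_link`` is the best class over the receptors present;
    the concordance requirement over the gatekeeper set applies to its
    non-receptor members (the methylation modifiers), while the full signed
    pattern over every present member is recorded.
    """
    if phenotype_gene not in matrix.index:
        raise ValueError(f"phenotype gene {phenotype_gene!r} absent from the matrix")
    receptors = [g for g in receptor_subset if g in matrix.index and g != phenotype_gene]
    gatekeepers = [g for g in gatekeeper_genes if g in matrix.index and g != phenotype_gene]
    modifiers = [g for g in gatekeepers if g not in set(receptor_subset)]

    receptor_best = "absent"
    for rec in receptors:
        _, cls = _corr_class(matrix, phenotype_gene, rec, groups, thresholds)
        if _CLASS_RANK[cls] > _CLASS_RANK[receptor_best]:
            receptor_best = cls
    receptor_link = {"strong": "strong", "approaching": "approaching", "absent": "none"}[
        receptor_best
    ]

    pattern = []
    modifier_classes = []
    for g in gatekeepers:
        r, cls = _corr_class(matrix, phenotype_gene, g, groups, thresholds)
        pattern.append((g, r, cls))
        if g in modifiers:
            modifier_classes.append(cls)

    if (
        receptor_link == "strong"
        and modifier_classes
        and all(c == "strong" for c in modifier_classes)
    ):
        concordance = "full"
    elif (
        receptor_link in ("strong", "approaching")
        and modifier_classes
        and all(c in ("strong", "approaching") for c in modifier_classes)
    ):
        concordance = "approaching"
    else:
        concordance = "none"

    return ConcordanceProfile(
        phenotype_gene=phenotype_gene,
        receptor_link=receptor_link,
        pattern=tuple(pattern),
        concordance_class=concordance,
    )


def concordance_summary(
    profiles: Iterable[ConcordanceProfile],
) -> dict[str, dict[str, float]]:
    """Tally and fraction of profiles per concordance class."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    total = len(profiles)
    out: dict[str, dict[str, float]] = {}
    for cls in ("full", "approaching", "none"):
        n = sum(1 for p in profiles if p.concordance_class == cls)
        out[cls] = {"count": n, "fraction": n / total}
    return out


def profiles_to_frame(profiles: Iterable[ConcordanceProfile]) -> pd.DataFrame:
    """Long-format table: one row per (phenotype gene, gatekeeper gene)."""
    rows = []
    for prof in profiles:
        for gene, r, cls in prof.pattern:
            rows.append(
                [prof.phenotype_gene, gene, r, cls, prof.receptor_link,
                 prof.concordance_class]
            )
    return pd.DataFrame(
        rows,
        columns=["phenotype_gene", "gatekeeper_gene", "r", "sig_class",
                 "receptor_link", "concordance_class"],
    )
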