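"""Cross-setting comparison of coexpression networks.

A coexpression relationship counts as conserved when the same unordered gene
pair is classified strong with the same correlation sign in several
settings. Edges that only approach significance never contribute. Pairs that
are strong with opposite signs in different settings are excluded from the
conserved list and reported separately as sign-discordant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .coexpression import CorrelationEdge

__all__ = [
    "ConservationRecord",
    "ConservationResult",
    "HubComparison",
    "conserved_edges",
    "occurrence_count",
    "occurrence_table",
    "hub_partner_comparison",
    "conservation_to_frame",
]


@dataclass(frozen=True)
class ConservationRecord:
    """One gene pair strong with a consistent sign in >= min_settings settings."""

    gene_pair: tuple[str, str]
    settings_observed: tuple[str, ...]
    sign: str  # "+" or "-"
    sign_consistent: bool = True

    @property
    def n_settings(self) -> int:
        return len(self.settings_observed)


@dataclass
class ConservationResult:
    """Conserved pairs plus the sign-discordant pairs excluded from them."""

    conserved: list[ConservationRecord] = field(default_factory=list)
    sign_discordant: list[ConservationRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.conserved)

    def __len__(self) -> int:
        return len(self.conserved)


def _strong_by_pair(
    networks: Mapping[str, Iterable[CorrelationEdge]]
) -> dict[tuple[str, str], list[tuple[str, str]]]:
    """pair -> [(setting, sign), ...] over strong edges, one entry per setting."""
    seen: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for setting_id, edges in networks.items():
        for edge in edges:
            if edge.sig_class != "strong":
                continue
            entries = seen.setdefault(edge.pair, [])
            if any(s == setting_id for s, _ in entries):
                continue  # one observation per pair per setting
            entries.append((setting_id, edge.sign))
    return seen


def conserved_edges(
    networks: Mapping[str, Iterable[CorrelationEdge]], min_settings: int
) -> ConservationResult:
    """Tally pairs strong with the same sign in at least ``min_settings`` settings.

    ``networks`` maps setting id to that setting's classified edge list.
    Sign-discordant pairs (strong + in one setting, strong - in another) are
    never conserved regardless of their count; they are returned on the
    ``sign_discordant`` attribute with ``sign_consistent=False``.
    """
    if min_settings < 1:
        raise ValueError("min_settings must be >= 1")
    result = ConservationResult()
    for pair, entries in sorted(_strong_by_pair(networks).items()):
        settings = tuple(s for s, _ in entries)
        signs = {sign for _, sign in entries}
        if len(signs) > 1:
            result.sign_discordant.append(
                ConservationRecord(pair, settings, sign="±", sign_consistent=False)
            )
            continue
        if len(settings) >= min_settings:
            result.conserved.append(
                ConservationRecord(pair, settings, sign=signs.pop(), sign_consistent=True)
            )
    return result


def occurrence_count(
    networks: Mapping[str, Iterable[CorrelationEdge]], gene: str
) -> int:
    """Total strong edges involving ``gene``, summed over settings."""
    count = 0
    seen_gene = False
    for edges in networks.values():
        for edge in edges:
            if gene in edge.pair:
                seen_gene = True
                if edge.sig_class == "strong":
                    count += 1
    if not seen_gene:
        warnings.warn(f"gene {gene!r} absent from every setting", stacklevel=2)
    return count


def occurrence_table(
    networks: Mapping[str, Iterable[CorrelationEdge]]
) -> pd.Series:
    """Strong-edge occurrence count per gene, sorted descending.

    Each strong edge contributes one occurrence to both of its endpoints, so
    the column sum equals twice the total strong-edge count.
    """
    counts: dict[str, int] = {}
    for edges in networks.values():
        for edge in edges:
            if edge.sig_class != "strong":
                continue
            for g in edge.pair:
                counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


@dataclass
class HubComparison:
    """Strong partners of a hub gene in control vs exposed networks."""

    hub: str
    partners_control: set[str]
    partners_exposed: set[str]

    @property
    def common(self) -> set[str]:
        return self.partners_control & self.partners_exposed

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.partners_control), len(self.partners_exposed), len(self.common))


def _strong_partners(
    edges: Iterable[CorrelationEdge], hub: str, restrict_to: set[str] | None
) -> tuple[set[str], bool]:
    partners: set[str] = set()
    present = False
    for edge in edges:
        if hub not in edge.pair:
            continue
        present = True
        if edge.sig_class != "strong":
            continue
        other = edge.gene_b if edge.gene_a == hub else edge.gene_a
        if restrict_to is None or other in restrict_to:
            partners.add(other)
    return partners, present


def hub_partner_comparison(
    network_control: Iterable[CorrelationEdge],
    network_exposed: Iterable[CorrelationEdge],
    hub: str,
    restrict_to: Iterable[str] | None = None,
) -> HubComparison:
    """Compare the strong partner sets of ``hub`` between two conditions.

    ``restrict_to`` optionally limits partners to one geneset category (e.g.
    the nuclear receptors, to ask how many receptors track the hub in
    controls vs exposed samples and how many are common to both).
    """
    restrict = set(restrict_to) if restrict_to is not None else None
    ctrl, present_c = _strong_partners(network_control, hub, restrict)
    expd, present_e = _strong_partners(network_exposed, hub, restrict)
    if not present_c:
        warnings.warn(f"hub {hub!r} absent from the control network", stacklevel=2)
    if not present_e:
        warnings.warn(f"hub {hub!r} absent from the exposed network", stacklevel=2)
    return HubComparison(hub=hub, partners_control=ctrl, partners_exposed=expd)


def conservation_to_frame(result: ConservationResult) -> pd.DataFrame:
    """Conservation report as the standard output table."""
    rows = [
        [r.gene_pair[0], r.gene_pair[1], r.sign, r.n_settings,
         ";".join(r.settings_observed), r.sign_consistent]
        for r in list(result.conserved) + list(result.sign_discordant)
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "sign", "n_settings", "settings", "sign_consistent"],
    )
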