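"""Synthetic log2 expression data with planted structure and ground truth.

The generator emulates RMA-normalized log2 intensity matrices at small
microarray sample sizes (4-12 samples per condition): planted correlated
gene modules, control/exposed conditions, subgroup (generation / cell-pool)
structure and planted fold changes, with full ground truth for every
downstream analysis stage.

Correlation modules use a latent-factor construction: module m has one
standard-normal factor f_m per sample and every member gene g loads on it
with loading lambda_g, giving

    x_gs = mu_g + beta_g * exposed_s + gamma_{g, subgroup(s)}
           + lambda_g * f_{m(g), s} + eps_gs,      eps ~ N(0, sigma^2)

so the within-module population correlation is
rho = lambda^2 / (lambda^2 + sigma^2) (sign = product of loading signs) and
positive-definiteness holds gene-by-gene by construction. Exposure-dependent
rewiring swaps in a different module membership for exposed samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "GroundTruth",
    "RecoveryReport",
    "generate",
    "ground_truth_edges",
    "recovery_report",
    "scenario",
    "SCENARIOS",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One planted correlation module.

    genes
        Member gene names; disjoint from other modules of the same condition.
    rho
        Target absolute within-module correlation in (0, 1); the loading is
        derived as |lambda| = sigma * sqrt(rho / (1 - rho)).
    signs
        Optional +1/-1 loading sign per member (default all +1); a pair's
        expected correlation sign is the product of its member signs.
    """

    genes: tuple[str, ...]
    rho: float = 0.9
    signs: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a module needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene within a module")
        if not (0.0 < self.rho < 1.0):
            raise ValueError(f"rho must be in (0, 1), got {self.rho}")
        if self.signs is not None:
            if len(self.signs) != len(self.genes):
                raise ValueError("signs must match genes in length")
            if any(s not in (-1, 1) for s in self.signs):
                raise ValueError("signs must be +1 or -1")

    def sign_of(self, gene: str) -> int:
        if self.signs is None:
            return 1
        return self.signs[self.genes.index(gene)]


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic biological setting.

    n_control / n_exposed
        Samples per condition; ``n_exposed=0`` gives a normal-only setting.
    modules
        Planted modules active in control (and exposed, unless rewired).
    modules_exposed
        Optional replacement module list for exposed samples
        (exposure-dependent rewiring); ``None`` keeps ``modules``.
    subgroup_levels / subgroup_effect
        Categorical subgroup labels cycled over samples within each
        condition, and the log2-unit effect size; gene-specific offsets are
        drawn as gamma_{g,l} ~ N(0, subgroup_effect^2) (0 disables them).
    de_genes
        Planted log2 fold changes (exposed minus control) per gene.
    noise_sd
        Residual sigma in log2 units.
    baseline_range
        Uniform range of per-gene baseline means (RMA-scale log2 units).
    """

    n_genes: int
    n_control: int
    n_exposed: int = 0
    modules: tuple[ModuleSpec, ...] = ()
    modules_exposed: tuple[ModuleSpec, ...] | None = None
    subgroup_levels: tuple[str, ...] = ()
    subgroup_effect: float = 0.0
    de_genes: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    baseline_range: tuple[float, float] = (6.0, 12.0)
    setting_id: str = "synthetic"
    species: str = "rat"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.n_control < 0 or self.n_exposed < 0 or self.n_samples < 3:
            raise ValueError("need at least 3 samples in total")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (self.baseline_range[0] <= self.baseline_range[1]):
            raise ValueError("invalid baseline_range")
        names = set(self.gene_names)
        for mods in (self.modules, self.modules_exposed or ()):
            seen: set[str] = set()
            for mod in mods:
                unknown = set(mod.genes) - names
                if unknown:
                    raise ValueError(f"module gene(s) not in the matrix: {sorted(unknown)}")
                overlap = seen & set(mod.genes)
                if overlap:
                    raise ValueError(f"modules overlap on {sorted(overlap)}")
                seen |= set(mod.genes)
        unknown_de = set(self.de_genes) - names
        if unknown_de:
            raise ValueError(f"de gene(s) not in the matrix: {sorted(unknown_de)}")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_exposed

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated setting.

    true_edges
        Within-module pairs (canonically ordered) with expected correlation
        sign and magnitude, keyed by condition ("control"/"exposed").
    true_de
        Planted (gene, log2fc) effects.
    subgroups
        Subgroup label per sample id.
    """

    true_edges: dict[str, tuple[tuple[str, str, int, float], ...]]
    true_de: tuple[tuple[str, float], ...]
    subgroups: dict[str, str]

    def edge_pairs(self, condition: str = "control") -> set[tuple[str, str]]:
        return {(a, b) for a, b, _s, _r in self.true_edges[condition]}

    def edge_signs(self, condition: str = "control") -> dict[tuple[str, str], int]:
        return {(a, b): s for a, b, s, _r in self.true_edges[condition]}


def _module_edges(modules: Iterable[ModuleSpec]) -> tuple[tuple[str, str, int, float], ...]:
    out = []
    for mod in modules:
        for ga, gb in combinations(mod.genes, 2):
            a, b = sorted((ga, gb))
            out.append((a, b, mod.sign_of(ga) * mod.sign_of(gb), mod.rho))
    return tuple(sorted(out))


def ground_truth_edges(config: SimulationConfig) -> GroundTruth:
    """Ground truth implied by a config, without generating data."""
    control = _module_edges(config.modules)
    exposed = _module_edges(
        config.modules if config.modules_exposed is None else config.modules_exposed
    )
    sample_ids, conditions, subgroups = _sample_layout(config)
    return GroundTruth(
        true_edges={"control": control, "exposed": exposed},
        true_de=tuple(sorted(config.de_genes.items())),
        subgroups=dict(zip(sample_ids, subgroups)),
    )


def _sample_layout(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    sample_ids, conditions, subgroups = [], [], []
    levels = config.subgroup_levels or ("",)
    for cond, count in (("control", config.n_control), ("exposed", config.n_exposed)):
        for i in range(count):
            level = levels[i % len(levels)]
            tag = f"_{level}" if level else ""
            sample_ids.append(f"{config.setting_id}_{cond}{tag}_{i:02d}")
            conditions.append(cond)
            subgroups.append(level)
    return sample_ids, conditions, subgroups


def generate(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression matrix, sample metadata, ground truth).

    Deterministic given ``config.seed``. The matrix is genes x samples on
    the log2 scale; metadata follows the standard columns (sample_id,
    setting_id, condition, subgroup, species, compound).
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    gene_pos = {g: i for i, g in enumerate(genes)}
    sample_ids, conditions, subgroups = _sample_layout(config)
    n, m = config.n_genes, len(sample_ids)
    exposed_mask = np.asarray([c == "exposed" for c in conditions])

    lo, hi = config.baseline_range
    baseline = rng.uniform(lo, hi, size=n)
    values = np.tile(baseline[:, None], (1, m))

    # planted condition effects
    for gene, fc in config.de_genes.items():
        values[gene_pos[gene], exposed_mask] += fc

    # gene-specific subgroup offsets, shared across conditions
    if config.subgroup_levels and config.subgroup_effect > 0:
        offsets = rng.normal(
            0.0, config.subgroup_effect, size=(n, len(config.subgroup_levels))
        )
        level_idx = {lev: j for j, lev in enumerate(config.subgroup_levels)}
        for s, lev in enumerate(subgroups):
            values[:, s] += offsets[:, level_idx[lev]]

    # latent-factor modules per condition
    sigma = config.noise_sd
    module_sets = {
        "control": config.modules,
        "exposed": config.modules
        if config.modules_exposed is None
        else config.modules_exposed,
    }
    for cond, mods in module_sets.items():
        mask = exposed_mask if cond == "exposed" else ~exposed_mask
        if not mask.any():
            continue
        for mod in mods:
            lam = sigma * math.sqrt(mod.rho / (1.0 - mod.rho))
            factor = rng.standard_normal(int(mask.sum()))
            for g in mod.genes:
                values[gene_pos[g], mask] += mod.sign_of(g) * lam * factor

    values += rng.normal(0.0, sigma, size=(n, m))

    matrix = pd.DataFrame(values, index=genes, columns=sample_ids)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "setting_id": config.setting_id,
            "condition": conditions,
            "subgroup": subgroups,
            "species": config.species,
            "compound": "",
        }
    )
    return matrix, metadata, ground_truth_edges(config)


@dataclass(frozen=True)
class RecoveryReport:
    """Confusion counts of detected vs planted edges over unordered pairs."""

    tp: int
    fp: int
    tn: int
    fn: int
    sign_matches: int
    sign_checked: int

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def sign_accuracy(self) -> float:
        return self.sign_matches / self.sign_checked if self.sign_checked else float("nan")


def recovery_report(
    detected,
    truth: GroundTruth,
    genes: Sequence[str],
    condition: str = "control",
) -> RecoveryReport:
    """Score detected edges against the planted ground truth.

    ``detected`` is an iterable of :class:`~coexprofiler.coexpression.CorrelationEdge`
    or plain (gene_a, gene_b) pairs (optionally (gene_a, gene_b, sign));
    ``genes`` fixes the pair universe for the negative counts.
    """
    true_pairs = truth.edge_pairs(condition)
    true_signs = truth.edge_signs(condition)
    det_pairs: set[tuple[str, str]] = set()
    det_signs: dict[tuple[str, str], int] = {}
    for item in detected:
        if hasattr(item, "pair"):
            pair = item.pair
            sign = 1 if item.r >= 0 else -1
        else:
            a, b = item[0], item[1]
            pair = tuple(sorted((a, b)))
            sign = int(item[2]) if len(item) > 2 else None
        det_pairs.add(pair)
        if sign is not None:
            det_signs[pair] = sign
    universe = {tuple(sorted(p)) for p in combinations(genes, 2)}
    stray = det_pairs - universe
    if stray:
        raise ValueError(f"detected pair(s) outside the gene universe: {sorted(stray)[:3]}")
    tp_pairs = det_pairs & true_pairs
    fp = len(det_pairs - true_pairs)
    fn = len(true_pairs - det_pairs)
    tn = len(universe) - len(true_pairs) - fp
    sign_checked = sum(1 for p in tp_pairs if p in det_signs)
    sign_matches = sum(
        1 for p in tp_pairs if p in det_signs and det_signs[p] == true_signs[p]
    )
    return RecoveryReport(
        tp=len(tp_pairs), fp=fp, tn=tn, fn=fn,
        sign_matches=sign_matches, sign_checked=sign_checked,
    )


def _experiment1_like(seed: int) -> dict[str, SimulationConfig]:
    """Three normal-only species settings (8 + 12 + 12 samples), shared modules."""
    shared = (
        ModuleSpec(genes=("g00", "g01", "g02", "g03", "g04"), rho=0.9),
        ModuleSpec(genes=("g05", "g06", "g07", "g08"), rho=0.9, signs=(1, 1, -1, -1)),
    )
    base = dict(n_genes=30, n_exposed=0, modules=shared, noise_sd=0.5)
    return {
        "human_testis": SimulationConfig(
            n_control=8, setting_id="human_testis", species="human",
            seed=seed, **base,
        ),
        "mouse_testis": SimulationConfig(
            n_control=12, setting_id="mouse_testis", species="mouse",
            seed=seed + 1, **base,
        ),
        "rat_testis": SimulationConfig(
            n_control=12, setting_id="rat_testis", species="rat",
            seed=seed + 2, **base,
        ),
    }


def _experiment2_like(seed: int) -> dict[str, SimulationConfig]:
    """Vinclozolin-style multigeneration design: 3 generations x (2 + 2),
    exposure-dependent rewiring and planted down-regulation."""
    control_modules = (
        ModuleSpec(genes=("g00", "g01", "g02"), rho=0.9),
    )
    exposed_modules = (
        ModuleSpec(genes=("g00", "g03", "g04", "g05"), rho=0.9),
    )
    return {
        "vinclozolin_f1f3": SimulationConfig(
            n_genes=20, n_control=6, n_exposed=6,
            modules=control_modules, modules_exposed=exposed_modules,
            subgroup_levels=("F1", "F2", "F3"), subgroup_effect=1.0,
            de_genes={"g06": -1.0, "g07": -0.8},
            setting_id="vinclozolin_f1f3", species="rat", seed=seed,
        )
    }


def _experiment6_like(seed: int) -> dict[str, SimulationConfig]:
    """Triazole-style design: controls plus six exposure groups of 4."""
    gatekeeper_like = ModuleSpec(
        genes=("g00", "g01", "g02", "g03", "g04", "g05"), rho=0.9,
        signs=(1, 1, 1, -1, 1, 1),
    )
    out: dict[str, SimulationConfig] = {
        "triazole_control": SimulationConfig(
            n_genes=24, n_control=4, modules=(gatekeeper_like,),
            setting_id="triazole_control", species="rat", seed=seed,
        )
    }
    for i, group in enumerate(
        ("myclo_low", "myclo_high", "propi_low", "propi_high", "triad_low", "triad_high")
    ):
        # only the high-triadimefon-like group keeps the planted module
        modules = (gatekeeper_like,) if group == "triad_high" else ()
        out[f"triazole_{group}"] = SimulationConfig(
            n_genes=24, n_control=0, n_exposed=4, modules=modules,
            setting_id=f"triazole_{group}", species="rat", seed=seed + 10 + i,
        )
    return out


SCENARIOS = {
    "experiment1": _experiment1_like,
    "experiment2": _experiment2_like,
    "experiment6": _experiment6_like,
}


def scenario(name: str, seed: int = 0) -> dict[str, SimulationConfig]:
    """Named multi-setting scenarios mirroring the source study designs."""
    try:
        return SCENARIOS[name](seed)
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
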