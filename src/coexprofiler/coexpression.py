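"""Thresholded Pearson / partial correlation networks within a setting.

For every unordered gene pair the sample Pearson correlation r is computed
and tested with the t-transform t = r sqrt(df) / sqrt(1 - r^2). An edge is
classified ``strong`` when |r| >= 0.75 with p < 0.05 (strict), ``approaching``
when |r| >= 0.75 with 0.05 <= p < 0.10, and ``absent`` otherwise.

Settings whose samples are grouped (pooled cell types, generations, time
points) use partial correlation: group means are removed from both genes and
the residuals are correlated, paying k - 1 degrees of freedom for k group
levels, so df = n - 2 - (k - 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Thresholds",
    "CorrelationEdge",
    "UndefinedCorrelationError",
    "pearson_with_p",
    "partial_with_p",
    "classify_edge",
    "build_network",
    "correlation_matrix",
    "null_strong_probability",
    "edges_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Study significance thresholds for edge classification.

    r_min
        absolute correlation bound (default 0.75).
    alpha
        strict p-value bound for a strong edge (default 0.05).
    approach_max
        upper p bound of the "approaching significance" band (default 0.10).
    """

    r_min: float = 0.75
    alpha: float = 0.05
    approach_max: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 < self.r_min <= 1.0):
            raise ValueError(f"r_min must be in (0, 1], got {self.r_min}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (self.alpha <= self.approach_max <= 1.0):
            raise ValueError("approach_max must satisfy alpha <= approach_max <= 1")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class CorrelationEdge:
    """A classified coexpression edge for one unordered gene pair."""

    gene_a: str
    gene_b: str
    r: float
    p: float
    n: int
    k_groups: int = 0
    method: str = "pearson"
    setting_id: str = ""
    sig_class: str = "absent"

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def sign(self) -> str:
        return "+" if self.r >= 0 else "-"


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance in a vector or residual)."""


def _as_float_array(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _snap(r: float) -> float:
    """Collapse correlations within 1e-12 of +-1 to exactly +-1."""
    return math.copysign(1.0, r) if abs(r) >= 1.0 - 1e-12 else r


def _p_from_r(r: float | np.ndarray, df: int) -> float | np.ndarray:
    """Two-sided p from the t-transform of r on df degrees of freedom."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # |r| = 1 makes t infinite; the exact tail is 0
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p) if np.ndim(r) else (
        0.0 if np.isclose(abs(float(r)), 1.0) else float(p)
    )


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson correlation with a two-sided t-test p-value.

    Requires n >= 3 finite observations and nonzero variance in both
    vectors; |r| = 1 returns p = 0 exactly.
    """
    xa, ya = _as_float_array(x, "x"), _as_float_array(y, "y")
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    xc, yc = xa - xa.mean(), ya - ya.mean()
    sx, sy = np.sqrt(xc @ xc), np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance; correlation undefined")
    r = _snap(float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0)))
    return r, _p_from_r(r, n - 2), n


def _residualize(v: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """Subtract group means (equivalent to partialling out k-1 indicators)."""
    out = v.astype(float).copy()
    for g in range(k):
        mask = codes == g
        out[mask] -= out[mask].mean()
    return out


def partial_with_p(
    x: Sequence[float], y: Sequence[float], groups: Sequence
) -> tuple[float, float, int, int]:
    """Partial correlation controlling a categorical grouping.

    Group means are removed from both vectors and the residuals correlated;
    the t-test spends one degree of freedom per extra group level:
    df = n - 2 - (k - 1). With a single group level this reduces exactly to
    :func:`pearson_with_p`.
    """
    xa, ya = _as_float_array(x, "x"), _as_float_array(y, "y")
    codes, levels = pd.factorize(np.asarray(groups))
    if xa.shape != ya.shape or xa.size != codes.size:
        raise ValueError("x, y and groups must have equal length")
    n, k = xa.size, len(levels)
    df = n - 2 - (k - 1)
    if df <= 0:
        raise ValueError(f"not enough samples: n={n}, k_groups={k} leaves df={df}")
    xr = _residualize(xa, codes, k)
    yr = _residualize(ya, codes, k)
    sx, sy = np.sqrt(xr @ xr), np.sqrt(yr @ yr)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError(
            "no within-group variance; partial correlation undefined"
        )
    r = _snap(float(np.clip((xr @ yr) / (sx * sy), -1.0, 1.0)))
    return r, _p_from_r(r, df), n, k


def classify_edge(r: float, p: float, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Classify an (r, p) pair against the study thresholds.

    ``strong``: |r| >= r_min and p < alpha (strict inequality — a pair at
    exactly p = 0.05 is only approaching); ``approaching``: |r| >= r_min and
    alpha <= p < approach_max; ``absent`` otherwise.
    """
    if not (-1.0 <= r <= 1.0) or not (0.0 <= p <= 1.0):
        raise ValueError(f"invalid (r, p) = ({r}, {p})")
    if abs(r) >= thresholds.r_min:
        if p < thresholds.alpha:
            return "strong"
        if p < thresholds.approach_max:
            return "approaching"
    return "absent"


def correlation_matrix(
    values: np.ndarray, groups: Sequence | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """All-pairs (plain or partial) correlation for a genes x samples array.

    Returns ``(R, P, df)``; rows with zero (residual) variance get NaN in
    their R/P entries. Vectorized equivalent of the scalar functions.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2:
        raise ValueError("values must be 2-D (genes x samples)")
    n = v.shape[1]
    if groups is None:
        centered = v - v.mean(axis=1, keepdims=True)
        df = n - 2
    else:
        codes, levels = pd.factorize(np.asarray(groups))
        if codes.size != n:
            raise ValueError("groups length must equal the sample count")
        k = len(levels)
        df = n - 2 - (k - 1)
        if df <= 0:
            raise ValueError(f"not enough samples: n={n}, k_groups={k} leaves df={df}")
        centered = v.copy()
        for g in range(k):
            mask = codes == g
            centered[:, mask] -= centered[:, mask].mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    ok = norms > 0
    safe = np.where(ok, norms, 1.0)
    unit = centered / safe[:, None]
    R = np.clip(unit @ unit.T, -1.0, 1.0)
    R = np.where(np.abs(R) >= 1.0 - 1e-12, np.sign(R), R)
    R[~ok, :] = np.nan
    R[:, ~ok] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt(df) / np.sqrt(1.0 - R * R)
        P = 2.0 * stats.t.sf(np.abs(t), df)
    P = np.where(np.isclose(np.abs(R), 1.0), 0.0, P)
    P = np.where(np.isnan(R), np.nan, P)
    return R, P, df


def build_network(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    *,
    method: str = "pearson",
    groups: Sequence | None = None,
    gene_pairs: Iterable[tuple[str, str]] | None = None,
    setting_id: str = "",
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> list[CorrelationEdge]:
    """Build the classified edge list for one biological setting.

    Parameters
    ----------
    matrix
        Gene-level log2 matrix (rows = genes, columns = samples), already
        restricted to the analysis set.
    metadata
        Optional per-sample table; when given and ``method="partial"`` the
        ``subgroup`` column supplies the grouping (unless ``groups`` is
        passed explicitly).
    method
        ``"pearson"`` or ``"partial"``; partial requires a grouping.
    gene_pairs
        Optional restriction to specific unordered pairs.
    setting_id
        Label stamped on every edge.

    Pairs with undefined correlation (zero variance) are logged and omitted.
    """
    if method not in ("pearson", "partial"):
        raise ValueError(f"unknown method {method!r}")
    if matrix.shape[1] < 3:
        raise ValueError(
            f"setting {setting_id!r} has {matrix.shape[1]} samples; need >= 3"
        )
    if matrix.index.duplicated().any():
        raise ValueError("matrix has duplicated gene rows")
    if method == "partial" and groups is None:
        if metadata is None:
            raise ValueError("partial correlation requires groups or metadata")
        meta = metadata.set_index("sample_id")
        try:
            groups = [meta.at[s, "subgroup"] for s in matrix.columns]
        except KeyError as exc:
            raise ValueError(f"sample {exc} missing from metadata") from exc
    if method == "pearson":
        groups = None

    genes = list(matrix.index)
    R, P, df = correlation_matrix(matrix.values, groups)
    n = matrix.shape[1]
    k = 0 if groups is None else len(pd.unique(np.asarray(groups)))

    if gene_pairs is None:
        index_pairs = list(combinations(range(len(genes)), 2))
    else:
        pos = {g: i for i, g in enumerate(genes)}
        index_pairs = []
        for a, b in gene_pairs:
            if a in pos and b in pos and a != b:
                i, j = sorted((pos[a], pos[b]))
                index_pairs.append((i, j))

    edges: list[CorrelationEdge] = []
    dropped = 0
    for i, j in index_pairs:
        r, p = R[i, j], P[i, j]
        if np.isnan(r):
            dropped += 1
            continue
        edges.append(
            CorrelationEdge(
                gene_a=genes[i], gene_b=genes[j], r=float(r), p=float(p), n=n,
                k_groups=k, method=method, setting_id=setting_id,
                sig_class=classify_edge(float(r), float(p), thresholds),
            )
        )
    if dropped:
        logger.info(
            "setting %s: %d pair(s) with undefined correlation omitted",
            setting_id, dropped,
        )
    return edges


def null_strong_probability(n: int, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> float:
    """Analytic P(edge classified strong | true correlation 0, n samples).

    Under the null, t = r sqrt(n-2)/sqrt(1-r^2) is Student-t with n-2 df, so
    the strong call requires |r| above both r_min and the r at which the
    two-sided p equals alpha; the probability is the t tail beyond the larger
    of the two.
    """
    df = n - 2
    if df <= 0:
        raise ValueError("need n >= 3")
    t_alpha = stats.t.isf(thresholds.alpha / 2.0, df)
    r_alpha = t_alpha / np.sqrt(df + t_alpha**2)
    r_crit = max(thresholds.r_min, float(r_alpha))
    if r_crit >= 1.0:
        return 0.0
    t_crit = r_crit * np.sqrt(df) / np.sqrt(1.0 - r_crit**2)
    return float(2.0 * stats.t.sf(t_crit, df))


def edges_to_frame(edges: Iterable[CorrelationEdge]) -> pd.DataFrame:
    """Edge list as the standard output table."""
    cols = ["gene_a", "gene_b", "r", "p", "n", "k_groups", "method", "setting_id", "sig_class"]
    return pd.DataFrame(
        [[getattr(e, c) for c in cols] for e in edges], columns=cols
    )
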