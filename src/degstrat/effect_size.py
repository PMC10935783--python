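"""Cohen's d DEG selection for two-population comparisons.

Genes are called up- or downregulated by a pure effect-size cutoff: the
standardized mean difference

    d = (M_X − M_Y) / sqrt((n_X s_X² + n_Y s_Y²) / (n_X + n_Y))

where M, s, n are the mean, sample standard deviation and size of each
population, with |d| > 0.8 ("large" effect) as the default threshold.  The
denominator pools the (n−1)-denominator sample variances with n weights —
this exact form, not the textbook (n−1)-weighted pooled SD.  No p-values and
no multiplicity correction are involved: selection is effect size only,
chosen over fold change because it balances means against the per-condition
spread when homoscedasticity across design cells cannot be assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["cohens_d", "cohens_d_matrix", "select_degs", "DegResult"]


def cohens_d(x, y, ddof: int = 1) -> float:
    """Cohen's d between sample vectors x (population X) and y (population Y).

    ``ddof`` selects the denominator of the per-population SDs (1 = sample
    SD, the default convention; 0 = population SD).  Zero pooled variance is
    resolved by sign: ±inf if the means differ, 0.0 if they agree.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both populations need at least 2 observations")
    nx, ny = x.size, y.size
    num = x.mean() - y.mean()
    pooled = (nx * x.var(ddof=ddof) + ny * y.var(ddof=ddof)) / (nx + ny)
    if pooled == 0.0:
        if num == 0.0:
            return 0.0
        return float(np.inf) if num > 0 else float(-np.inf)
    return float(num / np.sqrt(pooled))


def cohens_d_matrix(X: np.ndarray, Y: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Row-wise Cohen's d for genes × samples arrays X and Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] < 2 or Y.shape[1] < 2:
        raise ValueError("both populations need at least 2 samples")
    nx, ny = X.shape[1], Y.shape[1]
    num = X.mean(axis=1) - Y.mean(axis=1)
    pooled = (nx * X.var(axis=1, ddof=ddof) + ny * Y.var(axis=1, ddof=ddof)) / (nx + ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num / np.sqrt(pooled)
    zero = pooled == 0.0
    if zero.any():
        d[zero & (num > 0)] = np.inf
        d[zero & (num < 0)] = -np.inf
        d[zero & (num == 0)] = 0.0
    return d


@dataclass
class DegResult:
    """Per-gene d values for one comparison and the derived up/down sets."""

    comparison_label: str
    d_values: pd.Series
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    @property
    def up_genes(self) -> frozenset[str]:
        return frozenset(self.d_values.index[self.d_values > self.threshold])

    @property
    def down_genes(self) -> frozenset[str]:
        return frozenset(self.d_values.index[self.d_values < -self.threshold])

    def call(self, gene: str) -> str:
        d = self.d_values[gene]
        if d > self.threshold:
            return "up"
        if d < -self.threshold:
            return "down"
        return "ns"

    def to_frame(self) -> pd.DataFrame:
        calls = np.where(
            self.d_values > self.threshold,
            "up",
            np.where(self.d_values < -self.threshold, "down", "ns"),
        )
        return pd.DataFrame(
            {"gene_id": self.d_values.index, "d": self.d_values.to_numpy(), "call": calls}
        )


def select_degs(
    em: ExpressionMatrix,
    pop_x: dict,
    pop_y: dict,
    threshold: float = 0.8,
    ddof: int = 1,
    label: str | None = None,
) -> DegResult:
    """Per-gene Cohen's d with X/Y given as (arm, day) sample filters.

    ``pop_x`` / ``pop_y`` are dicts with optional ``arm`` and ``day`` keys,
    e.g. ``{"arm": "treated", "day": 7}``.  Filters must be disjoint and each
    must match at least 2 samples.  Genes with d > threshold are upregulated
    (higher in X), d < −threshold downregulated.
    """
    cols_x = em.columns_for(pop_x.get("arm"), pop_x.get("day"))
    cols_y = em.columns_for(pop_y.get("arm"), pop_y.get("day"))
    if len(cols_x) < 2 or len(cols_y) < 2:
        raise ValueError(
            f"need >= 2 samples per population; got {len(cols_x)} for X={pop_x}, "
            f"{len(cols_y)} for Y={pop_y}"
        )
    overlap = set(cols_x) & set(cols_y)
    if overlap:
        raise ValueError(f"populations overlap on samples: {sorted(overlap)}")
    d = cohens_d_matrix(
        em.values[cols_x].to_numpy(), em.values[cols_y].to_numpy(), ddof=ddof
    )
    if label is None:
        label = f"X={pop_x} vs Y={pop_y}"
    return DegResult(label, pd.Series(d, index=em.values.index), threshold)
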