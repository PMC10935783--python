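"""Dataset overview (PCA) and the effect-vector collinearity framework.

Treating the per-gene log-expression profile as a vector space, four
displacement vectors summarize the 2×2 design (cell means, log2 units):

* ``t``  — control-arm time effect: mean(control, day 7) − mean(control, day 2)
* ``t*`` — treated-arm time effect: mean(treated, day 7) − mean(treated, day 2)
* ``h2`` — treatment effect at day 2: mean(treated, day 2) − mean(control, day 2)
* ``h7`` — treatment effect at day 7: mean(treated, day 7) − mean(control, day 7)

Writing the day-2 control cell as C, the day-7 treated cell is both
C + h2 + t* and C + t + h7, so h7 − h2 = t* − t holds exactly (pure algebra
on means) — a built-in consistency audit.  The collinearity hypotheses
(t ∝ t*; h7 = β·h2) are operationalized as cosine similarity, the
least-squares scalar, and a Jaccard overlap of thresholded up/down sets;
none is privileged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ExpressionMatrix

__all__ = [
    "EffectVectors",
    "compute_effect_vectors",
    "CollinearityReport",
    "collinearity",
    "PcaOverview",
    "pca_overview",
    "loading_extremes",
]


@dataclass
class EffectVectors:
    """The four per-gene effect vectors of a 2×2 design, on one gene index."""

    t: pd.Series
    t_star: pd.Series
    h2: pd.Series
    h7: pd.Series

    @property
    def h7_minus_h2(self) -> pd.Series:
        return self.h7 - self.h2

    @property
    def closure_residual(self) -> float:
        """max |(h7 − h2) − (t* − t)| over genes; ~0 up to rounding."""
        return float(((self.h7 - self.h2) - (self.t_star - self.t)).abs().max())

    def __getitem__(self, name: str) -> pd.Series:
        try:
            return {"t": self.t, "t_star": self.t_star, "h2": self.h2,
                    "h7": self.h7, "h7_minus_h2": self.h7_minus_h2}[name]
        except KeyError:
            raise KeyError(f"unknown effect vector: {name!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "t_star": self.t_star, "h2": self.h2, "h7": self.h7}
        ).rename_axis("gene_id")


def compute_effect_vectors(em: ExpressionMatrix) -> EffectVectors:
    """Cell-mean displacement vectors; all four design cells must exist."""
    days = em.days
    if len(days) != 2:
        raise ValueError(f"need exactly two days, got {days}")
    early, late = days
    means = {}
    for arm in ("treated", "control"):
        for day in days:
            cols = em.columns_for(arm, day)
            if not cols:
                raise ValueError(f"design cell (arm={arm}, day={day}) has no samples")
            means[(arm, day)] = em.values[cols].mean(axis=1)
    return EffectVectors(
        t=means[("control", late)] - means[("control", early)],
        t_star=means[("treated", late)] - means[("treated", early)],
        h2=means[("treated", early)] - means[("control", early)],
        h7=means[("treated", late)] - means[("control", late)],
    )


@dataclass
class CollinearityReport:
    """Similarity of two effect vectors over a gene mask."""

    cosine: float
    scalar: float          # least-squares b in v2 ≈ b·v1
    residual_fraction: float  # ||v2 − b·v1||² / ||v2||²
    jaccard_up: float
    jaccard_down: float
    n_genes: int


def collinearity(
    v1: pd.Series,
    v2: pd.Series,
    gene_mask=None,
    set_threshold: float = 1.0,
) -> CollinearityReport:
    """Cosine, least-squares scalar, residual, and up/down-set Jaccard.

    ``gene_mask`` restricts to a gene subset.  The Jaccard overlaps compare
    sets derived by thresholding each vector at ±``set_threshold`` (log2
    units) — a practical set-based proxy for directional agreement.
    Zero-norm vectors yield NaN similarity with a warning.
    """
    if not v1.index.equals(v2.index):
        raise ValueError("effect vectors must share one gene index")
    if gene_mask is not None:
        idx = v1.index.intersection(pd.Index(sorted(gene_mask)))
        v1, v2 = v1.loc[idx], v2.loc[idx]
    a, b = v1.to_numpy(float), v2.to_numpy(float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("zero-norm effect vector; similarity undefined")
        cos, scal, res = float("nan"), float("nan"), float("nan")
    else:
        cos = float(a @ b / (na * nb))
        scal = float(a @ b / (a @ a))
        res = float(np.sum((b - scal * a) ** 2) / (b @ b))

    def _jac(sa: set, sb: set) -> float:
        union = sa | sb
        return len(sa & sb) / len(union) if union else float("nan")

    up1, up2 = set(v1.index[a > set_threshold]), set(v2.index[b > set_threshold])
    dn1, dn2 = set(v1.index[a < -set_threshold]), set(v2.index[b < -set_threshold])
    return CollinearityReport(cos, scal, res, _jac(up1, up2), _jac(dn1, dn2), len(v1))


@dataclass
class PcaOverview:
    """Sample scores, gene loadings, and contribution rates of a PCA."""

    coordinates: pd.DataFrame    # samples × PCs
    loadings: pd.DataFrame       # genes × PCs
    variance_ratios: np.ndarray

    def __post_init__(self) -> None:
        vr = np.asarray(self.variance_ratios, float)
        if np.any(np.diff(vr) > 1e-12):
            raise ValueError("variance ratios must be non-increasing")


def pca_overview(em: ExpressionMatrix, n_components: int = 2, scale: bool = False) -> PcaOverview:
    """Centered PCA of samples in gene space (no variance scaling by default).

    Loadings follow a fixed sign convention — the gene with the largest
    absolute loading on each component is made positive — so extreme-gene
    lists are deterministic across platforms.
    """
    X = em.values.to_numpy(float).T  # samples × genes
    max_comp = min(X.shape)
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_  # n_components × genes
    # sign convention: largest-|loading| gene positive on each component
    for j in range(n_components):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] *= -1
            scores[:, j] *= -1
    pcs = [f"PC{j + 1}" for j in range(n_components)]
    return PcaOverview(
        coordinates=pd.DataFrame(scores, index=em.values.columns, columns=pcs),
        loadings=pd.DataFrame(comps.T, index=em.values.index, columns=pcs),
        variance_ratios=pca.explained_variance_ratio_,
    )


def loading_extremes(pc: PcaOverview, component: int = 1, n: int = 15) -> tuple[list[str], list[str]]:
    """Top-n and bottom-n genes by loading on one (1-based) component.

    Ties break lexicographically by gene id; n beyond the gene count is
    truncated with a warning.
    """
    col = f"PC{component}"
    if col not in pc.loadings.columns:
        raise ValueError(f"component {component} not available")
    load = pc.loadings[col]
    if n > len(load):
        warnings.warn(f"n={n} exceeds gene count {len(load)}; truncating")
        n = len(load)
    order = load.to_frame("w").reset_index(names="gene_id")
    desc = order.sort_values(["w", "gene_id"], ascending=[False, True], kind="mergesort")
    asc = order.sort_values(["w", "gene_id"], ascending=[True, True], kind="mergesort")
    return list(desc["gene_id"].head(n)), list(asc["gene_id"].head(n))
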