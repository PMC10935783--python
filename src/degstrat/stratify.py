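"""Two-axis Venn stratification of up/down gene sets.

The comparison scheme selects genes with respect to one design factor (X)
and partitions them across the other factor (Y):

* **time axis** — day-7 vs day-2 DEGs within each arm, partitioned across
  arms into treated-exclusive / common / control-exclusive sets.  A large
  common cell means both arms follow a shared temporal trajectory.
* **treatment axis** — treated vs control DEGs at each day, partitioned
  across days.  The day-2-exclusive cell holds *early* treatment effects,
  the common cell *constant* (continuous) effects, and the day-7-exclusive
  cell *delayed* effects.

"Common" always requires same-direction regulation: the up and down
partitions are built separately, so a gene up in one comparison and down in
the other lands in the respective exclusive cells, never in common.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effect_size import select_degs
from .io import ExpressionMatrix
from .simulate import GENE_CLASSES, GroundTruth

__all__ = [
    "VennPartition",
    "venn_partition",
    "stratify_time_axis",
    "stratify_treatment_axis",
    "recovery_report",
    "TIME_AXIS_CELLS",
    "TREATMENT_AXIS_CELLS",
]


@dataclass
class VennPartition:
    """Three-way partition of two gene (or term) sets A and B."""

    label_a: str
    label_b: str
    only_a: frozenset
    common: frozenset
    only_b: frozenset
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.only_a & self.common or self.only_b & self.common or self.only_a & self.only_b:
            raise ValueError("Venn cells must be disjoint")

    @property
    def counts(self) -> dict[str, int]:
        return {
            self.label_a: len(self.only_a),
            "common": len(self.common),
            self.label_b: len(self.only_b),
        }

    @property
    def cells(self) -> dict[str, frozenset]:
        return {self.label_a: self.only_a, "common": self.common, self.label_b: self.only_b}

    @property
    def union(self) -> frozenset:
        return self.only_a | self.common | self.only_b

    def evenness(self) -> float:
        """Normalized Shannon entropy of the three cell sizes (0..1).

        An extension beyond the core scheme: 1.0 means perfectly even cells,
        0.0 means everything in one cell.  NaN for an empty partition.
        """
        sizes = np.array([len(self.only_a), len(self.common), len(self.only_b)], float)
        total = sizes.sum()
        if total == 0:
            return float("nan")
        p = sizes[sizes > 0] / total
        return float(-(p * np.log(p)).sum() / np.log(3))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": [self.label_a, "common", self.label_b],
                "direction": self.direction,
                "n": [len(self.only_a), len(self.common), len(self.only_b)],
            }
        )


def venn_partition(set_a, set_b, label_a: str = "A", label_b: str = "B", direction: str = "up") -> VennPartition:
    """Exact three-way set-algebra partition of two sets."""
    a, b = frozenset(set_a), frozenset(set_b)
    return VennPartition(label_a, label_b, a - b, a & b, b - a, direction)


def stratify_time_axis(
    em: ExpressionMatrix, threshold: float = 0.8, ddof: int = 1
) -> tuple[VennPartition, VennPartition]:
    """Day-7 vs day-2 DEGs within each arm, partitioned across arms.

    X = the later day, so "up" means higher expression at day 7.  Returns the
    (up, down) partitions with treated as side A and control as side B.
    """
    days = em.days
    if len(days) != 2:
        raise ValueError(f"time axis needs exactly two days, got {days}")
    early, late = days
    degs = {}
    for arm in ("treated", "control"):
        degs[arm] = select_degs(
            em,
            {"arm": arm, "day": late},
            {"arm": arm, "day": early},
            threshold=threshold,
            ddof=ddof,
            label=f"{arm}: day {late} vs day {early}",
        )
    up = venn_partition(
        degs["treated"].up_genes, degs["control"].up_genes, "treated", "control", "up"
    )
    down = venn_partition(
        degs["treated"].down_genes, degs["control"].down_genes, "treated", "control", "down"
    )
    return up, down


def stratify_treatment_axis(
    em: ExpressionMatrix, threshold: float = 0.8, ddof: int = 1
) -> tuple[VennPartition, VennPartition]:
    """Treated vs control DEGs at each day, partitioned across days.

    X = treated, so "up" means higher in treated samples.  Side A is the
    early day (early effects), common is constant, side B the late day
    (delayed effects).
    """
    days = em.days
    if len(days) != 2:
        raise ValueError(f"treatment axis needs exactly two days, got {days}")
    early, late = days
    degs = {}
    for day in days:
        degs[day] = select_degs(
            em,
            {"arm": "treated", "day": day},
            {"arm": "control", "day": day},
            threshold=threshold,
            ddof=ddof,
            label=f"day {day}: treated vs control",
        )
    la, lb = f"day{early}", f"day{late}"
    up = venn_partition(degs[early].up_genes, degs[late].up_genes, la, lb, "up")
    down = venn_partition(degs[early].down_genes, degs[late].down_genes, la, lb, "down")
    return up, down


def _cell(part: VennPartition, which: str) -> frozenset:
    return {"a": part.only_a, "common": part.common, "b": part.only_b}[which]


# planted class -> (direction, cell) mapping for each stratification axis
TREATMENT_AXIS_CELLS = {
    "early_up": ("up", "a"),
    "constant_up": ("up", "common"),
    "delayed_up": ("up", "b"),
    "early_down": ("down", "a"),
    "constant_down": ("down", "common"),
    "delayed_down": ("down", "b"),
}

TIME_AXIS_CELLS = {
    "common_time_up": ("up", "common"),
    "common_time_down": ("down", "common"),
    "treated_only_time": ("up", "a"),
    "control_only_time": ("up", "b"),
}


def recovery_report(
    up: VennPartition,
    down: VennPartition,
    truth: GroundTruth,
    axis: str = "treatment",
) -> pd.DataFrame:
    """Per-class precision/recall/F1 of planted classes against Venn cells.

    For each planted class the corresponding cell (per axis) is compared to
    the class's gene set: TP = planted genes in the cell, FP = any other
    genes in the cell (including nulls), FN = planted genes elsewhere.
    Classes with zero planted genes get NaN recall.
    """
    if axis == "treatment":
        mapping = TREATMENT_AXIS_CELLS
    elif axis == "time":
        mapping = TIME_AXIS_CELLS
    else:
        raise ValueError(f"unknown axis: {axis!r}")
    unknown = set(truth.class_of.values()) - set(GENE_CLASSES)
    if unknown:
        raise ValueError(f"unknown class labels in truth: {sorted(unknown)}")

    rows = []
    for cls, (direction, which) in mapping.items():
        cell = _cell(up if direction == "up" else down, which)
        planted = truth.genes_of(cls)
        tp = len(cell & planted)
        fp = len(cell - planted)
        fn = len(planted - cell)
        precision = tp / (tp + fp) if (tp + fp) else float("nan")
        recall = tp / (tp + fn) if planted else float("nan")
        f1 = (
            2 * precision * recall / (precision + recall)
            if (tp + fp) and planted and (precision + recall) > 0
            else float("nan")
        )
        rows.append(
            {
                "gene_class": cls,
                "cell": f"{direction}/{which}",
                "n_planted": len(planted),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows)
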