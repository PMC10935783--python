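"""Synthetic 2×2 (treatment × time) expression matrices with planted structure.

The generator emulates, in log2(TPM+1) space, the conceptual decomposition the
pipeline is built to recover: a shared temporal program present in both arms,
arm-exclusive temporal genes, and treatment-effect genes partitioned into
early-only, constant, and delayed-only classes.  Simulating directly in log
space (rather than through a count model) matches the space every downstream
statistic is computed in.

Gene classes
------------
``common_time_up/down``      ± shift at day 7 in both arms
``treated_only_time``        + shift at day 7, treated arm only
``control_only_time``        + shift at day 7, control arm only
``early_up/down``            ± treated-vs-control shift at day 2 only
``constant_up/down``         ± shift at both days
``delayed_up/down``          ± shift at day 7 only
``null``                     baseline + noise only
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnnotationMap, ExpressionMatrix

GENE_CLASSES = (
    "common_time_up",
    "common_time_down",
    "treated_only_time",
    "control_only_time",
    "early_up",
    "early_down",
    "constant_up",
    "constant_down",
    "delayed_up",
    "delayed_down",
    "null",
)

TREATMENT_CLASSES = (
    "early_up",
    "early_down",
    "constant_up",
    "constant_down",
    "delayed_up",
    "delayed_down",
)

TEMPORAL_CLASSES = (
    "common_time_up",
    "common_time_down",
    "treated_only_time",
    "control_only_time",
)

#: Shared temporal program classes — the planted ``t ∝ t*`` structure.
SHARED_PROGRAM_CLASSES = ("common_time_up", "common_time_down")


def _default_counts() -> dict[str, int]:
    return {
        "common_time_up": 150,
        "common_time_down": 150,
        "treated_only_time": 50,
        "control_only_time": 50,
        "early_up": 200,
        "early_down": 200,
        "constant_up": 200,
        "constant_down": 200,
        "delayed_up": 200,
        "delayed_down": 200,
    }


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic 2×2 design.

    Defaults: 5000 genes, 4 replicates per cell, ±2.0 log2-unit planted
    shifts, within-condition noise SD 0.5 log2 units, a 300-gene shared
    temporal program, 50 arm-exclusive temporal genes per arm, and 200 genes
    per treatment-effect class; baselines ~ Normal(5, 2) truncated at 0.
    """

    n_genes: int = 5000
    n_replicates: int = 4
    planted_counts: dict[str, int] = field(default_factory=_default_counts)
    effect_size_logfc: float = 2.0
    noise_sd: float = 0.5
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 2.0
    days: tuple[int, int] = (2, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.planted_counts) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if any(v < 0 for v in self.planted_counts.values()):
            raise ValueError("planted counts must be nonnegative")
        planted = sum(v for k, v in self.planted_counts.items() if k != "null")
        if planted > self.n_genes:
            raise ValueError(
                f"planted counts ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.noise_sd <= 0 or self.baseline_log_sd <= 0:
            raise ValueError("all SDs must be > 0")
        if self.effect_size_logfc <= 0:
            raise ValueError("effect_size_logfc must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per cell")
        if len(self.days) != 2 or self.days[0] >= self.days[1]:
            raise ValueError("days must be two increasing integers")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Planted class label per simulated gene."""

    class_of: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.class_of.values()) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")

    def genes_of(self, label: str) -> frozenset[str]:
        if label not in GENE_CLASSES:
            raise ValueError(f"unknown class label: {label!r}")
        return frozenset(g for g, c in self.class_of.items() if c == label)

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in GENE_CLASSES}
        for c in self.class_of.values():
            out[c] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.class_of), "gene_class": list(self.class_of.values())}
        )


def _shift(gene_class: str, arm: str, is_late_day: bool, effect: float) -> float:
    """Planted mean shift for one gene class in one design cell.

    The temporal program shifts day-7 cells; treatment effects shift treated
    cells at the days their class covers, signed by the class suffix.
    """
    s = 0.0
    # temporal component
    if is_late_day:
        if gene_class == "common_time_up":
            s += effect
        elif gene_class == "common_time_down":
            s -= effect
        elif gene_class == "treated_only_time" and arm == "treated":
            s += effect
        elif gene_class == "control_only_time" and arm == "control":
            s += effect
    # treatment component
    if arm == "treated" and gene_class in TREATMENT_CLASSES:
        phase, direction = gene_class.rsplit("_", 1)
        active = (
            (phase == "early" and not is_late_day)
            or (phase == "constant")
            or (phase == "delayed" and is_late_day)
        )
        if active:
            s += effect if direction == "up" else -effect
    return s


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one synthetic log2(TPM+1) matrix for the 2×2 design.

    Expression of gene g in sample (arm, day, rep) is
    ``baseline_g + shift(class_g, arm, day) + Normal(0, noise_sd)``, floored
    at 0.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes - 1)))
    genes = [f"g{i:0{width}d}" for i in range(cfg.n_genes)]

    labels: list[str] = []
    for cls in GENE_CLASSES:
        if cls == "null":
            continue
        labels.extend([cls] * cfg.planted_counts.get(cls, 0))
    labels.extend(["null"] * (cfg.n_genes - len(labels)))
    truth = GroundTruth(dict(zip(genes, labels)))

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    baseline = np.maximum(baseline, 0.0)

    cells = [
        (arm, day)
        for arm in ("treated", "control")
        for day in cfg.days
    ]
    columns, meta_rows = [], []
    blocks = []
    for arm, day in cells:
        is_late = day == cfg.days[1]
        shifts = np.array([_shift(c, arm, is_late, cfg.effect_size_logfc) for c in labels])
        mean = baseline + shifts
        noise = rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, cfg.n_replicates))
        blocks.append(np.maximum(mean[:, None] + noise, 0.0))
        for rep in range(1, cfg.n_replicates + 1):
            sid = f"{arm}_d{day}_r{rep}"
            columns.append(sid)
            meta_rows.append({"sample_id": sid, "arm": arm, "day": day, "replicate": rep})

    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    em = ExpressionMatrix(values, pd.DataFrame(meta_rows))
    return em, truth


def simulate_annotation(
    truth: GroundTruth,
    terms_per_class: int = 8,
    term_purity: float = 1.0,
    background_terms: int = 40,
    seed: int = 0,
    genes_per_term: int = 30,
) -> AnnotationMap:
    """Synthesize a term→gene map whose terms preferentially tag planted classes.

    For each non-null class, ``terms_per_class`` terms draw a fraction
    ``term_purity`` of their members from that class and the rest uniformly
    from other genes; ``background_terms`` terms draw uniformly from all
    genes.  Classes with no genes are skipped with a warning.
    """
    if not truth.class_of:
        raise ValueError("ground truth is empty")
    if not (0 < term_purity <= 1):
        raise ValueError("term_purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    all_genes = np.array(sorted(truth.class_of))
    membership: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}

    for cls in GENE_CLASSES:
        if cls == "null" or terms_per_class == 0:
            continue
        pool = np.array(sorted(truth.genes_of(cls)))
        if pool.size == 0:
            warnings.warn(f"class {cls!r} has no genes; skipping its terms")
            continue
        others = np.array(sorted(set(all_genes) - set(pool)))
        for i in range(terms_per_class):
            n_in_target = int(round(term_purity * genes_per_term))
            n_in = min(n_in_target, pool.size)
            # a short class shrinks the term rather than diluting its purity
            n_out = min(genes_per_term - n_in_target, others.size)
            members = set(rng.choice(pool, n_in, replace=False))
            if n_out > 0:
                members |= set(rng.choice(others, n_out, replace=False))
            tid = f"T:{cls}:{i:02d}"
            membership[tid] = frozenset(members)
            names[tid] = f"synthetic term {i} for class {cls}"

    for i in range(background_terms):
        size = min(genes_per_term, all_genes.size)
        tid = f"T:background:{i:02d}"
        membership[tid] = frozenset(rng.choice(all_genes, size, replace=False))
        names[tid] = f"synthetic background term {i}"

    return AnnotationMap(membership, names)
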