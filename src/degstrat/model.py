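"""Model/Results facade and the end-to-end pipeline.

`TwoAxisDecomposition` bundles the full analysis of a 2×2 treatment × time
expression design: DEG selection by Cohen's d, Venn stratification along
both axes, per-cell over-representation analysis, term-set Venns, term-
related-gene counts, and the effect-vector framework.  `fit()` returns a
`TwoAxisResults` carrying every table plus `summary()`.  `run_pipeline`
drives the same computation from a single config (real files or a
simulation) and writes all artifacts under an output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .enrichment import EnrichmentTable, TripleVenn, enrich_subset, term_venn
from .gotrg import GotrgCountTable, count_gotrgs, dominance_check
from .io import (
    AnnotationMap,
    ExpressionMatrix,
    load_annotation,
    load_expression,
    read_processed,
    write_expression,
    write_gmt,
)
from .simulate import (
    SHARED_PROGRAM_CLASSES,
    GroundTruth,
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
)
from .stratify import VennPartition, recovery_report, stratify_time_axis, stratify_treatment_axis
from .trajectory import collinearity, compute_effect_vectors

__all__ = ["TwoAxisDecomposition", "TwoAxisResults", "PipelineConfig", "run_pipeline"]


class TwoAxisDecomposition:
    """Two-axis decomposition model for a 2×2 expression design.

    Parameters
    ----------
    em
        Preprocessed expression matrix (log2(TPM+1)) with both arms at both
        days.
    annotation
        Optional gene→term map; enables enrichment/term-Venn/GOTRG stages.
    truth
        Optional planted ground truth (synthetic runs); enables the
        recovery report.
    """

    def __init__(
        self,
        em: ExpressionMatrix,
        annotation: AnnotationMap | None = None,
        truth: GroundTruth | None = None,
    ):
        if len(em.days) != 2 or len(em.arms) != 2:
            raise ValueError("model requires exactly two arms and two days")
        self.em = em
        self.annotation = annotation
        self.truth = truth

    @classmethod
    def from_files(
        cls,
        matrix_path,
        metadata_path,
        annotation_path=None,
        annotation_format: str = "auto",
    ) -> "TwoAxisDecomposition":
        em = load_expression(matrix_path, metadata_path)
        ann = load_annotation(annotation_path, annotation_format) if annotation_path else None
        return cls(em, ann)

    def fit(
        self,
        threshold: float = 0.8,
        alpha: float = 0.05,
        top_n: int = 30,
        correction: str = "bh",
        universe_policy: str = "measured",
        ddof: int = 1,
    ) -> "TwoAxisResults":
        em = self.em
        time_up, time_down = stratify_time_axis(em, threshold, ddof)
        treat_up, treat_down = stratify_treatment_axis(em, threshold, ddof)
        partitions = {
            ("time", "up"): time_up,
            ("time", "down"): time_down,
            ("treatment", "up"): treat_up,
            ("treatment", "down"): treat_down,
        }

        enrichments: dict[tuple[str, str, str], EnrichmentTable] = {}
        venns: dict[tuple[str, str], TripleVenn] = {}
        gotrgs: dict[tuple[str, str], GotrgCountTable] = {}
        if self.annotation is not None:
            if universe_policy == "measured":
                measured = frozenset(em.gene_ids)
            elif universe_policy == "annotation":
                measured = None
            else:
                raise ValueError(f"unknown universe policy: {universe_policy!r}")
            for (axis, direction), part in partitions.items():
                tabs = []
                for cell_label, genes in part.cells.items():
                    tab = enrich_subset(
                        genes,
                        self.annotation,
                        measured_genes=measured,
                        alpha=alpha,
                        correction=correction,
                        label=cell_label,
                    )
                    enrichments[(axis, direction, cell_label)] = tab
                    tabs.append(tab)
                venns[(axis, direction)] = term_venn(tabs, top_n=top_n)

            # term-related-gene counts: common-unique terms on the time axis
            # (which subset carries the shared trajectory), innermost terms on
            # the treatment axis (how the strongest effects build over time)
            for direction in ("up", "down"):
                tv = venns[("time", direction)]
                terms = sorted(tv.only("common"))
                if terms:
                    gotrgs[("time", direction)] = count_gotrgs(
                        terms,
                        partitions[("time", direction)].cells,
                        self.annotation,
                        within=frozenset(em.gene_ids),
                    )
                tv = venns[("treatment", direction)]
                terms = sorted(tv.innermost)
                if terms:
                    gotrgs[("treatment", direction)] = count_gotrgs(
                        terms,
                        partitions[("treatment", direction)].cells,
                        self.annotation,
                        within=frozenset(em.gene_ids),
                    )

        vectors = compute_effect_vectors(em)
        shared_mask = None
        if self.truth is not None:
            shared: set[str] = set()
            for cls in SHARED_PROGRAM_CLASSES:
                shared |= self.truth.genes_of(cls)
            shared_mask = frozenset(shared) or None
        similarity = {
            "t_vs_t_star": collinearity(vectors.t, vectors.t_star),
            "h2_vs_h7": collinearity(vectors.h2, vectors.h7),
        }
        if shared_mask is not None:
            similarity["t_vs_t_star_shared_program"] = collinearity(
                vectors.t, vectors.t_star, gene_mask=shared_mask
            )

        recovery = {}
        if self.truth is not None:
            recovery["time"] = recovery_report(time_up, time_down, self.truth, axis="time")
            recovery["treatment"] = recovery_report(
                treat_up, treat_down, self.truth, axis="treatment"
            )

        return TwoAxisResults(
            model=self,
            threshold=threshold,
            alpha=alpha,
            top_n=top_n,
            partitions=partitions,
            enrichments=enrichments,
            term_venns=venns,
            gotrg_tables=gotrgs,
            effect_vectors=vectors,
            similarity=similarity,
            recovery=recovery,
        )


@dataclass
class TwoAxisResults:
    """Fitted tables of a two-axis decomposition; see :meth:`summary`."""

    model: TwoAxisDecomposition
    threshold: float
    alpha: float
    top_n: int
    partitions: dict[tuple[str, str], VennPartition]
    enrichments: dict[tuple[str, str, str], EnrichmentTable]
    term_venns: dict[tuple[str, str], TripleVenn]
    gotrg_tables: dict[tuple[str, str], GotrgCountTable]
    effect_vectors: object
    similarity: dict
    recovery: dict = field(default_factory=dict)

    def venn_counts(self) -> pd.DataFrame:
        rows = []
        for (axis, direction), part in self.partitions.items():
            df = part.to_frame()
            df.insert(0, "axis", axis)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def similarity_frame(self) -> pd.DataFrame:
        rows = []
        for name, rep in self.similarity.items():
            rows.append(
                {
                    "pair": name,
                    "cosine": rep.cosine,
                    "scalar": rep.scalar,
                    "residual_fraction": rep.residual_fraction,
                    "jaccard_up": rep.jaccard_up,
                    "jaccard_down": rep.jaccard_down,
                    "n_genes": rep.n_genes,
                }
            )
        return pd.DataFrame(rows)

    def gotrg_dominance(self, axis: str = "time", direction: str = "up") -> tuple[pd.Series, float]:
        tab = self.gotrg_tables[(axis, direction)]
        return dominance_check(tab, "common")

    def summary(self) -> str:
        em = self.model.em
        lines = [
            "Two-axis decomposition results",
            "==============================",
            f"genes: {em.n_genes}   samples: {em.n_samples}   "
            f"days: {em.days}   threshold: ±{self.threshold} (Cohen's d)",
            "",
            "Venn cell counts (genes)",
        ]
        for (axis, direction), part in self.partitions.items():
            c = part.counts
            cells = "   ".join(f"{k}={v}" for k, v in c.items())
            lines.append(f"  {axis:<9} {direction:<4} {cells}   evenness={part.evenness():.3f}")
        if self.term_venns:
            lines.append("")
            lines.append(f"Term Venn (top {self.top_n} terms per cell, alpha={self.alpha})")
            for (axis, direction), tv in self.term_venns.items():
                inner = len(tv.innermost)
                commons = len(tv.only("common"))
                lines.append(
                    f"  {axis:<9} {direction:<4} common-only terms={commons}   innermost={inner}"
                )
        lines.append("")
        lines.append("Effect-vector similarity")
        for _, row in self.similarity_frame().iterrows():
            lines.append(
                f"  {row['pair']:<28} cosine={row['cosine']:+.3f}   "
                f"scalar={row['scalar']:+.3f}   residual={row['residual_fraction']:.3f}"
            )
        closure = self.effect_vectors.closure_residual
        lines.append(f"  closure residual max|h7-h2-(t*-t)| = {closure:.2e}")
        if self.recovery:
            lines.append("")
            lines.append("Planted-class recovery (treatment axis)")
            for _, r in self.recovery["treatment"].iterrows():
                lines.append(
                    f"  {r['gene_class']:<14} precision={r['precision']:.3f} "
                    f"recall={r['recall']:.3f} f1={r['f1']:.3f}"
                )
        return "\n".join(lines)


@dataclass
class PipelineConfig:
    """One-file configuration of a full run: real files XOR a simulation."""

    matrix_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    simulation: dict | None = None
    processed: bool = False  # matrix_path already log2(TPM+1)
    threshold: float = 0.8
    alpha: float = 0.05
    top_n: int = 30
    correction: str = "bh"
    universe_policy: str = "measured"
    seed: int = 0
    output_dir: str = "degstrat_out"

    def __post_init__(self) -> None:
        real = self.matrix_path is not None or self.metadata_path is not None
        if real and self.simulation is not None:
            raise ValueError("config must give real-data paths OR a simulation, not both")
        if not real and self.simulation is None:
            raise ValueError("config must give real-data paths or a simulation block")
        if real and (self.matrix_path is None or self.metadata_path is None):
            raise ValueError("real-data runs need both matrix_path and metadata_path")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _write_gene_lists(part: VennPartition, out: Path, stem: str) -> dict[str, str]:
    files = {}
    for cell_label, genes in part.cells.items():
        p = out / f"{stem}_{cell_label}.txt"
        p.write_text("".join(f"{g}\n" for g in sorted(genes)))
        files[cell_label] = p.name
    return files


def run_pipeline(cfg: PipelineConfig) -> TwoAxisResults:
    """Execute the full decomposition from one config and write all artifacts.

    Deterministic given the config (simulation runs derive every random
    stream from ``cfg.seed``).  After writing, gene-list files are recounted
    against the Venn tables as an internal consistency audit.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    annotation = None
    if cfg.simulation is not None:
        sim_kw = dict(cfg.simulation)
        ann_kw = {
            k: sim_kw.pop(k)
            for k in ("terms_per_class", "term_purity", "background_terms", "genes_per_term")
            if k in sim_kw
        }
        sim_cfg = SimulationConfig(**{**sim_kw, "seed": sim_kw.get("seed", cfg.seed)})
        em, truth = simulate_expression(sim_cfg)
        annotation = simulate_annotation(truth, seed=sim_cfg.seed + 1, **ann_kw)
        write_expression(em, out / "matrix.tsv", out / "metadata.tsv")
        write_gmt(annotation, out / "annotation.gmt")
        truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        if cfg.processed:
            em = read_processed(cfg.matrix_path, cfg.metadata_path)
        else:
            em = load_expression(cfg.matrix_path, cfg.metadata_path)
        if cfg.annotation_path:
            annotation = load_annotation(cfg.annotation_path)

    model = TwoAxisDecomposition(em, annotation, truth)
    res = model.fit(
        threshold=cfg.threshold,
        alpha=cfg.alpha,
        top_n=cfg.top_n,
        correction=cfg.correction,
        universe_policy=cfg.universe_policy,
    )

    files: dict[str, object] = {}
    res.venn_counts().to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    files["venn_counts"] = "venn_counts.tsv"
    for (axis, direction), part in res.partitions.items():
        files[f"genes_{axis}_{direction}"] = _write_gene_lists(
            part, out, f"genes_{axis}_{direction}"
        )
    for (axis, direction, cell), tab in res.enrichments.items():
        name = f"enrichment_{axis}_{direction}_{cell}.tsv"
        tab.rows.to_csv(out / name, sep="\t", index=False)
        files[f"enrichment_{axis}_{direction}_{cell}"] = name
    for (axis, direction), tv in res.term_venns.items():
        name = f"term_venn_{axis}_{direction}.tsv"
        tv.to_frame().to_csv(out / name, sep="\t", index=False)
        files[f"term_venn_{axis}_{direction}"] = name
    for (axis, direction), tab in res.gotrg_tables.items():
        name = f"gotrg_{axis}_{direction}.tsv"
        tab.to_long().to_csv(out / name, sep="\t", index=False)
        files[f"gotrg_{axis}_{direction}"] = name
    res.effect_vectors.to_frame().to_csv(out / "effect_vectors.tsv", sep="\t")
    files["effect_vectors"] = "effect_vectors.tsv"
    res.similarity_frame().to_csv(out / "similarity.tsv", sep="\t", index=False)
    files["similarity"] = "similarity.tsv"
    for axis, tab in res.recovery.items():
        name = f"recovery_{axis}.tsv"
        tab.to_csv(out / name, sep="\t", index=False)
        files[f"recovery_{axis}"] = name
    (out / "summary.txt").write_text(res.summary() + "\n")
    files["summary"] = "summary.txt"

    # internal consistency audit: gene-list files must recount to the tables
    for (axis, direction), part in res.partitions.items():
        for cell_label, genes in part.cells.items():
            p = out / f"genes_{axis}_{direction}_{cell_label}.txt"
            listed = [g for g in p.read_text().splitlines() if g]
            if len(listed) != len(genes):
                raise RuntimeError(
                    f"consistency audit failed for {p.name}: "
                    f"{len(listed)} listed vs {len(genes)} in partition"
                )

    cfg_dict = {k: v for k, v in vars(cfg).items()}
    manifest = {
        "package_version": _pkg_version,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return res
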