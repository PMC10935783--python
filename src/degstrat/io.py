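"""Expression matrices, sample metadata, and gene→term annotation maps.

The entry point for real data is a genes × samples table of TPM values plus a
metadata table assigning each sample column an arm (``treated``/``control``),
a day, and a replicate number.  Loading applies the fixed preprocessing:
NaN → 0, then log2(TPM + 1), in that order, exactly once — the loader always
consumes raw TPM, never already-transformed data.  Processed matrices written
with :func:`write_expression` are re-read with :func:`read_processed`, which
applies no transform, so the two paths cannot double-transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ARMS = ("treated", "control")

__all__ = [
    "ExpressionMatrix",
    "AnnotationMap",
    "load_expression",
    "read_processed",
    "write_expression",
    "load_annotation",
    "write_gmt",
    "subset_samples",
]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2(TPM+1) values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id.
    samples
        DataFrame with columns ``sample_id``, ``arm``, ``day``, ``replicate``,
        one row per column of ``values``, in column order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression values contain NaN after preprocessing")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("log2(TPM+1) values must be >= 0")
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dupes}")
        required = {"sample_id", "arm", "day", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        bad_arm = set(self.samples["arm"]) - set(ARMS)
        if bad_arm:
            raise ValueError(f"unknown arm labels {sorted(bad_arm)}; expected {ARMS}")
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("matrix columns do not match metadata sample_id order")
        triples = self.samples[["arm", "day", "replicate"]]
        if triples.duplicated().any():
            raise ValueError("(arm, day, replicate) triples must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def columns_for(self, arm: str | None = None, day: int | None = None) -> list[str]:
        """Sample ids matching an (arm, day) filter; either may be None."""
        mask = pd.Series(True, index=self.samples.index)
        if arm is not None:
            mask &= self.samples["arm"] == arm
        if day is not None:
            mask &= self.samples["day"] == int(day)
        return list(self.samples.loc[mask, "sample_id"])

    def subset(self, arm: str | None = None, day: int | None = None) -> "ExpressionMatrix":
        cols = self.columns_for(arm, day)
        if not cols:
            raise ValueError(f"no samples match filter (arm={arm!r}, day={day!r})")
        meta = self.samples[self.samples["sample_id"].isin(cols)].reset_index(drop=True)
        return ExpressionMatrix(self.values[cols], meta)

    @property
    def days(self) -> list[int]:
        return sorted(int(d) for d in self.samples["day"].unique())

    @property
    def arms(self) -> list[str]:
        return [a for a in ARMS if a in set(self.samples["arm"])]


def load_expression(
    matrix_path: str | Path,
    metadata_path: str | Path,
    sep: str | None = None,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Load a raw TPM table plus metadata and apply NaN→0 then log2(TPM+1).

    The matrix file holds gene ids in the first column and sample ids in the
    header (use ``transpose=True`` for samples-in-rows).  Every matrix column
    must have a metadata row; columns are reordered to metadata order.
    """
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    tpm = pd.read_csv(matrix_path, sep=_sep_for(matrix_path, sep), index_col=0,
                      float_precision="round_trip")
    if transpose:
        tpm = tpm.T
    if tpm.index.duplicated().any():
        dupes = sorted(tpm.index[tpm.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in {matrix_path}: {dupes}")

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path, sep))
    meta["sample_id"] = meta["sample_id"].astype(str)
    tpm.columns = tpm.columns.astype(str)
    missing = [c for c in tpm.columns if c not in set(meta["sample_id"])]
    if missing:
        raise ValueError(f"matrix columns without metadata: {missing}")
    extra = [s for s in meta["sample_id"] if s not in set(tpm.columns)]
    if extra:
        raise ValueError(f"metadata rows without matrix column: {extra}")
    meta = meta.reset_index(drop=True)
    meta["day"] = meta["day"].astype(int)
    meta["replicate"] = meta["replicate"].astype(int)

    # preprocessing: NaN -> 0 first, then log2(TPM + 1)
    tpm = tpm[list(meta["sample_id"])].astype(float).fillna(0.0)
    if (tpm.to_numpy() < 0).any():
        raise ValueError("raw TPM values must be nonnegative")
    values = np.log2(tpm + 1.0)
    return ExpressionMatrix(values, meta)


def write_expression(em: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path) -> None:
    """Write a processed (log-scale) matrix and its metadata as TSV/CSV."""
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    em.values.to_csv(matrix_path, sep=_sep_for(matrix_path, None), index_label="gene_id")
    em.samples.to_csv(metadata_path, sep=_sep_for(metadata_path, None), index=False)


def read_processed(
    matrix_path: str | Path, metadata_path: str | Path, sep: str | None = None
) -> ExpressionMatrix:
    """Re-read a matrix written by :func:`write_expression` (no transform)."""
    matrix_path, metadata_path = Path(matrix_path), Path(metadata_path)
    values = pd.read_csv(matrix_path, sep=_sep_for(matrix_path, sep), index_col=0,
                         float_precision="round_trip")
    values.columns = values.columns.astype(str)
    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path, sep))
    meta["sample_id"] = meta["sample_id"].astype(str)
    return ExpressionMatrix(values, meta)


def subset_samples(
    em: ExpressionMatrix, arm: str | None = None, day: int | None = None
) -> ExpressionMatrix:
    """Restrict to samples matching the filter; gene order is preserved."""
    return em.subset(arm=arm, day=day)


@dataclass
class AnnotationMap:
    """Term → gene-set membership map with a background universe.

    ``universe`` is always the union of all memberships; terms are non-empty.
    """

    membership: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.membership:
            raise ValueError("annotation map has no terms")
        empty = [t for t, g in self.membership.items() if not g]
        if empty:
            raise ValueError(f"empty terms not allowed: {sorted(empty)}")
        self.membership = {t: frozenset(g) for t, g in self.membership.items()}

    @property
    def term_ids(self) -> list[str]:
        return sorted(self.membership)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.membership.values():
            out |= genes
        return frozenset(out)

    def members(self, term_id: str) -> frozenset[str]:
        if term_id not in self.membership:
            raise KeyError(f"unknown term: {term_id!r}")
        return self.membership[term_id]

    def name_of(self, term_id: str) -> str:
        return self.term_names.get(term_id, term_id)


def load_annotation(path: str | Path, format: str = "auto") -> AnnotationMap:
    """Load a gene→term map from GMT or a two-column (gene<TAB>term) TSV.

    ``format='auto'`` picks GMT for ``.gmt`` files, two-column otherwise.
    Memberships are deduplicated; malformed lines raise with their line number.
    """
    path = Path(path)
    if format == "auto":
        format = "gmt" if path.suffix.lower() == ".gmt" else "two_column_tsv"
    if format not in ("gmt", "two_column_tsv"):
        raise ValueError(f"unknown annotation format: {format!r}")

    membership: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if format == "gmt":
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
                    )
                term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
                if not genes:
                    raise ValueError(f"{path}:{lineno}: GMT term {term!r} has no genes")
                membership.setdefault(term, set()).update(genes)
                if desc:
                    names[term] = desc
            else:
                if len(parts) != 2 or not parts[0] or not parts[1]:
                    raise ValueError(
                        f"{path}:{lineno}: expected exactly two tab-separated fields (gene, term)"
                    )
                gene, term = parts
                membership.setdefault(term, set()).add(gene)
    if not membership:
        raise ValueError(f"{path}: no terms found")
    return AnnotationMap({t: frozenset(g) for t, g in membership.items()}, names)


def write_gmt(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in ann.term_ids:
            genes = "\t".join(sorted(ann.membership[term]))
            fh.write(f"{term}\t{ann.name_of(term)}\t{genes}\n")
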