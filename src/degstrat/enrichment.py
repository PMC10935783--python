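"""Over-representation analysis of gene subsets against an annotation map.

One-sided upper-tail hypergeometric test (Fisher's exact, alternative
"greater") per term, with Benjamini–Hochberg (default) or Bonferroni
correction over the tested terms.  The universe defaults to the annotated
genes intersected with the measured genes when a measured list is supplied
("measured" policy); otherwise all annotated genes ("annotation" policy).
Term-size filters (3..2000 by default) drop degenerate terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

__all__ = [
    "hypergeom_test",
    "adjust_pvalues",
    "enrich_subset",
    "top_terms",
    "term_venn",
    "EnrichmentTable",
    "TripleVenn",
]

_TABLE_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "adj_p"]


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    k = overlap between the subset (size n) and the term (size K) within a
    universe of N genes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(
            f"k={k} outside support [{max(0, K + n - N)}, {min(K, n)}] "
            f"for K={K}, n={n}, N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(p_values, method: str = "bh") -> list[float]:
    """Multiple-testing adjustment: 'bh' (step-up FDR) or 'bonferroni'."""
    if method not in ("bh", "bonferroni"):
        raise ValueError(f"unknown correction: {method!r}")
    if len(p_values) == 0:
        return []
    key = "fdr_bh" if method == "bh" else "bonferroni"
    return list(multipletests(list(p_values), method=key)[1])


@dataclass
class EnrichmentTable:
    """Per-term over-representation statistics for one gene subset.

    Rows are sorted by (adj_p, p_value, term_id); ``significant`` applies
    adj_p < alpha.
    """

    subset_label: str
    rows: pd.DataFrame
    alpha: float = 0.05

    def __post_init__(self) -> None:
        missing = set(_TABLE_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"enrichment table missing columns: {sorted(missing)}")
        self.rows = (
            self.rows[_TABLE_COLUMNS]
            .sort_values(["adj_p", "p_value", "term_id"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def significant(self) -> pd.DataFrame:
        return self.rows[self.rows["adj_p"] < self.alpha]

    @property
    def significant_terms(self) -> frozenset[str]:
        return frozenset(self.significant["term_id"])

    def __len__(self) -> int:
        return len(self.rows)


def enrich_subset(
    genes,
    ann: AnnotationMap,
    measured_genes=None,
    alpha: float = 0.05,
    correction: str = "bh",
    min_term_size: int = 3,
    max_term_size: int = 2000,
    label: str = "subset",
) -> EnrichmentTable:
    """Test every overlapping term for over-representation of ``genes``.

    ``measured_genes`` selects the universe policy: when given, the universe
    is annotated ∩ measured genes and term sizes are recomputed within it;
    when None, the universe is all annotated genes.  Only terms with at
    least one subset member (and size within the filter) are tested;
    correction is applied over the tested terms.
    """
    genes = frozenset(genes)
    if measured_genes is None:
        universe = ann.universe
    else:
        universe = ann.universe & frozenset(measured_genes)
    subset = genes & universe
    N, n = len(universe), len(subset)
    if n == 0:
        warnings.warn(f"subset {label!r} is empty after intersecting with the universe")
        empty = pd.DataFrame(columns=_TABLE_COLUMNS)
        return EnrichmentTable(label, empty.astype({"p_value": float, "adj_p": float}), alpha)

    records = []
    for term in ann.term_ids:
        members = ann.membership[term] & universe
        K = len(members)
        if not (min_term_size <= K <= max_term_size):
            continue
        k = len(members & subset)
        if k == 0:
            continue
        records.append(
            {
                "term_id": term,
                "term_name": ann.name_of(term),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_test(k, K, n, N),
            }
        )
    if not records:
        warnings.warn(f"no terms overlap subset {label!r}")
        empty = pd.DataFrame(columns=_TABLE_COLUMNS)
        return EnrichmentTable(label, empty.astype({"p_value": float, "adj_p": float}), alpha)
    tab = pd.DataFrame.from_records(records)
    tab["adj_p"] = adjust_pvalues(tab["p_value"], correction)
    return EnrichmentTable(label, tab, alpha)


def top_terms(tab: EnrichmentTable, n: int = 30, significant_only: bool = True) -> list[str]:
    """First n term ids in table order (adj_p, then raw p, then term id).

    With ``significant_only`` (default) only terms with adj_p < alpha are
    eligible, so fewer than n may be returned.
    """
    rows = tab.significant if significant_only else tab.rows
    return list(rows["term_id"].head(n))


@dataclass
class TripleVenn:
    """Full 7-cell partition of three labelled sets (e.g. top-term lists)."""

    labels: tuple[str, str, str]
    sets: tuple[frozenset, frozenset, frozenset]
    cells: dict[str, frozenset] = field(init=False)

    def __post_init__(self) -> None:
        a, b, c = (frozenset(s) for s in self.sets)
        la, lb, lc = self.labels
        self.sets = (a, b, c)
        self.cells = {
            f"{la}_only": a - b - c,
            f"{lb}_only": b - a - c,
            f"{lc}_only": c - a - b,
            f"{la}&{lb}": (a & b) - c,
            f"{la}&{lc}": (a & c) - b,
            f"{lb}&{lc}": (b & c) - a,
            "innermost": a & b & c,
        }

    @property
    def innermost(self) -> frozenset:
        return self.cells["innermost"]

    def only(self, label: str) -> frozenset:
        return self.cells[f"{label}_only"]

    @property
    def counts(self) -> dict[str, int]:
        return {cell: len(s) for cell, s in self.cells.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell": list(self.cells), "n": [len(s) for s in self.cells.values()]}
        )


def term_venn(tables, top_n: int | None = 30, significant_only: bool = True) -> TripleVenn:
    """Triple Venn of the (top-n) term sets of three enrichment tables.

    ``tables`` may also be three raw (label, term-set) pairs.  ``top_n=None``
    uses every (significant) term.
    """
    labels, sets = [], []
    for t in tables:
        if isinstance(t, EnrichmentTable):
            labels.append(t.subset_label)
            k = len(t) if top_n is None else top_n
            sets.append(frozenset(top_terms(t, k, significant_only)))
        else:
            lab, s = t
            labels.append(lab)
            sets.append(frozenset(s))
    if len(labels) != 3:
        raise ValueError("term_venn needs exactly three tables or (label, set) pairs")
    return TripleVenn(tuple(labels), tuple(sets))
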