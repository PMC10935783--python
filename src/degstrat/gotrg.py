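"""Counting term-related genes per Venn-cell gene subset.

Enrichment p-values say a term is statistically surprising in a subset;
counting the term's annotated genes ("GO-term-related genes", GOTRGs) in
every subset shows which subset actually carries the term's signal — a
cross-check against the many-to-many tangle of genes and terms, where a
term found for one subset can still draw most of its genes from another.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import AnnotationMap

__all__ = ["GotrgCountTable", "count_gotrgs", "dominance_check"]


@dataclass
class GotrgCountTable:
    """Term × subset matrix of exact intersection counts."""

    counts: pd.DataFrame  # index: term_id, columns: subset labels

    @property
    def terms(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subsets(self) -> list[str]:
        return list(self.counts.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.counts.reset_index(names="term_id").melt(
            id_vars="term_id", var_name="subset", value_name="count"
        )
        return long.sort_values(["term_id", "subset"], kind="mergesort").reset_index(drop=True)


def count_gotrgs(
    terms,
    subsets: dict[str, frozenset[str] | set[str]],
    ann: AnnotationMap,
    within=None,
) -> GotrgCountTable:
    """Count |members(term) ∩ subset| for every term × subset pair.

    ``within`` optionally restricts term memberships to a gene universe
    (e.g. the measured genes) before counting.  Unknown terms raise.
    Raw counts, no normalization.
    """
    terms = list(terms)
    for t in terms:
        if t not in ann.membership:
            raise KeyError(f"unknown term: {t!r}")
    restrict = frozenset(within) if within is not None else None
    data = {}
    for label, genes in subsets.items():
        genes = frozenset(genes)
        col = []
        for t in terms:
            members = ann.membership[t]
            if restrict is not None:
                members = members & restrict
            col.append(len(members & genes))
        data[label] = col
    counts = pd.DataFrame(data, index=pd.Index(terms, name="term_id"))
    return GotrgCountTable(counts)


def dominance_check(tab: GotrgCountTable, reference_subset: str) -> tuple[pd.Series, float]:
    """Per term: does the reference subset strictly out-count every other?

    Ties and all-zero rows fail (strict inequality).  Returns the boolean
    Series and the fraction of terms where dominance holds.
    """
    if reference_subset not in tab.counts.columns:
        raise KeyError(f"reference subset {reference_subset!r} not in table")
    ref = tab.counts[reference_subset]
    others = tab.counts.drop(columns=[reference_subset])
    if others.shape[1] == 0:
        dominant = ref > 0
    else:
        dominant = ref.gt(others.max(axis=1)) & (ref > 0)
    fraction = float(dominant.mean()) if len(dominant) else float("nan")
    return dominant, fraction
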