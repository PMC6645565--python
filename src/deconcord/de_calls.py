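"""Trichotomous differential-expression calling.

A DE table (per-gene log2 fold change and p-value) is converted into a call
set: every gene in the table's universe is *up*, *down* or *unchanged*.
The canonical thresholds are |log2FC| >= 0.5 with a Benjamini-Hochberg
FDR-adjusted p <= 0.05, both boundaries inclusive; both are configurable.

The BH step-up adjustment is implemented here so the call set never depends
on which upstream tool produced the table. When a table already ships an
adjusted-p column (as a DESeq2 result frame would) it is used as-is by
default — this reproduces the upstream analysis without re-deriving its
adjustment set — with ``recompute_padj=True`` to override.

Genes whose adjusted p is undefined (NaN, e.g. filtered upstream) are
classified unchanged but remain in the universe: absence of evidence is not
removed from the set of tested genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables_io import DETable, GeneList, TableFormatError, register_report_type


@register_report_type
@dataclass(frozen=True)
class DECallSet:
    """Per-gene trichotomous DE status for one contrast.

    Invariants: ``up`` and ``down`` are disjoint subsets of ``universe``;
    the unchanged set is derived, never stored.
    """

    contrast_name: str
    universe: frozenset[str]
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down call sets overlap")
        if not (self.up <= self.universe and self.down <= self.universe):
            raise ValueError("called genes outside the universe")

    @property
    def unchanged(self) -> frozenset[str]:
        return self.universe - self.up - self.down

    def direction_set(self, direction: str) -> frozenset[str]:
        if direction == "up":
            return self.up
        if direction == "down":
            return self.down
        if direction == "any":
            return self.up | self.down
        raise ValueError(f"unknown direction {direction!r}")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    For sorted p-values p_(1) <= ... <= p_(m), the adjusted value at rank i is
    ``min_{j >= i} ( p_(j) * m / j )`` capped at 1 — i.e. p*m/rank followed by
    a cumulative minimum taken from the largest rank down. Output order
    matches input order; ties and permutations are handled exactly
    (the adjustment is order-equivariant and monotone).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.minimum(adjusted_sorted, 1.0, out=adjusted_sorted)
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out


def call_de(
    table: DETable,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
    *,
    recompute_padj: bool = False,
) -> DECallSet:
    """Classify every gene of a DE table as up / down / unchanged.

    ``up``: log2FC >= lfc_min and padj <= fdr_max; ``down``: log2FC <= -lfc_min
    and padj <= fdr_max (both boundaries inclusive). If the table has no
    adjusted-p column, or ``recompute_padj`` is set, adjusted p-values are
    computed from the raw p-values by BH over all rows of the table.
    """
    if lfc_min <= 0:
        raise ValueError("lfc_min must be > 0")
    if not 0 < fdr_max <= 1:
        raise ValueError("fdr_max must be in (0, 1]")
    df = table.data
    if table.has_padj and not recompute_padj:
        padj = df["padj"].to_numpy(dtype=float)
    else:
        padj = bh_adjust(df["pvalue"].to_numpy(dtype=float))
    lfc = df["log2fc"].to_numpy(dtype=float)
    # NaN padj compares False on both sides -> unchanged, stays in universe
    significant = padj <= fdr_max
    up_mask = significant & (lfc >= lfc_min)
    down_mask = significant & (lfc <= -lfc_min)
    genes = df["gene_id"].to_numpy()
    return DECallSet(
        contrast_name=table.contrast_name,
        universe=frozenset(genes),
        up=frozenset(genes[up_mask]),
        down=frozenset(genes[down_mask]),
    )


def screen_candidates(
    table_a: DETable,
    table_b: DETable,
    lfc_min: float = 0.5,
) -> GeneList:
    """Inclusive screen filter: genes downregulated in BOTH tables by fold alone.

    Selects genes with log2FC <= -lfc_min in both contrasts while ignoring
    p-values entirely — the deliberately permissive criterion used to pick
    knockdown candidates for an in-vivo screen, where a consistent direction
    of effect matters more than per-gene significance. Genes absent from
    either table are excluded.
    """
    if lfc_min <= 0:
        raise ValueError("lfc_min must be > 0")

    def down_genes(t: DETable) -> set[str]:
        df = t.data
        mask = df["log2fc"].to_numpy(dtype=float) <= -lfc_min
        return set(df["gene_id"].to_numpy()[mask])

    shared = down_genes(table_a) & down_genes(table_b)
    # deterministic order: as listed in table_a
    ordered = tuple(g for g in table_a.gene_ids if g in shared)
    name = f"screen_{table_a.contrast_name}_{table_b.contrast_name}"
    return GeneList(name, ordered)
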