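"""Curated-panel categorization and cross-contrast concordance counts.

A curated panel (e.g. a published list of E2F1-dependent genes) is looked up
in each contrast's call set and every gene receives one category per
contrast: *increased*, *decreased*, *unchanged* — or *untested* when the
gene is absent from that contrast's universe. Distinguishing untested from
unchanged matters: a panel gene the upstream pipeline never tested carries
no evidence of stability, and folding it into "unchanged" would conflate
absence with stability.

Concordance counts then ask, for every pair of contrasts and for the full
set, how many panel genes share a given category across all members of the
subset — the meta-analysis bar chart style of summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from typing import Mapping, Sequence

from .de_calls import DECallSet
from .tables_io import GeneList, register_report_type


def load_e2f1_myb_panel() -> GeneList:
    """The packaged 12-gene panel of E2F1- and Myb-dependent mitotic genes.

    These are the gene symbols reported as commonly downregulated across all
    three endoreplicating-cell contrasts, with their annotated functions as
    categories (documentation only).
    """
    ref = resources.files(__package__) / "data" / "e2f1_myb_common_down_panel.tsv"
    ids: list[str] = []
    categories: dict[str, str] = {}
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene, _, function = line.partition("\t")
        ids.append(gene)
        if function:
            categories[gene] = function
    return GeneList("e2f1_myb_common_down", tuple(ids), categories)

CATEGORIES = ("increased", "decreased", "unchanged", "untested")

#: maps a concordance category to the call-set attribute it corresponds to
_CATEGORY_DIRECTION = {"increased": "up", "decreased": "down"}


@register_report_type
@dataclass(frozen=True)
class PanelCategorization:
    """Per-gene x per-contrast category matrix for a curated panel.

    ``matrix`` maps each panel gene id to a tuple of categories, one per
    contrast in ``contrasts`` order.
    """

    panel_name: str
    genes: tuple[str, ...]
    contrasts: tuple[str, ...]
    matrix: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for gene in self.genes:
            row = self.matrix.get(gene)
            if row is None or len(row) != len(self.contrasts):
                raise ValueError(f"missing or malformed category row for {gene!r}")
            for cat in row:
                if cat not in CATEGORIES:
                    raise ValueError(f"unknown category {cat!r}")

    def category(self, gene: str, contrast: str) -> str:
        return self.matrix[gene][self.contrasts.index(contrast)]

    def per_contrast_counts(self) -> dict[str, dict[str, int]]:
        """Category tallies per contrast; each tallies to the panel size."""
        out: dict[str, dict[str, int]] = {}
        for j, contrast in enumerate(self.contrasts):
            counts = {c: 0 for c in CATEGORIES}
            for gene in self.genes:
                counts[self.matrix[gene][j]] += 1
            out[contrast] = counts
        return out


def categorize_panel(
    panel: GeneList,
    calls: Sequence[DECallSet],
) -> PanelCategorization:
    """Look up every panel gene in every contrast's trichotomous call set."""
    if len(panel) == 0:
        raise ValueError("panel is empty")
    contrasts = tuple(c.contrast_name for c in calls)
    matrix: dict[str, tuple[str, ...]] = {}
    for gene in panel.ids:
        row = []
        for cs in calls:
            if gene in cs.up:
                row.append("increased")
            elif gene in cs.down:
                row.append("decreased")
            elif gene in cs.universe:
                row.append("unchanged")
            else:
                row.append("untested")
        matrix[gene] = tuple(row)
    return PanelCategorization(
        panel_name=panel.name,
        genes=panel.ids,
        contrasts=contrasts,
        matrix=matrix,
    )


def concordance_counts(
    cat: PanelCategorization,
    category: str,
) -> dict[tuple[str, ...], int]:
    """Count panel genes sharing ``category`` across contrast subsets.

    Returns a mapping keyed by contrast subsets — every pair, and the full
    set of contrasts — to the number of panel genes categorized as
    ``category`` in all members of the subset. Counts are monotone: a subset
    can only count at least as many genes as any of its supersets.
    """
    if category not in ("increased", "decreased"):
        raise ValueError("category must be 'increased' or 'decreased'")
    if len(cat.contrasts) < 2:
        raise ValueError("need at least 2 contrasts")
    subsets: list[tuple[str, ...]] = list(combinations(cat.contrasts, 2))
    if len(cat.contrasts) > 2:
        subsets.append(tuple(cat.contrasts))
    out: dict[tuple[str, ...], int] = {}
    for subset in subsets:
        idx = [cat.contrasts.index(c) for c in subset]
        out[subset] = sum(
            1
            for gene in cat.genes
            if all(cat.matrix[gene][j] == category for j in idx)
        )
    return out
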