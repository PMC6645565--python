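"""Directional intersections and full Venn partitions across k DE call sets.

Given k contrasts' call sets, the directional overlap is the k-way
intersection of the up sets (or the down sets); the Venn partition assigns
every gene in the union to a membership signature — a k-bit pattern, one bit
per input call set in order. A gene that is up in one contrast and down in
another contributes to neither direction's intersection.

Because the contrasts were typically tested on slightly different gene
universes (different annotation filters upstream), sets are first restricted
to a resolved universe: by default the intersection of the per-contrast
universes, so the overlap is computed on commonly tested genes only. Union
and explicit-universe policies are available as overrides.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

from .de_calls import DECallSet
from .tables_io import register_report_type

DIRECTIONS = ("up", "down", "any")


@register_report_type
@dataclass(frozen=True)
class OverlapResult:
    """Observed k-way directional overlap plus the full Venn partition.

    ``venn_partitions`` maps every non-empty membership signature (string of
    k bits, ``'1'`` = gene in that call set's direction set, sets in input
    order) to the number of genes with exactly that membership; signatures
    with zero genes are included so the partition is always complete over
    the 2^k - 1 patterns.
    """

    direction: str
    contrast_names: tuple[str, ...]
    set_sizes: tuple[int, ...]
    observed_overlap: int
    venn_partitions: Mapping[str, int]
    universe_size: int

    def __post_init__(self) -> None:
        k = len(self.set_sizes)
        if self.observed_overlap > min(self.set_sizes, default=0):
            raise ValueError("observed overlap exceeds the smallest set")
        if any(n > self.universe_size for n in self.set_sizes):
            raise ValueError("set size exceeds universe size")
        if len(self.venn_partitions) != 2**k - 1:
            raise ValueError("venn partition is not complete over 2^k - 1 signatures")

    @property
    def k(self) -> int:
        return len(self.set_sizes)

    @property
    def union_size(self) -> int:
        return sum(self.venn_partitions.values())


def resolve_universe(
    calls: Sequence[DECallSet],
    policy: str = "intersection",
    explicit: Iterable[str] | None = None,
) -> frozenset[str]:
    """Resolve the shared gene universe for a k-way comparison."""
    universes = [c.universe for c in calls]
    if policy == "intersection":
        return frozenset.intersection(*universes)
    if policy == "union":
        return frozenset.union(*universes)
    if policy == "explicit":
        if explicit is None:
            raise ValueError("explicit universe policy requires a gene collection")
        return frozenset(explicit)
    raise ValueError(f"unknown universe policy {policy!r}")


def directional_overlap(
    calls: Sequence[DECallSet],
    direction: str,
    universe_policy: str = "intersection",
    explicit_universe: Iterable[str] | None = None,
) -> OverlapResult:
    """Observed directional intersection and Venn partition for k call sets.

    ``direction`` is ``"up"`` or ``"down"`` — the two are always analysed as
    separate overlaps, mirroring paired Venn diagrams of increased and
    decreased genes. ``direction="any"`` (up or down pooled per contrast) is
    supported but non-canonical: it conflates genes moving in opposite
    directions across contrasts.
    """
    if len(calls) < 2:
        raise ValueError("at least 2 call sets are required")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    universe = resolve_universe(calls, universe_policy, explicit_universe)
    if not universe:
        raise ValueError("resolved universe is empty")
    sets = [c.direction_set(direction) & universe for c in calls]
    k = len(sets)

    union = set().union(*sets)
    partitions = {
        "".join(bits): 0
        for bits in product("01", repeat=k)
        if "1" in bits
    }
    for gene in union:
        sig = "".join("1" if gene in s else "0" for s in sets)
        partitions[sig] += 1

    return OverlapResult(
        direction=direction,
        contrast_names=tuple(c.contrast_name for c in calls),
        set_sizes=tuple(len(s) for s in sets),
        observed_overlap=partitions["1" * k],
        venn_partitions=partitions,
        universe_size=len(universe),
    )
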