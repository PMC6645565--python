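"""Synthetic multi-contrast DE tables with planted concordance structure.

The generator emulates the table-level statistics of a three-contrast
endoreplication study: two induced-endoreplication knockdown contrasts
(CycA-like and Myb-like, each vs. a mitotic-cycling control) and one
developmental endoreplicating tissue contrast, over a universe of ~10^4
genes. Planted modules give the contrasts their concordance structure:

* a mitotic/cytokinesis module downregulated in all three contrasts
  (default 47 genes),
* an S-phase-like module downregulated only in the developmental contrast
  (default 25 genes),
* a shared upregulated module in the two knockdown contrasts
  (default 698 genes),

against a null background whose p-values are uniform.

Effects live on a latent z-scale: a module gene in a member contrast has
z = direction * mu_g + eps with eps ~ N(0,1) and a per-gene effect size
mu_g ~ N(effect_mean, effect_sd); background genes are pure noise. The
two-sided normal tail of z gives the p-value and log2FC = z * lfc_scale, so
sign and significance agree for strong effects while weak effects may be
discordant — as in real tables. No counts, library sizes or dispersions are
modelled: the pipeline consumes DE tables, so only table-level structure is
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import DETable, GeneList

DEFAULT_CONTRASTS = ("CycA_iEC", "Myb_iEC", "SG_devEC")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted gene module: who moves, where, and how strongly."""

    name: str
    size: int
    contrasts: tuple[str, ...]
    direction: str  # "up" or "down"
    effect_mean: float = 6.0
    effect_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("module size must be nonnegative")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.effect_mean <= 0:
            raise ValueError("effect_mean must be > 0")


def default_modules() -> tuple[ModuleSpec, ...]:
    return (
        ModuleSpec("shared_down_mitotic", 47, DEFAULT_CONTRASTS, "down"),
        ModuleSpec("devEC_only_down_Sphase", 25, ("SG_devEC",), "down"),
        ModuleSpec("shared_up", 698, ("CycA_iEC", "Myb_iEC"), "up"),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study-shaped simulation parameters.

    ``lfc_scale`` converts latent z to log2FC; with the default effect mean
    of 6 and scale 0.4, planted genes sit at |log2FC| ~ 2.4 (several-fold
    changes) with two-sided p ~ 1e-9 — the strong direct-target regime.
    """

    universe_size: int = 12_000
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    modules: tuple[ModuleSpec, ...] = field(default_factory=default_modules)
    lfc_scale: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(m.size for m in self.modules)
        if total > self.universe_size:
            raise ValueError("module sizes exceed the universe")
        for m in self.modules:
            unknown = set(m.contrasts) - set(self.contrasts)
            if unknown:
                raise ValueError(f"module {m.name!r} names unknown contrasts {unknown}")
        if self.lfc_scale <= 0:
            raise ValueError("lfc_scale must be > 0")


def _gene_ids(n: int) -> np.ndarray:
    return np.array([f"G{i:05d}" for i in range(n)])


def generate_contrasts(
    config: SynthConfig,
) -> tuple[list[DETable], dict[str, tuple[str, ...]]]:
    """Generate one DE table per contrast plus the ground-truth assignment.

    Module genes occupy disjoint leading blocks of the gene universe; the
    returned truth maps each module name to its member gene ids. The whole
    draw is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    N = config.universe_size
    genes = _gene_ids(N)

    # assign disjoint id blocks to modules
    truth: dict[str, tuple[str, ...]] = {}
    cursor = 0
    module_rows: list[tuple[ModuleSpec, np.ndarray]] = []
    for mod in config.modules:
        rows = np.arange(cursor, cursor + mod.size)
        cursor += mod.size
        truth[mod.name] = tuple(genes[rows])
        module_rows.append((mod, rows))

    # per-gene effect sizes, shared across member contrasts of a module
    mu = np.zeros(N)
    for mod, rows in module_rows:
        mu[rows] = np.abs(rng.normal(mod.effect_mean, mod.effect_sd, size=mod.size))

    tables: list[DETable] = []
    for contrast in config.contrasts:
        z = rng.normal(0.0, 1.0, size=N)
        for mod, rows in module_rows:
            if contrast in mod.contrasts:
                sign = 1.0 if mod.direction == "up" else -1.0
                z[rows] += sign * mu[rows]
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
        log2fc = z * config.lfc_scale
        tables.append(DETable(contrast, pd.DataFrame(
            {"gene_id": genes, "log2fc": log2fc, "pvalue": pvalue}
        )))
    return tables, truth


def generate_null_calibration(
    universe_size: int,
    sizes: Sequence[int],
    replicates: int,
    seed: int = 0,
) -> list[tuple[frozenset[int], ...]]:
    """Replicate draws of independent uniform gene sets with no structure.

    Supports type-I-error calibration of the permutation test: each
    replicate is a tuple of independently drawn label sets of the given
    sizes from a universe of ``universe_size`` integer labels.
    """
    if any(n > universe_size for n in sizes):
        raise ValueError("set size exceeds universe size")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(replicates):
        out.append(
            tuple(
                frozenset(rng.choice(universe_size, size=n, replace=False).tolist())
                for n in sizes
            )
        )
    return out


# ---------------------------------------------------------------------------
# Deterministic study-scale reconstruction
# ---------------------------------------------------------------------------

#: printed Venn structure of the study's three contrasts (see docs/methods.md):
#: the two knockdown contrasts share 698 increased and 268 decreased genes,
#: of which 158 and 109 respectively extend to the developmental contrast;
#: 25 further genes are decreased in the developmental contrast only.
STUDY_VENN_MODULES = (
    ModuleSpec("triple_up", 158, DEFAULT_CONTRASTS, "up"),
    ModuleSpec("iEC_pair_up", 540, ("CycA_iEC", "Myb_iEC"), "up"),
    ModuleSpec("triple_down", 109, DEFAULT_CONTRASTS, "down"),
    ModuleSpec("iEC_pair_down", 159, ("CycA_iEC", "Myb_iEC"), "down"),
    ModuleSpec("devEC_only_down_Sphase", 25, ("SG_devEC",), "down"),
)


def planted_overlap_tables(
    universe_size: int = 12_000,
    modules: tuple[ModuleSpec, ...] = STUDY_VENN_MODULES,
) -> tuple[list[DETable], dict[str, tuple[str, ...]]]:
    """Noise-free synthetic reconstruction of the study-scale Venn structure.

    A synthetic stand-in for the study's real per-contrast DE tables (which
    are not redistributed here): every planted gene is given log2FC = ±2 and
    p = 1e-12 in its member contrasts, every other (gene, contrast) pair is
    exactly null (log2FC = 0, p = 1), so downstream calling and intersection
    are deterministic set algebra. Useful for exercising the pipeline's
    bookkeeping at the study's printed overlap sizes.
    """
    genes = _gene_ids(universe_size)
    truth: dict[str, tuple[str, ...]] = {}
    cursor = 0
    rows_by_module = []
    for mod in modules:
        rows = np.arange(cursor, cursor + mod.size)
        cursor += mod.size
        truth[mod.name] = tuple(genes[rows])
        rows_by_module.append((mod, rows))
    if cursor > universe_size:
        raise ValueError("module sizes exceed the universe")

    tables = []
    for contrast in DEFAULT_CONTRASTS:
        log2fc = np.zeros(universe_size)
        pvalue = np.ones(universe_size)
        for mod, rows in rows_by_module:
            if contrast in mod.contrasts:
                log2fc[rows] = 2.0 if mod.direction == "up" else -2.0
                pvalue[rows] = 1e-12
        tables.append(
            DETable(contrast, pd.DataFrame(
                {"gene_id": genes, "log2fc": log2fc, "pvalue": pvalue}
            ))
        )
    return tables, truth


def truth_panel(truth: dict[str, tuple[str, ...]], module: str) -> GeneList:
    """A module's ground-truth members as a GeneList (for panel workflows)."""
    return GeneList(module, truth[module])
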