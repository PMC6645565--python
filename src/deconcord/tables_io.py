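"""Input/output for DE tables, gene lists, run configuration and result reports.

The canonical on-disk dialects are deliberately plain so that every artifact
round-trips through version control and diffs cleanly:

* DE tables: UTF-8 TSV with a header row. Column names are remapped via a
  ``column_map`` so heterogeneous upstream exports (e.g. DESeq2 result frames
  saved under different headers) can be read without editing the files.
* Gene lists: one identifier per line; an optional second tab-separated
  column carries a free-text category label; ``#`` starts a comment.
* Run configuration: JSON or YAML (by extension).
* Result reports: JSON key/value documents with a ``schema`` version and a
  ``type`` tag, containing every input needed to reproduce the result
  (thresholds, permutation count B, seed, universe size).

Gene identifiers are opaque, case-sensitive strings. FlyBase ``FBgn``
accessions are the recommended namespace for fly data but nothing is
validated against a registry.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("deconcord")

#: schema version stamped into every written report
REPORT_SCHEMA = 1

#: canonical field names of a DE table, in order
DE_FIELDS = ("gene_id", "log2fc", "pvalue", "padj")


class TableFormatError(ValueError):
    """A file violates a type invariant (duplicate ids, out-of-range p, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DETable:
    """Per-gene differential-expression results for one contrast.

    Parameters
    ----------
    contrast_name:
        Label of the contrast (e.g. ``"CycA_iEC"`` for a knockdown vs.
        mitotic-cycling control comparison).
    data:
        DataFrame with columns ``gene_id`` (unique strings), ``log2fc``
        (finite floats), ``pvalue`` (in [0, 1]) and optionally ``padj``
        (in [0, 1], NaN allowed for genes the upstream pipeline filtered).
    """

    contrast_name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ("gene_id", "log2fc", "pvalue") if c not in df.columns]
        if missing:
            raise TableFormatError(f"DE table missing columns: {missing}")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise TableFormatError(f"duplicate gene_id: {dup.iloc[0]!r}")
        self._check_numeric("log2fc", allow_nan=False, bounded=False)
        self._check_numeric("pvalue", allow_nan=False, bounded=True)
        if self.has_padj:
            self._check_numeric("padj", allow_nan=True, bounded=True)

    def _check_numeric(self, col: str, *, allow_nan: bool, bounded: bool) -> None:
        values = pd.to_numeric(self.data[col], errors="coerce")
        bad = values.isna() & ~(self.data[col].isna() if allow_nan else False)
        if not allow_nan:
            bad = values.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableFormatError(f"non-numeric {col} at row {row + 1}")
        if bounded:
            out = (values < 0) | (values > 1)
            if out.any():
                row = int(out.idxmax())
                raise TableFormatError(
                    f"{col}={values[out].iloc[0]} out of [0, 1] at row {row + 1}"
                )
        elif not allow_nan and not values.map(math.isfinite).all():
            raise TableFormatError(f"non-finite value in column {col}")

    @property
    def has_padj(self) -> bool:
        return "padj" in self.data.columns and self.data["padj"].notna().any()

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.data["gene_id"])

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_records(
        cls,
        contrast_name: str,
        records: Iterable[tuple],
        *,
        with_padj: bool = False,
    ) -> "DETable":
        """Build from (gene_id, log2fc, pvalue[, padj]) tuples."""
        cols = DE_FIELDS if with_padj else DE_FIELDS[:3]
        df = pd.DataFrame.from_records(list(records), columns=cols)
        return cls(contrast_name, df)


@dataclass(frozen=True)
class GeneList:
    """Named ordered set of gene identifiers, with optional per-gene labels."""

    name: str
    ids: tuple[str, ...]
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for g in self.ids:
                if g in seen:
                    raise TableFormatError(f"duplicate gene id in list: {g!r}")
                seen.add(g)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.ids)


UNIVERSE_POLICIES = ("intersection", "union", "explicit")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and sampling parameters for one analysis run.

    ``lfc_min``/``fdr_max`` are the DE-call thresholds (defaults |log2FC| >= 0.5
    and BH-adjusted p <= 0.05, both boundaries inclusive); ``permutations`` is
    the number of null samples B drawn by the enrichment test; ``seed`` drives
    every random draw and is recorded in each report.
    """

    lfc_min: float = 0.5
    fdr_max: float = 0.05
    permutations: int = 100_000
    seed: int = 0
    universe_policy: str = "intersection"

    def __post_init__(self) -> None:
        if self.lfc_min <= 0:
            raise ValueError("lfc_min must be > 0")
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if self.universe_policy not in UNIVERSE_POLICIES:
            raise ValueError(f"universe_policy must be one of {UNIVERSE_POLICIES}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_de_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    contrast_name: str | None = None,
) -> DETable:
    """Read a DE table from a header-row TSV.

    ``column_map`` maps canonical field names (``gene_id``, ``log2fc``,
    ``pvalue``, ``padj``) to the column headers actually present in the file;
    unmapped fields default to their canonical name. A missing ``padj``
    column leaves adjusted p-values unset (they are then computed on demand
    by the caller via BH adjustment).
    """
    path = Path(path)
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype={column_map.get("gene_id", "gene_id"): str})
    rename = {}
    for canon in DE_FIELDS:
        src = column_map.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon != "padj":
            raise TableFormatError(
                f"{path.name}: required column {src!r} (for {canon}) not in header "
                f"{list(df.columns)}"
            )
    df = df.rename(columns=rename)
    keep = [c for c in DE_FIELDS if c in df.columns]
    df = df[keep].copy()
    for col in keep[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    table = DETable(contrast_name or path.stem, df.reset_index(drop=True))
    logger.info("read DE table %s: %d genes (padj %s)", path.name, len(table),
                "present" if table.has_padj else "absent")
    return table


def write_de_table(table: DETable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a one-id-per-line gene list; optional tab-separated category."""
    path = Path(path)
    ids: list[str] = []
    categories: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        ids.append(parts[0])
        if len(parts) > 1 and parts[1]:
            categories[parts[0]] = parts[1]
    return GeneList(name or path.stem, tuple(ids), categories)


def write_gene_list(genes: GeneList, path: str | Path) -> None:
    lines = []
    for g in genes.ids:
        cat = genes.categories.get(g)
        lines.append(f"{g}\t{cat}" if cat else g)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from JSON or YAML (dispatch on extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return RunConfig(**raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    raw = dataclasses.asdict(config)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(raw, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(json.dumps(raw, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Result reports
# ---------------------------------------------------------------------------

# Registry of report-capable result types; populated by the modules that
# define them via register_report_type().
_REPORT_TYPES: dict[str, type] = {}


def register_report_type(cls: type) -> type:
    """Class decorator: make a dataclass serializable via write/read_report."""
    _REPORT_TYPES[cls.__name__] = cls
    return cls


def _jsonify(obj):
    if isinstance(obj, float) and math.isinf(obj):
        return "Infinity" if obj > 0 else "-Infinity"
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonify(v) for v in items]
    return obj


def _dejsonify(obj):
    if obj == "Infinity":
        return math.inf
    if obj == "-Infinity":
        return -math.inf
    if isinstance(obj, dict):
        return {k: _dejsonify(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_dejsonify(v) for v in obj]
    return obj


def write_report(result, path: str | Path) -> None:
    """Serialize a registered result dataclass to a JSON report.

    The report carries a schema version and the result type so the matching
    reader can reconstruct the object exactly. Validation happens before the
    file is opened: a partially populated result (any required field None)
    raises and leaves no file behind.
    """
    cls = type(result)
    if cls.__name__ not in _REPORT_TYPES:
        raise TypeError(f"{cls.__name__} is not a registered report type")
    payload = {}
    for f in dataclasses.fields(result):
        value = getattr(result, f.name)
        if value is None:
            raise ValueError(f"cannot write report: field {f.name!r} is unset")
        payload[f.name] = value
    doc = {
        "schema": REPORT_SCHEMA,
        "type": cls.__name__,
        **{k: _jsonify(v) for k, v in payload.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_report(path: str | Path):
    """Reconstruct a result object written by :func:`write_report`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("schema") != REPORT_SCHEMA:
        raise TableFormatError(f"unsupported report schema: {doc.get('schema')!r}")
    cls = _REPORT_TYPES.get(doc.get("type", ""))
    if cls is None:
        raise TableFormatError(f"unknown report type: {doc.get('type')!r}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in doc:
            raise TableFormatError(f"report missing field {f.name!r}")
        kwargs[f.name] = _coerce_field(_dejsonify(doc[f.name]), f.type)
    return cls(**kwargs)


def _coerce_field(value, annotation):
    # JSON collapses tuples and frozensets to lists; restore by annotation.
    ann = str(annotation)
    if value is None:
        return value
    if ann.startswith("frozenset"):
        return frozenset(value)
    if ann.startswith("tuple") and isinstance(value, list):
        return tuple(value)
    if ann.startswith("Mapping") and isinstance(value, dict):
        return {
            k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
        }
    return value
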