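"""Readers, writers, config parsing and run manifests.

Canonical on-disk dialects: tab-separated tables with a required header and
``#`` comment lines, one-symbol-per-line gene lists, two-column edge lists,
YAML (or JSON) scenario configs, and JSON for nested results.  Every reader
reports malformed input with the offending line number; every CLI invocation
writes a run manifest next to its outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml

from .allele_stats import REQUIRED_COLUMNS, VARIANT_TYPES
from .core_model import ArchitectureSpec, LocusClass, SolveResult
from .interaction_enrichment import EnrichmentResult, GeneSet, normalize_edges

__all__ = [
    "ParseError",
    "RunManifest",
    "EdgeListRead",
    "read_variant_table",
    "write_variant_table",
    "read_edge_list",
    "read_gene_list",
    "read_scenario_config",
    "spec_to_dict",
    "spec_from_dict",
    "result_to_dict",
    "write_result",
    "write_manifest",
]

logger = logging.getLogger("riskarch")

try:
    from importlib.metadata import version as _pkg_version
    VERSION = _pkg_version("riskarch")
except Exception:  # pragma: no cover - uninstalled tree
    VERSION = "unknown"


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


def _data_lines(path):
    """Yield (line_number, stripped_line) skipping blanks and '#' comments."""
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def read_variant_table(path) -> pd.DataFrame:
    """Read a TSV variant table (columns id, variant_type, raf, or_raw)."""
    rows = []
    header = None
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = fields
            missing = [c for c in REQUIRED_COLUMNS if c not in header]
            if missing:
                raise ParseError(f"{path}:{lineno}: missing columns {missing}")
            continue
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        rec = dict(zip(header, fields))
        if rec["variant_type"] not in VARIANT_TYPES:
            raise ParseError(
                f"{path}:{lineno}: unknown variant_type {rec['variant_type']!r}"
            )
        for col, lo, hi in (("raf", 0.0, 1.0), ("or_raw", 0.0, None)):
            try:
                val = float(rec[col])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric {col} {rec[col]!r}"
                ) from None
            if (col == "raf" and not lo <= val <= hi) or (col == "or_raw" and val <= 0):
                raise ParseError(f"{path}:{lineno}: {col} out of range: {val}")
            rec[col] = val
        rows.append(rec)
    if header is None:
        raise ParseError(f"{path}: empty file (no header)")
    if not rows:
        logger.warning("%s: header-only variant table, returning empty table", path)
    return pd.DataFrame(rows, columns=header).astype({"raf": float, "or_raw": float})


def write_variant_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene lists and edge lists
# ---------------------------------------------------------------------------

class EdgeListRead(NamedTuple):
    edges: frozenset
    n_self_loops: int
    n_duplicates: int


def read_edge_list(path) -> EdgeListRead:
    """Read a two-column TSV edge list; normalize and count what was dropped."""
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 2 or not all(f.strip() for f in fields):
            raise ParseError(f"{path}:{lineno}: expected two gene symbols")
        pairs.append((fields[0].strip(), fields[1].strip()))
    edges = normalize_edges(pairs)
    n_self = sum(1 for a, b in pairs if a == b)
    n_dup = len(pairs) - n_self - len(edges)
    if n_self or n_dup:
        logger.info("%s: dropped %d self-loops, collapsed %d duplicate edges",
                    path, n_self, n_dup)
    return EdgeListRead(edges=edges, n_self_loops=n_self, n_duplicates=n_dup)


def read_gene_list(path, label: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list (duplicates collapsed)."""
    genes = []
    for lineno, line in _data_lines(path):
        sym = line.strip()
        if "\t" in sym or " " in sym:
            raise ParseError(f"{path}:{lineno}: expected one gene symbol")
        genes.append(sym)
    dupes = len(genes) - len(set(genes))
    if dupes:
        logger.info("%s: collapsed %d duplicate symbols", path, dupes)
    return GeneSet(label=label or Path(path).stem, genes=frozenset(genes))


def write_gene_list(gene_set: GeneSet, path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.genes)) + "\n", encoding="utf-8")


def write_edge_list(edges, path) -> None:
    lines = [f"{a}\t{b}" for a, b in sorted(edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# Scenario configs
# ---------------------------------------------------------------------------

def spec_from_dict(data: dict) -> ArchitectureSpec:
    classes = tuple(
        LocusClass(
            label=c.get("label", f"class_{i + 1}"),
            vao=c.get("vao"),
            raf=c.get("raf"),
            partners=int(c.get("partners", 0)),
            fraction=float(c.get("fraction", 1.0)),
            flo_override=c.get("flo_override"),
        )
        for i, c in enumerate(data.get("classes", []))
    )
    return ArchitectureSpec(
        classes=classes,
        cnv_flos=tuple(float(f) for f in data.get("cnv_flos", [])),
        threshold=float(data.get("threshold", 0.01)),
        rounding=data.get("rounding", "none"),
    )


def spec_to_dict(spec: ArchitectureSpec) -> dict:
    return {
        "classes": [
            {k: v for k, v in dataclasses.asdict(c).items() if v is not None}
            for c in spec.classes
        ],
        "cnv_flos": list(spec.cnv_flos),
        "threshold": spec.threshold,
        "rounding": spec.rounding,
    }


def read_scenario_config(path) -> ArchitectureSpec:
    """Read a YAML (or JSON) scenario config into an ArchitectureSpec."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    try:
        return spec_from_dict(data)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: invalid scenario: {exc}") from exc


# ---------------------------------------------------------------------------
# Results and manifests
# ---------------------------------------------------------------------------

def result_to_dict(result) -> dict:
    """Serialize SolveResult / EnrichmentResult / dataclasses to plain dicts."""
    if isinstance(result, (SolveResult, EnrichmentResult)):
        return _plain(dataclasses.asdict(result))
    if dataclasses.is_dataclass(result):
        return _plain(dataclasses.asdict(result))
    if isinstance(result, dict):
        return _plain(result)
    raise TypeError(f"cannot serialize {type(result).__name__}")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, frozenset):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_result(result, path, fmt: str = "json") -> None:
    """Write a result as JSON (nested) or TSV (tabular sweeps)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(result_to_dict(result), indent=2, sort_keys=False)
                        + "\n", encoding="utf-8")
    elif fmt == "tsv":
        if not isinstance(result, pd.DataFrame):
            raise TypeError("tsv output requires a DataFrame")
        result.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"format must be 'json' or 'tsv', got {fmt!r}")


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Record of one CLI invocation, written alongside its outputs."""

    command: str
    parameters: dict
    seed: int | None
    inputs: list
    outputs: list
    version: str = VERSION
    timestamp: str = ""


def write_manifest(out_path, command: str, parameters: dict,
                   seed: int | None = None, inputs=(), outputs=()) -> Path:
    manifest = RunManifest(
        command=command,
        parameters=_plain(dict(parameters)),
        seed=seed,
        inputs=[str(p) for p in inputs],
        outputs=[str(p) for p in outputs],
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n",
                    encoding="utf-8")
    return path
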