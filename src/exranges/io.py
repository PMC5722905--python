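"""Readers and writers for the pipeline's tabular artifacts.

All artifacts are plain TSV/CSV (delimiter sniffed from the header line) or
JSON: expression matrices with a gene-id first column, sample design tables,
step-labeled feature matrices (columns ``series:from_time``), two- or
three-column edge lists, gene->category annotation maps, and per-run JSON
manifests recording the effective configuration, input digests and timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GoldStandard,
    StepMatrix,
    ValidationError,
    parse_step_label,
)

__all__ = [
    "read_expression",
    "read_design",
    "write_expression",
    "read_step_matrix",
    "write_step_matrix",
    "read_gene_list",
    "write_gene_list",
    "read_edges",
    "write_edges",
    "read_annotation",
    "read_scores",
    "write_scores",
    "file_digest",
    "write_manifest",
]

logger = logging.getLogger("exranges")


def _sniff_sep(path: Path) -> str:
    header = Path(path).open().readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path, index_col=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=index_col)


def read_design(path) -> pd.DataFrame:
    """Sample design table: sample_id, series_id, time[, cyclic]."""
    d = _read_table(path)
    for col in ("series_id", "time"):
        if col not in d.columns:
            raise ValidationError(f"{path}: design is missing column {col!r}")
    if "cyclic" in d.columns:
        d["cyclic"] = d["cyclic"].astype(bool)
    return d


def read_expression(path, design_path) -> ExpressionMatrix:
    """Load and validate a genes x samples matrix plus its design.

    Non-numeric cells, duplicate ids and matrix/design sample mismatches all
    raise :class:`ValidationError` with coordinates.
    """
    raw = _read_table(path)
    bad = raw.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        g, s = np.argwhere(bad.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}"
        )
    return ExpressionMatrix(bad.astype(float), read_design(design_path))


def write_expression(expr: ExpressionMatrix, path, design_path=None) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    if design_path is not None:
        expr.design.to_csv(design_path, sep="\t", index_label="sample_id")


def write_step_matrix(m: StepMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def read_step_matrix(path, design: pd.DataFrame | None = None) -> StepMatrix:
    """Read a step-labeled feature matrix; step metadata parsed from labels."""
    values = _read_table(path)
    rows = []
    for label in values.columns:
        series_id, from_time = parse_step_label(label)
        rows.append(
            {"series_id": series_id, "from_time": from_time,
             "to_time": np.nan, "from_sample": None}
        )
    steps = pd.DataFrame(rows, index=pd.Index(values.columns, name="step"))
    return StepMatrix(values=values.astype(float), steps=steps)


def read_gene_list(path) -> list:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [ln for ln in lines if ln and not ln.startswith("#")]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def read_edges(path, universe=None):
    """Edge list: 2 columns -> GoldStandard, 3 columns -> scored edge table.

    Duplicates are dropped with a logged warning; self-loops are flagged;
    malformed lines are reported with their line number.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    rows = []
    scored = None
    for i, line in enumerate(text, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split("\t")
        parts = [p.strip() for p in parts if p.strip() != ""]
        if i == 1 and parts[:2] == ["regulator", "target"]:
            continue  # header
        if len(parts) not in (2, 3):
            raise ValidationError(f"{path}:{i}: expected 2 or 3 columns, got {len(parts)}")
        if scored is None:
            scored = len(parts) == 3
        elif scored != (len(parts) == 3):
            raise ValidationError(f"{path}:{i}: inconsistent column count")
        if scored:
            try:
                score = float(parts[2])
            except ValueError:
                raise ValidationError(f"{path}:{i}: non-numeric score {parts[2]!r}")
            rows.append((parts[0], parts[1], score))
        else:
            rows.append((parts[0], parts[1]))
        if parts[0] == parts[1]:
            logger.warning("%s:%d: self-loop %s->%s", path, i, parts[0], parts[1])
    n_raw = len(rows)
    seen = dict.fromkeys(rows)
    rows = list(seen)
    if len(rows) < n_raw:
        logger.warning("%s: dropped %d duplicate edge(s)", path, n_raw - len(rows))
    if scored:
        return pd.DataFrame(rows, columns=["regulator", "target", "score"])
    positives: dict = {}
    for r, t in rows:
        positives.setdefault(r, set()).add(t)
    return GoldStandard(positives, universe=list(universe) if universe else [])


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> dict:
    """Two-column gene -> category map; genes may carry several categories."""
    table = pd.read_csv(path, sep=_sniff_sep(Path(path)), header=None,
                        names=["gene", "category"], comment="#")
    ann: dict = {}
    for g, c in zip(table["gene"], table["category"]):
        ann.setdefault(g, set()).add(c)
    return ann


def read_scores(path) -> pd.DataFrame:
    return _read_table(path)


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="regulator")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, *, config: dict, inputs: dict, seed, timings: dict,
                   version: str) -> None:
    """One JSON manifest per CLI run: effective config, input digests, timings."""
    manifest = {
        "version": version,
        "seed": seed,
        "config": config,
        "inputs": {name: file_digest(p) for name, p in inputs.items()},
        "timings_s": timings,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
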