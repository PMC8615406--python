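"""Shared table/format IO, coordinate-convention conversion and provenance.

All inter-stage tables are TSV with a header row; files written by the
pipeline carry a ``#``-prefixed provenance line (tool version, config hash,
seed) so that runs are diffable and byte-reproducible.

Coordinate conventions: genomic features are held 1-based inclusive (GFF3)
internally; island intervals cross the BED boundary (0-based half-open) in
exactly one pair of functions below.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# ---------------------------------------------------------------------------
# coordinate conversions — the single place where BED and GFF3 meet
# ---------------------------------------------------------------------------

def gff_interval_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start0, end0)."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based interval [{start}, {end}]")
    return start - 1, end


def bed_interval_to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive [start, end]."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"invalid 0-based interval [{start0}, {end0})")
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------

def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(config: Mapping | None = None, seed: int | None = None) -> str:
    parts = [f"effectome v{__version__}"]
    if config is not None:
        parts.append(f"config:{config_hash(config)}")
    if seed is not None:
        parts.append(f"seed:{seed}")
    return "# " + " ".join(parts)


# ---------------------------------------------------------------------------
# TSV with schema validation
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, *,
              config: Mapping | None = None, seed: int | None = None,
              provenance: bool = True) -> Path:
    """Write a TSV with an optional leading provenance comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance_line(config, seed) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path: str | Path, schema: Sequence[str] | None = None,
             dtypes: Mapping[str, type] | None = None) -> pd.DataFrame:
    """Read a TSV (skipping ``#`` comment lines), validating columns.

    Raises :class:`SchemaError` naming the offending column or line. Ragged
    rows are reported with their 1-based line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    with open(path) as fh:
        lines = fh.readlines()
    body = [(i + 1, ln.rstrip("\n")) for i, ln in enumerate(lines)
            if ln.strip() and not ln.startswith("#")]
    if not body:
        raise SchemaError(f"{path}: empty table")
    header = body[0][1].split("\t")
    ncol = len(header)
    for lineno, ln in body[1:]:
        if len(ln.split("\t")) != ncol:
            raise SchemaError(
                f"{path}: line {lineno} has {len(ln.split(chr(9)))} fields, "
                f"expected {ncol}")
    if schema is not None:
        missing = [c for c in schema if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    df = pd.read_csv(path, sep="\t", comment="#")
    if dtypes:
        for col, typ in dtypes.items():
            if col in df.columns:
                try:
                    df[col] = df[col].astype(typ)
                except (TypeError, ValueError) as exc:
                    raise SchemaError(f"{path}: column {col!r}: {exc}") from exc
    return df


# ---------------------------------------------------------------------------
# FASTA / BED / GFF3 writers (line formats; readers live with their stages)
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def write_bed(intervals: Sequence[tuple[str, int, int]], path: str | Path,
              names: Sequence[str] | None = None) -> Path:
    """Write 0-based half-open intervals as BED3/BED4."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for i, (contig, s0, e0) in enumerate(intervals):
            row = [contig, str(s0), str(e0)]
            if names is not None:
                row.append(names[i])
            fh.write("\t".join(row) + "\n")
    return path


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open), ignoring extra columns."""
    out = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_gff3(features: Sequence[Mapping], path: str | Path) -> Path:
    """Write GFF3 feature dicts (1-based inclusive coordinates).

    Each feature mapping needs: contig, source, type, start, end, score,
    strand, frame, attributes (an ordered mapping rendered as key=value).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f["attributes"].items())
            fh.write("\t".join([
                str(f["contig"]), str(f.get("source", "effectome")),
                str(f["type"]), str(f["start"]), str(f["end"]),
                str(f.get("score", ".")), str(f["strand"]),
                str(f.get("frame", ".")), attrs,
            ]) + "\n")
    return path
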