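"""Readers and writers for the tabular formats used across the pipeline.

Formats: intensity matrix as TSV (first column protein id, header row of
sample ids, missing = empty cell), sample design as CSV, pathway annotation
as GMT, microclimate as CSV with ISO timestamps, run configuration as YAML.

Validation is total: malformed input raises :class:`ParseError` naming the
offending row/column rather than loading partially.  By default exact zeros
in a raw matrix are treated as missing — DIA search engines commonly encode
non-detection as 0, and detection counting must not mistake 0 for an
observation; disable with ``zeros_as_missing=False``.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import AnnotationSets, IntensityMatrix, SampleDesign

logger = logging.getLogger("proteoheat")


class ParseError(ValueError):
    """Malformed input file; message names the file position at fault."""


# --------------------------------------------------------------------------
# intensity matrix
# --------------------------------------------------------------------------

def read_intensity_matrix(path, zeros_as_missing: bool = True) -> IntensityMatrix:
    """Read a proteins x samples TSV into an :class:`IntensityMatrix`.

    Empty cells (and, by default, exact zeros) become missing; the returned
    matrix has ``scale_flag="raw"``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise ParseError(f"{path}: header must contain at least one sample column")
    sample_ids = header[1:]
    ncol = len(header)
    protein_ids: list[str] = []
    data = np.full((len(rows) - 1, ncol - 1), np.nan)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise ParseError(
                f"{path}: line {i} has {len(row)} fields, expected {ncol} (ragged row)"
            )
        protein_ids.append(row[0])
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == "" or cell.upper() in ("NA", "NAN"):
                continue
            try:
                data[i - 2, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at line {i}, "
                    f"column {sample_ids[j]!r}"
                ) from None
    seen: set[str] = set()
    for pid in protein_ids:
        if pid in seen:
            raise ParseError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
    dup_samples = {s for s in sample_ids if sample_ids.count(s) > 1}
    if dup_samples:
        raise ParseError(f"{path}: duplicate sample id(s) {sorted(dup_samples)}")
    values = pd.DataFrame(data, index=protein_ids, columns=sample_ids)
    if zeros_as_missing:
        n_zero = int((values == 0).sum().sum())
        if n_zero:
            logger.info("read_intensity_matrix: treating %d exact zeros as missing", n_zero)
        values = values.mask(values == 0)
    logger.info(
        "read_intensity_matrix: %d proteins x %d samples from %s",
        values.shape[0], values.shape[1], path,
    )
    return IntensityMatrix.from_values(values, scale_flag="raw")


def write_intensity_matrix(matrix: IntensityMatrix, path) -> None:
    """Write matrix as TSV; missing cells are written empty.

    For imputed matrices the imputed values are written (the mask travels
    separately — see :func:`write_mask`).
    """
    out = matrix.values.copy()
    out.index.name = "protein_id"
    with open(path, "w", newline="") as fh:
        out.to_csv(fh, sep="\t", na_rep="", float_format="%.6g")


def write_mask(matrix: IntensityMatrix, path) -> None:
    """Write the detection mask as TSV of 0/1."""
    out = matrix.mask.astype(int).copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# sample design
# --------------------------------------------------------------------------

def read_sample_design(path) -> SampleDesign:
    """Read sample metadata CSV (sample_id, genotype, tolerance_class, day, replicate)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: design CSV must have a 'sample_id' column")
    df = df.set_index("sample_id")
    df["day"] = df["day"].astype(int)
    return SampleDesign(df)


def write_sample_design(design: SampleDesign, path) -> None:
    out = design.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


# --------------------------------------------------------------------------
# GMT pathway annotation
# --------------------------------------------------------------------------

def read_gmt(path) -> AnnotationSets:
    """Read GMT gene-set format: tab-separated set id, description, members."""
    path = Path(path)
    names: dict = {}
    members: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires id, description and >=1 member"
                )
            set_id, desc = fields[0], fields[1]
            if set_id in members:
                raise ParseError(f"{path}: duplicate set id {set_id!r} at line {lineno}")
            mem = [m for m in fields[2:] if m.strip()]
            uniq = set(mem)
            if len(uniq) < len(mem):
                logger.warning(
                    "read_gmt: %s line %d set %s has duplicated members; deduplicated",
                    path, lineno, set_id,
                )
            names[set_id] = desc
            members[set_id] = uniq
    return AnnotationSets(names=names, members=members)


def write_gmt(sets: AnnotationSets, path) -> None:
    with open(path, "w") as fh:
        for set_id in sets.members:
            mem = sorted(sets.members[set_id])
            fh.write("\t".join([set_id, sets.names.get(set_id, "")] + mem) + "\n")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def read_config(path) -> dict:
    """Load a YAML run configuration; must parse to a mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
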