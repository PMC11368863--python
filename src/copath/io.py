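"""Plain-text readers and writers for the pipeline's file formats.

* counts: TSV, first column ``gene_id``, remaining columns sample ids,
  integer cells for raw counts (normalized matrices carry reals).
* sample sheet: CSV with columns ``sample_id``, ``condition``.
* truth table: TSV with columns ``gene_id``, ``state_NC``, ``state_IV``,
  ``state_IC``, ``lfc_NC``, ``lfc_IV``, ``lfc_IC``.
* gene sets: GMT (tab-separated: name, description, member ids).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from copath.design import SampleDesign

TRUTH_COLUMNS = (
    "gene_id",
    "state_NC",
    "state_IV",
    "state_IC",
    "lfc_NC",
    "lfc_IV",
    "lfc_IC",
)

_STATES = {"+", "0", "-"}


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read a gene x sample count matrix (genes as rows)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    m.index = m.index.astype(str)
    if m.index.has_duplicates:
        dups = m.index[m.index.duplicated()].unique()
        raise ParseError(f"{path}: duplicate gene id(s): {', '.join(dups[:5])}")
    if m.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample columns")
    if (m.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative values in count matrix")
    return m


def write_counts(m: pd.DataFrame, path: str | os.PathLike, decimals: int | None = None) -> None:
    """Write a count matrix; ``decimals`` fixes the float format (normalized output)."""
    out = m.copy()
    out.index.name = "gene_id"
    fmt = None if decimals is None else f"%.{decimals}f"
    out.to_csv(path, sep="\t", float_format=fmt)


# ---------------------------------------------------------------------------
# sample sheets


def read_sample_sheet(path: str | os.PathLike) -> SampleDesign:
    frame = pd.read_csv(path)
    try:
        return SampleDesign.from_frame(frame)
    except ValueError as err:
        raise ParseError(f"{path}: {err}") from err


def write_sample_sheet(design: SampleDesign, path: str | os.PathLike) -> None:
    design.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# truth tables


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a simulation truth table (header always present, even if empty)."""
    missing = set(TRUTH_COLUMNS) - set(truth.columns)
    if missing:
        raise ValueError(f"truth table missing column(s): {', '.join(sorted(missing))}")
    truth.loc[:, list(TRUTH_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    """Read a truth table, validating states and fold changes line by line."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != list(TRUTH_COLUMNS):
            expected = "\t".join(TRUTH_COLUMNS)
            raise ParseError(f"{path}: line 1: expected header {expected!r}")
        rows = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(TRUTH_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(TRUTH_COLUMNS)} fields, got {len(fields)}"
                )
            gene, s_nc, s_iv, s_ic = fields[0], fields[1], fields[2], fields[3]
            if gene in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            for s in (s_nc, s_iv, s_ic):
                if s not in _STATES:
                    raise ParseError(f"{path}: line {lineno}: invalid state {s!r}")
            try:
                lfcs = [float(x) for x in fields[4:7]]
            except ValueError as err:
                raise ParseError(f"{path}: line {lineno}: {err}") from err
            rows.append((gene, s_nc, s_iv, s_ic, *lfcs))
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    if truth.empty:
        truth = truth.astype(
            {c: float for c in ("lfc_NC", "lfc_IV", "lfc_IC")} | {"gene_id": str}
        )
    return truth


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Parse a GMT file into ``set name -> member gene ids``.

    Empty sets are dropped; duplicate members within a set are collapsed
    keeping first occurrence.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(
                    f"{path}: line {lineno}: GMT rows need name, description, members"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = list(dict.fromkeys(g for g in fields[2:] if g))
            if members:
                sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | os.PathLike, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def file_sha256(path: str | os.PathLike) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
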