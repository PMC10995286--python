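"""Readers and writers for the pipeline's on-disk formats.

All formats are plain text, tab-separated, with ``#`` comment lines and blank
lines ignored. IDs are opaque case-sensitive strings; no mature-to-precursor
miRNA conversion is performed here (see :func:`apply_id_mapping` for the
user-supplied-mapping hook).

Formats
-------
association TSV   two columns: mirna_id <TAB> annotation_id
ontology TSV      two columns: child_term <TAB> parent_term
matrix TSV        header row + header column of ids, 12 significant digits
GMT               set_name <TAB> category <TAB> member1 <TAB> member2 ...
miRNA list        one ID per line
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import AssociationTable, LabeledSimilarityMatrix, MiRNASetKB, OntologyDAG

logger = logging.getLogger(__name__)


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    """(1-based line number, stripped content) for non-comment, non-blank lines."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((no, line))
    return out


def read_association_table(path: str | Path) -> AssociationTable:
    """Read a two-column miRNA/annotation TSV into a deduplicated table."""
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: no association records found")
    pairs = []
    for no, line in lines:
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}:{no}: expected at least 2 tab-separated fields")
        pairs.append((fields[0], fields[1]))
    table = AssociationTable(pairs)
    logger.info(
        "read %d pairs (%d unique) from %s", len(pairs), len(table), path
    )
    return table


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for left, right in sorted(table.pairs):
            fh.write(f"{left}\t{right}\n")


def read_ontology(path: str | Path) -> OntologyDAG:
    """Read child<TAB>parent edges; roots are inferred (terms with no parent)."""
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: no ontology edges found")
    edges = []
    terms: set[str] = set()
    for no, line in lines:
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}:{no}: expected child<TAB>parent")
        edges.append((fields[0], fields[1]))
        terms.update(fields[:2])
    dag = OntologyDAG(terms, edges)
    logger.info(
        "read ontology %s: %d terms, %d edges, roots=%s",
        path, len(dag), len(edges), sorted(dag.roots),
    )
    return dag


def write_ontology(dag: OntologyDAG, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for child, parent in sorted(dag.edges):
            fh.write(f"{child}\t{parent}\n")


def read_gmt(path: str | Path) -> MiRNASetKB:
    """Read a GMT file: set_name <TAB> category <TAB> members..."""
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"{path}: empty GMT file")
    sets = []
    for no, line in lines:
        fields = [f for f in line.split("\t")]
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{no}: GMT line needs name, category and >=1 member"
            )
        name, category, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if not members:
            raise ValueError(f"{path}:{no}: set {name!r} has no members")
        sets.append((name, category, members))
    kb = MiRNASetKB(sets)
    logger.info("read %d miRNA sets (universe %d) from %s", len(kb), len(kb.universe), path)
    return kb


def write_gmt(kb: MiRNASetKB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in kb.sets:
            fh.write("\t".join([s.name, s.category, *s.members]) + "\n")


def write_matrix(matrix: LabeledSimilarityMatrix, path: str | Path) -> None:
    """Write a similarity matrix as TSV with 12 significant digits."""
    df = pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="")


def read_matrix(path: str | Path) -> LabeledSimilarityMatrix:
    """Read a matrix TSV; symmetry is re-validated on read."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    ids = [str(i) for i in df.index]
    cols = [str(c) for c in df.columns]
    if ids != cols:
        raise ValueError(f"{path}: row ids do not match column ids")
    values = df.to_numpy(dtype=float)
    asym = float(np.max(np.abs(values - values.T))) if len(ids) else 0.0
    if asym > 1e-9:
        raise ValueError(f"{path}: matrix asymmetric on read, worst |delta| = {asym:.3e}")
    return LabeledSimilarityMatrix(ids, values)


def read_mirna_list(path: str | Path) -> list[str]:
    """Read one miRNA ID per line, preserving order, dropping duplicates."""
    lines = _data_lines(path)
    ids = [line.split("\t")[0].strip() for _, line in lines]
    dedup = list(dict.fromkeys(ids))
    if len(dedup) != len(ids):
        logger.info("%s: dropped %d duplicate ids", path, len(ids) - len(dedup))
    return dedup


def write_mirna_list(mirnas: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mirnas:
            fh.write(m + "\n")


def apply_id_mapping(
    ids: Iterable[str], mapping_path: str | Path
) -> list[str]:
    """Preprocessing hook: map IDs through a user-supplied two-column TSV.

    Intended for mature-to-precursor miRNA renaming, which is an upstream
    curation step with dataset-specific collision rules; the mapping file is
    the user's statement of those rules. IDs absent from the mapping pass
    through unchanged. The result is deduplicated preserving first occurrence.
    """
    table = {}
    for no, line in _data_lines(mapping_path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{mapping_path}:{no}: expected old_id<TAB>new_id")
        table[fields[0]] = fields[1]
    return list(dict.fromkeys(table.get(i, i) for i in ids))
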