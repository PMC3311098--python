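"""Readers and writers for the plain-text formats the pipeline touches.

Formats
-------
* network edge list: one interaction per line, two whitespace/tab/comma
  separated protein ids; ``#`` comment lines ignored; an optional vertex
  list file adds isolated proteins.
* similarity table: three columns ``idA idB score``.
* annotation table: two columns ``protein-id go-term`` (one term per line);
  GAF lines (15+ tab-separated columns) are also accepted, using columns 2
  (object id) and 5 (GO id).
* domain p-value table: three columns ``protein-id domain-id p-value``.
* alignment: one match-set per line, tab-separated protein ids
  (IsoRankN-compatible).
"""

from __future__ import annotations

import os
import re
from collections.abc import Iterator

from .core import (
    Alignment,
    AnnotationMap,
    InputFormatError,
    Network,
    NetworkCollection,
    SimilarityMatrix,
    _canon,
    logger,
)

_DELIM_RE = re.compile(r"[,\t ]+")


def _rows(path: str | os.PathLike) -> Iterator[tuple[int, list[str]]]:
    """Yield (line-number, fields) for data lines, auto-detecting the
    delimiter among tab / comma / whitespace.  Output is always tab."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, _DELIM_RE.split(line)


def read_network_edgelist(
    path: str | os.PathLike,
    network_id: str,
    *,
    vertex_list: str | os.PathLike | None = None,
) -> Network:
    """Read one network from a 2-column edge list.

    Duplicate edges (in either orientation) are collapsed and self-loops
    dropped with a logged count.  Isolated vertices can only enter through
    ``vertex_list`` (one protein id per line).
    """
    vertices: set[str] = set()
    edges: set[tuple[str, str]] = set()
    n_loops = 0
    n_lines = 0
    for lineno, fields in _rows(path):
        n_lines += 1
        if len(fields) < 2:
            raise InputFormatError(
                f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        vertices.add(a)
        vertices.add(b)
        if a == b:
            n_loops += 1
            continue
        edges.add(_canon(a, b))
    if n_lines == 0:
        raise InputFormatError(f"{path}: empty edge list")
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_loops)
    if vertex_list is not None:
        for lineno, fields in _rows(vertex_list):
            vertices.add(fields[0])
    return Network(network_id, frozenset(vertices), frozenset(edges))


def read_networks(
    paths: dict[str, str | os.PathLike],
) -> NetworkCollection:
    """Read several edge lists into one collection (ids namespaced on
    collision)."""
    return NetworkCollection(
        read_network_edgelist(p, nid) for nid, p in paths.items()
    )


def read_similarity_table(
    path: str | os.PathLike,
    nets: NetworkCollection,
    *,
    strict: bool = False,
) -> SimilarityMatrix:
    """Read a 3-column similarity table against an existing collection."""

    def rows() -> Iterator[tuple[str, str, float]]:
        for lineno, fields in _rows(path):
            if len(fields) < 3:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                score = float(fields[2])
            except ValueError:
                raise InputFormatError(
                    f"{path}:{lineno}: unparseable score {fields[2]!r}"
                ) from None
            yield fields[0], fields[1], score

    return SimilarityMatrix.from_entries(rows(), nets, strict=strict)


def read_annotations(path: str | os.PathLike) -> AnnotationMap:
    """Read protein -> GO-term annotations (2-column table or GAF subset)."""
    ann: AnnotationMap = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "!")):
                continue
            tabbed = line.split("\t")
            if len(tabbed) >= 15:  # GAF record
                protein, term = tabbed[1], tabbed[4]
            else:
                fields = _DELIM_RE.split(line.strip())
                if len(fields) < 2:
                    raise InputFormatError(
                        f"{path}: expected 'protein term' on line {line!r}"
                    )
                protein, term = fields[0], fields[1]
            ann.setdefault(protein, set()).add(term)
    return ann


def read_domain_pvalues(
    path: str | os.PathLike,
) -> dict[str, dict[str, float]]:
    """Read a protein -> {domain -> Pfam p-value} table."""
    table: dict[str, dict[str, float]] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 3:
            raise InputFormatError(
                f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
            )
        protein, domain = fields[0], fields[1]
        try:
            pv = float(fields[2])
        except ValueError:
            raise InputFormatError(
                f"{path}:{lineno}: unparseable p-value {fields[2]!r}"
            ) from None
        if not 0 < pv <= 1:
            raise InputFormatError(
                f"{path}:{lineno}: p-value {pv} outside (0, 1]"
            )
        table.setdefault(protein, {})[domain] = pv
    return table


def write_alignment(alignment: Alignment, path: str | os.PathLike) -> None:
    """Write one match-set per line, members tab-separated and sorted."""
    with open(path, "wt", encoding="utf-8") as fh:
        for ms in alignment:
            fh.write("\t".join(sorted(ms.members)) + "\n")


def read_alignment(
    path: str | os.PathLike,
    nets: NetworkCollection | None = None,
) -> Alignment:
    """Read an alignment file; raises if a protein occurs on two lines or
    (when ``nets`` is given) is unknown."""
    sets: list[frozenset[str]] = []
    for lineno, fields in _rows(path):
        members = frozenset(fields)
        if nets is not None:
            for v in members:
                if v not in nets:
                    raise InputFormatError(
                        f"{path}:{lineno}: unknown protein {v!r}"
                    )
        sets.append(members)
    return Alignment(sets)


def write_unaligned(
    proteins: set[str], path: str | os.PathLike
) -> None:
    """Sidecar listing proteins not covered by the alignment."""
    with open(path, "wt", encoding="utf-8") as fh:
        for v in sorted(proteins):
            fh.write(v + "\n")
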