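"""Readers and writers for the on-disk formats.

All formats are plain tab-separated text:

* scored pairs  — ``proteinA<TAB>proteinB<TAB>score``
* complexes     — one complex per line, tab-separated member IDs, with an
  optional leading identifier column
* clusters      — one cluster per line, tab-separated member IDs, with an
  optional leading ``score<TAB>`` prefix

Readers are total on well-formed files and raise :class:`ParseError` with a
line number otherwise.  Write/read round trips preserve content exactly.
"""

from __future__ import annotations

import logging
import os
from typing import Optional

from .types import Cluster, ClusterSet, ReferenceComplex, ReferenceComplexSet, ScoredPairTable

logger = logging.getLogger("swcnet")


class ParseError(ValueError):
    pass


def read_scored_pairs(
    path: str, source_name: str, min_score: Optional[float] = None
) -> ScoredPairTable:
    """Read a scored pair table, optionally dropping scores <= ``min_score``.

    The threshold is strict ("greater than"), matching the 0.5 cutoff applied
    to functional-association scores.  Duplicate unordered pairs keep the
    maximum score; self-pairs are dropped with a warning.  An empty file
    yields an empty table.
    """
    table = ScoredPairTable(source_name)
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns, got {len(cols)}"
                )
            u, v = cols[0], cols[1]
            try:
                score = float(cols[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: unparsable score {cols[2]!r}"
                ) from exc
            if u == v:
                logger.warning("%s:%d: self-pair %r dropped", path, lineno, u)
                continue
            if min_score is not None and score <= min_score:
                continue
            table.add(u, v, score)
    return table


def write_scored_pairs(table: ScoredPairTable, path: str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for (u, v), score in table:
            fh.write(f"{u}\t{v}\t{score:.17g}\n")


def read_complexes(
    path: str, role: Optional[str] = None, id_column: bool = False
) -> ReferenceComplexSet:
    """Read reference complexes, one per line of tab-separated member IDs.

    Complexes with fewer than two distinct members are dropped with a
    warning.  With ``id_column`` the first column names the complex;
    otherwise identifiers ``C1, C2, ...`` are assigned by line order.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"complex file not found: {path}")
    complexes = []
    with open(path, "rt", encoding="utf-8") as fh:
        n = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = [c for c in line.split("\t") if c]
            if id_column:
                ident, members = cols[0], frozenset(cols[1:])
            else:
                n += 1
                ident, members = f"C{n}", frozenset(cols)
            if len(members) < 2:
                logger.warning(
                    "%s:%d: complex %r has < 2 distinct members, dropped",
                    path, lineno, ident,
                )
                continue
            complexes.append(ReferenceComplex(ident, members))
    return ReferenceComplexSet(complexes, role=role)


def write_weighted_network(network, path: str) -> None:
    """Write a weighted network as a (proteinA, proteinB, weight) TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        for (u, v), data in network.edges():
            w = data.get("weight")
            if w is None:
                raise ValueError(f"edge ({u}, {v}) has no weight")
            fh.write(f"{u}\t{v}\t{w:.17g}\n")


def read_weighted_network(path: str):
    """Read a (proteinA, proteinB, weight) TSV into a weighted network.

    The single feature is named ``weight`` and doubles as the edge weight,
    so the result can feed the clusterers directly.
    """
    from .types import CompositeNetwork

    table = read_scored_pairs(path, "weight")
    network = CompositeNetwork(["weight"])
    for (u, v), w in table:
        network.add_edge(u, v, {"weight": w})
        network.edge_data(u, v)["weight"] = w
    return network


def write_clusters(clusters: ClusterSet, path: str, with_score: bool = True) -> None:
    """Write one cluster per line; members in canonical (sorted) order."""
    with open(path, "wt", encoding="utf-8") as fh:
        for c in clusters.sorted_by_score():
            members = "\t".join(c.sorted_members())
            if with_score:
                fh.write(f"{c.score:.17g}\t{members}\n")
            else:
                fh.write(members + "\n")


def read_clusters(
    path: str, algorithm_name: str, score_prefix: bool = False
) -> ClusterSet:
    """Read a cluster file, assigning provenance ``{algorithm_name}``.

    With ``score_prefix`` the first column is the cluster score (density is
    left 0 for recomputation downstream); empty lines are skipped with a
    warning.  This is the adapter through which externally produced
    clusterings (RNSC, IPCA, HACO, ClusterONE, ...) enter the pipeline.
    """
    out = []
    prov = frozenset([algorithm_name])
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                logger.warning("%s:%d: empty line skipped", path, lineno)
                continue
            cols = [c for c in line.split("\t") if c]
            if score_prefix:
                try:
                    score = float(cols[0])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: unparsable score {cols[0]!r}"
                    ) from exc
                members = frozenset(cols[1:])
                out.append(
                    Cluster(members=members, density=0.0, score=score, provenance=prov)
                )
            else:
                members = frozenset(cols)
                out.append(
                    Cluster(members=members, density=0.0, score=0.0, provenance=prov)
                )
    return ClusterSet(out)
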