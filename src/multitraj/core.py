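"""Data model and I/O for multiplex gene networks, patient cohorts, and entity maps.

A multiplex (multilayer) network is a collection of named undirected layers
sharing one node universe; each layer encodes a distinct type of gene-gene
association (e.g. protein interaction, shared pathway, common targeting drug).
A cohort maps patient identifiers to sets of altered genes, optionally with
reference subgroup labels.  Entity maps attach named entities (drugs,
pathways, diseases, metabolites) to the gene sets they touch within a layer,
for link-enrichment analysis.

All on-disk formats are plain UTF-8 tab-separated text with a header row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger("multitraj")

__all__ = [
    "MultitrajError",
    "ParseError",
    "ValidationError",
    "MultiplexNetwork",
    "Cohort",
    "EntityMap",
    "load_multiplex",
    "write_multiplex",
    "load_cohort",
    "write_cohort",
    "load_entity_map",
    "write_entity_map",
    "restrict_to_network",
]


class MultitrajError(Exception):
    """Base class for all package errors."""


class ParseError(MultitrajError):
    """A file could not be parsed; carries the offending line number."""


class ValidationError(MultitrajError):
    """An object violates a structural invariant."""


def _pair(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered node pair (lexicographically sorted)."""
    return (u, v) if u <= v else (v, u)


@dataclass
class MultiplexNetwork:
    """A multiplex network: ordered node universe plus named undirected layers.

    ``layers`` maps a layer name to ``{(u, v): (weight, annotation)}`` where
    ``(u, v)`` is the sorted node pair, ``weight`` a positive float and
    ``annotation`` an optional entity label.  Invariants (no self-loops,
    endpoints within the node universe, unique pairs per layer) are enforced
    by :meth:`validate`, which the loader always calls.
    """

    nodes: tuple[str, ...]
    layers: dict[str, dict[tuple[str, str], tuple[float, str | None]]]

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self, layer: str) -> int:
        return len(self.layers[layer])

    def validate(self) -> None:
        universe = set(self.nodes)
        if len(universe) != len(self.nodes):
            raise ValidationError("duplicate node identifiers in node universe")
        for name, edges in self.layers.items():
            for (u, v), (w, _ann) in edges.items():
                if u == v:
                    raise ValidationError(f"self-loop {u!r} in layer {name!r}")
                if (u, v) != _pair(u, v):
                    raise ValidationError(f"non-canonical pair ({u!r}, {v!r}) in layer {name!r}")
                if u not in universe or v not in universe:
                    raise ValidationError(f"edge endpoint outside node universe in layer {name!r}: {u!r}-{v!r}")
                if w <= 0:
                    raise ValidationError(f"non-positive weight on {u!r}-{v!r} in layer {name!r}")

    def adjacency(self, layer: str, weighted: bool = False) -> dict[str, dict[str, float]]:
        """Adjacency mapping of one layer; unit weights unless ``weighted``."""
        adj: dict[str, dict[str, float]] = {}
        for (u, v), (w, _ann) in self.layers[layer].items():
            wt = w if weighted else 1.0
            adj.setdefault(u, {})[v] = wt
            adj.setdefault(v, {})[u] = wt
        return adj

    def degrees(self, layer: str, weighted: bool = False) -> dict[str, float]:
        """Per-node degree within one layer (0 for nodes absent from it)."""
        deg = {n: 0.0 for n in self.nodes}
        for (u, v), (w, _ann) in self.layers[layer].items():
            wt = w if weighted else 1.0
            deg[u] += wt
            deg[v] += wt
        return deg


@dataclass
class Cohort:
    """Patient -> altered gene set mapping, plus optional reference labels."""

    patients: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for pid, genes in self.patients.items():
            if not genes:
                raise ValidationError(f"patient {pid!r} has an empty gene set")
        for pid in self.labels:
            if pid not in self.patients:
                raise ValidationError(f"label refers to unknown patient {pid!r}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients)

    def labelled(self) -> "Cohort":
        """Sub-cohort of patients carrying a reference label."""
        return Cohort(
            {p: g for p, g in self.patients.items() if p in self.labels},
            dict(self.labels),
        )


@dataclass
class EntityMap:
    """(layer, entity) -> gene set mapping used by enrichment analysis."""

    entries: dict[str, dict[str, frozenset[str]]]

    def genes(self, layer: str, entity: str) -> frozenset[str]:
        return self.entries[layer][entity]

    def entities(self, layer: str) -> list[str]:
        return list(self.entries.get(layer, {}))

    def validate(self, net: MultiplexNetwork | None = None) -> None:
        if net is not None:
            universe = set(net.nodes)
            for layer, ents in self.entries.items():
                for entity, genes in ents.items():
                    extra = genes - universe
                    if extra:
                        raise ValidationError(
                            f"entity {entity!r} in layer {layer!r} references "
                            f"genes outside the node universe: {sorted(extra)[:5]}"
                        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_NETWORK_HEADER = ("layer", "source", "target", "weight", "annotation")


def load_multiplex(path: str | Path, nodes_path: str | Path | None = None) -> MultiplexNetwork:
    """Read a multiplex network from a long-format TSV edge list.

    Columns: ``layer, source, target[, weight[, annotation]]``.  A header row
    is detected and skipped.  Duplicate unordered pairs within a layer are
    collapsed with their weights summed; self-loops are dropped (counted in a
    warning).  The node universe is the union of all endpoints, optionally
    extended by a one-column node list file.
    """
    path = Path(path)
    layers: dict[str, dict[tuple[str, str], tuple[float, str | None]]] = {}
    order: dict[str, None] = {}
    n_loops = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if lineno == 1 and [c.lower() for c in cols[:3]] == list(_NETWORK_HEADER[:3]):
                continue
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns (layer, source, target), got {len(cols)}")
            layer, u, v = cols[0], cols[1], cols[2]
            if not layer or not u or not v:
                raise ParseError(f"{path}:{lineno}: empty field")
            weight = 1.0
            if len(cols) >= 4 and cols[3] != "":
                try:
                    weight = float(cols[3])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad weight {cols[3]!r}") from exc
            annotation = cols[4] if len(cols) >= 5 and cols[4] != "" else None
            if u == v:
                n_loops += 1
                continue
            order.setdefault(u)
            order.setdefault(v)
            key = _pair(u, v)
            edges = layers.setdefault(layer, {})
            if key in edges:
                w0, ann0 = edges[key]
                edges[key] = (w0 + weight, ann0 if ann0 is not None else annotation)
            else:
                edges[key] = (weight, annotation)
    if n_loops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_loops)
    if nodes_path is not None:
        with open(nodes_path, encoding="utf-8") as fh:
            for raw in fh:
                name = raw.strip()
                if name and name.lower() != "node":
                    order.setdefault(name)
    net = MultiplexNetwork(tuple(order), layers)
    net.validate()
    return net


def write_multiplex(net: MultiplexNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_NETWORK_HEADER) + "\n")
        for layer, edges in net.layers.items():
            for (u, v), (w, ann) in sorted(edges.items()):
                fh.write(f"{layer}\t{u}\t{v}\t{w:g}\t{ann if ann is not None else ''}\n")


def load_cohort(
    genes_path: str | Path,
    labels_path: str | Path | None = None,
    net: MultiplexNetwork | None = None,
) -> Cohort:
    """Read a cohort from a long TSV (patient, gene) or a JSON mapping.

    If ``net`` is supplied, the count of each patient's genes absent from the
    network's node universe is logged (the cohort itself is not restricted;
    use :func:`restrict_to_network` for that).
    """
    genes_path = Path(genes_path)
    patients: dict[str, set[str]] = {}
    if genes_path.suffix.lower() == ".json":
        with open(genes_path, encoding="utf-8") as fh:
            mapping = json.load(fh)
        if not isinstance(mapping, dict):
            raise ParseError(f"{genes_path}: expected a JSON object mapping patient -> gene list")
        for pid, genes in mapping.items():
            patients[str(pid)] = {str(g) for g in genes}
    else:
        with open(genes_path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                cols = line.split("\t")
                if lineno == 1 and cols[0].lower() in ("patient", "patient_id"):
                    continue
                if len(cols) < 2:
                    raise ParseError(f"{genes_path}:{lineno}: expected 2 columns (patient, gene)")
                patients.setdefault(cols[0], set()).add(cols[1])
    labels: dict[str, str] = {}
    if labels_path is not None:
        with open(labels_path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                cols = line.replace(",", "\t").split("\t")
                if lineno == 1 and cols[0].lower() in ("patient", "patient_id"):
                    continue
                if len(cols) < 2:
                    raise ParseError(f"{labels_path}:{lineno}: expected 2 columns (patient, subgroup)")
                labels[cols[0]] = cols[1]
    cohort = Cohort({p: frozenset(g) for p, g in patients.items()}, labels)
    cohort.validate()
    if net is not None:
        universe = set(net.nodes)
        for pid, genes in cohort.patients.items():
            missing = len(genes - universe)
            if missing:
                logger.info("patient %s: %d of %d genes absent from the network", pid, missing, len(genes))
    return cohort


def write_cohort(cohort: Cohort, genes_path: str | Path, labels_path: str | Path | None = None) -> None:
    with open(genes_path, "w", encoding="utf-8") as fh:
        fh.write("patient\tgene\n")
        for pid, genes in cohort.patients.items():
            for g in sorted(genes):
                fh.write(f"{pid}\t{g}\n")
    if labels_path is not None:
        with open(labels_path, "w", encoding="utf-8") as fh:
            fh.write("patient,subgroup\n")
            for pid, lab in cohort.labels.items():
                fh.write(f"{pid},{lab}\n")


def load_entity_map(path: str | Path) -> EntityMap:
    """Read a (layer, entity, gene) long TSV into an :class:`EntityMap`."""
    entries: dict[str, dict[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if lineno == 1 and cols[0].lower() == "layer":
                continue
            if len(cols) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns (layer, entity, gene)")
            entries.setdefault(cols[0], {}).setdefault(cols[1], set()).add(cols[2])
    return EntityMap({lay: {e: frozenset(g) for e, g in ents.items()} for lay, ents in entries.items()})


def write_entity_map(emap: EntityMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("layer\tentity\tgene\n")
        for layer, ents in emap.entries.items():
            for entity, genes in ents.items():
                for g in sorted(genes):
                    fh.write(f"{layer}\t{entity}\t{g}\n")


def restrict_to_network(cohort: Cohort, net: MultiplexNetwork) -> Cohort:
    """Intersect every patient's gene set with the network's node universe.

    Raises :class:`ValidationError` naming the first patient whose gene set
    becomes empty.  Idempotent.
    """
    universe = set(net.nodes)
    restricted: dict[str, frozenset[str]] = {}
    for pid, genes in cohort.patients.items():
        kept = frozenset(genes & universe)
        dropped = len(genes) - len(kept)
        if dropped:
            logger.info("patient %s: dropped %d gene(s) absent from the network", pid, dropped)
        if not kept:
            raise ValidationError(f"patient {pid!r} has no genes left after restriction to the network")
        restricted[pid] = kept
    return Cohort(restricted, dict(cohort.labels))
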