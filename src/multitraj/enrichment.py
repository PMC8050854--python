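"""Link enrichment between minimal gene sets and layer entities (NEAT-style).

Given two gene sets A and B and one network layer with m edges, the test
asks whether the number of layer edges running between A and B exceeds what
their degrees predict.  Writing dA and dB for the summed layer degrees of A
and B, the null model follows the network enrichment analysis test: the
observed cross-link count n_AB is compared with a hypergeometric variable
X ~ Hypergeom(population 2m endpoint slots, dB successes, dA draws), whose
mean is mu_AB = dA * dB / (2m).  The reported p value is the upper tail
P(X >= n_AB) — overrepresentation only.

In the pipeline, A is a patient's selected minimal gene set and B the gene
set of a named entity (a drug's targets, a pathway's members, a disease's
variant genes, a metabolite's reaction genes) tested within the matching
layer.  p values are Benjamini-Hochberg adjusted per patient and layer
across entities; an entity is a cluster's *consensus* hit when adjusted
p <= alpha in every patient of the cluster, and *unique* when consensus in
that cluster only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import EntityMap, MultiplexNetwork, ValidationError

logger = logging.getLogger("multitraj")

__all__ = [
    "EnrichmentRecord",
    "neat_test",
    "bh_adjust",
    "patient_enrichment",
    "consensus_enrichment",
]


@dataclass
class EnrichmentRecord:
    layer: str
    entity: str
    patient: str
    n_ab: int
    mu_ab: float
    p: float
    p_adj: float | None = None


def neat_test(
    net: MultiplexNetwork,
    layer: str,
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    strict_overlap: bool = False,
) -> tuple[int, float, float]:
    """Network enrichment test of A-B cross-links in one layer.

    Returns (n_AB, mu_AB, p).  Overlapping sets are handled by replacing B
    with B \\ A (with a warning), or rejected in ``strict_overlap`` mode.
    Raises when either set has zero summed degree in the layer (the
    hypergeometric draw would be undefined).
    """
    if layer not in net.layers:
        raise ValidationError(f"unknown layer {layer!r}")
    edges = net.layers[layer]
    m = len(edges)
    if m < 1:
        raise ValidationError(f"layer {layer!r} has no edges")
    universe = set(net.nodes)
    a = set(set_a) & universe
    b = set(set_b) & universe
    if not a or not b:
        raise ValidationError("a gene set is empty after restriction to the node universe")
    if a & b:
        if strict_overlap:
            raise ValidationError("gene sets overlap (strict mode)")
        logger.warning("A and B overlap on %d gene(s); testing B \\ A", len(a & b))
        b = b - a
        if not b:
            raise ValidationError("B is empty after removing its overlap with A")
    deg = net.degrees(layer)
    d_a = int(sum(deg[g] for g in a))
    d_b = int(sum(deg[g] for g in b))
    if d_a == 0 or d_b == 0:
        raise ValidationError("a gene set has zero degree in this layer")
    n_ab = sum(1 for (u, v) in edges if (u in a and v in b) or (u in b and v in a))
    mu = d_a * d_b / (2.0 * m)
    # upper tail P(X >= n_AB), inclusive
    p = float(hypergeom.sf(n_ab - 1, 2 * m, d_b, d_a))
    return n_ab, mu, min(max(p, 0.0), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    if any(not (0.0 < p <= 1.0) for p in pvalues):
        raise ValidationError("p values must lie in (0, 1]")
    _rej, adj, *_ = multipletests(pvalues, method="fdr_bh")
    return [float(q) for q in adj]


def patient_enrichment(
    net: MultiplexNetwork,
    emap: EntityMap,
    selected_sets: Mapping[str, frozenset[str]],
    layers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """NEAT test of every patient's minimal set against every layer entity.

    Entities whose test is undefined for a patient (zero degree, empty
    difference) are skipped.  BH adjustment is applied per patient per layer
    across the entities actually tested.  Returns a long DataFrame with
    columns patient, layer, entity, n_ab, mu_ab, p, p_adj.
    """
    rows: list[EnrichmentRecord] = []
    layer_list = list(layers) if layers is not None else net.layer_names
    for pid in sorted(selected_sets):
        sel = selected_sets[pid]
        if not sel:
            continue
        for layer in layer_list:
            batch: list[EnrichmentRecord] = []
            for entity in sorted(emap.entities(layer)):
                try:
                    n_ab, mu, p = neat_test(net, layer, sel, emap.genes(layer, entity))
                except ValidationError:
                    continue
                batch.append(EnrichmentRecord(layer, entity, pid, n_ab, mu, p))
            if batch:
                for rec, q in zip(batch, bh_adjust([r.p for r in batch])):
                    rec.p_adj = q
                rows.extend(batch)
    return pd.DataFrame(
        [
            {"patient": r.patient, "layer": r.layer, "entity": r.entity,
             "n_ab": r.n_ab, "mu_ab": r.mu_ab, "p": r.p, "p_adj": r.p_adj}
            for r in rows
        ],
        columns=["patient", "layer", "entity", "n_ab", "mu_ab", "p", "p_adj"],
    )


def consensus_enrichment(
    records: pd.DataFrame,
    clusters: Mapping[str, int],
    alpha: float = 0.05,
) -> dict[int, dict[str, list[tuple[str, str]]]]:
    """Per-cluster consensus and unique (layer, entity) enrichments.

    An entity is CONSENSUS in a cluster iff its adjusted p <= alpha for
    every patient of the cluster (within one layer); it is UNIQUE iff it is
    consensus there and in no other cluster.  Returns
    {cluster: {"consensus": [...], "unique": [...]}} with (layer, entity)
    pairs.
    """
    cluster_ids = sorted(set(clusters.values()))
    patients_of = {c: sorted(p for p, cc in clusters.items() if cc == c) for c in cluster_ids}
    for c, pats in patients_of.items():
        if not pats:
            raise ValidationError(f"cluster {c} has no patients")
    consensus: dict[int, set[tuple[str, str]]] = {}
    for c, pats in patients_of.items():
        hits: set[tuple[str, str]] | None = None
        for pid in pats:
            sub = records[(records["patient"] == pid) & (records["p_adj"] <= alpha)]
            patient_hits = set(zip(sub["layer"], sub["entity"]))
            hits = patient_hits if hits is None else (hits & patient_hits)
        consensus[c] = hits or set()
    out: dict[int, dict[str, list[tuple[str, str]]]] = {}
    for c in cluster_ids:
        elsewhere = set().union(*[consensus[o] for o in cluster_ids if o != c]) if len(cluster_ids) > 1 else set()
        out[c] = {
            "consensus": sorted(consensus[c]),
            "unique": sorted(consensus[c] - elsewhere),
        }
    return out
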