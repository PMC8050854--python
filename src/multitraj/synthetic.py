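"""Planted-structure multiplex networks and synthetic patient cohorts.

The network generator plants two nested community scales: coarse modules,
each split into fine submodules.  Per layer, each node pair receives an edge
independently with probability p_fine (same submodule), p_coarse (same
module, different submodules) or p_background (different modules).  Layer
heterogeneity is created by *dropout*: per layer, each submodule is silenced
with a given probability, downgrading its internal edge probability from
p_fine to p_coarse in that layer only.

The cohort generator assigns each subgroup a disjoint set of signature
submodules; a patient's altered genes are its subgroup's signature genes
(each kept with probability 1 - signature_dropout) plus a fixed number of
background genes drawn uniformly from the non-signature genes.  Patients of
the same subgroup therefore share most of their signature, while background
genes overlap only by chance — the planted analogue of subgroup-specific
alteration profiles over a noisy mutational background.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np

from .core import Cohort, MultiplexNetwork, ValidationError

__all__ = [
    "PlantedTruth",
    "simulate_multiplex",
    "simulate_cohort",
    "default_scenario",
    "write_truth",
]


@dataclass
class PlantedTruth:
    """Ground truth of a planted multiplex: nested assignments and parameters."""

    genes: list[str]
    module_of: dict[str, int]
    submodule_of: dict[str, int]  # globally numbered fine submodules
    signature_submodules: dict[str, list[int]]  # subgroup -> submodule ids
    params: dict

    def submodule_members(self, sub: int) -> list[str]:
        return [g for g in self.genes if self.submodule_of[g] == sub]

    def module_assignment(self) -> dict[str, int]:
        return dict(self.module_of)

    def submodule_assignment(self) -> dict[str, int]:
        return dict(self.submodule_of)


def simulate_multiplex(
    n_genes: int = 300,
    n_modules: int = 4,
    submodules_per_module: int = 3,
    n_layers: int = 3,
    p_fine: float = 0.9,
    p_coarse: float = 0.05,
    p_background: float = 0.005,
    layer_dropout: float = 0.1,
    seed: int = 0,
) -> tuple[MultiplexNetwork, PlantedTruth]:
    """Sample a multiplex network with planted nested (multiscale) communities.

    Requires p_fine > p_coarse > p_background >= 0.  Deterministic given
    ``seed``.  Gene names are g000, g001, ...; genes are dealt round-free
    into contiguous modules and submodules of (near-)equal size.
    """
    for p in (p_fine, p_coarse, p_background, layer_dropout):
        if not 0.0 <= p <= 1.0:
            raise ValidationError("probabilities must lie in [0, 1]")
    if not (p_fine > p_coarse > p_background >= 0):
        raise ValidationError("need p_fine > p_coarse > p_background >= 0")
    if n_layers < 1:
        raise ValidationError("need at least one layer")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_genes - 1)))
    genes = [f"g{i:0{width}d}" for i in range(n_genes)]
    n_sub = n_modules * submodules_per_module
    # contiguous near-equal blocks
    sub_bounds = np.linspace(0, n_genes, n_sub + 1).astype(int)
    submodule_of = {}
    module_of = {}
    for s in range(n_sub):
        for i in range(sub_bounds[s], sub_bounds[s + 1]):
            submodule_of[genes[i]] = s
            module_of[genes[i]] = s // submodules_per_module
    sub_idx = np.array([submodule_of[g] for g in genes])
    mod_idx = np.array([module_of[g] for g in genes])

    iu, ju = np.triu_indices(n_genes, k=1)
    same_sub = sub_idx[iu] == sub_idx[ju]
    same_mod = mod_idx[iu] == mod_idx[ju]
    layers: dict[str, dict[tuple[str, str], tuple[float, str | None]]] = {}
    for ell in range(n_layers):
        silenced = rng.random(n_sub) < layer_dropout
        pair_sub = np.where(same_sub, sub_idx[iu], -1)
        p_pair = np.full(len(iu), p_background)
        p_pair[same_mod & ~same_sub] = p_coarse
        fine_mask = same_sub & ~silenced[np.maximum(pair_sub, 0)]
        downgraded = same_sub & silenced[np.maximum(pair_sub, 0)]
        p_pair[fine_mask] = p_fine
        p_pair[downgraded] = p_coarse
        keep = rng.random(len(iu)) < p_pair
        edges: dict[tuple[str, str], tuple[float, str | None]] = {}
        for a, b in zip(iu[keep], ju[keep]):
            edges[(genes[a], genes[b])] = (1.0, None)
        layers[f"layer{ell + 1}"] = edges
    net = MultiplexNetwork(tuple(genes), layers)
    net.validate()
    truth = PlantedTruth(
        genes,
        module_of,
        submodule_of,
        {},
        {
            "n_genes": n_genes,
            "n_modules": n_modules,
            "submodules_per_module": submodules_per_module,
            "n_layers": n_layers,
            "p_fine": p_fine,
            "p_coarse": p_coarse,
            "p_background": p_background,
            "layer_dropout": layer_dropout,
            "seed": seed,
        },
    )
    return net, truth


def simulate_cohort(
    truth: PlantedTruth,
    subgroups: int = 4,
    patients_per_subgroup: int = 8,
    signature_submodules_per_subgroup: int = 2,
    signature_dropout: float = 0.1,
    n_background_genes: int = 40,
    seed: int = 0,
) -> Cohort:
    """Sample a labelled cohort whose subgroups carry planted gene signatures.

    Signature submodules are assigned to subgroups disjointly (subgroup s
    takes the first free submodules in id order, spread across distinct
    coarse modules when possible).  Patient ids are P<subgroup>_<index>;
    labels are S1..S<subgroups>.
    """
    if not 0.0 <= signature_dropout <= 1.0:
        raise ValidationError("signature_dropout must lie in [0, 1]")
    n_sub = truth.params["n_modules"] * truth.params["submodules_per_module"]
    need = subgroups * signature_submodules_per_subgroup
    if need > n_sub:
        raise ValidationError(
            f"{need} signature submodules requested but only {n_sub} exist"
        )
    if signature_dropout >= 1.0 and n_background_genes == 0:
        raise ValidationError("full signature dropout with no background genes would empty every patient")
    rng = np.random.default_rng(seed)
    # spread signatures across coarse modules: order submodules by (rank within
    # module, module) so consecutive picks hit different modules first
    spm = truth.params["submodules_per_module"]
    order = sorted(range(n_sub), key=lambda s: (s % spm, s // spm))
    signature: dict[str, list[int]] = {}
    cursor = 0
    for s in range(subgroups):
        name = f"S{s + 1}"
        signature[name] = sorted(order[cursor : cursor + signature_submodules_per_subgroup])
        cursor += signature_submodules_per_subgroup
    truth.signature_submodules = signature
    signature_genes = {
        name: [g for g in truth.genes if truth.submodule_of[g] in subs]
        for name, subs in signature.items()
    }
    all_signature = {g for genes in signature_genes.values() for g in genes}
    background_pool = [g for g in truth.genes if g not in all_signature]
    patients: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    for name in signature:
        for i in range(patients_per_subgroup):
            pid = f"P{name[1:]}_{i + 1:02d}"
            kept = [g for g in signature_genes[name] if rng.random() >= signature_dropout]
            n_bg = min(n_background_genes, len(background_pool))
            bg = rng.choice(len(background_pool), size=n_bg, replace=False) if n_bg else []
            genes = frozenset(kept) | frozenset(background_pool[j] for j in bg)
            if not genes:
                raise ValidationError(f"patient {pid} came out empty; lower signature_dropout or add background genes")
            patients[pid] = genes
            labels[pid] = name
    cohort = Cohort(patients, labels)
    cohort.validate()
    return cohort


def default_scenario(seed: int = 0) -> tuple[MultiplexNetwork, PlantedTruth, Cohort]:
    """The package's reference synthetic study: 300 genes in 4 modules x 3
    submodules over 3 layers, and 4 subgroups x 8 patients with submodule
    signatures, 10% dropout and 40 background genes per patient."""
    net, truth = simulate_multiplex(seed=seed)
    cohort = simulate_cohort(truth, seed=seed + 1)
    return net, truth, cohort


def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "params": truth.params,
        "module_of": truth.module_of,
        "submodule_of": truth.submodule_of,
        "signature_submodules": truth.signature_submodules,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
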