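"""Synthetic study inputs: birth-death trees and random threat categories.

The comparison study runs on homogeneous birth-death phylogenies: every
extant lineage speciates at rate ``birth`` and goes extinct at rate ``death``,
both constant through time.  The study conditions are birth rate 0.5 with
death rates {0, 0.125, 0.25, 0.4} and tip counts {50, 100, 250, 500}, 1000
replicates per condition.

Simulation is forward in continuous time starting from two crown lineages.
The clock stops the first time the extant lineage count reaches the target,
plus one further exponential waiting time (truncating just before the next
event would fire), so pendant edges are never zero.  Extinct lineages are
pruned and unifurcations suppressed, leaving an ultrametric tree on exactly
``n_tips`` extant tips.  Whole-tree extinction triggers a fresh attempt, up
to a retry cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "BDConfig",
    "THREAT_CATEGORIES",
    "simulate_bd_tree",
    "simulate_bd_set",
    "simulate_threat_categories",
]

#: IUCN-style threat categories, least to most threatened.
THREAT_CATEGORIES: tuple[str, ...] = ("LC", "NT", "VU", "EN", "CR")


@dataclass
class BDConfig:
    """Birth-death simulation condition.

    Rates are events per lineage per unit time; ``death < birth`` is required
    for the simulation to reach the target tip count in practice.
    """

    n_tips: int = 100
    birth: float = 0.5
    death: float = 0.0
    seed: int | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if not self.birth > 0:
            raise ValueError("birth rate must be positive")
        if not (0 <= self.death < self.birth):
            raise ValueError("death rate must satisfy 0 <= death < birth")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")


def _one_attempt(n_tips: int, birth: float, death: float, rng: np.random.Generator):
    """One forward pass; returns (parent, t_start, t_end, extant) or None."""
    parent = [-1, -1]
    t_start = [0.0, 0.0]
    t_end = [np.nan, np.nan]
    alive = [0, 1]
    t = 0.0
    rate_per = birth + death
    while True:
        k = len(alive)
        if k == 0:
            return None
        t += rng.exponential(1.0 / (rate_per * k))
        if k >= n_tips:
            break  # target reached at the previous event; truncate here
        j = alive[rng.integers(k)]
        if rng.random() < birth / rate_per:
            t_end[j] = t
            for _ in range(2):
                parent.append(j)
                t_start.append(t)
                t_end.append(np.nan)
            alive.remove(j)
            alive.extend([len(parent) - 2, len(parent) - 1])
        else:
            t_end[j] = t
            alive.remove(j)
    for j in alive:
        t_end[j] = t
    return parent, t_start, t_end, set(alive)


def _prune_to_tree(parent, t_start, t_end, extant) -> PhyloTree:
    """Drop extinct lineages, suppress unifurcations, build a PhyloTree."""
    m = len(parent)
    children: list[list[int]] = [[] for _ in range(m)]
    roots = []
    for v in range(m):
        if parent[v] == -1:
            roots.append(v)
        else:
            children[parent[v]].append(v)
    keep = [False] * m
    for v in range(m - 1, -1, -1):  # children have larger ids than parents
        if v in extant:
            keep[v] = True
        else:
            keep[v] = any(keep[c] for c in children[v])
    # (node, accumulated extra length) in new postorder
    new_parent: list[int] = []
    new_length: list[float] = []
    labels: dict[int, str] = {}
    tip_counter = 0

    def build(v: int, extra: float) -> tuple[list, float]:
        """Collapse v (kept) to a (children_built, length) nested structure."""
        while True:
            kept = [c for c in children[v] if keep[c]]
            if v in extant:
                return ([], t_end[v] - t_start[v] + extra), v
            if len(kept) == 1:
                extra += t_end[v] - t_start[v]
                v = kept[0]
            else:
                built = [build(c, 0.0) for c in kept]
                return (built, t_end[v] - t_start[v] + extra), v

    # root handling: find surviving crown
    surv_roots = [r for r in roots if keep[r]]
    if not surv_roots:
        raise RuntimeError("no surviving lineage")

    def assemble(structure, orig) -> int:
        """Emit nested structure into postorder arrays; return new id."""
        nonlocal tip_counter
        (kids, length), v = structure, orig
        ids = [assemble(child_struct, child_orig) for child_struct, child_orig in kids]
        new_id = len(new_parent)
        new_parent.append(-1)
        new_length.append(length)
        for cid in ids:
            new_parent[cid] = new_id
        if not kids:
            labels[new_id] = f"t{tip_counter + 1}"
            tip_counter += 1
        return new_id

    if len(surv_roots) == 2:
        s1, v1 = build(surv_roots[0], 0.0)
        s2, v2 = build(surv_roots[1], 0.0)
        i1 = assemble(s1, v1)
        i2 = assemble(s2, v2)
        root_id = len(new_parent)
        new_parent.append(-1)
        new_length.append(0.0)
        new_parent[i1] = root_id
        new_parent[i2] = root_id
    else:
        # one crown lineage survived: its subtree root becomes the tree root
        s1, v1 = build(surv_roots[0], 0.0)
        rid = assemble(s1, v1)
        new_length[rid] = 0.0
    parent_arr = np.array(new_parent, dtype=np.int64)
    # reindex so postorder property (child < parent, root last) holds
    return _reindex_postorder(parent_arr, np.array(new_length), labels)


def _reindex_postorder(parent: np.ndarray, length: np.ndarray, labels: dict[int, str]) -> PhyloTree:
    m = parent.size
    children: list[list[int]] = [[] for _ in range(m)]
    root = -1
    for v in range(m):
        if parent[v] == -1:
            root = v
        else:
            children[parent[v]].append(v)
    order: list[int] = []
    stack: list[tuple[int, bool]] = [(root, False)]
    while stack:
        v, done = stack.pop()
        if done:
            order.append(v)
        else:
            stack.append((v, True))
            stack.extend((c, False) for c in children[v])
    remap = {old: new for new, old in enumerate(order)}
    new_parent = np.full(m, -1, dtype=np.int64)
    new_length = np.zeros(m)
    new_labels: dict[int, str] = {}
    for old in order:
        new = remap[old]
        if parent[old] != -1:
            new_parent[new] = remap[parent[old]]
            new_length[new] = length[old]
        if old in labels:
            new_labels[new] = labels[old]
    return PhyloTree(new_parent, new_length, new_labels)


def simulate_bd_tree(
    config: BDConfig | None = None,
    rng: np.random.Generator | None = None,
    max_retries: int = 1000,
    **kwargs,
) -> PhyloTree:
    """Simulate one ultrametric birth-death tree with exactly ``n_tips`` tips.

    Reproducible: ``BDConfig.seed`` (or an explicit ``rng``) fully determines
    the output newick string.  Raises ``RuntimeError`` if every attempt ends
    in whole-tree extinction.
    """
    if config is None:
        config = BDConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a BDConfig or keyword fields, not both")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for _ in range(max_retries):
        res = _one_attempt(config.n_tips, config.birth, config.death, rng)
        if res is None:
            continue
        tree = _prune_to_tree(*res)
        if tree.n_tips == config.n_tips:
            return tree
    raise RuntimeError(
        f"birth-death simulation failed {max_retries} times "
        f"(birth={config.birth}, death={config.death})"
    )


def simulate_bd_set(config: BDConfig, rng: np.random.Generator | None = None) -> list[PhyloTree]:
    """A replicate set of trees under one condition, from one seeded stream."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return [simulate_bd_tree(config, rng=rng) for _ in range(config.replicates)]


def simulate_threat_categories(
    species: list[str],
    seed: int | np.random.Generator | None = None,
    probabilities: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Random IUCN-style categories for a species list (EDGE exercises).

    Categories LC..CR are drawn independently per species, uniformly unless
    ``probabilities`` (summing to 1, in category order) is given.  Stands in
    for real red-list data, which carries phylogenetic signal this generator
    does not emulate.
    """
    if not species:
        raise ValueError("species list must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if probabilities is None:
        probabilities = (0.2,) * 5
    p = np.asarray(probabilities, dtype=float)
    if p.size != 5 or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("probabilities must be 5 non-negative values summing to 1")
    cats = rng.choice(len(THREAT_CATEGORIES), size=len(species), p=p)
    return pd.DataFrame(
        {"species": list(species), "category": [THREAT_CATEGORIES[c] for c in cats]}
    )
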