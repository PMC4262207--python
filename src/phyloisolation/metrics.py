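"""The eleven species-level evolutionary-isolation metrics.

Each metric maps a rooted (usually ultrametric) phylogeny to one non-negative
score per tip.  The canonical set used throughout the comparison study is

====== =======================================================================
PE     pendant edge length (the "uniqueness" end of the spectrum)
ED     fair proportion / evolutionary distinctiveness (alias ``FP``)
SV     Shapley value of the unrooted spanning-length game
ES     equal splits
VW     Vane-Wright node count (reciprocal)
MVW    May's modification: reciprocal of summed daughter-lineage counts
NWU    Nixon-Wheeler unweighted (binary larger-than-sister marks)
NWW    Nixon-Wheeler weighted (descendant counts along the root path)
APD    average pairwise (patristic) distance — the "originality" end
QE     weights maximising Rao's quadratic entropy
CHR    expected rarity of inherited novel characters
====== =======================================================================

Scores in branch-length units: PE, ED, SV, ES, APD (and the APD/PD variant is
dimensionless); the node-count metrics and QE/CHR are dimensionless.

Conventions that the original descriptions leave open are documented on each
function; see also the package methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import PhyloTree, warn_if_not_ultrametric

__all__ = [
    "CANONICAL_METRICS",
    "ChrParams",
    "resolve_metric",
    "pendant_edge",
    "fair_proportion",
    "equal_splits",
    "shapley_value",
    "shapley_bruteforce_oracle",
    "vane_wright",
    "may_vane_wright",
    "nixon_wheeler_unweighted",
    "nixon_wheeler_weighted",
    "average_pairwise_distance",
    "qe_index",
    "character_rarity",
    "compute_all",
]

#: Canonical metric order used in every score table and distance matrix.
CANONICAL_METRICS: tuple[str, ...] = (
    "PE", "ED", "SV", "ES", "VW", "MVW", "NWU", "NWW", "APD", "QE", "CHR",
)

_ALIASES = {"FP": "ED", "APD/PD": "APDPD"}


def resolve_metric(name: str) -> str:
    """Canonical metric id for ``name`` (``FP`` is an alias of ``ED``)."""
    key = name.upper()
    key = _ALIASES.get(key, key)
    if key not in CANONICAL_METRICS + ("APDPD",):
        raise KeyError(f"unknown metric {name!r}")
    return key


@dataclass(frozen=True)
class ChrParams:
    """Parameters of the character-rarity expectation.

    nu
        Origination rate of novel characters per unit branch length (> 0).
    rho
        Per-edge retention probability of a character (0 < rho <= 1); at
        ``rho = 1`` every character survives and rarity reduces to the
        fraction of the tree's species outside the clade it arose above.

    ``nu`` is a pure scale factor (standardisation removes it); the default
    ``rho`` is calibrated so the score shows its documented near-redundancy
    with average pairwise distance on birth-death trees (rank correlation
    above 0.95, normalised inter-metric distance about 0.12).
    """

    nu: float = 1.0
    rho: float = 0.995

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError("nu must be positive")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")


# --------------------------------------------------------------------------
# branch-length sharing metrics


def pendant_edge(tree: PhyloTree) -> np.ndarray:
    """Length of each tip's terminal branch."""
    return tree.length[tree.tip_ids].astype(float)


def fair_proportion(tree: PhyloTree) -> np.ndarray:
    """Fair proportion / evolutionary distinctiveness.

    Each edge's length is split equally among the tips that descend from it;
    a tip's score sums its shares along the root path.  Summed over tips this
    partitions the total tree length (PD).
    """
    share = tree.length / tree.ntips_below
    acc = tree.accumulate_down(share)
    return acc[tree.tip_ids]


def equal_splits(tree: PhyloTree) -> np.ndarray:
    """Equal splits: edge credit divides by daughter count at every node.

    Walking from the root towards tip *i*, the credit carried through an
    interior node is split equally among its daughter lineages, so an edge
    *n* bifurcating nodes above the tip contributes ``l_e * 0.5**n``.
    """
    s = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes - 2, -1, -1):
        p = tree.parent[v]
        s[v] = s[p] / len(tree.children[p]) + tree.length[v]
    return s[tree.tip_ids]


def _sv_edge_lengths(tree: PhyloTree) -> np.ndarray:
    """Edge lengths for the unrooted game: a bifurcating root's two edges merge."""
    length = tree.length.copy()
    kids = tree.children[tree.root]
    if len(kids) == 2:
        c1, c2 = kids
        length[c1] = length[c1] + length[c2]
        length[c2] = 0.0
    return length


def shapley_value(tree: PhyloTree) -> np.ndarray:
    """Shapley value of the spanning-length coalition game (closed form).

    The game is played on the unrooted tree (a bifurcating root is
    suppressed): a coalition's worth is the length of the minimal subtree
    connecting its members, and a tip's score is its expected marginal
    contribution over random arrival orders, equivalently

        SV(i) = sum_e  l_e * (N - a_e) / (N * a_e),

    with ``a_e`` the number of tips on *i*'s side of edge ``e``.  Scores sum
    to the total unrooted tree length (Shapley efficiency).
    """
    n = tree.n_tips
    length = _sv_edge_lengths(tree)
    ntips = tree.ntips_below.astype(float)
    # below-path term: edges with i underneath, a_e = n_e
    below = length * (n - ntips) / (n * ntips)
    below[tree.root] = 0.0
    # off-path term: a_e = n - n_e
    off = np.where(ntips < n, length * ntips / (n * np.maximum(n - ntips, 1)), 0.0)
    off[tree.root] = 0.0
    acc_below = tree.accumulate_down(below)
    acc_off = tree.accumulate_down(off)
    total_off = off.sum()
    return acc_below[tree.tip_ids] + (total_off - acc_off[tree.tip_ids])


def shapley_bruteforce_oracle(tree: PhyloTree, max_tips: int = 10) -> np.ndarray:
    """Exact Shapley value by subset enumeration (small trees only).

    Enumerates every coalition of tips and applies the combinatorial Shapley
    weights to the marginal spanning-length contributions.  Exponential in the
    number of tips, hence refused above ``max_tips``; exists purely as an
    independent check of :func:`shapley_value`.
    """
    n = tree.n_tips
    if n > max_tips:
        raise ValueError(f"brute-force Shapley limited to {max_tips} tips (got {n})")
    # bitmask of tips below each non-root node, positions in tip order
    masks = np.zeros(tree.n_nodes, dtype=np.int64)
    for v in range(tree.n_nodes):
        if not tree.children[v]:
            masks[v] = 1 << tree._tip_pos[v]
        else:
            for c in tree.children[v]:
                masks[v] |= masks[c]
    full = (1 << n) - 1
    edges = [(int(masks[v]), tree.length[v]) for v in range(tree.n_nodes - 1)]

    def worth(s: int) -> float:
        return sum(l for m, l in edges if (s & m) and (s & ~m & full))

    v_of = np.array([worth(s) for s in range(1 << n)])
    fact = [math.factorial(k) for k in range(n + 1)]
    out = np.zeros(n)
    for i in range(n):
        bit = 1 << i
        for s in range(1 << n):
            if s & bit:
                continue
            k = bin(s).count("1")
            w = fact[k] * fact[n - k - 1] / fact[n]
            out[i] += w * (v_of[s | bit] - v_of[s])
    return out


# --------------------------------------------------------------------------
# node-count metrics


def vane_wright(tree: PhyloTree) -> np.ndarray:
    """Reciprocal of the number of interior nodes on the root path.

    The root is counted and the tip itself is not, so the divisor is at
    least 1 and a tip hanging directly off the root scores 1.
    """
    return 1.0 / tree.n_ancestors[tree.tip_ids]


def may_vane_wright(tree: PhyloTree) -> np.ndarray:
    """Reciprocal of the summed daughter-lineage counts over root-path nodes.

    Counts the same nodes as :func:`vane_wright` but weighs each by its
    number of daughters; on a strictly bifurcating tree this is exactly
    ``VW / 2``.
    """
    s = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes - 2, -1, -1):
        p = tree.parent[v]
        s[v] = s[p] + len(tree.children[p])
    return 1.0 / s[tree.tip_ids]


def nixon_wheeler_unweighted(tree: PhyloTree) -> np.ndarray:
    """Nixon-Wheeler unweighted index.

    Walking from the tip to (but excluding) the root, each visited node's
    clade receives a mark of 1 when it holds strictly more tips than every
    sister clade; the score is ``1 / (1 + total marks)``, so a maximally
    isolated tip (never the larger side) scores 1.
    """
    ntips = tree.ntips_below
    b = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes - 1):
        sibs = [c for c in tree.children[tree.parent[v]] if c != v]
        if sibs and all(ntips[v] > ntips[s] for s in sibs):
            b[v] = 1.0
    acc = tree.accumulate_down(b)
    return 1.0 / (1.0 + acc[tree.tip_ids])


def nixon_wheeler_weighted(tree: PhyloTree) -> np.ndarray:
    """Nixon-Wheeler weighted index: reciprocal of summed descendant counts.

    Interior nodes on the root path (root included, tip excluded) contribute
    their total number of descendant tips; including the tip itself would
    merely add 1 everywhere.
    """
    ntips = tree.ntips_below
    s = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes - 2, -1, -1):
        p = tree.parent[v]
        s[v] = s[p] + ntips[p]
    return 1.0 / s[tree.tip_ids]


# --------------------------------------------------------------------------
# distance-based metrics


def average_pairwise_distance(tree: PhyloTree, standardise_by_pd: bool = False) -> np.ndarray:
    """Mean patristic distance from each tip to all other tips.

    With ``standardise_by_pd`` the mean distance is divided by the total tree
    length, which makes the score comparable across clades of different size
    (the APD/PD variant).
    """
    n = tree.n_tips
    if n < 2:
        raise ValueError("APD needs at least two tips")
    length = tree.length
    ntips = tree.ntips_below.astype(float)
    # sum_j d_ij = sum_e l_e n_e + sum_{e on path(i)} l_e (N - 2 n_e)
    base = float((length * ntips)[: tree.n_nodes - 1].sum())
    corr = length * (n - 2.0 * ntips)
    corr[tree.root] = 0.0
    acc = tree.accumulate_down(corr)
    apd = (base + acc[tree.tip_ids]) / (n - 1)
    if standardise_by_pd:
        apd = apd / tree.total_length
    return apd


def qe_index(tree: PhyloTree) -> np.ndarray:
    """Tip weights maximising Rao's quadratic entropy Q(p) = p' D p.

    Solved by an active-set scheme: solve ``D p = c 1`` on the current
    support, drop any tips whose weight goes negative (they score 0) and
    re-solve.  The result is the originality distribution: weights sum to 1
    and on the support the mean distance to the weighted assemblage is the
    common constant ``c`` (the KKT stationarity certificate).  Zeros can
    genuinely occur, in particular on non-ultrametric trees.
    """
    d = tree.patristic()
    n = tree.n_tips
    if not np.any(d):
        raise ValueError("degenerate (all-zero) distance matrix")
    warn_if_not_ultrametric(tree, "the Rao-entropy index")
    support = np.ones(n, dtype=bool)
    for _ in range(n):
        idx = np.flatnonzero(support)
        sub = d[np.ix_(idx, idx)]
        ones = np.ones(idx.size)
        try:
            x = np.linalg.solve(sub, ones)
        except np.linalg.LinAlgError:
            x = np.linalg.lstsq(sub, ones, rcond=None)[0]
        total = x.sum()
        if total == 0:
            raise ValueError("Rao-entropy system is degenerate on this tree")
        p_sub = x / total
        neg = p_sub < -1e-12
        if not neg.any():
            p = np.zeros(n)
            p[idx] = np.clip(p_sub, 0.0, None)
            p /= p.sum()
            return p
        support[idx[neg]] = False
        if support.sum() < 2:
            raise ValueError("Rao-entropy support collapsed below two tips")
    raise RuntimeError("active-set iteration failed to converge")  # pragma: no cover


def character_rarity(tree: PhyloTree, params: ChrParams | None = None) -> np.ndarray:
    """Expected rarity of novel characters inherited along the root path.

    Characters originate at rate ``nu`` per unit branch length on the edge
    above each node *k* and survive each subsequent edge with probability
    ``rho``.  A tip's score sums, over root-path nodes *k*, the expected
    number of characters arising above *k* that reach the tip, times their
    expected rarity across the tree's species:

        CHR(i) = sum_k  nu * l_k * rho**m(k,i) * (1 - f_k / N),
        f_k = sum over tips j below k of rho**m(k,j),

    where ``m(k, j)`` counts edges from *k* down to tip *j*; species outside
    *k*'s subtree can never carry the character, so ``1 - f_k/N`` is the
    expected fraction of species lacking it.  Characters confined to small,
    shallow clades are therefore the rarest, which is what makes the score
    track mean pairwise distance so closely.  A deterministic expectation —
    no character sampling is performed.
    """
    if params is None:
        params = ChrParams()
    nu, rho = params.nu, params.rho
    # f[k] = expected number of descendant tips carrying a character born above k
    f = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if not tree.children[v]:
            f[v] = 1.0
        else:
            f[v] = rho * sum(f[c] for c in tree.children[v])
    rarity = 1.0 - f / tree.n_tips
    term = nu * tree.length * rarity  # root edge length is 0
    h = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes - 2, -1, -1):
        h[v] = rho * h[tree.parent[v]] + term[v]
    return h[tree.tip_ids]


# --------------------------------------------------------------------------


def compute_all(
    tree: PhyloTree,
    chr_params: ChrParams | None = None,
    standardise: bool = False,
    include_apdpd: bool = False,
) -> pd.DataFrame:
    """Score table: one row per tip (sorted labels), one column per metric.

    ``standardise`` divides every metric by its mean over tips so that each
    column has mean 1 — the form used for all inter-metric comparisons.
    """
    cols: dict[str, np.ndarray] = {
        "PE": pendant_edge(tree),
        "ED": fair_proportion(tree),
        "SV": shapley_value(tree),
        "ES": equal_splits(tree),
        "VW": vane_wright(tree),
        "MVW": may_vane_wright(tree),
        "NWU": nixon_wheeler_unweighted(tree),
        "NWW": nixon_wheeler_weighted(tree),
        "APD": average_pairwise_distance(tree),
        "QE": qe_index(tree),
        "CHR": character_rarity(tree, chr_params),
    }
    if include_apdpd:
        cols["APDPD"] = average_pairwise_distance(tree, standardise_by_pd=True)
    table = pd.DataFrame(cols, index=list(tree.tip_labels))
    table.index.name = "species"
    if standardise:
        from .compare import standardize_scores

        table = standardize_scores(table)
    return table
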