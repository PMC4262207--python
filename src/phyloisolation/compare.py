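"""Inter-metric redundancy analysis.

Pipeline per simulated tree: standardise every metric to mean 1, form the
Euclidean distance matrix between the 11 standardised score vectors,
normalise it so the mean off-diagonal distance is 1, and cluster it with
average-linkage agglomeration.  Across a replicate set the per-tree
dendrograms are summarised by a 50% majority-rule consensus, and subsets of
metrics are scored by the fraction of total score variation they capture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .metrics import CANONICAL_METRICS, ChrParams, compute_all, resolve_metric
from .tree import PhyloTree, nested_clades

__all__ = [
    "standardize_scores",
    "metric_distance_matrix",
    "Dendrogram",
    "ConsensusTree",
    "hierarchical_cluster",
    "majority_consensus",
    "variation_captured",
    "major_groups",
    "select_dissimilar_subset",
    "clade_scaling_profile",
    "asymptote_slope",
]


def standardize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each metric column by its mean over tips (column means become 1).

    Idempotent; refuses columns whose mean is zero, since those carry no
    signal to rescale.
    """
    means = table.mean(axis=0)
    bad = means[means <= 0]
    if len(bad):
        raise ValueError(
            "cannot standardise metrics with non-positive mean: "
            + ", ".join(bad.index.astype(str))
        )
    return table / means


def metric_distance_matrix(
    table: pd.DataFrame, normalise: bool = True, scale: str = "unit-variance"
) -> pd.DataFrame:
    """Euclidean distances between the metrics' tip-score vectors.

    With the default ``scale="unit-variance"`` each metric's scores are
    centred and scaled to unit variance before taking Euclidean distances,
    which makes the distance a monotone function of the Pearson correlation
    between metrics: two metrics that are linear transforms of one another
    sit at distance 0 regardless of their spread.  This is the scaling under
    which the study's reported inter-metric distances and metric groupings
    reproduce.  ``scale="mean"`` instead uses the mean-1 standardised scores
    as they are, so the distance also reflects differences in relative
    spread.

    With ``normalise`` the matrix is divided by its mean off-diagonal entry,
    so the expected pairwise distance is 1 and matrices are comparable
    across trees.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two metrics")
    x = table.to_numpy(dtype=float)
    if scale == "unit-variance":
        sd = x.std(axis=0)
        if (sd == 0).any():
            flat = list(table.columns[sd == 0])
            raise ValueError(f"metrics with zero variance cannot be scaled: {flat}")
        x = (x - x.mean(axis=0)) / sd
    elif scale == "mean":
        if not np.allclose(x.mean(axis=0), 1.0, atol=1e-8):
            raise ValueError("scale='mean' expects a mean-standardised score table")
    else:
        raise ValueError(f"unknown scale {scale!r}")
    g = x.T @ x
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    d = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(d, 0.0)
    if normalise:
        k = d.shape[0]
        mean_off = d.sum() / (k * (k - 1))
        if mean_off == 0:
            raise ValueError("all metrics identical; cannot normalise distances")
        d = d / mean_off
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


# --------------------------------------------------------------------------
# clustering


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over the metrics of one tree."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix

    def clades(self) -> set[frozenset]:
        """Non-trivial rooted clades (size >= 2, excluding the full leaf set)."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out: set[frozenset] = set()
        for row_i, (a, b, _h, _c) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + row_i] = merged
            if 2 <= len(merged) < n:
                out.add(merged)
        return out

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


@dataclass(frozen=True)
class ConsensusTree:
    """Majority-rule consensus over dendrograms; support = clade frequency."""

    labels: tuple[str, ...]
    supports: dict[frozenset, float]

    def contains(self, clade) -> bool:
        return frozenset(clade) in self.supports

    def support(self, clade) -> float:
        return self.supports.get(frozenset(clade), 0.0)

    def groups(self) -> list[frozenset]:
        """Partition of the leaves into the maximal consensus clades.

        Leaves outside every retained clade form singleton groups; the result
        is the coarsest partition below the root.
        """
        maximal: list[frozenset] = []
        for clade in sorted(self.supports, key=len, reverse=True):
            if not any(clade <= m for m in maximal):
                maximal.append(clade)
        covered = set().union(*maximal) if maximal else set()
        singles = [frozenset([l]) for l in self.labels if l not in covered]
        return sorted(maximal + singles, key=lambda c: sorted(c)[0])

    def to_newick(self) -> str:
        """Newick with clade supports as internal node labels (no lengths)."""
        full = frozenset(self.labels)
        clades = sorted(self.supports, key=len, reverse=True)

        def write(members: frozenset, support: float | None) -> str:
            inner = [c for c in clades if c < members]
            direct: list[frozenset] = []
            for c in inner:
                if not any(c < other for other in direct):
                    # keep only maximal sub-clades
                    direct = [d for d in direct if not d < c]
                    direct.append(c)
            placed = set().union(*direct) if direct else set()
            parts = [write(c, self.supports[c]) for c in direct]
            parts += [lab for lab in sorted(members - placed)]
            parts.sort(key=lambda s: s.lstrip("("))
            body = "(" + ",".join(parts) + ")"
            if support is not None:
                body += f"{support:.3g}"
            return body

        return write(full, None) + ";"


def hierarchical_cluster(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage agglomerative clustering of a metric distance matrix."""
    labels = tuple(dist.columns)
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be square and symmetric")
    z = hierarchy.linkage(squareform(d, checks=False), method="average")
    return Dendrogram(labels=labels, linkage=z)


def majority_consensus(dendrograms: list[Dendrogram], min_frequency: float = 0.5) -> ConsensusTree:
    """Strict majority-rule consensus: clades in more than half of the inputs.

    Majority clades are pairwise compatible, so they nest into a single
    rooted tree; supports are occurrence proportions.
    """
    if not dendrograms:
        raise ValueError("need at least one dendrogram")
    labels = dendrograms[0].labels
    leafset = frozenset(labels)
    counts: dict[frozenset, int] = {}
    for dg in dendrograms:
        if frozenset(dg.labels) != leafset:
            raise ValueError("all dendrograms must share one leaf set")
        for clade in dg.clades():
            counts[clade] = counts.get(clade, 0) + 1
    n = len(dendrograms)
    supports = {c: k / n for c, k in counts.items() if k / n > min_frequency}
    return ConsensusTree(labels=labels, supports=supports)


# --------------------------------------------------------------------------
# captured variation


def _captured_one(table: pd.DataFrame, subset: list[str]) -> float:
    y = table.to_numpy(dtype=float)
    x = table[subset].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ssr = (resid**2).sum(axis=0)
    var = y.var(axis=0)
    sst = var * len(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, 1.0)
    r2 = np.clip(r2, 0.0, 1.0)
    total = var.sum()
    if total == 0:
        return 1.0
    return float((var * r2).sum() / total)


def _share_one(table: pd.DataFrame, subset: list[str]) -> float:
    var = table.var(axis=0, ddof=1)
    total = var.sum()
    if total == 0:
        return 1.0
    return float(var[subset].sum() / total)


def variation_captured(tables, subset, method: str = "variance-share") -> float:
    """Fraction of total metric variation captured by a metric subset.

    Per standardised table, under the default ``variance-share`` definition
    the total variation is the sum of the metrics' score variances (after
    mean-1 standardisation) and a subset captures the summed variance of its
    members — the definition under which the study's captured-variation
    curve reproduces.  Under ``regression``, each metric is regressed (OLS
    with intercept, pseudo-inverse for collinear subsets) on the subset's
    score vectors and the captured fraction is the variance-weighted mean of
    the coefficients of determination, ``sum_j var_j R2_j / sum_j var_j``;
    metrics in the subset contribute ``R2 = 1``, so redundancy with the
    subset counts as captured.  Either way the result is averaged over
    tables and is monotone in subset inclusion.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    subset = [resolve_metric(m) for m in subset]
    if not subset:
        raise ValueError("subset must be non-empty")
    if method == "variance-share":
        return float(np.mean([_share_one(t, subset) for t in tables]))
    if method == "regression":
        return float(np.mean([_captured_one(t, subset) for t in tables]))
    raise ValueError(f"unknown method {method!r}")


def major_groups(mean_dist: pd.DataFrame, k: int) -> list[frozenset]:
    """Partition the metrics into ``k`` groups from a pooled distance matrix.

    Cuts the average-linkage tree of the replicate-set mean normalised
    distance matrix into ``k`` clusters; used as the operational version of
    the study's "major groups" when drawing one metric per group.
    """
    dg = hierarchical_cluster(mean_dist)
    assignment = hierarchy.fcluster(dg.linkage, t=k, criterion="maxclust")
    groups: dict[int, set] = {}
    for lab, g in zip(dg.labels, assignment):
        groups.setdefault(int(g), set()).add(lab)
    return sorted((frozenset(g) for g in groups.values()), key=lambda c: sorted(c)[0])


def select_dissimilar_subset(
    tables,
    k: int,
    mode: str = "greedy",
    groups: list[frozenset] | None = None,
    rng: np.random.Generator | int | None = None,
    method: str = "variance-share",
) -> list[str]:
    """Choose ``k`` maximally complementary metrics.

    ``greedy``: forward selection, at each step adding the metric that most
    increases :func:`variation_captured` under ``method`` (ties broken by
    canonical order).  ``one-per-group``: one random member from each
    supplied group (``k`` must equal the number of groups); the draw is
    seeded via ``rng``.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    metric_pool = [m for m in CANONICAL_METRICS if m in tables[0].columns]
    if not 1 <= k <= len(metric_pool):
        raise ValueError(f"k must be between 1 and {len(metric_pool)}")
    if mode == "greedy":
        chosen: list[str] = []
        for _ in range(k):
            best, best_score = None, -np.inf
            for m in metric_pool:
                if m in chosen:
                    continue
                score = variation_captured(tables, chosen + [m], method=method)
                if score > best_score + 1e-12:
                    best, best_score = m, score
            chosen.append(best)
        return chosen
    if mode == "one-per-group":
        if groups is None:
            raise ValueError("one-per-group mode needs explicit groups")
        if k != len(groups):
            raise ValueError("k must equal the number of groups")
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        return [sorted(g)[gen.integers(len(g))] for g in groups]
    raise ValueError(f"unknown mode {mode!r}")


# --------------------------------------------------------------------------
# clade-size scaling


def clade_scaling_profile(
    tree: PhyloTree,
    tip: str,
    chr_params: ChrParams | None = None,
    scale_by_max: bool = True,
) -> pd.DataFrame:
    """A target tip's scores on increasingly large complete clades.

    Rows are the nested clades containing the tip (indexed by clade tip
    count, smallest to the full tree); columns are the 11 metrics plus the
    APD/PD variant.  With ``scale_by_max`` each column is divided by its
    maximum over clades, the form used to compare asymptote behaviour.
    """
    rows = []
    sizes = []
    for clade in nested_clades(tree, tip):
        table = compute_all(clade, chr_params=chr_params, include_apdpd=True)
        rows.append(table.loc[tip])
        sizes.append(clade.n_tips)
    profile = pd.DataFrame(rows)
    profile.index = pd.Index(sizes, name="clade_size")
    # equal-size ancestors (zero-length internal edges) keep separate rows
    if scale_by_max:
        maxima = profile.max(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile = profile.divide(maxima.where(maxima > 0, 1.0), axis=1)
    return profile


def asymptote_slope(profile: pd.DataFrame, size_window: tuple[float, float]) -> pd.Series:
    """OLS slope of score against clade size inside a size window, per metric."""
    lo, hi = size_window
    sub = profile[(profile.index >= lo) & (profile.index <= hi)]
    if len(sub) < 2:
        raise ValueError("size window must contain at least two clades")
    x = sub.index.to_numpy(dtype=float)
    slopes = {}
    for col in sub.columns:
        slopes[col] = float(np.polyfit(x, sub[col].to_numpy(dtype=float), 1)[0])
    return pd.Series(slopes, name="slope")
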