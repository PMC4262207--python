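"""EDGE-style conservation priority lists and their comparison.

EDGE scores combine evolutionary isolation with extinction risk:

    EDGE = ln(1 + isolation) + GE * ln 2,

where the isolation score is standardised (mean 1 over the tree's species)
and GE encodes the IUCN category, Least Concern = 0 up to Critically
Endangered = 4 — each category step doubles the implied weight.  Any of the
eleven isolation metrics can stand in for the isolation component, and the
resulting ranked lists are compared by top-k overlap and rank similarity.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import (
    ChrParams,
    average_pairwise_distance,
    character_rarity,
    compute_all,
    equal_splits,
    fair_proportion,
    may_vane_wright,
    nixon_wheeler_unweighted,
    nixon_wheeler_weighted,
    pendant_edge,
    qe_index,
    resolve_metric,
    shapley_value,
    vane_wright,
)
from .tree import PhyloTree

__all__ = ["GE_CODES", "edge_score", "build_edge_list", "compare_top_k"]

#: Ordinal threat codes used in the EDGE formula.
GE_CODES: dict[str, int] = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}

_METRIC_FUNCS = {
    "PE": pendant_edge,
    "ED": fair_proportion,
    "SV": shapley_value,
    "ES": equal_splits,
    "VW": vane_wright,
    "MVW": may_vane_wright,
    "NWU": nixon_wheeler_unweighted,
    "NWW": nixon_wheeler_weighted,
    "APD": average_pairwise_distance,
    "QE": qe_index,
}


def edge_score(isolation: float | np.ndarray, ge: int | str | np.ndarray):
    """EDGE = ln(1 + isolation) + GE * ln 2; isolation must be >= 0."""
    iso = np.asarray(isolation, dtype=float)
    if (iso < 0).any():
        raise ValueError("isolation scores must be non-negative")
    if isinstance(ge, str):
        ge = GE_CODES[ge]
    ge_arr = np.asarray(ge, dtype=float)
    out = np.log1p(iso) + ge_arr * math.log(2.0)
    return float(out) if out.ndim == 0 else out


def _threat_map(threat: pd.DataFrame) -> dict[str, int]:
    if not {"species", "category"} <= set(threat.columns):
        raise ValueError("threat table needs 'species' and 'category' columns")
    out: dict[str, int] = {}
    for sp, cat in zip(threat["species"], threat["category"]):
        if cat not in GE_CODES:
            raise ValueError(f"unknown threat category {cat!r} for {sp}")
        out[str(sp)] = GE_CODES[cat]
    return out


def build_edge_list(
    tree: PhyloTree,
    threat: pd.DataFrame,
    metric: str,
    chr_params: ChrParams | None = None,
) -> pd.DataFrame:
    """Ranked EDGE table for one isolation metric.

    The metric's scores are standardised by their mean, combined with each
    species' GE code, and ranked by descending EDGE score (ties get average
    ranks; rows are ordered by rank then species label).
    """
    key = resolve_metric(metric)
    ge_map = _threat_map(threat)
    missing = [lab for lab in tree.tip_labels if lab not in ge_map]
    if missing:
        raise ValueError(f"threat table lacks species: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if key == "CHR":
        scores = character_rarity(tree, chr_params)
    else:
        scores = _METRIC_FUNCS[key](tree)
    iso = scores / scores.mean()
    ge = np.array([ge_map[lab] for lab in tree.tip_labels], dtype=int)
    edge = edge_score(iso, ge)
    frame = pd.DataFrame(
        {
            "species": list(tree.tip_labels),
            "isolation": iso,
            "GE": ge,
            "EDGE": edge,
        }
    )
    frame["rank"] = frame["EDGE"].rank(method="average", ascending=False)
    frame = frame.sort_values(["rank", "species"], kind="mergesort").reset_index(drop=True)
    return frame


def _top_k(edge_list: pd.DataFrame, k: int) -> list[str]:
    ordered = edge_list.sort_values(["EDGE", "species"], ascending=[False, True], kind="mergesort")
    return list(ordered["species"].head(k))


def compare_top_k(reference: pd.DataFrame, other: pd.DataFrame, k: int):
    """Compare two EDGE lists through the reference list's top-k species.

    Returns ``(shared, rank_similarity, unique_scores_other)``: the overlap
    of the two top-k sets, the Spearman correlation of the two lists' full
    ranks restricted to the reference's top-k species, and the number of
    distinct isolation values the other metric assigns over all species
    (node-count metrics give many species identical scores).
    """
    ref_species = set(reference["species"])
    if ref_species != set(other["species"]):
        raise ValueError("EDGE lists must cover the same species")
    if k > len(reference):
        raise ValueError("k exceeds the list length")
    top_ref = _top_k(reference, k)
    top_other = set(_top_k(other, k))
    shared = len(set(top_ref) & top_other)
    ref_ranks = reference.set_index("species")["rank"]
    other_ranks = other.set_index("species")["rank"]
    a = ref_ranks.loc[top_ref].to_numpy(dtype=float)
    b = other_ranks.loc[top_ref].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(a, b).statistic)
    unique_scores = int(np.unique(np.round(other["isolation"].to_numpy(), 12)).size)
    return shared, rho, unique_scores
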