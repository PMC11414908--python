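"""Unit-type classification from post-EOD spike-timing histograms.

Units are represented by their unit-sum post-EOD histograms (2.5-40 ms, 1 ms
bins). Classification follows the agglomerative route: Euclidean distances
between histogram vectors, Ward minimum-variance linkage, and a cluster
count chosen from the Davies-Bouldin curve by a discrete second-difference
elbow rule. Two flavours of the Davies-Bouldin index are available:

* ``"textbook"`` (default): DB = mean_i max_{j != i} (S_i + S_j) / M_ij with
  S the mean distance of members to their centroid and M the centroid
  distances (lower is better);
* ``"ratio"``: minimum inter-cluster member distance divided by maximum
  intra-cluster member distance (higher is better; the looser gloss
  sometimes quoted for the index). The elbow rule handles either
  orientation by operating on the curve's discrete curvature.

The module also hosts the population-level statistics on unit properties:
all-pairs two-sample KS tests on raw spike latencies with Holm-Bonferroni
control, and Kruskal-Wallis + pairwise rank-sum group comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .events import ValidationError
from .histograms import PeriEODHistogram, peri_eod_profile
from .stats import TestResult, holm_bonferroni, kruskal_wallis, ks_two_sample, rank_sum

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "distance_matrix",
    "ward_cluster",
    "davies_bouldin_index",
    "davies_bouldin_curve",
    "select_k_elbow",
    "classify_units",
    "linkage_to_newick",
    "pairwise_ks_tests",
    "compare_groups",
]


@dataclass
class DistanceMatrix:
    """Condensed pairwise Euclidean distances between unit histograms."""

    unit_ids: list[str]
    condensed: np.ndarray
    vectors: np.ndarray  # (n_units, n_bins) histogram matrix

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def square(self) -> np.ndarray:
        return squareform(self.condensed)


@dataclass
class ClusterResult:
    unit_ids: list[str]
    linkage: np.ndarray
    db_curve: dict[int, float]
    chosen_k: int
    labels: dict[str, int]
    profiles: dict[int, dict] = field(default_factory=dict)


def distance_matrix(histograms: dict[str, PeriEODHistogram]) -> DistanceMatrix:
    """Euclidean distances between unit-sum post-EOD histogram vectors."""
    if len(histograms) < 2:
        raise ValidationError("distance_matrix needs at least two units")
    ids = list(histograms)
    ref = histograms[ids[0]].bin_centers_ms
    rows = []
    for uid in ids:
        h = histograms[uid]
        if h.normalization != "unit_sum":
            raise ValidationError(
                f"unit {uid}: distance_matrix requires unit_sum histograms"
            )
        if h.bin_centers_ms.shape != ref.shape or np.any(h.bin_centers_ms != ref):
            raise ValidationError(f"unit {uid}: mismatched binning")
        rows.append(h.values)
    X = np.vstack(rows)
    return DistanceMatrix(unit_ids=ids, condensed=pdist(X, metric="euclidean"),
                          vectors=X)


def ward_cluster(dm: DistanceMatrix) -> np.ndarray:
    """Ward minimum-within-cluster-variance agglomeration (full tree)."""
    if dm.n_units < 2:
        raise ValidationError("ward_cluster needs at least two units")
    return hierarchy.linkage(dm.condensed, method="ward")


def _labels_at_k(linkage: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.fcluster(linkage, t=k, criterion="maxclust")


def davies_bouldin_index(
    X: np.ndarray, labels: np.ndarray, variant: str = "textbook"
) -> float:
    """Davies-Bouldin cluster-quality index for a labelled point set.

    Returns NaN for degenerate partitions (fewer than two clusters, or
    coincident centroids in the textbook variant / zero intra-cluster spread
    in the ratio variant).
    """
    labs = np.unique(labels)
    if labs.size < 2:
        return float("nan")
    if variant == "textbook":
        cents = np.vstack([X[labels == l].mean(axis=0) for l in labs])
        S = np.array(
            [
                np.linalg.norm(X[labels == l] - cents[i], axis=1).mean()
                for i, l in enumerate(labs)
            ]
        )
        M = squareform(pdist(cents))
        with np.errstate(divide="ignore", invalid="ignore"):
            R = (S[:, None] + S[None, :]) / M
        np.fill_diagonal(R, -np.inf)
        if not np.all(np.isfinite(R[~np.eye(labs.size, dtype=bool)])):
            return float("nan")
        return float(np.max(R, axis=1).mean())
    if variant == "ratio":
        inter = np.inf
        intra = 0.0
        for i, li in enumerate(labs):
            Xi = X[labels == li]
            if Xi.shape[0] > 1:
                intra = max(intra, pdist(Xi).max())
            for lj in labs[i + 1:]:
                Xj = X[labels == lj]
                d = np.linalg.norm(Xi[:, None, :] - Xj[None, :, :], axis=2).min()
                inter = min(inter, d)
        if intra == 0.0:
            return float("nan")
        return float(inter / intra)
    raise ValueError(f"unknown Davies-Bouldin variant {variant!r}")


def davies_bouldin_curve(
    dm: DistanceMatrix,
    linkage: np.ndarray,
    k_range=range(2, 13),
    variant: str = "textbook",
) -> dict[int, float]:
    """Davies-Bouldin index of the tree cut at each k in ``k_range``.

    Cuts that do not realize k clusters, or degenerate partitions, are
    reported as NaN (missing).
    """
    curve: dict[int, float] = {}
    for k in k_range:
        if k >= dm.n_units:
            curve[k] = float("nan")
            continue
        labels = _labels_at_k(linkage, k)
        if np.unique(labels).size != k:
            curve[k] = float("nan")
            continue
        curve[k] = davies_bouldin_index(dm.vectors, labels, variant=variant)
    return curve


def select_k_elbow(db_curve: dict[int, float]) -> int:
    """Choose the cluster count at the elbow of the Davies-Bouldin curve.

    The usual textbook curve falls while genuine clusters are being
    separated and rises once they start being split, so an *interior* global
    minimum is the elbow and is returned directly. When the minimum sits at
    the upper end of the k range (an L-shaped, monotonically improving
    curve), the kink is located instead as the k with maximal discrete
    second difference v(k+1) - 2 v(k) + v(k-1). A curve with neither an
    interior minimum nor a convex kink (e.g. strictly linear) triggers a
    warning and falls back to the curve minimum.
    """
    ks = sorted(k for k, v in db_curve.items() if np.isfinite(v))
    if len(ks) < 4:
        raise ValidationError("elbow selection needs a curve over >= 4 k values")
    v = {k: db_curve[k] for k in ks}
    k_min = min(ks, key=lambda k: (v[k], k))
    if k_min != ks[-1]:
        return k_min
    d2 = {
        ks[i]: v[ks[i + 1]] - 2 * v[ks[i]] + v[ks[i - 1]]
        for i in range(1, len(ks) - 1)
    }
    best_k = max(d2, key=lambda k: (d2[k], -k))
    tol = 1e-9 * max(abs(db_curve[k]) for k in ks)
    if d2[best_k] <= tol:
        warnings.warn(
            "Davies-Bouldin curve has no convex elbow; falling back to its minimum",
            stacklevel=2,
        )
        return k_min
    return best_k


def classify_units(
    histograms: dict[str, PeriEODHistogram],
    k: int | None = None,
    k_range=range(2, 13),
    variant: str = "textbook",
    crosscorr: dict[str, PeriEODHistogram] | None = None,
) -> ClusterResult:
    """Full classification pass: distances, Ward tree, k selection, labels.

    ``k`` overrides elbow selection. When long cross-correlograms are
    supplied, per-cluster 20/50/80 percentile peri-EOD profiles over the
    -15..40 ms window are attached.
    """
    dm = distance_matrix(histograms)
    Z = ward_cluster(dm)
    curve = davies_bouldin_curve(dm, Z, k_range=k_range, variant=variant)
    chosen = int(k) if k is not None else select_k_elbow(curve)
    labels_arr = _labels_at_k(Z, chosen)
    labels = dict(zip(dm.unit_ids, (int(l) for l in labels_arr)))
    profiles: dict[int, dict] = {}
    source = crosscorr if crosscorr is not None else histograms
    for cl in sorted(set(labels.values())):
        members = [u for u in dm.unit_ids if labels[u] == cl]
        profiles[cl] = peri_eod_profile([source[u] for u in members])
    return ClusterResult(
        unit_ids=dm.unit_ids,
        linkage=Z,
        db_curve=curve,
        chosen_k=chosen,
        labels=labels,
        profiles=profiles,
    )


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def pairwise_ks_tests(
    latencies: dict[str, np.ndarray],
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001),
) -> dict:
    """All-pairs two-sample KS tests on per-unit spike-latency samples.

    Every unordered pair of units is tested; Holm's step-down adjustment is
    applied across all pairs and the fraction of significant comparisons is
    reported for each alpha. Pairs involving a degenerate sample (< 2
    latencies) are skipped and recorded.
    """
    ids = list(latencies)
    ok = [u for u in ids if np.asarray(latencies[u]).size >= 2]
    skipped = [u for u in ids if u not in ok]
    pairs = list(itertools.combinations(ok, 2))
    rows = []
    for a, b in pairs:
        res = ks_two_sample(latencies[a], latencies[b])
        rows.append((a, b, res.statistic, res.p_value))
    df = pd.DataFrame(rows, columns=["unit_a", "unit_b", "statistic", "p_value"])
    frac = {}
    if len(df):
        _, adj = holm_bonferroni(df["p_value"].to_numpy())
        df["p_adjusted"] = adj
        for a in alphas:
            df[f"significant_{a:g}"] = df["p_adjusted"] < a
            frac[a] = float((df["p_adjusted"] < a).mean())
    return {"pairs": df, "n_pairs": len(pairs), "fraction_significant": frac,
            "skipped_units": skipped}


def compare_groups(
    values: dict[str, float],
    labels: dict[str, object],
    alpha: float = 0.05,
) -> dict:
    """Kruskal-Wallis omnibus plus Holm-corrected pairwise rank-sum tests.

    ``values`` maps unit -> scalar property (depth, mean latency,
    spikes/EOD...); ``labels`` maps unit -> group. Groups with fewer than
    two members are excluded with a warning.
    """
    groups: dict[object, list[float]] = {}
    for u, v in values.items():
        if u in labels and np.isfinite(v):
            groups.setdefault(labels[u], []).append(v)
    excluded = [g for g, vals in groups.items() if len(vals) < 2]
    for g in excluded:
        warnings.warn(f"group {g!r} excluded (fewer than 2 members)", stacklevel=2)
        del groups[g]
    if len(groups) < 2:
        raise ValidationError("compare_groups needs >= 2 groups with >= 2 members")
    names = sorted(groups, key=str)
    omnibus = kruskal_wallis(*[groups[g] for g in names])
    rows = []
    for a, b in itertools.combinations(names, 2):
        res = rank_sum(groups[a], groups[b])
        rows.append((a, b, res.statistic, res.p_value))
    pw = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])
    if len(pw):
        reject, adj = holm_bonferroni(pw["p_value"].to_numpy(), alpha=alpha)
        pw["p_adjusted"] = adj
        pw["significant"] = reject
    return {"omnibus": omnibus, "pairwise": pw, "excluded_groups": excluded,
            "group_sizes": {g: len(groups[g]) for g in names}}
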