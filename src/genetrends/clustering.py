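"""Hierarchical and fuzzy clustering of gene/country profiles.

Countries are clustered hierarchically (complete linkage) on their gene
count profiles; cosine distance is the default so that publication volume
does not dominate. Genes are soft-clustered with fuzzy c-means (FCM) on
their per-country (or per-year) mention counts, and candidate cluster
counts are scored with four validity indices:

* partition coefficient  PC  = (1/n) sum_ik u_ik^2           (1/c .. 1)
* classification entropy CE  = -(1/n) sum_ik u_ik ln u_ik     (0 .. ln c)
* partition index        PI  = sum_i [sum_k u_ik^m ||x_k-v_i||^2]
                               / (n_i sum_j ||v_j-v_i||^2),  n_i = sum_k u_ik
* Xie-Beni index         XBI = sum_ik u_ik^m ||x_k-v_i||^2
                               / (n min_{i!=j} ||v_i-v_j||^2)

Crisper, more compact and better separated partitions give high PC, low
CE, low PI and low XBI. Index tables are reported for inspection; optimal
c is not chosen automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Complete-link hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Agglomerative merge history: (cluster_a, cluster_b, height, new_id).

    Leaves are 0..n-1 (row order of the profile matrix); merge i creates
    cluster id n+i. Complete linkage guarantees non-decreasing heights.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "new_id"]
        )

    def to_newick(self) -> str:
        """Nested-parenthesis text with branch lengths (height differences)."""
        height_of: dict[int, float] = {i: 0.0 for i in range(len(self.labels))}
        node: dict[int, str] = {
            i: _newick_escape(lab) for i, lab in enumerate(self.labels)
        }
        for a, b, height, new_id in self.merges:
            branch_a = height - height_of[a]
            branch_b = height - height_of[b]
            node[new_id] = f"({node[a]}:{branch_a:g},{node[b]}:{branch_b:g})"
            height_of[new_id] = height
        root = self.merges[-1][3] if self.merges else 0
        return node[root] + ";"


def _newick_escape(label: str) -> str:
    if any(ch in label for ch in "(),:; "):
        return "'" + label.replace("'", "''") + "'"
    return label


def _pairwise_distances(data: np.ndarray, metric) -> np.ndarray:
    n = data.shape[0]
    if callable(metric):
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                dist[i, j] = metric(data[i], data[j])
        if not np.allclose(dist, dist.T, atol=1e-12):
            raise ValueError("metric violates symmetry")
        return dist
    if metric == "euclidean":
        diff = data[:, None, :] - data[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "cosine":
        norms = np.linalg.norm(data, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        unit = data / safe[:, None]
        sim = unit @ unit.T
        dist = 1.0 - np.clip(sim, -1.0, 1.0)
        np.fill_diagonal(dist, 0.0)
        return dist
    raise ValueError(f"unknown metric {metric!r}")


def hierarchical_complete(
    profiles: pd.DataFrame, metric="cosine"
) -> Dendrogram:
    """Agglomerative clustering with complete (maximum) linkage.

    At each step the pair of active clusters with the smallest maximum
    pairwise distance merges; ties go to the lexicographically smallest
    (id_a, id_b) pair. ``metric`` is "euclidean", "cosine", or a symmetric
    callable on row vectors.
    """
    if profiles.shape[0] < 2:
        raise ValueError("hierarchical clustering needs >= 2 rows")
    data = np.asarray(profiles, dtype=float)
    n = data.shape[0]
    dist = {
        (i, j): d
        for i, row in enumerate(_pairwise_distances(data, metric))
        for j, d in enumerate(row)
        if i < j
    }
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        (a, b), height = min(
            ((pair, d) for pair, d in dist.items()
             if pair[0] in active and pair[1] in active),
            key=lambda kv: (kv[1], kv[0]),
        )
        # Lance-Williams update for complete link: d(new, k) = max(d(a,k), d(b,k))
        active -= {a, b}
        for k in active:
            dist[tuple(sorted((next_id, k)))] = max(
                dist[tuple(sorted((a, k)))], dist[tuple(sorted((b, k)))]
            )
        merges.append((a, b, height, next_id))
        active.add(next_id)
        next_id += 1
    return Dendrogram(merges=merges, labels=[str(x) for x in profiles.index])


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------


@dataclass
class FCMResult:
    """Fuzzy partition: centers (c x d), membership U (c x n), objective."""

    centers: np.ndarray
    membership: np.ndarray
    fuzzifier: float
    objective: float
    objective_history: list[float]
    n_iter: int
    converged: bool

    def hard_labels(self) -> np.ndarray:
        return self.membership.argmax(axis=0)


def _fcm_memberships(data: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Membership update: u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1)).

    A point coincident with a center gets membership 1 there (limit
    convention, split evenly over coincident centers).
    """
    dist = np.linalg.norm(data[None, :, :] - centers[:, None, :], axis=2)  # c x n
    u = np.zeros_like(dist)
    zero_mask = dist < 1e-12
    coincident = zero_mask.any(axis=0)
    with np.errstate(divide="ignore"):
        inv = dist ** (-2.0 / (m - 1.0))
    u[:, ~coincident] = inv[:, ~coincident] / inv[:, ~coincident].sum(axis=0)
    if coincident.any():
        u[:, coincident] = zero_mask[:, coincident] / zero_mask[:, coincident].sum(
            axis=0
        )
    return u


def fcm(
    data: pd.DataFrame | np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int = 0,
) -> FCMResult:
    """Fuzzy c-means by alternating membership/center updates.

    Initial centers are ``c`` distinct data points sampled with the seeded
    generator; iteration stops when the maximum center shift falls below
    ``tol`` or after ``max_iter`` sweeps. The objective
    J = sum_ik u_ik^m ||x_k - v_i||^2 is non-increasing across iterations.
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    if not 2 <= c <= n:
        raise ValueError(f"need 2 <= c <= n, got c={c}, n={n}")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    centers = x[rng.choice(n, size=c, replace=False)].copy()
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = _fcm_memberships(x, centers, m)
        um = u**m
        denom = um.sum(axis=1)
        # a cluster attracting no mass keeps its previous center
        new_centers = centers.copy()
        nz = denom > 1e-300
        new_centers[nz] = (um[nz] @ x) / denom[nz, None]
        dist2 = (
            np.linalg.norm(x[None, :, :] - new_centers[:, None, :], axis=2) ** 2
        )
        history.append(float((um * dist2).sum()))
        shift = np.linalg.norm(new_centers - centers, axis=1).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break
    u = _fcm_memberships(x, centers, m)
    return FCMResult(
        centers=centers,
        membership=u,
        fuzzifier=m,
        objective=history[-1],
        objective_history=history,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Validity indices
# ---------------------------------------------------------------------------


def validity(
    data: pd.DataFrame | np.ndarray, results: dict[int, FCMResult]
) -> pd.DataFrame:
    """PC / CE / PI / XBI per candidate cluster count.

    XBI is NaN when two centers coincide (separation denominator is zero).
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    rows = []
    for c in sorted(results):
        res = results[c]
        u = res.membership
        m = res.fuzzifier
        v = res.centers
        pc = float((u**2).sum() / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            logu = np.where(u > 0, np.log(u), 0.0)
        ce = float(-(u * logu).sum() / n)
        dist2 = np.linalg.norm(x[None, :, :] - v[:, None, :], axis=2) ** 2  # c x n
        center_dist2 = (
            np.linalg.norm(v[:, None, :] - v[None, :, :], axis=2) ** 2
        )
        n_i = u.sum(axis=1)
        pi_terms = []
        for i in range(len(v)):
            sep = center_dist2[i].sum()
            compact = ((u[i] ** m) * dist2[i]).sum()
            pi_terms.append(compact / (n_i[i] * sep) if sep > 0 and n_i[i] > 0 else np.nan)
        pi = float(np.sum(pi_terms))
        off_diag = center_dist2[~np.eye(len(v), dtype=bool)]
        min_sep = float(off_diag.min()) if off_diag.size else float("nan")
        if not np.isfinite(min_sep) or min_sep < 1e-12:
            xbi = float("nan")
        else:
            xbi = float(((u**m) * dist2).sum() / (n * min_sep))
        rows.append({"c": c, "PC": pc, "CE": ce, "PI": pi, "XBI": xbi})
    return pd.DataFrame(rows, columns=["c", "PC", "CE", "PI", "XBI"]).set_index("c")


def validity_scan(
    data: pd.DataFrame | np.ndarray,
    c_min: int = 2,
    c_max: int = 15,
    m: float = 2.0,
    seed: int = 0,
    **fcm_kwargs,
) -> tuple[pd.DataFrame, dict[int, FCMResult]]:
    """Run FCM for every c in [c_min, c_max] and tabulate the indices."""
    x = np.asarray(data, dtype=float)
    c_max = min(c_max, x.shape[0])
    results = {
        c: fcm(x, c=c, m=m, seed=seed, **fcm_kwargs)
        for c in range(c_min, c_max + 1)
    }
    return validity(x, results), results


def suggest_c(indices: pd.DataFrame) -> int:
    """Optional heuristic: the c with the largest relative PI drop.

    Index tables are meant for inspection (PI and XBI typically keep
    decreasing with c); the elbow — the step c-1 -> c with the largest
    relative decrease of PI — is a reasonable automatic pick but is never
    applied unless explicitly requested.
    """
    pi = indices["PI"]
    cs = sorted(indices.index)
    if len(cs) < 2:
        return int(cs[0])
    drops = {
        c: (pi[prev] - pi[c]) / pi[prev] if pi[prev] > 0 else 0.0
        for prev, c in zip(cs, cs[1:])
    }
    return int(max(drops, key=lambda c: (drops[c], -c)))


# ---------------------------------------------------------------------------
# 2-D projection and fuzzy-area cross-matching
# ---------------------------------------------------------------------------


def pca_2d(data: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Project rows onto the top-2 principal axes of column-centered data.

    Sign convention: each axis is flipped so its largest-magnitude loading
    is positive. Rank-1 data gets an all-zero second coordinate (with a
    warning).
    """
    x = np.asarray(data, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("pca_2d needs >= 2 rows and >= 2 columns")
    centered = x - x.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:2]
    for i in range(2):
        peak = np.abs(comps[i]).argmax()
        if comps[i, peak] < 0:
            comps[i] = -comps[i]
    if len(s) < 2 or s[1] < 1e-12 * max(s[0], 1.0):
        warnings.warn("rank-deficient data: second principal axis is degenerate",
                      stacklevel=2)
    return centered @ comps.T


def fuzzy_area_genes(
    U: np.ndarray, entities: list[str], tau: float = 0.6
) -> set[str]:
    """Entities whose largest membership falls below tau ("fuzzy area")."""
    top = np.asarray(U).max(axis=0)
    return {e for e, t in zip(entities, top) if t < tau}


def crossmatch_itemsets(
    itemsets, fuzzy_area: set[str], universe: set[str] | None = None
) -> pd.DataFrame:
    """Per itemset, the fraction of its genes lying in the fuzzy area.

    Genes absent from the clustered universe are excluded from the fraction
    and reported in the ``missing`` column.
    """
    rows = []
    for it in itemsets:
        items = list(it.items) if hasattr(it, "items") and not callable(it.items) \
            else list(it)
        if universe is not None:
            present = [g for g in items if g in universe]
            missing = [g for g in items if g not in universe]
        else:
            present, missing = items, []
        frac = (
            sum(g in fuzzy_area for g in present) / len(present) if present else 0.0
        )
        rows.append(
            {
                "items": ",".join(items),
                "fuzzy_fraction": frac,
                "missing": ",".join(missing),
            }
        )
    return pd.DataFrame(rows, columns=["items", "fuzzy_fraction", "missing"])
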