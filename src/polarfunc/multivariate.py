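"""Bray-Curtis distances, hierarchical clustering and distance-based
redundancy analysis (db-RDA).

The clustering backs two-way heatmap ordering of function tables; db-RDA
links a response table (e.g. carbon-substrate utilisation profiles) to
constraining variables (e.g. function-category abundances) by ordinating
principal coordinates of a sample distance matrix under a linear model of
the constraints.  With Euclidean distances db-RDA is exactly classical RDA
on the raw (column-centred) response — a property the tests verify
numerically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

LINKAGES = ("single", "complete", "average")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


def bray_curtis(matrix, labels: list[str] | None = None) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows: ``sum|x-y| / sum(x+y)``.

    Entries lie in [0, 1]; a comparison of two all-zero rows is defined as
    1 (disjoint "support" by convention).
    """
    x = np.asarray(matrix, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    if labels is None:
        labels = [str(i) for i in range(x.shape[0])]
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            d[i, j] = d[j, i] = (
                1.0 if denom == 0 else np.abs(x[i] - x[j]).sum() / denom
            )
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class Dendrogram:
    """Agglomeration result: ordered merges and a deterministic leaf order."""

    labels: list[str]
    merges: list[tuple[frozenset[str], frozenset[str], float]]
    leaf_order: list[str]
    newick: str


def hcluster(dm: DistanceMatrix, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering with label-sorted deterministic tie-breaks.

    At each step the pair of clusters at minimal linkage distance merges;
    ties are broken by the lexicographically smallest (sorted) label pair,
    so the merge sequence and leaf order are reproducible regardless of
    input order.  Naive O(n^3) agglomeration — fine at heatmap scale.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    index = {lab: i for i, lab in enumerate(dm.labels)}

    def cluster_dist(a: frozenset[str], b: frozenset[str]) -> float:
        pair = [dm.d[index[x], index[y]] for x in a for y in b]
        if linkage == "single":
            return min(pair)
        if linkage == "complete":
            return max(pair)
        return float(np.mean(pair))

    clusters: dict[frozenset[str], tuple[str, list[str]]] = {
        frozenset([lab]): (lab, [lab]) for lab in dm.labels
    }  # cluster -> (newick, leaf order)
    merges: list[tuple[frozenset[str], frozenset[str], float]] = []
    while len(clusters) > 1:
        keys = sorted(clusters, key=lambda c: tuple(sorted(c)))
        best: tuple[float, tuple, frozenset, frozenset] | None = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a, b = keys[i], keys[j]
                dist = cluster_dist(a, b)
                tie_key = tuple(sorted(a | b))
                cand = (dist, tie_key, a, b)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, _, a, b = best  # type: ignore[misc]
        # deterministic child order: smaller sorted label tuple first
        first, second = sorted((a, b), key=lambda c: tuple(sorted(c)))
        nwk_a, leaves_a = clusters.pop(first)
        nwk_b, leaves_b = clusters.pop(second)
        merged = first | second
        clusters[merged] = (
            f"({nwk_a},{nwk_b}):{dist:.6g}",
            leaves_a + leaves_b,
        )
        merges.append((first, second, float(dist)))
    newick, leaf_order = next(iter(clusters.values()))
    return Dendrogram(
        labels=list(dm.labels),
        merges=merges,
        leaf_order=leaf_order,
        newick=newick + ";",
    )


@dataclass
class OrdinationResult:
    axis_variances: np.ndarray  # fraction of total inertia per constrained axis
    unconstrained_variances: np.ndarray
    site_scores: np.ndarray  # samples x constrained axes
    variable_scores: np.ndarray | None  # response variables x axes (loadings)
    constraint_scores: np.ndarray  # predictors x axes (correlations)
    total_inertia: float
    dropped_constraints: list[int] = field(default_factory=list)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def db_rda(
    response,
    constraints,
    distance: str = "euclidean",
    labels: list[str] | None = None,
) -> OrdinationResult:
    """Distance-based redundancy analysis.

    Computes a sample distance matrix on ``response`` (rows = samples),
    Gower-centres it, extracts principal coordinates, regresses them on the
    centred ``constraints`` and eigen-decomposes the fitted values.  Axis
    variances are fractions of the total inertia, so constrained plus
    unconstrained fractions sum to 1 (negative eigenvalues from
    non-Euclidean distances are discarded with a warning).
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(constraints, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("response and constraints need the same sample rows")
    if y.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    n = y.shape[0]

    if distance == "euclidean":
        diff = y[:, None, :] - y[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    elif distance == "braycurtis":
        d = bray_curtis(y).d
    else:
        raise ValueError(f"unknown distance {distance!r}")

    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-8 * abs(eigval).max())
    if (eigval < -tol).any():
        logger.warning(
            "db_rda: discarding %d negative eigenvalue(s) from non-Euclidean "
            "distances", int((eigval < -tol).sum()),
        )
    keep = eigval > tol
    coords = eigvec[:, keep] * np.sqrt(eigval[keep])
    total_inertia = float(eigval[keep].sum())

    xc = x - x.mean(axis=0)
    # drop collinear predictor columns via rank-revealing QR
    q, r, piv = _qr_with_pivot(xc)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    dropped = sorted(piv[rank:].tolist())
    if dropped:
        logger.warning("db_rda: dropping collinear constraint columns %s", dropped)
    xr = xc[:, sorted(piv[:rank].tolist())]

    hat = xr @ np.linalg.pinv(xr.T @ xr) @ xr.T
    fitted = hat @ coords
    # constrained axes: PCA of fitted values
    u, sing, vt = np.linalg.svd(fitted, full_matrices=False)
    lam = sing**2
    keep_axes = lam > max(1e-12, 1e-10 * (lam.max() if lam.size else 1.0))
    lam = lam[keep_axes]
    site = u[:, keep_axes] * sing[keep_axes]
    resid = coords - fitted
    _, rsing, _ = np.linalg.svd(resid, full_matrices=False)
    rlam = rsing**2
    rlam = rlam[rlam > max(1e-12, 1e-10 * (rlam.max() if rlam.size else 1.0))]

    yc = y - y.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        variable_scores = _safe_corr(yc, site)
        constraint_scores = _safe_corr(xc, site)
    return OrdinationResult(
        axis_variances=lam / total_inertia,
        unconstrained_variances=rlam / total_inertia,
        site_scores=site,
        variable_scores=variable_scores,
        constraint_scores=constraint_scores,
        total_inertia=total_inertia,
        dropped_constraints=dropped,
    )


def _qr_with_pivot(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, np.asarray(piv)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise correlations between two matrices; constant columns -> 0."""
    out = np.zeros((a.shape[1], b.shape[1]))
    for i in range(a.shape[1]):
        sa = a[:, i].std()
        if sa == 0:
            continue
        for j in range(b.shape[1]):
            sb = b[:, j].std()
            if sb == 0:
                continue
            out[i, j] = np.corrcoef(a[:, i], b[:, j])[0, 1]
    return out
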