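"""Ensemble co-occurrence network inference over ZOTU abundances.

The approach scores every ZOTU pair with five association metrics —
Pearson and Spearman correlation, mutual information, Bray-Curtis
dissimilarity and symmetrised Kullback-Leibler divergence — keeps the top
(most co-occurring) and bottom (most mutually exclusive) ``k`` pairs per
metric, and assesses each candidate edge with a compositionality-aware
permutation/bootstrap scheme (ReBoot): each ZOTU's values are shuffled
across samples and samples renormalised to unit sum, removing the spurious
correlation closure induces.  Per-metric p-values are merged with Brown's
method (Fisher's combination generalised to dependent tests via a
moment-matched scaled chi-square, with the covariance of the per-metric
log-p estimated empirically from shared permutation replicates) and
filtered by Benjamini-Hochberg FDR.

Nodes are attributed to the lake holding >90% of their reads (N.A.
otherwise); the accepted network is summarised as per-lake positive and
negative degree totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .zotu_io import ZotuTable

METRICS = (
    "pearson",
    "spearman",
    "mutual_information",
    "bray_curtis",
    "kullback_leibler",
)
#: metrics where a large value means co-occurrence (vs. dissimilarities)
SIMILARITY_METRICS = frozenset({"pearson", "spearman", "mutual_information"})


# ---------------------------------------------------------------------------
# node filtering and lake attribution
# ---------------------------------------------------------------------------

def filter_nodes(table: ZotuTable, min_total: int = 10) -> ZotuTable:
    """Keep ZOTUs whose total read count across all samples is strictly
    greater than ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    sums = table.zotu_sums()
    keep = [z for z in table.zotu_ids if sums[z] > min_total]
    return table.select_zotus(keep)


@dataclass(frozen=True)
class NodeAttribution:
    zotu_id: str
    lake: str  # lake id or "N.A."
    specificity_fraction: float


def attribute_nodes(
    table: ZotuTable, lake_of: dict[str, str] | None = None
) -> list[NodeAttribution]:
    """Attribute each ZOTU to the lake holding >90% of its reads.

    ``lake_of`` maps sample id -> lake id (defaults to one sample per
    lake).  ZOTUs whose maximal lake share is at most 0.90 are "N.A.";
    in particular any share in (0.70, 0.90] also falls to N.A. because
    assignment requires the strict >90% rule.
    """
    if lake_of is None:
        lake_of = {s: s for s in table.sample_ids}
    lakes = sorted(set(lake_of[s] for s in table.sample_ids))
    totals = np.zeros((table.n_zotus, len(lakes)))
    for j, s in enumerate(table.sample_ids):
        totals[:, lakes.index(lake_of[s])] += table.counts[:, j]
    out: list[NodeAttribution] = []
    for i, zid in enumerate(table.zotu_ids):
        row_total = totals[i].sum()
        if row_total == 0:
            raise ValueError(
                f"ZOTU {zid!r} has zero reads (filter before attribution)"
            )
        share = totals[i] / row_total
        best = int(np.argmax(share))
        frac = float(share[best])
        out.append(
            NodeAttribution(
                zotu_id=zid,
                lake=lakes[best] if frac > 0.90 else "N.A.",
                specificity_fraction=frac,
            )
        )
    return out


# ---------------------------------------------------------------------------
# association metrics
# ---------------------------------------------------------------------------

def relative_abundance(counts) -> np.ndarray:
    """Normalise each sample (column) to unit sum."""
    x = np.asarray(counts, dtype=float)
    col = x.sum(axis=0)
    if (col <= 0).any():
        raise ValueError("every sample needs at least one read")
    return x / col


def mi_bins(n_samples: int) -> int:
    """Equal-frequency bin count for mutual information: floor(sqrt(n)),
    minimum 2."""
    return max(2, int(np.floor(np.sqrt(n_samples))))


def _row_corr(x: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; constant rows give NaN."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (xc @ xc.T) / np.outer(norm, norm)
    c[norm == 0, :] = np.nan
    c[:, norm == 0] = np.nan
    return np.clip(c, -1.0, 1.0, out=c)


def metric_matrices(rel: np.ndarray, bins: int | None = None) -> dict[str, np.ndarray]:
    """All five symmetric pairwise metric matrices for a relative-abundance
    matrix (rows = ZOTUs, columns = samples summing to 1)."""
    n, m = rel.shape
    if bins is None:
        bins = mi_bins(m)
    out: dict[str, np.ndarray] = {}
    out["pearson"] = _row_corr(rel)
    ranks = stats.rankdata(rel, axis=1)
    out["spearman"] = _row_corr(ranks)

    # Bray-Curtis between ZOTU profiles
    diff = np.abs(rel[:, None, :] - rel[None, :, :]).sum(axis=2)
    tot = rel.sum(axis=1)
    denom = tot[:, None] + tot[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(denom > 0, diff / denom, 1.0)
    np.fill_diagonal(bc, 0.0)
    out["bray_curtis"] = bc

    # symmetrised KL on pseudocounted, renormalised profiles
    nonzero = rel[rel > 0]
    pc = 0.5 * nonzero.min() if nonzero.size else 1e-6
    a = rel + pc
    a = a / a.sum(axis=1, keepdims=True)
    la = np.log(a)
    dkl = (a * la).sum(axis=1)[:, None] - a @ la.T
    kl = 0.5 * (dkl + dkl.T)
    np.fill_diagonal(kl, 0.0)
    out["kullback_leibler"] = np.maximum(kl, 0.0)

    # mutual information on equal-frequency discretisation
    order_ranks = stats.rankdata(rel, axis=1, method="ordinal") - 1
    dig = (order_ranks * bins) // m  # (n, m) in [0, bins)
    onehot = (dig[:, None, :] == np.arange(bins)[None, :, None]).astype(float)
    joint = np.einsum("ika,jla->ijkl", onehot, onehot) / m
    pmarg = onehot.sum(axis=2) / m  # (n, bins)
    outer = pmarg[:, None, :, None] * pmarg[None, :, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(joint > 0, joint * np.log(joint / outer), 0.0)
    mi = terms.sum(axis=(2, 3))
    np.fill_diagonal(mi, 0.0)
    out["mutual_information"] = np.maximum(mi, 0.0)
    return out


@dataclass
class AssociationScores:
    zotu_ids: list[str]
    matrices: dict[str, np.ndarray]
    bins: int

    def score(self, metric: str, a: str, b: str) -> float:
        i, j = self.zotu_ids.index(a), self.zotu_ids.index(b)
        return float(self.matrices[metric][i, j])


def association_scores(rel, zotu_ids: list[str] | None = None) -> AssociationScores:
    """Score all ZOTU pairs with the five ensemble metrics."""
    rel = np.asarray(rel, dtype=float)
    if zotu_ids is None:
        zotu_ids = [str(i) for i in range(rel.shape[0])]
    bins = mi_bins(rel.shape[1])
    return AssociationScores(
        zotu_ids=list(zotu_ids), matrices=metric_matrices(rel, bins), bins=bins
    )


# ---------------------------------------------------------------------------
# candidate edges, significance, merging
# ---------------------------------------------------------------------------

@dataclass
class EdgeRecord:
    zotu_a: str
    zotu_b: str
    scores: dict[str, float] = field(default_factory=dict)
    directions: dict[str, int] = field(default_factory=dict)  # supporting metrics
    p_values: dict[str, float] = field(default_factory=dict)
    merged_p: float = float("nan")
    q: float = float("nan")
    sign: str | None = None  # "positive" / "negative" after consensus

    @property
    def pair(self) -> tuple[str, str]:
        return (self.zotu_a, self.zotu_b)

    @property
    def supporting_metrics(self) -> frozenset[str]:
        return frozenset(self.directions)

    def consensus_sign(self) -> str | None:
        signs = set(self.directions.values())
        if signs == {1}:
            return "positive"
        if signs == {-1}:
            return "negative"
        return None  # conflict (or no supporting metric)


def candidate_edges(
    scores: AssociationScores, k: int, include_mi_bottom: bool = False
) -> list[EdgeRecord]:
    """Per metric, the ``k`` most co-occurring (top) and ``k`` most mutually
    exclusive (bottom) pairs; the candidate set is the union over metrics.

    Direction per metric: for correlations/MI, high score = co-occurrence;
    for dissimilarities, low = co-occurrence and high = exclusion.  MI
    contributes no bottom set by default (low MI means no association, not
    exclusion).  Ties break on the lexicographic pair id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ids = scores.zotu_ids
    n = len(ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    records: dict[tuple[str, str], EdgeRecord] = {}

    def record(i: int, j: int) -> EdgeRecord:
        key = (ids[i], ids[j])
        if key not in records:
            records[key] = EdgeRecord(zotu_a=key[0], zotu_b=key[1])
        return records[key]

    for metric in METRICS:
        mat = scores.matrices[metric]
        valid = [
            (i, j) for i, j in pairs if np.isfinite(mat[i, j])
        ]
        similarity = metric in SIMILARITY_METRICS
        # sort once by (score, pair-id); co-occurrence end depends on metric kind
        ordered = sorted(
            valid, key=lambda ij: (mat[ij[0], ij[1]], (ids[ij[0]], ids[ij[1]]))
        )
        if similarity:
            top = sorted(
                valid,
                key=lambda ij: (-mat[ij[0], ij[1]], (ids[ij[0]], ids[ij[1]])),
            )[:k]
            bottom = ordered[:k] if (metric != "mutual_information" or include_mi_bottom) else []
        else:
            top = ordered[:k]  # small dissimilarity = co-occurrence
            bottom = sorted(
                valid,
                key=lambda ij: (-mat[ij[0], ij[1]], (ids[ij[0]], ids[ij[1]])),
            )[:k]
        for i, j in top:
            rec = record(i, j)
            rec.scores[metric] = float(mat[i, j])
            rec.directions[metric] = 1
        for i, j in bottom:
            rec = record(i, j)
            rec.scores[metric] = float(mat[i, j])
            # a pair can be both ends only when k spans all pairs; keep -1
            rec.directions[metric] = -1 if metric not in rec.directions or rec.directions[metric] != 1 else 0
    for rec in records.values():
        # fill remaining metric scores for reporting
        i, j = ids.index(rec.zotu_a), ids.index(rec.zotu_b)
        for metric in METRICS:
            rec.scores.setdefault(metric, float(scores.matrices[metric][i, j]))
        rec.directions = {m: d for m, d in rec.directions.items() if d != 0}
    return [records[key] for key in sorted(records)]


@dataclass
class EdgeSignificance:
    """Per-edge, per-metric p-values plus the shared permutation replicates
    (needed by Brown's covariance estimate)."""

    edges: list[EdgeRecord]
    null_scores: dict[str, np.ndarray]  # metric -> (n_edges, n_iter)
    boot_scores: dict[str, np.ndarray]
    n_iter: int


def edge_significance(
    counts,
    zotu_ids: list[str],
    edges: list[EdgeRecord],
    n_iter: int = 100,
    seed: int = 0,
    bins: int | None = None,
) -> EdgeSignificance:
    """ReBoot-style edge significance.

    Null distribution: each ZOTU's values permuted independently across
    samples, then samples renormalised to unit sum (breaking association
    while preserving compositional closure).  Stability distribution:
    bootstrap resamples of samples.  The p-value is the two-sided tail of
    the bootstrap-mean score under a Gaussian fit to the permutation null;
    a degenerate null (sd 0) gives p = 1.  p-values are clamped below at
    ``1/(n_iter+1)``, never 0.  Identical seed and ``n_iter`` give
    identical p-values.
    """
    if n_iter < 10:
        raise ValueError("n_iter must be >= 10 (null too unstable below)")
    x = np.asarray(counts, dtype=float)
    n, m = x.shape
    if bins is None:
        bins = mi_bins(m)
    rng = np.random.default_rng(seed)
    idx = {z: i for i, z in enumerate(zotu_ids)}
    pair_idx = np.array(
        [(idx[e.zotu_a], idx[e.zotu_b]) for e in edges], dtype=int
    ).reshape(-1, 2)
    n_edges = len(edges)

    null_scores = {metric: np.empty((n_edges, n_iter)) for metric in METRICS}
    boot_scores = {metric: np.empty((n_edges, n_iter)) for metric in METRICS}

    def extract(mats: dict[str, np.ndarray], store: dict[str, np.ndarray], it: int):
        for metric in METRICS:
            store[metric][:, it] = mats[metric][pair_idx[:, 0], pair_idx[:, 1]]

    for it in range(n_iter):
        perm = np.empty_like(x)
        for i in range(n):
            perm[i] = x[i, rng.permutation(m)]
        extract(metric_matrices(relative_abundance(perm), bins), null_scores, it)
    for it in range(n_iter):
        take = rng.integers(0, m, size=m)
        boot = x[:, take]
        extract(metric_matrices(relative_abundance(boot), bins), boot_scores, it)

    p_floor = 1.0 / (n_iter + 1)
    for e_i, edge in enumerate(edges):
        for metric in METRICS:
            null = null_scores[metric][e_i]
            boot = boot_scores[metric][e_i]
            if not (np.isfinite(null).all() and np.isfinite(boot).all()):
                edge.p_values[metric] = 1.0
                continue
            mu, sd = null.mean(), null.std(ddof=1)
            if sd == 0:
                edge.p_values[metric] = 1.0
                continue
            z = (boot.mean() - mu) / sd
            p = 2.0 * stats.norm.sf(abs(z))
            edge.p_values[metric] = float(min(1.0, max(p, p_floor)))
    return EdgeSignificance(
        edges=edges, null_scores=null_scores, boot_scores=boot_scores, n_iter=n_iter
    )


def _pseudo_pvalues(null: np.ndarray) -> np.ndarray:
    """Empirical two-sided p-value of each permutation replicate within its
    own null distribution (used to learn the dependence between metrics)."""
    n = null.shape[-1]
    le = stats.rankdata(null, axis=-1, method="max") / n
    ge = 1.0 - (stats.rankdata(null, axis=-1, method="min") - 1) / n
    p = 2.0 * np.minimum(le, ge)
    return np.clip(p, 1.0 / (n + 1), 1.0)


def merge_pvalues(
    per_metric_p, null_scores: np.ndarray | None = None
) -> float:
    """Brown's method for combining dependent p-values.

    ``psi = -2 sum ln p_i`` is referred to a scaled chi-square
    ``c * chi2(f)`` with ``c = Var(psi) / (2 E[psi])`` and
    ``f = 2 E[psi]^2 / Var(psi)``, where ``E[psi] = 2k`` and ``Var(psi)``
    includes the pairwise covariances of ``-2 ln p`` estimated empirically
    from per-metric p-values recomputed on shared permutation replicates
    (``null_scores``, shape (k, n_iter)).  Without replicates the
    covariances are taken as zero and the method reduces to Fisher's.  A
    single p-value is returned unchanged; zeros are clamped to a positive
    floor before logging.
    """
    p = np.asarray(per_metric_p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("need at least one valid p-value")
    k = p.size
    floor = 1e-12
    if null_scores is not None:
        floor = 1.0 / (np.asarray(null_scores).shape[-1] + 1)
    p = np.clip(p, floor, 1.0)
    if k == 1:
        return float(p[0])
    psi = float(-2.0 * np.log(p).sum())
    e_psi = 2.0 * k
    if null_scores is None:
        var_psi = 4.0 * k  # independence: Fisher's method
    else:
        null_scores = np.asarray(null_scores, dtype=float)
        if null_scores.shape[0] != k:
            raise ValueError("null_scores must have one row per p-value")
        logs = -2.0 * np.log(_pseudo_pvalues(null_scores))
        # Under the null each -2 ln p is chi2(2) (variance 4) by construction;
        # only the dependence between metrics needs estimating.  Use the
        # empirical correlation with the known marginal variance, which keeps
        # the Fisher (independent) and duplicate-metric (identical) limits
        # exact despite the discreteness of rank-based pseudo p-values.
        sd = logs.std(axis=1, ddof=1)
        ok = sd > 0
        corr = np.eye(k)
        if ok.sum() >= 2:
            sub = np.corrcoef(logs[ok])
            corr[np.ix_(np.where(ok)[0], np.where(ok)[0])] = sub
        var_psi = float(4.0 * corr.sum())
        if not np.isfinite(var_psi) or var_psi <= 0:
            var_psi = 4.0 * k
    c = var_psi / (2.0 * e_psi)
    f = 2.0 * e_psi**2 / var_psi
    return float(stats.chi2.sf(psi / c, f))


def bh_correct(p_values, q_threshold: float = 0.05):
    """Benjamini-Hochberg step-up; returns (kept boolean array, q-values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q <= q_threshold, q


# ---------------------------------------------------------------------------
# summary and driver
# ---------------------------------------------------------------------------

@dataclass
class NetworkSummary:
    positive_degree: dict[str, int]
    negative_degree: dict[str, int]
    n_nodes: int
    n_edges: int
    n_conflicts: int

    def degree_total(self) -> int:
        return sum(self.positive_degree.values()) + sum(self.negative_degree.values())


def summarize_network(
    edges: list[EdgeRecord], attributions: list[NodeAttribution]
) -> NetworkSummary:
    """Per-lake signed degree totals over the accepted edges.

    An edge's sign is the consensus of its supporting metrics (correlation
    sign; a dissimilarity top hit counts positive, bottom negative); edges
    whose metrics disagree are dropped and counted as conflicts.  Each
    accepted edge contributes one degree of its sign at both endpoints.
    """
    lake_of_zotu = {a.zotu_id: a.lake for a in attributions}
    lakes = sorted(set(lake_of_zotu.values()))
    pos = {lake: 0 for lake in lakes}
    neg = {lake: 0 for lake in lakes}
    n_conflicts = 0
    n_accepted = 0
    touched: set[str] = set()
    for edge in edges:
        sign = edge.consensus_sign()
        if sign is None:
            n_conflicts += 1
            continue
        edge.sign = sign
        n_accepted += 1
        for z in edge.pair:
            if z not in lake_of_zotu:
                raise ValueError(f"edge endpoint {z!r} has no attribution")
            touched.add(z)
            if sign == "positive":
                pos[lake_of_zotu[z]] += 1
            else:
                neg[lake_of_zotu[z]] += 1
    return NetworkSummary(
        positive_degree=pos,
        negative_degree=neg,
        n_nodes=len(touched),
        n_edges=n_accepted,
        n_conflicts=n_conflicts,
    )


@dataclass
class NetworkResult:
    edges: list[EdgeRecord]  # all candidates, with p/q filled
    accepted: list[EdgeRecord]
    attributions: list[NodeAttribution]
    summary: NetworkSummary
    graph: nx.Graph


def infer_network(
    table: ZotuTable,
    lake_of: dict[str, str] | None = None,
    min_total: int = 10,
    k: int = 10,
    n_iter: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    include_mi_bottom: bool = False,
) -> NetworkResult:
    """Full ensemble network inference: filter, score, select candidates,
    assess significance, merge, FDR-filter, attribute and summarise."""
    filtered = filter_nodes(table, min_total=min_total)
    attributions = attribute_nodes(filtered, lake_of)
    rel = relative_abundance(filtered.counts)
    scores = association_scores(rel, filtered.zotu_ids)
    edges = candidate_edges(scores, k=k, include_mi_bottom=include_mi_bottom)
    if not edges:
        summary = summarize_network([], attributions)
        return NetworkResult(edges, [], attributions, summary, nx.Graph())
    sig = edge_significance(
        filtered.counts, filtered.zotu_ids, edges, n_iter=n_iter, seed=seed
    )
    for e_i, edge in enumerate(edges):
        ps = [edge.p_values[m] for m in METRICS if m in edge.p_values]
        nulls = np.stack(
            [sig.null_scores[m][e_i] for m in METRICS if m in edge.p_values]
        )
        edge.merged_p = merge_pvalues(ps, nulls)
    kept, q = bh_correct([e.merged_p for e in edges], q_threshold=alpha)
    for edge, qv in zip(edges, q):
        edge.q = float(qv)
    accepted = [e for e, keep in zip(edges, kept) if keep]
    summary = summarize_network(accepted, attributions)
    graph = nx.Graph()
    lake_of_zotu = {a.zotu_id: a.lake for a in attributions}
    abundance = filtered.zotu_sums()
    for a in attributions:
        graph.add_node(
            a.zotu_id,
            lake=a.lake,
            specificity=a.specificity_fraction,
            abundance=int(abundance[a.zotu_id]),
        )
    for edge in accepted:
        if edge.sign is None:
            continue
        graph.add_edge(
            edge.zotu_a, edge.zotu_b, sign=edge.sign, q=edge.q, p=edge.merged_p
        )
    return NetworkResult(edges, accepted, attributions, summary, graph)


def edges_to_dataframe(edges: list[EdgeRecord]) -> pd.DataFrame:
    rows = []
    for e in edges:
        row = {"zotu_a": e.zotu_a, "zotu_b": e.zotu_b, "sign": e.sign,
               "merged_p": e.merged_p, "q": e.q,
               "supporting": ",".join(sorted(e.directions))}
        for m in METRICS:
            row[f"score_{m}"] = e.scores.get(m, float("nan"))
            row[f"p_{m}"] = e.p_values.get(m, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def summary_to_dataframe(summary: NetworkSummary) -> pd.DataFrame:
    lakes = sorted(summary.positive_degree)
    return pd.DataFrame(
        {
            "lake": lakes,
            "positive_degree": [summary.positive_degree[l] for l in lakes],
            "negative_degree": [summary.negative_degree[l] for l in lakes],
        }
    )
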