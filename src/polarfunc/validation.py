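"""Statistical self-validation harness.

Runs the pipeline end-to-end on synthetic data with known ground truth and
measures its operating characteristics: the false-edge rate of the network
inference on null (independent-ZOTU) communities, its sensitivity to
strongly planted positive pairs, exactness of the signed-degree
bookkeeping, annotation round-trip recovery, CLPP plate recovery at zero
noise, and the Euclidean db-RDA / classical RDA equivalence.  Each routine
is a pure function of its parameters and a seed.

Problem sizes default to desk-scale settings (hundreds of null replicates
of a 15-ZOTU x 10-sample community; a 30-replicate sensitivity panel) that
complete in about a minute on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .coocnet import (
    EdgeRecord,
    NodeAttribution,
    infer_network,
    relative_abundance,
    summarize_network,
)
from .ecoplate import clpp_indices, load_layout, score_plate
from .faprotax import annotate, load_rules
from .multivariate import db_rda
from .synthetic import (
    GROUP_TAXON_FRAGMENTS,
    CommunitySpec,
    PlateSpec,
    generate_null_table,
    generate_plate,
    generate_zotu_table,
)


def _child_seeds(seed: int, n: int, salt: int) -> list[int]:
    """Deterministic sub-seeds below 2**31."""
    rng = np.random.default_rng([seed, salt])
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def null_edge_rate(
    n_replicates: int = 200,
    n_zotus: int = 15,
    n_samples: int = 10,
    n_iter: int = 100,
    k: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I behaviour on null communities (independent ZOTUs).

    Counts edges accepted at FDR ``alpha`` over all tested candidate edges
    across replicates, and the one-sided binomial 95% acceptance bound for
    a per-edge error rate of ``alpha``.
    """
    table_seeds = _child_seeds(seed, n_replicates, salt=1)
    infer_seeds = _child_seeds(seed, n_replicates, salt=2)
    accepted = tested = 0
    for rep in range(n_replicates):
        table = generate_null_table(
            n_zotus, n_samples, depth=2000, seed=table_seeds[rep]
        )
        result = infer_network(
            table, min_total=10, k=k, n_iter=n_iter, alpha=alpha,
            seed=infer_seeds[rep],
        )
        tested += len(result.edges)
        accepted += len(result.accepted)
    bound = int(stats.binom.ppf(0.95, tested, alpha)) if tested else 0
    return {
        "accepted": accepted,
        "tested": tested,
        "rate": accepted / tested if tested else 0.0,
        "nominal": alpha,
        "binomial_95_bound": bound,
        "within_bound": accepted <= bound,
    }


def planted_edge_sensitivity(
    n_replicates: int = 30,
    n_zotus: int = 15,
    n_samples: int = 16,
    n_planted: int = 3,
    strength: float = 3.0,
    min_effect_r: float = 0.9,
    n_iter: int = 100,
    k: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of planted positive pairs by the full inference pipeline.

    Sensitivity is the fraction of planted pairs with realised abundance
    correlation at least ``min_effect_r`` that are accepted with positive
    sign at FDR ``alpha``.
    """
    table_seeds = _child_seeds(seed, n_replicates, salt=3)
    infer_seeds = _child_seeds(seed, n_replicates, salt=4)
    planted_total = recovered = 0
    realized: list[float] = []
    positions = [(3 * i, 3 * i + 1) for i in range(n_planted)]
    for rep in range(n_replicates):
        spec = CommunitySpec(
            n_lakes=1,
            zotus_per_lake=0,
            n_shared=n_zotus,
            samples_per_lake=n_samples,
            depth_mean=2000,
            planted_edges=[(pos, "positive", strength) for pos in positions],
            seed=table_seeds[rep],
        )
        table, truth = generate_zotu_table(spec)
        rel = relative_abundance(table.counts)
        result = infer_network(
            table, min_total=10, k=k, n_iter=n_iter, alpha=alpha,
            seed=infer_seeds[rep],
        )
        accepted = {e.pair: e.sign for e in result.accepted}
        for (a, b), _, _ in truth["planted_edges"]:
            ia, ib = table.zotu_ids.index(a), table.zotu_ids.index(b)
            r = float(np.corrcoef(rel[ia], rel[ib])[0, 1])
            realized.append(r)
            if r < min_effect_r:
                continue
            planted_total += 1
            pair = (a, b) if (a, b) in accepted else (b, a)
            if accepted.get(pair) == "positive":
                recovered += 1
    return {
        "recovered": recovered,
        "eligible_planted": planted_total,
        "sensitivity": recovered / planted_total if planted_total else float("nan"),
        "median_realized_r": float(np.median(realized)),
    }


def degree_bookkeeping_errors(
    n_lakes: int = 4,
    positive_per_lake: int = 5,
    negative_per_lake: int = 3,
    seed: int = 0,
) -> dict:
    """Exactness of the signed per-lake degree summary on a planted network.

    Builds a network whose edges and signs are known by construction
    (within-lake positive edges, cross-lake negative edges anchored at each
    lake) and compares the summary against hand-counted truth.
    """
    rng = np.random.default_rng([seed, 5])
    lakes = [f"Lake{chr(ord('A') + i)}" for i in range(n_lakes)]
    nodes_per_lake = positive_per_lake + negative_per_lake + 1
    nodes = {
        lake: [f"{lake}_z{i}" for i in range(nodes_per_lake)] for lake in lakes
    }
    attributions = [
        NodeAttribution(zotu_id=z, lake=lake, specificity_fraction=0.95)
        for lake in lakes
        for z in nodes[lake]
    ]
    edges: list[EdgeRecord] = []
    expected_pos = {lake: 0 for lake in lakes}
    expected_neg = {lake: 0 for lake in lakes}
    for li, lake in enumerate(lakes):
        # positive edges inside the lake's sub-network
        for i in range(positive_per_lake):
            a, b = nodes[lake][i], nodes[lake][i + 1]
            edges.append(EdgeRecord(zotu_a=a, zotu_b=b, directions={"pearson": 1}))
            expected_pos[lake] += 2
        # negative (exclusion) edges towards the next lake
        other = lakes[(li + 1) % n_lakes]
        for i in range(negative_per_lake):
            a = nodes[lake][positive_per_lake + 1 + i]
            b = nodes[other][rng.integers(nodes_per_lake)]
            edges.append(
                EdgeRecord(zotu_a=a, zotu_b=b, directions={"bray_curtis": -1})
            )
            expected_neg[lake] += 1
            expected_neg[other] += 1
    summary = summarize_network(edges, attributions)
    errors = sum(
        summary.positive_degree[lake] != expected_pos[lake] for lake in lakes
    ) + sum(summary.negative_degree[lake] != expected_neg[lake] for lake in lakes)
    invariant_ok = summary.degree_total() == 2 * summary.n_edges
    return {
        "cell_errors": errors,
        "n_edges": summary.n_edges,
        "degree_invariant_holds": bool(invariant_ok),
    }


def annotation_recovery(
    n_zotus_hit: int = 40, n_unassigned: int = 20, seed: int = 0
) -> dict:
    """Round-trip: annotate a table whose taxonomies were generated from
    the bundled rules; report the fraction of planted (ZOTU, group)
    memberships recovered and whether recovery is exact (no extras)."""
    rules = load_rules()
    rng = np.random.default_rng([seed, 6])
    plantable = sorted(GROUP_TAXON_FRAGMENTS)
    rule_hits = {
        z: sorted(
            rng.choice(plantable, size=rng.integers(1, 4), replace=False).tolist()
        )
        for z in range(n_zotus_hit)
    }
    spec = CommunitySpec(
        n_lakes=2,
        zotus_per_lake=(n_zotus_hit + n_unassigned) // 2,
        n_shared=0,
        depth_mean=2000,
        rule_hits=rule_hits,
        seed=int(rng.integers(2**31 - 1)),
    )
    table, truth = generate_zotu_table(spec, rules)
    ftable = annotate(table, rules)
    planted_pairs = recovered_pairs = 0
    exact = True
    for group in rules.rules:
        expected = truth["function_memberships"][group]
        got = set(ftable.assignments[group])
        planted_pairs += len(expected)
        recovered_pairs += len(expected & got)
        if got != expected:
            exact = False
    return {
        "planted_memberships": planted_pairs,
        "recovered_memberships": recovered_pairs,
        "recovery_percent": 100.0 * recovered_pairs / planted_pairs,
        "exact": exact,
    }


def ecoplate_recovery(seed: int = 0) -> dict:
    """Noise-free plate round-trip: AWCD and richness recovered exactly,
    and a forced single-replicate positive zeroed by the scorer."""
    layout = load_layout()
    rng = np.random.default_rng([seed, 7])
    ranks = rng.integers(0, 4, size=31).astype(float)
    utilization = dict(zip(layout.substrate_ids, ranks))
    spec = PlateSpec(utilization=utilization, noise_sigma=0.0, seed=seed)
    wells = generate_plate(spec, layout)
    cuts = (25.0, 75.0, 125.0)  # rank midpoints at 50 intensity units/rank
    indices = clpp_indices(score_plate(wells, layout, cuts))
    truth_awcd = float(ranks.sum() / 31)
    truth_s = int((ranks > 0).sum())
    # false-positive exercise on a substrate planted positive in 1 replicate
    target = layout.substrate_ids[int(rng.integers(31))]
    fp_spec = PlateSpec(
        utilization={s: 1.0 for s in layout.substrate_ids},
        false_positive_substrate=target,
        seed=seed,
    )
    fp_profile = score_plate(generate_plate(fp_spec, layout), layout, cuts)
    return {
        "awcd": indices["AWCD"],
        "awcd_truth": truth_awcd,
        "awcd_abs_error": abs(indices["AWCD"] - truth_awcd),
        "richness": indices["S"],
        "richness_truth": truth_s,
        "false_positive_zeroed": not fp_profile.used[target],
    }


def dbrda_equivalence_deviation(
    n_samples: int = 6, n_vars: int = 4, n_constraints: int = 2, seed: int = 0
) -> dict:
    """Maximum deviation between Euclidean db-RDA axis variances and a
    direct classical RDA computation on the raw matrix."""
    rng = np.random.default_rng([seed, 8])
    y = rng.random((n_samples, n_vars)) * 10
    x = rng.random((n_samples, n_constraints))
    result = db_rda(y, x, distance="euclidean")
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    hat = xc @ np.linalg.pinv(xc.T @ xc) @ xc.T
    lam = np.linalg.svd(hat @ yc, compute_uv=False) ** 2
    lam = lam[lam > 1e-12]
    total = (np.linalg.svd(yc, compute_uv=False) ** 2).sum()
    expected = lam / total
    m = len(result.axis_variances)
    dev = float(np.abs(result.axis_variances - expected[:m]).max())
    return {"max_abs_deviation": dev, "n_axes": m}
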