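"""Seed-deterministic synthetic inputs with known ground truth.

Two generators emulate the pipeline's upstream data so every stage is
testable without downloads:

* :func:`generate_zotu_table` builds a multi-lake ZOTU count table with a
  log-normal rank-abundance structure, controllable lake-specificity (a
  target fraction of each specific ZOTU's mass in its home lake), taxonomy
  strings engineered to hit chosen groups of the bundled rule database,
  and planted co-occurring / mutually exclusive ZOTU pairs driven by a
  shared latent Gaussian factor on the log scale.  A truth record captures
  every planted property, including the closure-expanded function
  memberships implied by the rule database's ``add_group`` nesting.

* :func:`generate_plate` builds 96-well intensity grids (optionally a PNG
  photo) from a known substrate-utilisation rank profile plus Gaussian
  noise, with a switch to force a single-replicate positive that exercises
  the false-positive rule downstream.

Defaults mirror the study conditions the pipeline targets: 7 lakes, one
surface sample each, ~2000 reads per sample after rarefaction, log-normal
sigma 1.0, >90% home-lake mass for specific ZOTUs and an even spread
(maximal share well under 70%) for shared ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecoplate import PlateLayout, WellIntensities, load_layout
from .faprotax import FunctionRuleSet, load_rules
from .zotu_io import TaxonomyPath, ZotuTable, parse_taxonomy

#: One designated, unique taxon fragment per rule-database group with its own
#: patterns.  Building a taxonomy from these fragments plants membership in
#: exactly the chosen groups (plus their add_group ancestors).
GROUP_TAXON_FRAGMENTS: dict[str, str] = {
    "aerobic_chemoheterotrophy": "Sphingomonadaceae",
    "aromatic_hydrocarbon_degradation": "Gordonia",
    "cellulolysis": "Lewinella",
    "methanol_oxidation": "Paracoccus",
    "methanotrophy": "Methylomonaceae",
    "methylotrophy": "Methylophilaceae",
    "chemoheterotrophy": "Acinetobacter",
    "fermentation": "Carnobacteriaceae",
    "photoautotrophy": "Tychonema",
    "photoheterotrophy": "Rhodoferax",
    "denitrification": "Stenotrophomonas",
    "nitrate_respiration": "Marinobacter",
    "nitrate_reduction": "Ensifer",
    "nitrogen_fixation": "Bradyrhizobium",
    "nitrification": "Nitrosomonadaceae",
    "ureolysis": "Singulisphaera",
    "sulfate_respiration": "Desulfobacteraceae",
    "thiosulfate_respiration": "Alishewanella",
    "sulfur_respiration": "Desulfuromonas",
    "dark_sulfide_oxidation": "Thiobacillus",
    "iron_respiration": "Geobacter",
    "dark_hydrogen_oxidation": "Hydrogenophaga",
}


@dataclass
class CommunitySpec:
    """Parameters of a synthetic multi-lake community."""

    n_lakes: int = 7
    zotus_per_lake: int = 10
    n_shared: int = 10
    samples_per_lake: int = 1
    depth_mean: int = 2000
    specificity_target: float = 0.95
    lognormal_sigma: float = 1.0
    planted_edges: list[tuple[tuple[int, int], str, float]] = field(
        default_factory=list
    )  # ((zotu index a, b), "positive"/"negative", loading)
    rule_hits: dict[int, list[str]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_lakes < 1 or self.zotus_per_lake < 0 or self.n_shared < 0:
            raise ValueError("invalid community sizes")
        n = self.n_lakes * self.zotus_per_lake + self.n_shared
        if n == 0:
            raise ValueError("no ZOTUs requested")
        if not 0.0 <= self.specificity_target <= 1.0:
            raise ValueError("specificity_target must be in [0, 1]")
        if (
            self.specificity_target >= 1.0
            and self.n_lakes > 1
            and self.zotus_per_lake > 0
        ):
            raise ValueError(
                "specificity 1.0 is unreachable with multinomial sampling noise"
            )
        for (a, b), sign, strength in self.planted_edges:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise ValueError(f"planted pair ({a},{b}) out of range")
            if sign not in ("positive", "negative"):
                raise ValueError(f"planted sign {sign!r}")
            if strength < 0:
                raise ValueError("planted strength must be >= 0")
        for z in self.rule_hits:
            if not 0 <= z < n:
                raise ValueError(f"rule_hits index {z} out of range")


_FILLER_PHYLA = (
    "Planctomycetota", "Verrucomicrobiota", "Chloroflexota",
    "Acidobacteriota", "Armatimonadota", "Patescibacteria",
)


def _taxonomy_for(
    zid: str, groups: list[str], rng: np.random.Generator
) -> TaxonomyPath:
    """Build a SILVA-style taxonomy string containing the designated fragment
    of every requested group (or an unclassified filler lineage)."""
    unknown = [g for g in groups if g not in GROUP_TAXON_FRAGMENTS]
    if unknown:
        raise ValueError(f"no designated taxon fragment for groups {unknown}")
    fragments = [GROUP_TAXON_FRAGMENTS[g] for g in groups]
    if fragments:
        ranks = ["Bacteria", "SynthPhylum", "SynthClass", "SynthOrder"] + fragments
    else:
        phylum = _FILLER_PHYLA[int(rng.integers(len(_FILLER_PHYLA)))]
        ranks = ["Bacteria", phylum, f"Unclassified{zid}"]
    return parse_taxonomy(";".join(ranks))


def expected_memberships(
    rule_hits: dict[int, list[str]], rules: FunctionRuleSet
) -> dict[str, set[int]]:
    """Closure-expand planted group hits over the rule inclusion DAG:
    a group containing (via add_group) a planted group also matches."""
    # ancestors[g] = groups whose effective patterns include g's
    members: dict[str, set[int]] = {g: set() for g in rules.rules}

    def includes(group: str, target: str, seen: frozenset = frozenset()) -> bool:
        if group == target:
            return True
        if group in seen:
            return False
        return any(
            includes(inc, target, seen | {group})
            for inc in rules.rules[group].included_groups
        )

    for z, groups in rule_hits.items():
        for g in rules.rules:
            if any(includes(g, hit) for hit in groups):
                members[g].add(z)
    return members


def generate_zotu_table(
    spec: CommunitySpec, rules: FunctionRuleSet | None = None
) -> tuple[ZotuTable, dict]:
    """Generate a multi-lake ZOTU table plus its ground-truth record.

    Lake-specific ZOTUs place a ``specificity_target`` fraction of their
    expected mass in their home lake; shared ZOTUs spread evenly (maximal
    share ``1/n_lakes``).  Planted pairs co-vary (or anti-vary) through a
    shared standard-normal latent factor added on the log-abundance scale
    with the given loading.  Counts are multinomial at ``depth_mean`` per
    sample, so every sample is already at uniform depth.
    """
    spec.validate()
    if rules is None:
        rules = load_rules()
    rng = np.random.default_rng(spec.seed)
    n_specific = spec.n_lakes * spec.zotus_per_lake
    n = n_specific + spec.n_shared
    n_samples = spec.n_lakes * spec.samples_per_lake
    lakes = [f"Lake{chr(ord('A') + l)}" for l in range(spec.n_lakes)]
    sample_ids = [
        f"{lakes[l]}_s{r + 1}"
        for l in range(spec.n_lakes)
        for r in range(spec.samples_per_lake)
    ]
    lake_of_sample = {
        sid: lakes[i // spec.samples_per_lake] for i, sid in enumerate(sample_ids)
    }
    home_lake = {z: z // spec.zotus_per_lake for z in range(n_specific)}

    base = rng.lognormal(mean=0.0, sigma=spec.lognormal_sigma, size=n)
    log_lambda = np.zeros((n, n_samples))
    s = spec.specificity_target
    for z in range(n):
        for j, sid in enumerate(sample_ids):
            lake_idx = lakes.index(lake_of_sample[sid])
            if z < n_specific:
                if spec.n_lakes == 1:
                    w = 1.0
                elif lake_idx == home_lake[z]:
                    w = s
                else:
                    w = (1.0 - s) / (spec.n_lakes - 1)
            else:
                w = 1.0 / spec.n_lakes
            log_lambda[z, j] = np.log(base[z] * max(w, 1e-12))

    # planted associations: shared latent factor per sample on the log scale
    factors = rng.standard_normal((len(spec.planted_edges), n_samples))
    for e_i, ((a, b), sign, strength) in enumerate(spec.planted_edges):
        f = factors[e_i]
        log_lambda[a] += strength * f
        log_lambda[b] += strength * f if sign == "positive" else -strength * f

    counts = np.zeros((n, n_samples), dtype=np.int64)
    lam = np.exp(log_lambda)
    for j in range(n_samples):
        p = lam[:, j] / lam[:, j].sum()
        counts[:, j] = rng.multinomial(spec.depth_mean, p)

    zotu_ids = [f"Zotu{z + 1:04d}" for z in range(n)]
    taxonomy = {
        zid: _taxonomy_for(zid, spec.rule_hits.get(z, []), rng)
        for z, zid in enumerate(zotu_ids)
    }
    table = ZotuTable(
        zotu_ids=zotu_ids, sample_ids=sample_ids, counts=counts, taxonomy=taxonomy
    )
    memberships = expected_memberships(spec.rule_hits, rules)
    truth = {
        "lake_of_sample": lake_of_sample,
        "home_lake": {zotu_ids[z]: lakes[l] for z, l in home_lake.items()},
        "shared_zotus": [zotu_ids[z] for z in range(n_specific, n)],
        "planted_edges": [
            ((zotu_ids[a], zotu_ids[b]), sign, strength)
            for (a, b), sign, strength in spec.planted_edges
        ],
        "rule_hits": {
            zotu_ids[z]: list(groups) for z, groups in spec.rule_hits.items()
        },
        "function_memberships": {
            g: {zotu_ids[z] for z in zs} for g, zs in memberships.items()
        },
    }
    return table, truth


def generate_null_table(
    n_zotus: int = 15, n_samples: int = 10, depth: int = 2000, seed: int = 0,
    lognormal_sigma: float = 1.0,
) -> ZotuTable:
    """Independent-ZOTU table (no planted structure): every ZOTU's expected
    abundance is the same in all samples, so any inferred edge is spurious."""
    spec = CommunitySpec(
        n_lakes=1,
        zotus_per_lake=0,
        n_shared=n_zotus,
        samples_per_lake=n_samples,
        depth_mean=depth,
        lognormal_sigma=lognormal_sigma,
        seed=seed,
    )
    table, _ = generate_zotu_table(spec)
    return table


@dataclass
class PlateSpec:
    """Parameters of a synthetic CLPP plate."""

    utilization: dict[str, float] = field(default_factory=dict)  # substrate -> rank 0..3
    noise_sigma: float = 0.0
    control_intensity: float = 20.0
    signal_per_rank: float = 50.0
    false_positive_substrate: str | None = None  # force one replicate positive
    seed: int = 0

    def validate(self, layout: PlateLayout) -> None:
        for sub, rank in self.utilization.items():
            if sub not in layout.substrate_ids:
                raise ValueError(f"unknown substrate {sub!r}")
            if not 0.0 <= rank <= 3.0:
                raise ValueError(f"rank for {sub!r} outside [0, 3]")
        if self.false_positive_substrate is not None and (
            self.false_positive_substrate not in layout.substrate_ids
        ):
            raise ValueError("false_positive_substrate not in layout")


def generate_plate(
    spec: PlateSpec, layout: PlateLayout | None = None
) -> WellIntensities:
    """Well intensities from a planted utilisation profile.

    Each replicate well of a substrate with true rank ``r`` gets intensity
    ``control + r * signal_per_rank + N(0, noise_sigma)``; control wells
    get ``control + noise``.  If ``false_positive_substrate`` is set, only
    its first replicate receives a rank-2 signal (the other two stay at
    control level), which the scorer must reject as a false positive.
    """
    if layout is None:
        layout = load_layout()
    spec.validate(layout)
    rng = np.random.default_rng(spec.seed)
    grid = np.full((layout.n_rows, layout.n_cols), spec.control_intensity)
    for sub in layout.substrate_ids:
        rank = float(spec.utilization.get(sub, 0.0))
        for rep in (1, 2, 3):
            r, c = layout.well_positions[(sub, rep)]
            grid[r, c] = spec.control_intensity + rank * spec.signal_per_rank
    if spec.false_positive_substrate is not None:
        sub = spec.false_positive_substrate
        for rep in (1, 2, 3):
            r, c = layout.well_positions[(sub, rep)]
            grid[r, c] = spec.control_intensity + (
                2.0 * spec.signal_per_rank if rep == 1 else 0.0
            )
    if spec.noise_sigma > 0:
        grid = grid + rng.normal(0.0, spec.noise_sigma, size=grid.shape)
    return WellIntensities(intensity=np.maximum(grid, 0.0))


def render_plate_image(
    wells: WellIntensities,
    path,
    margin: int = 20,
    pitch: int = 24,
    radius: int = 8,
    background: int = 250,
):
    """Write a greyscale PNG plate photo whose well-disc darkness encodes
    intensity; returns the geometry needed to read it back."""
    from PIL import Image

    from .ecoplate import PlateGeometry

    n_rows, n_cols = wells.intensity.shape
    h = 2 * margin + (n_rows - 1) * pitch
    w = 2 * margin + (n_cols - 1) * pitch
    img = np.full((h, w), background, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    for r in range(n_rows):
        for c in range(n_cols):
            cy, cx = margin + r * pitch, margin + c * pitch
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
            value = int(np.clip(round(255.0 - wells.intensity[r, c]), 0, 255))
            img[disc] = value
    Image.fromarray(img, mode="L").save(path)
    return PlateGeometry(
        margin_x=margin, margin_y=margin, pitch_x=pitch, pitch_y=pitch, radius=radius
    )
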