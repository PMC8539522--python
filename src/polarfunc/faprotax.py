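"""Taxonomy-to-function annotation with a FAPROTAX-dialect rule database.

A rule database is flat text: a group header starts at column 0 and names a
metabolic function (optionally followed by tab-separated ``key:value``
metadata); indented lines below it are either taxon wildcard patterns or
``add_group:<name>`` directives that pull in all member patterns of another
group (the database's own nesting mechanism).  ``#`` starts a comment.

Matching a ZOTU to a group compares each member pattern against the ZOTU's
raw taxonomy string: ``*`` matches any substring (greedy, case-sensitive)
and a pattern containing ``*`` must cover the whole string; a pattern
without wildcards matches when it is a substring of a single rank segment.

Because of ``add_group`` nesting, the raw output assigns the same reads to
several overlapping categories (e.g. any aerobic chemoheterotroph is also a
chemoheterotroph).  :func:`deduplicate` applies a regrouping specification
that renames/merges raw groups into canonical categories and subtracts
nested ZOTU sets so the final categories are pairwise non-nested — e.g.
"Chemo-1" is aerobic chemoheterotrophy minus biopolymer, one-carbon and
aromatic-hydrocarbon degraders, and "dissimilatory nitrate reduction" is the
union of the three nitrate-respiring raw groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .zotu_io import ZotuTable

logger = logging.getLogger(__name__)

ELEMENTS = ("C", "N", "S", "Fe", "H", "other")


class RuleParseError(ValueError):
    pass


@dataclass
class FunctionRule:
    group_name: str
    member_patterns: list[str] = field(default_factory=list)
    included_groups: list[str] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)


@dataclass
class FunctionRuleSet:
    rules: dict[str, FunctionRule]
    version_tag: str = ""

    @property
    def n_groups(self) -> int:
        return len(self.rules)

    @property
    def n_annotations(self) -> int:
        """Number of member annotations (patterns + add_group directives)."""
        return sum(
            len(r.member_patterns) + len(r.included_groups)
            for r in self.rules.values()
        )

    def effective_patterns(self, name: str) -> list[str]:
        """Own patterns plus, transitively, those of all included groups."""
        seen: set[str] = set()
        out: list[str] = []

        def walk(g: str) -> None:
            if g in seen:
                return
            seen.add(g)
            rule = self.rules[g]
            out.extend(rule.member_patterns)
            for inc in rule.included_groups:
                walk(inc)

        walk(name)
        # keep order, drop duplicates
        uniq: list[str] = []
        for p in out:
            if p not in uniq:
                uniq.append(p)
        return uniq

    def inclusion_order(self) -> list[str]:
        """Topological order of the inclusion DAG (raises on cycles)."""
        state: dict[str, int] = {}
        order: list[str] = []

        def visit(g: str, stack: tuple[str, ...]) -> None:
            if state.get(g) == 2:
                return
            if state.get(g) == 1:
                cycle = " -> ".join(stack + (g,))
                raise RuleParseError(f"cyclic add_group inclusion: {cycle}")
            state[g] = 1
            for inc in self.rules[g].included_groups:
                visit(inc, stack + (g,))
            state[g] = 2
            order.append(g)

        for g in self.rules:
            visit(g, ())
        return order


def parse_rules(text: str, version_tag: str = "") -> FunctionRuleSet:
    """Parse a FAPROTAX-dialect rule database from text."""
    rules: dict[str, FunctionRule] = {}
    current: FunctionRule | None = None
    for lineno, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        indented = line[0] in (" ", "\t")
        body = line.strip()
        if not indented:
            fields = body.split("\t")
            name = fields[0].strip()
            if name in rules:
                raise RuleParseError(f"line {lineno}: duplicate group {name!r}")
            metadata = {}
            for f in fields[1:]:
                if ":" in f:
                    k, v = f.split(":", 1)
                    metadata[k.strip()] = v.strip()
            current = FunctionRule(group_name=name, metadata=metadata)
            rules[name] = current
        else:
            if current is None:
                raise RuleParseError(
                    f"line {lineno}: member line before any group header"
                )
            if body.startswith("add_group:"):
                current.included_groups.append(body.split(":", 1)[1].strip())
            else:
                current.member_patterns.append(body)
    rs = FunctionRuleSet(rules=rules, version_tag=version_tag)
    for rule in rs.rules.values():
        for inc in rule.included_groups:
            if inc not in rs.rules:
                raise RuleParseError(
                    f"group {rule.group_name!r}: add_group references "
                    f"unknown group {inc!r}"
                )
    rs.inclusion_order()  # raises on cycles
    if not rules:
        logger.warning("parse_rules: no groups found (comments/blank only)")
    logger.info(
        "parsed %d groups, %d member annotations", rs.n_groups, rs.n_annotations
    )
    return rs


def load_rules(path=None) -> FunctionRuleSet:
    """Load a rule database file; defaults to the bundled miniature set."""
    if path is None:
        text = (
            resources.files("polarfunc.data")
            .joinpath("mini_rules.txt")
            .read_text(encoding="utf-8")
        )
        return parse_rules(text, version_tag="polarfunc-mini")
    with open(path, "rt", encoding="utf-8") as fh:
        return parse_rules(fh.read(), version_tag=str(path))


def pattern_matches(pattern: str, taxonomy_raw: str, delimiter: str = ";") -> bool:
    """Wildcard taxon matching: ``*`` = any substring over the whole string;
    a literal pattern matches as a substring of one rank segment."""
    if "*" in pattern:
        regex = "^" + ".*".join(re.escape(p) for p in pattern.split("*")) + "$"
        return re.search(regex, taxonomy_raw) is not None
    return any(pattern in seg for seg in taxonomy_raw.split(delimiter))


@dataclass
class FunctionTable:
    """Function x sample read totals with the backing ZOTU assignment sets.

    ``reads[f, s]`` is the sum of counts in sample ``s`` over the ZOTUs
    assigned to function ``f``; ``source_counts`` retains the per-ZOTU
    counts so reads can be recomputed after regrouping.
    """

    function_names: list[str]
    sample_ids: list[str]
    reads: np.ndarray
    assignments: dict[str, frozenset[str]]
    n_total_zotus: int
    source_counts: pd.DataFrame = field(repr=False)

    @property
    def n_assigned_zotus(self) -> int:
        assigned: set[str] = set()
        for zotus in self.assignments.values():
            assigned |= zotus
        return len(assigned)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.reads, index=self.function_names, columns=self.sample_ids
        )


def _reads_from_assignments(
    assignments: dict[str, frozenset[str]],
    source_counts: pd.DataFrame,
    function_names: list[str],
) -> np.ndarray:
    reads = np.zeros((len(function_names), source_counts.shape[1]), dtype=np.int64)
    for i, name in enumerate(function_names):
        zotus = sorted(assignments[name])
        if zotus:
            reads[i] = source_counts.loc[zotus].to_numpy().sum(axis=0)
    return reads


def annotate(table: ZotuTable, rules: FunctionRuleSet) -> FunctionTable:
    """Assign every ZOTU to all groups whose (closure-expanded) patterns
    match its taxonomy, then sum reads per group and sample.

    A ZOTU may hit one group, several, or none; unmatched ZOTUs simply
    contribute to no function.
    """
    names = list(rules.rules)
    effective = {g: rules.effective_patterns(g) for g in names}
    assignments: dict[str, set[str]] = {g: set() for g in names}
    for zid in table.zotu_ids:
        raw = table.taxonomy[zid].raw
        for g in names:
            if any(pattern_matches(p, raw) for p in effective[g]):
                assignments[g].add(zid)
    frozen = {g: frozenset(z) for g, z in assignments.items()}
    source = table.to_dataframe()
    return FunctionTable(
        function_names=names,
        sample_ids=list(table.sample_ids),
        reads=_reads_from_assignments(frozen, source, names),
        assignments=frozen,
        n_total_zotus=table.n_zotus,
        source_counts=source,
    )


@dataclass
class RegroupSpec:
    """Mapping of raw rule-database groups onto canonical, non-nested
    categories.

    ``merge_map`` renames raw groups (several raw groups may map to one
    canonical name; their ZOTU sets are unioned).  ``subtract_map`` removes,
    from a canonical category, every ZOTU belonging to any of the listed
    canonical categories (the de-nesting step).  ``drop`` lists raw groups
    intentionally discarded (umbrella categories fully covered elsewhere).
    """

    merge_map: dict[str, str]
    subtract_map: dict[str, list[str]] = field(default_factory=dict)
    drop: list[str] = field(default_factory=list)

    @property
    def canonical_names(self) -> list[str]:
        seen: list[str] = []
        for name in self.merge_map.values():
            if name not in seen:
                seen.append(name)
        return seen


def load_regroup(path=None) -> tuple[RegroupSpec, "ElementMap"]:
    """Load a regroup spec + element map YAML; defaults to the bundled one."""
    if path is None:
        text = (
            resources.files("polarfunc.data")
            .joinpath("mini_regroup.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    spec = RegroupSpec(
        merge_map=dict(doc.get("merge_map", {})),
        subtract_map={k: list(v) for k, v in (doc.get("subtract_map") or {}).items()},
        drop=list(doc.get("drop") or []),
    )
    emap = ElementMap(element_of=dict(doc.get("elements") or {}))
    return spec, emap


def deduplicate(ftable: FunctionTable, spec: RegroupSpec) -> FunctionTable:
    """Merge raw groups into canonical categories and remove nested ZOTU sets.

    Every raw group present in ``ftable`` must appear in ``merge_map`` or
    ``drop``.  After merging, ``subtract_map`` entries are applied (e.g.
    Chemo-3 = chemoheterotrophy minus Chemo-1, Chemo-2 and the biopolymer /
    one-carbon / aromatic degraders) and reads are recomputed from the
    resulting ZOTU sets.
    """
    unmapped = [
        f
        for f in ftable.function_names
        if f not in spec.merge_map and f not in spec.drop
    ]
    if unmapped:
        raise ValueError(f"raw groups not covered by regroup spec: {unmapped}")
    merged: dict[str, set[str]] = {}
    order: list[str] = []
    for f in ftable.function_names:
        if f in spec.drop:
            continue
        canon = spec.merge_map[f]
        if canon not in merged:
            merged[canon] = set()
            order.append(canon)
        merged[canon] |= ftable.assignments[f]
    for canon, removals in spec.subtract_map.items():
        if canon not in merged:
            continue
        for other in removals:
            if other in merged:
                merged[canon] -= merged[other]
    frozen = {c: frozenset(z) for c, z in merged.items()}
    return FunctionTable(
        function_names=order,
        sample_ids=list(ftable.sample_ids),
        reads=_reads_from_assignments(frozen, ftable.source_counts, order),
        assignments=frozen,
        n_total_zotus=ftable.n_total_zotus,
        source_counts=ftable.source_counts,
    )


@dataclass
class ElementMap:
    """Function name -> biogeochemical cycle (C, N, S, Fe, H or other)."""

    element_of: dict[str, str]

    def __post_init__(self) -> None:
        bad = {e for e in self.element_of.values() if e not in ELEMENTS}
        if bad:
            raise ValueError(f"unknown elements: {sorted(bad)}")

    def counts_by_element(self) -> dict[str, int]:
        out = {e: 0 for e in ELEMENTS}
        for e in self.element_of.values():
            out[e] += 1
        return out


def load_element_map(path=None) -> ElementMap:
    """Load a TSV ``function<TAB>element`` map; defaults to the bundled
    synthetic 90-category catalog."""
    if path is None:
        text = (
            resources.files("polarfunc.data")
            .joinpath("element_map_synthetic90.tsv")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, "rt", encoding="utf-8") as fh:
            text = fh.read()
    element_of: dict[str, str] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        name, element = line.split("\t")
        element_of[name.strip()] = element.strip()
    return ElementMap(element_of=element_of)


def element_totals(
    ftable: FunctionTable, emap: ElementMap
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-sample read sums and category counts per element cycle.

    Returns ``(reads, n_functions)`` where ``reads`` is an element x sample
    DataFrame of summed assigned reads and ``n_functions`` counts the
    categories mapped to each element.  Every function name in ``ftable``
    must be mapped.
    """
    unmapped = [f for f in ftable.function_names if f not in emap.element_of]
    if unmapped:
        raise ValueError(f"functions without element mapping: {unmapped}")
    reads = pd.DataFrame(
        0, index=list(ELEMENTS), columns=ftable.sample_ids, dtype=np.int64
    )
    n_functions = {e: 0 for e in ELEMENTS}
    for i, f in enumerate(ftable.function_names):
        e = emap.element_of[f]
        reads.loc[e] += ftable.reads[i]
        n_functions[e] += 1
    return reads, n_functions
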