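"""Reading, writing and rarefying ZOTU count tables.

A ZOTU (zero-radius OTU) table is the root object of the pipeline: an
integer count matrix of amplicon sequence variants (rows) by samples
(columns), with one ranked taxonomy string per ZOTU.  The on-disk dialect
is a UTF-8 TSV whose first column is the ZOTU identifier, last column the
taxonomy string, and middle columns the per-sample counts::

    #OTU ID<TAB>L1<TAB>L2<TAB>taxonomy
    Zotu1<TAB>120<TAB>3<TAB>Bacteria;Proteobacteria;...;Pseudomonadaceae;Pseudomonas

Rarefaction subsamples each sample's reads without replacement to a common
depth (multivariate hypergeometric draw), which is the standard way to
normalise unequal sequencing effort before functional annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: SILVA-style rank prefixes such as ``D_0__`` or ``d__`` stripped from labels.
DEFAULT_RANK_PREFIX = re.compile(r"^[A-Za-z]_?\d*__")


@dataclass(frozen=True)
class TaxonomyPath:
    """A ranked taxonomy (domain -> genus) parsed from a delimited string."""

    ranks: tuple[str, ...]
    raw: str

    def __post_init__(self) -> None:
        if not self.ranks:
            raise ValueError("taxonomy must have at least one rank")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.raw


def parse_taxonomy(
    raw: str,
    delimiter: str = ";",
    strip_prefix: re.Pattern | None = DEFAULT_RANK_PREFIX,
) -> TaxonomyPath:
    """Split a taxonomy string into ranks, trimming whitespace and optional
    SILVA-dialect rank prefixes (``D_0__``, ``d__`` ...)."""
    parts = [p.strip() for p in raw.split(delimiter)]
    parts = [p for p in parts if p != ""]
    if strip_prefix is not None:
        parts = [strip_prefix.sub("", p) for p in parts]
    if not parts:
        parts = ["unclassified"]
    return TaxonomyPath(ranks=tuple(parts), raw=raw.strip())


def serialize_taxonomy(path: TaxonomyPath, delimiter: str = ";") -> str:
    return delimiter.join(path.ranks)


@dataclass
class ZotuTable:
    """ZOTU x sample integer counts plus per-ZOTU taxonomy.

    Invariants checked at construction: matrix dimensions match the id
    lists, counts are non-negative integers, and every ZOTU has a taxonomy
    entry.
    """

    zotu_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, TaxonomyPath] = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.zotu_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.zotu_ids)} ZOTUs x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.zotu_ids)) != len(self.zotu_ids):
            raise ValueError("duplicate ZOTU ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        missing = [z for z in self.zotu_ids if z not in self.taxonomy]
        if missing:
            raise ValueError(f"ZOTUs without taxonomy: {missing[:5]}")

    # -- convenience -------------------------------------------------------
    @property
    def n_zotus(self) -> int:
        return len(self.zotu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_sums(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids)

    def zotu_sums(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.zotu_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.zotu_ids, columns=self.sample_ids)

    def select_zotus(self, keep: list[str]) -> "ZotuTable":
        idx = [self.zotu_ids.index(z) for z in keep]
        return ZotuTable(
            zotu_ids=list(keep),
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :].copy(),
            taxonomy={z: self.taxonomy[z] for z in keep},
        )

    def select_samples(self, keep: list[str]) -> "ZotuTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return ZotuTable(
            zotu_ids=list(self.zotu_ids),
            sample_ids=list(keep),
            counts=self.counts[:, idx].copy(),
            taxonomy=dict(self.taxonomy),
        )


class ZotuParseError(ValueError):
    """Raised when a ZOTU table file is malformed; names the offending line."""


def read_zotu_table(
    path,
    delimiter: str = ";",
    strip_prefix: re.Pattern | None = DEFAULT_RANK_PREFIX,
) -> ZotuTable:
    """Read a TSV ZOTU table (id, per-sample counts, taxonomy)."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 3:
            raise ZotuParseError(
                f"{path}: header needs id, >=1 sample and taxonomy columns"
            )
        sample_ids = cols[1:-1]
        zotu_ids: list[str] = []
        rows: list[list[int]] = []
        taxonomy: dict[str, TaxonomyPath] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise ZotuParseError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            zid = fields[0].strip()
            if zid in taxonomy:
                raise ZotuParseError(f"{path}:{lineno}: duplicate ZOTU id {zid!r}")
            parsed: list[int] = []
            for value in fields[1:-1]:
                try:
                    count = int(value)
                except ValueError:
                    raise ZotuParseError(
                        f"{path}:{lineno}: non-integer count {value!r}"
                    ) from None
                if count < 0:
                    raise ZotuParseError(f"{path}:{lineno}: negative count {count}")
                parsed.append(count)
            zotu_ids.append(zid)
            rows.append(parsed)
            taxonomy[zid] = parse_taxonomy(
                fields[-1], delimiter=delimiter, strip_prefix=strip_prefix
            )
    if not zotu_ids:
        raise ZotuParseError(f"{path}: no data rows")
    return ZotuTable(
        zotu_ids=zotu_ids,
        sample_ids=sample_ids,
        counts=np.array(rows, dtype=np.int64),
        taxonomy=taxonomy,
    )


def write_zotu_table(table: ZotuTable, path) -> None:
    """Write a table in the same TSV dialect ``read_zotu_table`` consumes."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for i, zid in enumerate(table.zotu_ids):
            counts = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{zid}\t{counts}\t{table.taxonomy[zid].raw}\n")


def rarefy(table: ZotuTable, depth: int, seed: int) -> ZotuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a warning.  The
    draw is a multivariate hypergeometric per sample, so each rarefied cell
    is bounded by the original count and every retained column sums exactly
    to ``depth``.  The same seed always yields the same table.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = [s for s, t in zip(table.sample_ids, totals) if t >= depth]
    dropped = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if dropped:
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, ", ".join(dropped),
        )
    if not keep:
        raise ValueError(f"all samples have fewer than {depth} reads")
    out = np.zeros((table.n_zotus, len(keep)), dtype=np.int64)
    for j, sid in enumerate(keep):
        col = table.counts[:, table.sample_ids.index(sid)]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return ZotuTable(
        zotu_ids=list(table.zotu_ids),
        sample_ids=keep,
        counts=out,
        taxonomy=dict(table.taxonomy),
    )
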