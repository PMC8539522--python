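"""Functional diversity indices and the C:N:S metabolic ratio.

All indices are computed per sample from the per-category assigned-read
vector of a de-duplicated function table:

* richness ``S``: number of categories with at least one read;
* Shannon-Weaver ``H = -sum p_i ln p_i`` (natural log, nats);
* Shannon evenness ``J = H / ln S`` (0 when ``S == 1``);
* Menhinick ``S / sqrt(N)`` where ``N`` defaults to the total assigned
  reads in the sample (configurable — see note below);
* bias-corrected Chao1 ``S + F1(F1-1) / (2 (F2+1))`` with ``F1``/``F2`` the
  singleton/doubleton category counts.

The C:N:S metabolic ratio divides the summed carbon- and nitrogen-cycle
read assignments by the sulfur-cycle sum, i.e. it is reported normalised to
sulfur = 1 (``3:0.9:1`` style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DiversityProfile:
    richness: int
    shannon: float
    evenness: float
    menhinick: float
    chao1: float
    sample_size: int


def diversity_profile(
    assignment_counts, sample_size: int | None = None
) -> DiversityProfile:
    """Compute the index panel from a vector of per-category read counts.

    ``sample_size`` is the ``N`` used by Menhinick's index; when omitted it
    is the total of ``assignment_counts`` (total assigned reads).  Note that
    rarefaction depth is an equally defensible choice of ``N``; pass it
    explicitly to use it.
    """
    counts = np.asarray(assignment_counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError("expected a 1-D vector of per-category counts")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector: no assignments in sample")
    if sample_size is None:
        sample_size = int(round(total))
    positive = counts[counts > 0]
    s = int(positive.size)
    p = positive / total
    h = float(-(p * np.log(p)).sum())
    j = float(h / math.log(s)) if s >= 2 else 0.0
    f1 = int((positive == 1).sum())
    f2 = int((positive == 2).sum())
    chao1 = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return DiversityProfile(
        richness=s,
        shannon=h,
        evenness=j,
        menhinick=s / math.sqrt(sample_size),
        chao1=float(chao1),
        sample_size=sample_size,
    )


def shannon_from_evenness(evenness: float, richness: int) -> float:
    """Reconstruct ``H`` from a reported evenness ``J`` and richness ``S``
    via the defining relation ``J = H / ln S``."""
    if richness < 2:
        return 0.0
    return evenness * math.log(richness)


@dataclass(frozen=True)
class CnsRatio:
    """Summed C- and N-cycle read assignments relative to sulfur = 1.

    When no sulfur-cycle reads exist the ratio is undefined: ``defined`` is
    False and the raw sums are reported unscaled instead of dividing.
    """

    c: float
    n: float
    s_ref: float
    defined: bool = True

    def format(self, decimals: int = 1) -> str:
        def fmt(x: float) -> str:
            r = round(x, decimals)
            return str(int(r)) if float(r).is_integer() else str(r)

        if not self.defined:
            return f"{fmt(self.c)}:{fmt(self.n)}:{fmt(self.s_ref)} (raw, S=0)"
        return f"{fmt(self.c)}:{fmt(self.n)}:1"


def cns_ratio(element_reads: dict[str, float]) -> CnsRatio:
    """C:N:S ratio from per-element summed reads, normalised to S = 1."""
    c = float(element_reads.get("C", 0))
    n = float(element_reads.get("N", 0))
    s = float(element_reads.get("S", 0))
    if any(v < 0 for v in (c, n, s)):
        raise ValueError("element read sums must be non-negative")
    if s == 0:
        return CnsRatio(c=c, n=n, s_ref=0.0, defined=False)
    return CnsRatio(c=c / s, n=n / s, s_ref=1.0, defined=True)
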