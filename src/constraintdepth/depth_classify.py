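"""FDR control (Storey q-values) and constraint-depth classification.

An element's depth category comes from which clades' element-wise tests
survive q < alpha: significance must be nested (primate, then mammal, then
vertebrate); non-nested patterns and unconstrained elements overlapping a
conserved segment are excluded as ambiguous.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import GenomicElement

__all__ = [
    "QValueSet",
    "DepthCategory",
    "DepthCall",
    "storey_qvalues",
    "classify_depth",
    "dhs_core_window",
    "nearest_gene",
]


@dataclasses.dataclass
class QValueSet:
    p_values: np.ndarray
    pi0: float
    q_values: np.ndarray
    lam: float


def storey_qvalues(p_values: Sequence[float], lam: float = 0.5,
                   pi0: float | None = None) -> QValueSet:
    """Storey q-values with a fixed lambda.

    pi0 = #{p > lam} / ((1 - lam) * m), set to 1 when the raw estimate is 0
    and capped at 1. q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted
    p-values. Forcing ``pi0=1`` reproduces Benjamini-Hochberg exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < lam < 1):
        raise ValueError("lambda must be in (0, 1)")
    m = p.size
    if pi0 is None:
        raw = np.count_nonzero(p > lam) / ((1.0 - lam) * m)
        pi0 = 1.0 if raw <= 0 else min(1.0, raw)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")

    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueSet(p_values=p, pi0=float(pi0), q_values=q, lam=lam)


class DepthCategory(str, enum.Enum):
    UNCONSTRAINED = "unconstrained (<65 Ma)"
    PRIMATE = "primate (~65 Ma)"
    MAMMAL = "mammal (~100 Ma)"
    VERTEBRATE = "vertebrate (160-400 Ma)"
    AMBIGUOUS = "ambiguous-excluded"


@dataclasses.dataclass
class DepthCall:
    element_id: str | None
    primate_significant: bool
    mammal_significant: bool
    vertebrate_significant: bool
    phastcons_overlap: bool
    category: DepthCategory


def classify_depth(primate_q: float, mammal_q: float, vertebrate_q: float,
                   phastcons_overlap: bool = False, alpha: float = 0.05,
                   element_id: str | None = None) -> DepthCall:
    """Assign a constraint-depth category from per-clade q-values.

    Nested significance maps to primate/mammal/vertebrate depth; nothing
    significant is unconstrained unless the element overlaps a conserved
    segment (then ambiguous-excluded, as is any non-nested pattern such as
    mammal-without-primate).
    """
    for name, q in (("primate", primate_q), ("mammal", mammal_q),
                    ("vertebrate", vertebrate_q)):
        if q is None or not np.isfinite(q):
            raise ValueError(f"missing {name} q-value")
    P, M, V = primate_q < alpha, mammal_q < alpha, vertebrate_q < alpha
    if P and not M and not V:
        cat = DepthCategory.PRIMATE
    elif P and M and not V:
        cat = DepthCategory.MAMMAL
    elif P and M and V:
        cat = DepthCategory.VERTEBRATE
    elif not (P or M or V):
        cat = DepthCategory.AMBIGUOUS if phastcons_overlap else DepthCategory.UNCONSTRAINED
    else:
        cat = DepthCategory.AMBIGUOUS
    return DepthCall(element_id, P, M, V, phastcons_overlap, cat)


def dhs_core_window(element: GenomicElement, flank: int = 20) -> GenomicElement:
    """The 2*flank bp core window centred on the element's summit, [s-20, s+20)."""
    if element.summit is None:
        raise ValueError(
            f"{element.element_id}: no summit; use the element-midpoint mode "
            "(config core_window_mode=midpoint) instead"
        )
    start, end = element.summit - flank, element.summit + flank
    if start < 0:
        warnings.warn(
            f"{element.element_id}: core window clipped at contig start", stacklevel=2
        )
        start = 0
    return GenomicElement(element.chrom, start, end, element.element_id,
                          element.element_class, summit=element.summit,
                          motif=element.motif)


def nearest_gene(elements: Iterable[GenomicElement],
                 genes: Iterable[GenomicElement]) -> dict[str, tuple[str, int] | None]:
    """Closest gene per element by interval distance (0 when overlapping).

    Ties break toward the gene with the smaller start coordinate; elements on
    a chromosome with no genes map to None.
    """
    by_chrom: dict[str, list[GenomicElement]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.end))

    out: dict[str, tuple[str, int] | None] = {}
    for e in elements:
        glist = by_chrom.get(e.chrom)
        if not glist:
            out[e.element_id] = None
            continue
        best = None
        for g in glist:
            d = max(0, g.start - e.end, e.start - g.end)
            if best is None or d < best[1] or (d == best[1] and g.start < best[2]):
                best = (g.element_id, d, g.start)
        out[e.element_id] = (best[0], best[1])
    return out
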