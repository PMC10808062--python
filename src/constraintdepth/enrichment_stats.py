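"""Downstream enrichment statistics.

Fine-mapped-variant enrichment across the two PIP tails, motif-level
constraint odds ratios with length-binned fixed-effects meta-analysis,
per-element correlation of mutagenesis effects with truncated constraint
scores, and the assembly mismatch ~ heterozygosity regression.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .depth_classify import storey_qvalues

__all__ = [
    "EnrichmentResult",
    "dedupe_max_pip",
    "pip_enrichment",
    "motif_or_meta",
    "mpra_constraint_correlation",
    "mismatch_regression",
    "MismatchFit",
]


@dataclasses.dataclass
class EnrichmentResult:
    a: int                 # high-PIP variants inside the annotation
    A: int                 # all high-PIP variants
    b: int                 # low-PIP variants inside the annotation
    B: int                 # all low-PIP variants
    enrichment: float      # (a/A) / (b/B)
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    flags: tuple[str, ...] = ()


def dedupe_max_pip(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep each variant once, at its maximum PIP across traits/tissues/genes."""
    idx = variants.groupby("variant_id")["pip"].idxmax()
    return variants.loc[idx].reset_index(drop=True)


def pip_enrichment(variants: pd.DataFrame, annotation_col: str = "in_annotation",
                   hi: float = 0.5, lo: float = 0.01) -> EnrichmentResult:
    """Enrichment of high-PIP (> hi) vs low-PIP (< lo) variants in an annotation.

    ``variants`` needs columns ``pip`` and a boolean annotation membership;
    rows with lo <= PIP <= hi belong to neither tail and are dropped. The
    point estimate is the ratio of in-annotation proportions between tails;
    OR/CI from the conditional-MLE exact method, p from Fisher's exact test.
    """
    pip = variants["pip"].to_numpy(dtype=float)
    if np.any((pip < 0) | (pip > 1)):
        raise ValueError("PIP values must lie in [0, 1]")
    member = variants[annotation_col].to_numpy(dtype=bool)
    hi_mask, lo_mask = pip > hi, pip < lo
    a, A = int((hi_mask & member).sum()), int(hi_mask.sum())
    b, B = int((lo_mask & member).sum()), int(lo_mask.sum())
    if A == 0 or B == 0:
        raise ValueError(f"empty PIP tail (A={A}, B={B})")

    flags = []
    if a == 0 or b == 0:
        flags.append("zero-cell")
    enrichment = (a / A) / (b / B) if b > 0 else float("inf")

    table = [[a, A - a], [b, B - b]]
    orr = stats.contingency.odds_ratio(table)
    ci = orr.confidence_interval(0.95)
    _, p = stats.fisher_exact(table)
    return EnrichmentResult(a, A, b, B, float(enrichment),
                            float(orr.statistic), float(ci.low), float(ci.high),
                            float(p), tuple(flags))


# ---------------------------------------------------------------------- #
# motif-level footprint constraint, length-binned meta-analysis

def _woolf(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Woolf log odds ratio and variance, Haldane 0.5 on any zero cell."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    lor = np.log(a * d / (b * c))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return float(lor), float(var)


def motif_or_meta(footprints: pd.DataFrame, n_bins: int = 10,
                  min_footprints: int = 10, fdr_alpha: float = 0.05,
                  lam: float = 0.5) -> pd.DataFrame:
    """Per-motif odds ratio of primate- vs mammal-constrained footprints,
    pooled across footprint-length bins by fixed-effects meta-analysis.

    ``footprints`` needs columns ``length``, ``motif`` (one label per row;
    footprints with several motifs appear on several rows and are treated
    independently), ``primate_constrained`` and ``mammal_constrained``.
    The universe is constrained footprints only: category primate =
    primate-flag without mammal-flag, category mammal = mammal-flag. Bins are
    global length quantiles over the full table. Motifs with fewer than
    ``min_footprints`` constrained footprints are excluded.
    """
    df = footprints.copy()
    cat_primate = df["primate_constrained"].astype(bool) & ~df["mammal_constrained"].astype(bool)
    cat_mammal = df["mammal_constrained"].astype(bool)
    df["_cat"] = np.where(cat_primate, "primate", np.where(cat_mammal, "mammal", "none"))
    # equal-sized global length bins; ties broken by footprint_id so the
    # binning is invariant to row order
    tie_break = df["footprint_id"] if "footprint_id" in df.columns else df.index
    order = np.lexsort((np.asarray(tie_break, dtype="U32"), df["length"].to_numpy()))
    ranks = np.empty(len(df), dtype=np.int64)
    ranks[order] = np.arange(len(df))
    df["_bin"] = pd.qcut(ranks, q=n_bins, labels=False)
    df = df[df["_cat"] != "none"]

    rows = []
    for motif, grp in df.groupby("motif"):
        if len(grp) < min_footprints:
            continue
        lors, weights, tables = [], [], []
        for k in range(n_bins):
            in_bin = df["_bin"] == k
            in_motif = df["motif"] == motif
            a = int((in_bin & in_motif & (df["_cat"] == "primate")).sum())
            b = int((in_bin & ~in_motif & (df["_cat"] == "primate")).sum())
            c = int((in_bin & in_motif & (df["_cat"] == "mammal")).sum())
            d = int((in_bin & ~in_motif & (df["_cat"] == "mammal")).sum())
            tables.append((k, a, b, c, d))
            if (a + c) == 0 or (b + d) == 0 or (a + b) == 0 or (c + d) == 0:
                continue  # empty margin: bin carries no information for this motif
            lor, var = _woolf(a, b, c, d)
            lors.append(lor)
            weights.append(1.0 / var)
        if not lors:
            continue
        lors, weights = np.asarray(lors), np.asarray(weights)
        pooled = float(np.sum(weights * lors) / weights.sum())
        var_pooled = float(1.0 / weights.sum())
        se = np.sqrt(var_pooled)
        z = pooled / se
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append({
            "motif": motif, "n_footprints": int(len(grp)),
            "n_bins_used": int(len(lors)),
            "log_or": pooled, "se": se,
            "or": float(np.exp(pooled)),
            "ci_low": float(np.exp(pooled - 1.96 * se)),
            "ci_high": float(np.exp(pooled + 1.96 * se)),
            "p": p, "bins": tables,
        })
    if not rows:
        return pd.DataFrame(columns=["motif", "n_footprints", "n_bins_used", "log_or",
                                     "se", "or", "ci_low", "ci_high", "p", "q",
                                     "significant", "bins"])
    out = pd.DataFrame(rows)
    qset = storey_qvalues(out["p"].to_numpy(), lam=lam)
    out["q"] = qset.q_values
    out["significant"] = out["q"] < fdr_alpha
    return out.sort_values("motif").reset_index(drop=True)


# ---------------------------------------------------------------------- #

def mpra_constraint_correlation(per_nucleotide: pd.DataFrame,
                                use_abs: bool = True, fdr_alpha: float = 0.05,
                                lam: float = 0.5) -> pd.DataFrame:
    """Per-element Pearson correlation of substitution-effect magnitude with
    constraint scores truncated below at zero.

    ``per_nucleotide`` needs columns ``element_id``, ``effect`` (per-position
    mean substitution effect) and ``score``. Elements with zero variance in
    either vector are flagged untestable and excluded from the FDR universe.
    """
    rows = []
    for eid, grp in per_nucleotide.groupby("element_id"):
        x = grp["effect"].to_numpy(dtype=float)
        if use_abs:
            x = np.abs(x)
        y = np.clip(grp["score"].to_numpy(dtype=float), 0.0, None)
        testable = len(x) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0
        if testable:
            r, p = stats.pearsonr(x, y)
        else:
            r, p = np.nan, np.nan
        rows.append({"element_id": eid, "n": len(x), "r": float(r) if testable else np.nan,
                     "p": float(p) if testable else np.nan, "testable": bool(testable)})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    mask = out["testable"].to_numpy()
    if mask.any():
        qset = storey_qvalues(out.loc[mask, "p"].to_numpy(), lam=lam)
        out.loc[mask, "q"] = qset.q_values
    out["significant"] = out["q"] < fdr_alpha
    return out


# ---------------------------------------------------------------------- #

@dataclasses.dataclass
class MismatchFit:
    intercept: float
    slope: float
    r_squared: float
    residual_rate: float   # mismatch rate net of heterozygosity (= intercept)
    n: int


def mismatch_regression(mismatch: Sequence[float],
                        heterozygosity: Sequence[float]) -> MismatchFit:
    """OLS of per-species assembly mismatch rate on heterozygosity."""
    import statsmodels.api as sm

    m = np.asarray(mismatch, dtype=float)
    h = np.asarray(heterozygosity, dtype=float)
    if m.shape != h.shape or m.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.any(m < 0) or np.any(h < 0):
        raise ValueError("rates must be >= 0")
    if np.ptp(h) == 0:
        raise ValueError("heterozygosity is constant; slope not identifiable")
    res = sm.OLS(m, sm.add_constant(h)).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    return MismatchFit(intercept=intercept, slope=slope,
                       r_squared=float(res.rsquared),
                       residual_rate=intercept, n=m.size)
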