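"""Ultraconserved-element scanning over alignment columns.

A column is "perfect" when every non-missing species carries the same base;
strict mode forbids missing data entirely, relaxed mode tolerates up to
floor(fraction * n_species) missing species. UCEs are maximal perfect runs
of at least ``min_length`` reference bases; runs never cross coverage gaps.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .alignment_io import AlignmentColumnSet, GAP, GenomicElement

__all__ = [
    "UCERecord",
    "resolve_max_missing",
    "perfect_columns",
    "scan_uces",
    "uce_overlap",
]

MIN_UCE_LENGTH = 20


@dataclasses.dataclass
class UCERecord:
    chrom: str
    start: int
    end: int
    mode: str                # "strict" | "relaxed"
    n_missing_max: int = 0   # worst per-column missing count observed (relaxed)

    def __post_init__(self):
        if self.end - self.start < MIN_UCE_LENGTH:
            raise ValueError("UCE shorter than the minimum length")
        if self.mode not in ("strict", "relaxed"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def resolve_max_missing(n_species: int, tolerance_fraction: float) -> int:
    """floor(fraction * n_species): species allowed missing per relaxed column."""
    if not (0 <= tolerance_fraction < 1):
        raise ValueError("tolerance fraction must be in [0, 1)")
    return int(np.floor(tolerance_fraction * n_species))


def perfect_columns(cols: AlignmentColumnSet,
                    species: Sequence[str] | None = None,
                    max_missing: int = 0) -> np.ndarray:
    """Boolean mask over columns: all non-missing symbols identical.

    ``max_missing = 0`` is strict mode (no '-' or 'N' anywhere); otherwise at
    most ``max_missing`` species may be missing. A column where every species
    is missing is False in both modes.
    """
    codes = cols.codes
    if species is not None:
        idx = [cols.species.index(s) for s in species]
        codes = codes[idx]
    missing = codes >= GAP
    n_missing = missing.sum(axis=0)
    # identical non-missing symbols: min == max over observed bases
    masked = np.where(missing, np.uint8(255), codes)
    lo = masked.min(axis=0)
    hi = np.where(missing, np.uint8(0), codes).max(axis=0)
    all_missing = n_missing == codes.shape[0]
    identical = (~all_missing) & (lo == hi)
    return identical & (n_missing <= max_missing)


def scan_uces(mask: np.ndarray, coords: np.ndarray, chrom: str = "ref",
              min_length: int = MIN_UCE_LENGTH, mode: str = "strict",
              n_missing: np.ndarray | None = None) -> list[UCERecord]:
    """Maximal true-runs of the mask with length >= min_length.

    ``coords`` are the reference coordinates of the mask's columns; runs are
    broken wherever consecutive columns are not adjacent on the reference.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.asarray(coords, dtype=np.int64)
    if mask.shape != coords.shape:
        raise ValueError("mask and coords must align")
    if mask.size == 0:
        return []
    adjacent = np.concatenate(([False], np.diff(coords) == 1))
    # start a new run where mask turns on, or coverage breaks inside a run
    run_start = mask & (~np.concatenate(([False], mask[:-1])) | ~adjacent)
    run_id = np.cumsum(run_start)
    out: list[UCERecord] = []
    for rid in np.unique(run_id[mask]):
        sel = np.flatnonzero(mask & (run_id == rid))
        length = len(sel)
        if length >= min_length:
            worst = int(n_missing[sel].max()) if n_missing is not None else 0
            out.append(UCERecord(chrom, int(coords[sel[0]]), int(coords[sel[-1]]) + 1,
                                 mode=mode, n_missing_max=worst))
    return out


def uce_overlap(uces: Sequence, external: Sequence, min_bp: int = 1
                ) -> tuple[float, list[bool]]:
    """Fraction of external elements overlapped by >= min_bp of any UCE.

    Returns (fraction, per-external-element flags). Works on any records with
    chrom/start/end attributes (UCERecord or GenomicElement).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for u in uces:
        by_chrom.setdefault(u.chrom, []).append((u.start, u.end))
    for v in by_chrom.values():
        v.sort()
    flags: list[bool] = []
    for e in external:
        hit = False
        for s, t in by_chrom.get(e.chrom, ()):
            if s >= e.end:
                break
            if min(t, e.end) - max(s, e.start) >= min_bp:
                hit = True
                break
        flags.append(hit)
    frac = float(np.mean(flags)) if flags else 0.0
    return frac, flags
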