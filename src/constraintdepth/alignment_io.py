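"""Standard-format I/O: MAF, FASTA column slices, BED/TSV elements, Newick.

All internal coordinates are 0-based, half-open on the reference; conversions
happen only at I/O boundaries. Gap ('-') and unaligned/unknown ('N') are both
missing data for likelihood purposes but are stored distinctly (the UCE
scanner needs both).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO

from .phylogeny import Phylogeny

__all__ = [
    "SYMBOLS",
    "GAP",
    "UNKNOWN",
    "AlignmentColumnSet",
    "GenomicElement",
    "read_maf",
    "write_maf",
    "read_fasta_columns",
    "write_fasta_columns",
    "read_elements",
    "write_elements_bed",
    "extract_clade_columns",
]

SYMBOLS = np.frombuffer(b"ACGT-N", dtype="S1").astype("U1")
GAP = 4
UNKNOWN = 5
_CODE = {s: i for i, s in enumerate("ACGT-N")}
_COMPLEMENT = str.maketrans("ACGTN-acgtn", "TGCAN-tgcan")

ELEMENT_CLASSES = {"DHS", "footprint", "exon", "UCE", "other"}


def _encode(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        try:
            out[i] = _CODE[ch]
        except KeyError:
            out[i] = UNKNOWN  # IUPAC ambiguity codes collapse to missing
    return out


@dataclasses.dataclass
class GenomicElement:
    """An annotated interval on the reference (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    element_id: str
    element_class: str = "other"
    summit: int | None = None
    motif: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.element_id}: start {self.start} >= end {self.end}")
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(
                f"{self.element_id}: unknown element_class {self.element_class!r}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"{self.element_id}: summit {self.summit} outside [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class AlignmentColumnSet:
    """Reference-anchored alignment columns for a fixed species list.

    ``codes`` is a ``(n_species, n_columns)`` uint8 matrix over the alphabet
    A=0 C=1 G=2 T=3 '-'=4 'N'=5; ``coords`` holds strictly increasing 0-based
    reference positions.
    """

    def __init__(
        self,
        species: Sequence[str],
        coords: np.ndarray,
        codes: np.ndarray,
        reference_name: str,
        chrom: str = "ref",
    ):
        self.species = list(species)
        self.coords = np.asarray(coords, dtype=np.int64)
        self.codes = np.asarray(codes, dtype=np.uint8)
        self.reference_name = reference_name
        self.chrom = chrom
        if self.codes.shape != (len(self.species), len(self.coords)):
            raise ValueError("codes shape does not match species x coords")
        if len(self.coords) and np.any(np.diff(self.coords) <= 0):
            raise ValueError("reference coordinates must be strictly increasing")
        if self.codes.size and self.codes.max() > UNKNOWN:
            raise ValueError("invalid symbol code")
        if reference_name not in self.species:
            raise ValueError(f"reference {reference_name!r} not in species list")

    # ------------------------------------------------------------------ #

    @property
    def n_columns(self) -> int:
        return len(self.coords)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def symbols(self) -> np.ndarray:
        """Columns as single-character unicode array."""
        return SYMBOLS[self.codes]

    def column(self, i: int) -> dict[str, str]:
        return {sp: SYMBOLS[c] for sp, c in zip(self.species, self.codes[:, i])}

    def subset_species(self, keep: Sequence[str]) -> "AlignmentColumnSet":
        idx = [self.species.index(s) for s in keep]
        ref = self.reference_name if self.reference_name in keep else keep[0]
        return AlignmentColumnSet(
            list(keep), self.coords, self.codes[idx], ref, self.chrom
        )

    def slice(self, start: int, end: int) -> "AlignmentColumnSet":
        """Columns with reference coordinate in [start, end)."""
        m = (self.coords >= start) & (self.coords < end)
        return AlignmentColumnSet(
            self.species, self.coords[m], self.codes[:, m], self.reference_name, self.chrom
        )

    def contiguous_runs(self) -> list[tuple[int, int]]:
        """(column-index start, end) pairs of runs of consecutive coordinates."""
        if self.n_columns == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.coords) != 1) + 1
        bounds = np.concatenate([[0], breaks, [self.n_columns]])
        return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------- #
# MAF

def read_maf(path: str, reference: str) -> AlignmentColumnSet:
    """Read a reference-anchored MAF into columns keyed by reference coordinate.

    Species absent from a block receive 'N' at that block's columns. Blocks
    whose reference row is on the '-' strand are reverse-complemented into
    reference orientation. Duplicate reference coverage is an error.
    """
    species: list[str] = []
    chrom = None
    per_block: list[tuple[np.ndarray, dict[str, np.ndarray]]] = []
    try:
        blocks = list(AlignIO.parse(path, "maf"))
    except ValueError as exc:
        raise ValueError(f"malformed MAF {path}: {exc}") from exc

    for bi, block in enumerate(blocks):
        rows = {}
        ref_rec = None
        for rec in block:
            sp, _, src_chrom = rec.id.partition(".")
            rows[sp] = rec
            if sp == reference:
                ref_rec = rec
                chrom = src_chrom or chrom
        if ref_rec is None:
            raise ValueError(f"MAF block {bi}: no row for reference {reference!r}")

        strand = ref_rec.annotations.get("strand", 1)
        seqs = {sp: str(rec.seq) for sp, rec in rows.items()}
        start = int(ref_rec.annotations["start"])
        size = int(ref_rec.annotations["size"])
        if strand in (-1, "-"):
            src_size = int(ref_rec.annotations["srcSize"])
            start = src_size - start - size
            seqs = {sp: s.translate(_COMPLEMENT)[::-1] for sp, s in seqs.items()}

        ref_seq = seqs[reference]
        keep = np.array([c != "-" for c in ref_seq])
        if keep.sum() != size:
            raise ValueError(
                f"MAF block {bi}: reference row size {size} != non-gap length {int(keep.sum())}"
            )
        coords = start + np.arange(size, dtype=np.int64)
        col_codes = {sp: _encode(s)[keep] for sp, s in seqs.items()}
        per_block.append((coords, col_codes))
        for sp in rows:
            if sp not in species:
                species.append(sp)

    if not per_block:
        return AlignmentColumnSet([reference], np.empty(0, np.int64),
                                  np.empty((1, 0), np.uint8), reference, chrom or "ref")

    all_coords = np.concatenate([c for c, _ in per_block])
    if len(np.unique(all_coords)) != len(all_coords):
        raise ValueError(f"MAF {path}: duplicate reference coverage (input must be single-copy)")

    order = np.argsort(all_coords)
    codes = np.full((len(species), len(all_coords)), UNKNOWN, dtype=np.uint8)
    offset = 0
    for coords, col_codes in per_block:
        n = len(coords)
        for si, sp in enumerate(species):
            if sp in col_codes:
                codes[si, offset:offset + n] = col_codes[sp]
        offset += n
    return AlignmentColumnSet(species, all_coords[order], codes[:, order],
                              reference, chrom or "ref")


def write_maf(cols: AlignmentColumnSet, path: str) -> None:
    """Write columns as plus-strand MAF, one block per contiguous run."""
    sym = cols.symbols()
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for a, b in cols.contiguous_runs():
            start = int(cols.coords[a])
            size = b - a
            fh.write("a score=0.0\n")
            for si, sp in enumerate(cols.species):
                seq = "".join(sym[si, a:b])
                src = f"{sp}.{cols.chrom}" if sp == cols.reference_name else sp
                fh.write(f"s {src} {start if sp == cols.reference_name else 0} "
                         f"{size} + {start + size if sp == cols.reference_name else size} {seq}\n")
            fh.write("\n")


# ---------------------------------------------------------------------- #
# FASTA column slices

def read_fasta_columns(path: str, reference: str, start: int = 0,
                       chrom: str = "ref") -> AlignmentColumnSet:
    """Read an aligned FASTA as columns at reference coordinates start..start+L."""
    from Bio import SeqIO

    names, seqs = [], []
    for rec in SeqIO.parse(path, "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq))
    if not names:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unaligned FASTA (unequal lengths {sorted(lengths)})")
    codes = np.stack([_encode(s) for s in seqs])
    coords = start + np.arange(codes.shape[1], dtype=np.int64)
    return AlignmentColumnSet(names, coords, codes, reference, chrom)


def write_fasta_columns(cols: AlignmentColumnSet, path: str) -> None:
    sym = cols.symbols()
    with open(path, "w") as fh:
        for si, sp in enumerate(cols.species):
            fh.write(f">{sp}\n{''.join(sym[si])}\n")


# ---------------------------------------------------------------------- #
# elements

def read_elements(path: str, format: str = "bed", element_class: str = "other",
                  one_based: bool = False) -> list[GenomicElement]:
    """Read BED4/BED6 (+ optional summit column 7) or headered TSV elements.

    ``one_based`` declares a 1-based inclusive dialect (TSV only); intervals
    are converted to 0-based half-open on read.
    """
    elements: list[GenomicElement] = []
    if format == "bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                if len(f) < 4:
                    raise ValueError(f"{path}:{ln}: BED needs >= 4 fields")
                summit = int(f[6]) if len(f) >= 7 and f[6] != "." else None
                elements.append(GenomicElement(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), element_id=f[3],
                    element_class=element_class, summit=summit))
    elif format == "tsv":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "start", "end", "element_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
        shift = 1 if one_based else 0
        for row in df.itertuples(index=False):
            d = row._asdict()
            start = int(d["start"]) - shift
            end = int(d["end"])  # 1-based inclusive end == 0-based half-open end
            summit = d.get("summit")
            summit = None if summit is None or (isinstance(summit, float) and np.isnan(summit)) \
                else int(summit) - shift
            elements.append(GenomicElement(
                chrom=str(d["chrom"]), start=start, end=end,
                element_id=str(d["element_id"]),
                element_class=str(d.get("element_class", element_class)),
                summit=summit,
                motif=str(d["motif"]) if d.get("motif") not in (None, "") and
                not (isinstance(d.get("motif"), float) and np.isnan(d["motif"])) else None))
    else:
        raise ValueError(f"unknown element format {format!r}")
    return elements


def write_elements_bed(elements: Iterable[GenomicElement], path: str) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fields = [e.chrom, str(e.start), str(e.end), e.element_id]
            if e.summit is not None:
                fields += ["0", "+", str(e.summit)]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------- #

def extract_clade_columns(cols: AlignmentColumnSet, tree: Phylogeny,
                          clade: str | None, exclude: str | None = None) -> AlignmentColumnSet:
    """Restrict columns to the tips of a named clade.

    ``exclude`` removes a nested clade's tips (e.g. mammals minus primates);
    ``clade=None`` means all tips of the tree.
    """
    tips = tree.clade_tips(clade)
    if exclude is not None:
        drop = set(tree.clade_tips(exclude))
        tips = [t for t in tips if t not in drop]
    keep = [s for s in cols.species if s in set(tips)]
    if not keep:
        raise ValueError(f"no alignment species in clade {clade!r}")
    return cols.subset_species(keep)
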