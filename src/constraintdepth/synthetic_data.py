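"""Seeded generators for every input the pipeline consumes.

Alignments evolve a root sequence drawn from the model's equilibrium down
the tree; planted elements scale the branches of a named clade, planted UCE
intervals are copied unchanged from the root, and missing data is injected
per species. PIP tables and footprint tables reproduce the tail structure
and length-confounded constraint-call bias the enrichment statistics expect.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_io import AlignmentColumnSet, GenomicElement, UNKNOWN
from .phylo_core import SubstitutionModel
from .phylogeny import Phylogeny

__all__ = [
    "PlantedElement",
    "SimulationConfig",
    "simulate_alignment",
    "simulate_pip_table",
    "simulate_footprints",
    "desk_scale_tree",
    "planted_scenario",
]


@dataclasses.dataclass
class PlantedElement:
    start: int
    end: int
    clade: str
    rho: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty planted interval")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


@dataclasses.dataclass
class SimulationConfig:
    tree: Phylogeny
    model: SubstitutionModel
    length: int
    planted: Sequence[PlantedElement] = ()
    uce_intervals: Sequence[tuple[int, int]] = ()
    missing_rate: float = 0.0
    missing_block_length: int = 1
    seed: int = 0
    reference: str | None = None   # defaults to the first tip
    chrom: str = "chrSim"

    def __post_init__(self):
        for el in self.planted:
            if el.end > self.length:
                raise ValueError("planted interval beyond sequence length")
            if el.clade not in self.tree.clades:
                raise ValueError(f"planted clade {el.clade!r} not in tree")
        for s, e in self.uce_intervals:
            if not (0 <= s < e <= self.length):
                raise ValueError("UCE interval outside sequence")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")


def _sample_transitions(P: np.ndarray, parent_states: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    cum = P.cumsum(axis=1)
    u = rng.random(parent_states.size)
    return (u[:, None] > cum[parent_states]).sum(axis=1).astype(np.int8)


def simulate_alignment(config: SimulationConfig
                       ) -> tuple[AlignmentColumnSet, pd.DataFrame]:
    """Evolve columns down the tree; returns (alignment, planted-truth table)."""
    tree, model = config.tree, config.model
    rng = np.random.default_rng(config.seed)
    n = config.length

    # per-column branch scale multiplier for each clade carrying planted elements
    clade_rho = {}
    for el in config.planted:
        arr = clade_rho.setdefault(el.clade, np.ones(n))
        arr[el.start:el.end] *= el.rho
    clade_branch_sets = {c: set(tree.clade_branches(c).tolist()) for c in clade_rho}

    states = np.empty((tree.n_nodes, n), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=n, p=model.frequencies)
    for node in tree.postorder[::-1]:  # parents before children
        node = int(node)
        for child in tree.children[node]:
            t = tree.lengths[child]
            rho_col = np.ones(n)
            for c, arr in clade_rho.items():
                if child in clade_branch_sets[c]:
                    rho_col = rho_col * arr
            child_states = np.empty(n, dtype=np.int8)
            for rho in np.unique(rho_col):
                sel = rho_col == rho
                P = model.transition_matrix(float(t), float(rho))
                child_states[sel] = _sample_transitions(P, states[node, sel], rng)
            states[child] = child_states

    for s, e in config.uce_intervals:  # invariant blocks: copy the root state
        states[:, s:e] = states[tree.root, s:e]

    codes = states[: tree.n_tips].astype(np.uint8)
    if config.missing_rate > 0:
        for sp in range(tree.n_tips):
            mask = _missing_mask(n, config.missing_rate, config.missing_block_length, rng)
            codes[sp, mask] = UNKNOWN

    reference = config.reference or tree.tip_names[0]
    cols = AlignmentColumnSet(tree.tip_names, np.arange(n, dtype=np.int64),
                              codes, reference, config.chrom)
    truth = pd.DataFrame(
        [{"start": el.start, "end": el.end, "clade": el.clade, "rho": el.rho}
         for el in config.planted]
    )
    return cols, truth


def _missing_mask(n: int, rate: float, block_length: int,
                  rng: np.random.Generator) -> np.ndarray:
    if block_length <= 1:
        return rng.random(n) < rate
    n_blocks = int(np.ceil(rate * n / block_length))
    mask = np.zeros(n, dtype=bool)
    starts = rng.integers(0, n, size=n_blocks)
    lengths = rng.geometric(1.0 / block_length, size=n_blocks)
    for s, l in zip(starts, lengths):
        mask[s:s + l] = True
    return mask


# ---------------------------------------------------------------------- #
# tables for the enrichment statistics

def simulate_pip_table(n_variants: int, annotations: Sequence[GenomicElement],
                       causal_enrichment: float, seed: int = 0,
                       genome_length: int = 1_000_000,
                       base_causal_rate: float = 0.02,
                       n_traits: int = 1) -> pd.DataFrame:
    """Fine-mapped-variant table with causal variants enriched in annotations.

    Causal variants get PIPs skewed toward 1, non-causal toward 0; with
    ``n_traits > 1`` each variant is emitted once per trait with independent
    noise so the max-PIP deduplication path is exercised. Returns columns
    variant_id, position, trait, pip, in_annotation, causal (truth).
    """
    if causal_enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    covered = sum(max(0, min(a.end, genome_length) - max(a.start, 0))
                  for a in annotations)
    if annotations and covered == 0:
        raise ValueError("annotations cover zero positions in [0, genome_length)")
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, genome_length, size=n_variants)
    member = np.zeros(n_variants, dtype=bool)
    for a in annotations:
        member |= (pos >= a.start) & (pos < a.end)
    p_causal = np.where(member,
                        np.clip(base_causal_rate * causal_enrichment, 0, 1),
                        base_causal_rate)
    causal = rng.random(n_variants) < p_causal
    rows = []
    for trait in range(n_traits):
        pip = np.where(causal, rng.beta(8.0, 1.5, size=n_variants),
                       rng.beta(0.12, 8.0, size=n_variants))
        rows.append(pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(n_variants)],
            "position": pos, "trait": f"trait{trait}", "pip": pip,
            "in_annotation": member, "causal": causal,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_footprints(n: int, motifs: Sequence[str] = ("M0", "M1", "M2", "M3"),
                        motif_effects: dict[str, float] | None = None,
                        length_confounder: float = 0.0,
                        motif_length_shift: dict[str, float] | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Footprint table with length-dependent constraint-call bias.

    Shorter footprints are more likely to be called mammal-constrained when
    ``length_confounder > 0``; ``motif_length_shift`` shifts a motif's length
    distribution (creating confounding), ``motif_effects`` adds a true
    primate-constraint log-odds effect per motif. Columns: footprint_id,
    length, motif, primate_constrained, mammal_constrained.
    """
    rng = np.random.default_rng(seed)
    motif_effects = motif_effects or {}
    motif_length_shift = motif_length_shift or {}
    motif_arr = rng.choice(list(motifs), size=n)
    shift = np.array([motif_length_shift.get(m, 0.0) for m in motif_arr])
    log_len = rng.normal(3.0 + shift, 0.45)
    length = np.maximum(5, np.round(np.exp(log_len))).astype(int)
    # detection bias operates on the footprint's length decile (callers that
    # stratify by equal-sized length bins can therefore fully adjust for it)
    order = np.lexsort((np.arange(n), length))
    decile = np.empty(n, dtype=float)
    decile[order] = np.arange(n) * 10 // n
    z = (decile - 4.5) / 2.872

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    effect = np.array([motif_effects.get(m, 0.0) for m in motif_arr])
    p_mammal = sigmoid(-0.8 - length_confounder * z)
    p_primate = sigmoid(-0.8 + effect)
    return pd.DataFrame({
        "footprint_id": [f"fp{i}" for i in range(n)],
        "length": length, "motif": motif_arr,
        "primate_constrained": rng.random(n) < p_primate,
        "mammal_constrained": rng.random(n) < p_mammal,
    })


# ---------------------------------------------------------------------- #
# desk-scale scenario

def _balanced_newick(names: list[str], bl: float) -> str:
    if len(names) == 1:
        return f"{names[0]}:{bl}"
    mid = len(names) // 2
    left = _balanced_newick(names[:mid], bl)
    right = _balanced_newick(names[mid:], bl)
    return f"({left},{right}):{bl}"


def desk_scale_tree(branch_length: float = 0.05) -> Phylogeny:
    """Deterministic 40-tip tree with nested clades.

    primates (24 tips) < mammals (36 tips) < vertebrates (all 40 tips);
    the alignment reference is the first primate tip.
    """
    primates = [f"primate{i:02d}" for i in range(24)]
    other_mammals = [f"mammal{i:02d}" for i in range(12)]
    outgroup = [f"vert{i:02d}" for i in range(4)]
    p = _balanced_newick(primates, branch_length)
    m = _balanced_newick(other_mammals, 2 * branch_length)
    v = _balanced_newick(outgroup, 4 * branch_length)
    newick = f"(({p},{m}):{2 * branch_length},{v}):0;"
    return Phylogeny.from_newick(newick, clades={
        "primates": primates,
        "mammals": primates + other_mammals,
        "vertebrates": primates + other_mammals + outgroup,
    })


def planted_scenario(seed: int = 0, n_elements: int = 500,
                     n_planted: int = 50, element_length: int = 40,
                     rho: float = 0.2, clade: str = "primates",
                     missing_rate: float = 0.0,
                     model: SubstitutionModel | None = None,
                     tree: Phylogeny | None = None
                     ) -> tuple[SimulationConfig, list[GenomicElement], np.ndarray]:
    """Default desk-scale scenario: elements tiled end to end, a seeded random
    subset planted as clade-constrained. Returns (config, elements, truth mask).
    """
    tree = tree or desk_scale_tree()
    model = model or SubstitutionModel.hky(3.0, [0.3, 0.2, 0.2, 0.3])
    rng = np.random.default_rng(seed)
    planted_idx = np.zeros(n_elements, dtype=bool)
    planted_idx[rng.choice(n_elements, size=n_planted, replace=False)] = True
    elements = [
        GenomicElement("chrSim", i * element_length, (i + 1) * element_length,
                       f"el{i:04d}", "DHS")
        for i in range(n_elements)
    ]
    planted = [PlantedElement(e.start, e.end, clade, rho)
               for e, keep in zip(elements, planted_idx) if keep]
    config = SimulationConfig(tree=tree, model=model,
                              length=n_elements * element_length,
                              planted=planted, missing_rate=missing_rate,
                              seed=seed)
    return config, elements, planted_idx
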