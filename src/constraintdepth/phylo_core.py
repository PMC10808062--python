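"""Phylogenetic likelihood engine.

Reversible nucleotide substitution model (REV/GTR), transition probabilities
via symmetric eigendecomposition, Felsenstein pruning vectorized over
columns, and EM-style fitting of the neutral model from designated neutral
columns. Missing data ('-' and 'N') is marginalized: the tip partial is a
vector of ones.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment_io import AlignmentColumnSet, GAP
from .phylogeny import Phylogeny

__all__ = [
    "SubstitutionModel",
    "ScaledModel",
    "NeutralFit",
    "RegionalFit",
    "transition_matrix",
    "column_loglik",
    "alignment_loglik",
    "fit_neutral_model",
    "fit_regional_models",
    "write_model",
    "read_model",
]

BASES = "ACGT"
# upper-triangle order of exchangeabilities: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]

_SCALE_FLOOR = 1e-6
_SCALE_CEIL = 1e3


class SubstitutionModel:
    """General reversible 4-state model: Q_ij = s_ij * pi_j (i != j).

    Q is normalized to unit expected substitution rate, so all rate variation
    is carried by branch lengths and scale factors. Detailed balance
    pi_i Q_ij = pi_j Q_ji holds by construction from symmetric s.
    """

    def __init__(self, exchangeabilities: np.ndarray, frequencies: np.ndarray):
        s = np.asarray(exchangeabilities, dtype=float)
        pi = np.asarray(frequencies, dtype=float)
        if s.shape == (6,):
            m = np.zeros((4, 4))
            for k, (i, j) in enumerate(_PAIRS):
                m[i, j] = m[j, i] = s[k]
            s = m
        if s.shape != (4, 4) or not np.allclose(s, s.T):
            raise ValueError("exchangeabilities must be a symmetric 4x4 (or 6-vector)")
        if np.any(s[~np.eye(4, dtype=bool)] < 0):
            raise ValueError("exchangeabilities must be >= 0")
        if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("frequencies must be a positive 4-vector summing to 1")
        self.exchangeabilities = s.copy()
        np.fill_diagonal(self.exchangeabilities, 0.0)
        self.frequencies = pi / pi.sum()

        Q = self.exchangeabilities * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(np.dot(self.frequencies, np.diag(Q)))
        if rate <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        self.rate_matrix = Q / rate

        # symmetric similarity transform guarantees a real spectrum
        sq = np.sqrt(self.frequencies)
        sym = (sq[:, None] * self.rate_matrix) / sq[None, :]
        w, V = np.linalg.eigh((sym + sym.T) / 2)
        self._eigval = w
        self._left = V / sq[:, None]       # D^{-1/2} V
        self._right = V.T * sq[None, :]    # V^T D^{1/2}

    # ------------------------------------------------------------------ #

    def transition_matrix(self, t: float, rho: float = 1.0) -> np.ndarray:
        """P = exp(Q * rho * t); rows sum to 1."""
        if not np.isfinite(t) or not np.isfinite(rho) or t < 0 or rho < 0:
            raise ValueError(f"invalid branch length/scale: t={t}, rho={rho}")
        P = (self._left * np.exp(self._eigval * (rho * t))) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    @classmethod
    def jukes_cantor(cls) -> "SubstitutionModel":
        return cls(np.ones(6), np.full(4, 0.25))

    @classmethod
    def hky(cls, kappa: float, frequencies: Sequence[float]) -> "SubstitutionModel":
        s = np.ones(6)
        s[1] = s[4] = kappa  # AG, CT transitions
        return cls(s, np.asarray(frequencies, dtype=float))

    @classmethod
    def random(cls, rng: np.random.Generator) -> "SubstitutionModel":
        s = rng.uniform(0.3, 3.0, size=6)
        pi = rng.dirichlet(np.full(4, 10.0))
        return cls(s, pi)

    def exchangeability_vector(self) -> np.ndarray:
        return np.array([self.exchangeabilities[i, j] for i, j in _PAIRS])

    def __repr__(self) -> str:  # pragma: no cover
        s = ", ".join(f"{v:.3g}" for v in self.exchangeability_vector())
        pi = ", ".join(f"{v:.3g}" for v in self.frequencies)
        return f"SubstitutionModel(s=[{s}], pi=[{pi}])"


@dataclasses.dataclass
class ScaledModel:
    """A base model with branch scaling rho applied to a named clade."""

    base: SubstitutionModel
    scale_factor: float = 1.0
    scaled_clade: str | None = None

    def __post_init__(self):
        if self.scale_factor < 0:
            raise ValueError("scale_factor must be >= 0")


# ---------------------------------------------------------------------- #
# likelihood

def transition_matrix(model: SubstitutionModel, t: float, rho: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rho)


_TIP_PARTIALS = np.vstack([np.eye(4), np.ones((2, 4))])  # codes 4 ('-') and 5 ('N') marginalize


def _branch_matrices(tree: Phylogeny, model: SubstitutionModel, scale: np.ndarray) -> list:
    Ps: list = [None] * tree.n_nodes
    for i in range(tree.n_nodes):
        if tree.parent[i] >= 0:
            Ps[i] = model.transition_matrix(tree.lengths[i] * scale[i])
    return Ps


def _branch_scales(tree: Phylogeny, rho: float, clade: str | None,
                   base: float = 1.0) -> np.ndarray:
    scale = np.full(tree.n_nodes, base)
    if clade is None:
        scale *= rho
    else:
        scale[tree.clade_branches(clade)] *= rho
    return scale


def alignment_loglik(
    tree: Phylogeny,
    model: SubstitutionModel,
    cols: AlignmentColumnSet | np.ndarray,
    species: Sequence[str] | None = None,
    rho: float = 1.0,
    clade: str | None = None,
    branch_scale: float = 1.0,
    per_column: bool = False,
    weights: np.ndarray | None = None,
):
    """Felsenstein pruning, vectorized over columns; log-scaled (no underflow).

    ``rho`` scales the branches of ``clade`` (the whole tree when clade is
    None); ``branch_scale`` is a global multiplier applied everywhere (used
    by neutral fitting). Species in the tree but absent from the alignment
    are treated as missing.
    """
    if isinstance(cols, AlignmentColumnSet):
        codes, species = cols.codes, cols.species
    else:
        codes = np.asarray(cols, dtype=np.uint8)
        if species is None:
            raise ValueError("species order required with a raw code matrix")
    if codes.ndim == 1:
        codes = codes[:, None]
    unknown = [s for s in species if s not in tree.tip_index]
    if unknown:
        raise ValueError(f"alignment species not in tree: {unknown}")

    n_cols = codes.shape[1]
    tip_codes = np.full((tree.n_tips, n_cols), 5, dtype=np.uint8)
    for row, sp in enumerate(species):
        tip_codes[tree.tip_index[sp]] = codes[row]

    scale = _branch_scales(tree, rho, clade, base=branch_scale)
    Ps = _branch_matrices(tree, model, scale)

    store: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_cols)
    for node in tree.postorder:
        node = int(node)
        if node < tree.n_tips:
            part = _TIP_PARTIALS[np.minimum(tip_codes[node], 4)]
        else:
            part = None
            for c in tree.children[node]:
                contrib = store.pop(c) @ Ps[c].T
                part = contrib if part is None else part * contrib
            m = part.max(axis=1)
            nz = m > 0
            safe = np.where(nz, m, 1.0)
            part = part / safe[:, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(nz, np.log(safe), -np.inf)
        store[node] = part

    root_part = store[int(tree.root)]
    with np.errstate(divide="ignore"):
        ll = logscale + np.log(root_part @ model.frequencies)
    if per_column:
        return ll
    if weights is not None:
        return float(np.dot(ll, weights))
    return float(ll.sum())


def column_loglik(column, tree: Phylogeny, model: SubstitutionModel,
                  rho: float = 1.0, clade: str | None = None) -> float:
    """Log-likelihood of a single column (dict species->symbol or code vector)."""
    if isinstance(column, dict):
        from .alignment_io import _CODE

        species = list(column)
        codes = np.array([_CODE[column[s].upper()] for s in species], dtype=np.uint8)
    else:
        raise TypeError("column must be a dict of species -> symbol")
    return float(alignment_loglik(tree, model, codes[:, None], species,
                                  rho=rho, clade=clade))


# ---------------------------------------------------------------------- #
# neutral fitting

@dataclasses.dataclass
class NeutralFit:
    model: SubstitutionModel
    branch_scale: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: list[float] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class RegionalFit:
    window: tuple[int, int]
    fit: NeutralFit | None
    fallback: bool
    n_columns: int


def _compress_patterns(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(codes, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def fit_neutral_model(
    neutral_columns: AlignmentColumnSet | np.ndarray,
    tree: Phylogeny,
    species: Sequence[str] | None = None,
    init: SubstitutionModel | None = None,
    min_columns: int = 1000,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> NeutralFit:
    """Fit the REV neutral model by coordinate-ascent maximum likelihood.

    Equilibrium frequencies come from observed non-missing base counts (the
    expected sufficient statistics under marginalized missing data); the
    exchangeabilities (s_GT anchored at 1) and a single global branch-length
    multiplier are then alternately maximized, so the log-likelihood trace is
    monotone. Non-convergence returns ``converged=False`` rather than raising.
    """
    if isinstance(neutral_columns, AlignmentColumnSet):
        codes, species = neutral_columns.codes, neutral_columns.species
    else:
        codes = np.asarray(neutral_columns, dtype=np.uint8)
        if species is None:
            raise ValueError("species order required with a raw code matrix")

    informative = (codes < GAP).any(axis=0)
    if int(informative.sum()) < min_columns:
        raise ValueError(
            f"need >= {min_columns} informative columns, got {int(informative.sum())}"
        )

    counts = np.bincount(codes[codes < GAP].ravel(), minlength=4).astype(float)
    counts += 0.5  # guard empty categories
    pi = counts / counts.sum()

    patterns, weights = _compress_patterns(codes)

    if init is None:
        init = SubstitutionModel(np.ones(6), pi)
    log_s = np.log(np.maximum(init.exchangeability_vector()[:5] /
                              max(init.exchangeability_vector()[5], 1e-12), 1e-12))
    log_beta = 0.0

    def model_of(ls: np.ndarray) -> SubstitutionModel:
        s = np.ones(6)
        s[:5] = np.exp(ls)
        return SubstitutionModel(s, pi)

    def nll(ls: np.ndarray, lb: float) -> float:
        return -alignment_loglik(tree, model_of(ls), patterns, species,
                                 branch_scale=float(np.exp(lb)), weights=weights)

    ll = -nll(log_s, log_beta)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        res_s = minimize(lambda x: nll(x, log_beta), log_s, method="L-BFGS-B",
                         bounds=[(-12.0, 12.0)] * 5)
        if -res_s.fun >= ll:
            log_s, ll = res_s.x, -res_s.fun
        res_b = minimize_scalar(lambda b: nll(log_s, b), method="bounded",
                                bounds=(np.log(_SCALE_FLOOR), np.log(_SCALE_CEIL)),
                                options={"xatol": 1e-8})
        if -res_b.fun >= ll:
            log_beta, ll = float(res_b.x), -res_b.fun
        trace.append(ll)
        if trace[-1] - trace[-2] < tol:
            converged = True
            break

    return NeutralFit(
        model=model_of(log_s),
        branch_scale=float(np.exp(log_beta)),
        log_likelihood=float(ll),
        n_iterations=it,
        converged=converged,
        loglik_trace=trace,
    )


def fit_regional_models(
    cols: AlignmentColumnSet,
    tree: Phylogeny,
    window_size: int,
    sample_size: int,
    seed: int = 0,
    max_missing_frac: float = 0.2,
    min_columns: int = 200,
    global_fit: NeutralFit | None = None,
) -> list[RegionalFit]:
    """One neutral fit per reference window from a random column subsample.

    Columns with more than ``max_missing_frac`` missing species are trimmed;
    windows with fewer than ``min_columns`` eligible columns are flagged and
    fall back to the global model.
    """
    rng = np.random.default_rng(seed)
    if global_fit is None:
        global_fit = fit_neutral_model(cols, tree, min_columns=min_columns)

    lo = int(cols.coords.min()) if cols.n_columns else 0
    hi = int(cols.coords.max()) + 1 if cols.n_columns else 0
    fits: list[RegionalFit] = []
    for wstart in range(lo - lo % window_size, hi, window_size):
        wend = wstart + window_size
        sel = (cols.coords >= wstart) & (cols.coords < wend)
        codes = cols.codes[:, sel]
        missing_frac = (codes >= GAP).mean(axis=0)
        codes = codes[:, missing_frac <= max_missing_frac]
        n_elig = codes.shape[1]
        if n_elig < min_columns:
            fits.append(RegionalFit((wstart, wend), global_fit, True, n_elig))
            continue
        if n_elig > sample_size:
            idx = rng.choice(n_elig, size=sample_size, replace=False)
            codes = codes[:, np.sort(idx)]
        fit = fit_neutral_model(codes, tree, species=cols.species,
                                min_columns=min(min_columns, codes.shape[1]))
        fits.append(RegionalFit((wstart, wend), fit, False, codes.shape[1]))
    return fits


# ---------------------------------------------------------------------- #
# serialization: small key-value text format

def write_model(fit_or_model, path: str) -> None:
    if isinstance(fit_or_model, NeutralFit):
        model, scale = fit_or_model.model, fit_or_model.branch_scale
    else:
        model, scale = fit_or_model, 1.0
    names = ["AC", "AG", "AT", "CG", "CT", "GT"]
    with open(path, "w") as fh:
        for b, v in zip(BASES, model.frequencies):
            fh.write(f"pi_{b}\t{v:.10g}\n")
        for n, v in zip(names, model.exchangeability_vector()):
            fh.write(f"s_{n}\t{v:.10g}\n")
        fh.write(f"tree_scale\t{scale:.10g}\n")


def read_model(path: str) -> tuple[SubstitutionModel, float]:
    kv = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                k, v = line.split()
                kv[k] = float(v)
    pi = np.array([kv[f"pi_{b}"] for b in BASES])
    s = np.array([kv[f"s_{n}"] for n in ["AC", "AG", "AT", "CG", "CT", "GT"]])
    return SubstitutionModel(s, pi), kv.get("tree_scale", 1.0)
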