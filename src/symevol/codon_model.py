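"""Goldman-Yang codon substitution model with branch-class omega.

Implements the likelihood machinery for branch-model dN/dS tests: the 61-state
rate matrix Q with q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for
single-nucleotide codon changes, transition probabilities by spectral matrix
exponential, Felsenstein pruning over codon site patterns, bounded multi-start
maximum likelihood, the one-ratio vs two-ratio likelihood-ratio test, and ML
pairwise dN/dS for two-sequence ortholog groups.

Branch lengths are in expected substitutions per codon (each class's Q is
normalised to unit mean rate), so a fitted tree length is directly comparable
to tree-length cutoffs quoted in substitutions per codon.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.optimize import minimize
from scipy.stats import chi2

from .io_formats import BACKGROUND, FOREGROUND, LabeledTree, TreeNode, logger

# ---------------------------------------------------------------------------
# Genetic code tables (universal code, 61 sense codons)
# ---------------------------------------------------------------------------

_CODE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(sorted(_CODE.stop_codons))
CODONS: tuple[str, ...] = tuple(sorted(_CODE.forward_table))
N_CODONS = len(CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
AMINO_ACID: tuple[str, ...] = tuple(_CODE.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def _build_pair_masks() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    nonsyn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = (a in _PURINES) == (b in _PURINES)
            nonsyn[i, j] = AMINO_ACID[i] != AMINO_ACID[j]
    return single, transition, nonsyn


_SINGLE_STEP, _IS_TRANSITION, _IS_NONSYN = _build_pair_masks()

OMEGA_LOWER = 1e-6
OMEGA_UPPER = 999.0
KAPPA_LOWER = 1e-6
KAPPA_UPPER = 999.0
BL_LOWER = 1e-8
BL_UPPER = 99.0


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap- and stop-free aligned codon columns over 2-4 taxa."""

    taxa: list[str]
    codes: np.ndarray  # (n_taxa, n_codons) int codon indices

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_codons)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon ids")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= N_CODONS):
            raise ValueError("codon indices outside [0, 61)")

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "CodonAlignment":
        """Build from equal-length, gap- and stop-free nucleotide CDS strings."""
        taxa = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences differ in length")
        (nt_len,) = lengths
        if nt_len % 3:
            raise ValueError(f"sequence length {nt_len} not a multiple of 3")
        rows = []
        for taxon in taxa:
            seq = sequences[taxon].upper()
            row = []
            for k in range(0, nt_len, 3):
                codon = seq[k : k + 3]
                if codon in STOP_CODONS:
                    raise ValueError(f"stop codon {codon} at position {k + 1} in {taxon!r}")
                if codon not in CODON_INDEX:
                    raise ValueError(f"unrecognised codon {codon!r} at position {k + 1} in {taxon!r}")
                row.append(CODON_INDEX[codon])
            rows.append(row)
        return cls(taxa, np.array(rows, dtype=np.int64))

    def to_sequences(self) -> dict[str, str]:
        return {
            taxon: "".join(CODONS[c] for c in row)
            for taxon, row in zip(self.taxa, self.codes)
        }

    def subset(self, taxa: Sequence[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(list(taxa), self.codes[idx].copy())

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their counts (pruning works per pattern)."""
        pats, counts = np.unique(self.codes, axis=1, return_counts=True)
        return pats, counts.astype(float)


@dataclass
class CodonModelParams:
    """kappa, branch-class omegas and codon frequencies of a GY94 model."""

    kappa: float
    omega_by_class: dict[str, float]
    pi: np.ndarray  # 61 codon frequencies

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have {N_CODONS} entries")
        if np.any(self.pi < 0):
            raise ValueError("pi entries must be nonnegative")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError(f"pi sums to {self.pi.sum()}, not 1")
        if not (0 <= self.kappa <= KAPPA_UPPER):
            raise ValueError(f"kappa {self.kappa} outside [0, {KAPPA_UPPER}]")
        for cls_name, omega in self.omega_by_class.items():
            if not (0 <= omega <= OMEGA_UPPER):
                raise ValueError(f"omega[{cls_name}] = {omega} outside [0, {OMEGA_UPPER}]")

    def omega(self, branch_class: str) -> float:
        if branch_class in self.omega_by_class:
            return self.omega_by_class[branch_class]
        return self.omega_by_class[BACKGROUND]


def equal_pi() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def empirical_pi(aln: CodonAlignment, model: str = "F3x4") -> np.ndarray:
    """Codon frequencies from alignment nucleotide composition.

    ``F3x4`` uses position-specific nucleotide frequencies (codeml default),
    ``F1x4`` a single set, ``equal`` uniform 1/61.  Stop codons are excluded
    and the vector renormalised; a small floor keeps observed codons off zero
    frequency in short alignments.
    """
    if model == "equal":
        return equal_pi()
    seqs = aln.to_sequences()
    concat = "".join(seqs.values())
    base = "ACGT"
    if model == "F1x4":
        counts = np.array([concat.count(b) for b in base], dtype=float)
        freq = counts / counts.sum()
        pos_freqs = [freq, freq, freq]
    elif model == "F3x4":
        pos_freqs = []
        for pos in range(3):
            sub = concat[pos::3]
            counts = np.array([sub.count(b) for b in base], dtype=float)
            if counts.sum() == 0:
                counts[:] = 1.0
            pos_freqs.append(counts / counts.sum())
    else:
        raise ValueError(f"unknown frequency model {model!r}")
    pi = np.array(
        [
            pos_freqs[0][base.index(c[0])]
            * pos_freqs[1][base.index(c[1])]
            * pos_freqs[2][base.index(c[2])]
            for c in CODONS
        ]
    )
    pi = np.maximum(pi, 1e-8)
    return pi / pi.sum()


@dataclass
class FitResult:
    lnL: float
    params: CodonModelParams
    branch_lengths: dict[int, float]  # branch index (postorder, excl. root) -> length
    tree_length: float
    converged: bool
    n_restarts_used: int
    omega_defined: bool = True


@dataclass
class BranchTestResult:
    ortholog_id: str
    focal_clade: str
    n_taxa: int
    lnL_null: float
    lnL_alt: float
    omega_fg: float
    omega_bg: float
    lrt_stat: float
    p_value: float
    direction: str  # {higher, lower}
    converged: bool = True


@dataclass
class PairwiseDnDs:
    dN: float
    dS: float
    ratio: Optional[float]  # None when undefined (dN = dS = 0); inf when dS = 0 < dN
    t: float
    kappa: float = math.nan
    lnL: float = math.nan


# ---------------------------------------------------------------------------
# Rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def build_rate_matrix(params: CodonModelParams, omega_class: str = BACKGROUND) -> np.ndarray:
    """Normalised GY94 rate matrix for one branch class.

    Off-diagonal q_ij is nonzero only for single-nucleotide codon changes and
    equals pi_j, times kappa for transitions and omega for nonsynonymous
    changes.  The matrix is scaled so the stationary mean rate is 1
    (-sum_i pi_i q_ii = 1), putting branch lengths in substitutions per codon.
    """
    omega = params.omega(omega_class)
    Q = np.where(_SINGLE_STEP, params.pi[np.newaxis, :], 0.0)
    Q = Q * np.where(_IS_TRANSITION, params.kappa, 1.0)
    Q = Q * np.where(_IS_NONSYN, omega, 1.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(params.pi @ np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero mean rate)")
    return Q / scale


def flux_fractions(params: CodonModelParams, omega_class: str = BACKGROUND) -> tuple[float, float]:
    """(nonsynonymous, synonymous) fractions of substitution flux under Q."""
    Q = build_rate_matrix(params, omega_class)
    off = params.pi[:, np.newaxis] * Q
    rho_n = float(off[_IS_NONSYN & _SINGLE_STEP].sum())
    rho_s = float(off[~_IS_NONSYN & _SINGLE_STEP].sum())
    total = rho_n + rho_s
    return rho_n / total, rho_s / total


class _SpectralQ:
    """Cached symmetric eigendecomposition of a reversible Q for fast exp(Qt)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        S = (sqrt_pi[:, np.newaxis] * Q) / sqrt_pi[np.newaxis, :]
        S = 0.5 * (S + S.T)  # symmetrise away rounding noise
        self.eigvals, V = np.linalg.eigh(S)
        self.left = V / sqrt_pi[:, np.newaxis] * 1.0
        self.right = (V * sqrt_pi[:, np.newaxis]).T

    def expm(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.eigvals * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Left null vector of Q, normalised to a probability vector."""
    w, vl = np.linalg.eig(Q.T)
    k = int(np.argmin(np.abs(w)))
    pi = np.real(vl[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def transition_matrix(Q: np.ndarray, t: float, pi: Optional[np.ndarray] = None) -> np.ndarray:
    """P(t) = exp(Qt) via the pi^(1/2) similarity transform (reversible Q)."""
    if t < 0:
        raise ValueError(f"branch length t = {t} must be nonnegative")
    if pi is None:
        pi = stationary_distribution(Q)
    return _SpectralQ(Q, np.asarray(pi, dtype=float)).expm(t)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _class_decompositions(params: CodonModelParams) -> dict[str, _SpectralQ]:
    return {
        cls_name: _SpectralQ(build_rate_matrix(params, cls_name), params.pi)
        for cls_name in params.omega_by_class
    }


def _pruning_root_partial(
    tree: LabeledTree,
    params: CodonModelParams,
    leaf_codes: dict[str, np.ndarray],
    decomps: Optional[dict[str, _SpectralQ]] = None,
    branch_lengths: Optional[dict[int, float]] = None,
) -> np.ndarray:
    if decomps is None:
        decomps = _class_decompositions(params)
    branches = tree.branches()
    index_of = {id(n): i for i, n in enumerate(branches)}

    def length_of(node: TreeNode) -> float:
        if branch_lengths is None:
            return node.length
        return branch_lengths[index_of[id(node)]]

    def partial(node: TreeNode) -> np.ndarray:
        out = None
        for child in node.children:
            cls_name = child.label if child.label in params.omega_by_class else BACKGROUND
            P = decomps[cls_name].expm(length_of(child))
            if child.is_leaf:
                contrib = P.T[leaf_codes[child.name]]
            else:
                contrib = partial(child) @ P.T
            out = contrib if out is None else out * contrib
        return out

    return partial(tree.root)


def log_likelihood(
    aln: CodonAlignment,
    tree: LabeledTree,
    params: CodonModelParams,
    _decomps: Optional[dict[str, _SpectralQ]] = None,
    _branch_lengths: Optional[dict[int, float]] = None,
    _patterns: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> float:
    """Felsenstein pruning log-likelihood over codon site patterns."""
    if set(aln.taxa) != set(tree.leaf_names()):
        raise ValueError(f"alignment taxa {aln.taxa} != tree leaves {tree.leaf_names()}")
    pats, counts = aln.patterns() if _patterns is None else _patterns
    leaf_codes = {taxon: pats[aln.taxa.index(taxon)] for taxon in aln.taxa}
    root_partial = _pruning_root_partial(tree, params, leaf_codes, _decomps, _branch_lengths)
    site_lik = root_partial @ params.pi
    if np.any(site_lik <= 0):
        return -np.inf
    return float(counts @ np.log(site_lik))


def brute_force_log_likelihood(
    aln: CodonAlignment, tree: LabeledTree, params: CodonModelParams
) -> float:
    """Direct marginalisation over all internal-node states (test oracle).

    Exponential in the number of internal nodes; intended for <= 4 leaves and
    a handful of columns only.
    """
    decomps = _class_decompositions(params)
    internal = [n for n in tree.root.postorder() if not n.is_leaf]
    leaf_row = {taxon: aln.taxa.index(taxon) for taxon in aln.taxa}
    non_root = [n for n in tree.root.postorder() if n is not tree.root]
    parent_of = {id(n): _parent_of(tree.root, n) for n in non_root}
    P_of = {}
    for node in non_root:
        cls_name = node.label if node.label in params.omega_by_class else BACKGROUND
        P_of[id(node)] = decomps[cls_name].expm(node.length)
    total = 0.0
    for col in range(aln.length):
        site = 0.0
        for states in itertools.product(range(N_CODONS), repeat=len(internal)):
            state_of = {id(n): s for n, s in zip(internal, states)}
            prob = params.pi[state_of[id(tree.root)]]
            for node in non_root:
                ps = state_of[id(parent_of[id(node)])]
                cs = (
                    aln.codes[leaf_row[node.name], col]
                    if node.is_leaf
                    else state_of[id(node)]
                )
                prob *= P_of[id(node)][ps, cs]
            site += prob
        total += math.log(site)
    return total


def _parent_of(root: TreeNode, target: TreeNode) -> TreeNode:
    for node in root.postorder():
        if target in node.children:
            return node
    raise ValueError("node not in tree")


def reroot(tree: LabeledTree, new_root_leaf: str) -> LabeledTree:
    """Reroot at the parent edge of a named leaf (for root-invariance checks).

    The leaf's branch is split in half; labels travel with their branches.
    """
    tree = tree.copy()
    leaf = next(n for n in tree.leaves() if n.name == new_root_leaf)

    # Build adjacency with (length, label) on each undirected edge.
    edges: dict[int, list[tuple[TreeNode, float, str]]] = {}
    nodes = list(tree.root.postorder())
    for node in nodes:
        for child in node.children:
            edges.setdefault(id(node), []).append((child, child.length, child.label))
            edges.setdefault(id(child), []).append((node, child.length, child.label))

    half = leaf.length / 2.0
    new_root = TreeNode(name=None, length=0.0)

    def build(node: TreeNode, come_from: Optional[TreeNode], length: float, label: str) -> TreeNode:
        out = TreeNode(node.name, length, label)
        for neigh, l, lab in edges.get(id(node), []):
            if come_from is not None and neigh is come_from:
                continue
            out.children.append(build(neigh, node, l, lab))
        return out

    old_parent = _parent_of(tree.root, leaf)
    new_root.children.append(build(leaf, old_parent, half, leaf.label))
    new_root.children.append(build(old_parent, leaf, half, leaf.label))
    return LabeledTree(new_root)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _codon_p_distance(aln: CodonAlignment, i: int, j: int) -> float:
    diff = float(np.mean(aln.codes[i] != aln.codes[j])) if aln.length else 0.0
    return max(diff, 1e-3)


def _initial_branch_lengths(aln: CodonAlignment, tree: LabeledTree) -> list[float]:
    """p-distance heuristic: terminal branches get half the closest-neighbour
    codon p-distance, internal branches a quarter of the mean distance."""
    n = len(aln.taxa)
    dists = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dists[i, j] = dists[j, i] = _codon_p_distance(aln, i, j)
    mean_d = float(dists[np.triu_indices(n, 1)].mean()) if n > 1 else 0.1
    out = []
    for node in tree.branches():
        if node.is_leaf:
            i = aln.taxa.index(node.name)
            others = [dists[i, j] for j in range(n) if j != i]
            out.append(max(0.5 * min(others), 1e-3))
        else:
            out.append(max(0.25 * mean_d, 1e-3))
    return out


def fit(
    aln: CodonAlignment,
    tree: LabeledTree,
    model: str = "one_ratio",
    restarts: int = 3,
    seed: int = 0,
    frequency_model: str = "F3x4",
    pi: Optional[np.ndarray] = None,
    maxiter: int = 200,
) -> FitResult:
    """Maximum-likelihood fit of branch lengths, kappa and omega(s).

    ``one_ratio`` estimates a single omega for every branch; ``two_ratio``
    estimates a foreground omega on branches labeled foreground and a
    background omega elsewhere.  Parameters are optimised on log scale with
    L-BFGS-B and ``restarts`` jittered starts.  Omega estimates at the upper
    bound (999, codeml convention) are reported as infinite.
    """
    if model not in ("one_ratio", "two_ratio"):
        raise ValueError(f"unknown model {model!r}")
    if set(aln.taxa) != set(tree.leaf_names()):
        raise ValueError("alignment taxa and tree leaves differ")
    if model == "two_ratio" and not any(
        n.label == FOREGROUND for n in tree.branches()
    ):
        raise ValueError("two_ratio model requires a foreground-labeled branch")
    if aln.length < 10:
        logger.warning("alignment of %d codons is very short; fit may not converge", aln.length)

    pi_vec = np.asarray(pi, dtype=float) if pi is not None else empirical_pi(aln, frequency_model)
    classes = [BACKGROUND] if model == "one_ratio" else [BACKGROUND, FOREGROUND]

    branches = tree.branches()
    n_branches = len(branches)
    # For a 2-leaf tree only the path between the leaves is identifiable:
    # optimise the first branch and pin the second to ~0.
    two_leaf = len(aln.taxa) == 2 and n_branches == 2
    free_idx = [0] if two_leaf else list(range(n_branches))

    patterns = aln.patterns()
    pats, counts = patterns

    # Degenerate input: all taxa identical at every column.
    if bool(np.all(pats == pats[0:1, :])):
        lnL = float(counts @ np.log(pi_vec[pats[0]]))
        params = CodonModelParams(2.0, {c: 0.0 for c in classes}, pi_vec)
        return FitResult(
            lnL=lnL,
            params=params,
            branch_lengths={i: 0.0 for i in range(n_branches)},
            tree_length=0.0,
            converged=True,
            n_restarts_used=0,
            omega_defined=False,
        )

    init_bl = _initial_branch_lengths(aln, tree)
    rng = np.random.default_rng(seed)

    def unpack(x: np.ndarray):
        bl = np.full(n_branches, BL_LOWER)
        for k, i in enumerate(free_idx):
            bl[i] = math.exp(x[k])
        kappa = min(math.exp(x[len(free_idx)]), KAPPA_UPPER)
        omegas = [min(math.exp(v), OMEGA_UPPER) for v in x[len(free_idx) + 1 :]]
        return bl, kappa, dict(zip(classes, omegas))

    decomp_cache: dict[tuple, dict[str, _SpectralQ]] = {}

    def objective(x: np.ndarray) -> float:
        bl, kappa, omega_by_class = unpack(x)
        key = (round(kappa, 12), tuple(round(v, 12) for v in omega_by_class.values()))
        decomps = decomp_cache.get(key)
        params = CodonModelParams(kappa, omega_by_class, pi_vec)
        if decomps is None:
            decomps = _class_decompositions(params)
            if len(decomp_cache) > 256:
                decomp_cache.clear()
            decomp_cache[key] = decomps
        lnL = log_likelihood(
            aln, tree, params,
            _decomps=decomps,
            _branch_lengths={i: bl[i] for i in range(n_branches)},
            _patterns=patterns,
        )
        return -lnL if np.isfinite(lnL) else 1e12

    bounds = (
        [(math.log(BL_LOWER), math.log(BL_UPPER))] * len(free_idx)
        + [(math.log(KAPPA_LOWER), math.log(KAPPA_UPPER))]
        + [(math.log(OMEGA_LOWER), math.log(OMEGA_UPPER))] * len(classes)
    )

    best = None
    used = 0
    for attempt in range(max(restarts, 1)):
        used = attempt + 1
        bl0 = np.array([init_bl[i] for i in free_idx])
        kappa0, omega0 = 2.0, 0.4
        if attempt > 0:
            bl0 = bl0 * rng.lognormal(0.0, 0.5, size=bl0.shape)
            kappa0 *= rng.lognormal(0.0, 0.4)
            omega0 *= rng.lognormal(0.0, 0.8)
        x0 = np.concatenate([np.log(np.clip(bl0, BL_LOWER, BL_UPPER)),
                             [math.log(kappa0)],
                             np.full(len(classes), math.log(omega0))])
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.success and attempt + 1 >= min(restarts, 1):
            # keep cycling through requested restarts; no early exit beyond them
            pass

    bl, kappa, omega_by_class = unpack(best.x)
    reported = {
        c: (math.inf if v >= OMEGA_UPPER * (1 - 1e-4) else v)
        for c, v in omega_by_class.items()
    }
    params = CodonModelParams(
        kappa, {c: min(v, OMEGA_UPPER) for c, v in omega_by_class.items()}, pi_vec
    )
    params.omega_by_class = reported  # report inf past the bound, codeml style
    return FitResult(
        lnL=-float(best.fun),
        params=params,
        branch_lengths={i: float(bl[i]) for i in range(n_branches)},
        tree_length=float(np.sum(bl)),
        converged=bool(best.success),
        n_restarts_used=used,
    )


def branch_test(
    aln: CodonAlignment,
    tree: LabeledTree,
    focal_leaf: str,
    ortholog_id: str = "",
    restarts: int = 3,
    seed: int = 0,
    frequency_model: str = "F3x4",
    pi: Optional[np.ndarray] = None,
) -> BranchTestResult:
    """One-ratio vs two-ratio LRT with foreground = terminal branch of *focal_leaf*.

    The statistic 2(lnL_alt - lnL_null) is referred to chi-square with one
    degree of freedom; negative differences from numerical noise clip to 0.
    """
    from .stats_multiple_testing import lrt_pvalue

    null_tree = tree.clear_labels()
    alt_tree = tree.set_foreground_leaf(focal_leaf)
    pi_vec = np.asarray(pi, dtype=float) if pi is not None else empirical_pi(aln, frequency_model)

    fit0 = fit(aln, null_tree, "one_ratio", restarts=restarts, seed=seed, pi=pi_vec)
    fit1 = fit(aln, alt_tree, "two_ratio", restarts=restarts, seed=seed + 1, pi=pi_vec)
    # The alternative nests the null; never report lnL1 below lnL0.
    lnL1 = max(fit1.lnL, fit0.lnL)
    stat = max(0.0, 2.0 * (lnL1 - fit0.lnL))
    p = lrt_pvalue(fit0.lnL, lnL1)
    omega_fg = fit1.params.omega_by_class[FOREGROUND]
    omega_bg = fit1.params.omega_by_class[BACKGROUND]
    return BranchTestResult(
        ortholog_id=ortholog_id,
        focal_clade=focal_leaf,
        n_taxa=len(aln.taxa),
        lnL_null=fit0.lnL,
        lnL_alt=lnL1,
        omega_fg=omega_fg,
        omega_bg=omega_bg,
        lrt_stat=stat,
        p_value=p,
        direction="higher" if omega_fg > omega_bg else "lower",
        converged=fit0.converged and fit1.converged,
    )


# ---------------------------------------------------------------------------
# Pairwise dN/dS
# ---------------------------------------------------------------------------

def pairwise_dnds(
    seq1: str,
    seq2: str,
    restarts: int = 3,
    seed: int = 0,
    frequency_model: str = "F3x4",
    pi: Optional[np.ndarray] = None,
) -> PairwiseDnDs:
    """ML pairwise dN/dS between two gap/stop-free codon sequences.

    Fits (t, kappa, omega) on the single connecting branch, then decomposes t
    into dN and dS using the substitution-flux split of the fitted Q and the
    site counts implied by the omega=1 matrix (codeml's definition).
    Identical sequences give dN = dS = 0 with an undefined ratio; dS = 0 with
    dN > 0 reports an infinite ratio.
    """
    aln = CodonAlignment.from_sequences({"s1": seq1, "s2": seq2})
    pi_vec = np.asarray(pi, dtype=float) if pi is not None else empirical_pi(aln, frequency_model)

    if bool(np.all(aln.codes[0] == aln.codes[1])):
        return PairwiseDnDs(dN=0.0, dS=0.0, ratio=None, t=0.0)

    root = TreeNode(None, 0.0, BACKGROUND, [
        TreeNode("s1", 0.1), TreeNode("s2", 0.1),
    ])
    tree = LabeledTree(root)
    result = fit(aln, tree, "one_ratio", restarts=restarts, seed=seed, pi=pi_vec)
    t = result.tree_length
    kappa = result.params.kappa
    omega = result.params.omega_by_class[BACKGROUND]
    omega_capped = min(omega, OMEGA_UPPER) if math.isfinite(omega) else OMEGA_UPPER

    fitted = CodonModelParams(kappa, {BACKGROUND: omega_capped}, pi_vec)
    neutral = CodonModelParams(kappa, {BACKGROUND: 1.0}, pi_vec)
    rho_n, rho_s = flux_fractions(fitted)
    rho_n1, rho_s1 = flux_fractions(neutral)
    dN = t * rho_n / (3.0 * rho_n1)
    dS = t * rho_s / (3.0 * rho_s1)
    if omega <= OMEGA_LOWER * 1.5:
        dN = 0.0
    if not math.isfinite(omega) or omega >= OMEGA_UPPER * (1 - 1e-4):
        dS = 0.0
    if dS == 0.0:
        ratio: Optional[float] = None if dN == 0.0 else math.inf
    else:
        ratio = dN / dS
    return PairwiseDnDs(dN=dN, dS=dS, ratio=ratio, t=t, kappa=kappa, lnL=result.lnL)
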