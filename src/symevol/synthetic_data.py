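"""Generators for every pipeline input, with known ground truth.

Four families of fixtures: codon alignments evolved under the GY94 branch
model on a fixed tree; short marker reads drawn from a two-clade mixture of
three locus references; ortholog universes with planted CD/BCD/ABCD group
memberships; and joinable contig layouts with the expected join sets.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .codon_model import (
    _IS_NONSYN,
    _SINGLE_STEP,
    _SpectralQ,
    BACKGROUND,
    CODONS,
    CodonAlignment,
    CodonModelParams,
    N_CODONS,
    build_rate_matrix,
)
from .io_formats import HitRecord, LabeledTree, SequenceRecord, TreeNode
from .community_profile import MarkerReference

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Codon alignment simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    true_params: CodonModelParams
    tree: LabeledTree
    seed: int
    # branch index (postorder, excluding root) -> (synonymous, nonsynonymous)
    # realized substitution counts; populated only in "gillespie" mode.
    realized_substitutions: Optional[dict[int, tuple[int, int]]] = None


def clade_tree(
    foreground: Optional[str] = None,
    lengths: Optional[dict[str, float]] = None,
) -> LabeledTree:
    """The fixed 4-taxon clade tree ((B,C),D,A) used throughout.

    ``lengths`` maps leaf names (and "BC" for the internal branch) to branch
    lengths in substitutions per codon; default 0.2 everywhere.
    """
    L = lengths or {}

    def bl(key: str) -> float:
        return float(L.get(key, 0.2))

    root = TreeNode(None, 0.0, BACKGROUND, [
        TreeNode("BC", bl("BC"), BACKGROUND, [
            TreeNode("B", bl("B")),
            TreeNode("C", bl("C")),
        ]),
        TreeNode("D", bl("D")),
        TreeNode("A", bl("A")),
    ])
    # internal node name is a traversal aid only, not a leaf
    root.children[0].name = None
    tree = LabeledTree(root)
    if foreground is not None:
        tree = tree.set_foreground_leaf(foreground)
    return tree


def simulate_codon_alignment(
    tree: LabeledTree,
    params: CodonModelParams,
    n_codons: int,
    seed: int = 0,
    mode: str = "transition",
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve codon sites down *tree* under the branch-class GY94 model.

    ``transition`` mode (default) samples each child state directly from the
    row of the branch's transition matrix exp(Qt) — exact and fast.
    ``gillespie`` mode simulates the jump chain explicitly and records the
    realized synonymous/nonsynonymous substitution counts per branch in the
    returned truth; the marginal alignment distribution is identical.
    Stop codons are never emitted (the chain lives on the 61 sense codons).
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    pi = params.pi
    if pi.shape != (N_CODONS,):
        raise ValueError("params.pi must cover exactly the 61 sense codons")
    rng = np.random.default_rng(seed)
    root_states = rng.choice(N_CODONS, size=n_codons, p=pi)

    branches = tree.branches()
    branch_index = {id(n): i for i, n in enumerate(branches)}
    Q_by_class = {c: build_rate_matrix(params, c) for c in params.omega_by_class}
    decomp_by_class = {c: _SpectralQ(Q, pi) for c, Q in Q_by_class.items()}
    realized: dict[int, tuple[int, int]] = {}

    def evolve_exact(states: np.ndarray, node: TreeNode) -> np.ndarray:
        cls = node.label if node.label in params.omega_by_class else BACKGROUND
        P = decomp_by_class[cls].expm(node.length)
        # normalise rows (clipping can shave a hair off the sum)
        P = P / P.sum(axis=1, keepdims=True)
        child = np.empty_like(states)
        for s in np.unique(states):
            idx = np.nonzero(states == s)[0]
            child[idx] = rng.choice(N_CODONS, size=idx.size, p=P[s])
        return child

    def evolve_gillespie(states: np.ndarray, node: TreeNode) -> np.ndarray:
        cls = node.label if node.label in params.omega_by_class else BACKGROUND
        Q = Q_by_class[cls]
        rates = -np.diag(Q)
        jump = Q.copy()
        np.fill_diagonal(jump, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            jump = jump / jump.sum(axis=1, keepdims=True)
        n_syn = n_non = 0
        child = states.copy()
        for k in range(child.size):
            t_left = node.length
            s = int(child[k])
            while True:
                rate = rates[s]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait > t_left:
                    break
                t_left -= wait
                s_new = int(rng.choice(N_CODONS, p=jump[s]))
                if _IS_NONSYN[s, s_new]:
                    n_non += 1
                else:
                    n_syn += 1
                s = s_new
            child[k] = s
        realized[branch_index[id(node)]] = (n_syn, n_non)
        return child

    evolve = evolve_exact if mode == "transition" else evolve_gillespie
    if mode not in ("transition", "gillespie"):
        raise ValueError(f"unknown mode {mode!r}")

    rows: dict[str, np.ndarray] = {}

    def descend(states: np.ndarray, node: TreeNode) -> None:
        for child in node.children:
            child_states = evolve(states, child)
            if child.is_leaf:
                rows[child.name] = child_states
            else:
                descend(child_states, child)

    descend(root_states, tree.root)
    taxa = tree.leaf_names()
    aln = CodonAlignment(taxa, np.stack([rows[t] for t in taxa]))
    truth = SimulationTruth(
        true_params=params,
        tree=tree,
        seed=seed,
        realized_substitutions=realized if mode == "gillespie" else None,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Marker read simulation
# ---------------------------------------------------------------------------

@dataclass
class CommunityTruth:
    true_proportion_D: float
    reads_per_locus: dict[str, int]
    error_rate: float = 0.0
    duplicate_fraction: float = 0.0
    # filled by the simulator: read_id -> (locus, clade); planted duplicate ids
    origins: dict[str, tuple[str, str]] = field(default_factory=dict)
    planted_duplicates: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_proportion_D <= 1.0:
            raise ValueError("true_proportion_D must be in [0, 1]")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1]")
        if any(n < 0 for n in self.reads_per_locus.values()):
            raise ValueError("read counts must be >= 0")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_changes: int) -> str:
    """Apply exactly n_changes substitutions at distinct positions."""
    chars = list(seq)
    pos = rng.choice(len(chars), size=min(n_changes, len(chars)), replace=False)
    for p in pos:
        choices = [b for b in _BASES if b != chars[p]]
        chars[p] = choices[rng.integers(3)]
    return "".join(chars)


def synthetic_marker_references(seed: int = 1213) -> list[MarkerReference]:
    """Six synthetic marker references (3 loci x 2 clades), ~15% diverged.

    Lengths differ between clades at every locus so that the estimator's
    length normalisation is genuinely exercised.  Synthetic stand-ins for the
    clade-diagnostic ITS1/ITS2/cp23S sequences; not biological sequences.
    """
    rng = np.random.default_rng(seed)
    layout = {"ITS1": (320, 341), "ITS2": (362, 330), "cp23S": (702, 678)}
    refs: list[MarkerReference] = []
    for locus, (len_c, len_d) in layout.items():
        base_len = max(len_c, len_d)
        ancestral = _random_sequence(rng, base_len)
        seq_c = _mutate(rng, ancestral[:len_c], int(round(0.075 * len_c)))
        seq_d = _mutate(rng, ancestral[:len_d], int(round(0.075 * len_d)))
        refs.append(MarkerReference(locus=locus, clade="C", sequence=seq_c))
        refs.append(MarkerReference(locus=locus, clade="D", sequence=seq_d))
    return refs


_RC = str.maketrans("ACGTN", "TGCAN")


def simulate_marker_reads(
    references: Sequence[MarkerReference],
    truth: CommunityTruth,
    read_length: int = 36,
    seed: int = 0,
) -> tuple[list[SequenceRecord], CommunityTruth]:
    """Draw clade-mixture reads from the six marker references.

    For each locus, a read's clade is Bernoulli with success probability
    proportional to ``true_proportion_D * len_D`` against
    ``(1 - p) * len_C`` — longer references emit proportionally more reads,
    which is exactly the bias the estimator's length normalisation removes.
    Start positions are uniform; per-base substitution errors are applied at
    ``truth.error_rate``; a ``duplicate_fraction`` share of the reads are
    emitted as exact copies of previously emitted reads (same start, same
    sequence), emulating PCR duplicates.
    """
    by_locus: dict[str, dict[str, MarkerReference]] = {}
    for ref in references:
        by_locus.setdefault(ref.locus, {})[ref.clade] = ref
    for locus, pair in by_locus.items():
        if set(pair) != {"C", "D"}:
            raise ValueError(f"locus {locus}: need exactly one reference per clade")
        for ref in pair.values():
            if read_length > len(ref.sequence):
                raise ValueError(
                    f"read_length {read_length} exceeds reference {locus}|{ref.clade}"
                )

    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    p = truth.true_proportion_D
    counter = 0
    for locus in sorted(by_locus):
        n_total = truth.reads_per_locus.get(locus, 0)
        if n_total == 0:
            continue
        n_dup = int(round(truth.duplicate_fraction * n_total))
        n_fresh = n_total - n_dup
        ref_c, ref_d = by_locus[locus]["C"], by_locus[locus]["D"]
        w_d = p * len(ref_d.sequence)
        w_c = (1.0 - p) * len(ref_c.sequence)
        prob_d = w_d / (w_d + w_c) if (w_d + w_c) > 0 else 0.0
        fresh: list[SequenceRecord] = []
        for _ in range(n_fresh):
            clade = "D" if rng.random() < prob_d else "C"
            ref = ref_d if clade == "D" else ref_c
            start = int(rng.integers(0, len(ref.sequence) - read_length + 1))
            seq = ref.sequence[start : start + read_length]
            if truth.error_rate > 0:
                chars = list(seq)
                errs = np.nonzero(rng.random(read_length) < truth.error_rate)[0]
                for e in errs:
                    choices = [b for b in _BASES if b != chars[e]]
                    chars[e] = choices[rng.integers(3)]
                seq = "".join(chars)
            counter += 1
            rid = f"read_{counter:06d}"
            fresh.append(SequenceRecord(rid, seq))
            truth.origins[rid] = (locus, clade)
        reads.extend(fresh)
        if n_dup and fresh:
            originals = rng.choice(len(fresh), size=n_dup, replace=True)
            for k in originals:
                counter += 1
                rid = f"read_{counter:06d}"
                reads.append(SequenceRecord(rid, fresh[k].residues))
                truth.origins[rid] = truth.origins[fresh[k].id]
                truth.planted_duplicates.add(rid)
    return reads, truth


# ---------------------------------------------------------------------------
# Ortholog universe
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

TAXA = ("A", "B", "C", "D")


@dataclass
class OrthologUniverse:
    proteomes: dict[str, list[SequenceRecord]]
    # (taxon_pair like ("C","D")) -> {query_id: {subject_id: score}}
    score_tables: dict[tuple[str, str], dict[str, dict[str, float]]]
    # gene index -> expected group label in {"ABCD","BCD","CD",None}
    expected_groups: dict[int, Optional[str]]
    # gene index -> member id per taxon present
    members: dict[int, dict[str, str]]


def make_ortholog_universe(
    n_genes: int,
    divergence_per_clade: float = 0.1,
    paralog_fraction: float = 0.0,
    seed: int = 0,
    missing_taxa: Optional[dict[int, set[str]]] = None,
) -> OrthologUniverse:
    """Planted ortholog sets across taxa A-D with similarity score tables.

    Each gene has an ancestral protein; every taxon carries a lineage-mutated
    copy unless listed in ``missing_taxa``.  Similarity scores are hamming
    matches, so scores decay with mutation distance.  A ``paralog_fraction``
    share of genes receive an exact within-taxon duplicate in clade C, which
    creates score ties and must exclude the gene from reciprocal-best-hit
    pairing (expected group None).  Expected memberships follow the group
    rules: everything present -> ABCD, A missing -> BCD, A and B missing ->
    CD, C or D missing -> no group.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= paralog_fraction <= 1.0 or not 0.0 <= divergence_per_clade <= 1.0:
        raise ValueError("fractions must be in [0, 1]")
    missing_taxa = missing_taxa or {}
    rng = np.random.default_rng(seed)
    lengths = rng.integers(120, 260, size=n_genes)
    ancestors = ["".join(rng.choice(list(_AA20), size=int(L))) for L in lengths]

    def mutate_protein(seq: str) -> str:
        n = int(round(divergence_per_clade * len(seq)))
        chars = list(seq)
        pos = rng.choice(len(chars), size=min(n, len(chars)), replace=False)
        for pnt in pos:
            choices = [a for a in _AA20 if a != chars[pnt]]
            chars[pnt] = choices[rng.integers(len(choices))]
        return "".join(chars)

    n_paralog = int(round(paralog_fraction * n_genes))
    paralog_genes = set(rng.choice(n_genes, size=n_paralog, replace=False).tolist())

    proteomes: dict[str, list[SequenceRecord]] = {t: [] for t in TAXA}
    members: dict[int, dict[str, str]] = {}
    expected: dict[int, Optional[str]] = {}
    for g in range(n_genes):
        absent = missing_taxa.get(g, set())
        members[g] = {}
        for taxon in TAXA:
            if taxon in absent:
                continue
            sid = f"{taxon.lower()}_gene_{g}"
            proteomes[taxon].append(
                SequenceRecord(sid, mutate_protein(ancestors[g]), moltype="protein")
            )
            members[g][taxon] = sid
        if g in paralog_genes and "C" in members[g]:
            # exact duplicate -> tied best hits -> gene excluded by RBH
            src = next(r for r in proteomes["C"] if r.id == members[g]["C"])
            proteomes["C"].append(
                SequenceRecord(f"c_gene_{g}_dup", src.residues, moltype="protein")
            )
        present = set(members[g])
        if not {"C", "D"} <= present:
            expected[g] = None
        elif g in paralog_genes:
            expected[g] = None
        elif present == {"A", "B", "C", "D"}:
            expected[g] = "ABCD"
        elif {"B", "C", "D"} <= present:
            expected[g] = "BCD"
        else:
            expected[g] = "CD"

    def score(a: str, b: str) -> float:
        n = min(len(a), len(b))
        return float(sum(x == y for x, y in zip(a[:n], b[:n])))

    pairs = [("C", "D"), ("C", "B"), ("D", "B"), ("C", "A"), ("D", "A")]
    tables: dict[tuple[str, str], dict[str, dict[str, float]]] = {}
    for ta, tb in pairs:
        fwd: dict[str, dict[str, float]] = {}
        for ra in proteomes[ta]:
            fwd[ra.id] = {rb.id: score(ra.residues, rb.residues) for rb in proteomes[tb]}
        tables[(ta, tb)] = fwd
        tables[(tb, ta)] = {
            rb.id: {ra.id: fwd[ra.id][rb.id] for ra in proteomes[ta]}
            for rb in proteomes[tb]
        }
    return OrthologUniverse(proteomes, tables, expected, members)


# ---------------------------------------------------------------------------
# Joinable contigs
# ---------------------------------------------------------------------------

@dataclass
class FragmentSpec:
    """One contig drawn from ``reference[start..end]`` (1-based closed).

    ``overlap_mismatches`` substitutions are planted inside the first
    ``perturb_window`` bases of the fragment (the region that overlaps its
    left neighbour in tiling layouts), degrading overlap identity.
    """

    start: int
    end: int
    overlap_mismatches: int = 0
    perturb_window: int = 0


@dataclass
class ContigFixture:
    contigs: list[SequenceRecord]
    hits: list[HitRecord]
    expected_joins: list[set[str]]  # member-id sets expected to merge


def make_joinable_contigs(
    reference: SequenceRecord,
    fragment_layout: Sequence[FragmentSpec],
    seed: int = 0,
    min_overlap_identity: float = 0.95,
) -> ContigFixture:
    """Contigs cut from a reference plus the hit table and expected joins.

    Expected joins follow the three joining rules: same top reference,
    overlapping or directly adjacent reference intervals, and >= 95% identity
    in any overlap region.
    """
    rng = np.random.default_rng(seed)
    ref = reference.residues
    contigs: list[SequenceRecord] = []
    hits: list[HitRecord] = []
    frag_seqs: list[str] = []
    for k, frag in enumerate(fragment_layout):
        if not (1 <= frag.start <= frag.end <= len(ref)):
            raise ValueError(f"fragment {k}: interval outside reference")
        seq = ref[frag.start - 1 : frag.end]
        if frag.overlap_mismatches:
            window = frag.perturb_window or len(seq)
            seq = (
                _mutate(rng, seq[:window], frag.overlap_mismatches) + seq[window:]
            )
        cid = f"contig_{k}"
        frag_seqs.append(seq)
        contigs.append(SequenceRecord(cid, seq))
        n_mismatch = sum(a != b for a, b in zip(seq, ref[frag.start - 1 : frag.end]))
        identity = 1.0 - n_mismatch / len(seq)
        hits.append(
            HitRecord(
                query_id=cid,
                subject_id=reference.id,
                percent_identity=identity,
                alignment_length=len(seq),
                query_interval=(1, len(seq)),
                subject_interval=(frag.start, frag.end),
                score=float(len(seq)),
            )
        )

    # expected joins: left-to-right transitive merging per the three rules
    order = sorted(range(len(fragment_layout)), key=lambda k: fragment_layout[k].start)
    expected: list[set[str]] = []
    current = [order[0]] if order else []
    for k in order[1:]:
        prev = current[-1]
        fp, fk = fragment_layout[prev], fragment_layout[k]
        gap = fk.start - max(fragment_layout[m].end for m in current) - 1
        joinable = gap <= 0
        if joinable and gap < 0:
            ov = -gap
            left_tail = frag_seqs[prev][len(frag_seqs[prev]) - ov :]
            right_head = frag_seqs[k][:ov]
            ident = sum(a == b for a, b in zip(left_tail, right_head)) / ov
            joinable = ident >= min_overlap_identity
        if joinable:
            current.append(k)
        else:
            if len(current) > 1:
                expected.append({f"contig_{m}" for m in current})
            current = [k]
    if len(current) > 1:
        expected.append({f"contig_{m}" for m in current})
    return ContigFixture(contigs, hits, expected)
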