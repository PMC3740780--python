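"""From per-taxon transcript sets to filtered codon alignments and divergence.

Stages, in pipeline order: 6-frame ORF calling with the homology-or-length
retention rule; global protein alignment (affine-gap Needleman-Wunsch with
BLOSUM62, progressive profile merging in fixed taxon order D, C, B, A);
reciprocal-best-hit ortholog pairing with paralog-safe tie discard; CD/BCD/
ABCD group assembly; codon threading with gap and in-frame-stop column
removal; the tree-length filter cascade (<= 2 x n_taxa substitutions per
codon, falling back 4 -> 3 -> 2 taxa); raw and Kimura 2-parameter pairwise
divergences; and substitution-rate extrapolation from divergence times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .codon_model import CodonAlignment, STOP_CODONS
from .io_formats import SequenceRecord, logger

_CODE = CodonTable.unambiguous_dna_by_id[1]

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

@dataclass
class OrfCall:
    contig_id: str
    frame: int  # {-3..-1, +1..+3}
    protein: str
    cds: str
    has_homology: bool

    def __post_init__(self) -> None:
        if len(self.cds) != 3 * len(self.protein):
            raise ValueError("cds length must be 3 x protein length")
        if "*" in self.protein:
            raise ValueError("internal stop in ORF protein")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def call_orfs(
    contig: SequenceRecord, min_aa: int = 200, homology: bool = False
) -> list[OrfCall]:
    """Longest open reading frame across all 6 frames of a contig.

    An ORF is the longest stop-free codon run in a frame; transcript
    fragments rarely carry a start codon, so ATG is not required.  The call
    is retained only under the two retention categories: demonstrated
    homology to a known protein, or predicted protein >= ``min_aa`` residues.
    Returns a list with zero or one call.
    """
    seq = contig.residues
    if len(seq) < 3:
        raise ValueError(f"contig {contig.id!r} shorter than one codon")
    best: Optional[tuple[int, int, int, str]] = None  # (length_aa, frame, start, strand_seq)
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for off in range(3):
            frame = (off + 1) if strand == "+" else -(off + 1)
            codons = [s[k : k + 3] for k in range(off, len(s) - 2, 3)]
            run_start = 0
            k = 0
            n = len(codons)
            while k <= n:
                if k == n or codons[k] in STOP_CODONS or "N" in codons[k] or any(
                    b not in "ACGT" for b in codons[k]
                ):
                    run_len = k - run_start
                    if run_len > 0 and (best is None or run_len > best[0]):
                        cds = "".join(codons[run_start:k])
                        best = (run_len, frame, off + 3 * run_start, cds)
                    run_start = k + 1
                k += 1
    if best is None:
        return []
    run_len, frame, _, cds = best
    protein = str(Seq(cds).translate())
    if not (homology or len(protein) >= min_aa):
        return []
    return [OrfCall(contig.id, frame, protein, cds, homology)]


# ---------------------------------------------------------------------------
# Protein alignment (affine-gap NW over profiles)
# ---------------------------------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 11.0
GAP_EXTEND = 1.0
GAP = "-"


def _column_score(col_a: Sequence[str], col_b: Sequence[str]) -> float:
    """Mean BLOSUM62 score over residue pairs, ignoring gap characters."""
    total = 0.0
    n = 0
    for a in col_a:
        if a == GAP:
            continue
        for b in col_b:
            if b == GAP:
                continue
            total += _BLOSUM62[a, b]
            n += 1
    return total / n if n else 0.0


def _align_profiles(
    prof_a: list[str], prof_b: list[str]
) -> tuple[list[str], list[str]]:
    """Global affine-gap alignment of two profiles (lists of aligned rows).

    Three-state DP; a gap of length k costs GAP_OPEN + k * GAP_EXTEND.
    Traceback tie-break is deterministic: match > gap-in-B (consume A) >
    gap-in-A.  Returns both profiles padded to a common length.
    """
    cols_a = list(zip(*prof_a)) if prof_a[0] else []
    cols_b = list(zip(*prof_b)) if prof_b[0] else []
    la, lb = len(cols_a), len(cols_b)
    neg = -math.inf
    # state 0 = M (col vs col), 1 = Ix (gap in B), 2 = Iy (gap in A)
    M = np.full((la + 1, lb + 1), neg)
    Ix = np.full((la + 1, lb + 1), neg)
    Iy = np.full((la + 1, lb + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -(GAP_OPEN + i * GAP_EXTEND)
    for j in range(1, lb + 1):
        Iy[0, j] = -(GAP_OPEN + j * GAP_EXTEND)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _column_score(cols_a[i - 1], cols_b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(
                M[i - 1, j] - GAP_OPEN - GAP_EXTEND,
                Ix[i - 1, j] - GAP_EXTEND,
                Iy[i - 1, j] - GAP_OPEN - GAP_EXTEND,
            )
            Iy[i, j] = max(
                M[i, j - 1] - GAP_OPEN - GAP_EXTEND,
                Iy[i, j - 1] - GAP_EXTEND,
                Ix[i, j - 1] - GAP_OPEN - GAP_EXTEND,
            )
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    gap_a_row = GAP * len(prof_a)
    gap_b_row = GAP * len(prof_b)
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append("".join(cols_a[i - 1]))
            out_b.append("".join(cols_b[j - 1]))
            s = _column_score(cols_a[i - 1], cols_b[j - 1])
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            state = int(np.argmax(np.isclose(prev, M[i, j] - s)))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            out_a.append("".join(cols_a[i - 1]))
            out_b.append(gap_b_row)
            candidates = [
                M[i - 1, j] - GAP_OPEN - GAP_EXTEND,
                Ix[i - 1, j] - GAP_EXTEND,
                Iy[i - 1, j] - GAP_OPEN - GAP_EXTEND,
            ]
            state = int(np.argmax(np.isclose(candidates, Ix[i, j])))
            i -= 1
        elif state == 2 and j > 0:
            out_a.append(gap_a_row)
            out_b.append("".join(cols_b[j - 1]))
            candidates = [
                M[i, j - 1] - GAP_OPEN - GAP_EXTEND,
                Iy[i, j - 1] - GAP_EXTEND,
                Ix[i, j - 1] - GAP_OPEN - GAP_EXTEND,
            ]
            # candidate order maps to states (0, 2, 1)
            k = int(np.argmax(np.isclose(candidates, Iy[i, j])))
            state = (0, 2, 1)[k]
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[r] for col in out_a) for r in range(len(prof_a))]
    new_b = ["".join(col[r] for col in out_b) for r in range(len(prof_b))]
    return new_a, new_b


def align_proteins(p1: str, p2: str) -> tuple[str, str]:
    """Global pairwise protein alignment (BLOSUM62, affine gaps 11/1)."""
    if not p1 and not p2:
        return "", ""
    if not p1:
        return GAP * len(p2), p2
    if not p2:
        return p1, GAP * len(p1)
    a, b = _align_profiles([p1], [p2])
    return a[0], b[0]


PROGRESSIVE_ORDER = ("D", "C", "B", "A")


def align_protein_set(proteins: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment in the fixed taxon order D, C, B, A.

    Each taxon's sequence is aligned to the growing profile with the same
    affine-gap DP used pairwise — a documented simplification of a full
    guide-tree progressive aligner.
    """
    order = [t for t in PROGRESSIVE_ORDER if t in proteins]
    extra = [t for t in proteins if t not in order]
    order += sorted(extra)
    if not order:
        return {}
    if len(order) == 1:
        return {order[0]: proteins[order[0]]}
    profile = [proteins[order[0]]]
    for taxon in order[1:]:
        profile, new = _align_profiles(profile, [proteins[taxon]])
        profile = profile + new
    return {taxon: row for taxon, row in zip(order, profile)}


# ---------------------------------------------------------------------------
# Reciprocal best hits and ortholog groups
# ---------------------------------------------------------------------------

def _unique_best(scores: dict[str, float]) -> Optional[str]:
    if not scores:
        return None
    best_score = max(scores.values())
    winners = [s for s, v in scores.items() if v == best_score]
    return winners[0] if len(winners) == 1 else None


def reciprocal_best_hits(
    scores_ab: dict[str, dict[str, float]],
    scores_ba: dict[str, dict[str, float]],
) -> list[tuple[str, str]]:
    """Ortholog pairs (a, b) where each is the other's unique best hit.

    A tie for best hit (typically a recent paralog) discards the gene rather
    than guessing — comparison of non-orthologous sequences is worse than a
    smaller ortholog set.
    """
    pairs = []
    for a in sorted(scores_ab):
        b = _unique_best(scores_ab[a])
        if b is None:
            continue
        back = _unique_best(scores_ba.get(b, {}))
        if back == a:
            pairs.append((a, b))
    return pairs


@dataclass
class OrthologGroup:
    id: str
    members: dict[str, str]  # taxon -> sequence id

    def __post_init__(self) -> None:
        if not {"C", "D"} <= set(self.members):
            raise ValueError("every group contains C and D")
        if self.size == 3 and "B" not in self.members:
            raise ValueError("3-taxa groups are BCD")
        if self.size == 4 and set(self.members) != {"A", "B", "C", "D"}:
            raise ValueError("4-taxa groups are ABCD")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def label(self) -> str:
        return "".join(sorted(self.members))


def build_groups(
    pairs_CD: Sequence[tuple[str, str]],
    pairs_CB: Sequence[tuple[str, str]],
    pairs_DB: Sequence[tuple[str, str]],
    pairs_CA: Sequence[tuple[str, str]],
    pairs_DA: Sequence[tuple[str, str]],
) -> list[OrthologGroup]:
    """Assemble CD / BCD / ABCD groups from pairwise ortholog pairs.

    A CD pair grows to BCD when both members share the same best clade-B
    ortholog, and to ABCD when they additionally share the same clade-A
    ortholog (only BCD groups can grow to ABCD).  A B or A sequence claimed
    by an earlier group causes the later group to fall back (with a warning)
    so that every sequence appears in at most one group.
    """
    c_to_b = dict(pairs_CB)
    d_to_b = dict(pairs_DB)
    c_to_a = dict(pairs_CA)
    d_to_a = dict(pairs_DA)
    used_b: set[str] = set()
    used_a: set[str] = set()
    groups: list[OrthologGroup] = []
    for k, (c, d) in enumerate(sorted(pairs_CD)):
        members = {"C": c, "D": d}
        b = c_to_b.get(c)
        if b is not None and b == d_to_b.get(d):
            if b in used_b:
                logger.warning("clade B sequence %s already grouped; %s/%s stays CD", b, c, d)
            else:
                members["B"] = b
                used_b.add(b)
        if "B" in members:
            a = c_to_a.get(c)
            if a is not None and a == d_to_a.get(d):
                if a in used_a:
                    logger.warning("clade A sequence %s already grouped; group stays BCD", a)
                else:
                    members["A"] = a
                    used_a.add(a)
        groups.append(OrthologGroup(id=f"og_{k}", members=members))
    return groups


# ---------------------------------------------------------------------------
# Codon threading
# ---------------------------------------------------------------------------

def thread_codons(
    protein_alignment: dict[str, str], cds_by_taxon: dict[str, str]
) -> CodonAlignment:
    """Back-translate a protein alignment onto its CDS (codon alignment).

    Each aligned residue is replaced by its codon; columns containing any gap
    are removed, as are codon columns where any taxon carries an in-frame
    stop.  Each protein must translate its CDS exactly.
    """
    taxa = list(protein_alignment)
    lengths = {len(v) for v in protein_alignment.values()}
    if len(lengths) != 1:
        raise ValueError("protein alignment rows differ in length")
    codon_rows: dict[str, list[str]] = {}
    for taxon in taxa:
        aligned = protein_alignment[taxon]
        cds = cds_by_taxon[taxon].upper()
        ungapped = aligned.replace(GAP, "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"taxon {taxon!r}: CDS length {len(cds)} != 3 x protein length {len(ungapped)}"
            )
        codons = [cds[k : k + 3] for k in range(0, len(cds), 3)]
        for pos, (aa, codon) in enumerate(zip(ungapped, codons), 1):
            translated = _CODE.forward_table.get(codon, "*" if codon in STOP_CODONS else "X")
            if translated != aa:
                raise ValueError(
                    f"taxon {taxon!r}: codon {codon} at residue {pos} translates to "
                    f"{translated!r}, protein says {aa!r}"
                )
        row = []
        k = 0
        for aa in aligned:
            if aa == GAP:
                row.append(None)
            else:
                row.append(codons[k])
                k += 1
        codon_rows[taxon] = row

    (n_cols,) = lengths
    kept: dict[str, list[str]] = {t: [] for t in taxa}
    for col in range(n_cols):
        column = [codon_rows[t][col] for t in taxa]
        if any(c is None for c in column):
            continue
        if any(c in STOP_CODONS for c in column):
            continue
        for t, c in zip(taxa, column):
            kept[t].append(c)
    return CodonAlignment.from_sequences({t: "".join(kept[t]) for t in taxa})


# ---------------------------------------------------------------------------
# Tree-length cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    group_id: str
    n_taxa_used: int  # 0 when excluded
    tree_length: float
    decision: str  # {analyzed_4, analyzed_3, analyzed_2, excluded}


def tree_length_cascade(
    group: OrthologGroup,
    alignments: dict[int, CodonAlignment],
    fitter: Callable[[CodonAlignment], float],
    per_taxon_cutoff: float = 2.0,
) -> CascadeResult:
    """Apply the maximum-tree-length filter, dropping taxa A then B.

    The cutoff is ``per_taxon_cutoff`` x n_taxa substitutions per codon
    (8 for 4 taxa, 6 for 3, 4 for 2).  A group failing at one level is
    retried at the next smaller taxon set for which an alignment exists;
    failing the 2-taxa bound excludes it.
    """
    last_tl = math.nan
    for n_taxa in range(group.size, 1, -1):
        aln = alignments.get(n_taxa)
        if aln is None:
            continue
        tl = fitter(aln)
        last_tl = tl
        if tl <= per_taxon_cutoff * n_taxa:
            return CascadeResult(group.id, n_taxa, tl, f"analyzed_{n_taxa}")
    return CascadeResult(group.id, 0, last_tl, "excluded")


# ---------------------------------------------------------------------------
# Divergence statistics
# ---------------------------------------------------------------------------

@dataclass
class DivergenceResult:
    pair: tuple[str, str]
    compared_positions: int
    raw_p: float
    transitions_P: float
    transversions_Q: float
    k2p: Optional[float]  # None when the K2P log argument is nonpositive
    saturated: bool = False


_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def pairwise_divergence(seq1: str, seq2: str, pair: tuple[str, str] = ("x", "y")) -> DivergenceResult:
    """Raw and Kimura 2-parameter distance between two aligned rows.

    Positions where either sequence carries anything but A/C/G/T (ambiguity
    codes, N, gaps) are excluded from all counts.  K2P distance is
    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P the transition and Q the
    transversion fraction; saturation (nonpositive log argument) is flagged.
    """
    if len(seq1) != len(seq2):
        raise ValueError("rows differ in length")
    s1, s2 = seq1.upper(), seq2.upper()
    n = ts = tv = 0
    for a, b in zip(s1, s2):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if (a, b) in _TRANSITION_PAIRS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("zero comparable positions")
    P, Q = ts / n, tv / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return DivergenceResult(pair, n, P + Q, P, Q, None, saturated=True)
    k2p = -0.5 * math.log(arg1 * math.sqrt(arg2))
    return DivergenceResult(pair, n, P + Q, P, Q, k2p)


@dataclass
class RateEstimate:
    per_year: float
    divergence_time_My: float
    generation_days: float
    per_generation_correct: float
    per_generation_reported_convention: float


def substitution_rate(divergence: float, T_My: float, g_days: float) -> RateEstimate:
    """Substitution rate from pairwise divergence and a divergence time.

    ``per_year = divergence / (2 T)`` with T in years (each lineage
    accumulates half the pairwise divergence).  Two per-generation
    conversions are reported side by side: the dimensionally correct
    ``per_year * g / 365.25`` and the convention ``per_year * 365.25 / g``
    (rate per year times generations per year), which is the convention that
    published per-generation figures for these divergences follow.
    """
    if T_My <= 0 or g_days <= 0:
        raise ValueError("divergence time and generation time must be positive")
    if divergence < 0:
        raise ValueError("divergence must be nonnegative")
    per_year = divergence / (2.0 * T_My * 1e6)
    return RateEstimate(
        per_year=per_year,
        divergence_time_My=T_My,
        generation_days=g_days,
        per_generation_correct=per_year * g_days / DAYS_PER_YEAR,
        per_generation_reported_convention=per_year * DAYS_PER_YEAR / g_days,
    )
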