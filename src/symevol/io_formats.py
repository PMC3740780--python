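"""Readers and writers for the formats the pipeline touches, plus shared plumbing.

Sequence collections are plain lists of :class:`SequenceRecord`; similarity
tables are lists of :class:`HitRecord` (BLAST outfmt-6 dialect, 1-based closed
intervals); trees are :class:`LabeledTree` with a foreground/background class
per branch, expressed in newick with codeml-style ``#1`` tags.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import dendropy
from Bio import SeqIO

logger = logging.getLogger("symevol")

_NUC = set("ACGTUNRYSWKMBDHV")
_AA = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


def configure_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    logging.basicConfig(format="%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))


def log_stage(stage: str, n_in: int, n_out: int, threshold: str = "") -> None:
    """Log input/output counts for a pipeline stage and the threshold applied."""
    extra = f" [{threshold}]" if threshold else ""
    logger.info("%s: %d in, %d kept, %d filtered%s", stage, n_in, n_out, n_in - n_out, extra)


# ---------------------------------------------------------------------------
# Sequence records and FASTA/FASTQ
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named sequence, nucleotide or protein."""

    id: str
    residues: str
    moltype: str = "nucleotide"  # {nucleotide, protein}

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        self.residues = self.residues.upper()
        alphabet = _NUC if self.moltype == "nucleotide" else _AA
        bad = set(self.residues) - alphabet
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues {sorted(bad)} invalid for moltype {self.moltype}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class ParseError(ValueError):
    """Raised for malformed input files; message carries file/line context."""


def _check_unique_ids(records: list[SequenceRecord], path: str) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path, moltype: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (order preserved, residues uppercased)."""
    path = Path(path)
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ParseError(f"{path}: record {i + 1} has an empty header")
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq), moltype))
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    _check_unique_ids(records, str(path))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTQ file, discarding qualities (the classifier is quality-blind)."""
    path = Path(path)
    records = [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]
    _check_unique_ids(records, str(path))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTQ with uniform placeholder qualities."""
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{'I' * len(rec.residues)}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

@dataclass
class HitRecord:
    """One row of a BLAST outfmt-6-like table.

    Intervals are 1-based closed (BLAST convention); ``percent_identity`` is
    stored as a fraction in [0, 1] even though files carry the 0-100 scale.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 1.0:
            raise ValueError(f"percent identity {self.percent_identity} outside [0, 1]")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")
        for name, (s, e) in (("query", self.query_interval), ("subject", self.subject_interval)):
            if s > e:
                raise ValueError(f"{name} interval start {s} > end {e}")
        if self.score < 0:
            raise ValueError("score must be nonnegative")


def read_hits_table(path: str | Path) -> list[HitRecord]:
    """Read a 12-column outfmt-6 TSV into HitRecords, preserving row order.

    Subject intervals with start > end (minus-strand hits) are normalised to
    start <= end; orientation is recoverable downstream from the raw columns,
    so the joiner receives orientation explicitly where it matters.
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                pident = float(cols[2])
                if not 0.0 <= pident <= 100.0:
                    raise ValueError(f"percent identity {pident} outside [0, 100]")
                qs, qe, ss, se = (int(c) for c in cols[6:10])
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=pident / 100.0,
                        alignment_length=int(cols[3]),
                        query_interval=(min(qs, qe), max(qs, qe)),
                        subject_interval=(min(ss, se), max(ss, se)),
                        score=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            qs, qe = h.query_interval
            ss, se = h.subject_interval
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity * 100:.2f}\t"
                f"{h.alignment_length}\t0\t0\t{qs}\t{qe}\t{ss}\t{se}\t0.0\t{h.score:g}\n"
            )


def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO annotation TSV (one ``gene<TAB>GO:ID`` pair per row)."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            mapping.setdefault(cols[0], set()).add(cols[1])
    return mapping


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

FOREGROUND = "foreground"
BACKGROUND = "background"

DEFAULT_BRANCH_LENGTH = 0.1


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: float = DEFAULT_BRANCH_LENGTH  # length of the branch above this node
    label: str = BACKGROUND  # class of the branch above this node
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self


@dataclass
class LabeledTree:
    """Rooted representation of a (possibly unrooted) tree.

    Every non-root node carries the length and foreground/background class of
    the branch above it.  The likelihood machinery is root-invariant for
    reversible models, so the rooted representation is only a traversal aid.
    """

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[TreeNode]:
        """All nodes that sit below a branch (everything except the root)."""
        return [n for n in self.root.postorder() if n is not self.root]

    def n_branches(self) -> int:
        return len(self.branches())

    def set_foreground_leaf(self, leaf_name: str) -> "LabeledTree":
        """Return a copy with exactly the terminal branch of *leaf_name* tagged foreground."""
        tree = self.copy()
        found = False
        for node in tree.root.postorder():
            node.label = BACKGROUND
        for node in tree.leaves():
            if node.name == leaf_name:
                node.label = FOREGROUND
                found = True
        if not found:
            raise ValueError(f"leaf {leaf_name!r} not in tree {tree.leaf_names()}")
        return tree

    def clear_labels(self) -> "LabeledTree":
        tree = self.copy()
        for node in tree.root.postorder():
            node.label = BACKGROUND
        return tree

    def copy(self) -> "LabeledTree":
        def _copy(node: TreeNode) -> TreeNode:
            return TreeNode(node.name, node.length, node.label, [_copy(c) for c in node.children])

        return LabeledTree(_copy(self.root))

    def restrict(self, keep: set[str]) -> "LabeledTree":
        """Prune to the given leaf set, suppressing unifurcations (lengths add)."""

        def _restrict(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                return TreeNode(node.name, node.length, node.label) if node.name in keep else None
            kids = [k for k in (_restrict(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                child.length += node.length
                return child
            return TreeNode(node.name, node.length, node.label, kids)

        root = _restrict(self.root)
        if root is None or len([n for n in root.postorder() if n.is_leaf]) < 2:
            raise ValueError(f"restriction to {sorted(keep)} leaves fewer than 2 taxa")
        root.length = 0.0
        return LabeledTree(root)


def parse_newick(text: str) -> LabeledTree:
    """Parse newick text with optional branch lengths and ``#1`` foreground tags.

    Branches without a length default to 0.1.  A ``#1`` suffix on a leaf or
    internal node label (codeml convention) marks the branch above that node
    as foreground; all other branches are background.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed newick: {exc}") from exc

    def _convert(dnode) -> TreeNode:
        raw = dnode.taxon.label if dnode.taxon is not None else (dnode.label or None)
        label = BACKGROUND
        name = raw
        if raw is not None and raw.endswith("#1"):
            label = FOREGROUND
            name = raw[:-2].strip() or None
        length = dnode.edge.length if dnode.edge.length is not None else DEFAULT_BRANCH_LENGTH
        node = TreeNode(name=name, length=float(length), label=label)
        node.children = [_convert(c) for c in dnode.child_nodes()]
        return node

    root = _convert(dtree.seed_node)
    root.length = 0.0
    tree = LabeledTree(root)
    names = [n for n in tree.leaf_names()]
    if any(n is None for n in names):
        raise ParseError("malformed newick: unlabeled leaf")
    if len(names) != len(set(names)):
        raise ParseError(f"duplicate leaf labels in newick: {sorted(names)}")
    return tree


def write_newick(tree: LabeledTree) -> str:
    def _fmt(node: TreeNode, at_root: bool = False) -> str:
        tag = "#1" if node.label == FOREGROUND else ""
        if node.is_leaf:
            body = f"{node.name}{tag}"
        else:
            inner = ",".join(_fmt(c) for c in node.children)
            body = f"({inner}){node.name or ''}{tag}"
        if at_root:
            return body
        return f"{body}:{node.length:g}"

    return _fmt(tree.root, at_root=True) + ";"


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline thresholds.  Defaults are the study's printed values."""

    # community profiling
    min_read_length: int = 25          # accepted-alignment length floor (bp)
    read_length_floor: int = 20        # post-trim discard floor (bp)
    max_read_divergence: float = 0.10  # mismatch fraction tolerated vs. reference
    uniqueness_margin: int = 2         # best vs runner-up mismatches (MAPQ surrogate)
    min_library_reads: int = 25        # library pool-assignment confidence floor
    pool_proportion_cutoff: float = 0.95
    # contig joining
    min_hit_length: int = 100
    min_hit_identity: float = 0.85
    min_overlap_identity: float = 0.95
    # ortholog pipeline
    min_orf_aa: int = 200
    # codon model / cascade
    tree_length_per_taxon: float = 2.0  # cutoff = 2 x n_taxa
    alpha: float = 0.05
    omega_upper_bound: float = 999.0
    n_restarts: int = 3
    codon_frequency_model: str = "F3x4"  # {equal, F1x4, F3x4}
    # misc
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat ``key = value`` config file; unknown keys are an error."""
        cfg = cls()
        valid = {f.name: f.type for f in fields(cls)}
        with Path(path).open() as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParseError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in valid:
                    raise ParseError(f"{path}:{lineno}: unknown config key {key!r}")
                current = getattr(cfg, key)
                caster = type(current)
                try:
                    setattr(cfg, key, caster(value))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
        cfg.validate()
        return cfg

    def override(self, **kwargs) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        cfg = replace(self, **kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 <= self.max_read_divergence <= 1.0:
            raise ValueError("max_read_divergence must be in [0, 1]")
        if not 0.5 <= self.pool_proportion_cutoff <= 1.0:
            raise ValueError("pool_proportion_cutoff must be in [0.5, 1]")
        if not 0.0 <= self.min_hit_identity <= 1.0 or not 0.0 <= self.min_overlap_identity <= 1.0:
            raise ValueError("identity cutoffs must be in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.codon_frequency_model not in ("equal", "F1x4", "F3x4"):
            raise ValueError(f"unknown codon frequency model {self.codon_frequency_model!r}")
        for name in ("min_read_length", "read_length_floor", "uniqueness_margin",
                     "min_library_reads", "min_hit_length", "min_orf_aa", "n_restarts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
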