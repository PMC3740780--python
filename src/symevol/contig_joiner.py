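"""Reference-guided meta-assembly: join contigs via shared reference hits.

Two contigs are joined when (1) their top qualifying hits (>= 100 bp and
>= 85% identity) are to the same reference transcript, (2) the reference
regions they match are overlapping or directly adjacent (zero gap), and
(3) any overlap region is >= 95% identical between the contigs.  Merging is
transitive left-to-right along the reference; disagreements inside an
overlap are resolved toward the contig with the higher hit identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .io_formats import HitRecord, SequenceRecord, log_stage, logger


@dataclass
class ContigPlacement:
    contig_id: str
    ref_id: str
    ref_interval: tuple[int, int]  # 1-based closed
    orientation: str  # {+, -}
    identity: float
    hit_length: int

    def __post_init__(self) -> None:
        if self.hit_length < 1:
            raise ValueError("hit length must be >= 1")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        s, e = self.ref_interval
        if s > e or s < 1:
            raise ValueError(f"bad reference interval [{s}, {e}]")


@dataclass
class JoinRecord:
    new_contig_id: str
    member_ids: list[str]
    ref_id: str
    merged_interval: tuple[int, int]
    overlap_identities: list[float]


def select_placements(
    hits: Sequence[HitRecord],
    min_length: int = 100,
    min_identity: float = 0.85,
) -> list[ContigPlacement]:
    """Pick each contig's single top qualifying hit.

    Qualifying hits are >= ``min_length`` aligned bases at >= ``min_identity``.
    Score ties break toward the longer hit, then the lexicographically
    smaller reference id.  Contigs with no qualifying hit are unplaced.
    """
    by_contig: dict[str, list[HitRecord]] = {}
    n_qualifying = 0
    for h in hits:
        if h.alignment_length < min_length or h.percent_identity < min_identity:
            continue
        n_qualifying += 1
        by_contig.setdefault(h.query_id, []).append(h)
    placements = []
    for contig_id in sorted(by_contig):
        top = max(
            by_contig[contig_id],
            key=lambda h: (h.score, h.alignment_length, [-ord(c) for c in h.subject_id]),
        )
        qs, qe = top.query_interval
        orientation = "+" if qs <= qe else "-"
        # read_hits_table normalises intervals, so orientation is carried by
        # callers that construct HitRecords directly with reversed intervals.
        placements.append(
            ContigPlacement(
                contig_id=contig_id,
                ref_id=top.subject_id,
                ref_interval=top.subject_interval,
                orientation=orientation,
                identity=top.percent_identity,
                hit_length=top.alignment_length,
            )
        )
    log_stage("select_placements", len(hits), len(placements),
              f"length>={min_length}, identity>={min_identity}, top hit per contig")
    return placements


def join_contigs(
    placements: Sequence[ContigPlacement],
    sequences: dict[str, str],
    min_overlap_identity: float = 0.95,
) -> tuple[list[SequenceRecord], list[JoinRecord]]:
    """Merge contigs placed on the same reference per the three joining rules.

    Within each reference group, contigs are sorted by interval start and
    merged left to right whenever the next interval overlaps or directly
    abuts (zero-base gap) the merged region so far, and the overlapping
    segments (aligned by reference coordinates, ungapped) are at least
    ``min_overlap_identity`` identical.  Overlap disagreements resolve toward
    the member with the higher placement identity (ties toward the left).
    Minus-orientation contigs are reverse-complemented before grouping; a
    group mixing orientations after that is left unjoined.  Every input
    contig appears in exactly one output record.
    """
    by_ref: dict[str, list[ContigPlacement]] = {}
    for p in placements:
        by_ref.setdefault(p.ref_id, []).append(p)

    out_records: list[SequenceRecord] = []
    joins: list[JoinRecord] = []
    emitted: set[str] = set()
    join_counter = 0

    for ref_id in sorted(by_ref):
        group = sorted(by_ref[ref_id], key=lambda p: (p.ref_interval[0], p.contig_id))
        oriented: dict[str, str] = {}
        for p in group:
            seq = sequences[p.contig_id].upper()
            oriented[p.contig_id] = (
                seq if p.orientation == "+" else str(Seq(seq).reverse_complement())
            )

        # current merged run
        members: list[ContigPlacement] = []
        merged_seq = ""
        merged_end = 0
        merged_start = 0
        overlap_idents: list[float] = []

        def flush() -> None:
            nonlocal join_counter, members, merged_seq, overlap_idents
            if not members:
                return
            if len(members) == 1:
                p = members[0]
                out_records.append(SequenceRecord(p.contig_id, oriented[p.contig_id]))
                emitted.add(p.contig_id)
            else:
                join_counter += 1
                new_id = f"joined_{ref_id}_{join_counter}"
                out_records.append(SequenceRecord(new_id, merged_seq))
                joins.append(
                    JoinRecord(
                        new_contig_id=new_id,
                        member_ids=[p.contig_id for p in members],
                        ref_id=ref_id,
                        merged_interval=(merged_start, merged_end),
                        overlap_identities=list(overlap_idents),
                    )
                )
                emitted.update(p.contig_id for p in members)
            members = []
            merged_seq = ""
            overlap_idents = []

        for p in group:
            seq = oriented[p.contig_id]
            if not members:
                members = [p]
                merged_seq = seq
                merged_start, merged_end = p.ref_interval
                overlap_idents = []
                continue
            start, end = p.ref_interval
            gap = start - merged_end - 1
            if gap > 0:
                flush()
                members = [p]
                merged_seq = seq
                merged_start, merged_end = start, end
                continue
            overlap = -gap  # bases shared on the reference (0 when abutting)
            joinable = True
            identity = 1.0
            if overlap > 0:
                left_tail = merged_seq[len(merged_seq) - overlap :]
                right_head = seq[:overlap]
                n = min(len(left_tail), len(right_head))
                identity = (
                    sum(a == b for a, b in zip(left_tail[:n], right_head[:n])) / n
                    if n
                    else 1.0
                )
                joinable = identity >= min_overlap_identity
            if not joinable:
                logger.info(
                    "no join %s + %s on %s: overlap identity %.3f < %.2f",
                    members[-1].contig_id, p.contig_id, ref_id, identity, min_overlap_identity,
                )
                flush()
                members = [p]
                merged_seq = seq
                merged_start, merged_end = start, end
                continue
            if overlap > 0:
                # consensus: keep the higher-identity member's bases (tie -> left)
                prev = members[-1]
                if p.identity > prev.identity:
                    merged_seq = merged_seq[: len(merged_seq) - overlap] + seq
                else:
                    merged_seq = merged_seq + seq[overlap:]
                overlap_idents.append(identity)
            else:
                merged_seq = merged_seq + seq
            members.append(p)
            merged_end = max(merged_end, end)
        flush()

    # passthrough for contigs never placed
    for contig_id in sorted(sequences):
        if contig_id not in emitted and not any(
            p.contig_id == contig_id for p in placements
        ):
            out_records.append(SequenceRecord(contig_id, sequences[contig_id]))
    log_stage("join_contigs", len(sequences), len(out_records),
              f"overlap identity>={min_overlap_identity}, zero-gap adjacency")
    return out_records, joins
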