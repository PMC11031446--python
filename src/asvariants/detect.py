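"""Splicing-event inference from spliced alignments.

One pass over a SAM file yields three kinds of evidence: splice junctions
(N-gapped alignments with sufficient anchors), a per-base depth profile of
aligned bases, and the contiguous aligned blocks used to test whether reads
span exon-intron boundaries.  Junctions are classified against annotated
gene models into the AS taxonomy; intron retention is then called per
annotated intron by four criteria:

1. mean intron depth at least ``min_depth_ratio`` (default 20%) of the mean
   of the two flanking exons' depths;
2. cumulative intron depth strictly greater than ``min_cumulative_depth``
   (default 100);
3. at least ``min_boundary_reads`` reads aligned contiguously across the 5'
   or the 3' exon-intron boundary, anchored ``boundary_anchor_nt`` on each
   side;
4. no other AS event detected on the same intron in the same sample.

Calling is per replicate; replicate aggregation unions event types per gene
and sample group.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from .models import (
    ASEvent,
    ASType,
    DepthProfile,
    GeneModel,
    IRCriteriaConfig,
    IREvidence,
    Interval,
    Junction,
)

log = logging.getLogger(__name__)

_REF_QUERY_OPS = {0, 7, 8}  # M, =, X
_SKIP_OP = 3  # N


# ---------------------------------------------------------------------------
# Evidence extraction from SAM
# ---------------------------------------------------------------------------

@dataclass
class AlignmentEvidence:
    """Junctions, depth and contiguous aligned blocks from one sample."""

    junctions: list[Junction]
    depth: DepthProfile
    blocks: dict[str, tuple[np.ndarray, np.ndarray]]
    n_malformed: int = 0

    @classmethod
    def from_sam(cls, path: str | Path, anchor: int = 6) -> "AlignmentEvidence":
        header_lines: list[str] = []
        body: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                (header_lines if line.startswith("@") else body).append(line)
        header = pysam.AlignmentHeader.from_text("\n".join(header_lines) + "\n")
        lengths = {sq["SN"]: sq["LN"] for sq in header.to_dict().get("SQ", [])}
        depth = {cid: np.zeros(n, dtype=np.int64) for cid, n in lengths.items()}
        junc_counts: dict[tuple[str, int, int], int] = defaultdict(int)
        junc_strand: dict[tuple[str, int, int], str] = {}
        block_acc: dict[str, list[tuple[int, int]]] = defaultdict(list)

        n_bad = 0
        for line in body:
            try:
                rec = pysam.AlignedSegment.fromstring(line, header)
            except (ValueError, KeyError):
                n_bad += 1
                continue
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cid = rec.reference_name
            strand = "."
            if rec.has_tag("XS"):
                strand = rec.get_tag("XS")
            pos = rec.reference_start
            cig = rec.cigartuples or []
            aligned_lens = [l if op in _REF_QUERY_OPS else 0 for op, l in cig]
            run_start = None
            for i, (op, length) in enumerate(cig):
                if op in _REF_QUERY_OPS:
                    if run_start is None:
                        run_start = pos
                    depth[cid][pos : pos + length] += 1
                    pos += length
                elif op == _SKIP_OP:
                    if run_start is not None:
                        block_acc[cid].append((run_start, pos))
                        run_start = None
                    left = sum(aligned_lens[:i])
                    right = sum(aligned_lens[i + 1 :])
                    if left >= anchor and right >= anchor:
                        key = (cid, pos, pos + length)
                        junc_counts[key] += 1
                        junc_strand.setdefault(key, strand)
                    pos += length
                elif op == 2:  # D consumes reference, breaks base contiguity
                    if run_start is not None:
                        block_acc[cid].append((run_start, pos))
                        run_start = None
                    pos += length
                # I/S/H consume no reference
            if run_start is not None:
                block_acc[cid].append((run_start, pos))
        if n_bad:
            log.warning("skipped %d malformed alignment lines", n_bad)

        junctions = [
            Junction(cid, s, e, junc_strand[(cid, s, e)], count)
            for (cid, s, e), count in sorted(junc_counts.items())
        ]
        blocks = {
            cid: (
                np.array([s for s, _ in b], dtype=np.int64),
                np.array([e for _, e in b], dtype=np.int64),
            )
            for cid, b in block_acc.items()
        }
        return cls(junctions, DepthProfile(depth), blocks, n_bad)

    def boundary_reads(self, contig_id: str, boundary: int, anchor: int) -> int:
        """Reads aligned contiguously across ``boundary`` with the anchor."""
        if contig_id not in self.blocks:
            return 0
        starts, ends = self.blocks[contig_id]
        return int(np.sum((starts <= boundary - anchor) & (ends >= boundary + anchor)))


def extract_junctions(sam_path: str | Path, anchor: int = 6) -> list[Junction]:
    """Distinct splice gaps with anchored read support."""
    return AlignmentEvidence.from_sam(sam_path, anchor=anchor).junctions


def compute_depth(sam_path: str | Path) -> DepthProfile:
    """Per-base count of aligned (non-skipped, non-clipped) bases."""
    return AlignmentEvidence.from_sam(sam_path).depth


# ---------------------------------------------------------------------------
# Junction classification
# ---------------------------------------------------------------------------

def _tx_intron_index(gene: GeneModel, genomic_sorted_index: int) -> int:
    """1-based transcription-order intron index from a genomic-sorted one."""
    if gene.strand == "+":
        return genomic_sorted_index + 1
    return gene.n_introns - genomic_sorted_index


def _mxe_type(gene: GeneModel, exons_a: set[int], exons_b: set[int]) -> ASType:
    """Type a mutually exclusive exon pair by transcript position.

    Indices are transcription-order exon indices (0-based).  Pairs touching
    the first/last exon are alternative 5'/3' terminal exons.
    """
    union = exons_a | exons_b
    if 0 in union:
        return ASType.MXE_5P
    if gene.n_exons - 1 in union:
        return ASType.MXE_3P
    return ASType.MXE


def classify_junctions(
    junctions: Sequence[Junction],
    models: Sequence[GeneModel],
    min_junction_reads: int = 1,
    sample_id: str = "",
) -> list[ASEvent]:
    """Classify unannotated junctions into non-IR AS events.

    All splice-site semantics are in transcription orientation: the donor is
    the 5' end of the intron on the coding strand, so a donor-shifted
    junction is A5SS and an acceptor-shifted one is A3SS regardless of the
    genomic strand.  Junctions matching annotated introns exactly produce no
    event; junctions outside every gene are counted and ignored.
    """
    by_contig: dict[str, list[GeneModel]] = defaultdict(list)
    for m in models:
        by_contig[m.contig_id].append(m)

    per_gene: dict[str, list[Junction]] = defaultdict(list)
    gene_by_id = {m.gene_id: m for m in models}
    n_intergenic = 0
    for j in junctions:
        if j.read_count < min_junction_reads:
            continue
        host = None
        for g in by_contig.get(j.contig_id, []):
            gs, ge = g.span
            if gs <= j.start and j.end <= ge:
                host = g
                break
        if host is None:
            n_intergenic += 1
            continue
        per_gene[host.gene_id].append(j)
    if n_intergenic:
        log.info("%d junctions outside annotated genes ignored", n_intergenic)

    events: list[ASEvent] = []
    for gid, jlist in per_gene.items():
        events.extend(_classify_gene(gene_by_id[gid], jlist, sample_id))
    return events


def _classify_gene(
    gene: GeneModel, junctions: Sequence[Junction], sample_id: str
) -> list[ASEvent]:
    g_introns = sorted(gene.introns)  # genomic order
    g_exons = sorted(gene.exons)
    annotated = set(g_introns)
    plus = gene.strand == "+"
    novel = [j for j in junctions if j.interval not in annotated]
    if not novel:
        return []

    def intron_of(pos_lo: int, pos_hi: int) -> Optional[int]:
        for i, (s, e) in enumerate(g_introns):
            if s <= pos_lo and pos_hi <= e:
                return i
        return None

    events: list[ASEvent] = []
    consumed: set[Interval] = set()

    # Cassette exons: a donor-anchored and an acceptor-anchored novel
    # junction inside the same annotated intron, framing a novel exon.
    for i, (s, e) in enumerate(g_introns):
        inside = [j for j in novel if s <= j.start and j.end <= e]
        left_anchored = [j for j in inside if j.start == s and j.end < e]
        right_anchored = [j for j in inside if j.end == e and j.start > s]
        for j1 in left_anchored:
            for j2 in right_anchored:
                if j1.end < j2.start:
                    events.append(
                        ASEvent(
                            gene_id=gene.gene_id,
                            sample_id=sample_id,
                            as_type=ASType.CASSETTE,
                            intron_index=_tx_intron_index(gene, i),
                            coords=[(j1.end, j2.start)],
                            evidence=min(j1.read_count, j2.read_count),
                        )
                    )
                    consumed.update({j1.interval, j2.interval})

    es_events: list[tuple[ASEvent, set[int]]] = []
    for j in novel:
        if j.interval in consumed:
            continue
        i_left = intron_of(j.start, j.start + 1)
        i_right = intron_of(j.end - 1, j.end)
        if i_left is None or i_right is None:
            log.info(
                "%s: junction %d-%d has an end outside annotated introns; ignored",
                gene.gene_id,
                j.start,
                j.end,
            )
            continue
        if i_left == i_right:
            s, e = g_introns[i_left]
            left_match, right_match = j.start == s, j.end == e
            if plus:
                donor_match, acceptor_match = left_match, right_match
                head, tail = j.start - s, e - j.end
            else:
                donor_match, acceptor_match = right_match, left_match
                head, tail = e - j.end, j.start - s
            if donor_match and acceptor_match:
                continue  # annotated (already excluded, defensive)
            if donor_match:
                t = ASType.A3SS
            elif acceptor_match:
                t = ASType.A5SS
            else:
                t = ASType.A5SS_A3SS
            events.append(
                ASEvent(
                    gene_id=gene.gene_id,
                    sample_id=sample_id,
                    as_type=t,
                    intron_index=_tx_intron_index(gene, i_left),
                    coords=[j.interval],
                    evidence=j.read_count,
                    retained_head=head,
                    retained_tail=tail,
                )
            )
        else:
            # spans whole exon(s): exon skipping, possibly with a shifted end
            lo, hi = min(i_left, i_right), max(i_left, i_right)
            skipped = list(range(lo + 1, hi + 1))  # genomic exon indices
            left_match = j.start == g_introns[lo][0]
            right_match = j.end == g_introns[hi][1]
            if left_match and right_match:
                t = ASType.ES
            elif (plus and right_match) or (not plus and left_match):
                t = ASType.A5SS_ES  # donor side shifted
            elif (plus and left_match) or (not plus and right_match):
                t = ASType.A3SS_ES
            else:
                t = ASType.A5SS_ES
            coords = [g_exons[k] for k in skipped]
            tx_idx = (
                set(skipped)
                if plus
                else {gene.n_exons - 1 - k for k in skipped}
            )
            ev = ASEvent(
                gene_id=gene.gene_id,
                sample_id=sample_id,
                as_type=t,
                intron_index=None,
                coords=coords,
                evidence=j.read_count,
            )
            if t == ASType.ES:
                es_events.append((ev, tx_idx))
            else:
                events.append(ev)

    events.extend(_fold_mxe(gene, es_events, sample_id))
    return events


def _fold_mxe(
    gene: GeneModel,
    es_events: list[tuple[ASEvent, set[int]]],
    sample_id: str,
) -> list[ASEvent]:
    """Merge pairs of ES events skipping adjacent disjoint exon runs into
    mutually-exclusive-exon events; unpaired ES events pass through."""
    out: list[ASEvent] = []
    used = [False] * len(es_events)
    for a in range(len(es_events)):
        if used[a]:
            continue
        ev_a, set_a = es_events[a]
        for b in range(a + 1, len(es_events)):
            if used[b]:
                continue
            ev_b, set_b = es_events[b]
            if set_a & set_b:
                continue
            if max(set_a) + 1 == min(set_b) or max(set_b) + 1 == min(set_a):
                out.append(
                    ASEvent(
                        gene_id=gene.gene_id,
                        sample_id=sample_id,
                        as_type=_mxe_type(gene, set_a, set_b),
                        intron_index=None,
                        coords=ev_a.coords + ev_b.coords,
                        evidence=min(ev_a.evidence, ev_b.evidence),
                    )
                )
                used[a] = used[b] = True
                break
        if not used[a]:
            out.append(ev_a)
            used[a] = True
    return out


# ---------------------------------------------------------------------------
# Intron retention calling
# ---------------------------------------------------------------------------

@dataclass
class IRCallResult:
    """Per-criterion verdicts for one candidate intron."""

    evidence: IREvidence
    criteria: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())


#: Depth-comparison tie tolerance: criterion 1 is "at least 20%", so exact
#: equality must pass despite binary floating point (0.2 * 40 != 8 exactly).
_TIE_EPS = 1e-9


def evaluate_ir_criteria(
    evidence: IREvidence,
    has_other_event: bool,
    cfg: IRCriteriaConfig,
) -> IRCallResult:
    c1 = (
        evidence.mean_intron_depth
        >= cfg.min_depth_ratio * evidence.mean_flank_exon_depth - _TIE_EPS
    )
    c2 = evidence.cumulative_intron_depth > cfg.min_cumulative_depth
    c3 = (
        max(evidence.boundary_reads_5p, evidence.boundary_reads_3p)
        >= cfg.min_boundary_reads
    )
    c4 = not has_other_event
    return IRCallResult(
        evidence, {"depth_ratio": c1, "cumulative_depth": c2, "boundary": c3, "exclusive": c4}
    )


def call_intron_retention(
    models: Sequence[GeneModel],
    evidence: AlignmentEvidence,
    other_events: Sequence[ASEvent],
    cfg: IRCriteriaConfig = IRCriteriaConfig(),
    sample_id: str = "",
) -> list[ASEvent]:
    """Apply the four IR criteria to every annotated intron of every gene."""
    by_gene_events: dict[str, list[ASEvent]] = defaultdict(list)
    for ev in other_events:
        by_gene_events[ev.gene_id].append(ev)

    calls: list[ASEvent] = []
    for gene in models:
        cid = gene.contig_id
        if cid not in evidence.depth.depth:
            continue
        for k, (s, e) in enumerate(gene.introns):
            up, down = gene.exons[k], gene.exons[k + 1]
            mean_intron = evidence.depth.mean(cid, s, e)
            flank = 0.5 * (
                evidence.depth.mean(cid, *up) + evidence.depth.mean(cid, *down)
            )
            b_left = evidence.boundary_reads(cid, s, cfg.boundary_anchor_nt)
            b_right = evidence.boundary_reads(cid, e, cfg.boundary_anchor_nt)
            b5, b3 = (b_left, b_right) if gene.strand == "+" else (b_right, b_left)
            ire = IREvidence(
                mean_intron_depth=mean_intron,
                mean_flank_exon_depth=flank,
                cumulative_intron_depth=evidence.depth.total(cid, s, e),
                boundary_reads_5p=b5,
                boundary_reads_3p=b3,
            )
            veto = any(ev.overlaps((s, e)) for ev in by_gene_events[gene.gene_id])
            result = evaluate_ir_criteria(ire, veto, cfg)
            if result.passed:
                calls.append(
                    ASEvent(
                        gene_id=gene.gene_id,
                        sample_id=sample_id,
                        as_type=ASType.IR,
                        intron_index=k + 1,
                        coords=[(s, e)],
                        evidence=ire,
                    )
                )
    return calls


def detect_sample(
    sam_path: str | Path,
    models: Sequence[GeneModel],
    cfg: IRCriteriaConfig = IRCriteriaConfig(),
    min_junction_reads: int = 1,
    sample_id: str = "",
) -> list[ASEvent]:
    """Full per-replicate inference: junction events plus IR calls."""
    evidence = AlignmentEvidence.from_sam(sam_path, anchor=cfg.boundary_anchor_nt)
    junction_events = classify_junctions(
        evidence.junctions, models, min_junction_reads, sample_id
    )
    ir_events = call_intron_retention(models, evidence, junction_events, cfg, sample_id)
    return junction_events + ir_events


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

def aggregate_replicates(
    events: Sequence[ASEvent],
    sample_groups: Mapping[str, str],
) -> dict[tuple[str, str], set[ASType]]:
    """Union of event types per gene per group over replicate samples.

    A type is reported for a group as soon as it occurs in at least one
    replicate; criteria are never re-applied to pooled replicates.
    """
    cells: dict[tuple[str, str], set[ASType]] = defaultdict(set)
    for ev in events:
        if ev.sample_id not in sample_groups:
            raise ValueError(f"sample {ev.sample_id!r} has no group assignment")
        cells[(ev.gene_id, sample_groups[ev.sample_id])].add(ev.as_type)
    return dict(cells)
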