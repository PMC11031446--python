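"""Core domain types for splice-variant inference.

Coordinates are 0-based, half-open genomic intervals throughout; GFF3 I/O
converts at the boundary.  Exons of a :class:`GeneModel` are stored in
transcription order (genomically descending for minus-strand genes) so that
all event logic can reason in 5'->3' transcript orientation while genomic
records keep plus-strand coordinates plus a strand flag.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

Interval = tuple[int, int]

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ASType(str, enum.Enum):
    """Alternative-splicing event taxonomy.

    Enum declaration order is the deterministic rendering order used when a
    gene shows several event types in one sample group (e.g. ``ES/IR``).
    """

    ES = "ES"
    A5SS = "A5SS"
    A3SS = "A3SS"
    MXE = "MXE"
    MXE_5P = "5pMXE"
    MXE_3P = "3pMXE"
    A5SS_ES = "A5SS&ES"
    A3SS_ES = "A3SS&ES"
    CASSETTE = "CassetteExon"
    IR = "IR"
    A5SS_A3SS = "A5SS&A3SS"


#: Rendering order for "/"-joined cells in the aggregated report.
AS_TYPE_ORDER: dict[ASType, int] = {t: i for i, t in enumerate(ASType)}


@dataclass(frozen=True)
class Contig:
    """A reference sequence of the toy genome."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id}: non-DNA characters {sorted(bad)} "
                "(U/RNA and ambiguity codes other than N are rejected)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """One gene with a single mRNA model.

    ``exons`` are genomic intervals in transcription order.  ``cds_span`` is
    an interval in spliced-transcript coordinates (None for non-coding
    models).  ``name`` is the display symbol used in reports.
    """

    gene_id: str
    contig_id: str
    strand: str
    exons: list[Interval]
    cds_span: Optional[Interval] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty or inverted exon ({s},{e})")
        srt = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(srt, srt[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        for s, e in self.introns:
            if e - s < 4:
                raise ValueError(f"{self.gene_id}: intron shorter than 4 nt")
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if ce - cs < 3:
                raise ValueError(f"{self.gene_id}: CDS shorter than one codon")
            if cs < 0 or ce > self.transcript_length:
                raise ValueError(f"{self.gene_id}: CDS outside spliced transcript")

    # -- structure ---------------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def introns(self) -> list[Interval]:
        """Genomic intron intervals in transcription order."""
        out = []
        for up, down in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((up[1], down[0]))
            else:
                out.append((down[1], up[0]))
        return out

    @property
    def span(self) -> Interval:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_offsets(self) -> list[int]:
        """Transcript coordinate at which each exon starts."""
        offs, pos = [], 0
        for s, e in self.exons:
            offs.append(pos)
            pos += e - s
        return offs

    def splice(self, contig: Contig) -> str:
        """Spliced transcript sequence in 5'->3' orientation."""
        parts = []
        for s, e in self.exons:
            block = contig.seq[s:e]
            parts.append(block if self.strand == "+" else revcomp(block))
        return "".join(parts)

    def cds_sequence(self, contig: Contig) -> str:
        if self.cds_span is None:
            raise ValueError(f"{self.gene_id}: model is non-coding")
        tx = self.splice(contig)
        return tx[self.cds_span[0] : self.cds_span[1]]


@dataclass(frozen=True)
class Junction:
    """One splice junction supported by gapped alignments.

    ``start`` is the first intronic base, ``end`` one past the last (the
    spliced-out interval).  Strand is '.', '+' or '-' ('.' when the library
    carries no strand information).
    """

    contig_id: str
    start: int
    end: int
    strand: str = "."
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("junction end must exceed start")
        if self.read_count < 0:
            raise ValueError("negative junction read count")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


class DepthProfile:
    """Per-base aligned coverage, one vector per contig."""

    def __init__(self, depth: Mapping[str, np.ndarray]):
        self.depth = {k: np.asarray(v, dtype=np.int64) for k, v in depth.items()}
        for cid, vec in self.depth.items():
            if (vec < 0).any():
                raise ValueError(f"negative depth on {cid}")

    def __getitem__(self, contig_id: str) -> np.ndarray:
        return self.depth[contig_id]

    def mean(self, contig_id: str, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty interval")
        return float(self.depth[contig_id][start:end].mean())

    def total(self, contig_id: str, start: int, end: int) -> float:
        return float(self.depth[contig_id][start:end].sum())

    def mass(self) -> int:
        """Total aligned bases across the genome (conservation checks)."""
        return int(sum(v.sum() for v in self.depth.values()))


@dataclass
class IREvidence:
    """Measurements backing one intron-retention call decision."""

    mean_intron_depth: float
    mean_flank_exon_depth: float
    cumulative_intron_depth: float
    boundary_reads_5p: int
    boundary_reads_3p: int

    def __post_init__(self) -> None:
        for v in (
            self.mean_intron_depth,
            self.mean_flank_exon_depth,
            self.cumulative_intron_depth,
        ):
            if v < 0:
                raise ValueError("negative depth evidence")
        if self.boundary_reads_5p < 0 or self.boundary_reads_3p < 0:
            raise ValueError("negative boundary read count")


@dataclass
class IRCriteriaConfig:
    """Thresholds of the four-criterion intron-retention caller.

    Defaults: intron depth at least 20% of the flanking exons' depth,
    cumulative intron depth strictly greater than 100, at least one read
    aligned contiguously across the 5' or the 3' exon-intron boundary with
    a 6 nt anchor on each side.
    """

    min_depth_ratio: float = 0.20
    min_cumulative_depth: float = 100.0
    min_boundary_reads: int = 1
    boundary_anchor_nt: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.min_depth_ratio <= 1):
            raise ValueError("min_depth_ratio must lie in (0, 1]")
        if self.min_cumulative_depth <= 0:
            raise ValueError("min_cumulative_depth must be positive")
        if self.min_boundary_reads <= 0:
            raise ValueError("min_boundary_reads must be positive")
        if self.boundary_anchor_nt <= 0:
            raise ValueError("boundary_anchor_nt must be positive")


@dataclass
class ASEvent:
    """A classified splicing event in one sample.

    ``intron_index`` is 1-based in transcription order (the "1st intron").
    ``coords`` are the genomic interval(s) affected: for IR the retained
    intron; for alternative splice sites the novel spliced-out interval; for
    ES the skipped exon(s); for cassette exons the novel exon.
    """

    gene_id: str
    sample_id: str
    as_type: ASType
    intron_index: Optional[int] = None
    coords: list[Interval] = field(default_factory=list)
    evidence: object = None
    # Head/tail of the intron retained by alternative splice-site use, in
    # transcription orientation (A5SS/A3SS/A5SS&A3SS reconstruction).
    retained_head: int = 0
    retained_tail: int = 0

    def __post_init__(self) -> None:
        if self.as_type == ASType.IR and self.intron_index is None:
            raise ValueError("IR events require intron_index")
        if self.intron_index is not None and self.intron_index < 1:
            raise ValueError("intron_index is 1-based")

    def overlaps(self, interval: Interval) -> bool:
        s, e = interval
        return any(cs < e and s < ce for cs, ce in self.coords)


class Category(str, enum.Enum):
    """Protein-level outcome of applying a splicing event to a CDS."""

    IN_FRAME_INSERTION = "in_frame_insertion"
    IN_FRAME_DELETION = "in_frame_deletion"
    FRAMESHIFT_PTC = "frameshift_ptc"
    IN_FRAME_PTC = "in_frame_ptc"
    SILENT = "silent"


@dataclass
class ConsequenceRecord:
    """Protein-level consequence of one AS event.

    ``ptc_aa_position`` is the 1-based amino-acid index of the premature stop
    counting from the initiator methionine ("termination at the Nth aa");
    protein lengths never count the stop.
    """

    gene_id: str
    as_type: ASType
    category: Category
    normal_protein_len: int
    variant_protein_len: int
    inserted_aa: Optional[int] = None
    ptc_aa_position: Optional[int] = None
    utr_only: bool = False

    def __post_init__(self) -> None:
        if self.normal_protein_len < 0 or self.variant_protein_len < 0:
            raise ValueError("negative protein length")
        if self.category == Category.IN_FRAME_INSERTION and self.inserted_aa is None:
            raise ValueError("in-frame insertion requires inserted_aa")
        if self.category in (Category.FRAMESHIFT_PTC, Category.IN_FRAME_PTC):
            if self.ptc_aa_position is None:
                raise ValueError("PTC category requires ptc_aa_position")
            if self.variant_protein_len != self.ptc_aa_position - 1:
                raise ValueError("variant length must equal PTC position - 1")


# ---------------------------------------------------------------------------
# Event application: shared by the read simulator (isoform construction) and
# the consequence predictor (variant transcript reconstruction).
# ---------------------------------------------------------------------------

def variant_blocks(gene: GeneModel, event: ASEvent) -> list[Interval]:
    """Genomic blocks (transcription order) of the variant isoform.

    IR merges the flanking exons across the retained intron; alternative
    splice-site events extend the flanking exons by the retained head/tail of
    the intron; ES drops the skipped exon(s); cassette events insert the
    novel exon inside its intron.
    """
    exons = [tuple(x) for x in gene.exons]
    t = event.as_type
    if t == ASType.IR:
        k = _check_intron_index(gene, event)
        merged = (
            min(exons[k][0], exons[k + 1][0]),
            max(exons[k][1], exons[k + 1][1]),
        )
        return exons[:k] + [merged] + exons[k + 2 :]
    if t in (ASType.A5SS, ASType.A3SS, ASType.A5SS_A3SS):
        k = _check_intron_index(gene, event)
        h, tl = event.retained_head, event.retained_tail
        intron_len = abs(gene.introns[k][1] - gene.introns[k][0])
        if h < 0 or tl < 0 or h + tl > intron_len:
            raise ValueError(
                f"{gene.gene_id}: retained head+tail exceeds intron length"
            )
        up, down = exons[k], exons[k + 1]
        if gene.strand == "+":
            up = (up[0], up[1] + h)
            down = (down[0] - tl, down[1])
        else:
            up = (up[0] - h, up[1])
            down = (down[0], down[1] + tl)
        return exons[:k] + [up, down] + exons[k + 2 :]
    if t in (ASType.ES, ASType.A5SS_ES, ASType.A3SS_ES):
        skipped = set(map(tuple, event.coords))
        kept = [x for x in exons if x not in skipped]
        if len(kept) == len(exons):
            raise ValueError(f"{gene.gene_id}: ES coords match no annotated exon")
        if not kept:
            raise ValueError(f"{gene.gene_id}: ES would remove every exon")
        return kept
    if t == ASType.CASSETTE:
        if len(event.coords) != 1:
            raise ValueError("cassette event needs exactly one novel exon interval")
        novel = tuple(event.coords[0])
        for k, (s, e) in enumerate(gene.introns):
            if s <= novel[0] and novel[1] <= e:
                # between transcription-order exons k and k+1 on either strand
                return exons[: k + 1] + [novel] + exons[k + 1 :]
        raise ValueError(f"{gene.gene_id}: cassette exon not inside any intron")
    raise ValueError(f"unsupported event type for reconstruction: {t.value}")


def _check_intron_index(gene: GeneModel, event: ASEvent) -> int:
    if event.intron_index is None:
        raise ValueError(f"{event.as_type.value} event requires intron_index")
    k = event.intron_index - 1
    if not (0 <= k < gene.n_introns):
        raise ValueError(
            f"{gene.gene_id}: intron index {event.intron_index} out of range "
            f"(gene has {gene.n_introns} introns)"
        )
    return k


def splice_blocks(blocks: Sequence[Interval], contig: Contig, strand: str) -> str:
    """Sequence of an isoform given its blocks in transcription order."""
    parts = []
    for s, e in blocks:
        seg = contig.seq[s:e]
        parts.append(seg if strand == "+" else revcomp(seg))
    return "".join(parts)
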