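"""Synthetic data: toy genome, fixture genes, spliced reads, kinetics rates.

The generator builds multi-intron gene models on a toy genome (one gene per
contig, short intergenic padding), with canonical GT..AG introns on the
coding strand, and simulates error-free spliced reads from mixtures of the
normal isoform and splice-variant isoforms.  Five named fixture genes mimic
the documented enzyme-gene variants:

==========  =========================================================  ==========
fixture     planted event                                              normal CDS
==========  =========================================================  ==========
xynF1_like  A5SS&A3SS on intron 7 (first 22 + last 2 nt retained,      319 aa
            stop-free in frame)
abnC_like   IR of the 62-bp intron 1 (frameshift)                      318 aa
cbhC_like   IR of the 84-bp intron 1 carrying an in-frame stop         435 aa
bglM_like   IR of the 46-bp intron 2 (frameshift)                      765 aa
eglD_like   IR of the 141-bp intron 1, stop-free in frame              365 aa
==========  =========================================================  ==========

Reads model post-QC data: uniform fragment starts, no sequencing errors by
default, primary alignments only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import (
    ASEvent,
    ASType,
    Contig,
    GeneModel,
    Interval,
    revcomp,
    splice_blocks,
    variant_blocks,
)

log = logging.getLogger(__name__)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a, b, c in itertools.product(_BASES, repeat=3)
    if a + b + c not in _STOPS
]


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """What the toy genome should contain."""

    n_genes: int = 10
    exon_length_range: tuple[int, int] = (80, 200)
    intron_length_range: tuple[int, int] = (40, 120)
    include_paper_fixtures: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.exon_length_range, self.intron_length_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        if self.intron_length_range[0] < 20:
            raise ValueError("intron lengths must be >= 20 nt")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.include_paper_fixtures and self.n_genes < 5:
            raise ValueError("paper fixtures require n_genes >= 5")


@dataclass
class ReadSimConfig:
    read_length: int = 100
    target_depth: float = 50.0
    seed: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.read_length < 12:
            raise ValueError("read_length must be >= 12 (twice the anchor)")
        if self.target_depth <= 0:
            raise ValueError("target_depth must be positive")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass
class IsoformMixture:
    """Relative molar abundances of the isoforms of one gene.

    Components pair an event (or ``"normal"``) with a relative abundance;
    abundances are normalized to sum to one.
    """

    gene_id: str
    components: list[tuple[Union[str, ASEvent], float]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        total = sum(ab for _, ab in self.components)
        if total <= 0:
            raise ValueError("mixture abundances must sum to a positive value")
        self.components = [(ev, ab / total) for ev, ab in self.components]


@dataclass
class KineticsParams:
    """Michaelis-Menten simulation parameters.

    Km in mg/mL (substrate mass concentration), kcat in 1/min, E0 the enzyme
    molar amount (umol) so that Vmax = kcat * E0 is in umol/min.  Defaults
    reproduce the characterized xylanase variant (Km 7.41 mg/mL, kcat
    19.51 1/min) assayed over 0.2-15 mg/mL substrate.
    """

    km: float = 7.41
    kcat: float = 19.51
    e0: float = 0.05
    s_grid: Optional[np.ndarray] = None
    noise_cv: float = 0.02
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.km, self.kcat, self.e0) <= 0:
            raise ValueError("Km, kcat and E0 must be positive")
        if self.s_grid is None:
            # geometric spacing gives low-S resolution where Km lives
            self.s_grid = np.geomspace(0.2, 15.0, 12)
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        if (self.s_grid <= 0).any():
            raise ValueError("substrate concentrations must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass
class KineticsDataset:
    """Substrate/rate pairs with the (known) simulated enzyme amount."""

    data: pd.DataFrame  # columns: S, v, replicate
    e0: float


@dataclass
class Isoform:
    gene_id: str
    label: str
    contig_id: str
    strand: str
    blocks: list[Interval]
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# Sequence construction helpers
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _rand_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) sense codons + one stop codon."""
    body = "".join(rng.choice(_SENSE_CODONS, size=n_aa - 1))
    stop = rng.choice(sorted(_STOPS))
    return "ATG" + body + stop


def _plain_intron(rng: np.random.Generator, length: int) -> str:
    if length < 20:
        raise ValueError("intron shorter than 20 nt")
    return "GT" + _rand_seq(rng, length - 4) + "AG"


def _frame_safe_intron(rng: np.random.Generator, length: int) -> str:
    """GT..AG intron, length % 3 == 0, with no in-frame stop codon.

    Safe for insertion at a codon boundary: the retained sequence translates
    straight through (in-frame insertion fixtures).
    """
    if length % 3 != 0 or length < 21:
        raise ValueError("frame-safe intron needs length % 3 == 0 and >= 21")
    n_codons = length // 3
    first = "GT" + rng.choice(list(_BASES))  # GTN is never a stop
    mid = "".join(rng.choice(_SENSE_CODONS, size=n_codons - 2))
    last = rng.choice(list("ACG")) + "AG"  # avoid TAG
    return first + mid + last


def _stop_bearing_intron(rng: np.random.Generator, length: int, stop_codon_index: int) -> str:
    """Frame-safe-shaped intron with one planted in-frame TAA stop."""
    seq = list(_frame_safe_intron(rng, length))
    pos = 3 * stop_codon_index
    if not (3 <= pos <= length - 6):
        raise ValueError("planted stop collides with splice dinucleotides")
    seq[pos : pos + 3] = "TAA"
    return "".join(seq)


def _head_tail_safe_intron(rng: np.random.Generator, length: int, head: int, tail: int) -> str:
    """Intron whose first ``head`` + last ``tail`` nt are stop-free in frame.

    Used for the alternative-splice-site fixture: the variant retains the
    intron's head and tail, which must read through when (head + tail) % 3
    == 0 and the junction sits at a codon boundary.
    """
    if (head + tail) % 3 != 0:
        raise ValueError("retained head+tail must be a codon multiple")
    if head < 2 or tail < 2 or head + tail + 4 > length:
        raise ValueError("head/tail incompatible with intron length")
    retained_codons = (head + tail) // 3
    # Build the retained 24-mer as codons: GTN, sense codons, then N+"AG".
    first = "GT" + rng.choice(list(_BASES))
    mid = "".join(rng.choice(_SENSE_CODONS, size=retained_codons - 2))
    joiner = rng.choice(list("ACG"))
    retained = first + mid + joiner + "AG"
    assert len(retained) == head + tail
    # retained[:head] starts GT, retained[head:] ends AG (tail >= 2)
    interior = _rand_seq(rng, length - head - tail)
    return retained[:head] + interior + retained[head:]


def _translate(cds: str) -> tuple[str, bool]:
    """Minimal standard-code translation used for generator self-checks."""
    from Bio.Seq import Seq

    aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    stop = aa.find("*")
    if stop == -1:
        return aa, False
    return aa[:stop], True


# ---------------------------------------------------------------------------
# Gene builders
# ---------------------------------------------------------------------------

@dataclass
class _LocalGene:
    """Gene laid out on its own forward-oriented local sequence."""

    gene_id: str
    name: str
    seq: str
    exons: list[Interval]  # local coords, ascending
    cds_span: Interval  # transcript coords


@dataclass(frozen=True)
class _FixtureDef:
    name: str
    n_aa: int
    n_introns: int
    event_type: ASType
    event_intron: int  # 1-based
    special_intron_len: int
    head: int = 0
    tail: int = 0
    planted_stop_codon: Optional[int] = None


PAPER_FIXTURES: dict[str, _FixtureDef] = {
    "xynF1_like": _FixtureDef("xynF1", 319, 7, ASType.A5SS_A3SS, 7, 60, head=22, tail=2),
    "abnC_like": _FixtureDef("abnC", 318, 2, ASType.IR, 1, 62),
    "cbhC_like": _FixtureDef("cbhC", 435, 2, ASType.IR, 1, 84, planted_stop_codon=4),
    "bglM_like": _FixtureDef("bglM", 765, 3, ASType.IR, 2, 46),
    "eglD_like": _FixtureDef("eglD", 365, 2, ASType.IR, 1, 141),
}

_UTR5 = 30
_UTR3 = 30


def _assemble(
    gene_id: str,
    name: str,
    transcript: str,
    cds_span: Interval,
    intron_at: list[int],  # transcript positions, ascending
    intron_seqs: list[str],
) -> _LocalGene:
    parts, exons = [], []
    pos = 0
    local = 0
    for tpos, iseq in zip(intron_at, intron_seqs):
        exon = transcript[pos:tpos]
        parts.append(exon)
        exons.append((local, local + len(exon)))
        local += len(exon)
        parts.append(iseq)
        local += len(iseq)
        pos = tpos
    exon = transcript[pos:]
    parts.append(exon)
    exons.append((local, local + len(exon)))
    return _LocalGene(gene_id, name, "".join(parts), exons, cds_span)


def _build_fixture_gene(rng: np.random.Generator, key: str) -> _LocalGene:
    d = PAPER_FIXTURES[key]
    for _ in range(60):
        cds = _rand_cds(rng, d.n_aa)
        transcript = _rand_seq(rng, _UTR5) + cds + _rand_seq(rng, _UTR3)
        cds_span = (_UTR5, _UTR5 + len(cds))
        # intron codon positions, evenly spread; all at codon boundaries
        codons = [
            round(d.n_aa * i / (d.n_introns + 1)) for i in range(1, d.n_introns + 1)
        ]
        positions = [_UTR5 + 3 * c for c in codons]
        seqs = []
        for i in range(1, d.n_introns + 1):
            if i != d.event_intron:
                seqs.append(_plain_intron(rng, int(rng.integers(45, 91))))
            elif d.event_type == ASType.A5SS_A3SS:
                seqs.append(
                    _head_tail_safe_intron(rng, d.special_intron_len, d.head, d.tail)
                )
            elif d.planted_stop_codon is not None:
                seqs.append(
                    _stop_bearing_intron(rng, d.special_intron_len, d.planted_stop_codon)
                )
            elif d.special_intron_len % 3 == 0:
                seqs.append(_frame_safe_intron(rng, d.special_intron_len))
            else:
                seqs.append(_plain_intron(rng, d.special_intron_len))
        gene = _assemble(key, d.name, transcript, cds_span, positions, seqs)
        if _fixture_ok(gene, d):
            return gene
    raise RuntimeError(f"could not satisfy constraints for fixture {key}")


def _fixture_ok(gene: _LocalGene, d: _FixtureDef) -> bool:
    """Self-check: the planted event must have its documented outcome."""
    tx = _spliced_local(gene)
    normal, term = _translate(tx[gene.cds_span[0] : gene.cds_span[1]])
    if not term or len(normal) != d.n_aa:
        return False
    var = _variant_local(gene, d)
    vaa, vterm = _translate(var[gene.cds_span[0] :])
    if not vterm:
        return False
    delta = len(var) - len(tx)
    if d.event_type == ASType.A5SS_A3SS or (
        d.event_type == ASType.IR and delta % 3 == 0 and d.planted_stop_codon is None
    ):
        return len(vaa) == d.n_aa + delta // 3
    # frameshift or planted stop: must truncate
    return len(vaa) < d.n_aa


def _spliced_local(gene: _LocalGene) -> str:
    return "".join(gene.seq[s:e] for s, e in gene.exons)


def _variant_local(gene: _LocalGene, d: _FixtureDef) -> str:
    k = d.event_intron - 1
    intron = (gene.exons[k][1], gene.exons[k + 1][0])
    parts = []
    for i, (s, e) in enumerate(gene.exons):
        parts.append(gene.seq[s:e])
        if i == k:
            iseq = gene.seq[intron[0] : intron[1]]
            if d.event_type == ASType.IR:
                parts.append(iseq)
            else:
                parts.append(iseq[: d.head] + iseq[len(iseq) - d.tail :])
    return "".join(parts)


def _build_random_gene(
    rng: np.random.Generator, spec: FixtureSpec, gene_id: str
) -> _LocalGene:
    n_exons = int(rng.integers(2, 6))
    exon_lens = rng.integers(
        spec.exon_length_range[0], spec.exon_length_range[1] + 1, size=n_exons
    )
    intron_lens = rng.integers(
        spec.intron_length_range[0], spec.intron_length_range[1] + 1, size=n_exons - 1
    )
    tx_len = int(exon_lens.sum())
    utr5 = 15
    cds_len = 3 * ((tx_len - utr5 - 12) // 3)
    transcript = (
        _rand_seq(rng, utr5)
        + _rand_cds(rng, cds_len // 3)
        + _rand_seq(rng, tx_len - utr5 - cds_len)
    )
    positions = list(np.cumsum(exon_lens[:-1]))
    introns = [_plain_intron(rng, int(n)) for n in intron_lens]
    return _assemble(
        gene_id, gene_id, transcript, (utr5, utr5 + cds_len), positions, introns
    )


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

def make_toy_genome(spec: FixtureSpec) -> tuple[list[Contig], list[GeneModel]]:
    """Build the toy genome: one gene per contig with intergenic padding.

    With ``include_paper_fixtures`` the first five genes are the named
    fixture genes (all on the plus strand, so their documented coordinates
    read left to right); remaining genes are randomized under the seed, on
    either strand.
    """
    rng = np.random.default_rng(spec.seed)
    locals_: list[tuple[_LocalGene, str]] = []
    if spec.include_paper_fixtures:
        for key in PAPER_FIXTURES:
            locals_.append((_build_fixture_gene(rng, key), "+"))
    n_random = spec.n_genes - len(locals_)
    for i in range(n_random):
        strand = "+" if rng.random() < 0.5 else "-"
        locals_.append((_build_random_gene(rng, spec, f"g{i:03d}"), strand))

    contigs, models = [], []
    for lg, strand in locals_:
        pad_l = int(rng.integers(60, 121))
        pad_r = int(rng.integers(60, 121))
        body = lg.seq if strand == "+" else revcomp(lg.seq)
        seq = _rand_seq(rng, pad_l) + body + _rand_seq(rng, pad_r)
        cid = f"ctg_{lg.gene_id}"
        contigs.append(Contig(id=cid, seq=seq))
        n = len(lg.seq)
        exons = []
        for s, e in lg.exons:  # local fwd coords, transcription order
            if strand == "+":
                exons.append((pad_l + s, pad_l + e))
            else:
                exons.append((pad_l + n - e, pad_l + n - s))
        models.append(
            GeneModel(
                gene_id=lg.gene_id,
                contig_id=cid,
                strand=strand,
                exons=exons,
                cds_span=lg.cds_span,
                name=lg.name,
            )
        )
    return contigs, models


def fixture_event(gene: GeneModel, sample_id: str = "") -> ASEvent:
    """The documented splicing event of a named fixture gene."""
    if gene.gene_id not in PAPER_FIXTURES:
        raise KeyError(f"{gene.gene_id} is not a paper-mimetic fixture")
    d = PAPER_FIXTURES[gene.gene_id]
    s, e = gene.introns[d.event_intron - 1]
    if d.event_type == ASType.IR:
        coords = [(s, e)]
    else:
        # novel spliced-out interval after retaining head/tail (plus strand)
        coords = [(s + d.head, e - d.tail)]
    return ASEvent(
        gene_id=gene.gene_id,
        sample_id=sample_id,
        as_type=d.event_type,
        intron_index=d.event_intron,
        coords=coords,
        retained_head=d.head,
        retained_tail=d.tail,
    )


# ---------------------------------------------------------------------------
# Isoforms and spliced reads
# ---------------------------------------------------------------------------

def make_isoforms(
    gene: GeneModel, contig: Contig, events: Sequence[ASEvent]
) -> list[Isoform]:
    """Normal spliced isoform plus one variant isoform per event."""
    out = [
        Isoform(
            gene.gene_id,
            "normal",
            gene.contig_id,
            gene.strand,
            [tuple(x) for x in gene.exons],
            gene.splice(contig),
        )
    ]
    for ev in events:
        blocks = variant_blocks(gene, ev)
        label = ev.as_type.value + (
            f"@intron{ev.intron_index}" if ev.intron_index else ""
        )
        out.append(
            Isoform(
                gene.gene_id,
                label,
                gene.contig_id,
                gene.strand,
                blocks,
                splice_blocks(blocks, contig, gene.strand),
            )
        )
    return out


def _map_read(blocks: Sequence[Interval], strand: str, s: int, e: int) -> list[Interval]:
    """Genomic segments (ascending) covered by transcript interval [s, e)."""
    segs = []
    off = 0
    for bs, be in blocks:
        blen = be - bs
        lo, hi = max(s, off), min(e, off + blen)
        if lo < hi:
            if strand == "+":
                segs.append((bs + (lo - off), bs + (hi - off)))
            else:
                segs.append((be - (hi - off), be - (lo - off)))
        off += blen
    segs.sort()
    merged = [segs[0]]
    for cs, ce in segs[1:]:
        if cs == merged[-1][1]:
            merged[-1] = (merged[-1][0], ce)
        else:
            merged.append((cs, ce))
    return merged


def simulate_spliced_reads(
    mixtures: Sequence[IsoformMixture],
    models: Sequence[GeneModel],
    contigs: Sequence[Contig],
    cfg: ReadSimConfig,
) -> str:
    """Simulate spliced reads from isoform mixtures; returns SAM text.

    Read count per isoform is proportional to abundance x isoform length at
    the configured depth; starts are uniform; reads crossing spliced-out
    introns get N (skip) CIGAR operations, reads across retained sequence
    align contiguously.  Minus-strand isoforms are emitted as FLAG 16
    records whose SEQ is the forward-strand reference sequence.
    """
    model_by_id = {m.gene_id: m for m in models}
    contig_by_id = {c.id: c for c in contigs}
    rng = np.random.default_rng(cfg.seed)
    rl = cfg.read_length

    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in contigs:
        lines.append(f"@SQ\tSN:{c.id}\tLN:{len(c)}")
    lines.append("@PG\tID:asvariants\tPN:asvariants")

    n_skipped = 0
    for mix in mixtures:
        gene = model_by_id[mix.gene_id]
        contig = contig_by_id[gene.contig_id]
        events = [ev for ev, _ in mix.components if isinstance(ev, ASEvent)]
        isos = make_isoforms(gene, contig, events)
        it = iter(isos[1:])
        for comp, ab in mix.components:
            if comp == "normal":
                iso = isos[0]
            elif isinstance(comp, ASEvent):
                iso = next(it)
            else:
                raise ValueError(f"unknown mixture component {comp!r}")
            if len(iso) < rl:
                log.warning(
                    "isoform %s|%s shorter than read length; skipped",
                    iso.gene_id,
                    iso.label,
                )
                n_skipped += 1
                continue
            n_reads = int(round(ab * cfg.target_depth * len(iso) / rl))
            if n_reads == 0:
                continue
            starts = rng.integers(0, len(iso) - rl + 1, size=n_reads)
            for i, s in enumerate(starts):
                s = int(s)
                segs = _map_read(iso.blocks, iso.strand, s, s + rl)
                cigar = []
                for (s1, e1), (s2, _) in zip(segs, segs[1:]):
                    cigar.append(f"{e1 - s1}M{s2 - e1}N")
                cigar.append(f"{segs[-1][1] - segs[-1][0]}M")
                seq = "".join(contig.seq[a:b] for a, b in segs)
                if cfg.error_rate > 0:
                    seq = _add_errors(rng, seq, cfg.error_rate)
                flag = 0 if iso.strand == "+" else 16
                lines.append(
                    "\t".join(
                        [
                            f"{iso.gene_id}|{iso.label}|{i}",
                            str(flag),
                            contig.id,
                            str(segs[0][0] + 1),
                            "60",
                            "".join(cigar),
                            "*",
                            "0",
                            "0",
                            seq,
                            "*",
                            "NH:i:1",
                            f"XS:A:{iso.strand}",
                        ]
                    )
                )
    if n_skipped:
        log.warning("%d isoforms skipped (shorter than read length)", n_skipped)
    return "\n".join(lines) + "\n"


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        arr[i] = rng.choice([b for b in _BASES if b != arr[i]])
    return "".join(arr)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def simulate_kinetics(p: KineticsParams) -> KineticsDataset:
    """Initial-rate data v = kcat*E0*S/(Km+S) with multiplicative noise.

    Each rate is scaled by (1 + eps), eps ~ Normal(0, noise_cv^2); the
    replicate column indexes independent noise draws on the same grid.
    """
    rng = np.random.default_rng(p.seed)
    rows = []
    for rep in range(1, p.n_replicates + 1):
        v0 = p.kcat * p.e0 * p.s_grid / (p.km + p.s_grid)
        eps = rng.normal(0.0, p.noise_cv, size=p.s_grid.size) if p.noise_cv > 0 else 0.0
        v = v0 * (1.0 + eps)
        for s, vi in zip(p.s_grid, np.atleast_1d(v)):
            rows.append({"S": float(s), "v": float(vi), "replicate": rep})
    return KineticsDataset(data=pd.DataFrame(rows), e0=p.e0)
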