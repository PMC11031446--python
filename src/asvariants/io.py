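"""Readers and writers: FASTA genomes, GFF3 gene models, report tables.

GFF3 uses 1-based inclusive coordinates; everything internal is 0-based
half-open, converted here at the boundary.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AS_TYPE_ORDER, ASEvent, ASType, Contig, GeneModel


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> list[Contig]:
    """Read a genome FASTA into Contig records (upper-cased; U rejected)."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}:{lineno}: expected FASTA header '>', got {line[:30]!r}"
                    )
                break
        else:
            raise ParseError(f"{path}: empty FASTA")
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise ParseError(f"{path}: record {rec.id} contains U (RNA not accepted)")
        contigs.append(Contig(id=rec.id, seq=seq))
    return contigs


def write_genome(contigs: Iterable[Contig], path: str | Path) -> None:
    recs = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS models from GFF3 (one mRNA per gene).

    Exons are reordered into transcription order; CDS genomic intervals are
    mapped into spliced-transcript coordinates.  A gene without CDS rows is
    kept with ``cds_span=None`` (non-coding flag).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if len(mrnas) != 1:
            raise ParseError(
                f"gene {gene.id}: expected exactly one mRNA, found {len(mrnas)}"
            )
        mrna = mrnas[0]
        strand = gene.strand
        if strand not in "+-":
            raise ParseError(f"gene {gene.id}: missing strand")
        exons = [
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        ]
        if not exons:
            raise ParseError(f"gene {gene.id}: mRNA has no exons")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ParseError(f"gene {gene.id}: overlapping exons in one mRNA")
        if strand == "-":
            exons = exons[::-1]
        cds = [
            (f.start - 1, f.end)
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        cds_span = _cds_to_transcript_span(exons, cds, strand, gene.id) if cds else None
        name = gene.attributes.get("Name", [gene.id])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                strand=strand,
                exons=exons,
                cds_span=cds_span,
                name=name,
            )
        )
    return models


def _cds_to_transcript_span(
    exons: list[tuple[int, int]],
    cds: list[tuple[int, int]],
    strand: str,
    gene_id: str,
) -> tuple[int, int]:
    g_start = min(s for s, _ in cds)
    g_end = max(e for _, e in cds)
    t5 = _genomic_to_transcript(exons, strand, g_end - 1 if strand == "-" else g_start)
    t3 = _genomic_to_transcript(exons, strand, g_start if strand == "-" else g_end - 1)
    if t5 is None or t3 is None:
        raise ParseError(f"gene {gene_id}: CDS not contained in exons")
    return (t5, t3 + 1)


def _genomic_to_transcript(
    exons: list[tuple[int, int]], strand: str, gpos: int
) -> Optional[int]:
    off = 0
    for s, e in exons:
        if s <= gpos < e:
            return off + (gpos - s if strand == "+" else e - 1 - gpos)
        off += e - s
    return None


def write_annotation(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models as GFF3 (gene/mRNA/exon/CDS rows, correct CDS phase)."""
    lines = ["##gff-version 3"]
    for g in models:
        span_s, span_e = g.span
        base = f"{g.contig_id}\tasvariants\t"
        common = f"\t{span_s + 1}\t{span_e}\t.\t{g.strand}\t.\t"
        lines.append(base + "gene" + common + f"ID={g.gene_id};Name={g.name or g.gene_id}")
        mid = f"{g.gene_id}.t1"
        lines.append(base + "mRNA" + common + f"ID={mid};Parent={g.gene_id}")
        for i, (s, e) in enumerate(sorted(g.exons), start=1):
            lines.append(
                base
                + f"exon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                + f"ID={mid}.exon{i};Parent={mid}"
            )
        if g.cds_span is not None:
            for s, e, phase in _cds_genomic_pieces(g):
                lines.append(
                    base
                    + f"CDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                    + f"ID={mid}.cds;Parent={mid}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _cds_genomic_pieces(g: GeneModel) -> list[tuple[int, int, int]]:
    """CDS pieces as (genomic start, end, phase), genomically sorted."""
    cs, ce = g.cds_span
    pieces = []  # transcription order
    off = 0
    done = 0
    for s, e in g.exons:
        length = e - s
        lo, hi = max(cs, off), min(ce, off + length)
        if lo < hi:
            phase = (3 - done % 3) % 3
            if g.strand == "+":
                pieces.append((s + (lo - off), s + (hi - off), phase))
            else:
                pieces.append((e - (hi - off), e - (lo - off), phase))
            done += hi - lo
        off += length
    return sorted(pieces)


# ---------------------------------------------------------------------------
# Aggregated events table ("Table 1" shape)
# ---------------------------------------------------------------------------

def format_type_set(types: set[ASType]) -> str:
    """Render a cell: '-' for none, '/'-joined in taxonomy order otherwise."""
    if not types:
        return "-"
    return "/".join(t.value for t in sorted(types, key=AS_TYPE_ORDER.__getitem__))


def write_events_table(
    cells: Mapping[tuple[str, str], set[ASType]],
    group_order: Sequence[str],
    gene_order: Optional[Sequence[str]] = None,
    gene_names: Optional[Mapping[str, str]] = None,
    path: Optional[str | Path] = None,
) -> str:
    """Render the per-gene x per-group AS-type report as TSV text.

    A cell holds the union of event types seen in at least one replicate of
    the group; '-' marks groups where no replicate showed any event; multiple
    types are joined with '/'.  Rows are genes sorted by id (or an explicit
    order); columns follow ``group_order``.
    """
    known = set(group_order)
    for (_, grp) in cells:
        if grp not in known:
            raise ValueError(f"unknown group label {grp!r}")
    if gene_order is None:
        gene_order = sorted({g for g, _ in cells})
    gene_names = gene_names or {}
    buf = _io.StringIO()
    buf.write("gene_id\tgene_name\t" + "\t".join(group_order) + "\n")
    for gid in gene_order:
        row = [gid, gene_names.get(gid, gid)]
        for grp in group_order:
            row.append(format_type_set(cells.get((gid, grp), set())))
        buf.write("\t".join(row) + "\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Per-sample event table and kinetics TSV
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = [
    "gene_id",
    "sample_id",
    "as_type",
    "intron_index",
    "coords",
    "retained_head",
    "retained_tail",
]


def events_to_frame(events: Sequence[ASEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "gene_id": ev.gene_id,
                "sample_id": ev.sample_id,
                "as_type": ev.as_type.value,
                "intron_index": ev.intron_index,
                "coords": ";".join(f"{s}-{e}" for s, e in ev.coords),
                "retained_head": ev.retained_head,
                "retained_tail": ev.retained_tail,
            }
        )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def events_from_frame(df: pd.DataFrame) -> list[ASEvent]:
    """Inverse of :func:`events_to_frame` (evidence columns are not kept)."""
    events = []
    for row in df.itertuples(index=False):
        coords = [
            tuple(int(x) for x in part.split("-"))
            for part in str(row.coords).split(";")
            if part
        ]
        idx = None if pd.isna(row.intron_index) else int(row.intron_index)
        events.append(
            ASEvent(
                gene_id=row.gene_id,
                sample_id=row.sample_id,
                as_type=ASType(row.as_type),
                intron_index=idx,
                coords=coords,
                retained_head=int(row.retained_head),
                retained_tail=int(row.retained_tail),
            )
        )
    return events


def read_rates(path: str | Path) -> pd.DataFrame:
    """Read a kinetics TSV with columns S (mg/mL), v (rate), replicate."""
    df = pd.read_csv(path, sep="\t")
    missing = {"S", "v"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
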