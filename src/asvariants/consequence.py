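"""Protein-level consequences of splicing events.

Variant transcripts are reconstructed from the gene model and the event,
the open reading frame is re-translated with the standard nuclear genetic
code, and the outcome is classified: silent, in-frame insertion (retained
length a codon multiple, no new stop), in-frame PTC (a stop inside the
retained in-frame segment), frameshift PTC (retained length not a codon
multiple), or in-frame deletion (frame-preserving exon skipping).

Premature-stop positions are reported 1-based from the initiator
methionine ("termination at the Nth aa"); protein lengths exclude the
stop codon.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .models import (
    ASEvent,
    ASType,
    Category,
    ConsequenceRecord,
    Contig,
    GeneModel,
    splice_blocks,
    variant_blocks,
)

_STOPS = set(standard_dna_table.stop_codons)


class Translation(NamedTuple):
    protein: str
    terminated: bool


def translate_cds(cds: str) -> Translation:
    """Standard-code translation up to (excluding) the first stop codon.

    ``terminated`` is False when the sequence runs out before any stop.
    Ambiguous bases inside a translated codon are an error.
    """
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    cds = cds.upper()
    usable = cds[: len(cds) - len(cds) % 3]
    aa = str(Seq(usable).translate())
    stop = aa.find("*")
    protein = aa if stop == -1 else aa[:stop]
    checked = usable[: (len(protein) + 1) * 3]
    if "N" in checked:
        raise ValueError("ambiguous base (N) within translated codons")
    return Translation(protein, stop != -1)


def reconstruct_variant(gene: GeneModel, contig: Contig, event: ASEvent) -> str:
    """Variant transcript DNA (5'->3'), orientation-correct for both strands."""
    return splice_blocks(variant_blocks(gene, event), contig, gene.strand)


def _event_transcript_position(gene: GeneModel, event: ASEvent) -> int:
    """Transcript coordinate where the variant first diverges from normal."""
    offs = gene.exon_offsets()
    t = event.as_type
    if t in (ASType.IR, ASType.A5SS, ASType.A3SS, ASType.A5SS_A3SS, ASType.CASSETTE):
        # insertion point at the end of the upstream exon
        if event.intron_index is not None:
            k = event.intron_index - 1
        else:  # cassette located by its intron interval
            k = next(
                i
                for i, (s, e) in enumerate(gene.introns)
                if s <= event.coords[0][0] and event.coords[0][1] <= e
            )
        return offs[k] + (gene.exons[k][1] - gene.exons[k][0])
    if t in (ASType.ES, ASType.A5SS_ES, ASType.A3SS_ES):
        skipped = set(map(tuple, event.coords))
        for i, x in enumerate(gene.exons):
            if tuple(x) in skipped:
                return offs[i]
        raise ValueError(f"{gene.gene_id}: ES coords match no exon")
    raise ValueError(f"unsupported event type for consequence: {t.value}")


def predict_consequence(
    gene: GeneModel, contig: Contig, event: ASEvent
) -> ConsequenceRecord:
    """Translate normal and variant ORFs and classify the outcome."""
    if gene.cds_span is None:
        raise ValueError(f"{gene.gene_id}: gene has no CDS")
    cds_start, cds_end = gene.cds_span
    normal_tx = gene.splice(contig)
    variant_tx = reconstruct_variant(gene, contig, event)
    delta = len(variant_tx) - len(normal_tx)
    normal = translate_cds(normal_tx[cds_start:cds_end])

    if delta == 0 and variant_tx == normal_tx:
        return ConsequenceRecord(
            gene_id=gene.gene_id,
            as_type=event.as_type,
            category=Category.SILENT,
            normal_protein_len=len(normal.protein),
            variant_protein_len=len(normal.protein),
        )

    pos = _event_transcript_position(gene, event)
    utr_only = (delta > 0 and (pos <= cds_start or pos >= cds_end)) or (
        delta < 0 and (pos + (-delta) <= cds_start or pos >= cds_end)
    )
    if utr_only:
        return ConsequenceRecord(
            gene_id=gene.gene_id,
            as_type=event.as_type,
            category=Category.SILENT,
            normal_protein_len=len(normal.protein),
            variant_protein_len=len(normal.protein),
            utr_only=True,
        )
    if delta < 0 and pos < cds_start:
        raise ValueError(f"{gene.gene_id}: event removes the start codon")

    # at this point the event lies within (or downstream into) the CDS, so
    # the start codon keeps its transcript coordinate
    variant = translate_cds(variant_tx[cds_start:])
    if not variant.terminated:
        raise ValueError(
            f"{gene.gene_id}: variant open reading frame has no stop codon"
        )
    return _classify(gene, event, normal.protein, variant.protein, delta)


def _classify(
    gene: GeneModel,
    event: ASEvent,
    normal: str,
    variant: str,
    delta: int,
) -> ConsequenceRecord:
    base = dict(
        gene_id=gene.gene_id,
        as_type=event.as_type,
        normal_protein_len=len(normal),
        variant_protein_len=len(variant),
    )
    if variant == normal:
        return ConsequenceRecord(category=Category.SILENT, **base)
    in_frame = delta % 3 == 0
    if len(variant) < len(normal):
        cat = Category.IN_FRAME_PTC if in_frame else Category.FRAMESHIFT_PTC
        if in_frame and delta < 0 and _is_contiguous_edit(normal, variant):
            return ConsequenceRecord(category=Category.IN_FRAME_DELETION, **base)
        return ConsequenceRecord(
            category=cat, ptc_aa_position=len(variant) + 1, **base
        )
    if in_frame and len(variant) > len(normal):
        # contiguous insertion; the junction codon may be recoded, which
        # still reads as an in-frame insertion at the protein level
        return ConsequenceRecord(
            category=Category.IN_FRAME_INSERTION,
            inserted_aa=len(variant) - len(normal),
            **base,
        )
    if not in_frame:
        # frameshift that happens to terminate at/after the normal length
        return ConsequenceRecord(
            category=Category.FRAMESHIFT_PTC, ptc_aa_position=len(variant) + 1, **base
        )
    # same length, different sequence: substitution-only edit
    return ConsequenceRecord(category=Category.SILENT, **base)


def _is_contiguous_edit(longer: str, shorter: str) -> bool:
    """True if ``shorter`` equals ``longer`` minus one contiguous block."""
    k = 0
    while k < len(shorter) and longer[k] == shorter[k]:
        k += 1
    gap = len(longer) - len(shorter)
    return longer[k + gap :] == shorter[k:]


# ---------------------------------------------------------------------------
# Report ("Table 2" shape)
# ---------------------------------------------------------------------------

def _ordinal(n: int) -> str:
    if 11 <= n % 100 <= 13:
        return f"{n}th"
    return f"{n}{ {1: 'st', 2: 'nd', 3: 'rd'}.get(n % 10, 'th') }"


def format_product(rec: ConsequenceRecord) -> str:
    if rec.category in (Category.FRAMESHIFT_PTC, Category.IN_FRAME_PTC):
        return f"Termination at the {_ordinal(rec.ptc_aa_position)} aa"
    return f"{rec.variant_protein_len} aa"


def consequence_table(records: Sequence[ConsequenceRecord], gene_names=None) -> pd.DataFrame:
    """Putative translational products of AS variants, one row per event."""
    gene_names = gene_names or {}
    rows = []
    for r in records:
        rows.append(
            {
                "gene": gene_names.get(r.gene_id, r.gene_id),
                "as_type": r.as_type.value,
                "normal_product": f"{r.normal_protein_len} aa",
                "variant_product": format_product(r),
                "category": r.category.value,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "as_type", "normal_product", "variant_product", "category"]
    )
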