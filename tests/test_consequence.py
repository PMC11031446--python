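"""Variant reconstruction, translation, and consequence classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from asvariants import simulate as sim
from asvariants.consequence import (
    predict_consequence,
    reconstruct_variant,
    translate_cds,
)
from asvariants.models import (
    ASEvent,
    ASType,
    Category,
    Contig,
    GeneModel,
    revcomp,
)
from asvariants.simulate import _frame_safe_intron, _plain_intron, _rand_cds, _rand_seq

_STOPS = {"TAA", "TAG", "TGA"}
_CODE = None


def _oracle_translate(cds: str) -> tuple[str, bool]:
    """Linear codon scan with an explicit codon table (independent path)."""
    global _CODE
    if _CODE is None:
        from Bio.Data.CodonTable import standard_dna_table

        _CODE = dict(standard_dna_table.forward_table)
    out = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            return "".join(out), True
        out.append(_CODE[codon])
    return "".join(out), False


def _oracle_ir_variant(gene: GeneModel, contig: Contig, intron_index: int) -> str:
    """Rebuild the IR transcript by direct string surgery on the genome."""
    gs, ge = gene.span
    if gene.strand == "+":
        seq = contig.seq[gs:ge]
        exons = [(s - gs, e - gs) for s, e in gene.exons]
    else:
        seq = revcomp(contig.seq[gs:ge])
        exons = [(ge - e, ge - s) for s, e in gene.exons]
    parts = []
    for i, (s, e) in enumerate(exons):
        parts.append(seq[s:e])
        if i == intron_index - 1:
            parts.append(seq[e : exons[i + 1][0]])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def test_two_codon_translation():
    assert translate_cds("ATGAAATAG") == ("MK", True)


def test_internal_stop_truncates():
    assert translate_cds("ATGTAAAAAAAA").protein == "M"


def test_missing_stop_flagged():
    assert translate_cds("ATGAAAAAA") == ("MKK", False)


def test_ambiguous_base_in_translated_codon_rejected():
    with pytest.raises(ValueError, match="ambiguous"):
        translate_cds("ATGNNNTAG")
    # N after the stop codon is never translated, so it is acceptable
    assert translate_cds("ATGTAANNN").protein == "M"


def test_fixture_cds_translates_to_319_aa(models_by_id, contigs_by_id):
    g = models_by_id["xynF1_like"]
    cds = g.cds_sequence(contigs_by_id[g.contig_id])
    assert len(cds) == 960  # 319 aa + stop
    assert len(translate_cds(cds).protein) == 319


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def test_ir_reconstruction_inserts_intron_in_place(models_by_id, contigs_by_id):
    g = models_by_id["eglD_like"]
    c = contigs_by_id[g.contig_id]
    var = reconstruct_variant(g, c, sim.fixture_event(g))
    assert var == _oracle_ir_variant(g, c, 1)


def test_empty_splice_site_event_reproduces_normal(models_by_id, contigs_by_id):
    g = models_by_id["g000"]
    c = contigs_by_id[g.contig_id]
    s, e = g.introns[0]
    noop = ASEvent(
        g.gene_id, "s", ASType.A5SS_A3SS, intron_index=1, coords=[(s, e)],
        retained_head=0, retained_tail=0,
    )
    assert reconstruct_variant(g, c, noop) == g.splice(c)
    rec = predict_consequence(g, c, noop)
    assert rec.category == Category.SILENT and not rec.utr_only


def test_unsupported_event_type_rejected(models_by_id, contigs_by_id):
    g = models_by_id["g000"]
    ev = ASEvent(g.gene_id, "s", ASType.MXE, coords=[g.exons[0]])
    with pytest.raises(ValueError, match="unsupported"):
        reconstruct_variant(g, contigs_by_id[g.contig_id], ev)


def test_event_outside_gene_rejected(models_by_id, contigs_by_id):
    g = models_by_id["g000"]
    ev = ASEvent(g.gene_id, "s", ASType.IR, intron_index=g.n_introns + 3,
                 coords=[(0, 10)])
    with pytest.raises(ValueError, match="out of range"):
        reconstruct_variant(g, contigs_by_id[g.contig_id], ev)


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

def test_utr_intron_retention_is_silent():
    # 5' UTR exon split by an intron upstream of the CDS
    rng = np.random.default_rng(4)
    utr_a, utr_b = _rand_seq(rng, 20), _rand_seq(rng, 10)
    cds = _rand_cds(rng, 50)
    intron = _plain_intron(rng, 40)
    seq = utr_a + intron + utr_b + cds
    contig = Contig("c", seq)
    gene = GeneModel(
        "g", "c", "+",
        exons=[(0, 20), (60, len(seq))],
        cds_span=(30, 30 + len(cds)),
    )
    ev = ASEvent("g", "s", ASType.IR, intron_index=1, coords=[gene.introns[0]])
    rec = predict_consequence(gene, contig, ev)
    assert rec.category == Category.SILENT and rec.utr_only


def test_frame_preserving_exon_skip_is_in_frame_deletion():
    rng = np.random.default_rng(8)
    cds = _rand_cds(rng, 90)  # 273 nt incl. stop
    utr5 = _rand_seq(rng, 15)
    tx = utr5 + cds + _rand_seq(rng, 15)
    # exon boundaries at codon boundaries inside the CDS: middle exon 60 nt
    b1, b2 = 15 + 90, 15 + 150
    i1, i2 = _plain_intron(rng, 50), _plain_intron(rng, 50)
    seq = tx[:b1] + i1 + tx[b1:b2] + i2 + tx[b2:]
    contig = Contig("c", seq)
    gene = GeneModel(
        "g", "c", "+",
        exons=[(0, b1), (b1 + 50, b2 + 50), (b2 + 100, len(seq))],
        cds_span=(15, 15 + len(cds)),
    )
    ev = ASEvent("g", "s", ASType.ES, coords=[gene.exons[1]])
    rec = predict_consequence(gene, contig, ev)
    assert rec.category == Category.IN_FRAME_DELETION
    assert rec.variant_protein_len == rec.normal_protein_len - 20


def test_ir_consequences_match_independent_oracle():
    """Category and PTC position agree with direct string-surgery
    reconstruction plus a linear codon scan, over random genes on both
    strands and every intron."""
    spec = sim.FixtureSpec(n_genes=30, include_paper_fixtures=False, seed=123)
    contigs, models = sim.make_toy_genome(spec)
    cbyid = {c.id: c for c in contigs}
    n_checked = 0
    for g in models:
        c = cbyid[g.contig_id]
        normal_aa, _ = _oracle_translate(g.cds_sequence(c))
        for k in range(1, g.n_introns + 1):
            ev = ASEvent(g.gene_id, "s", ASType.IR, intron_index=k,
                         coords=[g.introns[k - 1]])
            oracle_tx = _oracle_ir_variant(g, c, k)
            oracle_aa, oracle_term = _oracle_translate(oracle_tx[g.cds_span[0] :])
            if not oracle_term:
                with pytest.raises(ValueError, match="stop"):
                    predict_consequence(g, c, ev)
                continue
            rec = predict_consequence(g, c, ev)
            assert rec.variant_protein_len == len(oracle_aa)
            assert rec.normal_protein_len == len(normal_aa)
            delta = len(oracle_tx) - g.transcript_length
            if delta % 3 != 0:
                assert rec.category == Category.FRAMESHIFT_PTC
                assert rec.ptc_aa_position == len(oracle_aa) + 1
            elif len(oracle_aa) < len(normal_aa):
                assert rec.category == Category.IN_FRAME_PTC
                assert rec.ptc_aa_position == len(oracle_aa) + 1
            else:
                assert rec.category == Category.IN_FRAME_INSERTION
                assert rec.inserted_aa == len(oracle_aa) - len(normal_aa)
            n_checked += 1
    assert n_checked >= 50


# ---------------------------------------------------------------------------
# Frame arithmetic (property)
# ---------------------------------------------------------------------------

def _minigene_with_intron(seed: int, intron_len: int, codon_pos: int):
    rng = np.random.default_rng(seed)
    cds = _rand_cds(rng, 60)
    utr5, utr3 = _rand_seq(rng, 12), _rand_seq(rng, 12)
    tx = utr5 + cds + utr3
    cut = 12 + 3 * codon_pos
    intron = (
        _frame_safe_intron(rng, intron_len)
        if intron_len % 3 == 0
        else _plain_intron(rng, intron_len)
    )
    seq = tx[:cut] + intron + tx[cut:]
    contig = Contig("c", seq)
    gene = GeneModel(
        "g", "c", "+",
        exons=[(0, cut), (cut + intron_len, len(seq))],
        cds_span=(12, 12 + len(cds)),
    )
    return gene, contig


@given(
    intron_len=st.integers(min_value=21, max_value=72),
    codon_pos=st.integers(min_value=2, max_value=58),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_retained_length_frame_arithmetic(intron_len, codon_pos, seed):
    gene, contig = _minigene_with_intron(seed, intron_len, codon_pos)
    ev = ASEvent("g", "s", ASType.IR, intron_index=1, coords=[gene.introns[0]])
    if intron_len % 3 == 0:
        rec = predict_consequence(gene, contig, ev)
        assert rec.category == Category.IN_FRAME_INSERTION
        assert rec.inserted_aa == intron_len // 3
        assert rec.variant_protein_len - rec.normal_protein_len == rec.inserted_aa
    else:
        try:
            rec = predict_consequence(gene, contig, ev)
        except ValueError:
            return  # frameshifted ORF ran off the transcript without a stop
        assert rec.category != Category.IN_FRAME_INSERTION
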