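"""Junction extraction, AS-type classification, IR criteria, aggregation."""

from __future__ import annotations

import pytest

from asvariants import detect, simulate as sim
from asvariants.detect import (
    AlignmentEvidence,
    aggregate_replicates,
    call_intron_retention,
    classify_junctions,
    evaluate_ir_criteria,
)
from asvariants.models import (
    ASEvent,
    ASType,
    GeneModel,
    IRCriteriaConfig,
    IREvidence,
    Junction,
)

from conftest import sam_from_reads, write_sam

# three-exon plus-strand gene: exons 0-100, 200-300, 400-500
GENE3 = GeneModel("g3", "c", "+", exons=[(0, 100), (200, 300), (400, 500)])
GENE3_MINUS = GeneModel("g3m", "c", "-", exons=[(400, 500), (200, 300), (0, 100)])
GENE4 = GeneModel(
    "g4", "c", "+", exons=[(0, 100), (150, 200), (250, 300), (350, 450)]
)


# ---------------------------------------------------------------------------
# SAM parsing: junctions and depth
# ---------------------------------------------------------------------------

def test_gapped_read_yields_one_junction(tmp_path):
    text = sam_from_reads([("r1", 0, "c", 51, "50M100N50M")])
    junctions = detect.extract_junctions(write_sam(tmp_path, text))
    assert junctions == [Junction("c", 100, 200, ".", 1)]


def test_ungapped_read_yields_no_junction_and_unit_depth(tmp_path):
    text = sam_from_reads([("r1", 0, "c", 11, "100M")])
    path = write_sam(tmp_path, text)
    assert detect.extract_junctions(path) == []
    depth = detect.compute_depth(path)
    assert depth.total("c", 10, 110) == 100
    assert depth.total("c", 0, 600) == 100


def test_short_anchor_reads_are_not_counted(tmp_path):
    text = sam_from_reads(
        [
            ("ok", 0, "c", 51, "50M100N50M"),
            ("short", 0, "c", 98, "3M100N97M"),
        ]
    )
    junctions = detect.extract_junctions(write_sam(tmp_path, text), anchor=6)
    assert [j.read_count for j in junctions] == [1]


def test_gapped_read_depth_skips_intron(tmp_path):
    text = sam_from_reads([("r1", 0, "c", 51, "50M141N50M")])
    depth = detect.compute_depth(write_sam(tmp_path, text))
    assert depth.total("c", 50, 100) == 50
    assert depth.total("c", 100, 241) == 0
    assert depth.total("c", 241, 291) == 50


def test_empty_sam_gives_zero_profile(tmp_path):
    depth = detect.compute_depth(write_sam(tmp_path, sam_from_reads([])))
    assert depth.mass() == 0


def test_malformed_lines_skipped_with_warning(tmp_path, caplog):
    text = sam_from_reads([("r1", 0, "c", 11, "100M")])
    text += "this is not\ta sam line\n"
    with caplog.at_level("WARNING"):
        ev = AlignmentEvidence.from_sam(write_sam(tmp_path, text))
    assert ev.n_malformed == 1
    assert "malformed" in caplog.text
    assert ev.depth.mass() == 100


# ---------------------------------------------------------------------------
# Junction classification
# ---------------------------------------------------------------------------

def _j(start, end, count=5):
    return Junction("c", start, end, "+", count)


def test_annotated_junction_produces_no_event():
    assert classify_junctions([_j(100, 200)], [GENE3]) == []


def test_exon_skipping_from_donor1_to_acceptor2():
    events = classify_junctions([_j(100, 400)], [GENE3])
    assert [e.as_type for e in events] == [ASType.ES]
    assert events[0].coords == [(200, 300)]


def test_alternative_splice_sites_plus_strand():
    # donor matches, acceptor shifted into the intron -> A3SS
    (a3,) = classify_junctions([_j(100, 180)], [GENE3])
    assert a3.as_type == ASType.A3SS and a3.retained_tail == 20
    # acceptor matches, donor shifted -> A5SS
    (a5,) = classify_junctions([_j(122, 200)], [GENE3])
    assert a5.as_type == ASType.A5SS and a5.retained_head == 22
    # both shifted within one intron -> A5SS&A3SS
    (both,) = classify_junctions([_j(122, 198)], [GENE3])
    assert both.as_type == ASType.A5SS_A3SS
    assert (both.retained_head, both.retained_tail) == (22, 2)
    assert both.intron_index == 1


def test_alternative_splice_sites_minus_strand_mirror():
    # on the minus strand the donor is the genomically rightmost intron end
    (ev,) = classify_junctions([_j(100, 180)], [GENE3_MINUS])
    assert ev.as_type == ASType.A5SS
    assert ev.retained_head == 20 and ev.retained_tail == 0
    assert ev.intron_index == 2  # transcription order counts from the right


def test_combined_splice_site_and_exon_skipping():
    (ev,) = classify_junctions([_j(122, 400)], [GENE3])
    assert ev.as_type == ASType.A5SS_ES


def test_cassette_exon_inside_annotated_intron():
    events = classify_junctions([_j(100, 130), _j(160, 200)], [GENE3])
    assert [e.as_type for e in events] == [ASType.CASSETTE]
    assert events[0].coords == [(130, 160)]


def test_mutually_exclusive_exons_fold_from_es_pair():
    # skip exon 2 (junction intron1->intron2) and skip exon 3 (intron2->intron3)
    events = classify_junctions([_j(100, 250), _j(200, 350)], [GENE4])
    assert [e.as_type for e in events] == [ASType.MXE]


def test_terminal_mxe_typing_by_transcript_end():
    from asvariants.detect import _mxe_type

    assert _mxe_type(GENE4, {0}, {1}) == ASType.MXE_5P
    assert _mxe_type(GENE4, {2}, {3}) == ASType.MXE_3P
    assert _mxe_type(GENE4, {1}, {2}) == ASType.MXE


def test_intergenic_junction_ignored():
    assert classify_junctions([Junction("other", 10, 60, ".", 3)], [GENE3]) == []


def test_junction_read_threshold():
    assert classify_junctions([_j(122, 198, count=1)], [GENE3], min_junction_reads=2) == []


# ---------------------------------------------------------------------------
# IR criteria
# ---------------------------------------------------------------------------

CFG = IRCriteriaConfig()


def _evidence(mean_intron=10.0, flank=40.0, cum=1000.0, b5=3, b3=0):
    return IREvidence(
        mean_intron_depth=mean_intron,
        mean_flank_exon_depth=flank,
        cumulative_intron_depth=cum,
        boundary_reads_5p=b5,
        boundary_reads_3p=b3,
    )


def test_all_criteria_pass_for_well_supported_intron():
    res = evaluate_ir_criteria(_evidence(), has_other_event=False, cfg=CFG)
    assert res.passed


def test_each_criterion_is_load_bearing():
    failures = {
        "depth_ratio": _evidence(mean_intron=4.0, flank=40.0),  # ratio 0.10
        "cumulative_depth": _evidence(cum=80.0),
        "boundary": _evidence(b5=0, b3=0),
    }
    for name, ev in failures.items():
        res = evaluate_ir_criteria(ev, has_other_event=False, cfg=CFG)
        assert not res.passed
        assert res.criteria[name] is False
        others = {k: v for k, v in res.criteria.items() if k != name}
        assert all(others.values())
    res = evaluate_ir_criteria(_evidence(), has_other_event=True, cfg=CFG)
    assert not res.passed and res.criteria["exclusive"] is False


def test_boundary_reads_spanning_requires_anchor(tmp_path):
    # contiguous read across the exon/intron boundary at 100
    text = sam_from_reads(
        [
            ("span", 0, "c", 95, "20M"),  # 6 nt each side of 100
            ("touch", 0, "c", 98, "20M"),  # only 3 nt on the left
        ]
    )
    ev = AlignmentEvidence.from_sam(write_sam(tmp_path, text))
    assert ev.boundary_reads("c", 100, anchor=6) == 1


def test_ir_called_end_to_end_and_vetoed_by_other_event(tmp_path):
    # uniform contiguous coverage over exon1-intron1-exon2 of GENE3
    reads = [(f"r{i}", 0, "c", 1 + i, "100M") for i in range(0, 201, 2)]
    ev = AlignmentEvidence.from_sam(write_sam(tmp_path, sam_from_reads(reads)))
    calls = call_intron_retention([GENE3], ev, [], CFG, sample_id="s")
    assert [(c.intron_index, c.as_type) for c in calls] == [(1, ASType.IR)]
    ire = calls[0].evidence
    assert ire.cumulative_intron_depth == pytest.approx(
        ire.mean_intron_depth * 100, rel=1e-12
    )
    # a co-located alternative splice site vetoes the IR call
    other = ASEvent("g3", "s", ASType.A5SS, intron_index=1, coords=[(122, 200)])
    assert call_intron_retention([GENE3], ev, [other], CFG) == []


def test_ir_monotone_in_variant_abundance(tmp_path, toy_genome, models_by_id):
    contigs, models = toy_genome
    g = models_by_id["eglD_like"]
    called = {}
    for ab in (0.1, 0.5):
        mixes = []
        for m in models:
            comps = [("normal", 1.0)]
            if m.gene_id == g.gene_id:
                comps = [("normal", 1 - ab), (sim.fixture_event(m), ab)]
            mixes.append(sim.IsoformMixture(m.gene_id, comps))
        text = sim.simulate_spliced_reads(
            mixes, models, contigs, sim.ReadSimConfig(target_depth=120, seed=21)
        )
        p = write_sam(tmp_path, text, name=f"ab{ab}.sam")
        events = detect.detect_sample(p, models, sample_id="s")
        called[ab] = {
            (e.gene_id, e.intron_index) for e in events if e.as_type == ASType.IR
        }
    assert called[0.1] <= called[0.5]
    assert (g.gene_id, 1) in called[0.5]


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

GROUPS = {"WS1": "WS", "WS2": "WS", "WS3": "WS", "G1": "G"}


def test_single_replicate_event_reported_for_group():
    events = [ASEvent("gA", "WS1", ASType.IR, intron_index=1, coords=[(0, 10)])]
    cells = aggregate_replicates(events, GROUPS)
    assert cells == {("gA", "WS"): {ASType.IR}}


def test_disagreeing_replicates_union():
    events = [
        ASEvent("gA", "WS1", ASType.ES, coords=[(0, 10)]),
        ASEvent("gA", "WS2", ASType.IR, intron_index=1, coords=[(0, 10)]),
    ]
    cells = aggregate_replicates(events, GROUPS)
    assert cells[("gA", "WS")] == {ASType.ES, ASType.IR}


def test_sample_without_group_is_an_error():
    events = [ASEvent("gA", "XX9", ASType.IR, intron_index=1, coords=[(0, 10)])]
    with pytest.raises(ValueError, match="group"):
        aggregate_replicates(events, GROUPS)
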