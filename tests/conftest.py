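from __future__ import annotations

import pytest
from hypothesis import settings

from asvariants import simulate as sim

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome():
    """Toy genome with the five paper-mimetic fixture genes plus randoms."""
    spec = sim.FixtureSpec(n_genes=8, include_paper_fixtures=True, seed=7)
    contigs, models = sim.make_toy_genome(spec)
    return contigs, models


@pytest.fixture(scope="session")
def models_by_id(toy_genome):
    _, models = toy_genome
    return {m.gene_id: m for m in models}


@pytest.fixture(scope="session")
def contigs_by_id(toy_genome):
    contigs, _ = toy_genome
    return {c.id: c for c in contigs}


def write_sam(tmp_path, text, name="reads.sam"):
    p = tmp_path / name
    p.write_text(text)
    return p


def sam_from_reads(reads, contigs=None):
    """Hand-crafted SAM text. ``reads`` are (name, flag, rname, pos1, cigar)."""
    contigs = contigs or {"c": 600}
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for cid, ln in contigs.items():
        lines.append(f"@SQ\tSN:{cid}\tLN:{ln}")
    for name, flag, rname, pos1, cigar in reads:
        qlen = _query_length(cigar)
        lines.append(
            "\t".join(
                [name, str(flag), rname, str(pos1), "60", cigar, "*", "0", "0",
                 "A" * qlen, "*"]
            )
        )
    return "\n".join(lines) + "\n"


def _query_length(cigar):
    import re

    qlen = 0
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        if op in "MIS=X":
            qlen += int(length)
    return qlen
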