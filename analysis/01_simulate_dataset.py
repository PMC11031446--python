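#!/usr/bin/env python
"""Simulate the study-shaped dataset.

Builds a toy genome carrying the five fixture enzyme genes plus random
multi-intron genes, then simulates spliced reads for two culture-condition
groups (WS: wheat straw, G: glucose), three replicates each.  Splice
variants are planted group-wise the way the real genes behaved: the
xynF1-, abnC- and cbhC-mimetic events only under WS; the bglM- and
eglD-mimetic events under both conditions.

Writes results/sim/{genome.fa, genes.gff3, reads_<sample>.sam, samples.tsv}.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from asvariants import io, simulate as sim

GROUPS = {"WS": ["WS1", "WS2", "WS3"], "G": ["G1", "G2", "G3"]}
PLANTED = {
    "xynF1_like": (["WS"], 0.5),
    "abnC_like": (["WS"], 0.4),
    "cbhC_like": (["WS"], 0.4),
    "bglM_like": (["WS", "G"], 0.4),
    "eglD_like": (["WS", "G"], 0.5),
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    ap.add_argument("--n-genes", type=int, default=12)
    ap.add_argument("--depth", type=float, default=80.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = sim.FixtureSpec(n_genes=args.n_genes, seed=args.seed)
    contigs, models = sim.make_toy_genome(spec)
    io.write_genome(contigs, args.out / "genome.fa")
    io.write_annotation(models, args.out / "genes.gff3")
    print(f"toy genome: {len(contigs)} contigs, {len(models)} genes "
          f"({sum(m.n_introns for m in models)} introns)")

    rows = []
    idx = 0
    for grp, samples in GROUPS.items():
        for sample in samples:
            mixtures = []
            for m in models:
                comps = [("normal", 1.0)]
                planted = PLANTED.get(m.gene_id)
                if planted and grp in planted[0]:
                    ab = planted[1]
                    comps = [("normal", 1 - ab), (sim.fixture_event(m, sample), ab)]
                mixtures.append(sim.IsoformMixture(m.gene_id, comps))
            cfg = sim.ReadSimConfig(
                target_depth=args.depth, seed=(args.seed * 1009 + idx) % 2**31
            )
            text = sim.simulate_spliced_reads(mixtures, models, contigs, cfg)
            (args.out / f"reads_{sample}.sam").write_text(text)
            n_reads = sum(1 for l in text.splitlines() if not l.startswith("@"))
            print(f"  {sample} ({grp}): {n_reads} reads")
            rows.append(f"{sample}\t{grp}")
            idx += 1
    (args.out / "samples.tsv").write_text("sample\tgroup\n" + "\n".join(rows) + "\n")


if __name__ == "__main__":
    main()
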