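#!/usr/bin/env python
"""Predict the translational products of the detected splice variants.

Takes the per-sample events detected in step 02, deduplicates them to one
event per gene x type x intron, reconstructs each variant transcript from
the toy genome, re-translates the open reading frame and classifies the
outcome: in-frame insertion (extra amino acids) or a premature termination
codon from a frameshift or an in-frame stop.

Writes results/variant_consequences.tsv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from asvariants import consequence as cq, io


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--events-dir", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results/variant_consequences.tsv"))
    args = ap.parse_args()

    contigs = {c.id: c for c in io.read_genome(args.sim / "genome.fa")}
    models = {m.gene_id: m for m in io.read_annotation(args.sim / "genes.gff3")}

    events, seen = [], set()
    for path in sorted(args.events_dir.glob("events_*.tsv")):
        for ev in io.events_from_frame(pd.read_csv(path, sep="\t")):
            key = (ev.gene_id, ev.as_type, ev.intron_index, tuple(ev.coords))
            if key not in seen:
                seen.add(key)
                events.append(ev)

    records = []
    for ev in sorted(events, key=lambda e: e.gene_id):
        gene = models[ev.gene_id]
        records.append(cq.predict_consequence(gene, contigs[gene.contig_id], ev))
    names = {m.gene_id: m.name for m in models.values()}
    table = cq.consequence_table(records, gene_names=names)
    table.to_csv(args.out, sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
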