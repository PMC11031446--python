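# asvariants

Alternative-splicing (AS) inference for lignocellulose-degrading enzyme
genes, in the style of a bulk RNA-seq splice-variant screen in *Aspergillus
niger*: junction-based AS-type classification, a four-criterion
intron-retention caller, replicate aggregation into a gene × condition
report, protein-level consequence prediction for the variant transcripts,
and Michaelis–Menten kinetics fitting for a characterized variant enzyme.
A synthetic-data module (toy genome, fixture genes, spliced-read simulator)
makes the whole pipeline runnable and testable with no external data.

## Who this is for

Anyone who wants to detect splice variants of annotated genes from spliced
alignments (SAM) plus an annotation (GFF3), and to ask what each variant
does to the protein — extra amino acids, a frameshift, or a premature
termination codon (PTC).

## The inference

**AS taxonomy.** Unannotated splice junctions are classified per gene in
transcription orientation: a junction with the annotated donor but a
shifted acceptor is an alternative 3′ splice site (A3SS); a shifted donor
is A5SS; both shifted inside one intron is A5SS&A3SS; a junction from the
donor of intron *i* to the acceptor of intron *j* > *i* is exon skipping
(ES, with A5SS&ES / A3SS&ES when an end is also shifted); a pair of novel
junctions framing a novel exon inside an annotated intron is a cassette
exon; paired ES junctions over mutually exclusive exons give MXE
(5pMXE/3pMXE at transcript ends).

**Intron retention (IR).** An annotated intron is called retained in a
sample iff all four criteria hold:

1. mean intron base depth ≥ 20% of the mean of the two flanking exons'
   depths;
2. cumulative intron depth > 100 (strict);
3. at least one read aligned contiguously across the 5′ or the 3′
   exon–intron boundary (6 nt anchor each side);
4. no other AS event detected on that intron in that sample.

Calling is per replicate; the report marks a gene × group cell with every
type seen in ≥ 1 replicate ("`-`" for none, "`/`"-joined when replicates
disagree).

**Consequences.** Each variant transcript is reconstructed from the gene
model and re-translated: retained length ≡ 0 (mod 3) with no new stop →
in-frame insertion of `retained/3` aa; retained length ≢ 0 (mod 3) →
frameshift PTC; an in-frame stop inside the retained segment → in-frame
PTC. PTC positions are 1-based from the initiator Met; lengths exclude the
stop.

**Kinetics.** v = V<sub>max</sub>·S/(K<sub>m</sub>+S) fitted by unweighted
nonlinear least squares on untransformed rates; k<sub>cat</sub> =
V<sub>max</sub>/E₀.

## Worked example

The numbered scripts under `analysis/` run the whole study shape:

```bash
python analysis/01_simulate_dataset.py --seed 1   # toy genome + 6 samples
python analysis/02_detect_events.py               # per-replicate detection
python analysis/03_variant_consequences.py        # variant translation
python analysis/04_fit_kinetics.py --seed 1       # Michaelis-Menten fit
```

Step 02 prints the aggregated gene × condition report (WS = wheat straw,
G = glucose):

```
gene_id	gene_name	WS	G
abnC_like	abnC	IR	-
bglM_like	bglM	IR	IR
cbhC_like	cbhC	IR	-
eglD_like	eglD	IR	IR
...
xynF1_like	xynF1	A5SS&A3SS	-
```

i.e. the planted variants are recovered exactly where they were planted:
the xynF1-mimetic A5SS&A3SS event (first 22 + last 2 nt of intron 7
retained) only under WS, the eglD- and bglM-mimetic intron retentions
under both conditions. Step 03 prints what each variant does to the
protein:

```
 gene   as_type normal_product             variant_product           category
 abnC        IR         318 aa Termination at the 138th aa     frameshift_ptc
 bglM        IR         765 aa Termination at the 391st aa     frameshift_ptc
 cbhC        IR         435 aa Termination at the 150th aa       in_frame_ptc
 eglD        IR         365 aa                      412 aa in_frame_insertion
xynF1 A5SS&A3SS         319 aa                      327 aa in_frame_insertion
```

The 24 retained nucleotides of the xynF1-mimetic event add 8 amino acids
(319 → 327 aa); the 141-bp retained intron of the eglD-mimetic gene adds
47 (365 → 412 aa); the frame-breaking retentions truncate the product at a
premature stop. Step 04 recovers K<sub>m</sub> ≈ 7.41 mg mL⁻¹ and
k<sub>cat</sub> ≈ 19.51 min⁻¹ from noisy simulated rate data.

The same flow is available as a CLI (`asvariants run -c config.yaml -o
out/`, plus `detect`, `consequence`, `report`, `kinetics-fit` subcommands)
and as library calls (`asvariants.detect.detect_sample`,
`asvariants.consequence.predict_consequence`, ...).

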