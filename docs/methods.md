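# Methods

## Coordinate model

All internal coordinates are 0-based half-open genomic intervals; GFF3
(1-based inclusive) is converted at the I/O boundary. Exons of a gene model
are stored in transcription order — genomically descending for minus-strand
genes — with plus-strand coordinates plus a strand flag. All splice-site
semantics ("donor", "5′ end of the intron", retained "head"/"tail") are in
transcription orientation, so for a minus-strand gene the donor is the
genomically rightmost intron end. This keeps the event logic strand-free at
the cost of one orientation conversion per I/O operation, and eliminates
off-by-one arithmetic in intron bookkeeping. Each annotated gene carries
exactly one mRNA model; multi-isoform annotations are out of scope.

## Evidence extraction

One pass over a SAM file produces (i) junctions: distinct N-gap intervals
from primary alignments with at least `boundary_anchor_nt` (default 6)
aligned bases on each side of the gap; (ii) a per-base depth profile
counting aligned (M/=/X) bases only — skips, clips and deletions contribute
nothing; (iii) the contiguous aligned blocks of every read, used to count
reads spanning an exon–intron boundary with the same 6-nt anchor. Malformed
alignment lines are skipped and counted, not fatal. BAM/CRAM are not
supported; at toy-genome scale SAM text suffices.

## AS-type classification

Per gene, each unannotated junction with read support ≥ `min_junction_reads`
(default 1 — no junction-count threshold beyond existence, configurable for
noisier data) is matched against the annotated introns:

- both ends inside one annotated intron: donor match + shifted acceptor →
  A3SS; acceptor match + shifted donor → A5SS; both shifted → A5SS&A3SS.
  The shifted boundaries define the retained head/tail used later for
  reconstruction.
- ends in two different introns: exon skipping of the in-between exon(s);
  a shifted donor/acceptor end upgrades the call to A5SS&ES / A3SS&ES
  (ties resolve to the more specific combined type).
- a donor-anchored plus an acceptor-anchored novel junction inside the same
  intron, framing a novel exon, fold into one cassette-exon event; the two
  junctions are consumed so they are not double-reported as A3SS/A5SS.
- two ES calls skipping disjoint adjacent exon runs fold into one mutually
  exclusive exon (MXE) event; a pair touching the first/last exon is typed
  5pMXE/3pMXE. With single-mRNA annotation and junction-only evidence,
  alternative *terminal* exons cannot arise from the simulator, so the
  terminal typing rule is exercised directly by unit tests rather than by
  simulation.

Junctions identical to annotated introns produce no event.

## Intron-retention calling

For every annotated intron of every gene, per replicate:

1. **depth ratio** — mean intron depth ≥ `min_depth_ratio` (default 0.20)
   × the unweighted mean of the two flanking exons' mean depths. The
   combination of the two flanks is not dictated by the rule's wording; the
   unweighted mean is symmetric and robust to exon-length imbalance. The
   comparison uses a 1e-9 absolute tie tolerance so that exact equality
   ("at least 20%") passes despite binary floating point.
2. **cumulative depth** — summed intron depth strictly greater than
   `min_cumulative_depth` (default 100); a cumulative depth of exactly 100
   is rejected.
3. **boundary support** — at least `min_boundary_reads` (default 1) reads
   aligned contiguously across the 5′ *or* the 3′ exon–intron boundary
   (logical OR), anchored 6 nt each side.
4. **exclusivity** — no other AS event overlaps the intron in the same
   sample; e.g. an A5SS&A3SS junction inside intron 7 vetoes an IR call
   there even when criteria 1–3 pass.

Criteria are evaluated per replicate and never on pooled replicates;
aggregation only unions the called types per gene × group. Mean × intron
length equals cumulative depth exactly (integer sums), which the tests
assert as a conservation check.

## Variant reconstruction and consequences

Events are applied to the exon block list: IR merges the flanking exons
across the intron; A5SS/A3SS/A5SS&A3SS extend the flanking exons by the
retained head/tail; ES drops exons; cassette inserts the novel exon. The
variant transcript is spliced from the blocks in transcription orientation
and re-translated with the standard nuclear genetic code (the organism
modeled is an ascomycete; no alternative code applies) from the unchanged
start-codon position.

Classification: identical protein → silent; longer protein with retained
length ≡ 0 mod 3 → in-frame insertion (`inserted_aa = retained/3`; the
junction codon may be recoded when the insertion is not at a codon
boundary, which still reads as an insertion at the protein level);
truncated with retained ≢ 0 mod 3 → frameshift PTC; truncated with
retained ≡ 0 mod 3 → in-frame PTC (stop inside the retained segment). A
frameshift whose first novel stop falls downstream of the normal stop is
still reported as frameshift PTC with the measured stop position.
Frame-preserving exon skipping is reported as `in_frame_deletion` — the
insertion/truncation taxonomy alone cannot label it truthfully. Events
confined to untranslated regions are silent with a UTR flag; an event
removing the start codon, or a frameshifted ORF that runs off the
transcript without any stop, raises an explicit error rather than guessing.
PTC positions are 1-based amino-acid indices from the initiator methionine;
protein lengths never count the stop codon.

## Synthetic data

The generator emulates *post-QC* bulk RNA-seq over a toy genome with one
gene per contig (60–120 nt intergenic padding): uniform fragment starts,
error-free reads by default, primary alignments only, minimal SAM dialect
(`@HD`/`@SQ`, FLAG 0/16, MAPQ 60). Reads per isoform are proportional to
abundance × isoform length at the configured depth, so junction support
scales linearly with spliced-isoform abundance. It does **not** model
sequencing error profiles, positional/GC bias, paired ends, duplicated
reads or expression-level realism — passing tests therefore demonstrate
correctness of the inference given clean alignments, not robustness to
alignment artifacts in real libraries.

Random genes have 2–5 exons (80–200 nt) and introns of 40–120 nt, all
GT..AG on the coding strand, a short 5′ UTR and an open reading frame built
from sense codons. Read length defaults to 100 nt and depth is
configurable; these are generator conventions, not values taken from any
particular sequencing platform.

The five named fixture genes reproduce the documented variant structures:
normal CDS lengths 319/318/435/765/365 aa; event introns of 62, 84 (with a
planted in-frame TAA), 46 and 141 bp; and a 7-intron gene whose 7th intron
supports retention of its first 22 and last 2 nt. Only lengths and outcomes
are fixed by the emulated structures; sequence content is random under the
seed, constrained where needed (stop-free in frame for the in-frame
fixtures), and the generator self-checks each fixture's outcome during
construction, resampling under the same seeded stream if a random draw
violates a constraint. The real genes' PTC positions depend on their actual
NCBI sequences and are deliberately not targeted; the fixtures test the
mechanism.

## Kinetics

`simulate_kinetics` draws v = k<sub>cat</sub>E₀S/(K<sub>m</sub>+S) ×
(1+ε), ε ~ N(0, cv²), on a geometric grid of 12 concentrations spanning
0.2–15 mg mL⁻¹ (geometric spacing resolves the low-S region where
K<sub>m</sub> = 7.41 mg mL⁻¹ lies), triplicate by default. E₀ defaults to
0.05 µmol — the enzyme amount is a simulator-side quantity needed to turn
V<sub>max</sub> into k<sub>cat</sub>, chosen to give rates of order
1 µmol min⁻¹.

The fit is unweighted least squares on untransformed rates (no
Lineweaver–Burk linearization, no weighting), initialized at V<sub>max</sub>⁰
= max v and K<sub>m</sub>⁰ = the concentration whose rate is closest to
half V<sub>max</sub>⁰, run to tight tolerances (1e-14 relative) within 500
evaluations. Standard errors come from the Gauss–Newton covariance.
Negative estimates raise; non-convergence raises with the last iterate. A
fit is flagged ill-conditioned when the normal matrix is near-singular,
when the K<sub>m</sub> standard error exceeds ten times the estimate, or
when K<sub>m</sub> lands more than two decades outside the sampled
concentration range — the saturated-only design where K<sub>m</sub> carries
no information collapses to the third condition.

## Problem sizes and determinism

Every stochastic component consumes a `numpy` `Generator` seeded from
explicit configuration; identical seeds give byte-identical FASTA, GFF3 and
SAM outputs. The recovery studies use 50-gene genomes at 100× depth over
20 seeds (detection) and 100 seeded simulations (kinetics); both finish in
well under a minute each, and scale linearly if larger studies are wanted.

## Known limitations

- Junction strand is taken from the simulator's XS tags when present;
  unstranded real libraries rely on the host gene's annotated strand.
- MXE detection is heuristic (paired ES calls); it can fold two genuine
  independent double-skip events into one MXE.
- The A5SS/A3SS retained-head/tail reconstruction assumes retention-style
  alternative sites (novel site inside the intron); exonic alternative
  sites are logged and ignored.
- No statistical testing or PSI quantification is attempted — the screen
  reports presence/absence per replicate, mirroring the report shape it
  emulates.
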