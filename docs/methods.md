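# Methods

## Coordinate model

Coordinates are 1-based inclusive, matching GenBank and the tabular
gene-organization layouts of the mitogenomics literature. The stored
sequence is the heavy (H/"J") strand 5′→3′; light (L/"N") strand genes
are read as the reverse complement of their slice. A feature with
`end < start` spans the origin of the circular molecule and its sequence
concatenates the tail and head of the stored string. `+/−` and `J/N` are
accepted as strand synonyms on input and normalized to `H/L`.

Intergenic values are signed: for consecutive features *i*, *i+1* the
value is `start(i+1) − end(i) − 1` (positive = spacer, negative =
overlap, 0 = abutting), attached to the upstream gene; the last→first
pair closes the circle. This gives the exact conservation law checked
throughout the test suite: gene lengths plus signed gaps telescope to
the genome length. The control region is derived, not trusted from
input: it is the trnP→trnF interval under circular closure. With the
bundled annotation (genome 16,497 bp, trnP ending at 15,433, trnF at 1)
that yields 1,064 bp; the published per-row intergenic figure for trnP
(321) contradicts this closure and is deliberately not used.

### Known discrepancies in the bundled reference annotation

The published organization table is not fully self-consistent:

* **ND4.** The printed coordinates (10,165–11,542) span 1,378 nt while
  the printed length cell says 1,383 and the regional PCG total
  (11,405 bp) equals the sum of the length column, i.e. it embeds 1,383.
  Two printed columns against one: the bundled annotation carries ND4 as
  10,165–11,547 (length 1,383), implying a 5 bp ND4/trnH overlap. The
  ND4L/ND4 overlap (−7) depends only on start coordinates and is
  unaffected.
* **trnP intergenic (321)** — inconsistent with the 1,064 bp control
  region derived by circular closure; the closure is authoritative.
* **ND6 start/stop "TCT"/"CAT"** — artifacts of reading the H-strand
  annotation for an L-strand gene. The package reports codons verbatim
  from the encoded-strand sequence, so these cells are not reproduced.
* One whole-genome composition row (*T.* sp. 2) has base cells summing
  to 100.7% while its printed A+T%/G+C% totals are internally
  consistent; the data file carries both, and multi-genome A+T averaging
  uses the printed totals column.

## Composition and skews

Base percentages are computed from integer counts over unambiguous
bases; IUPAC ambiguity codes stay in the sequence but are excluded from
both numerator and denominator (`size_bp` still reports raw length).
AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), reported ×100. Both are
scale-invariant, so counts and percentages give identical skews; skews
are rotation-invariant (circularity) and flip sign under reverse
complement — both property-tested. Region rows concatenate
encoded-strand gene sequences; positions inside gene overlaps contribute
to every gene containing them (not deduplicated), which is what makes
the PCG concatenation size equal the plain sum of annotated lengths.
Rounding (composition 1 d.p., skews 3 s.f. by default, both
configurable) happens only in report writers, never internally. Skews
recomputed from 1-d.p. printed compositions can differ from
raw-count-derived published values by up to ~0.2 in the second decimal;
tests that start from printed tables use tolerances of that order.

## Codon usage

CDS extraction trims the 3′ end to a codon boundary (vertebrate
mitochondrial genes often end in incomplete T/TA stops completed by
polyadenylation) and optionally removes a terminal stop. Codon counts
pool all 13 PCGs per genome (per-gene mode available); start codons are
included in the counts and incomplete terminal codons never are. RSCU
families are synonymous codon sets under the chosen code — one family
per amino acid by default, so Leu and Ser are 6-codon families under
table 2; an option splits 6-fold families into their 2+4 boxes for
sensitivity analysis. Stop codons are excluded from RSCU; unused
families report RSCU 0 for all members. Codons display in the RNA
alphabet by default (DNA internally).

## Ka/Ks (NG86 + Jukes–Cantor)

Site counting assigns each codon position a synonymous fraction =
(number of its 3 single-nucleotide changes that are synonymous)/3, with
changes that create stop codons never counted synonymous, so s + n = 3
per codon. Under table 2 this matters more than under the standard code:
four stops (TAA, TAG, AGA, AGG) prune both the synonymous neighbor sets
and the substitution pathways. Pairwise differences enumerate all k!
orderings of the differing positions, discard orderings passing through
a stop codon, and average the synonymous/nonsynonymous step counts over
the rest; if every ordering is blocked the average is taken uniformly
over all orderings. S and N are averaged over the two sequences, Sd and
Nd summed over codon pairs; pS = Sd/S and pN = Nd/N receive the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3). p ≥ 0.75 is reported as
saturated with the rate (and ratio) undefined, as is Ks = 0 — no
infinities. Classification compares Ka/Ks to 1 exactly by default, with
a configurable tolerance band for "neutral".

The method is the classical fully specified pairwise scheme; it is
verified against a brute-force pathway-enumeration oracle (equality to
1e−12 on random short pairs) and cross-checked against an independent
NG86 implementation (Biopython's `cal_dn_ds`) on random mito-code
alignments. Codon columns containing gaps, ambiguity codes or stops in
either sequence are skipped pairwise. Alignment production is out of
scope: cross-species use requires externally codon-aligned input;
generator pairs are aligned by construction. Exact numeric agreement
with any particular GUI package's Ka/Ks output is not promised, since
those tools do not always document their variant; the sign of the ratio
against 1 — the quantity the selection screen interprets — is robust
across classical NG variants.

Gene preparation for the screen: terminal stop removed, light-strand
genes (ND6) taken from the encoded strand, and the 13-gene concatenation
built in genomic order with overlap positions present in both genes
(hence twice in the concatenation), so every codon of every gene is
analysed.

## Synthetic genome generator

The generator exists so that every analysis stage can be validated
against planted ground truth. Defaults define the simulated conditions:

* **Layout** — the published 37-gene arrangement with its real spacers
  and overlaps (including ATP8/ATP6 −43 and ND4L/ND4 −7) and a 1,064 bp
  control region between trnP and trnF; genome length 16,497 bp.
* **Composition** — target (A, C, G, T) = (34.3, 23.9, 11.6, 30.2)%,
  the published whole-genome composition; realized composition is tuned
  to within ±1 percentage point (typically ±0.5) by adjusting
  non-coding positions only.
* **Codon bias** — sampling weight of A/T-ending codons multiplied by 2,
  planting the third-position A/U preference real mitogenomes show, so
  RSCU rankings on synthetic data qualitatively mirror real ones.

PCGs are valid ORFs under table 2: start codon from {ATG, ATA, ATT,
GTG}, no internal stops, terminal TAA/TAG or an incomplete T/TA stop
when the annotated length is not a multiple of 3. Overlapping reading
frames are handled by constraint-aware codon placement: start and
terminal codons of all genes are reserved first, then internal codons
are sampled (weighted by target composition × third-position bias)
filtered against every protein-coding frame covering the affected
positions, with rollback if a candidate would complete a stop in a
neighbouring frame. tRNA/rRNA/spacer/control bases are
composition-matched random nucleotides with no structural realism — so
passing tests demonstrate correctness of the accounting, not biological
realism of tRNA sequences.

Derived genomes plant exactly `n_syn` synonymous and `n_nonsyn`
nonsynonymous single-nucleotide changes per gene, each in a distinct
codon, never creating a stop, avoiding the start codon, terminal stop,
and any position shared with another PCG; this guarantees NG86 recovers
(Sd, Nd) = (n_syn, n_nonsyn) exactly and makes Ka/Ks > 1 equivalent to
the planted pN > pS. A single integer seed drives one `numpy` PCG64
stream per genome (no global state); identical specs produce
byte-identical FASTA/feature-table/ledger output. There is no
tree-based simulation, no indels and no rate heterogeneity — pairwise
planted-change divergence only.

## Problem sizes

All simulations are full-genome scale (16.5 kb, 37 genes, 13 ORFs);
generation takes ~0.2 s per genome, and the complete test suite runs in
a few seconds. Oracle comparisons use 1,000 random short codon pairs
and 20 random RSCU count tables, sizes at which the brute-force oracles
are exhaustive.

## Known limitations

* No de-novo annotation, assembly, alignment, tRNA structure prediction,
  phylogenetics, dating or biogeography — upstream/downstream tools own
  those steps.
* No codon-model ML selection tests (branch-site/PAML-style) and no
  modified-NG / LWL / YN00 variants; the NG86 machinery is structured so
  such variants could slot in at the site/difference-counting layer.
* Percentage composition of real rounded tables cannot always be
  reconciled exactly (see discrepancies above); raw-sequence inputs are
  always internally consistent.
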