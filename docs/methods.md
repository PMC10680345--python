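# Methods

## Scope and data model

The package analyzes annotated circular mitochondrial genomes of the
standard animal type: 13 protein-coding genes (PCGs), 22 tRNAs, two rRNAs
and one long A+T-rich control region (CR). Coordinates are 1-based
inclusive on the deposited plus strand, as in GenBank feature tables. The
plus strand is called J (majority) and its complement N (minority),
following leafhopper mitogenomics convention. A feature that spans the
origin of the circle carries `wraps_origin=True` with `end < start`; its
length is `end − start + 1 + L` for genome length `L`. Gene names are
normalized to a canonical 37-gene vocabulary through an embedded dialect
table (extensible via `register_gene_alias`); the serine and leucine
isoacceptors are disambiguated by anticodon (trnS1 reads the AGN family,
trnS2 UCN, trnL1 CUN, trnL2 UUR), since a bare "tRNA-Ser" is otherwise
ambiguous. Unmappable names are kept raw and flagged, never guessed.

## Composition and skew

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C), over unambiguous bases
only; IUPAC ambiguity letters are excluded from numerators and
denominators everywhere. An empty denominator yields `None` (an undefined
marker), never zero. Published per-region skews of this genome type do not
state whether they were computed on the deposited strand or the coding
sense, and the two differ in sign for N-strand genes; both variants are
therefore computed and labelled (`at_skew_plus` / `at_skew_coding`), and
the reported convention is plus strand for the whole genome and CR,
coding sense for gene-class concatenations. Concatenated gene regions sum
each gene's full span, so nucleotides shared by overlapping genes count
once per gene — this matches how published region lengths equal the sum of
per-gene lengths. Codon-position A+T% pools complete codons across the
given PCGs, reading each from its annotated frame; trailing partial codons
are dropped.

Report rendering rounds percentages to one decimal and skews to three;
machine outputs (TSV/JSON) keep full precision.

## Codon analysis

Translation uses the invertebrate mitochondrial code (NCBI table 5),
embedded as data and cross-checked in the test suite against Biopython's
codon table: AGA/AGG→Ser, ATA→Met, TGA→Trp, stops TAA/TAG only. Start
codons are canonical when they match ATN. Stops are classified as the
terminal complete codon when it is TAA/TAG, otherwise a trailing "T"/"TA"
is read as an incomplete stop ("T-"/"TA-") completed to TAA by
polyadenylation; any other gene end is flagged "no stop found" rather than
coerced. Codon usage pools complete codons of all PCGs in coding sense,
excluding terminal complete stops and incomplete tails — under this rule a
10,945 bp PCG set with twelve complete stops and one 1-bp tail contains
(10,945 − 36 − 1)/3 = 3,636 non-stop codons, the published counting
identity. RSCU(c) = n(c)·|F| / Σ_{c′∈F} n(c′) within each synonymous
family of table 5 (serine is one 6-codon family); unused families get
RSCU 0 for all members and are flagged. Amino-acid ranking sorts by count
descending with alphabetical tie-break on the three-letter names.

## Architecture

Features are sorted by start position; each consecutive pair on the circle
(including the wrap-around pair) yields a junction with
`gap = next.start − prev.end − 1`, corrected for origin crossing. Negative
gaps are overlaps, positive gaps spacers. Two conventions keep the
summaries comparable with published junction tallies: (1) the two
junctions flanking the CR are flagged and excluded from overlap/spacer
summaries, because published tallies cover gene–gene junctions only and
treat the CR as its own region; (2) a feature fully contained in another
is excluded from gap arithmetic, so the length-conservation identity
Σ gene lengths + Σ gaps = L holds on fully annotated circles. Spacer ties
break to the first occurrence in circle order. The control region is
returned as annotated, or synthesized as the span from the base after
rrnS to the base before trnI — its conserved location in this genome
organization.

Gene order is the circular sequence of (gene, strand) by start coordinate,
CR excluded, rotated to trnI. Breakpoint distance counts circular
adjacencies of one order absent from the other; the default is
strand-blind (rearrangement studies of this group discuss order, not
inversions), with a signed variant (`signed=True`) that matches
adjacencies up to reading direction. The distance is symmetric for
same-size orders, rotation-invariant and zero iff the circular orders are
rotations of each other; the suite verifies it against a brute-force
neighbour-scanning oracle on random permutations. The 37-gene ancestral
insect order with strands is embedded as `ANCESTRAL_ORDER`.

## tRNA structures

Structures are consumed as sequence + dot-bracket text, never predicted;
reproducing a structure annotator's folding is out of scope. T and U are
equivalent on input (U internally). Matched brackets give a nested pair
list; stacked pairs group into helices, and nested helices (bulged stems)
merge into one arm. The outermost enclosing helix is the acceptor stem;
helices directly inside it are assigned DHU, anticodon and TψC in 5′→3′
order. With only two inner stem-loops the missing arm is identified
positionally: a longer unpaired run on the 5′ side of the first inner
helix than on the 3′ side of the last one marks a lost DHU arm (the trnS1
case), otherwise the TψC arm is the one lost; ties default to DHU-absent,
the overwhelmingly more common loss in animal mitogenomes. The anticodon
triplet is the middle three bases of the anticodon loop when that loop has
at least 7 bases. Pair types: A-U/G-C in either orientation are
Watson–Crick, G-U/U-G wobble, anything else mismatch; the three tallies
always sum to the pair count.

## Synthetic mitogenome generator

The generator is the package's study-condition fixture: its defaults are
the published parameterization of the 16,391 bp genome (per-gene lengths,
start/stop codons, the eleven junction overlaps totalling 36 bp, the
trnC–trnY spacer, whole-genome A+T 0.762 with AT-skew 0.091 and GC-skew
−0.144, CR A+T 0.825, codon-position A+T (0.781, 0.711, 0.729)); the
presets module adds the other two published parameterizations. Per-tRNA
lengths are a synthetic assignment within the published 61–76 bp range
summing to the published class totals, since individual tRNA lengths are
not printed. Spacer placements other than trnC–trnY are likewise
synthetic, chosen so the regions tile the published genome length exactly
where the printed numbers permit (they do for the daozhenensis- and
expansivus-like presets; the yunshanensis-like printed region lengths sum
to ~500 bp more than the printed total under any non-negative spacer
assignment, so that preset's realized total differs and is not used as an
expected value).

Generation is deterministic per seed (one `numpy` Generator per call, no
global state) and proceeds:

1. **Layout.** Coordinates follow the circular gene order from position 1
   (trnI first by default), applying the specified junction gaps; the CR
   follows the last gene (rrnS). Overlaps are realized as shared sequence:
   one plus-strand array, two features covering the same bases.
   Optionally the finished genome is rotated so the CR spans the origin.
2. **Composition targets.** Plus-strand base probabilities come from
   p_A = at·(1+s_AT)/2, p_T = at·(1−s_AT)/2, p_G = gc·(1+s_GC)/2,
   p_C = gc·(1−s_GC)/2. The CR and the PCG codon positions have their own
   A+T levels; the remaining sequence (rRNA, tRNA, spacers) receives the
   A+T level and skews that make the length-weighted mixture hit the
   whole-genome targets exactly in expectation. Infeasible mixtures (a
   rest-region probability outside (0,1) or skew outside (−1,1)) are
   rejected before any drawing.
3. **PCG bodies.** Body codons are drawn from the exact joint distribution
   of three position-specific base vectors conditioned on "not TAA/TAG",
   with per-position marginals calibrated by iterative proportional
   fitting (200 sweeps over the 62 non-stop codons) so that stop exclusion
   does not bias composition — without this the A/T-rich stop codons'
   removal would depress PCG A+T by ~1 percentage point. Start codons
   (ATN) and stops (TAA/TAG or literal "T"/"TA" tails) are written
   verbatim. N-strand genes draw their coding sense from
   complement-swapped vectors so the deposited strand keeps the global
   skew.
4. **Assembly.** A spacer background is drawn for the whole circle, then
   tRNA/rRNA, CR and finally PCGs are written, so at shared bases the most
   constrained sequence wins; after assembly every PCG is re-extracted and
   checked (ATN start intact, stop intact, no internal stops), and
   generation fails loudly if an overlap corrupted one. The CR begins with
   a tandem repeat (default 4 copies of a 50 bp unit, one draw tiled) and
   continues with independent CR-composition draws.
5. **Ground truth.** All recorded values are realized, not targets:
   region base counts tallied directly from the emitted sequence with
   plain counters, per-gene start/stop, pooled codon counts, junction
   gaps, strands, order, repeat unit.

The tRNA-structure generator builds canonical cloverleafs (7 bp acceptor,
4 bp DHU, 5 bp anticodon and TψC stems, 7 nt loops) whose flexible loops
absorb the per-tRNA length targets; requested arms are replaced by a 6 nt
unpaired loop; each stem pair is G-U wobble with configurable probability
(default 0.1), otherwise Watson–Crick; the biological anticodon is written
into the anticodon loop. Injected G-U counts are returned as ground truth.

### What the generator does and does not emulate

It reproduces the architecture exactly (lengths, order, strands, gaps,
start/stop types) and the composition statistically (A+T and skews per
region and codon position, binomial noise ~0.3 percentage points of A+T at
16 kb). It does **not** emulate amino-acid-level codon bias: codons are
drawn from base composition alone, so six-codon families (Ser, Leu) are
overrepresented relative to real transcriptomes and the published top-four
amino-acid ranking (Ile, Met, Asn, Lys) is not recovered synthetically —
the ranking operation is exercised on hand-built profiles instead. Nor
does it model mutational gradients along genes, realistic rRNA/tRNA
sequence motifs beyond composition, or phylogenetic correlation between
genomes. Passing tests therefore demonstrate correctness of the
measurement pipeline and of the architecture bookkeeping, not realism of
the sequences themselves. G-U wobble totals of the real structures
(35/36/26) depend on the real structure files and are only exercised when
such files are supplied.

## Numerical and design choices

- Undefined statistics are `None`, never silently 0.
- Percentage tolerance in generator-recovery tests: ±1.0 A+T points for a
  single 16 kb genome, ±0.5 on the mean over 20 seeds, ±0.05 on skews —
  3–4 standard errors of the corresponding binomial draws.
- Degenerate inputs: single-feature genomes have no junctions; an
  all-ambiguous region reports `None`; a gene shorter than one codon after
  its frame offset is an error; zero inner stem-loops flag a
  non-cloverleaf structure.
- Problem sizes: every test and the acceptance script run on full-size
  (~16 kb) synthetic genomes; the whole suite generates a few dozen
  genomes and completes in seconds.

## Known limitations

- Real-data anchors (deposited accessions) require a one-time fetch with
  `scripts/fetch_accessions.py`; the library never touches the network.
- The GenBank writer emits one canonical feature per gene (typed feature
  with `gene` qualifier), not the `gene`+`CDS` duplication of archival
  records; the reader accepts both.
- Breakpoint distance is a count of broken adjacencies, not an
  evolutionary event distance (no DCJ/inversion inference).
- CR tandem repeats are generated, not detected; repeat annotation of real
  control regions is out of scope.
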