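# Methods

This note records the models, parameter choices and numerical decisions
behind the pipeline, and what the synthetic studies do and do not
demonstrate about real data.

## Site classification model

Every assembly position with pooled read depth ≥10 is classified from
three pileups (individual 1, individual 2, pooled = union of retained
alignments, re-piled). Per-dataset categories use inclusive frequency
thresholds over all covering reads (N bases included in depth):
reference type at ≥80 % agreement, non-reference at ≥80 % discordance,
allelic when two alleles each reach ≥40 %, low depth below 10 reads.
Two alleles at ≥40 % is automatically a two-allele definition: a third
allele cannot also reach 40 %. Sites matching no rule (e.g. 70/30) are
an internal *unresolved precursor* (U); the published rules genuinely
leave that region undefined, and such sites are excluded from all class
counts.

### Combination table

Only the inputs and outputs of the dataset-combination step are
published, so the table here is a documented reconstruction:

| individual 1 | individual 2 | pooled | class |
|---|---|---|---|
| R | R | · | reference |
| N | N (same allele) | · | sequencing error |
| N | N (different allele) | · | unresolved |
| N/R split | | A, N or U | allelic difference between individuals |
| N/R split | | R | unresolved |
| A | R (or A, same allele) | alt seen | allele within individual (carrier = A side) |
| A | N | · | unresolved |
| L | L | L | low depth |
| L or U | informative | · | defer to pooled, cross-checked against the informative set |

Two choices deserve justification:

* **No pooled-frequency requirement for within-alleles.** A
  heterozygous site in one individual contributes alt reads only from
  that individual, so its pooled alt fraction is bounded near
  `d_carrier / (2 · d_total)` and can never reach 40 % unless the
  carrier dominates the pooled depth. Requiring pooled ≥40 % support
  would silently erase every heterozygous site in the shallower
  dataset; we require only that the allele is observed (≥2 reads) in
  the pooled pileup.
* **Pooled category is advisory for between-sites.** A homozygous
  split produces a pooled mixture whose category reflects nothing but
  the two datasets' depth ratio (alt fraction `d₁/(d₁+d₂)`). The two
  individuals' own 80 % calls carry the evidence, so any non-reference
  pooled reading (A, N or U) is accepted; a pooled *reference* reading
  contradicts the non-reference dataset and yields unresolved.

### The 40 % window is a hard ceiling on heterozygote recovery

For a true heterozygote at carrier depth *d*, the alt-read count is
Binomial(*d*, ½) and the site is called allelic only when the fraction
lands in [0.4, 0.6]. That window has probability ≈0.74 at *d* = 20,
≈0.80 at *d* = 30, and reaches 0.95 only near *d* ≈ 100. Recovery of
within-individual alleles at the study's ~20× per-individual depth is
therefore intrinsically ≈0.65–0.75 — a property of the published rule,
not of the implementation. The acceptance suite asserts the documented
floors (within ≥0.45, between ≥0.70) plus zero cross-class confusion;
error recovery is asserted at ≥0.95 sensitivity and ≥0.99 precision.

### Indel calling

1–4 bp indel alleles are anchored at the reference base immediately
left of the event and left-normalized against the assembly, so all
reads report one canonical allele. Two numerical details matter:

* **Canonical alignment.** Under unit gap costs the placement of a
  multi-base indel is degenerate: an aligner may split a 4 bp deletion
  into 1+3 bp pieces around a coincidentally matching base at equal
  cost, differently in different reads. Same-type indels separated by
  match runs of ≤4 bp are merged before normalization. Without this,
  indel recovery fragments badly (sensitivity ~0.91, precision ~0.82
  in the 1 Mb study; 0.99/1.0 with it).
* **Event-spanning denominators.** A read ending inside or just past
  an indel cannot vote for or against it; at 36 bp read length such
  boundary reads dilute the allele frequency below the 80 % rule at
  true error sites. Frequencies therefore use as denominator the reads
  whose alignment spans the event plus a 3 bp flank. Support counts
  are pooled over inserted/deleted sequences of one length, with the
  majority sequence reported, so a sequencing error inside an inserted
  run does not split the allele.

Sequencing-error calls whose correction intervals overlap (e.g. a
substitution call inside a called deletion) are resolved greedily
before application — the larger event wins — because the correction
operator itself treats overlapping records as a hard error.

## Mapping

The built-in mapper is a seed-and-extend unique mapper adequate for
synthetic genomes: exact 16-mer seeds at three offsets per strand
anchor candidates (k-mers with more than 64 genome hits are ignored),
edlib verifies each candidate with banded edit distance (cap
max(4, len/12), ≤8), and a read is *unique* only when its best
placement strictly beats every other candidate; exact repeat copies
tie and become *multiple*. Mapping confidence is 60 for unique and 0
for tied placements — only the ≥20 cutoff downstream is meaningful.
External alignments can be ingested from SAM and produce identical
pileups for identical placements. Insert-size bounds for proper-pair
flagging are mean ± 4 sd of the first 10,000 uniquely mapped pairs.

## Split-read large indels

Local hits come from exact-seed diagonal clustering (step 4, minimum
hit span 30 bp); because both hits of a pair share the read, endpoint
wobble moves read and reference coordinates along the same diagonal
and the inferred size — the difference of the two hit diagonals — is
exact even with sequencing errors. Candidate pairs must be
unambiguous, same chromosome and strand, non-overlapping on the read,
within 1 Mbp on the reference, and cover >90 % of the (post-trim) read.
Reads more than half-covered by short-unit tandem repeats are skipped.

A genuinely novel ≥100 bp insertion can never satisfy the >90 %
coverage rule — the inserted sequence has no alignment — so
insertion-type reference errors are modelled as **collapsed tandem
duplications**: the individuals carry two adjacent copies of a unit,
the assembly one. A read spanning the copy junction aligns as two hits
that overlap on the reference (negative reference gap), covering the
whole read; the detector accepts these, rejecting only pairs whose
reference intervals are fully disjoint in reversed order (true
rearrangements). Breakpoint/size clustering at ±10 bp with ≥2
supporting reads replaces manual candidate curation; an optional
short-read depth check corroborates deletion-type events by the
coverage drop across the removed interval.

## Optical-map alignment

Restriction maps are aligned by dynamic programming over blocks pairing
runs of up to 3 fragments per side, with per-fragment skips. Block
score = match bonus (5) − merge penalty × extra fragments − χ², with
χ = size difference / σ and σ = max(cv × size, 500 bp). The merge
penalty (3) approximates the log-odds of a missed/extra cut at the
~2 % per-cut error rate, which keeps genuine missing-cut merges
attractive while preventing whole extra fragments from being absorbed
into large blocks. Ties prefer fewer merged fragments, then the
leftmost structure; the DP is property-tested against exhaustive
enumeration on all maps up to 8 fragments per side.

Discordance classification walks the alignment, grouping adjacent
unmatched fragments and discordant blocks into loci: a locus on an
annotated N-gap is class 1; one unmatched fragment on each side is a
size difference (class 3 when ≥5 kb); ≥3 unmatched fragments with
non-comparable totals (>10 %) are class 5; one-sided unmatched mass
≥5 kb is class 2; remaining cut-site disagreements pair up within
100 kb windows as class 4. Sub-5 kb missed/extra/size events are
suppressed, following the published annotation threshold.

Gap sizes are the sum of unmatched optical fragments at the gap locus
(plus the optical excess of a block the gap aligned inside). When a
gap falls mid-fragment the estimate necessarily includes the flanking
sequence out to the nearest cut sites and overestimates; in the real
setting gaps sit at contig ends where cut boundaries are close.

## Synthetic data

The generator emulates the study structure: a GC-44 % genome with
exact repeat copies (units 200–2000 bp, default 10 % of the genome);
an assembly derived from the true genome by injecting substitution
errors, 1–4 bp indels (assembly missing or carrying extra bases),
≥100 bp large events (collapsed duplications and extra segments) and
1,000-N physical-gap placeholders; two diploid individuals with
homozygous between-individual differences and heterozygous
within-individual sites; a single-end 36/51 bp library and a 76 bp
paired-end library at ~150 bp inserts with per-base error 0.5 %,
constant Q38 with geometric low-quality tails, and occasional adapter
read-through on short inserts; long reads of mean 377 bp; and an
optical map with multiplicative sizing noise (cv 5 %), missing/extra
cuts (2 % each) and a minimum detectable fragment of 500 bp.

Depth defaults (26× raw per dataset) are set so that the pooled
*mapped* pileup depth is ~40× after trimming and unique-mapping losses,
matching how the study quotes its depths. Error and allele sites are
placed in non-repeat sequence with ≥50 bp spacing; large events ≥10 kb
apart. All randomness derives from the mandatory config seed through
named streams.

What passing tests do *not* show about real data: the error model has
no instrument-specific biases (no quality-dependent miscalls, no
homopolymer indel noise typical of pyrosequencing), repeats are exact
copies rather than diverged families, there is no recombination or
structural heterozygosity, and the optical sizing model is a plain
per-fragment normal. Recovery rates measured here are therefore upper
bounds on real-data behaviour.

## Reported precision

Rates per 10,000 nucleotides print at 2 decimals (4 when below 0.01),
genome sizes at 0.1 Mbp, percentages at 0.1 %. Effect severity for
site-level summaries is Nonsense > Missense > Silent > UTR > Intron >
Intergenic, with start-loss/stop-loss folded into Missense and
splice-region positions into Intron, matching the six-way scheme.

## Known limitations

* The internal mapper is desk-scale: a dictionary k-mer index and
  per-read candidate verification; it is not a BWT aligner and is not
  intended for real genomes.
* The dataset-combination table is a reconstruction; real studies
  publishing their combination rules should be ingested instead.
* Optical class-4/5 thresholds (100 kb window, >10 % total
  disagreement) are explicit stand-ins for qualitative published
  definitions.
* Gap-size estimates are flank-inclusive for mid-fragment gaps (above).
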