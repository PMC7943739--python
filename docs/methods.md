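# Methods

## Model of the data

A heavy-chain repertoire read is modeled as a full-length 5'RACE transcript:
it begins at the first base of its germline V segment, crosses a V(D)J
junction assembled by exonucleolytic trimming and random N-nucleotide
addition, and ends at the 3' end of its J segment. Divergence from germline
is substitution-only: somatic hypermutation (SHM) and sequencing error are
independent per-base substitution processes. Indels are **not** modeled —
neither in the simulator nor in the annotator, which performs gap-free
5'-anchored (V) and 3'-anchored (J) comparisons. On real data a read with
an indel would accumulate mismatches downstream of it and fall out of the
unique-assignment set rather than being misassigned; this is a documented
scope limit, acceptable because the analysis consumes only unequivocally
assigned reads.

Expression is modeled at the transcript level: each read draws its
chromosome (haplotype) uniformly, then its V allele from the haplotype's
relative weight vector, so an allele with normalized weight w on one
haplotype contributes ≈ w/2 of all reads. This matches the currency of the
analysis, which is read frequency, not cell counts.

## Unique assignment and the frequency denominator

For each read, mismatches against every V allele are counted over the
leading overlap of read and allele (both start at the V 5' end); alleles
exceeding `max_mismatch_frac` (default 0.10) of the compared length are
discarded, and the read is *uniquely assigned* iff a single allele attains
the minimal mismatch count among survivors. The rule is deliberately
threshold-free among survivors: adding a second copy of the best allele
always breaks uniqueness. J assignment is symmetric but anchored at the
read's 3' end, with a small offset search (0–6 nt). Reads shorter than
100 nt are flagged `too_short`; reads whose junction anchors (V 2nd-CYS,
IMGT 104; J-TRP, IMGT 118) fall outside the read are flagged
`anchor_lost` and count as non-productive. Every read lands in exactly one
of the buckets {unique, ambiguous, too_short, anchor_lost}, and **all**
buckets stay in the frequency denominator: an allele's expression frequency
is its uniquely assigned reads divided by the total rows of the input file.
This makes frequencies comparable across subjects regardless of annotation
quality.

`max_mismatch_frac = 0.10` leaves room for SHM at 2–6% plus junction-side
noise while keeping candidate sets small; the exact tie semantics of the
reference annotation service this emulates are unpublished, so the
singleton-minimum rule is this package's operationalization of
"unequivocally assigned".

## Haplotyping

Subjects are haplotypable when exactly two IGHJ6 alleles each hold ≥ 20% of
the uniquely assigned IGHJ6 reads and ≥ 50 reads (a second allele below
that is annotation noise; three substantial alleles make the subject
unusable). Haplotype 1 is the lowest-alphanumeric IGHJ6 allele, fixing
labels across runs. A V allele's haplotype call uses reads uniquely
assigned to both the V allele and one of the two IGHJ6 alleles: H1/H2 at
≥ 85% dominance with ≥ 5 anchored reads, BOTH when neither side drops below
15%, UNDETERMINED otherwise. The 0.85 dominance quantifies "primarily
associated" — no published number exists; it tolerates a 15% anchor-side
error while still separating opposite-haplotype alleles. Only IGHJ6
anchoring is implemented; D-based anchoring is an extension point.

## Occupancy, background nulls and carrier calls

A **major** allele has frequency ≥ `major_threshold` = 0.2% of reads —
between the rare band (≤ 0.1%) and the common-allele band (≥ 0.6%); this is
a configuration choice, not a literature value. Gene slots are counted from
the majors' haplotype calls; a single major called BOTH is the homozygous
case and fills both slots. Without a heterozygous IGHJ6 context, occupancy
is unknown unless two distinct majors exist, and detection degrades to
AMBIGUOUS rather than guessing.

The null for allele *a* is estimated from subjects whose both slots of
*a*'s gene are held by other majors: any reads of *a* there are
misassignment background. Because a read of a 1-nt neighbor needs only one
specific substitution to become uniquely closest to *a* (probability
≈ SHM-rate/3 per read, i.e. ~0.7% at 2% SHM), while distant alleles need
several, the background is stratified by whether *a*'s nearest germline
neighbor is among the subject's majors. The carrier test compares against
the stratum matching the tested subject's own genotype — the most specific
null available; it falls back to the pooled mean when that stratum is
empty or zero, and to an absolute floor of 10 reads per file when every
mean is zero or the cohort is smaller than 3 subjects.

A CARRIER call requires all three: n_unique ≥ `read_min` (5), frequency
≥ `fold_min` (10) × the chosen background mean, and — when exactly one
haplotype slot is open and anchored reads exist — the anchored reads
dominantly on the open slot. Observed carrier/background margins for real
poorly expressed alleles are 37–50-fold, so a 10-fold requirement leaves
headroom while excluding neighbor-inflated noise. Haplotype consistency is
judged on the anchored read counts themselves (dominant anchor at ≥ 85%,
any positive count) rather than the thresholded 5-read haplotype call: a
rare allele at 0.05% of a 20k-read file yields only ~7 anchored reads, and
a handful of consistently anchored reads is exactly the evidence this
check is after; zero anchored reads leave consistency unknown → AMBIGUOUS.

Statistical contrasts: the one-sided Mann-Whitney test computes the exact
tail of the U distribution (counting recurrence) when min(n) ≤ 10 with no
ties, else a normal approximation with continuity and tie correction;
degenerate all-equal input reports p = 1 with a flag. Carrier
co-segregation of two alleles uses the one-sided hypergeometric tail over
the carrier 2×2 table, plus a count of shared carriers whose dominant
haplotype anchors agree. No multiple-testing layer is applied (single
planned contrasts). Cohort summaries report mean ± sample SD (ddof = 1) of
carrier frequencies in percent at 4 significant digits, and genes with an
anchored haplotype lacking any detected allele are reported as deletion
*candidates*, never deletion assertions.

## Hotspot motifs and the focal codon

`hotspot_scan` matches the literal IUPAC motifs RGYW, WRCY (4-mers) and
WA, TA (2-mers) in any window covering a position; RGYW/WRCY mirror under
reverse complement. The focal-codon profile maps a 1-based IMGT codon to
read coordinates through the gapped germline alignment (identical to the
ungapped mapping for indel-free data when no gap precedes the codon),
translates that codon in every productive read with ≥ `min_mutations`
V-region mismatches, and tabulates residues. Use `min_mutations = 2` when
sequencing error is present so a lone error does not pass as
hypermutation; stops tabulate as '*' (and by the productivity definition
can never appear at an in-V codon of a productive read). The bundled locus
places the focal cysteine codon (IMGT 92 of the IGHV7-4-1\*01 analog) in a
context engineered to contain no hotspot window, so substitution there
cannot be attributed to mutator targeting.

## The simulator and what passing tests mean

The simulator's junction draw (geometric trims with mean `trim_mean` = 2,
capped so anchors survive; uniform 0–8 nt N inserts per side) is redrawn
up to 100× until the read's frame matches a Bernoulli(1 − 
`passenger_fraction`) in-frame target, so the out-of-frame passenger
fraction is controlled exactly; stop codons arise naturally from N bases,
D-segment frame shifts and SHM. The default passenger fraction (0.15) is a
free parameter of the simulation, not a measured value. SHM is uniform
across positions by default — the focal-codon argument concerns a
non-hotspot codon, so hotspot-biased SHM is deliberately not the default.

Study-condition cohorts (in `ighvrare.cohorts`) fix the simulation
scenarios: a 24-subject carrier-recovery cohort (8 carriers of the rare
allele at ~0.055% of reads on haplotype 1; 6 of the 16 non-carriers
carrying the 1-nt neighbor at ~0.6% of reads; SHM 2%, sequencing error
0.1%, 20,000 reads/subject), a noise-free haplotyping cohort with allele
pairs on opposite chromosomes, a matched near/far neighbor pair for the
background contrast, and a high-SHM (5%) subject for the focal-codon
analysis. The 20k reads/subject size keeps the full five-seed recovery
suite desk-sized while holding the expected carrier read count (~11) in
the regime the thresholds were designed for; the real datasets are ~10×
deeper, where every margin is wider.

Passing tests demonstrate that the *method* recovers planted truth under
its own model assumptions (substitution-only noise, uniform SHM, exact
frame control, a small clean reference). They do not demonstrate
robustness to indels, primer artifacts, chimeric PCR reads, clonal
expansion (every simulated read is an independent rearrangement), allele
references absent from the database, or library-specific error profiles —
all of which real repertoires contain.

## Numerical and degenerate-input choices

- Mismatch comparisons span the leading (V) or trailing (J) overlap; the
  padded tail of a trimmed segment contributes identical noise to every
  candidate of equal length, so minimal-mismatch ranking is unbiased.
- Nearest-neighbor and haplotype ties break lexicographically; frames,
  sort orders and per-subject seeds (config seed + subject index) make
  every pipeline output byte-reproducible.
- Zero IGHJ6 reads, empty cohorts, zero carriers and all-identical rank
  samples return flagged degenerate results (UNDETERMINED / p = 1 / empty
  profile), never exceptions; a pipeline stage failure aborts with a
  stage-named error.
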