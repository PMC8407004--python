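# Methods

## Fragment model and profiles

The unit of evidence is a protected fragment: a 0-based half-open genomic
interval \([s, e)\) reconstructed from one read pair.  Three per-base vectors
summarise a fragment set: coverage depth, 5′-start pileup and 3′-end pileup
(the position of the last covered base).  Two conservation identities hold by
construction and are asserted throughout the suite: the depth vector sums to
the total fragment length, and each end vector sums to the fragment count.

## Component calling

A component is a window \([i, j+1)\) satisfying

1. width \(j - i + 1 \in [w_{\min}, w_{\max}]\) — defaults 70 and 110 bp, the
   expected size range of DNase I-protected fragments;
2. edge support: at least `end_support_min` fragments start exactly at \(i\)
   and at least as many end exactly at \(j\).  The source procedure requires
   "high" end pileups without quantifying them; making the cutoff an explicit
   count (default 3) keeps the criterion testable.  The candidate set is then
   small enough to enumerate exactly, and the test suite checks the
   enumeration against a brute-force oracle over every \((i, j)\) pair;
3. mean depth over the window at or above the sample's threshold.

Candidates are reduced greedily in descending mean depth (ties: wider first,
then leftmost — a deterministic order).  A candidate is discarded only when
both of its edges fall within ±2 bp of an already selected component's edges;
overlapping components with distinct edges are retained deliberately, since
several protected regions can sit inside one binding peak.  Peaks are the
transitive closure of component overlap (≥1 shared base; half-open intervals,
so abutting components do not merge).  An optional
`max_components_per_peak` cap trims each peak to its top-scoring members.

Threshold scaling across libraries uses exact integer arithmetic with
truncation: \(\lfloor T_0 N / N_{\mathrm{ref}} \rfloor\).  Truncation (rather
than round-half-up) is the rule that reproduces all three published scaled
thresholds simultaneously from their library sizes; it is documented here as
inferred from those printed values.

## Occupancy comparison

Components from all conditions are clustered transitively by ≥50% reciprocal
overlap into union rows (the source material matches regions across
timepoints by locus without stating a rule; reciprocal overlap is the
standard, testable choice).  Per condition a row reports:

- `read_count`: fragments overlapping the union interval by ≥1 bp (the
  simplest monotone rule; stated in the output header);
- `normalized_reads`: `read_count` divided by that library's mapped total,
  making occupancy comparable across libraries;
- `avg_depth`: the maximum member-component depth when that condition called
  a component in the cluster, otherwise the best caller-width window mean
  inside the union interval;
- `above`: `avg_depth >=` that library's scaled threshold — a pure function
  of `avg_depth` and the threshold, matching the convention that a starred
  entry is one not identified as a highest-binding region at that timepoint.

Rows below threshold in every condition are dropped.  Specificity labels are
a total function of the flag pattern: above at the pre-initiation timepoint
only ⇒ pre-initiation-specific; above at the transient timepoint only ⇒
post-initiation-transient; above everywhere ⇒ constitutive; anything else ⇒
sporadic.  Ranking within a condition is by descending `avg_depth`, ties by
`normalized_reads` then position.  No statistical test is attached:
comparisons are threshold- and rank-based by design.

The qPCR helpers are plain arithmetic: yield % = 100 × purified/input, and
locus copy ratios \(r(t) = (a(t)/b(t)) / (a(t_{\mathrm{ref}})/b(t_{\mathrm{ref}}))\),
exactly 1 at the reference timepoint.

## Read preparation

With 100 bp reads and 70–110 bp inserts, reads run through the insert into
the library adapter.  `trim_adapter` finds the smallest offset whose read
suffix matches an adapter prefix — mismatch-tolerant (default rate 0.1) for
overlaps of ≥6 bp, exact below that — and iterates to a fixed point, so
trimming is idempotent.  The fixed-point iteration can erode 1–2 genomic
bases whose sequence coincides with the adapter start; this is harmless for
fragment reconstruction because the fragment start comes from the forward
mate's placement and the end from the reverse mate's placement plus its
length, both invariant to suffix erosion.  On error-free synthetic data the
trim→map round trip recovers ≥99% of fragment intervals exactly.

Mapping is exact and unique: a k-mer seed table (k = 20) plus full-prefix
verification; a mate with more than one perfect placement makes the pair
ambiguous and it is dropped, which removes repeat-region artifacts without a
curation step.  Accepted pairs must be convergent with an implied length in
(0, `ewt` + 40] bp.  The original workflow instead mapped untrimmed reads
with a large mismatch allowance and inferred boundaries afterwards; trimming
first with exact placement has the same intent (minimising unmapped reads)
with a simpler, testable contract, and is exact on synthetic genomes.  No
gapped or mismatch-tolerant alignment is attempted; externally aligned data
can enter through `load_fragments` (BED/BEDPE; the 6-column forms are
ambiguous, so the `.bedpe` extension selects the BEDPE dialect).

## Synthetic data: what it emulates and what it does not

The generator emulates the features the caller's inference relies on:
protected fragments of uniform length 70–110 bp always containing their
site's motif, with start jitter uniform subject to containment; uniform
background digestion; per-site, per-condition occupancy as a binomial draw
from `enrichment_depth` trials; adapter read-through in both mates; constant
high base qualities.  The uniform length distribution within the 70–110 bp
band is an assumption — the real distribution inside that range is not
characterised — as is the uniform background (appropriate for
replication-synchronised cells, where no origin-to-terminus dosage gradient
is expected).  Not modelled: GC-dependent cut bias, PCR duplicates,
replication-fork dosage, sequencing-quality decay (an optional uniform
substitution rate exists for robustness checks).  Passing tests therefore
demonstrate correctness of the inference under these idealised conditions,
not performance on real libraries.

Fragments are generated with non-wrapping starts (uniform over
\([0, G - L]\)), and planted sites may not span the linearization origin of
the circular genome; the caller likewise treats the sequence linearly.  This
loses a ~110 bp neighbourhood of the origin, negligible at the scales used.

## Canonical study conditions

The four-condition cell-cycle experiment (`demo_config`) uses a 100 kb
genome, conditions `0min`, `10min`, `20min`, `random`, and 12 planted sites:
an origin-like site with occupancy {0.9, 0.05, 0.05, 0.2}, a transient site
{0.05, 0.8, 0.05, 0.2} (consensus `TAAnnnnTTGATW`), and ten constitutive
sites at 0.6 (consensus `WATCARnnnnTTR`), with `enrichment_depth` 200.
Values not fixed by the schedules above were chosen once, analytically:
20,000 background fragments give a mean background depth of ≈18×, so planted
sites stand out roughly an order of magnitude the way prominent peaks do in
real data; the base threshold of 90 is 5× that mean background depth,
mirroring the "high threshold" strategy used to select comparable
highest-binding regions, and sits between the expected best-window depth of a
site at occupancy 0.2 (~55×) and one at 0.6 (~105×).  Per-library mapped
totals (~21,000) are the printed tens-of-millions scale reduced ~700-fold;
all rates and ratios are scale-free, and test problem sizes (20 replicates at
100 kb; 100 random ≤2.5 kb oracle instances; 50 kb scan sequences) keep the
full suite in the minutes range on one CPU.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally and in all BED/bedGraph
  output; the human-readable TSV uses 1-based inclusive coordinates with
  thousands separators ([3925748, 3925842) renders as "3,925,749
  3,925,842").
- Threshold comparisons use `>=`; thresholds are integers by construction.
- Empty fragment sets yield empty component lists; an empty genome is an
  error.  `merge_peaks([])` is `[]`.
- `scale_threshold` rejects non-integer or non-positive inputs rather than
  silently truncating.
- The IUPAC scanner treats a reference `N` as matching only a pattern `N`;
  minus-strand hits are reported in plus-strand coordinates.  PWM information
  content uses a uniform background (2 + Σ f log₂ f bits per column);
  genome-composition backgrounds are out of scope.
- Seeds: every stochastic routine takes an explicit integer seed; the
  pipeline derives per-stage child seeds from the run seed through a single
  generator in a fixed order, so fragment streams are identical whether or
  not the FASTQ round trip runs, and reruns are byte-identical.

## Known limitations

- Exact-match mapping is only adequate for clean or synthetic genomes; real
  libraries should be aligned externally and ingested as BED/BEDPE.
- Per-sequence calling only: multi-chromosome inputs are processed
  independently, with no cross-sequence merging.
- De-novo motif discovery is delegated (regions are exported as FASTA);
  only consensus scanning and PWM summarisation are built in, so published
  logo-coordinate offsets of discovered motifs are not reproduced here.
- The above/below-threshold comparison carries no error model; conclusions
  are rank- and threshold-based, as in the source procedure.
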