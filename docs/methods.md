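# Methods

This note records the models, conventions and numerical choices behind
`refotu`, and what the synthetic-data experiments do and do not demonstrate.

## Alignment kernel and identity

All identity thresholds in the pipeline (99.8% dereplication, 96% mapping,
97% reference clustering, 96% de-novo OTUs, pairwise V1–V2 similarity) are
evaluated by one kernel so they are mutually comparable: a semi-global
affine-gap alignment (match +1, mismatch −2, gap open −5, extend −2) with
end gaps free on the *reference* side only, so a ~300 bp amplicon aligns
inside a ~1.5 kb gene without penalty while read overhangs still pay.
Identity is matching columns divided by alignment columns within the query's
aligned span; coverage is the fraction of query bases aligned to reference
bases. IUPAC codes match when their base sets intersect. The dynamic
programming is Biopython's `PairwiseAligner` (C implementation) with a
16-letter substitution matrix.

Two shortcuts keep the search tractable without changing results: candidate
references are ranked by shared 8-mers and aligned inside a window around
the best seed diagonal (±60 bp), and the candidate scan stops once the
q-gram bound — an edit of size *e* destroys at most *k·e* of the query's
*L−k+1* k-mers, taken with a 1.5× slack for the gap between edit distance
and column identity — proves no remaining candidate can beat the current
best. The same bound lets the greedy clusterer skip hopeless centroids, and
identical sequences are deduplicated before clustering (identical inputs
provably make identical greedy decisions). Equivalence with exhaustive
all-pairs alignment is asserted by tests on instances of up to a few hundred
sequences.

Greedy clustering order is descending length, then ascending id; a sequence
joins the *first* (oldest) centroid at or above the threshold, else founds a
new one. This is deterministic and mirrors the behaviour of greedy centroid
clusterers used in amplicon work.

## Reference filtering

The three quality rules apply sequentially — length < 1,400 bp, then ≥ 4
ambiguous bases, then the eukaryote flag — so each removed record is charged
to exactly one rule and the counts add up with the survivors to the input
size. Eukaryote status is an input annotation, not a classifier: the
generator plants it, and real users supply it, because no detection rule
belongs to this pipeline. A record with exactly 3 ambiguous bases survives;
one with 4 does not.

## Read preparation

Mean read quality is the arithmetic mean of the integer Phred scores, and
the filter is strict (> 25, so a flat-25 read fails). Primer trimming
requires the forward primer (27Fmod, `agrgtttgatymtggctcag`) at the 5′ end
with at most 2 IUPAC-aware mismatches; the reverse complement of 338R
(`tgctgcctcccgtaggagt`) is removed from the 3′ end when present, since
pyrosequencing reads may stop short of it. Trimming precedes the fixed-depth
draw so primer rejections cannot leave a sample below 3,000 reads; the
subsample itself is uniform without replacement from an RNG substream keyed
by the run seed and a CRC-32 of the sample id, so any one sample is
reproducible in isolation.

## Profiling and the abundance table

Reads map by best hit (highest identity, then highest coverage, then
smallest reference id). References receiving at least one hit are clustered
at 97% over their full length into species-level rclust units, and each
read's count follows its best-hit reference into that unit — reads are never
re-mapped to cluster representatives. Unmapped reads cluster de novo at 96%.
Group mean relative abundance is the unweighted mean over samples of
count/3,000, which the fixed depth makes equivalent to a count mean; a unit
is kept when that mean reaches 0.1% in at least one group.

## Taxonomy

The deepest reliable rank comes from the best-hit identity of the unit's
representative: ≥ 96% species (the mapping threshold, i.e. the operative
known/novel split), 94–96% genus, 70–94% phylum, below that unassigned.
Genus and phylum names are taken from the best hit's lineage even when the
species rank is not granted. When a second species sits within 0.3
percentage points of the best, it is reported as a secondary hit rather
than arbitrated. Aggregation to genus/phylum sums unit counts and pools
too-shallow assignments into `unclassified`, so column totals are conserved
at every rank.

## Diversity

Observed OTUs, Chao1 and Shannon all derive from one 96% clustering of the
same 3,000 prepared reads (the depth contract is strict — a sample with any
other count is an error, not a silent rarefaction). Chao1 uses the
bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))`, defined even when no
doubletons exist; consequently richness equals `S_obs` exactly when F1 ≤ 1.
Shannon is reported in nats.

UniFrac runs over a midpoint-rooted NJ tree built from 1 − identity of the
retained units' representative sequences (the study never states which tree
its implementation used; this one is deterministic and derives from the same
kernel as everything else). Unweighted UniFrac is unique branch length over
the union's branch length; weighted UniFrac is Σ l·|A−B| over descending
read fractions, normalised by Σ l·(A+B) by default so values stay in [0, 1].
PCoA is classical scaling (double-centred −½D², symmetric eigendecomposition);
negative eigenvalues are dropped and their mass reported. ANOSIM is the
rank-based statistic with label permutations; an exhaustive mode enumerates
all orderings for small n and is the oracle for the sampled mode. Group
distance summaries test pair-class mean differences with a sample-label
permutation test, because distance pairs sharing a sample are not
independent and a t-test over pairs would be anti-conservative.

## Differential abundance

Welch's t runs on relative abundances (equivalent to counts up to the fixed
1/3,000 scale), two-sided, with Welch–Satterthwaite degrees of freedom; the
degenerate both-groups-constant case returns p = 1 for equal means. BH
q-values come from the standard step-up procedure (statsmodels backend; a
hand-computed oracle is in the tests). The fold change is
log10(mean MS / mean HC) on the count scale with the not-detected rule: a
group mean of exactly 0 reads is replaced by 1 read before the ratio, so
fold changes are always finite. The main significance flag mirrors raw
p < 0.05, with q reported alongside — the two selections are both computed
because published species tables of this kind print raw p-values while
methods sections cite BH correction, and neither choice is imposed here.

Longitudinal validation recomputes the fold change of each significant unit
against the control mean at each timepoint (mean over the subjects sampled
at that timepoint; subjects missing a timepoint simply do not contribute)
and scores the fraction of timepoints whose sign matches the
cross-sectional direction.

## Phylogenetics

NJ follows Saitou–Nei with the Q-criterion minimised deterministically
(first minimal pair in label order), negative branch lengths clamped to zero
with the clamped total recorded, a three-point formula finish, and a single
edge for the two-taxon case. On additive matrices the reconstruction is
exact (topology and branch lengths), which the tests verify up to 12 taxa.
Distances are p-distances (1 − identity) with no substitution-model
correction — the similarity trees this reproduces are themselves
uncorrected. Bootstrap resamples alignment columns with replacement,
rebuilds the NJ tree per replicate, and counts recovered bipartitions
(encoded root-invariantly). The multiple alignment comes from MAFFT, an
established aligner, rather than a bespoke progressive aligner; for a fixed
input MAFFT is deterministic, so supports replay exactly under a fixed seed.

## The synthetic-data generator

The generator emulates the study design it is modelled on: 20 case (MS) and
40 control (HC) cross-sectional samples; 18 longitudinal control subjects ×
9 timepoints; per-sample read totals negative-binomial around 7,080 ± 825
(case) and 7,590 ± 616 (control), floored well above the 3,000-read depth;
0.5% per-base substitution error; a 130-species community of which 12 are
withheld from the reference database so roughly 9% of reads fail mapping and
surface as de-novo OTUs; and 21 planted effects — 2 enrichments and 19
depletions with |log10 FC| between 0.4 and 1.8, six of them on the withheld
species so the significant set spans both unit kinds.

Species sequences evolve by substitution along a random birth–death tree
(tips relabelled, height scaled to 0.12 expected substitutions per site,
tip edges floored at 0.04) from a random 1,500 bp root whose primer sites
are held invariant; the amplicon is the 339 bp between and including the
primers. The tip-edge floor keeps every species pair below ~93% V1–V2
identity, so mapping separates species cleanly and the generating tree is
recoverable by NJ. Genus and phylum labels are defined by average-linkage
clustering of patristic distances (4 phyla, ~n/6 genera), giving taxonomy a
consistent ground truth. Reference redundancy is planted as near-identical
copies (≤ 2 substitutions) of each species sequence; defect records (short,
ambiguous, eukaryote-flagged) are disjoint by construction.

Community composition: planted species receive absolute control proportions
log-uniform in [0.5%, 3%], withheld species log-uniform in [0.2%, 1%], and
the background shares the remaining mass by lognormal weights (σ = 1).
Planted effects multiply case proportions by 10^FC with the remainder
renormalised proportionally (compositional closure). Per-subject
compositions are Dirichlet draws around the group expectation with
concentration 500 (HC) and 250 (MS) — the lower case concentration plants
the higher inter-individual dispersion the emulated study observed.
Longitudinal subjects keep one subject-level composition with small
per-timepoint wobble (concentration 2,000 around the subject mean), making
planted effects persistent across the series. Read qualities are per-read
means around 32 (σ 3) with per-base σ 6, plus a 6% low-quality read fraction
(mean 20) so the Q > 25 filter has real work. All randomness derives from
one integer seed via named substreams; identical configurations produce
byte-identical FASTA/FASTQ output, and each read id carries its true source
species.

What the generator does **not** emulate: 454 homopolymer errors, chimeras,
primer-site mutations beyond the global error rate, length variation among
reference genes, or taxon-specific abundance correlations. Passing tests
therefore demonstrate the correctness of the pipeline's algorithms and
bookkeeping under a controlled model, not performance on real gut data.

## Problem sizes and calibration experiments

The test suite and the acceptance script run at sizes chosen to exercise
each claim meaningfully: the reference-filter arithmetic at the full
221,537-record composition; the subsampling contract at the full 60-sample
design; oracle-equivalence checks at ≤ 500 sequences (where exhaustive
alignment is feasible); statistical calibration over 200 count-level
replicates of the full design; and the sequence-level end-to-end run at 10
samples × 3,000 reads against a 30-species reference.

Two statistical findings are worth stating plainly. First, Welch's raw
type-I error on null communities averages ≈ 0.05–0.06 — nominal within the
replicate spread, but with a heavier-than-t extreme tail, because
overdispersed compositional data are skewed; consequently BH can make
occasional false discoveries on *pure-null* communities more often than a
naive reading of "FDR ≤ 5%" suggests (the acceptance script reports this
rate honestly). Second, BH's FDR control is verified where its premises
hold — mixed simulations with valid p-values — and holds there with margin.
On mixed *community* simulations the compositional closure makes every
non-planted species a genuinely (slightly) shifted feature, so an "FDR
against the planted set" is not a false-discovery rate at all; extra
detections there are largely real closure effects. This is a known property
of t-based testing on compositions, not of this implementation.

## Known limitations

- Coverage is computed on the read side of the alignment; a BLAST
  implementation computing it over alignment length would differ at the
  margins.
- The greedy clusterer reproduces one documented insertion order; other
  orders yield slightly different partitions, as with any greedy method.
- Taxonomy is nearest-neighbour by identity; no naive-Bayes classifier is
  provided.
- The UniFrac tree is a pipeline choice (NJ over representatives); with a
  user-supplied Newick tree results will differ accordingly.
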