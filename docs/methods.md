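# Methods

This note records the models, parameter choices and numerical decisions
behind `triplexmeth`, and what the synthetic benchmark does and does not
establish.

## Differential methylation classification

Beta values (methylation fractions in [0, 1]) are compared between
mutation carriers and wild-type samples probe by probe with a two-sided
two-sample t-test.  Welch's unpooled-variance form is the default: the
motivating cohorts are strongly unbalanced (13 carriers vs 173 wild-type)
and per-group variances on the beta scale differ systematically with mean
methylation; Student's pooled form is available as `test_variant=
"student"`.  Multiple testing is handled by Benjamini–Hochberg step-up,
the conventional reading of "FDR" on arrays.  Classes are

* HM:   q ≤ `fdr_threshold` (0.05) and Δ ≥ `delta_threshold` (0.1),
* NHM:  q > 0.05 and |Δ| < 0.1,
* OTHER: the remainder (significant hypomethylation, or sub-threshold
  shifts with small q),

with Δ = mean(mut) − mean(wt), so HM means *gain* of methylation in
carriers.  Probes with any missing beta are dropped rather than imputed;
probes that are exactly constant in both groups get the conventions
t = 0, p = 1 (equal means) or p = 0 with a log warning (unequal means —
data like this indicates a processing artifact upstream).  Constancy is
detected by zero range rather than zero floating-point variance.

## RNA accessibility model

Triplex formation requires single-stranded RNA, so positions likely to be
base-paired are masked before the search.  Pairing probabilities come
from an exact partition function over all pseudoknot-free secondary
structures in which a structure with `p` pairs and `s` stacked pairs
(pair (i, j) with (i+1, j−1) also paired) has weight

    W(S) = pair_weight^p · stack_weight^s .

Allowed pairs are Watson–Crick plus G:U wobble; hairpin loops enclose at
least `min_loop = 3` nt.  Defaults are `pair_weight = e^-3` and
`stack_weight = e^4` (at 310 K these correspond to roughly +1.9 kcal/mol
for initiating a pair and −2.5 kcal/mol per stack, i.e. a net −0.6
kcal/mol per propagated helix pair).  The split matters: with a purely
per-pair weight the ensemble is dominated by register entropy — even a
perfect planted 10-bp stem keeps every individual pair below ~5%
probability at any transcript length, because each nucleotide has many
interchangeable partners — so no per-pair law can both mask planted
helices and leave unstructured purine tracts open.  Penalising initiation
and rewarding stacks concentrates probability on contiguous helices, the
same physics that makes nearest-neighbour models helix-selective.
Setting `stack_weight = 1` recovers the plain per-pair model; exactness
tests run under both laws against an explicit structure-enumeration
oracle (≤ 20 nt).

Implementation: the inside recursion tracks region partition functions
`Z(i, j)` and pair-closed functions `Zb(i, j)`; a matching exterior
recursion (organised so each pair costs one dot product, via a running
accumulator over enclosing pairs) yields exact pair probabilities in
roughly cubic time.  All tables are rescaled by a per-nucleotide factor
estimated on a 150-nt prefix so kilobase transcripts stay inside double
precision; an explicit `scale` can override the estimate, and overflow
raises rather than returning garbage.

Masking replaces position i with 'N' when `max_j P(i, j) ≥
pairing_cutoff` (0.1).  The max-over-partners semantics mirrors
RNAplfold's `-c` per-pair cutoff, as opposed to thresholding the total
paired probability; both quantities are reported in the profile
(`p_paired`, `1 − p_unpaired`) so users can mask on either.  For real
kilobase transcripts a ViennaRNA `_lunp` accessibility track can be
supplied instead of the built-in fold (`io.read_lunp`, CLI `--lunp`); the
two-parameter model is deliberately simple — exact, enumerable and
sufficient for a binary paired/unpaired call — not a thermodynamic
replacement.

## Triplex search

The masked RNA is aligned gap-free against the purine strand of each
target window under the canonical triplet chemistries:

| motif | TFO alphabet | triplets (TFO·purine) | orientation |
|-------|--------------|------------------------|-------------|
| Y     | T, C         | T·A, C·G               | parallel |
| R     | G, A         | G·G, A·A               | antiparallel |
| GT    | G, T         | G·G, T·A               | both |

Both duplex strands are tried as the purine strand; 'N' on either side is
always an error.  A hit must satisfy length ≥ `min_length` (10),
errors/length ≤ `max_error_rate` (0.20), at most
`max_consecutive_errors` (1) errors in a row, and a TTS guanine fraction
≥ `min_guanine_rate` (0.70).  The guanine constraint is interpreted as
the G fraction of the TTS purine strand (the published "G-C content" of
such screens is ambiguous between TTS guanine rate, TFO guanine rate and
duplex G+C; the TTS reading matches the parameter's role in the search
tools this emulates).  Masked positions count as errors rather than hard
breaks, so a hit may span an isolated masked base within its error
budget.

Reported hits are **containment-maximal per alignment register**: no
other valid hit with the same motif, orientation, strand and register
strictly contains them.  Endpoints are not forced to be matches — a
window that can absorb a flanking error within its budget is the larger,
reported hit.  Correctness is defined declaratively by
`brute_force_triplexes`, which enumerates every equal-length substring
pair (RNA ≤ 30 nt, DNA ≤ 60 nt guard), applies the same filters and
reduction, and must agree exactly; the scanning engine gets its speed
from a register prefilter (any valid hit of length L ≥ L₀ contains an
L₀-block with at most ⌊2·e·L₀⌋ errors, by a disjoint-block average
argument) and from splitting each register at error runs longer than the
consecutive-error cap.  `find_tts_tracts` reports, per strand, the
maximal intervals whose purine strand has no non-purine run above that
cap and enough purines for a legal hit; every hit's TTS provably lies
inside one.

Internal Triplexator heuristics (q-gram filtering, duplicate merging,
low-complexity masks, scoring weights) are not replicated;
`filter_repeats` is accepted for config compatibility but only the
published "off" setting is supported.

## Target windows

Windows are `width` = 100 nt centered on each CpG: `start = pos −
width/2`, placing the probe's C at 0-based offset 50.  Probe coordinates
are assumed to point at the C of the CpG (the 450K manifest convention).
Windows overhanging a chromosome end are clipped and flagged; off-
chromosome probes are skipped with a log entry.  Nearest-gene annotation
measures signed distance from the window midpoint to the gene span (0
when inside), breaking ties on smaller start then name.

## Protection and enrichment statistics

The headline test is Fisher's exact test (two-sided, probability-mass
criterion, via the hypergeometric law) on the 2×2 table of HM/NHM class
against triplex-positive/negative window status; OTHER probes are
excluded.  Protection appears as an odds ratio below 1.  The table is
built explicitly and reported in full, since published analyses of this
kind rarely print their margins.

TFO intervals on the RNA are merged into DNA-binding domains (DBDs) when
they overlap or fall within `gap_tolerance` (0) of each other.  Each
DBD's number of distinct target regions hit is compared against
`n_resamples` = 100 random draws of |targets| regions from a background
pool (drawn without replacement when the pool allows): reported are
`z = (obs − mean)/sd` (NaN when sd = 0) and the one-sided add-one
empirical p-value `(1 + #{resample ≥ obs})/(n_resamples + 1)`, with BH
correction across DBDs alongside the raw values.  In the pipeline the
background pool is a set of random genome windows placed disjoint from
every probe window (the analogue of masking zero-triplex loci out of the
genomic background), sized at twice the number of positive windows (at
least 50).

Rank-sum comparisons (methylation deltas at validated vs other sites) use
Mann–Whitney U, exact by full enumeration of group assignments when the
pooled sample is ≤ 12 (the enumeration handles ties, which scipy's exact
mode does not), otherwise the normal approximation with tie and
continuity corrections.  All values tied gives p = 1.

## Colocalization with RNA–chromatin contacts

Contacts whose RNA anchor overlaps the lncRNA source locus by ≥ 1 bp are
kept.  Windows are expanded by ±`flank` (3000 bp, clipped at chromosome
bounds); a contact is confirmed when its DNA anchor intersects an
expanded triplex-positive window, and a window is contacted when any
contact anchor intersects its expanded interval (the two views commute
with moving the expansion onto the contacts, a tested invariant).  The
association table is {positive, negative windows} × {contacted, not},
again with the full table reported.  All intervals are 0-based half-open;
1-based inclusive region strings are converted on ingest.  Inputs must
share one assembly; coordinate liftover is out of scope.

## Synthetic benchmark

The generator plants every signal the analysis is meant to detect, at
desk scale, with group sizes (13/173) and contact counts (29 true + 128
other = 157) matching the motivating study:

* genome: 2 × 80 kb chromosomes, GC 0.5; 200 CpG probes, each on a
  planted CG; 30% of probes carry a ~40-nt guanine-rich purine tract
  (G:A = 0.8:0.2) across their window — the triplex target signal;
* methylation: per-probe baseline ~ U(0.2, 0.6), Gaussian noise
  (sd 0.05) clipped to [0, 1]; 35% of probes gain Δ = 0.2 in the carrier
  group.  With `couple_protection=True` (default) the hyper draw avoids
  tract-bearing probes, planting protected ≡ triplex-positive; switching
  it off makes methylation class independent of positivity — the null
  used for calibration;
* lncRNA: 800 nt with a purine (G-rich) 3' tract at 77.5–92.5% of the
  length (the triplex-forming region, unpaired by construction) and three
  14-bp perfect hairpins elsewhere.  Stem words are rejection-sampled to
  have a unique pairing register; otherwise probability mass spreads over
  shifted helices and no single pair dominates, a real degeneracy of
  repetitive stems, not an artifact;
* contacts: true contacts put a 200-bp DNA anchor within the 3-kb flank
  of an (actually fitted) triplex-positive window; decoys go to free
  genomic space ≥ 2×flank from every probe window, so they can never be
  confirmed; optional offsite records carry an RNA anchor away from the
  locus and test the contact filter.

Two deterministic layout choices trade realism for exactness: tract and
plain probes occupy separate strata of each chromosome (so decoy
placement is always feasible), and plain-probe windows are sanitised so
no 10-mer holds ≥ 7 G (or ≥ 7 C) — making "window contains a purine
tract" a planted fact rather than a high-probability event.  Fixed seeds
give byte-identical outputs; all randomness flows through seeded
`numpy` generators with per-stage streams.

What passing on this benchmark shows: the engine and statistics recover
planted effects exactly and stay calibrated under the null.  What it does
not show: performance on real arrays (cross-hybridising probes,
normalisation artifacts, correlated probes), real chromatin contacts
(cell-type specificity, coverage bias), or thermodynamic accuracy of the
accessibility model on real transcripts.

## Problem sizes and runtime

Default synthetic conditions: 200 probes × 186 samples, 800-nt RNA,
100-nt windows, 157 contacts; a full fit takes ~10 s on one CPU (folding
~2 s, triplex search ~7 s).  The test suite (including a 500-instance
engine-vs-oracle fuzz, structure enumeration up to 18 nt, 200 null
classifier replicates and two end-to-end fits) runs in about a minute;
`scripts/acceptance.py` in about half a minute.  The exact partition
function is practical to ~2–3 kb; beyond that, supply an RNAplfold track.

## Known limitations

* The accessibility model has two parameters, not a nearest-neighbour
  energy table; its absolute pairing probabilities are not comparable to
  ViennaRNA's, only its paired/unpaired calls at the chosen cutoff are
  designed to behave analogously.
* Triplexator's scoring and internal filters are not reproduced, so hit
  lists will not match it record for record; the declarative rule set +
  oracle defines this package's semantics.
* The 2×2 constructions (which margins enter the Fisher tests) follow
  the default readings documented above and are configurable; published
  analyses of this design rarely state theirs.
* DBD enrichment resamples windows, ignoring chromatin context and GC
  covariates of real backgrounds.
* One assembly throughout; no liftover, no array normalisation, no GO
  enrichment.
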