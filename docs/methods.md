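# Methods

## Problem setting

An AP-MS experiment purifies a tagged bait protein together with whatever
co-elutes: genuine complex partners, the overexpressed bait itself, and
nonspecific "sticky" binders (ribosomal proteins, tubulins, chaperones)
that also appear in mock-tag control purifications. The package works
entirely at the spectral-count level — the number of MS/MS spectra matched
to each protein per LC-MS/MS run — which is semi-quantitative: counts scale
with abundance and with protein length, saturate for very abundant
proteins, and carry counting noise well approximated as Poisson.

The pipeline has four inferential stages, each behind its own module:
identification filtering (`io`), interaction probability (`scoring`),
relative enrichment (`enrichment`), and peptide-level isoform evidence
(`digest`), with `simulate` providing ground-truth data and `pipeline`/
`cli` the orchestration.

## Identification filters

Two standard spectral-count filters are applied before any inference:
peptides shorter than 7 residues are discarded (when peptide-level evidence
is available) and the affected proteins' counts re-tallied; and a protein
must accumulate ≥ 2 spectra across a bait's replicate series to count as
identified for that bait (an alternative reading — detection in ≥ 2
replicates — is available via `require_replicate_presence`). Filtering is
idempotent and monotone: it only zeroes or removes, never adds. Removal is
per bait (counts zeroed in that bait's runs only), since a protein can be
real prey for one bait and noise for another.

## Interaction probability model

The probability that prey *i* truly interacts with bait *b* is computed
from a two-component Poisson model. Background rates per unit depth are
estimated from control runs with pseudocount smoothing,

λ0_i = (Σ control counts_i + α) / (Σ control depths + α·n_proteins), α = 0.1,

pooling replicated controls depth-weighted. The enriched rate λ1_i is the
prey's pooled rate over the bait's own replicates (method of moments),
clamped to ≥ λ0_i. Per replicate, with equal prior odds,

p_r = Poisson(x_r; d_r λ1) / [Poisson(x_r; d_r λ0) + Poisson(x_r; d_r λ1)],

evaluated in log space; probabilities are averaged arithmetically over
replicates and thresholded at 0.9 (inclusive; configurable). The clamp
makes the model one-sided by construction: a prey at or below its control
rate scores exactly 0.5 and can never qualify, so depletion is never
mistaken for interaction. Estimating λ1 from the same counts being scored
makes the probability conservative for small counts (a single spectrum
cannot reach 0.9) — the intended behaviour for an identification filter.
This is a deliberately minimal, fully specified model in the tradition of
probabilistic spectral-count scorers; it is not a numerical re-implementation
of any published tool, and the test suite checks its *calibration* (data
simulated from the model yields empirical enrichment frequencies matching
the stated probabilities within ±0.05 per decile) rather than agreement
with external software.

## NSAF and the relative enrichment factor

NSAF_i = (SpC_i/L_i)/Σ_j(SpC_j/L_j) within each run; condition-level
profiles are the arithmetic mean of per-replicate profiles (pooled-count
NSAF is available via `profile_mode="pooled"`). Each prey's AP/WCL NSAF
quotient is normalised by the mean quotient of the reference set minus the
bait, giving the REF. Choices worth noting:

- **Zero-WCL preys** are excluded from REF with a log message rather than
  floored: inventing a denominator would manufacture unbounded enrichment.
  A pseudo-floor is deliberately not the default.
- **The bait is reported but never normalises.** Its REF (≈ overexpression
  factor when reference enrichments average 1) is informative but would
  bias the reference mean.
- REF tables round to two decimals in the written reports; full precision
  is kept internally and in the returned frames.
- The normalisation identity — mean REF over non-bait reference members
  present equals 1 — holds to machine precision and is asserted in tests.

Candidate nomination ranks non-reference preys by minimum REF across baits;
"member-like" requires REF ≥ 0.3 in every bait, and the report lists
everything reaching 0.1 anywhere. Thresholds are configurable; the defaults
match the conventions of the motivating MSC study.

## Digestion and isoform evidence

Trypsin is modelled as cleavage C-terminal to K/R, suppressed before
proline — the simple rule consistent with observed uncleaved K–P peptides
in real data — with up to one missed cleavage and a 7-residue minimum by
default. Coordinates are 1-based inclusive. N-terminal processing emits the
Met-retained and (when residue 2 is A/C/G/P/S/T/V, the standard
aminopeptidase specificity) Met-excised forms of the first tryptic peptide,
each with or without +42 Da acetylation; the modification is tracked
nominally as the integer 42 with no exact-mass bookkeeping.

A peptide is **unique** to an isoform iff it occurs, honouring digestion
boundaries (or as a processed N-terminal form), in exactly one database
sequence; occurrences in several make it **shared**, except the diagnostic
coincidence where a canonical protein's Met-retained N-terminal peptide is
also an internal tryptic peptide of an N-terminally extended isoform —
flagged **ambiguous N-terminal**, since the spectrum cannot tell the two
proteoforms apart. Uniqueness is checked database-wide, never merely within
an isoform group. Spectral tallies sum unique-peptide counts per isoform;
shared and ambiguous counts are reported separately and never apportioned.

## Synthetic data generator

`simulate` emulates the study conditions the analysis assumes: a 12-member
core complex, three members overexpressed 4× as baits with three biological
replicates each, one mock-control run, one whole-cell-lysate run at 100 000
expected spectra (bait/control runs at 20 000), 200 background proteins of
which 30% bind stickily at 10% of their WCL abundance (placing their REF
near 0.1, where real ribosomal/tubulin contaminants sit), per-member
complex enrichment drawn uniformly from [0.3, 1.7], and one candidate
member planted at enrichment 0.5 but excluded from the reference set.
Counts are independent Poisson draws of depth × relative abundance after
per-run log-normal abundance jitter (σ = 0.2, renormalised so expected run
totals equal the configured depth). Sequences are uniform-random over the
20 residues (lengths 150–1500) — no homology structure, since only
digestion/uniqueness structure matters downstream — plus two engineered
isoform pairs: a 24-residue N-terminal extension and an internal deletion
whose junction-spanning tryptic peptide is verified unique across the
database (regenerated under a bounded retry if not).

What this does and does not show: recovery tests demonstrate that the
pipeline's inferences are correct *under its own noise model* (Poisson
counts, log-normal replicate variability, independent proteins). Real
AP-MS data add peptide-level sampling biases, shared-peptide protein
inference, saturation of abundant species, batch structure and correlated
contaminants, none of which are simulated; passing tests certify the
statistical machinery, not instrument-level realism.

Sampling-variability consequences worth knowing when interpreting single
runs: a bait's self-REF is (overexpression) ÷ (mean of 11 draws from
U[0.3, 1.7]), so individual experiments scatter roughly between 2 and 6
around the expected ≈4 — seed-level means, not single seeds, sit reliably
in the 3–5 band — and the candidate's per-experiment REF inherits its WCL
sampling error across all baits at once. Recovery assertions therefore
aggregate over 20 seeds, while all-core-members-qualify holds seed by seed.

## Numerical and interface choices

- Posteriors are computed from log-pmfs with the log-odds clipped to ±700
  before exponentiation; probabilities are exact at the extremes.
- Filtering, scoring and reports are deterministic given inputs; the
  simulator is deterministic given `seed` (database, counts and peptide
  streams use distinct seed offsets so stages can be regenerated
  independently).
- Tables are UTF-8 TSV with a header row; blank count cells read as 0;
  counts must be non-negative integers.
- Ties in the qualified-prey ordering break by total spectra (descending)
  then accession, making reports reproducible byte for byte.
- The FASTA reader tracks line numbers so malformed input is reported by
  line; duplicate accessions are rejected at read time.
- Problem sizes in the test suite (databases of ~217 proteins, depths of
  2×10⁴–10⁵ spectra, 20-seed recovery sweeps, 50-sequence digestion
  oracles) were chosen as the smallest scales at which the planted effects
  are statistically unambiguous.

## Known limitations

- Protein inference is per accession; the optional greedy parsimony
  collapse merges only *identical* peptide sets and is no substitute for
  full protein-grouping algorithms.
- The interaction model ignores replicate covariance and prey-prey
  correlation; its FDR on real data should be estimated against real
  controls rather than assumed from the synthetic analogue.
- NSAF's dynamic-range compression is inherited by REF: values rank
  enrichment but should not be read as stoichiometry.
- Only N-terminal acetylation (+42) is modelled; other PTMs are out of
  scope, as are raw-spectrum formats (mzML/mgf/pepXML) — inputs are
  count tables, not spectra.
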