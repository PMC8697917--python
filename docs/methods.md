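# Methods

## Measurement model and diagnostic features

The unit of observation is a single worm.  Each specimen carries up to 21
haptoral and 2 genital length measurements in micrometres: five lengths per
anchor (dorsal/ventral), two per transversal bar, seven marginal hook pair
lengths (pairs I–V ventral, VI–VII dorsal), and the axial lengths of the
copulatory tube and accessory piece (AP).  Two categorical characters are
carried alongside: the side (left/right/unknown) from which the AP loops the
copulatory tube, and an optional boolean for "broad inner anchor roots", a
qualitative character with no numeric definition.

Missing values are a first-class state, distinct from zero.  Diagnostic
ratios (inner/outer root length per anchor; inner root length over hook pair
I; dorsal length-to-notch and dorsal bar branch length over hook pair I) are
computed per specimen and propagate missingness: a ratio is `None` exactly
when an operand is missing.  Summary proportions are averages of
per-specimen ratios, never ratios of averaged lengths — the embedded tables
follow the same convention, which is why a printed mean proportion (e.g.
3.2) can differ from the quotient of the printed means (16.0/4.9 ≈ 3.27).
Units are fixed to µm throughout; there is no conversion layer.

## Reference tables

Twelve species profiles are embedded (eleven newly delineated species plus
*K. pellonulae*, whose column was compiled from its original description).
*K. chochamandai* carries two host-specific measurement columns
(*Microthrissa moeruensis*, the type host, and *Potamothrissa
acutirostris*).  Each cell stores (min, mean, max, n); single-value cells
are stored with min = mean = max, and range-only cells (all of the
*K. pellonulae* column) expose the midpoint as a working mean flagged as
imputed.  A cross-check compares every printed proportion row against the
ratio of the corresponding length means and reports (rather than fails on)
gross disagreements; at a 35% relative tolerance none arises.

Thirty host-survey rows are embedded, one per museum lot or fresh
collection, totalling 172 examined fish.  Worm counts per infected host are
attached wherever the published infection account fixes the per-host
distribution, including two cases resolvable by arithmetic: "one or two
worms each" over 8 hosts with 11 worms total fixes five singles and three
doubles (*K. rochetteae*), and the same phrase over 3 hosts at intensity 1.3
fixes `[1, 1, 2]` (*K. hahni*).  Counts published only as a range (e.g. "one
to three worms") stay unresolved; those records expose the reported infected
count and mean intensity but no per-host vector, and the statistics module
refuses to summarize them rather than guessing.  Where an infection account
pools several survey rows, the counts are attached to the row holding the
symbiotype lot with a pooling note.  Locality spellings follow the survey
table; textual variants ("Manianga", "Aboumé") are handled by an alias map,
as are host-name variants ("Odaxothrissa ansorgi").

## The key as a decision tree

The printed key has 13 couplets and 14 terminal species spanning 11 host
species.  Conditions are conjunctions of atomic clauses over measurements,
ratios, the AP loop side, and (in couplets 1, 4 and 6) the host identity.
Couplet 1's second lead, "anchors different", is modeled as the logical
complement of the first lead.

Evaluation is three-valued.  A clause over a missing operand is undecided;
so is a strict comparison landing exactly on its threshold (the key defines
"< 19" and "> 19" but not 19).  A conjunction is false as soon as one clause
is false, undecided if none is false and one is undecided.  Two clauses are
*optional* — the broad-roots boolean and couplet 1's host gloss — meaning
they are skipped (not undecided) when the information is absent, so the
quantitative conditions alone decide.  A lead is followed alone only when it
is the single lead not known to be false; in every other situation both
leads are explored, the candidate sets are unioned, and a note records the
reason (missing operand/boundary, both leads satisfied, or neither —
the latter meaning the key itself is contradictory for that specimen).

Host use defaults on because two couplets are purely host-based; a host-free
mode treats host clauses as undecided.  With host information, candidates
never recorded from the specimen's host are dropped at the end when at least
one consistent candidate remains (noted in the trace).  This filter is what
makes the candidate set a subset of the species recorded from the host even
where the key is internally contradictory.  Two modes exist: `strict`
(exactly as printed, default) and `annotated` (identical routing, plus
warnings at couplets known to conflict with the species accounts).  No
"corrected" key is fabricated.

### Known key/table conflicts

Routing the mean measurements of every embedded profile column (host-aware)
reproduces the species' own terminal for nine of the thirteen columns.  The
four exceptions are genuine conflicts in the source material, enumerated by
`validate_key` and asserted in the tests:

1. **Couplet 11 (AP side).**  The key sends AP-right specimens to
   *K. rochetteae*, but the accounts describe the loop of *K. rochetteae*
   from the left and of *K. bisthoveni* from the right.  Both species
   therefore satisfy *neither* lead of couplet 11 (their hook VI–VII lengths
   sit on the opposite side of 15 µm from their AP side), both leads are
   explored, and only the host filter resolves them.
2. **Couplet 10 (*K. boegeri*).**  Its mean dorsal inner root (11.2 µm) is
   shorter than its hook pair I (16.2 µm), a ratio below 1, so the key
   routes it toward couplet 13 although it is keyed out at couplet 12.
3. **Couplet 13 (*K. chochamandai* ex *P. acutirostris*).**  The single
   specimen's ventral length to notch is 18.5 µm, below the "> 19 µm" lead
   that names its species.

A fifth, milder conflict is annotated rather than counted: the mean
measurements of *K. verbisti* satisfy couplet 1's quantitative conditions
despite the species not infecting *Odaxothrissa*; with host information the
host clause resolves it correctly.

The *K. hahni* column has no dorsal-anchor measurements at all, so couplet 8
cannot be decided for it; its mean specimen returns {*hahni*, *verbisti*}
with a missing-data note.  That is classified as a match with missing data,
not a key inconsistency.

### A note on monotonicity

Adding a measurement to a record never enlarges its candidate set — except
when a routing passes through a couplet at which neither lead is satisfied
(the couplet-11 contradiction): there, extra information can reveal the
contradiction and force both branches.  The property test is therefore
scoped to contradiction-free routings.

## Infection statistics

Prevalence = infected/examined hosts, mean intensity = worms per infected
host (undefined at zero infected), mean abundance = worms per examined host,
so abundance = prevalence × intensity.  Arithmetic is exact
(`fractions.Fraction`); display rounding is half-up to one decimal, matching
the published convention (11/8 → 1.4).  Pooling is examined-weighted.

## Ordination

The morphometric matrix uses 20 haptoral parameters: hook pair VII is
excluded outright as the structure most often impossible to measure.
Variables and then specimens with more than 50% missing entries (the
threshold is configurable) are dropped, columns first; residual missing
cells take the column mean, with every imputation logged so that users can
compare strategies — the source protocol is silent on residual missingness.
Columns are standardized (mean 0, sd 1, ddof = 1) before analysis; this is
the package's rendering of "autotransformation", which is
software-specific — morphometric lengths share a unit, and standardization
gives every parameter equal weight.  A no-transform switch exists.

PCA is a full eigendecomposition of the standardized matrix; explained
percentages cover all axes, are non-increasing, and sum to 100.  Axis signs
follow a deterministic convention (largest-magnitude loading positive).
Zero-variance columns are dropped with a warning.

NMDS minimizes Kruskal stress-1 (isotonic disparities) on Euclidean
dissimilarities of the standardized data by default — community-ecology
software often defaults to Bray-Curtis, which suits abundances rather than
lengths; the metric is configurable.  The optimizer runs SMACOF from a
classical-scaling start plus seeded random restarts (8 by default) and keeps
the lowest-stress configuration; the classical start recovers stress 0
exactly on data that are already k-dimensional.  Stress is non-increasing in
k on fixed data and seed.

The published first-two-axes variance figures were obtained from the raw
per-specimen appendix, which is not part of this package; the tests and the
acceptance script run the identical protocol end to end on simulated
specimens of every species and check structural validity, and the
acceptance output reports the simulated-data axis percentages under their
own names.

## Synthetic specimens

The tables publish only (min, mean, max, n), so the generator models each
parameter as a normal truncated to [min, max] with sd = f·(max − min).  The
default f = 0.25 treats the printed range as roughly a ±2 sd interval, a
common reading of range summaries at these sample sizes.  Because
truncation at asymmetric bounds biases the realized mean, the latent
location is solved numerically (Brent root-finding on the truncated-normal
mean) so that the *truncated* mean equals the printed mean; targets within
3% of the range of a bound are clamped to the attainable region, which only
affects near-degenerate cells whose printed mean coincides with an endpoint.
Single-value cells are reproduced verbatim.

A per-specimen latent size factor z induces a Gaussian-copula correlation ρ
(default 0.5) across all length parameters of one worm, a minimal model of
allometry; no covariance data are published, so ρ is a free knob.  Ratios
are never sampled — operands are sampled and ratios computed — so a tail
specimen can fall outside the printed proportion rows; the recovery report
surfaces this rather than clamping it.  Missingness is applied after
sampling, 5% per parameter by default and 50% for hook pair VII.
Parameters absent from a profile column are emitted missing with a warning.
Surveys are simulated as independent Bernoulli infections with
zero-truncated Poisson worm counts (inverse-CDF conditional on ≥ 1 worm).

### What the generator does and does not emulate

It matches the printed location, range and (approximately) dispersion of
every parameter, the qualitative characters, and a crude allometric
correlation.  It does not model measurement error, fixation-method size
effects, within-host dependence between worms, bilateral asymmetry, or the
true covariance structure of sclerite growth.  Passing recovery tests
therefore show that the key separates species *under the published
summaries' own geometry* — not that field identification reaches the same
accuracy.

## Parameter recovery

For each of the 13 measurement columns, specimens are simulated without
missingness and identified host-aware.  A column is *decision-path
eligible* when the printed ranges alone decide every couplet on its path:
the whole range (printed proportion rows are preferred for ratio clauses,
interval arithmetic on operand ranges otherwise) lies strictly on the
deciding side of every threshold, and no decision parameter is absent.
Seven columns are eligible (voreli, marispastoris, parisellei, pellonulae,
hugei, verbisti, chochamandai ex type host) and identify as the sole
candidate at ≥ 99% over 1000 specimens per column.  The ineligible columns
each carry a reason: *K. sefcae*'s ventral length-to-notch range (18.2–33.3)
straddles couplet 1's 24 µm threshold, so a few percent of simulated
specimens take the wrong first branch — an honest overlap between table and
key; *K. hahni* lacks dorsal-anchor data; the remaining four are the
key/table conflicts above.  Accuracy counts a specimen only when the
generating species is the sole candidate; the confusion matrix reports
everything else, including ambiguous outcomes.

## Problem sizes and numerical choices

The recovery study uses 1000 specimens per column (13 000 identifications);
generator calibration checks use n = 2000 per parameter; the all-species
protocol run uses 10 specimens per column; the survey calibration uses
10 000 hosts.  The NMDS SMACOF tolerance is 1e-9 with 500 iterations and 8
starts; the truncated-normal location solver uses brentq at xtol = 1e-10.
All randomness in any run flows from a single integer seed.

## Known limitations

- The key engine is generic over couplet lists but only the
  *Kapentagyrus* key ships; no probabilistic or fuzzy identification.
- Morphometric profiles of the two Lake Tanganyika species are published
  elsewhere and are not embedded; they participate only as key terminals
  and registry entries.
- Proposed future characters (root angles, root widths, bulb widths) have
  no measurement protocol and are not modeled.
- The ordination does not attempt to reproduce published figures
  graphically, and no vector-fitting significance tests are provided.
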