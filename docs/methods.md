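# Methods

## Substitution model and distances

Sequence evolution and distance correction both use Kimura's 2-parameter
model.  Rates are normalized so that one unit of branch length equals one
expected substitution per site: with transition/transversion rate ratio
κ (default 2.0), β = 1/(κ+2), α = κβ, and the probability that a site shows
a transition (P) or transversion (Q) difference after branch length *t* is

    P(t) = ¼ + ¼·e^(−4βt) − ½·e^(−2(α+β)t)
    Q(t) = ½ − ½·e^(−4βt)

The simulator samples each site independently from these closed forms (no
Gillespie simulation is needed because sites are independent and the model
is time-reversible).  The estimator inverts the observed proportions:

    d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

Sites with a gap or ambiguous base in either sequence are excluded
(pairwise deletion).  When `1−2P−Q ≤ 0` or `1−2Q ≤ 0` the distance is
undefined (saturation); such pairs are reported as a distinct signal (NaN in
matrices, a typed exception in scalar calls) and tree building refuses to
proceed until they are removed.  At a 1:2 transition:transversion ratio the
formula reduces exactly to the Jukes–Cantor distance, which the tests use
as a cross-check.

## Simulator

The forward simulator evolves a TE family down a rooted host strain tree.
A full-length element is `5'LTR + internal + 3'LTR` (defaults 300 bp +
4000 bp + 300 bp; the two subfamily references are generated by evolving a
common ancestor by 0.25 substitutions/site, so their internal regions are
column-homologous by construction).  Per-element events are Poisson in
branch length: transposition (copy), solo-LTR formation (intra-element
LTR–LTR recombination leaving one LTR), truncation (a contiguous 20–70 %
terminal deletion), and loss.  Scheduled events address branches by node
label: HTT copies one donor element's state at a stated fraction of the
donor branch into a recipient branch (donors are processed before
recipients via a topological sort, so cross-subtree transfers are exact);
recombination splices the internal regions of two co-occurring subfamilies
at stated breakpoints; subfamily extinction removes all copies of a
subfamily on a branch, which is how lineage-restricted distributions are
produced.

Design choices and what they imply:

* **No indels.**  Truth alignments are gap-free column stacks of internal
  regions ('N' over truncated spans).  This keeps homology bookkeeping
  exact; real data require an external aligner, and alignment error is
  outside what these tests exercise.
* **Host background is i.i.d. random sequence.**  Sufficient for depth
  baselines and insertion context; no gene structure, GC structure or
  repeats, so mappability artifacts of real genomes are not modeled.
* **Read simulation** samples uniform start positions and projects reads
  onto query coordinates through the truth homology map — no aligner is
  involved, so divergence-dependent mapping loss is not modeled.  Base
  errors are symmetric substitutions at a configurable rate.
* **No within-genome homogenization.**  Gene conversion between copies is
  not simulated, so within-strain copies coalesce at their transposition
  times, not recently; simulated data therefore do *not* reproduce the
  concerted-evolution pattern seen in real Ty4/Tsu4 data, and
  `concerted_evolution_check` is validated on constructed datasets instead.
* **Truncation uses full-length sequence bookkeeping**: the unretained part
  of a truncated element continues to evolve silently.  A scheduled
  recombination event prefers intact parents and falls back to any
  surviving copy's full-length sequence state when none remains.

## Copy number, presence, activity

Copy number for a region is `mean(depth over region) / baseline depth`,
edges included; LTR copy number is the mean over the union of both LTR
intervals normalized once (an explicit assumption — per-LTR normalization
then summing would differ at partially deleted copies).  The baseline is
the mean depth over single-copy background truth intervals in synthetic
mode and a user-supplied scalar otherwise.  Fold coverage above 100× is
capped by seeded binomial read thinning.  Presence thresholds are strict:
LTR > 1.0, internal > 0.5.  Interpretation: internal presence or any FLE ⇒
recent activity; LTR-only ⇒ recent or past activity; neither ⇒ no evidence.

## Annotation

Hits (whitespace-delimited, 0-based half-open, plus-frame query
coordinates) are chained into elements when same-target/strand/query,
target gap ≤ 250 bp, and query-collinear for the strand.  Classification
from per-region query coverage: solo_LTR if ≥ 0.8 of one LTR and < 5 % of
the internal region; FLE if ≥ 0.9 of the internal and ≥ 0.8 of both LTRs;
else truncated.  The 0.9/0.8/5 % thresholds are this package's choices
(exposed in config); they separate the three classes cleanly on simulated
data because simulated truncations remove 20–70 % of an element.

The de novo LTR-pair detector seeds exact 12-mers, extends ungapped with an
X-drop, and enforces repeat length 100–1000, start-to-start distance
1.5–15 kb, identity ≥ 0.80, a 5-bp target-site duplication and `tg…ca`
termini (all configurable).  Because maximal-score extension can overrun
identical repeats by a few chance flank matches, boundaries are refined
within a ±10 bp vicinity to anchor the terminal motif.  Overlapping
candidates are resolved best-first by identity × length.

Rescue of divergent subfamilies promotes truncated elements to FLE when
(a) the element span reciprocally overlaps an LTR-pair prediction by ≥ 80 %
and (b) it belongs to a connected group of ≥ 3 elements with pairwise
identity ≥ 0.8 (edit-distance identity via edlib) dispersed over ≥ 2 target
sequences.

## Consensus

Per-site base counts (records with mapq < 20 or baseq < 20 discarded) are
reduced to a majority consensus; ties and zero-depth sites emit 'N' — never
the query base, so missingness is explicit rather than reference-biased.
No IUPAC ambiguity codes beyond 'N' are emitted.  A strain's consensus is
kept only when normalized internal depth > 0.75 and breadth > 0.9 (strict).

## Breakpoint calling

Sliding windows (50 bp window, 10 bp step, in alignment columns) yield
d(candidate, parent) per parent; windows with < 50 % comparable sites are
missing and break evidence runs.  Δd = d(·,A) − d(·,B) changes sign at a
breakpoint; runs of ≥ 3 same-sign windows delimit segments and the
breakpoint is placed midway between flanking window centers.  Because
adjacent windows share columns, a cluster of private mutations can flip a
few consecutive windows without any parent switch; runs whose mean |Δd| is
below 0.5× the profile's median |Δd| are therefore discarded as weak
evidence (`min_delta_ratio`, config).  The sign-run rule was chosen over
chi-square maximization for transparency; with visually-localized
breakpoints as the only precedent, agreement is expected at segment level,
within about one window of the true coordinate.

## Trees and HTT flags

NJ (classic) and BIONJ (variance-weighted reduction with λ clamped to
[0, 1]) are implemented directly so that additive matrices are recovered
exactly (branch lengths to 1e−9) and agglomeration tie-breaks are
deterministic (lexicographically smallest representative pair).  Negative
branch estimates are clamped to zero with the deficit moved to the paired
branch.  Bootstrap supports resample column indices only, so they are
invariant to taxon input order; replicates with saturated pairs are
discarded from the denominator.  Midpoint rooting and patristic distances
use dendropy.

HTT flags:

* **incongruence** — a maximal single-species group of elements nested,
  with support, inside another species' diversity when that species is not
  the host-tree sister of its own.  The placement is read from the smallest
  split side with bootstrap support ≥ 70 that encloses the group: walking
  one level up past an unstable attachment (it rarely matters *which* donor
  element is closest) while still requiring the enclosing context to be a
  single other species.  Three guards keep the test specific: the other
  species must have elements on *both* sides of the split (true nesting —
  vertical descent under incomplete sampling, e.g. a lineage whose copies
  all decayed to solo LTRs, yields clean sister placements instead); the
  group must attach at a patristic distance below `incongruence_ratio`
  (default 0.5) × the host divergence of the species pair (an arbitrary
  but well-resampled resolution of a deep paralog polytomy attaches at full
  depth); and the enclosing species must differ from the host-tree sister.
  In the pipeline, flags are evaluated on one TE tree per subfamily: mixing
  subfamilies in one tree lets differential solo-LTR loss masquerade as
  discordance.
* **excess_similarity** — for a species pair, the minimum cross-species TE
  patristic distance is below `ratio` (default 0.5) × the median
  within-species TE distance *and* below `ratio` × the host divergence of
  the pair.  The second condition is this package's addition: with deep
  within-genome paralog diversity the median within-species distance alone
  is not a stringent yardstick, whereas vertical descent bounds the closest
  cross-species TE pair from below by host divergence.
* **patchy_distribution** — a subfamily present in a set of host tips that
  is not a clade of the rooted host tree (rooted semantics deliberately,
  since presence patterns are polarized by the root), with at least 2
  absent tips (`patchy_min_absent`): one absent strain is parsimoniously a
  single loss event, not a patchy distribution.

ML tree inference is deliberately not implemented: the claims the pipeline
reproduces are clade-membership statements that distance methods resolve on
simulated data.

## Bundled scenarios

`vertical_only` (both subfamilies everywhere, no events),
`recombinant_only` (chimera without transfer), `htt_single` (Tsu4-like
restricted to one of three lineages by scheduled extinction, then
transferred into a non-sister lineage's strain), and
`htt_plus_recombinant` (additionally, a chimera with two breakpoints —
default 1300/3300, bounding a ~2 kb middle segment — forms in the recipient
genome; a single 5′ breakpoint variant is a config change).  Defaults: 9
strains in 3 lineages, exponential branch lengths with mean 0.01
substitutions/site and deepened lineage stems, 2 root copies per subfamily,
transposition rate 2.0 and solo-LTR/truncation rates 0.5 per element per
branch-length unit, 150 kb backgrounds, 30× coverage with 100-bp reads and
1 % read error, hit fragmentation probability 0.3.  These sizes keep a full
run under ~5 s while leaving every stage non-trivial (multi-copy strains,
fragmented hits, all three element classes).

## Evaluation battery

`retrohtt.evaluation` re-derives each stage's operating characteristics
from scratch: K2P closed-form and symmetry checks; exact NJ/BIONJ recovery
of 50 random additive 6-taxon trees; a copy-number ladder (k ∈ {0,1,5,20},
20 replicates, 30×); classification of ≥ 200 simulated elements at ≤ 15 %
divergence with fragmentation probability 0.5; planted LTR-pair recall and
a 1 Mb random-sequence false-positive scan; consensus fidelity with and
without read error; planted chimera breakpoint recovery over 20 seeds; the
HTT × recombination factorial (5 seeds per cell, any-flag sensitivity vs
false-flag rate); and partitioned-tree placement of a mid-point-breakpoint
chimera with each parent (support ≥ 70).  `scripts/acceptance.py` runs the
battery and the end-to-end scenario and writes all metrics as JSON.

## Known limitations

Real-data inputs (BAM pileups, RepeatMasker output) are consumed only
through the documented text formats; read mapping, alignment construction
and variant calling are upstream concerns.  The flags' false-positive
behavior is characterized under the simulator's assumptions (no gene
conversion, no incomplete lineage sorting, clock-like rates); ILS in
particular can mimic incongruence and is not modeled.  Copy-number
estimates ignore mappability and GC bias.  Breakpoint coordinates are
window-resolution, not base-resolution.
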