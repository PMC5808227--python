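# Methods

## Scope and model

`barcodegap` screens a single-locus sequence collection for entries whose
pairwise-distance pattern is inconsistent with their species label. The
screen assumes a barcode gap: within-species divergence concentrated well
below a threshold `t_intra` and between-species divergence well above a
threshold `t_inter`. Both thresholds are quoted in percent on the command
line (defaults 1% and 10%, the conventional ruler for mitochondrial
protein-coding markers in fishes) and stored as fractions internally.

Divergence is the Kimura 2-parameter (K2P) estimate
`d = −½ ln[(1−2P−Q)√(1−2Q)]`, with P and Q the transition and transversion
difference proportions over the sites compared. K2P assumes equal base
frequencies and a single transition/transversion rate ratio; at the depths
the ruler cares about (≤ ~20%) it is nearly indistinguishable from more
highly parameterized corrections, and it is the estimator the screening
tradition is calibrated to.

## Anchoring and trimming

Fragments of heterogeneous extent are standardized by pairwise alignment to
one full-length reference coding sequence (global alignment with free end
gaps; match +2, mismatch −3, gap open −5, gap extend −2; both orientations
tried, higher score kept). The alignment is projected to reference
coordinates: insertions relative to the reference are dropped, and terminal
aligned blocks are extended diagonally to the sequence ends, because a
fragment is a contiguous subsequence of the gene and free end gaps would
otherwise shave mismatching terminal bases off the anchored extent.
A fragment whose overall identity to the reference (matches over fragment
length) falls below 0.50 is reported as unanchorable and excluded —
a guard against non-homologous contaminants.

This replaces a multiple alignment: for an indel-sparse protein-coding
locus, reference-coordinate projection yields directly comparable columns
at O(N·L²) instead of O(N²·L), and an externally computed MSA can still be
ingested as a pre-aligned FASTA. The cost is that reference-relative
insertions are invisible to the screen; for this locus they are rare and
carry little distance information.

The analysis window is selected over the breakpoint set of fragment starts
and ends, maximizing (number of fragments fully covering the window) ×
(window length); ties prefer the longer window, then the smaller start.
A minimum-coverage-fraction objective (longest window covered by a given
fraction of fragments) is available as an alternative. Window coverage of
a fragment is its anchored *extent* over the window: occasional internal
alignment gaps do not disqualify a spanning fragment, they simply drop out
of individual comparisons through pairwise deletion. At the default
coverage of 1.0 the result is a fixed-length dataset; partial-window rows
can be admitted by lowering it.

## Distances

All pairs are computed with pairwise deletion: a site is skipped for a pair
when either sequence carries a gap or any non-ACGT IUPAC code (ambiguity
codes are excluded outright, never fractionally matched, so the matrix is
deterministic and symmetric). Two sentinels replace numbers: saturation
(log argument ≤ 0) and insufficient overlap (fewer than `min_overlap`
compared sites, default 100 — guards against distances estimated from tiny
fragment overlaps; configurable down to ~50 for very short fragments).
Sentinels propagate: they are counted and reported, never flagged on, and
neighbor joining refuses a matrix containing them rather than imputing.

## Saturation test

Iss is the observed mean per-site Shannon entropy over the expected entropy
at full substitution saturation, H_FSS, computed from the alignment's base
composition — exactly (multinomial enumeration) for NumOTU ≤ 8, by Monte
Carlo (20 000 seeded draws) above. Iss is evaluated on 32 random subsamples
per NumOTU ∈ {4, 8, 16, 32}; the standard error is
sd(per-site H)/(H_FSS·√sites), T = (Iss.c − Iss)/SE is referred to a t
distribution with DF = sites − 1, and a two-sided p is reported for both
the symmetric- and asymmetric-topology critical value.

Critical values are pluggable. The bundled default table (NumOTU 4/8/16/32,
symmetric 0.817/0.784/0.766/0.742, asymmetric 0.785/0.677/0.565/0.431)
carries reference values appropriate for alignments of roughly a thousand
sites. Alternatively `calibrate_iss_c` derives Iss.c by simulation: evolve
alignments on a balanced (symmetric) or caterpillar (asymmetric) topology
across a grid of edge depths, record mean Iss and the fraction of replicates
in which neighbor joining recovers the generating topology, monotone-smooth
recovery along the depth grid, and linearly interpolate the Iss at which
recovery crosses 0.95. The 0.95 criterion and linear interpolation are this
package's choices; recovery is also low at *very* shallow depths (no
substitutions, arbitrary resolution), which the shallowest-grid-point error
surfaces rather than hides.

## Flags

- `DEEP_INTRA`, sequence level: the minimum distance from a sequence to any
  conspecific strictly exceeds `t_intra` — the isolation signature of a
  mislabel, contaminant or submission error. Species level (the accession
  column carries the species name): the species' intraspecific range
  exceeds `t_intra` but no single sequence is isolated — the signature of a
  cryptic complex. The two levels are mutually exclusive per species.
- `SHALLOW_INTER`, one flag per unordered species pair whose minimum
  interspecific distance is strictly below `t_inter`: recent divergence,
  introgression, synonymy or misidentification.
- `INVERSION`: a sequence strictly closer to some heterospecific than to
  any conspecific, *given* both ruler conditions are violated (its
  conspecific minimum exceeds `t_intra`, its heterospecific minimum falls
  below `t_inter`). The conditioning reflects that inversions are drawn
  from the already-problematic set; without it, every ordinary conspecific
  of an anomalous sequence would flip a coin on whether the anomaly happens
  to be its nearest neighbor, flooding the flag set with sequences whose
  own divergences are perfectly ordinary.

Both thresholds are strict inequalities. Severity is the threshold
exceedance (for inversions, the conspecific–heterospecific margin); reports
deduplicate to one row per (accession, category), sorted by severity then
accession, and are byte-reproducible for identical inputs.

## Neighbor joining and bootstrap

Saitou–Nei agglomeration in the O(n³) Studier–Keppler form, joining the
pair minimizing Q(i,j) = (r−2)d(i,j) − R_i − R_j. Ties break on the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest leaf), making the tree deterministic. Negative branch-length
estimates are clamped to zero with the deficit moved to the sister edge
(spread over the remaining edges at the final trifurcation); on additive
matrices nothing is clamped and the unique generating tree is recovered
exactly. Bootstrap support resamples alignment columns with replacement,
rebuilds K2P + NJ per replicate, and reports the percentage of replicates
containing each original bipartition; replicates producing sentinel
distances are dropped and counted, with a warning above 10%. Case trees are
built on per-flag subsets (flagged species plus their evidence partners,
capped at 30 leaves), not on the full matrix.

## Synthetic data

The generator emulates the structure the screen assumes, with ground truth.
A species tree with a birth-process (Yule) topology is drawn; terminal
species branches are fixed at 45% of the interspecific depth and internal
branches are exponential, rescaled so the expected between-species
*sequence* divergence equals `inter_depth` (the species-path target is
`inter_depth − intra_depth`, since tips add `intra_depth/2` each). Fixing
the stems concentrates species divergences near `inter_depth` — even sister
species differ by ≥ ~90% of it — mirroring the deep, well-separated
interspecific distances of a real barcode-gap locus. Within species, tips
hang off the species root in a star at depth `intra_depth/2`, so every
conspecific pair has expected divergence exactly `intra_depth`; a star was
chosen over a coalescent precisely to make that scale exact. Sequences
evolve site-independently under a two-rate substitution model
(transition/transversion rate ratio `kappa`, default 4) using closed-form
per-branch substitution probabilities — no event simulation.

Defaults are the package's study conditions: 40 species × 5 sequences,
918 bp, `intra_depth` 0.005, `inter_depth` 0.15, uniform base frequencies.

Anomalies are injected disjointly per sequence, counts = round(rate × n):
mislabels (label swapped to another species), introgression (sequence
re-evolved from the nearest other species' ancestor, label kept), chimeras
(back half from another species), cryptic splits (a conspecific subcluster
offset by 10 × `intra_depth`), and synonym pairs (part of a species
relabeled under a generated alias, registered in a synonym table). At most
one anomaly may bridge any (bases-origin species, label species) pair: two
anomalies sharing a bridge would be each other's nearest "conspecifics" and
neither could be recovered from distances, which would make the ground
truth ambiguous. Fragmentation, when enabled, truncates each record to a
sampled (offset, length) window; the reference is always emitted
full-length.

What the generator does **not** emulate: coalescent variance in
intraspecific genealogies, indels, sequencing error, rate variation among
lineages or sites, and base-composition bias. Tests passing on this
generator therefore demonstrate the *logic* of the screen — that the flag
rules recover the injected anomaly classes under a clean barcode gap — not
its behavior on data violating those assumptions.

One consequence of honest noise is worth stating: with a true conspecific
divergence of 0.005 estimated from 918 sites, roughly 1–2% of conspecific
pairs exceed the 1% ruler by sampling error alone, so even anomaly-free
datasets of 200 sequences usually carry a few marginal species-level rows
and occasionally an isolated-sequence flag. This is intrinsic to applying
a hard threshold to a binomial estimate, and it is the same effect that
makes marginal entries near 1% in real databases ambiguous.

## Numerical and policy choices

- Coordinates 0-based half-open internally; reports print 1-based inclusive.
- Distances are exact binary floats internally; reports round to 4 decimals.
- Degenerate saturation cases: SE = 0 yields T = ±∞ with p = 0 (p = 1 when
  Iss equals Iss.c exactly); H_FSS = 0 (degenerate composition) makes Iss
  undefined.
- All randomness (simulation, subsampling, bootstrap, calibration) flows
  from explicit integer seeds; identical seeds give bit-identical output.
- Pipeline stages write their artifacts before the next stage starts; a
  failing stage halts with its name and preserves prior artifacts, and the
  manifest contains no timestamps so identical runs are byte-identical.

## Known limitations

- No cause attribution: a flag says the distances are inconsistent with the
  label, not why; recent divergence, introgression and misidentification
  can produce identical signatures at a single locus.
- Single-reference anchoring assumes the collection is homologous to one
  contiguous coding region; spliced or rearranged loci are out of scope.
- The bundled Iss.c values are fixed constants; alignments far from ~10³
  sites or extreme compositions warrant recalibration.
- Problem sizes in the test-suite simulations (tens of species, hundreds of
  sequences) are chosen to exercise every code path at desk scale; the
  distance stage is vectorized and handles thousands of rows, but the
  O(n³) NJ is deliberately reserved for per-case subsets.
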