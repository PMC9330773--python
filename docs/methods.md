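# Methods

This note records the models, numerical choices and deliberate
simplifications behind `specmatch`, in enough detail that a user can
judge what the passing test suite does and does not demonstrate.

## Slicing and peak grouping

Every MS2 scan seeds a closed rectangle in (m/z, RT) space centered on
its precursor m/z and scan time, with half-widths of 20 ppm (converted
to Th at the precursor, then frozen — merged slices keep Th bounds) and
0.5 min. Rectangles that overlap in *both* axes are merged into their
coordinate-wise union, across samples, until no two overlap. A shared
endpoint counts as overlap so ties merge deterministically. The
production merger is a sort-and-sweep iterated to a fixed point (a
union can create new overlaps); its contract is defined by a quadratic
brute-force oracle in the test suite, and the sweep is only an
optimization. Output order and seed lists are canonicalized, making the
result independent of input order.

Within each merged slice, each sample's MS1 scans give one EIC (summed
centroid intensity inside the m/z window at each scan time). EICs are
summed on the union of their RT grids with no interpolation — a sample
without a scan at some RT contributes zero there, which avoids
inventing signal at the cost of slightly jagged merged traces when
samples' scan grids differ.

Peak detection is deliberately simple and fully specified: a centered
moving average (default window 5 scans, reflected at the edges), strict
local maxima above a minimum height (default 1e4), boundaries extended
to the nearest local minimum or zero on each side. One peak group per
merged-EIC peak; per-sample peaks join the group whose RT window
contains their apex (nearest window edge otherwise); groups with no
sample peaks are dropped. Seed MS2 scans go to the group with the
nearest apex, if within 0.5 min, each scan to at most one group. Groups
without MS2 evidence can be kept (flagged unannotatable) or discarded.

Consensus spectra cluster fragments greedily: descending-intensity
seeds absorb all unclustered fragments within a ppm window (default
20); each cluster becomes one peak at the intensity-weighted mean m/z
with the mean intensity over scans. The presence filter
(`min_presence_fraction`) defaults to 0 — the hypergeometric score
tolerates chimeric extras, so fragments are kept rather than guessed
away.

## Fragment matching and scores

Matching is greedy one-to-one: reference fragments in descending
intensity order each claim the nearest unmatched observed fragment
within the ppm tolerance; distance ties go to the lower observed m/z.
Greedy (not optimal-assignment) matching is the field norm and makes k
well defined and deterministic.

The hypergeometric score is
`−ln[ C(m,k)·C(N−m,n−k) / C(N,n) ]`, computed with log-binomials. A
direct log-gamma evaluation cancels catastrophically when N is large
(three terms of magnitude ~1e8 differing by ~10), so `ln C(a,b)` is
computed as `Σ ln((a−i)/(b'−i))` over the b' = min(b, a−b) factors
whenever b' ≤ 1e4, falling back to log-gamma otherwise. This keeps
agreement with an exact big-integer rational oracle at ~1e-13 relative
(floored at 1 nat; scores below ~1e-3 nats are limited by double
precision, not by the method). Invalid (k, m, n, N) tuples — including
n−k > N−m, which signals an N too small for the spectra — raise rather
than clamp, so a misconfigured bucket count is loud. Note that
unmatched observed fragments do lower the score (through C(m,k)): 50
noise fragments on a perfect 10-fragment match at N=1e5 cost
ln C(60,10) ≈ 25 nats of 100 — a real but bounded penalty, versus the
cosine score collapsing by ~59% in the same construction.

MVH splits the reference fragments into three intensity-rank classes
(sizes as equal as possible, top class first) and scores
`−ln[ Πᵢ C(nᵢ,kᵢ) · C(N−n, m−k) / C(N,m) ]`. This form was chosen
because it reduces *exactly* to the hypergeometric score for a single
class (binomial symmetry) and needs no arbitrary per-class bucket
rounding; it is our interpretation of the multi-class weighting, not a
transcription of any particular tool's code.

The cosine uses intensity^0.5 weighting by default (exponent
configurable; 1.0 recovers the plain cosine); matched pairs contribute
to the inner product, unmatched fragments only to the norms. k/n and
TIC-fraction scores raise on empty references rather than returning 0.

N defaults to 100,000, appropriate for high-resolution instruments; it
should scale with resolving power so that fragments that belong
together share a bucket.

## Library search

Candidates are filtered by polarity and by precursor m/z within 20 ppm
of the slice center — the slice is precursor-centered, so its center is
the natural precursor estimate (not a peak apex m/z, which chimeric
MS1 signal can bias). Ties in score break by higher k, then
lexicographic compound name; isomers with identical predicted spectra
are therefore ordered arbitrarily but reproducibly, and no claim of
isomer resolution is made. Only the rank-1 hit per (group, library)
enters the annotation table; full rankings are available from
`search_group`.

## In-silico lipid libraries

Species are enumerated as multisets of acyl chains (sn-position is not
resolved, so PC 16:0/18:1 ≡ PC 18:1/16:0); with T chain types and c
chains the count is C(T+c−1, c). The default chain space is even
carbons 12–22 with 0–6 double bonds. The per-chain double-bond cap is
`carbons // 2`, a permissive structural bound that admits the full
default grid; chemically implausible corners (e.g. 12:6) are priced in
as enumeration completeness rather than curated out.

Formulas are built by closed-form bookkeeping: backbone (e.g.
glycerophosphocholine C8H20NO6P for PC, glycerol for TG, cholesterol
for CE, the d18:1 sphingosylphosphorylcholine for SM) plus free fatty
acids minus one water per ester/amide bond, using a single monoisotopic
mass table good to 1e-6 Da. Precursor m/z = (M + adduct delta)/charge.

Fragments come from per-class declarative rule templates: the intact
adduct ion, constant head-group ions (the phosphocholine ion at m/z
184.0733 for PC and SM), neutral losses, per-chain acyl losses as free
acid or ketene, and per-chain carboxylate anions in negative mode.
Adducts without their own template borrow one ([M+NH4]+ and [M+K]+
reuse [M+Na]+; [M+Cl]− and [M+AcOH−H]− reuse [M+FA−H]−): rules flagged
as retaining the charge carrier are re-evaluated at the borrower's mass
delta, the rest keep the donor's m/z. Peaks below 0.2% of the base peak
are removed and spectra are normalized to base peak 100, making that
cutoff a plain threshold of 0.2. Template *intensities* are synthetic
stand-ins chosen to rank each class's canonical diagnostic ions the way
published HCD spectra do — they are not measured values, and classes
can be marked `measured=False` to emit mass-only spectra with uniform
intensities. User classes load from YAML files with the same schema as
the shipped tables, so extending coverage requires no code changes.

## Cross-library comparison and the RBP

Lipid names parse from the shorthand grammar (`CLASS C:D` or
`CLASS c1:d1/c2:d2[/...]`, sphingoid prefixes like `d18:1` tolerated).
Agreement between two libraries' annotations of one feature is the
highest level satisfied: same class → +same adduct → +same summed
composition → +same chain composition (full agreement); adducts compare
as exact strings. The RBP objective is a right-continuous step function
changing only at observed scores, so candidate thresholds are exactly
the observed values; the implementation evaluates all of them
vectorized, with integer-count arithmetic matching the definitional
`(scores >= t).mean()` bit-for-bit so ties break identically, taking
the lowest maximizing threshold (retaining the most annotations).
Reconciliation applies each library's own RBP, classifies every feature
into exactly one category, and reports feature counts plus
adduct-collapsed compound counts (compound identity = class plus chain
composition, or summed composition when chains are unresolved).

## Synthetic data

The generator is the package's test instrument: it plants library
compounds as Gaussian chromatographic peaks (σ = 0.05 min, base height
1e6) at distinct RTs across a configurable gradient, emits MS1 scans on
a 1 s grid with ppm-jittered precursor centroids and exponential
baseline noise peaks, and fires MS2 scans DDA-style — top-3 precursors
per cycle above 1e4, 15 s dynamic exclusion — carrying the library
fragment spectrum with 3 ppm m/z jitter, 10% intensity CV, and a few
exponential chemical-noise fragments. With a chimerism rate, a
co-eluting compound's fragments are merged into an MS2 scan with that
probability, emulating co-isolation. `height_decades` spreads compound
abundances over orders of magnitude (0 by default; 2 decades in the
chimeric benchmark, where dynamic range is what makes chimerism hurt
intensity-based scores). All randomness flows from one
`numpy.random.default_rng(seed)`, so runs are bit-reproducible.

What it does not emulate — and hence what green tests do not show about
real data: isotope envelopes, adduct co-detection, RT drift between
samples, peak tailing, detector saturation, and real chromatographic
backgrounds. Identification rates of ~100% on clean synthetic runs are
a correctness check of the plumbing, not a performance claim.

The chimeric precision benchmark works on a deliberately crowded
gradient (20 compounds in 3 min, so neighbors genuinely co-elute),
removes 8 planted compounds from the search library (their peak groups
model features whose true identity is absent and can only be annotated
wrongly), and adds decoys — library entries with the precursor of a
real species but half their fragment m/z values shifted by several Da —
built from the full library, so a held-out compound's decoy sits at its
precursor like an isobaric wrong species. Precision is compared at the
best recall both scores reach, each score ranking by its own scale.
Under these conditions the hypergeometric score's precision matches or
exceeds the cosine's across seeds, driven by sparse references and
chimera-diluted intensities misleading the cosine.

The comparison-score generator draws agreement/disagreement scores from
zero-truncated normals; the default planted condition
(agree ~ N(30,3), disagree ~ N(10,3), 500 each) mimics well-separated
unimodal score histograms and is recovered by the RBP in essentially
every seed.

## Problem sizes

The default test and acceptance workloads are sized for quick
single-machine iteration: 20 planted compounds × 3 samples per run,
~300-entry libraries for pipeline tests, a ~13,000-entry library for
index checks, ~3,000 oracle tuples for the score grid, 1,000 random
slices/score-sets/windows for the oracle comparisons, and 1,000 seeds
for RBP recovery. All sizes are parameters, and the generator and rule
engine scale to larger studies unchanged.

## Known limitations

- Peak detection is a minimal moving-average detector; it will split
  shoulders and merge badly co-eluting peaks that dedicated detectors
  handle. It is the specification here, not an approximation of one.
- mzML support targets centroided spectra with 32/64-bit float arrays
  (zlib or uncompressed); profile data is accepted with a warning but
  not centroided.
- The SQLite library schema is this package's own documented format,
  not interchange with any other tool.
- Fragmentation templates cover six lipid classes with auditable rules;
  intensity values are declared stand-ins.
- No FDR estimation by decoys is offered as a method: the RBP is
  a pragmatic cross-library surrogate, and the decoy machinery in
  `synthetic_data` exists only for benchmarking.
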