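# specmatch

Headless MS/MS-seeded peak grouping and spectral-library annotation for
data-dependent acquisition (DDA) LC-MS metabolomics and lipidomics.

Untargeted LC-MS/MS experiments produce thousands of chromatographic
features per run, and naming them is the bottleneck: a feature is only a
candidate compound once its fragmentation spectrum has been matched
against a reference library, and the match score must be trustworthy
even when spectra are chimeric (co-isolated precursors) or when the
library carries no intensity information (in-silico libraries).
`specmatch` implements that workflow end to end for people who want a
scriptable, testable pipeline rather than a GUI:

1. **MS2-seeded slicing** — every MS/MS scan seeds a rectangle in
   (m/z, RT) space centered on its precursor; overlapping rectangles are
   merged across samples until none overlap, which confines peak
   detection to regions with fragmentation evidence.
2. **Peak grouping** — per-sample extracted ion chromatograms (EICs)
   inside each slice are summed into a merged EIC whose peaks define
   cross-sample peak groups; MS2 scans are assigned to groups by RT
   proximity and combined into one consensus spectrum per group.
3. **Library search** — consensus spectra are scored against libraries
   (NIST msp, CSV, or an SQLite store) after precursor m/z and polarity
   filtering.
4. **In-silico lipid libraries** — a rule engine enumerates lipid
   species per class over acyl-chain ranges and emits predicted HCD
   fragment spectra per adduct, written as msp.
5. **Cross-library reconciliation** — when two libraries annotate the
   same dataset, agreement levels are classified and a per-library score
   threshold (the Retention Balance Point) is derived to arbitrate.

## The scores

For an observed spectrum with *m* fragments, a reference spectrum with
*n* fragments, *k* one-to-one fragment matches, and *N* non-overlapping
m/z buckets in which a chance match could occur, the **hypergeometric
score (HGS)** is

```
Score(k, m, n, N) = −ln [ C(m,k) · C(N−m, n−k) / C(N,n) ]
```

the negative log-probability of the observed match count arising by
chance. It uses no intensity information, so chimeric contamination
enters only through *m* and in-silico libraries without intensities are
searchable. N reflects instrument resolving power; for high-resolution
data use N ≥ 1e5 (the default).

Also provided: **MVH** (reference fragments split into three intensity
classes, scored under a multivariate hypergeometric model), the
**cosine / dot product** on square-root intensities, **fraction of
reference fragments matched** (k/n), and **fraction of reference TIC
matched**.

The **Retention Balance Point (RBP)** of a library, given score lists
for features where two libraries agree and disagree, is the threshold t
maximizing

```
(#agreements ≥ t)/(#agreements) − (#disagreements ≥ t)/(#disagreements)
```

Annotations scoring below their library's RBP are discarded; a feature
kept by only one library keeps that library's annotation.

## Worked example

```sh
# 1. build a small in-silico lipid library
specmatch build-lipid-library --classes PC,CE --carbons 14:18:2 --db 0:2 \
    --out lib.msp
# -> wrote 162 entries to lib.msp

# 2. simulate a 2-sample DDA run planting 10 of those compounds
specmatch simulate --n-compounds 10 --n-samples 2 --seed 5 \
    --library lib.msp --out run/
# -> wrote 2 mzML files and ground_truth.csv to run/

# 3. group peaks and annotate against the library
specmatch search --mzml run/sample_1.mzML --mzml run/sample_2.mzML \
    --library lib.msp --score hgs --out annotations.csv
# -> 10 annotatable peak groups; table written to annotations.csv
```

`annotations.csv` has one row per peak group with its m/z, apex RT and,
per library, the best-scoring compound, adduct, score and the (k, m, n)
match counts behind it. On this run all 10 planted compounds come back
as rank-1 annotations of themselves, e.g.

```
group_id,mz,rt,lib_compound,lib_adduct,lib_score,lib_k,lib_m,lib_n
0,653.623106,4.35,CE 18:0,[M+H]+,16.89,2,22,2
1,674.475532,10.10,PC 14:0/14:2,[M+H]+,50.15,6,26,6
```

A full match of all 6 PC fragments at N = 1e5 scores ≈ 50.15 nats even
though the consensus carries m = 26 observed fragments (library
fragments plus chemical noise) — unmatched observed peaks barely
penalize the hypergeometric score. The sparse 2-fragment CE reference
can reach at most ≈ 16.9 nats, which is why score thresholds are best
set per library (see the Retention Balance Point above).

The same operations are available as a library
(`specmatch.pipeline.annotate_run`, `specmatch.lipid_library.build_library`,
`specmatch.library_compare.compute_rbp`, ...) and that is the interface
the test suite exercises.

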