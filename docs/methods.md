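# Methods

This note documents the models, conventions and design choices behind
`ltpmap`, in the order the pipeline applies them.

## Array design and tiling

Mature allergen sequences (signal peptide removed; the removed residue
count is kept as `precursor_offset` so precursor numbering stays
recoverable — 25 for Jug r 3, 0 for the others) are tiled into 15-mers
starting every 5 residues. The final tile starts on the 5-residue grid
and is truncated at the C-terminus, which for the three bundled
allergens (92/94/91 aa) yields 17 tiles each with final lengths
12/14/11. Tiles shorter than 8 residues raise a warning, not an error.
Coordinates are 1-based inclusive throughout. The bundled mature
sequences are not stored as strings but reconstructed from the
overlapping peptide table, which doubles as a consistency check: any
overlap disagreement or coverage gap is an error naming the first
offending residue.

`X` (unknown residue) is accepted in reference/fixture sequences when
explicitly allowed, rejected in array protein inputs otherwise.

## Signal model and aggregation

Spot-level SNR values are taken as produced by the scanner software;
when a table carries both an SNR column and foreground/background
statistics, the SNR column wins (reproducibility over recomputation).
The `(fg_median − bg_median)/bg_sd` formula is provided only as a
fallback for GenePix-style files lacking an SNR column. Replicates are
summarized by the median of however many spots survive; missing
subject × peptide cells stay missing and are excluded from both the
numerator and denominator of downstream prevalences. ISAC values below
the assay's 0.3–100 ISU-E operating range are flagged, never dropped;
negative values are rejected.

## Calling conventions

Both decision thresholds are inclusive: positivity at median SNR ≥ 3 and
major classification at a positive fraction ≥ 0.5. The major call uses
the exact fraction n⁺/n, not the display-rounded percentage, so a
49.95% cohort is never promoted by rounding. Display percentages are
rounded to one decimal. Epitope regions merge overlapping *and abutting*
intervals (end + 1 = next start), since residue coverage is contiguous
across abutting tiles. Intensity bins: heat-map scheme < 3 / [3, 10] /
> 10; structure scheme none (< 3), pink [3, 5), purple (≥ 5).

## Exact statistics

**Fisher test.** Two-sided p-value under the "sum of small p-values"
convention: with margins fixed, all feasible tables are enumerated and
point probabilities ≤ the observed one are summed, with a relative
tolerance of 1e−7 for floating-point ties. Point probabilities are
computed in log space from a cumulative log-factorial table, so N = 72
(and far larger) is exact without overflow. The implementation is
cross-checked in the test suite against an independent oracle on random
tables.

**FDR.** Benjamini–Hochberg step-up, applied within each protein
(family size 17). The per-protein family was chosen because it
reproduces every published adjusted value exactly (e.g. the smallest
Ara h 9 raw p of 1.63e−3 × 17 → 0.03), whereas a global family over all
51 tests does not. Adjusted p-values are displayed with two decimals,
floored at "<0.001" and ceilinged at ">0.99".

**Rank-sum.** The Wilcoxon rank-sum test uses the exact permutation
null when both samples have ≤ 12 observations without ties, otherwise
the normal approximation with tie correction and a 0.5 continuity
correction.

## Property distance (PD)

Each standard residue is represented by a five-dimensional descriptor
vector (principal components of a large panel of measured physicochemical
properties); `X` maps to the centroid. The distance between equal-length
peptides is

PD(a, b) = s · Σᵢ √( Σₖ λₖ (Eₖ(aᵢ) − Eₖ(bᵢ))² )

where λ = (0.456, 0.192, 0.151, 0.113, 0.088) are the fractions of
property variance explained by the five components and s = 4.0071 is a
frozen scale constant. The scale was calibrated once, as the median
ratio of published to unscaled distances over a published reference set
of 34 scored 15-mer windows, so that the conventional interpretation
bands apply (0–3 high similarity, 3–10 recognizable similarity, > 10
unrelated; random 15-mer pairs score ≈ 15–20). Only PD = 0 and the rank
ordering of matches are treated as reproducible across implementations;
on the calibration set the rank agreement is Spearman ≈ 0.997 and
absolute values agree to about ±0.2. The per-position sum (rather than a
single grand-sum square root) was chosen because it is a metric per
position, scales linearly with peptide length, and is what reproduces
the published rank ordering.

## Alignment

Global Needleman–Wunsch with BLOSUM62 and affine gap penalties (open 10,
extend 0.5), computed with Biopython's `PairwiseAligner`; the score is
cross-checked against an independently written Gotoh DP in the tests.
Percent identity is identical pairs over aligned non-gap columns;
percent similarity additionally counts pairs within one ClustalW strong
group {STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW}. `X` counts in
the denominator but never as identical/similar. The software originally
used for the published identity matrix does not document its
denominator convention, so cross-protein identities are validated to a
±3-point tolerance, not exactly. Epitope projection carries source
residues through alignment columns, skipping gap columns; a target tile
is linked when it shares ≥ 5 residues (configurable) with the projected
interval.

## Synthetic cohorts

The generator's defaults are the study conditions: 55 US and 17 Spanish
subjects; per-peptide positivity prevalences equal to the published
percentages for all 51 protein/peptide pairs; ISAC binding probabilities
0.02 (US — "essentially none", no US rate is published) and
0.71/0.65/0.76 (Spain, Ara h 9/Jug r 3/Pru p 3).

Per subject, peptide truths are independent Bernoulli draws (no
between-peptide correlation — none is published; an optional log-normal
subject reactivity multiplier exists but defaults to off). Spot SNRs
are log-normal per replicate: median 7 for true positives (inside the
5–9 range of the published per-peptide medians), median 1 for
negatives, log-sd 0.5. Under this model a single replicate falls on the
wrong side of the threshold with probability 0.045 (positives) and
0.014 (negatives), and the triplicate median misclassifies with
probability ≈ 0.006 / 0.0006 — comfortably under the < 1% design goal.
Replicates drop out independently at 0.02, with a guard keeping at
least one. ISU-E values are log-normal (median 2, log-sd 0.8) for
binders and uniform on [0, 0.25] for non-binders. All draws come from
one seeded generator in a fixed order (subjects → peptides → replicates
→ ISAC), so output is bit-reproducible from the seed.

What the simulation does *not* emulate: within-subject correlation of
peptide responses, spatial array artifacts, inter-array normalization
drift, the one missing US ISAC sample, and any relation between linear
and conformational reactivity in the same serum. Tests passing on
synthetic cohorts therefore validate the analysis pipeline's behavior
under the stated statistical model, not biological claims about real
sera.

A deterministic count-faithful variant (`cohort_from_counts`) assigns
well-separated SNRs (8 vs 1) so that calling reproduces a given count
table exactly; it drives the end-to-end reproduction of the published
comparison table.

In the acceptance tests, prevalence recovery at n = 500/500 is judged
against the 99% binomial interval of the *effective* call probability —
the generating prevalence folded through the triplicate-median miscall
rates above — because at degenerate prevalences (0 or 1) the raw
interval has zero width and the noise model itself guarantees occasional
miscalls. Simulation sizes used in tests (200 cohorts for calibration
checks, 1000 for the null-FDR check, one 500/500 cohort for recovery)
were chosen to keep Monte-Carlo error well inside the asserted margins.

## Structure annotation

Helix/loop/coil boundaries are user-supplied data, not computed; the
bundled `synthetic_ltp_segments.tsv` is an illustrative, synthetic
annotation in the typical four-helix nsLTP layout and carries no claim
about the real proteins' boundaries. Region/segment intersection
conserves residues: per epitope interval, segment overlaps plus the
implicit "other" remainder sum to the interval length.

## Known limitations

- PD absolute values depend on the frozen calibration; only PD = 0 and
  rank order should be compared across implementations.
- Identity/similarity percentages are convention-dependent (±3 points).
- The Fisher/BH reproduction starts from published cohort-level counts;
  subject-level concordance cannot be checked without raw data.
- The GenePix reader covers a minimal named-column subset, not full GPR
  metadata blocks.
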