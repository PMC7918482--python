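# Methods

## Scope and model

`acetylfq` implements the downstream quantification of a label-free
two-growth-phase proteomics experiment with a matched acetyl-lysine
enrichment. It consumes search-engine output (one row per peptide-spectrum
match with sequence, modifications, MS1 area, XCorr, q-value and sample
coordinates) and never performs spectrum-level processing: database
searching, FDR estimation and site-localization scoring are upstream
concerns whose results arrive as table columns.

The quantitative model is deliberately simple and matches standard MS1
label-free practice: a peptide's integrated MS1 area is proportional to its
abundance times an unknown peptide-specific response factor; protein
abundance is estimated as the mean of the three most intense peptides
(top-3), which suppresses response-factor variance without modelling it;
systematic between-run intensity shifts are removed by per-sample median
centring in log10 space.

## Filtering and status rules

PSMs pass iff `q_value < 0.01` **and** `xcorr > 2.0`. Both inequalities are
strict, so a record at exactly the threshold is rejected; the boundary
behaviour is tested. Contaminants are excluded by accession prefix
(`cRAP` by default) because the contaminant database is only visible to us
through the accessions it contributed.

A protein (or acetylation site) is *quantified* in a phase iff it is
observed in strictly more than 50 % of that phase's biological replicates —
2 of 3 in the default design. One observation gives *identified* (*id.* for
sites); none gives *absent* (*n.d.*). The same rule is applied at protein
and site level; the site-level statuses drive which ratios are reported.

## Normalization

Log10 abundances are median-centred per sample (medians computed over the
proteins present in that sample only — the detected proteome, not the
genome) and then shifted by one global constant so the dataset minimum is
exactly zero. Consequences worth knowing:

- after normalization every sample's median equals the global shift;
- the transform is invariant to per-sample multiplicative rescaling of raw
  areas (a 10× change in one run's overall intensity changes nothing);
- the global shift adds one dataset-wide constant to every protein
  abundance and therefore subtracts it from every acetylation ratio. Ratios
  are thus comparable within a dataset but carry an additive offset
  relative to raw-scale ratios. `normalize_abundances` returns the sample
  medians and shift (`NormalizationInfo`) so callers can undo the offset;
  the noise-free recovery test uses exactly this to verify that ratios
  equal log10 stoichiometry once medians are aligned.

Normalization is computed per dataset as presented to the pipeline; if two
experiments must be normalized separately, run them separately.

## Acetylation ratios

Observations of the same (protein, peptide, acetyl-position set) that
differ only in methionine-oxidation (or static carbamidomethyl) status are
summed — oxidation splits a peptide's signal across variants without
changing what is acetylated — and the log10 is taken after summing. The
estimated log10 acetylation abundance ratio subtracts the parent protein's
phase-level mean normalized abundance from the site's phase-level mean
log10 area (means over the replicates where the site was observed, reported
only when the site is quantified and the protein is quantified in that
phase). A replicate-matched mode (each replicate's site area against the
same replicate's protein abundance) is available by flag; the default uses
phase means because sites are frequently missing in individual replicates.

The Kac-eluate areas themselves are *not* median-normalized — only the
protein term is — so the ratio inherits the enrichment efficiency of the
Kac purification as an unknown multiplicative constant. Ratios are
therefore proxies for relative stoichiometry, not occupancies.

Highly acetylated sites are those whose best per-phase ratio is ≥ −1.0
(acetyl peptide at ≥ 10 % of protein signal); a −1.1 preset
(`TABLE_PRESET_THRESHOLD`) is provided because tabular reporting sometimes
uses the slightly laxer cutoff, and we take no position on which is
preferable — the default follows the 10 % interpretation.

Site labels render lysine positions as `K<pos>` in 1-based protein
coordinates; candidate sets (ambiguous localization) join with `|`. An
acetylated peptide N-terminus maps to the protein N-terminus only when the
peptide starts at residue 1; otherwise it is recorded at the peptide's
first residue and labelled `Nt<pos>`, because an internal peptide's
N-terminal acetyl mark cannot be attributed to the protein N-terminus.
N-terminal-only sites are excluded from the acetylated-protein proportion,
which counts proteins with at least one acetylated *lysine*. Met-excision
is not modelled.

## Digestion

Tryptic digestion cuts C-terminal to K or R unless followed by P (the
common search-engine default; the residue sets are configurable), and
enumerates all peptides with up to `max_missed` missed cleavages (default
4, mirroring typical search settings for acetylome work, where acetylated
lysines resist cleavage). Coordinates are 1-based inclusive. The
implementation is checked against a brute-force enumeration of all
substrings bounded by valid cleavage points and against an independent
digestion routine (pyteomics) in the tests.

## Statistics

Phase comparisons use two-tailed homoscedastic Student's t-tests
(df = nA + nB − 2): at protein level on normalized replicate values of
proteins quantified in both phases (≥ 2 values per phase), with
Benjamini–Hochberg adjustment across all tested proteins; at pathway level
on per-replicate coverages, unadjusted by default (adjustment available by
flag). Star encoding is strict and nested (\*\*\* < 0.001 ⊂ \*\* < 0.01 ⊂
\* < 0.05).

Per-replicate pathway coverage is defined by evaluating the detected set
for each replicate separately; phase-level coverage uses the phase's
quantified-protein set (proteome layer) or the proteins with any site seen
in ≥ 1 replicate (acetylome layer). Two degenerate cases are handled
explicitly: identical constant coverage in both phases gives p = 1 (no
evidence), and constant-but-different groups have zero pooled variance, so
rather than fabricate a finite p the row reports p = 0 with a `degenerate`
flag. The acetylome layer's zero-exponential-coverage convention (log2 fold
change = 0) exists because a ratio against zero coverage is undefined while
"newly covered in stationary phase" is still worth displaying; the proteome
layer reports such rows as missing.

## The simulator

`simulate` generates what the pipeline's assumptions describe, with known
ground truth: random protein sequences (length uniform 100–600; K and R at
~5.5 % each so tryptic peptides average ~9 residues), log10 abundances
N(3.0, 0.6) with a phase effect (sd 0.4) on 20 % of proteins, acetylated
proteins at 5 % (exponential) / 11 % (stationary) prevalence with 1–6 sites
each on lysines covered by a detectable peptide, and per-site log10
stoichiometries uniform in [−3, −0.5]. Observations get a fixed per-peptide
response factor (log10 sd 0.25) and multiplicative lognormal noise (log10
sd 0.15); Kac records scale the covering peptide's signal by stoichiometry
and an enrichment gain (default 1); 30 % of methionine-containing acetyl
peptides are split into oxidized/unoxidized variant pairs
(area-conserving); dropout removes records with probability falling
logistically in log10 area (logistic centred at the dropout-rate quantile
of the table's areas, scale 0.35, overall rate ~20 %); 5 % contaminant
records carry failing scores and a `cRAP_` prefix. Simulated observations
are generated from the fully cleaved digest (length ≥ 6); the digest module
itself supports missed cleavages — the simulation simply does not need
overlapping peptides, which would complicate the area bookkeeping without
testing anything new.

What the simulator does **not** emulate: charge states, retention time,
co-elution and interference, missing-at-random search failures, shared
peptides between homologous proteins (sequences are random), realistic
score distributions (xcorr/q exist only to exercise the filters), and
enrichment-efficiency variation between samples. Passing recovery tests
therefore demonstrates the pipeline's correctness under its own model
assumptions — ranking and calibration of ratios against true
stoichiometries, conservation under variant collapsing, correct status
calls under dropout — not robustness to everything real data does.

## Problem sizes and numerics

The default simulated experiment is 1000 proteins (≈ 100k proteome PSMs,
≈ 1.4k Kac PSMs), which runs the full pipeline in a few seconds; the
noise-free recovery check uses 300 proteins. Test oracles run at small n
(sequences ≤ 80 residues for the digestion oracle, 1000 random vectors for
the top-3 and BH oracles). Floats are written with shortest round-trip
representation so table round-trips are bit-exact. Zero-area observations
count as detections but contribute no log area and no ratio. Ties in top-3
need no special handling (the mean is order-independent); BH uses the
standard step-up with a running minimum.

## Known limitations

- One protein assignment per PSM is trusted from the search engine; our own
  unique-peptide rule only removes peptide sequences assigned to multiple
  proteins within the table.
- No imputation, no match-between-runs, no iBAQ/LFQ-style cross-sample
  inference; missing means missing.
- Stoichiometry ratios are relative, not occupancies; cross-dataset
  comparison requires equal enrichment efficiency.
- Localization ambiguity is carried, not resolved: candidate sets are never
  merged with overlapping unambiguous sites.
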