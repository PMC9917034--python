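# Methods

## Overview

`degradomics` analyzes in-vitro protein digests by purified proteasomes. The
input is the peptide identification table a proteomic search engine exports
after LC-MS/MS of a single-substrate hydrolysate (one row per identified
peptide-form per sample, with variable-modification annotations and an ion
current area). The pipeline anchors each peptide back onto the substrate,
summarizes where the protease cut and what it prefers to cut after, compares
conditions, extracts consensus "core regions" from the 9–10-mer ligand-sized
products, and joins those candidates with HLA class I percentile-rank
predictions. A stochastic digestion simulator provides ground-truth data so
every stage is testable offline.

The reference substrate shipped with the package is the 170-residue 18.5 kDa
classic isoform of human myelin basic protein (MBP, UniProt P02686-5), the
canonical multiple-sclerosis autoantigen; any substrate FASTA can be
substituted.

## Coordinates and peptide mapping

Coordinates are 1-based inclusive `[start, end]`. Peptide bond *i* is the
bond between residues *i* and *i+1*; its P1 residue (the residue N-terminal
to the scissile bond, the one protease specificity is indexed by) is residue
*i*, so bond index equals P1 position.

Deamidation converts Gln→Glu and Asn→Asp, changing the residue letter the
search engine reports. Mapping therefore matches a peptide at a substrate
position if every residue matches directly, or is an E/D at a *revertible*
position whose germline form (Q/N) matches. Two modes control revertibility:

* `declared-only` (default): only positions carrying a parsed deamidation
  modification may revert — we trust the search engine's variable-mod calls;
* `infer-all`: any E/D may revert — for tables whose modification
  annotations were lost.

Oxidation is a mass-only modification and never affects matching. A peptide
matching nowhere is "irrelevant" (not substrate-derived) and goes to the
unmapped report; a multi-locus match is flagged ambiguous and resolved by
policy: `distribute` (default; intensity and count weight split equally
across loci — unbiased for positional profiles, and the flag lets downstream
consumers exclude split records), `first`, or `drop-ambiguous`. Ile and Leu
are *not* treated as interchangeable. The exhaustive-enumeration oracle in
the test suite (every window × every reversion subset) pins the matching
semantics.

## Abundance and profiles

**TIC normalization.** A peptide's relative abundance is
`100 × intensity / Σ intensity` over all substrate-derived peptides in its
(sample, substrate) group, in percent. Tables without an intensity column run
in *count mode*: every peptide-form contributes its count weight (1, or 1/m
after an m-fold ambiguous split).

**Cleavage profile.** Each located peptide contributes one hydrolysis event
at bond `start−1` (if `start > 1`) and one at bond `end` (if `end < L`);
substrate termini are not hydrolysis events because protein ends are not
proteolytic products. Event weights are 1 per peptide-species (`count`,
default — matching counted-peptide displays) or the TIC-relative abundance
(`tic` — a copy-number-weighted profile). Frequencies are events normalized
to the total event count.

**Terminal matrix.** A 20×20 count of (first residue, last residue)
combinations over observed (deamidated) sequences, normalized by total
peptide count.

**Activity signature.** P1 residues are grouped into the three classical
proteasome specificity classes — chymotryptic-like {F, Y, W, L, M},
tryptic-like {K, R}, caspase-like {D, E} — plus `other` (configurable; the
sets mirror the LLVY/LRR/LLE fluorogenic substrates used to assay the three
catalytic activities). The signature reports the event fraction per class and
an availability-corrected weight: event fraction divided by the fraction of
substrate bonds in that class, renormalized to sum to 1. The correction
removes substrate-composition bias so weights estimate the enzyme's intrinsic
class preference, comparable across substrates.

## Condition comparison

Peptide-forms are keyed by (substrate, start, end, deamidation state);
deamidated and native forms are distinct points, with a
`collapse_deamidation` switch that merges them by summing abundances.
Per-form output is the B/A ratio of TIC-relative abundances when detected in
both conditions; otherwise the form is ND (not detected) — a categorical
outcome reported as the literal token `ND`, never imputed as 0 or ∞ and never
given a pseudo-count. No hypothesis testing is attached: with no replicates
the ratios are descriptive.

## Core regions

9–10-mer candidates are clustered by single linkage on interval overlap:
two candidates join when they share ≥ `min_overlap` residues (default 7, the
minimum overlap of two 9-mers sharing a binding core; values > 10 are
rejected since they can never cluster 9–10-mers). Per cluster the *region* is
the union of member intervals and the *core* their intersection;
"immunodominance" is operationalized purely as rank by summed TIC-relative
abundance (no hard cutoff; `min_total_abundance` is exposed for filtering).
Output order is deterministic: summed abundance descending, ties by start.

Degenerate case: a long single-linkage chain (member starts drifting more
than the length slack across the cluster) can empty the strict intersection.
The core then falls back to the leftmost contiguous run of maximally covered
positions. This cannot occur for the compact, well-separated clusters the
method targets, but keeps the output total.

## HLA annotation

Candidates are cross-joined with a class I allele panel (default 27 alleles:
12 MS-risk-associated and 4 MS-protective alleles at 4-digit resolution from
the MS genetics literature, padded with 11 common unlabeled alleles; shipped
as editable YAML). Ranks follow the IEDB percentile convention (lower =
stronger) and are classified as high ≤ 0.5, moderate ≤ 2, low ≤ 10, else
non (configurable; the 0.5/2 cuts are the community strong/weak convention,
extended with 10 to express "moderate to low" affinity). A (peptide, allele)
pair with no available prediction is reported `missing`, never fabricated,
and the predictor sees the observed (deamidated) sequence, so deamidated
forms are annotated as distinct peptides.

Real analyses should ingest an external prediction table (e.g. an IEDB tools
export; `iedb_adapter` formats the request and parses the response offline).
For self-contained, deterministic testing the package includes a PSSM scorer:
score = Σ position weights, with the percentile of a score computed against
the sorted scores of M = 10,000 seeded uniform-random background peptides as
`max(0.01, 100 × (#greater + 0.5 × #ties) / M)`. The 0.01 floor matches the
display floor of percentile-rank gradients. This scorer is a labelled test
double (`pssm-internal` in outputs), not a binding predictor.

## Digestion simulator

Each of `n_events` substrate molecules is digested independently; bond *i* is
cut with probability `p_i = 1 − exp(−κ·w_i)` where `w_i` is the phenotype's
activity weight for the bond's P1 class. With the default per-event hazard
κ = 0.05 the model is in the linear regime (`p_i ≈ κ·w_i`), so relative cut
rates encode class preferences directly and recovery is analytically
checkable. Fragments between consecutive cuts are retained when their length
falls in the detectability window (default 6–30 residues, approximating
peptide-range LC-MS/MS observability); each retained copy draws a log-normal
intensity multiplier (default μ = 13, σ = 1 on the log scale, giving
realistically dispersed ion-current areas), and each N/Q residue of a
retained copy deamidates independently with probability q = 0.05 per copy,
emitted as a separate modified row — the way a search engine reports modified
forms. A single seed governs all draws and is recorded in the ground truth.

Phenotype presets (class weights over chymotryptic/tryptic/caspase/other):

* constitutive: (1.0, 0.6, 0.6, 0.05)
* immuno: (1.5, 0.6, 0.3, 0.05)

calibrated so the immuno:constitutive chymotryptic-to-caspase ratio-of-ratios
is (1.5/0.3)/(1.0/0.6) = 3, the shift measured for IFNγ-induced proteasomes,
with the immuno preset having more chymotryptic and less caspase activity.

Hotspots model preferred excision of specific intervals: the two flanking
bonds (`start−1`, `end`) have their weight raised to the boost value
(default 30, applied as a floor). The boost is an absolute weight rather than
a multiplier so that excision strength does not depend on which residue class
happens to flank the interval — the seeded hotspots are the ground truth for
"high-abundance regions" and must dominate regardless of local sequence.

**Parameter recovery.** The recovery check pushes a simulated digest through
map → TIC-normalize → cleavage profile (TIC weighting) → activity signature
and compares availability-corrected weights with the preset's normalized
weights; the pass bound is ±25 % relative error per class at
n_events ≥ 2000. TIC weighting is used because intensity is proportional to
copy number, making the profile an unbiased estimate of per-bond cut rates;
a per-species count profile saturates at frequently cut bonds and cannot
recover the weights.

**What the simulator does and does not emulate.** It reproduces the
structure of real digest tables — phenotype-dependent cleavage preferences,
a detectability window, skewed intensities, deamidated peptide-forms,
multi-locus ambiguity (when the substrate contains repeats) — so passing
tests demonstrate the pipeline's bookkeeping, normalization and estimation
are correct on data of that shape. It does not model proteolysis kinetics or
processivity, dual-cleavage spacing preferences, missed-cleavage chemistry,
ionization/detectability bias by sequence, chimeric or mis-identified PSMs,
or replicate variance; agreement on simulated data therefore does not certify
accuracy on any particular real dataset.

## Problem sizes and numerical choices

Default simulations digest 2,000 molecules of the 170-residue substrate
(~800 peptide-forms per condition), sized so the ±25 % recovery bound holds
with margin while a full pipeline run takes well under a second. Frequencies
are exact ratios of non-negative floats (sums asserted to 1 within 1e−9);
profile normalization of an event-free profile returns all-zero frequencies
rather than NaN; empty samples TIC-normalize to empty output. Region ties
break by start position; all stochastic components take explicit seeds and
are bit-reproducible.

## Known limitations

* Single-substrate design: peptides are mapped against one protein, not a
  proteome (matching the single-protein in-vitro digest setting).
* The default allele panel's unlabeled padding is a documented approximation;
  edit the YAML to match a study's exact panel.
* The internal PSSM ranks carry no biological meaning; only external
  predictions should be interpreted.
* ND handling is categorical, so fold-change summaries silently exclude
  condition-exclusive peptides (they are reported separately via overlap
  counts and `ND(only_a)`/`ND(only_b)` tokens).
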