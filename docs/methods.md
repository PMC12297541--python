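# Methods

This note documents the models and procedures `pairedab` implements, the
assumptions behind them, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Data model and curation

A *paired record* is one B cell's curated heavy (IGH) + light (IGK or IGL)
rearrangement: gene calls (V/J/C), productivity, mean assembly coverage,
nucleotide and amino-acid sequences, and a map from IMGT positions (1–128,
optional insertion letter) to amino-acid symbols. Reading a paired AIRR TSV
applies the curation used by large single-cell resources:

1. non-productive rows are dropped (productive = no stop codon, in-frame);
2. if a cell has several rows for one chain class — allelic exclusion fails
   in ~1% of cells — the row with the highest mean coverage is kept; ties
   are broken by the lexicographically smallest nucleotide sequence so that
   curation is reproducible (no tie rule is standard; any deterministic one
   serves);
3. cells lacking a surviving heavy or light chain are dropped.

Gene labels parse as locus (IGH/IGK/IGL) + subgroup (text before the first
hyphen, so `IGKV1D-39` keeps subgroup `IGKV1D` rather than being merged
with `IGKV1`) + optional gene and allele. Ambiguous multi-gene calls
resolve to the first listed call. An empty dataset after curation raises
rather than returning silently.

## Chao2 richness

Studies are sampling units; the species key is the concatenation of heavy
and light variable-region sequences (nucleotide or amino-acid — both modes
are supported and recorded in outputs, since dataset-scale totals can be
quoted in either currency), joined by `|`, which occurs in neither
alphabet, so concatenation is unambiguous. Incidence, not abundance: a key
occurring a thousand times within one study is *present* in that study
once. The estimator is the classic form S + q1²/(2 q2); when q2 = 0 the
standard bias-corrected form S + q1(q1−1)/2 is used and flagged in the
result. The estimate is a lower-bound-style extrapolation and inherits
Chao2's assumptions (exchangeable sampling units, detection independence);
cross-study heterogeneity in protocols biases it in ways the package does
not model. Filtering to one organism is the caller's responsibility.

## Pairing-preference tests

The contingency table cross-tabulates a heavy-chain feature against a
light-chain feature (V subgroup by default; the inter-chain V–J analyses
are the same code with J selectors). Kappa and lambda are analyzed
separately. Cells with co-occurrence below `min_pair_count` (default 5) are
masked.

* **Global test:** Pearson chi-square of independence on the table with
  masked cells excluded (their counts zeroed, matching an analysis in
  which rare pairs are filtered before testing); all-zero rows/columns are
  dropped; Yates continuity correction applies only in the 2×2 case.
* **Per-pair tests:** for each unmasked cell (h, l), the 2×2 table
  [[n_hl, n_hl′], [n_h′l, n_h′l′]] aggregates all other subgroups into h′
  and l′. Masked cells are excluded from testing but their counts still
  enter the marginals and n_total, keeping expectations faithful to the
  data. Tests are two-sided (Yates-corrected chi-square); the direction
  (enriched iff observed > marginal-product expectation) is stored
  separately, and "preferential pairing" = rejected AND enriched.
  Bonferroni divides by the number of tests actually performed.
* **Usage comparison:** a G×2 chi-square across the union of features of
  two datasets; a feature absent from one dataset counts zero there.

A caveat established while validating power (and worth knowing when
interpreting real data): when pairing enrichment exists anywhere in the
table, renormalization shifts *every* cell's collapsed odds ratio away
from 1 — for cells sharing no row or column with an enriched pair,
OR = 1 + (Z−1)/((1−p_h)(1−p_l)) where Z−1 is the total injected excess
mass. At large n the per-pair test correctly detects this spillover on
high-mass cells. Flags on pairs other than the strongly enriched ones are
therefore not necessarily artifacts; they can be the arithmetic shadow of
enrichment elsewhere in the table.

## Interface contacts

Chains are paired through IMGT position 104 (the conserved second
cysteine): every H–L pair whose 104 Cα atoms lie within 20 Å is a
candidate; greedy nearest-first matching with each chain used at most once
resolves multi-Fab asymmetric units deterministically. Chains lacking 104
or its Cα are skipped with a warning; a non-cysteine identity at 104
(engineered variants) is logged but accepted. A residue pair across the
interface is a contact when any two non-hydrogen atoms are within 4.5 Å.
Both thresholds are inclusive ("within a maximum distance of" read as ≤)
and configurable. Hydrogens are identified by the element field, inferred
from the atom-name convention (and logged) when the column is blank.
Waters, ligands and unmapped residues are excluded before any distance
computation; for disordered atoms only the highest-occupancy altloc is
kept.

Aggregation counts one occurrence per paired chain per structure (a
position present in two Fabs of one file counts twice); the contact ratio
is contacts/occurrences. Key interface residues are positions above
configurable occurrence and ratio thresholds — no specific threshold pair
is claimed to reproduce any published key-residue set, so both are
explicit parameters. IMGT regions use the standard delimitation (FWR1
1–26, CDR1 27–38, FWR2 39–55, CDR2 56–65, FWR3 66–104, CDR3 105–117, FWR4
118–128); insertion-lettered positions inherit their integer's region.

The Vernier-zone comparison ships an *editable* data file
(`data/vernier_imgt.tsv`) holding the Foote & Winter framework positions
translated from Kabat to IMGT in-house (anchored on the conserved Cys
23/104 and Trp 41, interpolated between anchors). Positions adjacent to
CDR loops are approximate because that correspondence depends on loop
length; the overlap operation itself is exact set algebra, so users with a
preferred lookup can replace the file.

## Amino-acid profiles

Per-position distributions exclude records lacking the position (shorter
loops); gaps are not a 21st symbol. TVD is half the L1 distance over the
union of supports, clamped to [0, 1] against floating-point overshoot of a
few ulp. The goodness-of-fit test scales reference proportions to the
compared sample size; symbols observed fewer than `min_bin` (default 5)
times are pooled into "other" with the corresponding expected mass
(including reference-only symbols) pooled in parallel, so totals are
conserved; df = bins − 1. Bonferroni across positions is applied by the
caller over tests performed.

The random-pairing null for joint (H, L) amino-acid pairs defaults to the
analytic outer product of the marginals — the exact expectation, free of
Monte-Carlo noise; a permutation mode (one seeded shuffle of light chains
across records) is provided because "randomly paired" can also mean a
single shuffle, and the mode used is recorded in outputs.

## Synthetic data: what it does and does not emulate

The repertoire generator draws (heavy subgroup, light subgroup) pairs from
`enrichment × (product of marginals)`, renormalized — the minimal
alternative hypothesis to "pairing follows usage". Defaults state a
human-like world: IGHV3-dominated heavy usage, a 60:40 kappa:lambda split,
IGHJ4-dominated heavy J usage, conserved cysteines at IMGT 23/104, and
concentrated framework/CDR3 position profiles. Amino acids are drawn
independently per position unless a coupling table overrides an (H, L)
position pair jointly. Sequences are IMGT-position-indexed amino acids
plus a random 10-mer junction tail and random 48-nt nucleotide backfill —
enough to make clone keys unique for incidence counting. Clones recur in a
second study with `share_prob` as exact sequence copies, since Chao2 keys
on exact identity.

Not emulated: somatic hypermutation and clonal lineages, biological CDR3
length variation, realistic junction chemistry, per-study batch effects.
A green test therefore establishes the *statistical machinery* (curation
rules, estimators, calibration, power) — not robustness to repertoire
biology the generator does not contain.

The structure generator places both chains' 128 residues on well-separated
lines (8 Å spacing, 50 Å between chains), moves each designed (H, L)
contact's light residue to a minimum heavy-atom distance drawn uniformly
in 3.6–4.2 Å, anchors the two 104 Cα atoms at the configured separation,
and adds Gaussian jitter clipped at 3σ. Validation rejects any
configuration whose worst-case jitter (2 atoms × 3σ × √3 per coordinate)
could cross the 4.5 Å contact boundary or the 20 Å pairing threshold, so
the designed contact map is recovered exactly by construction. These are
distance fixtures, not physically plausible folds.

Each generator derives its RNG stream from (config seed, fixed stream id),
so adding a generator never shifts existing draws; equal seeds give
bitwise-identical outputs, including written PDB bytes.

## Pipeline

`run_pipeline` executes simulate → richness → pairing → contacts →
aa-profiles from a single config (Python object or YAML file), writes all
results as CSV, and records a JSON manifest echoing every parameter and
the SHA-256 of every output file; identical config + inputs reproduce
identical digests. A stage failure aborts but still writes the manifest
with the stages completed.

## Known limitations

* IMGT numbering and germline assignment are delegated to external tools;
  the structure reader requires a sidecar numbering map.
* Chao2 variance/confidence intervals and alternative richness estimators
  (ICE, jackknife) are out of scope.
* The gapped-alignment serialization covers plain positions 1–128;
  insertion-lettered positions survive in memory but not in the TSV
  round-trip.
* The Vernier IMGT translation is approximate near CDR boundaries (see
  above).
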