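# Methods

This note records the models and procedures implemented in carboxmeta, the
assumptions and defaults behind them, and the choices made where the design
was genuinely open.

## Enrichment testing

Two communities' annotated gene pools are compared per functional category
as 2×2 tables (category vs rest, community 1 vs community 2). The
statistic is the Wald log odds ratio with a Haldane–Anscombe pseudocount
c = 0.5 added unconditionally to all four cells:

    LOR = ln[(x1+c)/(n1−x1+c)] − ln[(x2+c)/(n2−x2+c)]
    SE  = sqrt(Σ 1/cell),   Z = LOR/SE

Unconditional addition keeps the statistic finite and continuous at empty
cells, the common situation for rare Pfams; c is configurable. Two-sided
p-values use the standard normal, and q-values are Benjamini–Hochberg over
all categories of the database being tested (α = 0.05 default, the usual
"FDR equivalent to p < 0.05" convention). Categories are processed in
sorted label order so p-value ties resolve deterministically.

"Z-normalization" admits two readings and both are provided: the primary
one is the Wald standardization Z = LOR/SE, which feeds the p-values; a
secondary across-category standardization of the LOR vector
(z′ = (LOR − mean)/sd, sample or population sd by `ddof`) is a
presentation transform for plotting signed enrichment and never alters
p/q.

Counting unit: one count per gene per distinct category it carries
(duplicate assignments of the same category to one gene collapse). The
library size n is therefore the number of (gene, category) assignments.
Depth-weighted counting is available via `build_profile(..., depth=...)`
but off by default, since per-gene counting matches the way annotated
protein-coding gene proportions are reported in this field.

Known property: with c = 0.5 and very unbalanced totals (e.g. n1 = 10 vs
n2 = 200), the sign of the adjusted LOR can differ from the raw
odds-ratio direction on near-tie tables; in an exhaustive grid sweep all
such disagreements had |Z| ≤ 1.11, i.e. far from significance. For equal
totals the direction identity is exact.

## E-value filtering

Defaults: KEGG 1e-5, COG 1e-2 (RPS-BLAST searches are scored more
leniently), GH 1e-6, and 1e-5 for PFAM and EC, for which no canonical
convention exists; all are editable via the cutoffs mapping. Retention is
`e_value ≤ cutoff`, order-preserving, and idempotent.

## GH family tables

Percent of total GH per family, half-up to two decimals, over a shipped
editable list of 29 families in four CAZy function groups (cellulases,
endo-hemicellulases, debranching enzymes, oligosaccharide degradation);
unlisted families aggregate into "All other GH" so the column sums to 100
within rounding.

## Genome recruitment

Each metagenome gene is assigned to the genome of its highest-identity
hit, ties broken by (identity desc, genome label asc, subject gene asc);
a gene counts for at most one genome. Coverage is rounded half-up to the
nearest integer percent; published tables of this kind occasionally print
a floor instead (77.7 → 77), but nearest-integer matches the large
majority of cells and is used throughout. Species groups with several
sequenced isolates are supported by mapping member genomes to one group:
homologs are deduplicated across members and coverage is reported as a
range over the member gene counts. Recruitment-plot identity classes are
lower-exclusive — (30,60], (60,90], (90,100] — matching ">30/>60/>90 %"
plotting conventions; hits at ≤30 % identity are dropped.

## Composition binning

Contigs are represented by strand-symmetric 3-mer frequency vectors:
overlapping trinucleotides of the sequence and its reverse complement are
pooled and normalized (ambiguous bases skipped). This plain vector is the
simplest representation consistent with 3-mer composition binning;
chain-based encodings used by some binning tools are not reproduced
byte-for-byte. Assignment is nearest-centroid with Euclidean distance by
default (Manhattan by option) and a distance cutoff, 0.01 by default.
Exact ties (within 1e-12) leave a contig unbinned with the tie recorded.

Composition distances shrink roughly as 1/sqrt(length), so a fixed cutoff
tuned for one contig-length regime misbehaves in another: on 5–8 kb
synthetic contigs the median contig-to-centroid distance is near 0.01
itself and the fixed default binned only ~58 %. `calibrate_cutoff`
therefore recalibrates the cutoff as the 99th percentile of within-taxon
distances on labeled training contigs; with it, recovery on three
well-separated taxa exceeds 95 %.

Outlier pruning is a single deterministic pass: per bin with ≥2 members,
the mean and population SD (ddof = 0) of G+C and depth are computed over
the pre-pruning membership, and members deviating strictly more than one
SD in either variable are unbinned with `outlier_flag` set (one-member
bins untouched; identical members give SD 0 and the strict inequality
prunes nothing). The origin bin of a pruned contig is retained on the
assignment, so re-running the pass on its own output recomputes the same
frozen statistics and is a no-op.

## Bin QC

Completeness = 100 × (distinct order-level pangenome core genes detected)
/ (core genes expected), two decimals half-up. CSCG duplication =
100 × (detected conserved single-copy genes with multiplicity ≥2) /
(CSCGs detected); when none is detected the score is 0.00 with a warning,
since there is no evidence of over-binning either way. Function flags use
ANY-of semantics across alternative marker sets and ALL-of within a set.
The shipped ten-function marker map (cellulose degradation through
valerate/caproate production) is illustrative — plausible KO choices such
as acetate kinase + phosphotransacetylase for acetate production — and
explicitly non-authoritative; real analyses should supply their own map.
Pangenome core/CSCG reference sets are user-supplied inputs: building
them requires a curated genome collection that is outside this package's
scope.

## Fermentation metrics

VS = oven-dry − ash mass of the solids. Conversion, selectivity, yield
and productivity are defined as in the README; yield = conversion ×
selectivity holds as an algebraic identity whenever selectivity is
defined (VS digested > 0). Zero digestion with measurable acids, or
selectivity > 1, set an inconsistency flag rather than raising, because
measurement error on the solids balance can produce both. Product
spectra sum isomers into chain classes C2–C6, normalize per replicate to
100 %, and report mean ± SE with SE = sample sd/√n. Chain classes with
zero mass in every replicate are marked ND (not detected).

Three significance modes are provided because published treatment
comparisons describe "paired" t-tests without stating the pairing unit:
`paired` (replicate-index pairing), `welch_from_replicates`, and
`welch_from_summary` for printed mean ± SE tables. Summary-mode inputs
are exactly the numbers a reader has; it is the mode used for
printed-table comparisons here. Identical inputs return p = 1 by
convention (the t statistic is 0/0).

## Synthetic data

The generators plant known effects using the simplest consistent noise
models — they exercise the analysis, not the biology:

- **Communities**: multinomial gene counts over a Zipf-like baseline
  (weight ∝ 1/rank over 200 categories, a realistic abundance skew),
  50,000 genes per community by default; community B's weights are
  baseline × planted factors, renormalized. Default plants are one
  factor-4 and one factor-1/4 category.
- **Contigs**: sequences are sampled from the second-order Markov chain
  implied by the taxon's 3-mer distribution, so the empirical 3-mer vector
  converges to the specified distribution as length grows (constructors guarantee a
  self-consistent distribution; i.i.d.-nucleotide specs at a given G+C
  are also strand-symmetric). Per-contig planted G+C is drawn from a
  truncated normal and steers the chain through an exponential tilt of
  G/C emissions (bisection on the stationary G+C), so metadata and
  realized composition agree to ~1.5 percentage points; depth is truncated
  normal. Default taxa: three order-level signatures at G+C 32/50/68 %
  with depths in the 9–35× range typical of fermentor bins, 40 contigs of
  5–8 kb each. Not modeled: reads, quality scores, assembly artifacts,
  chimeras, repeats — so binning recovery here bounds what clean
  assemblies allow, not what raw data deliver.
- **Hit tables**: exactly round(fraction × genome genes) distinct
  metagenome genes get a best hit, identities drawn from a mixture over
  (30,60]/(60,90]/(90,100], positions uniform. Fractions up to 1.75
  emulate multi-strain over-recruitment.
- **QC inventories**: round(present_fraction × n_core) core genes
  present; all CSCGs detected once with round(duplicated_fraction ×
  n_cscg) duplicated — making the downstream scores exact by
  construction.
- **Fermentation**: per-acid normal draws (floored at 0, renormalized to
  100 so spectra stay compositions), n = 3 replicates by default, with SDs
  set to SE·√3 of the printed per-acid standard errors. The VS-balance
  defaults (32 g VS loaded, 16 g digested, 8 g total acids, 0.4 L liquid,
  16 d) are realistic laboratory batch-fermentor values consistent with a
  ~50 % conversion, ~50 % selectivity run; they are not taken from any
  published balance.

All generators are bit-reproducible under a fixed seed.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses 20 seeded runs of the 50,000-gene community
plant for enrichment recovery, 120 contigs (3 taxa × 40) for binning
recovery, the 123-core/59-CSCG plant for QC, and 1,000 random batches for
the yield identity — sizes at which every planted effect is comfortably
detectable while the whole script runs in seconds.

## Known limitations

- The Wald z is mildly anti-conservative for very small counts; with BH
  control the realized false-flag rate on null categories is ~0.3 % in the
  synthetic conditions, but rank agreement with Fisher's exact test, not
  exact p-value agreement, is the supported guarantee.
- The fixed 0.01 binning cutoff is length-regime specific (see above);
  calibration on labeled contigs is recommended whenever training data
  exist.
- Function flags are marker-presence checks, not parsimony pathway
  reconstruction; absence of a flag is weak evidence against a capability.
- GH profiling and enrichment consume annotation tables as given; search
  sensitivity differences upstream (BLAST vs HMM) are invisible to the
  package.
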