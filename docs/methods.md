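# Methods

## Scope and model

`ribopara` quantifies tissue-specific ribosome heterogeneity from
peptide-spectrum-match (PSM) level TMT reporter tables. The object of
inference is, per tissue and per ribosomal-protein paralog pair, the
*alternative fraction* f: the proportion of ribosomes whose shared
position is occupied by the alternative rather than the canonical paralog.
Everything downstream of the database search is in scope; spectrum
processing, search-engine protein inference, isotope-impurity correction
and any wet-lab or structural analysis are not.

## The abundance chain

Protein abundance in a reporter channel is the **sum of reporter S/N over
all PSMs** matched to the protein, computed from unique peptides only
(uniqueness evaluated against the supplied registry by exhaustive tryptic
digestion). The chain of matrix stages is explicit and enforced:

* **raw → normalized**: each channel is rescaled so all channels carry the
  same total signal. The common target is the mean of the observed column
  totals — any common target yields identical downstream ratios; the mean
  keeps magnitudes interpretable. Within-channel ratios between proteins
  are preserved exactly.
* **normalized → scaled**: division by a per-run reference, either the
  run's pooled-reference channel (`pooled`) or the mean of the run's
  sample channels (`replicate_mean`). Which mode fits a given run depends
  on its design; the mode is configuration, not inference. Division by a
  missing or zero reference produces a missing cell, never a zero.
* **scaled → zscore**: row standardisation (n−1 denominator) for
  clustering; zero-variance rows map to all-zeros so degenerate synthetic
  rows cluster rather than crash.

Missing reporter values are treated as non-detections throughout: excluded
from sums, references and tests, never imputed as zero (zero would bias
every ratio toward the detected side). The PSM q-value filter is inclusive
at the boundary (q ≤ 0.05 satisfies a 5% FDR).

## Enrichment testing

Per-protein tissue comparisons use the difference of per-channel log₂
means, with a two-sided Welch (unequal-variance) t-test on the log₂
values. "Standard t-test" admits either pooled or unequal-variance
flavours; Welch is the safer default and pooled variance is one flag away
(`test="pooled"`). The enrichment call requires fold change above a
threshold *and* P below a threshold (defaults 1.5-fold, 0.05). The
fold-change threshold is interpreted on the linear scale by default
(|log₂FC| > log₂ 1.5 ≈ 0.585); a `log2` scale option applies the number to
|log₂FC| directly, since both conventions appear in practice. No
multiple-testing correction is applied to these per-protein tests — the
headline calls are deliberately the same simple volcano rule users plot.

Hierarchical clustering uses Euclidean distance with complete linkage by
default. The leaf order is re-derived by a deterministic traversal
(smaller cluster first, ties to the lowest original row index) so repeated
runs and round-trips through the Newick export are stable.

## Discriminating peptide pairs

The stoichiometry estimator exploits pairs of unique tryptic peptides,
one per paralog, of identical length and Hamming distance 1–2 — near
identical sequences whose ionization and fragmentation behaviour is
comparable, so their reporter ratio is a direct stoichiometry readout.
Defaults allow 1 or 2 substitutions (`min_subs=1`, `max_subs=2`),
matching the canonical printed example (DIDQHAVTK / EIDQHVVTK, two
substitutions); both bounds are configurable.

Matching is deterministic rather than curated: candidate pairs are scored
by (substitution count ascending, aligned-coordinate offset ascending) and
selected greedily with each peptide used at most once. A pair is
*anchored* when the canonical peptide's start coordinate maps inside the
alternative peptide's interval under a global alignment of the two parent
sequences; unanchored lookalike pairs are retained in the match table but
excluded from estimation by default. An optional filter additionally
requires the two peptides' observed PSM charge-state sets to intersect;
predicted charge is not computed.

Per tissue, replicate and pair, the estimate is
log₂(Σ S/N alternative / Σ S/N canonical), summing over the tissue's
channels and all PSMs of each peptide (summing is consistent with the
sum-based protein abundances; per-PSM averaging is available via
`method="mean"`). Pairs with a zero or absent side are skipped and
counted. The per-replicate value is the **median over pairs** — robust to
a single aberrant pair — and per-pair values are always retained in the
output because individual pairs are informative. Pairs whose sequences
offer no usable unique peptides (identical-sequence pairs such as RpS14a/b,
or pairs whose substitutions destroy cleavage sites) yield an empty result
and propagate to `insufficient_data`, never an error.

## Status calls

Per (pair, tissue), with m the median log₂ difference across replicates:

| status | rule |
|---|---|
| `co_equal` | \|m\| ≤ `equal_band` (0.5) |
| `switched` | alternative enriched and m ≥ `switch_threshold` (1.0) |
| `enriched_minor` | alternative enriched and m ≤ −`switch_threshold` |
| `canonical_dominant` | anything else with data |
| `insufficient_data` | no ratio estimate and no enrichment call |

`co_equal` takes precedence when rules overlap because stoichiometry
evidence is more direct than enrichment evidence. The numeric defaults are
explicit operationalisations of the qualitative notions "larger
proportion" (alternative at least 2× the canonical) and "around equal
levels" (within ±0.5 log₂ units); no field-standard boundary exists, so
both are configuration fields and results should be read with them in
mind. "Alternative enriched in tissue T" means any configured comparison
with T on one side called the alternative enriched on that side; the
pipeline compares every tissue against a reference tissue (default
`head`, the least heterogeneous sample) plus testis vs ovary when both are
present.

RNA/protein concordance joins protein log₂ fold-changes with RPKM ratios
(pseudocount 0.1 admits zero-RPKM genes) and classifies by sign agreement
and threshold exceedance (`concordant`, `protein_only`, `rna_only`,
`neither`; opposite-sign cases where both levels move fall in `neither`).

## The synthetic generator

The generator emulates the statistical structure the analysis assumes:

* copy numbers L·R·(1−f) / L·R·f for a pair's members (R tissue ribosome
  abundance, L channel loading) and L·R·multiplier for singletons;
* per-peptide ionization efficiency e ~ log-normal, median 1, sd `sigma_e`
  (default 0.3) — median-1 parameterisation makes the zero-noise limit
  exactly 1, so closed-form checks are exact;
* spectral counts per (peptide, run) ~ Poisson(`psm_depth`·e); one
  spectrum carries all of a run's reporter channels, matching TMT
  multiplexing. Default depth 5 expected PSMs per peptide, a desk-scale
  stand-in for real coverage;
* reporter S/N = copy number · e · ε with ε ~ log-normal(median 1,
  `sigma_r`, default 0.3) independent per PSM and channel;
* PSMs are generated per peptide *sequence*, as a search engine reports
  them: the S/N carries the summed copy number of all parent proteins and
  the protein column lists every parent, so the uniqueness filter operates
  on realistic input;
* each run's pooled channel contains the mean of the run's sample-channel
  copy numbers (mixed from the samples before loading, so loading
  differences do not distort pool composition);
* RNA tables are RPKM proportional to copy number with independent
  log-normal noise (`sigma_rna`), keeping concordance classes
  non-degenerate.

**Coupling of homologous peptides.** Discriminating-pair peptides share
their canonical partner's efficiency and spectral-count draws
(`pair_coupling=True`). This encodes the very assumption that licenses the
pair estimator — near-identical peptides ionize and sample comparably —
and it is what makes the zero-noise pair ratio exactly log₂(f/(1−f)) in
every replicate; with fully independent draws the estimator would inherit
an irreducible per-pair offset from the efficiency ratio and a spectral-
count ratio, which is exactly the failure mode one can study by switching
the flag off.

What the generator does **not** emulate: chromatographic behaviour,
co-isolation interference, systematic missingness, inter-peptide
correlation beyond pair coupling, and real sequence composition (the
bundled fly registry carries synthetic tryptic-block sequences with the
real gene symbols and pair structure; see below). Passing tests therefore
demonstrate correctness of the analysis logic under the stated model, not
robustness to every artefact of real spectra.

The bundled gonad-switching truth (`data/gonad_switching_truth.yaml`) encodes
the qualitative gonad findings as stand-in fractions — testis f = 0.8 for
the RpL22 and RpL37 pairs, 0.5 for RpS19 and RpS5, 0.1 for
RpS15A/RpS10/RpS28; ovary f = 0.8 for RpS5 and 0.25 for the
RpL24/RpL7/RpLP0 alternatives; 0.05 elsewhere. These are modelling
stand-ins consistent with the described biology, not measurements.

## The bundled registry fixture

Real fly RP sequences cannot ship with the package, so the fixture
(`data/dm_rp_synthetic.fasta`, regenerated deterministically by
`scripts/make_registry_fixture.py`) is explicitly synthetic: 93 proteins
(39 SSU, 54 LSU) under the real gene symbols, 13 paralog pairs with
RpS14a/b sequence-identical, and every distinguishable pair carrying six
internal tryptic peptides with 1–2 substitutions — the structure that
matters for every pipeline property (counts, uniqueness classes,
discriminating pairs), without claiming sequence realism. User-supplied
registries replace it via two files (FASTA + annotation TSV). Uniqueness
is always relative to the supplied registry; proteome-wide uniqueness
requires a proteome-scale registry.

## Numerical and design choices

* Tryptic rule: cleave after K/R unless followed by P (the proline
  exception is configurable off); peptide length window 6–50 residues and
  ≤ 2 missed cleavages by default, typical search settings. Initiator
  methionine is not removed — the registry owns sequence curation.
* Modifications affect mass, not identity: uniqueness and PSM joining use
  the stripped sequence.
* Multi-protein PSMs are dropped by the uniqueness filter; without it they
  count once per listed protein (logged).
* Welch P is undefined (NaN) below two values per group; NaN never counts
  as significant.
* The t-test's type-I error is calibrated against an i.i.d. log-normal
  null matrix (2000 proteins, 3 vs 3), where the test's nominal size is
  exact. A full-simulation null would share Poisson count draws across
  channels of a run, making the unpaired test conservative — a property of
  run-paired designs worth knowing, not a flaw of the test.
* All simulation randomness flows from one integer seed through a single
  `numpy` generator with fixed iteration order; identical seeds give
  bit-identical tables, and the pipeline itself is deterministic.
* Desk-scale problem sizes: the bundled integration run uses ~80 k
  simulated PSMs (depth 5, 3 replicates, 4 tissues + pooled channel);
  Monte-Carlo calibrations use a 6-protein toy registry at ~2000 PSMs per
  repetition, 50 repetitions per stoichiometry setting. These sizes were
  chosen as the package's own test scale.

## Known limitations

* Differential ionization between the two peptides of a pair is assumed
  away (inherited from the method itself); `pair_coupling=False` exists to
  probe that assumption but no correction is offered.
* Only two-member paralog groups are modelled; no isoforms, no more-than-
  two-gene families.
* Enrichment evidence is binary per tissue (any configured comparison);
  no meta-analysis across comparisons.
* The status thresholds have no external calibration; they are honest
  configuration, and the `insufficient_data`/`canonical_dominant`
  boundary depends on which comparisons were configured.
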