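# Methods

## Assay model and sensitivity index

A CSRA plate for one specimen × drug carries treated wells at six
concentrations on a geometric ladder — 6.25, 12.5, 25, 50, 100, 200% of the
100% test drug concentration (TDC) — plus ≥3 vehicle-control wells and ≥1
medium-only blank. Signals are arbitrary fluorescence units from a
resazurin-type viability readout; only their affine structure matters.
Normalization subtracts the mean blank and scales by the vehicle–blank
window:

    inhibition(c) = 100 · (1 − (mean treated(c) − mean blank) / (mean vehicle − mean blank))

This makes inhibition invariant under common rescaling of all signals.
Replicates are aggregated by arithmetic mean (no aggregation rule is
standard; the mean is the obvious choice for 2–3 replicates). A plate whose
vehicle mean does not exceed its blank mean is rejected as degenerate rather
than silently producing nonsense.

The sensitivity index is the complement of total observed inhibition:

    SI = 600 − Σ_c inhibition(c),  c over the six fractions.

**Clamping.** Noise can push per-fraction inhibition below 0 (apparent
stimulation) or above 100 (signal below blank). By default each fraction is
clamped to [0, 100] before summation, keeping SI on its constructed 0–600
scale; the unclamped values and the unclamped SI are always carried
alongside for audit, and the call can be switched to the raw SI
(`clamp=False` / `--no-clamp`).

**Call threshold.** Sensitive ⇔ SI < 250. The source convention defines
sensitive strictly below and resistant strictly above 250, leaving equality
unspecified; we assign SI = 250 to **resistant** — the conservative
direction for a resistance phenotype — and document the policy here rather
than hiding it in code.

Drug identities and their 100% TDCs are carried as configuration
(`DEFAULT_DRUGS`: Dox 1.0, Ifo 3.0, Dox+Ifo 1.0+3.0, Doc 11.3, Gem 25.0,
Doc+Gem 11.3+25.0, unit string "mg/mL" as configured). The unit is an opaque
label and is never converted; combinations are scored exactly like single
agents on their own ladder, with no interaction modeling. Dose-response
curves are never fitted — the SI is a sum of sampled inhibitions, not a
parameter estimate.

## Panel variants and mutation status

Upstream variant calling and annotation are out of scope; input is an
annotated variant table (TSV with specimen, gene, genomic change, protein
change, consequence, optional COSMIC id and LOF class; or a VCF whose
ANN/CSQ field supplies gene, consequence term and HGVS.p). Consequence terms
are mapped onto a closed set {missense, nonsense, frameshift, splice,
other}; a variant **qualifies** when its gene is in the user-supplied panel
and its consequence is protein-altering (everything but "other").
Pathogenicity-database narratives are not reproducible algorithmically, so
no pathogenicity filter is applied by default; `require_cosmic=True`
restricts to records carrying a COSMIC id. Gene symbols match
case-insensitively after whitespace stripping, with no alias resolution.

The mutation matrix is binary over the full cohort (all-zero rows kept), so
duplicated variant records cannot change it and enlarging the panel can only
keep or add Mut+ specimens — both properties are tested.

## One-sided exact association

For each drug and stratum (UPS, SS, pooled STS) the 2×2 table crosses
Mut+/Mut− with sensitive/resistant. Conditional on all margins, the
resistant count X among the n Mut+ specimens is hypergeometric with cohort
size N and total resistant K. The pmf is computed in log space from a
cached log-factorial table (stable to N in the hundreds and vectorized over
all arguments). Tails:

- upper: P(X ≥ x) — resistance enriched among Mut+,
- lower: P(X ≤ x) — resistance depleted,
- **auto** (default): the smaller of the two, labeled with its direction.

The auto rule is the one-sided test in the direction of the observed
deviation; it reproduces every reproducible published p-value (see
Limitations). Both fixed tails remain available. A table with an empty Mut+
or Mut− row is uninformative: p = 1.0 with a `degenerate-margin` flag rather
than an exception. Note the auto rule is *not* a valid p-value at large
thresholds (its null exceedance is bounded by 2α, not α); at the α = 0.05
used throughout, discreteness keeps it conservative, which the type-I-error
simulation verifies at the study's cohort size.

Specimens lacking an assay call for a drug are deleted pairwise from that
drug's tables, which is why evaluable totals vary by drug (e.g. 27 of 37 for
ifosfamide). No multiple-testing correction is applied across the 18
drug × stratum tests, matching the analysis being reproduced; a
Benjamini–Hochberg column is available (`add_bh_adjusted`) but off by
default.

**Partial-LOF reassignment.** Variants can carry a loss-of-function class
(total / partial / unknown). A specimen whose qualifying panel variants are
*all* partial retains some pathway function; the sensitivity analysis either
moves such specimens to Mut− (default, `policy="reassign"`) or drops them
(`policy="exclude"`). Reassign is the default because in the reference
cohort it yields the exact point mass C(23,9)/C(37,9) ≈ 0.0066, matching the
published "0.006" to one significant figure, versus 0.0087 for exclusion.
The only shipped LOF annotation is TP53 p.L344R → partial (reduced
tetramerization); everything else defaults to "unknown", which blocks
reassignment.

**Gene-class distribution test.** Among mutated specimens only, a 2×2 of
histotype (UPS/SS) against TP53-mutated vs other-panel-gene-only, tested
with the same auto-tail rule. On the reference cohort: UPS 6/1, SS 0/3,
p = 1/30 ≈ 0.033.

## Synthetic cohort generator

The generator's defaults are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| n_ups, n_ss | 25, 12 | published cohort composition |
| mut_prevalence | 0.27 | published panel-alteration prevalence |
| baseline_resistance_prob | 14/27 ≈ 0.52 | Mut− doxorubicin resistance in the published counts |
| odds_ratio | (9/1)/(14/13) ≈ 8.36 | the published doxorubicin effect |
| hill_sensitive | Imax 95%, EC50 0.10 TDC, h 1 | noiseless SI ≈ 187 (sensitive mode) |
| hill_resistant | Imax 60%, EC50 0.35 TDC, h 1 | noiseless SI ≈ 419 (resistant mode) |
| vehicle, blank, noise | 20000, 1000, 500 units | ~2.6% of the dynamic window, a clean plate-reader regime |
| replicates | 3 | triplicate wells |

Resistance phenotype is drawn first (Bernoulli; Mut+ odds multiplied by the
odds ratio, for doxorubicin only — no effect is planted for the other
drugs), then plates are synthesized from the phenotype's Hill curve
inhibition(c) = Imax·cʰ/(EC50ʰ + cʰ) with additive Gaussian well noise
truncated at zero. Generating the phenotype before the curve keeps the
planted truth unambiguous and makes the SI distribution bimodal with modes
straddling the 250 threshold, ~115 SI units clear of it on each side — so
at the default noise the pipeline classifies without error, and with zero
noise the recovered SI equals the Hill-curve value exactly. One qualifying
variant (random panel gene, missense or nonsense) is planted per Mut+
specimen. All randomness flows from one `numpy` Generator seed; identical
(config, seed) gives byte-identical output files.

What the generator does **not** emulate: plate-position effects, partial
dose-response (phenotypes between the two modes), multi-variant specimens,
histotype-dependent effect sizes, or correlated drug responses within a
specimen. Passing round-trip tests therefore demonstrates correctness of
the scoring/association machinery under a clean bimodal regime, not
robustness to messy real plates.

`gen_table4_fixture()` is the other data source: it rebuilds the published
cohort from printed inputs. The 10 mutated specimens and their 11 variants
are as published (histotype split derived from the reported gene
distribution: the six TP53 carriers and the CSF2RB carrier are UPS; the
ATM/NTRK1, PIK3R1 and PIK3CB carriers are SS). The 27 unmutated specimens
get placeholder ids (`SYN-U*`, `SYN-S*`), and calls/NA within each
histotype × status group are assigned in a fixed arbitrary order consistent
with every printed per-histotype count cell; for doxorubicin the one
sensitive mutated specimen is pinned to AF98b as reported. Missing assays
(ten each for Ifo and Dox+Ifo) fall on unmutated specimens.

## Problem sizes and numerical checks

The test suite runs the exact test against two independent oracles — an
exact-fraction enumeration of the hypergeometric support and scipy
(`stats.hypergeom`, `stats.fisher_exact`) — on 1,000 random tables (N ≤ 40),
sweeps pmf normalization exhaustively over every margin triple up to
N = 200, verifies type-I control at α = 0.05 over 2,000 simulated null
cohorts of 37 specimens, and checks Monte-Carlo power (600 cohorts) against
full enumeration of the rejection probability. These sizes give Monte-Carlo
standard errors well under a percentage point while keeping the default
suite around a minute of CPU.

## Known limitations

- Two published p-values are not reproducible from their own printed
  counts under any standard Fisher tail: SS doxorubicin prints 0.38 where
  the counts [[0,3],[6,3]] give 0.091 (upper) / 0.18 (two-sided), and UPS
  ifosfamide prints 0.52 where the counts give 0.5257 (which rounds to
  0.53). Both are reported as discrepancies and deliberately not forced.
- The published pooled Dox+Ifo column (4/5 | 12/6) is inconsistent with its
  own histotype columns (which pool to 5/5 | 10/7); no specimen-level cohort
  can satisfy both. The fixture follows the histotype columns; pooled
  Dox+Ifo statistics from printed counts use the printed pooled cells
  directly.
- The published "0.006" for the reassignment analysis is matched to one
  significant figure: the exact computation gives 0.00657, which rounds to
  0.007. The printed value's rounding provenance is unknown.
- Published per-specimen SI values were never released; the fixture encodes
  calls, not SI scores, so SI-distribution statements can only be checked on
  synthetic cohorts.
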