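# Methods

## Rate estimation from spiked slurry incubations

A slurry incubation spikes one sulfur species (sulfide, thiosulfate, or
sulfite) into a sediment suspension and follows the concentrations of all
measurable species over time in three groups: experimental (live
sediment), control (heat-killed sediment, capturing chemical
transformation), and blank (buffer without sediment, capturing assay
drift). Because substrate limitation and product accumulation slow every
transformation as the incubation proceeds, per-interval rates decline
monotonically, and the maximal rate is taken from the first sampling
interval after addition (*first-interval convention*). Concentration
changes are converted to sediment-mass-specific rates by

rate (µmol h⁻¹ g⁻¹) = |Δc (µmol L⁻¹)| × V_liquid (L) / (Δt (h) × m_sediment (g)).

The liquid volume is the added buffer/diluent volume; porewater is
ignored, which is consistent for the strongly diluted slurries this
convention targets (1:100 for the sulfide design). Replicates are
estimated independently; the reported value is their mean and the SEM
their standard deviation over √n. If a blank series exists on the same
time grid, its mean drift is subtracted from the concentration changes
first; with no blank, correction is skipped.

For processes that remain linear over the whole incubation (the
thiosulfate-accumulation case), the first interval is dominated by noise
rather than kinetics, and a whole-period ordinary least-squares slope is
used instead (`method="whole_period_linear"`). Method choice is explicit
per species; a heuristic (whole-period fit R² > 0.98) only flags series
that look linear, it never switches methods silently.

Derived quantities:

* biological = total − chemical, SEMs propagated in quadrature. A
  negative difference is returned as-is with a flag — clipping would bias
  averages of replicate estimates.
* ZVS→sulfite = net sulfite production + thiosulfate production + sulfite
  consumption (zerovalent sulfur cannot be spiked, so its oxidation flux
  is inferred from the budget of its product pool).
* unknown fate = ZVS production − ZVS→sulfite − thiosulfate production;
  the sign is preserved and negative values flagged. Whether this
  residual contains abiotic sinks (e.g. FeS formation) is not decidable
  from the budget; the package only reports it.

Two published conventions exist for the sulfite-consumption addend: the
total measured sulfite consumption (13.10 µmol h⁻¹ g⁻¹, giving
ZVS→sulfite = 48.53) and the directly reported biological sulfite
oxidation (12.8, giving 48.2). Both are exposed
(`fig6_total_sulfite_consumption`, default, and
`text_biological_sulfite_oxidation`); note 12.8 is not the
total-minus-chemical difference (13.10 − 1.34 = 11.76), so the two
conventions are kept strictly separate rather than reconciled. Published
rate values themselves appear in two printings that disagree in the last
digit; the figure-caption printing is taken as canonical. Reported values
are rounded half-up to two decimals.

Values below the assay detection limit are treated as missing and
flagged; no LOD/2 substitution is applied, because no censoring rule
accompanies the published detection limits. A series whose first
post-addition interval is censored cannot be estimated by the
first-interval method and raises an explicit error.

## Capability calling

Gene families are validated against a controlled vocabulary with a
case-insensitive synonym map (e.g. FCSD ↔ fccB). Substrate rules are
disjunctions of gene-set requirements (see README); they ship as editable
YAML together with the autotrophy pathway definitions. Decisions embedded
in the rules:

* The Sox thiosulfate rule requires soxA, soxB, soxX, soxY, soxZ; soxC is
  optional and soxD is never required (it is absent in the sediments this
  emulates; its absence is flagged as `sox_lacks_soxD`, marking partial
  thiosulfate oxidation to sulfate plus ZVS).
* The indirect sulfite route requires the complete Sat-AprAB set (all
  three genes); Sat alone never fires it.
* FccB (the catalytic FCSD subunit) alone suffices for a sulfide call;
  requiring the cytochrome subunit FccA would undercount fragmented
  genomes.
* rDsr functional-context co-occurrences (DsrC; DsrEFH with TusA) and
  putative sulfur reducers (reductive DsrAB plus PhsA) are reported as
  flags, not used in capability booleans.

**sHdr synteny.** Genes on a scaffold are ordered by start coordinate.
A cluster is a run of consecutive sHdr subunits whose subtype sequence
follows HdrC1-HdrB1-HdrA-HYP-HdrC2-HdrB2, or its exact reversal (a
minus-strand operon appears reversed in coordinate order; strand labels
are informational because annotation strands are unreliable across
binning pipelines). Runs of ≥5 subunits count; scanning is greedy,
leftmost-first, non-overlapping, taking the longest valid run at each
start. "Consecutive" is strict — one interleaved foreign gene breaks the
run — with a `max_gap` switch for robustness experiments.

**Genome QC.** Completeness > 50% and contamination < 10%, both strict,
matching the catalog definition the calling emulates.

**Autotrophy.** A pathway is confirmed iff ≥70% of its genes are present,
or all marker genes are present and more than 50% of the accessory genes
are. A pathway defined without accessory genes is confirmed by its
markers alone (the accessory branch would otherwise be vacuously
unsatisfiable). One confirmed pathway labels the genome autotroph;
otherwise heterotroph-or-mixotroph. The shipped pathway gene lists are
reconstructions from standard carbon-fixation biochemistry (the curated
lists of any given study live in its supplementary material); they are
plain YAML and meant to be replaced.

## Abundance and transcript normalizations

Scaffold relative abundance = mapped reads / (scaffold length × library
size) × 10⁶; gene abundance is the sum over carrying scaffolds (the 10⁶
factor commutes with the summation; the scaffold-first order follows the
usual presentation). Scaffolds under 2,000 bp are rejected by default
because only longer scaffolds are annotated upstream. MAG fraction
tables must contain an explicit `unmapped` row per sample; it is removed
and the remaining fractions renormalized to sum to one (±1e-9 enforced).

Sediment layers: surface 0–2 cm, middle 8–30 cm, bottom >30 cm. The
scheme leaves 2–8 cm undefined, and sample lists in the source scheme are
ambiguous at exactly 30 cm; depths in the gap are explicitly
`unassigned` (never forced), and 30 cm falls in the middle layer per the
stated range.

Transcript abundance = depth / total cleaned reads × 10⁹;
log2FC = log2(experimental) − log2(control). The contrast is undefined at
zero, so a pseudocount policy is explicit: default `auto` (the smallest
nonzero normalized abundance across both conditions), alternatives
`fixed` and `skip_zeros`. Group-level contrasts sum abundances within the
group per condition before the log ratio (ratio of sums), so a group's
fold change is that of its pooled transcript mass; a mean-of-logs variant
exists behind a flag. Statistical testing of fold changes is out of
scope — the contrasts are descriptive.

## Synthetic data

`simulate_incubation` defaults mirror the sulfide design: 1 mM spike,
1 g sediment, 99 mL buffer, 10-min sampling over 1 h, three replicates,
Gaussian measurement noise of 50 µM (5% of the initial concentration),
detection limit 0.5 µM. Substrate decays first-order (guaranteeing the
monotone per-interval premise of the first-interval convention; a
saturating Michaelis–Menten-like form is available to stress-test it),
the control decays at the chemical rate only, products accrue by fixed
split fractions (so total sulfur is conserved exactly in noiseless runs),
and noise plus LOD censoring are applied last.

Under continuously declining kinetics the first-interval estimator
targets the *average* rate over the first interval, which is strictly
below the instantaneous initial rate (relative discretization bias
≈ kΔt/2, about 11% at the defaults). The truth record therefore carries
both; recovery is assessed against the first-interval average, which is
the estimand of the convention. Recovery at the default noise is unbiased
with a relative error of the mean (100 seeded runs) around 2–3%.

`simulate_community` plants per-genome gene complements (whole complexes
— Sox, rDsrAB, Sat-AprAB — planted jointly so complete sets occur at
realistic rates; prevalences loosely mirror a coastal-sediment catalog
with PDO the commonest ZVS gene and SoxD absent), valid sHdr runs and
shuffled decoys (decoys re-shuffled until no ≥5 window is canonically
ordered, giving the detector a false-positive surface), autotrophy
pathways with optional gene dropout, lognormal genome abundances
converted to coverage tables by inverting the ×10⁶ formula, MAG depth
fractions with an unmapped pool, and paired transcript depths with
planted fold changes (default: 76-fold pdo upregulation in
Planctomycetota). Capability truth is evaluated from the planted presence
sets with the same boolean rules the caller uses — deliberately a closed
loop that verifies the table plumbing and the synteny detector, while
rule correctness itself is established independently against exhaustive
truth-table and all-windows oracles in the test suite.

All generators draw from named streams derived from one integer seed, so
identical seeds give byte-identical outputs and adding draws to one stage
never shifts another.

What the synthetic data does *not* emulate: real gene-calling and
annotation error, incomplete genomes truncating operons mid-cluster,
correlated taxonomic structure in gene content, compositional coupling
between samples, or kinetic forms outside the two implemented. Passing
tests therefore demonstrate the correctness of the computations, not the
field accuracy of annotations or measured rates, and full-scale
real-data panels (a 5,233-genome catalog, per-phylum compositions, the
measured rates themselves) require the original sequencing and chemistry
data.

## Problem sizes

Default analysis and verification sizes were chosen to keep everything
comfortably runnable on a laptop core: 100 seeded incubations for
recovery, 1,000-genome communities for caller agreement, 1,000 randomized
rate sets for the budget identity, 500 random scaffolds (≤50 genes) for
the synteny oracle, and exhaustive 2¹² truth tables per rule block.
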