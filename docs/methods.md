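# Methods

## Scope and model

The package reproduces, in silico, the workflow used to detect DNA cytidine
deamination by differential DNA denaturation PCR (3DPCR): a population of
amplicon molecules is edited by a context-preferring deaminase, passed
through a denaturation-temperature gradient that selectively amplifies
AT-enriched (edited) templates, and clones sampled from the lowest positive
band are analysed for substitution spectrum and 5' dinucleotide editing
context.

### Editing model

Deamination converts C to U (or 5-methyl-C to T); after amplification either
lesion reads as C→T on the edited strand.  Per molecule, one strand is
exposed according to the strand policy (`plus_only`, `minus_only`, or
`both_random` with a fair coin; the default is `both_random` because clone
sets typically show both C→T and G→A substitutions and no strand ratio is
established).  On the exposed strand, each eligible cytidine is edited
independently with probability `rate × w(context)/max(w)`.  Normalising by
the maximum weight keeps `rate` interpretable as the editing probability at
the preferred context; absolute per-context rates are not identifiable from
clone data.  Edits are independent within a molecule — no processivity is
modelled, as there is no quantitative processivity information for APOBEC1
to calibrate one.

A cytidine whose 5' neighbour is missing (first position of its strand) or
ambiguous (N) has no defined context and is ineligible for editing; the
analysis drops such events from context counts symmetrically, so simulator
and analysis agree site for site.

Minus-strand editing is implemented by applying the plus-strand rule to the
reverse complement of the reference, sharing the same random matrix.  This
makes strand symmetry exact by construction: a minus-only simulation of a
target is, realisation for realisation, the plus-only simulation of its
reverse complement under the same seed.  Minus-strand events appear as G→A
on the plus-strand read, and their context is the reference base 3' of the
G, complemented — the standard APOBEC reporting convention, which makes
plus- and minus-strand events poolable.

The 5Me-dC substrate mode changes no sequence outcome (both lesions read as
T); it is carried as a label only.  Background (non-deamination) errors are
off by default; when enabled they hit un-edited positions uniformly at
`error_rate` per base with a uniform choice among the three alternatives,
so the ground-truth edit list remains exact.

### Melting-temperature and gradient model

Tm is a calibrated linear proxy anchored at the reference:

    Tm = restrictive_td − delta_per_sub × #(GC→AT substitutions)

Substitutions that do not convert a G/C into an A/T contribute nothing.
Nearest-neighbour thermodynamics are deliberately not used: wet-lab
restrictive temperatures are amplicon- and buffer-specific (reported anchors
for different amplicons span roughly 82–90 °C), so only an anchor plus a
per-substitution decrement transfers between settings.  Defaults:

| parameter        | default | units | rationale |
|------------------|---------|-------|-----------|
| `restrictive_td` | 85.7    | °C    | typical restrictive Td of a moderate-GC ~500-bp amplicon |
| `delta_per_sub`  | 0.04    | °C    | ≈1 °C per 1% composition change on a 500-bp amplicon; places the detection limit within the reported 2–4 substitutions/kb sensitivity of 3DPCR |
| `epsilon`        | 0       | °C    | no amplification tolerance; selection is a sharp threshold |
| gradient         | 12 wells, restrictive −5 °C to +4 °C | °C | ≈0.8 °C step, mimicking typical printed gradient spreads |
| `min_templates`  | 1       | molecules | the wet-lab template count per band is unknown; configurable |

Amplification is all-or-none (a molecule is a template at Td iff
Td ≥ Tm − ε) with no per-cycle stochastic enrichment; 3DPCR selectivity is
reported at up to 10⁴-fold, so threshold behaviour dominates.  Recovery sets
are therefore nested along the gradient, and the "last positive band" is
the lowest Td with at least `min_templates` templates.  A run counts as
detecting editing when that band lies strictly below the restrictive
temperature.

### Clone-set statistics

* **Mutation matrix**: 4×4 reference-base × observed-base substitution
  counts; positions with N in either sequence are skipped.  Clones must
  match the reference length — 3DPCR amplicons are fixed-length and only
  substitutions are modelled, so mismatched input is rejected rather than
  aligned.
* **Expected context**: %NpC = 100 × #NpC / #eligible C from reference
  composition alone, pooled over the requested strands (minus-strand Cs are
  reference Gs, context read on the reverse complement).
* **χ² test**: classical goodness-of-fit Σ(O−E)²/E with
  Eᵢ = total observed × expected %/100 over categories with Eᵢ > 0,
  df = retained − 1 (3 for the usual four contexts).  Expected counts below
  5 raise a validity flag but do not switch methods.  The exact multinomial
  test is not used; the χ² convention matches how context deviations are
  conventionally reported.
* **Hypermutant call**: a clone is `hypermutated` iff its pooled C→T + G→A
  count k has one-sided binomial tail P(X ≥ k | n, p = background_rate)
  < 10⁻³ and k ≥ 2, with n the number of reference C/G positions (every
  site at which a deamination event could be observed).  The threshold is
  an explicit operational definition, since "hypermutated" has no standard
  quantitative one; `background_rate` defaults to 10⁻⁴ per base, a typical
  PCR-plus-sequencing error scale.

### Pipeline

`run_pipeline` executes simulate → gradient → sample → analyze.  By default
clones are sampled at the lowest positive Td, matching the wet-lab practice
of sequencing the band just below the restrictive temperature.  Stage seeds
are derived from the master seed via a seeded generator; replicate
aggregation uses master seed + replicate index.  Never wall-clock entropy —
a run is reproducible bit for bit from its config, whose SHA-256 hash is
recorded in every report.  When no band appears below the restrictive
temperature (the mock-transfection / dead-enzyme outcome), the run still
samples and analyses the restrictive band, reports the (all-zero) matrix,
and carries status `"no sub-restrictive recovery"`; this is a valid
scientific outcome and the CLI exits 0.

`detection_threshold_scan` inverts the editing rate from a requested mean
mutation load (substitutions/kb) using the closed-form expected edits per
molecule under the model, simulates replicate populations per grid load,
and returns the smallest load whose band falls below the restrictive Td in
at least half the replicates.

## Synthetic targets

Real 3DPCR amplicon sequences are not bundled; `generate_target` draws
i.i.d. bases at a specified GC fraction (default 500 bp, GC 0.45 — a
plausible moderate-GC amplicon, not a measured value).  The generator
emulates length and composition only: it has no codon structure, CpG
depletion, repeats or primer sites, and i.i.d. bases mean dinucleotide
frequencies follow mononucleotide products, so expected-context percentages
are smoother than for real loci.  Passing tests therefore demonstrate
correctness of the editing/selection/statistics machinery, not calibration
to any particular real amplicon.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; reports are 1-based.
* Temperatures are compared with a 10⁻⁹ °C slack when testing "strictly
  below restrictive"; reports round to 0.1 °C.
* Modal context ties break by fixed ApC < CpC < GpC < TpC order.
* Context weights must sum to 1 within 10⁻⁹; all-zero weights are rejected.
* A reference with no eligible cytidine raises a "no editable sites" error
  in the analysis and yields a zero-edit population (with a warning) in the
  simulator.
* Sampling more clones than a band recovered falls back to sampling with
  replacement, flagged in the log.

## Problem sizes used in the test suite

The repeated-run checks use populations the statistics are comfortably
powered for at interactive runtimes: 100 end-to-end replicates of the
default 500-bp/1,000-molecule/20-clone configuration for context recovery;
100 seeds of a 300-bp/100-molecule negative control; 1,000 random
60-bp/8-molecule populations for the gradient invariants; and a 20-replicate
threshold scan on the default configuration.

## Known limitations

* The Tm proxy is relative, not predictive: it will not reproduce absolute
  wet-lab Td values for a given amplicon or buffer.
* All-or-none amplification ignores PCR efficiency gradients, primer bias
  and per-cycle error accumulation (background error is a single post-hoc
  per-base rate).
* No indels, no repair chemistry (UNG/BER), no processivity, no RNA
  editing.
* Tetranucleotide-level signature decomposition (e.g. YTCA vs RTCA) is out
  of scope.
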