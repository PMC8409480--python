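# Methods

This note records the models, conventions, parameter choices and known
limitations behind `amplitrace`, in the order a read travels through the
toolkit.

## Plate geometry

Wells are 0-based `(row, col)` with row A at the top-left; labels follow
the `A1`..`H12` convention (`A1`..`P24` for 384-well plates). Distances are
Euclidean in well-pitch units with row and column pitch treated as equal —
standard SBS plates have a single 9 mm (96-well) or 4.5 mm (384-well) pitch
in both axes, so this is exact for real hardware. "Rounded" distances round
half away from zero, so the diagonal neighbour (√2 ≈ 1.41) bins at 1.

Only the 180° rotation is modelled for the rotation check: a rectangular
plate cannot be seated rotated 90° in a rectangular holder.

## Barcode design

All generation is seeded rejection sampling: candidate sequences are drawn
uniformly, filtered on composition, then on distance to the already
accepted set, with an attempt budget (default 10⁶) so infeasible requests
fail loudly with the partial count achieved. Deterministic given the seed.

Composition defaults: GC fraction in [0.40, 0.60], homopolymer runs ≤ 3.
These operationalize "reasonably balanced GC, no extended homopolymers";
neither bound is critical and both are exposed as parameters. Internal
complementarity (hairpin/dimer propensity) is not scored; thermodynamic
screening belongs to synthesis-vendor tools.

**MIDs.** Lengths 8–10 nt; within an orientation, MIDs of equal length are
kept at Levenshtein ≥ 2 (single-error detectability). Two additional
cross-length rules are enforced at generation time:

1. *Prefix freedom* — no MID is a prefix of a longer MID in the same
   orientation. Without it, a perfect read of the longer MID is
   indistinguishable from a perfect read of the shorter MID whose template
   happens to begin with the right bases.
2. *Cross-length distance ≥ 3* — a single indel changes a MID's apparent
   length by one; if the edited sequence lay within one edit of a MID of
   the neighbouring length, longest-first matching could assign the read
   to the wrong sample with zero observable inconsistency. Distance ≥ 3
   between different-length MIDs removes that channel entirely; the
   remaining cross-length confusions require the primer to align shifted
   by 1–2 bases, which real locus primers reject at ≤ 2 allowed
   mismatches. The safety property (no single edit in the MID region can
   reassign a read) is verified exhaustively in the test suite over every
   single-base substitution, insertion and deletion of all 192 MIDs.

**Coligo identifiers.** 13 nt, pairwise Levenshtein ≥ 3. Minimum distance 3
is the smallest bound under which every single-edit corruption has a unique
nearest identifier, i.e. detection *and correction* of one substitution,
insertion or deletion. A full coligo is
`fwd_primer + identifier + reverse_complement(rev_primer)` (52 nt with the
515F/806R pair), so it amplifies with the same chemistry as the biological
locus.

**Mixture schemes.** The comparator design pools k oligos from a panel of
n per well (3 of 12 → C(12,3) = 220 mixtures). `assign_mixtures_to_plate`
places mixtures greedily in row-major order, maximizing at each step the
minimum symmetric difference against already-placed orthogonal neighbours
(seeded tie-breaking). `mixture_detectability` enumerates every ordered
(donor set, recipient) event; the observable evidence is
F = (∪ donors) \ recipient, and an event counts as detected iff exactly
one candidate donor set reproduces F. For the unrestricted 220-mixture
pairwise case only donors disjoint from the recipient are unambiguous,
giving C(9,3)/219 ≈ 38.4% — the published ~60% figure for this family of
designs depends on a specific plate arrangement that was never published,
so it is not reproduced here and the greedy placement is deliberately not
tuned toward it. Donor candidates are restricted to mixtures actually
placed on the plate when a well assignment exists. Internally mixtures are
bitmasks over the panel, which keeps the 220 × 219 single-donor enumeration
instantaneous and the two-donor case tractable.

## Demultiplexing

Matching is primer-anchored and longest-MID-first: for each candidate
length L (descending), the first L bases are compared to the MIDs of that
length (Levenshtein ≤ `max_mid_edits`, default 1) and the following bases
to the locus primer (substitutions only, IUPAC-aware, default ≤ 2). The
unique candidate minimizing (MID edits, primer mismatches) wins; ties are
`ambiguous_mid`, and failures return reason codes (`no_mid`, `no_primer`,
`locus_conflict`, `unknown_pairing`) rather than exceptions. Both mates
must agree on the locus; the sample is the (forward, reverse) MID pair
looked up in the plate layout. `max_mid_edits` must stay below the set's
same-length distance floor, which the configuration enforces.

Primer matching allows no indels by default — a deliberate simplicity/speed
trade-off; polymerase indel rates over a 19–20 nt window are far below the
substitution tolerance already granted. Quality strings are trimmed
identically to sequences and otherwise untouched: quality filtering belongs
downstream. Unassigned reads go to a single `undetermined` pair with the
reason code in the header. One-step and two-step library preparations
produce the same amplicon structure and are handled identically.

Read-count conservation (assigned + unassigned = input) is asserted on
every run.

## Contamination analytics

The 13 bases after the forward primer of each *forward* read are matched to
the tracer set (short tracer inserts make read merging unreliable, so
reverse reads are ignored). Exact match wins; otherwise the window flexes
±1 base to absorb an indel and the unique identifier within 1 edit is
taken (exact-only mode available via `max_edits=0`).

Report conventions:

- A well counts as contaminated iff it holds ≥ `min_foreign_reads` of some
  foreign tracer (default 1; a single read can be residual sequencing
  error even with distance-3 identifiers, so the threshold is exposed).
- Wells with zero tracer reads have undefined proportions: they are
  excluded from medians and tallied separately rather than imputed as 0 —
  dividing by zero tracer reads is meaningless, and such wells tend to be
  low-depth.
- `overall_out_of_place_proportion` is total foreign tracer reads over
  total tracer reads, plate-wide.
- The distance profile emits one event per (recipient, foreign tracer)
  pair at the rounded Euclidean distance from the tracer's home well;
  several foreign tracers in one well are several events. Tracers with no
  home well on the layout bin as `"external"`.
- The rotation check scores each orientation by the fraction of tracer
  reads explained (read-weighted, hence robust to uneven well depth);
  exact ties keep 0° with a warning.

Tracer-synthesis cross-contamination is indistinguishable from handling
contamination in this framework; a nonzero floor in an otherwise clean run
may reflect the oligo pool itself.

## ISD normalization

`match_isd_esvs` flags features whose global-alignment identity to the ISD
reference is ≥ 0.95 over ≥ 0.9 coverage (identity = 1 − edits/max length,
unit costs). The thresholds are pragmatic defaults for denoiser-splintered
variants of a ~170 nt molecule and are exposed as flags. Matched features
are summed into one ISD feature (per-sample totals conserved), then

    y_i = count_i / count_ISD

per sample. Tracer features are excluded from the output — their read
counts vary too much between technical replicates to serve as standards.
Samples with zero ISD counts are flagged `no_isd` with NaN ratios rather
than pseudocounted; an explicit pseudocount is a modelling decision the
caller should make knowingly. Absolute abundance is y_i × spike amount, in
the spike's unit.

The dilution check regresses log₁₀(p/(1−p)) of the ISD read proportion on
log₁₀(spike amount): on the odds scale the expected slope is exactly 1
across the whole range, whereas raw proportions saturate at high spike
levels. Levels with zero ISD reads are excluded and reported.

No between-taxon scaling is offered anywhere: marker-locus copy number
varies within and among taxa, so only within-taxon, across-sample
contrasts are defensible.

## Simulator

The simulator emulates the read structure the pipeline assumes —
`R1 = fwd MID + amplicon`, `R2 = rev MID + reverse complement(amplicon)`,
amplicons carrying the locus primers with degenerate positions resolved to
concrete bases per molecule — with per-well pools mixing a log-normal
background community, one tracer per well, and the ISD.

Defaults and what they emulate:

- `coligo_fraction = 0.01`, `isd_fraction = 0.005` molecule fractions: the
  top of the realized spike-read band observed in real complex libraries
  (10⁻⁸ % – 1 % of reads), chosen so per-well tracer counts stay
  informative at desk-scale depth. Spikes are specified as molecule
  fractions; mass-to-molarity conversion is out of scope.
- Reads per well ~ negative binomial (mean 1000, shape 10): overdispersed
  per-well depth as seen across real plates.
- Contamination: events per well ~ Poisson(rate); the donor is drawn with
  probability ∝ (1−ε)·exp(−d/λ) + ε over other wells (λ = 1.5 wells,
  ε = 0.05) — near wells dominate but remote donors keep a uniform floor,
  matching the qualitative observation that migration decays with distance
  yet remote events are common. Each event moves a Beta(1, 50) fraction
  (mean 2%, minor contamination) of the donor's *native* pool into the
  recipient; using pre-event pools as the source keeps events independent
  of application order. This generating model is a phenomenological
  stand-in — the real contamination process was observed, never modelled —
  so parameter estimates from it validate the analytics, not the biology.
- Errors: independent per-base substitutions and indels at configured
  rates; constant quality scores. No chimeras, no cycle-dependent error
  profiles, no instrument-specific spectra — conclusions about error
  *spectra* cannot be drawn from these simulations, only about the
  tolerance properties actually tested (edit-bounded correction).
- Templates shorter than the read (tracers are ~52 nt inserts) are padded
  with an adapter stub then random bases, modelling read-through of short
  fragments ("staggering").

`sample_coligo_counts` draws the wells × tracers matrix multinomially from
the pool's tracer components directly, skipping read construction; the
contamination-recovery analyses use it at 1400 tracer reads per well
(≈ 1.4 × 10⁵ reads/well at the 1% tracer fraction, the depth of a typical
high-output run). The FASTQ path is exercised end to end by the closed-loop
demultiplexing checks and the pipeline smoke test.

**Migration-fraction estimator.** For an event moving fraction m of a
donor pool into a recipient with equal tracer spike fractions, the
expected ratio of (donor-tracer reads)/(recipient-own-tracer reads) within
the recipient equals m exactly, independent of depth and of the absolute
tracer fraction. The toolkit therefore estimates m as foreign/expected
within the recipient; the regression of these estimates on injected truth
has slope 1 within sampling error (verified over ~200 events across 20
plates).

## Problem sizes and determinism

All stochastic components consume a `numpy` `default_rng` seed; CLI runs
record it in the manifest, and identical configurations reproduce outputs
byte-for-byte. The standard verification sizes are: two simulated 96-well
plates of ~10⁵ read pairs each for the closed-loop demultiplexing checks,
20 plates (~200 events) for contamination recovery, and 6 dilution levels
spanning five orders of magnitude for the spike-in check; these sizes keep
each analysis under a minute on one core while leaving binomial sampling
error well inside the tested tolerance bands.

## Known limitations

- Reproduction of the exact published barcode/tracer sequences is a
  non-goal; sets are regenerated under the stated constraints.
- No statistical contaminant removal (decontam-style modelling of negative
  controls) and no between-plate contamination model.
- Heterogeneity-spacer library layouts are not parsed.
- Technical-variance decomposition from ISD replicates (subtracting
  technical from among-replicate variance) is a future extension.
- The detectability figures for mixture schemes depend on the plate
  arrangement; only arrangements constructed by this package (or supplied
  by the user) are analysed.
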