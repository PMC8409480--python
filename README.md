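# amplitrace

Laboratory-informatics toolkit for high-throughput amplicon (metabarcoding)
studies of microbiomes: variable-length dual-index demultiplexing,
cross-contamination tracing with per-well spike-in oligos, and
internal-standard normalization of compositional count data — plus a
closed-loop simulator so every step can be validated against known ground
truth without sequencing anything.

## Who this is for

Labs running 96-well (or 384-well) plates of 16S/ITS amplicon libraries on
modern short-read sequencers, multiplexing hundreds to thousands of samples
per run, who need to (a) assign reads back to wells reliably, (b) know when
and where material migrated between wells, and (c) place relative-abundance
read counts on a scale proportional to absolute abundance.

## The methods

**Variable-length dual indexing.** Each sample is tagged inline with a
forward and a reverse molecular identifier (MID) of 8–10 nt placed directly
before the locus primer, so sample identity is the ordered MID pair: *n*
MIDs per side address *n*² samples (96 + 96 → 9,216). MIDs of equal length
are kept at Levenshtein distance ≥ 2, so a single sequencing error is
detectable and correctable during primer-anchored matching, and the length
variation itself injects the base diversity Illumina machines need at the
start of reads. Because the indexes ride inside the read, assignment is
immune to index hopping.

**Coligos (cross-contamination checking oligos).** A unique 13-nt
identifier bookended by the locus primer sequences is spiked into every
well. Identifiers are pairwise Levenshtein ≥ 3 apart, so any single
substitution, insertion or deletion is corrected unambiguously. After
sequencing, the 13 bases following the forward primer of each forward read
are matched to the tracer set; foreign tracers in a well quantify
contamination: per-well expected/foreign proportions, migration-distance
histograms (contamination typically decays with Euclidean well distance),
and a 180°-plate-rotation check. The comparator mixture design (k oligos
from a small panel, e.g. 3 of 12 → 220 mixtures) is implemented too, with
an exhaustive donor-identifiability analysis.

**Internal-standard (ISD) normalization.** Sequencer output is
compositional; adding a fixed quantity of a reference molecule to every
replicate lets each taxon's relative abundance x_i be rescaled as

    y_i = x_i / x_ISD

which is depth-invariant and subcompositionally coherent; multiplying by
the known spike amount estimates absolute abundance in the spike's unit.
Features splintered into several sequence variants of the ISD by denoising
are summed before the ratio is taken. Copy-number variation still forbids
between-taxon comparisons; only within-taxon, across-sample contrasts are
supported.

## Worked example

```python
import tempfile
from amplitrace import sim, demux, contamination as cont, isd
from amplitrace.io import read_fastq_paired

cfg = sim.SimConfig(seed=7, n_taxa=8, reads_per_well_mean=300,
                    contamination_rate=0.3)
plate = sim.simulate_plate(cfg)
d = tempfile.mkdtemp()
truth = sim.simulate_reads(plate, f"{d}/r1.fastq", f"{d}/r2.fastq")

config = demux.DemuxConfig(mid_set=plate.mid_set,
                           primers={"16S": (cfg.fwd_primer, cfg.rev_primer)},
                           layout=plate.layout)
result = demux.demultiplex_run(
    read_fastq_paired(f"{d}/r1.fastq", f"{d}/r2.fastq"),
    config, out_dir=f"{d}/demux")
print(f"assigned {result.n_assigned} of {result.n_input} read pairs")

counts = sim.sample_coligo_counts(plate, coligo_reads_per_well=1400)
matrix = cont.ColigoCountMatrix(counts=counts, total_reads=counts.sum(axis=1))
report = cont.contamination_report(matrix, plate.layout)
s = report.summary
print(f"wells with any foreign coligo: {s['frac_wells_with_any_foreign']:.1%}")
print(f"out-of-place coligo reads:     {s['overall_out_of_place_proportion']:.2%}")
profile = cont.contamination_distance_profile(matrix, plate.layout)
print(f"migration events by distance:  {dict(sorted(profile.items()))}")

df = sim.dilution_series(cfg, [0.4 * 10 ** k for k in range(6)])
res = isd.isd_dilution_check(df["isd_proportion"], df["amount"])
print(f"dilution slope: {res['slope']:.3f}, monotone: {res['monotone']}")
```

Output:

```
assigned 28783 of 28783 read pairs
wells with any foreign coligo: 28.1%
out-of-place coligo reads:     0.67%
migration events by distance:  {1: 6, 2: 6, 3: 3, 4: 7, 5: 3, 8: 2, 9: 4}
dilution slope: 0.989, monotone: True
```

Every read pair of the error-free simulated plate returns to its source
well. With contamination injected at 0.3 events per well, 28% of wells show
at least one foreign tracer but only 0.67% of tracer reads are out of
place — severe contamination is rare even when minor contamination is
common, which is exactly the situation per-well tracers exist to
distinguish. The dilution slope near 1 on the log-odds scale confirms the
spike-in behaves quantitatively: doubling the spike doubles its read odds.

## Command line

```
amplitrace design-mids     --n-per-length 8:32,9:32,10:32 --seed 1 --out mids/
amplitrace design-coligos  --n 96 --seed 1 --out coligos/
amplitrace simulate        --config sim.yaml --out simout/
amplitrace demux           --r1 R1.fastq.gz --r2 R2.fastq.gz \
                           --sample-sheet layout.tsv --mids mids.tsv --out demuxout/
amplitrace coligo-report   --counts coligo_counts.tsv --layout layout.tsv --out report/
amplitrace isd-normalize   --table features.tsv --isd-fasta isd.fasta --out norm/
```

Each run writes a `manifest.json` (version, resolved options, input
digests, seed) into its output directory.

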