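"""Closed-loop simulator for dual-indexed amplicon plates.

Generates a plate layout with MIDs, tracer coligos, an internal standard
and a background community; mixes per-well molecule pools with seeded
contamination events; and emits paired FASTQ reads of the form
``MID + primer + template`` alongside a truth table, so the demultiplexer,
contamination analytics and ISD normalization can all be tested end to end
against known ground truth.

The contamination model is a phenomenological stand-in, not an empirical
one: each well receives a Poisson number of events whose donor is drawn
with probability proportional to ``(1 - eps) * exp(-d / lambda) + eps``
over the other wells (near wells dominate, but remote donors keep a uniform
floor), and each event moves a Beta-distributed fraction of the donor's
native pool into the recipient.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .barcodes import (
    Coligo,
    MIDSet,
    build_coligo,
    generate_coligo_identifiers,
    generate_mid_set,
    reverse_complement,
)
from .plate import PlateLayout, Well, WellAssignment, well_distance

__all__ = [
    "SimConfig",
    "SimulatedPlate",
    "ContaminationEvent",
    "simulate_plate",
    "simulate_reads",
    "sample_coligo_counts",
    "dilution_series",
]

# 515F / 806R, the 16S primer pair carried by the tracer oligos
DEFAULT_FWD_PRIMER = "GTGYCAGCMGCCGCGGTAA"
DEFAULT_REV_PRIMER = "GGACTACNVGGGTWTCTAAT"

ADAPTER_STUB = "AGATCGGAAGAGC"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated plate.

    Spike fractions are molecule fractions of each well's pool.  The
    defaults put realized tracer/ISD read fractions near the top of the
    band observed in real libraries (~1% of reads), which keeps per-well
    tracer counts informative at desk-scale depth.
    """

    seed: int
    n_rows: int = 8
    n_cols: int = 12
    n_taxa: int = 20
    taxon_length: int = 230
    taxon_log_mean: float = 0.0
    taxon_log_sd: float = 1.0
    isd_length: int = 170
    isd_fraction: float = 0.005
    coligo_fraction: float = 0.01
    contamination_rate: float = 0.0       # expected events per well (Poisson)
    kernel_lambda: float = 1.5            # e-folding distance of the donor kernel
    kernel_uniform_eps: float = 0.05      # uniform floor mixed into the kernel
    migration_beta: tuple[float, float] = (1.0, 50.0)
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    reads_per_well_mean: float = 1000.0
    reads_per_well_dispersion: float = 10.0  # NB shape; larger = closer to Poisson
    read_length: int = 150
    quality_char: str = "I"
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER

    def __post_init__(self) -> None:
        for name in ("isd_fraction", "coligo_fraction", "sub_rate", "indel_rate",
                     "kernel_uniform_eps"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.isd_fraction + self.coligo_fraction > 1:
            raise ValueError("isd_fraction + coligo_fraction exceed 1")


@dataclass(frozen=True)
class ContaminationEvent:
    donor: str
    recipient: str
    migration_fraction: float


@dataclass
class SimulatedPlate:
    """A plate with reagents, per-well molecule pools, and injected events."""

    config: SimConfig
    layout: PlateLayout
    mid_set: MIDSet
    coligos: list[Coligo]
    isd_sequence: str
    taxon_sequences: dict[str, str]
    pools: dict[str, dict[str, float]]     # well -> template name -> weight
    events: list[ContaminationEvent]
    # template name -> amplicon sequence (primers included)
    amplicons: dict[str, str] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


_IUPAC_CHOICES = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _resolve_iupac(seq: str, rng: np.random.Generator) -> str:
    """Fix each degenerate position to one concrete base (synthesized oligos
    are mixtures; any one molecule carries a single base per position)."""
    return "".join(
        base if base in "ACGT" else _IUPAC_CHOICES[base][int(rng.integers(0, len(_IUPAC_CHOICES[base])))]
        for base in seq
    )


def _donor_weights(recipient: Well, wells: list[Well], cfg: SimConfig) -> np.ndarray:
    w = np.array([
        (1.0 - cfg.kernel_uniform_eps)
        * math.exp(-well_distance(recipient, other) / cfg.kernel_lambda)
        + cfg.kernel_uniform_eps
        for other in wells
    ])
    return w / w.sum()


def simulate_plate(config: SimConfig) -> SimulatedPlate:
    """Build the plate: reagents, layout, native pools, contamination events.

    Each well's pool mixes its taxa (log-normal abundances), its single
    assigned coligo at ``coligo_fraction`` and the ISD at ``isd_fraction``
    (expected molecule fractions).  Contamination events then move a
    Beta-distributed fraction of each donor's *native* pool into the
    recipient, so chained events cannot compound.  Deterministic given the
    seed.
    """
    rng = np.random.default_rng(config.seed)
    n_wells = config.n_rows * config.n_cols

    n8 = n_wells // 3
    n9 = n_wells // 3
    n10 = n_wells - n8 - n9
    mid_set = generate_mid_set({8: n8, 9: n9, 10: n10},
                               seed=int(rng.integers(0, 2**31 - 1)))
    identifiers = generate_coligo_identifiers(
        n_wells, seed=int(rng.integers(0, 2**31 - 1)))
    coligos = [build_coligo(i, config.fwd_primer, config.rev_primer)
               for i in identifiers]

    taxon_sequences = {
        f"taxon{k + 1:02d}": _random_dna(rng, config.taxon_length)
        for k in range(config.n_taxa)
    }
    isd_sequence = _random_dna(rng, config.isd_length)

    assignments: dict[str, WellAssignment] = {}
    wells: list[Well] = []
    i = 0
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            w = Well(r, c, config.n_rows, config.n_cols)
            wells.append(w)
            assignments[w.label] = WellAssignment(
                sample_id=f"S{i + 1:03d}",
                fwd_mid_id=mid_set.forward[i].id,
                rev_mid_id=mid_set.reverse[i].id,
                expected_coligo_id=identifiers[i].id,
                isd_amount=1.0,
                role="sample",
            )
            i += 1
    layout = PlateLayout(n_rows=config.n_rows, n_cols=config.n_cols,
                         assignments=assignments)

    # native pools
    pools: dict[str, dict[str, float]] = {}
    for idx, w in enumerate(wells):
        abund = rng.lognormal(config.taxon_log_mean, config.taxon_log_sd,
                              size=config.n_taxa)
        bio_fraction = 1.0 - config.isd_fraction - config.coligo_fraction
        abund = abund / abund.sum() * bio_fraction
        pool = {name: float(a) for name, a in zip(taxon_sequences, abund)}
        pool[identifiers[idx].id] = config.coligo_fraction
        pool["ISD"] = config.isd_fraction
        pools[w.label] = pool

    native = {label: dict(pool) for label, pool in pools.items()}
    events: list[ContaminationEvent] = []
    if config.contamination_rate > 0:
        for w in wells:
            n_events = rng.poisson(config.contamination_rate)
            if n_events == 0:
                continue
            others = [o for o in wells if o.label != w.label]
            weights = _donor_weights(w, others, config)
            for _ in range(n_events):
                donor = others[rng.choice(len(others), p=weights)]
                frac = float(rng.beta(*config.migration_beta))
                events.append(ContaminationEvent(donor.label, w.label, frac))
                for name, weight in native[donor.label].items():
                    pools[w.label][name] = pools[w.label].get(name, 0.0) \
                        + frac * weight

    amplicons = {}
    for name, seq in taxon_sequences.items():
        amplicons[name] = _resolve_iupac(
            config.fwd_primer + seq + reverse_complement(config.rev_primer), rng)
    for ident, col in zip(identifiers, coligos):
        amplicons[ident.id] = _resolve_iupac(col.full_sequence, rng)
    amplicons["ISD"] = _resolve_iupac(
        config.fwd_primer + isd_sequence + reverse_complement(config.rev_primer),
        rng)

    return SimulatedPlate(
        config=config, layout=layout, mid_set=mid_set, coligos=coligos,
        isd_sequence=isd_sequence, taxon_sequences=taxon_sequences,
        pools=pools, events=events, amplicons=amplicons,
    )


def _apply_errors(seq: str, rng: np.random.Generator, sub_rate: float,
                  indel_rate: float) -> str:
    if sub_rate == 0 and indel_rate == 0:
        return seq
    out = []
    for base in seq:
        r = rng.random()
        if r < sub_rate:
            out.append("ACGT"[(("ACGT".index(base) if base in "ACGT" else 0)
                               + 1 + int(rng.integers(0, 3))) % 4])
        elif r < sub_rate + indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)
            out.append("ACGT"[int(rng.integers(0, 4))])  # insertion after
        else:
            out.append(base)
    return "".join(out)


def _build_read(mid: str, amplicon: str, read_length: int, forward: bool,
                rng: np.random.Generator) -> str:
    insert = amplicon if forward else reverse_complement(amplicon)
    read = mid + insert
    if len(read) < read_length:
        read += ADAPTER_STUB
    if len(read) < read_length:
        read += _random_dna(rng, read_length - len(read))
    return read[:read_length]


def simulate_reads(plate: SimulatedPlate, r1_path, r2_path) -> pd.DataFrame:
    """Sample paired reads from the pools and write FASTQ (.gz by extension).

    Per well the read count is negative-binomial; each read draws a
    template proportionally to the pool, builds
    ``R1 = fwd MID + amplicon`` and ``R2 = rev MID + rc(amplicon)``, pads
    short inserts with an adapter stub then random bases (read-through),
    applies per-base errors, and records a truth row.  Returns the truth
    table (read_id, well, sample_id, template).  Deterministic given the
    plate (which carries the seed).
    """
    cfg = plate.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    mids = plate.mid_set.by_id()
    max_prefix = max(len(m.sequence) for m in mids.values()) \
        + max(len(cfg.fwd_primer), len(cfg.rev_primer))
    if cfg.read_length < max_prefix:
        raise ValueError(
            f"read_length {cfg.read_length} shorter than the longest "
            f"MID+primer prefix ({max_prefix})"
        )

    def opener(path):
        return gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")

    truth_rows = []
    shape = cfg.reads_per_well_dispersion
    read_no = 0
    with opener(r1_path) as f1, opener(r2_path) as f2:
        for label in plate.pools:
            a = plate.layout.assignments[label]
            fwd_mid = mids[a.fwd_mid_id].sequence
            rev_mid = mids[a.rev_mid_id].sequence
            # gamma-Poisson mixture = negative binomial
            lam = rng.gamma(shape, cfg.reads_per_well_mean / shape)
            n_reads = int(rng.poisson(lam))
            names = list(plate.pools[label])
            weights = np.array([plate.pools[label][n] for n in names])
            weights = weights / weights.sum()
            draws = rng.choice(len(names), size=n_reads, p=weights)
            for d in draws:
                template = names[d]
                amplicon = plate.amplicons[template]
                read_no += 1
                rid = f"sim_{read_no:07d}"
                r1 = _build_read(fwd_mid, amplicon, cfg.read_length, True, rng)
                r2 = _build_read(rev_mid, amplicon, cfg.read_length, False, rng)
                r1 = _apply_errors(r1, rng, cfg.sub_rate, cfg.indel_rate)
                r2 = _apply_errors(r2, rng, cfg.sub_rate, cfg.indel_rate)
                q1 = cfg.quality_char * len(r1)
                q2 = cfg.quality_char * len(r2)
                f1.write(f"@{rid}\n{r1}\n+\n{q1}\n")
                f2.write(f"@{rid}\n{r2}\n+\n{q2}\n")
                truth_rows.append({
                    "read_id": rid, "well": label, "sample_id": a.sample_id,
                    "template": template,
                })
    return pd.DataFrame(truth_rows,
                        columns=["read_id", "well", "sample_id", "template"])


def sample_coligo_counts(plate: SimulatedPlate,
                         coligo_reads_per_well: int = 100) -> pd.DataFrame:
    """Sample the wells x coligos count matrix directly from the pools.

    Shortcut for contamination analytics at scale: draws
    ``coligo_reads_per_well`` tracer reads per well multinomially from the
    coligo components of the pool, skipping read construction entirely.
    Deterministic given the plate's seed.
    """
    cfg = plate.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    coligo_ids = [c.identifier.id for c in plate.coligos]
    counts = pd.DataFrame(0, index=list(plate.pools), columns=coligo_ids,
                          dtype=int)
    for label, pool in plate.pools.items():
        weights = np.array([pool.get(cid, 0.0) for cid in coligo_ids])
        total = weights.sum()
        if total == 0:
            continue
        counts.loc[label] = rng.multinomial(coligo_reads_per_well,
                                            weights / total)
    return counts


def dilution_series(
    config: SimConfig,
    amounts: Sequence[float],
    reads_per_level: int = 50_000,
    odds_per_unit: float = 0.01,
) -> pd.DataFrame:
    """Simulate one sample per spike amount against a fixed background.

    The ISD:background molecule odds are proportional to the spike amount
    (``odds = odds_per_unit * amount``), the exact behavior of adding more
    of one molecule to a fixed background, so the expected slope of
    log-odds(ISD read fraction) on log10(amount) is 1.  Returns a frame
    with columns amount, isd_reads, total_reads, isd_proportion, suitable
    for :func:`amplitrace.isd.isd_dilution_check`.
    """
    amounts = list(amounts)
    if len(amounts) < 2:
        raise ValueError("need at least 2 spike amounts")
    if any(a <= 0 for a in amounts):
        raise ValueError("spike amounts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    rows = []
    for amount in amounts:
        odds = odds_per_unit * amount
        p_isd = odds / (1.0 + odds)
        isd_reads = int(rng.binomial(reads_per_level, p_isd))
        rows.append({
            "amount": amount,
            "isd_reads": isd_reads,
            "total_reads": reads_per_level,
            "isd_proportion": isd_reads / reads_per_level,
        })
    return pd.DataFrame(rows)
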