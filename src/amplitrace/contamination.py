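"""Cross-contamination analytics from per-well tracer-oligo counts.

Every well of a plate receives one known 13-nt tracer ("coligo").  After
sequencing and demultiplexing, the 13 bases following the forward primer of
each forward read are matched against the tracer set; reads carrying a
tracer that does not belong to their well are direct evidence that material
migrated between wells.  This module builds the wells x coligos count
matrix, summarizes contamination per well and per plate, profiles migration
distance, and checks for an inadvertently rotated plate.

Only forward reads are used for tracer detection: the tracer inserts are
too short for reliable read merging (mates "stagger"), so the forward read
alone carries the identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .barcodes import ColigoIdentifier, levenshtein
from .plate import PlateLayout, rotate_layout, well_distance

__all__ = [
    "ColigoCountMatrix",
    "ContaminationReport",
    "extract_coligo_id",
    "count_coligos",
    "contamination_report",
    "contamination_distance_profile",
    "detect_plate_rotation",
    "spikein_fraction_summary",
]


def extract_coligo_id(
    seq: str,
    identifiers: Sequence[ColigoIdentifier],
    id_length: int = 13,
    max_edits: int = 1,
) -> str | None:
    """Identify the tracer at the 5' end of a primer-trimmed forward read.

    The first ``id_length`` bases are compared to every identifier; an exact
    match wins immediately.  Otherwise the window flexes by one base
    (id_length - 1 .. id_length + 1) to absorb an indel, and the unique
    identifier within ``max_edits`` Levenshtein edits is returned.  Ties or
    no match within tolerance return ``None``.
    """
    seq = seq.upper()
    if len(seq) < id_length - 1:
        return None
    window = seq[:id_length]
    for ident in identifiers:
        if ident.sequence == window:
            return ident.id
    if max_edits <= 0:
        return None
    best_id = None
    best_d = max_edits + 1
    tie = False
    for ident in identifiers:
        d = min(
            levenshtein(seq[:L], ident.sequence)
            for L in (id_length - 1, id_length, id_length + 1)
            if L <= len(seq)
        )
        if d < best_d:
            best_id, best_d, tie = ident.id, d, False
        elif d == best_d:
            tie = True
    if best_d <= max_edits and not tie:
        return best_id
    return None


@dataclass
class ColigoCountMatrix:
    """Wells x coligos read counts plus per-well total read depth.

    ``counts`` is a DataFrame indexed by well label with one column per
    coligo id; ``total_reads`` is the per-well count of *all* reads (tracer
    and biological), used to report what fraction of a well's reads the
    tracers consumed.
    """

    counts: pd.DataFrame
    total_reads: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("coligo counts must be nonnegative")
        self.total_reads = self.total_reads.reindex(self.counts.index).fillna(0)
        short = self.counts.sum(axis=1) > self.total_reads
        if short.any():
            raise ValueError(
                f"wells with more coligo reads than total reads: "
                f"{list(self.counts.index[short])}"
            )

    @property
    def wells(self) -> list[str]:
        return list(self.counts.index)

    @property
    def coligo_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "total_reads", self.total_reads)
        out.to_csv(path, sep="\t", index_label="well")

    @classmethod
    def from_tsv(cls, path) -> "ColigoCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="well")
        totals = df.pop("total_reads")
        return cls(counts=df, total_reads=totals)


def count_coligos(
    reads_per_well: Mapping[str, Iterable[str]],
    identifiers: Sequence[ColigoIdentifier],
    layout: PlateLayout,
    total_reads_per_well: Mapping[str, int] | None = None,
    id_length: int = 13,
    max_edits: int = 1,
) -> ColigoCountMatrix:
    """Match trimmed forward reads to tracers and tabulate counts per well.

    ``reads_per_well`` maps well labels to primer-trimmed forward-read
    sequences; reads matching no identifier are ignored.  When
    ``total_reads_per_well`` is omitted, the number of supplied reads per
    well is used as the depth.
    """
    unknown = [w for w in reads_per_well if w not in layout.assignments]
    if unknown:
        raise ValueError(f"wells absent from layout: {sorted(unknown)}")
    coligo_ids = [i.id for i in identifiers]
    wells = [w.label for w in layout.wells() if w.label in layout.assignments]
    counts = pd.DataFrame(0, index=wells, columns=coligo_ids, dtype=int)
    totals = pd.Series(0, index=wells, dtype=int)
    for well, reads in reads_per_well.items():
        n = 0
        for seq in reads:
            n += 1
            hit = extract_coligo_id(seq, identifiers, id_length=id_length,
                                    max_edits=max_edits)
            if hit is not None:
                counts.at[well, hit] += 1
        totals[well] = n
    if total_reads_per_well is not None:
        for well, n in total_reads_per_well.items():
            totals[well] = n
    return ColigoCountMatrix(counts=counts, total_reads=totals)


@dataclass
class ContaminationReport:
    per_well: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "per_well": self.per_well.reset_index()
                            .rename(columns={"index": "well"})
                            .to_dict(orient="records"),
            "summary": self.summary,
        }


def contamination_report(
    matrix: ColigoCountMatrix,
    layout: PlateLayout,
    min_foreign_reads: int = 1,
) -> ContaminationReport:
    """Per-well and plate-level cross-contamination metrics.

    For each well: reads of its own expected tracer, foreign tracer reads,
    the proportion of its tracer reads that are the expected one, the number
    of distinct foreign tracers at or above ``min_foreign_reads``, and the
    fraction of all its reads that are tracers.  Wells with zero tracer
    reads have undefined proportions (NaN) and are excluded from medians
    but tallied separately.

    Summary: fraction of wells with any/multiple foreign tracers, the
    median foreign proportion, and the overall fraction of tracer reads
    that were out of place.
    """
    expected_ids = {}
    for label in matrix.wells:
        a = layout.assignments.get(label)
        if a is None or not a.expected_coligo_id:
            raise ValueError(f"well {label} has no expected coligo in the layout")
        expected_ids[label] = a.expected_coligo_id

    rows = []
    for well in matrix.wells:
        row = matrix.counts.loc[well]
        total = int(row.sum())
        exp_id = expected_ids[well]
        expected = int(row.get(exp_id, 0))
        foreign = total - expected
        foreign_counts = row.drop(labels=[exp_id], errors="ignore")
        n_distinct = int((foreign_counts >= min_foreign_reads).sum())
        depth = int(matrix.total_reads[well])
        rows.append({
            "well": well,
            "expected_coligo_reads": expected,
            "foreign_coligo_reads": foreign,
            "proportion_expected": expected / total if total > 0 else np.nan,
            "n_distinct_foreign": n_distinct,
            "coligo_fraction_of_reads": total / depth if depth > 0 else np.nan,
            "contaminated": foreign >= min_foreign_reads,
        })
    per_well = pd.DataFrame(rows).set_index("well")

    observed = per_well["proportion_expected"].notna()
    n_obs = int(observed.sum())
    foreign_prop = 1.0 - per_well.loc[observed, "proportion_expected"]
    total_coligo = int(per_well["expected_coligo_reads"].sum()
                       + per_well["foreign_coligo_reads"].sum())
    total_foreign = int(per_well["foreign_coligo_reads"].sum())
    n_wells = len(per_well)
    summary = {
        "n_wells": n_wells,
        "n_wells_no_coligo": n_wells - n_obs,
        "frac_wells_with_any_foreign":
            float(per_well["contaminated"].mean()) if n_wells else np.nan,
        "frac_wells_with_multiple_foreign":
            float((per_well["n_distinct_foreign"] >= 2).mean()) if n_wells else np.nan,
        "median_foreign_proportion":
            float(foreign_prop.median()) if n_obs else np.nan,
        "overall_out_of_place_proportion":
            total_foreign / total_coligo if total_coligo else np.nan,
    }
    return ContaminationReport(per_well=per_well, summary=summary)


def contamination_distance_profile(
    matrix: ColigoCountMatrix,
    layout: PlateLayout,
    min_foreign_reads: int = 1,
    rounded: bool = True,
) -> dict:
    """Histogram of migration distances: distance bin -> number of events.

    Every (recipient well, foreign tracer) pair with at least
    ``min_foreign_reads`` reads is one event, binned at the Euclidean
    distance between the tracer's home well and the recipient (rounded to
    the nearest integer by default).  A well holding several foreign
    tracers contributes several events.  Foreign tracers with no home well
    on the layout fall in the ``"external"`` bin.
    """
    homes = layout.coligo_home_wells()
    hist: dict = {}
    for well in matrix.wells:
        exp_id = layout.assignments[well].expected_coligo_id
        row = matrix.counts.loc[well]
        for coligo_id, n in row.items():
            if coligo_id == exp_id or n < min_foreign_reads:
                continue
            home = homes.get(coligo_id)
            if home is None:
                key = "external"
            else:
                d = well_distance(layout.well(home), layout.well(well),
                                  rounded=rounded)
                key = int(d) if rounded else d
            hist[key] = hist.get(key, 0) + 1
    return hist


def detect_plate_rotation(matrix: ColigoCountMatrix, layout: PlateLayout) -> dict:
    """Check whether tracer counts fit the layout better after 180-degree rotation.

    ``score_0`` (resp. ``score_180``) is the fraction of all tracer reads
    that match the expected tracer of their well under the supplied
    (resp. rotated) layout.  The plate is flagged as rotated when the
    rotated layout explains strictly more reads; an exact tie keeps the 0
    degree orientation with a warning.
    """
    total = int(matrix.counts.to_numpy().sum())
    if total == 0:
        raise ValueError("rotation undeterminable: zero coligo reads")

    def score(lay: PlateLayout) -> float:
        s = 0
        for well in matrix.wells:
            a = lay.assignments.get(well)
            if a is None or not a.expected_coligo_id:
                continue
            s += int(matrix.counts.loc[well].get(a.expected_coligo_id, 0))
        return s / total

    score_0 = score(layout)
    score_180 = score(rotate_layout(layout))
    flagged = score_180 > score_0
    return {
        "orientation": 180 if flagged else 0,
        "score_0": score_0,
        "score_180": score_180,
        "flagged": flagged,
        "warning": "tie between orientations" if score_0 == score_180 else "",
    }


def spikein_fraction_summary(
    counts: pd.DataFrame,
    coligo_ids: Sequence[str],
    isd_id: str,
    n_bins: int = 20,
) -> dict:
    """Per-sample fractions of reads that are tracers or internal standard.

    ``counts`` is a samples x features table.  Returns per-sample coligo
    and ISD read fractions plus frequency-histogram bins on a log10 axis
    (zero fractions excluded from the histogram, reported as a count).
    """
    totals = counts.sum(axis=1)
    coligo_cols = [c for c in coligo_ids if c in counts.columns]
    coligo_frac = counts[coligo_cols].sum(axis=1) / totals if coligo_cols \
        else pd.Series(0.0, index=counts.index)
    isd_frac = counts[isd_id] / totals if isd_id in counts.columns \
        else pd.Series(0.0, index=counts.index)

    def hist(frac: pd.Series) -> dict:
        nz = frac[frac > 0]
        if nz.empty:
            return {"bin_edges_log10": [], "counts": [], "n_zero": int(len(frac))}
        vals = np.log10(nz.to_numpy())
        counts_, edges = np.histogram(vals, bins=n_bins)
        return {"bin_edges_log10": edges.tolist(), "counts": counts_.tolist(),
                "n_zero": int((frac == 0).sum())}

    return {
        "coligo_fraction": coligo_frac,
        "isd_fraction": isd_frac,
        "coligo_histogram": hist(coligo_frac),
        "isd_histogram": hist(isd_frac),
    }
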