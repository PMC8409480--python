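"""Internal-standard (spike-in) normalization of compositional count tables.

Sequencers emit a fixed read budget per sample, so raw counts carry only
relative-abundance information.  When a known quantity of a reference
molecule (the internal standard, ISD) is added to every replicate before
library prep, dividing each taxon's relative abundance x_i by the ISD's
relative abundance x_ISD places all samples on a common, abundance-
proportional scale:

    y_i = x_i / x_ISD

The ratio is identical whether raw counts or proportions are used, and is
unchanged by adding or removing other taxa from the table (subcompositional
coherence).  Multiplying y_i by the absolute amount of ISD spiked into the
sample yields an absolute-abundance estimate in the spike's own unit.
Denoising typically splinters the ISD into several sequence variants, so
all features aligning to the ISD reference are summed before the ratio is
taken.

Between-taxon comparisons remain invalid after this normalization: marker-
gene copy number varies across taxa, so only within-taxon, across-sample
contrasts are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .barcodes import levenshtein

__all__ = [
    "FeatureTable",
    "RatioTable",
    "SpikeDesign",
    "match_isd_esvs",
    "collapse_isd",
    "isd_normalize",
    "absolute_abundance",
    "isd_dilution_check",
]

ISD_FEATURE = "ISD"


@dataclass
class FeatureTable:
    """Samples x features count table with feature annotations.

    ``counts``: DataFrame, samples as rows, features as columns, counts >= 0.
    ``feature_meta``: optional DataFrame indexed by feature id with columns
    ``sequence`` (str) and ``role`` in {"taxon", "isd", "coligo"}.
    """

    counts: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("feature counts must be nonnegative")
        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(
                {"sequence": "", "role": "taxon"}, index=self.counts.columns
            )

    def features_with_role(self, role: str) -> list[str]:
        return list(self.feature_meta.index[self.feature_meta["role"] == role])

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        """Read a TSV table; orientation auto-detected by the index header.

        An index column named ``feature``/``feature_id``/``#OTU ID`` marks a
        features x samples table, which is transposed on read; anything else
        (e.g. ``sample``) is taken as samples x features.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        if str(df.index.name).lower() in {"feature", "feature_id", "#otu id", "otu"}:
            df = df.T
        return cls(counts=df)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")


@dataclass
class RatioTable:
    """Per-sample taxon/ISD ratios with a validity flag per sample."""

    ratios: pd.DataFrame
    status: pd.Series  # "ok" | "no_isd"

    def to_tsv(self, path) -> None:
        out = self.ratios.copy()
        out.insert(0, "status", self.status)
        out.to_csv(path, sep="\t", index_label="sample")


@dataclass
class SpikeDesign:
    """Absolute ISD amount added to each sample, with its unit."""

    amounts: pd.Series
    unit: str = "copies"
    isd_sequence: str = ""

    def __post_init__(self) -> None:
        if (self.amounts < 0).any():
            raise ValueError("spike amounts must be nonnegative")


def _global_identity(a: str, b: str) -> float:
    """Identity of a unit-cost global alignment: 1 - edits/max(len)."""
    if not a or not b:
        return 0.0
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def match_isd_esvs(
    feature_sequences: Mapping[str, str],
    isd_sequence: str,
    min_identity: float = 0.95,
    min_coverage: float = 0.9,
) -> set[str]:
    """Find features whose sequence aligns to the ISD reference.

    A feature matches when its global-alignment identity to the reference is
    at least ``min_identity`` and its length covers at least
    ``min_coverage`` of the reference.  Denoisers commonly emit several
    variants of the spiked molecule; all of them should be summed before
    normalization.
    """
    if not isd_sequence:
        raise ValueError("ISD reference sequence must be nonempty")
    isd = isd_sequence.upper()
    matched = set()
    for fid, seq in feature_sequences.items():
        s = (seq or "").upper()
        if not s:
            continue
        coverage = min(len(s), len(isd)) / len(isd)
        if coverage < min_coverage:
            continue
        if _global_identity(s, isd) >= min_identity:
            matched.add(fid)
    return matched


def collapse_isd(
    table: FeatureTable,
    isd_feature_ids: Sequence[str],
    isd_feature: str = ISD_FEATURE,
) -> FeatureTable:
    """Sum all ISD-matching features into a single ISD feature.

    Per-sample totals are conserved.  An empty id set yields a zero-count
    ISD feature and a warning (those samples will be flagged ``no_isd``
    downstream).
    """
    ids = [i for i in isd_feature_ids if i in table.counts.columns]
    missing = set(isd_feature_ids) - set(ids)
    if missing:
        raise ValueError(f"ISD feature ids not in table: {sorted(missing)}")
    if not ids:
        warnings.warn("no ISD features matched; ISD counts set to zero")
        isd_counts = pd.Series(0, index=table.counts.index)
    else:
        isd_counts = table.counts[ids].sum(axis=1)
    counts = table.counts.drop(columns=ids)
    counts[isd_feature] = isd_counts
    meta = table.feature_meta.drop(index=ids, errors="ignore").copy()
    meta.loc[isd_feature] = {"sequence": "", "role": "isd"}
    return FeatureTable(counts=counts, feature_meta=meta)


def isd_normalize(table: FeatureTable, isd_feature: str = ISD_FEATURE) -> RatioTable:
    """Divide each biological feature by the ISD count, sample by sample.

    Equivalent to dividing relative abundances (the per-sample total cancels),
    so the result is invariant to sequencing depth.  Tracer (coligo) features
    are excluded from the output: their read counts vary too much technically
    to serve as standards, and they are not biology.  Samples with zero ISD
    counts are flagged ``no_isd`` with NaN ratios.
    """
    if isd_feature not in table.counts.columns:
        raise ValueError(f"table has no ISD feature {isd_feature!r}")
    isd = table.counts[isd_feature].astype(float)
    drop = [isd_feature] + table.features_with_role("coligo")
    biological = table.counts.drop(columns=[c for c in drop
                                            if c in table.counts.columns])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = biological.div(isd.replace(0, np.nan), axis=0)
    status = pd.Series(np.where(isd > 0, "ok", "no_isd"), index=table.counts.index)
    return RatioTable(ratios=ratios, status=status)


def absolute_abundance(ratios: RatioTable, design: SpikeDesign) -> pd.DataFrame:
    """Scale ISD ratios by the known per-sample spike amount.

    estimate_i = y_i * isd_amount(sample), in the design's unit.  Samples
    flagged ``no_isd`` stay NaN.  Raises if the design is missing samples.
    """
    missing = [s for s in ratios.ratios.index if s not in design.amounts.index]
    if missing:
        raise ValueError(f"spike design missing samples: {missing}")
    amounts = design.amounts.reindex(ratios.ratios.index).astype(float)
    if (amounts == 0).any():
        warnings.warn("spike amount 0 for some samples; estimates degenerate to 0")
    return ratios.ratios.mul(amounts, axis=0)


def isd_dilution_check(
    isd_proportions: Sequence[float],
    spike_amounts: Sequence[float],
) -> dict:
    """Verify quantitative spike-in behavior over a dilution series.

    ``isd_proportions``: per-level fraction of reads assigned to the ISD;
    ``spike_amounts``: the amount spiked at each level.  Fits least squares
    of log10(p / (1 - p)) on log10(amount).  The log-odds transform keeps
    the expected slope at exactly 1 over the whole range: proportions
    saturate near 1 at high spike levels, odds do not.  Levels with zero
    ISD reads are excluded and reported.  Returns slope, intercept, r-value,
    the excluded levels, and whether proportions increase strictly
    monotonically with amount.
    """
    p = np.asarray(isd_proportions, dtype=float)
    a = np.asarray(spike_amounts, dtype=float)
    if p.shape != a.shape:
        raise ValueError("proportions and amounts must have equal length")
    if len(p) < 3:
        raise ValueError("need at least 3 dilution levels")
    if (a <= 0).any():
        raise ValueError("spike amounts must be positive")
    if np.log10(a.max() / a.min()) <= 1:
        raise ValueError("dilution series must span more than one order of magnitude")

    order = np.argsort(a)
    monotone = bool(np.all(np.diff(p[order]) > 0))

    keep = p > 0
    excluded = [float(x) for x in a[~keep]]
    if keep.sum() < 3:
        raise ValueError("fewer than 3 levels with nonzero ISD reads")
    pk, ak = p[keep], a[keep]
    if (pk >= 1).any():
        raise ValueError("ISD proportion of 1 leaves no biological reads to normalize")
    fit = stats.linregress(np.log10(ak), np.log10(pk / (1 - pk)))
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "rvalue": float(fit.rvalue),
        "monotone": monotone,
        "excluded_amounts": excluded,
    }
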