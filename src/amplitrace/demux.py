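"""Primer-anchored demultiplexing of variable-length dual-indexed reads.

Read structure on both mates is ``MID + locus primer + template``.  The MID
lengths vary (8-10 nt by default), so matching tries the longest MID length
first: for each candidate length L the first L bases are compared against
the MIDs of that length (Levenshtein, up to ``max_mid_edits``) and the next
``len(primer)`` bases against the locus primer (substitutions only, IUPAC
degeneracy honored).  A read is assigned only when a unique best candidate
exists; the sample is then the (forward MID, reverse MID) pair looked up in
the plate layout.

Because same-length MIDs are >= 2 edits apart and no MID is a prefix of a
longer one, one edit in the MID region can never silently move a read to a
different sample: it is either corrected back or the read is left
unassigned.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .barcodes import MIDSet, levenshtein
from .plate import PlateLayout

__all__ = [
    "ReadPair",
    "DemuxConfig",
    "Assignment",
    "DemuxResult",
    "match_prefix",
    "demultiplex_pair",
    "demultiplex_run",
    "iupac_mismatches",
]

# reason codes for unassigned reads
NO_MID = "no_mid"
AMBIGUOUS_MID = "ambiguous_mid"
NO_PRIMER = "no_primer"
LOCUS_CONFLICT = "locus_conflict"
UNKNOWN_PAIRING = "unknown_pairing"

_IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


class _PrimerMatcher:
    """Precompiled IUPAC primer for fast mismatch counting."""

    __slots__ = ("primer", "sets", "length")

    def __init__(self, primer: str):
        self.primer = primer.upper()
        self.sets = [_IUPAC_SETS[b] for b in self.primer]
        self.length = len(self.primer)

    def mismatches(self, region: str, cap: int) -> int:
        """Substitution count vs the primer; returns cap+1 early when exceeded."""
        if len(region) < self.length:
            return cap + 1
        mm = 0
        for base, allowed in zip(region, self.sets):
            if base not in allowed:
                mm += 1
                if mm > cap:
                    return mm
        return mm


def iupac_mismatches(primer: str, region: str) -> int:
    """Substitutions between a degenerate primer and an observed region."""
    m = _PrimerMatcher(primer)
    return m.mismatches(region.upper(), cap=m.length)


@dataclass
class DemuxConfig:
    mid_set: MIDSet
    primers: Mapping[str, tuple[str, str]]  # locus -> (fwd_primer, rev_primer)
    layout: PlateLayout
    max_mid_edits: int = 1
    max_primer_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.max_mid_edits >= self.mid_set.constraints.min_same_length_distance:
            raise ValueError(
                "max_mid_edits must be below the MID set's same-length distance "
                "floor, otherwise error correction is ambiguous"
            )
        self._fwd_index = _MIDIndex(self.mid_set.forward)
        self._rev_index = _MIDIndex(self.mid_set.reverse)
        self._primer_matchers = {
            locus: (_PrimerMatcher(f), _PrimerMatcher(r))
            for locus, (f, r) in self.primers.items()
        }
        self._pair_to_sample = self.layout.mid_pair_to_sample()


class _MIDIndex:
    """MIDs of one orientation indexed for longest-first prefix matching."""

    def __init__(self, mids):
        self.by_length: dict[int, list] = {}
        self.exact: dict[str, str] = {}
        for m in mids:
            self.by_length.setdefault(len(m.sequence), []).append(m)
            self.exact[m.sequence] = m.id
        self.lengths = sorted(self.by_length, reverse=True)


def match_prefix(seq: str, index: _MIDIndex, primer: _PrimerMatcher,
                 max_mid_edits: int, max_primer_mismatches: int):
    """Match the 5' end of one mate: (mid_id, consumed, corrected) or (None, reason, None).

    Tries MID lengths longest-first.  At each length the unique candidate
    minimizing (MID edit distance, primer mismatches) within the configured
    tolerances wins; a tie between candidates makes the read
    ``ambiguous_mid``.  ``consumed`` is the MID length plus primer length,
    i.e. the technical prefix to trim.  ``corrected`` is True when the MID
    needed error correction.
    """
    best = None  # (edits, primer_mm, mid_id, consumed)
    tie = False
    saw_mid = False
    for L in index.lengths:
        prefix = seq[:L]
        if len(prefix) < L:
            continue
        # fast path: exact MID; prefix rule guarantees uniqueness across lengths
        exact_id = index.exact.get(prefix)
        if exact_id is not None:
            mm = primer.mismatches(seq[L:L + primer.length], max_primer_mismatches)
            if mm <= max_primer_mismatches:
                return exact_id, L + primer.length, False
            saw_mid = True
            continue
        for m in index.by_length[L]:
            edits = levenshtein(prefix, m.sequence)
            if edits > max_mid_edits:
                continue
            saw_mid = True
            mm = primer.mismatches(seq[L:L + primer.length], max_primer_mismatches)
            if mm > max_primer_mismatches:
                continue
            key = (edits, mm)
            if best is None or key < (best[0], best[1]):
                best = (edits, mm, m.id, L + primer.length)
                tie = False
            elif key == (best[0], best[1]):
                tie = True
        if best is not None and not tie:
            return best[2], best[3], best[0] > 0
        if tie:
            return None, AMBIGUOUS_MID, None
    if saw_mid:
        return None, NO_PRIMER, None
    return None, NO_MID, None


@dataclass
class Assignment:
    read_id: str
    sample_id: str | None
    reason: str | None
    locus: str | None = None
    fwd_mid_id: str | None = None
    rev_mid_id: str | None = None
    trimmed: ReadPair | None = None
    fwd_corrected: bool = False
    rev_corrected: bool = False

    @property
    def assigned(self) -> bool:
        return self.sample_id is not None


def demultiplex_pair(pair: ReadPair, config: DemuxConfig) -> Assignment:
    """Assign one read pair to a sample, or return the failure reason.

    The forward MID+primer is matched on R1 and the reverse MID+primer on
    R2; both mates must agree on the locus.  Technical prefixes (MID and
    primer) are trimmed from both mates of an assigned pair, qualities
    trimmed identically.
    """
    r1 = pair.r1_seq.upper()
    r2 = pair.r2_seq.upper()
    fwd_hits: dict[str, tuple] = {}
    rev_hits: dict[str, tuple] = {}
    fwd_reasons: list[str] = []
    rev_reasons: list[str] = []
    for locus, (fwd_m, rev_m) in config._primer_matchers.items():
        f_id, f_info, f_corr = match_prefix(r1, config._fwd_index, fwd_m,
                                            config.max_mid_edits,
                                            config.max_primer_mismatches)
        if f_id is not None:
            fwd_hits[locus] = (f_id, f_info, f_corr)
        else:
            fwd_reasons.append(f_info)
        r_id, r_info, r_corr = match_prefix(r2, config._rev_index, rev_m,
                                            config.max_mid_edits,
                                            config.max_primer_mismatches)
        if r_id is not None:
            rev_hits[locus] = (r_id, r_info, r_corr)
        else:
            rev_reasons.append(r_info)

    common = set(fwd_hits) & set(rev_hits)
    if not common:
        if fwd_hits and rev_hits:
            return Assignment(pair.read_id, None, LOCUS_CONFLICT)
        # propagate the most informative single-mate reason
        reasons = (fwd_reasons if not fwd_hits else []) + (rev_reasons if not rev_hits else [])
        for code in (AMBIGUOUS_MID, NO_PRIMER, NO_MID):
            if code in reasons:
                return Assignment(pair.read_id, None, code)
        return Assignment(pair.read_id, None, NO_MID)
    if len(common) > 1:
        return Assignment(pair.read_id, None, LOCUS_CONFLICT)
    locus = common.pop()
    f_id, f_consumed, f_corr = fwd_hits[locus]
    r_id, r_consumed, r_corr = rev_hits[locus]
    sample = config._pair_to_sample.get((f_id, r_id))
    if sample is None:
        return Assignment(pair.read_id, None, UNKNOWN_PAIRING,
                          locus=locus, fwd_mid_id=f_id, rev_mid_id=r_id)
    trimmed = ReadPair(
        read_id=pair.read_id,
        r1_seq=pair.r1_seq[f_consumed:], r1_qual=pair.r1_qual[f_consumed:],
        r2_seq=pair.r2_seq[r_consumed:], r2_qual=pair.r2_qual[r_consumed:],
    )
    return Assignment(pair.read_id, sample, None, locus=locus,
                      fwd_mid_id=f_id, rev_mid_id=r_id, trimmed=trimmed,
                      fwd_corrected=f_corr, rev_corrected=r_corr)


@dataclass
class DemuxResult:
    n_input: int = 0
    per_sample: Counter = field(default_factory=Counter)   # (sample, locus) -> n
    unassigned: Counter = field(default_factory=Counter)   # reason -> n
    corrected_fwd: Counter = field(default_factory=Counter)
    corrected_rev: Counter = field(default_factory=Counter)

    @property
    def n_assigned(self) -> int:
        return sum(self.per_sample.values())

    @property
    def n_unassigned(self) -> int:
        return sum(self.unassigned.values())

    def stats_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "locus": l, "n_reads": n,
             "n_fwd_mid_corrected": self.corrected_fwd.get((s, l), 0),
             "n_rev_mid_corrected": self.corrected_rev.get((s, l), 0)}
            for (s, l), n in sorted(self.per_sample.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "locus", "n_reads",
                           "n_fwd_mid_corrected", "n_rev_mid_corrected"])

    def reasons_frame(self) -> pd.DataFrame:
        rows = [{"reason": r, "n_reads": n} for r, n in sorted(self.unassigned.items())]
        return pd.DataFrame(rows, columns=["reason", "n_reads"])


def demultiplex_run(pairs: Iterable[ReadPair], config: DemuxConfig,
                    out_dir: str | None = None) -> DemuxResult:
    """Demultiplex a stream of read pairs, optionally writing FASTQ output.

    With ``out_dir`` set, assigned pairs go to ``<sample>_R1.fastq`` /
    ``<sample>_R2.fastq`` (trimmed) and unassigned pairs to
    ``undetermined_R1/2.fastq`` untrimmed, with the reason code appended to
    the header.  Statistics TSVs are written alongside.  Read-count
    conservation (assigned + unassigned = input) always holds.
    """
    result = DemuxResult()
    writers: dict[str, tuple] = {}
    undet = None
    try:
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            undet = (open(os.path.join(out_dir, "undetermined_R1.fastq"), "w"),
                     open(os.path.join(out_dir, "undetermined_R2.fastq"), "w"))
        for pair in pairs:
            result.n_input += 1
            a = demultiplex_pair(pair, config)
            if a.assigned:
                key = (a.sample_id, a.locus)
                result.per_sample[key] += 1
                if a.fwd_corrected:
                    result.corrected_fwd[key] += 1
                if a.rev_corrected:
                    result.corrected_rev[key] += 1
                if out_dir is not None:
                    if a.sample_id not in writers:
                        writers[a.sample_id] = (
                            open(os.path.join(out_dir, f"{a.sample_id}_R1.fastq"), "w"),
                            open(os.path.join(out_dir, f"{a.sample_id}_R2.fastq"), "w"),
                        )
                    w1, w2 = writers[a.sample_id]
                    t = a.trimmed
                    w1.write(f"@{t.read_id}\n{t.r1_seq}\n+\n{t.r1_qual}\n")
                    w2.write(f"@{t.read_id}\n{t.r2_seq}\n+\n{t.r2_qual}\n")
            else:
                result.unassigned[a.reason] += 1
                if undet is not None:
                    u1, u2 = undet
                    u1.write(f"@{pair.read_id} reason={a.reason}\n"
                             f"{pair.r1_seq}\n+\n{pair.r1_qual}\n")
                    u2.write(f"@{pair.read_id} reason={a.reason}\n"
                             f"{pair.r2_seq}\n+\n{pair.r2_qual}\n")
    finally:
        for w1, w2 in writers.values():
            w1.close()
            w2.close()
        if undet is not None:
            undet[0].close()
            undet[1].close()
    if out_dir is not None:
        result.stats_frame().to_csv(os.path.join(out_dir, "demux_stats.tsv"),
                                    sep="\t", index=False)
        result.reasons_frame().to_csv(os.path.join(out_dir, "unassigned_reasons.tsv"),
                                      sep="\t", index=False)
    assert result.n_assigned + result.n_unassigned == result.n_input
    return result
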