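"""Design and validation of error-tolerant sample barcodes and tracer oligos.

Three families of short synthetic sequences are designed here:

* **MIDs** (molecular identifiers): 8-10 nt inline sample barcodes used as a
  dual index.  MIDs of equal length must be at least Levenshtein distance 2
  apart so a single sequencing error can be detected; variable lengths
  inject base diversity at the start of reads, which Illumina instruments
  need for cluster calling.
* **Coligo identifiers**: 13 nt sequences at pairwise Levenshtein distance
  >= 3, so any single substitution, insertion or deletion can be *corrected*
  (unique nearest neighbour within one edit).  One coligo is spiked into
  each well of a plate; foreign coligo reads reveal well-to-well
  cross-contamination.
* **Mixture schemes**: the comparator design in which k oligos from a small
  panel are combined per well (e.g. 3 of 12 gives C(12,3) = 220 distinct
  mixtures); :func:`mixture_detectability` quantifies how often a
  contamination event can be attributed to a unique donor.

Generation is seeded rejection sampling under composition constraints
(GC bounds, homopolymer cap) with an attempt budget.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq

__all__ = [
    "MID",
    "MIDSet",
    "MIDConstraints",
    "ColigoIdentifier",
    "Coligo",
    "MixtureScheme",
    "ValidationReport",
    "levenshtein",
    "reverse_complement",
    "gc_fraction",
    "max_homopolymer",
    "validate_mid_set",
    "generate_mid_set",
    "dual_index_capacity",
    "generate_coligo_identifiers",
    "validate_coligo_set",
    "build_coligo",
    "enumerate_mixtures",
    "assign_mixtures_to_plate",
    "mixture_detectability",
]

DNA_ALPHABET = "ACGT"
IUPAC_DNA = set("ACGTRYSWKMBDHVN")


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions, insertions, deletions)."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def reverse_complement(seq: str) -> str:
    """Reverse complement honoring IUPAC degeneracy codes."""
    bad = set(seq.upper()) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return str(Seq(seq.upper()).reverse_complement())


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run."""
    best = 0
    for _, group in itertools.groupby(seq.upper()):
        best = max(best, sum(1 for _ in group))
    return best


# ---------------------------------------------------------------------------
# MIDs


@dataclass(frozen=True)
class MID:
    id: str
    sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        bad = set(self.sequence.upper()) - set(DNA_ALPHABET)
        if bad:
            raise ValueError(f"MID {self.id}: non-ACGT characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MIDConstraints:
    """Composition and distance rules for a MID set.

    ``min_same_length_distance`` is the published rule (>= 2 so one error is
    detectable).  ``min_cross_length_distance`` is a generation-time safety
    margin: an insertion into a shorter MID must not land within one edit of
    a longer MID, or a single error could silently reassign a read; distance
    >= 3 between MIDs of different lengths rules that out.
    """

    min_same_length_distance: int = 2
    min_cross_length_distance: int = 3
    max_homopolymer: int = 3
    gc_bounds: tuple[float, float] = (0.4, 0.6)
    length_range: tuple[int, int] = (8, 10)


@dataclass
class MIDSet:
    forward: list[MID] = field(default_factory=list)
    reverse: list[MID] = field(default_factory=list)
    constraints: MIDConstraints = field(default_factory=MIDConstraints)

    def by_id(self) -> dict[str, MID]:
        out = {}
        for m in self.forward + self.reverse:
            out[m.id] = m
        return out

    def oriented(self, orientation: str) -> list[MID]:
        if orientation == "forward":
            return self.forward
        if orientation == "reverse":
            return self.reverse
        raise ValueError(orientation)


@dataclass
class Violation:
    check: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, check: str, message: str) -> None:
        self.violations.append(Violation(check, message))

    def __str__(self) -> str:
        if self.passed:
            return "OK"
        return "\n".join(f"[{v.check}] {v.message}" for v in self.violations)


def _validate_composition(report: ValidationReport, label: str, seq: str,
                          max_homopoly: int, gc_bounds: tuple[float, float]) -> None:
    if max_homopolymer(seq) > max_homopoly:
        report.add("homopolymer",
                   f"{label} ({seq}): homopolymer run {max_homopolymer(seq)} > {max_homopoly}")
    gc = gc_fraction(seq)
    if not (gc_bounds[0] <= gc <= gc_bounds[1]):
        report.add("gc_content",
                   f"{label} ({seq}): GC fraction {gc:.2f} outside {gc_bounds}")


def validate_mid_set(mid_set: MIDSet) -> ValidationReport:
    """Check every constraint a usable MID set must satisfy.

    Violations are collected, not raised: length range, unique ids,
    composition (homopolymer, GC), the same-length pairwise Levenshtein
    floor, and the cross-length prefix rule (no MID may be a prefix of a
    longer MID in the same orientation, which would make variable-length
    matching ambiguous).
    """
    report = ValidationReport()
    c = mid_set.constraints
    ids: dict[str, int] = {}
    for m in mid_set.forward + mid_set.reverse:
        ids[m.id] = ids.get(m.id, 0) + 1
    for mid_id, n in ids.items():
        if n > 1:
            report.add("unique_ids", f"id {mid_id!r} used {n} times")

    for orientation in ("forward", "reverse"):
        mids = mid_set.oriented(orientation)
        for m in mids:
            if not (c.length_range[0] <= len(m) <= c.length_range[1]):
                report.add("length", f"{m.id} ({m.sequence}): length {len(m)} "
                                     f"outside {c.length_range}")
            _validate_composition(report, m.id, m.sequence, c.max_homopolymer, c.gc_bounds)
        # same-length pairwise distance floor
        by_len: dict[int, list[MID]] = {}
        for m in mids:
            by_len.setdefault(len(m), []).append(m)
        for length, group in by_len.items():
            for a, b in itertools.combinations(group, 2):
                d = levenshtein(a.sequence, b.sequence)
                if d < c.min_same_length_distance:
                    report.add(
                        "min_distance",
                        f"{orientation} {a.id}/{b.id} (length {length}): "
                        f"Levenshtein {d} < {c.min_same_length_distance}",
                    )
        # cross-length prefix ambiguity
        seqs = sorted((m.sequence for m in mids), key=len)
        for i, s in enumerate(seqs):
            for t in seqs[i + 1:]:
                if len(t) > len(s) and t.startswith(s):
                    report.add("prefix", f"{orientation} MID {s} is a prefix of {t}")
    return report


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


def _passes_composition(seq: str, max_homopoly: int, gc_bounds: tuple[float, float]) -> bool:
    if max_homopolymer(seq) > max_homopoly:
        return False
    return gc_bounds[0] <= gc_fraction(seq) <= gc_bounds[1]


def generate_mid_set(
    n_per_length: Mapping[int, int],
    constraints: MIDConstraints | None = None,
    seed: int = 0,
    attempt_budget: int = 1_000_000,
) -> MIDSet:
    """Generate forward and reverse MID sets by seeded rejection sampling.

    ``n_per_length`` maps MID length to the number of MIDs of that length
    wanted *per orientation* (so ``{8: 32, 9: 32, 10: 32}`` yields 96
    forward plus 96 reverse MIDs).  The returned set passes
    :func:`validate_mid_set`.  Raises ``RuntimeError`` when the attempt
    budget is exhausted before the request is met.
    """
    if constraints is None:
        lengths = tuple(n_per_length)
        constraints = MIDConstraints(length_range=(min(lengths), max(lengths)))
    rng = np.random.default_rng(seed)
    mid_set = MIDSet(constraints=constraints)
    for orientation, prefix in (("forward", "F"), ("reverse", "R")):
        accepted: list[str] = []
        counter = 0
        for length in sorted(n_per_length):
            want = n_per_length[length]
            if 4 ** length < want:
                raise RuntimeError(
                    f"infeasible request: {want} MIDs of length {length} exceeds "
                    f"the {4 ** length} possible sequences"
                )
            got = 0
            attempts = 0
            while got < want:
                if attempts >= attempt_budget:
                    raise RuntimeError(
                        f"attempt budget {attempt_budget} exhausted generating "
                        f"{orientation} MIDs of length {length}: got {got} of {want}"
                    )
                attempts += 1
                cand = _random_seq(rng, length)
                if not _passes_composition(cand, constraints.max_homopolymer,
                                           constraints.gc_bounds):
                    continue
                ok = True
                for prev in accepted:
                    if len(prev) == length:
                        if levenshtein(prev, cand) < constraints.min_same_length_distance:
                            ok = False
                            break
                    else:
                        if cand.startswith(prev) or levenshtein(prev, cand) < \
                                constraints.min_cross_length_distance:
                            ok = False
                            break
                if not ok:
                    continue
                accepted.append(cand)
                counter += 1
                mid_set.oriented(orientation).append(
                    MID(id=f"{prefix}{counter:03d}", sequence=cand, orientation=orientation)
                )
                got += 1
    return mid_set


def dual_index_capacity(n_fwd: int, n_rev: int) -> int:
    """Number of samples addressable with dual indexing: n_fwd * n_rev."""
    if n_fwd < 0 or n_rev < 0:
        raise ValueError("MID counts must be nonnegative")
    return n_fwd * n_rev


# ---------------------------------------------------------------------------
# Coligo identifiers and full coligos


@dataclass(frozen=True)
class ColigoIdentifier:
    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Coligo:
    """A full tracer oligo: forward primer + identifier + rc(reverse primer).

    The primer-complementary flanks make the oligo amplifiable by the same
    PCR as the biological marker locus, so it rides through library prep
    with the sample it was spiked into.
    """

    identifier: ColigoIdentifier
    fwd_primer: str
    rev_primer: str

    @property
    def full_sequence(self) -> str:
        return self.fwd_primer + self.identifier.sequence + reverse_complement(self.rev_primer)

    def __len__(self) -> int:
        return len(self.full_sequence)


def generate_coligo_identifiers(
    n: int,
    length: int = 13,
    min_distance: int = 3,
    max_homopoly: int = 3,
    gc_bounds: tuple[float, float] = (0.4, 0.6),
    seed: int = 0,
    attempt_budget: int = 1_000_000,
) -> list[ColigoIdentifier]:
    """Generate ``n`` identifiers at pairwise Levenshtein >= ``min_distance``.

    Minimum distance 3 (the default) guarantees that any single edit leaves
    the read closer to its true identifier than to any other, enabling
    single-error correction during matching.
    """
    if 4 ** length < n:
        raise RuntimeError(
            f"infeasible request: {n} identifiers of length {length} exceeds "
            f"the {4 ** length} possible sequences"
        )
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        if attempts >= attempt_budget:
            raise RuntimeError(
                f"attempt budget {attempt_budget} exhausted: "
                f"got {len(accepted)} of {n} identifiers"
            )
        attempts += 1
        cand = _random_seq(rng, length)
        if not _passes_composition(cand, max_homopoly, gc_bounds):
            continue
        if any(levenshtein(prev, cand) < min_distance for prev in accepted):
            continue
        accepted.append(cand)
    return [ColigoIdentifier(id=f"coligo{i + 1:03d}", sequence=s)
            for i, s in enumerate(accepted)]


def validate_coligo_set(
    identifiers: Sequence[ColigoIdentifier],
    min_distance: int = 3,
    length: int = 13,
    max_homopoly: int = 3,
    gc_bounds: tuple[float, float] = (0.4, 0.6),
) -> ValidationReport:
    """Re-validate an identifier set: pairwise distance floor plus composition."""
    report = ValidationReport()
    if not identifiers:
        report.add("empty", "no identifiers supplied")
        return report
    for ident in identifiers:
        if len(ident) != length:
            report.add("length", f"{ident.id}: length {len(ident)} != {length}")
        _validate_composition(report, ident.id, ident.sequence, max_homopoly, gc_bounds)
    for a, b in itertools.combinations(identifiers, 2):
        d = levenshtein(a.sequence, b.sequence)
        if d < min_distance:
            report.add("min_distance",
                       f"{a.id}/{b.id}: Levenshtein {d} < {min_distance}")
    return report


def build_coligo(identifier: ColigoIdentifier, fwd_primer: str, rev_primer: str) -> Coligo:
    """Assemble a full coligo; primers may contain IUPAC degeneracy codes."""
    if not identifier.sequence:
        raise ValueError("coligo identifier must be nonempty")
    for name, p in (("fwd_primer", fwd_primer), ("rev_primer", rev_primer)):
        if not p:
            raise ValueError(f"{name} must be nonempty")
        bad = set(p.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return Coligo(identifier=identifier, fwd_primer=fwd_primer.upper(),
                  rev_primer=rev_primer.upper())


# ---------------------------------------------------------------------------
# Mixture schemes (k-of-n oligo panel, the comparator design)


@dataclass
class MixtureScheme:
    """k-subsets of an oligo panel used as per-well tracer mixtures."""

    panel_size: int
    mixture_size: int
    mixtures: list[frozenset[int]]
    well_assignment: dict[str, frozenset[int]] | None = None

    def __post_init__(self) -> None:
        limit = math.comb(self.panel_size, self.mixture_size)
        if len(set(self.mixtures)) != len(self.mixtures):
            raise ValueError("mixtures must be distinct")
        if len(self.mixtures) > limit:
            raise ValueError(f"more mixtures than C({self.panel_size},{self.mixture_size})={limit}")
        for m in self.mixtures:
            if len(m) != self.mixture_size:
                raise ValueError(f"mixture {sorted(m)} has size {len(m)} != {self.mixture_size}")
            if not all(0 <= x < self.panel_size for x in m):
                raise ValueError(f"mixture {sorted(m)} references oligos outside the panel")


def enumerate_mixtures(panel_size: int, mixture_size: int) -> MixtureScheme:
    """All unordered ``mixture_size``-subsets of the panel, lexicographic order."""
    if mixture_size <= 0 or mixture_size > panel_size:
        raise ValueError(
            f"mixture_size must be in (0, panel_size]; got {mixture_size} of {panel_size}"
        )
    mixtures = [frozenset(c) for c in
                itertools.combinations(range(panel_size), mixture_size)]
    return MixtureScheme(panel_size=panel_size, mixture_size=mixture_size,
                         mixtures=mixtures)


def _orthogonal_neighbors(r: int, c: int, n_rows: int, n_cols: int):
    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        rr, cc = r + dr, c + dc
        if 0 <= rr < n_rows and 0 <= cc < n_cols:
            yield rr, cc


def assign_mixtures_to_plate(
    scheme: MixtureScheme,
    n_rows: int = 8,
    n_cols: int = 12,
    seed: int = 0,
) -> dict[str, frozenset[int]]:
    """Greedily place mixtures so adjacent wells are as distinct as possible.

    Wells are filled in row-major order; each well takes an unused mixture
    maximizing the minimum symmetric-difference size against already-placed
    orthogonal neighbors (ties broken by a seeded shuffle).  Returns a
    well-label -> mixture mapping, also stored on the scheme.
    """
    n_wells = n_rows * n_cols
    if len(scheme.mixtures) < n_wells:
        raise ValueError(
            f"{len(scheme.mixtures)} mixtures cannot fill {n_wells} wells"
        )
    rng = np.random.default_rng(seed)
    pool = list(scheme.mixtures)
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    grid: dict[tuple[int, int], frozenset[int]] = {}
    assignment: dict[str, frozenset[int]] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            neighbors = [grid[(rr, cc)] for rr, cc in
                         _orthogonal_neighbors(r, c, n_rows, n_cols) if (rr, cc) in grid]
            best_i, best_score = 0, -1
            for i, cand in enumerate(pool):
                score = min((len(cand ^ nb) for nb in neighbors), default=2 * scheme.mixture_size)
                if score > best_score:
                    best_i, best_score = i, score
                    if score == 2 * scheme.mixture_size:
                        break
            chosen = pool.pop(best_i)
            grid[(r, c)] = chosen
            label = f"{chr(ord('A') + r)}{c + 1}"
            assignment[label] = chosen
    scheme.well_assignment = assignment
    return assignment


def mixture_detectability(scheme: MixtureScheme, n_donors: int = 1) -> float:
    """Fraction of contamination events attributable to a unique donor set.

    Enumerates every ordered (donor-set, recipient) choice among the
    scheme's mixtures (restricted to those placed on the plate when a well
    assignment exists).  The observable evidence of an event is the set of
    foreign oligos F = (union of donor mixtures) minus the recipient's own
    mixture.  The event is unambiguously detected iff exactly one candidate
    donor set of the same size could have produced F; F = empty set (donors
    hiding entirely inside the recipient's mixture) is never detectable.
    """
    if n_donors not in (1, 2):
        raise ValueError("n_donors must be 1 or 2")
    if scheme.well_assignment is not None:
        mixtures = list(scheme.well_assignment.values())
    else:
        mixtures = list(scheme.mixtures)
    if len(mixtures) < n_donors + 1:
        raise ValueError("scheme must contain at least n_donors + 1 mixtures")

    masks = [sum(1 << x for x in m) for m in mixtures]
    n = len(masks)
    detected = 0
    total = 0
    for r_i, r_mask in enumerate(masks):
        donors = [m for i, m in enumerate(masks) if i != r_i]
        # group donor sets by the foreign-oligo evidence they would leave
        evidence: dict[int, int] = {}
        if n_donors == 1:
            keys = [d & ~r_mask for d in donors]
        else:
            keys = [(d1 | d2) & ~r_mask
                    for d1, d2 in itertools.combinations(donors, 2)]
        for k in keys:
            evidence[k] = evidence.get(k, 0) + 1
        for k in keys:
            total += 1
            if k != 0 and evidence[k] == 1:
                detected += 1
    return detected / total
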