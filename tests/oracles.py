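"""Independent reference implementations used only to check the package.

These are deliberately written from first principles (full DP matrices,
explicit complement tables, brute-force enumeration) and must stay
decoupled from the implementations they certify.
"""

from __future__ import annotations

import itertools


def dp_levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance via the full Wagner-Fischer matrix."""
    n, m = len(a), len(b)
    dist = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        dist[i][0] = i
    for j in range(m + 1):
        dist[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            dist[i][j] = min(
                dist[i - 1][j] + 1,        # deletion
                dist[i][j - 1] + 1,        # insertion
                dist[i - 1][j - 1] + cost,  # substitution / match
            )
    return dist[n][m]


_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def table_reverse_complement(seq: str) -> str:
    """IUPAC reverse complement from an explicit lookup table."""
    return "".join(_COMPLEMENT[base] for base in reversed(seq.upper()))


def brute_force_detectability(mixtures, n_donors: int) -> float:
    """Fraction of (donor-set, recipient) events with a unique explanation.

    Direct enumeration with Python sets: for each event, the foreign
    evidence F = union(donors) - recipient is compared against every
    candidate donor set of the same size; detected iff exactly one
    candidate reproduces F and F is nonempty.
    """
    mixtures = [frozenset(m) for m in mixtures]
    detected = total = 0
    for r_i, recipient in enumerate(mixtures):
        donors = [m for i, m in enumerate(mixtures) if i != r_i]
        donor_sets = (
            [(d,) for d in donors] if n_donors == 1
            else list(itertools.combinations(donors, 2))
        )
        for ds in donor_sets:
            evidence = frozenset().union(*ds) - recipient
            total += 1
            if not evidence:
                continue
            n_explaining = sum(
                1 for cand in donor_sets
                if frozenset().union(*cand) - recipient == evidence
            )
            if n_explaining == 1:
                detected += 1
    return detected / total


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: 1 - edits / max(len), via the DP oracle."""
    if not a or not b:
        return 0.0
    return 1.0 - dp_levenshtein(a, b) / max(len(a), len(b))
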