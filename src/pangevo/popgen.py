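"""Per-orthogroup neutrality statistics and between-group comparisons.

Tajima's D contrasts two estimators of the population mutation rate theta:
the mean pairwise difference count pi and the Watterson estimator S/a1
(S = segregating sites, a1 = sum_{i<n} 1/i).  Under the standard neutral
model D is approximately standard normal; an excess of rare alleles
(expansion, sweeps) drives it negative, an excess of intermediate-frequency
alleles (balancing selection, contraction) positive.

Alignment columns containing any character outside {A,C,G,T} (gaps, Ns) are
excluded entirely before computing either statistic — complete-column
deletion, applied identically to S and pi so the two estimators see the
same sites.

Distribution comparisons use the Mann-Whitney U test with the
common-language effect size CLES = U/(n1*n2): the probability that a random
observation from the first group exceeds one from the second (ties counted
half).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .io_formats import Alignment

_ACGT = frozenset(b"ACGT")


@dataclass
class TajimaConstants:
    """The n-dependent constants of Tajima's variance formula."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_sample_size(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("need n >= 2 sequences")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass
class TajimaDResult:
    orthogroup_id: Optional[str]
    n: int
    n_sites_used: int
    S: int
    pi: float
    D: Optional[float]
    defined: bool


def _retained_columns(aln: Alignment) -> np.ndarray:
    """Byte matrix of the columns where every sequence has an A/C/G/T."""
    mat = np.frombuffer("".join(aln.seqs).encode(), dtype="S1").reshape(aln.n_seqs, aln.length)
    is_acgt = (mat == b"A") | (mat == b"C") | (mat == b"G") | (mat == b"T")
    ok = is_acgt.all(axis=0)
    return mat[:, ok]


def segregating_sites(aln: Alignment) -> tuple[int, int]:
    """(S, retained-column count): S is the number of retained columns with
    at least two distinct bases."""
    if aln.n_seqs < 2:
        raise ValueError("need >=2 sequences")
    cols = _retained_columns(aln)
    if cols.shape[1] == 0:
        return 0, 0
    varying = (cols != cols[0]).any(axis=0)
    return int(varying.sum()), cols.shape[1]


def nucleotide_diversity(aln: Alignment) -> float:
    """Mean pairwise difference count over all n(n-1)/2 sequence pairs,
    computed on retained columns (count units, not per-site)."""
    if aln.n_seqs < 2:
        raise ValueError("need >=2 sequences")
    cols = _retained_columns(aln)
    n = aln.n_seqs
    total = 0
    for i in range(n):
        diff = (cols[i + 1 :] != cols[i]).sum()
        total += int(diff)
    return total / (n * (n - 1) / 2)


def tajimas_d(aln: Alignment, orthogroup_id: Optional[str] = None) -> TajimaDResult:
    """Tajima's D: (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).

    Undefined (flagged, D=None) when S == 0 or n < 4; undefined rows are
    kept so downstream denominator choices stay explicit.
    """
    S, used = segregating_sites(aln)
    pi = nucleotide_diversity(aln)
    n = aln.n_seqs
    if n < 4 or S == 0:
        return TajimaDResult(orthogroup_id, n, used, S, pi, None, False)
    k = TajimaConstants.for_sample_size(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    D = (pi - S / k.a1) / math.sqrt(var)
    return TajimaDResult(orthogroup_id, n, used, S, pi, float(D), True)


@dataclass
class GroupComparison:
    label_a: str
    label_b: str
    n1: int
    n2: int
    U: float
    p: float
    cles: float
    median_a: float
    median_b: float
    method: str


def mann_whitney_u(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """U statistic by direct pair scoring: 1 per (a > b) pair, 0.5 per tie."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
    exact_max_pairs: int = 400,
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison with CLES.

    The p-value uses the exact null distribution when n1*n2 <=
    ``exact_max_pairs`` and the data are tie-free, otherwise the
    tie-corrected normal approximation.  CLES = U/(n1*n2).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u = mann_whitney_u(a, b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size * b.size <= exact_max_pairs and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n1=int(a.size),
        n2=int(b.size),
        U=u,
        p=float(res.pvalue),
        cles=u / (a.size * b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method=method,
    )
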