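"""Pairwise selection metrics and the cross-cluster differential-selection
screen.

The nonsynonymous/synonymous rate ratio omega = dN/dS is estimated per
sequence pair with the Nei-Gojobori (1986) counting method: fractional
synonymous/nonsynonymous site opportunity per codon position, per-codon
difference counting with averaging over all single-step substitution
pathways (pathways through stop codons excluded), and the Jukes-Cantor
multiple-hit correction d = -(3/4) ln(1 - (4/3) p).  Pairwise Tajima-Nei
(1984) distances provide the companion nucleotide distance, which corrects
for unequal base composition.

The screen compares, per orthogroup, the omega values of two genomic
species clusters (each member measured against a common outgroup sequence)
and flags orthogroups whose medians differ at least two-fold
(|log2 ratio| > 1) with Mann-Whitney p < 0.05.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import Alignment, CodonAlignment
from .popgen import compare_groups

_TABLE = CodonTable.unambiguous_dna_by_id[11]
#: codon -> amino acid for the 61 sense codons; stops map to '*'.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = sorted(c for c in CODON_TO_AA if c not in STOP_CODONS)

_NUCS = "ACGT"
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _syn_sites(codon: str) -> float:
    """Fractional synonymous site count of a sense codon.

    At each position, the synonymous fraction is (synonymous non-stop
    changes)/3; a change creating a stop codon therefore counts toward the
    nonsynonymous opportunity.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                s += 1.0 / 3.0
    return s


_SYN_SITES = {c: _syn_sites(c) for c in SENSE_CODONS}


@functools.lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> Optional[tuple[float, float]]:
    """(syn, nonsyn) difference counts between two sense codons, averaged
    over all single-step substitution pathways.

    Pathways whose intermediates are stop codons are excluded; if every
    pathway is blocked, the average falls back to all pathways.  Returns
    None for identical codons.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return None
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        current = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if CODON_TO_AA.get(nxt, "*") == CODON_TO_AA.get(current, "*"):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        # endpoints are sense codons; only intermediates can be stops
        (blocked if through_stop else valid).append((sd, nd))
    pool = valid if valid else blocked
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    return sd, nd


def _jc_correct(p: float) -> Optional[float]:
    """Jukes-Cantor multiple-hit correction; None at/after saturation."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class Ng86Result:
    dN: Optional[float]
    dS: Optional[float]
    omega: Optional[float]
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons_used: int
    usable: bool
    reason: str = ""


def ng86_pair(seq1: str, seq2: str) -> Ng86Result:
    """Nei-Gojobori dN/dS for a codon-aligned sequence pair.

    Codons containing a gap or N in either sequence, and codons that are
    stop codons in either sequence, are skipped pairwise.  omega is defined
    only when dS > 0.
    """
    if len(seq1) != len(seq2) or len(seq1) % 3 != 0:
        raise ValueError("sequences must be codon-aligned and equal length")
    s_sites = n_sites = 0.0
    s_diffs = n_diffs = 0.0
    used = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 not in _SYN_SITES or c2 not in _SYN_SITES:
            continue  # gap/N/stop codon in either sequence
        used += 1
        s_sites += (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2.0
        n_sites += 3.0 - (_SYN_SITES[c1] + _SYN_SITES[c2]) / 2.0
        counts = _pathway_counts(c1, c2)
        if counts is not None:
            s_diffs += counts[0]
            n_diffs += counts[1]
    if used == 0:
        return Ng86Result(None, None, None, 0, 0, 0, 0, 0, False, "no_analyzable_codons")
    pS = s_diffs / s_sites if s_sites > 0 else 0.0
    pN = n_diffs / n_sites if n_sites > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    if dS is None or dN is None:
        return Ng86Result(
            dN, dS, None, s_sites, n_sites, s_diffs, n_diffs, used, False, "saturated"
        )
    omega = dN / dS if dS > 0 else None
    return Ng86Result(dN, dS, omega, s_sites, n_sites, s_diffs, n_diffs, used, True)


def tajima_nei_pair(seq1: str, seq2: str) -> Optional[float]:
    """Tajima-Nei (1984) distance for an aligned nucleotide pair.

    Sites with a non-ACGT character in either sequence are excluded.
    Returns None (unusable) on a log-domain violation (excess divergence)
    or when no sites remain.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be equal length")
    pairs = [
        (a, b)
        for a, b in zip(seq1, seq2)
        if a in _NUCS and b in _NUCS
    ]
    if not pairs:
        return None
    L = len(pairs)
    mismatches = [(a, b) for a, b in pairs if a != b]
    p = len(mismatches) / L
    if p == 0:
        return 0.0
    # average base frequencies over the two sequences
    freq = {n: 0.0 for n in _NUCS}
    for a, b in pairs:
        freq[a] += 0.5 / L
        freq[b] += 0.5 / L
    # pair-frequency term over unordered mismatch types
    x: dict[frozenset, float] = {}
    for a, b in mismatches:
        key = frozenset((a, b))
        x[key] = x.get(key, 0.0) + 1.0 / L
    c = 0.0
    for key, xij in x.items():
        i, j = sorted(key)
        c += xij**2 / (2.0 * freq[i] * freq[j])
    b_term = 0.5 * (1.0 - sum(f**2 for f in freq.values()) + p**2 / c)
    arg = 1.0 - p / b_term
    if arg <= 0:
        return None
    return -b_term * math.log(arg)


# ---------------------------------------------------------------------------
# codon-aware back-translation
# ---------------------------------------------------------------------------

_START_TOLERANT = {"GTG": "M", "TTG": "M", "ATG": "M"}


def _translate_cds(cds: str, seq_id: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"{seq_id}: CDS length {len(cds)} not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon not in CODON_TO_AA:
            raise ValueError(f"{seq_id}: unrecognized codon {codon!r} at position {i}")
        aa = CODON_TO_AA[codon]
        if i == 0 and codon in _START_TOLERANT:
            aa = "M"  # bacterial alternative starts read as Met
        aas.append(aa)
    return "".join(aas)


def backtranslate(
    protein_ids: Sequence[str],
    protein_seqs: Sequence[str],
    cds: dict[str, str],
    labels: Optional[dict[str, str]] = None,
    orthogroup_id: Optional[str] = None,
) -> CodonAlignment:
    """Expand a gapped protein alignment to a codon alignment using each
    sequence's source CDS.

    Each CDS must translate exactly (standard code; GTG/TTG start read as
    Met) to its ungapped protein; a retained trailing stop codon is
    trimmed.  Protein gaps become ``---``.
    """
    out_seqs = []
    for sid, prot in zip(protein_ids, protein_seqs):
        if sid not in cds:
            raise ValueError(f"no CDS provided for {sid!r}")
        nt = cds[sid].upper()
        ungapped = prot.replace("-", "").upper()
        expected = len(ungapped) * 3
        if len(nt) == expected + 3:
            last = nt[-3:]
            if last in STOP_CODONS:
                nt = nt[:-3]
            else:
                raise ValueError(f"{sid}: CDS length exceeds protein by one non-stop codon")
        elif len(nt) != expected:
            raise ValueError(
                f"{sid}: CDS length {len(nt)} does not match protein length {len(ungapped)}"
            )
        translated = _translate_cds(nt, sid)
        for pos, (aa_t, aa_p) in enumerate(zip(translated, ungapped)):
            if aa_t == "*":
                raise ValueError(f"{sid}: internal stop codon at protein position {pos}")
            if aa_t != aa_p:
                raise ValueError(
                    f"{sid}: translation mismatch at protein position {pos}: "
                    f"CDS gives {aa_t!r}, alignment has {aa_p!r}"
                )
        codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
        it = iter(codons)
        out_seqs.append("".join("---" if aa == "-" else next(it) for aa in prot.upper()))
    return CodonAlignment(
        ids=list(protein_ids),
        seqs=out_seqs,
        labels=dict(labels or {}),
        codon=True,
        orthogroup_id=orthogroup_id,
    )


# ---------------------------------------------------------------------------
# filtering and the differential-selection screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionRecord:
    orthogroup_id: str
    seq_a: str
    seq_b: str
    cluster_a: str
    cluster_b: str
    dN: Optional[float]
    dS: Optional[float]
    omega: Optional[float]
    tn_distance: Optional[float]
    usable: bool = True
    reason: str = ""


@dataclass
class FilterPolicy:
    """The discard rules applied before any median or test: zero Tajima-Nei
    distance, dN/dS above ``max_omega``, dS above ``max_ds``, and (optionally)
    same-cluster pairs."""

    drop_zero_distance: bool = True
    max_omega: float = 5.0
    max_ds: float = 10.0
    cross_cluster_only: bool = True


def apply_filters(
    records: Sequence[SelectionRecord], policy: Optional[FilterPolicy] = None
) -> tuple[list[SelectionRecord], dict[str, int]]:
    """Apply the discard rules; returns (kept records, per-rule tally).

    Rules are checked in a fixed order but are order-independent (a record
    violating several rules is tallied under the first); filtering is
    idempotent.
    """
    policy = policy or FilterPolicy()
    kept: list[SelectionRecord] = []
    tally = {
        "unusable": 0,
        "zero_distance": 0,
        "omega_above_max": 0,
        "ds_above_max": 0,
        "same_cluster": 0,
        "kept": 0,
    }
    for rec in records:
        if not rec.usable or rec.tn_distance is None or rec.dS is None:
            tally["unusable"] += 1
            continue
        if policy.drop_zero_distance and rec.tn_distance == 0:
            tally["zero_distance"] += 1
            continue
        if rec.omega is not None and rec.omega > policy.max_omega:
            tally["omega_above_max"] += 1
            continue
        if rec.dS > policy.max_ds:
            tally["ds_above_max"] += 1
            continue
        if policy.cross_cluster_only and rec.cluster_a == rec.cluster_b:
            tally["same_cluster"] += 1
            continue
        kept.append(rec)
        tally["kept"] += 1
    return kept, tally


def pairwise_selection(
    aln: CodonAlignment,
    outgroup_label: Optional[str] = None,
    mode: str = "outgroup",
) -> list[SelectionRecord]:
    """All pairwise (dN, dS, omega, Tajima-Nei) records for one orthogroup.

    ``mode="outgroup"`` (default): each ingroup sequence against the
    designated outgroup sequence; when multiple outgroup paralogs exist the
    one with the smallest median Tajima-Nei distance to the ingroup is used
    (ties: first in alignment order).  ``mode="cross-cluster"``: all pairs
    from different clusters.
    """
    if mode not in ("outgroup", "cross-cluster"):
        raise ValueError("mode must be 'outgroup' or 'cross-cluster'")
    labels = aln.labels
    og_id = aln.orthogroup_id or ""

    def record(i: int, j: int) -> SelectionRecord:
        s1, s2 = aln.seqs[i], aln.seqs[j]
        ng = ng86_pair(s1, s2)
        tn = tajima_nei_pair(s1, s2)
        usable = ng.usable and tn is not None
        reason = ng.reason if not ng.usable else ("tn_undefined" if tn is None else "")
        return SelectionRecord(
            orthogroup_id=og_id,
            seq_a=aln.ids[i],
            seq_b=aln.ids[j],
            cluster_a=labels.get(aln.ids[i], ""),
            cluster_b=labels.get(aln.ids[j], ""),
            dN=ng.dN,
            dS=ng.dS,
            omega=ng.omega,
            tn_distance=tn,
            usable=usable,
            reason=reason,
        )

    if mode == "cross-cluster":
        return [
            record(i, j)
            for i in range(aln.n_seqs)
            for j in range(i + 1, aln.n_seqs)
            if labels.get(aln.ids[i]) != labels.get(aln.ids[j])
        ]

    if outgroup_label is None:
        raise ValueError("outgroup mode requires outgroup_label")
    out_idx = [i for i, sid in enumerate(aln.ids) if labels.get(sid) == outgroup_label]
    in_idx = [i for i, sid in enumerate(aln.ids) if labels.get(sid) != outgroup_label]
    if not out_idx:
        raise ValueError(f"no outgroup sequences labeled {outgroup_label!r}")
    if len(out_idx) > 1:
        # deterministic paralog choice: smallest median distance to ingroup
        med = []
        for o in out_idx:
            ds = [
                d
                for i in in_idx
                if (d := tajima_nei_pair(aln.seqs[o], aln.seqs[i])) is not None
            ]
            med.append(float(np.median(ds)) if ds else math.inf)
        out_idx = [out_idx[int(np.argmin(med))]]
    o = out_idx[0]
    return [record(i, o) for i in in_idx]


@dataclass
class ScreenResult:
    orthogroup_id: str
    cluster_a: str
    cluster_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    log2_ratio: float
    U: float
    p: float
    flag: str  # higher_in_A | higher_in_B | ns


def screen(
    orthogroup_id: str,
    omegas_a: Sequence[float],
    omegas_b: Sequence[float],
    cluster_a: str = "A",
    cluster_b: str = "B",
    log2_cutoff: float = 1.0,
    alpha: float = 0.05,
) -> ScreenResult:
    """Differential-selection call for one orthogroup.

    Flags ``higher_in_A``/``higher_in_B`` iff |log2(medianA/medianB)| >
    ``log2_cutoff`` AND Mann-Whitney p < ``alpha``; otherwise ``ns``.
    """
    if len(omegas_a) == 0 or len(omegas_b) == 0:
        raise ValueError("both omega sets must be non-empty after filtering")
    comp = compare_groups(omegas_a, omegas_b, cluster_a, cluster_b)
    if comp.median_a > 0 and comp.median_b > 0:
        ratio = math.log2(comp.median_a / comp.median_b)
    else:
        ratio = math.inf if comp.median_a > comp.median_b else (-math.inf if comp.median_b > comp.median_a else 0.0)
    flag = "ns"
    if abs(ratio) > log2_cutoff and comp.p < alpha:
        flag = "higher_in_A" if ratio > 0 else "higher_in_B"
    return ScreenResult(
        orthogroup_id=orthogroup_id,
        cluster_a=cluster_a,
        cluster_b=cluster_b,
        n_a=comp.n1,
        n_b=comp.n2,
        median_a=comp.median_a,
        median_b=comp.median_b,
        log2_ratio=ratio,
        U=comp.U,
        p=comp.p,
        flag=flag,
    )


def screen_from_records(
    records: Sequence[SelectionRecord],
    cluster_a: str,
    cluster_b: str,
    policy: Optional[FilterPolicy] = None,
    log2_cutoff: float = 1.0,
    alpha: float = 0.05,
) -> tuple[list[ScreenResult], dict[str, int]]:
    """Run the screen over filtered records grouped by orthogroup.

    Each record's ingroup cluster is whichever of its two cluster labels is
    ``cluster_a`` or ``cluster_b``; orthogroups where either cluster has no
    usable omega after filtering are skipped (logged in the tally).
    """
    kept, tally = apply_filters(records, policy)
    by_og: dict[str, dict[str, list[float]]] = {}
    for rec in kept:
        if rec.omega is None:
            continue
        ingroup = [lab for lab in (rec.cluster_a, rec.cluster_b) if lab in (cluster_a, cluster_b)]
        if len(ingroup) != 1:
            # a pair between the two ingroup clusters has no single owner
            continue
        by_og.setdefault(rec.orthogroup_id, {}).setdefault(ingroup[0], []).append(rec.omega)
    results = []
    skipped = 0
    for og in sorted(by_og):
        groups = by_og[og]
        if cluster_a not in groups or cluster_b not in groups:
            skipped += 1
            continue
        results.append(
            screen(og, groups[cluster_a], groups[cluster_b], cluster_a, cluster_b, log2_cutoff, alpha)
        )
    tally["orthogroups_skipped"] = skipped
    return results, tally


def records_to_frame(records: Sequence[SelectionRecord]) -> pd.DataFrame:
    return pd.DataFrame([rec.__dict__ for rec in records])
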