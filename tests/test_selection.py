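import itertools
import math

import numpy as np
import pytest

from pangevo.io_formats import CodonAlignment
from pangevo.selection import (
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    FilterPolicy,
    SelectionRecord,
    apply_filters,
    backtranslate,
    ng86_pair,
    pairwise_selection,
    screen,
    tajima_nei_pair,
)

# ---------------------------------------------------------------------------
# independent NG86 oracle: explicit per-codon site fractions and explicit
# pathway enumeration, coded directly from the counting definitions
# ---------------------------------------------------------------------------


def oracle_sites(codon):
    syn = 0.0
    for pos, base in enumerate(codon):
        for nt in "ACGT":
            if nt == base:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def oracle_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        steps = []
        cur = c1
        stop_free = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                stop_free = False
            steps.append((cur, nxt))
            cur = nxt
        paths.append((stop_free, steps))
    usable = [steps for ok, steps in paths if ok] or [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if CODON_TO_AA.get(a, "*") == CODON_TO_AA.get(b, "*"):
                syn += 1
            else:
                nonsyn += 1
    return syn / len(usable), nonsyn / len(usable)


def oracle_ng86(seq1, seq2):
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 not in SENSE_CODONS or c2 not in SENSE_CODONS:
            continue
        for c in (c1, c2):
            s, n = oracle_sites(c)
            s_sites += s / 2
            n_sites += n / 2
        ds, dn = oracle_diffs(c1, c2)
        sd += ds
        nd += dn
    pS, pN = sd / s_sites, nd / n_sites

    def jc(p):
        return None if p >= 0.75 else (-0.75 * math.log(1 - 4 * p / 3) if p > 0 else 0.0)

    return jc(pN), jc(pS)


class TestNg86:
    def test_identical_sequences_zero_rates(self):
        res = ng86_pair("ATGAAA", "ATGAAA")
        assert res.dN == 0.0 and res.dS == 0.0 and res.omega is None

    def test_single_synonymous_change(self):
        # TTT vs TTC (Phe->Phe) in enough invariant context that the
        # synonymous proportion stays below the saturation bound
        ctx = "ATGAAACCCGGG"
        res = ng86_pair(ctx + "TTT", ctx + "TTC")
        assert res.nonsyn_diffs == 0.0 and res.syn_diffs == 1.0
        assert res.dN == 0.0 and res.dS > 0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        s1 = "".join(rng.choice(SENSE_CODONS, size=30))
        s2 = "".join(rng.choice(SENSE_CODONS, size=30))
        a, b = ng86_pair(s1, s2), ng86_pair(s2, s1)
        assert (a.dN, a.dS, a.syn_diffs, a.nonsyn_diffs) == (b.dN, b.dS, b.syn_diffs, b.nonsyn_diffs)

    def test_two_position_codon_difference_matches_pathway_oracle(self):
        # context codons keep the proportions small enough for JC
        context = "ATGAAACCC"
        pair = ("TTT", "TAC")  # differs at positions 2 and 3
        s1 = context + pair[0]
        s2 = context + pair[1]
        res = ng86_pair(s1, s2)
        dn, ds = oracle_ng86(s1, s2)
        assert res.dN == pytest.approx(dn, abs=1e-12)
        assert res.dS == pytest.approx(ds, abs=1e-12)

    def test_gap_and_stop_codons_skipped(self):
        gap = ng86_pair("ATG---AAA", "ATGAAAAAA")
        assert gap.n_codons_used == 2
        stop = ng86_pair("ATGTAAAAA", "ATGTAAAAA")
        assert stop.n_codons_used == 2

    def test_omega_undefined_when_ds_zero(self):
        # every codon differs nonsynonymously, no synonymous change
        res = ng86_pair("ATG" * 10, "TGG" * 10)
        assert res.dS == 0.0 and res.omega is None and res.dN > 0

    def test_saturation_flagged_unusable(self):
        # a lone synonymous change in a single-codon pair gives pS = 3 >= 3/4
        res = ng86_pair("TTT", "TTC")
        assert not res.usable and res.reason == "saturated"


class TestTajimaNei:
    def test_identical_zero(self):
        assert tajima_nei_pair("ACGTACGT", "ACGTACGT") == 0.0

    def test_equal_frequency_limit_matches_jukes_cantor(self):
        # balanced composition, small p
        s1 = "ACGT" * 25
        s2 = "ACGT" * 24 + "ACGA"  # one T->A mismatch in 100 sites
        d = tajima_nei_pair(s1, s2)
        p = 0.01
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert d == pytest.approx(jc, abs=1e-3)

    def test_correction_expands_large_divergence(self):
        rng = np.random.default_rng(5)
        bases = list("ACGT")
        s1 = "".join(rng.choice(bases, size=400))
        s2 = "".join(
            c if rng.random() > 0.5 else rng.choice([b for b in bases if b != c])
            for c in s1
        )
        p = sum(a != b for a, b in zip(s1, s2)) / 400
        d = tajima_nei_pair(s1, s2)
        assert d is None or d > p

    def test_non_acgt_sites_excluded(self):
        assert tajima_nei_pair("ACN-", "ACGT") == 0.0


class TestBacktranslate:
    def test_gap_expansion(self):
        aln = backtranslate(["s1"], ["M-K"], {"s1": "ATGAAA"})
        assert aln.seqs == ["ATG---AAA"]

    def test_trailing_stop_trimmed(self):
        aln = backtranslate(["s1"], ["MK"], {"s1": "ATGAAATAA"})
        assert aln.seqs == ["ATGAAA"]

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            backtranslate(["s1"], ["MK"], {"s1": "ATGTGAAAA"})

    def test_translation_mismatch_names_sequence_and_position(self):
        with pytest.raises(ValueError, match="s1.*position 1"):
            backtranslate(["s1"], ["MM"], {"s1": "ATGAAA"})

    def test_ungapped_alignment_is_codon_concatenation(self):
        cds = {"s1": "ATGAAACCC", "s2": "GTGAAACCC"}  # GTG start tolerated as Met
        aln = backtranslate(["s1", "s2"], ["MKP", "MKP"], cds)
        assert aln.seqs == ["ATGAAACCC", "GTGAAACCC"]

    def test_backtranslation_round_trip_is_identity_on_protein(self):
        rng = np.random.default_rng(9)
        codons = [c for c in SENSE_CODONS]
        prot_rows = []
        cds = {}
        for sid in ("a", "b"):
            picks = rng.choice(codons, size=12)
            cds[sid] = "".join(picks)
            prot = "".join(CODON_TO_AA[c] for c in picks)
            # insert a gap into sequence b
            prot_rows.append(prot[:5] + "-" + prot[5:] if sid == "b" else prot + "-")
        aln = backtranslate(["a", "b"], prot_rows, cds)
        for seq, prot in zip(aln.seqs, prot_rows):
            back = "".join(
                "-" if seq[i : i + 3] == "---" else CODON_TO_AA[seq[i : i + 3]]
                for i in range(0, len(seq), 3)
            )
            assert back == prot


def make_record(**kwargs):
    base = dict(
        orthogroup_id="OG1",
        seq_a="x",
        seq_b="y",
        cluster_a="A",
        cluster_b="B",
        dN=0.1,
        dS=0.2,
        omega=0.5,
        tn_distance=0.3,
        usable=True,
    )
    base.update(kwargs)
    return SelectionRecord(**base)


class TestFilters:
    @pytest.mark.parametrize(
        "record,reason",
        [
            (make_record(tn_distance=0.0), "zero_distance"),
            (make_record(omega=6.0), "omega_above_max"),
            (make_record(dS=12.0), "ds_above_max"),
            (make_record(cluster_b="A"), "same_cluster"),
            (make_record(usable=False, tn_distance=None), "unusable"),
        ],
    )
    def test_each_rule_fires(self, record, reason):
        kept, tally = apply_filters([record])
        assert kept == [] and tally[reason] == 1

    def test_idempotent(self):
        records = [make_record(), make_record(omega=6.0), make_record(tn_distance=0.0)]
        once, _ = apply_filters(records)
        twice, _ = apply_filters(once)
        assert once == twice


class TestScreen:
    def test_identical_sets_not_significant(self):
        res = screen("OG1", [0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.log2_ratio == 0.0 and res.flag == "ns"

    def test_two_fold_example_exact_enumeration(self):
        res = screen("OG1", [0.8, 0.9, 1.0], [0.2, 0.225, 0.25])
        assert res.log2_ratio == pytest.approx(2.0)
        assert res.U == 9.0  # complete separation over the 9 pairs
        # exact two-sided p for complete separation at n1=n2=3 is 0.1
        assert res.p == pytest.approx(0.1)
        assert res.flag == "ns"

    def test_outgroup_mode_pairs_each_ingroup_sequence_once(self):
        aln = CodonAlignment(
            ids=["o", "a1", "a2", "b1"],
            seqs=["ATGAAATTT", "ATGAAATTC", "ATGAATTTT", "ATGCAATTT"],
            labels={"o": "OUT", "a1": "A", "a2": "A", "b1": "B"},
            codon=True,
            orthogroup_id="OG1",
        )
        records = pairwise_selection(aln, outgroup_label="OUT")
        assert len(records) == 3
        assert all(r.cluster_b == "OUT" for r in records)

    def test_cross_cluster_mode_excludes_within_cluster_pairs(self):
        aln = CodonAlignment(
            ids=["a1", "a2", "b1"],
            seqs=["ATGAAATTT", "ATGAAATTC", "ATGCAATTT"],
            labels={"a1": "A", "a2": "A", "b1": "B"},
            codon=True,
            orthogroup_id="OG1",
        )
        records = pairwise_selection(aln, mode="cross-cluster")
        assert len(records) == 2
        assert all({r.cluster_a, r.cluster_b} == {"A", "B"} for r in records)
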