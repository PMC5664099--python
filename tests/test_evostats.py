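"""NG86 Ka/Ks against an independent pathway-enumeration oracle, plus
G+C, exon-structure and expression summaries."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from ntnl_forge import evostats, synthdata
from ntnl_forge.seqio import ExpressionMatrix


# ---------------------------------------------------------------------------
# independent NG86 oracle (kept deliberately naive and separate from the
# implementation: recursive pathway enumeration straight from the codon table)
# ---------------------------------------------------------------------------

from Bio.Data import CodonTable

_T = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_T.forward_table)
_STOPS = set(_T.stop_codons)


def oracle_sites(codon):
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1:]
            if nb not in _STOPS and _AA[nb] == _AA[codon]:
                syn += 1
    return syn / 3, 3 - syn / 3


def oracle_pair(c1, c2):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(c1), 3):
        a, b = c1[i:i + 3], c2[i:i + 3]
        sa, na = oracle_sites(a)
        sb, nb = oracle_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        diff = [j for j in range(3) if a[j] != b[j]]
        if not diff:
            continue
        ok, bad = [], []
        for order in permutations(diff):
            cur, s, n, stop = a, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + b[pos] + cur[pos + 1:]
                if nxt in _STOPS or cur in _STOPS:
                    stop = True
                    n += 1
                elif _AA[nxt] == _AA[cur]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            (bad if stop else ok).append((s, n))
        paths = ok or bad
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    ps, pn = Sd / S, Nd / N
    jc = lambda p: None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return S, N, Sd, Nd, jc(ps), jc(pn)


class TestNg86Sites:
    def test_phe_codon(self):
        assert evostats.ng86_sites("TTT") == pytest.approx((1 / 3, 8 / 3))

    def test_trp_codon_fully_nonsynonymous(self):
        assert evostats.ng86_sites("TGG") == (0.0, 3.0)

    def test_all_sense_codons_sum_to_three(self):
        for codon in evostats.SENSE_CODONS:
            s, n = evostats.ng86_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert s >= 0 and n >= 0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            evostats.ng86_sites("TAA")


class TestNg86Pair:
    def test_identical_sequences(self):
        res = evostats.ng86_pair("ATGAAA", "ATGAAA")
        assert res.syn_diffs == res.nonsyn_diffs == 0
        assert res.ks == 0.0 and res.ka == 0.0
        assert res.ratio is None

    def test_lysine_worked_example(self):
        """Ten AAA codons with one synonymous AAG change: S = 10/3,
        ps = 0.3, Ks = -(3/4) ln(0.6) ≈ 0.383, Ka = 0."""
        res = evostats.ng86_pair("AAA" * 10, "AAA" * 9 + "AAG")
        assert res.syn_sites == pytest.approx(10 / 3)
        assert res.syn_diffs == 1.0 and res.nonsyn_diffs == 0.0
        assert res.ps == pytest.approx(0.3)
        assert res.ks == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)
        assert res.ks == pytest.approx(0.383, abs=5e-4)
        assert res.ka == 0.0

    def test_oracle_equivalence_200_random_pairs(self):
        rng = np.random.default_rng(2024)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for k in range(200):
            protein = "M" + "".join(rng.choice(aas, 40))
            anc = synthdata.reverse_translate(protein, 0.5, 1000 + k)
            a, b = synthdata.mutate_cds_family(
                anc, 2, n_attempts=int(rng.integers(5, 60)),
                nonsyn_accept=float(rng.uniform(0.1, 1.0)), seed=2000 + k,
            )
            res = evostats.ng86_pair(a, b)
            S, N, Sd, Nd, ks, ka = oracle_pair(a, b)
            assert res.syn_sites == pytest.approx(S, abs=1e-12)
            assert res.nonsyn_sites == pytest.approx(N, abs=1e-12)
            assert res.syn_diffs == pytest.approx(Sd, abs=1e-12)
            assert res.nonsyn_diffs == pytest.approx(Nd, abs=1e-12)
            if ks is not None:
                assert res.ks == pytest.approx(ks, abs=1e-12)
            if ka is not None:
                assert res.ka == pytest.approx(ka, abs=1e-12)

    def test_biopython_ng86_cross_check(self):
        """Independent library implementation of the same estimator agrees.

        Restricted to pairs whose differing codons differ at one position:
        for multi-hit codons the library averages over all mutational
        pathways including stop-passing ones, whereas this package
        excludes them, so exact agreement is only defined where no
        multi-step pathway exists.
        """
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(7)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        n_compared = 0
        for k in range(40):
            anc = synthdata.reverse_translate("M" + "".join(rng.choice(aas, 50)), 0.5, k)
            a, b = synthdata.mutate_cds_family(anc, 2, n_attempts=5,
                                               nonsyn_accept=0.5, seed=100 + k)
            single_hit_only = all(
                sum(x != y for x, y in zip(a[i:i + 3], b[i:i + 3])) <= 1
                for i in range(0, len(a), 3)
            )
            if not single_hit_only:
                continue
            res = evostats.ng86_pair(a, b)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            assert res.ka == pytest.approx(dn, abs=1e-9)
            assert res.ks == pytest.approx(ds, abs=1e-9)
            n_compared += 1
        assert n_compared >= 10

    def test_symmetry(self):
        a = "ATGAAATTTGGGCCC"
        b = "ATGAAGTTAGGCCCC"
        r1, r2 = evostats.ng86_pair(a, b), evostats.ng86_pair(b, a)
        assert r1 == r2

    def test_length_mismatch_and_internal_stop(self):
        with pytest.raises(ValueError, match="length"):
            evostats.ng86_pair("ATG", "ATGATG")
        with pytest.raises(ValueError, match="stop"):
            evostats.ng86_pair("ATGTAAAAA", "ATGAAAAAA")

    def test_monotone_in_planted_synonymous_changes(self):
        """Ks grows as more synonymous substitutions are planted."""
        base = "AAA" * 30
        last = -1.0
        for k in range(0, 8):
            variant = "AAG" * k + "AAA" * (30 - k)
            res = evostats.ng86_pair(base, variant)
            assert res.ks > last
            last = res.ks


class TestSubcladeSummary:
    def test_identical_members_all_undefined(self):
        members = [("a", "ATGAAA"), ("b", "ATGAAA"), ("c", "ATGAAA")]
        s = evostats.subclade_kaks_summary(members, "x")
        assert s.n_defined_pairs == 0 and s.avg_ratio is None
        assert s.n_pairs == 3

    def test_purifying_family_below_one(self):
        anc = synthdata.reverse_translate("M" + "DERPANT" * 20, 0.5, 42)
        fam = synthdata.mutate_cds_family(anc, 8, n_attempts=80,
                                          nonsyn_accept=0.2, seed=11)
        s = evostats.subclade_kaks_summary([(f"m{i}", c) for i, c in enumerate(fam)], "pur")
        assert s.avg_ratio is not None and s.avg_ratio < 1
        assert s.min_ratio <= s.avg_ratio <= s.max_ratio

    def test_diversifying_family_above_one(self):
        anc = synthdata.reverse_translate("M" + "DERPANT" * 20, 0.5, 42)
        fam = synthdata.mutate_cds_family(anc, 8, n_attempts=80,
                                          syn_accept=1 / 3, nonsyn_accept=1.0, seed=12)
        s = evostats.subclade_kaks_summary([(f"m{i}", c) for i, c in enumerate(fam)], "div")
        assert s.avg_ratio is not None and s.avg_ratio > 1

    def test_too_few_members(self):
        with pytest.raises(ValueError):
            evostats.subclade_kaks_summary([("a", "ATG")], "x")


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("AT", 0.0)])
    def test_basic(self, seq, expected):
        assert evostats.gc_content(seq) == expected

    def test_ambiguity_codes_excluded(self):
        assert evostats.gc_content("GCNN") == 1.0

    def test_reverse_complement_invariant(self):
        from ntnl_forge.seqio import reverse_complement
        seq = "ATGCGTTACGGA"
        assert evostats.gc_content(seq) == evostats.gc_content(reverse_complement(seq))

    def test_generator_recovery(self):
        """reverse_translate at gc target 0.7 lands within 0.05 at >= 1 kb."""
        rng = np.random.default_rng(5)
        protein = "".join(rng.choice(list(synthdata.SAFE_AA + "L"), 400))
        cds = synthdata.reverse_translate(protein, 0.7, 9)
        assert len(cds) >= 1000
        assert abs(evostats.gc_content(cds) - 0.7) <= 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evostats.gc_content("")


class TestExonStats:
    def test_simple_group(self):
        stats = evostats.exon_stats({"CNL": [3, 5, 10]})
        assert stats["CNL"] == (10, 3, 6.0)

    def test_empty_group_zero_convention(self):
        assert evostats.exon_stats({"CNL-A": []})["CNL-A"] == (0, 0, 0.0)

    def test_planned_exon_counts_recovered(self, default_bundle):
        truth = default_bundle.truth_by_id()
        plans = {p.gene_id: p for p in default_bundle.spec.gene_plan}
        groups: dict[str, list[int]] = {}
        for g in default_bundle.genes:
            if truth[g.gene_id].expected_keep:
                groups.setdefault(truth[g.gene_id].expected_subgroup_label, []).append(
                    g.n_exons
                )
                assert g.n_exons == plans[g.gene_id].n_exons
        stats = evostats.exon_stats(groups)
        for label, counts in groups.items():
            mx, mn, avg = stats[label]
            assert (mx, mn) == (max(counts), min(counts))
            # reported average is the true mean rounded half-up to 1 decimal
            assert avg == pytest.approx(sum(counts) / len(counts), abs=0.05000001)


class TestSummarizeExpression:
    def _matrix(self, data, groups):
        return ExpressionMatrix(values=pd.DataFrame(data), replicate_groups=groups)

    def test_replicate_averaging_then_log2(self):
        em = self._matrix(
            {"s1": [3.0], "s2": [5.0]}, {"s1": "c1", "s2": "c1"}
        )
        df = evostats.summarize_expression(em)
        assert df.loc[0, "c1"] == pytest.approx(math.log2(5.0), abs=1e-9)

    def test_degenerate_all_equal_is_all_mid(self):
        em = self._matrix(
            {"s1": [2.0, 2.0, 2.0], "s2": [2.0, 2.0, 2.0]},
            {"s1": "c1", "s2": "c2"},
        )
        df = evostats.summarize_expression(em)
        assert set(df["category"]) == {"mid"}

    def test_unknown_sample_rejected(self):
        em = ExpressionMatrix(
            values=pd.DataFrame({"s1": [1.0]}), replicate_groups={"s1": "c1"}
        )
        em.values["s2"] = [2.0]  # sneak in an unmapped sample
        with pytest.raises(KeyError):
            evostats.summarize_expression(em)

    def test_planted_high_genes_recovered(self, default_bundle):
        df = evostats.summarize_expression(default_bundle.expression)
        high = set(default_bundle.spec.expression_plan.high_gene_ids)
        called = set(df.index[df["category"] == "high"])
        assert len(high & called) / len(high) >= 0.95
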