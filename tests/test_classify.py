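"""Identification criteria, subgroup labelling and clade tabulation."""

from itertools import product

import pytest

from ntnl_forge import classify, motifscan
from ntnl_forge.motifscan import MotifHit


def hits_for(*motifs, order=("PLOOP", "KINASE2", "GLPL")):
    """Minimal hit dictionary with core motifs in the given N→C order."""
    d = {m: [] for m in motifscan.SUPPORTED_MOTIFS}
    pos = {name: 10 + 30 * i for i, name in enumerate(order)}
    for m in motifs:
        start = pos.get(m, 200)
        matched = "LLVLDDVD" if m == "KINASE2" else ""
        d[m] = [MotifHit(m, start, start + 8, 1.0, matched)]
    return d


class TestIdentificationCriteria:
    def test_tir_rejected_regardless(self):
        call = classify.apply_identification_criteria(
            "g", hits_for("PLOOP", "KINASE2", "GLPL", "LRR", "TIR")
        )
        assert call.status == classify.REJECTED_TIR

    def test_no_nbarc_rejected(self):
        call = classify.apply_identification_criteria("g", hits_for("CC", "LRR"))
        assert call.status == classify.REJECTED_NO_NBARC

    def test_complete_candidate_proceeds(self):
        call = classify.apply_identification_criteria(
            "g", hits_for("CC", "PLOOP", "KINASE2", "GLPL", "LRR")
        )
        assert call.status == ""


class TestVerifyCoreMotifs:
    def test_in_order_true(self):
        assert classify.verify_core_motifs(hits_for("PLOOP", "KINASE2", "GLPL"))

    def test_missing_glpl_false(self):
        assert not classify.verify_core_motifs(hits_for("PLOOP", "KINASE2"))

    def test_out_of_order_false(self):
        hits = hits_for("PLOOP", "KINASE2", "GLPL", order=("GLPL", "KINASE2", "PLOOP"))
        assert not classify.verify_core_motifs(hits)


class TestKinase2Rule:
    @pytest.mark.parametrize(
        "matched,expected",
        [("LLVLDDVD", "nTNL_type"), ("LLVLDDVW", "TNL_type"), ("LLVLDDVA", "indeterminate")],
    )
    def test_terminal_residue_mapping(self, matched, expected):
        hit = MotifHit("KINASE2", 0, 8, 1.0, matched)
        assert classify.kinase2_rule(hit) == expected

    def test_mapping_is_configurable(self):
        hit = MotifHit("KINASE2", 0, 8, 1.0, "LLVLDDVD")
        swapped = {"D": "TNL_type", "W": "nTNL_type"}
        assert classify.kinase2_rule(hit, swapped) == "TNL_type"


class TestClassifyArchitecture:
    @pytest.mark.parametrize(
        "domains,label",
        [
            ({"NBS"}, "N"),
            ({"NBS", "LRR"}, "NL"),
            ({"CC", "NBS"}, "CN"),
            ({"CC", "NBS", "LRR"}, "CNL"),
            ({"RPW8", "CC", "NBS", "LRR"}, "RCNL"),
            ({"BED", "CC", "NBS", "LRR"}, "BCNL"),
        ],
    )
    def test_named_examples(self, domains, label):
        flags = {d: d in domains for d in ("CC", "NBS", "LRR", "RPW8", "BED", "TIR")}
        assert classify.classify_architecture(flags) == label

    def test_full_enumeration_yields_exactly_12_labels(self):
        """Over all flag combinations with NBS set and not both RPW8+BED,
        the classifier is total and covers exactly the 12 subgroups."""
        seen = set()
        for cc, lrr, rpw8, bed in product([False, True], repeat=4):
            flags = {"CC": cc, "NBS": True, "LRR": lrr, "RPW8": rpw8, "BED": bed}
            if rpw8 and bed:
                with pytest.raises(ValueError):
                    classify.classify_architecture(flags)
            else:
                seen.add(classify.classify_architecture(flags))
        assert seen == set(classify.SUBGROUP_LABELS)

    def test_nbs_required(self):
        with pytest.raises(ValueError):
            classify.classify_architecture({"NBS": False})


class TestPseudogeneFilter:
    LRR = MotifHit("LRR", 300, 327, 3.0, "")

    def test_stop_before_lrr_removed(self):
        protein = "M" + "A" * 49 + "*" + "A" * 300
        assert classify.pseudogene_filter(protein, self.LRR)

    def test_trailing_stop_kept(self):
        assert not classify.pseudogene_filter("M" + "A" * 340 + "*", self.LRR)
        assert not classify.pseudogene_filter("MAAA*", None)

    def test_clean_protein_kept(self):
        assert not classify.pseudogene_filter("M" + "A" * 340, self.LRR)

    def test_no_lrr_any_internal_stop_removed(self):
        assert classify.pseudogene_filter("MAA*AAA", None)


class TestTruthRecovery:
    def test_status_and_subgroup_match_truth(self, default_bundle):
        """Every generated gene classifies to its planted subgroup; the 12
        classes are all exercised."""
        seen = set()
        statuses = []
        for truth in default_bundle.truth:
            protein = default_bundle.proteins[truth.gene_id]
            hits = motifscan.scan_architecture(protein)
            call = classify.classify_gene(truth.gene_id, protein, hits)
            statuses.append(call.status)
            assert (call.status == classify.KEPT) == truth.expected_keep, truth.gene_id
            if truth.expected_keep:
                assert call.subgroup_label == truth.expected_subgroup_label
                seen.add(call.subgroup_label)
        assert seen == set(classify.SUBGROUP_LABELS)
        # partition: every gene gets exactly one status
        assert len(statuses) == len(default_bundle.truth)
        assert all(s in classify.STATUSES for s in statuses)

    def test_rejection_reasons_match_plan(self, default_bundle):
        truth = default_bundle.truth_by_id()
        for plan in default_bundle.spec.gene_plan:
            if truth[plan.gene_id].expected_keep:
                continue
            protein = default_bundle.proteins[plan.gene_id]
            call = classify.classify_gene(
                plan.gene_id, protein, motifscan.scan_architecture(protein)
            )
            if "TIR" in plan.architecture:
                assert call.status == classify.REJECTED_TIR
            elif plan.premature_stop_before_lrr:
                assert call.status == classify.REJECTED_PSEUDOGENE
            else:
                assert call.status == classify.REJECTED_NO_NBARC


class TestTabulateByClade:
    SPECIES = ["At", "Gm", "Mt", "Os", "Pv", "Pt"]
    CLADES = ["CNL-A", "CNL-B", "CNL-C", "CNL-D", "Unnested"]
    # published per-species, per-clade distribution of the 908 genes
    COUNTS = {
        ("At", "CNL-A"): 8, ("Gm", "CNL-A"): 14, ("Mt", "CNL-A"): 19,
        ("Os", "CNL-A"): 0, ("Pv", "CNL-A"): 1, ("Pt", "CNL-A"): 7,
        ("At", "CNL-B"): 25, ("Gm", "CNL-B"): 37, ("Mt", "CNL-B"): 22,
        ("Os", "CNL-B"): 3, ("Pv", "CNL-B"): 17, ("Pt", "CNL-B"): 61,
        ("At", "CNL-C"): 7, ("Gm", "CNL-C"): 134, ("Mt", "CNL-C"): 191,
        ("Os", "CNL-C"): 145, ("Pv", "CNL-C"): 75, ("Pt", "CNL-C"): 124,
        ("At", "CNL-D"): 12, ("Gm", "CNL-D"): 2, ("Mt", "CNL-D"): 1,
        ("Os", "CNL-D"): 0, ("Pv", "CNL-D"): 1, ("Pt", "CNL-D"): 1,
        ("Os", "Unnested"): 1,
    }

    def test_grand_total_and_row_total(self):
        table = classify.tabulate_by_clade(
            counts=self.COUNTS, species_order=self.SPECIES, clade_order=self.CLADES
        )
        assert table.loc["Total", "Total"] == 908
        assert list(table.loc["Total", self.SPECIES]) == [52, 187, 233, 149, 94, 193]
        assert table.loc["CNL-C", "Total"] == 676

    def test_empty_assignments(self):
        table = classify.tabulate_by_clade(
            assignments=[], species_order=["At"], clade_order=["CNL-A"]
        )
        assert table.values.sum() == 0

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            classify.tabulate_by_clade(
                assignments=[("Zz", "CNL-A")], species_order=["At"], clade_order=["CNL-A"]
            )
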