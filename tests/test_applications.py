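"""Downstream analyses: list mapping, percent-of-sum, isoform switches, subsetting."""

import numpy as np
import pandas as pd
import pytest

from gepa.applications import (
    classify_isoforms,
    detect_isoform_switches,
    map_external_list,
    percent_of_sum,
    subset_by_annotation,
)
from gepa.core import PatternLabel, category_counts, classify_matrix
from gepa.expression_io import ExpressionTable, GeneList, IsoformTable
from gepa.preprocess import PreprocessConfig, prepare_matrix
from gepa.synthetic import PlantSpec, generate_isoform_table, generate_matrix


@pytest.fixture(scope="module")
def classified(request):
    samples = ["ES", "MCP", "CM", "SM", "EC"]
    specs = [
        PlantSpec(PatternLabel.enriched(["MCP"]), 5, margin=4.0),
        PlantSpec(PatternLabel.enriched(["CM", "SM"]), 4, margin=4.0),
        PlantSpec(PatternLabel.even(), 3),
        PlantSpec(PatternLabel.gradient(), 2, margin=3.5),
    ]
    raw, truth = generate_matrix(specs, samples, 2.5, seed=12)
    table = prepare_matrix(raw)
    return samples, table, classify_matrix(table, 2.5), truth


class TestMapExternalList:
    def test_counting_with_unmatched(self, classified):
        samples, _, records, truth = classified
        mcp = [g for g, lab in truth.items() if lab.key == frozenset({"MCP"})][:5]
        even = [g for g, lab in truth.items() if lab.key == "Even"][:3]
        ext = GeneList(tuple(mcp + even + ["ghost1", "ghost2"]), "external")
        dist = map_external_list(records, ext, samples)
        assert dist.n_matched == 8 and dist.n_unmatched == 2
        assert dist.counts["MCP"] == 5 and dist.counts["Even"] == 3
        assert dist.percentages["MCP"] == pytest.approx(62.5)
        assert dist.percentages["Even"] == pytest.approx(37.5)
        assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=1e-9)
        assert dist.unmatched_ids == ("ghost1", "ghost2")

    def test_full_universe_matches_category_counts(self, classified):
        samples, _, records, _ = classified
        ext = GeneList(tuple(r.gene_id for r in records), "external")
        dist = map_external_list(records, ext, samples)
        cc = category_counts(records, samples)
        assert dict(dist.counts) == dict(cc.counts)

    def test_grouping_map(self, classified):
        # group every enriched category under one coarse "LEG" bar
        from gepa.core import enumerate_categories

        samples, _, records, _ = classified
        ext = GeneList(tuple(r.gene_id for r in records), "external")
        grouping = {l.canonical(): "LEG" for l in enumerate_categories(samples, False)}
        dist = map_external_list(records, ext, samples, grouping=grouping)
        assert dist.grouped["LEG"] == 9  # 5 MCP + 4 CM&SM planted enriched genes

    def test_disjoint_list_is_error(self, classified):
        _, _, records, _ = classified
        with pytest.raises(ValueError):
            map_external_list(records, GeneList(("nope",), "external"))


class TestPercentOfSum:
    def test_equal_values_give_20s(self, samples):
        df = pd.DataFrame([[5.0] * 5], index=["g"], columns=samples)
        t = ExpressionTable(df, normalized=True)
        out = percent_of_sum(t, ["g"])
        assert np.allclose(out.to_numpy(), 20.0)

    def test_values_summing_to_100_pass_through(self, samples):
        df = pd.DataFrame([[80.0, 10.0, 5.0, 3.0, 2.0]], index=["g"], columns=samples)
        t = ExpressionTable(df, normalized=True)
        out = percent_of_sum(t, ["g"])
        assert np.allclose(out.to_numpy(), [80, 10, 5, 3, 2])

    def test_rows_sum_to_100_and_scale_invariant(self, samples):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(2, 1, size=(20, 5)) + 1
        t = ExpressionTable(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(20)], columns=samples),
            normalized=True,
        )
        out = percent_of_sum(t, t.gene_ids)
        assert np.allclose(out.sum(axis=1), 100.0, atol=1e-9)
        t2 = ExpressionTable(t.data * 3.7, normalized=True)
        assert np.allclose(percent_of_sum(t2, t.gene_ids).to_numpy(), out.to_numpy())

    def test_unknown_gene_named(self, samples):
        t = ExpressionTable(
            pd.DataFrame([[1.0] * 5], index=["g"], columns=samples), normalized=True
        )
        with pytest.raises(ValueError, match="mystery"):
            percent_of_sum(t, ["mystery"])


class TestClassifyIsoforms:
    def test_planted_isoform_categories_recovered(self, samples):
        plans = {
            "FGFR1like": [
                PatternLabel.enriched(["ES", "MCP"]),
                PatternLabel.enriched(["CM", "SM", "EC"]),
            ],
            "flatgene": [PatternLabel.even(), PatternLabel.even()],
            "single": [PatternLabel.enriched(["EC"])],
        }
        iso, truth, gene_of = generate_isoform_table(plans, samples, 2.5, seed=3)
        cls = classify_isoforms(iso, PreprocessConfig(), 2.5)
        got = {r.gene_id: r.label for r in cls.records}
        for iso_id, lab in truth.items():
            assert got[iso_id].key == lab.key, iso_id
        # LOWDATA isoforms never reach classification
        assert not any("lowdata" in i for i in got)

    def test_single_isoform_matches_gene_level(self, samples):
        # when one isoform carries all of a gene's signal, isoform-level and
        # gene-level classification agree
        plans = {
            "soloA": [PatternLabel.enriched(["CM"])],
            "soloB": [PatternLabel.gradient()],
            "soloC": [PatternLabel.even()],
        }
        iso, truth, _ = generate_isoform_table(plans, samples, 2.5, seed=8, n_lowdata=0)
        iso_records = {r.gene_id: r.label for r in classify_isoforms(iso, threshold=2.5).records}
        from gepa.preprocess import aggregate_isoforms
        gene_table = prepare_matrix(aggregate_isoforms(iso))
        gene_records = {r.gene_id: r.label for r in classify_matrix(gene_table, 2.5)}
        for iso_id, gene_id in (("soloA.iso1", "soloA"), ("soloB.iso1", "soloB"), ("soloC.iso1", "soloC")):
            assert iso_records[iso_id].key == gene_records[gene_id].key

    def test_all_zero_isoform_removed(self, samples):
        rows = [("i1", "G", s, 10.0, "OK") for s in samples]
        rows += [("i2", "G", s, 0.0, "OK") for s in samples]
        rows += [("i3", "H", s, v, "OK") for s, v in zip(samples, [50, 5, 5, 5, 5])]
        iso = IsoformTable(pd.DataFrame(rows, columns=["isoform_id", "gene_id", "sample_id", "fpkm", "status"]))
        cls = classify_isoforms(iso)
        assert {r.gene_id for r in cls.records} == {"i1", "i3"}


class TestIsoformSwitches:
    def _records(self, labels):
        from gepa.core import ClassificationRecord

        return {
            gene: [
                ClassificationRecord(f"{gene}.iso{i}", lab, 3.0, ("A", "B"))
                for i, lab in enumerate(labels_)
            ]
            for gene, labels_ in labels.items()
        }

    def test_discordant_enriched_pair_is_switch(self):
        groups = self._records(
            {"G": [PatternLabel.enriched(["A", "B"]), PatternLabel.enriched(["C"])]}
        )
        calls = detect_isoform_switches(groups)
        assert calls[0].switch_flag and "vs" in calls[0].reason

    @pytest.mark.parametrize(
        "labels, reason",
        [
            ([PatternLabel.even(), PatternLabel.even()], "concordant"),
            ([PatternLabel.gradient(), PatternLabel.even()], "no_enriched_label"),
            ([PatternLabel.enriched(["A"])], "single_isoform"),
        ],
    )
    def test_non_switch_cases(self, labels, reason):
        calls = detect_isoform_switches(self._records({"G": labels}))
        assert not calls[0].switch_flag and calls[0].reason == reason

    def test_enriched_vs_sentinel_is_switch(self):
        calls = detect_isoform_switches(
            self._records({"G": [PatternLabel.enriched(["A"]), PatternLabel.even()]})
        )
        assert calls[0].switch_flag

    def test_symmetric_in_isoform_order(self):
        labs = [PatternLabel.enriched(["A"]), PatternLabel.even(), PatternLabel.gradient()]
        fwd = detect_isoform_switches(self._records({"G": labs}))
        rev = detect_isoform_switches(self._records({"G": labs[::-1]}))
        assert fwd[0].switch_flag == rev[0].switch_flag

    def test_fgfr1_like_fixture_flags_exactly_one_gene(self, samples):
        plans = {
            "FGFR1like": [
                PatternLabel.enriched(["ES", "MCP"]),
                PatternLabel.enriched(["CM", "SM", "EC"]),
            ],
            "steady": [PatternLabel.even(), PatternLabel.even()],
        }
        iso, _, _ = generate_isoform_table(plans, samples, 2.5, seed=21)
        cls = classify_isoforms(iso, threshold=2.5)
        calls = detect_isoform_switches(cls.by_gene())
        flagged = {c.gene_id for c in calls if c.switch_flag}
        assert flagged == {"FGFR1like"}


class TestSubsetByAnnotation:
    def test_restriction_and_distribution(self, classified):
        samples, _, records, truth = classified
        cm_sm = [g for g, lab in truth.items() if lab.key == frozenset({"CM", "SM"})][:1]
        even = [g for g, lab in truth.items() if lab.key == "Even"][:1]
        annot = GeneList(tuple(cm_sm + even), "annotation")
        sub, dist = subset_by_annotation(records, annot, samples)
        assert len(sub) == 2
        assert dist.percentages["CM&SM"] == pytest.approx(50.0)
        assert dist.percentages["Even"] == pytest.approx(50.0)

    def test_full_annotation_is_identity(self, classified):
        samples, _, records, _ = classified
        annot = GeneList(tuple(r.gene_id for r in records), "annotation")
        sub, _ = subset_by_annotation(records, annot, samples)
        assert sub == list(records)

    def test_disjoint_annotation_is_error(self, classified):
        _, _, records, _ = classified
        with pytest.raises(ValueError):
            subset_by_annotation(records, GeneList(("none",), "annotation"))
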