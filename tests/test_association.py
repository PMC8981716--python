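"""Consequence grouping, outlier-variant association and gene-class enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnadx import (
    GeneAnnotation,
    VariantTable,
    assign_consequence_group,
    gene_class_enrichment,
    outlier_variant_association,
    potential_ptv_flag,
)


class TestConsequenceGroups:
    @pytest.mark.parametrize("term,group", [
        ("stop gained", "stop"),
        ("5 prime UTR", "UTR"),
        ("stop retained", "synonymous"),
        ("splice donor", "splice"),
        ("frameshift", "frameshift"),
        ("intron", "non-coding"),
        ("missense", "coding"),
        ("start lost", "UTR"),
    ])
    def test_printed_mapping(self, term, group):
        assert assign_consequence_group(term) == group

    def test_unknown_term_errors(self):
        with pytest.raises(KeyError, match="exotic"):
            assign_consequence_group("exotic")

    def test_multi_consequence_takes_highest_impact(self):
        assert assign_consequence_group(["synonymous", "stop gained"]) == "stop"
        assert assign_consequence_group(["intron", "splice region"]) == "splice"


def _variants(rows):
    return VariantTable(pd.DataFrame(
        rows, columns=["sample", "chromosome", "position", "ref", "alt", "genotype",
                       "consequence", "maf_population", "maf_cohort", "qd", "fs",
                       "alt_reads", "gene_id"]))


def _var_row(sample, gene, consequence, pos=100):
    return (sample, "chr1", pos, "A", "G", "het", consequence, 1e-4, 1e-3, 10.0, 1.0, 10, gene)


class TestAssociation:
    def test_fisher_matches_hypergeometric_oracle(self):
        table = np.array([[8, 2], [10, 180]])
        p_impl = stats.fisher_exact(table)[1]
        # enumeration over the hypergeometric support
        n_draw = table[0].sum()
        K = table[:, 0].sum()
        N = table.sum()
        probs = stats.hypergeom.pmf(np.arange(0, min(n_draw, K) + 1), N, K, n_draw)
        p_obs = stats.hypergeom.pmf(table[0, 0], N, K, n_draw)
        expected = probs[probs <= p_obs * (1 + 1e-12)].sum()
        assert p_impl == pytest.approx(expected, rel=1e-9)

    def test_planted_stop_association_recovered(self):
        """Stop variants planted to cause most underexpression outliers come
        out as the lowest-p, highest-proportion group for that class."""
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(30)]
        genes = [f"G{i}" for i in range(40)]
        calls, var_rows = [], []
        pos = 100
        for s in samples:
            out_genes = rng.choice(genes, 4, replace=False)
            for i, g in enumerate(out_genes):
                calls.append((s, g, "underexpression"))
                pos += 1
                if i < 3:  # 75% of outliers carry a stop variant
                    var_rows.append(_var_row(s, g, "stop gained", pos))
            for g in rng.choice(list(set(genes) - set(out_genes)), 3, replace=False):
                pos += 1
                var_rows.append(_var_row(s, g, rng.choice(["synonymous", "intron"]), pos))
        calls = pd.DataFrame(calls, columns=["sample", "gene", "class"])
        props, excluded = outlier_variant_association(calls, _variants(var_rows))
        assert not excluded
        under = props[props["class"] == "underexpression"].set_index("group")
        assert under["fisher_p"].idxmin() == "stop"
        assert under["proportion"].idxmax() == "stop"
        assert under.loc["stop", "ci_low"] < under.loc["stop", "proportion"] < under.loc["stop", "ci_high"]

    def test_null_association_flat(self):
        """Identical variant rates across classes: no group stands out at
        stringent significance."""
        rng = np.random.default_rng(2)
        samples = [f"S{i}" for i in range(20)]
        genes = [f"G{i}" for i in range(30)]
        calls, var_rows = [], []
        pos = 0
        for s in samples:
            for g in rng.choice(genes, 3, replace=False):
                calls.append((s, g, "underexpression"))
            for g in rng.choice(genes, 5, replace=False):
                pos += 1
                var_rows.append(_var_row(s, g, rng.choice(["stop gained", "synonymous"]), pos))
        calls = pd.DataFrame(calls, columns=["sample", "gene", "class"])
        props, _ = outlier_variant_association(calls, _variants(var_rows))
        assert (props["fisher_p"] > 1e-3).all()

    def test_sample_exclusion_rule(self):
        calls = pd.DataFrame(
            [("S_hot", f"G{i}", "underexpression") for i in range(25)]
            + [("S_ok", "G0", "underexpression")],
            columns=["sample", "gene", "class"])
        variants = _variants([_var_row("S_ok", "G0", "stop gained")])
        props, excluded = outlier_variant_association(calls, variants,
                                                      max_outliers_per_sample=20)
        assert excluded == ["S_hot"]

    def test_proportions_sum_below_one(self):
        calls = pd.DataFrame([("S1", "G1", "underexpression"),
                              ("S1", "G2", "underexpression")],
                             columns=["sample", "gene", "class"])
        variants = _variants([_var_row("S1", "G1", "stop gained")])
        props, _ = outlier_variant_association(calls, variants)
        assert props.groupby("class")["proportion"].sum().le(1 + 1e-12).all()


class TestEnrichment:
    @staticmethod
    def _annotation(n_genes, list_genes):
        return GeneAnnotation(
            pd.DataFrame({
                "chromosome": "chr1", "start": 1, "end": 10,
                "gene_length": 1000, "n_exons": 5,
            }, index=pd.Index([f"G{i}" for i in range(n_genes)], name="gene_id")),
            gene_lists={"mito": set(list_genes)})

    def test_null_odds_ratio_near_one(self):
        """Category with the background outlier rate: OR CI covers 1 in most
        replicates."""
        rng = np.random.default_rng(3)
        ann = self._annotation(60, [f"G{i}" for i in range(20)])
        covered = 0
        n_rep = 50
        for _ in range(n_rep):
            calls = []
            for s in range(15):
                for g in rng.choice(60, 6, replace=False):
                    calls.append((f"S{s}", f"G{g}", "underexpression"))
            calls = pd.DataFrame(calls, columns=["sample", "gene", "class"])
            out = gene_class_enrichment(calls, ann,
                                        sample_ids=[f"S{s}" for s in range(15)])
            row = out.iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered / n_rep >= 0.9

    def test_planted_threefold_enrichment_recovered(self):
        rng = np.random.default_rng(4)
        members = [f"G{i}" for i in range(50)]
        ann = self._annotation(200, members)
        calls = []
        for s in range(60):
            for g in range(200):
                rate = 0.09 if g < 50 else 0.03
                if rng.random() < rate:
                    calls.append((f"S{s}", f"G{g}", "underexpression"))
        calls = pd.DataFrame(calls, columns=["sample", "gene", "class"])
        out = gene_class_enrichment(calls, ann,
                                    sample_ids=[f"S{s}" for s in range(60)])
        row = out.iloc[0]
        # odds ratio of ~3.2 at these rates; CI must cover the truth
        true_or = (0.09 / 0.91) / (0.03 / 0.97)
        assert row["ci_low"] < true_or < row["ci_high"]
        assert row["odds_ratio"] == pytest.approx(true_or, rel=0.35)

    def test_separation_fallback_flagged(self):
        ann = self._annotation(10, ["G0", "G1"])
        calls = pd.DataFrame([("S1", "G5", "underexpression")],
                             columns=["sample", "gene", "class"])
        out = gene_class_enrichment(calls, ann, sample_ids=["S1"])
        assert out.iloc[0]["flag"] == "separation-fallback"


class TestPotentialPTV:
    def _setup(self, consequence, exon_index, expressed):
        ann = GeneAnnotation(pd.DataFrame(
            {"chromosome": ["chr1"], "start": [1], "end": [10],
             "gene_length": [1000], "n_exons": [10]},
            index=pd.Index(["G1"], name="gene_id")))
        vt = VariantTable(pd.DataFrame({
            "sample": ["S1"], "chromosome": ["chr1"], "position": [100],
            "ref": ["A"], "alt": ["G"], "genotype": ["het"],
            "consequence": [consequence], "maf_population": [1e-4],
            "maf_cohort": [1e-3], "qd": [10.0], "fs": [1.0], "alt_reads": [10],
            "gene_id": ["G1"], "exon_index": [exon_index],
        }))
        return vt, ann, {("chr1", 100): expressed}

    def test_stop_in_last_exon_false(self):
        vt, ann, mask = self._setup("stop gained", 10, True)
        assert not potential_ptv_flag(vt, ann, mask)[0]

    def test_frameshift_expressed_mid_gene_true(self):
        vt, ann, mask = self._setup("frameshift", 3, True)
        assert potential_ptv_flag(vt, ann, mask)[0]

    def test_unexpressed_position_false(self):
        vt, ann, mask = self._setup("stop gained", 3, False)
        assert not potential_ptv_flag(vt, ann, mask)[0]
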