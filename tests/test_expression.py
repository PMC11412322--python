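"""TPM summaries, ranks, and dominant-paralog calls."""

import math

import pandas as pd
import pytest

from detoxrep.io import ExpressionMatrix
from detoxrep.expression import dominant_paralog, summarize_expression, top_ranked


def matrix(values: dict[str, dict[str, float]]) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    df.index.name = "gene_id"
    return ExpressionMatrix(
        tpm=df.astype(float),
        replicate_species={c: c.split("|")[0] for c in df.columns},
    )


def repertoire(rows):
    return pd.DataFrame(rows, columns=["gene_id", "species", "family"])


REPS = ["spA|r1", "spA|r2", "spA|r3"]


class TestSummarize:
    def test_mean_and_log(self):
        m = matrix({"g1": dict(zip(REPS, [10, 20, 30]))})
        s = summarize_expression(m, repertoire([("g1", "spA", "CYP")]))
        row = s.row("g1")
        assert row.mean_tpm == pytest.approx(20.0)
        assert row.log10_mean == pytest.approx(math.log10(21), abs=1e-9)

    def test_all_zero_gene_hits_pseudocount_floor(self):
        m = matrix({"g1": dict(zip(REPS, [0, 0, 0]))})
        s = summarize_expression(m, repertoire([("g1", "spA", "CYP")]))
        assert s.row("g1").log10_mean == 0.0

    def test_missing_gene_warns_and_is_zero(self):
        m = matrix({"g1": dict(zip(REPS, [5, 5, 5]))})
        with pytest.warns(UserWarning, match="g2"):
            s = summarize_expression(m, repertoire([("g1", "spA", "CYP"),
                                                    ("g2", "spA", "CYP")]))
        assert s.row("g2").mean_tpm == 0.0

    def test_ties_ranked_by_id_and_flagged(self):
        m = matrix({"gB": dict(zip(REPS, [5, 5, 5])), "gA": dict(zip(REPS, [5, 5, 5]))})
        s = summarize_expression(m, repertoire([("gB", "spA", "CYP"),
                                                ("gA", "spA", "CYP")]))
        assert s.row("gA")["rank"] == 1 and s.row("gB")["rank"] == 2
        assert bool(s.row("gA").tied)

    def test_pseudocount_must_be_positive(self):
        m = matrix({"g1": dict(zip(REPS, [1, 1, 1]))})
        with pytest.raises(ValueError):
            summarize_expression(m, repertoire([("g1", "spA", "CYP")]), pseudocount=0)


class TestDominance:
    def two_gene_summary(self, hi, lo):
        m = matrix({"g1": dict(zip(REPS, [hi] * 3)), "g2": dict(zip(REPS, [lo] * 3))})
        return summarize_expression(
            m, repertoire([("g1", "spA", "CYP"), ("g2", "spA", "CYP")])
        )

    def test_dominant_pair(self):
        d = dominant_paralog(self.two_gene_summary(1000, 5), "g1", "g2")
        assert d["fold"] == pytest.approx(200.0) and d["is_dominant"]

    def test_small_fold_not_dominant(self):
        d = dominant_paralog(self.two_gene_summary(50, 40), "g1", "g2")
        assert d["fold"] == pytest.approx(1.25) and not d["is_dominant"]

    def test_zero_competitor_floored(self):
        d = dominant_paralog(self.two_gene_summary(100, 0), "g1", "g2")
        assert d["denominator_floored"] and d["fold"] >= 1e6

    def test_cross_species_rejected(self):
        m = matrix(
            {
                "g1": {"spA|r1": 10.0, "spB|r1": 0.0},
                "g2": {"spA|r1": 0.0, "spB|r1": 10.0},
            }
        )
        s = summarize_expression(
            m, repertoire([("g1", "spA", "CYP"), ("g2", "spB", "CYP")])
        )
        with pytest.raises(ValueError, match="within-species"):
            dominant_paralog(s, "g1", "g2")


class TestTopRanked:
    def summary(self):
        m = matrix(
            {
                "g1": dict(zip(REPS, [100] * 3)),
                "g2": dict(zip(REPS, [10] * 3)),
                "g3": dict(zip(REPS, [1] * 3)),
            }
        )
        return summarize_expression(
            m, repertoire([(g, "spA", "CYP") for g in ("g1", "g2", "g3")])
        )

    def test_order_and_truncation(self):
        s = self.summary()
        assert top_ranked(s, "CYP", "spA", 2) == ["g1", "g2"]
        assert top_ranked(s, "CYP", "spA", 10) == ["g1", "g2", "g3"]

    def test_k1_matches_rank1(self):
        s = self.summary()
        assert top_ranked(s, "CYP", "spA", 1) == ["g1"]

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            top_ranked(self.summary(), "GST", "spA", 1)


class TestInvariances:
    def test_scale_equivariance(self):
        vals = {"g1": dict(zip(REPS, [3, 6, 9])), "g2": dict(zip(REPS, [30, 60, 90]))}
        rep = repertoire([("g1", "spA", "CYP"), ("g2", "spA", "CYP")])
        s1 = summarize_expression(matrix(vals), rep)
        scaled = {g: {r: 7.5 * v for r, v in d.items()} for g, d in vals.items()}
        s2 = summarize_expression(matrix(scaled), rep)
        assert list(s1.table["rank"]) == list(s2.table["rank"])
        f1 = dominant_paralog(s1, "g2", "g1")["fold"]
        f2 = dominant_paralog(s2, "g2", "g1")["fold"]
        assert f1 == pytest.approx(f2)

    def test_ranks_invariant_to_pseudocount(self):
        vals = {"g1": dict(zip(REPS, [3, 6, 9])), "g2": dict(zip(REPS, [30, 60, 90]))}
        rep = repertoire([("g1", "spA", "CYP"), ("g2", "spA", "CYP")])
        r1 = summarize_expression(matrix(vals), rep, pseudocount=1).table
        r2 = summarize_expression(matrix(vals), rep, pseudocount=0.01).table
        assert list(r1.gene_id) == list(r2.gene_id)
        assert list(r1["rank"]) == list(r2["rank"])
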