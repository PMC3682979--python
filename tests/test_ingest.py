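"""Readers, preprocessing and presence calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from devotf import ingest
from devotf.containers import (
    OrthologMap,
    ParseError,
    PresenceTable,
    ProbeTable,
    TimeAlignment,
)


# ---------------------------------------------------------------------------
# TF assignment files
# ---------------------------------------------------------------------------

class TestTFAssignments:
    def test_multi_domain_genes_accumulate_families(self, tmp_path):
        f = tmp_path / "x.tf.ass"
        f.write_text("g1\tHomeobox\ng1\tzf-C2H2\ng2\tbZIP\n")
        cat = ingest.read_tf_assignments(f)
        assert cat.assignments == {
            "g1": frozenset({"Homeobox", "zf-C2H2"}),
            "g2": frozenset({"bZIP"}),
        }

    def test_comment_only_file_is_an_error(self, tmp_path):
        f = tmp_path / "x.tf.ass"
        f.write_text("# nothing here\n# still nothing\n")
        with pytest.raises(ParseError, match="no assignments"):
            ingest.read_tf_assignments(f)

    def test_duplicate_rows_collapse_by_set_semantics(self, tmp_path):
        rows = [(f"g{i}", fam) for i in range(10) for fam in ("Homeobox", "Ets")][:17]
        rows += rows[:3]  # three duplicated (gene, family) rows
        assert len(rows) == 20
        f = tmp_path / "x.tf.ass"
        f.write_text("".join(f"{g}\t{fam}\n" for g, fam in rows))
        cat = ingest.read_tf_assignments(f)
        n_assignments = sum(len(v) for v in cat.assignments.values())
        assert n_assignments == 17

    def test_malformed_row_names_line_number(self, tmp_path):
        f = tmp_path / "x.tf.ass"
        f.write_text("g1\tHomeobox\ng2 only one field\n")
        with pytest.raises(ParseError, match=":2"):
            ingest.read_tf_assignments(f)

    def test_roundtrip(self, tmp_path, small_pair):
        path = tmp_path / "a.tf.ass"
        ingest.write_tf_assignments(small_pair.a.catalog, path)
        back = ingest.read_tf_assignments(path, small_pair.a.catalog.species)
        assert back.assignments == small_pair.a.catalog.assignments


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        x = np.array([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        assert np.allclose(ingest.quantile_normalize(x), x)

    def test_two_by_two_rank_means(self):
        # columns [1,3] and [2,4]: rank-wise means make both columns [1.5, 3.5]
        out = ingest.quantile_normalize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_ties_get_the_mean_over_their_rank_span(self):
        x = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = ingest.quantile_normalize(x)
        ref = np.sort(x, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert np.allclose(out[:, 0], [(ref[0] + ref[1]) / 2] * 2 + [ref[2]])
        assert np.allclose(np.sort(out[:, 1]), ref)

    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(3, 20), st.integers(2, 5)),
            elements=st.floats(-50, 50, allow_nan=False),
            unique=True,
        )
    )
    def test_postcondition_sorted_columns_identical(self, x):
        out = ingest.quantile_normalize(x)
        ref = np.sort(x, axis=0).mean(axis=1)
        assert np.abs(np.sort(out, axis=0) - ref[:, None]).max() < 1e-9

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ingest.quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# probe collapse and presence calling
# ---------------------------------------------------------------------------

def _probe_table(values, probe_to_gene, n_reps, time_labels):
    cols = [f"T{t}_r{r + 1}" for t in time_labels for r in range(n_reps)]
    df = pd.DataFrame(values, index=list(probe_to_gene), columns=cols)
    info = {c: (c[1 : c.rfind("_r")], int(c[c.rfind("_r") + 2 :])) for c in cols}
    return ProbeTable(df, dict(probe_to_gene), info)


class TestCollapseProbes:
    def test_two_probes_average(self):
        t = _probe_table([[2.0], [4.0]], {"p1": "g1", "p2": "g1"}, 1, ["0"])
        x = ingest.collapse_probes(t)
        assert x.values.loc["g1", "0"] == pytest.approx(3.0)

    def test_replicates_average(self):
        t = _probe_table([[5.0, 7.0]], {"p1": "g1"}, 2, ["0"])
        assert ingest.collapse_probes(t).values.loc["g1", "0"] == pytest.approx(6.0)

    def test_matches_brute_force_mean(self, rng):
        vals = rng.normal(size=(3, 4))  # 3 probes x (2 times x 2 reps)
        t = _probe_table(vals, {"p1": "g1", "p2": "g1", "p3": "g1"}, 2, ["0", "6"])
        x = ingest.collapse_probes(t)
        assert x.values.loc["g1", "0"] == pytest.approx(vals[:, :2].mean())
        assert x.values.loc["g1", "6"] == pytest.approx(vals[:, 2:].mean())

    def test_commutes_with_probe_permutation(self, rng):
        vals = rng.normal(size=(5, 6))
        mapping = {f"p{i}": f"g{i % 2}" for i in range(5)}
        t = _probe_table(vals, mapping, 2, ["0", "6", "12"])
        perm = rng.permutation(5)
        t2 = _probe_table(
            vals[perm], {f"q{i}": mapping[f"p{j}"] for i, j in enumerate(perm)}, 2,
            ["0", "6", "12"],
        )
        a, b = ingest.collapse_probes(t), ingest.collapse_probes(t2)
        assert np.allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_unmapped_probes_dropped_and_counted(self):
        t = _probe_table([[1.0], [9.0]], {"p1": "g1", "p2": "-"}, 1, ["0"])
        t.probe_to_gene = {"p1": "g1"}
        x = ingest.collapse_probes(t)
        assert list(x.genes) == ["g1"]
        assert x.meta["n_unmapped_probes_dropped"] == 1


class TestPresenceCalls:
    def test_all_probes_all_replicates_flagged_means_present(self):
        t = _probe_table(np.ones((2, 2)), {"p1": "g1", "p2": "g1"}, 2, ["0"])
        p = ingest.call_presence_flags(t)
        assert bool(p.values.loc["g1", "0"]) is True

    def test_single_false_flag_means_absent(self):
        vals = np.ones((2, 2))
        vals[1, 1] = 0.0
        t = _probe_table(vals, {"p1": "g1", "p2": "g1"}, 2, ["0"])
        assert bool(ingest.call_presence_flags(t).values.loc["g1", "0"]) is False

    def test_matches_brute_force_conjunction(self, rng):
        # property over 100 random flag tables
        for _ in range(100):
            flags = rng.random((5, 6)) > 0.3
            mapping = {f"p{i}": f"g{i % 2}" for i in range(5)}
            t = _probe_table(flags.astype(float), mapping, 2, ["0", "6", "12"])
            p = ingest.call_presence_flags(t)
            for g in ("g0", "g1"):
                probes = [i for i in range(5) if mapping[f"p{i}"] == g]
                for ti, tl in enumerate(["0", "6", "12"]):
                    expected = flags[np.ix_(probes, [2 * ti, 2 * ti + 1])].all()
                    assert bool(p.values.loc[g, tl]) == expected

    @pytest.mark.parametrize(
        "fpkm,present", [(1.0, False), (1.0001, True), (0.0, False), (50.0, True)]
    )
    def test_fpkm_threshold_is_strict(self, fpkm, present):
        df = pd.DataFrame({"0": [fpkm]}, index=["g1"])
        p = ingest.call_presence_fpkm(df)
        assert bool(p.values.loc["g1", "0"]) is present


class TestLogTransform:
    def test_arithmetic(self):
        df = pd.DataFrame({"0": [1.0, 0.0]}, index=["g1", "g2"])
        x = ingest.log_transform_fpkm(df, pseudocount=0.01)
        assert x.values.loc["g1", "0"] == pytest.approx(np.log2(1.01))
        assert x.values.loc["g2", "0"] == pytest.approx(np.log2(0.01))
        assert x.meta["pseudocount"] == 0.01

    def test_pseudocount_must_be_positive(self):
        df = pd.DataFrame({"0": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="pseudocount"):
            ingest.log_transform_fpkm(df, pseudocount=0.0)

    def test_negative_fpkm_rejected(self):
        df = pd.DataFrame({"0": [-1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="non-negative"):
            ingest.log_transform_fpkm(df)

    def test_monotone(self, rng):
        a = np.sort(rng.uniform(0, 100, size=20))
        df = pd.DataFrame({"0": a}, index=[f"g{i}" for i in range(20)])
        out = ingest.log_transform_fpkm(df).values["0"].to_numpy()
        assert (np.diff(out) > 0).all()


# ---------------------------------------------------------------------------
# tables round-trip and schema errors
# ---------------------------------------------------------------------------

class TestTableIO:
    def test_expression_roundtrip(self, tmp_path, small_pair):
        path = tmp_path / "a.expr.tsv"
        ingest.write_expression_table(small_pair.a.expression, path)
        back = ingest.read_expression_table(path, small_pair.a.expression.species)
        assert back.genes == small_pair.a.expression.genes
        assert back.time_points == small_pair.a.expression.time_points
        assert np.allclose(
            back.values.to_numpy(),
            small_pair.a.expression.values.to_numpy(),
            atol=1e-4,
        )

    def test_presence_roundtrip(self, tmp_path, small_pair):
        path = tmp_path / "a.presence.tsv"
        ingest.write_presence_table(small_pair.a.presence, path)
        back = ingest.read_presence_table(path)
        assert (back.values.to_numpy() == small_pair.a.presence.values.to_numpy()).all()

    def test_ortholog_roundtrip_and_dedup(self, tmp_path):
        path = tmp_path / "om.tsv"
        path.write_text("a1\tb1\na2\tb2\na1\tb1\n")
        om = ingest.read_ortholog_table(path)
        assert om.pairs == [("a1", "b1"), ("a2", "b2")]
        assert om.n_duplicates_dropped == 1
        out = tmp_path / "om2.tsv"
        ingest.write_ortholog_table(om, out)
        assert ingest.read_ortholog_table(out).pairs == om.pairs

    def test_alignment_roundtrip(self, tmp_path, small_pair):
        path = tmp_path / "al.tsv"
        ingest.write_alignment(small_pair.alignment, path)
        back = ingest.read_alignment(path)
        assert back.label_pairs == small_pair.alignment.label_pairs

    def test_non_monotone_alignment_rejected_at_read(self, tmp_path):
        path = tmp_path / "al.tsv"
        path.write_text("1\t2\n3\t1\n")
        with pytest.raises(ParseError, match="increasing"):
            ingest.read_alignment(path)

    def test_non_numeric_expression_value_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\t0\t6\ng1\t1.5\toops\n")
        with pytest.raises(ParseError, match="non-numeric"):
            ingest.read_expression_table(path)

    def test_presence_entries_must_be_binary(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\t0\ng1\t2\n")
        with pytest.raises(ParseError, match="0 or 1"):
            ingest.read_presence_table(path)
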