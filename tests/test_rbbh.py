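"""Hit-table parsing, RBBH extraction and the co-assembly diagnostics."""

import io

import numpy as np
import pandas as pd
import pytest

from orthoexpress import (
    classify_pairs_de,
    coassembly_chi2,
    direction_partition,
    expected_reciprocal_fraction,
    parse_hit_table,
    percent,
    pipeline_comparison_report,
    reciprocal_best_hits,
)
from orthoexpress.rbbh import OUTFMT6_COLUMNS, write_hit_table

LINE = "x|q1\ty|s1\t98.5\t240\t3\t0\t1\t240\t1\t240\t1e-120\t433.0"


def hits_df(rows):
    return pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS))


def hit(q, s, bitscore, evalue=1e-50, length=100):
    return (q, s, 95.0, length, 2, 0, 1, length, 1, length, evalue, bitscore)


def test_parse_single_line_reads_bitscore_from_column_12():
    recs = parse_hit_table(io.StringIO(LINE + "\n"))
    assert len(recs) == 1
    assert recs["bitscore"].iloc[0] == 433.0
    assert recs["qseqid"].iloc[0] == "x|q1"


def test_parse_empty_stream_gives_empty_table():
    assert parse_hit_table(io.StringIO("")).empty


def test_parse_errors_carry_line_numbers():
    with pytest.raises(ValueError, match="line 2"):
        parse_hit_table(io.StringIO(LINE + "\n" + "a\tb\tc\n"))
    bad_num = LINE.replace("433.0", "notanumber")
    with pytest.raises(ValueError, match="line 1.*bitscore"):
        parse_hit_table(io.StringIO(bad_num + "\n"))


def test_write_then_parse_round_trip(tmp_path, rng):
    rows = [
        hit(f"x|t{i}", f"y|t{rng.integers(100)}", float(rng.integers(50, 500)))
        for i in range(100)
    ]
    table = hits_df(rows)
    path = tmp_path / "hits.tsv"
    write_hit_table(table, path)
    back = parse_hit_table(path)
    pd.testing.assert_frame_equal(back, table.reset_index(drop=True), check_dtype=False)


def test_mutual_best_pair_is_recovered():
    table = hits_df([hit("x|1", "y|1", 300), hit("y|1", "x|1", 290)])
    pairs = reciprocal_best_hits(table, "x", "y")
    assert list(pairs["a"]) == ["x|1"] and list(pairs["b"]) == ["y|1"]


def test_asymmetric_best_hits_form_no_pair():
    table = hits_df(
        [
            hit("x|1", "y|1", 300),
            hit("y|1", "x|2", 500),
            hit("y|1", "x|1", 100),
            hit("x|2", "y|2", 50),
        ]
    )
    pairs = reciprocal_best_hits(table, "x", "y")
    assert pairs.empty


def brute_force_rbbh(table, tx, ty):
    """All-pairs mutual-best enumeration, independent of the library."""

    def taxon(s):
        return s.split("|", 1)[0]

    def best(queries_from, to_taxon):
        best_of = {}
        for rec in queries_from.itertuples(index=False):
            if taxon(rec.qseqid) != queries_from.attrs["qt"]:
                continue
            if taxon(rec.sseqid) != to_taxon:
                continue
            key = rec.qseqid
            cand = (-rec.bitscore, rec.evalue, -rec.length, rec.sseqid)
            if key not in best_of or cand < best_of[key][0]:
                best_of[key] = (cand, rec.sseqid)
        return {q: s for q, (c, s) in best_of.items()}

    table = table.copy()
    table.attrs["qt"] = tx
    fwd = best(table, ty)
    table.attrs["qt"] = ty
    rev = best(table, tx)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


def test_random_tables_match_all_pairs_enumeration(rng):
    for _ in range(30):
        n = int(rng.integers(5, 40))
        rows = []
        for _ in range(n):
            q = f"{'x' if rng.random() < 0.5 else 'y'}|{rng.integers(6)}"
            s = f"{'x' if rng.random() < 0.5 else 'y'}|{rng.integers(6)}"
            rows.append(hit(q, s, float(rng.integers(10, 60)),
                            evalue=float(10.0 ** -rng.integers(5, 50)),
                            length=int(rng.integers(50, 200))))
        table = hits_df(rows)
        pairs = reciprocal_best_hits(table, "x", "y")
        got = sorted(zip(pairs["a"], pairs["b"]))
        assert got == brute_force_rbbh(table, "x", "y")


def test_rbbh_is_symmetric_in_the_taxa(rng):
    rows = [
        hit(f"{'xy'[rng.integers(2)]}|{rng.integers(8)}",
            f"{'xy'[rng.integers(2)]}|{rng.integers(8)}",
            float(rng.integers(10, 99)))
        for _ in range(60)
    ]
    table = hits_df(rows)
    ab = {(a, b) for a, b in zip(*(reciprocal_best_hits(table, "x", "y")[c] for c in "ab"))}
    ba = {(b, a) for a, b in zip(*(reciprocal_best_hits(table, "y", "x")[c] for c in "ab"))}
    assert ab == ba


def pairs_df(pairs):
    return pd.DataFrame(pairs, columns=["a", "b"])


def test_pair_de_categories_and_relations():
    de = pd.DataFrame(
        {"de_flag": [True, True, True, False, True, True],
         "direction": ["up_in_first", "up_in_second", "up_in_first", "none",
                       "up_in_first", "up_in_first"]},
        index=["a1", "b1", "a2", "b2", "a3", "b3"],
    )
    classes = classify_pairs_de(pairs_df([("a1", "b1"), ("a2", "b2"), ("a3", "b3")]), de)
    assert list(classes["category"]) == ["both", "one", "both"]
    assert classes["relation"].iloc[0] == "reciprocal"  # bro>fru with bro<fru
    assert classes["relation"].iloc[2] == "same_direction"
    with pytest.raises(KeyError, match="zz"):
        classify_pairs_de(pairs_df([("a1", "zz")]), de)


def classes_of(n_both, n_one, n_neither, n_rec=0, dirs=None):
    rows = []
    for i in range(n_both):
        rel = "reciprocal" if i < n_rec else "same_direction"
        da, db = dirs[i] if dirs else (
            ("up_in_first", "up_in_second") if rel == "reciprocal"
            else ("up_in_first", "up_in_first")
        )
        rows.append((f"a{i}", f"b{i}", "both", rel, da, db))
    for i in range(n_one):
        rows.append((f"c{i}", f"d{i}", "one", None, None, None))
    for i in range(n_neither):
        rows.append((f"e{i}", f"f{i}", "neither", None, None, None))
    return pd.DataFrame(
        rows, columns=["a", "b", "category", "relation", "direction_a", "direction_b"]
    )


def test_degenerate_contingency_is_flagged_undefined():
    rep = coassembly_chi2(classes_of(0, 0, 50))
    assert not rep.defined and rep.chi2 is None and rep.phi is None


def test_contingency_matches_hand_evaluated_formula():
    rep = coassembly_chi2(classes_of(20, 20, 60))
    p = (2 * 20 + 20) / 200.0  # 0.3 from the 2N members
    exp = [100 * p**2, 200 * p * (1 - p), 100 * (1 - p) ** 2]
    chi2_hand = sum(
        (o - e) ** 2 / e for o, e in zip([20, 20, 60], exp)
    )
    assert rep.p_hat == pytest.approx(p)
    assert rep.chi2 == pytest.approx(chi2_hand)
    assert rep.phi == pytest.approx(np.sqrt(chi2_hand / 100))
    assert sum(rep.expected) == pytest.approx(rep.n_pairs)
    assert rep.n_both + rep.n_one + rep.n_neither == rep.n_pairs


def test_expected_reciprocal_fraction_examples():
    assert expected_reciprocal_fraction(7, 1) == pytest.approx(0.21875)
    assert expected_reciprocal_fraction(1, 1) == pytest.approx(0.5)
    assert expected_reciprocal_fraction(5, 0) == 0.0
    with pytest.raises(ValueError):
        expected_reciprocal_fraction(0, 0)


def test_direction_partition_pipeline5_and_pipeline4_examples():
    rep = direction_partition(classes_of(93, 0, 0, n_rec=18))
    assert rep.n_reciprocal == 18 and rep.n_same == 75
    assert percent(rep.n_reciprocal, rep.n_reciprocal + rep.n_same, 1) == 19.4

    dirs = [("up_in_first", "up_in_second")] + [("up_in_first", "up_in_first")] * 3
    rep4 = direction_partition(classes_of(4, 0, 0, n_rec=1, dirs=dirs))
    assert rep4.observed_fraction == pytest.approx(0.25)
    assert rep4.q_hat == pytest.approx(7 / 8)
    assert rep4.expected_fraction == pytest.approx(0.21875)


def test_direction_partition_edge_cases():
    rep = direction_partition(classes_of(5, 0, 0, n_rec=0))
    assert rep.observed_fraction == 0.0
    with pytest.raises(ValueError):
        direction_partition(classes_of(0, 3, 3))


def test_pipeline_comparison_report_prints_table_percentages():
    report = pipeline_comparison_report(
        {
            "p1": {"n_loci": 794_264, "n_de": 16_834},
            "p5": {"n_loci": 37_256, "n_de": 2_786,
                   "classes": classes_of(93, 40, 60, n_rec=18)},
            "empty": {"n_loci": 1000, "n_de": 0},
        }
    )
    assert report.loc["p1", "pct_de"] == 2.12
    assert report.loc["p5", "pct_de"] == 7.48
    assert report.loc["p5", "pct_reciprocal"] == 19.4
    assert report.loc["p5", "pct_same"] == 80.6
    assert report.loc["empty", "pct_de"] == 0.0
    assert pd.isna(report.loc["empty", "chi2"])
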