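"""Reciprocal-best-hit co-assembly diagnostics.

When reads from orthologous loci of two species fail to co-assemble,
each species ends up with its own contig and the pair is recoverable as
a reciprocal best blast hit (RBBH).  Such pairs produce a false signal
of differential expression in opposite directions, whereas genuinely DE
paralogs that fail to co-assemble tend to be DE in the same direction.
This module identifies RBBHs from a BLAST tabular (outfmt 6) hit table,
cross-tabulates their DE status against an independence null (chi-square
with the phi = sqrt(chi2/N) effect size), and partitions both-DE pairs
into reciprocally-DE vs same-direction-DE, whose chance expectation is
``2q(1-q)`` for a marginal bro>fru direction frequency ``q``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import binomtest, chi2

__all__ = [
    "OUTFMT6_COLUMNS",
    "parse_hit_table",
    "write_hit_table",
    "reciprocal_best_hits",
    "classify_pairs_de",
    "ContingencyReport",
    "coassembly_chi2",
    "expected_reciprocal_fraction",
    "DirectionReport",
    "direction_partition",
    "percent",
    "pipeline_comparison_report",
]

logger = logging.getLogger(__name__)

OUTFMT6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)
_NUMERIC = {
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
}


def parse_hit_table(source) -> pd.DataFrame:
    """Parse BLAST tabular (outfmt 6) records into a DataFrame.

    ``source`` may be a path or an open text stream.  Lines must have at
    least 12 tab-separated fields; extra fields are ignored.  Malformed
    lines raise ``ValueError`` with the offending line number.
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        fh = open(source, "rt")
        close = True
    else:
        fh = source
    rows = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"line {lineno}: expected >= 12 tab-separated columns, got {len(fields)}"
                )
            rec = {"qseqid": fields[0], "sseqid": fields[1]}
            if not rec["qseqid"] or not rec["sseqid"]:
                raise ValueError(f"line {lineno}: empty sequence id")
            for name, value in zip(OUTFMT6_COLUMNS[2:], fields[2:12]):
                try:
                    rec[name] = _NUMERIC[name](value)
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: cannot parse {name}={value!r}"
                    ) from exc
            rows.append(rec)
    finally:
        if close:
            fh.close()
    if not rows:
        return pd.DataFrame(columns=list(OUTFMT6_COLUMNS))
    return pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS))


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", header=False, index=False, columns=list(OUTFMT6_COLUMNS))


def _default_taxon_of(seqid: str) -> str | None:
    """Default id convention: taxon prefix before the first '|'."""
    if "|" in seqid:
        return seqid.split("|", 1)[0]
    return None


def _resolve_taxon_of(taxon_of) -> Callable[[str], str | None]:
    if taxon_of is None:
        return _default_taxon_of
    if isinstance(taxon_of, Mapping):
        return lambda s: taxon_of.get(s)
    return taxon_of


def _best_hits(hits: pd.DataFrame) -> pd.Series:
    """Best subject per query: max bitscore, then min e-value, then
    longest alignment, then lexicographically smallest subject id.
    Multiple HSPs of one (query, subject) pair collapse to the best HSP
    under the same ordering."""
    ordered = hits.sort_values(
        by=["qseqid", "bitscore", "evalue", "length", "sseqid"],
        ascending=[True, False, True, False, True],
    )
    return ordered.groupby("qseqid", sort=False)["sseqid"].first()


def reciprocal_best_hits(
    hits: pd.DataFrame,
    taxon_x: str,
    taxon_y: str,
    taxon_of: Callable[[str], str | None] | Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mutual best hits between transcripts of two taxa.

    Returns a DataFrame with columns ``a`` (taxon X member), ``b``
    (taxon Y member), ``bitscore_fwd`` and ``bitscore_rev``, sorted by
    ``a``.  A missing direction yields an empty result with a warning.
    """
    tax = _resolve_taxon_of(taxon_of)
    if hits.empty:
        logger.warning("empty hit table: no RBBH pairs")
        return pd.DataFrame(columns=["a", "b", "bitscore_fwd", "bitscore_rev"])
    tq = hits["qseqid"].map(tax)
    ts = hits["sseqid"].map(tax)
    fwd = hits[(tq == taxon_x) & (ts == taxon_y)]
    rev = hits[(tq == taxon_y) & (ts == taxon_x)]
    if fwd.empty or rev.empty:
        logger.warning(
            "missing hit direction between %s and %s: no RBBH pairs", taxon_x, taxon_y
        )
        return pd.DataFrame(columns=["a", "b", "bitscore_fwd", "bitscore_rev"])
    best_f = _best_hits(fwd)
    best_r = _best_hits(rev)
    score_f = fwd.groupby(["qseqid", "sseqid"])["bitscore"].max()
    score_r = rev.groupby(["qseqid", "sseqid"])["bitscore"].max()
    pairs = []
    for a, b in best_f.items():
        if best_r.get(b) == a:
            pairs.append(
                {
                    "a": a,
                    "b": b,
                    "bitscore_fwd": score_f[(a, b)],
                    "bitscore_rev": score_r[(b, a)],
                }
            )
    out = pd.DataFrame(pairs, columns=["a", "b", "bitscore_fwd", "bitscore_rev"])
    return out.sort_values("a").reset_index(drop=True)


CATEGORY_BOTH = "both"
CATEGORY_ONE = "one"
CATEGORY_NEITHER = "neither"
RELATION_RECIPROCAL = "reciprocal"
RELATION_SAME = "same_direction"


def classify_pairs_de(pairs: pd.DataFrame, de_table: pd.DataFrame) -> pd.DataFrame:
    """DE category (both / one / neither) and, for both-DE pairs, the
    direction relation of each RBBH pair.

    ``de_table`` is a DE result for the parental comparison, indexed by
    locus with ``de_flag`` and ``direction`` columns.  Opposite
    directions give ``reciprocal``, equal directions ``same_direction``.
    """
    records = []
    for row in pairs.itertuples(index=False):
        for t in (row.a, row.b):
            if t not in de_table.index:
                raise KeyError(f"transcript {t!r} absent from the DE table")
        fa, fb = bool(de_table.at[row.a, "de_flag"]), bool(de_table.at[row.b, "de_flag"])
        if fa and fb:
            category = CATEGORY_BOTH
            da, db = de_table.at[row.a, "direction"], de_table.at[row.b, "direction"]
            relation = RELATION_SAME if da == db else RELATION_RECIPROCAL
            dirs = (da, db)
        else:
            category = CATEGORY_ONE if (fa or fb) else CATEGORY_NEITHER
            relation, dirs = None, (None, None)
        records.append(
            {
                "a": row.a,
                "b": row.b,
                "category": category,
                "relation": relation,
                "direction_a": dirs[0],
                "direction_b": dirs[1],
            }
        )
    return pd.DataFrame(
        records, columns=["a", "b", "category", "relation", "direction_a", "direction_b"]
    )


@dataclass
class ContingencyReport:
    """Observed vs independence-expected both/one/neither counts."""

    n_pairs: int
    n_both: int
    n_one: int
    n_neither: int
    p_hat: float
    expected: tuple[float, float, float]
    chi2: float | None
    df: int
    pvalue: float | None
    phi: float | None
    defined: bool
    null: str = "members"

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_both": self.n_both,
            "n_one": self.n_one,
            "n_neither": self.n_neither,
            "p_hat": self.p_hat,
            "expected_both": self.expected[0],
            "expected_one": self.expected[1],
            "expected_neither": self.expected[2],
            "chi2": self.chi2,
            "df": self.df,
            "pvalue": self.pvalue,
            "phi": self.phi,
            "defined": self.defined,
            "null": self.null,
        }


def coassembly_chi2(
    classes: pd.DataFrame, marginal_rate: float | None = None
) -> ContingencyReport:
    """Chi-square test of RBBH DE-status association.

    Under independence with marginal DE rate ``p`` the expected counts
    are ``(N p^2, 2N p(1-p), N (1-p)^2)``.  By default ``p`` is
    estimated from the 2N RBBH members themselves; pass
    ``marginal_rate`` to use e.g. the transcriptome-wide DE rate
    instead.  Degenerate marginals (p in {0, 1}) return a report with
    the test flagged undefined.
    """
    n = len(classes)
    if n < 1:
        raise ValueError("need at least one RBBH pair")
    n_both = int((classes["category"] == CATEGORY_BOTH).sum())
    n_one = int((classes["category"] == CATEGORY_ONE).sum())
    n_neither = int((classes["category"] == CATEGORY_NEITHER).sum())
    null = "members" if marginal_rate is None else "external_rate"
    p = (
        (2 * n_both + n_one) / (2 * n)
        if marginal_rate is None
        else float(marginal_rate)
    )
    expected = (n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2)
    if p <= 0.0 or p >= 1.0:
        return ContingencyReport(
            n, n_both, n_one, n_neither, p, expected, None, 1, None, None, False, null
        )
    obs = np.array([n_both, n_one, n_neither], dtype=float)
    exp = np.array(expected)
    stat = float(((obs - exp) ** 2 / exp).sum())
    # three cells, one estimated parameter -> df = 1
    return ContingencyReport(
        n,
        n_both,
        n_one,
        n_neither,
        p,
        expected,
        stat,
        1,
        float(chi2.sf(stat, 1)),
        float(np.sqrt(stat / n)),
        True,
        null,
    )


def expected_reciprocal_fraction(n_up: int, n_down: int) -> float:
    """Chance fraction of reciprocally-DE pairs, ``2q(1-q)``.

    ``q`` is the frequency of the bro>fru direction among the both-DE
    RBBH members; with random pairing the chance that the two members of
    a pair disagree in direction is ``2q(1-q)`` (at most 0.5).
    """
    if n_up < 0 or n_down < 0 or n_up + n_down < 1:
        raise ValueError("need at least one directed member")
    q = n_up / (n_up + n_down)
    return 2.0 * q * (1.0 - q)


@dataclass
class DirectionReport:
    """Observed vs expected partition of both-DE pairs by direction.

    The exact binomial comparison of the observed reciprocal count with
    the ``2q(1-q)`` expectation is a formalization added by this
    package; the original analysis compared the two informally.
    """

    n_reciprocal: int
    n_same: int
    observed_fraction: float
    q_hat: float
    expected_fraction: float
    binom_pvalue: float
    note: str = "binomial test is an extension beyond the informal comparison"

    def as_dict(self) -> dict:
        return {
            "n_reciprocal": self.n_reciprocal,
            "n_same": self.n_same,
            "observed_fraction": self.observed_fraction,
            "q_hat": self.q_hat,
            "expected_fraction": self.expected_fraction,
            "binom_pvalue": self.binom_pvalue,
            "note": self.note,
        }


def direction_partition(
    classes: pd.DataFrame, up_direction: str = "up_in_first"
) -> DirectionReport:
    """Partition both-DE RBBH pairs into reciprocal vs same-direction.

    ``q_hat`` is the frequency of ``up_direction`` (bro>fru for the
    (bro, fru) comparison) among the 2 x n_both member directions.
    """
    both = classes[classes["category"] == CATEGORY_BOTH]
    if both.empty:
        raise ValueError("no both-DE pairs to partition")
    n_rec = int((both["relation"] == RELATION_RECIPROCAL).sum())
    n_same = int((both["relation"] == RELATION_SAME).sum())
    members = pd.concat([both["direction_a"], both["direction_b"]])
    n_up = int((members == up_direction).sum())
    q = n_up / len(members)
    expected = 2.0 * q * (1.0 - q)
    test = binomtest(n_rec, n_rec + n_same, p=min(max(expected, 0.0), 1.0))
    return DirectionReport(
        n_reciprocal=n_rec,
        n_same=n_same,
        observed_fraction=n_rec / (n_rec + n_same),
        q_hat=q,
        expected_fraction=expected,
        binom_pvalue=float(test.pvalue),
    )


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage at the requested printed precision."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * numerator / denominator, decimals)


def pipeline_comparison_report(pipelines: Mapping[str, Mapping]) -> pd.DataFrame:
    """Summary table across assembly/orthology pipelines.

    Each value of ``pipelines`` supplies ``n_loci`` and ``n_de`` plus,
    optionally, a ``classes`` DataFrame (from :func:`classify_pairs_de`)
    from which the chi-square, phi and direction partition are derived.
    Percentages follow the printed precisions: % DE at 2 decimals,
    direction percentages at 1.
    """
    rows = []
    for name, info in pipelines.items():
        n_loci, n_de = int(info["n_loci"]), int(info["n_de"])
        row = {
            "pipeline": name,
            "n_loci": n_loci,
            "n_de": n_de,
            "pct_de": percent(n_de, n_loci, 2) if n_loci else None,
            "chi2": None,
            "chi2_pvalue": None,
            "phi": None,
            "n_reciprocal": None,
            "pct_reciprocal": None,
            "n_same": None,
            "pct_same": None,
        }
        classes = info.get("classes")
        if classes is not None and len(classes):
            rep = coassembly_chi2(classes)
            row["chi2"] = rep.chi2
            row["chi2_pvalue"] = rep.pvalue
            row["phi"] = rep.phi
            if (classes["category"] == CATEGORY_BOTH).any():
                part = direction_partition(classes)
                tot = part.n_reciprocal + part.n_same
                row["n_reciprocal"] = part.n_reciprocal
                row["pct_reciprocal"] = percent(part.n_reciprocal, tot, 1)
                row["n_same"] = part.n_same
                row["pct_same"] = percent(part.n_same, tot, 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("pipeline")
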