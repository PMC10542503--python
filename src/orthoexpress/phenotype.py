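"""Expression-phenotype classification for two parents and two hybrids.

Each locus is reduced to six DE indicators, one per ordered taxon pair
in the fixed order (bro,fru), (bro,sun), (bro,lem), (fru,sun),
(fru,lem), (sun,lem).  A truth table over these indicators assigns the
phenotype classes: DE between the parents (A), novel expression in one
or both hybrid species (B), parent-like expression in one or both
hybrids (C), and DE between the two hybrids (D).  Each class row
constrains some comparisons to be DE, some to be not-DE, and leaves the
rest free; a locus matches a row when every constrained comparison
agrees.

Because free cells let rows overlap, a single *primary* label is
resolved by precedence (shared hybrid classes before species-specific
parent-like classes before species-specific novel classes before bare
A); A and D totals are reported as marginals, which is how the class
counts add up in the source-style accounting.  Novel loci are further
annotated as transgressive (hybrid mean outside the parental range) or
intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARISONS",
    "TABLE_ROWS",
    "PRECEDENCE",
    "classify_locus",
    "resolve_primary",
    "classify_all",
    "annotate_novel_mode",
    "parent_bias_summary",
    "novel_total",
]

COMPARISONS: tuple[tuple[str, str], ...] = (
    ("bro", "fru"),
    ("bro", "sun"),
    ("bro", "lem"),
    ("fru", "sun"),
    ("fru", "lem"),
    ("sun", "lem"),
)

NE, EQ, ANY = "ne", "eq", "any"

# class label -> constraint per comparison, in COMPARISONS order
TABLE_ROWS: dict[str, tuple[str, ...]] = {
    "parental_de": (NE, ANY, ANY, ANY, ANY, ANY),
    "novel_sun": (ANY, NE, ANY, NE, ANY, NE),
    "novel_lem": (ANY, ANY, NE, ANY, NE, NE),
    "novel_both": (ANY, NE, NE, NE, NE, EQ),
    "sun_bro_like": (NE, EQ, ANY, NE, ANY, ANY),
    "sun_fru_like": (NE, NE, ANY, EQ, ANY, ANY),
    "lem_bro_like": (NE, ANY, EQ, ANY, NE, ANY),
    "lem_fru_like": (NE, ANY, NE, ANY, EQ, ANY),
    "both_bro_like": (NE, EQ, EQ, NE, NE, EQ),
    "both_fru_like": (NE, NE, NE, EQ, EQ, EQ),
    "hybrid_de": (ANY, ANY, ANY, ANY, ANY, NE),
}

NOVEL_LABELS = ("novel_sun", "novel_lem", "novel_both")
PARENT_LIKE_LABELS = (
    "sun_bro_like",
    "sun_fru_like",
    "lem_bro_like",
    "lem_fru_like",
    "both_bro_like",
    "both_fru_like",
)

# precedence for the single primary label: shared classes, then
# species-specific parent-like, then species-specific novel, then bare A
PRECEDENCE: tuple[str, ...] = (
    "novel_both",
    "both_bro_like",
    "both_fru_like",
    "sun_bro_like",
    "sun_fru_like",
    "lem_bro_like",
    "lem_fru_like",
    "novel_sun",
    "novel_lem",
    "parental_de",
)

COUNT_TABLE_ROWS: tuple[str, ...] = (
    "parental_de",
    "novel_sun",
    "novel_lem",
    "novel_both",
    "sun_bro_like",
    "sun_fru_like",
    "lem_bro_like",
    "lem_fru_like",
    "both_bro_like",
    "both_fru_like",
    "hybrid_de",
)


def classify_locus(flags: Sequence[bool]) -> set[str]:
    """All truth-table labels matched by six DE indicators."""
    flags = tuple(bool(f) for f in flags)
    if len(flags) != 6:
        raise ValueError("exactly six DE indicators are required")
    matched = set()
    for label, row in TABLE_ROWS.items():
        ok = True
        for cell, flag in zip(row, flags):
            if cell == NE and not flag:
                ok = False
                break
            if cell == EQ and flag:
                ok = False
                break
        if ok:
            matched.add(label)
    return matched


def resolve_primary(matched: set[str]) -> tuple[str | None, bool]:
    """Precedence-resolved primary label and a dual-novel flag.

    ``hybrid_de`` is excluded (reported independently).  A locus
    matching both ``novel_sun`` and ``novel_lem`` (all four
    hybrid-parent comparisons DE and the hybrids DE from each other) is
    returned as ``novel_sun`` with the dual flag set; the count table
    adds it to both hybrids' novel tallies.
    """
    dual = "novel_sun" in matched and "novel_lem" in matched
    for label in PRECEDENCE:
        if label in matched:
            return label, dual
    return None, False


def _six_flags(de_tables: Mapping[tuple[str, str], pd.DataFrame]) -> pd.DataFrame:
    for pair in COMPARISONS:
        if pair not in de_tables:
            raise KeyError(f"missing DE table for comparison {pair}")
    base = de_tables[COMPARISONS[0]].index
    flags = {}
    for pair in COMPARISONS:
        table = de_tables[pair]
        missing = base.difference(table.index)
        if len(missing) or len(table.index.difference(base)):
            raise ValueError(
                f"DE table for {pair} covers a different locus set "
                f"(e.g. missing {list(missing[:3])})"
            )
        flags[pair] = table.loc[base, "de_flag"].astype(bool)
    return pd.DataFrame(flags, index=base)


def annotate_novel_mode(
    means: Mapping[str, float],
    hybrid: str,
    parents: tuple[str, str] = ("bro", "fru"),
) -> str:
    """Transgressive vs intermediate annotation for a novel locus.

    ``transgressive_up`` when the hybrid's normalized mean exceeds both
    parents', ``transgressive_down`` when below both, ``intermediate``
    otherwise.
    """
    try:
        h = means[hybrid]
        p1, p2 = means[parents[0]], means[parents[1]]
    except KeyError as exc:
        raise KeyError(f"missing group mean for taxon {exc}") from exc
    if h > max(p1, p2):
        return "transgressive_up"
    if h < min(p1, p2):
        return "transgressive_down"
    return "intermediate"


def classify_all(
    de_tables: Mapping[tuple[str, str], pd.DataFrame],
    group_means: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-locus phenotype calls plus a class count table.

    ``de_tables`` maps each of the six ordered comparisons to a DE
    result (``de_flag`` column) over one shared locus set.
    ``group_means`` (loci x taxa normalized CPM means) enables the
    transgressive/intermediate annotation of novel loci.

    The count table gives precedence-resolved counts for the B and C
    classes and marginal counts for ``parental_de`` and ``hybrid_de``;
    dual-novel loci increment both hybrids' novel rows.
    """
    flags = _six_flags(de_tables)
    records = []
    counts = {label: 0 for label in COUNT_TABLE_ROWS}
    for locus, row in flags.iterrows():
        matched = classify_locus(tuple(row))
        primary, dual = resolve_primary(matched)
        if "parental_de" in matched:
            counts["parental_de"] += 1
        if "hybrid_de" in matched:
            counts["hybrid_de"] += 1
        if primary is not None and primary != "parental_de":
            if dual:
                counts["novel_sun"] += 1
                counts["novel_lem"] += 1
            else:
                counts[primary] += 1
        modes = {"sun": "not_applicable", "lem": "not_applicable"}
        if group_means is not None and primary in NOVEL_LABELS:
            hybrids = (
                ("sun",)
                if primary == "novel_sun" and not dual
                else ("lem",)
                if primary == "novel_lem"
                else ("sun", "lem")
            )
            for h in hybrids:
                modes[h] = annotate_novel_mode(group_means.loc[locus], h)
        records.append(
            {
                "locus": locus,
                **{f"de_{a}_{b}": bool(f) for (a, b), f in row.items()},
                "matched": ";".join(sorted(matched)),
                "primary": primary,
                "dual_novel": dual,
                "novel_mode_sun": modes["sun"],
                "novel_mode_lem": modes["lem"],
            }
        )
    calls = pd.DataFrame.from_records(records).set_index("locus") if records else (
        pd.DataFrame(
            columns=[
                *(f"de_{a}_{b}" for a, b in COMPARISONS),
                "matched",
                "primary",
                "dual_novel",
                "novel_mode_sun",
                "novel_mode_lem",
            ]
        )
    )
    return calls, pd.Series(counts, name="n_loci")


def parent_bias_summary(
    counts: pd.Series, hybrid: str
) -> tuple[int, int, str | None]:
    """Combined parent-like counts and a rounded percent ratio.

    Adds the hybrid-specific and shared parent-like counts for each
    parent; the ratio string rounds the bro-like share to the nearest
    percent with the complement forced to sum to 100.  Returns
    ``(n_bro_like, n_fru_like, ratio)`` with ``ratio=None`` flagged when
    both counts are zero.
    """
    if hybrid not in ("sun", "lem"):
        raise ValueError("hybrid must be 'sun' or 'lem'")
    n_bro = int(counts[f"{hybrid}_bro_like"] + counts["both_bro_like"])
    n_fru = int(counts[f"{hybrid}_fru_like"] + counts["both_fru_like"])
    if n_bro + n_fru == 0:
        return 0, 0, None
    share = round(100 * n_bro / (n_bro + n_fru))
    return n_bro, n_fru, f"{share}:{100 - share}"


def novel_total(counts: pd.Series) -> int:
    """Total loci with novel expression in one or both hybrids."""
    return int(sum(counts[label] for label in NOVEL_LABELS))
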