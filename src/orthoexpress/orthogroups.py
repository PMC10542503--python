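"""Orthogroup parsing, one-to-one ortholog extraction and paralog
filtering by genus monophyly.

Two filtering modes mirror the two orthology-based quantification
strategies: keeping only one-to-one orthologs (one member per required
taxon, nothing else), and keeping all orthogroups but discarding those
whose gene tree shows a genus's transcripts to be non-monophyletic
(likely paralog contamination).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .trees import genus_monophyly, kmer_distance_matrix, neighbor_joining

__all__ = [
    "OgMember",
    "Orthogroup",
    "parse_orthogroups",
    "write_orthogroups",
    "one_to_one_orthogroups",
    "size_summary",
    "read_orthogroup_fasta",
    "write_orthogroup_fasta",
    "FilterReport",
    "filter_paralogous_orthogroups",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OgMember:
    transcript: str
    taxon: str
    genus: str | None = None


@dataclass
class Orthogroup:
    """One orthogroup: id, members, and (optionally) their sequences."""

    id: str
    members: list[OgMember]
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [m.transcript for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate member ids in orthogroup {self.id}")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def taxa(self) -> set[str]:
        return {m.taxon for m in self.members}

    @property
    def genera(self) -> set[str]:
        return {m.genus for m in self.members if m.genus is not None}


def parse_orthogroups(
    source,
    taxon_to_genus: Mapping[str, str] | None = None,
) -> list[Orthogroup]:
    """Parse an ``Orthogroups.tsv``-style table.

    The header row names the species columns; each following row holds
    the orthogroup id and comma-separated gene lists per species (empty
    cells allowed).  ``taxon_to_genus`` optionally maps each species
    column to a genus for downstream monophyly testing.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    taxa = list(df.columns[1:])
    if not taxa:
        raise ValueError("orthogroup table has no species columns")
    ogs: list[Orthogroup] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        og_id = row.iloc[0].strip()
        if not og_id:
            warnings.warn("skipping row with empty orthogroup id")
            continue
        if og_id in seen:
            raise ValueError(f"duplicate orthogroup id {og_id!r}")
        seen.add(og_id)
        members = []
        for taxon in taxa:
            cell = row[taxon].strip()
            if not cell:
                continue
            for gene in cell.split(","):
                gene = gene.strip()
                if gene:
                    members.append(
                        OgMember(
                            transcript=gene,
                            taxon=taxon,
                            genus=(taxon_to_genus or {}).get(taxon),
                        )
                    )
        ogs.append(Orthogroup(id=og_id, members=members))
    return ogs


def write_orthogroups(ogs: Sequence[Orthogroup], path, taxa: Sequence[str] | None = None) -> None:
    """Write orthogroups back to the Orthogroups.tsv dialect."""
    if taxa is None:
        taxa = sorted({m.taxon for og in ogs for m in og.members})
    rows = []
    for og in ogs:
        row = {"Orthogroup": og.id}
        for t in taxa:
            row[t] = ", ".join(m.transcript for m in og.members if m.taxon == t)
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *taxa]).to_csv(path, sep="\t", index=False)


def one_to_one_orthogroups(
    ogs: Sequence[Orthogroup], required_taxa: Sequence[str]
) -> list[Orthogroup]:
    """Orthogroups with exactly one member per required taxon and no
    members from any other taxon."""
    required = list(required_taxa)
    out = []
    for og in ogs:
        per_taxon = {t: 0 for t in required}
        ok = True
        for m in og.members:
            if m.taxon not in per_taxon:
                ok = False
                break
            per_taxon[m.taxon] += 1
        if ok and all(c == 1 for c in per_taxon.values()):
            out.append(og)
    return out


def size_summary(
    ogs: Sequence[Orthogroup], thresholds: Sequence[int] = (5, 10)
) -> dict[int, float]:
    """Fraction of orthogroups with member count <= each threshold."""
    n = len(ogs)
    if n == 0:
        return {t: float("nan") for t in thresholds}
    sizes = [og.size for og in ogs]
    return {t: sum(s <= t for s in sizes) / n for t in thresholds}


# -- FASTA attachment -----------------------------------------------------

def read_orthogroup_fasta(path) -> dict[str, dict[str, str]]:
    """Read member sequences from FASTA with headers
    ``<og_id>|<genus>|<taxon>|<transcript_id>``.

    Returns ``{og_id: {transcript_id: sequence}}``.
    """
    out: dict[str, dict[str, str]] = {}
    og = tid = None
    chunks: list[str] = []

    def flush():
        if og is not None and tid is not None:
            out.setdefault(og, {})[tid] = "".join(chunks)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("|")
                if len(fields) != 4:
                    raise ValueError(f"bad orthogroup FASTA header: {line!r}")
                og, _, _, tid = fields
                chunks = []
            else:
                chunks.append(line)
    flush()
    return out


def write_orthogroup_fasta(ogs: Sequence[Orthogroup], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for og in ogs:
            if not og.sequences:
                continue
            for m in og.members:
                seq = og.sequences.get(m.transcript)
                if seq is None:
                    continue
                fh.write(f">{og.id}|{m.genus or 'NA'}|{m.taxon}|{m.transcript}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# -- paralog filter -------------------------------------------------------

@dataclass
class FilterReport:
    """Accounting of the monophyly-based paralog filter."""

    n_input: int
    n_removed: int
    n_untested: int
    per_orthogroup: pd.DataFrame | None = None

    @property
    def n_kept(self) -> int:
        """Orthogroups retained for analysis (tested-and-clean plus
        untested), i.e. input minus removed."""
        return self.n_input - self.n_removed

    @property
    def n_tested_clean(self) -> int:
        return self.n_input - self.n_removed - self.n_untested


def _og_is_paralogous(
    og: Orthogroup, focal_genus: str | None, k: int
) -> tuple[bool, dict[str, bool]]:
    genus_of = {m.transcript: m.genus for m in og.members}
    seqs = {m.transcript: og.sequences[m.transcript] for m in og.members}
    dist, labels = kmer_distance_matrix(seqs, k=k)
    tree = neighbor_joining(dist, labels)
    counts: dict[str, int] = {}
    for m in og.members:
        counts[m.genus] = counts.get(m.genus, 0) + 1
    testable = [
        g
        for g, c in counts.items()
        if c >= 2 and (focal_genus is None or g == focal_genus) and c < og.size
    ]
    if not testable:
        return False, {}
    mono = genus_monophyly(tree, genus_of, genera=testable)
    return any(not ok for ok in mono.values()), mono


def filter_paralogous_orthogroups(
    ogs: Sequence[Orthogroup],
    focal_genus: str | None = None,
    k: int = 6,
    min_size: int = 4,
) -> tuple[list[Orthogroup], list[Orthogroup], FilterReport]:
    """Remove orthogroups whose gene tree shows genus non-monophyly.

    An orthogroup is *tested* when it has sequences, at least
    ``min_size`` members and more than one genus; tested orthogroups
    where any genus with >= 2 members (or just ``focal_genus`` if
    given) is non-monophyletic are removed.  Untested orthogroups are
    kept but flagged.  Returns ``(kept, removed, report)``; kept
    includes the untested ones, and the report partitions the input.
    """
    kept: list[Orthogroup] = []
    removed: list[Orthogroup] = []
    records = []
    n_untested = 0
    for og in ogs:
        has_seqs = bool(og.sequences) and all(
            m.transcript in og.sequences for m in og.members
        )
        has_genera = all(m.genus is not None for m in og.members)
        if not has_seqs or not has_genera or og.size < min_size or len(og.genera) < 2:
            n_untested += 1
            kept.append(og)
            records.append({"orthogroup": og.id, "status": "untested"})
            continue
        paralogous, mono = _og_is_paralogous(og, focal_genus, k)
        if not mono:
            n_untested += 1
            kept.append(og)
            records.append({"orthogroup": og.id, "status": "untested"})
            continue
        if paralogous:
            removed.append(og)
            records.append({"orthogroup": og.id, "status": "removed"})
        else:
            kept.append(og)
            records.append({"orthogroup": og.id, "status": "kept"})
    report = FilterReport(
        n_input=len(ogs),
        n_removed=len(removed),
        n_untested=n_untested,
        per_orthogroup=pd.DataFrame(records, columns=["orthogroup", "status"]),
    )
    return kept, removed, report
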