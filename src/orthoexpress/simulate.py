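"""Synthetic data with known ground truth for the whole pipeline.

The generator emulates the statistical structure of a four-taxon bulk
RNA-seq experiment (two parents ``bro``/``fru``, two homoploid hybrids
``sun``/``lem``; six replicates each): negative-binomial counts with a
common dispersion, configurable fractions of each expression-phenotype
class, plus two injectable co-assembly artifacts — *split orthologs*
(one locus fractured into two lineage-specific transcripts, creating a
false reciprocal DE signal) and *DE paralogs* (two transcripts genuinely
DE in the same direction) — together with a matching BLAST-style hit
table and orthogroup sequence sets with known genus-monophyly status.

Every emitted transcript has exactly one truth record; identical
configurations and seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .orthogroups import OgMember, Orthogroup
from .rbbh import OUTFMT6_COLUMNS

__all__ = [
    "PHENOTYPE_PATTERNS",
    "EXPECTED_PRIMARY",
    "DEFAULT_PHENOTYPE_FRACTIONS",
    "SimulationConfig",
    "simulate_counts",
    "inject_split_orthologs",
    "inject_de_paralogs",
    "emit_hit_table",
    "simulate_orthogroup_sequences",
    "write_truth",
]

TAXA_DEFAULT = ("bro", "fru", "sun", "lem")

# log2 mean offsets per taxon, in units of the configured effect size.
# Each pattern realises one truth-table class exactly (see EXPECTED_PRIMARY
# for the class its mean pattern implies under the classifier).
PHENOTYPE_PATTERNS: dict[str, tuple[float, float, float, float]] = {
    "parental_de": (1.0, 0.0, 0.5, 0.5),  # hybrids at the parental midpoint
    "novel_sun": (0.0, 0.0, 1.0, 0.0),
    "novel_lem": (0.0, 0.0, 0.0, 1.0),
    "novel_both": (0.0, 0.0, 1.0, 1.0),
    "both_bro_like": (0.0, 1.0, 0.0, 0.0),
    "both_fru_like": (1.0, 0.0, 0.0, 0.0),
    "sun_bro_like": (1.0, 0.0, 1.0, -1.0),
    "sun_fru_like": (0.0, 1.0, 1.0, -1.0),
    "lem_bro_like": (1.0, 0.0, -1.0, 1.0),
    "lem_fru_like": (0.0, 1.0, -1.0, 1.0),
}

# class the classifier should assign to each canonical mean pattern;
# intermediate hybrids (parental_de) are, by the truth table, a shared
# novel phenotype once the half-effect is detectable.
EXPECTED_PRIMARY: dict[str, str] = {
    label: label for label in PHENOTYPE_PATTERNS
} | {"parental_de": "novel_both"}

# fractions follow the class proportions observed among the study-scale
# orthogroup set (Table-3-style accounting over ~37k orthogroups)
DEFAULT_PHENOTYPE_FRACTIONS: dict[str, float] = {
    "parental_de": 0.0085,
    "novel_sun": 0.0004,
    "novel_lem": 0.0003,
    "novel_both": 0.0009,
    "sun_bro_like": 0.0129,
    "sun_fru_like": 0.0125,
    "lem_bro_like": 0.0176,
    "lem_fru_like": 0.0109,
    "both_bro_like": 0.0070,
    "both_fru_like": 0.0053,
}

TRUTH_COLUMNS = (
    "transcript",
    "label",
    "expected_class",
    "sign",
    "artifact",
    "partner",
    "lineage",
    "mean_bro",
    "mean_fru",
    "mean_sun",
    "mean_lem",
)


@dataclass
class SimulationConfig:
    """Study-shaped simulation settings.

    ``baseline_mean`` is the expected count of a non-DE locus in a
    unit-size library; ``dispersion`` the NB dispersion (variance
    ``mu + phi mu^2``, 0 = Poisson); ``effect_size`` the log2 fold
    change applied to DE contrasts; ``phenotype_fractions`` the class
    mix (remainder = no-DE loci); ``split_fraction`` /
    ``paralog_fraction`` convert that share of eligible no-DE loci into
    co-assembly artifacts.
    """

    n_loci: int = 2000
    n_reps: int = 6
    taxa: tuple[str, ...] = TAXA_DEFAULT
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    lib_sizes: Sequence[float] | None = None
    phenotype_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_FRACTIONS)
    )
    effect_size: float = 2.0
    split_fraction: float = 0.0
    paralog_fraction: float = 0.0
    leak_rate: float = 0.01
    split_hybrid_lineage: str = "bro"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if self.n_reps < 2:
            raise ValueError("need >= 2 replicates per taxon")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        for frac in (self.split_fraction, self.paralog_fraction, self.leak_rate):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        total = 0.0
        for label, frac in self.phenotype_fractions.items():
            if label not in PHENOTYPE_PATTERNS:
                raise ValueError(f"unknown phenotype label {label!r}")
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction for {label!r} outside [0, 1]")
            total += frac
        if total > 1.0 + 1e-12:
            raise ValueError("phenotype fractions sum to more than 1")
        if self.lib_sizes is not None:
            sizes = np.asarray(self.lib_sizes, dtype=float)
            if sizes.shape != (self.n_reps * len(self.taxa),):
                raise ValueError("lib_sizes must have one entry per sample")
            if (sizes <= 0).any():
                raise ValueError("lib_sizes must be positive")
        if self.split_hybrid_lineage not in ("bro", "fru"):
            raise ValueError("split_hybrid_lineage must be 'bro' or 'fru'")


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix plus a per-locus truth table.

    Truth columns: generative ``label`` (``none`` for null loci), the
    ``expected_class`` the classifier should assign, the effect
    ``sign``, artifact bookkeeping (``artifact``/``partner``), the
    assembly ``lineage`` of the transcript, and the true per-taxon means
    (unit library).
    """
    rng = np.random.default_rng(config.seed)
    taxa = list(config.taxa)
    n = config.n_loci
    labels_pool = list(config.phenotype_fractions)
    probs = [config.phenotype_fractions[l] for l in labels_pool]
    probs.append(max(0.0, 1.0 - sum(probs)))
    labels = rng.choice(len(labels_pool) + 1, size=n, p=np.array(probs) / sum(probs))
    label_names = np.array(labels_pool + ["none"], dtype=object)[labels]
    signs = rng.choice([1, -1], size=n)

    offsets = np.zeros((n, len(taxa)))
    for i, lab in enumerate(label_names):
        if lab == "none":
            continue
        pat = PHENOTYPE_PATTERNS[lab]
        offsets[i] = np.array(pat) * config.effect_size * signs[i]
    means = config.baseline_mean * 2.0**offsets  # loci x taxa, unit library

    if config.lib_sizes is None:
        lib_factor = np.ones(config.n_reps * len(taxa))
    else:
        sizes = np.asarray(config.lib_sizes, dtype=float)
        lib_factor = sizes / sizes.mean()

    sample_ids, sample_taxon, sample_rep = [], [], []
    for t in taxa:
        for r in range(1, config.n_reps + 1):
            sample_ids.append(f"{t}_{r}")
            sample_taxon.append(t)
            sample_rep.append(r)
    mu = np.empty((n, len(sample_ids)))
    for j, t in enumerate(sample_taxon):
        mu[:, j] = means[:, taxa.index(t)] * lib_factor[j]
    counts = _draw_counts(rng, mu, config.dispersion)

    locus_ids = [f"L{i:06d}" for i in range(n)]
    lineages = np.array(["bro", "fru"], dtype=object)[rng.integers(0, 2, size=n)]

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(locus_ids, name="locus"), columns=sample_ids),
        samples=pd.DataFrame(
            {"taxon": sample_taxon, "replicate": sample_rep},
            index=pd.Index(sample_ids, name="sample"),
        ),
    )
    truth = pd.DataFrame(
        {
            "transcript": locus_ids,
            "label": label_names,
            "expected_class": [
                EXPECTED_PRIMARY.get(l, "none") for l in label_names
            ],
            "sign": signs,
            "artifact": "none",
            "partner": pd.array([None] * n, dtype=object),
            "lineage": lineages,
            "mean_bro": means[:, taxa.index("bro")] if "bro" in taxa else np.nan,
            "mean_fru": means[:, taxa.index("fru")] if "fru" in taxa else np.nan,
            "mean_sun": means[:, taxa.index("sun")] if "sun" in taxa else np.nan,
            "mean_lem": means[:, taxa.index("lem")] if "lem" in taxa else np.nan,
        }
    ).set_index("transcript", drop=False)
    return cm, truth


def _lineage_taxa(lineage: str, hybrid_lineage: str) -> set[str]:
    taxa = {lineage}
    if hybrid_lineage == lineage:
        taxa.update({"sun", "lem"})
    return taxa


def inject_split_orthologs(
    cm: CountMatrix,
    truth: pd.DataFrame,
    fraction: float,
    seed: int,
    leak_rate: float = 0.01,
    hybrid_lineage: str = "bro",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Convert a fraction of eligible no-DE loci into split-ortholog pairs.

    Each selected locus is replaced by two transcripts: one carries the
    counts of the bro-lineage samples (hybrids follow ``hybrid_lineage``),
    the other the fru-lineage counts, with only a binomial ``leak_rate``
    share of each sample's reads crossing over — per-sample count mass is
    conserved exactly.  Downstream this fabricates reciprocal parental DE.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return cm, truth
    rng = np.random.default_rng(seed)
    eligible = (truth["label"] == "none") & (truth["artifact"] == "none")
    selected = set(truth.index[eligible & (rng.random(len(truth)) < fraction)])
    if not selected:
        return cm, truth
    taxon_of_sample = cm.samples["taxon"]
    bro_samples = taxon_of_sample.isin(_lineage_taxa("bro", hybrid_lineage)).to_numpy()

    count_rows: list[pd.DataFrame | pd.Series] = []
    truth_rows: list[pd.Series] = []
    new_counts: dict[str, np.ndarray] = {}
    order: list[str] = []
    drop: list[str] = []
    for locus in cm.locus_ids:
        if locus not in selected:
            order.append(locus)
            continue
        c = cm.counts.loc[locus].to_numpy()
        leak = rng.binomial(c, leak_rate)
        main = c - leak
        t_bro = np.where(bro_samples, main, leak)
        t_fru = np.where(bro_samples, leak, main)
        id_bro, id_fru = f"{locus}.bro", f"{locus}.fru"
        new_counts[id_bro] = t_bro
        new_counts[id_fru] = t_fru
        order.extend([id_bro, id_fru])
        drop.append(locus)
    counts = cm.counts.drop(index=drop)
    counts = pd.concat(
        [counts, pd.DataFrame(new_counts, index=cm.sample_ids).T]
    ).loc[order]
    counts.index.name = "locus"
    out_cm = CountMatrix(counts, cm.samples.copy())

    base = truth.drop(index=drop)
    added = []
    for locus in drop:
        row = truth.loc[locus]
        for lineage, partner_lineage in (("bro", "fru"), ("fru", "bro")):
            tid = f"{locus}.{lineage}"
            mean_cols = {}
            for taxon in ("bro", "fru", "sun", "lem"):
                orig = row[f"mean_{taxon}"]
                on = taxon in _lineage_taxa(lineage, hybrid_lineage)
                mean_cols[f"mean_{taxon}"] = orig * (1 - leak_rate) if on else orig * leak_rate
            added.append(
                {
                    "transcript": tid,
                    "label": row["label"],
                    "expected_class": "none",
                    "sign": 0,
                    "artifact": "split_ortholog",
                    "partner": f"{locus}.{partner_lineage}",
                    "lineage": lineage,
                    **mean_cols,
                }
            )
    out_truth = pd.concat(
        [base, pd.DataFrame(added).set_index("transcript", drop=False)]
    ).loc[order]
    return out_cm, out_truth


def inject_de_paralogs(
    cm: CountMatrix,
    truth: pd.DataFrame,
    fraction: float,
    seed: int,
    effect_size: float = 2.0,
    dispersion: float = 0.1,
    hybrid_lineage: str = "bro",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Convert a fraction of eligible no-DE loci into DE-paralog pairs.

    Each selected locus is replaced by two transcripts that are both
    genuinely DE between the parents in the same (random) direction,
    with hybrids following ``hybrid_lineage``; counts are drawn fresh at
    half the locus's baseline per paralog.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return cm, truth
    rng = np.random.default_rng(seed)
    eligible = (truth["label"] == "none") & (truth["artifact"] == "none")
    selected = set(truth.index[eligible & (rng.random(len(truth)) < fraction)])
    if not selected:
        return cm, truth
    taxon_idx = {t: i for i, t in enumerate(("bro", "fru", "sun", "lem"))}
    sample_taxa = cm.samples["taxon"].to_numpy()

    new_counts: dict[str, np.ndarray] = {}
    order: list[str] = []
    drop: list[str] = []
    added = []
    for locus in cm.locus_ids:
        if locus not in selected:
            order.append(locus)
            continue
        drop.append(locus)
        base_mean = max(float(truth.loc[locus, "mean_bro"]), 1.0) / 2.0
        s = int(rng.choice([1, -1]))
        taxon_means = {}
        for taxon in ("bro", "fru", "sun", "lem"):
            in_bro_group = taxon in _lineage_taxa("bro", hybrid_lineage)
            taxon_means[taxon] = base_mean * (2.0 ** (s * effect_size) if in_bro_group else 1.0)
        for lineage, partner_lineage in (("bro", "fru"), ("fru", "bro")):
            tid = f"{locus}.{lineage}"
            mu = np.array([taxon_means[t] for t in sample_taxa])
            new_counts[tid] = _draw_counts(rng, mu, dispersion)
            order.append(tid)
            added.append(
                {
                    "transcript": tid,
                    "label": "none",
                    "expected_class": "none",
                    "sign": s,
                    "artifact": "de_paralog",
                    "partner": f"{locus}.{partner_lineage}",
                    "lineage": lineage,
                    **{f"mean_{t}": taxon_means[t] for t in ("bro", "fru", "sun", "lem")},
                }
            )
    counts = cm.counts.drop(index=drop)
    counts = pd.concat(
        [counts, pd.DataFrame(new_counts, index=cm.sample_ids).T]
    ).loc[order]
    counts.index.name = "locus"
    out_cm = CountMatrix(counts, cm.samples.copy())
    out_truth = pd.concat(
        [truth.drop(index=drop), pd.DataFrame(added).set_index("transcript", drop=False)]
    ).loc[order]
    return out_cm, out_truth


def emit_hit_table(
    truth: pd.DataFrame,
    noise_hits: int = 0,
    seed: int = 0,
    background_pairs: int = 0,
) -> pd.DataFrame:
    """BLAST outfmt-6 style hit table matching the truth's artifacts.

    Every split/paralog partner pair appears as mutual high-scoring
    hits.  ``background_pairs`` additional *benign* mutual-best pairs
    are formed between random opposite-lineage transcripts (emulating
    recent duplicates or similar sequences whose expression carries no
    co-assembly artifact — these supply the one/neither-DE RBBH
    categories).  ``noise_hits`` one-directional background hits with
    strictly lower bitscores and no reciprocal duplicates are added last,
    so the partner and background pairs are exactly the recoverable
    RBBHs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    used_pairs: set[frozenset[str]] = set()

    def _mutual_pair(q: str, s: str, score: float) -> None:
        length = int(rng.integers(300, 500))
        for a, b in ((q, s), (s, q)):
            rows.append(
                {
                    "qseqid": a,
                    "sseqid": b,
                    "pident": float(np.round(rng.uniform(95, 99.9), 2)),
                    "length": length,
                    "mismatch": int(rng.integers(0, 10)),
                    "gapopen": 0,
                    "qstart": 1,
                    "qend": length,
                    "sstart": 1,
                    "send": length,
                    "evalue": 0.0,
                    "bitscore": score,
                }
            )

    partnered = truth[truth["partner"].notna()]
    for tid, row in partnered.iterrows():
        partner = row["partner"]
        if tid > partner:
            continue  # emit each unordered pair once (both directions)
        used_pairs.add(frozenset((tid, partner)))
        _mutual_pair(tid, partner, 500.0 + float(np.round(rng.uniform(0, 50), 1)))

    if background_pairs > 0:
        plain = truth.index[truth["partner"].isna()]
        bro_ids = [t for t in plain if truth.at[t, "lineage"] == "bro"]
        fru_ids = [t for t in plain if truth.at[t, "lineage"] == "fru"]
        n_bg = min(background_pairs, len(bro_ids), len(fru_ids))
        pick_b = rng.choice(len(bro_ids), size=n_bg, replace=False)
        pick_f = rng.choice(len(fru_ids), size=n_bg, replace=False)
        for ib, jf in zip(pick_b, pick_f):
            q, s = bro_ids[ib], fru_ids[jf]
            used_pairs.add(frozenset((q, s)))
            _mutual_pair(q, s, 300.0 + float(np.round(rng.uniform(0, 100), 1)))
    ids = list(truth.index)
    attempts = 0
    added = 0
    while added < noise_hits and attempts < noise_hits * 50 + 1000 and len(ids) >= 2:
        attempts += 1
        q, s = (ids[k] for k in rng.choice(len(ids), size=2, replace=False))
        key = frozenset((q, s))
        if key in used_pairs:
            continue
        used_pairs.add(key)
        length = int(rng.integers(80, 300))
        rows.append(
            {
                "qseqid": q,
                "sseqid": s,
                "pident": float(np.round(rng.uniform(70, 92), 2)),
                "length": length,
                "mismatch": int(rng.integers(5, 40)),
                "gapopen": int(rng.integers(0, 5)),
                "qstart": 1,
                "qend": length,
                "sstart": 1,
                "send": length,
                "evalue": float(10.0 ** -rng.uniform(5, 40)),
                "bitscore": float(np.round(rng.uniform(50, 200), 1)),
            }
        )
        added += 1
    return pd.DataFrame(rows, columns=list(OUTFMT6_COLUMNS))


# -- orthogroup sequence simulation --------------------------------------

FOCAL_GENUS = "Argyranthemum"
FOCAL_TAXA = ("bro", "fru", "sun", "lem")
OUTGROUPS = (("hel", "Helianthus"), ("lac", "Lactuca"))
_ALPHABET = np.array(list("ACGT"))


def _mutate(rng: np.random.Generator, seq: np.ndarray, p: float) -> np.ndarray:
    """Jukes-Cantor-style per-site substitution with probability p."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < p)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = (out[hit] + shift) % 4
    return out


def simulate_orthogroup_sequences(
    n_ogs: int,
    paralog_fraction: float = 0.0,
    divergence: float = 0.05,
    seed: int = 0,
    seq_length: int = 400,
) -> tuple[list[Orthogroup], pd.DataFrame]:
    """Orthogroup sequence sets with known genus-monophyly status.

    Each orthogroup holds one transcript per focal taxon (genus
    Argyranthemum) plus two outgroup-genus transcripts, evolved down a
    fixed ((focal),(outgroup)) topology by uniform per-site substitution
    at rate ``divergence`` per branch.  With probability
    ``paralog_fraction`` an orthogroup is contaminated: an extra
    focal-genus transcript descends from the outgroup ancestor, so the
    focal genus's leaves are non-monophyletic.  Returns the orthogroups
    (with sequences attached) and a truth table.
    """
    if not (0.0 < divergence < 0.5):
        raise ValueError("divergence must lie in (0, 0.5)")
    if not (0.0 <= paralog_fraction <= 1.0):
        raise ValueError("paralog_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ogs: list[Orthogroup] = []
    records = []
    for i in range(n_ogs):
        og_id = f"OG{i:05d}"
        root = rng.integers(0, 4, size=seq_length)
        focal_anc = _mutate(rng, root, divergence)
        out_anc = _mutate(rng, root, divergence)
        members: list[OgMember] = []
        seqs: dict[str, str] = {}
        for taxon in FOCAL_TAXA:
            tid = f"{og_id}_{taxon}"
            members.append(OgMember(tid, taxon, FOCAL_GENUS))
            seqs[tid] = "".join(_ALPHABET[_mutate(rng, focal_anc, divergence)])
        # first outgroup leaf gets its own ancestor so a paralog can be
        # grafted inside the outgroup clade (sister to that leaf)
        first_anc = _mutate(rng, out_anc, divergence)
        first_taxon, first_genus = OUTGROUPS[0]
        tid = f"{og_id}_{first_taxon}"
        members.append(OgMember(tid, first_taxon, first_genus))
        seqs[tid] = "".join(_ALPHABET[_mutate(rng, first_anc, divergence)])
        for taxon, genus in OUTGROUPS[1:]:
            tid = f"{og_id}_{taxon}"
            members.append(OgMember(tid, taxon, genus))
            seqs[tid] = "".join(_ALPHABET[_mutate(rng, out_anc, divergence)])
        contaminated = bool(rng.random() < paralog_fraction)
        if contaminated:
            # focal-genus-labelled transcript nested within the outgroup
            # clade: the focal genus's leaves cannot form a clade
            tid = f"{og_id}_bro_para"
            members.append(OgMember(tid, "bro", FOCAL_GENUS))
            seqs[tid] = "".join(_ALPHABET[_mutate(rng, first_anc, divergence)])
        ogs.append(Orthogroup(id=og_id, members=members, sequences=seqs))
        records.append({"orthogroup": og_id, "contaminated": contaminated})
    truth = pd.DataFrame(records, columns=["orthogroup", "contaminated"]).set_index(
        "orthogroup"
    )
    return ogs, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
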