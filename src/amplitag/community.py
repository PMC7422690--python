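"""OTU-table post-processing, trait annotation and diversity summaries.

The table is an OTU x sample matrix of read counts with per-OTU taxonomy
(best BLAST-style hit parsed at a hard e-value gate) and per-sample metadata
(ecosystem G/F, region, year).  Post-clustering steps implemented here:

* rare-cluster removal (dataset-wide relative abundance below 0.01% by
  default; equality retained),
* best-hit selection per query and non-target (non Cercozoa/Endomyxa) removal,
* functional-trait (nutrition / morphology / locomotion) annotation by
  most-specific-rank lookup,
* guild relative abundances weighted by reads or by OTU counts, overall and
  per ecosystem,
* shared/unique OTU counts between strata, and Shannon H (nats), Pielou's
  J = H / ln S and Bray-Curtis dissimilarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TraitTable",
    "NUTRITION",
    "MORPHOLOGY",
    "LOCOMOTION",
    "RANK_FALLBACK",
    "rare_filter",
    "parse_best_hits",
    "split_taxonomy_path",
    "remove_nontarget",
    "annotate_traits",
    "guild_relabund",
    "sharing_stats",
    "shannon",
    "pielou",
    "bray_curtis",
    "bray_curtis_matrix",
    "alpha_diversity",
]

NUTRITION = {
    "bacterivore", "eukaryvore", "omnivore", "plant parasite",
    "hyperparasite of Oomycota", "autotroph", "unknown",
}
MORPHOLOGY = {
    "naked flagellate", "amoeboflagellate", "naked amoeba",
    "testate-organic/agglutinated", "testate-siliceous",
}
LOCOMOTION = {"creeping/gliding", "swimming", "non-motile", "unknown"}

TRAIT_FACETS = ("nutrition", "morphology", "locomotion")

#: annotation looks up the most specific rank first
RANK_FALLBACK = ("species", "genus", "family", "order", "class")

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class OtuTable:
    """OTU x sample abundance matrix with taxonomy and sample metadata.

    ``counts``: DataFrame, index = OTU ids, columns = sample ids, integers.
    ``taxonomy``: DataFrame indexed by OTU id; any of the columns phylum,
    class, order, family, genus, species plus best-hit identity/evalue.
    ``samples``: DataFrame indexed by sample id with e.g. ecosystem, region,
    year.  Trait columns (nutrition, morphology, locomotion, trait_rank) are
    added by :func:`annotate_traits`.
    """

    counts: pd.DataFrame
    taxonomy: Optional[pd.DataFrame] = None
    samples: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.counts.index.duplicated().any():
            raise ValueError("OTU ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        self.counts.index.name = "otu_id"
        self.counts.columns.name = "sample_id"

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset_otus(self, otu_ids: Sequence) -> "OtuTable":
        tax = self.taxonomy.loc[otu_ids] if self.taxonomy is not None else None
        return OtuTable(self.counts.loc[otu_ids].copy(), tax, self.samples)

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=1) > 0
        return self.subset_otus(self.counts.index[keep])

    # --- I/O -----------------------------------------------------------------

    def write(self, counts_path, taxonomy_path=None, samples_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="otu_id")
        if taxonomy_path is not None and self.taxonomy is not None:
            self.taxonomy.to_csv(taxonomy_path, sep="\t", index_label="otu_id")
        if samples_path is not None and self.samples is not None:
            self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, counts_path, taxonomy_path=None, samples_path=None) -> "OtuTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="otu_id")
        tax = (
            pd.read_csv(taxonomy_path, sep="\t", index_col="otu_id")
            if taxonomy_path is not None
            else None
        )
        samples = (
            pd.read_csv(samples_path, sep="\t", index_col="sample_id")
            if samples_path is not None
            else None
        )
        return cls(counts, tax, samples)


@dataclass
class TraitTable:
    """Functional-trait lookup keyed by (taxon name, rank).

    Vocabularies are closed: a trait file using a category outside the
    nutrition/morphology/locomotion sets is rejected on load.
    """

    table: pd.DataFrame  # columns: taxon, rank, nutrition, morphology, locomotion

    def __post_init__(self) -> None:
        required = {"taxon", "rank", *TRAIT_FACETS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"trait table missing columns: {sorted(missing)}")
        keys = list(zip(self.table["taxon"], self.table["rank"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (taxon, rank) keys in trait table")
        vocab = {
            "nutrition": NUTRITION,
            "morphology": MORPHOLOGY | {"unknown"},
            "locomotion": LOCOMOTION,
        }
        for facet, allowed in vocab.items():
            bad = set(self.table[facet]) - allowed
            if bad:
                raise ValueError(f"unknown {facet} categories: {sorted(bad)}")
        self._index = {
            (row.taxon, row.rank): row for row in self.table.itertuples(index=False)
        }

    def lookup(self, taxon: str, rank: str):
        return self._index.get((taxon, rank))

    @classmethod
    def read(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def default(cls) -> "TraitTable":
        """Small built-in catalog for the Cercozoa/Endomyxa lineages discussed
        in the study system (order-level defaults plus key species)."""
        from importlib.resources import files

        data = files("amplitag.data").joinpath("default_traits.tsv").read_text()
        return cls(pd.read_csv(StringIO(data), sep="\t"))


# --- filtering ----------------------------------------------------------------


def rare_filter(
    table: OtuTable, threshold_frac: float = 0.0001, pool_total: Optional[int] = None
) -> OtuTable:
    """Drop OTUs whose dataset-wide read sum is below ``threshold_frac`` of
    the grand total (default 0.01%); equality is retained.

    ``pool_total`` overrides the reference total, for applying a cutoff
    derived from a larger read pool (e.g. before taxonomy filtering).
    """
    total = pool_total if pool_total is not None else table.grand_total
    if total <= 0:
        raise ValueError("table has no reads")
    sums = table.counts.sum(axis=1)
    keep = table.counts.index[sums >= threshold_frac * total]
    return table.subset_otus(keep)


def parse_best_hits(
    hits: Union[pd.DataFrame, str, Path],
    max_evalue: float = 1e-50,
) -> pd.DataFrame:
    """Reduce tabular (BLAST outfmt-6 style) alignments to one best hit per query.

    Best = minimal e-value, ties broken by highest identity then first
    occurrence.  Queries whose best e-value exceeds ``max_evalue`` are marked
    unassigned (gate is <=, so hits exactly at the cutoff are kept).
    Malformed rows are skipped with a warning.
    """
    cols = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    if isinstance(hits, pd.DataFrame):
        df = hits.copy()
        if "query" not in df.columns:
            df.columns = cols[: len(df.columns)]
    else:
        rows = []
        text = Path(hits).read_text() if not str(hits).startswith(">") else str(hits)
        for ln, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                warnings.warn(f"skipping malformed hit row {ln}: {line[:60]!r}")
                continue
            try:
                rows.append(
                    dict(
                        zip(
                            cols,
                            parts[:2]
                            + [float(parts[2]), int(parts[3]), int(parts[4]), int(parts[5]),
                               int(parts[6]), int(parts[7]), int(parts[8]), int(parts[9]),
                               float(parts[10]), float(parts[11])],
                        )
                    )
                )
            except ValueError:
                warnings.warn(f"skipping malformed hit row {ln}: {line[:60]!r}")
        df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return pd.DataFrame(columns=["subject", "pident", "evalue", "assigned"])
    df = df.reset_index(drop=True)
    df["_order"] = np.arange(len(df))
    df = df.sort_values(["query", "evalue", "pident", "_order"],
                        ascending=[True, True, False, True])
    best = df.groupby("query", sort=True).first()
    best["assigned"] = best["evalue"] <= max_evalue
    return best[["subject", "pident", "evalue", "assigned"]]


def split_taxonomy_path(path_str: str, sep: str = ";") -> dict[str, str]:
    """Split a 'phylum;class;order;family;genus;species' path into ranks.

    Shorter paths fill the leading ranks; missing ranks come back empty.
    """
    parts = [p.strip() for p in str(path_str).split(sep)]
    out = dict.fromkeys(TAXONOMY_RANKS, "")
    for rank, part in zip(TAXONOMY_RANKS, parts):
        out[rank] = part
    return out


def remove_nontarget(
    table: OtuTable, target_phyla: frozenset[str] = frozenset({"Cercozoa", "Endomyxa"})
) -> tuple[OtuTable, float]:
    """Drop OTUs whose taxonomy lacks a target phylum; returns (table,
    retained fraction of OTUs)."""
    if table.taxonomy is None or "phylum" not in table.taxonomy.columns:
        raise ValueError("taxonomy with a 'phylum' column is required")
    phyla = table.taxonomy.loc[table.counts.index, "phylum"]
    keep = table.counts.index[phyla.isin(target_phyla)]
    retained = len(keep) / table.n_otus if table.n_otus else 0.0
    return table.subset_otus(keep), retained


def annotate_traits(table: OtuTable, traits: TraitTable) -> OtuTable:
    """Attach nutrition/morphology/locomotion to every OTU.

    Lookup walks species -> genus -> family -> order -> class and stops at the
    first rank present in the trait table; OTUs matching nowhere get
    'unknown' in every facet.  The rank used is recorded in ``trait_rank``.
    """
    if table.taxonomy is None:
        raise ValueError("taxonomy is required for trait annotation")
    tax = table.taxonomy.copy()
    annotations = {f: [] for f in TRAIT_FACETS}
    used_rank = []
    for otu in table.counts.index:
        row = tax.loc[otu]
        hit, rank_used = None, ""
        for rank in RANK_FALLBACK:
            name = str(row.get(rank, "") or "")
            if not name:
                continue
            hit = traits.lookup(name, rank)
            if hit is not None:
                rank_used = rank
                break
        for facet in TRAIT_FACETS:
            annotations[facet].append(getattr(hit, facet) if hit is not None else "unknown")
        used_rank.append(rank_used)
    for facet in TRAIT_FACETS:
        tax[facet] = pd.Series(annotations[facet], index=table.counts.index)
    tax["trait_rank"] = pd.Series(used_rank, index=table.counts.index)
    return OtuTable(table.counts.copy(), tax, table.samples)


# --- summaries ----------------------------------------------------------------


def _strata(table: OtuTable, stratum: str) -> dict[str, list[str]]:
    if table.samples is None or stratum not in table.samples.columns:
        raise ValueError(f"sample metadata column {stratum!r} is required")
    meta = table.samples.loc[table.counts.columns, stratum]
    groups: dict[str, list[str]] = {}
    for sid, val in meta.items():
        groups.setdefault(str(val), []).append(sid)
    return dict(sorted(groups.items()))


def guild_relabund(
    table: OtuTable,
    facet: str = "nutrition",
    weight: str = "reads",
    stratum: str = "ecosystem",
) -> pd.DataFrame:
    """Per-category percentages for one trait facet, overall and per stratum.

    ``weight='reads'`` weights categories by read counts; ``weight='otus'``
    by the number of OTUs present (nonzero) in the stratum.  Every column
    sums to 100 (within 1e-9) whenever the stratum has any signal.
    """
    if facet not in TRAIT_FACETS:
        raise ValueError(f"facet must be one of {TRAIT_FACETS}")
    if weight not in ("reads", "otus"):
        raise ValueError("weight must be 'reads' or 'otus'")
    if table.taxonomy is None or facet not in table.taxonomy.columns:
        raise ValueError("annotate_traits must run before guild_relabund")
    labels = table.taxonomy.loc[table.counts.index, facet]
    columns: dict[str, pd.Series] = {"all": pd.Series(True, index=table.counts.columns)}
    if table.samples is not None and stratum in (table.samples.columns if table.samples is not None else []):
        for value, sids in _strata(table, stratum).items():
            columns[value] = pd.Series(
                [s in set(sids) for s in table.counts.columns], index=table.counts.columns
            )
    out = {}
    for col_name, mask in columns.items():
        sub = table.counts.loc[:, mask[mask].index]
        if weight == "reads":
            per_otu = sub.sum(axis=1).astype(float)
        else:
            per_otu = (sub.sum(axis=1) > 0).astype(float)
        total = per_otu.sum()
        by_cat = per_otu.groupby(labels).sum()
        out[col_name] = 100.0 * by_cat / total if total > 0 else by_cat * 0.0
    result = pd.DataFrame(out).fillna(0.0)
    result.index.name = facet
    result.attrs["weight"] = weight  # label which weighting produced these numbers
    return result


def sharing_stats(table: OtuTable, stratum: str = "ecosystem") -> dict:
    """Counts of OTUs present in all stratum values (shared) and in exactly
    one (unique per value).  Presence = nonzero read sum within the stratum."""
    groups = _strata(table, stratum)
    if len(groups) < 2:
        raise ValueError("sharing requires at least two stratum values")
    presence = pd.DataFrame(
        {val: table.counts[sids].sum(axis=1) > 0 for val, sids in groups.items()}
    )
    n_present = presence.sum(axis=1)
    shared = int((n_present == len(groups)).sum())
    unique = {
        val: int((presence[val] & (n_present == 1)).sum()) for val in groups
    }
    return {"shared": shared, "unique": unique, "total": int(table.n_otus)}


# --- diversity ----------------------------------------------------------------


def shannon(abundances: Sequence[float], base: Optional[float] = None) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default).

    Input is normalized internally; zero entries contribute nothing.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("at least one abundance must be positive")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def pielou(h: float, s: int) -> float:
    """Pielou's evenness J = H / ln S; defined as 0 when S <= 1."""
    if s <= 1:
        return 0.0
    return h / math.log(s)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(a - b).sum() / denom)


def bray_curtis_matrix(table: OtuTable) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples (relative
    abundances per sample, as in standard community workflows)."""
    m = table.counts.to_numpy(dtype=float)
    totals = m.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("every sample needs at least one read")
    rel = m / totals
    n = rel.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(rel[:, i][:, None] - rel[:, i + 1 :]).sum(axis=0)
        sums = (rel[:, i][:, None] + rel[:, i + 1 :]).sum(axis=0)
        out[i, i + 1 :] = diff / sums
    out = out + out.T
    return pd.DataFrame(out, index=table.counts.columns, columns=table.counts.columns)


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness S, Shannon H (nats) and Pielou's J."""
    rows = []
    for sid in table.counts.columns:
        x = table.counts[sid].to_numpy(dtype=float)
        s = int((x > 0).sum())
        h = shannon(x) if x.sum() > 0 else 0.0
        rows.append({"sample_id": sid, "richness": s, "shannon": h, "pielou": pielou(h, s)})
    return pd.DataFrame(rows).set_index("sample_id")
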