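"""Count-matrix and metadata I/O, library-size normalization, expression
filters, and the variance-stabilizing transform used for ordination.

The central containers are :class:`CountMatrix` (genes x samples integer
reads, optionally with a matching matrix of per-(gene, sample) length
offsets) and :class:`SampleTable` (per-sample species, species-pair and
habitat factors).  The study design is a set of phylogenetically
independent species pairs, each pairing one desert specialist with a
mesic relative; every statistical contrast downstream is desert vs.
mesic within pair, so the table enforces exactly one species of each
habitat per pair.

Normalization follows the median-of-ratios convention: reference genes
are those with nonzero counts in every sample, each sample's factor is
the median across reference genes of its count divided by the gene's
geometric mean.  The variance-stabilizing transform is
``log2(count / size_factor + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HABITATS = ("desert", "mesic")


class ValidationError(ValueError):
    """Malformed input data (bad counts, duplicate ids, unknown levels)."""


class DesignError(ValueError):
    """Metadata that violates the paired desert/mesic study design."""


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample.
    length_offsets
        Optional strictly positive per-(gene, sample) factors (e.g.
        relative transcript lengths) entering downstream GLMs as known
        multiplicative offsets.  Same shape/labels as ``counts``.
    """

    counts: pd.DataFrame
    length_offsets: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("counts contain missing values")
        if (arr < 0).any():
            bad = c.index[(arr < 0).any(axis=1)][0]
            raise ValidationError(f"negative count in gene {bad!r}")
        if not np.allclose(arr, np.round(arr)):
            bad = c.index[(arr != np.round(arr)).any(axis=1)][0]
            raise ValidationError(f"non-integer count in gene {bad!r}")
        c = c.astype(np.int64)
        c.index.name = "gene_id"
        c.columns.name = None
        object.__setattr__(self, "counts", c)
        lo = self.length_offsets
        if lo is not None:
            if lo.shape != c.shape or list(lo.index) != list(c.index) or list(lo.columns) != list(c.columns):
                raise ValidationError("length_offsets must match counts in shape and labels")
            if not (lo.to_numpy() > 0).all():
                raise ValidationError("length_offsets must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes) -> "CountMatrix":
        genes = [g for g in self.counts.index if g in set(genes)]
        lo = self.length_offsets.loc[genes] if self.length_offsets is not None else None
        return CountMatrix(self.counts.loc[genes], lo)

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        lo = self.length_offsets[samples] if self.length_offsets is not None else None
        return CountMatrix(self.counts[samples], lo)


@dataclass(frozen=True)
class SampleTable:
    """Per-sample design factors: species, species pair, habitat.

    Each pair must contain exactly one desert and one mesic species and
    every species needs at least two replicates so that within-cell
    variability (hence dispersion) is estimable.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "species", "pair", "habitat")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        bad = set(t["habitat"]) - set(HABITATS)
        if bad:
            raise ValidationError(f"unknown habitat level(s): {sorted(bad)}; expected {HABITATS}")
        for pair, sub in t.groupby("pair"):
            habs = sub.groupby("species")["habitat"].agg(lambda s: s.iloc[0])
            mixed = sub.groupby("species")["habitat"].nunique()
            if (mixed > 1).any():
                raise DesignError(f"species with inconsistent habitat in pair {pair!r}")
            if sorted(habs.tolist()) != ["desert", "mesic"]:
                raise DesignError(
                    f"pair {pair!r} must have exactly one desert and one mesic species, got {habs.to_dict()}"
                )
        reps = t.groupby("species").size()
        if (reps < 2).any():
            few = reps[reps < 2].index.tolist()
            raise DesignError(f"species with < 2 replicates: {few}")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def pairs(self) -> list[str]:
        return sorted(self.table["pair"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def subset_pair(self, pair: str) -> "SampleTable":
        sub = self.table[self.table["pair"] == pair]
        if sub.empty:
            raise DesignError(f"pair {pair!r} absent from metadata")
        return SampleTable(sub.copy())

    def aligned_to(self, sample_ids) -> "SampleTable":
        """Reorder rows to a given sample order (all ids must be present)."""
        t = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleTable(t)

    def desert_indicator(self) -> np.ndarray:
        return (self.table["habitat"] == "desert").to_numpy(dtype=float)


def read_counts(path, length_offsets_path=None) -> CountMatrix:
    """Read a gene x sample count TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty count table")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise ValidationError(f"{path}: non-numeric count at gene {row!r}, sample {col!r}")
        df[col] = coerced
    lo = None
    if length_offsets_path is not None:
        lo = pd.read_csv(length_offsets_path, sep="\t", index_col=0)
    return CountMatrix(df, lo)


def write_counts(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> SampleTable:
    """Read the sample metadata TSV (sample_id, species, pair, habitat)."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    return SampleTable(t)


def write_metadata(meta: SampleTable, path) -> None:
    meta.table.to_csv(path, sep="\t", index=False)


def check_samples_match(cm: CountMatrix, meta: SampleTable) -> None:
    missing = set(meta.sample_ids) - set(cm.sample_ids)
    if missing:
        raise ValidationError(f"metadata samples absent from count matrix: {sorted(missing)}")


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios library-size factors.

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median over reference genes of
    ``count / geometric_mean``.
    """
    counts = cm.counts.to_numpy(dtype=float)
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValidationError(
            "no gene has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference (pseudo-reference fallback is disabled)"
        )
    refc = counts[ref]
    log_geomean = np.log(refc).mean(axis=1)
    ratios = np.exp(np.log(refc) - log_geomean[:, None])
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=cm.sample_ids, name="size_factor")


def filter_genes(cm: CountMatrix, meta: SampleTable, rule: str = "shared_model",
                 pair: str | None = None, shared_min: float = 20.0,
                 pairwise_min: float = 10.0) -> list[str]:
    """Expression filters on raw counts.

    ``shared_model`` keeps genes whose mean count per sample is strictly
    greater than ``shared_min`` within *every* species; ``pairwise``
    keeps genes whose mean count across the named pair's samples is at
    least ``pairwise_min``.
    """
    check_samples_match(cm, meta)
    counts = cm.counts[meta.sample_ids]
    if rule == "shared_model":
        keep = pd.Series(True, index=counts.index)
        for _, sub in meta.table.groupby("species"):
            m = counts[list(sub["sample_id"])].mean(axis=1)
            keep &= m > shared_min
    elif rule == "pairwise":
        if pair is None:
            raise ValueError("rule='pairwise' requires a pair argument")
        sub = meta.subset_pair(pair)
        keep = counts[sub.sample_ids].mean(axis=1) >= pairwise_min
    else:
        raise ValueError(f"unknown filter rule {rule!r}")
    kept = list(counts.index[keep])
    if not kept:
        logger.warning("filter_genes(%s) kept no genes", rule)
    return kept


def vst(cm: CountMatrix, sf: pd.Series) -> pd.DataFrame:
    """log2(normalized count + 1): monotone, zero-preserving at s=1."""
    s = sf.loc[cm.sample_ids].to_numpy(dtype=float)
    if not (s > 0).all():
        raise ValidationError("size factors must be strictly positive")
    x = cm.counts.to_numpy(dtype=float) / s
    return pd.DataFrame(np.log2(x + 1.0), index=cm.gene_ids, columns=cm.sample_ids)
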