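"""End-to-end orchestration: filter -> shared model -> classification ->
permutation null -> pairwise DE -> concordance -> correlations ->
ordination -> gene-list overlaps, with every output written to disk and
a machine-readable JSON report.  Deterministic for a fixed seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io_norm import filter_genes, read_counts, read_metadata, size_factors, vst
from .nbglm import pairwise_de
from .ordination import linkage_to_newick, sample_cluster, sample_pca
from .overlap import hypergeometric_overlap, read_gene_list
from .permute import permutation_null
from .shared import (classify_shared, direction_concordance, fit_shared_model,
                     fold_change_correlation, magnitude_filter, shared_counts)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration; defaults are the analysis cutoffs."""

    counts: str
    metadata: str
    out_dir: str
    seed: int
    length_offsets: str | None = None
    gene_lists: dict[str, str] = field(default_factory=dict)
    fdr_habitat: float = 0.01
    fdr_interaction: float = 0.05
    pairwise_fdr: float = 0.01
    shared_filter_min: float = 20.0
    pairwise_filter_min: float = 10.0
    magnitude_threshold: float = 0.5
    n_perm: int = 10000

    def __post_init__(self) -> None:
        for name in ("fdr_habitat", "fdr_interaction", "pairwise_fdr"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1); got {v}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.seed is None:
            raise ValueError("an explicit seed is required for reproducibility")
        for p in [self.counts, self.metadata, self.length_offsets, *self.gene_lists.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the report dictionary (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed}

    cm = read_counts(cfg.counts, cfg.length_offsets)
    meta = read_metadata(cfg.metadata)
    sf = size_factors(cm)
    sf.to_csv(out / "size_factors.tsv", sep="\t", header=True)

    analyzed = filter_genes(cm, meta, rule="shared_model", shared_min=cfg.shared_filter_min)
    report["n_genes_input"] = cm.shape[0]
    report["n_genes_analyzed"] = len(analyzed)

    logger.info("shared model on %d genes", len(analyzed))
    results = fit_shared_model(cm, meta, sf=sf, genes=analyzed)
    classified = classify_shared(results, cfg.fdr_habitat, cfg.fdr_interaction)
    classified.to_csv(out / "shared_classification.tsv", sep="\t", index=False)
    counts = shared_counts(classified)
    report["shared"] = counts
    big = magnitude_filter(classified, threshold=cfg.magnitude_threshold)
    report["shared"]["n_above_magnitude"] = len(big)

    logger.info("permutation null (%d permutations)", cfg.n_perm)
    null = permutation_null(cm, meta, n_perm=cfg.n_perm, seed=cfg.seed,
                            fdr_habitat=cfg.fdr_habitat,
                            fdr_interaction=cfg.fdr_interaction, sf=sf, genes=analyzed)
    report["permutation"] = null.summary()
    with open(out / "permutation_null.tsv", "w") as fh:
        fh.write("null_count\n")
        for c in null.null_counts:
            fh.write(f"{int(c)}\n")

    de_tables = []
    for pair in meta.pairs:
        tab = pairwise_de(cm, meta, pair, sf=sf)
        tab.to_csv(out / f"pairwise_de_{pair}.tsv", sep="\t", index=False)
        de_tables.append(tab)
    report["pairwise"] = {
        pair: {"n_tested": len(tab),
               "n_significant": int((tab["q_value"] < cfg.pairwise_fdr).sum())}
        for pair, tab in zip(meta.pairs, de_tables)}

    all_sig, concordant = direction_concordance(de_tables, q_threshold=cfg.pairwise_fdr)
    report["concordance"] = {"n_all_significant": len(all_sig),
                             "n_concordant": len(concordant)}
    report["fold_change_correlations"] = {}
    for i in range(len(de_tables)):
        for j in range(i + 1, len(de_tables)):
            rho, p = fold_change_correlation(de_tables[i], de_tables[j])
            key = f"{meta.pairs[i]}_vs_{meta.pairs[j]}"
            report["fold_change_correlations"][key] = {"rho": rho, "p": p}

    x = vst(cm.subset_genes(analyzed), sf)
    pca = sample_pca(x)
    with open(out / "pca_scores.tsv", "w") as fh:
        fracs = ", ".join(f"{v:.4f}" for v in pca.variance_fractions[:6])
        fh.write(f"# variance fractions: {fracs}\n")
        pca.scores.to_csv(fh, sep="\t")
    report["pca_variance_fractions"] = [float(v) for v in pca.variance_fractions[:6]]
    z, labels = sample_cluster(x)
    (out / "sample_tree.nwk").write_text(linkage_to_newick(z, labels))

    if cfg.gene_lists:
        shared_set = set(classified.loc[classified["status"] != "not_shared", "gene_id"])
        universe = set(analyzed)
        report["overlaps"] = {}
        for name, path in cfg.gene_lists.items():
            genes = read_gene_list(path)
            ov = hypergeometric_overlap(genes, shared_set, universe)
            report["overlaps"][name] = ov.to_dict()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
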