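"""Structured permutation null for the shared-gene count.

The null hypothesis is that desert/mesic labels carry no information
beyond the species structure.  For each gene independently, and within
each species pair independently, the two species' habitat labels are
exchanged with probability 1/2 — all replicates of a species move
together — giving 2^P equally likely label configurations per gene
(8 for three pairs).  Each permuted dataset is pushed through the same
shared-model fit, BH adjustment and classification rule as the observed
data, and the number of shared genes is recorded; the observed count is
ranked against this null with the add-one empirical p-value
``(1 + #{null >= observed}) / (n_perm + 1)``.

Only the (pair + habitat) model's log-likelihood depends on the habitat
labeling — the pair-only and saturated models are invariant under
within-pair swaps — so the fit for each of the 2^P configurations is
computed once and each permuted dataset's statistics are assembled by
lookup.  This is exactly equivalent to refitting every permutation.
Per-gene dispersions are estimated once on the observed data (the
species cells, hence the dispersion estimator, are label-free).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_norm import CountMatrix, SampleTable
from .nbglm import bh_adjust, lrt_pvalues
from .shared import SharedModelData

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """Observed shared-gene count against its label-swap null distribution."""

    observed_count: int
    null_counts: np.ndarray
    n_perm: int
    seed: int
    empirical_p: float

    def summary(self) -> dict:
        return {
            "observed_count": int(self.observed_count),
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
            "empirical_p": float(self.empirical_p),
            "null_mean": float(np.mean(self.null_counts)),
            "null_max": int(np.max(self.null_counts)),
        }


def permute_assignment(meta: SampleTable, rng: np.random.Generator,
                       n_genes: int = 1) -> np.ndarray:
    """Draw per-gene, per-pair habitat swap indicators (n_genes x P bool)."""
    P = len(meta.pairs)
    return rng.integers(0, 2, size=(n_genes, P)).astype(bool)


def swapped_desert(meta: SampleTable, swap: np.ndarray) -> np.ndarray:
    """Desert indicator after exchanging labels within flagged pairs."""
    desert = meta.desert_indicator().astype(int)
    pair_index = meta.table["pair"].map({p: i for i, p in enumerate(meta.pairs)}).to_numpy()
    flip = np.asarray(swap, dtype=int)[pair_index]
    return (desert ^ flip).astype(float)


def _config_bits(c: int, P: int) -> np.ndarray:
    return np.array([(c >> k) & 1 for k in range(P)], dtype=bool)


def empirical_pvalue(observed: int, null_counts) -> float:
    """Add-one empirical upper-tail p-value."""
    null_counts = np.asarray(null_counts)
    if null_counts.size == 0:
        raise ValueError("null_counts is empty")
    return float((1 + int((null_counts >= observed).sum())) / (null_counts.size + 1))


def shared_count_pvalues(data: SharedModelData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-configuration habitat/interaction p-value matrices.

    Returns ``habitat_p`` and ``interaction_p`` with shape (2^P, G) plus
    the boolean gene mask (converged under every configuration) that
    fixes the gene universe for BH within each permuted dataset.
    """
    P = data.n_pairs
    n_config = 2 ** P
    G = len(data.genes)
    habitat_p = np.empty((n_config, G))
    interaction_p = np.empty((n_config, G))
    mask = np.asarray(data.converged, dtype=bool).copy()
    for c in range(n_config):
        desert = swapped_desert(data.meta, _config_bits(c, P))
        ll_ph, conv = data.habitat_loglik(desert)
        habitat_p[c] = lrt_pvalues(ll_ph, data.ll_pair, df=1)
        interaction_p[c] = lrt_pvalues(data.ll_full, ll_ph, df=P - 1)
        mask &= np.asarray(conv, dtype=bool)
    return habitat_p, interaction_p, mask


def _count_shared(hab_p: np.ndarray, int_p: np.ndarray, fdr_habitat: float,
                  fdr_interaction: float) -> int:
    q_h = bh_adjust(hab_p)
    q_i = bh_adjust(int_p)
    return int(((q_h < fdr_habitat) & (q_i > fdr_interaction)).sum())


def permutation_null(cm: CountMatrix, meta: SampleTable, n_perm: int = 10000,
                     seed: int = 0, fdr_habitat: float = 0.01,
                     fdr_interaction: float = 0.05, sf: pd.Series | None = None,
                     genes: list[str] | None = None,
                     per_gene: bool = True) -> PermutationNull:
    """Monte-Carlo null distribution of the shared-gene count.

    ``genes`` should be the observed-data filtered set (the filter is
    not recomputed per permutation).  ``per_gene=False`` switches to a
    dataset-level swap (one configuration for all genes per permuted
    dataset) for sensitivity analysis.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    data = SharedModelData.build(cm, meta, sf=sf, genes=genes)
    habitat_p, interaction_p, mask = shared_count_pvalues(data)
    if not mask.any():
        raise ValueError("no gene converged under every label configuration")
    habitat_p = habitat_p[:, mask]
    interaction_p = interaction_p[:, mask]
    G = int(mask.sum())
    n_config = habitat_p.shape[0]

    observed = _count_shared(habitat_p[0], interaction_p[0], fdr_habitat, fdr_interaction)

    rng = np.random.default_rng(seed)
    gene_idx = np.arange(G)
    null_counts = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        if per_gene:
            cfg = rng.integers(0, n_config, size=G)
        else:
            cfg = np.full(G, rng.integers(0, n_config))
        null_counts[b] = _count_shared(habitat_p[cfg, gene_idx],
                                       interaction_p[cfg, gene_idx],
                                       fdr_habitat, fdr_interaction)
    p = empirical_pvalue(observed, null_counts)
    logger.info("permutation null: observed=%d, null max=%d, p=%.3g",
                observed, int(null_counts.max()), p)
    return PermutationNull(observed, null_counts, n_perm, seed, p)
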