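"""Shared (convergent) expression shifts across species pairs.

A gene shows a shared desert shift when the habitat main effect is
significant (BH q below ``fdr_habitat``, default 0.01) while the
habitat x pair interaction is not (q above ``fdr_interaction``, default
0.05) — i.e. the desert/mesic contrast is consistent in magnitude across
all pairs.  The habitat test is the likelihood-ratio test of
(pair + habitat) vs. (pair); the interaction test is the joint LRT of
the saturated model vs. (pair + habitat) with P-1 degrees of freedom.
Per-pair log2 fold changes come from the saturated model's cell means.

Shared genes are further labeled ``shared_up`` / ``shared_down`` when
all per-pair fold changes agree in sign, else ``shared_discordant``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_norm import CountMatrix, SampleTable, check_samples_match, size_factors
from .nbglm import (LOG2, bh_adjust, build_design, estimate_dispersion,
                    estimate_dispersion_cr, irls_many, log_offsets, lrt_pvalues)

logger = logging.getLogger(__name__)

STATUSES = ("shared_up", "shared_down", "shared_discordant", "not_shared")


@dataclass
class SharedModelData:
    """Precomputed per-gene quantities for the shared model.

    The pair-only and saturated-model log-likelihoods are invariant
    under within-pair habitat label swaps (a swap only renames which
    species cell carries the desert label), so they are computed once;
    ``habitat_loglik`` refits only the (pair + habitat) model for a
    given desert indicator.  The permutation null exploits this.
    """

    genes: list[str]
    meta: SampleTable
    Y: np.ndarray
    offsets: np.ndarray
    alpha: np.ndarray
    ll_pair: np.ndarray
    ll_full: np.ndarray
    full_beta: np.ndarray
    converged: np.ndarray

    @classmethod
    def build(cls, cm: CountMatrix, meta: SampleTable, sf: pd.Series | None = None,
              genes: list[str] | None = None, dispersion: str = "cr") -> "SharedModelData":
        check_samples_match(cm, meta)
        for pair in meta.pairs:
            sub = meta.subset_pair(pair).table
            per_hab = sub.groupby("habitat").size().reindex(["desert", "mesic"]).fillna(0)
            if (per_hab < 2).any():
                raise ValueError(f"pair {pair!r} has < 2 samples in some habitat")
        if sf is None:
            sf = size_factors(cm)
        if genes is None:
            genes = cm.gene_ids
        sub_cm = cm.subset_genes(genes).subset_samples(meta.sample_ids)
        Y = sub_cm.counts.to_numpy(dtype=float)
        offs = log_offsets(sub_cm, sf, meta.sample_ids)
        design = build_design(meta)
        if dispersion == "cr":
            alpha = estimate_dispersion_cr(Y, design.full, offs)
        elif dispersion == "moments":
            species = meta.table["species"].to_numpy()
            alpha = estimate_dispersion(Y, species, sf.loc[meta.sample_ids].to_numpy())
        else:
            raise ValueError(f"unknown dispersion method {dispersion!r}")
        _, ll_pair, conv_p, _ = irls_many(Y, design.pair_only, offs, alpha)
        beta_f, ll_full, conv_f, _ = irls_many(Y, design.full, offs, alpha)
        return cls(sub_cm.gene_ids, meta, Y, offs, alpha, ll_pair, ll_full,
                   beta_f, conv_p & conv_f)

    @property
    def n_pairs(self) -> int:
        return len(self.meta.pairs)

    def habitat_loglik(self, desert: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(pair + habitat) model log-likelihoods for a desert labeling."""
        design = build_design(self.meta, desert=desert)
        _, ll, conv, _ = irls_many(self.Y, design.pair_habitat, self.offsets, self.alpha)
        return ll, conv

    def pair_log2fc(self) -> np.ndarray:
        """(G, P) desert-vs-mesic log2 fold changes from the saturated fit."""
        P = self.n_pairs
        hab = self.full_beta[:, P]  # columns: intercept, P-1 pair, habitat, P-1 interactions
        fcs = [hab]
        for k in range(1, P):
            fcs.append(hab + self.full_beta[:, P + k])
        return np.column_stack(fcs) / LOG2


def fit_shared_model(cm: CountMatrix, meta: SampleTable, sf: pd.Series | None = None,
                     genes: list[str] | None = None, desert: np.ndarray | None = None,
                     dispersion: str = "cr") -> pd.DataFrame:
    """Per-gene habitat and interaction tests plus per-pair log2FC.

    Returns a DataFrame with columns ``habitat_p``, ``habitat_q``,
    ``interaction_p``, ``interaction_q``, ``log2FC_<pair>`` for each
    pair, and ``converged``.  BH is applied separately to the habitat
    and interaction p-vectors over the converged genes.
    """
    data = SharedModelData.build(cm, meta, sf=sf, genes=genes, dispersion=dispersion)
    ll_ph, conv_h = data.habitat_loglik(desert)
    P = data.n_pairs
    habitat_p = lrt_pvalues(ll_ph, data.ll_pair, df=1)
    interaction_p = lrt_pvalues(data.ll_full, ll_ph, df=P - 1)
    conv = data.converged & conv_h
    out = pd.DataFrame({"gene_id": data.genes, "habitat_p": habitat_p,
                        "interaction_p": interaction_p, "converged": conv})
    fcs = data.pair_log2fc()
    for k, pair in enumerate(data.meta.pairs):
        out[f"log2FC_{pair}"] = fcs[:, k]
    out["habitat_q"] = np.nan
    out["interaction_q"] = np.nan
    if (~conv).any():
        logger.warning("fit_shared_model: %d gene(s) did not converge; excluded from FDR",
                       int((~conv).sum()))
    mask = conv.to_numpy() if hasattr(conv, "to_numpy") else conv
    out.loc[mask, "habitat_q"] = bh_adjust(out.loc[mask, "habitat_p"].to_numpy())
    out.loc[mask, "interaction_q"] = bh_adjust(out.loc[mask, "interaction_p"].to_numpy())
    return out


def classify_shared(results: pd.DataFrame, fdr_habitat: float = 0.01,
                    fdr_interaction: float = 0.05) -> pd.DataFrame:
    """Apply the shared-shift rule and direction labels.

    shared iff habitat_q < fdr_habitat and interaction_q > fdr_interaction;
    within shared genes, up/down when all per-pair log2FC share one sign,
    discordant otherwise.
    """
    fc_cols = [c for c in results.columns if c.startswith("log2FC_")]
    q_h = results["habitat_q"].to_numpy(dtype=float)
    q_i = results["interaction_q"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        shared = (q_h < fdr_habitat) & (q_i > fdr_interaction)
    shared &= ~np.isnan(q_h) & ~np.isnan(q_i)
    fcs = results[fc_cols].to_numpy(dtype=float)
    all_up = (fcs > 0).all(axis=1)
    all_down = (fcs < 0).all(axis=1)
    status = np.where(~shared, "not_shared",
                      np.where(all_up, "shared_up",
                               np.where(all_down, "shared_down", "shared_discordant")))
    out = results.copy()
    out["status"] = status
    return out


def shared_counts(classified: pd.DataFrame) -> dict[str, int]:
    vc = classified["status"].value_counts()
    counts = {s: int(vc.get(s, 0)) for s in STATUSES}
    counts["shared_total"] = counts["shared_up"] + counts["shared_down"] + counts["shared_discordant"]
    return counts


def direction_concordance(de_tables: list[pd.DataFrame], q_threshold: float = 0.01
                          ) -> tuple[set[str], set[str]]:
    """Genes significant in every pair, and the subset with one sign.

    ``all_sig`` collects genes with q below threshold in every table;
    ``concordant`` keeps those whose log2FC sign agrees across tables.
    """
    sigs = []
    signs = {}
    for tab in de_tables:
        sub = tab[tab["q_value"] < q_threshold]
        sigs.append(set(sub["gene_id"]))
        signs[id(tab)] = dict(zip(sub["gene_id"], np.sign(sub["log2FC"])))
    all_sig = set.intersection(*sigs) if sigs else set()
    if not all_sig:
        logger.info("direction_concordance: no gene significant in every pair")
    concordant = set()
    for g in all_sig:
        s = {signs[id(tab)][g] for tab in de_tables}
        if len(s) == 1 and 0 not in s:
            concordant.add(g)
    return all_sig, concordant


def magnitude_filter(classified: pd.DataFrame, threshold: float = 0.5,
                     mode: str = "mean") -> list[str]:
    """Shared genes whose fold-change magnitude clears ``threshold``.

    ``mode='mean'`` (default) requires the mean |log2FC| across pairs to
    exceed the threshold; ``mode='min'`` requires every pair to exceed it.
    """
    fc_cols = [c for c in classified.columns if c.startswith("log2FC_")]
    sh = classified[classified["status"] != "not_shared"]
    mags = sh[fc_cols].abs().to_numpy(dtype=float)
    if mode == "mean":
        keep = mags.mean(axis=1) > threshold
    elif mode == "min":
        keep = (mags > threshold).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return list(sh["gene_id"].to_numpy()[keep])


def fold_change_correlation(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation of log2FC over the common gene set."""
    merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
    if len(merged) < 10:
        raise ValueError(f"only {len(merged)} genes in common; need >= 10")
    x = merged["log2FC_a"].to_numpy()
    y = merged["log2FC_b"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant fold-change vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
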