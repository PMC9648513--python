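"""Synthetic RNA-seq counts with the paired desert/mesic study structure.

The generator runs the analysis model forward: gene *i*, sample *j* gets
``y_ij ~ NB(mean = s_j * exp(eta_ij), dispersion = alpha_i)`` with
``Var = mu + alpha mu^2``, where ``eta`` stacks a per-gene baseline,
a per-(gene, pair) offset, an optional per-(gene, species) offset, and
the planted habitat effects.  Genes fall into three truth classes:

* ``null`` — no habitat effect anywhere;
* ``shared`` — one log2 fold change applied identically to the desert
  species of every pair (sign drawn from the configured up-fraction);
* ``interaction`` — independent per-pair log2 fold changes (possibly
  opposite signs), i.e. lineage-specific shifts.

Defaults mirror the study design this pipeline targets: three species
pairs, five replicates per species with one species at four, ~8,000
analyzed genes, modest shared effect sizes, and per-gene dispersions
typical of bulk RNA-seq.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import math

import numpy as np
import pandas as pd
import yaml

from .io_norm import CountMatrix, SampleTable

NB_ALPHA_POISSON = 1e-6  # below this, draw straight Poisson


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_pairs: int = 3
    replicates: int = 5
    unbalanced: bool = True          # one species gets replicates - 1
    n_genes: int = 8000
    baseline_log_mean: float = 5.0   # natural-log scale of per-gene mean count
    baseline_log_sd: float = 1.5
    pair_offset_sd: float = 0.5      # per-(gene, pair) expression divergence
    species_offset_sd: float = 0.0   # habitat-independent lineage noise
    shared_fraction: float = 0.08
    shared_log2fc_mean: float = math.log(0.4)  # lognormal params of |log2FC|
    shared_log2fc_sd: float = 0.6
    shared_log2fc_min: float = 0.0           # magnitude floor for planted effects
    shared_up_fraction: float = 0.48
    interaction_fraction: float = 0.15
    interaction_log2fc_sd: float = 1.2       # per-pair Normal(0, sd) effects
    dispersion_log_mean: float = math.log(0.08)
    dispersion_log_sd: float = 0.8
    dispersion_max: float | None = None      # cap for planted dispersions
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.shared_fraction <= 1 and 0 <= self.interaction_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.shared_fraction + self.interaction_fraction > 1:
            raise ValueError("shared + interaction fractions exceed 1")
        for name in ("baseline_log_sd", "pair_offset_sd", "species_offset_sd",
                     "interaction_log2fc_sd", "dispersion_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be positive and ordered")

    def to_yaml(self, path) -> None:
        d = {k: (float(v) if isinstance(v, (float, np.floating)) else v)
             for k, v in asdict(self).items()}
        d["size_factor_range"] = [float(x) for x in self.size_factor_range]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("size_factor_range") is not None:
            d["size_factor_range"] = tuple(d["size_factor_range"])
        return cls(**d)


def _draw_nb(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draws with Var = mu + alpha mu^2; Poisson at tiny alpha."""
    out = np.empty(mu.shape, dtype=np.int64)
    a = np.broadcast_to(alpha[:, None], mu.shape)
    poisson = a < NB_ALPHA_POISSON
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        lam = rng.gamma(shape=1.0 / a[~poisson], scale=a[~poisson] * mu[~poisson])
        out[~poisson] = rng.poisson(lam)
    return out


def _sample_layout(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for k in range(cfg.n_pairs):
        pair = f"pair{k + 1}"
        for hab in ("desert", "mesic"):
            species = f"sp_{pair}_{hab}"
            reps = cfg.replicates
            if cfg.unbalanced and k == cfg.n_pairs - 1 and hab == "mesic":
                reps = max(cfg.replicates - 1, 2)
            for r in range(reps):
                rows.append({"sample_id": f"{species}_r{r + 1}", "species": species,
                             "pair": pair, "habitat": hab})
    return pd.DataFrame(rows)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SampleTable, pd.DataFrame]:
    """Simulate (CountMatrix, SampleTable, truth table) from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    layout = _sample_layout(cfg)
    meta = SampleTable(layout)
    n = len(layout)
    G = cfg.n_genes
    P = cfg.n_pairs
    pairs = meta.pairs
    pair_idx = layout["pair"].map({p: i for i, p in enumerate(pairs)}).to_numpy()
    species_list = sorted(layout["species"].unique())
    species_idx = layout["species"].map({s: i for i, s in enumerate(species_list)}).to_numpy()
    desert = (layout["habitat"] == "desert").to_numpy()

    # truth classes by exact integer allocation
    n_shared = int(round(cfg.shared_fraction * G))
    n_inter = int(round(cfg.interaction_fraction * G))
    classes = np.array(["shared"] * n_shared + ["interaction"] * n_inter
                       + ["null"] * (G - n_shared - n_inter))

    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=G)
    pair_off = rng.normal(0.0, cfg.pair_offset_sd, size=(G, P))
    species_off = rng.normal(0.0, cfg.species_offset_sd, size=(G, len(species_list))) \
        if cfg.species_offset_sd > 0 else np.zeros((G, len(species_list)))

    log2fc = np.zeros((G, P))
    if n_shared:
        mag = rng.lognormal(cfg.shared_log2fc_mean, cfg.shared_log2fc_sd, size=n_shared)
        mag = np.clip(mag, cfg.shared_log2fc_min, None)
        sign = np.where(rng.random(n_shared) < cfg.shared_up_fraction, 1.0, -1.0)
        log2fc[:n_shared] = (mag * sign)[:, None]
    if n_inter:
        log2fc[n_shared:n_shared + n_inter] = rng.normal(
            0.0, cfg.interaction_log2fc_sd, size=(n_inter, P))

    alpha = rng.lognormal(cfg.dispersion_log_mean, cfg.dispersion_log_sd, size=G)
    if cfg.dispersion_max is not None:
        alpha = np.clip(alpha, None, cfg.dispersion_max)
    lo, hi = cfg.size_factor_range
    sf = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    eta = (baseline[:, None] + pair_off[:, pair_idx] + species_off[:, species_idx]
           + np.log(2.0) * log2fc[:, pair_idx] * desert[None, :])
    if np.max(eta) > 30:
        raise ValueError("simulated log-mean exceeds 30; reduce baseline/effect scales")
    mu = sf[None, :] * np.exp(eta)
    counts = _draw_nb(rng, mu, alpha)

    gene_ids = [f"g{i + 1:05d}" for i in range(G)]
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=layout["sample_id"]))
    truth = pd.DataFrame({"gene_id": gene_ids, "class": classes, "dispersion": alpha})
    for k, p in enumerate(pairs):
        truth[f"log2FC_{p}"] = log2fc[:, k]
    return cm, meta, truth


def simulate_gene_sets(universe_size: int, size_a: int, size_b: int,
                       planted_overlap: int, seed: int = 0
                       ) -> tuple[set[str], set[str], set[str]]:
    """Two gene sets from a universe with an exact planted intersection."""
    if planted_overlap > min(size_a, size_b):
        raise ValueError("planted overlap exceeds a set size")
    if size_a + size_b - planted_overlap > universe_size:
        raise ValueError("sets cannot fit in the universe with this overlap")
    rng = np.random.default_rng(seed)
    universe = [f"g{i + 1}" for i in range(universe_size)]
    perm = rng.permutation(universe_size)
    shared = perm[:planted_overlap]
    only_a = perm[planted_overlap:size_a]
    only_b = perm[size_a:size_a + size_b - planted_overlap]
    a = {universe[i] for i in np.concatenate([shared, only_a]).astype(int)}
    b = {universe[i] for i in np.concatenate([shared, only_b]).astype(int)}
    return a, b, set(universe)
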