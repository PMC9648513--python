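"""Gene-set overlap tests and set accounting.

The overlap between two gene sets drawn from a shared universe is
judged against the hypergeometric distribution: with ``|A|`` and ``|B|``
genes drawn from a universe of ``|U|``, the enrichment p-value is the
upper tail ``P(X >= k)`` of the observed intersection size ``k``, with
expectation ``|A||B|/|U|``.  The universe must be supplied explicitly —
it is the intersection of the analyzed-gene sets of the two experiments
being compared, and the result is meaningless without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetOverlap:
    n_a: int
    n_b: int
    n_universe: int
    overlap: int
    expected: float
    p_value: float

    def to_dict(self) -> dict:
        return {"n_a": self.n_a, "n_b": self.n_b, "n_universe": self.n_universe,
                "overlap": self.overlap, "expected": self.expected,
                "p_value": self.p_value}


def hypergeometric_overlap(a, b, universe, alternative: str = "enrichment") -> GeneSetOverlap:
    """Hypergeometric test of the overlap between gene sets ``a`` and ``b``.

    Both sets are intersected with the universe first.  ``alternative``
    is ``'enrichment'`` (upper tail, P(X >= k)) or ``'depletion'``
    (lower tail, P(X <= k)).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    a = set(a) & universe
    b = set(b) & universe
    k = len(a & b)
    M, nA, nB = len(universe), len(a), len(b)
    expected = nA * nB / M
    if alternative == "enrichment":
        p = float(stats.hypergeom.sf(k - 1, M, nA, nB))
    elif alternative == "depletion":
        p = float(stats.hypergeom.cdf(k, M, nA, nB))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return GeneSetOverlap(nA, nB, M, k, expected, p)


def set_fraction(k: int, n: int, decimals: int = 1) -> float:
    """Percentage 100*k/n rounded half-up to ``decimals`` places."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= k <= n:
        raise ValueError("numerator must lie in [0, n]")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(k) / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def read_gene_list(path) -> set[str]:
    """Read a plain-text gene list (one id per line, '#' comments)."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.add(line)
    if not genes:
        logger.warning("gene list %s is empty", path)
    return genes


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
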