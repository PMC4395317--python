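"""Bayesian diploid genotype inference from pileup data.

The model assigns one of the ten diploid genotypes to a site in a single
sample from the stack of base observations covering it.  Base-calling
errors are not spread uniformly over the three wrong bases: the chance of
misreading into a base is taken proportional to that base's abundance in
the target territory, parameterised by its GC content.  At 50% GC the
model collapses to the familiar uniform e/3 error split; at GC/AT = 2/3
the probability of misreading an A as a C is (2/7)e.

A genotype is only *called* when its posterior dominates the other nine by
a large factor (1000x by default) and the site is covered by more than a
minimum number of qualified reads; otherwise the call is UNCERTAIN, which
downstream logic treats as "no information", never as wild-type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import ALL_GENOTYPES, BASES, Genotype, GenotypeCall, PileupColumn

__all__ = [
    "BaseCompositionModel",
    "base_given_allele",
    "base_given_genotype",
    "genotype_prior",
    "genotype_posterior",
    "call_genotype",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class BaseCompositionModel:
    """Per-base composition weights derived from GC content.

    w_G = w_C = gc/2 and w_A = w_T = (1-gc)/2, so the four weights sum
    to one.  Default 0.41, the average GC content of human exome capture
    territory.
    """

    gc_content: float = 0.41
    weights: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        gc = self.gc_content
        if not 0.0 < gc < 1.0:
            raise ValueError(f"gc_content must be in (0, 1), got {gc}")
        w = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
        object.__setattr__(self, "weights", w)

    def weight(self, base: str) -> float:
        return self.weights[base]


def base_given_allele(b: str, allele: str, e: float, comp: BaseCompositionModel) -> float:
    """p(b | A): probability of observing base ``b`` from a template
    carrying allele ``allele`` when the base-error probability is ``e``.

    The correct base is seen with probability 1 - e; the error mass e is
    split among the three other bases proportionally to their composition
    weights, i.e. p(b|A) = e * w_b / (1 - w_A) for b != A.  The four
    values over b always sum to one.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"error probability {e} outside [0, 1]")
    if b == allele:
        return 1.0 - e
    return e * comp.weight(b) / (1.0 - comp.weight(allele))


def base_given_genotype(b: str, g: Genotype, e: float, comp: BaseCompositionModel) -> float:
    """p(b | {A1, A2}) = 1/2 p(b|A1) + 1/2 p(b|A2).

    A read samples one of the two chromosomes uniformly, so the genotype
    likelihood is the even mixture of the two allele terms; for a
    homozygote this reduces to the single-allele probability.
    """
    a1, a2 = g.alleles
    if a1 == a2:
        return base_given_allele(b, a1, e, comp)
    return 0.5 * base_given_allele(b, a1, e, comp) + 0.5 * base_given_allele(b, a2, e, comp)


def genotype_prior(comp: BaseCompositionModel) -> dict[Genotype, float]:
    """Prior over the ten diploid genotypes from composition weights.

    Hardy-Weinberg products of the per-base weights: p({A,A}) = w_A**2 and
    p({A1,A2}) = 2 w_A1 w_A2 for A1 != A2.  This is the GC-aware,
    reference-free prior; it sums to one by construction.
    """
    prior: dict[Genotype, float] = {}
    for g in ALL_GENOTYPES:
        a1, a2 = g.alleles
        if a1 == a2:
            prior[g] = comp.weight(a1) ** 2
        else:
            prior[g] = 2.0 * comp.weight(a1) * comp.weight(a2)
    return prior


_TABLE_CACHE: dict[tuple[float, float], np.ndarray] = {}


def _log_base_table(e: float, comp: BaseCompositionModel) -> np.ndarray:
    """4x10 table of log p(b | G) for one error probability (cached:
    pileups typically reuse a handful of Phred values)."""
    key = (e, comp.gc_content)
    tab = _TABLE_CACHE.get(key)
    if tab is None:
        tab = np.empty((4, len(ALL_GENOTYPES)))
        for j, g in enumerate(ALL_GENOTYPES):
            for i, b in enumerate(BASES):
                p = base_given_genotype(b, g, e, comp)
                tab[i, j] = math.log(p) if p > 0.0 else -np.inf
        if len(_TABLE_CACHE) > 4096:
            _TABLE_CACHE.clear()
        _TABLE_CACHE[key] = tab
    return tab


def genotype_posterior(
    col: PileupColumn,
    prior: dict[Genotype, float],
    comp: BaseCompositionModel,
) -> dict[Genotype, float]:
    """Posterior p(G | D) over the ten genotypes given one pileup column.

    p(D|G) is the product of per-read terms p(b|G); the evidence p(D) is
    constant across genotypes and cancels in the normalisation.  An empty
    pileup returns the prior unchanged.  Likelihoods are accumulated in
    log space and normalised by max-subtraction so deep pileups at low
    error rates cannot underflow.
    """
    log_post = np.array([math.log(prior[g]) for g in ALL_GENOTYPES])
    if col.observations:
        # group observations by error probability: the log-likelihood is a
        # base-count vector dotted with a 4x10 log-probability table per
        # distinct e, which keeps deep columns cheap
        by_e: dict[float, np.ndarray] = {}
        for b, e, _ in col.observations:
            counts = by_e.setdefault(e, np.zeros(4))
            counts[_BASE_INDEX[b]] += 1
        for e, counts in by_e.items():
            log_post = log_post + counts @ _log_base_table(e, comp)
    m = log_post.max()
    if not np.isfinite(m):  # pragma: no cover - needs prior mass 0
        raise ValueError("all genotypes have zero posterior mass")
    w = np.exp(log_post - m)
    w /= w.sum()
    return dict(zip(ALL_GENOTYPES, w))


def call_genotype(
    col: PileupColumn,
    prior: dict[Genotype, float],
    comp: BaseCompositionModel,
    min_depth: int = 5,
    ratio_threshold: float = 1000.0,
    min_mapq: int | None = None,
) -> GenotypeCall:
    """Call the genotype at one site, or UNCERTAIN.

    The call succeeds only when the number of qualified reads strictly
    exceeds ``min_depth`` (default 5, i.e. "more than 5 qualified reads")
    and the top genotype's posterior is at least ``ratio_threshold`` times
    the summed posterior of the other nine.  ``min_mapq``, when given,
    drops observations whose mapping quality is not strictly greater.
    Ties at the maximum yield UNCERTAIN (a tie can never satisfy the
    dominance rule).
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    obs = col.observations
    if min_mapq is not None:
        obs = [o for o in obs if o[2] > min_mapq]
    qualified = PileupColumn(col.site, obs)
    depth = qualified.depth

    posterior = genotype_posterior(qualified, prior, comp)
    probs = np.array([posterior[g] for g in ALL_GENOTYPES])
    order = np.argsort(probs)
    top, second = probs[order[-1]], probs[order[-2]]
    tail = 1.0 - top
    ratio = math.inf if tail <= 0.0 else top / tail

    if depth <= min_depth or ratio < ratio_threshold or top == second:
        return GenotypeCall(None, posterior, ratio, depth)
    return GenotypeCall(ALL_GENOTYPES[order[-1]], posterior, ratio, depth)
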