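"""Parallel-evolution statistics across replicate phage populations.

The headline statistic is the conservative same-gene hit probability: given
that one replicate acquired a mutation in a gene of length ``L_gene``, the
chance that all of the remaining ``k_hit - 1`` replicates independently hit
the same gene under uniform placement is ``(L_gene / L_genome)**(k_hit - 1)``.
Two null oracles accompany it: a closed-form probability that every one of
``k`` populations placing ``m`` uniform mutations hits the gene at least
once, and a seeded Monte-Carlo estimator (optionally conditioned on the
first population hitting, which converges to the conservative formula at
``m = 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .mutation_annotation import (
    INTERGENIC,
    MutationAnnotation,
)

AA_CHANGING = ("nonsynonymous", "nonsense")


@dataclass(frozen=True)
class GeneHitMatrix:
    """Per-gene presence of qualifying mutations across populations."""

    hits: pd.DataFrame  # boolean, populations x genes
    mutation_counts: pd.Series  # qualifying mutations per population

    @property
    def populations(self) -> list[str]:
        return list(self.hits.index)

    @property
    def genes(self) -> list[str]:
        return list(self.hits.columns)

    def k_hit(self, gene: str) -> int:
        return int(self.hits[gene].sum())


def build_hit_matrix(
    annotations_by_population: Mapping[str, Sequence[MutationAnnotation]],
    hit_filter: str = "any",
    exclude_preexisting: Optional[Iterable[tuple[int, str]]] = None,
) -> GeneHitMatrix:
    """Tabulate which populations carry >= 1 qualifying mutation per gene.

    ``hit_filter`` is ``"any"`` (any genic mutation counts) or
    ``"nonsynonymous_only"``; intergenic changes never count.
    ``exclude_preexisting`` removes (position, change) keys — e.g. stock
    polymorphisms — before counting.
    """
    if hit_filter not in ("any", "nonsynonymous_only"):
        raise ValueError(f"unknown hit filter {hit_filter!r}")
    excluded = set(exclude_preexisting or ())

    hits: dict[str, dict[str, bool]] = {}
    counts: dict[str, int] = {}
    for pop, annotations in annotations_by_population.items():
        counts[pop] = 0
        hits[pop] = {}
        for ann in annotations:
            if ann.record.key in excluded or ann.effect == INTERGENIC:
                continue
            if hit_filter == "nonsynonymous_only" and not ann.is_aa_changing:
                continue
            gene = ann.gene_no
            if gene is None:
                # genic indel: gene comes from the containing span
                gene = _containing_gene(ann)
            if gene is None:
                continue
            counts[pop] += 1
            hits[pop][gene] = True

    genes = sorted({g for row in hits.values() for g in row})
    frame = pd.DataFrame(
        [[hits[p].get(g, False) for g in genes] for p in hits],
        index=list(hits),
        columns=genes,
        dtype=bool,
    )
    return GeneHitMatrix(hits=frame, mutation_counts=pd.Series(counts))


def _containing_gene(ann: MutationAnnotation) -> Optional[str]:
    if ann.locus.is_genic and ann.locus.codon is not None:
        return ann.locus.codon.gene_no
    return None


# ---------------------------------------------------------------------------
# probabilities


@dataclass(frozen=True)
class ConservativeProbability:
    value: float
    display: str
    L_gene: int
    L_genome: int
    k_hit: int

    def __float__(self) -> float:
        return self.value


def display_1sf(x: float) -> str:
    """Round to one significant figure, printed in plain decimal notation."""
    if x == 0:
        return "0"
    exponent = math.floor(math.log10(abs(x)))
    mantissa = round(x / 10**exponent)
    if mantissa == 10:
        mantissa, exponent = 1, exponent + 1
    value = mantissa * 10.0**exponent
    if exponent < 0:
        return f"{value:.{-exponent}f}"
    return f"{value:.0f}"


def conservative_parallel_probability(
    L_gene: int, L_genome: int, k_hit: int
) -> ConservativeProbability:
    """Probability that the remaining k_hit - 1 replicates hit a gene already
    hit once, under uniform placement: ``(L_gene / L_genome)**(k_hit - 1)``."""
    if not 0 < L_gene <= L_genome:
        raise ValueError(f"need 0 < L_gene <= L_genome, got {L_gene}/{L_genome}")
    if k_hit < 1:
        raise ValueError("k_hit must be >= 1 (the probability conditions on one hit)")
    value = (L_gene / L_genome) ** (k_hit - 1)
    return ConservativeProbability(
        value=value,
        display=display_1sf(value),
        L_gene=L_gene,
        L_genome=L_genome,
        k_hit=k_hit,
    )


def null_parallel_probability_exact(
    L_gene: int, L_genome: int, k: int, m: int
) -> float:
    """Probability that each of ``k`` populations placing ``m`` uniform,
    independent mutations hits the gene at least once:
    ``(1 - (1 - L_gene/L_genome)**m)**k``."""
    if m < 1 or k < 1:
        raise ValueError("need m >= 1 and k >= 1")
    if not 0 < L_gene <= L_genome:
        raise ValueError(f"need 0 < L_gene <= L_genome, got {L_gene}/{L_genome}")
    p_hit = 1.0 - (1.0 - L_gene / L_genome) ** m
    return p_hit**k


@dataclass(frozen=True)
class MonteCarloEstimate:
    estimate: float
    standard_error: float
    n_effective: int  # simulations entering the estimate (after conditioning)


def null_parallel_probability_mc(
    L_gene: int,
    L_genome: int,
    k: int,
    m: int,
    n_sims: int = 100_000,
    seed: int = 0,
    condition_on_first: bool = False,
) -> MonteCarloEstimate:
    """Monte-Carlo null: uniform placement of ``m`` mutations in each of
    ``k`` populations, WLOG with the gene at positions ``1..L_gene``.

    With ``condition_on_first`` the estimate is the conditional probability
    that the remaining ``k - 1`` populations hit, given population 1 hit —
    the quantity the conservative formula approximates.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000")
    rng = np.random.default_rng(seed)
    chunk = max(1, min(n_sims, int(4e6) // (k * m)))
    successes = 0
    conditioning = 0
    done = 0
    while done < n_sims:
        n = min(chunk, n_sims - done)
        positions = rng.integers(1, L_genome + 1, size=(n, k, m))
        pop_hits = (positions <= L_gene).any(axis=2)  # n x k
        if condition_on_first:
            first = pop_hits[:, 0]
            conditioning += int(first.sum())
            successes += int((pop_hits[first, 1:].all(axis=1)).sum())
        else:
            successes += int(pop_hits.all(axis=1).sum())
        done += n
    denom = conditioning if condition_on_first else n_sims
    if denom == 0:
        raise RuntimeError(
            "no simulations satisfied the conditioning event; increase n_sims"
        )
    p = successes / denom
    se = math.sqrt(p * (1.0 - p) / denom)
    return MonteCarloEstimate(estimate=p, standard_error=se, n_effective=denom)


@dataclass(frozen=True)
class ParallelismResult:
    gene: str
    k_hit: int
    n_pop: int
    L_gene: int
    L_genome: int
    conservative: ConservativeProbability
    null_exact: Optional[float] = None
    null_mc: Optional[MonteCarloEstimate] = None


def parallelism_report(
    matrix: GeneHitMatrix,
    gene_lengths: Mapping[str, int],
    L_genome: int,
    m_per_population: Optional[int] = None,
    mc_sims: int = 0,
    seed: int = 0,
) -> list[ParallelismResult]:
    """Conservative probability (and optional nulls) for every hit gene."""
    results = []
    n_pop = len(matrix.populations)
    for gene in matrix.genes:
        k = matrix.k_hit(gene)
        if k == 0:
            continue
        L = gene_lengths[gene]
        exact = mc = None
        if m_per_population:
            exact = null_parallel_probability_exact(L, L_genome, n_pop, m_per_population)
            if mc_sims:
                mc = null_parallel_probability_mc(
                    L, L_genome, n_pop, m_per_population, n_sims=mc_sims, seed=seed
                )
        results.append(
            ParallelismResult(
                gene=gene,
                k_hit=k,
                n_pop=n_pop,
                L_gene=L,
                L_genome=L_genome,
                conservative=conservative_parallel_probability(L, L_genome, k),
                null_exact=exact,
                null_mc=mc,
            )
        )
    return results


def shared_polymorphisms(
    annotations_by_population: Mapping[str, Sequence[MutationAnnotation]],
    min_freq: float = 0.05,
    min_populations: int = 2,
) -> list[tuple[int, str, dict[str, float]]]:
    """Sub-fixation alleles recurring across populations.

    Returns (position, change, {population: frequency}) for every allele
    with read frequency in ``[min_freq, 1)`` in at least ``min_populations``
    populations.
    """
    found: dict[tuple[int, str], dict[str, float]] = {}
    for pop, annotations in annotations_by_population.items():
        for ann in annotations:
            freq = ann.record.read_frequency
            if freq is None:
                raise ValueError("shared_polymorphisms requires read frequencies")
            if min_freq <= freq < 1.0:
                found.setdefault(ann.record.key, {})[pop] = freq
    return sorted(
        (pos, change, pops)
        for (pos, change), pops in found.items()
        if len(pops) >= min_populations
    )
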