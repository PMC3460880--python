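"""Significance of multi-list gene overlaps: closed-form and permutation nulls.

Two null models score an observed overlap of m phenotype gene lists (sizes
n_1..n_m) drawn from a pool of N genes:

**Closed form.**  Each list is an independent uniform random subset of its
size.  For m = 2 the intersection size follows the classical hypergeometric
law and the exact upper tail is used.  For m >= 3 there is no standard
multi-list hypergeometric; each gene is in the intersection with probability
p = prod(n_i / N), and the intersection size is modelled as Binomial(N, p).
The per-gene indicators are exchangeable and only weakly (negatively)
dependent when the n_i are small relative to N, so the binomial tail is an
accurate approximation in the regimes of interest; a without-replacement
Monte Carlo sampler is provided as the oracle to quantify that approximation.

**Weighted permutation.**  Catalog genes recur — several SNPs, or several
phenotypes, can implicate the same gene — so the uniform-pool assumption is
optimistic.  The weighted null resamples each phenotype list without
replacement with probability proportional to the gene's catalog multiplicity
(number of distinct (SNP, phenotype) appearances), 10,000 replicates by
default, and reports the add-one estimator p = (1 + b) / (R + 1), which is
never zero and is exact for exchangeable replicates.

Weighted sampling without replacement uses the Efraimidis–Spirakis
exponential-key construction (keys log(U_i)/w_i, take the top n), which is
distribution-identical to sequential draws with weight renormalization and
vectorizes over replicates.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REPLICATES = 10_000


@dataclass(frozen=True)
class OverlapTest:
    """Inputs to one overlap significance computation."""

    list_sizes: tuple[int, ...]
    pool_size: int
    k_observed: int
    method: str = "closed_form"  # closed_form | exact_2way | monte_carlo

    def __post_init__(self) -> None:
        if len(self.list_sizes) < 2:
            raise ValueError("need at least two lists")
        if not all(0 <= n <= self.pool_size for n in self.list_sizes):
            raise ValueError("list sizes must lie in [0, pool_size]")
        if self.k_observed < 0 or self.k_observed > min(self.list_sizes):
            raise ValueError(
                f"k_observed={self.k_observed} outside [0, min(list_sizes)="
                f"{min(self.list_sizes)}]"
            )


@dataclass
class WeightedPool:
    """Gene pool with positive integer multiplicity weights."""

    weights: dict[str, int]

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.weights.values()):
            raise ValueError("all weights must be >= 1")

    @property
    def size(self) -> int:
        return len(self.weights)

    def arrays(self) -> tuple[list[str], np.ndarray]:
        genes = sorted(self.weights)
        return genes, np.array([self.weights[g] for g in genes], dtype=float)


@dataclass
class SignificanceResult:
    phenotypes: tuple[str, ...]
    k_observed: int
    list_sizes: tuple[int, ...]
    pool_size: int
    hypergeom_p: float
    permutation_p: float | None
    replicates: int
    seed: int | None
    method: str = "closed_form"
    shared_genes: tuple[str, ...] = field(default_factory=tuple)


# --------------------------------------------------------------------------
# closed-form null

def hypergeom_pvalue(test: OverlapTest) -> float:
    """Upper-tail probability P(intersection >= k_observed) under the
    uniform-subset null.

    m = 2 uses the exact hypergeometric survival function; m >= 3 the
    Binomial(N, prod n_i/N) tail (see module docstring).
    """
    k = test.k_observed
    if k == 0:
        return 1.0
    N = test.pool_size
    sizes = test.list_sizes
    if len(sizes) == 2:
        n1, n2 = sizes
        return float(stats.hypergeom.sf(k - 1, N, n1, n2))
    p = math.prod(n / N for n in sizes)
    return float(stats.binom.sf(k - 1, N, p))


def monte_carlo_pvalue(
    test: OverlapTest,
    draws: int = 100_000,
    rng: np.random.Generator | int | None = None,
    chunk: int = 2_000,
) -> tuple[float, float]:
    """Without-replacement Monte Carlo oracle for the uniform-subset null.

    Each draw samples every list as a uniform subset without replacement and
    counts the intersection.  Returns ``(p_hat, se)`` where ``p_hat`` is the
    add-one tail estimate and ``se`` its binomial standard error.
    """
    rng = np.random.default_rng(rng)
    N = test.pool_size
    k = test.k_observed
    if k == 0:
        return 1.0, 0.0
    hits = 0
    done = 0
    while done < draws:
        r = min(chunk, draws - done)
        inter = np.ones((r, N), dtype=bool)
        for n in test.list_sizes:
            keys = rng.random((r, N))
            # membership in a uniform n-subset: the n smallest keys per row
            thresh = np.partition(keys, n - 1, axis=1)[:, n - 1 : n]
            inter &= keys <= thresh
        hits += int((inter.sum(axis=1) >= k).sum())
        done += r
    p_hat = (hits + 1) / (draws + 1)
    se = math.sqrt(p_hat * (1 - p_hat) / draws)
    return p_hat, se


# --------------------------------------------------------------------------
# weighted permutation null

def build_weighted_pool(gene_rows: pd.DataFrame) -> WeightedPool:
    """Multiplicity weights: distinct (SNP, phenotype) appearances per gene.

    A gene implicated by three different SNPs under one phenotype gets weight
    3; a gene implicated by one SNP under two phenotypes gets weight 2.  Pool
    cardinality is the number of distinct genes.
    """
    if gene_rows.empty:
        return WeightedPool(weights={})
    w = (
        gene_rows.drop_duplicates(["gene", "snp_id", "phenotype"])
        .groupby("gene")
        .size()
    )
    return WeightedPool(weights={g: int(c) for g, c in w.items()})


def weighted_sample_memberships(
    rng: np.random.Generator, weights: np.ndarray, size: int, replicates: int
) -> np.ndarray:
    """Boolean (replicates, pool) membership matrix of weight-proportional
    samples without replacement (Efraimidis–Spirakis keys)."""
    G = weights.shape[0]
    if size > G:
        raise ValueError(f"sample size {size} exceeds pool cardinality {G}")
    if size == 0:
        return np.zeros((replicates, G), dtype=bool)
    u = rng.random((replicates, G))
    keys = np.log(u) / weights  # larger key <=> earlier selection
    thresh = np.partition(keys, G - size, axis=1)[:, G - size : G - size + 1]
    return keys >= thresh


def weighted_permutation_pvalue(
    pool: WeightedPool,
    list_sizes: tuple[int, ...],
    k_observed: int,
    replicates: int = DEFAULT_REPLICATES,
    seed: int | np.random.Generator | None = 0,
    chunk: int = 1_000,
) -> float:
    """Permutation p-value for the observed intersection under the weighted
    null.

    Each replicate draws one weight-proportional sample without replacement
    per list and intersects them; p = (1 + #{intersection >= k_observed}) /
    (replicates + 1).  Deterministic for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    genes, w = pool.arrays()
    for n in list_sizes:
        if n > pool.size:
            raise ValueError(f"list size {n} exceeds pool cardinality {pool.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < replicates:
        r = min(chunk, replicates - done)
        inter = np.ones((r, pool.size), dtype=bool)
        for n in list_sizes:
            inter &= weighted_sample_memberships(rng, w, n, r)
        hits += int((inter.sum(axis=1) >= k_observed).sum())
        done += r
    return (hits + 1) / (replicates + 1)


# --------------------------------------------------------------------------
# batch scoring

def _combo_seed(base_seed: int, phenotypes: tuple[str, ...]) -> np.random.SeedSequence:
    """Deterministic per-combination substream: adding or removing one
    combination never perturbs the draws of another."""
    tag = zlib.crc32(";".join(phenotypes).encode())
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(tag,))


def score_all_overlaps(
    overlaps,
    pool: WeightedPool | None,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    method: str = "closed_form",
    mc_draws: int = 100_000,
) -> list[SignificanceResult]:
    """Score every overlap with both nulls.

    ``method='closed_form'`` (default) uses the exact/binomial tail for the
    first p-value; ``'monte_carlo'`` replaces it with the without-replacement
    Monte Carlo estimate.  The permutation p-value is computed whenever a
    weighted pool is supplied.  Results are deterministic given ``seed``.
    """
    results = []
    for ov in overlaps:
        test = OverlapTest(
            list_sizes=tuple(ov.list_sizes),
            pool_size=ov.pool_size,
            k_observed=ov.k_observed,
            method=method,
        )
        ss = _combo_seed(seed, tuple(ov.phenotypes))
        if method == "monte_carlo":
            hg, _ = monte_carlo_pvalue(test, draws=mc_draws, rng=np.random.default_rng(ss))
        else:
            hg = hypergeom_pvalue(test)
        perm = None
        if pool is not None and pool.size > 0:
            perm = weighted_permutation_pvalue(
                pool,
                tuple(ov.list_sizes),
                ov.k_observed,
                replicates=replicates,
                seed=np.random.default_rng(ss.spawn(1)[0]),
            )
        results.append(
            SignificanceResult(
                phenotypes=tuple(ov.phenotypes),
                k_observed=ov.k_observed,
                list_sizes=tuple(ov.list_sizes),
                pool_size=ov.pool_size,
                hypergeom_p=hg,
                permutation_p=perm,
                replicates=replicates,
                seed=seed,
                method=method,
                shared_genes=tuple(sorted(ov.shared_genes)),
            )
        )
    return results


def results_to_frame(results: list[SignificanceResult]) -> pd.DataFrame:
    rows = [
        {
            "phenotypes": ";".join(r.phenotypes),
            "shared_genes": ";".join(r.shared_genes),
            "k_observed": r.k_observed,
            "list_sizes": ";".join(map(str, r.list_sizes)),
            "pool_size": r.pool_size,
            "hypergeom_p": r.hypergeom_p,
            "permutation_p": r.permutation_p,
            "replicates": r.replicates,
            "seed": r.seed,
            "method": r.method,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "phenotypes",
            "shared_genes",
            "k_observed",
            "list_sizes",
            "pool_size",
            "hypergeom_p",
            "permutation_p",
            "replicates",
            "seed",
            "method",
        ],
    )
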