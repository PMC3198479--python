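"""Birth-order test statistics and their within-family permutation null.

Three statistics probe different departures from a uniform distribution
of affected offspring across birth ranks:

* **rank-sum** — the sum of birth ranks of all affected offspring;
  sensitive to monotone (linear) trends in risk across ranks.
* **inverse rank-sum** — the same sum with ranks replaced by V-shaped
  weights ``|2z - N - 1|`` that are largest at the first and last births
  and smallest in the middle; sensitive to V-shaped risk profiles.
* **chi2-type** — a goodness-of-fit sum ``sum_z (O_z - E_z)^2 / E_z``
  comparing observed affected counts per birth rank with the counts
  expected if affecteds were placed uniformly within each sibship size.
  Because counts across ranks are dependent, its null distribution is
  *not* a central chi-square and must be obtained by permutation.

Significance for all three is assessed the same way: affection status is
shuffled uniformly at random within each sibship (conserving sibship
sizes and per-family affected counts), the statistic is recomputed for
each of K shuffles, and the two-sided p-value is the fraction of null
statistics at least as far from the null mean as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Union

import numpy as np

from .families import FamilyCollection

TEST_NAMES = ("rank_sum", "inverse_rank_sum", "chi2_type")

# rows of random keys generated per permutation block (memory/speed knob)
_BLOCK_BUDGET = 4_000_000


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def rank_sum_statistic(c: FamilyCollection) -> float:
    """Sum of birth ranks of all affected offspring, over all families."""
    _require_nonempty(c)
    total = 0.0
    any_affected = False
    for sib in c:
        for o in sib.offspring:
            if o.affected:
                total += o.birth_rank
                any_affected = True
    if not any_affected:
        warnings.warn(
            "collection has no affected offspring; statistic is 0 and the "
            "permutation p-value will be 1",
            stacklevel=2,
        )
    return total


def inverse_rank_weights(n: int) -> np.ndarray:
    """V-shaped integer weights for a sibship of size ``n``.

    Weight for rank ``z`` is ``|2z - n - 1|``: zero (odd ``n``) or one
    (even ``n``) at the middle, increasing by two toward both extremes,
    so early- and late-born children carry the largest weights.

    >>> inverse_rank_weights(5)
    array([4, 2, 0, 2, 4])
    """
    if n < 2:
        raise ValueError(f"sibship size must be >= 2, got {n}")
    z = np.arange(1, n + 1, dtype=np.int64)
    return np.abs(2 * z - n - 1)


def inverse_rank_sum_statistic(c: FamilyCollection) -> float:
    """Sum of V-shaped rank weights of all affected offspring."""
    _require_nonempty(c)
    total = 0.0
    any_affected = False
    for sib in c:
        w = inverse_rank_weights(sib.size)
        for o, wz in zip(sib.offspring, w):
            if o.affected:
                total += float(wz)
                any_affected = True
    if not any_affected:
        warnings.warn(
            "collection has no affected offspring; statistic is 0 and the "
            "permutation p-value will be 1",
            stacklevel=2,
        )
    return total


@dataclass(frozen=True)
class CountTable:
    """Observed and expected affected counts per birth rank.

    ``observed[z-1]`` is the number of affected offspring at rank ``z``
    across all sibships of size >= z. ``expected[z-1]`` assumes affecteds
    are uniformly distributed within each sibship size: with ``A_s`` the
    total affected in sibships of size ``s``, the expected count at rank
    ``z`` is ``sum_{s >= z} A_s / s``. Both sides sum to the total number
    of affected offspring.
    """

    observed: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        if self.observed.shape != self.expected.shape:
            raise ValueError("observed/expected length mismatch")

    @property
    def max_rank(self) -> int:
        return len(self.observed)


def chi2_count_table(c: FamilyCollection) -> CountTable:
    """Build the per-rank observed/expected table for the chi2-type test."""
    _require_nonempty(c)
    z_max = c.max_sibship_size
    observed = np.zeros(z_max, dtype=np.float64)
    affected_by_size = np.zeros(z_max + 1, dtype=np.float64)  # A_s, index s
    for sib in c:
        affected_by_size[sib.size] += sib.n_affected
        for o in sib.offspring:
            if o.affected:
                observed[o.birth_rank - 1] += 1
    # E_z = sum over sizes s >= z of A_s / s
    sizes = np.arange(1, z_max + 1, dtype=np.float64)
    per_rank_share = affected_by_size[1:] / sizes  # A_s / s
    expected = np.cumsum(per_rank_share[::-1])[::-1]
    return CountTable(observed=observed, expected=expected)


def chi2_statistic(t: CountTable) -> float:
    """Goodness-of-fit sum over ranks with positive expected count.

    Ranks with ``E_z = 0`` necessarily have ``O_z = 0`` (no affected
    offspring exist in any sibship reaching that rank) and are excluded;
    an ``E_z = 0`` with ``O_z > 0`` violates the table invariant.
    """
    zero = t.expected == 0
    if np.any(zero & (t.observed > 0)):
        raise ValueError("observed count positive where expected count is 0")
    mask = ~zero
    diff = t.observed[mask] - t.expected[mask]
    return float(np.sum(diff * diff / t.expected[mask]))


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


def permute_within_families(
    c: FamilyCollection, rng: np.random.Generator
) -> FamilyCollection:
    """Shuffle affection status uniformly at random within each sibship.

    Sibship sizes, ranks, sexes, ages and per-family affected counts are
    untouched; only the assignment of affection to birth positions moves.
    """
    shuffled = []
    for sib in c:
        y = sib.affected_vector
        shuffled.append(sib.with_affected(y[rng.permutation(sib.size)]))
    return c.with_sibships(shuffled)


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation p-value.

    ``n_permutations`` (K) random within-family shuffles are drawn from a
    generator seeded with ``seed``. With ``plus_one`` False the p-value
    is the raw exceedance fraction ``#{|T_k - Tbar| >= |T_obs - Tbar|}/K``
    (zero is attainable); True switches to the conventional
    ``(# + 1)/(K + 1)`` estimator.
    """

    n_permutations: int = 10_000
    seed: int = 0
    plus_one: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one permutation test."""

    test_name: str
    statistic: float
    null_mean: float
    p_value: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "null_mean": self.null_mean,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


StatisticSpec = Union[str, Callable[[FamilyCollection], float]]


def permutation_pvalue(
    c: FamilyCollection,
    statistic: StatisticSpec,
    cfg: PermutationConfig,
) -> TestResult:
    """Two-sided permutation p-value for one of the birth-order statistics.

    ``statistic`` is one of ``"rank_sum"``, ``"inverse_rank_sum"``,
    ``"chi2_type"`` (fast vectorized path) or any callable mapping a
    collection to a real statistic (generic path; K collection copies).

    The p-value is centred at the permutation mean: with ``T_1..T_K`` the
    null draws and ``Tbar`` their mean, ``p = #{k: |T_k - Tbar| >=
    |T_obs - Tbar|} / K``. Ties count toward the numerator.
    """
    _require_nonempty(c)
    if callable(statistic):
        name = getattr(statistic, "__name__", "custom")
        t_obs = float(statistic(c))
        rng = np.random.default_rng(cfg.seed)
        null = np.empty(cfg.n_permutations)
        for k in range(cfg.n_permutations):
            null[k] = statistic(permute_within_families(c, rng))
    else:
        if statistic not in TEST_NAMES:
            raise ValueError(
                f"unknown statistic {statistic!r}; expected one of {TEST_NAMES}"
            )
        name = statistic
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_obs, null = _fast_null_distribution(c, statistic, cfg)
        if c.n_affected == 0:
            warnings.warn(
                "collection has no affected offspring; p-value is 1",
                stacklevel=2,
            )
    t_bar = float(null.mean())
    d_obs = abs(t_obs - t_bar)
    hits = int(np.count_nonzero(np.abs(null - t_bar) >= d_obs))
    if cfg.plus_one:
        p = (hits + 1) / (cfg.n_permutations + 1)
    else:
        p = hits / cfg.n_permutations
    return TestResult(
        test_name=name,
        statistic=t_obs,
        null_mean=t_bar,
        p_value=p,
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
    )


def run_all_tests(
    c: FamilyCollection, cfg: PermutationConfig
) -> Mapping[str, TestResult]:
    """Run all three tests; each uses an independent permutation stream.

    Per-test seeds are derived deterministically from ``cfg.seed``, so
    repeated calls with the same collection and config are bitwise equal.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(len(TEST_NAMES))
    out = {}
    for name, child in zip(TEST_NAMES, children):
        sub_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        sub_cfg = PermutationConfig(
            n_permutations=cfg.n_permutations,
            seed=sub_seed,
            plus_one=cfg.plus_one,
        )
        out[name] = permutation_pvalue(c, name, sub_cfg)
    return out


# ---------------------------------------------------------------------------
# vectorized internals
# ---------------------------------------------------------------------------


def _require_nonempty(c: FamilyCollection) -> None:
    if c.n_families == 0:
        raise ValueError("empty collection")


def _collection_arrays(c: FamilyCollection):
    """Flatten a collection into family-blocked arrays.

    Offspring appear grouped by family and sorted by rank; ``fam_idx``
    labels the block of each offspring.
    """
    sizes = np.array([s.size for s in c], dtype=np.int64)
    fam_idx = np.repeat(np.arange(len(sizes)), sizes)
    ranks = np.concatenate([s.ranks for s in c])
    y = np.concatenate([s.affected_vector for s in c]).astype(np.float64)
    return fam_idx, sizes, ranks, y


def _fast_null_distribution(
    c: FamilyCollection, statistic: str, cfg: PermutationConfig
):
    """Observed statistic plus K permuted statistics, vectorized.

    Random within-family shuffles are realised by sorting
    ``fam_idx + Uniform(0,1)`` keys: family blocks stay in place while
    the order inside each block is uniformly random. Permutations are
    processed in blocks of rows to bound memory.
    """
    fam_idx, sizes, ranks, y = _collection_arrays(c)
    n = y.size
    base = fam_idx.astype(np.float64)

    if statistic == "rank_sum":
        w = ranks.astype(np.float64)
        block_stat = lambda ymat: ymat @ w  # noqa: E731
        t_obs = float(y @ w)
    elif statistic == "inverse_rank_sum":
        w = np.concatenate(
            [inverse_rank_weights(s.size) for s in c]
        ).astype(np.float64)
        block_stat = lambda ymat: ymat @ w  # noqa: E731
        t_obs = float(y @ w)
    else:  # chi2_type
        table = chi2_count_table(c)
        expected = table.expected
        mask = expected > 0
        e_pos = expected[mask]
        z_max = table.max_rank
        # indicator matrix offspring -> rank column, for O = Y @ R
        rank_ind = np.zeros((n, z_max), dtype=np.float64)
        rank_ind[np.arange(n), ranks - 1] = 1.0

        def block_stat(ymat):
            obs = ymat @ rank_ind
            diff = obs[:, mask] - e_pos
            return np.sum(diff * diff / e_pos, axis=1)

        t_obs = chi2_statistic(table)

    rng = np.random.default_rng(cfg.seed)
    k_total = cfg.n_permutations
    block = max(1, min(k_total, _BLOCK_BUDGET // max(n, 1)))
    null = np.empty(k_total)
    done = 0
    while done < k_total:
        b = min(block, k_total - done)
        keys = base[None, :] + rng.random((b, n))
        perm = np.argsort(keys, axis=1)
        null[done : done + b] = block_stat(np.take(y, perm))
        done += b
    return t_obs, null
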