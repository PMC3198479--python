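"""Shared fixtures: compact collection builders and an exact-enumeration
oracle for permutation p-values."""

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from birthorder.families import FamilyCollection, Offspring, Sibship

settings.register_profile(
    "default",
    settings(
        deadline=None,
        derandomize=True,
        max_examples=30,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("default")


def make_sibship(pattern: str, family_id: str = "F1", **kid_kwargs) -> Sibship:
    """Build a sibship from an affection pattern string, e.g. '010'.

    Character z-1 gives the status of the rank-z child ('1' = affected).
    """
    kids = tuple(
        Offspring(
            individual_id=f"{family_id}-{z}",
            birth_rank=z,
            affected=ch == "1",
            **kid_kwargs,
        )
        for z, ch in enumerate(pattern, start=1)
    )
    return Sibship(
        family_id=family_id,
        offspring=kids,
        father_id=f"{family_id}-dad",
        mother_id=f"{family_id}-mom",
    )


def make_collection(*patterns: str) -> FamilyCollection:
    return FamilyCollection(
        sibships=tuple(
            make_sibship(p, family_id=f"F{i + 1}") for i, p in enumerate(patterns)
        )
    )


def exact_pvalue(c: FamilyCollection, stat_fn) -> float:
    """Two-sided permutation p-value by exhaustive orbit enumeration.

    Enumerates every distinct assignment of each family's affected count
    to birth positions (all equally likely under uniform within-family
    shuffling) and applies the centred two-sided rule with the exact
    orbit mean. Independent of the Monte-Carlo engine.
    """
    per_family = []
    for sib in c:
        variants = []
        for pos in combinations(range(sib.size), sib.n_affected):
            variants.append(
                sib.with_affected([i in pos for i in range(sib.size)])
            )
        per_family.append(variants)
    t_obs = stat_fn(c)
    values = np.array(
        [
            stat_fn(FamilyCollection(sibships=combo))
            for combo in product(*per_family)
        ]
    )
    t_bar = values.mean()
    return float(np.mean(np.abs(values - t_bar) >= abs(t_obs - t_bar)))


def orbit_size(c: FamilyCollection) -> int:
    from math import comb

    n = 1
    for sib in c:
        n *= comb(sib.size, sib.n_affected)
    return n


def orbit_values(c: FamilyCollection, stat_fn) -> np.ndarray:
    """Every orbit value of the statistic (one per distinct assignment)."""
    per_family = []
    for sib in c:
        per_family.append(
            [
                sib.with_affected([i in pos for i in range(sib.size)])
                for pos in combinations(range(sib.size), sib.n_affected)
            ]
        )
    return np.array(
        [
            stat_fn(FamilyCollection(sibships=combo))
            for combo in product(*per_family)
        ]
    )


def exact_pvalue_bounds(
    c: FamilyCollection, stat_fn, eps: float = 1e-9
) -> tuple[float, float]:
    """Exact limits of the centred two-sided p-value under mean estimation.

    Rank statistics live on an integer lattice and every family orbit is
    symmetric, so an orbit atom typically sits exactly at the reflection
    point ``2*Tbar - T_obs``. The centred rule counts that atom iff the
    estimated null mean falls on the observed side of the exact mean, so
    a Monte-Carlo run converges to one of two values: the exact p with
    the reflection atom excluded (lower) or included (upper). Atoms at
    the observed value itself are counted under either mean.
    """
    values = orbit_values(c, stat_fn)
    t_bar = values.mean()
    t_obs = stat_fn(c)
    d = abs(t_obs - t_bar)
    if d < eps:
        return 1.0, 1.0
    dev = np.abs(values - t_bar)
    at_obs = np.abs(values - t_obs) < eps
    lower = float(np.mean((dev > d + eps) | at_obs))
    upper = float(np.mean((dev >= d - eps) | at_obs))
    return lower, upper


@st.composite
def small_collections(draw, max_families: int = 6, max_size: int = 5):
    """Random small collections with at least one non-degenerate family."""
    n_fam = draw(st.integers(1, max_families))
    patterns = []
    for _ in range(n_fam):
        size = draw(st.integers(2, max_size))
        patterns.append(
            "".join(draw(st.sampled_from("01")) for _ in range(size))
        )
    # ensure at least one affected somewhere so statistics are informative
    if all(p.count("1") == 0 for p in patterns):
        patterns[0] = "1" + patterns[0][1:]
    return make_collection(*patterns)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
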