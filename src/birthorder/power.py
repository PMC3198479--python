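"""Monte-Carlo type I error and power estimation for the birth-order tests.

One power cell = simulate R independent collections under a risk model,
run one permutation test on each, and report the fraction of p-values at
or below the significance level, with its binomial Monte-Carlo standard
error. A grid runner reproduces the layout of a full power table
(models x tests x sample sizes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import (
    DEFAULT_SIBSHIP_LAMBDA,
    AgeAssignment,
    RiskModel,
    SimulationConfig,
    model_to_spec,
    simulate_collection,
)
from .stats import TEST_NAMES, PermutationConfig, permutation_pvalue


@dataclass(frozen=True)
class PowerEstimate:
    """Rejection rate of one test under one model at one sample size."""

    test_name: str
    model: dict
    n_families: int
    alpha: float
    n_reps: int
    n_permutations: int
    rejection_rate: float
    mc_se: float
    seed: int


def estimate_power(
    model: RiskModel,
    test: str,
    n_families: int,
    alpha: float = 0.05,
    n_reps: int = 100,
    n_permutations: int = 2000,
    seed: int = 0,
    sibship_lambda: float = DEFAULT_SIBSHIP_LAMBDA,
    age_model: Optional[AgeAssignment] = None,
) -> PowerEstimate:
    """Estimate rejection probability at level ``alpha`` by simulation.

    Rejection is ``p <= alpha`` (non-strict). Per-replicate simulation
    and permutation seeds are spawned deterministically from ``seed``.
    """
    if test not in TEST_NAMES:
        raise ValueError(f"unknown test {test!r}; expected one of {TEST_NAMES}")
    if n_reps < 1 or n_permutations < 1:
        raise ValueError("n_reps and n_permutations must be >= 1")
    rep_seeds = np.random.SeedSequence(seed).spawn(n_reps)
    rejections = 0
    for rep_ss in rep_seeds:
        sim_ss, perm_ss = rep_ss.spawn(2)
        cfg = SimulationConfig(
            n_families=n_families,
            sibship_lambda=sibship_lambda,
            age_model=age_model,
        )
        coll = simulate_collection(cfg, model, rng=np.random.default_rng(sim_ss))
        perm_seed = int(perm_ss.generate_state(1)[0] & 0x7FFFFFFF)
        result = permutation_pvalue(
            coll,
            test,
            PermutationConfig(n_permutations=n_permutations, seed=perm_seed),
        )
        if result.p_value <= alpha:
            rejections += 1
    rate = rejections / n_reps
    return PowerEstimate(
        test_name=test,
        model=model_to_spec(model),
        n_families=n_families,
        alpha=alpha,
        n_reps=n_reps,
        n_permutations=n_permutations,
        rejection_rate=rate,
        mc_se=float(np.sqrt(rate * (1.0 - rate) / n_reps)),
        seed=seed,
    )


def power_table(
    models: Mapping[str, RiskModel],
    tests: Sequence[str] = TEST_NAMES,
    n_families: Iterable[int] = (500, 1000),
    alpha: float = 0.05,
    n_reps: int = 100,
    n_permutations: int = 2000,
    seed: int = 0,
    sibship_lambda: float = DEFAULT_SIBSHIP_LAMBDA,
    age_model: Optional[AgeAssignment] = None,
    progress=None,
    cache_dir=None,
) -> pd.DataFrame:
    """One :func:`estimate_power` cell per (n_families, test, model).

    Every cell gets an independent seed spawned from ``seed``, so the
    table is reproducible and insensitive to cell order. ``progress``
    (optional callable) receives a text label as each cell completes.
    With ``cache_dir`` set, finished cells are stored as JSON keyed by a
    hash of their full specification, making interrupted runs resumable
    per cell. Rows are (n_families, test); columns are model names,
    matching the layout of a power table over birth-order models.
    """
    cells = [
        (n, t, name)
        for n in n_families
        for t in tests
        for name in models
    ]
    cell_seeds = np.random.SeedSequence(seed).spawn(len(cells))
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for (n, t, name), ss in zip(cells, cell_seeds):
        cell_seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        cache_file = None
        if cache_dir is not None:
            spec = {
                "model": model_to_spec(models[name]),
                "test": t,
                "n_families": n,
                "alpha": alpha,
                "n_reps": n_reps,
                "n_permutations": n_permutations,
                "sibship_lambda": sibship_lambda,
                "seed": cell_seed,
            }
            digest = hashlib.sha1(
                json.dumps(spec, sort_keys=True).encode()
            ).hexdigest()[:16]
            cache_file = cache_dir / f"cell-{digest}.json"
        if cache_file is not None and cache_file.exists():
            cached = json.loads(cache_file.read_text())
            rate, se = cached["power"], cached["mc_se"]
        else:
            est = estimate_power(
                models[name],
                t,
                n,
                alpha=alpha,
                n_reps=n_reps,
                n_permutations=n_permutations,
                seed=cell_seed,
                sibship_lambda=sibship_lambda,
                age_model=age_model,
            )
            rate, se = est.rejection_rate, est.mc_se
            if cache_file is not None:
                cache_file.write_text(json.dumps({"power": rate, "mc_se": se}))
        records.append(
            {
                "n_families": n,
                "test": t,
                "model": name,
                "power": rate,
                "mc_se": se,
            }
        )
        if progress is not None:
            progress(f"n={n} test={t} model={name}: power={rate:.2f}")
    df = pd.DataFrame(records)
    wide = df.pivot_table(
        index=["n_families", "test"],
        columns="model",
        values="power",
        sort=False,
    )
    wide = wide[[name for name in models]]  # preserve model order
    return wide.reset_index()
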