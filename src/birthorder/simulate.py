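"""Synthetic family collections under null and birth-order-effect models.

Family structures mirror the study population: sibship sizes are drawn
from a Poisson distribution with mean ``lambda = 2.39`` (the US average
number of children per family) conditioned on at least two offspring,
since one-child families cannot enter a birth-order study.

Risk models come in two flavours:

* **rank models** — affection probability is a function of birth rank
  directly: constant (null), linear in rank (increasing or decreasing),
  V-shaped (distinct risk at the middle rank versus the extremes), or a
  family-level mixture of increasing and decreasing linear trends.
* **age model** — affection probability follows a logistic curve in
  parental age at birth, ``risk(x) = b / (1 + exp(-beta * (x - a)))``,
  with maximum risk ``b``, half-maximum age ``a`` and rate ``beta``.
  Setting ``beta = 0`` gives the age-independent null (constant risk
  ``b/2``). Parental ages are generated from an age-at-first-birth
  distribution plus inter-birth gaps, so ages strictly increase with
  rank within a family and rank effects emerge only through the
  age-risk curve.

All draws go through one :class:`numpy.random.Generator`, so a given
seed reproduces a collection bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .families import FamilyCollection, Offspring, Sibship

DEFAULT_SIBSHIP_LAMBDA = 2.39


# ---------------------------------------------------------------------------
# risk models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UniformRisk:
    """Constant affection probability at every rank (the null model)."""

    prob: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"prob must be in [0,1], got {self.prob}")


@dataclass(frozen=True)
class LinearRankRisk:
    """Affection probability linear in birth rank.

    ``increasing``: risk at rank z is ``intercept + slope * z``.
    ``decreasing``: the profile is reflected within the sibship,
    ``intercept + slope * (N + 1 - z)``, so the two directions are
    mirror images over the same range of probabilities.

    Probabilities are validated at construction for every rank up to
    ``max_rank``; sibships larger than that are rejected at draw time.
    The defaults span risks 0.10-0.30 over ranks 1-5.
    """

    intercept: float = 0.05
    slope: float = 0.05
    direction: str = "increasing"
    max_rank: int = 12

    def __post_init__(self) -> None:
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError(f"bad direction {self.direction!r}")
        for z in range(1, self.max_rank + 1):
            p = self.intercept + self.slope * z
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"risk {p:.3f} at rank {z} outside [0,1]; "
                    "adjust intercept/slope/max_rank"
                )


@dataclass(frozen=True)
class VShapedRankRisk:
    """Distinct risk at the middle rank versus the first and last ranks.

    Risk is interpolated linearly from ``edge_risk`` at ranks 1 and N to
    ``middle_risk`` at rank (N+1)/2. With ``middle_risk > edge_risk``
    middle births carry the highest risk (an inverse-V profile in rank
    weights); swapping the two gives the opposite pattern.
    """

    edge_risk: float = 0.05
    middle_risk: float = 0.25

    def __post_init__(self) -> None:
        for p in (self.edge_risk, self.middle_risk):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"risk {p} outside [0,1]")


@dataclass(frozen=True)
class MixtureRankRisk:
    """Family-level mixture of opposite linear trends.

    Each family is independently assigned the increasing version of
    ``component`` with probability ``p0`` and the decreasing version
    otherwise, once per family. ``p0 = 0.9`` and ``p0 = 0.3`` give the
    9:1 and 3:7 increasing/decreasing mixtures of the power study.
    """

    p0: float = 0.9
    component: LinearRankRisk = field(default_factory=LinearRankRisk)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0,1], got {self.p0}")


@dataclass(frozen=True)
class LogisticAgeRisk:
    """Logistic parental-age risk ``b / (1 + exp(-beta * (age - a)))``.

    ``b`` is the maximum risk (default 0.1), ``a`` the age in years at
    which risk reaches ``b/2`` and ``beta`` the intrinsic rate of
    increase (or decrease, if negative). ``beta = 0, a = 0`` is the
    age-independent null with constant risk ``b/2``.
    """

    beta: float
    a: float
    b: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.b <= 1.0:
            raise ValueError(f"maximum risk b must be in (0,1], got {self.b}")


RankRiskModel = Union[UniformRisk, LinearRankRisk, VShapedRankRisk]
RiskModel = Union[RankRiskModel, MixtureRankRisk, LogisticAgeRisk]


@dataclass(frozen=True)
class AgeAssignment:
    """How parental ages at each birth are generated.

    Age at first birth is Normal(``mean_first_birth``, ``sd_first_birth``)
    truncated to [``min_first_birth``, ``max_first_birth``]; each
    subsequent birth adds an independent Uniform(``gap_min``,
    ``gap_max``) gap in years, so ages strictly increase with rank.
    """

    mean_first_birth: float = 25.0
    sd_first_birth: float = 5.0
    min_first_birth: float = 15.0
    max_first_birth: float = 45.0
    gap_min: float = 1.0
    gap_max: float = 4.0

    def __post_init__(self) -> None:
        if self.gap_min <= 0:
            raise ValueError("gap_min must be positive (ages must increase)")
        if self.gap_max < self.gap_min:
            raise ValueError("gap_max < gap_min")
        if self.max_first_birth <= self.min_first_birth:
            raise ValueError("empty truncation interval for age at first birth")


@dataclass(frozen=True)
class SimulationConfig:
    """Size, sibship-size distribution and seed of a simulated collection.

    ``min_affected`` models the ascertainment of a disease-family
    collection: candidate families are drawn until ``n_families`` of
    them contain at least that many affected offspring (the default, 1,
    mirrors how family collections are assembled — a family enters a
    study through an affected child). Set 0 to sample families from the
    population unconditionally. Conditioning on the per-family affected
    count does not disturb the within-family permutation null, so type I
    error is unaffected; it determines how many informative families a
    collection of a given size contains, and therefore power.
    """

    n_families: int
    sibship_lambda: float = DEFAULT_SIBSHIP_LAMBDA
    seed: int = 0
    age_model: Optional[AgeAssignment] = None
    min_affected: int = 1

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.sibship_lambda <= 0:
            raise ValueError("sibship_lambda must be positive")
        if self.min_affected < 0:
            raise ValueError("min_affected must be >= 0")


# ---------------------------------------------------------------------------
# elementary draws
# ---------------------------------------------------------------------------


def sample_sibship_size(
    cfg: SimulationConfig, rng: np.random.Generator
) -> int:
    """One Poisson(lambda) draw conditioned on the outcome being >= 2."""
    return int(_sample_sizes(1, cfg.sibship_lambda, rng)[0])


def _sample_sizes(
    n: int, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Poisson(lam) conditioned >= 2, by rejection."""
    out = np.empty(n, dtype=np.int64)
    need = n
    start = 0
    while need > 0:
        # acceptance prob is 1 - P(0) - P(1); oversample accordingly
        accept = 1.0 - math.exp(-lam) * (1.0 + lam)
        batch = max(16, int(need / max(accept, 1e-9) * 1.2))
        draws = rng.poisson(lam, size=batch)
        good = draws[draws >= 2][:need]
        out[start : start + good.size] = good
        start += good.size
        need -= good.size
    return out


def logistic_risk(age: Union[float, np.ndarray], m: LogisticAgeRisk):
    """Affection probability at a given parental age under ``m``."""
    return m.b / (1.0 + np.exp(-m.beta * (np.asarray(age, dtype=float) - m.a)))


def rank_risk(z: int, n: int, model: RankRiskModel) -> float:
    """Affection probability at rank ``z`` in a sibship of size ``n``.

    For :class:`MixtureRankRisk` the trend direction is a per-family
    latent variable; draw it first (see :func:`assign_mixture_component`)
    and pass the resulting :class:`LinearRankRisk` here.
    """
    if not 1 <= z <= n:
        raise ValueError(f"rank {z} outside 1..{n}")
    if isinstance(model, UniformRisk):
        return model.prob
    if isinstance(model, LinearRankRisk):
        if n > model.max_rank:
            raise ValueError(
                f"sibship size {n} exceeds validated max_rank {model.max_rank}"
            )
        zz = z if model.direction == "increasing" else n + 1 - z
        return model.intercept + model.slope * zz
    if isinstance(model, VShapedRankRisk):
        mid = (n + 1) / 2.0
        frac = abs(z - mid) / (mid - 1.0)  # 0 at middle, 1 at the edges
        return model.middle_risk + (model.edge_risk - model.middle_risk) * frac
    if isinstance(model, MixtureRankRisk):
        raise TypeError(
            "MixtureRankRisk has a per-family latent direction; use "
            "assign_mixture_component(model, rng) first"
        )
    raise TypeError(f"not a rank-risk model: {model!r}")


def assign_mixture_component(
    model: MixtureRankRisk, rng: np.random.Generator
) -> LinearRankRisk:
    """Draw one family's trend direction from the mixture."""
    direction = "increasing" if rng.random() < model.p0 else "decreasing"
    return LinearRankRisk(
        intercept=model.component.intercept,
        slope=model.component.slope,
        direction=direction,
        max_rank=model.component.max_rank,
    )


# ---------------------------------------------------------------------------
# collection generation
# ---------------------------------------------------------------------------


_MAX_CANDIDATES = 50_000_000  # ascertainment rejection-sampling guard


def simulate_collection(
    cfg: SimulationConfig,
    model: RiskModel,
    rng: Optional[np.random.Generator] = None,
) -> FamilyCollection:
    """Generate a :class:`FamilyCollection` under the given risk model.

    Candidate families are drawn in vectorized batches — per batch:
    sibship sizes, mixture directions (mixture models only), parental
    ages (age models only), offspring sexes (50/50), affection
    indicators — and families with fewer than ``cfg.min_affected``
    affected offspring are rejected, until ``cfg.n_families`` have been
    accepted. Age models record the generated parental age as both the
    maternal and paternal age at birth; the simulator tracks a single
    parental-age process. Output is bitwise reproducible given a seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    needs_ages = isinstance(model, LogisticAgeRisk)
    age_spec = (cfg.age_model or AgeAssignment()) if needs_ages else None

    kept_sizes: list[np.ndarray] = []
    kept_kids: list[np.ndarray] = []  # columns: affected, sex-is-male, age
    remaining = cfg.n_families
    batch = cfg.n_families if cfg.min_affected == 0 else max(2 * cfg.n_families, 64)
    candidates = 0
    while remaining > 0:
        sizes = _sample_sizes(batch, cfg.sibship_lambda, rng)
        total = int(sizes.sum())
        ages = (
            _draw_ages(sizes, total, age_spec, rng) if needs_ages else None
        )
        probs = _affection_probs(sizes, total, ages, model, rng)
        male = rng.random(total) < 0.5
        affected = rng.random(total) < probs
        candidates += batch

        if cfg.min_affected > 0:
            starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
            counts = np.add.reduceat(affected.astype(np.int64), starts)
            fam_keep = counts >= cfg.min_affected
        else:
            fam_keep = np.ones(batch, dtype=bool)
        n_ok = int(fam_keep.sum())
        if n_ok > remaining:  # truncate to the first `remaining` accepted
            extra = np.flatnonzero(fam_keep)[remaining:]
            fam_keep[extra] = False
            n_ok = remaining
        kid_keep = np.repeat(fam_keep, sizes)
        kept_sizes.append(sizes[fam_keep])
        kept_kids.append(
            np.column_stack(
                [
                    affected[kid_keep],
                    male[kid_keep],
                    ages[kid_keep] if ages is not None else np.full(int(kid_keep.sum()), np.nan),
                ]
            )
        )
        remaining -= n_ok
        if remaining > 0:
            if candidates >= _MAX_CANDIDATES:
                raise RuntimeError(
                    f"ascertainment acceptance too low: {cfg.n_families - remaining}"
                    f"/{cfg.n_families} families after {candidates} candidates; "
                    "is the risk model (near-)degenerate?"
                )
            rate = max((cfg.n_families - remaining) / candidates, 1.0 / candidates)
            batch = int(min(2_000_000, max(64, 1.3 * remaining / rate)))

    sizes = np.concatenate(kept_sizes)
    kids = np.vstack(kept_kids)
    sibships = []
    pos = 0
    for fam, n in enumerate(sizes):
        fam_id = f"F{fam + 1:05d}"
        offspring = []
        for z in range(1, int(n) + 1):
            aff, male_flag, age = kids[pos]
            offspring.append(
                Offspring(
                    individual_id=f"{fam_id}-{z}",
                    birth_rank=z,
                    affected=bool(aff),
                    sex="male" if male_flag else "female",
                    maternal_age_at_birth=None if np.isnan(age) else float(age),
                    paternal_age_at_birth=None if np.isnan(age) else float(age),
                )
            )
            pos += 1
        sibships.append(
            Sibship(
                family_id=fam_id,
                offspring=tuple(offspring),
                father_id=f"{fam_id}-dad",
                mother_id=f"{fam_id}-mom",
            )
        )
    return FamilyCollection(
        sibships=tuple(sibships), label=f"simulated:{type(model).__name__}"
    )


def _affection_probs(
    sizes: np.ndarray,
    total: int,
    ages: Optional[np.ndarray],
    model: RiskModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-offspring affection probability for one batch of families."""
    if isinstance(model, LogisticAgeRisk):
        return logistic_risk(ages, model)
    if isinstance(model, MixtureRankRisk):
        increasing = rng.random(sizes.size) < model.p0
        probs = np.empty(total)
        pos = 0
        for fam, n in enumerate(sizes):
            comp = LinearRankRisk(
                intercept=model.component.intercept,
                slope=model.component.slope,
                direction="increasing" if increasing[fam] else "decreasing",
                max_rank=model.component.max_rank,
            )
            for z in range(1, int(n) + 1):
                probs[pos] = rank_risk(z, int(n), comp)
                pos += 1
        return probs
    if isinstance(model, UniformRisk):
        return np.full(total, model.prob)
    probs = np.empty(total)
    pos = 0
    for n in sizes:
        for z in range(1, int(n) + 1):
            probs[pos] = rank_risk(z, int(n), model)
            pos += 1
    return probs


def _draw_ages(
    sizes: np.ndarray, total: int, spec: AgeAssignment, rng: np.random.Generator
) -> np.ndarray:
    """Parental age at each birth; strictly increasing within a family."""
    n_fam = sizes.size
    first = np.empty(n_fam)
    need = np.ones(n_fam, dtype=bool)
    while need.any():  # truncated-normal age at first birth, by rejection
        k = int(need.sum())
        draws = rng.normal(spec.mean_first_birth, spec.sd_first_birth, size=k)
        ok = (draws >= spec.min_first_birth) & (draws <= spec.max_first_birth)
        idx = np.flatnonzero(need)[ok]
        first[idx] = draws[ok]
        need[idx] = False
    gaps = rng.uniform(spec.gap_min, spec.gap_max, size=total)
    fam_idx = np.repeat(np.arange(n_fam), sizes)
    # cumulative gaps within each family, first birth gets gap 0
    starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
    gaps[starts] = 0.0
    cum = np.cumsum(gaps)
    cum -= np.repeat(cum[starts], sizes)
    return first[fam_idx] + cum


# ---------------------------------------------------------------------------
# config-file model specs
# ---------------------------------------------------------------------------

_MODEL_TYPES = {
    "uniform": UniformRisk,
    "linear_rank": LinearRankRisk,
    "v_shaped": VShapedRankRisk,
    "mixture": MixtureRankRisk,
    "logistic_age": LogisticAgeRisk,
}


def model_from_spec(spec: dict) -> RiskModel:
    """Build a risk model from a plain dict (e.g. parsed YAML).

    ``{"type": "logistic_age", "beta": 0.5, "a": 45}`` etc.; a mixture's
    ``component`` key holds a nested linear spec without its ``type``.
    """
    spec = dict(spec)
    kind = spec.pop("type", None)
    if kind not in _MODEL_TYPES:
        raise ValueError(
            f"unknown model type {kind!r}; expected one of {sorted(_MODEL_TYPES)}"
        )
    if kind == "mixture" and "component" in spec:
        spec["component"] = LinearRankRisk(**spec["component"])
    return _MODEL_TYPES[kind](**spec)


def model_to_spec(model: RiskModel) -> dict:
    """Inverse of :func:`model_from_spec`, for metadata sidecars."""
    for name, cls in _MODEL_TYPES.items():
        if isinstance(model, cls) and type(model) is cls:
            break
    else:  # pragma: no cover - all model types are registered
        raise TypeError(f"unregistered model {model!r}")
    out = {"type": name}
    for fname in model.__dataclass_fields__:
        val = getattr(model, fname)
        if isinstance(val, LinearRankRisk):
            val = {
                k: getattr(val, k) for k in val.__dataclass_fields__
            }
        out[fname] = val
    return out
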