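"""Reading, filtering and subsetting family data in a PED-like dialect.

The on-disk format is the standard 6-column pedigree layout (family id,
individual id, father id, mother id, sex, phenotype), tab-separated,
optionally extended with named columns (``birth_year``, ``birth_rank``,
``twin_group``, ``father_age``, ``mother_age``). Standard PED has no
field for birth order, so extended columns are declared in a header line
beginning with ``#``; a file without a header is read as plain 6-column
PED. A :class:`ColumnMap` (optionally loaded from a ``key=value`` file)
renames columns when a source file uses different labels.

Coding conventions follow PED practice: phenotype 2 = affected, 1 =
unaffected, 0 or -9 = missing (the individual is dropped with a logged
warning, or the whole family with ``strict_missing``); sex 1 = male,
2 = female, 0 = unknown; parent id 0 = unknown parent. Rows whose father
and mother are both unknown are treated as founders and skipped.

Study filtering (:func:`filter_collection`) applies the inclusion rules
of a birth-order study: two-parent families with at least two offspring
of known birth order; twin sets (explicit ``twin_group`` label, or
identical birth years) concordant for affection are collapsed to one
individual, and families containing a discordant twin set are excluded;
ranks are renumbered 1..N afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .families import FamilyCollection, Offspring, Sibship

logger = logging.getLogger(__name__)

STANDARD_COLUMNS = ("fam", "ind", "father", "mother", "sex", "phen")
EXTENDED_COLUMNS = (
    "birth_year",
    "birth_rank",
    "twin_group",
    "father_age",
    "mother_age",
)
MISSING = {"", ".", "NA", "na"}

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


@dataclass(frozen=True)
class ColumnMap:
    """Maps logical column roles to the labels used in a source file."""

    fam: str = "fam"
    ind: str = "ind"
    father: str = "father"
    mother: str = "mother"
    sex: str = "sex"
    phen: str = "phen"
    birth_year: str = "birth_year"
    birth_rank: str = "birth_rank"
    twin_group: str = "twin_group"
    father_age: str = "father_age"
    mother_age: str = "mother_age"

    @classmethod
    def from_file(cls, path) -> "ColumnMap":
        """Load overrides from a ``key=value`` file (one pair per line)."""
        overrides = {}
        valid = {f.name for f in dc_fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(
                    f"{path}:{lineno}: expected key=value, got {line!r}"
                )
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in valid:
                raise ValueError(
                    f"{path}:{lineno}: unknown column role {key!r}"
                )
            overrides[key] = value
        return cls(**overrides)


def read_ped(
    path,
    columns: Optional[ColumnMap] = None,
    strict_missing: bool = False,
) -> FamilyCollection:
    """Parse a PED-like file into a :class:`FamilyCollection`.

    One sibship is produced per nuclear family (same father and mother).
    Offspring are ordered by an explicit ``birth_rank`` column when
    present for the whole sibship, otherwise by ``birth_year``; a family
    whose offspring carry neither is dropped with a warning. Individuals
    with missing phenotype are dropped (the family, with
    ``strict_missing=True``) and the sibship re-ranked.
    """
    path = Path(path)
    cmap = columns or ColumnMap()
    lines = path.read_text().splitlines()

    header: Optional[List[str]] = None
    body_start = 0
    for i, raw in enumerate(lines):
        if not raw.strip():
            continue
        if raw.startswith("#"):
            header = raw.lstrip("#").strip().split("\t")
            body_start = i + 1
        else:
            body_start = i
        break

    if header is not None:
        positions = {name: j for j, name in enumerate(header)}
        for role in STANDARD_COLUMNS:
            label = getattr(cmap, role)
            if label not in positions:
                raise ValueError(
                    f"{path}: required column {label!r} ({role}) missing "
                    f"from header {header}"
                )
        ncol = len(header)
    else:
        positions = {
            getattr(cmap, role): j for j, role in enumerate(STANDARD_COLUMNS)
        }
        ncol = len(STANDARD_COLUMNS)

    def col(row: List[str], role: str) -> Optional[str]:
        label = getattr(cmap, role)
        j = positions.get(label)
        if j is None:
            return None
        val = row[j].strip()
        return None if val in MISSING else val

    # family -> (father, mother) -> list of raw offspring records
    raw_families: Dict[Tuple[str, str, str], List[dict]] = {}
    n_missing_phen = 0
    families_missing_phen = set()
    for lineno in range(body_start, len(lines)):
        raw = lines[lineno]
        if not raw.strip() or raw.startswith("#"):
            continue
        row = raw.split("\t")
        if len(row) != ncol:
            raise ValueError(
                f"{path}:{lineno + 1}: expected {ncol} tab-separated fields, "
                f"got {len(row)}"
            )
        fam = col(row, "fam")
        ind = col(row, "ind")
        if fam is None or ind is None:
            raise ValueError(f"{path}:{lineno + 1}: missing family/individual id")
        father = col(row, "father") or "0"
        mother = col(row, "mother") or "0"
        if father == "0" and mother == "0":
            continue  # founder row
        phen = col(row, "phen")
        if phen in (None, "0", "-9"):
            n_missing_phen += 1
            families_missing_phen.add((fam, father, mother))
            logger.warning(
                "%s:%d: individual %s has missing phenotype; dropped",
                path,
                lineno + 1,
                ind,
            )
            continue
        if phen not in ("1", "2"):
            raise ValueError(
                f"{path}:{lineno + 1}: phenotype must be 1/2/0/-9, got {phen!r}"
            )
        sex_code = col(row, "sex") or "0"
        if sex_code not in _SEX_CODES:
            raise ValueError(
                f"{path}:{lineno + 1}: sex must be 0/1/2, got {sex_code!r}"
            )
        rec = {
            "ind": ind,
            "affected": phen == "2",
            "sex": _SEX_CODES[sex_code],
            "birth_year": _to_int(col(row, "birth_year"), path, lineno),
            "birth_rank": _to_int(col(row, "birth_rank"), path, lineno),
            "twin_group": col(row, "twin_group"),
            "father_age": _to_float(col(row, "father_age"), path, lineno),
            "mother_age": _to_float(col(row, "mother_age"), path, lineno),
        }
        raw_families.setdefault((fam, father, mother), []).append(rec)

    if strict_missing and families_missing_phen:
        for key in families_missing_phen:
            raw_families.pop(key, None)
        logger.warning(
            "strict_missing: dropped %d families containing missing phenotypes",
            len(families_missing_phen),
        )

    # disambiguate ids when one family id holds several parent pairs
    pair_counts: Dict[str, int] = {}
    for fam, _, _ in raw_families:
        pair_counts[fam] = pair_counts.get(fam, 0) + 1

    sibships = []
    n_unordered = 0
    for (fam, father, mother), recs in raw_families.items():
        ordered = _order_offspring(recs)
        if ordered is None:
            n_unordered += 1
            logger.warning(
                "family %s (parents %s/%s): no birth_rank or complete "
                "birth_year data; family dropped",
                fam,
                father,
                mother,
            )
            continue
        sib_id = fam if pair_counts[fam] == 1 else f"{fam}/{father}+{mother}"
        kids = tuple(
            Offspring(
                individual_id=r["ind"],
                birth_rank=z,
                affected=r["affected"],
                sex=r["sex"],
                birth_year=r["birth_year"],
                paternal_age_at_birth=r["father_age"],
                maternal_age_at_birth=r["mother_age"],
                twin_group=r["twin_group"],
            )
            for z, r in enumerate(ordered, start=1)
        )
        sibships.append(
            Sibship(
                family_id=sib_id,
                offspring=kids,
                father_id=father,
                mother_id=mother,
            )
        )

    if not sibships:
        raise ValueError(f"{path}: no families parsed")
    if n_missing_phen:
        logger.warning(
            "%s: dropped %d individuals with missing phenotype",
            path,
            n_missing_phen,
        )
    return FamilyCollection(sibships=tuple(sibships), label=str(path))


def _order_offspring(recs: List[dict]) -> Optional[List[dict]]:
    """Sort a family's offspring records into birth order, or None."""
    if all(r["birth_rank"] is not None for r in recs):
        return sorted(recs, key=lambda r: r["birth_rank"])
    if all(r["birth_year"] is not None for r in recs):
        # stable sort: twins (tied years) keep input order until collapse
        return sorted(recs, key=lambda r: r["birth_year"])
    return None


def _to_int(val: Optional[str], path, lineno: int) -> Optional[int]:
    if val is None:
        return None
    try:
        return int(val)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno + 1}: bad integer {val!r}") from exc


def _to_float(val: Optional[str], path, lineno: int) -> Optional[float]:
    if val is None:
        return None
    try:
        return float(val)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno + 1}: bad number {val!r}") from exc


# ---------------------------------------------------------------------------
# study filtering
# ---------------------------------------------------------------------------


def filter_collection(c: FamilyCollection) -> FamilyCollection:
    """Apply the study inclusion rules; idempotent.

    Keeps sibships with both parents recorded and at least two offspring
    of known birth order after twin handling. Twin sets concordant for
    affection collapse to a single representative; any discordant twin
    set excludes the family. Ranks are renumbered 1..N.
    """
    kept = []
    n_no_parents = n_small = n_discordant = 0
    for sib in c:
        if not sib.father_id or not sib.mother_id or sib.father_id == "0" or sib.mother_id == "0":
            n_no_parents += 1
            continue
        collapsed = _collapse_twins(sib)
        if collapsed is None:
            n_discordant += 1
            continue
        if collapsed.size < 2:
            n_small += 1
            continue
        kept.append(collapsed)
    if n_no_parents or n_small or n_discordant:
        logger.info(
            "filter_collection: removed %d single-parent, %d undersized, "
            "%d discordant-twin families; %d retained",
            n_no_parents,
            n_small,
            n_discordant,
            len(kept),
        )
    return c.with_sibships(kept)


def _twin_sets(sib: Sibship) -> List[List[Offspring]]:
    """Group offspring into twin sets by explicit label or tied birth year."""
    groups: Dict[object, List[Offspring]] = {}
    for o in sib.offspring:
        if o.twin_group is not None:
            key = ("label", o.twin_group)
        elif o.birth_year is not None:
            key = ("year", o.birth_year)
        else:
            key = ("solo", o.individual_id)
        groups.setdefault(key, []).append(o)
    return list(groups.values())


def _collapse_twins(sib: Sibship) -> Optional[Sibship]:
    """Collapse concordant twin sets; None if any set is discordant."""
    sets = _twin_sets(sib)
    if all(len(g) == 1 for g in sets):
        return _renumber(sib, list(sib.offspring))
    reps = []
    for group in sets:
        statuses = {o.affected for o in group}
        if len(statuses) > 1:
            return None  # discordant twins: family excluded
        reps.append(group[0])  # concordant set counts as one individual
    reps.sort(key=lambda o: o.birth_rank)
    return _renumber(sib, reps)


def _renumber(sib: Sibship, kids: List[Offspring]) -> Sibship:
    kids = sorted(kids, key=lambda o: o.birth_rank)
    renumbered = tuple(
        replace(o, birth_rank=z) for z, o in enumerate(kids, start=1)
    )
    return replace(sib, offspring=renumbered)


def subset_by_affected_sex(c: FamilyCollection, sex: str) -> FamilyCollection:
    """Sibships in which every affected offspring is of the given sex.

    Families with no affected offspring, with an affected child of the
    other (or unknown) sex, are excluded; unaffected siblings of either
    sex are retained. An empty result is allowed (with a warning).
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    kept = [
        sib
        for sib in c
        if sib.n_affected > 0
        and all(o.sex == sex for o in sib.offspring if o.affected)
    ]
    if not kept:
        logger.warning(
            "subset_by_affected_sex: no families with all affecteds %s", sex
        )
    return replace(
        c, sibships=tuple(kept), label=f"{c.label} (affected {sex}s only)"
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def parental_age_profile(
    c: FamilyCollection, parent: str = "maternal", bin_width: float = 1.0
) -> pd.DataFrame:
    """Proportion of affected children among all children per age bin.

    Ages are binned as ``floor(age / bin_width) * bin_width``; offspring
    without the chosen parental age are skipped and bins with zero total
    are omitted. Columns: ``age_bin``, ``n_affected``, ``n_total``,
    ``proportion_affected``.
    """
    if parent not in ("maternal", "paternal"):
        raise ValueError(f"parent must be 'maternal' or 'paternal', got {parent!r}")
    attr = f"{parent}_age_at_birth"
    ages, affected = [], []
    for sib in c:
        for o in sib.offspring:
            age = getattr(o, attr)
            if age is not None:
                ages.append(age)
                affected.append(o.affected)
    if not ages:
        raise ValueError(f"no {parent} ages recorded in collection")
    bins = np.floor(np.asarray(ages) / bin_width) * bin_width
    df = pd.DataFrame({"age_bin": bins, "affected": affected})
    out = (
        df.groupby("age_bin")["affected"]
        .agg(n_affected="sum", n_total="count")
        .reset_index()
    )
    out["proportion_affected"] = out["n_affected"] / out["n_total"]
    return out


def summary_table(collections: Dict[str, FamilyCollection]) -> pd.DataFrame:
    """Per-collection counts: families, children, affected, size ranges."""
    rows = []
    for label, c in collections.items():
        sizes = [s.size for s in c]
        naff = [s.n_affected for s in c]
        rows.append(
            {
                "collection": label,
                "n_families": c.n_families,
                "n_children": c.n_children,
                "n_affected": c.n_affected,
                "sibship_size": f"{min(sizes)}-{max(sizes)}" if sizes else "-",
                "affected_sibs": f"{min(naff)}-{max(naff)}" if naff else "-",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_ped(
    c: FamilyCollection, path, include_parents: bool = True
) -> None:
    """Write a collection back to the extended PED dialect.

    Always emits the 6 standard columns plus ``birth_rank``; other
    extended columns are emitted only when some offspring carries them.
    Parental ages are written with full float precision so a write/read
    cycle reproduces the collection exactly.
    """
    kids = [o for sib in c for o in sib.offspring]
    extras = ["birth_rank"]
    if any(o.birth_year is not None for o in kids):
        extras.append("birth_year")
    if any(o.twin_group is not None for o in kids):
        extras.append("twin_group")
    if any(o.paternal_age_at_birth is not None for o in kids):
        extras.append("father_age")
    if any(o.maternal_age_at_birth is not None for o in kids):
        extras.append("mother_age")

    def fmt(val) -> str:
        return "." if val is None else str(val)

    lines = ["#" + "\t".join(STANDARD_COLUMNS + tuple(extras))]
    pad = "\t".join(["."] * len(extras))
    for i, sib in enumerate(c):
        father = sib.father_id or f"P{i + 1}F"
        mother = sib.mother_id or f"P{i + 1}M"
        if include_parents:
            lines.append("\t".join([sib.family_id, father, "0", "0", "1", "1", pad]))
            lines.append("\t".join([sib.family_id, mother, "0", "0", "2", "1", pad]))
        for o in sib.offspring:
            row = [
                sib.family_id,
                o.individual_id,
                father,
                mother,
                _SEX_TO_CODE[o.sex],
                "2" if o.affected else "1",
            ]
            for extra in extras:
                if extra == "birth_rank":
                    row.append(str(o.birth_rank))
                elif extra == "birth_year":
                    row.append(fmt(o.birth_year))
                elif extra == "twin_group":
                    row.append(fmt(o.twin_group))
                elif extra == "father_age":
                    row.append(fmt(o.paternal_age_at_birth))
                else:
                    row.append(fmt(o.maternal_age_at_birth))
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
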