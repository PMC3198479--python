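"""Tests for PED-dialect parsing, study filtering, sex subsets and
parental-age profiles."""

import logging

import numpy as np
import pytest
from hypothesis import given

from birthorder.families import FamilyCollection, Offspring, Sibship
from birthorder.pedigree_io import (
    ColumnMap,
    filter_collection,
    parental_age_profile,
    read_ped,
    subset_by_affected_sex,
    summary_table,
    write_ped,
)

from conftest import make_collection, make_sibship, small_collections


def write_lines(path, *lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPed:
    def test_birth_year_ordering(self, tmp_path):
        """Children born 1990/1992/1995, middle one affected."""
        ped = write_lines(
            tmp_path / "fam.ped",
            "#fam\tind\tfather\tmother\tsex\tphen\tbirth_year",
            "F1\tdad\t0\t0\t1\t1\t.",
            "F1\tmom\t0\t0\t2\t1\t.",
            "F1\tc3\tdad\tmom\t1\t1\t1995",
            "F1\tc2\tdad\tmom\t2\t2\t1992",
            "F1\tc1\tdad\tmom\t1\t1\t1990",
        )
        coll = read_ped(ped)
        assert coll.n_families == 1
        sib = coll.sibships[0]
        assert sib.size == 3
        assert sib.affected_vector.tolist() == [False, True, False]
        assert [o.individual_id for o in sib.offspring] == ["c1", "c2", "c3"]

    def test_missing_phenotype_drops_individual_and_reranks(self, tmp_path, caplog):
        ped = write_lines(
            tmp_path / "fam.ped",
            "#fam\tind\tfather\tmother\tsex\tphen\tbirth_rank",
            "F1\tc1\tdad\tmom\t1\t1\t1",
            "F1\tc2\tdad\tmom\t2\t-9\t2",
            "F1\tc3\tdad\tmom\t1\t2\t3",
        )
        with caplog.at_level(logging.WARNING):
            coll = read_ped(ped)
        sib = coll.sibships[0]
        assert sib.size == 2
        assert [o.individual_id for o in sib.offspring] == ["c1", "c3"]
        assert [o.birth_rank for o in sib.offspring] == [1, 2]
        assert "missing phenotype" in caplog.text

    def test_strict_missing_drops_family(self, tmp_path):
        ped = write_lines(
            tmp_path / "fam.ped",
            "#fam\tind\tfather\tmother\tsex\tphen\tbirth_rank",
            "F1\tc1\tdad\tmom\t1\t1\t1",
            "F1\tc2\tdad\tmom\t2\t0\t2",
            "F2\tk1\tpa\tma\t1\t2\t1",
            "F2\tk2\tpa\tma\t2\t1\t2",
        )
        coll = read_ped(ped, strict_missing=True)
        assert [s.family_id for s in coll] == ["F2"]

    def test_empty_file_raises(self, tmp_path):
        ped = write_lines(tmp_path / "empty.ped", "")
        with pytest.raises(ValueError, match="no families parsed"):
            read_ped(ped)

    def test_malformed_row_names_line_number(self, tmp_path):
        ped = write_lines(
            tmp_path / "bad.ped",
            "F1\tc1\tdad\tmom\t1\t1",
            "F1\tc2\tdad\tmom\t1",
        )
        with pytest.raises(ValueError, match="bad.ped:2"):
            read_ped(ped)

    def test_family_without_rank_or_year_dropped_with_warning(
        self, tmp_path, caplog
    ):
        ped = write_lines(
            tmp_path / "fam.ped",
            "#fam\tind\tfather\tmother\tsex\tphen\tbirth_year",
            "F1\tc1\tdad\tmom\t1\t2\t.",
            "F1\tc2\tdad\tmom\t2\t1\t.",
            "F2\tk1\tpa\tma\t1\t2\t1990",
            "F2\tk2\tpa\tma\t2\t1\t1993",
        )
        with caplog.at_level(logging.WARNING):
            coll = read_ped(ped)
        assert [s.family_id for s in coll] == ["F2"]
        assert "family dropped" in caplog.text

    def test_headerless_six_column_file(self, tmp_path):
        # plain PED: no birth data at all -> every family dropped -> error
        ped = write_lines(
            tmp_path / "plain.ped",
            "F1\tc1\tdad\tmom\t1\t2",
            "F1\tc2\tdad\tmom\t2\t1",
        )
        with pytest.raises(ValueError, match="no families parsed"):
            read_ped(ped)

    def test_column_map_renames(self, tmp_path):
        ped = write_lines(
            tmp_path / "renamed.ped",
            "#FID\tIID\tPAT\tMAT\tSEX\tPHENO\tyob",
            "F1\tc1\tdad\tmom\t1\t2\t1990",
            "F1\tc2\tdad\tmom\t2\t1\t1993",
        )
        cfg = write_lines(
            tmp_path / "cols.cfg",
            "fam=FID",
            "ind=IID",
            "father=PAT",
            "mother=MAT",
            "sex=SEX",
            "phen=PHENO",
            "birth_year=yob",
        )
        coll = read_ped(ped, columns=ColumnMap.from_file(cfg))
        assert coll.sibships[0].affected_vector.tolist() == [True, False]

    def test_unknown_column_role_rejected(self, tmp_path):
        cfg = write_lines(tmp_path / "cols.cfg", "bogus=X")
        with pytest.raises(ValueError, match="unknown column role"):
            ColumnMap.from_file(cfg)


class TestFilterCollection:
    def test_concordant_twins_collapse(self):
        """Affected twins at ranks 2-3 of four collapse to one individual."""
        sib = Sibship(
            family_id="F1",
            father_id="d",
            mother_id="m",
            offspring=tuple(
                Offspring(f"c{z}", z, aff, twin_group=tg)
                for z, aff, tg in [
                    (1, False, None),
                    (2, True, "tw1"),
                    (3, True, "tw1"),
                    (4, False, None),
                ]
            ),
        )
        out = filter_collection(FamilyCollection(sibships=(sib,)))
        assert out.n_families == 1
        kept = out.sibships[0]
        assert kept.size == 3
        assert kept.affected_vector.tolist() == [False, True, False]
        assert [o.birth_rank for o in kept.offspring] == [1, 2, 3]

    def test_tied_birth_years_treated_as_twins(self):
        sib = Sibship(
            family_id="F1",
            father_id="d",
            mother_id="m",
            offspring=tuple(
                Offspring(f"c{z}", z, aff, birth_year=yr)
                for z, aff, yr in [
                    (1, False, 1990),
                    (2, True, 1993),
                    (3, True, 1993),
                ]
            ),
        )
        out = filter_collection(FamilyCollection(sibships=(sib,)))
        assert out.sibships[0].size == 2
        assert out.sibships[0].affected_vector.tolist() == [False, True]

    def test_discordant_twins_remove_family(self):
        sib = Sibship(
            family_id="F1",
            father_id="d",
            mother_id="m",
            offspring=(
                Offspring("c1", 1, False),
                Offspring("c2", 2, True, twin_group="tw"),
                Offspring("c3", 3, False, twin_group="tw"),
            ),
        )
        out = filter_collection(FamilyCollection(sibships=(sib,)))
        assert out.n_families == 0

    def test_singleton_family_removed(self):
        solo = Sibship(
            family_id="F1",
            father_id="d",
            mother_id="m",
            offspring=(Offspring("c1", 1, True),),
        )
        out = filter_collection(FamilyCollection(sibships=(solo,)))
        assert out.n_families == 0

    def test_missing_parent_removed(self):
        sib = Sibship(
            family_id="F1",
            father_id="0",
            mother_id="m",
            offspring=(Offspring("c1", 1, True), Offspring("c2", 2, False)),
        )
        out = filter_collection(FamilyCollection(sibships=(sib,)))
        assert out.n_families == 0

    @given(small_collections())
    def test_idempotent_and_canonical(self, c):
        once = filter_collection(c)
        twice = filter_collection(once)
        assert once == twice
        for sib in once:
            assert sib.has_canonical_ranks
            assert sib.size >= 2


class TestSubsetByAffectedSex:
    def _family(self, fid, statuses):
        return Sibship(
            family_id=fid,
            father_id="d",
            mother_id="m",
            offspring=tuple(
                Offspring(f"{fid}-{z}", z, aff, sex=sex)
                for z, (aff, sex) in enumerate(statuses, start=1)
            ),
        )

    def test_mixed_sex_multiplex_excluded_from_both(self):
        fam = self._family(
            "F1", [(True, "male"), (True, "female"), (False, "male")]
        )
        c = FamilyCollection(sibships=(fam,))
        assert subset_by_affected_sex(c, "male").n_families == 0
        assert subset_by_affected_sex(c, "female").n_families == 0

    def test_simplex_female_proband_in_female_subset_only(self):
        fam = self._family("F1", [(False, "male"), (True, "female")])
        c = FamilyCollection(sibships=(fam,))
        assert subset_by_affected_sex(c, "female").n_families == 1
        assert subset_by_affected_sex(c, "male").n_families == 0

    def test_unaffected_siblings_of_either_sex_retained(self):
        fam = self._family(
            "F1", [(True, "male"), (False, "female"), (False, "male")]
        )
        out = subset_by_affected_sex(
            FamilyCollection(sibships=(fam,)), "male"
        )
        assert out.sibships[0].size == 3

    def test_empty_subset_allowed(self, caplog):
        fam = self._family("F1", [(True, "male"), (False, "male")])
        with caplog.at_level(logging.WARNING):
            out = subset_by_affected_sex(
                FamilyCollection(sibships=(fam,)), "female"
            )
        assert out.n_families == 0
        assert "no families" in caplog.text

    def test_affected_counts_conserved_in_kept_families(self):
        fams = (
            self._family("F1", [(True, "male"), (False, "female")]),
            self._family("F2", [(True, "female"), (True, "female")]),
        )
        c = FamilyCollection(sibships=fams)
        out = subset_by_affected_sex(c, "female")
        assert out.n_affected == 2  # F2 only, intact


class TestParentalAgeProfile:
    def test_small_example(self):
        kids = [
            Offspring("a", 1, True, maternal_age_at_birth=30.0),
            Offspring("b", 2, False, maternal_age_at_birth=30.5),
            Offspring("c", 3, True, maternal_age_at_birth=40.0),
        ]
        c = FamilyCollection(
            sibships=(Sibship("F1", tuple(kids), "d", "m"),)
        )
        prof = parental_age_profile(c, "maternal", bin_width=1.0)
        assert prof.set_index("age_bin")["proportion_affected"].to_dict() == {
            30.0: 0.5,
            40.0: 1.0,
        }

    def test_all_unaffected_gives_zero_proportions(self):
        kids = [
            Offspring("a", 1, False, paternal_age_at_birth=25.0),
            Offspring("b", 2, False, paternal_age_at_birth=28.0),
        ]
        c = FamilyCollection(
            sibships=(Sibship("F1", tuple(kids), "d", "m"),)
        )
        prof = parental_age_profile(c, "paternal", bin_width=5.0)
        assert (prof["proportion_affected"] == 0).all()

    def test_no_ages_recorded_raises(self):
        c = make_collection("01")
        with pytest.raises(ValueError, match="no maternal ages"):
            parental_age_profile(c, "maternal")

    def test_logistic_collection_profile_nondecreasing(self):
        """Under rising age risk the affected proportion climbs with age."""
        from birthorder.simulate import (
            LogisticAgeRisk,
            SimulationConfig,
            simulate_collection,
        )

        coll = simulate_collection(
            SimulationConfig(n_families=20_000, seed=3, min_affected=0),
            LogisticAgeRisk(beta=0.5, a=45),
        )
        prof = parental_age_profile(coll, "maternal", bin_width=5.0)
        busy = prof[prof["n_total"] >= 200].reset_index(drop=True)
        props = busy["proportion_affected"].to_numpy()
        assert (np.diff(props) >= -0.02).all()


class TestWriteAndSummary:
    def test_write_read_roundtrip(self, tmp_path):
        from birthorder.simulate import (
            LogisticAgeRisk,
            SimulationConfig,
            simulate_collection,
        )

        coll = simulate_collection(
            SimulationConfig(n_families=30, seed=8),
            LogisticAgeRisk(beta=0.2, a=45),
        )
        path = tmp_path / "sim.ped"
        write_ped(coll, path)
        back = read_ped(path)
        assert back.sibships == coll.sibships

    def test_summary_table_shape(self):
        c = make_collection("01", "101", "0011")
        df = summary_table({"demo": c})
        row = df.iloc[0]
        assert row["n_families"] == 3
        assert row["n_children"] == 9
        assert row["n_affected"] == 5
        assert row["sibship_size"] == "2-4"
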