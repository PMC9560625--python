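"""Selection filter, NISP tallies and ZooMS/morphology integration."""

import numpy as np
import pytest

from zooms_screen.identify import TaxonAssignment
from zooms_screen.screening_summary import (
    BoneRecord,
    bone_records_to_frame,
    format_percent,
    integrate_zooms_nisp,
    load_bone_records,
    percent_within_group,
    round_half_up,
    select_for_zooms,
    tally_counts,
)


def record(specimen_id="x", site="s", size_cm=3.0, taxon="unidentified",
           group="indet", flags=(), **kw):
    defaults = dict(
        trabeculae_visible=True,
        in_situ_position_known=True,
        cortical_quality_ok=True,
    )
    defaults.update(kw)
    return BoneRecord(
        specimen_id=specimen_id, site=site, size_cm=size_cm,
        morphological_taxon=taxon, order_group=group,
        taphonomy_flags=frozenset(flags), **defaults,
    )


def site_records(site, determinate, n_indet, n_unid):
    """Build a site's records from {(taxon, group): count} plus filler."""
    records = []
    i = 0
    for (taxon, group), n in determinate.items():
        for _ in range(n):
            records.append(record(f"{site}-{i}", site, taxon=taxon, group=group))
            i += 1
    for _ in range(n_indet):
        records.append(record(f"{site}-{i}", site, taxon="indeterminate"))
        i += 1
    for _ in range(n_unid):
        records.append(record(f"{site}-{i}", site, taxon="unidentified"))
        i += 1
    return records


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (9.745, 1, 9.7), (25.776, 1, 25.8), (1.436, 1, 1.4),
        (89.36, 0, 89.0), (45.65, 0, 46.0), (0.25, 1, 0.3),
    ])
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected

    def test_format_drops_trailing_zero(self):
        assert format_percent(22.0) == "22"
        assert format_percent(25.8) == "25.8"


class TestSelect:
    def test_small_fragment_excluded(self):
        assert select_for_zooms([record(size_cm=1.5)]) == []

    def test_all_criteria_met_included(self):
        assert select_for_zooms([record("keep")]) == ["keep"]

    def test_determined_fragment_not_sampled(self):
        assert select_for_zooms([record(taxon="Cervus elaphus")]) == []

    def test_missing_field_excluded_with_warning(self, caplog):
        rec = record("m", trabeculae_visible=None)
        with caplog.at_level("WARNING"):
            assert select_for_zooms([rec]) == []
        assert "missing criterion" in caplog.text

    def test_taphonomy_severity_levels(self):
        rec = record("f", flags={"concretion"})
        assert select_for_zooms([rec], "none") == []
        assert select_for_zooms([rec], "moderate") == ["f"]
        rec2 = record("g", flags={"concretion", "manganese"})
        assert select_for_zooms([rec2], "moderate") == []
        assert select_for_zooms([rec2], "heavy") == ["g"]

    def test_matches_enumeration_oracle(self, rng):
        """Brute-force filter over randomized records must agree exactly."""
        records = []
        for i in range(50):
            records.append(record(
                f"r{i}",
                size_cm=float(rng.uniform(0.5, 6.0)),
                taxon=str(rng.choice(["unidentified", "indeterminate", "Sus scrofa"])),
                flags=set(rng.choice(["combustion", "manganese", "concretion"],
                                     rng.integers(0, 3), replace=False)),
                trabeculae_visible=bool(rng.random() < 0.8),
                in_situ_position_known=bool(rng.random() < 0.8),
                cortical_quality_ok=bool(rng.random() < 0.8),
            ))
        expected = [
            r.specimen_id for r in records
            if r.morphological_taxon == "unidentified" and r.size_cm > 2
            and r.trabeculae_visible and r.in_situ_position_known
            and r.cortical_quality_ok and len(r.taphonomy_flags) <= 1
        ]
        assert select_for_zooms(records, "moderate") == expected


class TestTally:
    @pytest.mark.parametrize("nisp,nr,expected", [
        (612, 6280, 9.7), (515, 1998, 25.8), (174, 12114, 1.4),
    ])
    def test_determinate_fraction(self, nisp, nr, expected):
        records = site_records(
            "s", {("Cervus elaphus", "Ungulata"): nisp}, nr - nisp, 0
        )
        summary = tally_counts(records)["s"]
        assert summary.total_nr == nr
        assert summary.total_nisp == nisp
        assert summary.determinate_pct == expected

    def test_group_percentages_sum_to_100(self):
        records = site_records("s", {
            ("Cervus elaphus", "Ungulata"): 37,
            ("Vulpes vulpes", "Carnivora"): 44,
            ("Lepus sp.", "Lagomorpha"): 11,
        }, 10, 5)
        s = tally_counts(records)["s"]
        assert sum(s.group_nisp.values()) == s.total_nisp
        assert abs(sum(s.group_pct.values()) - 100.0) <= 0.2

    def test_permutation_invariant(self, rng):
        records = site_records("s", {
            ("Cervus elaphus", "Ungulata"): 5,
            ("Canis lupus", "Carnivora"): 3,
        }, 4, 2)
        shuffled = list(records)
        rng.shuffle(shuffled)
        a = tally_counts(records)["s"]
        b = tally_counts(shuffled)["s"]
        assert (a.total_nr, a.total_nisp, a.group_nisp) == (
            b.total_nr, b.total_nisp, b.group_nisp
        )

    def test_status_partition_conserved(self):
        records = site_records("s", {("Sus scrofa", "Ungulata"): 7}, 11, 13)
        s = tally_counts(records)["s"]
        n_indet = sum(r.morphological_taxon == "indeterminate" for r in records)
        n_unid = sum(r.morphological_taxon == "unidentified" for r in records)
        assert s.total_nisp + n_indet + n_unid == s.total_nr


class TestPercentWithinGroup:
    def test_group_denominator_convention(self):
        # red deer 112 of 509 ungulates prints as 22; fox 44 of 55 carnivores as 80
        rss = tally_counts(site_records("rss", {
            ("Cervus elaphus", "Ungulata"): 112,
            ("Bos/Bison", "Ungulata"): 397,
        }, 0, 0))["rss"]
        assert percent_within_group(rss, "Cervus elaphus") == 22.0
        assert format_percent(percent_within_group(rss, "Cervus elaphus")) == "22"

        uc = tally_counts(site_records("uc", {
            ("Vulpes vulpes", "Carnivora"): 44,
            ("Canis lupus", "Carnivora"): 11,
        }, 0, 0))["uc"]
        assert percent_within_group(uc, "Vulpes vulpes") == 80.0

    def test_absent_taxon_is_zero(self):
        s = tally_counts(site_records("s", {("Sus scrofa", "Ungulata"): 3}, 0, 0))["s"]
        assert percent_within_group(s, "Equus ferus") == 0.0


class TestIntegrate:
    def _assignment(self, sid, label):
        return TaxonAssignment(sample_id=sid, assignment=label, n_diagnostic=2)

    def test_no_assignments_is_identity(self):
        records = site_records("s", {("Sus scrofa", "Ungulata"): 4}, 2, 3)
        df = integrate_zooms_nisp(records, [])
        assert df.set_index("category").loc["Sus scrofa", "combined_nisp"] == 4
        assert (df["zooms_nisp"] == 0).all()

    def test_zooms_adds_group_level_category(self):
        records = site_records("s", {("Sus scrofa", "Ungulata"): 4}, 0, 5)
        unid = [r.specimen_id for r in records if not r.is_determinate]
        assignments = [self._assignment(sid, "Bos/Bison") for sid in unid]
        df = integrate_zooms_nisp(records, assignments).set_index("category")
        assert df.loc["Bos/Bison", "zooms_nisp"] == 5
        assert df.loc["Bos/Bison", "combined_nisp"] == 5
        assert df.loc["Sus scrofa", "combined_nisp"] == 4

    def test_morphology_wins_on_conflict(self, caplog):
        records = site_records("s", {("Sus scrofa", "Ungulata"): 1}, 0, 0)
        sid = records[0].specimen_id
        with caplog.at_level("WARNING"):
            df = integrate_zooms_nisp(records, [self._assignment(sid, "Bos/Bison")])
        assert "conflict" in caplog.text
        idx = df.set_index("category")
        assert idx.loc["Sus scrofa", "combined_nisp"] == 1
        assert "Bos/Bison" not in idx.index

    def test_duplicate_assignment_counted_once(self):
        records = site_records("s", {}, 0, 1)
        sid = records[0].specimen_id
        df = integrate_zooms_nisp(
            records,
            [self._assignment(sid, "Cervidae"), self._assignment(sid, "Cervidae")],
        )
        assert df.set_index("category").loc["Cervidae", "combined_nisp"] == 1


def test_bone_records_csv_round_trip(tmp_path):
    records = [
        record("a", "s1", flags={"manganese"}),
        record("b", "s2", size_cm=1.2, taxon="Lepus sp.", group="Lagomorpha"),
    ]
    path = tmp_path / "bones.csv"
    bone_records_to_frame(records).to_csv(path, index=False)
    back = load_bone_records(path)
    assert [r.specimen_id for r in back] == ["a", "b"]
    assert back[0].taphonomy_flags == frozenset({"manganese"})
    assert back[1].size_class == "1-2"
    assert back[1].is_determinate
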