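import numpy as np
import pandas as pd
import pytest

from amplitrace import barcodes as bc
from amplitrace import contamination as cont
from amplitrace.plate import PlateLayout, WellAssignment, rotate_layout

from conftest import make_toy_layout
from oracles import dp_levenshtein

TAIL = "GGTTCCAAGGTTCCAA"


@pytest.fixture(scope="module")
def identifiers():
    return bc.generate_coligo_identifiers(8, seed=31)


def full_layout_96(identifiers_96):
    assignments = {}
    for i in range(96):
        r, c = divmod(i, 12)
        label = f"{chr(ord('A') + r)}{c + 1}"
        assignments[label] = WellAssignment(
            sample_id=f"S{i + 1}", fwd_mid_id=f"F{i + 1}", rev_mid_id=f"R{i + 1}",
            expected_coligo_id=identifiers_96[i].id,
        )
    return PlateLayout(assignments=assignments)


def matrix_from_dict(layout, identifiers, counts_by_well, totals=None):
    ids = [i.id for i in identifiers]
    wells = list(layout.assignments)
    counts = pd.DataFrame(0, index=wells, columns=ids, dtype=int)
    for well, row in counts_by_well.items():
        for cid, n in row.items():
            counts.at[well, cid] = n
    total = pd.Series({w: counts.loc[w].sum() for w in wells})
    if totals:
        for w, n in totals.items():
            total[w] = n
    return cont.ColigoCountMatrix(counts=counts, total_reads=total)


class TestExtractColigoId:
    def test_exact_prefix(self, identifiers):
        seq = identifiers[6].sequence + TAIL
        assert cont.extract_coligo_id(seq, identifiers) == identifiers[6].id

    def test_single_substitution_corrected(self, identifiers):
        target = identifiers[6]
        mutated = ("A" if target.sequence[0] != "A" else "C") + target.sequence[1:]
        others = [i for i in identifiers if i.id != target.id]
        assert all(dp_levenshtein(mutated, o.sequence) > 1 for o in others)
        assert cont.extract_coligo_id(mutated + TAIL, identifiers) == target.id

    def test_single_indel_corrected_by_flexible_window(self, identifiers):
        target = identifiers[3]
        deleted = target.sequence[1:]  # 12-base window holds the id minus one
        assert cont.extract_coligo_id(deleted + TAIL, identifiers) == target.id
        inserted = target.sequence[:5] + "T" + target.sequence[5:]
        assert cont.extract_coligo_id(inserted + TAIL, identifiers) == target.id

    def test_distant_sequence_rejected(self, identifiers):
        rng = np.random.default_rng(5)
        for _ in range(20):
            probe = "".join("ACGT"[i] for i in rng.integers(0, 4, 13))
            dists = [dp_levenshtein(probe, i.sequence) for i in identifiers]
            if min(dists) >= 2:
                assert cont.extract_coligo_id(probe + TAIL, identifiers) is None

    def test_too_short_read(self, identifiers):
        assert cont.extract_coligo_id("ACGT", identifiers) is None

    def test_exact_only_mode(self, identifiers):
        target = identifiers[0]
        mutated = ("A" if target.sequence[0] != "A" else "C") + target.sequence[1:]
        assert cont.extract_coligo_id(mutated + TAIL, identifiers,
                                      max_edits=0) is None


class TestCountColigos:
    def test_diagonal_when_uncontaminated(self, identifiers):
        layout = make_toy_layout(n_wells=4)
        reads = {
            f"A{i + 1}": [identifiers[i].sequence + TAIL] * (5 + i)
            for i in range(4)
        }
        m = cont.count_coligos(reads, identifiers, layout)
        arr = m.counts.loc[[f"A{i+1}" for i in range(4)],
                           [identifiers[i].id for i in range(4)]].to_numpy()
        assert (np.diag(np.diag(arr)) == arr).all()
        assert list(np.diag(arr)) == [5, 6, 7, 8]

    def test_unmatched_reads_ignored_but_counted_in_totals(self, identifiers):
        layout = make_toy_layout(n_wells=1)
        reads = {"A1": [identifiers[0].sequence + TAIL, "T" * 30]}
        m = cont.count_coligos(reads, identifiers, layout)
        assert m.counts.loc["A1"].sum() == 1
        assert m.total_reads["A1"] == 2

    def test_unknown_well_rejected(self, identifiers):
        layout = make_toy_layout(n_wells=1)
        with pytest.raises(ValueError, match="Z9"):
            cont.count_coligos({"Z9": []}, identifiers, layout)

    def test_empty_reads_all_zero(self, identifiers):
        layout = make_toy_layout(n_wells=2)
        m = cont.count_coligos({"A1": [], "A2": []}, identifiers, layout)
        assert m.counts.to_numpy().sum() == 0


class TestContaminationReport:
    def test_toy_table_structure(self, coligo_identifiers_96):
        """Wells 1-3 pure; well 4 heavily contaminated by coligo 1; well 96
        carries two minor contaminants."""
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        counts = {f"{chr(ord('A') + r)}{c + 1}":
                  {ids[r * 12 + c].id: 100} for r in range(8) for c in range(12)}
        counts["A4"] = {ids[3].id: 40, ids[0].id: 60}
        counts["H12"] = {ids[95].id: 100, ids[10].id: 2, ids[20].id: 1}
        m = matrix_from_dict(layout, ids, counts)
        report = cont.contamination_report(m, layout)
        contaminated = report.per_well.index[report.per_well["contaminated"]]
        assert set(contaminated) == {"A4", "H12"}
        assert (report.per_well.loc["A4", "proportion_expected"]
                < report.per_well.loc["H12", "proportion_expected"])
        assert report.per_well.loc["H12", "n_distinct_foreign"] == 2
        assert report.summary["frac_wells_with_any_foreign"] == pytest.approx(2 / 96)
        assert report.summary["frac_wells_with_multiple_foreign"] == pytest.approx(1 / 96)

    def test_half_foreign_well(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        counts = {f"{chr(ord('A') + r)}{c + 1}": {ids[r * 12 + c].id: 10}
                  for r in range(8) for c in range(12)}
        counts["A1"] = {ids[0].id: 10, ids[1].id: 10}
        m = matrix_from_dict(layout, ids, counts)
        report = cont.contamination_report(m, layout)
        assert report.per_well.loc["A1", "proportion_expected"] == pytest.approx(0.5)

    def test_clean_plate_summary_zeros(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        counts = {f"{chr(ord('A') + r)}{c + 1}": {ids[r * 12 + c].id: 10}
                  for r in range(8) for c in range(12)}
        m = matrix_from_dict(layout, ids, counts)
        report = cont.contamination_report(m, layout)
        assert report.summary["frac_wells_with_any_foreign"] == 0
        assert report.summary["overall_out_of_place_proportion"] == 0
        assert report.summary["median_foreign_proportion"] == 0

    def test_zero_coligo_well_excluded_from_median(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        counts = {f"{chr(ord('A') + r)}{c + 1}": {ids[r * 12 + c].id: 10}
                  for r in range(8) for c in range(12)}
        counts["B2"] = {}
        m = matrix_from_dict(layout, ids, counts, totals={"B2": 50})
        report = cont.contamination_report(m, layout)
        assert np.isnan(report.per_well.loc["B2", "proportion_expected"])
        assert report.summary["n_wells_no_coligo"] == 1
        assert report.summary["median_foreign_proportion"] == 0

    def test_conservation_expected_plus_foreign(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        rng = np.random.default_rng(0)
        counts = {}
        for r in range(8):
            for c in range(12):
                label = f"{chr(ord('A') + r)}{c + 1}"
                own = ids[r * 12 + c].id
                counts[label] = {own: int(rng.integers(0, 50))}
                for _ in range(rng.integers(0, 3)):
                    counts[label][ids[rng.integers(0, 96)].id] = int(rng.integers(1, 5))
        m = matrix_from_dict(layout, ids, counts)
        report = cont.contamination_report(m, layout)
        totals = m.counts.sum(axis=1)
        for well in report.per_well.index:
            row = report.per_well.loc[well]
            assert row["expected_coligo_reads"] + row["foreign_coligo_reads"] \
                == totals[well]

    def test_permutation_invariance_of_summary(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        rng = np.random.default_rng(3)
        counts = {f"{chr(ord('A') + r)}{c + 1}":
                  {ids[r * 12 + c].id: 20, ids[int(rng.integers(0, 96))].id: 2}
                  for r in range(8) for c in range(12)}
        m = matrix_from_dict(layout, ids, counts)
        base = cont.contamination_report(m, layout).summary
        perm = rng.permutation(len(m.counts))
        shuffled = cont.ColigoCountMatrix(
            counts=m.counts.iloc[perm], total_reads=m.total_reads.iloc[perm])
        assert cont.contamination_report(shuffled, layout).summary == base


class TestDistanceProfile:
    def test_single_adjacent_migration(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        counts = {f"{chr(ord('A') + r)}{c + 1}": {ids[r * 12 + c].id: 10}
                  for r in range(8) for c in range(12)}
        counts["A2"][ids[0].id] = 3  # A1's coligo seen in A2
        m = matrix_from_dict(layout, ids, counts)
        # exactly one event at distance 1
        assert cont.contamination_distance_profile(m, layout) == {1: 1}

    def test_two_events_rounded_diagonal(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        counts = {f"{chr(ord('A') + r)}{c + 1}": {ids[r * 12 + c].id: 10}
                  for r in range(8) for c in range(12)}
        counts["A2"][ids[0].id] = 2   # A1 -> A2, distance 1
        counts["B2"][ids[0].id] = 2   # A1 -> B2, sqrt(2) rounds to 1
        m = matrix_from_dict(layout, ids, counts)
        assert cont.contamination_distance_profile(m, layout) == {1: 2}

    def test_diagonal_matrix_empty_histogram(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        counts = {f"{chr(ord('A') + r)}{c + 1}": {ids[r * 12 + c].id: 10}
                  for r in range(8) for c in range(12)}
        m = matrix_from_dict(layout, ids, counts)
        assert cont.contamination_distance_profile(m, layout) == {}

    def test_homeless_coligo_binned_external(self, identifiers):
        layout = make_toy_layout(n_wells=2)
        ids = identifiers[:4]
        counts = pd.DataFrame(0, index=["A1", "A2"],
                              columns=[i.id for i in ids], dtype=int)
        counts.at["A1", ids[0].id] = 5
        counts.at["A1", ids[3].id] = 2  # coligo004 has no home well
        m = cont.ColigoCountMatrix(counts=counts,
                                   total_reads=counts.sum(axis=1))
        layout.assignments["A1"] = layout.assignments["A1"]
        prof = cont.contamination_distance_profile(m, layout)
        assert prof == {"external": 1}


class TestRotationCheck:
    def _diagonal(self, layout, ids):
        counts = {f"{chr(ord('A') + r)}{c + 1}": {ids[r * 12 + c].id: 10}
                  for r in range(8) for c in range(12)}
        return counts

    def test_correct_orientation(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        m = matrix_from_dict(layout, coligo_identifiers_96,
                             self._diagonal(layout, coligo_identifiers_96))
        res = cont.detect_plate_rotation(m, layout)
        assert res["orientation"] == 0
        assert res["score_0"] == 1.0
        assert not res["flagged"]

    def test_rotated_plate_flagged(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        rotated = rotate_layout(layout)
        # each well holds the coligo the *rotated* layout says it should
        counts = {label: {a.expected_coligo_id: 10}
                  for label, a in rotated.assignments.items()}
        m = matrix_from_dict(rotated, coligo_identifiers_96, counts)
        res = cont.detect_plate_rotation(m, layout)
        assert res["orientation"] == 180
        assert res["score_180"] == 1.0
        assert res["flagged"]

    def test_mixture_scores(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        ids = coligo_identifiers_96
        counts = {}
        for r in range(8):
            for c in range(12):
                label = f"{chr(ord('A') + r)}{c + 1}"
                own = ids[r * 12 + c].id
                opposite = ids[(7 - r) * 12 + (11 - c)].id
                counts[label] = {own: 6}
                counts[label][opposite] = counts[label].get(opposite, 0) + 4
        m = matrix_from_dict(layout, ids, counts)
        res = cont.detect_plate_rotation(m, layout)
        assert res["orientation"] == 0
        assert res["score_0"] == pytest.approx(0.6)
        assert res["score_180"] == pytest.approx(0.4)

    def test_zero_reads_undeterminable(self, coligo_identifiers_96):
        layout = full_layout_96(coligo_identifiers_96)
        m = matrix_from_dict(layout, coligo_identifiers_96, {})
        with pytest.raises(ValueError, match="undeterminable"):
            cont.detect_plate_rotation(m, layout)


class TestSpikeinFractions:
    def test_simple_fraction(self):
        counts = pd.DataFrame({"taxon1": [99], "coligo001": [1]}, index=["s1"])
        out = cont.spikein_fraction_summary(counts, ["coligo001"], "ISD")
        assert out["coligo_fraction"]["s1"] == pytest.approx(0.01)
        assert out["isd_fraction"]["s1"] == 0.0

    def test_isd_fraction_and_histogram(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame({
            "taxon1": rng.integers(900, 1000, 20),
            "ISD": rng.integers(1, 50, 20),
        }, index=[f"s{i}" for i in range(20)])
        out = cont.spikein_fraction_summary(counts, [], "ISD")
        expected = counts["ISD"] / counts.sum(axis=1)
        assert np.allclose(out["isd_fraction"], expected)
        assert sum(out["isd_histogram"]["counts"]) == 20
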