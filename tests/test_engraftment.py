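"""Colonization ladder classification, contingency and roll-ups."""

import numpy as np
import pandas as pd
import pytest

from hmaengraft import (
    Status,
    TaxonomyTable,
    classify_colonizers,
    classify_persistent,
    cross_model_contingency,
    detect_presence,
    identify_core_asvs,
    percentage,
    rollup_by_taxon,
    round_half_away,
    summarize_engraftment,
    union_rollup,
)
from hmaengraft.engraftment import ColonizationCall
from hmaengraft.model import StudyDesign, filter_samples_by_depth

from conftest import SCHEDULE, study_from_presence


def brute_force_calls(presence, fraction=0.5, min_days=4):
    """Direct transcription of the classification rule from a boolean
    (animals x days x ASVs) tensor, independent of the implementation."""
    presence = np.asarray(presence, dtype=bool)
    n_animals, n_days, n_asvs = presence.shape
    out = []
    for k in range(n_asvs):
        detected = presence[:, :, k].any()
        qualifying = 0
        for d in range(n_days):
            det = presence[:, d, k].sum()
            if det / n_animals > fraction:
                qualifying += 1
        if qualifying >= min_days:
            status = Status.persistent_colonizer
        elif detected:
            status = Status.colonizer
        else:
            status = Status.non_colonizer
        out.append((status, qualifying))
    return out


def classify_tensor(presence, design=None):
    table, meta = study_from_presence(presence)
    core_asvs = [a for a in table.asv_ids if a != "filler"]
    from hmaengraft.core import CoreSet

    core = CoreSet("D1", tuple(core_asvs), 3)
    pres = detect_presence(table, design)
    return classify_persistent(pres, meta, "D1", "mouse", core, design)


class TestColonizerRule:
    def test_single_detection_in_one_animal_is_a_colonizer(self):
        presence = np.zeros((3, 7, 2), dtype=bool)
        presence[1, 4, 0] = True  # one mouse, one day, first ASV
        calls = classify_tensor(presence)
        assert calls[0].status == Status.colonizer
        assert calls[1].status == Status.non_colonizer

    def test_inoculum_only_detection_is_not_colonization(self):
        # aliquots always contain every ASV in this fixture; zero fecal
        # presence must still yield non_colonizer
        presence = np.zeros((2, 7, 1), dtype=bool)
        calls = classify_tensor(presence)
        assert calls[0].status == Status.non_colonizer

    def test_colonizer_only_variant_agrees_with_full_ladder(self):
        rng = np.random.default_rng(0)
        presence = rng.random((3, 7, 5)) < 0.3
        table, meta = study_from_presence(presence)
        from hmaengraft.core import CoreSet

        core = CoreSet("D1", tuple(a for a in table.asv_ids if a != "filler"), 3)
        pres = detect_presence(table)
        col = classify_colonizers(pres, meta, "D1", "mouse", core)
        full = classify_persistent(pres, meta, "D1", "mouse", core)
        for c, f in zip(col, full):
            assert (c.status >= Status.colonizer) == (f.status >= Status.colonizer)


class TestPersistenceRule:
    def test_four_qualifying_days_reach_persistence(self):
        # 2 of 3 piglets on days {2,7,14,21}; absent otherwise
        presence = np.zeros((3, 7, 1), dtype=bool)
        presence[0, :4, 0] = True
        presence[1, :4, 0] = True
        calls = classify_tensor(presence)
        assert calls[0].status == Status.persistent_colonizer
        assert calls[0].n_majority_timepoints == 4

    def test_exactly_half_the_animals_does_not_qualify(self):
        # 5/10 mice on all 7 days: 0.5 is not > 0.5
        presence = np.zeros((10, 7, 1), dtype=bool)
        presence[:5, :, 0] = True
        calls = classify_tensor(presence)
        assert calls[0].status == Status.colonizer
        assert calls[0].n_majority_timepoints == 0

    def test_two_of_three_animals_qualifies(self):
        presence = np.zeros((3, 7, 1), dtype=bool)
        presence[:2, :, 0] = True
        calls = classify_tensor(presence)
        assert calls[0].n_majority_timepoints == 7

    def test_agrees_with_brute_force_on_random_tensors(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            n_animals = int(rng.integers(1, 6))
            presence = rng.random((n_animals, 7, 6)) < rng.uniform(0.2, 0.8)
            calls = classify_tensor(presence)
            expected = brute_force_calls(presence)
            got = [(c.status, c.n_majority_timepoints) for c in calls]
            assert got == expected

    def test_invariant_to_animal_and_day_ordering(self):
        rng = np.random.default_rng(4)
        presence = rng.random((4, 7, 5)) < 0.5
        base = [(c.asv_id, c.status, c.n_majority_timepoints)
                for c in classify_tensor(presence)]
        table, meta = study_from_presence(presence)
        shuffled = table.select_samples(list(rng.permutation(table.sample_ids)))
        from hmaengraft.core import CoreSet

        core = CoreSet("D1", tuple(a for a in table.asv_ids if a != "filler"), 3)
        calls = classify_persistent(
            detect_presence(shuffled), meta, "D1", "mouse", core
        )
        assert [(c.asv_id, c.status, c.n_majority_timepoints) for c in calls] == base

    def test_missing_day_contributes_nothing(self):
        # detection in >50% animals on 4 days, but one of those days has
        # no samples at all -> only 3 qualifying days -> not persistent
        presence = np.ones((2, 7, 1), dtype=bool)
        presence[:, 4:, 0] = False
        table, meta = study_from_presence(presence)
        drop_day = SCHEDULE[0]
        keep = [s for s in table.sample_ids if not s.endswith(f"_d{drop_day}")]
        from hmaengraft.core import CoreSet

        core = CoreSet("D1", ("asv0",), 3)
        calls = classify_persistent(
            detect_presence(table.select_samples(keep)), meta.subset(keep),
            "D1", "mouse", core,
        )
        assert calls[0].n_majority_timepoints == 3
        assert calls[0].status == Status.colonizer

    def test_dead_animals_shrink_the_denominator(self):
        # 1 of 2 animals detects on every day; with both sampled that is
        # not >50%, but if the other animal has no samples from day 14 on,
        # the fraction becomes 1/1 on five days -> persistent
        presence = np.zeros((2, 7, 1), dtype=bool)
        presence[0, :, 0] = True
        table, meta = study_from_presence(presence)
        dead_days = SCHEDULE[2:]
        drop = {f"D1_mouse_a1_d{d}" for d in dead_days}
        keep = [s for s in table.sample_ids if s not in drop]
        from hmaengraft.core import CoreSet

        core = CoreSet("D1", ("asv0",), 3)
        calls = classify_persistent(
            detect_presence(table.select_samples(keep)), meta.subset(keep),
            "D1", "mouse", core,
        )
        assert calls[0].n_majority_timepoints == 5
        assert calls[0].status == Status.persistent_colonizer
        # enrolled-denominator mode keeps dividing by 2
        calls_enrolled = classify_persistent(
            detect_presence(table.select_samples(keep)), meta.subset(keep),
            "D1", "mouse", core, denominator="enrolled",
        )
        assert calls_enrolled[0].status == Status.colonizer


class TestLadderMonotonicity:
    def test_persistent_implies_colonizer_implies_core(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            presence = rng.random((3, 7, 6)) < rng.uniform(0.1, 0.9)
            calls = classify_tensor(presence)
            core_ids = {f"asv{k}" for k in range(6)}
            for c in calls:
                assert c.asv_id in core_ids
                if c.status == Status.persistent_colonizer:
                    assert c.n_majority_timepoints >= 4
                    # persistent implies detected somewhere
                    assert presence[:, :, int(c.asv_id[3:])].any()


class TestSummaries:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(21, 26, 80.8), (65, 76, 85.5), (0, 10, 0.0), (16, 26, 61.5)],
    )
    def test_percentage_convention(self, count, total, expected):
        assert percentage(count, total) == expected

    def test_half_away_from_zero_rounding(self):
        assert round_half_away(0.5) == 1.0
        assert round_half_away(2.25, 1) == 2.3
        assert round_half_away(-2.25, 1) == -2.3

    def test_summary_counts_and_depth(self):
        presence = np.zeros((3, 7, 4), dtype=bool)
        presence[:, :, 0] = True              # persistent
        presence[0, 0, 1] = True              # colonizer only
        calls = classify_tensor(presence)
        table, meta = study_from_presence(presence)
        s = summarize_engraftment(calls, table, meta)
        assert (s.n_core, s.n_colonizers, s.n_persistent) == (4, 2, 1)
        assert s.pct_colonizers == 50.0
        assert s.pct_persistent == 25.0
        expected_depth = int(round(table.select_samples(
            [x for x in table.sample_ids if "_d" in x]).depths().mean()))
        assert s.mean_fecal_depth == expected_depth


def make_calls(statuses, donor="D1", host="mouse"):
    return [
        ColonizationCall(donor, host, f"asv{k}", s, 0, ())
        for k, s in enumerate(statuses)
    ]


class TestContingency:
    def test_partition_counts_sum_to_core(self):
        rng = np.random.default_rng(2)
        n = 40
        a = make_calls(rng.choice(list(Status), size=n), host="mouse")
        b = make_calls(rng.choice(list(Status), size=n), host="piglet")
        c = cross_model_contingency(a, b)
        assert c.n_core == n

    def test_disjoint_colonizer_sets_have_empty_intersection(self):
        a = make_calls([Status.colonizer, Status.non_colonizer], host="mouse")
        b = make_calls([Status.non_colonizer, Status.colonizer], host="piglet")
        c = cross_model_contingency(a, b)
        assert c.both_hosts == 0
        assert c.host_a_only == c.host_b_only == 1

    def test_identical_calls_have_no_exclusive_cells(self):
        a = make_calls([Status.colonizer, Status.persistent_colonizer], host="mouse")
        b = make_calls([Status.colonizer, Status.persistent_colonizer], host="piglet")
        c = cross_model_contingency(a, b)
        assert c.host_a_only == 0 and c.host_b_only == 0

    def test_mismatched_core_sets_error(self):
        a = make_calls([Status.colonizer], host="mouse")
        b = make_calls([Status.colonizer, Status.colonizer], host="piglet")
        with pytest.raises(ValueError, match="different core sets"):
            cross_model_contingency(a, b)

    def test_persistent_basis_uses_the_higher_rung(self):
        a = make_calls([Status.colonizer, Status.persistent_colonizer], host="mouse")
        b = make_calls([Status.persistent_colonizer] * 2, host="piglet")
        c = cross_model_contingency(a, b, basis=Status.persistent_colonizer)
        assert (c.both_hosts, c.host_b_only) == (1, 1)


def toy_taxonomy(phyla):
    rows = []
    for k, ph in enumerate(phyla):
        rows.append({"asv_id": f"asv{k}", "domain": "Bacteria", "phylum": ph,
                     "class": "", "order": "", "family": "", "genus": "",
                     "species": ""})
    return TaxonomyTable(pd.DataFrame(rows).set_index("asv_id"))


class TestRollups:
    def test_single_phylum_rollup_equals_ungrouped_totals(self):
        calls = make_calls(
            [Status.persistent_colonizer, Status.colonizer, Status.non_colonizer]
        )
        tax = toy_taxonomy(["Firmicutes"] * 3)
        r = rollup_by_taxon(calls, tax, "phylum")
        assert len(r) == 1
        assert r.loc[0, ["n_core", "n_colonizers", "n_persistent"]].tolist() == [3, 2, 1]

    def test_merging_phyla_adds_counts(self):
        rng = np.random.default_rng(6)
        statuses = list(rng.choice(list(Status), size=12))
        calls = make_calls(statuses)
        fine = toy_taxonomy(["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        merged = toy_taxonomy(["AB"] * 8 + ["C"] * 4)
        rf = rollup_by_taxon(calls, fine, "phylum").set_index("taxon")
        rm = rollup_by_taxon(calls, merged, "phylum").set_index("taxon")
        for col in ("n_core", "n_colonizers", "n_persistent"):
            assert rm.loc["AB", col] == rf.loc["A", col] + rf.loc["B", col]
            assert rf[col].sum() == rm[col].sum() == len(calls) if col == "n_core" else True

    def test_missing_assignment_grouped_as_unclassified(self):
        calls = make_calls([Status.colonizer, Status.colonizer])
        tax = toy_taxonomy(["Firmicutes"])  # asv1 absent from the taxonomy
        r = rollup_by_taxon(calls, tax, "phylum")
        assert set(r["taxon"]) == {"Firmicutes", "unclassified"}

    def test_unknown_rank_errors(self):
        calls = make_calls([Status.colonizer])
        with pytest.raises(ValueError, match="unknown rank"):
            rollup_by_taxon(calls, toy_taxonomy(["F"]), "kingdom")


class TestUnionRollup:
    def test_asv_counted_once_and_status_is_the_best_across_donors(self):
        tax = toy_taxonomy(["F"])
        calls = (
            make_calls([Status.non_colonizer], donor="D1")
            + make_calls([Status.colonizer], donor="D2")
        )
        r = union_rollup(calls, tax, "phylum")
        assert r.loc[0, "n_core"] == 1
        assert r.loc[0, "n_colonizers"] == 1

    def test_disjoint_donor_cores_add_up(self):
        tax = TaxonomyTable(
            pd.DataFrame(
                [{"asv_id": a, "domain": "Bacteria", "phylum": "F", "class": "",
                  "order": "", "family": "", "genus": "", "species": ""}
                 for a in ("asv0", "x0")]
            ).set_index("asv_id")
        )
        calls = make_calls([Status.colonizer], donor="D1") + [
            ColonizationCall("D2", "mouse", "x0", Status.persistent_colonizer, 5, ())
        ]
        r = union_rollup(calls, tax, "phylum")
        assert r.loc[0, "n_core"] == 2
        assert r.loc[0, "n_persistent"] == 1

    def test_matches_brute_force_set_union(self):
        rng = np.random.default_rng(8)
        universe = [f"asv{k}" for k in range(15)]
        tax = toy_taxonomy(["P"] * 15)
        calls = []
        for donor in ("D1", "D2", "D3"):
            members = [a for a in universe if rng.random() < 0.5]
            for a in members:
                calls.append(
                    ColonizationCall(
                        donor, "mouse", a,
                        Status(int(rng.integers(0, 3))), 0, (),
                    )
                )
        r = union_rollup(calls, tax, "phylum")
        seen = {c.asv_id for c in calls}
        colonized = {c.asv_id for c in calls if c.status >= Status.colonizer}
        persistent = {c.asv_id for c in calls if c.status >= Status.persistent_colonizer}
        assert r.loc[0, "n_core"] == len(seen)
        assert r.loc[0, "n_colonizers"] == len(colonized)
        assert r.loc[0, "n_persistent"] == len(persistent)


class TestSaturatedRegimeRecovery:
    def test_calls_match_simulation_truth_exactly(self, saturated_study):
        """With certain colonization, zero extinction and deep sequencing,
        classifier output equals ground truth for every ASV whose expected
        per-sample count is at least ~10 reads."""
        study = saturated_study
        design = StudyDesign()
        table = filter_samples_by_depth(study.table, design.min_sample_depth)
        presence = detect_presence(table, design)
        labels = study.truth.labels.set_index(["donor_id", "host", "asv_id"])
        from hmaengraft import relative_abundance

        for donor in study.metadata.donors():
            core = identify_core_asvs(table, study.metadata, donor, design)
            inoc = study.metadata.inoculum_samples(donor)
            donor_abund = relative_abundance(table.select_samples(inoc)).mean(axis=0)
            for host in ("mouse", "piglet"):
                calls = classify_persistent(
                    presence, study.metadata, donor, host, core, design
                )
                for c in calls:
                    if donor_abund[c.asv_id] < 10 / 500_000:
                        continue
                    truth = labels.loc[(donor, host, c.asv_id)]
                    assert (c.status >= Status.colonizer) == truth["true_colonizer"]
                    assert (
                        c.status >= Status.persistent_colonizer
                    ) == truth["true_persistent"]
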