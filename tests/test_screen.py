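"""Candidate filtering, ranking, redundancy collapse and shortlisting."""

import itertools

import pytest

from acpforge.libgen import PeptideLibrary, PeptideWindow
from acpforge.scores import consensus_score
from acpforge.screen import (
    SELECTED,
    ScreenConfig,
    apply_filters,
    candidates_frame,
    collapse_redundant,
    run_screen,
    select_top,
)


def annotations_from(candidates, candidate_library, candidate_ids):
    charges, helix, cons = {}, {}, {}
    for name, info in candidates.items():
        pid = candidate_ids[name]
        charges[pid] = info["charge"]
        helix[pid] = "helix" in info["structure"]
        cons[pid] = consensus_score(info["probs"])
    return charges, helix, cons


@pytest.fixture
def table1(candidates, candidate_library, candidate_ids):
    charges, helix, cons = annotations_from(candidates, candidate_library, candidate_ids)
    return candidate_library, charges, helix, cons


def mini_library(seqs, charges=3, consensus=0.9, helix=True):
    lib = PeptideLibrary(
        [PeptideWindow("s", 1 + 50 * i, 50 * i + len(s), s) for i, s in enumerate(seqs)],
        min(map(len, seqs)), max(map(len, seqs)), 1,
    )
    ids = [w.peptide_id for w in lib]
    as_map = lambda v: dict(zip(ids, v if isinstance(v, (list, tuple)) else [v] * len(ids)))
    return lib, as_map(charges), as_map(helix), as_map(consensus)


class TestApplyFilters:
    def test_published_ordering_and_helix_filter(self, table1, candidate_ids):
        lib, charges, helix, cons = table1
        ranked = apply_filters(lib, charges, helix, cons)
        order = [c.peptide_id for c in ranked if c.status == SELECTED]
        assert order == [candidate_ids[n] for n in
                         ["BMP-S6", "ALA-A1", "ALA-A3", "ALA-A2"]]
        a4 = next(c for c in ranked if c.peptide_id == candidate_ids["ALA-A4"])
        assert a4.status == "filtered_out:require_helix"
        assert a4.rank is None

    def test_all_neutral_filtered_by_charge(self):
        lib, charges, helix, cons = mini_library(["AAAAA", "CCCCC"], charges=0)
        ranked = apply_filters(lib, charges, helix, cons)
        assert all(c.status.startswith("filtered_out:min_charge") for c in ranked)

    def test_low_consensus_filtered(self):
        lib, charges, helix, cons = mini_library(["AAAAA"], consensus=0.3)
        ranked = apply_filters(lib, charges, helix, cons)
        assert ranked[0].status.startswith("filtered_out:consensus")

    def test_tie_break_deterministic(self):
        seqs = ["KKKAA", "KKKKCC"]  # equal consensus; charge 3 vs 4
        lib, charges, helix, cons = mini_library(seqs, charges=[3, 4], consensus=0.9)
        for _ in range(3):
            ranked = apply_filters(lib, charges, helix, cons)
            survivors = [c.peptide.sequence for c in ranked if c.rank]
            assert survivors == ["KKKKCC", "KKKAA"]  # higher charge first

    def test_strict_mode_names_missing_annotation(self, table1, candidate_ids):
        lib, charges, helix, cons = table1
        incomplete = dict(helix)
        incomplete.pop(candidate_ids["ALA-A1"])
        with pytest.raises(ValueError, match="structure"):
            apply_filters(lib, charges, incomplete, cons)

    def test_structure_needed_only_for_charge_passers(self):
        # the expensive structure annotation may legitimately cover only
        # peptides that already passed the charge filter
        lib, charges, helix, cons = mini_library(["KKKAA", "AAAAA"], charges=[3, 0])
        helix.pop(lib.windows[1].peptide_id)
        ranked = apply_filters(lib, charges, helix, cons)  # must not raise
        assert len(ranked) == 2

    def test_idempotent_on_survivors(self, table1):
        lib, charges, helix, cons = table1
        ranked = apply_filters(lib, charges, helix, cons)
        survivors = [c for c in ranked if c.status == SELECTED]
        sub = PeptideLibrary([c.peptide for c in survivors], 5, 25, 1)
        again = apply_filters(sub, charges, helix, cons)
        assert [c.peptide_id for c in again if c.status == SELECTED] == [
            c.peptide_id for c in survivors
        ]


class TestCollapseRedundant:
    def test_substring_collapse_of_published_pairs(self, table1, candidate_ids):
        lib, charges, helix, cons = table1
        collapsed = collapse_redundant(apply_filters(lib, charges, helix, cons))
        status = {c.peptide_id: c.status for c in collapsed}
        assert status[candidate_ids["ALA-A3"]] == f"redundant_of:{candidate_ids['ALA-A1']}"

    def test_disjoint_sequences_both_kept(self):
        lib, charges, helix, cons = mini_library(["KKKAA", "RRRCC"])
        collapsed = collapse_redundant(apply_filters(lib, charges, helix, cons))
        assert sum(c.status == SELECTED for c in collapsed) == 2

    def test_kept_set_has_no_substring_pair(self):
        seqs = ["KKKAACC", "KKKAA", "CCKKKAACC", "RRRWW", "RRRWWY"]
        lib, charges, helix, cons = mini_library(
            seqs, consensus=[0.9, 0.8, 0.7, 0.95, 0.6])
        collapsed = collapse_redundant(apply_filters(lib, charges, helix, cons))
        kept = [c.peptide.sequence for c in collapsed if c.status == SELECTED]
        for a, b in itertools.combinations(kept, 2):
            assert a not in b and b not in a

    def test_kept_candidates_reranked_without_gaps(self):
        seqs = ["KKKAACC", "KKKAA", "RRRWW"]
        lib, charges, helix, cons = mini_library(seqs, consensus=[0.9, 0.8, 0.7])
        collapsed = collapse_redundant(apply_filters(lib, charges, helix, cons))
        ranks = sorted(c.rank for c in collapsed if c.rank is not None)
        assert ranks == list(range(1, len(ranks) + 1))

    def test_overlap_fraction_mode_uses_coordinates(self):
        w1 = PeptideWindow("s", 1, 20, "K" * 20)
        w2 = PeptideWindow("s", 3, 22, "K" * 2 + "R" * 18)  # 18/20 = 0.9 overlap
        lib = PeptideLibrary([w1, w2], 20, 20, 1)
        ids = [w.peptide_id for w in lib]
        config = ScreenConfig(redundancy_mode="overlap_fraction",
                              overlap_fraction_cutoff=0.8)
        ranked = apply_filters(lib, dict.fromkeys(ids, 3), dict.fromkeys(ids, True),
                               {ids[0]: 0.9, ids[1]: 0.8}, config)
        collapsed = collapse_redundant(ranked, config)
        assert sum(c.status == SELECTED for c in collapsed) == 1


class TestSelection:
    def test_published_shortlist_excludes_control(self, table1, candidate_ids):
        lib, charges, helix, cons = table1
        collapsed, shortlist = run_screen(
            lib, charges, helix, cons, control_ids=[candidate_ids["BMP-S6"]])
        assert [c.peptide_id for c in shortlist] == [
            candidate_ids["ALA-A1"], candidate_ids["ALA-A2"]]
        control = next(c for c in collapsed if c.peptide_id == candidate_ids["BMP-S6"])
        assert control.status == "control"

    def test_top_1(self, table1, candidate_ids):
        lib, charges, helix, cons = table1
        collapsed, _ = run_screen(lib, charges, helix, cons,
                                  control_ids=[candidate_ids["BMP-S6"]])
        assert [c.peptide_id for c in select_top(collapsed, 1)] == [
            candidate_ids["ALA-A1"]]

    def test_fewer_survivors_than_top_k_warns_not_errors(self):
        lib, charges, helix, cons = mini_library(["KKKAA"], charges=0)
        collapsed, shortlist = run_screen(lib, charges, helix, cons)
        assert shortlist == []

    def test_report_frame_covers_all_candidates(self, table1):
        lib, charges, helix, cons = table1
        collapsed, _ = run_screen(lib, charges, helix, cons)
        df = candidates_frame(collapsed)
        assert len(df) == len(lib)
        assert {"rank", "sequence", "net_charge", "consensus", "status"} <= set(df.columns)


class TestScreeningRecovery:
    def test_precision_beats_base_rate_on_synthetic_scores(self):
        from acpforge import synth
        from acpforge.libgen import enumerate_windows
        from acpforge.scores import score_consensus
        from acpforge.synth import SynthScoreParams

        rec = synth.gen_protein(120, seed=7)
        lib = enumerate_windows(rec, 5, 12)
        table, truth = synth.gen_score_table(lib, SynthScoreParams(seed=7))
        cons = {r.peptide_id: r.consensus for r in score_consensus(table)}
        top = sorted(cons, key=cons.get, reverse=True)[:20]
        precision = truth.loc[top].mean()
        assert precision > truth.mean() + 0.2
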