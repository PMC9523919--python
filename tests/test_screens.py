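"""Screen scanning and consensus: orientation, per-pair tests, planted recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from crgi.datatypes import InteractionType, MutationCatalog, Orientation, ScreenDataset
from crgi.screens import (
    consensus,
    eligible_tissues,
    orient_to_viability,
    scan_candidates,
)
from crgi.screens import test_pair as pair_test
from crgi.simulate import SimulationConfig, generate_screens


def _screen(scores, orientation=Orientation.HIGH_IS_VIABLE, tissues=None):
    lineages = pd.Series(tissues or {c: "lung" for c in scores.columns})
    return ScreenDataset(name="s", orientation=orientation, scores=scores,
                         lineages=lineages)


def _catalog(rows):
    return MutationCatalog(
        records=pd.DataFrame(rows, columns=["sample", "gene", "mutation_class"])
    )


class TestOrientation:
    def test_high_is_viable_unchanged(self):
        m = pd.DataFrame([[1.0, -2.0]], index=["g"], columns=["a", "b"])
        s = _screen(m)
        assert orient_to_viability(s) is s

    def test_low_is_viable_negated(self):
        m = pd.DataFrame([[1.0, -2.0]], index=["g"], columns=["a", "b"])
        s = _screen(m, Orientation.LOW_IS_VIABLE)
        out = orient_to_viability(s)
        assert out.orientation is Orientation.HIGH_IS_VIABLE
        assert (out.scores.values == -m.values).all()

    def test_idempotent(self):
        m = pd.DataFrame([[3.0]], index=["g"], columns=["a"])
        s = _screen(m, Orientation.LOW_IS_VIABLE)
        once = orient_to_viability(s)
        twice = orient_to_viability(once)
        pd.testing.assert_frame_equal(once.scores, twice.scores)


class TestEligibleTissues:
    @pytest.mark.parametrize("n_lines, included", [(3, False), (4, True)])
    def test_more_than_three_rule(self, n_lines, included):
        cols = [f"c{i}" for i in range(n_lines)]
        m = pd.DataFrame([np.zeros(n_lines)], index=["g"], columns=cols)
        s = _screen(m, tissues={c: "breast" for c in cols})
        assert ("breast" in eligible_tissues(s)) is included

    def test_min_lines_one_keeps_all(self):
        m = pd.DataFrame([[0.0, 0.0]], index=["g"], columns=["a", "b"])
        s = _screen(m, tissues={"a": "t1", "b": "t2"})
        assert eligible_tissues(s, min_lines=1) == ["t1", "t2"]


class TestTestPair:
    def test_enumeration_example(self):
        # 3 mutant lines far below 4 wild-type: most extreme split,
        # p = 1 / C(7,3) = 1/35
        cols = [f"c{i}" for i in range(7)]
        scores = pd.DataFrame([[-3.0, -2.5, -2.0, 0.0, 0.1, 0.2, 0.3]],
                              index=["T"], columns=cols)
        cat = _catalog([(c, "P", "missense") for c in cols[:3]])
        res = pair_test(_screen(scores), cat, "lung", "T", "P")
        assert res.p_lethal == pytest.approx(1 / math.comb(7, 3))
        assert res.n_mut == 3 and res.n_wt == 4

    def test_directions_not_both_small(self):
        rng = np.random.default_rng(0)
        cols = [f"c{i}" for i in range(40)]
        scores = pd.DataFrame([rng.normal(size=40)], index=["T"], columns=cols)
        cat = _catalog([(c, "P", "missense") for c in cols[:15]])
        res = pair_test(_screen(scores), cat, "lung", "T", "P")
        assert not (res.p_lethal < 0.5 and res.p_viable < 0.5)

    def test_small_group_flagged_untested(self):
        cols = [f"c{i}" for i in range(6)]
        scores = pd.DataFrame([np.arange(6.0)], index=["T"], columns=cols)
        cat = _catalog([(cols[0], "P", "missense")])
        res = pair_test(_screen(scores), cat, "lung", "T", "P", min_group=3)
        assert not res.tested and "small" in res.reason

    def test_unoriented_screen_rejected(self):
        m = pd.DataFrame([[0.0] * 6], index=["T"],
                         columns=[f"c{i}" for i in range(6)])
        s = _screen(m, Orientation.LOW_IS_VIABLE)
        with pytest.raises(ValueError, match="oriented"):
            pair_test(s, _catalog([]), "lung", "T", "P")

    def test_absent_target_skip_record(self):
        m = pd.DataFrame([[0.0] * 4], index=["other"],
                         columns=[f"c{i}" for i in range(4)])
        res = pair_test(_screen(m), _catalog([]), "lung", "T", "P")
        assert not res.tested and "absent" in res.reason


class TestScanCandidates:
    def test_planted_pair_retained_and_non_cr_skipped(self, small_config, small_screens):
        screens, catalogs = small_screens
        table = scan_candidates(screens, catalogs, small_config.cr_genes,
                                small_config.targets, pairs=small_config.pair_design)
        target, partner = small_config.planted_csl[0]
        rows = table[(table.target == target) & (table.partner == partner)]
        assert len(rows) == len(screens)
        assert rows["sig_lethal"].all()
        # pairs without a CR side are never tested
        no_cr = scan_candidates(screens, catalogs, cr_genes=set(),
                                targets=small_config.targets,
                                pairs=small_config.pair_design)
        assert no_cr.empty

    def test_alpha_one_marks_everything(self, small_config, small_screens):
        screens, catalogs = small_screens
        table = scan_candidates(screens, catalogs, small_config.cr_genes,
                                small_config.targets,
                                pairs=small_config.pair_design, alpha=1.0)
        assert (table.sig_lethal | table.sig_viable).all()

    def test_direction_symmetry_under_negation(self, small_config, small_screens):
        """Negating viability swaps every CSL call to CSV and vice versa."""
        screens, catalogs = small_screens
        flipped = [
            ScreenDataset(name=s.name,
                          orientation=(Orientation.LOW_IS_VIABLE
                                       if s.orientation is Orientation.HIGH_IS_VIABLE
                                       else Orientation.HIGH_IS_VIABLE),
                          scores=s.scores, lineages=s.lineages)
            for s in screens
        ]
        kw = dict(cr_genes=small_config.cr_genes, targets=small_config.targets,
                  pairs=small_config.pair_design)
        t1 = scan_candidates(screens, catalogs, **kw)
        t2 = scan_candidates(flipped, catalogs, **kw)
        merged = t1.merge(t2, on=["screen", "tissue", "target", "partner"],
                          suffixes=("_a", "_b"))
        assert len(merged) == len(t1)
        assert np.allclose(merged.p_lethal_a, merged.p_viable_b)
        assert np.allclose(merged.p_viable_a, merged.p_lethal_b)


class TestConsensus:
    def _table(self, rows):
        cols = ["screen", "tissue", "target", "partner", "p_lethal", "p_viable",
                "n_mut", "n_wt", "sig_lethal", "sig_viable"]
        return pd.DataFrame(rows, columns=cols)

    def test_two_screen_support_combined(self):
        rows = [
            ("s1", "lung", "T", "P", 0.01, 0.99, 10, 20, True, False),
            ("s2", "lung", "T", "P", 0.01, 0.99, 10, 20, True, False),
        ]
        recs, conflicts = consensus(self._table(rows))
        assert len(recs) == 1 and not conflicts
        rec = recs[0]
        assert rec.itype is InteractionType.CSL
        assert rec.support == {"s1", "s2"}
        from crgi.stats import fisher_combine

        assert rec.combined_p == pytest.approx(fisher_combine([0.01, 0.01]))

    def test_single_screen_dropped(self):
        rows = [("s1", "lung", "T", "P", 0.01, 0.99, 10, 20, True, False),
                ("s2", "lung", "T", "P", 0.50, 0.50, 10, 20, False, False)]
        recs, _ = consensus(self._table(rows))
        assert recs == []

    def test_untested_screen_excluded_from_combination(self):
        """A pair tested in only 2 of 3 screens combines those 2 p-values."""
        rows = [("s1", "lung", "T", "P", 0.01, 0.99, 10, 20, True, False),
                ("s3", "lung", "T", "P", 0.02, 0.98, 10, 20, True, False)]
        recs, _ = consensus(self._table(rows))
        assert len(recs) == 1
        assert set(recs[0].per_dataset_p) == {"s1", "s3"}

    def test_opposing_directions_become_conflict(self):
        rows = [("s1", "lung", "T", "P", 0.01, 0.99, 10, 20, True, False),
                ("s2", "lung", "T", "P", 0.99, 0.01, 10, 20, False, True),
                ("s3", "lung", "T", "P", 0.01, 0.99, 10, 20, True, False)]
        recs, conflicts = consensus(self._table(rows))
        assert recs == []
        assert {c.itype for c in conflicts} == {InteractionType.CSL, InteractionType.CSV}
        assert all(c.conflict for c in conflicts)

    def test_planted_recovery_small(self, small_config, small_screens):
        screens, catalogs = small_screens
        table = scan_candidates(screens, catalogs, small_config.cr_genes,
                                small_config.targets, pairs=small_config.pair_design)
        recs, _ = consensus(table)
        found = {(r.target, r.partner): r.itype.value for r in recs}
        for t, p in small_config.planted_csl:
            assert found.get((t, p)) == "CSL"
        for t, p in small_config.planted_csv:
            assert found.get((t, p)) == "CSV"


class TestGeneratorScreens:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=5, n_csl=2, n_csv=1, n_null_pairs=5,
                               tissues={"lung": 30})
        s1, c1 = generate_screens(cfg)
        s2, c2 = generate_screens(cfg)
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.scores, b.scores)
        for name in c1:
            pd.testing.assert_frame_equal(c1[name].records, c2[name].records)

    def test_orientation_mix_matches_config(self, small_config, small_screens):
        screens, _ = small_screens
        assert [s.orientation for s in screens] == list(small_config.orientations)

    def test_planted_shift_visible_in_viability_space(self, small_config, small_screens):
        screens, catalogs = small_screens
        s = orient_to_viability(screens[0])
        target, partner = small_config.planted_csl[0]
        mut = catalogs[screens[0].name].altered_samples(partner)
        scores = s.scores.loc[target]
        is_mut = scores.index.isin(mut)
        diff = scores[is_mut].mean() - scores[~is_mut].mean()
        assert diff < -1.0  # planted 2-sigma lethality shift
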