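"""Stimulus classification, decorrelated selection and design assembly."""
import numpy as np
import pandas as pd
import pytest

from wordpatch import (
    ConditionDesign,
    Thresholds,
    classify_candidate,
    match_words,
    select_category_items,
)
from wordpatch.ngram import build_ngram_table, enumerate_candidates
from wordpatch.stimuli import LEVELS, stat_column


def flat_thresholds(langs=("E", "F"), low=0.3, high=0.7):
    return Thresholds({(l, n): (low, high) for l in langs for n in (1, 2, 4)})


def stats_dict(**kv):
    """Build a (lang, n) -> value mapping from letE/bigF-style keys."""
    name_to_n = {"let": 1, "big": 2, "quad": 4}
    return {(k[-1], name_to_n[k[:-1]]): v for k, v in kv.items()}


class TestClassifyCandidate:
    def test_low_letters_both_languages(self):
        s = stats_dict(letE=0.1, letF=0.2, bigE=0.5, bigF=0.5, quadE=0.5, quadF=0.5)
        assert classify_candidate(s, flat_thresholds(), ("E", "F")) == "L-"

    def test_high_english_low_french_letters(self):
        s = stats_dict(letE=0.9, letF=0.1, bigE=0.5, bigF=0.5, quadE=0.5, quadF=0.5)
        assert classify_candidate(s, flat_thresholds(), ("E", "F")) == "LE"

    def test_decorrelation_constraint_rejects(self):
        # high letters AND high quadrigrams: no level has neutral companions
        s = stats_dict(letE=0.9, letF=0.9, bigE=0.5, bigF=0.5, quadE=0.9, quadF=0.9)
        assert classify_candidate(s, flat_thresholds(), ("E", "F")) is None

    def test_all_cells_reachable(self):
        for lvl, n in LEVELS.items():
            for va, vb, expect in (
                (0.1, 0.1, "-"), (0.9, 0.1, "E"), (0.1, 0.9, "F"), (0.9, 0.9, "+")
            ):
                s = {(l, m): 0.5 for l in "EF" for m in (1, 2, 4)}
                s[("E", n)] = va
                s[("F", n)] = vb
                got = classify_candidate(s, flat_thresholds(), ("E", "F"))
                assert got == f"{lvl}{expect}"

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError, match="low"):
            Thresholds({("E", 1): (0.8, 0.2)})


def _toy_pool(rng, per_cell=6):
    """Candidates spread over all 12 cells with jittered neutral stats."""
    rows = []
    cols = [stat_column(n, l) for l in "EF" for n in (1, 2, 4)]
    for lvl, n in LEVELS.items():
        for va, vb, suffix in (
            (0.1, 0.1, "-"), (0.9, 0.1, "E"), (0.1, 0.9, "F"), (0.9, 0.9, "+")
        ):
            for i in range(per_cell):
                row = {c: float(rng.uniform(0.4, 0.6)) for c in cols}
                row[stat_column(n, "E")] = va + rng.uniform(-0.05, 0.05)
                row[stat_column(n, "F")] = vb + rng.uniform(-0.05, 0.05)
                row["cell"] = f"{lvl}{suffix}"
                row["string"] = f"{lvl}{suffix}{i:03d}"
                rows.append(row)
    return pd.DataFrame(rows)


class TestSelectCategoryItems:
    def setup_method(self):
        self.pool = _toy_pool(np.random.default_rng(0))
        self.design = ConditionDesign.en_fr(items_per_category=2)

    def test_counts_and_cell_consistency(self):
        items, achieved = select_category_items(self.pool, self.design, seed=1)
        assert len(items) == 24
        assert (items["category"] == items["cell"]).all()
        assert set(achieved) == set(self.design.nonword_categories)

    def test_deterministic_given_seed(self):
        a, _ = select_category_items(self.pool, self.design, seed=5)
        b, _ = select_category_items(self.pool, self.design, seed=5)
        assert a.equals(b)

    def test_infeasible_cell_reported(self):
        design = ConditionDesign.en_fr(items_per_category=10)
        with pytest.raises(ValueError, match="L-"):
            select_category_items(self.pool, design, seed=1)


class TestMatchWords:
    cols = [stat_column(n, l) for l in "EF" for n in (1, 2, 4)]

    def _words(self, rows):
        df = pd.DataFrame(rows, columns=self.cols)
        df.insert(0, "string", [f"W{i}" for i in range(len(df))])
        return df

    def test_identity_match_has_zero_deltas(self):
        words = self._words([[0.5] * 6] * 4)
        target = {c: 0.5 for c in self.cols}
        got = match_words(words, target, n_items=2, tolerance=0.0)
        assert got.attrs["match_deltas"] == {c: 0.0 for c in self.cols}

    def test_zero_tolerance_mismatch_errors_with_deltas(self):
        words = self._words([[0.6] * 6] * 3)
        target = {c: 0.5 for c in self.cols}
        with pytest.raises(ValueError, match=r"\+0\.1"):
            match_words(words, target, n_items=2, tolerance=0.0)

    def test_selects_the_two_within_tolerance_words(self):
        # two words near the target, two far away; tolerance admits only
        # selections built from the near pair
        words = self._words(
            [[0.55] * 6, [0.45] * 6, [1.0] * 6, [1.2] * 6]
        )
        target = {c: 0.5 for c in self.cols}
        got = match_words(words, target, n_items=2, tolerance=0.2)
        assert sorted(got["string"]) == ["W0", "W1"]
        # hand-computed deltas: mean(0.55, 0.45) - 0.5 = 0
        assert all(abs(d) < 1e-12 for d in got.attrs["match_deltas"].values())


class TestBuildDesign:
    def test_toy_design_counts(self, toy_design):
        items = toy_design.items
        assert len(items) == 28
        assert items["category"].nunique() == 14
        assert len(toy_design.design.nonword_categories) == 12

    def test_categories_disjoint_no_repeats(self, toy_design):
        assert not toy_design.items["string"].duplicated().any()

    def test_deterministic(self, toy_lexica):
        from wordpatch import build_design

        a, b = toy_lexica
        r1 = build_design(a, b, items_per_category=1, seed=3, match_tolerance=0.3)
        r2 = build_design(a, b, items_per_category=1, seed=3, match_tolerance=0.3)
        assert r1.items.equals(r2.items)

    def test_every_item_passes_enumeration_filters(self, toy_lexica, toy_design):
        """Independent re-check of every emitted nonword against the filters."""
        a, b = toy_lexica
        quads = set(build_ngram_table(a, 4).logfreq) | set(
            build_ngram_table(b, 4).logfreq
        )
        words5plus = {
            w for lex in (a, b) for w in lex.words if len(w) >= 5
        }
        all_words = set(a.words) | set(b.words)
        for _, row in toy_design.items.iterrows():
            s = row["string"]
            assert len(s) == 6
            if row["category"].startswith("W"):
                assert s in all_words
                continue
            assert any(s[i : i + 4] in quads for i in range(3))
            assert s not in all_words
            for wlen in (5, 6):
                for i in range(6 - wlen + 1):
                    assert s[i : i + wlen] not in words5plus

    def test_nonwords_classify_consistently(self, toy_design):
        th = toy_design.design.thresholds
        for _, row in toy_design.items.iterrows():
            if row["category"].startswith("W"):
                continue
            stats = {
                (l, n): row[stat_column(n, l)] for l in "EF" for n in (1, 2, 4)
            }
            assert classify_candidate(stats, th, ("E", "F")) == row["category"]

    def test_full_scale_cross_level_decorrelation(self, full_design):
        """Within each category, manipulated-level statistics stay decorrelated
        from the other levels (|r| below the ceiling at n = 180)."""
        items = full_design.items
        for lab in full_design.design.nonword_categories:
            sub = items[items["category"] == lab]
            n = LEVELS[lab[0]]
            targets = [stat_column(n, l) for l in "EF"]
            others = [
                stat_column(m, l) for l in "EF" for m in (1, 2, 4) if m != n
            ]
            for t in targets:
                for o in others:
                    r = np.corrcoef(sub[t], sub[o])[0, 1]
                    assert abs(r) < 0.3, (lab, t, o, r)
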