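"""Construction of the 14-category bilingual word-similarity design.

Twelve nonword categories cross the orthographic component being
manipulated (letters, bigrams, quadrigrams) with a 2 x 2 layout of
low/high mean component frequency in each of the two languages, and two
real-word categories (one per language) are matched to the corresponding
high-quadrigram nonword categories.  With the reference design's 180 items per
category this yields 2520 six-letter strings, each used exactly once.

Selection of nonword items is a greedy procedure that, within each
category, keeps the statistic of the manipulated level as decorrelated as
possible from the statistics of the other levels, so that e.g. an apparent
quadrigram-frequency effect cannot be carried by bigram frequency.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ngram import (
    DEFAULT_FLOOR,
    ComponentStats,
    Lexicon,
    NgramTable,
    build_ngram_table,
    _candidate_codes,
    _decode,
    _encode,
    _window_means,
    _word_codes_by_len,
)

__all__ = [
    "LEVELS",
    "Thresholds",
    "ConditionDesign",
    "DesignResult",
    "classify_candidate",
    "select_category_items",
    "match_words",
    "build_design",
]

#: Level code -> n-gram order.
LEVELS: dict[str, int] = {"L": 1, "B": 2, "Q": 4}

#: Column-name prefixes for the six per-string statistics.
STAT_PREFIX: dict[int, str] = {1: "let", 2: "big", 4: "quad"}


def stat_column(n: int, language_id: str) -> str:
    return f"{STAT_PREFIX[n]}{language_id}"


def nonword_labels(lang_a: str, lang_b: str) -> list[str]:
    """The 12 nonword labels: per level, both-low, high-A, high-B, both-high."""
    return [
        f"{lvl}{suffix}"
        for lvl in LEVELS
        for suffix in ("-", lang_a, lang_b, "+")
    ]


@dataclass(frozen=True)
class Thresholds:
    """Low / neutral / high bands per (language, n-gram order).

    ``bands[(lang, n)] = (low_max, high_min)``: a statistic is *low* when
    <= low_max, *high* when >= high_min, and *neutral* when it lies within
    [low_max, high_min].  Defaults place low/high in the outer quartiles of
    the candidate population and treat the interquartile range as neutral.
    """

    bands: Mapping[tuple[str, int], tuple[float, float]]

    def __post_init__(self) -> None:
        for key, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"threshold low >= high for {key}: {lo} >= {hi}")

    @classmethod
    def from_quantiles(
        cls,
        stats: pd.DataFrame,
        language_ids: Sequence[str],
        q_low: float = 0.25,
        q_high: float = 0.75,
    ) -> "Thresholds":
        bands = {}
        for lang in language_ids:
            for n in LEVELS.values():
                col = stats[stat_column(n, lang)].to_numpy()
                bands[(lang, n)] = (
                    float(np.quantile(col, q_low)),
                    float(np.quantile(col, q_high)),
                )
        return cls(bands)

    def band(self, lang: str, n: int, value: float) -> str:
        lo, hi = self.bands[(lang, n)]
        if value <= lo:
            return "low"
        if value >= hi:
            return "high"
        return "neutral"


@dataclass
class ConditionDesign:
    """The ordered condition axis of one experiment."""

    labels: tuple[str, ...]
    items_per_category: int
    language_ids: tuple[str, str]
    thresholds: Thresholds | None = None

    def __post_init__(self) -> None:
        if self.items_per_category < 1:
            raise ValueError("items_per_category must be positive")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("condition labels must be unique")

    @classmethod
    def en_fr(
        cls,
        items_per_category: int = 180,
        language_ids: tuple[str, str] = ("E", "F"),
        thresholds: Thresholds | None = None,
    ) -> "ConditionDesign":
        a, b = language_ids
        labels = tuple(nonword_labels(a, b)) + (f"W{a}", f"W{b}")
        return cls(labels, items_per_category, language_ids, thresholds)

    @classmethod
    def en_cn(cls, items_per_category: int = 180) -> "ConditionDesign":
        """Alphabetic/logographic design: 7 English + 7 Chinese conditions.

        The Chinese hierarchy (strokes S, stroke groups SG, radicals in
        impossible RI / possible RP positions, character pairs CP, low/high
        frequency words WL/WH) is hand-constructed in practice; the labels are
        represented here only so downstream analyses can address them.
        """
        labels = ("L-", "L+", "B-", "B+", "Q-", "Q+", "WE",
                  "S", "SG", "RI", "RP", "CP", "WL", "WH")
        return cls(labels, items_per_category, ("E", "C"))

    @property
    def nonword_categories(self) -> list[str]:
        a, b = self.language_ids
        return [lab for lab in self.labels if lab in set(nonword_labels(a, b))]

    @property
    def word_categories(self) -> list[str]:
        return [lab for lab in self.labels if lab.startswith("W")]


def classify_candidate(
    stats: ComponentStats | Mapping[tuple[str, int], float],
    thresholds: Thresholds,
    language_ids: Sequence[str],
) -> str | None:
    """Assign a candidate to one 2 x 2 cell of one level, or reject (None).

    For a target level the candidate's statistic must be low or high in
    *both* languages, while every other level's statistics must be neutral in
    both languages (the decorrelation constraint).  Levels are tried in the
    order letters, bigrams, quadrigrams.
    """
    a, b = language_ids
    get = stats.get if isinstance(stats, ComponentStats) else (
        lambda lang, n: stats[(lang, n)]
    )
    bands = {
        (lang, n): thresholds.band(lang, n, get(lang, n))
        for lang in (a, b)
        for n in LEVELS.values()
    }
    for lvl, n in LEVELS.items():
        ba, bb = bands[(a, n)], bands[(b, n)]
        if "neutral" in (ba, bb):
            continue
        others_ok = all(
            bands[(lang, m)] == "neutral"
            for lang in (a, b)
            for m in LEVELS.values()
            if m != n
        )
        if not others_ok:
            continue
        suffix = {"lowlow": "-", "highhigh": "+", "highlow": a, "lowhigh": b}[ba + bb]
        return f"{lvl}{suffix}"
    return None


def _assign_cells(
    stats: pd.DataFrame, thresholds: Thresholds, language_ids: Sequence[str]
) -> pd.Series:
    """Vectorized :func:`classify_candidate` over a stats frame."""
    a, b = language_ids
    band_code = {}
    for lang in (a, b):
        for n in LEVELS.values():
            lo, hi = thresholds.bands[(lang, n)]
            x = stats[stat_column(n, lang)].to_numpy()
            code = np.full(len(x), 1, dtype=np.int8)  # neutral
            code[x <= lo] = 0
            code[x >= hi] = 2
            band_code[(lang, n)] = code
    labels = np.full(len(stats), None, dtype=object)
    unassigned = np.ones(len(stats), dtype=bool)
    for lvl, n in LEVELS.items():
        ba, bb = band_code[(a, n)], band_code[(b, n)]
        others = np.ones(len(stats), dtype=bool)
        for m in LEVELS.values():
            if m != n:
                others &= (band_code[(a, m)] == 1) & (band_code[(b, m)] == 1)
        for ca, cb, suffix in ((0, 0, "-"), (2, 0, a), (0, 2, b), (2, 2, "+")):
            mask = unassigned & others & (ba == ca) & (bb == cb)
            labels[mask] = f"{lvl}{suffix}"
            unassigned &= ~mask
    return pd.Series(labels, index=stats.index, name="cell")


def _greedy_decorrelate(
    x: np.ndarray,
    target_cols: Sequence[int],
    other_cols: Sequence[int],
    k: int,
    rng: np.random.Generator,
    pool_cap: int = 4000,
    mean_target: np.ndarray | None = None,
    mean_weight: float = 0.0,
) -> np.ndarray:
    """Pick ``k`` rows of ``x`` greedily minimizing max cross-level |r|.

    At each step the candidate whose addition minimizes the maximum absolute
    Pearson correlation between any target-level column and any other-level
    column (within the growing selection) is added.  Running first and second
    moments make each step O(candidates).  With ``mean_target`` set, a
    penalty ``mean_weight * max |selection mean - target|`` is added to the
    step objective, steering the category means (used to co-adapt the
    quadrigram cells with the real-word categories).
    """
    n_rows = x.shape[0]
    if k > n_rows:
        raise ValueError(f"cannot select {k} items from {n_rows} candidates")
    avail = np.arange(n_rows)
    if n_rows > pool_cap:
        avail = np.sort(rng.choice(n_rows, size=max(pool_cap, k), replace=False))
    chosen: list[int] = []
    if mean_target is not None and mean_weight > 0:
        first = int(np.argmin(np.abs(x[avail] - mean_target[None, :]).max(axis=1)))
    else:
        first = int(rng.integers(len(avail)))
    chosen.append(int(avail[first]))
    avail = np.delete(avail, first)
    s = x[chosen[0]].astype(float).copy()
    m = np.outer(x[chosen[0]], x[chosen[0]]).astype(float)
    count = 1
    eps = 1e-12
    while count < k:
        xc = x[avail]
        n1 = count + 1
        s1 = s[None, :] + xc
        max_r = np.zeros(len(avail))
        for t in target_cols:
            vt = n1 * (m[t, t] + xc[:, t] ** 2) - s1[:, t] ** 2
            for o in other_cols:
                vo = n1 * (m[o, o] + xc[:, o] ** 2) - s1[:, o] ** 2
                cov = n1 * (m[t, o] + xc[:, t] * xc[:, o]) - s1[:, t] * s1[:, o]
                denom = np.sqrt(np.clip(vt * vo, 0.0, None))
                r = np.where(denom > eps, np.abs(cov) / np.maximum(denom, eps), 0.0)
                np.maximum(max_r, r, out=max_r)
        if mean_target is not None and mean_weight > 0:
            gap = np.abs(s1 / n1 - mean_target[None, :]).max(axis=1)
            max_r = max_r + mean_weight * gap
        best = int(np.argmin(max_r))
        idx = int(avail[best])
        chosen.append(idx)
        avail = np.delete(avail, best)
        s += x[idx]
        m += np.outer(x[idx], x[idx])
        count += 1
    return np.asarray(chosen)


def _cross_level_corr(x: np.ndarray, target_cols, other_cols) -> float:
    """Max |Pearson r| between target-level and other-level columns."""
    worst = 0.0
    for t in target_cols:
        for o in other_cols:
            xt, xo = x[:, t], x[:, o]
            if np.std(xt) < 1e-12 or np.std(xo) < 1e-12:
                continue
            worst = max(worst, abs(float(np.corrcoef(xt, xo)[0, 1])))
    return worst


def select_category_items(
    candidates: pd.DataFrame,
    design: ConditionDesign,
    seed: int,
    corr_ceiling: float = 0.3,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Select ``items_per_category`` strings for each nonword category.

    ``candidates`` must carry a ``cell`` column (from the classifier), the six
    statistic columns, and a ``string`` column.  Returns the selected items
    (with a ``category`` column) and the achieved max cross-level |r| per
    category.  Raises if any cell has too few eligible candidates.
    """
    a, b = design.language_ids
    k = design.items_per_category
    counts = candidates["cell"].value_counts()
    deficient = {
        lab: int(counts.get(lab, 0))
        for lab in design.nonword_categories
        if counts.get(lab, 0) < k
    }
    if deficient:
        raise ValueError(
            f"infeasible cells (need {k} items each): {deficient}"
        )
    rng = np.random.default_rng(seed)
    stat_cols = [stat_column(n, lang) for lang in (a, b) for n in LEVELS.values()]
    achieved: dict[str, float] = {}
    frames = []
    for lab in design.nonword_categories:
        n = LEVELS[lab[0]]
        target_cols = [stat_cols.index(stat_column(n, lang)) for lang in (a, b)]
        other_cols = [i for i in range(6) if i not in target_cols]
        pool = candidates[candidates["cell"] == lab]
        x = pool[stat_cols].to_numpy(float)
        sel = _greedy_decorrelate(x, target_cols, other_cols, k, rng)
        picked = pool.iloc[sel].copy()
        picked["category"] = lab
        achieved[lab] = _cross_level_corr(x[sel], target_cols, other_cols)
        if k >= 10 and achieved[lab] > corr_ceiling:
            warnings.warn(
                f"category {lab}: cross-level correlation "
                f"{achieved[lab]:.3f} exceeds the ceiling {corr_ceiling}",
                stacklevel=2,
            )
        frames.append(picked)
    out = pd.concat(frames, ignore_index=True)
    return out, achieved


def _match_core(
    x: np.ndarray,
    target: np.ndarray,
    n_items: int,
    seed: int,
    max_swaps: int = 800,
) -> tuple[np.ndarray, np.ndarray]:
    """Best-effort mean matching: greedy init plus steepest-swap refinement.

    Returns (boolean selection mask, per-statistic mean deltas).
    """
    n_pool = len(x)
    rng = np.random.default_rng(seed)
    selected = np.zeros(n_pool, dtype=bool)
    total = np.zeros(x.shape[1])
    dist0 = np.abs(x - target).max(axis=1)
    for idx in np.argsort(dist0, kind="stable")[:n_items]:
        selected[idx] = True
        total += x[idx]
    # swap one selected word for one unselected word whenever it reduces the
    # worst per-statistic deviation of the category mean
    for _ in range(max_swaps):
        delta = total / n_items - target
        sel_idx = np.flatnonzero(selected)
        out_idx = np.flatnonzero(~selected)
        if len(out_idx) == 0:
            break
        if len(out_idx) > 2000:
            out_idx = rng.choice(out_idx, 2000, replace=False)
        diff = (x[out_idx][None, :, :] - x[sel_idx][:, None, :]) / n_items
        cand = np.abs(delta[None, None, :] + diff).max(axis=2)
        i, j = np.unravel_index(np.argmin(cand), cand.shape)
        if cand[i, j] >= float(np.abs(delta).max()) - 1e-12:
            break
        selected[sel_idx[i]] = False
        selected[out_idx[j]] = True
        total += x[out_idx[j]] - x[sel_idx[i]]
    return selected, total / n_items - target


def match_words(
    words: pd.DataFrame,
    target_means: Mapping[str, float],
    n_items: int,
    tolerance: float = 0.1,
    seed: int = 0,
    max_swaps: int = 800,
) -> pd.DataFrame:
    """Select real words whose category means match a quadrigram category.

    ``words`` carries ``string`` plus the six statistic columns;
    ``target_means`` maps each statistic column to the mean of the
    corresponding high-quadrigram nonword category.  Selection greedily
    tracks the target mean, then refines by pairwise swaps; raises (reporting
    the best achievable per-statistic deltas) if any |delta| > tolerance.
    """
    cols = list(target_means)
    target = np.array([target_means[c] for c in cols], float)
    x = words[cols].to_numpy(float)
    if len(x) < n_items:
        raise ValueError(f"only {len(x)} candidate words for {n_items} slots")
    selected, delta = _match_core(x, target, n_items, seed, max_swaps)
    deltas = {c: float(d) for c, d in zip(cols, delta)}
    if any(abs(d) > tolerance for d in deltas.values()):
        raise ValueError(
            f"no word selection within tolerance {tolerance}; best deltas: "
            + ", ".join(f"{c}={d:+.4f}" for c, d in deltas.items())
        )
    out = words[selected].copy()
    out.attrs["match_deltas"] = deltas
    return out


@dataclass
class DesignResult:
    """Output of :func:`build_design`: design, items, and diagnostics."""

    design: ConditionDesign
    items: pd.DataFrame
    diagnostics: dict

    def to_tsv(self, path: str | Path) -> None:
        self.items.to_csv(path, sep="\t", index=False)

    def manifest(self) -> dict:
        return self.diagnostics

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_tsv(out / "stimuli.tsv")
        with (out / "design_manifest.json").open("w") as fh:
            json.dump(self.diagnostics, fh, indent=2, default=float)


def _score_codes(
    codes: np.ndarray,
    tables: Mapping[str, Mapping[int, NgramTable]],
    language_ids: Sequence[str],
    alphabet: str,
) -> pd.DataFrame:
    a = len(alphabet)
    data = {}
    for lang in language_ids:
        for n, table in tables[lang].items():
            data[stat_column(n, lang)] = _window_means(codes, table.as_array(), n, a)
    return pd.DataFrame(data)


def build_design(
    lexicon_a: Lexicon,
    lexicon_b: Lexicon,
    items_per_category: int = 180,
    seed: int = 0,
    floor: float = DEFAULT_FLOOR,
    q_low: float = 0.25,
    q_high: float = 0.75,
    match_tolerance: float = 0.1,
    word_freq_range: tuple[float, float] = (0.5, 10000.0),
    corr_ceiling: float = 0.3,
    string_length: int = 6,
    embed_min_len: int = 5,
) -> DesignResult:
    """Run the full pipeline: enumerate, classify, select, match words.

    Returns a :class:`DesignResult` whose ``items`` frame has one row per
    stimulus (``items_per_category`` per category, 14 categories) with the six
    per-language component statistics.
    """
    if lexicon_a.alphabet != lexicon_b.alphabet:
        raise ValueError("the two lexica must share one alphabet")
    alphabet = lexicon_a.alphabet
    la, lb = lexicon_a.language_id, lexicon_b.language_id
    tables = {
        lex.language_id: {n: build_ngram_table(lex, n, floor=floor) for n in LEVELS.values()}
        for lex in (lexicon_a, lexicon_b)
    }
    quads = sorted(set(tables[la][4].logfreq) | set(tables[lb][4].logfreq))
    quad_codes = _encode(quads, alphabet)
    word_codes = _word_codes_by_len(
        (lexicon_a, lexicon_b), alphabet, embed_min_len, string_length
    )
    codes = _candidate_codes(alphabet, string_length, quad_codes, word_codes, embed_min_len)
    if codes.shape[0] == 0:
        raise ValueError("candidate enumeration produced no strings")
    stats = _score_codes(codes, tables, (la, lb), alphabet)
    thresholds = Thresholds.from_quantiles(stats, (la, lb), q_low, q_high)
    design = ConditionDesign.en_fr(items_per_category, (la, lb), thresholds)
    stats["cell"] = _assign_cells(stats, thresholds, (la, lb))
    pool = stats[stats["cell"].notna()].copy()
    pool.insert(0, "string", _decode(codes[pool.index.to_numpy()], alphabet))
    nonwords, achieved = select_category_items(pool, design, seed, corr_ceiling)
    # Real-word categories matched to the high-quadrigram cells.  The match
    # is co-adaptive: if the words cannot meet the Q-cell means, the Q cell is
    # re-selected (decorrelation plus a mean-tracking penalty) toward the
    # midpoint between the two clouds, mirroring the joint optimization of
    # the original design.
    stat_cols = [stat_column(n, lang) for lang in (la, lb) for n in LEVELS.values()]
    word_frames = []
    match_deltas = {}
    rng = np.random.default_rng(seed + 1)
    for lang, lex, other in ((la, lexicon_a, lexicon_b), (lb, lexicon_b, lexicon_a)):
        exclusive = [
            w
            for w in lex.words_of_length(string_length)
            if w not in other
            and word_freq_range[0] <= lex.entries[w] <= word_freq_range[1]
        ]
        if len(exclusive) < items_per_category:
            raise ValueError(
                f"only {len(exclusive)} exclusive {string_length}-letter words "
                f"in {lang} within the frequency range"
            )
        wcodes = _encode(exclusive, alphabet)
        wstats = _score_codes(wcodes, tables, (la, lb), alphabet)
        wstats.insert(0, "string", exclusive)
        wx = wstats[stat_cols].to_numpy(float)
        q_label = f"Q{lang}"
        q_cell_pool = pool[pool["cell"] == q_label]
        qx = q_cell_pool[stat_cols].to_numpy(float)
        n4 = LEVELS["Q"]
        t_cols = [stat_cols.index(stat_column(n4, l)) for l in (la, lb)]
        o_cols = [i for i in range(6) if i not in t_cols]
        q_sel_df = nonwords[nonwords["category"] == q_label]
        q_sel_idx = None
        for _ in range(6):
            target = (
                q_sel_df[stat_cols].mean().to_numpy()
                if q_sel_idx is None
                else qx[q_sel_idx].mean(axis=0)
            )
            w_mask, delta = _match_core(
                wx, target, items_per_category, seed=int(rng.integers(2**31))
            )
            if np.all(np.abs(delta) <= match_tolerance):
                break
            joint = target + delta / 2  # midpoint between the two clouds
            q_sel_idx = _greedy_decorrelate(
                qx, t_cols, o_cols, items_per_category, rng,
                mean_target=joint, mean_weight=4.0,
            )
        if q_sel_idx is not None:
            # adopt the re-selected Q cell
            picked = q_cell_pool.iloc[q_sel_idx].copy()
            picked["category"] = q_label
            nonwords = pd.concat(
                [nonwords[nonwords["category"] != q_label], picked],
                ignore_index=True,
            )
            achieved[q_label] = _cross_level_corr(qx[q_sel_idx], t_cols, o_cols)
            if items_per_category >= 10 and achieved[q_label] > corr_ceiling:
                warnings.warn(
                    f"category {q_label}: cross-level correlation "
                    f"{achieved[q_label]:.3f} exceeds the ceiling {corr_ceiling}",
                    stacklevel=2,
                )
            target = qx[q_sel_idx].mean(axis=0)
        matched = match_words(
            wstats,
            dict(zip(stat_cols, target)),
            items_per_category,
            tolerance=match_tolerance,
            seed=seed,
        )
        matched["category"] = f"W{lang}"
        match_deltas[f"W{lang}"] = matched.attrs["match_deltas"]
        word_frames.append(matched)
    items = pd.concat([nonwords] + word_frames, ignore_index=True)
    items = items[["string", "category"] + stat_cols]
    dup = items["string"].duplicated()
    if dup.any():
        items = items[~dup]  # a real word can in principle collide across languages
    diagnostics = {
        "seed": seed,
        "language_ids": [la, lb],
        "items_per_category": items_per_category,
        "n_candidates": int(codes.shape[0]),
        "thresholds": {f"{k[0]}:{k[1]}": list(v) for k, v in thresholds.bands.items()},
        "achieved_cross_level_corr": achieved,
        "word_match_deltas": match_deltas,
        "labels": list(design.labels),
    }
    return DesignResult(design, items, diagnostics)
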