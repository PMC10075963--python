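"""Letter, bigram and quadrigram statistics of word-frequency lexica.

The sensitivity of ventral occipitotemporal cortex to written words is
driven by how well a letter string matches the n-gram statistics of the
reader's language(s).  This module provides the primitives for quantifying
that match: frequency lexica, n-gram frequency tables derived from them
(in log10 occurrences per million), per-string component statistics, and
the enumeration of candidate pseudo-word strings that contain at least one
attested quadrigram while embedding no real word.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "DEFAULT_ALPHABET",
    "DEFAULT_FLOOR",
    "Lexicon",
    "NgramTable",
    "ComponentStats",
    "build_ngram_table",
    "string_component_stats",
    "enumerate_candidates",
]

#: Roman alphabet; accented letters are deliberately excluded so that both
#: languages of a bilingual pair share one symbol set.
DEFAULT_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: log10 frequency assigned to unattested n-grams (0.01 per million): finite,
#: clearly below any attested value, but not so extreme that a single missing
#: n-gram dominates a string's mean.
DEFAULT_FLOOR = -2.0

NGRAM_ORDERS = (1, 2, 4)


@dataclass
class Lexicon:
    """A word -> frequency-per-million table for one language.

    Words are uppercased on ingestion and must be drawn from ``alphabet``;
    frequencies are strictly positive occurrences per million.
    """

    language_id: str
    entries: dict[str, float]
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon must contain at least one word")
        allowed = set(self.alphabet)
        clean: dict[str, float] = {}
        for word, freq in self.entries.items():
            w = word.upper()
            if not w:
                raise ValueError("empty word in lexicon")
            bad = set(w) - allowed
            if bad:
                raise ValueError(
                    f"word {w!r} uses symbols outside the alphabet: {sorted(bad)}"
                )
            if not np.isfinite(freq) or freq <= 0:
                raise ValueError(f"word {w!r} has non-positive frequency {freq!r}")
            if w in clean:
                raise ValueError(f"duplicate word {w!r} in lexicon")
            clean[w] = float(freq)
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word.upper() in self.entries

    @property
    def words(self) -> list[str]:
        return list(self.entries)

    def words_of_length(self, n: int) -> list[str]:
        return [w for w in self.entries if len(w) == n]

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        language_id: str | None = None,
        alphabet: str | None = DEFAULT_ALPHABET,
    ) -> "Lexicon":
        """Read a two-column ``word<TAB>freq_per_million`` TSV.

        A header line is auto-detected (second field not parseable as a
        number); lines starting with ``#`` are ignored.  ``alphabet=None``
        infers the alphabet from the letters actually observed (useful for
        lexica over reduced symbol sets).
        """
        path = Path(path)
        entries: dict[str, float] = {}
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{i + 1}: expected two tab-separated columns")
                try:
                    freq = float(parts[1])
                except ValueError:
                    if not entries and i < 2:  # header
                        continue
                    raise
                entries[parts[0]] = freq
        if alphabet is None:
            alphabet = "".join(sorted({c for w in entries for c in w.upper()}))
        return cls(language_id or path.stem, entries, alphabet=alphabet)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("word\tfreq_per_million\n")
            for w, f in self.entries.items():
                fh.write(f"{w}\t{f:g}\n")


@dataclass
class NgramTable:
    """log10 per-million frequencies of the n-grams of one language.

    Unattested n-grams are looked up as ``floor``.
    """

    language_id: str
    n: int
    logfreq: dict[str, float]
    floor: float = DEFAULT_FLOOR
    alphabet: str = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        for g, v in self.logfreq.items():
            if len(g) != self.n:
                raise ValueError(f"n-gram {g!r} does not have length {self.n}")
            if not np.isfinite(v):
                raise ValueError(f"non-finite log-frequency for {g!r}")
            if v < self.floor:
                raise ValueError(f"log-frequency of {g!r} below the floor {self.floor}")

    def lookup(self, gram: str) -> float:
        if len(gram) != self.n:
            raise ValueError(f"expected an n-gram of length {self.n}, got {gram!r}")
        return self.logfreq.get(gram.upper(), self.floor)

    def __len__(self) -> int:
        return len(self.logfreq)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("ngram\tlog10_freq\n")
            for g, v in sorted(self.logfreq.items()):
                fh.write(f"{g}\t{v:.6f}\n")

    def as_array(self) -> np.ndarray:
        """Dense lookup array over all ``len(alphabet)**n`` codes (internal fast path)."""
        size = len(self.alphabet) ** self.n
        arr = np.full(size, self.floor, dtype=np.float64)
        for g, v in self.logfreq.items():
            arr[_pack(_encode([g], self.alphabet), len(self.alphabet))[0]] = v
        return arr


@dataclass(frozen=True)
class ComponentStats:
    """Mean log10 n-gram frequencies of one string, per language and level."""

    string: str
    values: Mapping[tuple[str, int], float]

    def __getitem__(self, key: tuple[str, int]) -> float:
        return self.values[key]

    def get(self, language_id: str, n: int) -> float:
        return self.values[(language_id, n)]


def _occurrence_counts(word: str, n: int) -> dict[str, int]:
    """Count overlapping occurrences of every length-n window of ``word``."""
    counts: dict[str, int] = {}
    for i in range(len(word) - n + 1):
        g = word[i : i + n]
        counts[g] = counts.get(g, 0) + 1
    return counts


def build_ngram_table(
    lexicon: Lexicon,
    n: int,
    floor: float = DEFAULT_FLOOR,
    token_weighted: bool = True,
) -> NgramTable:
    """Aggregate n-gram frequencies over a lexicon.

    For each n-gram ``g`` the raw frequency is the sum over words of the
    number of (overlapping) occurrences of ``g`` in the word, weighted by the
    word's corpus frequency per million (``token_weighted=True``) or by 1 per
    word type (``token_weighted=False``).  The table stores
    ``log10(raw frequency)``.
    """
    if n not in NGRAM_ORDERS:
        raise ValueError(f"n must be one of {NGRAM_ORDERS}, got {n}")
    raw: dict[str, float] = {}
    for word, freq in lexicon.entries.items():
        if len(word) < n:
            raise ValueError(f"word {word!r} is shorter than the n-gram order {n}")
        w = freq if token_weighted else 1.0
        for g, k in _occurrence_counts(word, n).items():
            raw[g] = raw.get(g, 0.0) + k * w
    logfreq = {g: float(np.log10(v)) for g, v in raw.items()}
    lo = min(logfreq.values())
    if lo < floor:
        raise ValueError(
            f"floor {floor} exceeds the smallest attested log-frequency {lo:.4f}; "
            "lower the floor"
        )
    return NgramTable(lexicon.language_id, n, logfreq, floor=floor, alphabet=lexicon.alphabet)


def string_component_stats(
    s: str, tables: Mapping[str, Mapping[int, NgramTable]]
) -> ComponentStats:
    """Mean log10 frequency of the letters, bigrams and quadrigrams of ``s``.

    ``tables`` maps language id -> n-gram order -> :class:`NgramTable`.  The
    mean runs over all ``len(s) - n + 1`` contiguous windows; unattested
    windows contribute the table's floor.
    """
    s = s.upper()
    if len(s) < max(max(t) for t in tables.values()):
        raise ValueError(
            f"string {s!r} is shorter than the largest n-gram order"
        )
    values: dict[tuple[str, int], float] = {}
    for lang, by_n in tables.items():
        for n, table in by_n.items():
            bad = set(s) - set(table.alphabet)
            if bad:
                raise ValueError(
                    f"string {s!r} uses symbols outside the alphabet: {sorted(bad)}"
                )
            grams = [s[i : i + n] for i in range(len(s) - n + 1)]
            values[(lang, n)] = float(np.mean([table.lookup(g) for g in grams]))
    return ComponentStats(s, values)


# ---------------------------------------------------------------------------
# Vectorized internals shared with the stimulus generator.

def _encode(strings: Iterable[str], alphabet: str) -> np.ndarray:
    """Strings -> uint8 code matrix (row per string, column per position)."""
    index = {c: i for i, c in enumerate(alphabet)}
    rows = []
    for s in strings:
        try:
            rows.append([index[c] for c in s])
        except KeyError as exc:
            raise ValueError(f"symbol {exc.args[0]!r} outside the alphabet") from None
    return np.asarray(rows, dtype=np.uint8)


def _decode(codes: np.ndarray, alphabet: str) -> list[str]:
    letters = np.asarray(list(alphabet))
    return ["".join(row) for row in letters[codes]]


def _pack(codes: np.ndarray, a: int) -> np.ndarray:
    """Base-``a`` packing of code rows into int64 (lexicographic order)."""
    out = np.zeros(codes.shape[0], dtype=np.int64)
    for j in range(codes.shape[1]):
        out = out * a + codes[:, j]
    return out


def _window_means(codes: np.ndarray, table_arr: np.ndarray, n: int, a: int) -> np.ndarray:
    """Mean table value over all length-n windows of each code row."""
    length = codes.shape[1]
    idx = np.zeros((codes.shape[0], length - n + 1), dtype=np.int64)
    for k in range(n):
        idx = idx * a + codes[:, k : length - n + 1 + k]
    return table_arr[idx].mean(axis=1)


def _candidate_codes(
    alphabet: str,
    length: int,
    quad_codes: np.ndarray,
    word_codes_by_len: Mapping[int, np.ndarray],
    embed_min_len: int,
) -> np.ndarray:
    """All strings of ``length`` containing >=1 quadrigram, embedding no word.

    Returns a deduplicated uint8 code matrix sorted lexicographically.
    ``quad_codes`` is (Q, 4); ``word_codes_by_len[k]`` is a sorted int64 array
    of packed words of length ``k``.
    """
    a = len(alphabet)
    if length < 4:
        raise ValueError("candidate length must be at least 4")
    if quad_codes.size == 0:
        return np.empty((0, length), dtype=np.uint8)
    n_free = length - 4
    free = np.zeros((a**n_free, n_free), dtype=np.uint8)
    for i, combo in enumerate(itertools.product(range(a), repeat=n_free)):
        free[i] = combo
    blocks = []
    for p in range(length - 3):
        out = np.empty((quad_codes.shape[0], free.shape[0], length), dtype=np.uint8)
        out[:, :, p : p + 4] = quad_codes[:, None, :]
        if p:
            out[:, :, :p] = free[None, :, :p]
        if p + 4 < length:
            out[:, :, p + 4 :] = free[None, :, p:]
        blocks.append(out.reshape(-1, length))
    codes = np.concatenate(blocks, axis=0)
    packed = _pack(codes, a)
    _, first = np.unique(packed, return_index=True)
    codes = codes[np.sort(first)]  # keep, then re-sort below
    packed = _pack(codes, a)
    order = np.argsort(packed, kind="stable")
    codes = codes[order]
    # remove candidates embedding a real word (length >= embed_min_len), or
    # being one themselves
    keep = np.ones(codes.shape[0], dtype=bool)
    for wlen, words in word_codes_by_len.items():
        if words.size == 0:
            continue
        if wlen == length:  # the candidate must not itself be a word
            keep &= ~np.isin(_pack(codes, a), words)
        elif wlen >= embed_min_len:
            for off in range(length - wlen + 1):
                sub = _pack(codes[:, off : off + wlen], a)
                keep &= ~np.isin(sub, words)
    return codes[keep]


def _word_codes_by_len(
    lexica: Iterable[Lexicon], alphabet: str, min_len: int, max_len: int
) -> dict[int, np.ndarray]:
    a = len(alphabet)
    out: dict[int, np.ndarray] = {}
    for k in range(min_len, max_len + 1):
        words = sorted({w for lex in lexica for w in lex.words_of_length(k)})
        if words:
            out[k] = np.sort(_pack(_encode(words, alphabet), a))
    return out


def enumerate_candidates(
    alphabet: str,
    attested_quadrigrams: Iterable[str],
    lexica: Iterable[Lexicon] = (),
    length: int = 6,
    embed_min_len: int = 5,
) -> Iterator[str]:
    """Yield, in lexicographic order, every candidate pseudo-word string.

    A candidate (i) has the requested length, (ii) contains at least one
    attested quadrigram, (iii) embeds no word of length >= ``embed_min_len``
    from any of the lexica, and (iv) is not itself a word.
    """
    quads = sorted({q.upper() for q in attested_quadrigrams})
    for q in quads:
        if len(q) != 4:
            raise ValueError(f"attested quadrigram {q!r} does not have length 4")
    lexica = list(lexica)
    quad_codes = (
        _encode(quads, alphabet) if quads else np.empty((0, 4), dtype=np.uint8)
    )
    words = _word_codes_by_len(lexica, alphabet, min(embed_min_len, length), length)
    codes = _candidate_codes(alphabet, length, quad_codes, words, embed_min_len)
    yield from _decode(codes, alphabet)
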