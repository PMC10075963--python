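"""Synthetic bilingual lexica and ROI cohorts with planted structure.

Every downstream stage of the pipeline is testable without any real
MRI data: this module generates (i) pairs of word-frequency lexica over a
shared alphabet with Zipf-distributed frequencies and controllable
divergence of their letter/bigram statistics, and (ii) cohorts of
participants carrying word-specific ROIs whose condition betas embed a
known posterior-to-anterior word-similarity gradient, optional
language-specific patches with elevated face responses, behavioral
reading scores, and voxel noise.  Every planted parameter is recorded in
a ground-truth manifest so recovery can be checked exactly.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ngram import Lexicon
from .roistats import Predictor
from .schedule import LOCALIZER_CATEGORIES, Schedule
from .hemo import design_matrix_from_schedule

__all__ = [
    "SyntheticLexiconSpec",
    "CohortSpec",
    "ROIRecord",
    "ParticipantData",
    "CohortData",
    "make_synthetic_lexica",
    "generate_feasible_design",
    "simulate_cohort",
    "make_dominance_fixture",
    "planted_correlation_vector",
    "simulate_roi_timecourses",
]


# ---------------------------------------------------------------------------
# Lexica

@dataclass(frozen=True)
class SyntheticLexiconSpec:
    """Parameters of a synthetic bilingual lexicon pair.

    Word frequencies follow a Zipf law (``top_freq / rank**zipf_exponent``
    per million).  Letters are drawn from a first-order Markov chain whose
    stationary preferences differ between the two languages by
    ``letter_divergence`` (0 = identical statistics, 1 = independent);
    ``markov_strength`` adds language-specific bigram structure beyond the
    letter preferences.  ``rare_word_temperature`` flattens the chain for
    low-frequency words (sampling probabilities are raised to
    ``1 / (1 + temperature * rank / n)``), reproducing the real-lexicon
    property that rare words are built from rarer letter combinations.
    ``overlap`` is the fraction of shared vocabulary.
    """

    language_ids: tuple[str, str] = ("E", "F")
    alphabet: str = "ABCDEFGHIJ"
    n_words: int = 20000
    length_probs: Mapping[int, float] = field(
        default_factory=lambda: {5: 0.25, 6: 0.5, 7: 0.25}
    )
    zipf_exponent: float = 1.3
    top_freq: float = 30000.0
    letter_divergence: float = 0.7
    markov_strength: float = 0.8
    rare_word_temperature: float = 1.0
    overlap: float = 0.02

    def __post_init__(self) -> None:
        if self.n_words < 1:
            raise ValueError("n_words must be at least 1")
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must lie in [0, 1]")
        if not 0 <= self.letter_divergence <= 1:
            raise ValueError("letter_divergence must lie in [0, 1]")
        total = sum(self.length_probs.values())
        if abs(total - 1) > 1e-9:
            raise ValueError("length probabilities must sum to 1")
        if min(self.length_probs) < 4:
            raise ValueError("words must be at least 4 letters for quadrigram tables")


def _language_chain(spec: SyntheticLexiconSpec, rng: np.random.Generator):
    """Initial letter distribution and transition matrix for one language."""
    a = len(spec.alphabet)
    base = 1.0 / np.arange(1, a + 1)  # Zipf-ish letter preferences
    base /= base.sum()
    own = base[rng.permutation(a)]
    d = spec.letter_divergence
    p = base ** (1 - d) * own**d
    p /= p.sum()
    g = rng.standard_normal((a, a))
    trans = p[None, :] * np.exp(spec.markov_strength * g)
    trans /= trans.sum(axis=1, keepdims=True)
    return p, trans


def _temper(dist: np.ndarray, inv_temp: float) -> np.ndarray:
    q = dist**inv_temp
    return q / q.sum(axis=-1, keepdims=True)


def _sample_words(
    n: int,
    lengths: np.ndarray,
    p: np.ndarray,
    trans: np.ndarray,
    alphabet: str,
    rng: np.random.Generator,
    temperature: float = 0.0,
    forbidden: set[str] = frozenset(),
    max_factor: int = 60,
) -> list[str]:
    """Sample ``n`` unique Markov-chain words; index i has rank i + 1.

    With ``temperature`` > 0 the chain is progressively flattened toward the
    tail of the rank list, so low-frequency words use rarer combinations.
    """
    letters = np.asarray(list(alphabet))
    words: list[str] = []
    seen: set[str] = set()
    tries = 0
    i = 0
    while len(words) < n:
        if tries > max_factor * n:
            raise ValueError(
                f"alphabet of {len(alphabet)} letters cannot honor "
                f"{n} unique words with the requested lengths"
            )
        inv_t = 1.0 / (1.0 + temperature * i / max(n - 1, 1))
        length = int(lengths[i % len(lengths)])
        codes = np.empty(length, dtype=int)
        codes[0] = rng.choice(len(p), p=_temper(p, inv_t))
        for k in range(1, length):
            codes[k] = rng.choice(len(p), p=_temper(trans[codes[k - 1]], inv_t))
        w = "".join(letters[codes])
        tries += 1
        if w in seen or w in forbidden:
            continue
        seen.add(w)
        words.append(w)
        i += 1
    return words


def make_synthetic_lexica(
    spec: SyntheticLexiconSpec = SyntheticLexiconSpec(), seed: int = 0
) -> tuple[Lexicon, Lexicon]:
    """Two synthetic lexica over one alphabet, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    lens = sorted(spec.length_probs)
    probs = np.array([spec.length_probs[k] for k in lens])
    counts = np.round(probs * spec.n_words).astype(int)
    counts[-1] = spec.n_words - counts[:-1].sum()
    lengths = np.repeat(lens, counts)
    rng.shuffle(lengths)

    la, lb = spec.language_ids
    pa, ta = _language_chain(spec, rng)
    pb, tb = _language_chain(spec, rng)
    temp = spec.rare_word_temperature
    words_a = _sample_words(
        spec.n_words, lengths, pa, ta, spec.alphabet, rng, temperature=temp
    )
    words_b = _sample_words(
        spec.n_words,
        lengths,
        pb,
        tb,
        spec.alphabet,
        rng,
        temperature=temp,
        forbidden=set(words_a),
    )
    # vocabulary overlap: shared words keep their rank slot in each language
    n_shared = int(round(spec.overlap * spec.n_words))
    if n_shared:
        slots = rng.choice(spec.n_words, n_shared, replace=False)
        src = rng.permutation(spec.n_words)[:n_shared]
        for slot, s in zip(slots, src):
            words_b[int(slot)] = words_a[int(s)]
        if len(set(words_b)) != spec.n_words:  # collision: re-deduplicate
            seen: set[str] = set()
            dedup = []
            for w in words_b:
                if w not in seen:
                    seen.add(w)
                    dedup.append(w)
            extra = _sample_words(
                spec.n_words - len(dedup),
                lengths,
                pb,
                tb,
                spec.alphabet,
                rng,
                temperature=temp,
                forbidden=set(words_a) | seen,
            )
            words_b = dedup + extra

    freqs = spec.top_freq / np.arange(1, spec.n_words + 1) ** spec.zipf_exponent
    lex_a = Lexicon(la, dict(zip(words_a, freqs)), spec.alphabet)
    lex_b = Lexicon(lb, dict(zip(words_b, freqs)), spec.alphabet)
    return lex_a, lex_b


def generate_feasible_design(
    spec: SyntheticLexiconSpec = SyntheticLexiconSpec(),
    seed: int = 0,
    items_per_category: int = 180,
    max_draws: int = 5,
    **design_kwargs,
):
    """Draw synthetic lexica until the full stimulus design is feasible.

    A random language pair occasionally admits no word selection matching the
    quadrigram categories within tolerance; the real languages are a single
    fixed instance for which the design is known to be constructible, so the
    generator conditions on feasibility by redrawing the languages (new
    lexicon seed derived from ``seed``) up to ``max_draws`` times.  Returns
    ``(lexicon_a, lexicon_b, DesignResult)``; deterministic given the seed.
    """
    from .stimuli import build_design

    last_error: Exception | None = None
    for draw in range(max_draws):
        lex_a, lex_b = make_synthetic_lexica(spec, seed=seed + 1000 * draw)
        try:
            result = build_design(
                lex_a, lex_b, items_per_category=items_per_category,
                seed=seed, **design_kwargs,
            )
        except ValueError as exc:
            last_error = exc
            continue
        result.diagnostics["lexicon_draws"] = draw + 1
        return lex_a, lex_b, result
    raise ValueError(
        f"no feasible design in {max_draws} lexicon draws; last error: {last_error}"
    )


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic ROI cohort.

    Each ROI voxel's main-run beta is
    ``baseline + slope(Y) * predictor_weight + patch_offset + noise`` with
    ``slope(Y) = gradient_coefficient * (Y - y_anchor)`` (slope units per mm
    of TAL Y, anterior positive).  In the ``logographic-split`` scenario a
    fraction of ROIs receives an additive offset on one language's
    conditions and an elevated localizer face response, mimicking
    script-specific patches.
    """

    n_participants: int = 21
    rois_per_participant: int = 10
    voxels_per_roi: int = 30
    region: str = "VOTC"
    hemisphere: str = "L"
    tal_x_range: tuple[float, float] = (-48.0, -30.0)
    tal_y_range: tuple[float, float] = (-75.0, -25.0)
    tal_z_range: tuple[float, float] = (-22.0, -6.0)
    gradient_coefficient: float = 0.0443
    y_anchor: float = -80.0
    baseline: float = 0.3
    noise_sd: float = 0.1
    slope_jitter_sd: float = 0.0
    scenario: str = "shared-alphabet"
    patch_fraction: float = 0.25
    patch_effect: float = 0.5
    patch_language: str = "C"
    face_amplitude: float = 0.8
    word_amplitude: float = 1.0
    localizer_baseline: float = 0.15
    dominance_range: tuple[float, float] = (-0.5, 0.5)
    reading_total_mean: float = 230.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least two participants")
        if self.voxels_per_roi < 1:
            raise ValueError("need at least one voxel per ROI")
        if not 0 <= self.patch_fraction <= 1:
            raise ValueError("patch_fraction must lie in [0, 1]")
        if self.scenario not in ("shared-alphabet", "logographic-split"):
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected "
                "'shared-alphabet' or 'logographic-split'"
            )


@dataclass
class ROIRecord:
    """One word-specific ROI: metadata plus voxel x condition betas."""

    roi_id: str
    hemisphere: str
    region: str
    centroid: tuple[float, float, float]  # TAL mm
    betas_main: pd.DataFrame
    betas_localizer: pd.DataFrame

    @property
    def tal_y(self) -> float:
        return self.centroid[1]

    def mean_betas(self) -> pd.Series:
        return self.betas_main.mean(axis=0)


@dataclass
class ParticipantData:
    participant_id: str
    dominance: float
    reading_counts: tuple[float, float]
    rois: list[ROIRecord]


@dataclass
class CohortData:
    """A cohort of participants plus the ground truth that generated it."""

    participants: list[ParticipantData]
    condition_labels: tuple[str, ...]
    localizer_labels: tuple[str, ...]
    ground_truth: dict

    def roi_table(self) -> pd.DataFrame:
        """Flat per-ROI metadata table (one row per ROI)."""
        rows = []
        for part in self.participants:
            for roi in part.rois:
                rows.append(
                    {
                        "participant": part.participant_id,
                        "roi_id": roi.roi_id,
                        "hemisphere": roi.hemisphere,
                        "region": roi.region,
                        "tal_x": roi.centroid[0],
                        "tal_y": roi.centroid[1],
                        "tal_z": roi.centroid[2],
                    }
                )
        return pd.DataFrame(rows)

    def mean_beta_table(self) -> pd.DataFrame:
        """ROI-averaged main-run betas, one row per ROI (metadata included)."""
        meta = self.roi_table()
        betas = []
        for part in self.participants:
            for roi in part.rois:
                betas.append(roi.mean_betas())
        return pd.concat([meta, pd.DataFrame(betas).reset_index(drop=True)], axis=1)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "condition_labels": list(self.condition_labels),
            "localizer_labels": list(self.localizer_labels),
            "ground_truth": self.ground_truth,
            "participants": [],
        }
        for part in self.participants:
            pdir = out / part.participant_id
            pdir.mkdir(exist_ok=True)
            entry = {
                "participant_id": part.participant_id,
                "dominance": part.dominance,
                "reading_counts": list(part.reading_counts),
                "rois": [],
            }
            for roi in part.rois:
                stem = f"{part.participant_id}_{roi.roi_id}"
                roi.betas_main.to_csv(pdir / f"{stem}_main.csv", index=False)
                roi.betas_localizer.to_csv(pdir / f"{stem}_localizer.csv", index=False)
                entry["rois"].append(
                    {
                        "roi_id": roi.roi_id,
                        "hemisphere": roi.hemisphere,
                        "region": roi.region,
                        "centroid": list(roi.centroid),
                    }
                )
            manifest["participants"].append(entry)
        with (out / "cohort_manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, default=float)

    @classmethod
    def load(cls, in_dir: str | Path) -> "CohortData":
        root = Path(in_dir)
        with (root / "cohort_manifest.json").open() as fh:
            manifest = json.load(fh)
        participants = []
        for entry in manifest["participants"]:
            pid = entry["participant_id"]
            rois = []
            for r in entry["rois"]:
                stem = f"{pid}_{r['roi_id']}"
                rois.append(
                    ROIRecord(
                        roi_id=r["roi_id"],
                        hemisphere=r["hemisphere"],
                        region=r["region"],
                        centroid=tuple(r["centroid"]),
                        betas_main=pd.read_csv(root / pid / f"{stem}_main.csv"),
                        betas_localizer=pd.read_csv(root / pid / f"{stem}_localizer.csv"),
                    )
                )
            participants.append(
                ParticipantData(
                    participant_id=pid,
                    dominance=entry["dominance"],
                    reading_counts=tuple(entry["reading_counts"]),
                    rois=rois,
                )
            )
        return cls(
            participants=participants,
            condition_labels=tuple(manifest["condition_labels"]),
            localizer_labels=tuple(manifest["localizer_labels"]),
            ground_truth=manifest["ground_truth"],
        )


def _language_conditions(labels: Sequence[str], language: str) -> list[str]:
    """Conditions belonging to one language of a design's axis."""
    if language == "C":  # logographic hierarchy
        return [l for l in labels if l in ("S", "SG", "RI", "RP", "CP", "WL", "WH")]
    return [l for l in labels if l.endswith(language)]


def simulate_cohort(
    spec: CohortSpec,
    predictor: Predictor | None = None,
    seed: int = 0,
    localizer_labels: Sequence[str] = LOCALIZER_CATEGORIES,
) -> CohortData:
    """Generate a cohort with a planted word-similarity gradient.

    ``predictor`` fixes the condition axis and the weights that scale each
    ROI's planted slope (default: the 14-condition alphabetic design).
    """
    predictor = predictor or Predictor.en_fr()
    rng = np.random.default_rng(seed)
    labels = list(predictor.labels)
    w = predictor.array
    loc_labels = list(localizer_labels)
    word_cats = [l for l in loc_labels if l.startswith("word")]
    participants = []
    truth_rois = []
    dominances = rng.uniform(*spec.dominance_range, size=spec.n_participants)
    for pi in range(spec.n_participants):
        pid = f"sub-{pi + 1:02d}"
        dom = float(dominances[pi])
        total = float(rng.normal(spec.reading_total_mean, 15.0))
        counts = (total * (1 + dom) / 2, total * (1 - dom) / 2)
        rois = []
        for ri in range(spec.rois_per_participant):
            cx = float(rng.uniform(*spec.tal_x_range))
            cy = float(rng.uniform(*spec.tal_y_range))
            cz = float(rng.uniform(*spec.tal_z_range))
            slope = spec.gradient_coefficient * (cy - spec.y_anchor)
            if spec.slope_jitter_sd > 0:
                slope += float(rng.normal(0.0, spec.slope_jitter_sd))
            flagged = (
                spec.scenario == "logographic-split"
                and rng.random() < spec.patch_fraction
            )
            mean_profile = spec.baseline + slope * w
            if flagged:
                for cond in _language_conditions(labels, spec.patch_language):
                    mean_profile[labels.index(cond)] += spec.patch_effect
            betas = mean_profile[None, :] + rng.normal(
                0.0, spec.noise_sd, size=(spec.voxels_per_roi, len(labels))
            )
            loc_profile = np.full(len(loc_labels), spec.localizer_baseline)
            for cat in word_cats:
                loc_profile[loc_labels.index(cat)] = spec.word_amplitude
            if flagged:
                loc_profile[loc_labels.index("faces")] = spec.face_amplitude
            loc = loc_profile[None, :] + rng.normal(
                0.0, spec.noise_sd, size=(spec.voxels_per_roi, len(loc_labels))
            )
            roi_id = f"roi-{ri + 1:02d}"
            rois.append(
                ROIRecord(
                    roi_id=roi_id,
                    hemisphere=spec.hemisphere,
                    region=spec.region,
                    centroid=(cx, cy, cz),
                    betas_main=pd.DataFrame(betas, columns=labels),
                    betas_localizer=pd.DataFrame(loc, columns=loc_labels),
                )
            )
            truth_rois.append(
                {
                    "participant": pid,
                    "roi_id": roi_id,
                    "tal_y": cy,
                    "slope": float(slope),
                    "language_patch": bool(flagged),
                }
            )
        participants.append(ParticipantData(pid, dom, counts, rois))
    truth = {
        "spec": asdict(spec),
        "seed": seed,
        "predictor": predictor.name,
        "rois": truth_rois,
    }
    return CohortData(participants, tuple(labels), tuple(loc_labels), truth)


# ---------------------------------------------------------------------------
# Deterministic correlation planting

def planted_correlation_vector(
    x: Sequence[float],
    target_r: float,
    seed: int = 0,
    scale: float = 1.0,
    mean: float = 0.0,
) -> np.ndarray:
    """A vector whose sample Pearson correlation with ``x`` equals target_r.

    Orthogonalize-and-rescale: a seeded noise vector is orthogonalized
    against the centered ``x``, both parts are standardized, and the mixture
    ``r * zx + sqrt(1 - r^2) * ze`` is rescaled; the construction is exact up
    to floating-point arithmetic.
    """
    x = np.asarray(x, dtype=float)
    if not -1 <= target_r <= 1:
        raise ValueError("target correlation must lie in [-1, 1]")
    if np.std(x) == 0:
        raise ValueError("x must have nonzero variance")
    rng = np.random.default_rng(seed)
    zx = (x - x.mean()) / x.std()
    e = rng.standard_normal(len(x))
    e = e - e.mean()
    e = e - (e @ zx) / (zx @ zx) * zx
    if np.linalg.norm(e) < 1e-12:
        raise ValueError("degenerate noise vector; try another seed")
    ze = e / e.std()
    y = target_r * zx + np.sqrt(1 - target_r**2) * ze
    return mean + scale * y


def make_dominance_fixture(
    n_participants: int = 21,
    target_r: float = -0.550,
    region: str = "fusiform",
    pair: tuple[str, str] = ("WE", "WF"),
    seed: int = 0,
    effect_scale: float = 0.15,
    predictor: Predictor | None = None,
) -> CohortData:
    """A noise-free cohort embodying an exact dominance-activity correlation.

    Participants carry one ``region`` ROI each; the per-participant beta
    difference ``pair[0] - pair[1]`` is constructed (orthogonalize-and-
    rescale) so its sample correlation with the dominance scores equals
    ``target_r`` exactly.
    """
    predictor = predictor or Predictor.en_fr()
    rng = np.random.default_rng(seed)
    labels = list(predictor.labels)
    doms = np.linspace(-0.6, 0.6, n_participants)
    doms = doms[rng.permutation(n_participants)]
    diffs = planted_correlation_vector(
        doms, target_r, seed=seed + 1, scale=effect_scale
    )
    loc_labels = list(LOCALIZER_CATEGORIES)
    participants = []
    for pi in range(n_participants):
        pid = f"sub-{pi + 1:02d}"
        base = 0.5 + 0.2 * predictor.array
        betas = np.tile(base, (5, 1))
        betas[:, labels.index(pair[0])] += diffs[pi]
        # small unplanted variation elsewhere keeps the other contrast pairs
        # non-degenerate without touching the planted pair
        for j, lab in enumerate(labels):
            if lab not in pair:
                betas[:, j] += 0.01 * float(rng.standard_normal())
        loc = np.full((5, len(loc_labels)), 0.15)
        for cat in loc_labels:
            if cat.startswith("word"):
                loc[:, loc_labels.index(cat)] = 1.0 + 0.01 * float(rng.standard_normal())
        roi = ROIRecord(
            roi_id="roi-01",
            hemisphere="L",
            region=region,
            centroid=(-40.0, -45.0, -15.0),
            betas_main=pd.DataFrame(betas, columns=labels),
            betas_localizer=pd.DataFrame(loc, columns=loc_labels),
        )
        total = 230.0
        counts = (total * (1 + doms[pi]) / 2, total * (1 - doms[pi]) / 2)
        participants.append(ParticipantData(pid, float(doms[pi]), counts, [roi]))
    truth = {
        "target_r": target_r,
        "region": region,
        "pair": list(pair),
        "dominance": doms.tolist(),
        "differences": diffs.tolist(),
        "seed": seed,
    }
    return CohortData(participants, tuple(labels), tuple(loc_labels), truth)


# ---------------------------------------------------------------------------
# Time courses

def simulate_roi_timecourses(
    roi_betas: Mapping[str, float] | pd.Series,
    schedule: Schedule,
    hrf_params: dict | None = None,
    noise_sd: float = 0.0,
    ar_coef: float = 0.0,
    seed: int | None = None,
    scale: str = "percent",
    baseline: float = 1000.0,
) -> np.ndarray:
    """Forward-simulate an ROI time course from condition betas.

    Condition boxcars are HRF-convolved, scaled by their betas, summed and
    sampled at the TR; AR(1) Gaussian noise with stationary standard
    deviation ``noise_sd`` is added.  ``scale='percent'`` returns percent-
    signal units directly; ``scale='raw'`` modulates a raw baseline
    (``baseline * (1 + signal / 100)``).
    """
    if isinstance(roi_betas, pd.Series):
        roi_betas = roi_betas.to_dict()
    X = design_matrix_from_schedule(schedule, hrf_params=hrf_params)
    missing = set(X.columns) - set(roi_betas)
    if missing:
        raise ValueError(f"betas missing for conditions: {sorted(missing)}")
    beta_vec = np.array([roi_betas[c] for c in X.columns], dtype=float)
    signal = X.to_numpy() @ beta_vec
    if not -1 < ar_coef < 1:
        raise ValueError("AR(1) coefficient must lie in (-1, 1)")
    noise = np.zeros(len(signal))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        innov_sd = noise_sd * np.sqrt(1 - ar_coef**2)
        eps = rng.normal(0.0, innov_sd, size=len(signal))
        noise[0] = rng.normal(0.0, noise_sd)
        for t in range(1, len(signal)):
            noise[t] = ar_coef * noise[t - 1] + eps[t]
    pct = signal + noise
    if scale == "percent":
        return pct
    if scale == "raw":
        return baseline * (1 + pct / 100.0)
    raise ValueError("scale must be 'percent' or 'raw'")
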