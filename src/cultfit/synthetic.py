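"""Synthetic study generator: ratings, lexicon, corpus, with known truth.

The generator emulates the structure the fit measures assume: two cultural
groups with distinct per-situation mean emotion profiles and distinct
word-category emission distributions, plus an optional migrant group whose
generating means interpolate between the heritage and host patterns with an
acculturation weight lambda.  Everything is reproducible from one master seed,
expanded into independent substreams for the ratings, the lexicon and the
corpus.

What is emulated, and what is not: Likert discretisation (round-then-clamp of
a continuous latent), per-situation valence/motive structure strong enough to
pass the pipeline's own screening, multinomial token emission with a filler
fraction the dictionary does not cover.  Real interview speech, translation
noise and demographic covariates are not modelled.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import RatingDataset, TranscriptCorpus
from .lexicon import Category, Lexicon, LexiconEntry
from .terms import SITUATIONS, SITUATION_VALENCE, EmotionTermSet, default_term_set

#: valence of the screening-only and literature terms outside the subscales
_EXTRA_TERM_VALENCE = {
    "calm": "positive",
    "worried": "negative",
    "nervous": "negative",
    "fearful": "negative",
    "sad": "negative",
    "surprised": None,
}

_ENTRY_ALPHABET = "abcdefghijklm"     # lexicon words
_FILLER_ALPHABET = "nopqrstuvwxyz"    # filler words can never match an entry


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; the defaults are the study conditions.

    Group sizes default to 100 per cultural group, matching the sample the
    measures were designed for; rating noise (sd 0.7 on a 1-5 scale) and a
    valence boost of 1.0 produce data that pass the valence screen while
    leaving individual profiles clearly noisy.  A group size of 0 disables
    that group (sizes of 1-2 are rejected: no reference can be built).
    """

    n_heritage: int = 100
    n_host: int = 100
    n_migrant: int = 100
    terms: EmotionTermSet = field(default_factory=default_term_set)
    n_categories: int = 64            # total lexicon categories incl. psych root
    n_psych: int = 25                 # psych root + its children
    entries_per_category: int = 50
    wildcard_rate: float = 0.2
    d_emotion: float = 1.0            # distance between cultural mean profiles
    d_language: float = 1.0           # distance between emission log-weights
    acculturation: float = 0.5        # lambda: migrant position heritage->host
    rating_noise_sd: float = 0.7
    language_noise_sd: float = 0.3
    tokens_per_doc: int = 500
    filler_rate: float = 0.3
    valence_boost: float = 1.0
    coder_unclear_rate: float = 0.05
    coder_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_heritage", "n_host", "n_migrant"):
            n = getattr(self, name)
            if n != 0 and n < 3:
                raise ParameterError(f"{name} must be 0 (absent) or >= 3")
        if self.n_heritage == 0 or self.n_host == 0:
            raise ParameterError("heritage and host groups are both required")
        if not (0 <= self.acculturation <= 1):
            raise ParameterError("acculturation lambda must lie in [0, 1]")
        if self.rating_noise_sd <= 0 or self.language_noise_sd < 0:
            raise ParameterError("noise sds must be positive")
        if self.d_emotion < 0 or self.d_language < 0:
            raise ParameterError("divergences must be >= 0")
        if self.d_emotion + self.valence_boost > 3.0:
            raise ParameterError(
                "d_emotion + valence_boost > 3.0: cultural means cannot fit "
                "inside the [1.5, 4.5] latent box"
            )
        if not (2 <= self.n_psych < self.n_categories):
            raise ParameterError("need 2 <= n_psych < n_categories")
        if not (0 <= self.filler_rate < 1) or not (0 <= self.wildcard_rate <= 1):
            raise ParameterError("rates must lie in [0, 1)")
        if self.tokens_per_doc < 10:
            raise ParameterError("tokens_per_doc must be >= 10")


@dataclass
class GeneratorTruth:
    """Realised generating quantities, for parameter-recovery checks."""

    rating_means: Dict[Tuple[str, str], pd.Series]   # (group, situation) -> terms
    acculturation: float
    emission_logits: Optional[Dict[str, np.ndarray]] = None
    emission_probs: Optional[Dict[str, pd.Series]] = None   # group -> leaf cat ids
    leaf_category_ids: Optional[List[int]] = None


def _groups(config: SyntheticConfig) -> Dict[str, List[str]]:
    out = {}
    if config.n_heritage:
        out["heritage"] = [f"her{i:03d}" for i in range(config.n_heritage)]
    if config.n_host:
        out["host"] = [f"host{i:03d}" for i in range(config.n_host)]
    if config.n_migrant:
        out["migrant"] = [f"mig{i:03d}" for i in range(config.n_migrant)]
    return out


def _situation_means(config: SyntheticConfig, situation: str,
                     rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """Latent mean vectors (over all terms) for heritage/host in one situation."""
    terms = config.terms
    b, d = config.valence_boost, config.d_emotion
    valence = SITUATION_VALENCE[situation]
    lo, hi = 1.5 + d / 2, 4.5 - d / 2 - b
    base = rng.uniform(lo, hi, size=len(terms.terms))
    center = np.empty(len(terms.terms))
    divergent = np.ones(len(terms.terms), dtype=bool)
    for i, term in enumerate(terms.terms):
        if term in ("good", "bad"):
            matches = (term == "good") == (valence == "positive")
            center[i] = min(4.5, 1.5 + 2.5 * b) if matches else 1.5
            divergent[i] = False       # anchors are culture-neutral
            continue
        elevation = 0.0
        sub = terms.subscale_of(term)
        if sub == situation:
            elevation = b
        elif sub is not None and SITUATION_VALENCE[sub] == valence:
            elevation = b / 2
        elif sub is None and _EXTRA_TERM_VALENCE.get(term) == valence:
            elevation = b / 2
        center[i] = base[i] + elevation
    if d > 0 and divergent.sum() >= 2:
        u = rng.standard_normal(int(divergent.sum()))
        u /= np.linalg.norm(u)
        offset = np.zeros(len(terms.terms))
        offset[divergent] = (d / 2) * u
    else:
        offset = np.zeros(len(terms.terms))
    return {"heritage": center - offset, "host": center + offset}


def generate_ratings(config: SyntheticConfig,
                     rng: np.random.Generator | None = None,
                     ) -> Tuple[RatingDataset, GeneratorTruth]:
    """Draw a ratings dataset; returns it with the realised generating truth.

    Per situation, heritage and host latent mean vectors sit inside
    [1.5, 4.5], separated by ``d_emotion`` (the valence anchors good/bad are
    culture-neutral); the migrant mean is the exact convex combination with
    weight ``acculturation``.  A participant's rating is the group mean plus
    iid Gaussian noise, rounded and clamped to {1..5}.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    terms = config.terms
    lam = config.acculturation
    groups = _groups(config)
    means: Dict[Tuple[str, str], np.ndarray] = {}
    for situation in SITUATIONS:
        cultural = _situation_means(config, situation, rng)
        means[("heritage", situation)] = cultural["heritage"]
        means[("host", situation)] = cultural["host"]
        means[("migrant", situation)] = ((1 - lam) * cultural["heritage"]
                                         + lam * cultural["host"])

    rows, coder_rows = [], []
    for group, pids in groups.items():
        for pid in pids:
            for situation in SITUATIONS:
                if config.missing_rate and rng.random() < config.missing_rate:
                    continue
                latent = means[(group, situation)] + rng.normal(
                    0.0, config.rating_noise_sd, size=len(terms.terms))
                ratings = np.clip(np.round(latent), 1, 5).astype(int)
                row = {"participant_id": pid, "culture": group,
                       "situation_type": situation}
                row.update(dict(zip(terms.terms, ratings)))
                rows.append(row)
                expected = SITUATION_VALENCE[situation]
                roll = rng.random()
                if roll < config.coder_error_rate:
                    label = "negative" if expected == "positive" else "positive"
                elif roll < config.coder_error_rate + config.coder_unclear_rate:
                    label = "unclear"
                else:
                    label = expected
                coder_rows.append({"participant": pid, "situation": situation,
                                   "coder_label": label})

    table = pd.DataFrame(rows, columns=["participant_id", "culture",
                                        "situation_type", *terms.terms])
    coder = pd.DataFrame(coder_rows, columns=["participant", "situation",
                                              "coder_label"])
    dataset = RatingDataset(table=table, terms=terms, coder_labels=coder)
    truth = GeneratorTruth(
        rating_means={key: pd.Series(vec, index=list(terms.terms))
                      for key, vec in means.items()},
        acculturation=lam,
    )
    return dataset, truth


def _random_word(rng: np.random.Generator, alphabet: str,
                 lo: int = 4, hi: int = 9) -> str:
    length = int(rng.integers(lo, hi))
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def generate_lexicon(config: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> Lexicon:
    """Build a synthetic .dic-dialect lexicon with a psych subtree.

    Category 1 is the psychological-processes root; categories 2..n_psych are
    its children (their entries list both the child id and the root id, per
    the multi-id hierarchy convention); the remaining categories are flat.
    About ``wildcard_rate`` of entries are prefix stems.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    categories: Dict[int, Category] = {1: Category(1, "psychproc", None)}
    for cid in range(2, config.n_psych + 1):
        categories[cid] = Category(cid, f"psych{cid:02d}", parent=1)
    for cid in range(config.n_psych + 1, config.n_categories + 1):
        categories[cid] = Category(cid, f"cat{cid:02d}", None)

    used: set = set()
    entries: List[LexiconEntry] = []
    for cid, cat in categories.items():
        if cid == 1:
            continue                      # the root is carried by its children
        ids = frozenset({cid, 1}) if cat.parent == 1 else frozenset({cid})
        for _ in range(config.entries_per_category):
            while True:
                word = _random_word(rng, _ENTRY_ALPHABET)
                wildcard = rng.random() < config.wildcard_rate
                surface = word[:max(3, len(word) - 2)] if wildcard else word
                if surface not in used:
                    used.add(surface)
                    break
            entries.append(LexiconEntry(surface, wildcard, ids))
    return Lexicon(categories=categories, entries=entries)


def _emission_model(config: SyntheticConfig, lexicon: Lexicon,
                    rng: np.random.Generator) -> Tuple[List[int], Dict[str, np.ndarray]]:
    """Leaf category ids and per-group emission logits (distance d_language)."""
    leaves = [cid for cid, cat in lexicon.categories.items()
              if cid != 1]
    base = rng.normal(0.0, 0.8, size=len(leaves))
    if config.d_language > 0:
        u = rng.standard_normal(len(leaves))
        u /= np.linalg.norm(u)
        offset = (config.d_language / 2) * u
    else:
        offset = np.zeros(len(leaves))
    lam = config.acculturation
    logits = {"heritage": base - offset, "host": base + offset}
    logits["migrant"] = (1 - lam) * logits["heritage"] + lam * logits["host"]
    return leaves, logits


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def generate_corpus(config: SyntheticConfig, lexicon: Lexicon,
                    truth: GeneratorTruth,
                    rng: np.random.Generator | None = None) -> TranscriptCorpus:
    """Emit one document per participant-situation by multinomial sampling.

    Each document draws ``tokens_per_doc`` tokens: a ``filler_rate`` fraction
    from an uncovered filler vocabulary, the rest from category vocabularies
    with the participant's emission probabilities (group logits plus
    individual Gaussian noise).  Fills ``truth.emission_probs`` in place.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    leaves, logits = _emission_model(config, lexicon, rng)
    truth.emission_logits = logits
    truth.leaf_category_ids = leaves
    truth.emission_probs = {
        group: pd.Series(_softmax(vec), index=leaves)
        for group, vec in logits.items()
    }

    # concrete token pools: literal entries emit their surface, stems a suffix
    pools: Dict[int, List[str]] = {cid: [] for cid in leaves}
    for entry in lexicon.entries:
        for cid in entry.category_ids:
            if cid not in pools:
                continue
            if entry.wildcard:
                suffix = _random_word(rng, _ENTRY_ALPHABET, 1, 4)
                pools[cid].append(entry.surface + suffix)
            else:
                pools[cid].append(entry.surface)
    pool_arrays = {cid: np.array(p) for cid, p in pools.items() if p}
    filler_vocab = np.array([_random_word(rng, _FILLER_ALPHABET)
                             for _ in range(500)])

    documents: Dict[Tuple[str, str], str] = {}
    for group, pids in _groups(config).items():
        group_logits = logits[group]
        for pid in pids:
            person = group_logits + rng.normal(0.0, config.language_noise_sd,
                                               size=len(leaves))
            probs = _softmax(person)
            for situation in SITUATIONS:
                n_filler = rng.binomial(config.tokens_per_doc, config.filler_rate)
                n_content = config.tokens_per_doc - n_filler
                counts = rng.multinomial(n_content, probs)
                tokens: List[str] = []
                for cid, count in zip(leaves, counts):
                    if count == 0:
                        continue
                    pool = pool_arrays[cid]
                    tokens.extend(pool[rng.integers(0, len(pool), count)])
                tokens.extend(filler_vocab[rng.integers(0, len(filler_vocab),
                                                        n_filler)])
                order = rng.permutation(len(tokens))
                documents[(pid, situation)] = " ".join(
                    tokens[i] for i in order) + "."
    return TranscriptCorpus(documents=documents, language="synthetic")


@dataclass
class StudyData:
    """One fully generated synthetic study."""

    config: SyntheticConfig
    ratings: RatingDataset
    truth: GeneratorTruth
    lexicon: Optional[Lexicon] = None
    corpus: Optional[TranscriptCorpus] = None

    @property
    def cultures(self) -> Mapping[str, str]:
        return {row.participant_id: row.culture
                for row in self.ratings.participants.itertuples()}


def generate_study(config: SyntheticConfig,
                   include_language: bool = True) -> StudyData:
    """Generate ratings (and optionally lexicon + corpus) from one seed.

    The master seed is expanded with ``SeedSequence.spawn`` into independent
    substreams for ratings, lexicon and corpus, so e.g. regenerating with a
    different ``tokens_per_doc`` leaves the ratings bit-identical.
    """
    streams = np.random.SeedSequence(config.seed).spawn(3)
    ratings, truth = generate_ratings(config, np.random.default_rng(streams[0]))
    lexicon = corpus = None
    if include_language:
        lexicon = generate_lexicon(config, np.random.default_rng(streams[1]))
        corpus = generate_corpus(config, lexicon, truth,
                                 np.random.default_rng(streams[2]))
    return StudyData(config=config, ratings=ratings, truth=truth,
                     lexicon=lexicon, corpus=corpus)


def recovery_benchmark(cells: Sequence[Mapping[str, object]],
                       n_replicates: int = 100,
                       seed: int = 0,
                       include_language: bool = False,
                       base_config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Recover the expected fit orderings over a grid of generator settings.

    Each cell overrides fields of the base config (e.g. ``d_emotion``,
    ``acculturation``, ``rating_noise_sd``, group sizes); per replicate the
    study is regenerated with a fresh seed and the emotional (optionally also
    language) fit table computed.  Reported per cell x replicate: each
    culture's mean fit-to-own minus fit-to-other and the migrant group's mean
    fit toward the host culture.
    """
    from .fit import ProfileFitModel

    base = base_config or SyntheticConfig()
    root = np.random.SeedSequence(seed)
    rows = []
    for ci, overrides in enumerate(cells):
        for rep in range(n_replicates):
            rep_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            config = replace(base, seed=rep_seed, **dict(overrides))
            study = generate_study(config, include_language=include_language)
            measures = {"emotion": ProfileFitModel.from_ratings(study.ratings)
                        .fit().table}
            if include_language:
                from .lexicon import corpus_profiles
                prof = corpus_profiles(study.corpus, study.lexicon, "all")
                measures["language"] = (ProfileFitModel
                                        .from_category_profiles(prof, study.cultures)
                                        .fit().table)
            row: Dict[str, object] = {"cell": ci, "replicate": rep,
                                      **dict(overrides)}
            for measure, table in measures.items():
                for culture, other in (("heritage", "host"), ("host", "heritage")):
                    own = table[(table["culture"] == culture)
                                & (table["target_culture"] == culture)]["z"].mean()
                    cross = table[(table["culture"] == culture)
                                  & (table["target_culture"] == other)]["z"].mean()
                    row[f"{measure}_own_minus_other_{culture}"] = own - cross
                if config.n_migrant:
                    mig = table[(table["culture"] == "migrant")
                                & (table["target_culture"] == "host")]["z"].mean()
                    row[f"{measure}_migrant_fit_host"] = mig
            rows.append(row)
    return pd.DataFrame(rows)
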