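"""Synthetic labelled collections and simulated screening processes.

Real screening collections (public-health literature searches of 86–5000
references with 0.28%–30% relevant) are not redistributable, so this module
generates collections with the same statistical shape: a Zipfian background
vocabulary, per-theme boosted word blocks, and relevant documents that place
``signal_strength`` of their topic mass on designated relevant themes.
Titles and abstracts are sampled independently from the same document-level
theme mixture, so the topical signal that separates relevant from
irrelevant references is recoverable by the classifier — or not, when
``signal_strength`` is 0 (the null model).

Screening strategies mirror how reviewers use such a system:

* ``random`` — uniform shuffle (the null baseline);
* ``active_learning`` — random until both classes are seen, then repeat
  {retrain every ``batch_size`` decisions, screen the top-confidence
  unscreened references};
* ``topics_then_random`` — screen the 45-reference lists of designated
  topics first, then the remainder in random order;
* ``topics_then_AL`` — as above, then switch to active learning.

The simulated screener is an infallible oracle (labels = ground truth);
reviewer error is deliberately out of scope so the engine, not reviewer
behaviour, is what gets measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .corpus import Collection, Reference, build_vocabulary, tokenise_collection
from .errors import ConfigurationError
from .evaluation import ScreeningTrace, aur, recall_curve, wss95
from .features import build_features, fit_tfidf
from .lda import TopicModel, TopicModelParams, fit_lda
from .prioritiser import ClassifierConfig, ScreeningSession

__all__ = [
    "SynthConfig",
    "SimulationStrategy",
    "generate_collection",
    "ScreeningEngine",
    "simulate_screening",
    "designate_topics_by_overlap",
    "strategy_comparison_report",
]


@dataclass(frozen=True)
class SynthConfig:
    n_references: int = 1000
    specificity: float = 0.05
    n_themes: int = 6
    vocab_size: int = 600
    relevant_theme_ids: frozenset[int] = frozenset({0})
    signal_strength: float = 0.9
    title_mean_length: int = 10
    abstract_mean_length: int = 70
    theme_block_weight: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.specificity < 1:
            raise ConfigurationError("specificity must lie in (0, 1)")
        if round(self.n_references * self.specificity) < 1:
            raise ConfigurationError(
                "specificity × n_references must yield at least one relevant reference"
            )
        if not 0 <= self.signal_strength <= 1:
            raise ConfigurationError("signal_strength must lie in [0, 1]")
        if not self.relevant_theme_ids or max(self.relevant_theme_ids) >= self.n_themes:
            raise ConfigurationError("relevant_theme_ids must be a non-empty subset of themes")


def _theme_distributions(cfg: SynthConfig) -> np.ndarray:
    """(n_themes, vocab_size) word distributions: boosted block + Zipf tail."""
    V = cfg.vocab_size
    block = V // (cfg.n_themes + 1)  # one block reserved for shared background
    zipf = 1.0 / np.arange(1, V + 1)
    background = zipf / zipf.sum()
    themes = np.empty((cfg.n_themes, V))
    for t in range(cfg.n_themes):
        boosted = np.zeros(V)
        lo, hi = t * block, (t + 1) * block
        boosted[lo:hi] = 1.0 / block
        themes[t] = cfg.theme_block_weight * boosted + (1 - cfg.theme_block_weight) * background
    return themes


def _word_names(cfg: SynthConfig) -> list[str]:
    """Token strings that survive tokenisation and lemmatisation unchanged."""
    block = cfg.vocab_size // (cfg.n_themes + 1)
    names = []
    for v in range(cfg.vocab_size):
        theme = v // block if v < cfg.n_themes * block else None
        prefix = f"theme{theme}w" if theme is not None else "bgw"
        names.append(f"{prefix}{v:04d}")
    return names


def generate_collection(config: SynthConfig) -> tuple[Collection, dict[str, bool]]:
    """Generate a labelled collection; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_references
    n_rel = int(round(n * config.specificity))
    relevant_idx = set(rng.choice(n, size=n_rel, replace=False).tolist())
    themes = _theme_distributions(config)
    words = np.asarray(_word_names(config))
    rel_themes = sorted(config.relevant_theme_ids)
    other_themes = [t for t in range(config.n_themes) if t not in config.relevant_theme_ids]
    if not other_themes:
        raise ConfigurationError("at least one non-relevant theme is required")

    references = []
    labels: dict[str, bool] = {}
    for i in range(n):
        relevant = i in relevant_idx
        mix = np.zeros(config.n_themes)
        bg = rng.dirichlet(np.ones(len(other_themes)))
        if relevant:
            for t in rel_themes:
                mix[t] = config.signal_strength / len(rel_themes)
            mix[other_themes] = (1 - config.signal_strength) * bg
        else:
            mix[other_themes] = bg
        word_dist = mix @ themes
        title_len = max(3, int(rng.poisson(config.title_mean_length)))
        abstract_len = max(10, int(rng.poisson(config.abstract_mean_length)))
        title_words = words[rng.choice(config.vocab_size, size=title_len, p=word_dist)]
        abstract_words = words[rng.choice(config.vocab_size, size=abstract_len, p=word_dist)]
        ref_id = f"SYN-{i + 1:05d}"
        references.append(
            Reference(
                id=ref_id,
                title=" ".join(title_words).capitalize(),
                abstract=" ".join(abstract_words),
                metadata={
                    "AU": f"Author {int(rng.integers(1, 200)):03d}",
                    "PY": str(int(rng.integers(1990, 2020))),
                },
            )
        )
        labels[ref_id] = relevant
    name = f"synthetic-n{n}-s{config.specificity:g}-seed{config.seed}"
    return Collection(references, name=name), labels


# ---------------------------------------------------------------------------
# Engine bundle and simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreeningEngine:
    """Fitted feature pipeline reused across retrains of one collection."""

    collection: Collection
    session: ScreeningSession
    topic_model: TopicModel | None

    @classmethod
    def build(
        cls,
        collection: Collection,
        min_count: int = 5,
        topic_params: TopicModelParams | None = None,
        classifier_config: ClassifierConfig | None = None,
        include_topics: bool = True,
    ) -> "ScreeningEngine":
        tokenised = tokenise_collection(collection)
        vocab = build_vocabulary(collection, min_count=min_count, tokenised=tokenised)
        tfidf_title = fit_tfidf(collection, vocab, "title", tokenised=tokenised)
        tfidf_abstract = fit_tfidf(collection, vocab, "abstract", tokenised=tokenised)
        topic_model = None
        if include_topics:
            params = topic_params or TopicModelParams(K=15, n_iterations=150, seed=0)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                topic_model = fit_lda(collection, vocab, params, tokenised=tokenised)
        feats = build_features(collection, tfidf_title, tfidf_abstract, topic_model)
        session = ScreeningSession(collection, feats, classifier_config)
        return cls(collection=collection, session=session, topic_model=topic_model)


@dataclass(frozen=True)
class SimulationStrategy:
    name: str = "active_learning"
    batch_size: int = 25
    initial_batch: int = 50
    designated_topics: tuple[int, ...] = ()
    seed: int = 0

    _NAMES = ("random", "active_learning", "topics_then_random", "topics_then_AL")

    def __post_init__(self):
        if self.name not in self._NAMES:
            raise ConfigurationError(f"unknown strategy {self.name!r}; one of {self._NAMES}")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


def designate_topics_by_overlap(
    topic_model: TopicModel, labels: dict[str, bool], n_topics: int = 3
) -> tuple[int, ...]:
    """Topics whose 45-reference lists are richest in relevant references.

    A stand-in for a reviewer's a-priori keyword-matched topic choice:
    designation is by ground-truth overlap with each topic's associated
    reference list.
    """
    scores = []
    for k, refs in enumerate(topic_model.top_refs):
        frac = np.mean([labels[r] for r in refs]) if refs else 0.0
        scores.append((-frac, k))
    return tuple(k for _, k in sorted(scores)[:n_topics])


def _oracle_decision(labels: dict[str, bool], ref_id: str) -> str:
    return "include" if labels[ref_id] else "exclude"


def simulate_screening(
    engine: ScreeningEngine,
    labels: dict[str, bool],
    strategy: SimulationStrategy,
) -> ScreeningTrace:
    """Run one complete simulated screening; returns the full trace.

    The oracle screener labels whatever the strategy presents next, so the
    returned trace is a permutation of the collection ids.
    """
    collection = engine.collection
    session = ScreeningSession(collection, engine.session.features, engine.session.config)
    rng = np.random.default_rng(strategy.seed)
    order: list[str] = []

    def screen(ref_id: str) -> None:
        session.record_decision(ref_id, _oracle_decision(labels, ref_id))
        order.append(ref_id)

    def screen_random_until(stop_condition) -> None:
        while len(order) < len(collection) and not stop_condition():
            batch = session.random_batch(1, rng)
            screen(batch[0])

    if strategy.name == "random":
        perm = rng.permutation(len(collection))
        for j in perm:
            screen(collection.ids[int(j)])
    else:
        if strategy.name in ("topics_then_random", "topics_then_AL"):
            if engine.topic_model is None:
                raise ConfigurationError("topic strategies need a fitted topic model")
            if not strategy.designated_topics:
                raise ConfigurationError(
                    "topic strategies require designated_topics; see "
                    "designate_topics_by_overlap"
                )
            K = engine.topic_model.K
            bad = [t for t in strategy.designated_topics if not 0 <= t < K]
            if bad:
                raise ConfigurationError(f"undesignated/unknown topic ids: {bad}")
            for t in strategy.designated_topics:
                for ref_id in engine.topic_model.top_refs[t]:
                    if ref_id not in session.decisions:
                        screen(ref_id)
        if strategy.name == "topics_then_random":
            remaining = [i for i in collection.ids if i not in session.decisions]
            for j in rng.permutation(len(remaining)):
                screen(remaining[int(j)])
        else:
            # active learning (possibly after a topic prefix)
            if strategy.name == "active_learning":
                n_init = min(strategy.initial_batch, len(collection))
                for ref_id in session.random_batch(n_init, rng):
                    screen(ref_id)
            screen_random_until(session.can_train)
            while len(order) < len(collection):
                session.retrain()
                ranking = session.ranking()
                for ref_id in ranking.top(strategy.batch_size):
                    screen(ref_id)
    rows = [(ref_id, _oracle_decision(labels, ref_id), None) for ref_id in order]
    return ScreeningTrace.from_rows(rows, {i: bool(v) for i, v in labels.items()})


def strategy_comparison_report(
    engine: ScreeningEngine,
    labels: dict[str, bool],
    strategies: Iterable[SimulationStrategy],
    seeds: Iterable[int],
    significance_level: float = 0.01,
) -> pd.DataFrame:
    """One row per (strategy, seed) with WSS@95%, AUR and the exact p-value,
    plus one aggregate mean row per strategy; significant rows are starred.
    """
    strategies = list(strategies)
    seeds = list(seeds)
    if not strategies:
        raise ConfigurationError("at least one strategy is required")
    rows = []
    for strat in strategies:
        for seed in seeds:
            trace = simulate_screening(
                engine, labels,
                SimulationStrategy(
                    name=strat.name, batch_size=strat.batch_size,
                    initial_batch=strat.initial_batch,
                    designated_topics=strat.designated_topics, seed=seed,
                ),
            )
            curve = recall_curve(trace)
            w = wss95(curve)
            a = aur(curve)
            rows.append({
                "strategy": strat.name, "seed": seed, "wss95": w.wss95,
                "aur": a.aur, "p_value": w.p_value,
                "significant": w.p_value < significance_level,
            })
    df = pd.DataFrame(rows)
    aggregates = (
        df.groupby("strategy", sort=False)[["wss95", "aur"]].mean().reset_index()
    )
    aggregates["seed"] = "mean"
    aggregates["p_value"] = np.nan
    aggregates["significant"] = pd.NA
    return pd.concat([df, aggregates], ignore_index=True)[
        ["strategy", "seed", "wss95", "aur", "p_value", "significant"]
    ]
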