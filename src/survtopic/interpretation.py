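"""Filtered, ordered topic summaries and the topic heatmap.

A fitted survival-topic model is summarized as a heatmap whose columns
are topics (sorted so the leftmost column is associated with the
shortest survival, each labeled with its survival coefficient — the
background topic's coefficient is exactly 0) and whose rows are events
kept by a prevalence filter, sorted by their maximum probability across
topics.  Bins of the same underlying variable are displayed as one
adjacent block at the position of the variable's best-ranked bin, so a
clinician can compare a measurement's bins at a glance.

Heatmap construction is a pure read of the model: it never mutates
trained parameters, and the same model with the same filter settings
always yields an identical layout.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .corpus import CountsCorpus, EventDescriptor, prevalence_filter
from .scholar import ScholarModel
from .training import extract_head

__all__ = [
    "TopicSummary",
    "HeatmapLayout",
    "extract_topics",
    "order_features",
    "build_heatmap",
    "layout_table",
    "plot_heatmap",
]


class EmptyLayoutError(ValueError):
    """Raised when no feature survives the prevalence filter."""


@dataclasses.dataclass
class TopicSummary:
    """Per-topic word scores plus the survival coefficient.

    ``display`` rows are probabilities over events (for the SAGE
    decoder, the induced single-topic distributions softmax(gamma+H_g));
    ``raw`` rows are the SAGE log-deviations H_g when applicable, where
    a value of 3 means the event occurs e^3 times its background
    frequency.  ``higher_risk_is_larger`` records the sign convention:
    True for Cox beta (larger = shorter survival), False for AFT theta.
    """

    display: np.ndarray  # (k, d) probabilities, rows sum to 1
    coefficients: np.ndarray  # (k,), background topic exactly 0
    raw: np.ndarray | None  # (k, d) SAGE log-deviations, else None
    higher_risk_is_larger: bool


def extract_topics(model: ScholarModel) -> TopicSummary:
    """Read per-topic event distributions and survival coefficients."""
    display = model.topic_word_matrix()
    head = extract_head(model)
    coef = head.beta if model.survival_kind == "cox" else head.theta
    raw = model.params["dec.H"].value.copy() if model.decoder_kind == "sage" else None
    return TopicSummary(
        display=display,
        coefficients=np.asarray(coef, dtype=np.float64),
        raw=raw,
        higher_risk_is_larger=model.survival_kind == "cox",
    )


def order_features(
    A: np.ndarray, vocab: list[EventDescriptor], kept: np.ndarray | None = None
) -> np.ndarray:
    """Row order for display: by max topic probability, variables grouped.

    Events are ranked by ``max_g A[g, v]`` descending (score ties keep
    vocabulary order).  All kept bins of one variable are then moved
    adjacent to that variable's best-ranked bin, in bin-index order.
    """
    A = np.asarray(A)
    if np.any(A < 0):
        raise ValueError("display matrix must be nonnegative")
    kept = np.arange(A.shape[1]) if kept is None else np.asarray(kept)
    scores = A[:, kept].max(axis=0)
    ranked = kept[np.argsort(-scores, kind="stable")]
    ordered: list[int] = []
    emitted: set[str] = set()
    by_variable: dict[str, list[int]] = {}
    for v in kept:
        by_variable.setdefault(vocab[v].variable_name, []).append(int(v))
    for v in ranked:
        name = vocab[v].variable_name
        if name in emitted:
            continue
        emitted.add(name)
        group = sorted(by_variable[name], key=lambda u: (vocab[u].bin_index, u))
        ordered.extend(group)
    return np.array(ordered, dtype=int)


@dataclasses.dataclass
class HeatmapLayout:
    """Everything needed to draw (or tabulate) the topic heatmap."""

    topic_order: np.ndarray  # column order, leftmost = shortest survival
    coefficients: np.ndarray  # survival coefficient per ordered column
    feature_order: np.ndarray  # kept word indices, top row first
    values: np.ndarray  # (n_features, n_topics) display probabilities
    raw_values: np.ndarray | None  # SAGE log-deviations, same layout
    vocab: list[EventDescriptor]
    min_frac: float
    max_frac: float
    higher_risk_is_larger: bool


def _reweight_scores(A: np.ndarray, scheme: str | None) -> np.ndarray:
    """Optional ranking scores; displayed values stay raw probabilities.

    ``tfidf`` emphasizes words unusually probable for one topic (score
    A_gv * log(A_gv / geometric-mean_h A_hv)); ``idf`` damps words
    over-represented in many topics.  Neither clearly improves ordering
    in practice, hence both are off by default.
    """
    if scheme is None:
        return A
    eps = 1e-12
    if scheme == "tfidf":
        gm = np.exp(np.log(A + eps).mean(axis=0, keepdims=True))
        return A * np.log((A + eps) / gm)
    if scheme == "idf":
        k, d = A.shape
        df = (A >= 1.0 / d).sum(axis=0)
        return A * (np.log((k + 1) / (df + 1)) + 1.0)
    raise ValueError(f"unknown reweighting scheme {scheme!r}")


def build_heatmap(
    model: ScholarModel,
    corpus: CountsCorpus,
    min_frac: float = 0.02,
    max_frac: float = 0.50,
    max_features: int | None = None,
    reweight: str | None = None,
) -> HeatmapLayout:
    """Prevalence-filter, order and truncate a fitted model's topics.

    ``max_features`` truncates the row count *after* categorical
    grouping: whole variable blocks are added in rank order until the
    budget is reached, so the final count can slightly exceed it.
    ``reweight`` switches the row-ranking score to "tfidf" or "idf".
    """
    topics = extract_topics(model)
    if topics.display.shape[1] != corpus.n_events:
        raise ValueError("model and corpus vocabularies differ in size")
    kept = prevalence_filter(corpus.X, min_frac=min_frac, max_frac=max_frac)
    if kept.size == 0:
        raise EmptyLayoutError(
            f"no event has prevalence within [{min_frac}, {max_frac}]"
        )
    rank_scores = _reweight_scores(topics.display, reweight)
    rank_scores = rank_scores - rank_scores.min()  # order_features wants >= 0
    ordered = order_features(rank_scores, corpus.vocab, kept)
    if max_features is not None and max_features < ordered.size:
        # cut at a variable-block boundary at or past the budget
        names = [corpus.vocab[v].variable_name for v in ordered]
        cut = max_features
        while cut < len(names) and names[cut] == names[cut - 1]:
            cut += 1
        ordered = ordered[:cut]
    coef = topics.coefficients
    # leftmost column = shortest survival: descending beta for Cox,
    # ascending theta for AFT (larger theta means longer survival)
    col_order = np.argsort(-coef if topics.higher_risk_is_larger else coef, kind="stable")
    return HeatmapLayout(
        topic_order=col_order,
        coefficients=coef[col_order],
        feature_order=ordered,
        values=topics.display[np.ix_(col_order, ordered)].T,
        raw_values=None if topics.raw is None else topics.raw[np.ix_(col_order, ordered)].T,
        vocab=[corpus.vocab[v] for v in ordered],
        min_frac=min_frac,
        max_frac=max_frac,
        higher_risk_is_larger=topics.higher_risk_is_larger,
    )


def layout_table(layout: HeatmapLayout) -> pd.DataFrame:
    """Long-form table: (topic, coefficient, word, display_value, raw_value)."""
    rows = []
    for j, (topic, coef) in enumerate(zip(layout.topic_order, layout.coefficients)):
        for i, desc in enumerate(layout.vocab):
            rows.append(
                {
                    "topic": int(topic),
                    "coefficient": float(coef),
                    "word": desc.word,
                    "display_value": float(layout.values[i, j]),
                    "raw_value": (
                        float(layout.raw_values[i, j]) if layout.raw_values is not None else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def plot_heatmap(layout: HeatmapLayout, path: str | None = None, annot: bool = False):
    """Draw the layout with seaborn; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    coef_symbol = "beta" if layout.higher_risk_is_larger else "theta"
    cols = [f"{coef_symbol}={c:.2f}" for c in layout.coefficients]
    df = pd.DataFrame(layout.values, index=[v.word for v in layout.vocab], columns=cols)
    height = max(3.0, 0.22 * len(df) + 1.5)
    fig, ax = plt.subplots(figsize=(1.1 * len(cols) + 3, height))
    sns.heatmap(df, cmap="Reds", ax=ax, annot=annot, fmt=".2f",
                cbar_kws={"label": "P(event | topic)"})
    ax.set_xlabel(
        "topics, left = shorter survival"
        + ("" if layout.higher_risk_is_larger else " (larger theta = longer survival)")
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
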