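"""Bag-of-events survival corpora.

A subject is represented as counts of binary historical clinical events
("words"): continuous measurements are discretized into quantile bins so
that, e.g., "white blood count in the bottom quintile" is one event that
may occur several times.  Alongside the counts matrix each subject
carries a right-censored survival label (observed time, event
indicator).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "EventDescriptor",
    "CountsCorpus",
    "discretize_quantiles",
    "normalize_rows",
    "prevalence_filter",
    "split_dataset",
    "counts_from_dataframe",
    "load_corpus",
    "save_corpus",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally unusable (e.g. all missing)."""


@dataclasses.dataclass(frozen=True)
class EventDescriptor:
    """One vocabulary entry: a (variable, bin) pair.

    ``bin_index`` orders the bins of a discretized variable (1-based);
    purely categorical variables use one descriptor per level.
    """

    variable_name: str
    bin_label: str
    bin_index: int

    @property
    def word(self) -> str:
        return f"{self.variable_name}={self.bin_label}"


@dataclasses.dataclass
class CountsCorpus:
    """Subjects-by-events count matrix with survival labels.

    Attributes
    ----------
    X : (n, d) ndarray of nonnegative integers
        Number of times each event occurred per subject.
    vocab : list of EventDescriptor, length d
    times : (n,) ndarray, observed time per subject (event or censoring)
    events : (n,) ndarray of {0, 1}, 1 = the event (e.g. death) was observed
    subject_ids : (n,) array of unique identifiers
    """

    X: np.ndarray
    vocab: list[EventDescriptor]
    times: np.ndarray
    events: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if sparse.issparse(self.X):  # pragma: no cover - defensive
            self.X = self.X.toarray()
        self.times = np.asarray(self.times, dtype=np.float64)
        self.events = np.asarray(self.events)
        self.subject_ids = np.asarray(self.subject_ids)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n, d = self.X.shape
        if np.any(self.X < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.X, np.round(self.X)):
            raise ValueError("counts must be integer-valued")
        if len(self.vocab) != d:
            raise ValueError(f"vocab length {len(self.vocab)} != {d} columns")
        pairs = {(v.variable_name, v.bin_label) for v in self.vocab}
        if len(pairs) != d:
            raise ValueError("duplicate (variable_name, bin_label) pairs in vocab")
        if self.times.shape != (n,) or self.events.shape != (n,):
            raise ValueError("labels must align with rows of X")
        if np.any(self.times < 0):
            raise ValueError("observed times must be nonnegative")
        if not np.isin(self.events, [0, 1]).all():
            raise ValueError("event indicators must be 0 or 1")
        if len(np.unique(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        row_sums = self.X.sum(axis=1)
        if np.any(row_sums == 0):
            bad = self.subject_ids[row_sums == 0]
            raise ValueError(
                f"subjects with zero recorded events: {list(bad[:5])}; "
                "the topic-model likelihood is undefined for empty documents — "
                "drop these subjects or add events before building the corpus"
            )

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_events(self) -> int:
        return self.X.shape[1]

    def normalized(self) -> np.ndarray:
        """Row-normalized counts (each subject weighted equally)."""
        return normalize_rows(self.X, subject_ids=self.subject_ids)

    def subset(self, idx: np.ndarray) -> "CountsCorpus":
        return CountsCorpus(
            X=self.X[idx],
            vocab=list(self.vocab),
            times=self.times[idx],
            events=self.events[idx],
            subject_ids=self.subject_ids[idx],
        )


# ---------------------------------------------------------------------------


def discretize_quantiles(
    values: Sequence[float], n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Assign values to empirical-quantile bins.

    Bin edges are the empirical quantiles of the non-missing values;
    duplicate edges arising from heavy ties are merged, which can reduce
    the effective number of bins.  Missing values (NaN) receive bin 0,
    meaning they contribute no event counts.

    Parameters
    ----------
    values : array-like of float, NaN marks missing
    n_bins : int
        Requested number of bins (e.g. 5 for quintiles).

    Returns
    -------
    assignments : (n,) int ndarray
        Bin in ``1..n_bins`` for non-missing entries, 0 for missing.
    edges : ndarray
        Interior bin edges actually used (after tie collapsing).
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    values = np.asarray(values, dtype=np.float64)
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        raise DegenerateInputError("all values are missing; nothing to discretize")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.unique(np.quantile(observed, qs)) if qs.size else np.array([])
    assignments = np.zeros(values.shape, dtype=np.int64)
    mask = ~np.isnan(values)
    # right-closed bins: value <= edge_1 -> bin 1, etc.
    assignments[mask] = np.searchsorted(edges, values[mask], side="left") + 1
    return assignments, edges


def normalize_rows(X: np.ndarray, subject_ids: np.ndarray | None = None) -> np.ndarray:
    """Divide each row of a counts matrix by its sum.

    Raises on all-zero rows, naming the offending subject when ids are
    supplied: the normalized representation is undefined there.
    """
    X = np.asarray(X, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("counts must be nonnegative")
    sums = X.sum(axis=1)
    zero = sums == 0
    if np.any(zero):
        which = (
            list(np.asarray(subject_ids)[zero][:5])
            if subject_ids is not None
            else list(np.flatnonzero(zero)[:5])
        )
        raise ValueError(f"cannot normalize zero-count rows for subjects {which}")
    return X / sums[:, None]


def prevalence_filter(
    X: np.ndarray, min_frac: float = 0.02, max_frac: float = 0.50
) -> np.ndarray:
    """Columns whose prevalence lies in ``[min_frac, max_frac]``.

    Prevalence of an event is the fraction of subjects with at least one
    occurrence.  Intended for post-training display filtering: events
    too rare do not explain enough of the cohort, events too common do
    not help interpretation.  Never touches a trained model.
    """
    if not (0 <= min_frac <= max_frac <= 1):
        raise ValueError(f"need 0 <= min_frac <= max_frac <= 1, got ({min_frac}, {max_frac})")
    X = np.asarray(X)
    prev = (X > 0).mean(axis=0)
    return np.flatnonzero((prev >= min_frac) & (prev <= max_frac))


def split_dataset(
    corpus: CountsCorpus,
    test_frac: float = 0.2,
    val_frac_of_train: float = 0.2,
    seed: int = 0,
    stratify_by_event: bool = False,
) -> tuple[CountsCorpus, CountsCorpus, CountsCorpus]:
    """Random subject-level train/validation/test partition.

    The test set takes ``round(n * test_frac)`` subjects; the validation
    set takes ``round(n_trainval * val_frac_of_train)`` of the rest.
    The same seed always yields the same partition.  With
    ``stratify_by_event`` the permutation interleaves censored and
    uncensored subjects so all parts get similar event fractions.
    """
    if not (0 < test_frac < 1) or not (0 < val_frac_of_train < 1):
        raise ValueError("fractions must lie strictly in (0, 1)")
    n = corpus.n_subjects
    rng = np.random.default_rng(seed)
    if stratify_by_event:
        groups = [rng.permutation(np.flatnonzero(corpus.events == e)) for e in (1, 0)]
        order = np.argsort(
            np.concatenate([np.linspace(0, 1, g.size, endpoint=False) for g in groups]),
            kind="stable",
        )
        perm = np.concatenate(groups)[order]
    else:
        perm = rng.permutation(n)
    n_test = int(round(n * test_frac))
    n_val = int(round((n - n_test) * val_frac_of_train))
    n_train = n - n_test - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"partition would be empty: train={n_train}, val={n_val}, test={n_test}"
        )
    test_idx = np.sort(perm[:n_test])
    val_idx = np.sort(perm[n_test : n_test + n_val])
    train_idx = np.sort(perm[n_test + n_val :])
    return corpus.subset(train_idx), corpus.subset(val_idx), corpus.subset(test_idx)


# ---------------------------------------------------------------------------
# construction and I/O


def counts_from_dataframe(
    df: pd.DataFrame,
    n_bins: int = 5,
    categorical: Sequence[str] = (),
    missing_indicator: bool = False,
) -> tuple[np.ndarray, list[EventDescriptor]]:
    """Build a counts matrix from a subjects-by-variables table.

    Continuous columns are discretized into ``n_bins`` empirical
    quantile bins; columns listed in ``categorical`` get one event per
    observed level.  Missing entries contribute no counts by default;
    with ``missing_indicator`` each variable additionally gets an
    explicit "missing" event word.
    """
    columns: list[np.ndarray] = []
    vocab: list[EventDescriptor] = []
    n = len(df)
    for name in df.columns:
        col = df[name]
        if missing_indicator and col.isna().any():
            columns.append(col.isna().to_numpy(dtype=np.int64))
            vocab.append(EventDescriptor(name, "missing", 0))
        if name in categorical:
            levels = sorted(col.dropna().unique(), key=str)
            for j, level in enumerate(levels, start=1):
                columns.append((col == level).to_numpy(dtype=np.int64))
                vocab.append(EventDescriptor(name, str(level), j))
        else:
            assignments, edges = discretize_quantiles(col.to_numpy(dtype=np.float64), n_bins)
            n_eff = len(edges) + 1
            for b in range(1, n_eff + 1):
                columns.append((assignments == b).astype(np.int64))
                vocab.append(EventDescriptor(name, f"bin{b}", b))
    X = np.stack(columns, axis=1) if columns else np.zeros((n, 0), dtype=np.int64)
    return X, vocab


def save_corpus(corpus: CountsCorpus, out_dir: str | Path, sparse_counts: bool = True) -> None:
    """Write counts (MTX or CSV), vocabulary CSV and labels CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sparse_counts:
        spio.mmwrite(out / "counts.mtx", sparse.coo_matrix(corpus.X))
    else:
        pd.DataFrame(corpus.X).to_csv(out / "counts.csv", index=False, header=False)
    pd.DataFrame(
        {
            "word_id": np.arange(corpus.n_events),
            "variable_name": [v.variable_name for v in corpus.vocab],
            "bin_label": [v.bin_label for v in corpus.vocab],
            "bin_index": [v.bin_index for v in corpus.vocab],
        }
    ).to_csv(out / "vocab.csv", index=False)
    pd.DataFrame(
        {
            "subject_id": corpus.subject_ids,
            "time": corpus.times,
            "event": corpus.events.astype(np.int64),
        }
    ).to_csv(out / "labels.csv", index=False, float_format="%.17g")  # exact round-trip


def load_corpus(
    data_dir: str | Path,
    counts: str | None = None,
    vocab: str | None = None,
    labels: str | None = None,
) -> CountsCorpus:
    """Read a corpus written by :func:`save_corpus` (or matching files)."""
    d = Path(data_dir)
    counts_path = Path(counts) if counts else _first_existing(d, ["counts.mtx", "counts.csv"])
    vocab_path = Path(vocab) if vocab else d / "vocab.csv"
    labels_path = Path(labels) if labels else d / "labels.csv"
    if counts_path.suffix == ".mtx":
        X = np.asarray(spio.mmread(counts_path).todense())
    else:
        X = pd.read_csv(counts_path, header=None).to_numpy()
    vdf = pd.read_csv(vocab_path).sort_values("word_id")
    vocab_list = [
        EventDescriptor(str(r.variable_name), str(r.bin_label), int(r.bin_index))
        for r in vdf.itertuples()
    ]
    ldf = pd.read_csv(labels_path, float_precision="round_trip")
    return CountsCorpus(
        X=np.asarray(np.round(X), dtype=np.int64),
        vocab=vocab_list,
        times=ldf["time"].to_numpy(dtype=np.float64),
        events=ldf["event"].to_numpy(dtype=np.int64),
        subject_ids=ldf["subject_id"].to_numpy(),
    )


def _first_existing(d: Path, names: Sequence[str]) -> Path:
    for name in names:
        if (d / name).exists():
            return d / name
    raise FileNotFoundError(f"none of {names} found in {d}")
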