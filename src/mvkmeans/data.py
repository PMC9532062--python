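"""Multi-view survey data model.

Aligned per-view feature matrices over the same respondents, categorical
encoding through a code book, CSV I/O, per-column standardization, and the
train/test split used by the experimental protocol.

A *view* is one feature block describing the same respondents (e.g. a
basic-information table and a questionnaire); multi-view data is an ordered
list of such blocks with rows aligned across views.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "CodeBook",
    "MultiViewDataset",
    "SplitSpec",
    "encode_records",
    "decode_records",
    "load_views_csv",
    "save_views_csv",
    "load_codebooks",
    "standardize",
    "train_test_split",
    "basic_info_codebook",
    "questionnaire_codebook",
]


class DataError(ValueError):
    """Raised when input data violate the loading or alignment contracts."""


# ---------------------------------------------------------------------------
# Code book
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodeBook:
    """Mapping from categorical survey values to integer codes, per attribute.

    ``mapping[attribute][value] -> code``. Codes are unique within each
    attribute so that ``decode(encode(x)) == x`` for every listed value.
    """

    mapping: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for attr, values in self.mapping.items():
            if not values:
                raise DataError(f"code book attribute {attr!r} has no values")
            codes = list(values.values())
            if len(set(codes)) != len(codes):
                raise DataError(f"code book attribute {attr!r} has duplicate codes")

    @property
    def attributes(self) -> list[str]:
        return list(self.mapping)

    def encode_value(self, attribute: str, value: str) -> int:
        try:
            table = self.mapping[attribute]
        except KeyError:
            raise DataError(f"attribute {attribute!r} missing from code book") from None
        try:
            return table[value]
        except KeyError:
            raise DataError(
                f"unknown value {value!r} for attribute {attribute!r}; "
                f"known values: {sorted(table)}"
            ) from None

    def decode_value(self, attribute: str, code: int) -> str:
        try:
            table = self.mapping[attribute]
        except KeyError:
            raise DataError(f"attribute {attribute!r} missing from code book") from None
        for value, c in table.items():
            if c == code:
                return value
        raise DataError(f"code {code!r} not listed for attribute {attribute!r}")

    def levels(self, attribute: str) -> list[str]:
        """Values of one attribute in code order (ascending code)."""
        table = self.mapping[attribute]
        return sorted(table, key=table.__getitem__)

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "CodeBook":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(_normalize_codebook_mapping(raw))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {a: dict(v) for a, v in self.mapping.items()},
                fh,
                default_flow_style=False,
                sort_keys=False,
                allow_unicode=True,
            )


def _normalize_codebook_mapping(raw) -> dict[str, dict[str, int]]:
    if not isinstance(raw, Mapping):
        raise DataError("code book must be a mapping {attribute: {value: code}}")
    out: dict[str, dict[str, int]] = {}
    for attr, values in raw.items():
        if not isinstance(values, Mapping):
            raise DataError(f"code book attribute {attr!r} must map values to codes")
        # YAML may parse bare Yes/No as booleans; keep them as strings
        out[str(attr)] = {_yaml_key(v): int(c) for v, c in values.items()}
    return out


def _yaml_key(value) -> str:
    if value is True:
        return "Yes"
    if value is False:
        return "No"
    return str(value)


def _load_resource_codebook(name: str) -> CodeBook:
    text = resources.files("mvkmeans").joinpath(f"resources/{name}").read_text("utf-8")
    return CodeBook(_normalize_codebook_mapping(yaml.safe_load(text)))


def basic_info_codebook() -> CodeBook:
    """Packaged default code book for the basic-information view (codes 11-85)."""
    return _load_resource_codebook("basic_info_codebook.yaml")


def questionnaire_codebook() -> CodeBook:
    """Packaged option-index code book (A->1, B->2, ...) for the questionnaire view."""
    return _load_resource_codebook("questionnaire_codebook.yaml")


def load_codebooks(path) -> list[CodeBook]:
    """Load one or several code books from a YAML file.

    Accepts either a single ``{attribute: {value: code}}`` mapping or a YAML
    sequence of such mappings (one per view, in view order).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, Sequence) and not isinstance(raw, (str, bytes)):
        return [CodeBook(_normalize_codebook_mapping(item)) for item in raw]
    return [CodeBook(_normalize_codebook_mapping(raw))]


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_records(records: pd.DataFrame, codebook: CodeBook) -> np.ndarray:
    """Encode a table of categorical strings into its numeric code matrix.

    Column order is preserved; cell (i, j) becomes the integer code of
    ``records.iloc[i, j]`` under the code book entry for column j.
    """
    out = np.empty(records.shape, dtype=float)
    for j, col in enumerate(records.columns):
        if col not in codebook.mapping:
            raise DataError(f"column {col!r} missing from code book")
        table = codebook.mapping[col]
        for i, value in enumerate(records[col].tolist()):
            key = _yaml_key(value)
            if key not in table:
                raise DataError(
                    f"unknown value {value!r} for attribute {col!r} at row {i}"
                )
            out[i, j] = table[key]
    return out


def decode_records(matrix: np.ndarray, columns: Sequence[str], codebook: CodeBook) -> pd.DataFrame:
    """Inverse of :func:`encode_records` for audit round-trips."""
    matrix = np.asarray(matrix)
    data = {}
    for j, col in enumerate(columns):
        data[col] = [codebook.decode_value(col, int(round(c))) for c in matrix[:, j]]
    return pd.DataFrame(data, columns=list(columns))


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class MultiViewDataset:
    """Aligned per-view numeric matrices over the same respondents.

    ``views[v]`` has shape (N, d_v); row i in every view is respondent i.
    ``labels`` is an optional ground-truth state per respondent (5 levels in
    the survey protocol), ``ids`` optional respondent identifiers.
    """

    views: list[np.ndarray]
    labels: np.ndarray | None = None
    ids: np.ndarray | None = None
    columns: list[list[str]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.views) < 1:
            raise DataError("a multi-view dataset needs at least one view")
        views = []
        for v, X in enumerate(self.views):
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] < 1:
                raise DataError(f"view {v} must be a 2-D matrix with >=1 column")
            if np.isnan(X).any():
                raise DataError(f"view {v} contains missing values after loading")
            views.append(X)
        n = views[0].shape[0]
        for v, X in enumerate(views):
            if X.shape[0] != n:
                raise DataError(
                    f"row-count mismatch across views: view 0 has {n} rows, "
                    f"view {v} has {X.shape[0]}"
                )
        self.views = views
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise DataError("labels must be a vector with one entry per respondent")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != n:
                raise DataError("ids must have one entry per respondent")
        if self.columns is not None:
            if len(self.columns) != len(views):
                raise DataError("columns must list names for every view")
            for v, (names, X) in enumerate(zip(self.columns, views)):
                if len(names) != X.shape[1]:
                    raise DataError(f"column names of view {v} do not match its width")

    @property
    def n_samples(self) -> int:
        return self.views[0].shape[0]

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(X.shape[1] for X in self.views)

    def concatenated(self) -> np.ndarray:
        """Column-wise concatenation of all views (single-view baselines)."""
        return np.hstack(self.views)

    def subset(self, indices: np.ndarray) -> "MultiViewDataset":
        indices = np.asarray(indices)
        return MultiViewDataset(
            views=[X[indices] for X in self.views],
            labels=None if self.labels is None else self.labels[indices],
            ids=None if self.ids is None else self.ids[indices],
            columns=self.columns,
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_views_csv(
    paths: Sequence,
    codebooks: CodeBook | Sequence[CodeBook | None] | None = None,
    label_column: str | None = None,
    drop_incomplete: bool = False,
) -> MultiViewDataset:
    """Load one CSV per view into an aligned :class:`MultiViewDataset`.

    Raw categorical files are encoded through the per-view code book; numeric
    files pass through unchanged. ``label_column``, if present in a view, is
    stripped from the features into ``labels``. Missing cells fail fast unless
    ``drop_incomplete`` is set, in which case offending rows are dropped from
    every view (aligned) and the count is logged.
    """
    paths = list(paths)
    if codebooks is None or isinstance(codebooks, CodeBook):
        books: list[CodeBook | None] = [codebooks] * len(paths)  # type: ignore[list-item]
    else:
        books = list(codebooks)
        if len(books) != len(paths):
            raise DataError("one code book (or None) required per view")

    frames = [pd.read_csv(p) for p in paths]
    counts = {str(p): len(f) for p, f in zip(paths, frames)}
    if len(set(counts.values())) > 1:
        raise DataError(f"row-count mismatch across views: {counts}")

    labels = None
    if label_column is not None:
        for frame in frames:
            if label_column in frame.columns:
                col = frame[label_column]
                if labels is None:
                    labels = col.to_numpy()
                elif not np.array_equal(labels, col.to_numpy()):
                    raise DataError(f"label column {label_column!r} differs across views")
        if labels is None:
            raise DataError(f"label column {label_column!r} not found in any view")
        frames = [f.drop(columns=[label_column], errors="ignore") for f in frames]

    incomplete = np.zeros(len(frames[0]), dtype=bool)
    for frame in frames:
        incomplete |= frame.isna().any(axis=1).to_numpy()
    if incomplete.any():
        if not drop_incomplete:
            raise DataError(
                f"{int(incomplete.sum())} row(s) contain missing values; "
                "pass drop_incomplete=True to drop them"
            )
        logger.warning("dropping %d incomplete row(s)", int(incomplete.sum()))
        keep = ~incomplete
        frames = [f.loc[keep].reset_index(drop=True) for f in frames]
        if labels is not None:
            labels = labels[keep]

    views, columns = [], []
    for v, (frame, book) in enumerate(zip(frames, books)):
        columns.append([str(c) for c in frame.columns])
        if book is not None:
            views.append(encode_records(frame, book))
        else:
            try:
                views.append(frame.to_numpy(dtype=float))
            except (TypeError, ValueError) as exc:
                raise DataError(
                    f"view {v} ({paths[v]}) has non-numeric cells and no code book: {exc}"
                ) from None

    if labels is not None:
        labels = np.asarray(labels, dtype=int)
    return MultiViewDataset(views=views, labels=labels, columns=columns)


def save_views_csv(dataset: MultiViewDataset, paths: Sequence, label_column: str | None = None) -> None:
    """Write the encoded numeric views back to CSV for audit."""
    paths = list(paths)
    if len(paths) != dataset.n_views:
        raise DataError("one output path required per view")
    for v, (X, path) in enumerate(zip(dataset.views, paths)):
        names = dataset.columns[v] if dataset.columns else [f"x{j}" for j in range(X.shape[1])]
        frame = pd.DataFrame(X, columns=names)
        if label_column is not None and dataset.labels is not None and v == 0:
            frame[label_column] = dataset.labels
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(dataset: MultiViewDataset, method: str = "none") -> MultiViewDataset:
    """Per view-column standardization.

    ``none`` returns the dataset unchanged (raw codes feed Euclidean distance
    directly, the protocol default). ``zscore`` centers each column to mean 0
    and scales to unit population variance; constant columns map to all zeros.
    """
    if method == "none":
        return dataset
    if method != "zscore":
        raise ValueError(f"unknown standardization method {method!r}")
    views = []
    for X in dataset.views:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)  # population convention (ddof=0)
        safe = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / safe
        Z[:, sd == 0] = 0.0
        views.append(Z)
    return MultiViewDataset(
        views=views, labels=dataset.labels, ids=dataset.ids, columns=dataset.columns
    )


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Row split specification (protocol default: 600 train / 200 test)."""

    n_train: int
    n_test: int
    seed: int = 0
    shuffled: bool = True

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_test <= 0:
            raise DataError("both split sides must be positive")


def train_test_split(
    dataset: MultiViewDataset, spec: SplitSpec
) -> tuple[MultiViewDataset, MultiViewDataset]:
    """Disjoint, exhaustive row partition, reproducible from the seed.

    The same permutation is applied to every view and to the labels.
    """
    n = dataset.n_samples
    if spec.n_train + spec.n_test != n:
        raise DataError(
            f"n_train + n_test = {spec.n_train + spec.n_test} does not match N = {n}"
        )
    if spec.shuffled:
        order = np.random.default_rng(spec.seed).permutation(n)
    else:
        order = np.arange(n)
    return dataset.subset(order[: spec.n_train]), dataset.subset(order[spec.n_train :])
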