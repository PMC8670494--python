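"""Data model for multi-task regression collections and model persistence.

A *task* is one regression problem: a feature matrix over a shared attribute
schema plus a real-valued target.  A *collection* is a set of such tasks that
share the schema — the unit the transformational-ML machinery operates on.
The :class:`ModelRegistry` stores fitted per-task models keyed by
``(task_id, learner digest, representation tag)`` so the transform stage can
look up "the models trained on all the other tasks".

File layouts supported by :func:`load_collection`:

* a directory with one delimited file per task named ``<task_id>.csv`` (or
  ``.tsv``): first column example id, last column target, middle columns
  features;
* a single wide table with columns ``task_id``, ``example_id``, the feature
  columns, and ``target``.

A feature column holding packed fingerprint bitstrings (named with an ``fp:``
prefix, or nominated explicitly) is expanded into one binary column per bit.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import joblib
import numpy as np
import pandas as pd

from ._exceptions import (
    DependencyError,
    FingerprintParseError,
    FormatError,
    IntegrityError,
    SchemaError,
)

_REGISTRY_FORMAT_VERSION = 1

RESERVED_COLUMNS = ("task_id", "example_id", "target")


def parse_fingerprint(bitstring: str) -> np.ndarray:
    """Parse a '0'/'1' string into a binary feature vector.

    Order is preserved: character ``i`` becomes element ``i``.

    Raises
    ------
    FingerprintParseError
        If the string is empty or contains a character other than 0/1; the
        error carries the 1-based position of the first offender.
    """
    if not isinstance(bitstring, str) or len(bitstring) == 0:
        raise FingerprintParseError("fingerprint bitstring is empty", position=0)
    for i, ch in enumerate(bitstring):
        if ch not in "01":
            raise FingerprintParseError(
                f"illegal character {ch!r} at position {i + 1} in fingerprint",
                position=i + 1,
            )
    return np.frombuffer(bitstring.encode("ascii"), dtype=np.uint8) - ord("0")


def expand_fingerprint_column(
    frame: pd.DataFrame, column: str, prefix: str = "fp"
) -> pd.DataFrame:
    """Replace a packed-bitstring column with one float column per bit.

    Columns are named ``<prefix>_0000`` ... zero-padded to the width of the
    fingerprint length so lexicographic order equals bit order.
    """
    bits = [parse_fingerprint(str(s)) for s in frame[column]]
    lengths = {len(b) for b in bits}
    if len(lengths) != 1:
        raise FormatError(
            f"fingerprint column {column!r} has inconsistent lengths {sorted(lengths)}"
        )
    n_bits = lengths.pop()
    width = max(4, len(str(n_bits - 1)))
    names = [f"{prefix}_{i:0{width}d}" for i in range(n_bits)]
    mat = pd.DataFrame(
        np.asarray(bits, dtype=float), columns=names, index=frame.index
    )
    rest = frame.drop(columns=[column])
    return pd.concat([rest, mat], axis=1)


@dataclass
class Task:
    """One learning problem: feature matrix ``X`` and target vector ``y``.

    ``X`` is a DataFrame indexed by example id with named feature columns;
    ``y`` is aligned to the same index.  Feature values are stored as float64
    even when binary so fingerprint and continuous features share a code path.
    """

    task_id: str
    X: pd.DataFrame
    y: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = self.X.astype(float)
        if len(self.X) != len(self.y):
            raise IntegrityError(
                f"task {self.task_id!r}: {len(self.X)} feature rows vs "
                f"{len(self.y)} targets"
            )
        self.y = pd.Series(np.asarray(self.y, dtype=float), index=self.X.index)
        if self.X.index.has_duplicates:
            dupes = self.X.index[self.X.index.duplicated()].unique().tolist()
            raise IntegrityError(
                f"task {self.task_id!r}: duplicate example ids {dupes[:5]}"
            )
        if not np.isfinite(self.X.to_numpy()).all():
            raise IntegrityError(f"task {self.task_id!r}: non-finite feature values")
        if self.y.isna().any() or not np.isfinite(self.y.to_numpy()).all():
            raise IntegrityError(f"task {self.task_id!r}: missing/non-finite targets")

    @property
    def n_examples(self) -> int:
        return len(self.X)

    @property
    def example_ids(self) -> list[str]:
        return [str(i) for i in self.X.index]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


class TaskCollection:
    """An ordered set of tasks over one shared feature schema.

    Iteration order is deterministic: tasks sorted by ``task_id`` regardless
    of insertion or file-discovery order.
    """

    def __init__(self, tasks: list[Task], collection_id: str = "collection"):
        if not tasks:
            raise IntegrityError("a collection needs at least one task")
        ids = [t.task_id for t in tasks]
        if len(set(ids)) != len(ids):
            raise IntegrityError("duplicate task_ids in collection")
        schema = tasks[0].feature_names
        for t in tasks:
            if t.feature_names != schema:
                raise SchemaError(
                    f"task {t.task_id!r} feature columns do not match the "
                    f"collection schema (task {tasks[0].task_id!r})"
                )
        self._tasks = {t.task_id: t for t in sorted(tasks, key=lambda t: t.task_id)}
        self.feature_schema = schema
        self.collection_id = collection_id

    def __iter__(self) -> Iterator[Task]:
        return iter(self._tasks.values())

    def __len__(self) -> int:
        return len(self._tasks)

    def __contains__(self, task_id: str) -> bool:
        return task_id in self._tasks

    def __getitem__(self, task_id: str) -> Task:
        return self._tasks[task_id]

    @property
    def task_ids(self) -> list[str]:
        return list(self._tasks)

    @property
    def n_features(self) -> int:
        return len(self.feature_schema)


def _read_delimited(
    path: Path, delimiter: str | None, fingerprint_col: str | None = None
) -> pd.DataFrame:
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        header = pd.read_csv(path, sep=delimiter, nrows=0).columns
        # bitstring columns must stay strings or leading zeros are lost
        str_cols = [c for c in header if c.startswith("fp:") or c == fingerprint_col]
        for idc in ("example_id", "task_id"):
            if idc in header:
                str_cols.append(idc)
        frame = pd.read_csv(
            path, sep=delimiter, dtype={**{c: str for c in str_cols}, header[0]: str}
        )
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: fewer than two columns")
    return frame


def _expand_fp_columns(frame: pd.DataFrame, fingerprint_col: str | None) -> pd.DataFrame:
    targets = [c for c in frame.columns if c.startswith("fp:")]
    if fingerprint_col is not None:
        if fingerprint_col not in frame.columns:
            raise FormatError(f"fingerprint column {fingerprint_col!r} not found")
        targets.append(fingerprint_col)
    for col in targets:
        prefix = re.sub(r"^fp:", "", col) or "fp"
        if not col.startswith("fp:"):
            prefix = col
        frame = expand_fingerprint_column(frame, col, prefix=prefix)
    return frame


def _task_from_frame(
    task_id: str, frame: pd.DataFrame, fingerprint_col: str | None, origin: str
) -> Task:
    if frame.columns[-1] != "target" and "target" not in frame.columns:
        raise FormatError(f"{origin}: no 'target' column")
    id_col = frame.columns[0]
    frame = frame.set_index(id_col)
    if frame.index.has_duplicates:
        raise IntegrityError(f"{origin}: duplicate example ids for task {task_id!r}")
    y = frame.pop("target")
    frame = _expand_fp_columns(frame, fingerprint_col)
    if frame.isna().any().any():
        raise IntegrityError(f"{origin}: missing feature values (no imputation)")
    return Task(task_id=task_id, X=frame, y=y)


def load_collection(
    path: str | Path,
    delimiter: str | None = None,
    fingerprint_col: str | None = None,
    collection_id: str | None = None,
) -> TaskCollection:
    """Load a task collection from a directory of per-task files or one wide table.

    Raises :class:`SchemaError` naming the offending task if feature columns
    differ between tasks, :class:`FormatError` for a missing target column,
    and :class:`IntegrityError` for duplicate ``(task_id, example_id)`` pairs.
    """
    path = Path(path)
    tasks: list[Task] = []
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".csv", ".tsv", ".tab")
        )
        if not files:
            raise FormatError(f"no task files found in {path}")
        for f in files:
            frame = _read_delimited(f, delimiter, fingerprint_col)
            tasks.append(_task_from_frame(f.stem, frame, fingerprint_col, str(f)))
        schema = tasks[0].feature_names
        for t, f in zip(tasks, files):
            if t.feature_names != schema:
                raise SchemaError(
                    f"{f}: feature columns differ from {files[0]} "
                    f"({len(t.feature_names)} vs {len(schema)} columns or renamed)"
                )
    else:
        frame = _read_delimited(path, delimiter, fingerprint_col)
        for col in ("task_id", "example_id", "target"):
            if col not in frame.columns:
                raise FormatError(f"{path}: wide layout needs a {col!r} column")
        if frame.duplicated(subset=["task_id", "example_id"]).any():
            raise IntegrityError(f"{path}: duplicate (task_id, example_id) pairs")
        for task_id, group in frame.groupby("task_id", sort=True):
            sub = group.drop(columns=["task_id"]).set_index("example_id")
            y = sub.pop("target")
            sub = _expand_fp_columns(sub, fingerprint_col)
            if sub.isna().any().any():
                raise IntegrityError(f"{path}: missing feature values in {task_id!r}")
            tasks.append(Task(task_id=str(task_id), X=sub, y=y))
    return TaskCollection(tasks, collection_id=collection_id or path.stem)


def save_collection(collection: TaskCollection, path: str | Path) -> None:
    """Write the directory-of-tasks layout (one CSV per task)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for task in collection:
        frame = task.X.copy()
        frame.insert(0, "example_id", task.X.index)
        frame["target"] = task.y.to_numpy()
        frame.to_csv(path / f"{task.task_id}.csv", index=False)


@dataclass(frozen=True)
class RegistryKey:
    task_id: str
    learner_digest: str
    representation_tag: str  # baseline | tml | combined

    def __post_init__(self) -> None:
        if self.representation_tag not in ("baseline", "tml", "combined"):
            raise IntegrityError(
                f"unknown representation tag {self.representation_tag!r}"
            )


class ModelRegistry:
    """Fitted models keyed by (task, learner digest, representation tag).

    At most one entry per key; every stored model carries the feature-column
    order it expects and refuses prediction on mismatched schemas (enforced
    by the model adapter itself, see :mod:`tml.learners`).
    """

    def __init__(self) -> None:
        self._entries: dict[RegistryKey, object] = {}
        self._meta: dict[RegistryKey, dict] = {}

    def add(
        self,
        task_id: str,
        learner_digest: str,
        model,
        representation_tag: str = "baseline",
        overwrite: bool = False,
        **metadata,
    ) -> None:
        key = RegistryKey(task_id, learner_digest, representation_tag)
        if key in self._entries and not overwrite:
            raise IntegrityError(f"registry already holds an entry for {key}")
        self._entries[key] = model
        self._meta[key] = dict(metadata)

    def get(self, task_id: str, learner_digest: str, representation_tag: str = "baseline"):
        key = RegistryKey(task_id, learner_digest, representation_tag)
        try:
            return self._entries[key]
        except KeyError:
            raise DependencyError(
                f"no registered model for task {key.task_id!r}, learner "
                f"{key.learner_digest[:12]}..., tag {key.representation_tag!r}"
            ) from None

    def metadata(self, task_id: str, learner_digest: str, representation_tag: str = "baseline") -> dict:
        return self._meta[RegistryKey(task_id, learner_digest, representation_tag)]

    def models_for(
        self, learner_digest: str, representation_tag: str = "baseline"
    ) -> Mapping[str, object]:
        """All models of one learner spec and tag, keyed and sorted by task id."""
        out = {
            k.task_id: m
            for k, m in self._entries.items()
            if k.learner_digest == learner_digest
            and k.representation_tag == representation_tag
        }
        return dict(sorted(out.items()))

    def enumerate(self) -> list[RegistryKey]:
        return sorted(
            self._entries,
            key=lambda k: (k.task_id, k.learner_digest, k.representation_tag),
        )

    def __len__(self) -> int:
        return len(self._entries)


def save_registry(registry: ModelRegistry, path: str | Path) -> None:
    """Persist a registry as a directory: JSON index + one blob per entry."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = {"format_version": _REGISTRY_FORMAT_VERSION, "entries": []}
    for i, key in enumerate(registry.enumerate()):
        blob = f"model_{i:05d}.joblib"
        joblib.dump(registry._entries[key], path / blob)
        index["entries"].append(
            {
                "task_id": key.task_id,
                "learner_digest": key.learner_digest,
                "representation_tag": key.representation_tag,
                "blob": blob,
                "metadata": registry._meta[key],
            }
        )
    (path / "index.json").write_text(json.dumps(index, indent=2, default=str))


def load_registry(path: str | Path) -> ModelRegistry:
    """Reload a persisted registry.

    Round-trip identity: a reloaded deterministic model predicts bit-for-bit
    identically to the original.  A version mismatch raises
    :class:`FormatError` rather than risking silent misprediction.
    """
    path = Path(path)
    index_file = path / "index.json"
    if not index_file.exists():
        raise FormatError(f"{path}: not a registry (no index.json)")
    text = index_file.read_text()
    if not text.strip():
        raise FormatError(f"{index_file}: empty file")
    try:
        index = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{index_file}: invalid JSON: {exc}") from exc
    version = index.get("format_version")
    if version != _REGISTRY_FORMAT_VERSION:
        raise FormatError(
            f"registry format version {version!r} is incompatible with this "
            f"package (expected {_REGISTRY_FORMAT_VERSION})"
        )
    registry = ModelRegistry()
    for entry in index["entries"]:
        model = joblib.load(path / entry["blob"])
        registry.add(
            entry["task_id"],
            entry["learner_digest"],
            model,
            representation_tag=entry["representation_tag"],
            **entry.get("metadata", {}),
        )
    return registry
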