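"""Data model and text I/O for complete rankings.

A group ranking experiment yields, for each of J participants, a complete
ranking of the same N items.  Two equivalent textual representations are
supported:

* **ordering** — the items listed in the sequence they were placed
  (first-placed item first);
* **ranking** — for each item, the position it was placed in.

Each is the inverse permutation of the other.  Internally everything is
0-based; on disk, positions and item references are 1-based, matching the
human convention that the best item is "ranked 1st".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Ordering",
    "Ranking",
    "RankingDataset",
    "ordering_to_ranking",
    "ranking_to_ordering",
    "read_dataset",
    "write_dataset",
]

PathLike = Union[str, Path]


def _validate_permutation(values: np.ndarray, kind: str) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 1:
        raise ValueError(f"{kind} must be one-dimensional, got shape {values.shape}")
    n = values.size
    if n < 2:
        raise ValueError(f"{kind} needs at least 2 items, got {n}")
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(values == np.floor(values)):
            raise ValueError(f"{kind} entries must be integers, got {values!r}")
        values = values.astype(np.int64)
    out_of_range = (values < 0) | (values >= n)
    if out_of_range.any():
        bad = values[out_of_range][0]
        raise ValueError(
            f"{kind} entry {bad} is out of range for {n} items (expected 0..{n - 1})"
        )
    counts = np.bincount(values, minlength=n)
    if (counts != 1).any():
        dup = int(np.argmax(counts > 1))
        raise ValueError(f"{kind} is not a permutation: value {dup} appears {counts[dup]} times")
    return values.astype(np.int64)


class _Permutation:
    """Immutable validated permutation of 0..N-1."""

    __slots__ = ("_values",)
    _kind = "permutation"

    def __init__(self, values: Sequence[int]):
        arr = _validate_permutation(np.asarray(values), self._kind)
        arr.setflags(write=False)
        self._values = arr

    def as_array(self) -> np.ndarray:
        return self._values

    def __len__(self) -> int:
        return self._values.size

    def __getitem__(self, i) -> int:
        return int(self._values[i])

    def __iter__(self) -> Iterator[int]:
        return iter(self._values.tolist())

    def __eq__(self, other) -> bool:
        if isinstance(other, _Permutation):
            return bool(np.array_equal(self._values, other._values))
        return bool(np.array_equal(self._values, np.asarray(other)))

    def __hash__(self) -> int:
        return hash(tuple(self._values.tolist()))

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self._values.tolist()})"


class Ordering(_Permutation):
    """Items listed in placed order: position ``p`` holds the item placed p-th."""

    _kind = "ordering"

    def to_ranking(self) -> "Ranking":
        return ordering_to_ranking(self)


class Ranking(_Permutation):
    """Placed position per item: entry ``i`` is the position item ``i`` received."""

    _kind = "ranking"

    def to_ordering(self) -> "Ordering":
        return ranking_to_ordering(self)


def ordering_to_ranking(o: Ordering) -> Ranking:
    """Invert an ordering into its ranking representation.

    ``result[o[p]] = p``: the item placed p-th gets rank position p.
    """
    if not isinstance(o, Ordering):
        o = Ordering(o)
    return Ranking(np.argsort(o.as_array()))


def ranking_to_ordering(r: Ranking) -> Ordering:
    """Invert a ranking into its ordering representation."""
    if not isinstance(r, Ranking):
        r = Ranking(r)
    return Ordering(np.argsort(r.as_array()))


@dataclass(frozen=True)
class RankingDataset:
    """J complete rankings of N labelled items, with optional ground truth.

    Parameters
    ----------
    item_labels : unique strings, length N.
    participant_ids : unique strings, length J.
    rankings : (J, N) integer matrix; ``rankings[j, i]`` is the 0-based
        position participant ``j`` gave item ``i``.  Every row must be a
        permutation of 0..N-1.
    truth : the true ordering of the items, if one exists for the task.
    """

    item_labels: tuple
    participant_ids: tuple
    rankings: np.ndarray
    truth: Optional[Ordering] = None

    def __post_init__(self):
        labels = tuple(str(x) for x in self.item_labels)
        ids = tuple(str(x) for x in self.participant_ids)
        if len(set(labels)) != len(labels):
            raise ValueError("item labels must be unique")
        if len(set(ids)) != len(ids):
            raise ValueError("participant IDs must be unique")
        if len(ids) < 1:
            raise ValueError("dataset needs at least one participant")
        mat = np.asarray(self.rankings)
        if mat.ndim != 2 or mat.shape != (len(ids), len(labels)):
            raise ValueError(
                f"rankings matrix shape {mat.shape} does not match "
                f"J={len(ids)} participants x N={len(labels)} items"
            )
        rows = np.empty_like(mat, dtype=np.int64)
        for j in range(mat.shape[0]):
            try:
                rows[j] = Ranking(mat[j]).as_array()
            except ValueError as exc:
                raise ValueError(f"participant {ids[j]!r}: {exc}") from exc
        rows.setflags(write=False)
        if self.truth is not None:
            truth = self.truth if isinstance(self.truth, Ordering) else Ordering(self.truth)
            if len(truth) != len(labels):
                raise ValueError("ground-truth ordering length does not match item count")
            object.__setattr__(self, "truth", truth)
        object.__setattr__(self, "item_labels", labels)
        object.__setattr__(self, "participant_ids", ids)
        object.__setattr__(self, "rankings", rows)

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def ranking(self, j: int) -> Ranking:
        return Ranking(self.rankings[j])

    def ordering(self, j: int) -> Ordering:
        return ranking_to_ordering(Ranking(self.rankings[j]))

    def ordering_matrix(self) -> np.ndarray:
        """(J, N) matrix whose row j lists participant j's items in placed order."""
        return np.argsort(self.rankings, axis=1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RankingDataset):
            return NotImplemented
        return (
            self.item_labels == other.item_labels
            and self.participant_ids == other.participant_ids
            and np.array_equal(self.rankings, other.rankings)
            and self.truth == other.truth
        )


_DELIMS = {".csv": ",", ".tsv": "\t"}


def _delimiter_for(path: Path) -> str:
    try:
        return _DELIMS[path.suffix.lower()]
    except KeyError:
        raise ValueError(
            f"cannot infer delimiter from extension {path.suffix!r}; use .csv or .tsv"
        ) from None


def _read_rows(path: Path) -> tuple[list[str], list[tuple[str, list[str]]]]:
    delim = _delimiter_for(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 3:
            raise ValueError(f"{path}: header must list a participant column plus >=2 items")
        labels = [h.strip() for h in header[1:]]
        body = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: ragged row has {len(row)} cells, expected {len(header)}"
                )
            body.append((row[0].strip(), [c.strip() for c in row[1:]]))
    return labels, body


def _cells_to_ints(cells: list[str], where: str) -> np.ndarray:
    out = np.empty(len(cells), dtype=np.int64)
    for i, c in enumerate(cells):
        try:
            out[i] = int(c)
        except ValueError:
            raise ValueError(f"{where}: cell {c!r} is not an integer") from None
    return out


def _row_to_ranking(cells: np.ndarray, representation: str, where: str) -> np.ndarray:
    vals = cells - 1  # files are 1-based
    try:
        if representation == "ranking":
            return Ranking(vals).as_array()
        return ordering_to_ranking(Ordering(vals)).as_array()
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def read_dataset(
    path: PathLike,
    representation: str = "ordering",
    truth_path: Optional[PathLike] = None,
) -> RankingDataset:
    """Read a delimited ranking table (.csv or .tsv).

    The header row holds item labels after a leading participant-ID column.
    In the *ranking* representation the cell under item ``i`` is the 1-based
    position the participant gave that item.  In the *ordering*
    representation the k-th data cell is the 1-based header index of the item
    placed k-th (the header then serves as the item legend).

    ``truth_path`` points to a single-row file with the same header carrying
    the ground-truth order in the same representation.
    """
    if representation not in ("ordering", "ranking"):
        raise ValueError(f"representation must be 'ordering' or 'ranking', got {representation!r}")
    path = Path(path)
    labels, body = _read_rows(path)
    if not body:
        raise ValueError(f"{path}: no participant rows")
    ids, rows = [], []
    for pid, cells in body:
        where = f"{path} participant {pid!r}"
        rows.append(_row_to_ranking(_cells_to_ints(cells, where), representation, where))
    ids = [pid for pid, _ in body]
    if len(set(ids)) != len(ids):
        seen = set()
        dup = next(pid for pid in ids if pid in seen or seen.add(pid))
        raise ValueError(f"{path}: duplicate participant ID {dup!r}")

    truth = None
    if truth_path is not None:
        truth_path = Path(truth_path)
        t_labels, t_body = _read_rows(truth_path)
        if t_labels != labels:
            raise ValueError(
                f"{truth_path}: item labels do not match {path} "
                f"({t_labels!r} vs {labels!r})"
            )
        if len(t_body) != 1:
            raise ValueError(f"{truth_path}: ground-truth file must have exactly one row")
        where = f"{truth_path} ground truth"
        r = _row_to_ranking(_cells_to_ints(t_body[0][1], where), representation, where)
        truth = ranking_to_ordering(Ranking(r))

    return RankingDataset(tuple(labels), tuple(ids), np.vstack(rows), truth)


def write_dataset(
    d: RankingDataset,
    path: PathLike,
    representation: str = "ordering",
    truth_path: Optional[PathLike] = None,
) -> None:
    """Write a dataset (and optionally its ground truth) in the given representation."""
    if representation not in ("ordering", "ranking"):
        raise ValueError(f"representation must be 'ordering' or 'ranking', got {representation!r}")
    path = Path(path)
    delim = _delimiter_for(path)

    def row_cells(ranking_row: np.ndarray) -> list[int]:
        if representation == "ranking":
            return (ranking_row + 1).tolist()
        return (np.argsort(ranking_row) + 1).tolist()

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["participant", *d.item_labels])
        for j, pid in enumerate(d.participant_ids):
            writer.writerow([pid, *row_cells(d.rankings[j])])

    if truth_path is not None:
        if d.truth is None:
            raise ValueError("dataset has no ground truth to write")
        truth_path = Path(truth_path)
        tdelim = _delimiter_for(truth_path)
        truth_ranking = ordering_to_ranking(d.truth).as_array()
        with open(truth_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=tdelim)
            writer.writerow(["participant", *d.item_labels])
            writer.writerow(["truth", *row_cells(truth_ranking)])
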