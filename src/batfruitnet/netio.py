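"""Data model, validation and file I/O for interaction matrices and metadata.

Matrix files are delimiter-separated (comma or tab, auto-detected), UTF-8,
with the first row holding plant labels and the first column holding animal
labels.  Orientation is fixed: rows are animals (bats), columns are plants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import DegenerateMatrixError, MatrixFormatError

Side = Literal["animal", "plant"]

FRUGIVORY_LEVELS = ("primary", "secondary", "occasional", "not_applicable")


@dataclass(frozen=True)
class InteractionMatrix:
    """A labeled non-negative animal x plant weight matrix.

    Parameters
    ----------
    animal_ids
        Row labels (bat species), unique.
    plant_ids
        Column labels (plant species), unique.
    weights
        ``A x P`` array of non-negative interaction weights (counts of fecal
        samples, or 0/1 presence).
    """

    animal_ids: tuple[str, ...]
    plant_ids: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "animal_ids", tuple(str(a) for a in self.animal_ids))
        object.__setattr__(self, "plant_ids", tuple(str(p) for p in self.plant_ids))
        object.__setattr__(self, "weights", w)
        if w.ndim != 2:
            raise MatrixFormatError(f"weights must be 2-D, got shape {w.shape}")
        if w.shape != (len(self.animal_ids), len(self.plant_ids)):
            raise MatrixFormatError(
                f"weights shape {w.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.plant_ids)} plants"
            )
        if np.any(w < 0):
            i, j = np.argwhere(w < 0)[0]
            raise MatrixFormatError(
                f"negative cell at row '{self.animal_ids[i]}', "
                f"column '{self.plant_ids[j]}': {w[i, j]}"
            )
        if not np.all(np.isfinite(w)):
            raise MatrixFormatError("non-finite cell value in matrix")
        for side, labels in (("animal", self.animal_ids), ("plant", self.plant_ids)):
            if len(set(labels)) != len(labels):
                seen: set[str] = set()
                dup = next(x for x in labels if x in seen or seen.add(x))
                raise MatrixFormatError(f"duplicate {side} label: '{dup}'")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.weights, (0.0, 1.0)).all())

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def presence(self) -> np.ndarray:
        """0/1 presence pattern as an integer array."""
        return (self.weights > 0).astype(int)

    def row_degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)

    def col_degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)

    def species_ids(self) -> tuple[str, ...]:
        """All labels, animals first then plants."""
        return self.animal_ids + self.plant_ids

    def side_of(self, species_id: str) -> Side:
        if species_id in self.animal_ids:
            return "animal"
        if species_id in self.plant_ids:
            return "plant"
        raise KeyError(f"species '{species_id}' not in matrix")

    def drop_species(self, species_id: str) -> "InteractionMatrix":
        """Matrix without one species (and its interactions). No other cleanup."""
        side = self.side_of(species_id)
        if side == "animal":
            keep = [i for i, a in enumerate(self.animal_ids) if a != species_id]
            return InteractionMatrix(
                tuple(self.animal_ids[i] for i in keep), self.plant_ids, self.weights[keep, :]
            )
        keep = [j for j, p in enumerate(self.plant_ids) if p != species_id]
        return InteractionMatrix(
            self.animal_ids, tuple(self.plant_ids[j] for j in keep), self.weights[:, keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.animal_ids), columns=list(self.plant_ids))


@dataclass(frozen=True)
class SpeciesMeta:
    """Per-species classification record.

    ``frugivory_level`` applies only to animals; plants carry
    ``"not_applicable"``.
    """

    species_id: str
    side: Side
    genus: str
    frugivory_level: str

    def __post_init__(self) -> None:
        if self.side not in ("animal", "plant"):
            raise MatrixFormatError(f"'{self.species_id}': side must be animal or plant, got '{self.side}'")
        if self.frugivory_level not in FRUGIVORY_LEVELS:
            raise MatrixFormatError(
                f"'{self.species_id}': unknown frugivory_level '{self.frugivory_level}' "
                f"(expected one of {FRUGIVORY_LEVELS})"
            )
        if self.side == "plant" and self.frugivory_level != "not_applicable":
            raise MatrixFormatError(
                f"plant '{self.species_id}' cannot have frugivory_level '{self.frugivory_level}'"
            )
        if self.side == "animal" and self.frugivory_level == "not_applicable":
            raise MatrixFormatError(
                f"animal '{self.species_id}' must have a frugivory_level (primary/secondary/occasional)"
            )


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    if "\t" in first:
        return "\t"
    return ","


def load_matrix(path: str | Path, delimiter: str | None = None) -> InteractionMatrix:
    """Read a labeled interaction matrix from a delimited text file.

    First row: plant labels (the top-left cell is ignored).  First column:
    animal labels.  Cells must parse as non-negative numbers.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if delimiter is None:
        delimiter = _sniff_delimiter(text)
    rows = [r for r in csv.reader(text.splitlines(), delimiter=delimiter) if r]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise MatrixFormatError(f"{path}: need at least one animal row and one plant column")
    plant_ids = [c.strip() for c in rows[0][1:]]
    animal_ids = []
    weights = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(plant_ids) + 1:
            raise MatrixFormatError(f"{path}: line {r} has {len(row)} fields, expected {len(plant_ids) + 1}")
        animal_ids.append(row[0].strip())
        vals = []
        for j, cell in enumerate(row[1:]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise MatrixFormatError(
                    f"{path}: cell at row '{row[0].strip()}', column '{plant_ids[j]}' "
                    f"is not a number: '{cell}'"
                ) from exc
            if v < 0:
                raise MatrixFormatError(
                    f"{path}: negative cell at row '{row[0].strip()}', column '{plant_ids[j]}': {cell}"
                )
            vals.append(v)
        weights.append(vals)
    return InteractionMatrix(tuple(animal_ids), tuple(plant_ids), np.array(weights, dtype=float))


def write_matrix(m: InteractionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix in the same labeled layout ``load_matrix`` reads.

    Integer-valued weights are written as integers so integer counts
    round-trip bit-exactly.
    """
    path = Path(path)
    integral = bool(np.all(m.weights == np.round(m.weights)))

    def fmt(v: float) -> str:
        return str(int(v)) if integral else repr(v)

    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["species", *m.plant_ids])
        for i, a in enumerate(m.animal_ids):
            writer.writerow([a, *(fmt(v) for v in m.weights[i])])


@dataclass
class ValidationReport:
    dropped_animals: list[str] = field(default_factory=list)
    dropped_plants: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_animals) + len(self.dropped_plants)


def validate_matrix(
    m: InteractionMatrix, drop_empty: bool = True
) -> tuple[InteractionMatrix, ValidationReport]:
    """Check structural invariants; optionally drop all-zero rows/columns.

    Returns the (possibly reduced) matrix plus a report naming dropped
    species.  Raises :class:`DegenerateMatrixError` if fewer than two
    animals or two plants remain.
    """
    report = ValidationReport()
    empty_rows = np.flatnonzero(m.weights.sum(axis=1) == 0)
    empty_cols = np.flatnonzero(m.weights.sum(axis=0) == 0)
    if (len(empty_rows) or len(empty_cols)) and not drop_empty:
        names = [m.animal_ids[i] for i in empty_rows] + [m.plant_ids[j] for j in empty_cols]
        raise MatrixFormatError(f"matrix has all-zero lines for: {', '.join(names)}")
    if len(empty_rows) or len(empty_cols):
        report.dropped_animals = [m.animal_ids[i] for i in empty_rows]
        report.dropped_plants = [m.plant_ids[j] for j in empty_cols]
        keep_r = [i for i in range(m.n_animals) if i not in set(empty_rows)]
        keep_c = [j for j in range(m.n_plants) if j not in set(empty_cols)]
        m = InteractionMatrix(
            tuple(m.animal_ids[i] for i in keep_r),
            tuple(m.plant_ids[j] for j in keep_c),
            m.weights[np.ix_(keep_r, keep_c)],
        )
    if m.n_animals < 2 or m.n_plants < 2:
        raise DegenerateMatrixError(
            f"matrix degenerate after validation: {m.n_animals} animals x {m.n_plants} plants "
            "(need at least 2 x 2)"
        )
    return m, report


def binarize(m: InteractionMatrix) -> InteractionMatrix:
    """Presence/absence version of the matrix (idempotent, labels preserved)."""
    return InteractionMatrix(m.animal_ids, m.plant_ids, (m.weights > 0).astype(float))


METADATA_COLUMNS = ("species_id", "side", "genus", "frugivory_level")


def load_metadata(path: str | Path) -> dict[str, SpeciesMeta]:
    """Read the tab-separated species metadata table, keyed by species_id."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MatrixFormatError(f"{path}: missing metadata column(s): {', '.join(missing)}")
    records: dict[str, SpeciesMeta] = {}
    for _, row in df.iterrows():
        rec = SpeciesMeta(
            species_id=str(row["species_id"]).strip(),
            side=str(row["side"]).strip(),
            genus=str(row["genus"]).strip(),
            frugivory_level=str(row["frugivory_level"]).strip(),
        )
        if rec.species_id in records:
            raise MatrixFormatError(f"{path}: duplicate species_id '{rec.species_id}'")
        records[rec.species_id] = rec
    return records


def write_metadata(meta: Iterable[SpeciesMeta] | dict[str, SpeciesMeta], path: str | Path) -> None:
    if isinstance(meta, dict):
        meta = meta.values()
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for rec in meta:
            writer.writerow([rec.species_id, rec.side, rec.genus, rec.frugivory_level])


def export_edge_list(m: InteractionMatrix, path: str | Path) -> int:
    """Write one tab-separated line per nonzero cell: animal, plant, weight.

    Returns the number of lines written (= number of nonzero cells).
    """
    integral = bool(np.all(m.weights == np.round(m.weights)))
    n = 0
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        for i, a in enumerate(m.animal_ids):
            for j, p in enumerate(m.plant_ids):
                w = m.weights[i, j]
                if w > 0:
                    out = str(int(w)) if integral else repr(w)
                    fh.write(f"{a}\t{p}\t{out}\n")
                    n += 1
    return n


def resolve_meta(m: InteractionMatrix, meta: dict[str, SpeciesMeta]) -> dict[str, SpeciesMeta]:
    """Check every matrix label resolves to exactly one metadata record."""
    missing = [s for s in m.species_ids() if s not in meta]
    if missing:
        raise MatrixFormatError(f"species without metadata record: {', '.join(missing[:10])}")
    out = {}
    for s in m.species_ids():
        rec = meta[s]
        expected = m.side_of(s)
        if rec.side != expected:
            raise MatrixFormatError(
                f"species '{s}' is a matrix {expected} but metadata says '{rec.side}'"
            )
        out[s] = rec
    return out
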