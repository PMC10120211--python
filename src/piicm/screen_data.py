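"""Screen tables, unit-box concentration scaling and stage-2 matrix assembly.

Long-format viability screens are read into per-experiment record groups,
each experiment is rescaled onto a common equispaced grid in the unit box,
and stage-1 latent summaries are packed into the ``Z``/``S`` response and
noise matrices used by the multi-output model, with reversed drug orderings
and unobserved experiments masked by dummy values.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ScreenFormatError",
    "ViabilityRecord",
    "ExperimentKey",
    "CommonGrid",
    "ConcentrationScaler",
    "Screen",
    "ScreenMatrices",
    "load_screen",
    "write_screen",
    "scale_to_common_grid",
    "extended_pair_ordering",
    "assemble_matrices",
]

CSV_COLUMNS = ["cell_line", "drug_a", "drug_b", "conc_a", "conc_b", "replicate", "viability"]

DEFAULT_Z0 = -999.0
DEFAULT_EPSILON = 1e-12


class ScreenFormatError(ValueError):
    """Raised when a screen table violates the expected CSV dialect."""


@dataclass(frozen=True)
class ViabilityRecord:
    """One viability measurement.

    Monotherapy rows carry exactly one drug/concentration; combination rows
    carry both.  Concentrations are on the log10 scale.
    """

    cell_line: str
    drug_a: str
    drug_b: str | None
    conc_a: float
    conc_b: float | None
    replicate: int
    viability: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if (self.drug_b is None) != (self.conc_b is None):
            raise ValueError("drug_b and conc_b must be both present or both absent")

    @property
    def is_monotherapy(self) -> bool:
        return self.drug_b is None


@dataclass(frozen=True, order=True)
class ExperimentKey:
    """Identity of one (cell line, drug pair) combination experiment."""

    cell_line: str
    drug_pair: tuple[str, str]

    @classmethod
    def canonical(cls, cell_line: str, drug_a: str, drug_b: str) -> "ExperimentKey":
        """Canonical key: the pair sorted lexicographically."""
        if drug_a == drug_b:
            raise ValueError(f"degenerate pair ({drug_a}, {drug_b})")
        pair = (drug_a, drug_b) if drug_a < drug_b else (drug_b, drug_a)
        return cls(cell_line=cell_line, drug_pair=pair)

    @property
    def is_canonical(self) -> bool:
        return self.drug_pair[0] < self.drug_pair[1]

    def reversed(self) -> "ExperimentKey":
        return ExperimentKey(self.cell_line, (self.drug_pair[1], self.drug_pair[0]))


@dataclass(frozen=True)
class CommonGrid:
    """Equispaced k x k Cartesian grid on the unit box.

    Grid indexing is row-major over (axis-1 concentration, axis-2
    concentration): point ``i`` is ``(X[i // k], X[i % k])`` with
    ``X = linspace(0, 1, k)``.  The grid is closed under the coordinate
    reflection ``(x1, x2) -> (x2, x1)``.
    """

    k: int
    points: np.ndarray = field(repr=False, compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"grid size k must be >= 2, got {self.k}")
        if self.points is None:
            axis = np.linspace(0.0, 1.0, self.k)
            pts = np.stack(np.meshgrid(axis, axis, indexing="ij"), axis=-1).reshape(-1, 2)
            object.__setattr__(self, "points", pts)

    @property
    def n(self) -> int:
        return self.k * self.k

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.k)

    def reflection_index(self) -> np.ndarray:
        """Index map r with points[r[i]] == reflected points[i]; an involution."""
        k = self.k
        i1, i2 = np.divmod(np.arange(self.n), k)
        return i2 * k + i1


@dataclass(frozen=True)
class ConcentrationScaler:
    """Per-experiment affine maps from log10 concentrations to the unit box."""

    lo: tuple[float, float]
    hi: tuple[float, float]

    def __post_init__(self) -> None:
        for axis in (0, 1):
            if not self.hi[axis] > self.lo[axis]:
                raise ValueError(
                    f"degenerate concentration range on axis {axis}: "
                    f"[{self.lo[axis]}, {self.hi[axis]}]"
                )

    def forward(self, conc: np.ndarray) -> np.ndarray:
        """Map (n, 2) log10 concentrations into [0, 1]^2."""
        conc = np.asarray(conc, dtype=float)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return (conc - lo) / (hi - lo)

    def inverse(self, unit: np.ndarray) -> np.ndarray:
        unit = np.asarray(unit, dtype=float)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return lo + unit * (hi - lo)


@dataclass
class Screen:
    """Viability records grouped by canonical experiment key.

    ``combinations`` maps each canonical :class:`ExperimentKey` to its
    combination records (concentrations stored in canonical drug order);
    ``monotherapies`` maps ``(cell_line, drug)`` to single-drug records.
    """

    combinations: dict[ExperimentKey, list[ViabilityRecord]] = field(default_factory=dict)
    monotherapies: dict[tuple[str, str], list[ViabilityRecord]] = field(default_factory=dict)

    def add(self, rec: ViabilityRecord) -> None:
        if rec.is_monotherapy:
            self.monotherapies.setdefault((rec.cell_line, rec.drug_a), []).append(rec)
            return
        key = ExperimentKey.canonical(rec.cell_line, rec.drug_a, rec.drug_b)
        if rec.drug_a != key.drug_pair[0]:
            rec = ViabilityRecord(
                cell_line=rec.cell_line,
                drug_a=rec.drug_b,
                drug_b=rec.drug_a,
                conc_a=rec.conc_b,
                conc_b=rec.conc_a,
                replicate=rec.replicate,
                viability=rec.viability,
            )
        self.combinations.setdefault(key, []).append(rec)

    @property
    def cell_lines(self) -> list[str]:
        cells = {k.cell_line for k in self.combinations}
        cells.update(c for c, _ in self.monotherapies)
        return sorted(cells)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted({k.drug_pair for k in self.combinations})

    def records(self) -> list[ViabilityRecord]:
        out: list[ViabilityRecord] = []
        for recs in self.combinations.values():
            out.extend(recs)
        for recs in self.monotherapies.values():
            out.extend(recs)
        return out

    def monotherapy_for(self, cell_line: str, drug: str) -> list[ViabilityRecord]:
        return self.monotherapies.get((cell_line, drug), [])


def _parse_row(row: Mapping[str, str], line_no: int, raw_molar: bool) -> ViabilityRecord:
    def _num(col: str) -> float:
        try:
            return float(row[col])
        except (TypeError, ValueError):
            raise ScreenFormatError(
                f"line {line_no}: column {col!r} is non-numeric: {row[col]!r}"
            ) from None

    drug_b = row["drug_b"].strip() or None
    conc_a = _num("conc_a")
    conc_b = _num("conc_b") if drug_b is not None else None
    if raw_molar:
        if conc_a <= 0 or (conc_b is not None and conc_b <= 0):
            raise ScreenFormatError(f"line {line_no}: raw concentrations must be positive")
        conc_a = float(np.log10(conc_a))
        conc_b = None if conc_b is None else float(np.log10(conc_b))
    try:
        replicate = int(row["replicate"])
    except (TypeError, ValueError):
        raise ScreenFormatError(
            f"line {line_no}: column 'replicate' is non-numeric: {row['replicate']!r}"
        ) from None
    return ViabilityRecord(
        cell_line=row["cell_line"].strip(),
        drug_a=row["drug_a"].strip(),
        drug_b=drug_b,
        conc_a=conc_a,
        conc_b=conc_b,
        replicate=replicate,
        viability=_num("viability"),
    )


def load_screen(path, raw_molar: bool = False) -> Screen:
    """Read a long-format CSV screen table.

    Blank ``drug_b`` denotes monotherapy.  Concentrations are expected on the
    log10 scale unless ``raw_molar`` is set, in which case they are converted.
    Combination records are stored under their canonical (lexicographic) key
    with concentrations swapped accordingly.
    """
    screen = Screen()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return screen
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ScreenFormatError(f"missing required columns: {missing}")
        for line_no, row in enumerate(reader, start=2):
            screen.add(_parse_row(row, line_no, raw_molar))
    return screen


def write_screen(screen: Screen, path) -> None:
    """Write a screen back to the CSV dialect read by :func:`load_screen`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in screen.records():
            writer.writerow(
                [
                    rec.cell_line,
                    rec.drug_a,
                    rec.drug_b or "",
                    repr(rec.conc_a),
                    "" if rec.conc_b is None else repr(rec.conc_b),
                    rec.replicate,
                    repr(rec.viability),
                ]
            )


def scale_to_common_grid(
    records: Sequence[ViabilityRecord], k: int
) -> tuple[ConcentrationScaler, CommonGrid]:
    """Affine maps sending each drug's observed log-concentration range to [0, 1].

    The range is taken over the combination records of one experiment; the
    returned scaler stores the inverse map so predictions can be reported on
    the original concentration scale.
    """
    combos = [r for r in records if not r.is_monotherapy]
    if not combos:
        raise ValueError("no combination records to scale")
    conc = np.array([[r.conc_a, r.conc_b] for r in combos], dtype=float)
    lo = conc.min(axis=0)
    hi = conc.max(axis=0)
    scaler = ConcentrationScaler(lo=(lo[0], lo[1]), hi=(hi[0], hi[1]))
    return scaler, CommonGrid(k=k)


def extended_pair_ordering(pairs: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    """Canonical pairs sorted alphabetically, then all reversed pairs in the
    same order — the 2*N_d layout of the drug-combination covariance."""
    canonical = sorted(set(pairs))
    for a, b in canonical:
        if not a < b:
            raise ValueError(f"pair {(a, b)} is not in canonical (lexicographic) order")
    return canonical + [(b, a) for a, b in canonical]


@dataclass
class ScreenMatrices:
    """Stage-2 response/noise matrices with ordering metadata and mask.

    ``Z`` and ``S`` are n x (N_c * 2 N_d); column blocks are cell-line-major
    and pair-minor, with canonical pairs first and reversed pairs second
    within each block.  Masked entries (reversed orderings and unobserved
    experiments) hold ``Z = z0`` and ``S = 1/epsilon``.
    """

    Z: np.ndarray
    S: np.ndarray
    mask: np.ndarray  # True where observed
    cell_lines: list[str]
    extended_pairs: list[tuple[str, str]]
    grid: CommonGrid
    z0: float = DEFAULT_Z0
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        n = self.grid.n
        cols = len(self.cell_lines) * len(self.extended_pairs)
        for name, arr in (("Z", self.Z), ("S", self.S), ("mask", self.mask)):
            if arr.shape != (n, cols):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, cols)}")

    @property
    def n(self) -> int:
        return self.grid.n

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)

    @property
    def n_extended_pairs(self) -> int:
        return len(self.extended_pairs)

    @property
    def M(self) -> int:
        """Number of observed entries."""
        return int(self.mask.sum())

    @property
    def N(self) -> int:
        """Total number of entries (observed + dummies)."""
        return int(self.mask.size)

    def column_index(self, key: ExperimentKey) -> int:
        try:
            c = self.cell_lines.index(key.cell_line)
        except ValueError:
            raise KeyError(f"unknown cell line {key.cell_line!r}") from None
        try:
            d = self.extended_pairs.index(key.drug_pair)
        except ValueError:
            raise KeyError(f"unknown drug pair {key.drug_pair!r}") from None
        return c * len(self.extended_pairs) + d

    def vec_Z(self) -> np.ndarray:
        """Column-stacked Z; index layout (cell line, pair, grid point)."""
        return np.ravel(self.Z, order="F")

    def vec_S(self) -> np.ndarray:
        return np.ravel(self.S, order="F")

    def vec_mask(self) -> np.ndarray:
        return np.ravel(self.mask, order="F")

    def with_mask(self, observed_keys: Iterable[ExperimentKey]) -> "ScreenMatrices":
        """Copy with only ``observed_keys`` unmasked (e.g. for hold-out)."""
        keep = {k for k in observed_keys}
        Z = np.full_like(self.Z, self.z0)
        S = np.full_like(self.S, 1.0 / self.epsilon)
        mask = np.zeros_like(self.mask)
        for key in keep:
            j = self.column_index(key)
            if not self.mask[:, j].all():
                raise KeyError(f"experiment {key} is not observed in the source matrices")
            Z[:, j] = self.Z[:, j]
            S[:, j] = self.S[:, j]
            mask[:, j] = True
        return ScreenMatrices(
            Z=Z, S=S, mask=mask, cell_lines=list(self.cell_lines),
            extended_pairs=list(self.extended_pairs), grid=self.grid,
            z0=self.z0, epsilon=self.epsilon,
        )


def assemble_matrices(
    summaries: Mapping[ExperimentKey, object],
    cell_lines: Sequence[str],
    pairs: Sequence[tuple[str, str]],
    grid: CommonGrid,
    z0: float = DEFAULT_Z0,
    epsilon: float = DEFAULT_EPSILON,
) -> ScreenMatrices:
    """Pack stage-1 latent summaries into masked ``Z``/``S`` matrices.

    ``summaries`` maps canonical keys to objects exposing ``z_mean`` and
    ``z_var`` vectors of length ``grid.n``.  Reversed-order columns and
    experiments without a summary are filled with the dummies
    ``(z0, 1/epsilon)`` and masked.
    """
    cell_lines = list(cell_lines)
    extended = extended_pair_ordering(pairs)
    n = grid.n
    cols = len(cell_lines) * len(extended)
    Z = np.full((n, cols), z0, dtype=float)
    S = np.full((n, cols), 1.0 / epsilon, dtype=float)
    mask = np.zeros((n, cols), dtype=bool)
    out = ScreenMatrices(
        Z=Z, S=S, mask=mask, cell_lines=cell_lines, extended_pairs=extended,
        grid=grid, z0=z0, epsilon=epsilon,
    )
    seen: set[ExperimentKey] = set()
    for key, summary in summaries.items():
        if not key.is_canonical:
            raise ValueError(f"summary key {key} is not canonical")
        if key in seen:
            raise ValueError(f"duplicate summary for {key}")
        seen.add(key)
        z_mean = np.asarray(summary.z_mean, dtype=float)
        z_var = np.asarray(summary.z_var, dtype=float)
        if z_mean.shape != (n,) or z_var.shape != (n,):
            raise ValueError(
                f"summary for {key} has length {z_mean.shape}/{z_var.shape}, expected ({n},)"
            )
        j = out.column_index(key)
        Z[:, j] = z_mean
        S[:, j] = z_var
        mask[:, j] = True
    return out
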