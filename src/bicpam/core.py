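"""Shared domain types and I/O for expression matrices and bicluster solutions.

The package works on real-valued matrices with rows as genes (or other
molecular units) and columns as conditions/samples.  Missing entries are
carried as NaN internally (``MISSING``); an optional outlier mask excludes
cells from mean/dispersion computations without removing them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Sentinel for missing cells.  Stored as NaN inside the value array; use
#: :func:`is_missing` rather than ``==`` comparisons.
MISSING = float("nan")

DEFAULT_MISSING_MARKERS = frozenset({"", "NA", "NaN", "?"})


def is_missing(x) -> np.ndarray | bool:
    """True where ``x`` is the MISSING sentinel (NaN)."""
    return np.isnan(x)


class MatrixParseError(ValueError):
    """Raised when a TSV matrix file is malformed."""


@dataclass
class ExpressionMatrix:
    """A real-valued ``n x m`` matrix with missing values and an outlier mask.

    Parameters
    ----------
    values
        Float array of shape ``(n, m)``; NaN encodes MISSING.
    row_ids, col_ids
        Unique string identifiers per axis.
    outlier_mask
        Boolean array, True for cells excluded from mean/dispersion
        computations (they keep their values).
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    outlier_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        n, m = self.values.shape
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(self.row_ids) != n or len(self.col_ids) != m:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.row_ids)) != n or len(set(self.col_ids)) != m:
            raise ValueError("row/column ids must be unique")
        if self.outlier_mask is None:
            self.outlier_mask = np.zeros((n, m), dtype=bool)
        else:
            self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
            if self.outlier_mask.shape != (n, m):
                raise ValueError("outlier_mask shape mismatch")
        bad = np.isinf(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"non-finite value at cell ({i},{j})")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def observed_mask(self) -> np.ndarray:
        """Cells usable for statistics: neither missing nor outlier-masked."""
        return ~self.missing_mask & ~self.outlier_mask

    def value_range(self) -> float:
        obs = self.values[self.observed_mask]
        if obs.size == 0:
            return 0.0
        return float(obs.max() - obs.min())

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.row_ids), list(self.col_ids),
            self.outlier_mask.copy(),
        )


def transpose(mx: ExpressionMatrix) -> ExpressionMatrix:
    """Swap rows and columns (an involution; masks follow the values)."""
    return ExpressionMatrix(
        mx.values.T.copy(), list(mx.col_ids), list(mx.row_ids),
        mx.outlier_mask.T.copy(),
    )


def read_matrix(path, missing_markers: Iterable[str] = DEFAULT_MISSING_MARKERS) -> ExpressionMatrix:
    """Read a TSV matrix: header row of column ids, first field per data row
    is the row id.  Cells matching ``missing_markers`` become MISSING."""
    markers = set(missing_markers)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixParseError(f"{path}: empty file")
        col_ids = header.split("\t")[1:]
        m = len(col_ids)
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != m + 1:
                raise MatrixParseError(
                    f"{path}: line {lineno} has {len(fields) - 1} values, expected {m}"
                )
            row_ids.append(fields[0])
            vals = []
            for j, tok in enumerate(fields[1:]):
                if tok in markers:
                    vals.append(MISSING)
                else:
                    try:
                        v = float(tok)
                    except ValueError:
                        raise MatrixParseError(
                            f"{path}: cell ({fields[0]}, {col_ids[j]}) on line "
                            f"{lineno}: cannot parse {tok!r} as a number"
                        ) from None
                    if math.isnan(v):
                        v = MISSING
                    vals.append(v)
            rows.append(vals)
    return ExpressionMatrix(np.array(rows, dtype=float), row_ids, col_ids)


def write_matrix(mx: ExpressionMatrix, path, missing_marker: str = "NA") -> None:
    """Write a TSV matrix in the format accepted by :func:`read_matrix`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["id"] + list(mx.col_ids)) + "\n")
        for i, rid in enumerate(mx.row_ids):
            toks = [rid]
            for v in mx.values[i]:
                toks.append(missing_marker if math.isnan(v) else repr(float(v)))
            fh.write("\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# Biclusters

#: Recognised coherency labels.  ``symmetric+<base>`` composes row signs with
#: a base coherency.
COHERENCIES = (
    "constant_rows", "constant_cols", "constant_overall",
    "additive", "multiplicative",
    "symmetric+constant", "symmetric+additive", "symmetric+multiplicative",
)


@dataclass(frozen=True)
class Bicluster:
    """A submatrix (row set I, column set J) with a coherency model.

    ``profile`` is the per-column symbol pattern for row-coherent biclusters.
    ``model_params`` carries per-row adjustments (offsets, factors or signs)
    recorded by the alignment that discovered the bicluster, enabling
    reconstruction of the itemized cell values.
    """

    rows: tuple[int, ...]
    cols: tuple[int, ...]
    coherency: str = "constant_rows"
    profile: tuple | None = None
    model_params: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(sorted(set(int(r) for r in self.rows))))
        object.__setattr__(self, "cols", tuple(sorted(set(int(c) for c in self.cols))))
        if self.profile is not None:
            object.__setattr__(self, "profile", tuple(self.profile))

    @property
    def area(self) -> int:
        return len(self.rows) * len(self.cols)

    @property
    def row_set(self) -> frozenset:
        cached = self.__dict__.get("_row_set")
        if cached is None:
            cached = frozenset(self.rows)
            object.__setattr__(self, "_row_set", cached)
        return cached

    @property
    def col_set(self) -> frozenset:
        cached = self.__dict__.get("_col_set")
        if cached is None:
            cached = frozenset(self.cols)
            object.__setattr__(self, "_col_set", cached)
        return cached

    def key(self) -> tuple:
        return (self.rows, self.cols)


def validate_bicluster(bic: Bicluster, n: int, m: int) -> None:
    """Check the shared type invariants; raise ValueError on violation."""
    if not bic.rows or not bic.cols:
        raise ValueError("bicluster must have non-empty rows and cols")
    if bic.rows[0] < 0 or bic.rows[-1] >= n:
        raise ValueError(f"row indices out of range 0..{n - 1}")
    if bic.cols[0] < 0 or bic.cols[-1] >= m:
        raise ValueError(f"col indices out of range 0..{m - 1}")
    if bic.coherency not in COHERENCIES:
        raise ValueError(f"unknown coherency {bic.coherency!r}")
    if bic.coherency == "constant_rows" and bic.profile is not None:
        if len(bic.profile) != len(bic.cols):
            raise ValueError("constant_rows profile length must equal |cols|")


@dataclass
class BiclusteringSolution:
    """A list of biclusters plus the full parameter record that produced it."""

    biclusters: list[Bicluster] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def validate(self, n: int, m: int) -> None:
        seen = set()
        for b in self.biclusters:
            validate_bicluster(b, n, m)
            if b.key() in seen:
                raise ValueError(f"duplicate bicluster {b.key()}")
            seen.add(b.key())


def _profile_to_json(profile):
    if profile is None:
        return None
    return [p if isinstance(p, (int, float, str)) else list(p) for p in profile]


def solution_to_dict(sol: BiclusteringSolution,
                     row_ids: Sequence[str] | None = None,
                     col_ids: Sequence[str] | None = None) -> dict:
    """Serializable form; indices are mapped to ids when ids are given."""
    def rid(i):
        return row_ids[i] if row_ids is not None else i

    def cid(j):
        return col_ids[j] if col_ids is not None else j

    recs = []
    for b in sol.biclusters:
        recs.append({
            "rows": [rid(i) for i in b.rows],
            "cols": [cid(j) for j in b.cols],
            "coherency": b.coherency,
            "profile": _profile_to_json(b.profile),
            "model_params": b.model_params,
        })
    return {"biclusters": recs, "provenance": sol.provenance}


def solution_from_dict(doc: dict,
                       row_ids: Sequence[str] | None = None,
                       col_ids: Sequence[str] | None = None) -> BiclusteringSolution:
    row_index = {r: i for i, r in enumerate(row_ids)} if row_ids is not None else None
    col_index = {c: j for j, c in enumerate(col_ids)} if col_ids is not None else None

    def ridx(r):
        if row_index is not None:
            return row_index[str(r)]
        return int(r)

    def cidx(c):
        if col_index is not None:
            return col_index[str(c)]
        return int(c)

    bics = []
    for rec in doc.get("biclusters", []):
        bics.append(Bicluster(
            rows=tuple(ridx(r) for r in rec["rows"]),
            cols=tuple(cidx(c) for c in rec["cols"]),
            coherency=rec.get("coherency", "constant_rows"),
            profile=tuple(rec["profile"]) if rec.get("profile") is not None else None,
            model_params=rec.get("model_params"),
        ))
    return BiclusteringSolution(bics, dict(doc.get("provenance", {})))


def write_solution(sol: BiclusteringSolution, path,
                   row_ids: Sequence[str] | None = None,
                   col_ids: Sequence[str] | None = None) -> None:
    """Write a solution as JSON.  Reading it back reproduces the solution."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(solution_to_dict(sol, row_ids, col_ids), fh, indent=1)


def read_solution(path,
                  row_ids: Sequence[str] | None = None,
                  col_ids: Sequence[str] | None = None) -> BiclusteringSolution:
    with open(path, "r", encoding="utf-8") as fh:
        return solution_from_dict(json.load(fh), row_ids, col_ids)
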