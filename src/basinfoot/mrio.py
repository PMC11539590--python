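"""Multi-basin input-output core: data model, coefficients, inverses, balance.

The economy is a set of ``m`` river basins, each hosting the same list of
``c`` sectors.  All matrices share a single basin-major, sector-minor
flattening of the (basin, sector) index: position ``b * c + s`` holds basin
``b``'s sector ``s``.  The intermediate-transaction matrix ``Z`` records
purchases of column basin-sectors from row basin-sectors; final demand ``Y``
has one column per consuming basin plus a trailing international-exports
column; primary inputs ``V`` have one row per value-added category plus a
trailing international-imports row.  Gross output ``X`` closes both the row
identity (X = Z·1 + Y·1) and the column identity (X = 1ᵀZ + 1ᵀV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("basinfoot")

#: Label used for the international-exports final-demand column and the
#: international-imports primary-input row.
ABROAD = "abroad"

#: Default relative tolerance for row/column balance validation.
BALANCE_TOL = 1e-8

#: Default tolerance for row-stochastic normalisation checks.
NORMALIZATION_TOL = 1e-10


class BasinfootError(Exception):
    """Base class for all package errors."""


class StructuralError(BasinfootError):
    """Dimension or labelling mismatch among table components."""


class BalanceError(BasinfootError):
    """Row/column balance identity violated beyond tolerance."""


class NonProductiveEconomyError(BasinfootError):
    """Spectral radius of a coefficient matrix is >= 1."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MRIOTable:
    """A balanced multi-basin input-output table.

    Parameters
    ----------
    basins
        Ordered basin identifiers (length ``m``).
    sectors
        Ordered sector identifiers (length ``c``), shared by every basin.
    Z
        Intermediate transactions, shape ``(m·c, m·c)``, currency units.
    Y
        Final demand, shape ``(m·c, m+1)``; the last column is international
        exports.
    V
        Primary inputs, shape ``(p+1, m·c)``; the last row is international
        imports.
    X
        Gross output, length ``m·c``.
    primary_inputs
        Ordered labels of the ``p`` value-added categories (the imports row
        is appended implicitly and labelled ``"abroad"``).
    """

    basins: tuple[str, ...]
    sectors: tuple[str, ...]
    Z: np.ndarray
    Y: np.ndarray
    V: np.ndarray
    X: np.ndarray
    primary_inputs: tuple[str, ...] = ("value_added",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "basins", tuple(self.basins))
        object.__setattr__(self, "sectors", tuple(self.sectors))
        object.__setattr__(self, "primary_inputs", tuple(self.primary_inputs))
        for name in ("Z", "Y", "V", "X"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        m, c, n = self.m, self.c, self.n
        if m == 0 or c == 0:
            raise StructuralError("empty table: need at least one basin and one sector")
        if self.Z.shape != (n, n):
            raise StructuralError(f"Z has shape {self.Z.shape}, expected {(n, n)}")
        if self.Y.shape != (n, m + 1):
            raise StructuralError(f"Y has shape {self.Y.shape}, expected {(n, m + 1)}")
        if self.V.shape[1] != n or self.V.shape[0] < 2:
            raise StructuralError(
                f"V has shape {self.V.shape}, expected (p+1>=2, {n})"
            )
        if self.X.shape != (n,):
            raise StructuralError(f"X has shape {self.X.shape}, expected {(n,)}")
        if len(self.primary_inputs) != self.V.shape[0] - 1:
            raise StructuralError(
                "primary_inputs must label all V rows except the imports row"
            )

    # -- layout helpers ----------------------------------------------------

    @property
    def m(self) -> int:
        return len(self.basins)

    @property
    def c(self) -> int:
        return len(self.sectors)

    @property
    def n(self) -> int:
        return self.m * self.c

    @property
    def consumers(self) -> tuple[str, ...]:
        """Final-demand column labels: basins then the export column."""
        return self.basins + (ABROAD,)

    @property
    def suppliers(self) -> tuple[str, ...]:
        """Primary-input supplier labels: basins then the imports row."""
        return self.basins + (ABROAD,)

    def index(self, basin: str, sector: str) -> int:
        """Flat position of ``(basin, sector)`` under basin-major ordering."""
        try:
            b = self.basins.index(basin)
            s = self.sectors.index(sector)
        except ValueError as exc:
            raise KeyError(f"unknown basin/sector {(basin, sector)}") from exc
        return b * self.c + s

    def basin_slice(self, basin: str) -> slice:
        """Column/row slice covering one basin's sector block."""
        try:
            b = self.basins.index(basin)
        except ValueError as exc:
            raise KeyError(f"unknown basin {basin!r}") from exc
        return slice(b * self.c, (b + 1) * self.c)

    def row_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_product(
            [self.basins, self.sectors], names=["basin", "sector"]
        )

    def y_total(self) -> np.ndarray:
        """Total final demand per basin-sector (row sums of Y)."""
        return self.Y.sum(axis=1)

    def v_total(self) -> np.ndarray:
        """Total primary input per basin-sector (column sums of V)."""
        return self.V.sum(axis=0)

    def basin_sums(self, values: np.ndarray) -> np.ndarray:
        """Sum a length-n basin-sector vector into per-basin totals."""
        return np.asarray(values, dtype=float).reshape(self.m, self.c).sum(axis=1)

    def supplier_matrix(self) -> np.ndarray:
        """Primary inputs split by supplying basin, shape ``(m+1, n)``.

        Domestic value added is supplied by the basin where production takes
        place, so row ``b`` carries the value-added column sums restricted to
        basin ``b``'s block; the last row is the international-imports row.
        """
        va = self.V[:-1, :].sum(axis=0)
        out = np.zeros((self.m + 1, self.n))
        for b in range(self.m):
            sl = slice(b * self.c, (b + 1) * self.c)
            out[b, sl] = va[sl]
        out[self.m, :] = self.V[-1, :]
        return out


@dataclass
class BalanceReport:
    """Per-basin-sector balance gaps and the validation verdict."""

    row_gaps: np.ndarray
    col_gaps: np.ndarray
    tol: float
    labels: pd.MultiIndex

    @property
    def max_gap(self) -> float:
        return float(max(self.row_gaps.max(initial=0.0), self.col_gaps.max(initial=0.0)))

    @property
    def passed(self) -> bool:
        return self.max_gap <= self.tol

    def worst(self) -> tuple[str, tuple[str, str], float]:
        """(axis, (basin, sector), relative gap) of the worst offender."""
        if self.row_gaps.max(initial=0.0) >= self.col_gaps.max(initial=0.0):
            i = int(np.argmax(self.row_gaps))
            return "row", tuple(self.labels[i]), float(self.row_gaps[i])
        i = int(np.argmax(self.col_gaps))
        return "column", tuple(self.labels[i]), float(self.col_gaps[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"row_gap": self.row_gaps, "col_gap": self.col_gaps}, index=self.labels
        )


def validate_balance(table: MRIOTable, tol: float = BALANCE_TOL) -> BalanceReport:
    """Check the row and column accounting identities of a table.

    Relative gaps are measured against ``max(X[t], 1)`` so zero-output
    basin-sectors are held to an absolute standard.
    """
    denom = np.maximum(np.abs(table.X), 1.0)
    row_gap = np.abs(table.X - table.Z.sum(axis=1) - table.Y.sum(axis=1)) / denom
    col_gap = np.abs(table.X - table.Z.sum(axis=0) - table.V.sum(axis=0)) / denom
    report = BalanceReport(row_gap, col_gap, tol, table.row_index())
    logger.info(
        "balance check: max relative gap %.3e (tol %.1e) -> %s",
        report.max_gap,
        tol,
        "pass" if report.passed else "FAIL",
    )
    return report


def require_balanced(table: MRIOTable, tol: float = BALANCE_TOL) -> None:
    report = validate_balance(table, tol)
    if not report.passed:
        axis, (basin, sector), gap = report.worst()
        raise BalanceError(
            f"table unbalanced: worst {axis} gap {gap:.3e} at "
            f"({basin}, {sector}), tolerance {tol:.1e}"
        )


# ---------------------------------------------------------------------------
# coefficients and inverses
# ---------------------------------------------------------------------------


@dataclass
class CoefficientMatrices:
    """Technical (A) and allocation (B) coefficients with optional inverses."""

    A: np.ndarray
    Balloc: np.ndarray
    L: np.ndarray | None = None
    G: np.ndarray | None = None


def spectral_radius(A: np.ndarray) -> float:
    """Perron root of a square (here non-negative) matrix.

    Dense eigenvalues for small systems; power iteration for large ones,
    where the non-negativity of coefficient matrices makes it reliable.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n <= 600:
        return float(np.max(np.abs(np.linalg.eigvals(A)))) if n else 0.0
    x = np.full(n, 1.0 / n)
    rho = 0.0
    for _ in range(1000):
        y = A @ x
        nrm = np.linalg.norm(y)
        if nrm == 0.0:
            return 0.0
        y /= nrm
        rho_new = float(y @ (A @ y) / (y @ y))
        if abs(rho_new - rho) <= 1e-12 * max(1.0, abs(rho_new)):
            return rho_new
        rho, x = rho_new, y
    return rho


def technical_coefficients(
    table: MRIOTable, tol: float = BALANCE_TOL
) -> CoefficientMatrices:
    """A = Z·X̂⁻¹ (inputs per unit output) and B = X̂⁻¹·Z (outputs per unit input).

    Zero-output basin-sectors yield an all-zero A column and B row, keeping
    the inverses finite.
    """
    require_balanced(table, tol)
    inv_x = np.where(table.X > 0, 1.0 / np.where(table.X > 0, table.X, 1.0), 0.0)
    A = table.Z * inv_x[np.newaxis, :]
    Balloc = table.Z * inv_x[:, np.newaxis]
    return CoefficientMatrices(A=A, Balloc=Balloc)


def leontief_inverse(A: np.ndarray) -> np.ndarray:
    """(I − A)⁻¹, the total-requirements matrix of the demand-driven model."""
    A = np.asarray(A, dtype=float)
    rho = spectral_radius(A)
    if rho >= 1.0:
        raise NonProductiveEconomyError(
            f"technical-coefficient matrix has spectral radius {rho:.4f} >= 1"
        )
    eye = np.eye(A.shape[0])
    return np.linalg.solve(eye - A, eye)


def ghosh_inverse(Balloc: np.ndarray) -> np.ndarray:
    """(I − B)⁻¹, the total-allocation matrix of the supply-driven model."""
    Balloc = np.asarray(Balloc, dtype=float)
    rho = spectral_radius(Balloc)
    if rho >= 1.0:
        raise NonProductiveEconomyError(
            f"allocation-coefficient matrix has spectral radius {rho:.4f} >= 1"
        )
    eye = np.eye(Balloc.shape[0])
    return np.linalg.solve(eye - Balloc, eye)


def coefficient_system(table: MRIOTable, tol: float = BALANCE_TOL) -> CoefficientMatrices:
    """Coefficients plus both inverses in one call."""
    coef = technical_coefficients(table, tol)
    coef.L = leontief_inverse(coef.A)
    coef.G = ghosh_inverse(coef.Balloc)
    return coef


# ---------------------------------------------------------------------------
# CSV exchange format
# ---------------------------------------------------------------------------

_METADATA_FILE = "metadata.yaml"


def save_table(table: MRIOTable, directory: str | Path) -> None:
    """Write a table as Z.csv / Y.csv / V.csv plus a metadata file.

    Z carries two header rows and two index columns (basin, sector); Y has
    consuming-basin columns plus the export column; V has primary-input rows
    plus the imports row.  X is derived on load and cross-checked, not stored.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    idx = table.row_index()
    pd.DataFrame(table.Z, index=idx, columns=idx).to_csv(directory / "Z.csv")
    pd.DataFrame(table.Y, index=idx, columns=list(table.consumers)).to_csv(
        directory / "Y.csv"
    )
    pd.DataFrame(
        table.V, index=list(table.primary_inputs) + [ABROAD], columns=idx
    ).to_csv(directory / "V.csv")
    meta = {
        "basins": list(table.basins),
        "sectors": list(table.sectors),
        "primary_inputs": list(table.primary_inputs),
        "currency": "currency-unit",
        "year": None,
    }
    (directory / _METADATA_FILE).write_text(yaml.safe_dump(meta, sort_keys=False))


def load_table(directory: str | Path, tol: float = BALANCE_TOL) -> MRIOTable:
    """Read a table written by :func:`save_table` and validate its balance.

    Negative final-demand entries (inventory drawdown) are accepted as long
    as every Y column sum stays non-negative.
    """
    directory = Path(directory)
    meta = yaml.safe_load((directory / _METADATA_FILE).read_text())
    basins = [str(b) for b in meta["basins"]]
    sectors = [str(s) for s in meta["sectors"]]
    primary = [str(p) for p in meta["primary_inputs"]]
    Z = pd.read_csv(directory / "Z.csv", header=[0, 1], index_col=[0, 1])
    Y = pd.read_csv(directory / "Y.csv", header=0, index_col=[0, 1])
    V = pd.read_csv(directory / "V.csv", header=[0, 1], index_col=0)
    expected = pd.MultiIndex.from_product([basins, sectors])
    for name, got in (("Z rows", Z.index), ("Y rows", Y.index), ("Z cols", Z.columns),
                      ("V cols", V.columns)):
        if list(got) != list(expected):
            raise StructuralError(f"{name} do not match metadata basin/sector order")
    Zv, Yv, Vv = Z.to_numpy(float), Y.to_numpy(float), V.to_numpy(float)
    if np.any(Zv < 0) or np.any(Vv < 0):
        raise StructuralError("Z and V must be non-negative")
    if np.any(Yv.sum(axis=0) < -tol * max(1.0, float(np.abs(Yv).sum()))):
        raise StructuralError("negative final-demand column sum")
    X = Zv.sum(axis=1) + Yv.sum(axis=1)
    table = MRIOTable(
        basins=tuple(basins), sectors=tuple(sectors),
        Z=Zv, Y=Yv, V=Vv, X=X, primary_inputs=tuple(primary),
    )
    require_balanced(table, tol)
    return table
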