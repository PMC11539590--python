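"""Counterfactual trade regimes: no-trade, adjacent-only, distant-only.

A scenario removes a set of interbasin trade links and assumes each basin
produces, with its own technology, the goods it formerly imported over the
removed links: disallowed import coefficients are folded into the importing
basin's domestic block, and disallowed final-demand imports are reassigned
to the importer's own supply of the same commodity.  Gross output is then
re-solved from the substituted Leontief system and threats are re-attributed
with the baseline per-unit intensities, so the comparison isolates the
relocation of production, not any change in threat technology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mrio import (
    BasinfootError,
    MRIOTable,
    StructuralError,
    ghosh_inverse,
    leontief_inverse,
    spectral_radius,
    technical_coefficients,
)
from .satellite import IntensityMatrix

logger = logging.getLogger("basinfoot")

SCENARIO_MODES = ("full", "no_trade", "adjacent_only", "distant_only")


class ScenarioError(BasinfootError):
    """Infeasible or ill-specified counterfactual."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencyMap:
    """Symmetric, irreflexive land-boundary relation between basins."""

    basins: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "basins", tuple(self.basins))
        mat = np.asarray(self.matrix, dtype=bool)
        m = len(self.basins)
        if mat.shape != (m, m):
            raise StructuralError(f"adjacency has shape {mat.shape}, expected {(m, m)}")
        if not np.array_equal(mat, mat.T):
            raise StructuralError("adjacency must be symmetric")
        if np.any(np.diag(mat)):
            raise StructuralError("adjacency must be irreflexive (no self-loops)")
        object.__setattr__(self, "matrix", mat)

    @classmethod
    def from_edges(
        cls, basins: tuple[str, ...], edges: list[tuple[str, str]]
    ) -> "AdjacencyMap":
        basins = tuple(basins)
        pos = {b: i for i, b in enumerate(basins)}
        mat = np.zeros((len(basins), len(basins)), dtype=bool)
        for a, b in edges:
            if a not in pos or b not in pos:
                raise KeyError(f"edge ({a}, {b}) references unknown basin")
            mat[pos[a], pos[b]] = mat[pos[b], pos[a]] = True
        np.fill_diagonal(mat, False)
        return cls(basins, mat)

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for i, a in enumerate(self.basins):
            for j in range(i + 1, len(self.basins)):
                if self.matrix[i, j]:
                    out.append((a, self.basins[j]))
        return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Which interbasin links survive and how substitution is performed.

    ``technology`` chooses whose input recipe newly-domestic production
    uses: "importer" (default) keeps the importing basin's own columns;
    "exporter" blends in the former exporters' column recipes, localized to
    the importer, weighted by the substituted demand.  International trade
    (the export column and imports row) is kept in every mode.
    """

    mode: str
    technology: str = "importer"
    substitute_final_demand: bool = True

    def __post_init__(self) -> None:
        if self.mode not in SCENARIO_MODES:
            raise ScenarioError(f"unknown scenario mode {self.mode!r}")
        if self.technology not in ("importer", "exporter"):
            raise ScenarioError(f"unknown technology rule {self.technology!r}")


def allowed_matrix(spec: ScenarioSpec, adjacency: AdjacencyMap | None) -> np.ndarray:
    """Basin x basin boolean: may basin-row sell to basin-column? Diagonal True."""
    if spec.mode in ("adjacent_only", "distant_only") and adjacency is None:
        raise ScenarioError(f"mode {spec.mode!r} requires an adjacency map")
    if spec.mode == "full":
        m = len(adjacency.basins) if adjacency is not None else 0
        if m == 0:
            raise ScenarioError("full mode needs adjacency (for the basin count)")
        return np.ones((m, m), dtype=bool)
    m = len(adjacency.basins)
    eye = np.eye(m, dtype=bool)
    if spec.mode == "no_trade":
        return eye
    if spec.mode == "adjacent_only":
        return eye | adjacency.matrix
    return eye | (~adjacency.matrix & ~eye)  # distant_only


# ---------------------------------------------------------------------------
# substitution
# ---------------------------------------------------------------------------


@dataclass
class CounterfactualSystem:
    """Substituted coefficient system plus the re-solved economy."""

    table: MRIOTable
    allowed: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    X: np.ndarray | None = None
    L: np.ndarray | None = None
    G: np.ndarray | None = None
    supplier_matrix: np.ndarray | None = None


def substitute_trade(
    source: MRIOTable | CounterfactualSystem,
    allowed: np.ndarray,
    technology: str = "importer",
    substitute_final_demand: bool = True,
) -> CounterfactualSystem:
    """Fold disallowed interbasin flows into domestic self-supply.

    For each importing basin r and disallowed exporter q, the import
    coefficient block A_qr is added to the domestic block A_rr and zeroed,
    and (optionally) basin r's final-demand imports from q are reassigned to
    basin r's own supply of the same commodity.  Accepts either a baseline
    table or a previously substituted system, so substitutions compose.
    """
    if isinstance(source, MRIOTable):
        table = source
        coef = technical_coefficients(table)
        A0, Y0 = coef.A, table.Y
    else:
        table = source.table
        A0, Y0 = source.A, source.Y
    m, c = table.m, table.c
    allowed = np.asarray(allowed, dtype=bool)
    if allowed.shape != (m, m):
        raise StructuralError(f"allowed relation has shape {allowed.shape}, expected {(m, m)}")
    if not np.all(np.diag(allowed)):
        raise ScenarioError("own-basin flows must always be allowed")

    A = A0.copy()
    Y = Y0.copy()
    blk = lambda b: slice(b * c, (b + 1) * c)
    for r in range(m):
        for q in range(m):
            if q == r or allowed[q, r]:
                continue
            A[blk(r), blk(r)] += A0[blk(q), blk(r)]
            A[blk(q), blk(r)] = 0.0
            if substitute_final_demand:
                Y[blk(r), r] += Y0[blk(q), r]
                Y[blk(q), r] = 0.0

    if technology == "exporter":
        A = _blend_exporter_technology(A0, A, Y0, table, allowed)

    _patch_missing_sectors(A, Y, table, allowed)

    rho = spectral_radius(A)
    if rho >= 1.0:
        raise ScenarioError(
            f"substituted economy is not productive (spectral radius {rho:.4f})"
        )
    return CounterfactualSystem(table=table, allowed=allowed, A=A, Y=Y)


def _folded_demand(
    table: MRIOTable, allowed: np.ndarray, q: int, r: int, s: int
) -> float:
    """Baseline demand of basin r for commodity s imported from disallowed q."""
    c = table.c
    row = q * c + s
    inter = float(table.Z[row, r * c : (r + 1) * c].sum())
    final = float(table.Y[row, r])
    return inter + final


def _localized_column(
    A: np.ndarray, col: int, r: int, table: MRIOTable, allowed: np.ndarray
) -> np.ndarray:
    """A column recipe with sources disallowed for basin r folded domestically."""
    c = table.c
    out = np.zeros(table.n)
    src = A[:, col].reshape(table.m, c)
    for q in range(table.m):
        if allowed[q, r]:
            out[q * c : (q + 1) * c] += src[q]
        else:
            out[r * c : (r + 1) * c] += src[q]
    return out


def _blend_exporter_technology(
    A0: np.ndarray,
    A: np.ndarray,
    Y0: np.ndarray,
    table: MRIOTable,
    allowed: np.ndarray,
) -> np.ndarray:
    """Rebuild importing columns as demand-weighted blends of exporter recipes."""
    m, c = table.m, table.c
    out = A.copy()
    for r in range(m):
        disallowed = [q for q in range(m) if q != r and not allowed[q, r]]
        if not disallowed:
            continue
        for s in range(c):
            col = r * c + s
            w_own = float(table.X[col])
            parts = [(w_own, _localized_column(A0, col, r, table, allowed))]
            for q in disallowed:
                f_q = _folded_demand(table, allowed, q, r, s)
                if f_q > 0:
                    parts.append(
                        (f_q, _localized_column(A0, q * c + s, r, table, allowed))
                    )
            total = sum(w for w, _ in parts)
            if total <= 0 or len(parts) == 1:
                continue
            out[:, col] = sum(w * v for w, v in parts) / total
    return out


def _patch_missing_sectors(
    A: np.ndarray, Y: np.ndarray, table: MRIOTable, allowed: np.ndarray
) -> None:
    """Give newly demanded zero-output sectors a national-average recipe.

    A basin-sector with zero baseline output has an all-zero technology
    column; if substitution routes demand to it, producing there for free
    would understate upstream effects.  Its column is filled with the
    national average input recipe for that sector, localized to the basin.
    """
    m, c = table.m, table.c
    for r in range(m):
        for s in range(c):
            col = r * c + s
            if table.X[col] > 0:
                continue
            demanded = float(Y[col].sum()) > 0 or float(A[col, :].sum()) > 0
            if not demanded:
                continue
            nat_x = sum(table.X[b * c + s] for b in range(m))
            if nat_x <= 0:
                continue
            nat_col = np.zeros(table.n)
            for b in range(m):
                nat_col += table.Z[:, b * c + s]
            recipe = (nat_col / nat_x).reshape(m, c).sum(axis=0)  # by source sector
            A[r * c : (r + 1) * c, col] = recipe
            logger.info(
                "scenario: zero-output sector (%s, %s) received demand; "
                "national-average recipe applied",
                table.basins[r], table.sectors[s],
            )


# ---------------------------------------------------------------------------
# scenario evaluation
# ---------------------------------------------------------------------------


def solve_counterfactual(system: CounterfactualSystem) -> CounterfactualSystem:
    """Re-solve output, inverses and supplier coefficients for a scenario."""
    table = system.table
    y = system.Y.sum(axis=1)
    system.L = leontief_inverse(system.A)
    system.X = system.L @ y
    Zp = system.A * system.X[np.newaxis, :]
    inv_x = np.where(system.X > 0, 1.0 / np.where(system.X > 0, system.X, 1.0), 0.0)
    Balloc = Zp * inv_x[:, np.newaxis]
    system.G = ghosh_inverse(Balloc)
    # baseline supplier coefficients applied to counterfactual output
    sup0 = table.supplier_matrix()
    inv_x0 = np.where(table.X > 0, 1.0 / np.where(table.X > 0, table.X, 1.0), 0.0)
    sup_coef = sup0 * inv_x0[np.newaxis, :]
    # column sums of A are preserved by substitution, so these coefficients
    # keep the counterfactual economy balanced column-wise as well
    system.supplier_matrix = sup_coef * system.X[np.newaxis, :]
    return system


def scenario_footprints(
    table: MRIOTable,
    intensity: IntensityMatrix | np.ndarray,
    spec: ScenarioSpec,
    adjacency: AdjacencyMap | None,
) -> tuple[pd.DataFrame, CounterfactualSystem]:
    """Per-basin production/consumption/income threats under a scenario.

    Threat intensities are the baseline per-unit-output coefficients applied
    to the counterfactual production pattern.  Returns a frame indexed by
    basins plus "abroad" with one column per perspective, and the solved
    counterfactual system.
    """
    phi = intensity.phi if isinstance(intensity, IntensityMatrix) else np.asarray(intensity, float)
    if phi.shape != (table.n,):
        raise StructuralError("intensity vector does not match table layout")
    allowed = allowed_matrix(spec, adjacency if adjacency is not None
                             else AdjacencyMap(table.basins, np.zeros((table.m, table.m), bool)))
    system = substitute_trade(
        table, allowed, technology=spec.technology,
        substitute_final_demand=spec.substitute_final_demand,
    )
    solve_counterfactual(system)

    m, c = table.m, table.c
    prod = (phi * system.X).reshape(m, c).sum(axis=1)
    cons = phi @ (system.L @ system.Y)  # m+1 consumers
    reach = system.supplier_matrix @ system.G
    inc = reach @ phi  # m+1 suppliers
    frame = pd.DataFrame(
        {
            "production": np.concatenate([prod, [0.0]]),
            "consumption": cons,
            "income": inc,
        },
        index=list(table.consumers),
    )
    frame.index.name = "basin"
    return frame, system


def scenario_delta(
    baseline: pd.DataFrame,
    scenario: pd.DataFrame,
    positions: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-basin scenario-minus-baseline deltas and net-position group summaries.

    Groups are the baseline net importers and net exporters; the summary
    gives mean, min, max and the standard error sd/sqrt(n) over the basins
    in each group (a single-basin group reports SE 0 and is flagged).
    """
    if list(baseline.index) != list(scenario.index):
        raise StructuralError("baseline and scenario basin sets differ")
    deltas = scenario - baseline
    rows = []
    for group in ("net importer", "net exporter"):
        members = [b for b in positions.index if positions.loc[b, "position"] == group]
        if not members:
            raise ScenarioError(f"no basins classified as {group}; summary undefined")
        sub = deltas.loc[members]
        for perspective in deltas.columns:
            vals = sub[perspective].to_numpy(float)
            n = len(vals)
            se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            rows.append(
                (group, perspective, n, float(vals.mean()), float(vals.min()),
                 float(vals.max()), se, n == 1)
            )
    summary = pd.DataFrame(
        rows,
        columns=["group", "perspective", "n", "mean", "min", "max",
                 "standard_error", "single_basin"],
    )
    return deltas, summary
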