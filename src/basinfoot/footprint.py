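"""Production-, consumption- and income-based threat attribution and fluxes.

With direct intensities phi (threatened-species equivalents per unit output),
Leontief inverse L and Ghosh inverse G:

* production-based:  P = phi ∘ X          (threats where they are exerted)
* consumption-based: C_j = phi' L Y_j     (threats driven by basin j's demand)
* income-based:      S_j = V_j G phi      (threats enabled by basin j's
  primary inputs)

All three attribute the same national total — the number of species in the
account — because phi' L y = phi' X and v G phi = X' phi.  Interbasin flux
matrices restrict phi to one producing basin at a time; the international
export column of Y and import row of V appear as a consumer/supplier named
"abroad" with no domestic threat intensity of its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mrio import BasinfootError, MRIOTable, StructuralError
from .satellite import IntensityMatrix

logger = logging.getLogger("basinfoot")

PERSPECTIVES = ("production", "consumption", "income")


class UndefinedShareError(BasinfootError):
    """Trade share requested on an all-zero flux matrix."""


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class FootprintResult:
    """Basin x sector attribution under one perspective.

    ``by_basin_sector`` rows are basins (consumption and income results
    include an extra "abroad" row for international trade); its grand total
    equals the account's species count.  For consumption the sector axis is
    the consumed commodity's sector; for income it is the sector receiving
    the primary input.
    """

    perspective: str
    by_basin_sector: pd.DataFrame

    @property
    def basin_totals(self) -> pd.Series:
        return self.by_basin_sector.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.by_basin_sector.to_numpy().sum())

    def to_tidy(self) -> pd.DataFrame:
        out = self.by_basin_sector.stack().rename("value").reset_index()
        out.columns = ["basin", "sector", "value"]
        out.insert(2, "perspective", self.perspective)
        return out


@dataclass
class FluxMatrix:
    """Embodied-threat fluxes: producing basin x partner basin.

    ``partners`` are consuming basins plus "abroad" (consumption form) or
    supplying basins plus "abroad" (income form).  Row sums equal the
    production-based basin totals; domestic-partner column sums equal the
    partner's consumption- (income-) based totals.
    """

    perspective: str
    matrix: pd.DataFrame  # producers x partners

    @property
    def producers(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def partners(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def total(self) -> float:
        return float(self.matrix.to_numpy().sum())

    def domestic(self) -> pd.DataFrame:
        """Square basin part (the "abroad" partner column removed)."""
        return self.matrix[self.producers]

    def to_tidy(self) -> pd.DataFrame:
        out = self.matrix.stack().rename("value").reset_index()
        out.columns = ["producer", "partner", "value"]
        out.insert(2, "perspective", self.perspective)
        return out


def _phi_of(intensity: IntensityMatrix | np.ndarray) -> np.ndarray:
    if isinstance(intensity, IntensityMatrix):
        return intensity.phi
    return np.asarray(intensity, dtype=float)


def _check_layout(phi: np.ndarray, table: MRIOTable) -> None:
    if phi.shape != (table.n,):
        raise StructuralError(
            f"intensity vector has shape {phi.shape}, table expects ({table.n},)"
        )


# ---------------------------------------------------------------------------
# the three perspectives
# ---------------------------------------------------------------------------


def production_based(
    intensity: IntensityMatrix | np.ndarray, table: MRIOTable
) -> FootprintResult:
    """Threats attributed to the basin-sector exerting them: phi ∘ X."""
    phi = _phi_of(intensity)
    _check_layout(phi, table)
    values = (phi * table.X).reshape(table.m, table.c)
    frame = pd.DataFrame(values, index=list(table.basins), columns=list(table.sectors))
    return FootprintResult("production", frame)


def consumption_based(
    intensity: IntensityMatrix | np.ndarray,
    L: np.ndarray,
    Y: np.ndarray,
    table: MRIOTable,
) -> FootprintResult:
    """Threats attributed to final consumers: phi' L Y.

    Row ``j`` of the result is consumer ``j``'s footprint resolved by the
    sector of the commodity consumed (summed over the commodity's basin of
    origin); the "abroad" row is the international-export column.
    """
    phi = _phi_of(intensity)
    _check_layout(phi, table)
    e = phi @ L  # embodied threat per unit of each delivered commodity
    embodied = e[:, np.newaxis] * Y  # n x (m+1)
    # collapse the commodity's origin basin, keep its sector
    per_sector = embodied.reshape(table.m, table.c, table.m + 1).sum(axis=0)
    frame = pd.DataFrame(
        per_sector.T, index=list(table.consumers), columns=list(table.sectors)
    )
    return FootprintResult("consumption", frame)


def income_based(
    intensity: IntensityMatrix | np.ndarray,
    G: np.ndarray,
    table: MRIOTable,
    supplier_matrix: np.ndarray | None = None,
) -> FootprintResult:
    """Threats attributed to primary-input suppliers: V G phi.

    Row ``j`` is supplier ``j``'s footprint resolved by the sector receiving
    the primary input; the "abroad" row is the international-imports row.
    """
    phi = _phi_of(intensity)
    _check_layout(phi, table)
    sup = table.supplier_matrix() if supplier_matrix is None else supplier_matrix
    enabled = G @ phi  # threats enabled downstream per unit input into t
    values = sup * enabled[np.newaxis, :]  # (m+1) x n
    per_sector = values.reshape(table.m + 1, table.m, table.c).sum(axis=1)
    frame = pd.DataFrame(
        per_sector, index=list(table.suppliers), columns=list(table.sectors)
    )
    return FootprintResult("income", frame)


# ---------------------------------------------------------------------------
# flux decomposition
# ---------------------------------------------------------------------------


def flux_consumption(
    intensity: IntensityMatrix | np.ndarray,
    L: np.ndarray,
    Y: np.ndarray,
    table: MRIOTable,
) -> FluxMatrix:
    """F[i, j] = phi_i' L Y_j: threats exerted in basin i serving consumer j."""
    phi = _phi_of(intensity)
    _check_layout(phi, table)
    contrib = phi[:, np.newaxis] * (L @ Y)  # n x (m+1): producing sector x consumer
    by_basin = contrib.reshape(table.m, table.c, table.m + 1).sum(axis=1)
    frame = pd.DataFrame(
        by_basin, index=list(table.basins), columns=list(table.consumers)
    )
    return FluxMatrix("consumption", frame)


def flux_income(
    intensity: IntensityMatrix | np.ndarray,
    G: np.ndarray,
    table: MRIOTable,
    supplier_matrix: np.ndarray | None = None,
) -> FluxMatrix:
    """F[i, j] = V_j G phi_i: threats exerted in basin i enabled by supplier j."""
    phi = _phi_of(intensity)
    _check_layout(phi, table)
    sup = table.supplier_matrix() if supplier_matrix is None else supplier_matrix
    reach = sup @ G  # (m+1) x n: supplier j's forward reach into producers
    contrib = reach * phi[np.newaxis, :]
    by_basin = contrib.reshape(table.m + 1, table.m, table.c).sum(axis=2)
    frame = pd.DataFrame(
        by_basin.T, index=list(table.basins), columns=list(table.suppliers)
    )
    return FluxMatrix("income", frame)


# ---------------------------------------------------------------------------
# reporting operations
# ---------------------------------------------------------------------------


def net_trade_classification(
    flux: FluxMatrix, include_international: bool = True
) -> pd.DataFrame:
    """Per-basin embodied trade balance and net-importer/exporter label.

    balance(b) = sum_{j != b} F[b, j] − sum_{i != b} F[i, b]; positive means
    net exporter of embodied threats.  ``include_international`` keeps the
    "abroad" partner column in the export leg (there is no "abroad" producer
    row, so the import leg is always domestic).
    """
    mat = flux.matrix if include_international else flux.domestic()
    basins = flux.producers
    rows = []
    for b in basins:
        exports = float(mat.loc[b].drop(labels=b).sum())
        imports = float(flux.domestic()[b].drop(labels=b).sum())
        balance = exports - imports
        position = (
            "net exporter" if balance > 0
            else "net importer" if balance < 0
            else "balanced"
        )
        rows.append((b, exports, imports, balance, position))
    return pd.DataFrame(
        rows,
        columns=["basin", "embodied_exports", "embodied_imports", "balance", "position"],
    ).set_index("basin")


def trade_share(flux: FluxMatrix) -> pd.Series:
    """Fraction of national threats whose partner lies outside the producer.

    Returns the overall nonlocal share plus each basin's export-linked
    (off-diagonal row) and import-linked (off-diagonal column) fractions.
    The "abroad" partner counts as nonlocal.
    """
    total = flux.total
    if total <= 0:
        raise UndefinedShareError("flux matrix has zero total; share undefined")
    diag = sum(float(flux.matrix.loc[b, b]) for b in flux.producers)
    out = {"nonlocal_share": (total - diag) / total}
    for b in flux.producers:
        row_total = float(flux.matrix.loc[b].sum())
        col_total = float(flux.matrix[b].sum())
        own = float(flux.matrix.loc[b, b])
        out[f"export_linked:{b}"] = (row_total - own) / row_total if row_total > 0 else 0.0
        out[f"import_linked:{b}"] = (col_total - own) / col_total if col_total > 0 else 0.0
    return pd.Series(out)


def group_trade_shares(flux: FluxMatrix, positions: pd.DataFrame) -> pd.Series:
    """Aggregate nonlocal shares for the net-importer and net-exporter groups.

    Importer group: fraction of the group's partner-side (column) totals
    produced outside each member basin.  Exporter group: fraction of the
    group's produced (row) totals whose partner is outside the basin.
    """
    importers = [b for b in flux.producers if positions.loc[b, "position"] == "net importer"]
    exporters = [b for b in flux.producers if positions.loc[b, "position"] == "net exporter"]
    out = {}
    if importers:
        tot = sum(float(flux.matrix[b].sum()) for b in importers)
        own = sum(float(flux.matrix.loc[b, b]) for b in importers)
        out["importer_group_import_linked"] = (tot - own) / tot if tot > 0 else 0.0
    if exporters:
        tot = sum(float(flux.matrix.loc[b].sum()) for b in exporters)
        own = sum(float(flux.matrix.loc[b, b]) for b in exporters)
        out["exporter_group_export_linked"] = (tot - own) / tot if tot > 0 else 0.0
    return pd.Series(out, dtype=float)


def top_fluxes(flux: FluxMatrix, n: int = 10) -> pd.DataFrame:
    """The n largest off-diagonal fluxes, ties broken by (producer, partner) index."""
    if n < 1:
        raise ValueError("n must be >= 1")
    entries = []
    for i, prod in enumerate(flux.producers):
        for j, part in enumerate(flux.partners):
            if prod == part:
                continue
            v = float(flux.matrix.iloc[i, j])
            if v > 0:
                entries.append((-v, i, j, prod, part, v))
    entries.sort()
    if n > len(entries):
        logger.info("top_fluxes: only %d nonzero off-diagonal entries", len(entries))
    rows = [(e[3], e[4], e[5]) for e in entries[:n]]
    return pd.DataFrame(rows, columns=["producer", "partner", "value"])


def sector_sources(
    results: dict[str, FootprintResult], k: int = 3
) -> pd.DataFrame:
    """Top-k sector contributions per basin and perspective, with shares."""
    rows = []
    for perspective, res in results.items():
        for basin, series in res.by_basin_sector.iterrows():
            total = float(series.sum())
            top = series.sort_values(ascending=False).head(min(k, len(series)))
            for rank, (sector, value) in enumerate(top.items(), start=1):
                share = float(value) / total if total > 0 else 0.0
                rows.append((basin, perspective, rank, sector, float(value), share))
    return pd.DataFrame(
        rows, columns=["basin", "perspective", "rank", "sector", "value", "share"]
    )


def supply_chain_matrix(
    intensity: IntensityMatrix | np.ndarray,
    L: np.ndarray,
    Y: np.ndarray,
    table: MRIOTable,
) -> pd.DataFrame:
    """E = phî L ŷ: embodied threats from source to final-destination sector.

    Row sums reproduce the production-based values, column sums the
    consumption-based commodity values, and the grand total the species
    count.
    """
    phi = _phi_of(intensity)
    _check_layout(phi, table)
    y = np.asarray(Y, dtype=float).sum(axis=1)
    E = phi[:, np.newaxis] * L * y[np.newaxis, :]
    idx = table.row_index()
    return pd.DataFrame(E, index=idx, columns=idx)


def top_supply_chains(E: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Largest source -> destination entries of a supply-chain matrix."""
    E = E.copy()
    E.index = E.index.set_names(["source_basin", "source_sector"])
    E.columns = E.columns.set_names(["dest_basin", "dest_sector"])
    stacked = E.stack([0, 1], future_stack=True).rename("value").reset_index()
    stacked = stacked[stacked["value"] > 0]
    return stacked.sort_values(
        ["value", "source_basin", "source_sector", "dest_basin", "dest_sector"],
        ascending=[False, True, True, True, True],
    ).head(n).reset_index(drop=True)


def species_footprint(
    intensity: IntensityMatrix,
    species: str,
    L: np.ndarray,
    G: np.ndarray,
    Y: np.ndarray,
    table: MRIOTable,
) -> dict[str, object]:
    """All attribution forms for a single species (total mass 1).

    Returns production/consumption/income footprints and both flux matrices
    computed from the species' own intensity row.
    """
    phi_s = intensity.row(species)
    return {
        "species": species,
        "production": production_based(phi_s, table),
        "consumption": consumption_based(phi_s, L, Y, table),
        "income": income_based(phi_s, G, table),
        "flux_consumption": flux_consumption(phi_s, L, Y, table),
        "flux_income": flux_income(phi_s, G, table),
    }
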