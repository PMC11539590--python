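"""Species-threat satellite account.

Builds the bridge from Red-List-style threat records to the economy: a
threat-factor -> sector binary concordance is expanded per basin, normalised
to row-stochastic form with output (or, for climate-change factors, CO2)
weights, mapped onto (species, basin, cause) records, aggregated to
(species, basin) pairs, weighted by species distribution area and basin-level
human-influence intensity, normalised so every species carries total threat
mass 1, and finally collapsed to a species x basin-sector attribution matrix
whose rows divided by gross output give the direct threat intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mrio import (
    BasinfootError,
    MRIOTable,
    NORMALIZATION_TOL,
    StructuralError,
)

logger = logging.getLogger("basinfoot")


class SatelliteError(BasinfootError):
    """Inconsistent satellite-account inputs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThreatFactor:
    """One standardised threat cause (e.g. dams, overfishing, climate change).

    ``is_climate_change`` selects the CO2 normalisation scheme instead of the
    gross-output scheme when the factor's concordance row is made stochastic.
    """

    id: str
    name: str = ""
    is_climate_change: bool = False


@dataclass(frozen=True)
class ThreatRecordSet:
    """Unique (species, basin, factor) threat records."""

    records: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        recs = tuple((str(s), str(b), str(k)) for s, b, k in self.records)
        if len(set(recs)) != len(recs):
            raise SatelliteError("duplicate (species, basin, factor) records")
        object.__setattr__(self, "records", recs)

    @property
    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s, _, _ in self.records:
            seen.setdefault(s)
        return tuple(seen)

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        """Distinct (species, basin) pairs, in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for s, b, _ in self.records:
            seen.setdefault((s, b))
        return tuple(seen)

    def causes(self, species: str, basin: str) -> tuple[str, ...]:
        return tuple(k for s, b, k in self.records if s == species and b == basin)

    def validate_against(
        self, basins: tuple[str, ...], factors: list[ThreatFactor]
    ) -> None:
        basin_set = set(basins)
        factor_set = {f.id for f in factors}
        for s, b, k in self.records:
            if b not in basin_set:
                raise SatelliteError(f"record ({s},{b},{k}): unknown basin {b!r}")
            if k not in factor_set:
                raise SatelliteError(f"record ({s},{b},{k}): unknown factor {k!r}")


@dataclass(frozen=True)
class WeightData:
    """Normalisation weights for the account.

    gross_output and co2 are per basin-sector (length m*c, table layout);
    area maps (species, basin) to the species' distribution area in that
    basin; hii maps basin to its Human Influence Index.
    """

    gross_output: np.ndarray
    co2: np.ndarray
    area: dict[tuple[str, str], float]
    hii: dict[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gross_output", np.asarray(self.gross_output, float))
        object.__setattr__(self, "co2", np.asarray(self.co2, float))
        if np.any(self.gross_output < 0) or np.any(self.co2 < 0):
            raise SatelliteError("gross output and CO2 weights must be non-negative")
        if any(v < 0 for v in self.area.values()) or any(
            v < 0 for v in self.hii.values()
        ):
            raise SatelliteError("areas and HII must be non-negative")


@dataclass
class ConcordanceSet:
    """Factor->sector concordances: binary B1, expanded per basin, normalised."""

    factors: list[ThreatFactor]
    B1: np.ndarray  # K x c, binary
    basins: tuple[str, ...]
    sectors: tuple[str, ...]
    Nc: dict[str, np.ndarray] = field(default_factory=dict)  # basin -> K x (m*c)

    @property
    def factor_index(self) -> dict[str, int]:
        return {f.id: i for i, f in enumerate(self.factors)}


@dataclass
class IntensityMatrix:
    """Direct threat intensities per unit gross output.

    Phi is species x basin-sector (threatened-species equivalents per unit
    currency); phi is its column-sum vector used for economy-wide results.
    """

    species: tuple[str, ...]
    Phi: np.ndarray
    phi: np.ndarray

    def row(self, species: str) -> np.ndarray:
        try:
            i = self.species.index(species)
        except ValueError as exc:
            raise KeyError(f"unknown species {species!r}") from exc
        return self.Phi[i]


@dataclass
class SatelliteAccount:
    """All intermediate matrices of the account, for inspection and export."""

    records: ThreatRecordSet
    concordance: ConcordanceSet
    C: np.ndarray          # records x n
    C_ag: np.ndarray       # pairs x n
    pairs: tuple[tuple[str, str], ...]
    R: np.ndarray          # pairs x n
    R_ag: np.ndarray       # species x n
    species: tuple[str, ...]
    unattributable: dict[str, float]  # species -> dropped/renormalised cause fraction


# ---------------------------------------------------------------------------
# construction steps
# ---------------------------------------------------------------------------


def expand_concordance(
    B1: np.ndarray, basin: str, basins: tuple[str, ...], sectors: tuple[str, ...]
) -> np.ndarray:
    """Place the K x c factor->sector map into one basin's block of K x (m*c)."""
    B1 = np.asarray(B1, dtype=float)
    m, c = len(basins), len(sectors)
    if B1.shape[1] != c:
        raise StructuralError(f"B1 has {B1.shape[1]} sector columns, expected {c}")
    try:
        b = basins.index(basin) if isinstance(basins, tuple) else list(basins).index(basin)
    except ValueError as exc:
        raise KeyError(f"unknown basin {basin!r}") from exc
    out = np.zeros((B1.shape[0], m * c))
    out[:, b * c : (b + 1) * c] = B1
    return out


def normalize_concordance(
    Bc: np.ndarray, weights: WeightData, factors: list[ThreatFactor]
) -> np.ndarray:
    """Make each factor row stochastic over its mapped basin-sectors.

    Climate-change factors weight their mapped sectors by CO2 emissions, all
    others by gross output; rows whose selected weights sum to zero (or that
    map to no sector) come back all-zero.  This single-counting of each
    recorded cause is what prevents a cause mapped to several sectors from
    being counted several times.
    """
    Bc = np.asarray(Bc, dtype=float)
    if Bc.shape[0] != len(factors):
        raise StructuralError("one concordance row per factor required")
    out = np.zeros_like(Bc)
    for k, factor in enumerate(factors):
        w = weights.co2 if factor.is_climate_change else weights.gross_output
        row = Bc[k] * w
        total = row.sum()
        if total > 0:
            out[k] = row / total
        elif Bc[k].sum() > 0:
            logger.warning(
                "factor %s maps only to zero-weight sectors; row left empty",
                factor.id,
            )
    return out


def build_concordances(
    B1: np.ndarray,
    factors: list[ThreatFactor],
    weights: WeightData,
    basins: tuple[str, ...],
    sectors: tuple[str, ...],
) -> ConcordanceSet:
    """Expand B1 to every basin and normalise each expansion."""
    conc = ConcordanceSet(factors=list(factors), B1=np.asarray(B1, float),
                          basins=tuple(basins), sectors=tuple(sectors))
    for basin in basins:
        Bc = expand_concordance(conc.B1, basin, conc.basins, conc.sectors)
        conc.Nc[basin] = normalize_concordance(Bc, weights, factors)
    return conc


def map_records(records: ThreatRecordSet, concordance: ConcordanceSet) -> np.ndarray:
    """Record-level attribution: row of record (s, b, k) is row k of N^(b).

    Rows sum to 1 for mapped causes and to 0 for causes whose factor maps to
    no (or only zero-weight) sectors; zero rows are retained and reported by
    :func:`weight_and_normalize`.
    """
    fidx = concordance.factor_index
    n = len(concordance.basins) * len(concordance.sectors)
    C = np.zeros((len(records.records), n))
    for i, (s, b, k) in enumerate(records.records):
        if k not in fidx:
            raise SatelliteError(f"record ({s},{b},{k}): unknown factor {k!r}")
        if b not in concordance.Nc:
            raise SatelliteError(f"record ({s},{b},{k}): no concordance for basin {b!r}")
        C[i] = concordance.Nc[b][fidx[k]]
    return C


def aggregate_records(
    C: np.ndarray, records: ThreatRecordSet
) -> tuple[np.ndarray, tuple[tuple[str, str], ...]]:
    """Sum record rows over identical (species, basin) pairs.

    Each aggregated row sums to that pair's number of mapped causes.
    """
    pairs = records.pairs
    pos = {p: i for i, p in enumerate(pairs)}
    C_ag = np.zeros((len(pairs), C.shape[1]))
    for i, (s, b, _) in enumerate(records.records):
        C_ag[pos[(s, b)]] += C[i]
    return C_ag, pairs


def weight_and_normalize(
    C_ag: np.ndarray,
    pairs: tuple[tuple[str, str], ...],
    records: ThreatRecordSet,
    weights: WeightData,
    unattributable: str = "renormalize",
) -> tuple[np.ndarray, dict[str, float]]:
    """Weight pairs by area x HII across each species' basins; normalise to 1.

    The weight of pair (s, b) is area(s,b)*hii(b), normalised over the
    species' basins; within a pair every cause receives an equal share, which
    its stochastic concordance row then spreads over sectors.  Causes whose
    factor maps to no sector carry no mass: with ``unattributable =
    "renormalize"`` (default) the lost mass is redistributed over the
    species' mapped causes so each species still sums to exactly 1; with
    ``"drop"`` it is simply discarded and the species sums to less than 1.
    Returns the weighted matrix R and the per-species unattributable
    fraction.
    """
    if unattributable not in ("renormalize", "drop"):
        raise ValueError(f"unknown unattributable policy {unattributable!r}")
    n_causes = {p: 0 for p in pairs}
    for s, b, _ in records.records:
        n_causes[(s, b)] += 1
    # mapped-cause count per pair == row sum of C_ag (stochastic rows sum to 1)
    mapped = C_ag.sum(axis=1)

    raw_w = np.empty(len(pairs))
    for i, (s, b) in enumerate(pairs):
        if (s, b) not in weights.area:
            raise SatelliteError(f"no distribution area for pair ({s}, {b})")
        if b not in weights.hii:
            raise SatelliteError(f"no HII for basin {b!r}")
        raw_w[i] = weights.area[(s, b)] * weights.hii[b]

    by_species: dict[str, list[int]] = {}
    for i, (s, _) in enumerate(pairs):
        by_species.setdefault(s, []).append(i)

    R = np.zeros_like(C_ag)
    lost: dict[str, float] = {}
    for species, rows in by_species.items():
        idx = np.array(rows)
        w = raw_w[idx]
        if unattributable == "renormalize":
            # only pairs with at least one mapped cause carry weight
            eff = w * (mapped[idx] > NORMALIZATION_TOL)
            denom_causes = mapped[idx]
        else:
            eff = w
            denom_causes = np.array([float(n_causes[pairs[i]]) for i in idx])
        total = eff.sum()
        full = w.sum()
        if total <= 0:
            raise SatelliteError(
                f"species {species!r} has zero total attribution weight"
            )
        lost_frac = 0.0
        for j, i in enumerate(idx):
            if denom_causes[j] <= NORMALIZATION_TOL:
                lost_frac += w[j] / full if full > 0 else 0.0
                continue
            share = eff[j] / total
            R[i] = C_ag[i] * (share / denom_causes[j])
            if unattributable == "drop":
                # mass actually placed is share * mapped/denom; track remainder
                lost_frac += share * (1.0 - mapped[i] / denom_causes[j])
        if lost_frac > NORMALIZATION_TOL:
            lost[species] = float(lost_frac)
            logger.info(
                "species %s: %.4f of its threat mass was unattributable (%s)",
                species, lost_frac, unattributable,
            )
    return R, lost


def aggregate_species(
    R: np.ndarray, pairs: tuple[tuple[str, str], ...]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Sum pair rows over species identity to the species x basin-sector form."""
    species: dict[str, int] = {}
    for s, _ in pairs:
        species.setdefault(s, len(species))
    R_ag = np.zeros((len(species), R.shape[1]))
    for i, (s, _) in enumerate(pairs):
        R_ag[species[s]] += R[i]
    return R_ag, tuple(species)


def intensities(
    R_ag: np.ndarray, species: tuple[str, ...], table: MRIOTable
) -> IntensityMatrix:
    """Phi = R_ag · X̂⁻¹: direct threat per unit gross output.

    Attribution mass on a zero-output basin-sector signals inconsistent
    inputs and is an error rather than an infinity.
    """
    R_ag = np.asarray(R_ag, dtype=float)
    if R_ag.shape[1] != table.n:
        raise StructuralError("R_ag columns do not match table layout")
    zero = table.X <= 0
    if np.any(R_ag[:, zero] > 0):
        t = int(np.argmax(R_ag[:, zero].sum(axis=0) > 0))
        col = np.where(zero)[0][t]
        b, s = divmod(col, table.c)
        raise SatelliteError(
            f"attribution mass on zero-output basin-sector "
            f"({table.basins[b]}, {table.sectors[s]})"
        )
    inv_x = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, table.X))
    Phi = R_ag * inv_x[np.newaxis, :]
    return IntensityMatrix(species=tuple(species), Phi=Phi, phi=Phi.sum(axis=0))


def build_satellite_account(
    records: ThreatRecordSet,
    factors: list[ThreatFactor],
    B1: np.ndarray,
    weights: WeightData,
    table: MRIOTable,
    unattributable: str = "renormalize",
) -> tuple[SatelliteAccount, IntensityMatrix]:
    """Run the whole chain B1 -> N^(c) -> C -> C_ag -> R -> R_ag -> Phi."""
    records.validate_against(table.basins, factors)
    conc = build_concordances(B1, factors, weights, table.basins, table.sectors)
    C = map_records(records, conc)
    C_ag, pairs = aggregate_records(C, records)
    R, lost = weight_and_normalize(C_ag, pairs, records, weights, unattributable)
    R_ag, species = aggregate_species(R, pairs)
    account = SatelliteAccount(
        records=records, concordance=conc, C=C, C_ag=C_ag, pairs=pairs,
        R=R, R_ag=R_ag, species=species, unattributable=lost,
    )
    intens = intensities(R_ag, species, table)
    logger.info(
        "satellite account: %d records, %d pairs, %d species, total mass %.6f",
        len(records.records), len(pairs), len(species), float(R_ag.sum()),
    )
    return account, intens


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def save_account_inputs(
    directory: str | Path,
    records: ThreatRecordSet,
    factors: list[ThreatFactor],
    B1: np.ndarray,
    weights: WeightData,
    basins: tuple[str, ...],
    sectors: tuple[str, ...],
) -> None:
    """Write records, factor metadata, B1 and weights as labelled CSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(records.records, columns=["species", "basin", "cause"]).to_csv(
        directory / "records.csv", index=False
    )
    pd.DataFrame(
        [(f.id, f.name, int(f.is_climate_change)) for f in factors],
        columns=["id", "name", "is_climate_change"],
    ).to_csv(directory / "factors.csv", index=False)
    pd.DataFrame(
        np.asarray(B1, dtype=int), index=[f.id for f in factors], columns=list(sectors)
    ).to_csv(directory / "b1.csv", index_label="factor")
    idx = pd.MultiIndex.from_product([basins, sectors], names=["basin", "sector"])
    pd.DataFrame({"co2": weights.co2}, index=idx).to_csv(directory / "co2.csv")
    pd.DataFrame(
        [(s, b, a) for (s, b), a in weights.area.items()],
        columns=["species", "basin", "area"],
    ).to_csv(directory / "areas.csv", index=False)
    pd.DataFrame(
        sorted(weights.hii.items()), columns=["basin", "hii"]
    ).to_csv(directory / "hii.csv", index=False)


def load_account_inputs(
    directory: str | Path, table: MRIOTable
) -> tuple[ThreatRecordSet, list[ThreatFactor], np.ndarray, WeightData]:
    """Read the satellite inputs written by :func:`save_account_inputs`."""
    directory = Path(directory)
    rec_df = pd.read_csv(directory / "records.csv", dtype=str)
    records = ThreatRecordSet(
        tuple(rec_df[["species", "basin", "cause"]].itertuples(index=False, name=None))
    )
    fac_df = pd.read_csv(directory / "factors.csv", dtype={"id": str, "name": str})
    factors = [
        ThreatFactor(r.id, r.name if isinstance(r.name, str) else "",
                     bool(int(r.is_climate_change)))
        for r in fac_df.itertuples(index=False)
    ]
    b1_df = pd.read_csv(directory / "b1.csv", index_col=0)
    if list(b1_df.index) != [f.id for f in factors]:
        raise StructuralError("b1.csv rows do not match factors.csv order")
    if list(map(str, b1_df.columns)) != list(table.sectors):
        raise StructuralError("b1.csv columns do not match table sectors")
    co2_df = pd.read_csv(directory / "co2.csv", index_col=[0, 1])
    if list(co2_df.index) != list(table.row_index()):
        raise StructuralError("co2.csv rows do not match table layout")
    area_df = pd.read_csv(directory / "areas.csv", dtype={"species": str, "basin": str})
    hii_df = pd.read_csv(directory / "hii.csv", dtype={"basin": str})
    weights = WeightData(
        gross_output=table.X,
        co2=co2_df["co2"].to_numpy(float),
        area={(r.species, r.basin): float(r.area) for r in area_df.itertuples(index=False)},
        hii={r.basin: float(r.hii) for r in hii_df.itertuples(index=False)},
    )
    return records, factors, b1_df.to_numpy(float), weights


def save_account(account: SatelliteAccount, directory: str | Path) -> None:
    """Serialise the account matrices as labelled CSVs plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = pd.MultiIndex.from_product(
        [account.concordance.basins, account.concordance.sectors],
        names=["basin", "sector"],
    )
    rec_idx = pd.MultiIndex.from_tuples(
        account.records.records, names=["species", "basin", "cause"]
    )
    pair_idx = pd.MultiIndex.from_tuples(account.pairs, names=["species", "basin"])
    pd.DataFrame(account.C, index=rec_idx, columns=cols).to_csv(directory / "C.csv")
    pd.DataFrame(account.C_ag, index=pair_idx, columns=cols).to_csv(
        directory / "C_ag.csv"
    )
    pd.DataFrame(account.R, index=pair_idx, columns=cols).to_csv(directory / "R.csv")
    pd.DataFrame(account.R_ag, index=list(account.species), columns=cols).to_csv(
        directory / "R_ag.csv", index_label="species"
    )
    manifest = pd.DataFrame(
        {
            "quantity": ["records", "pairs", "species", "total_mass"],
            "value": [
                len(account.records.records),
                len(account.pairs),
                len(account.species),
                float(account.R_ag.sum()),
            ],
        }
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
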