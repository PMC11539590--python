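"""Synthetic inputs: balanced multi-basin economies and threat accounts.

The generator emulates the structure of a multi-basin study system — a
connected basin adjacency graph, a balanced input-output table with
gravity-decayed interbasin trade, and a Red-List-style threat account
(species/basin/cause records, a sparse factor-to-sector concordance, and
area/HII/CO2 weights) — so the whole pipeline is testable without any
external data.

Balance is exact by construction: every column of the technical-coefficient
matrix A is normalized to a common sum equal to ``spectral_target``, which
makes that target the exact Perron root (the all-ones row vector is a left
eigenvector) and guarantees positive primary inputs
V = (1 − colsum A)·X > 0 without any repair step.  Gross output is then the
Leontief solution for the drawn final demand, so the row identity holds to
solver precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .mrio import BasinfootError, MRIOTable
from .satellite import ThreatFactor, ThreatRecordSet, WeightData
from .scenarios import AdjacencyMap

logger = logging.getLogger("basinfoot")


class GenerationError(BasinfootError):
    """Requested synthetic structure cannot be produced."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study system.

    trade_openness is the share of every sector's intermediate-input bill
    sourced from other basins (realized exactly, per column); distance_decay
    is the gravity exponent gamma in the interbasin weight d^(−gamma);
    spectral_target is the exact Perron root of A (also every sector's
    intermediate-input share of output).
    """

    n_basins: int = 4
    n_sectors: int = 5
    n_species: int = 30
    n_factors: int = 12
    n_records: int = 90
    trade_openness: float = 0.3
    distance_decay: float = 1.0
    spectral_target: float = 0.6
    export_share: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.spectral_target <= 0.95):
            raise GenerationError("spectral_target must lie in (0, 0.95]")
        if not (0.0 <= self.trade_openness <= 1.0):
            raise GenerationError("trade_openness must lie in [0, 1]")
        for name in ("n_basins", "n_sectors", "n_species", "n_factors", "n_records"):
            if getattr(self, name) < 1:
                raise GenerationError(f"{name} must be >= 1")


#: Named presets.  "full-scale" matches the scale of the study system this
#: package emulates: 16 basins x 82 sectors (1,312 basin-sectors), 348
#: threatened species, 166 standard threat factors, 1,846 records.
PRESETS: dict[str, GeneratorConfig] = {
    "small": GeneratorConfig(),
    "full-scale": GeneratorConfig(
        n_basins=16, n_sectors=82, n_species=348, n_factors=166, n_records=1846
    ),
}


def preset(name: str, seed: int | None = None) -> GeneratorConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, seed=seed) if seed is not None else cfg


def _rng(seed: int, stream: int) -> np.random.Generator:
    # one independent stream per artifact component, derived from the master
    # seed by a fixed offset, so regenerating one component is reproducible
    return np.random.default_rng([stream, seed % (2**31)])


def _basin_names(m: int) -> tuple[str, ...]:
    return tuple(f"B{i + 1:02d}" for i in range(m))


def _sector_names(c: int) -> tuple[str, ...]:
    return tuple(f"S{i + 1:02d}" for i in range(c))


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


def generate_adjacency(n_basins: int, seed: int = 0) -> AdjacencyMap:
    """Random connected basin graph with at least one distant pair (m >= 4).

    A random spanning tree guarantees connectivity; a few extra edges
    thicken it.  If the graph comes out complete, one cycle edge is removed
    so distant trade exists.
    """
    if n_basins < 2:
        raise GenerationError("need at least two basins for an adjacency graph")
    rng = _rng(seed, 11)
    basins = _basin_names(n_basins)
    g = nx.random_labeled_tree(n_basins, seed=int(rng.integers(2**31)))
    extra = max(0, int(0.4 * n_basins) - 1)
    nodes = list(g.nodes)
    for _ in range(extra):
        a, b = rng.choice(nodes, size=2, replace=False)
        g.add_edge(int(a), int(b))
    if n_basins >= 4:
        while g.number_of_edges() == n_basins * (n_basins - 1) // 2:
            a, b = rng.choice(nodes, size=2, replace=False)
            if g.degree[int(a)] > 1 and g.degree[int(b)] > 1:
                g.remove_edge(int(a), int(b))
                if not nx.is_connected(g):
                    g.add_edge(int(a), int(b))
    mat = np.zeros((n_basins, n_basins), dtype=bool)
    for a, b in g.edges:
        mat[a, b] = mat[b, a] = True
    return AdjacencyMap(basins, mat)


def graph_distances(adjacency: AdjacencyMap) -> np.ndarray:
    """All-pairs shortest-path lengths on the basin graph."""
    g = nx.from_numpy_array(adjacency.matrix.astype(int))
    m = len(adjacency.basins)
    dist = np.full((m, m), np.inf)
    for i, lengths in nx.all_pairs_shortest_path_length(g):
        for j, d in lengths.items():
            dist[i, j] = d
    return dist


# ---------------------------------------------------------------------------
# economy
# ---------------------------------------------------------------------------


def generate_mrio(
    config: GeneratorConfig, adjacency: AdjacencyMap | None = None
) -> MRIOTable:
    """Balanced multi-basin table with gravity-decayed interbasin trade."""
    m, c = config.n_basins, config.n_sectors
    if adjacency is None and m >= 2:
        adjacency = generate_adjacency(m, config.seed)
    rng = _rng(config.seed, 23)
    basins, sectors = _basin_names(m), _sector_names(c)
    n = m * c
    if m >= 2:
        dist = graph_distances(adjacency)
    else:
        dist = np.zeros((1, 1))

    # technical coefficients, column by column: a fixed domestic share
    # (1 - openness) and a cross share split over basins by gravity weight
    A = np.zeros((n, n))
    open_eff = config.trade_openness if m > 1 else 0.0
    for r in range(m):
        dom = rng.uniform(0.5, 1.5, size=(c, c))
        dom /= dom.sum(axis=0, keepdims=True)
        cross_w = np.array(
            [dist[q, r] ** (-config.distance_decay) if q != r else 0.0 for q in range(m)]
        )
        cross_w = cross_w / cross_w.sum() if cross_w.sum() > 0 else cross_w
        cols = slice(r * c, (r + 1) * c)
        A[cols, cols] = (1.0 - open_eff) * dom
        if open_eff > 0:
            for q in range(m):
                if q == r or cross_w[q] == 0:
                    continue
                blk = rng.uniform(0.5, 1.5, size=(c, c))
                blk /= blk.sum(axis=0, keepdims=True)
                A[q * c : (q + 1) * c, cols] = open_eff * cross_w[q] * blk
    A *= config.spectral_target  # every column sums to the target => rho == target

    # final demand with a domestic bias and gravity decay; one export column
    Y = np.zeros((n, m + 1))
    for j in range(m):
        for q in range(m):
            base = rng.uniform(0.5, 1.5, size=c) * 100.0
            if q == j:
                w = 3.0
            else:
                w = open_eff * dist[q, j] ** (-config.distance_decay)
            Y[q * c : (q + 1) * c, j] = base * w
    exports = rng.uniform(0.5, 1.5, size=n) * 100.0
    domestic_total = Y[:, :m].sum()
    if config.export_share > 0:
        exports *= (config.export_share * domestic_total /
                    ((1 - config.export_share) * exports.sum()))
        Y[:, m] = exports

    y = Y.sum(axis=1)
    X = np.linalg.solve(np.eye(n) - A, y)
    Z = A * X[np.newaxis, :]
    v_total = X - Z.sum(axis=0)  # == (1 - spectral_target) * X > 0
    shares = rng.dirichlet([6.0, 3.0, 1.0], size=n)  # labor, capital, imports
    V = (shares * v_total[:, np.newaxis]).T
    table = MRIOTable(
        basins=basins, sectors=sectors, Z=Z, Y=Y, V=V, X=X,
        primary_inputs=("labor", "capital"),
    )
    logger.info(
        "generated economy: %d basins x %d sectors, openness %.2f, rho %.2f",
        m, c, config.trade_openness, config.spectral_target,
    )
    return table


def interbasin_intermediate_share(table: MRIOTable) -> float:
    """Realized share of intermediate use sourced from other basins."""
    m, c = table.m, table.c
    Z = table.Z
    total = Z.sum()
    dom = sum(
        Z[b * c : (b + 1) * c, b * c : (b + 1) * c].sum() for b in range(m)
    )
    return float((total - dom) / total) if total > 0 else 0.0


# ---------------------------------------------------------------------------
# threat account
# ---------------------------------------------------------------------------


def generate_threat_account(
    config: GeneratorConfig, table: MRIOTable
) -> tuple[ThreatRecordSet, list[ThreatFactor], np.ndarray, WeightData]:
    """Records, factors, B1 concordance and weights for the satellite account.

    Every species receives 1-4 basins (positive distribution areas) and each
    (species, basin) pair 1-5 distinct causes; the total record count equals
    ``config.n_records`` exactly.  Every used factor maps to at least one
    sector in B1 and exactly one factor is flagged as climate change.
    """
    m, c = table.m, table.c
    rng = _rng(config.seed, 37)
    max_basins = min(4, m)
    capacity = config.n_species * max_basins * min(5, config.n_factors)
    if not (config.n_species <= config.n_records <= capacity):
        raise GenerationError(
            f"n_records={config.n_records} outside feasible range "
            f"[{config.n_species}, {capacity}]"
        )

    factors = [
        ThreatFactor(id=f"F{k + 1:03d}", name=f"threat factor {k + 1}",
                     is_climate_change=(k == 0))
        for k in range(config.n_factors)
    ]
    B1 = np.zeros((config.n_factors, c))
    for k in range(config.n_factors):
        n_map = int(rng.integers(1, min(3, c) + 1))
        B1[k, rng.choice(c, size=n_map, replace=False)] = 1.0

    species = tuple(f"sp{i + 1:04d}" for i in range(config.n_species))
    pair_causes: dict[tuple[str, str], set[str]] = {}
    species_basins: dict[str, list[str]] = {s: [] for s in species}

    def add_basin(sp: str) -> bool:
        if len(species_basins[sp]) >= max_basins:
            return False
        avail = [b for b in table.basins if b not in species_basins[sp]]
        b = str(rng.choice(avail))
        species_basins[sp].append(b)
        pair_causes[(sp, b)] = set()
        return True

    def add_cause(sp: str, b: str) -> bool:
        used = pair_causes[(sp, b)]
        if len(used) >= min(5, config.n_factors):
            return False
        avail = [f.id for f in factors if f.id not in used]
        used.add(str(rng.choice(avail)))
        return True

    count = 0
    for sp in species:  # seed every species with one basin and one cause
        add_basin(sp)
        add_cause(sp, species_basins[sp][0])
        count += 1
    while count < config.n_records:
        sp = str(rng.choice(species))
        if rng.random() < 0.35 and add_basin(sp):
            add_cause(sp, species_basins[sp][-1])
            count += 1
        else:
            b = str(rng.choice(species_basins[sp]))
            if add_cause(sp, b):
                count += 1

    records = ThreatRecordSet(
        tuple(
            (sp, b, k)
            for sp in species
            for b in species_basins[sp]
            for k in sorted(pair_causes[(sp, b)])
        )
    )
    assert len(records.records) == config.n_records

    # areas in km^2 (log-normal spread), HII on its conventional 0-64 scale,
    # CO2 per basin-sector in mass units
    area = {
        pair: float(np.exp(rng.normal(8.0, 1.0))) for pair in pair_causes
    }
    hii = {b: float(rng.uniform(5.0, 40.0)) for b in table.basins}
    co2 = np.exp(rng.normal(3.0, 1.0, size=table.n))
    weights = WeightData(gross_output=table.X, co2=co2, area=area, hii=hii)
    logger.info(
        "generated threat account: %d species, %d pairs, %d records",
        config.n_species, len(pair_causes), config.n_records,
    )
    return records, factors, B1, weights


def generate_study_system(
    config: GeneratorConfig,
) -> tuple[MRIOTable, AdjacencyMap, ThreatRecordSet, list[ThreatFactor], np.ndarray, WeightData]:
    """Everything the pipeline needs, from one config."""
    adjacency = (generate_adjacency(config.n_basins, config.seed)
                 if config.n_basins >= 2 else
                 AdjacencyMap(_basin_names(1), np.zeros((1, 1), bool)))
    table = generate_mrio(config, adjacency)
    records, factors, B1, weights = generate_threat_account(config, table)
    return table, adjacency, records, factors, B1, weights
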