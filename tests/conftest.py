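"""Shared fixtures and small hand-built economies."""

from __future__ import annotations

import numpy as np
import pytest

import basinfoot as bf


def table_from_A(
    A: np.ndarray,
    Y: np.ndarray,
    m: int,
    c: int,
    primary_split=(0.7, 0.2, 0.1),
) -> bf.MRIOTable:
    """Balanced table with given technical coefficients and final demand.

    X solves the Leontief system for Y's row sums; Z = A·X̂; primary inputs
    take the column residual, split into labor/capital/imports shares.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = m * c
    assert A.shape == (n, n) and Y.shape == (n, m + 1)
    X = np.linalg.solve(np.eye(n) - A, Y.sum(axis=1))
    Z = A * X[np.newaxis, :]
    v_total = X - Z.sum(axis=0)
    V = np.outer(np.asarray(primary_split), v_total)
    return bf.MRIOTable(
        basins=tuple(f"B{i + 1:02d}" for i in range(m)),
        sectors=tuple(f"S{i + 1:02d}" for i in range(c)),
        Z=Z, Y=Y, V=V, X=X, primary_inputs=("labor", "capital"),
    )


def table_from_ZX(Z: np.ndarray, X: np.ndarray, m: int, c: int) -> bf.MRIOTable:
    """Balanced table with given transactions and gross output."""
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    n = m * c
    y = X - Z.sum(axis=1)
    Y = np.zeros((n, m + 1))
    for b in range(m):
        Y[b * c : (b + 1) * c, b] = y[b * c : (b + 1) * c]
    v_total = X - Z.sum(axis=0)
    V = np.outer([0.7, 0.2, 0.1], v_total)
    return bf.MRIOTable(
        basins=tuple(f"B{i + 1:02d}" for i in range(m)),
        sectors=tuple(f"S{i + 1:02d}" for i in range(c)),
        Z=Z, Y=Y, V=V, X=X, primary_inputs=("labor", "capital"),
    )


@pytest.fixture(scope="session")
def study_system():
    """Default small synthetic study system (4 basins x 5 sectors, seed 1)."""
    cfg = bf.GeneratorConfig(seed=1)
    return bf.generate_study_system(cfg)


@pytest.fixture(scope="session")
def table(study_system):
    return study_system[0]


@pytest.fixture(scope="session")
def adjacency(study_system):
    return study_system[1]


@pytest.fixture(scope="session")
def coef(table):
    return bf.coefficient_system(table)


@pytest.fixture(scope="session")
def account_and_intensity(study_system):
    table, _, records, factors, B1, weights = study_system
    return bf.build_satellite_account(records, factors, B1, weights, table)


@pytest.fixture(scope="session")
def account(account_and_intensity):
    return account_and_intensity[0]


@pytest.fixture(scope="session")
def intensity(account_and_intensity):
    return account_and_intensity[1]
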