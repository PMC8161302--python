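"""Area-level datasets: observed counts, expected counts, covariates.

The unit of analysis is a small areal unit (e.g. a census block group) with
a population, two count outcomes ``y1`` and ``y2`` (counts of events of two
kinds recorded in the area), expected counts ``e1``/``e2`` and an optional
covariate matrix.  Expected counts act as the offset of the Poisson models;
when not supplied they are computed by internal standardization, i.e.
proportional to population so that the expected counts of each outcome sum
to its observed total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AreaDataset",
    "SimulationTruth",
    "compute_expected_counts",
    "read_area_table",
]

_RESERVED_COLUMNS = {"area_id", "population", "y1", "y2", "e1", "e2"}


def compute_expected_counts(
    population: np.ndarray, total_counts: Sequence[float]
) -> np.ndarray:
    """Expected counts by internal standardization on population.

    ``E[i, k] = total_counts[k] * population[i] / sum(population)``, so each
    column of the result sums exactly to its outcome total and the latent
    surface of a Poisson model offset by ``log E`` reads as relative risk
    against the all-area average.

    Parameters
    ----------
    population : (n,) positive array
    total_counts : (K,) positive totals, one per outcome

    Returns
    -------
    (n, K) array of positive expected counts.
    """
    pop = np.asarray(population, dtype=float)
    totals = np.asarray(total_counts, dtype=float).ravel()
    if pop.ndim != 1 or pop.size == 0:
        raise ValueError("population must be a non-empty 1-d array")
    if np.any(pop <= 0):
        bad = np.flatnonzero(pop <= 0)
        raise ValueError(f"population must be strictly positive (rows {bad.tolist()})")
    if np.any(totals <= 0):
        raise ValueError("total counts must be strictly positive")
    share = pop / pop.sum()
    return np.outer(share, totals)


@dataclass
class AreaDataset:
    """Observed and expected counts for two outcomes over ordered areas.

    Attributes
    ----------
    area_ids : tuple of str
        Area labels, in the canonical order shared with the ``AreaGraph``.
    population : (n,) array of positive counts
    Y : (n, 2) array of non-negative integer observed counts
    E : (n, 2) array of positive expected counts
    X : (n, p) covariate matrix or None
    covariate_names : tuple of str, empty when X is None
    """

    area_ids: tuple[str, ...]
    population: np.ndarray
    Y: np.ndarray
    E: np.ndarray
    X: np.ndarray | None = None
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.area_ids = tuple(str(a) for a in self.area_ids)
        n = len(self.area_ids)
        self.population = np.asarray(self.population, dtype=float)
        self.Y = np.asarray(self.Y)
        self.E = np.asarray(self.E, dtype=float)
        if self.population.shape != (n,):
            raise ValueError("population must have one entry per area")
        if self.Y.shape != (n, 2) or self.E.shape != (n, 2):
            raise ValueError("Y and E must have shape (n_areas, 2)")
        if np.any(self.population <= 0):
            raise ValueError("population must be strictly positive")
        if np.any(self.Y < 0) or not np.all(np.equal(np.mod(self.Y, 1), 0)):
            raise ValueError("Y must contain non-negative integers")
        self.Y = self.Y.astype(np.int64)
        if np.any(self.E <= 0):
            raise ValueError("E must be strictly positive (zero E is rejected)")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.ndim != 2 or self.X.shape[0] != n:
                raise ValueError("X must have shape (n_areas, p)")
            if len(self.covariate_names) != self.X.shape[1]:
                raise ValueError("covariate_names must match X columns")
            self.covariate_names = tuple(self.covariate_names)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (`area_id,population,y1,y2,e1,e2[,covariates...]`)."""
        out = pd.DataFrame(
            {
                "area_id": self.area_ids,
                "population": self.population,
                "y1": self.Y[:, 0],
                "y2": self.Y[:, 1],
                "e1": self.E[:, 0],
                "e2": self.E[:, 1],
            }
        )
        if self.X is not None:
            for j, name in enumerate(self.covariate_names):
                out[name] = self.X[:, j]
        return out

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_area_table(path: str | Path) -> AreaDataset:
    """Read an area table CSV into a validated :class:`AreaDataset`.

    Required columns: ``area_id, population, y1, y2``.  If ``e1, e2`` are
    present they are taken verbatim; otherwise expected counts are computed
    by internal standardization on population.  Any remaining columns are
    treated as covariates in file order.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in ("area_id", "population", "y1", "y2") if c not in table]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("y1", "y2"):
        bad = table.index[table[col] < 0]
        if len(bad):
            raise ValueError(
                f"{path}: negative count in column {col!r} at row {int(bad[0]) + 2} "
                "(1-based, counting the header)"
            )
    pop = table["population"].to_numpy(dtype=float)
    Y = table[["y1", "y2"]].to_numpy()
    if "e1" in table or "e2" in table:
        if not ("e1" in table and "e2" in table):
            raise ValueError(f"{path}: supply both e1 and e2 or neither")
        E = table[["e1", "e2"]].to_numpy(dtype=float)
    else:
        E = compute_expected_counts(pop, Y.sum(axis=0))
    covariates = [c for c in table.columns if c not in _RESERVED_COLUMNS]
    X = table[covariates].to_numpy(dtype=float) if covariates else None
    return AreaDataset(
        area_ids=tuple(table["area_id"].astype(str)),
        population=pop,
        Y=Y,
        E=E,
        X=X,
        covariate_names=tuple(covariates),
    )


@dataclass
class SimulationTruth:
    """Ground-truth parameters behind a simulated dataset.

    ``phi`` is the full shared field (structured + heterogeneous part) and
    ``psi`` the (2, n) outcome-specific fields; ``delta`` the shared-component
    scaling factor; ``sigma`` maps field names to the scale used to draw
    them; ``beta`` holds covariate coefficients for regression scenarios.
    """

    alpha: tuple[float, float]
    delta: float
    phi: np.ndarray
    psi: np.ndarray
    sigma: dict[str, float]
    seed: int
    beta: np.ndarray | None = None
    phi_str: np.ndarray | None = None
    psi_str: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    def realized_variance_ratios(self) -> tuple[float, float]:
        """Empirical shared-variance fractions of the realized truth.

        ``eta_k = V(c_k * phi) / (V(c_k * phi) + V(psi_k))`` with
        ``c_1 = delta`` and ``c_2 = 1/delta``, V the across-area variance.
        """
        out = []
        for k, c in enumerate((self.delta, 1.0 / self.delta)):
            vs = float(np.var(c * self.phi))
            vk = float(np.var(self.psi[k]))
            out.append(vs / (vs + vk) if vs + vk > 0 else float("nan"))
        return out[0], out[1]

    def to_json_dict(self) -> dict:
        return {
            "alpha": list(self.alpha),
            "delta": float(self.delta),
            "phi": self.phi.tolist(),
            "psi": self.psi.tolist(),
            "sigma": {k: float(v) for k, v in self.sigma.items()},
            "beta": None if self.beta is None else np.asarray(self.beta).tolist(),
            "seed": int(self.seed),
        }
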