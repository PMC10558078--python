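"""Fixation-probability curves x_i(r) with method dispatch and serialization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brute import brute_force_fixation
from .chains import family_fixation, moran_fixation
from .hypergraph import Hypergraph

__all__ = ["FixationCurve", "default_r_grid", "fixation_curve_exact", "moran_curve"]

FAMILIES = ("complete3", "cyclic3", "star3", "complete_graph")


def default_r_grid(n: int = 25, lo: float = 0.25, hi: float = 4.0) -> np.ndarray:
    """Log-spaced fitness grid over [lo, hi] containing r = 1 exactly."""
    grid = np.geomspace(lo, hi, n)
    grid[np.argmin(np.abs(grid - 1.0))] = 1.0
    if 1.0 not in grid:
        grid = np.sort(np.append(grid, 1.0))
    return grid


@dataclass(frozen=True)
class FixationCurve:
    """Fixation probability of ``i`` initial mutants across a fitness grid.

    ``method`` records how each point was produced (``closed_form``,
    ``reduced_exact``, ``brute_force``, ``simulation``, ``moran``);
    ``stderr`` is populated for simulation curves only.
    """

    i: int
    r_values: np.ndarray
    x: np.ndarray
    method: str
    N: int
    model: int | None = None
    label: str = ""
    stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "r_values", np.asarray(self.r_values, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if len(self.r_values) != len(self.x):
            raise ValueError("r_values and x must have equal length")
        if ((self.x < -1e-12) | (self.x > 1 + 1e-12)).any():
            raise ValueError("fixation probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"r": self.r_values, "x": self.x, "method": self.method})
        if self.stderr is not None:
            df["stderr"] = self.stderr
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def moran_curve(N: int, i: int, r_grid: np.ndarray) -> FixationCurve:
    x = np.array([moran_fixation(N, r, i) for r in r_grid])
    return FixationCurve(i=i, r_values=r_grid, x=x, method="moran", N=N, label="moran")


def fixation_curve_exact(
    target: str | Hypergraph,
    model: int,
    i: int,
    r_grid: np.ndarray,
    N: int | None = None,
    solver: str = "auto",
) -> FixationCurve:
    """Exact fixation curve for a symmetric family or a small hypergraph.

    Families dispatch to the reduced-chain solve (closed form for cyclic
    model 2); an explicit ``Hypergraph`` goes through the 2^N brute-force
    solver (N <= 14).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if (r_grid <= 0).any():
        raise ValueError("all r values must be positive")
    if isinstance(target, Hypergraph):
        x = np.array([brute_force_fixation(target, model, r, i=i) for r in r_grid])
        return FixationCurve(
            i=i, r_values=r_grid, x=x, method="brute_force", N=target.N, model=model,
            label=f"hypergraph(N={target.N})",
        )
    if target not in FAMILIES:
        raise ValueError(f"unknown family {target!r}; expected one of {FAMILIES}")
    if N is None:
        raise ValueError("N is required when a family name is given")
    method = "closed_form" if (target, model) == ("cyclic3", 2) else "reduced_exact"
    x = np.array([family_fixation(target, model, N, r, i, method=solver) for r in r_grid])
    return FixationCurve(
        i=i, r_values=r_grid, x=x, method=method, N=N, model=model, label=target
    )
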