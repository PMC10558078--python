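"""Figure-level experiment driver: curves, verdicts and companion sweeps.

``run_experiment`` reproduces the study designs the library supports:
exact fixation-probability sweeps for the symmetric families, and, for
hypergraphs loaded from file or built programmatically, simulation sweeps
together with the weighted one-mode projection and a degree/size-preserving
randomization of the same hypergraph.  Results are written as CSV curves
plus a JSON verdict/parameter log.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .classify import Verdict, classify_selection
from .curves import FixationCurve, default_r_grid, fixation_curve_exact, moran_curve
from .hypergraph import (
    Hypergraph,
    is_connected,
    one_mode_projection,
    randomize_hypergraph,
    read_hyperedge_list,
)
from .simulate import estimate_fixation

__all__ = ["simulate_curve", "run_experiment"]


def simulate_curve(
    H: Hypergraph,
    model: int,
    i: int,
    r_grid: np.ndarray,
    runs_per_start: int,
    seed: int = 0,
    max_steps: int | None = None,
) -> FixationCurve:
    """Monte-Carlo fixation curve over a fitness grid (one seed per r point)."""
    xs, ses = [], []
    for k, r in enumerate(np.asarray(r_grid, dtype=float)):
        est = estimate_fixation(
            H, model, float(r), i,
            runs_per_start=runs_per_start,
            seed=seed + 1_000_003 * k,
            max_steps=max_steps,
        )
        xs.append(est.estimate)
        ses.append(est.stderr)
    return FixationCurve(
        i=i, r_values=np.asarray(r_grid, dtype=float), x=np.array(xs),
        method="simulation", N=H.N, model=model, label=f"simulated(N={H.N})",
        stderr=np.array(ses),
    )


def _verdict_json(v: Verdict) -> dict:
    d = asdict(v)
    for key in ("r_values", "delta", "signs"):
        d[key] = np.asarray(d[key]).tolist()
    return d


def run_experiment(config: dict, outdir) -> dict:
    """Run one configured experiment and write its artifacts.

    Config keys: ``family`` or ``file`` (or ``hypergraph``), ``model`` (1|2),
    ``N`` (families), ``i``, ``method`` ("exact" | "simulate"), ``r_grid``
    (optional), ``runs_per_start`` / ``seed`` / ``max_steps`` (simulation),
    ``with_projection`` / ``with_randomized`` (companion sweeps, simulation
    only), ``tol``.  Returns {"curves": {...}, "verdicts": {...}}.
    """
    cfg = dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    known = {
        "family", "file", "hypergraph", "model", "N", "i", "method", "r_grid",
        "runs_per_start", "seed", "max_steps", "with_projection",
        "with_randomized", "tol",
    }
    bad = set(cfg) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")

    model = int(cfg.get("model", 1))
    i = int(cfg.get("i", 1 if model == 1 else 2))
    method = cfg.get("method", "exact")
    r_grid = np.asarray(cfg.get("r_grid", default_r_grid()), dtype=float)
    tol = float(cfg.get("tol", 1e-9))
    seed = int(cfg.get("seed", 0))

    sources = [k for k in ("family", "file", "hypergraph") if k in cfg]
    if len(sources) != 1:
        raise ValueError("config must name exactly one of family, file, hypergraph")
    if "family" in cfg:
        target: str | Hypergraph = cfg["family"]
        N = int(cfg["N"])
        H = None
    else:
        H = cfg["hypergraph"] if "hypergraph" in cfg else read_hyperedge_list(cfg["file"])
        N = H.N
        target = H

    curves: dict[str, FixationCurve] = {}
    if method == "exact":
        if H is not None and H.N > 14:
            raise ValueError(
                f"exact solve for an arbitrary hypergraph is capped at N <= 14 "
                f"(got N={H.N}); use method='simulate' instead"
            )
        curves["main"] = fixation_curve_exact(target, model, i, r_grid, N=N)
    elif method == "simulate":
        if H is None:
            from .hypergraph import make_model_hypergraph

            H = make_model_hypergraph(target, N)
        runs = int(cfg.get("runs_per_start", 1000))
        max_steps = cfg.get("max_steps")
        curves["main"] = simulate_curve(
            H, model, i, r_grid, runs_per_start=runs, seed=seed, max_steps=max_steps
        )
        if cfg.get("with_projection"):
            curves["projection"] = simulate_curve(
                one_mode_projection(H, weighted=True), model, i, r_grid,
                runs_per_start=runs, seed=seed + 1, max_steps=max_steps,
            )
        if cfg.get("with_randomized"):
            HR = randomize_hypergraph(H, seed=seed + 2)
            curves["randomized"] = simulate_curve(
                HR, model, i, r_grid, runs_per_start=runs, seed=seed + 3,
                max_steps=max_steps,
            )
            cfg["_randomized_connected"] = bool(is_connected(HR))
    else:
        raise ValueError(f"unknown method {method!r}; use 'exact' or 'simulate'")

    curves["moran"] = moran_curve(N, i, r_grid)

    verdicts = {
        name: classify_selection(curve, N=N, tol=tol)
        for name, curve in curves.items()
        if name != "moran"
    }

    for name, curve in curves.items():
        curve.to_csv(outdir / f"curve_{name}.csv")
    log = {
        "config": {
            k: (v if not isinstance(v, (Hypergraph, np.ndarray)) else str(v))
            for k, v in cfg.items()
        },
        "r_grid": r_grid.tolist(),
        "python": sys.version,
        "verdicts": {k: _verdict_json(v) for k, v in verdicts.items()},
    }
    (outdir / "verdicts.json").write_text(json.dumps(log, indent=2))
    return {"curves": curves, "verdicts": verdicts}
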