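"""Model-comparison benchmark and the ARB accuracy metric.

Accuracy of a fitted model is the absolute relative bias (ARB): the
median over the nonzero true coefficients of ``|estimate - truth| /
|truth|``, with the intercept excluded (its truth depends on the
mean-scale normalization).  Failed fits are recorded as NA, counted, and
excluded from aggregates — a model that cannot estimate a cell is data,
not an error.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .regression import ModelSpec, fit_variant
from .simulate import ScenarioConfig, simulate_scenario

__all__ = ["absolute_relative_bias", "run_benchmark", "summarize_arb"]

_CELL_COLS = ["n", "effect_level", "phi", "inv_theta"]


def absolute_relative_bias(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Median over coefficients with nonzero truth of |est - truth|/|truth|."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("estimate and truth must have the same shape")
    nz = truth != 0
    if not np.any(nz):
        raise ValueError("truth has no nonzero entries; ARB is undefined")
    return float(np.median(np.abs(estimate[nz] - truth[nz]) / np.abs(truth[nz])))


def run_benchmark(
    grid: list[ScenarioConfig],
    models: list[str],
    replicates: int = 10,
    base_spec: ModelSpec | None = None,
    zero_mech: str = "tau",
    out_path=None,
) -> pd.DataFrame:
    """Simulate every cell, fit every model, record ARB or NA.

    Returns a tidy table with one row per (cell, model, replicate):
    scenario columns, ``model``, ``replicate``, ``arb``,
    ``est_inv_theta`` and ``failed``.  Fully seeded from each cell's
    seed; if ``out_path`` is given rows are appended incrementally after
    each cell so an interrupted run can be inspected or resumed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base_spec = base_spec or ModelSpec()
    rows: list[dict] = []
    wrote_header = False
    for cell in grid:
        cell_rows: list[dict] = []
        for rep in range(replicates):
            scen = ScenarioConfig(
                n=cell.n,
                effect_level=cell.effect_level,
                phi=cell.phi,
                inv_theta=cell.inv_theta,
                replicate=rep,
                seed=cell.seed,
            )
            sim = simulate_scenario(scen, zero_mech=zero_mech)
            truth = sim["beta"][1:]  # intercept excluded from ARB
            fit_seed = int(
                np.random.SeedSequence([scen.seed, rep, 7]).generate_state(1)[0] % (2**31)
            )
            for model in models:
                spec = replace(base_spec, variant=model, seed=fit_seed)
                try:
                    fit = fit_variant(model, sim["B"], sim["y"], spec, param_names=sim["names"])
                except Exception:
                    # degenerate draws (e.g. an all-zero replicate) count as failures
                    fit = None
                if fit is None or fit.failed:
                    arb = np.nan
                    est_it = np.nan
                    failed = True
                else:
                    est = fit.beta.reindex(sim["names"][1:]).to_numpy()
                    arb = absolute_relative_bias(est, truth)
                    est_it = fit.inv_theta
                    failed = False
                cell_rows.append(
                    {
                        "n": cell.n,
                        "effect_level": cell.effect_level,
                        "phi": cell.phi,
                        "inv_theta": cell.inv_theta,
                        "replicate": rep,
                        "model": model,
                        "arb": arb,
                        "est_inv_theta": est_it,
                        "failed": failed,
                    }
                )
        rows.extend(cell_rows)
        if out_path is not None:
            pd.DataFrame(cell_rows).to_csv(
                out_path, mode="a", header=not wrote_header, index=False
            )
            wrote_header = True
    return pd.DataFrame(rows)


def summarize_arb(result: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Aggregate a benchmark table.

    Returns ``per_model`` — median ARB across all non-failed rows plus
    the NA count (the box-plot style summary) — and ``per_cell`` — mean
    and sd of ARB per (cell, model) with NA counts (the tabular
    "ARB (sd)" style summary).
    """
    if result.empty:
        raise ValueError("empty benchmark result")
    r = result.copy()
    per_model = (
        r.groupby("model", sort=False)
        .agg(
            median_arb=("arb", lambda s: np.nan if s.notna().sum() == 0 else float(s.median())),
            n_failed=("failed", "sum"),
            n_total=("arb", "size"),
        )
        .reset_index()
    )
    per_cell = (
        r.groupby(_CELL_COLS + ["model"], sort=False)
        .agg(
            mean_arb=("arb", lambda s: np.nan if s.notna().sum() == 0 else float(s.mean())),
            sd_arb=("arb", lambda s: np.nan if s.notna().sum() < 2 else float(s.std())),
            mean_est_inv_theta=(
                "est_inv_theta",
                lambda s: np.nan if s.notna().sum() == 0 else float(s.mean()),
            ),
            n_failed=("failed", "sum"),
            n_total=("arb", "size"),
        )
        .reset_index()
    )
    return {"per_model": per_model, "per_cell": per_cell}
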