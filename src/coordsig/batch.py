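"""Batch execution of simulation grids with classification and summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ScenarioConfig
from .dynamics import run
from .structures import classify, expected_payoffs, extract_structure, is_optimal
from .pid import joint_from_structure, pid_synergy

__all__ = ["run_one", "run_batch", "summarize", "rarity_count", "load_results", "export_heatmap"]

RARITY_THRESHOLD = 0.005


def run_one(cfg: ScenarioConfig, threshold: float = 0.90, optimality: bool = True) -> dict:
    """Execute run -> extract_structure -> classify (-> optimality, payoffs,
    synergy) for a single configuration; returns one flat result row."""
    result = run(cfg)
    structure = extract_structure(result.final_state, cfg, threshold)
    label = classify(structure, cfg)
    row = {
        "preset": cfg.name,
        "family": cfg.family,
        **{k: v for k, v in cfg.params.items()},
        "signal_cost": cfg.signal_cost,
        "seed": cfg.seed,
        "label": label.label,
        "category": label.category,
        "detail": label.detail,
        "converged": result.converged,
        "steps_used": result.steps_used,
    }
    if optimality:
        cert = is_optimal(structure, cfg)
        row["optimal"] = bool(cert)
        row["optimality_status"] = cert.status
    payoffs = expected_payoffs(structure, cfg)
    for lbl, val in payoffs.items():
        row[f"payoff_{lbl}"] = val
    if structure.space.dims == 2:
        try:
            row["synergy_fraction"] = pid_synergy(
                joint_from_structure(structure, cfg)
            ).synergy_fraction
        except Exception:
            row["synergy_fraction"] = np.nan
    return row


def run_batch(
    grid: list[ScenarioConfig],
    replicates: int = 1,
    base_seed: int = 0,
    threshold: float = 0.90,
    optimality: bool = True,
    log_path: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """One row per (config, replicate); deterministic given ``base_seed``.

    Replicate seeds are derived from the config seed and the replicate index.
    Individual run failures are recorded in the row, not raised.  When
    ``log_path`` is given, rows are appended as JSON lines as they complete,
    making batches resumable by reloading the log.
    """
    rows = []
    done = set()
    log_fh = None
    if log_path is not None:
        log_path = Path(log_path)
        if log_path.exists():
            for line in log_path.read_text().splitlines():
                if line.strip():
                    row = json.loads(line)
                    rows.append(row)
                    done.add((row["preset"], row["seed"]))
        log_fh = open(log_path, "a")
    try:
        for i, cfg in enumerate(grid):
            for rep in range(replicates):
                cfg_rep = ScenarioConfig(**{**cfg.__dict__})
                cfg_rep.seed = (int(base_seed) + cfg.seed + 7919 * rep) % (2**31)
                if (cfg_rep.name, cfg_rep.seed) in done:
                    continue
                try:
                    row = run_one(cfg_rep, threshold, optimality)
                except Exception as err:  # recorded, not fatal to the batch
                    row = {
                        "preset": cfg.name,
                        "family": cfg.family,
                        **cfg.params,
                        "seed": cfg_rep.seed,
                        "label": "error",
                        "category": f"error:{type(err).__name__}",
                        "detail": str(err),
                        "converged": False,
                        "steps_used": 0,
                    }
                rows.append(row)
                if log_fh is not None:
                    log_fh.write(json.dumps(row, default=float) + "\n")
                    log_fh.flush()
            if progress:
                print(f"[coordsig] grid cell {i + 1}/{len(grid)} done", flush=True)
    finally:
        if log_fh is not None:
            log_fh.close()
    return pd.DataFrame(rows)


def load_results(path: str | Path) -> pd.DataFrame:
    return pd.DataFrame([json.loads(l) for l in Path(path).read_text().splitlines() if l.strip()])


def summarize(
    results: pd.DataFrame,
    cell_keys: list[str] | None = None,
    rarity_threshold: float = RARITY_THRESHOLD,
) -> pd.DataFrame:
    """Outcome-frequency table per parameter cell.

    Frequencies sum to 1 within each cell.  The returned frame carries the
    pooled count of categories at or above ``rarity_threshold`` in
    ``attrs['rare_category_count']``.  Idempotent: summarizing a summary
    reproduces it.
    """
    if results.empty:
        raise ValueError("empty results")
    if {"frequency", "category"} <= set(results.columns) and "seed" not in results.columns:
        return results.copy()
    if cell_keys is None:
        cell_keys = [
            c for c in results.columns
            if c not in {
                "seed", "label", "category", "detail", "converged", "steps_used",
                "optimal", "optimality_status", "synergy_fraction",
            } and not c.startswith("payoff_")
        ]
    out = (
        results.groupby(cell_keys + ["category"], dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = out.groupby(cell_keys)["count"].transform("sum")
    out["frequency"] = out["count"] / totals
    out.attrs["rare_category_count"] = rarity_count(results, rarity_threshold)
    return out


def rarity_count(results: pd.DataFrame, threshold: float = RARITY_THRESHOLD) -> int:
    """Number of outcome categories with pooled frequency >= threshold."""
    freqs = results["category"].value_counts(normalize=True)
    return int((freqs >= threshold).sum())


def export_heatmap(
    summary: pd.DataFrame, category: str, x: str, y: str, path: str | Path
) -> None:
    """Simple frequency heatmap of one outcome category over two axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[summary["category"] == category]
    pivot = sub.pivot_table(index=y, columns=x, values="frequency", fill_value=0.0)
    fig, ax = plt.subplots()
    im = ax.imshow(pivot.values, origin="lower", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(len(pivot.columns)), [f"{v:g}" for v in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{v:g}" for v in pivot.index])
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.set_title(category)
    fig.colorbar(im, ax=ax, label="frequency")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
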