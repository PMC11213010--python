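"""Experimental-design sweeps: simulate -> fit -> call -> score against truth.

Metrics follow the usual screen-benchmarking conventions: sensitivity is
the fraction of true-effect genes called, the true FDR is the fraction of
calls that are false, and "sensitivity at true FDR x" walks the
PIP-descending gene ranking to the largest prefix whose realized FDR
stays at or below x.  Calls use the model's rule (PIP > 1 - q and the
(1 - q) credible interval excluding zero); ranking-based curves use the
PIP ordering only.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from .hierarchy import Hyperparameters
from .mcmc import SamplerConfig, call_hits, fit
from .simulate import SimulationConfig, simulate_screen

__all__ = [
    "SweepGrid",
    "evaluate_calls",
    "sensitivity_at_true_fdr",
    "run_sweep",
    "child_seed",
    "fit_simulated",
]

LARGE_EFFECT_SD = 0.2  # |mu| above this counts as a large effect


@dataclass(frozen=True)
class SweepGrid:
    """Cartesian grid over experimental-design knobs.

    ``axes`` maps a SimulationConfig field name (``coverage``, ``moi``,
    ``n_replicates``, ``guides_per_gene``, ``n_controls``, ...) or the
    special axis ``bin_scheme`` (value: ``(bin_masses, collected_bins)``)
    to the list of values to test.  ``fixed_gene_coverage``, when set,
    reinterprets a ``guides_per_gene`` axis at constant gene-level
    coverage (per-guide coverage = gene coverage / guides per gene).
    """

    base: SimulationConfig
    axes: dict
    repetitions: int = 1
    q: float = 0.10
    fdr_targets: tuple = (0.05,)
    fixed_gene_coverage: float | None = None

    def __post_init__(self) -> None:
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("grid must have at least one non-empty axis")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def evaluate_calls(calls: pd.Series | dict, truth_psi: pd.Series | dict) -> dict:
    """Confusion-matrix core metrics over a shared gene set.

    ``sensitivity = TP / (TP + FN)`` over true-effect genes (0 when there
    are none); ``fdr = FP / max(1, TP + FP)`` so an empty call set scores
    FDR 0.
    """
    calls = pd.Series(calls)
    truth = pd.Series(truth_psi).astype(bool)
    if set(calls.index) != set(truth.index):
        raise ValueError("call and truth gene sets differ")
    calls = calls.reindex(truth.index).astype(bool)
    tp = int((calls & truth).sum())
    fp = int((calls & ~truth).sum())
    fn = int((~calls & truth).sum())
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / max(1, tp + fp)
    return {"sensitivity": sens, "fdr": fdr, "tp": tp, "fp": fp, "fn": fn}


def _prefix_at_true_fdr(ranked_genes, truth_psi: pd.Series, target_fdr: float):
    """Largest ranking prefix whose realized FDR <= target; returns gene list."""
    truth = pd.Series(truth_psi).astype(bool)
    best, tp, fp = 0, 0, 0
    for i, g in enumerate(ranked_genes, start=1):
        if truth.get(g, False):
            tp += 1
        else:
            fp += 1
        if fp / i <= target_fdr:
            best = i
    return list(ranked_genes[:best])


def sensitivity_at_true_fdr(ranked_genes, truth_psi, target_fdr: float) -> float:
    """Sensitivity at the largest PIP-ranking prefix with realized FDR <= target."""
    truth = pd.Series(truth_psi).astype(bool)
    n_true = int(truth.sum())
    if n_true == 0:
        return 0.0
    prefix = _prefix_at_true_fdr(list(ranked_genes), truth, target_fdr)
    return sum(truth.get(g, False) for g in prefix) / n_true


def child_seed(master_seed: int, *coords) -> int:
    """Stable per-cell seed < 2**31 from the master seed and grid coordinates."""
    key = f"{master_seed}|" + "|".join(map(repr, coords))
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4], "big") % (2 ** 31)


def fit_simulated(screen, sampler: SamplerConfig,
                  hyper: Hyperparameters | None = None):
    """Fit one simulated screen, switching on two-bin mode when needed."""
    cfg = screen.config
    full = tuple(range(cfg.n_bins))
    if cfg.collected != full:
        hyper = replace(hyper or Hyperparameters(),
                        w0=np.asarray(cfg.bin_masses, dtype=float))
        sampler = replace(sampler, two_bin_mode=True, observed_bins=cfg.collected)
    return fit(screen.table, screen.library, hyper, sampler)


def _apply_axis(config: SimulationConfig, grid: SweepGrid, axis: str, value):
    if axis == "bin_scheme":
        masses, collected = value
        return replace(config, bin_masses=tuple(masses),
                       collected_bins=tuple(collected) if collected is not None else None)
    if axis == "coverage":
        return replace(config, coverage=float(value), n_cells=None)
    if axis == "n_cells":
        return replace(config, n_cells=int(value), coverage=None)
    if axis == "guides_per_gene" and grid.fixed_gene_coverage is not None:
        return replace(config, guides_per_gene=int(value),
                       coverage=grid.fixed_gene_coverage / int(value), n_cells=None)
    return replace(config, **{axis: value})


def run_sweep(grid: SweepGrid, sampler: SamplerConfig | None = None,
              master_seed: int = 0, out_path=None,
              hyper: Hyperparameters | None = None) -> pd.DataFrame:
    """One row per (grid cell x repetition); crash-safe streaming output.

    Child seeds are derived from the master seed and the cell coordinates,
    so any row reproduces in isolation.  Failures of individual cells are
    recorded (``error`` column) and the sweep continues.  Sweep-scale
    sampler defaults are deliberately light (2 chains x 1000 + 1000);
    pass a full-scale :class:`SamplerConfig` for final runs.
    """
    sampler = sampler or SamplerConfig(n_chains=2, n_samples=1000, n_burnin=1000)
    names = list(grid.axes)
    rows = []
    handle = open(out_path, "w") if out_path is not None else None
    wrote_header = False
    try:
        for values in itertools.product(*(grid.axes[a] for a in names)):
            for rep in range(grid.repetitions):
                seed = child_seed(master_seed, *zip(names, values), rep)
                row = {**dict(zip(names, [str(v) if isinstance(v, tuple) else v
                                          for v in values])),
                       "repetition": rep, "seed": seed}
                try:
                    cfg = grid.base
                    for a, v in zip(names, values):
                        cfg = _apply_axis(cfg, grid, a, v)
                    row.update(_run_cell(cfg, grid, sampler, seed, hyper))
                    row["error"] = ""
                except Exception as exc:  # noqa: BLE001 - sweep must continue
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
                if handle is not None:
                    df_row = pd.DataFrame([row])
                    df_row.to_csv(handle, sep="\t", index=False, header=not wrote_header)
                    wrote_header = True
                    handle.flush()
    finally:
        if handle is not None:
            handle.close()
    return pd.DataFrame(rows)


def _run_cell(cfg: SimulationConfig, grid: SweepGrid, sampler: SamplerConfig,
              seed: int, hyper: Hyperparameters | None) -> dict:
    rng = np.random.default_rng(seed)
    screen = simulate_screen(cfg, rng)
    summary = fit_simulated(screen, replace(sampler, seed=seed), hyper)
    ranked = call_hits(summary, grid.q)
    truth_psi = screen.gene_truth.set_index("gene")["psi"]
    truth_mu = screen.gene_truth.set_index("gene")["mu"]
    calls = ranked.set_index("gene")["called"]
    out = evaluate_calls(calls, truth_psi)
    large = truth_psi.astype(bool) & (truth_mu.abs() > LARGE_EFFECT_SD)
    called_set = set(ranked.loc[ranked["called"], "gene"])
    out["sensitivity_large"] = (
        sum(g in called_set for g in large.index[large]) / int(large.sum())
        if large.any() else np.nan
    )
    ranking = list(ranked["gene"])
    for t in grid.fdr_targets:
        prefix = set(_prefix_at_true_fdr(ranking, truth_psi, t))
        n_true = int(truth_psi.sum())
        out[f"sens_at_fdr_{t:g}"] = (
            sum(g in prefix for g in truth_psi.index[truth_psi.astype(bool)]) / n_true
            if n_true else 0.0
        )
        out[f"sens_large_at_fdr_{t:g}"] = (
            sum(g in prefix for g in large.index[large]) / int(large.sum())
            if large.any() else np.nan
        )
    out["bayes_fdr"] = ranked.attrs.get("bayes_fdr", np.nan)
    out["n_genes"] = cfg.n_genes
    out["effective_coverage"] = cfg.moi * (
        cfg.n_cells if cfg.n_cells is not None else 0
    ) / cfg.library_size if cfg.coverage is None else cfg.coverage
    return out
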