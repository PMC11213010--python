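"""Cell-level generative model of a pooled CRISPR FACS screen.

Each replicate is simulated cell by cell:

1. guide-representation simplex rho ~ Dirichlet(tau_rep / p * 1_p) over
   the p library members (one independent draw per replicate);
2. per cell, the number of viral integrations k ~ Poisson(MOI); cells
   with k = 0 are uninfected and discarded (mirroring GFP+ selection);
   the k guide identities are drawn with replacement from rho;
3. the cell's marker deviate is z - sum(beta) over its distinct effect
   guides (additive, no interactions; a duplicate integration of the
   same guide counts once biologically), z ~ N(0, 1), and the cell is
   gated by the cutpoints of the configured null bin masses — sorted on
   the same convention the inference model uses, so effect signs agree
   end to end; cells falling in uncollected middle gates are discarded;
4. cell-level guide x bin counts credit EVERY integration the cell
   carries (sequencing its gDNA amplifies each integrated construct);
5. sequencing reads per bin are Dirichlet-multinomial across guides,
   centred on the bin's cell counts, at the configured depth and
   sequencing dispersion phi_seq.

Ground truth (per-gene inclusion and effect, per-guide effect) rides
along for power evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker import BinScheme, cutpoints_from_masses
from .screen_io import BinCountTable, GuideLibrary

__all__ = [
    "SimulationConfig",
    "SimulatedScreen",
    "simulate_screen",
    "draw_guides_per_cell",
    "draw_effect_sizes",
    "effective_coverage",
    "required_cells",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic screen.

    Effect sizes are in marker standard deviations.  ``coverage`` is the
    target effective (MOI-adjusted) measurements per guide; exactly one of
    ``coverage`` / ``n_cells`` must be set.  ``bin_masses`` are the null
    bin fractions of the full gate scheme (sum to 1); ``collected_bins``
    lists the gates actually sorted and sequenced (default: all), so an
    outer-bins-only design is e.g. masses (.15, .35, .35, .15) with
    collected (0, 3).  ``depth_per_bin`` of None sequences each bin at its
    collected-cell total.
    """

    n_genes: int
    guides_per_gene: int = 4
    n_controls: int = 20
    fraction_effect: float = 0.1
    effect_family: str = "truncated_normal"
    effect_params: tuple = (("sd", 0.25), ("min_abs", 0.02))
    moi: float = 0.3
    coverage: float | None = None
    n_cells: int | None = None
    tau_rep: float = 1000.0
    tau_guide: float = 0.05
    bin_masses: tuple = (0.25, 0.25, 0.25, 0.25)
    collected_bins: tuple | None = None
    n_replicates: int = 2
    depth_per_bin: int | None = None
    phi_seq: float = 200.0
    keep_cell_log: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1 or self.n_controls < 0:
            raise ValueError("invalid library layout")
        if not 0.0 <= self.fraction_effect <= 1.0:
            raise ValueError("fraction_effect must be in [0, 1]")
        if self.moi < 0:
            raise ValueError("MOI must be nonnegative")
        if (self.coverage is None) == (self.n_cells is None):
            raise ValueError("set exactly one of coverage / n_cells")
        w = np.asarray(self.bin_masses, dtype=float)
        if w.size < 2 or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("bin_masses must be >= 2 positive fractions summing to 1")
        if self.collected_bins is not None:
            cb = sorted(set(int(b) for b in self.collected_bins))
            if not cb or cb[0] < 0 or cb[-1] >= w.size:
                raise ValueError("collected_bins out of range")
            object.__setattr__(self, "collected_bins", tuple(cb))
        if self.tau_rep <= 0 or self.tau_guide < 0 or self.phi_seq <= 0:
            raise ValueError("dispersions must be positive")

    @property
    def library_size(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_controls

    @property
    def n_bins(self) -> int:
        return len(self.bin_masses)

    @property
    def collected(self) -> tuple:
        return self.collected_bins if self.collected_bins is not None \
            else tuple(range(self.n_bins))

    def params(self) -> dict:
        return dict(self.effect_params)


@dataclass
class SimulatedScreen:
    """Count table + library + ground truth (+ optional per-cell log)."""

    table: BinCountTable
    library: GuideLibrary
    gene_truth: pd.DataFrame   # gene, psi, mu
    guide_truth: pd.DataFrame  # guide_id, gene_id, is_control, beta
    config: SimulationConfig
    cell_counts: np.ndarray | None = None   # (N, p, J_collected) pre-sequencing
    cell_log: list | None = None


def draw_guides_per_cell(moi: float, rng: np.random.Generator) -> int:
    """Number of viral integrations for one cell: Poisson(MOI)."""
    if moi < 0:
        raise ValueError("MOI must be nonnegative")
    return int(rng.poisson(moi))


def required_cells(config: SimulationConfig) -> int:
    """Cells to infect to reach the target effective per-guide coverage."""
    if config.n_cells is not None:
        return config.n_cells
    if config.moi == 0:
        raise ValueError("cannot reach any coverage at MOI 0")
    return math.ceil(config.coverage * config.library_size / config.moi)


def effective_coverage(config: SimulationConfig) -> float:
    """Expected measurements per library guide: n_cells * MOI / p.

    A cell carrying k guides contributes k measurements, so raising the
    MOI raises effective coverage without adding cells.
    """
    return required_cells(config) * config.moi / config.library_size


def draw_effect_sizes(config: SimulationConfig, rng: np.random.Generator):
    """Ground-truth effects: per-gene (psi, mu) and per-guide beta.

    A fixed-count fraction of genes (round(fraction_effect * n_genes),
    chosen uniformly) gets psi = 1 with mu drawn from the configured
    family; their guides get beta = mu + N(0, tau_guide^2).  Excluded
    genes and controls have beta = 0 exactly — simulation truth is
    sparse even though the inference prior jitters null guides.

    Families: ``point`` (value), ``normal`` (sd), ``truncated_normal``
    (sd, min_abs: normal resampled away from (-min_abs, min_abs)).
    """
    G, k = config.n_genes, config.guides_per_gene
    n_eff = int(round(config.fraction_effect * G))
    psi = np.zeros(G, dtype=np.int64)
    psi[rng.choice(G, size=n_eff, replace=False)] = 1
    mu = np.zeros(G)
    pars = config.params()
    if n_eff:
        if config.effect_family == "point":
            mu[psi == 1] = float(pars["value"])
        elif config.effect_family == "normal":
            mu[psi == 1] = rng.normal(0.0, float(pars["sd"]), n_eff)
        elif config.effect_family == "truncated_normal":
            sd, min_abs = float(pars["sd"]), float(pars.get("min_abs", 0.0))
            draws = rng.normal(0.0, sd, n_eff)
            while np.any(np.abs(draws) < min_abs):
                redo = np.abs(draws) < min_abs
                draws[redo] = rng.normal(0.0, sd, int(redo.sum()))
            mu[psi == 1] = draws
        else:
            raise ValueError(f"unknown effect family {config.effect_family!r}")
    beta = np.repeat(mu, k)
    jitter = np.repeat(psi, k) == 1
    beta[jitter] += rng.normal(0.0, config.tau_guide, int(jitter.sum()))
    beta = np.concatenate([beta, np.zeros(config.n_controls)])
    return psi, mu, beta


def _make_library(config: SimulationConfig) -> GuideLibrary:
    ids, genes, ctrl = [], [], []
    for g in range(config.n_genes):
        for j in range(config.guides_per_gene):
            ids.append(f"g{g:04d}_{j + 1}")
            genes.append(f"gene{g:04d}")
            ctrl.append(False)
    for c in range(config.n_controls):
        ids.append(f"ctrl_{c + 1:03d}")
        genes.append("")
        ctrl.append(True)
    return GuideLibrary(np.array(ids, dtype=object), np.array(genes, dtype=object),
                        np.array(ctrl), allow_no_controls=config.n_controls == 0)


def simulate_screen(config: SimulationConfig, rng: np.random.Generator) -> SimulatedScreen:
    """Run the full generative process and return counts plus truth."""
    p = config.library_size
    library = _make_library(config)
    psi, mu, beta = draw_effect_sizes(config, rng)
    n_cells = required_cells(config)
    scheme: BinScheme = cutpoints_from_masses(np.asarray(config.bin_masses, float))
    cut = scheme.cutpoints()          # length J+1, +-inf ends
    inner = cut[1:-1]
    collected = np.asarray(config.collected, dtype=int)
    J_col = collected.size
    col_pos = -np.ones(config.n_bins, dtype=int)
    col_pos[collected] = np.arange(J_col)

    seq_counts = np.zeros((config.n_replicates, p, J_col), dtype=np.int64)
    cell_counts = np.zeros_like(seq_counts)
    logs = [] if config.keep_cell_log else None

    for n in range(config.n_replicates):
        rho = rng.dirichlet(np.full(p, config.tau_rep / p))
        k = rng.poisson(config.moi, n_cells)
        k = k[k > 0]
        if k.size == 0:
            raise RuntimeError(
                f"no infected cells in replicate {n + 1}: MOI {config.moi} "
                f"with {n_cells} cells is the bottleneck"
            )
        total = int(k.sum())
        ids = rng.choice(p, size=total, p=rho)
        cell_of = np.repeat(np.arange(k.size), k)

        # distinct-guide effect per cell: duplicates of one guide count once
        order = np.lexsort((ids, cell_of))
        so_ids, so_cell = ids[order], cell_of[order]
        first = np.ones(total, dtype=bool)
        first[1:] = (so_ids[1:] != so_ids[:-1]) | (so_cell[1:] != so_cell[:-1])
        effect = np.zeros(k.size)
        np.add.at(effect, so_cell[first], beta[so_ids[first]])

        marker = rng.standard_normal(k.size) - effect
        bins = np.searchsorted(inner, marker, side="left")
        keep_cell = col_pos[bins] >= 0
        if not keep_cell.any():
            raise RuntimeError(
                f"no cells fell in collected gates in replicate {n + 1}: "
                f"gates {config.collected} of masses {config.bin_masses} are the bottleneck"
            )
        keep_int = keep_cell[cell_of]
        np.add.at(cell_counts[n], (ids[keep_int], col_pos[bins[cell_of[keep_int]]]), 1)

        for j in range(J_col):
            m_j = int(cell_counts[n, :, j].sum())
            if m_j == 0:
                continue
            depth = config.depth_per_bin if config.depth_per_bin is not None else m_j
            # phi_seq is the concentration of an average-representation guide,
            # so total concentration scales with library size and sequencing
            # noise per guide is library-size invariant
            alpha = config.phi_seq * p * cell_counts[n, :, j] / m_j
            g = rng.gamma(np.maximum(alpha, 0.0))
            s = g.sum()
            seq_counts[n, :, j] = rng.multinomial(depth, g / s)

        if logs is not None:
            logs.append({"k": k, "marker": marker, "bin": bins,
                         "collected": keep_cell,
                         "n_effect_guides": np.bincount(
                             cell_of[np.isin(ids, np.nonzero(beta != 0)[0])],
                             minlength=k.size)})

    table = BinCountTable(
        counts=seq_counts,
        guide_id=library.guide_id,
        replicate_labels=[f"rep{n + 1}" for n in range(config.n_replicates)],
        bin_labels=[f"bin{j + 1}" for j in collected],
    )
    gene_truth = pd.DataFrame({
        "gene": [f"gene{g:04d}" for g in range(config.n_genes)],
        "psi": psi,
        "mu": mu,
    })
    guide_truth = pd.DataFrame({
        "guide_id": library.guide_id,
        "gene_id": library.gene_id,
        "is_control": library.is_control,
        "beta": beta,
    })
    return SimulatedScreen(table=table, library=library, gene_truth=gene_truth,
                           guide_truth=guide_truth, config=config,
                           cell_counts=cell_counts, cell_log=logs)
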