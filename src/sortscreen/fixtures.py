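"""Deterministic toy screens for tests, docs and smoke runs.

Every preset regenerates bit-identically from its (config, seed) pair;
the sha256 digest of the deterministic artifacts (counts + labels) is
pinned here.  Posterior summaries are never digest-pinned — MCMC goldens
are brittle — only the generated data are.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .screen_io import table_digest, write_counts, write_library
from .simulate import SimulatedScreen, SimulationConfig, simulate_screen

__all__ = ["PRESETS", "make_toy_screen"]

PRESETS: dict[str, tuple[SimulationConfig, int]] = {
    # pure-null screen: every gene excluded
    "null_only": (
        SimulationConfig(n_genes=50, guides_per_gene=4, n_controls=10,
                         fraction_effect=0.0, coverage=100, moi=0.3,
                         n_replicates=2),
        11,
    ),
    # one enormous effect (mu = 3 SD) planted among 50 nulls at deep coverage
    "one_big_hit": (
        SimulationConfig(n_genes=51, guides_per_gene=4, n_controls=10,
                         fraction_effect=1.0 / 51, effect_family="point",
                         effect_params=(("value", 3.0),), coverage=500,
                         moi=0.3, n_replicates=2),
        12,
    ),
    # realistic small screen: 200 genes, 10% effects from the default family
    "mixed_small": (
        SimulationConfig(n_genes=200, guides_per_gene=4, n_controls=20,
                         fraction_effect=0.1, coverage=50, moi=0.3,
                         n_replicates=2),
        13,
    ),
    # outer-gates-only design: 15% tails collected, middle dropped
    "two_bin": (
        SimulationConfig(n_genes=50, guides_per_gene=4, n_controls=10,
                         fraction_effect=0.1, coverage=100, moi=0.3,
                         bin_masses=(0.15, 0.35, 0.35, 0.15),
                         collected_bins=(0, 3), n_replicates=2),
        14,
    ),
}

# sha256 of the generated count table per preset (see tests/test_fixtures.py)
EXPECTED_DIGESTS: dict[str, str] = {
    "mixed_small": "4424f1ac5068bdb85a543aa24564d3c700081be9048c3e3aa408ba50d5281d85",
    "null_only": "985c86644223c87a6400a80de8b5a608d529e7f4299ea06746c020df2d1a5ed7",
    "one_big_hit": "d8a57045dae51a0bfc23a7af02e9dff75e016942392e2077f31b2c933502a856",
    "two_bin": "659f72126314ea0123518f327833c0c9849f25b7a990ddc9f0bc2708777cd7e3",
}


def make_toy_screen(name: str, out_dir=None) -> SimulatedScreen:
    """Generate a preset screen; optionally write counts/library/truth TSVs."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    config, seed = PRESETS[name]
    screen = simulate_screen(config, np.random.default_rng(seed))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts(screen.table, screen.library, out / f"{name}_counts.tsv")
        write_library(screen.library, out / f"{name}_library.tsv")
        truth = screen.guide_truth.merge(
            screen.gene_truth, how="left", left_on="gene_id", right_on="gene")
        truth = truth.drop(columns=["gene"]).fillna({"psi": 0, "mu": 0.0})
        truth.to_csv(out / f"{name}_truth.tsv", sep="\t", index=False)
    return screen


def preset_digest(name: str) -> str:
    return table_digest(make_toy_screen(name).table)
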