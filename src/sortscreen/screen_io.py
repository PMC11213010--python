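"""On-disk formats and in-memory containers for sorted-screen count data.

The canonical count-table format is a wide, MAGeCK-style TSV: one row per
guide with ``guide_id`` and ``gene_id`` columns followed by one column per
(replicate, bin) pair named ``<rep>_<bin>``.  Bin 1 is the lowest marker
gate.  Parsing is header-driven, so column order never matters.
"""

from __future__ import annotations

import hashlib
import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GuideLibrary",
    "BinCountTable",
    "PosteriorSummary",
    "read_library",
    "write_library",
    "read_counts",
    "write_counts",
    "write_results",
    "read_results",
]


@dataclass(frozen=True)
class GuideLibrary:
    """Guide -> gene annotation with negative-control flags.

    Controls are identified by the explicit ``is_control`` flag.  A
    convenience prefix match (e.g. guides named ``ctrl_*``) exists in
    :func:`read_library` but must be asked for; gene-name pattern matching
    is never applied silently.
    """

    guide_id: np.ndarray
    gene_id: np.ndarray
    is_control: np.ndarray
    allow_no_controls: bool = False

    def __post_init__(self) -> None:
        gid = np.asarray(self.guide_id, dtype=object)
        gene = np.asarray(self.gene_id, dtype=object)
        ctrl = np.asarray(self.is_control, dtype=bool)
        if not (gid.size == gene.size == ctrl.size):
            raise ValueError("guide_id, gene_id, is_control must have equal length")
        if len(set(gid)) != gid.size:
            dupes = pd.Series(gid)[pd.Series(gid).duplicated()].unique()
            raise ValueError(f"duplicate guide ids: {list(dupes)[:5]}")
        missing = [g for g, gn, c in zip(gid, gene, ctrl) if not c and (gn is None or gn == "")]
        if missing:
            raise ValueError(f"non-control guides without gene_id: {missing[:5]}")
        if not ctrl.any() and not self.allow_no_controls:
            raise ValueError(
                "library has no control guides; pass allow_no_controls=True to "
                "fall back on the assumption that most guides are null"
            )
        object.__setattr__(self, "guide_id", gid)
        object.__setattr__(self, "gene_id", gene)
        object.__setattr__(self, "is_control", ctrl)

    @property
    def n_guides(self) -> int:
        return self.guide_id.size

    @property
    def genes(self) -> list[str]:
        """Target genes (controls excluded), in first-appearance order."""
        seen: dict[str, None] = {}
        for g, c in zip(self.gene_id, self.is_control):
            if not c and g not in seen:
                seen[g] = None
        return list(seen)

    def gene_index(self) -> tuple[np.ndarray, list[str]]:
        """Per-guide gene index (controls get -1) and the gene list."""
        genes = self.genes
        lookup = {g: i for i, g in enumerate(genes)}
        idx = np.array(
            [-1 if c else lookup[g] for g, c in zip(self.gene_id, self.is_control)],
            dtype=np.int64,
        )
        return idx, genes


@dataclass
class BinCountTable:
    """gRNA x bin sequencing counts for each replicate.

    ``counts`` has shape ``(n_replicates, n_guides, n_bins)``; bin axis is
    ordered low -> high marker.  ``totals`` caches the per-guide row sums
    (the guide coverage ``c_nh``).
    """

    counts: np.ndarray
    guide_id: np.ndarray
    replicate_labels: list[str]
    bin_labels: list[str]
    totals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValueError("counts must be (replicates, guides, bins)")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if c.shape[0] != len(self.replicate_labels) or c.shape[2] != len(self.bin_labels):
            raise ValueError("counts shape inconsistent with labels")
        if c.shape[1] != np.asarray(self.guide_id).size:
            raise ValueError("counts shape inconsistent with guide ids")
        self.counts = c.astype(np.int64)
        self.guide_id = np.asarray(self.guide_id, dtype=object)
        self.totals = self.counts.sum(axis=2)

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    @property
    def n_guides(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


@dataclass
class PosteriorSummary:
    """Posterior summaries of one fit.

    ``genes``: one row per gene — ``gene``, ``pip``, ``effect_mean``,
    ``ci_lo``, ``ci_hi`` (slab-conditional central interval), ``n_guides``,
    ``called``.  ``guides``: per-guide posterior mean effect.
    ``replicates``: posterior mean bin masses and dispersion per replicate.
    ``diagnostics``: sampler metadata (chains, draws, split-R-hat table,
    acceptance rates).
    """

    genes: pd.DataFrame
    guides: pd.DataFrame
    replicates: pd.DataFrame
    diagnostics: dict
    credible_level: float = 0.10


# ---------------------------------------------------------------------------
# readers / writers

def read_library(path, control_prefix: str | None = None,
                 allow_no_controls: bool = False) -> GuideLibrary:
    """Read a guide library TSV with columns guide_id, gene_id, is_control.

    ``is_control`` accepts 0/1/true/false.  If ``control_prefix`` is given,
    guides whose id starts with it are ALSO flagged as controls (explicit
    opt-in convenience).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"guide_id", "gene_id", "is_control"}
    if not required.issubset(df.columns):
        raise ValueError(f"library file missing columns: {sorted(required - set(df.columns))}")
    ctrl = df["is_control"].str.strip().str.lower().isin(["1", "true", "t", "yes"]).to_numpy()
    if control_prefix:
        ctrl = ctrl | df["guide_id"].str.startswith(control_prefix).to_numpy()
    gene = df["gene_id"].fillna("").str.strip().to_numpy(dtype=object)
    return GuideLibrary(
        guide_id=df["guide_id"].str.strip().to_numpy(dtype=object),
        gene_id=gene,
        is_control=ctrl,
        allow_no_controls=allow_no_controls,
    )


def write_library(library: GuideLibrary, path) -> None:
    df = pd.DataFrame(
        {
            "guide_id": library.guide_id,
            "gene_id": library.gene_id,
            "is_control": library.is_control.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


_SAMPLE_COL = re.compile(r"^(?P<rep>.+)_(?P<bin>[^_]+)$")


def read_counts(path, library: GuideLibrary, bin_order: list[str]) -> BinCountTable:
    """Read a wide count TSV; sample columns are named ``<rep>_<bin>``.

    Bins are returned in the order given by ``bin_order`` (low -> high
    marker), regardless of column order in the file.  Guides present in the
    file but absent from the library raise an error naming the offenders.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = [str(c).strip() for c in df.columns]
    if "guide_id" not in df.columns or "gene_id" not in df.columns:
        raise ValueError("count file must have guide_id and gene_id columns")
    if df["guide_id"].duplicated().any():
        dupes = df.loc[df["guide_id"].duplicated(), "guide_id"].unique()
        raise ValueError(f"duplicate guide rows in count file: {list(dupes)[:5]}")

    known = set(library.guide_id)
    unknown = [g for g in df["guide_id"] if g not in known]
    if unknown:
        raise ValueError(f"guides in count file absent from library: {unknown[:10]}")

    sample_cols = [c for c in df.columns if c not in ("guide_id", "gene_id")]
    parsed = {}
    for col in sample_cols:
        m = _SAMPLE_COL.match(col)
        if m is None or m.group("bin") not in bin_order:
            raise ValueError(
                f"sample column {col!r} does not parse as <rep>_<bin> with bins {bin_order}"
            )
        parsed[col] = (m.group("rep"), m.group("bin"))
    reps = sorted({r for r, _ in parsed.values()})
    expected = {(r, b) for r in reps for b in bin_order}
    if set(parsed.values()) != expected:
        missing = sorted(expected - set(parsed.values()))
        raise ValueError(f"missing sample columns for (replicate, bin) pairs: {missing[:10]}")

    # align to library order, restricted to guides present in the file
    order = {g: i for i, g in enumerate(df["guide_id"])}
    keep = [g for g in library.guide_id if g in order]
    df = df.iloc[[order[g] for g in keep]].reset_index(drop=True)

    counts = np.zeros((len(reps), len(keep), len(bin_order)), dtype=np.int64)
    for col, (r, b) in parsed.items():
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
        counts[reps.index(r), :, bin_order.index(b)] = vals.to_numpy()
    return BinCountTable(
        counts=counts,
        guide_id=np.asarray(keep, dtype=object),
        replicate_labels=reps,
        bin_labels=list(bin_order),
    )


def write_counts(table: BinCountTable, library: GuideLibrary, path) -> None:
    """Write the wide TSV that :func:`read_counts` reads back."""
    gene_of = dict(zip(library.guide_id, library.gene_id))
    data: dict[str, object] = {
        "guide_id": table.guide_id,
        "gene_id": [gene_of.get(g, "") for g in table.guide_id],
    }
    for n, rep in enumerate(table.replicate_labels):
        for j, b in enumerate(table.bin_labels):
            data[f"{rep}_{b}"] = table.counts[n, :, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


_RESULT_COLS = ["gene", "pip", "effect_mean", "ci_lo", "ci_hi", "n_guides", "called"]


def write_results(summary: PosteriorSummary, path, header_meta: dict | None = None) -> None:
    """Write the per-gene results TSV (stable column order, 6 sig digits).

    ``header_meta`` entries are written as ``# key: value`` comment lines
    for provenance (seed, config hash, package version...).
    """
    df = summary.genes.loc[:, _RESULT_COLS].copy()
    buf = _io.StringIO()
    for k, v in (header_meta or {}).items():
        buf.write(f"# {k}: {v}\n")
    df["called"] = df["called"].astype(bool)
    df.to_csv(buf, sep="\t", index=False, float_format="%.6f")
    Path(path).write_text(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def table_digest(table: BinCountTable) -> str:
    """sha256 of the count array + labels; used to pin deterministic fixtures."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(table.counts).tobytes())
    h.update("|".join(map(str, table.guide_id)).encode())
    h.update("|".join(table.replicate_labels).encode())
    h.update("|".join(table.bin_labels).encode())
    return h.hexdigest()
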