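"""Abundance tables, sample metadata, and alpha-diversity measures.

An :class:`AbundanceTable` holds a samples x taxa matrix (raw read counts or
relative abundances) together with per-sample metadata: the production site
the sample came from and its matrix, one of the four sampled material types
CF (cow feces), LIT (litter), MIL (raw milk) and PC (cheese at day one of
ripening).

Alpha diversity follows the usual definitions: Chao1 richness with the
bias-corrected fallback when no doubletons are observed, Shannon entropy in
nats, and rarefaction by subsampling reads without replacement at evenly
spaced depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon

from .errors import ChainTraceError, FormatError

MATRICES = ("CF", "LIT", "MIL", "PC")

_META_COLS = ["site", "matrix", "replicate"]


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with per-sample (site, matrix) labels.

    Parameters
    ----------
    values:
        DataFrame indexed by sample id, one column per taxon, non-negative.
    meta:
        DataFrame indexed by sample id with columns ``site``, ``matrix``
        (one of CF/LIT/MIL/PC) and ``replicate``.
    relative:
        True if rows are relative abundances (row sums <= 1 + 1e-9),
        False if raw counts.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    relative: bool = True

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.meta = self.meta.copy()
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if not self.values.index.equals(self.meta.index):
            raise FormatError("values and metadata list different samples")
        missing = [c for c in _META_COLS if c not in self.meta.columns]
        if missing:
            raise FormatError(f"metadata misses columns: {missing}")
        bad_matrix = sorted(set(self.meta["matrix"]) - set(MATRICES))
        if bad_matrix:
            raise FormatError(
                f"unknown matrix labels {bad_matrix}; expected one of {MATRICES}"
            )
        if self.values.size:
            arr = self.values.to_numpy(dtype=float)
            if np.isnan(arr).any():
                raise FormatError("NaN abundance; encode absence as 0")
            if (arr < 0).any():
                r, c = np.argwhere(arr < 0)[0]
                raise FormatError(
                    f"negative abundance at sample {self.values.index[r]!r}, "
                    f"taxon {self.values.columns[c]!r}"
                )
            if self.relative and (arr.sum(axis=1) > 1 + 1e-9).any():
                bad = self.values.index[arr.sum(axis=1) > 1 + 1e-9][0]
                raise FormatError(f"relative abundances of sample {bad!r} exceed 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sites(self) -> list[str]:
        return sorted(set(self.meta["site"]))

    def group_samples(self, site: str, matrix: str) -> pd.Index:
        """Sample ids belonging to one (site, matrix) group."""
        m = (self.meta["site"] == site) & (self.meta["matrix"] == matrix)
        return self.meta.index[m]

    def groups(self) -> list[tuple[str, str]]:
        """All (site, matrix) groups present in the metadata, sorted."""
        pairs = {(s, m) for s, m in zip(self.meta["site"], self.meta["matrix"])}
        return sorted(pairs, key=lambda p: (p[0], MATRICES.index(p[1])))


def write_table(table: AbundanceTable, path: str | Path) -> None:
    """Write an abundance table as TSV (sample_id, site, matrix, replicate, taxa...)."""
    out = pd.concat([table.meta[_META_COLS], table.values], axis=1)
    out.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write(f"# relative={'1' if table.relative else '0'}\n")
        out.to_csv(fh, sep="\t")


def read_table(path: str | Path) -> AbundanceTable:
    """Read a TSV abundance table; inverse of :func:`write_table`."""
    path = Path(path)
    relative = True
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            relative = "relative=1" in first.replace(" ", "")
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col="sample_id")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    meta = df[_META_COLS]
    values = df.drop(columns=_META_COLS)
    values.columns.name = None
    return AbundanceTable(values=values, meta=meta, relative=relative)


@dataclass(frozen=True)
class DiversityResult:
    """Alpha-diversity summary for one sample."""

    sample_id: str
    s_obs: int
    f1: int  # singleton taxa
    f2: int  # doubleton taxa
    chao1: float
    shannon: float
    depth: int  # reads used


def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1 or arr.size == 0:
        raise ChainTraceError("expected a non-empty 1-d count vector")
    if np.any(arr < 0):
        raise ChainTraceError("counts must be non-negative")
    if not np.all(arr == np.floor(arr)):
        raise ChainTraceError(
            "diversity estimators need raw integer read counts, "
            "not relative abundances"
        )
    if arr.sum() == 0:
        raise ChainTraceError("all-zero count vector")
    return arr.astype(np.int64)


def chao1(counts) -> tuple[float, int, int, int]:
    """Chao1 richness estimate.

    Uses the classic estimator S_obs + F1^2 / (2 F2) when doubletons exist,
    and the bias-corrected form S_obs + F1(F1-1) / (2(F2+1)) when F2 = 0.

    Returns
    -------
    (chao1, s_obs, f1, f2)
    """
    arr = _check_counts(counts)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    est = float(_skbio_chao1(arr, bias_corrected=(f2 == 0)))
    return est, s_obs, f1, f2


def shannon(counts, base: float = np.e) -> float:
    """Shannon diversity H = -sum p_i log p_i (natural log by default)."""
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or arr.size == 0 or arr.sum() <= 0:
        raise ChainTraceError("expected counts with at least one positive entry")
    if np.any(arr < 0):
        raise ChainTraceError("counts must be non-negative")
    return float(_skbio_shannon(arr, base=base))


def rarefaction_curve(
    counts,
    n_points: int = 10,
    seed: int | None = 0,
    n_repeats: int = 10,
) -> list[tuple[int, float]]:
    """Observed-taxa rarefaction at evenly spaced subsampling depths.

    Depths are ``n_points`` values from total/n_points up to the full read
    total; at each depth reads are subsampled without replacement
    (multivariate hypergeometric) ``n_repeats`` times and the observed taxon
    counts averaged. At full depth the curve equals S_obs exactly.
    """
    arr = _check_counts(counts)
    total = int(arr.sum())
    if total < n_points:
        raise ChainTraceError(f"need >= {n_points} reads for {n_points} depths")
    rng = np.random.default_rng(seed)
    depths = [round(total * (i + 1) / n_points) for i in range(n_points)]
    curve = []
    for depth in depths:
        if depth == total:
            obs = float((arr > 0).sum())
        else:
            vals = [
                (rng.multivariate_hypergeometric(arr, depth) > 0).sum()
                for _ in range(n_repeats)
            ]
            obs = float(np.mean(vals))
        curve.append((depth, obs))
    return curve


def sample_diversity(
    table: AbundanceTable,
    n_points: int = 10,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Chao1 + Shannon per sample of a count table, as a tidy DataFrame."""
    if table.relative:
        raise ChainTraceError("diversity needs a raw count table")
    rows = []
    for sid in table.values.index:
        counts = table.values.loc[sid].to_numpy()
        est, s_obs, f1, f2 = chao1(counts)
        rows.append(
            DiversityResult(
                sample_id=str(sid),
                s_obs=s_obs,
                f1=f1,
                f2=f2,
                chao1=est,
                shannon=shannon(counts),
                depth=int(counts.sum()),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")


def prevalence(table: AbundanceTable, group, taxon: str) -> float:
    """Fraction of the group's samples in which the taxon is detected (> 0)."""
    group = list(group)
    if not group:
        raise ChainTraceError("empty sample group")
    if taxon not in table.values.columns:
        return 0.0
    vals = table.values.loc[group, taxon]
    return float((vals > 0).mean())
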