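"""Transcriptome screen: RPKM and the strict >n-fold up-regulation filter.

RPKM (reads per kilobase of gene per million mapped reads) is computed as

    RPKM = numReads / (geneLength/1000 * totalNumReads/1e6)

and a gene passes the screen when its condition/control RPKM ratio is
strictly greater than the fold threshold (default 3). A gene silent in the
control but expressed in the condition has an infinite ratio and passes,
flagged as such; genes silent in both are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ChainTraceError


def rpkm(num_reads: float, gene_length: int, total_num_reads: int) -> float:
    """Reads per kilobase per million mapped reads."""
    if gene_length <= 0:
        raise ChainTraceError("gene_length must be positive")
    if total_num_reads <= 0:
        raise ChainTraceError("totalNumReads must be positive")
    if num_reads < 0:
        raise ChainTraceError("numReads must be non-negative")
    return num_reads / (gene_length / 1000 * total_num_reads / 1_000_000)


@dataclass(frozen=True)
class FoldChangeRecord:
    gene_id: str
    rpkm_condition: float
    rpkm_control: float
    fold_change: float  # inf when control is 0 and condition > 0
    passes: bool


def fold_screen(
    condition_rpkm: dict[str, float] | pd.Series,
    control_rpkm: dict[str, float] | pd.Series,
    fold: float = 3.0,
) -> list[FoldChangeRecord]:
    """Genes up-regulated strictly more than ``fold``-fold over the control.

    Both inputs must cover the same gene set. Output order follows sorted
    gene ids (invariant to input ordering).
    """
    cond = dict(condition_rpkm)
    ctrl = dict(control_rpkm)
    if set(cond) != set(ctrl):
        only_a = sorted(set(cond) - set(ctrl))[:3]
        only_b = sorted(set(ctrl) - set(cond))[:3]
        raise ChainTraceError(
            f"mismatched gene sets (e.g. condition-only {only_a}, "
            f"control-only {only_b})"
        )
    out = []
    for gene in sorted(cond):
        a, b = float(cond[gene]), float(ctrl[gene])
        if a == 0 and b == 0:
            continue
        ratio = float("inf") if b == 0 else a / b
        out.append(
            FoldChangeRecord(
                gene_id=gene,
                rpkm_condition=a,
                rpkm_control=b,
                fold_change=ratio,
                passes=ratio > fold,
            )
        )
    return out


def screen_table(
    counts: pd.DataFrame,
    total_condition: int | None = None,
    total_control: int | None = None,
    fold: float = 3.0,
) -> pd.DataFrame:
    """Full screen from a gene count table.

    ``counts`` needs columns gene_id, length_bp, reads_condition,
    reads_control. Library sizes (totalNumReads) are taken from explicit
    ``total_condition`` / ``total_control`` columns if present (the whole
    library, which a gene subset does not sum to), then from the keyword
    arguments, then fall back to the column sums. Returns a DataFrame with
    RPKMs, fold change, and the pass flag.
    """
    required = {"gene_id", "length_bp", "reads_condition", "reads_control"}
    missing = required - set(counts.columns)
    if missing:
        raise ChainTraceError(f"count table misses columns {sorted(missing)}")
    if total_condition is None and "total_condition" in counts.columns:
        total_condition = int(counts["total_condition"].iloc[0])
    if total_control is None and "total_control" in counts.columns:
        total_control = int(counts["total_control"].iloc[0])
    total_condition = total_condition or int(counts["reads_condition"].sum())
    total_control = total_control or int(counts["reads_control"].sum())
    cond = {
        r.gene_id: rpkm(r.reads_condition, r.length_bp, total_condition)
        for r in counts.itertuples()
    }
    ctrl = {
        r.gene_id: rpkm(r.reads_control, r.length_bp, total_control)
        for r in counts.itertuples()
    }
    records = fold_screen(cond, ctrl, fold=fold)
    return pd.DataFrame([r.__dict__ for r in records]).set_index("gene_id")
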