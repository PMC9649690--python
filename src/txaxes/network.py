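"""High-confidence RBP-transcript regulatory network.

An edge RBP -> transcript requires two independent lines of evidence:

* the transcript is significantly changed upon knockdown of the RBP —
  |fold change| > 1.5 and FDR < 0.05 (both strict, fold change on the
  linear scale so the cut is |log2FC| > log2(1.5));
* at least one of that RBP's binding peaks overlaps the transcript
  (default: its exonic intervals; ``span`` mode relaxes to the full locus).

Edge direction is the sign of the knockdown log2 fold change (``up`` =
transcript increases when the RBP is removed). Peaks carrying a strand are
matched same-strand; strand ``.`` matches either strand.

The module also summarises CRISPR dependency matrices: a gene is essential
in a cell line when its dependency score is < -1 (strict).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import TranscriptModel
from .errors import ConfigurationError, DataError

__all__ = [
    "filter_significant",
    "build_network",
    "summarize_network",
    "essentiality_summary",
]

DE_COLUMNS = ["transcript_id", "log2fc", "fdr"]


def filter_significant(
    de: pd.DataFrame, fc_threshold: float = 1.5, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Rows with |fold change| > fc_threshold AND fdr < fdr_threshold.

    ``fc_threshold`` is on the linear fold-change scale; the table carries
    log2 fold changes. Both comparisons are strict, so a row at exactly
    1.5-fold or FDR exactly 0.05 is dropped.
    """
    if fc_threshold <= 0:
        raise ConfigurationError("fc_threshold must be positive")
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise DataError(f"DE table lacks columns {missing}")
    if ((de["fdr"] < 0) | (de["fdr"] > 1)).any():
        raise DataError("FDR values must lie in [0, 1]")
    keep = (de["log2fc"].abs() > np.log2(fc_threshold)) & (
        de["fdr"] < fdr_threshold
    )
    return de.loc[keep].copy()


def _exon_tree(
    models: dict[str, TranscriptModel], use: str
) -> dict[str, IntervalTree]:
    """Index transcript intervals per chromosome; 1-based closed stored as
    half-open [start, end+1). Data payload = (transcript_id, strand)."""
    trees: dict[str, IntervalTree] = {}
    for m in models.values():
        tree = trees.setdefault(m.chrom, IntervalTree())
        intervals = m.exons if use == "exon" else (m.span,)
        for a, b in intervals:
            tree.addi(a, b + 1, (m.id, m.strand))
    return trees


def build_network(
    de_set: dict[str, pd.DataFrame],
    peaks: dict[str, pd.DataFrame],
    models: dict[str, TranscriptModel],
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    overlap: str = "exon",
) -> pd.DataFrame:
    """Intersect knockdown DE with binding peaks into an edge table.

    ``de_set``/``peaks``: mapping RBP id -> DE table / BED DataFrame.
    Returns columns (rbp_id, transcript_id, direction, n_supporting_peaks,
    log2fc, fdr). RBPs with peaks but no DE table are skipped with a
    warning.
    """
    if overlap not in ("exon", "span"):
        raise ConfigurationError(f"unknown overlap policy {overlap!r}")
    trees = _exon_tree(models, overlap)
    orphan = sorted(set(peaks) - set(de_set))
    if orphan:
        warnings.warn(f"RBPs with peaks but no DE table skipped: {orphan}")
    rows = []
    for rbp, de in de_set.items():
        sig = filter_significant(de, fc_threshold, fdr_threshold)
        if sig.empty:
            continue
        sig_ids = set(sig["transcript_id"])
        peak_hits: dict[str, int] = {}
        for _, pk in peaks.get(rbp, pd.DataFrame(columns=["chrom"])).iterrows():
            tree = trees.get(str(pk["chrom"]))
            if tree is None:
                continue
            # BED half-open [start, end) -> 1-based closed [start+1, end];
            # a peak spanning several exons of one transcript counts once
            hit_tids = set()
            for iv in tree.overlap(int(pk["start"]) + 1, int(pk["end"]) + 1):
                tid, strand = iv.data
                pk_strand = str(pk.get("strand", "."))
                if pk_strand in ("+", "-") and pk_strand != strand:
                    continue
                if tid in sig_ids:
                    hit_tids.add(tid)
            for tid in hit_tids:
                peak_hits[tid] = peak_hits.get(tid, 0) + 1
        for _, row in sig.iterrows():
            tid = row["transcript_id"]
            n = peak_hits.get(tid, 0)
            if n >= 1:
                rows.append(
                    {
                        "rbp_id": rbp,
                        "transcript_id": tid,
                        "direction": "up" if row["log2fc"] > 0 else "down",
                        "n_supporting_peaks": n,
                        "log2fc": row["log2fc"],
                        "fdr": row["fdr"],
                    }
                )
    columns = ["rbp_id", "transcript_id", "direction", "n_supporting_peaks",
               "log2fc", "fdr"]
    edges = pd.DataFrame(rows, columns=columns)
    return edges.sort_values(["rbp_id", "transcript_id"], ignore_index=True)


def summarize_network(edges: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-RBP counts (total/up/down), per-transcript distinct-RBP degree,
    and the degree distribution of transcripts over RBPs."""
    if edges.empty:
        empty_rbp = pd.DataFrame(columns=["rbp_id", "total", "up", "down"])
        empty_t = pd.DataFrame(columns=["transcript_id", "n_rbps"])
        empty_d = pd.DataFrame(columns=["n_rbps", "n_transcripts"])
        return {"per_rbp": empty_rbp, "per_transcript": empty_t,
                "degree_distribution": empty_d}
    per_rbp = (
        edges.pivot_table(
            index="rbp_id", columns="direction", values="transcript_id",
            aggfunc="count", fill_value=0,
        )
        .reindex(columns=["up", "down"], fill_value=0)
        .reset_index()
    )
    per_rbp.columns.name = None
    per_rbp["total"] = per_rbp["up"] + per_rbp["down"]
    per_rbp = per_rbp[["rbp_id", "total", "up", "down"]]
    per_transcript = (
        edges.groupby("transcript_id")["rbp_id"].nunique().rename("n_rbps")
        .reset_index()
    )
    degree = (
        per_transcript.groupby("n_rbps").size().rename("n_transcripts")
        .reset_index()
    )
    return {
        "per_rbp": per_rbp,
        "per_transcript": per_transcript,
        "degree_distribution": degree,
    }


def essentiality_summary(dep: pd.DataFrame, threshold: float = -1.0) -> pd.Series:
    """Count, per gene (row), the cell lines with dependency score strictly
    below ``threshold`` (default -1, the conventional essentiality cut)."""
    if dep.empty:
        return pd.Series(dtype=int, name="n_essential_cell_lines")
    return (
        (dep < threshold).sum(axis=1).rename("n_essential_cell_lines")
    )
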