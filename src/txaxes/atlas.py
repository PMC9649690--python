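"""Expression atlas handling and lineage-specificity scoring.

A transcript expression atlas is a nonnegative TPM matrix (transcripts x
cell lines) together with a mapping from each cell line to its lineage of
origin. Two derived objects matter downstream:

* a :class:`LineageProfile` — per-lineage aggregated expression ``x_it``
  and the row-normalised expression ratios ``p_it = x_it / sum_i x_it``;
* a specificity table scoring each transcript with

      S_t = log2(N) - H(p_t),   H(p_t) = -sum_i p_it log2 p_it,

  where ``N`` is the number of lineages. ``S_t = 0`` for a perfectly
  uniform transcript and ``log2(N)`` for one expressed in a single lineage.

A transcript is called lineage specific when its largest expression ratio
exceeds twice the second largest AND ``S_t > 1`` (both strict); the called
lineage is the argmax-ratio lineage. A relaxed rule using only ``S_t > 1``
(used when scoring genes such as RBPs rather than transcripts) is available
via ``require_ratio=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "ExpressionAtlas",
    "LineageProfile",
    "load_expression",
    "write_expression",
    "prevalence_filter",
    "aggregate_by_lineage",
    "specificity_scores",
    "call_lineage_specific",
]


@dataclass
class ExpressionAtlas:
    """TPM matrix (rows: transcripts, columns: cell lines) plus lineage map."""

    values: pd.DataFrame
    lineage_of: pd.Series  # index: cell line id -> lineage label

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise DataError("duplicate transcript ids in expression matrix")
        if v.columns.has_duplicates:
            raise DataError("duplicate cell line ids in expression matrix")
        if (v.to_numpy() < 0).any():
            raise DataError("negative expression values are not valid TPM")
        missing = v.columns.difference(self.lineage_of.index)
        if len(missing):
            raise DataError(
                f"cell lines without a lineage label: {list(missing)[:5]}"
            )
        # restrict + order the map to the matrix columns
        self.lineage_of = self.lineage_of.loc[v.columns]

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_line_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def lineages(self) -> list[str]:
        return sorted(self.lineage_of.unique())

    def subset(self, transcript_ids) -> "ExpressionAtlas":
        return ExpressionAtlas(self.values.loc[transcript_ids], self.lineage_of)


@dataclass
class LineageProfile:
    """Lineage-aggregated expression and expression ratios.

    ``x``: transcript x lineage aggregated TPM; ``p``: expression ratios
    (rows sum to 1 for transcripts with any expression); ``undefined``:
    boolean Series flagging all-zero transcripts whose ratios are undefined
    and which are excluded from scoring.
    """

    x: pd.DataFrame
    p: pd.DataFrame
    undefined: pd.Series = field(repr=False)

    @property
    def n_lineages(self) -> int:
        return self.x.shape[1]


def load_expression(path, lineage_path=None, *, lineage_of=None) -> ExpressionAtlas:
    """Read a TPM matrix from TSV (first column: transcript id) plus a
    two-column lineage map TSV (cell_line, lineage).

    Either ``lineage_path`` or an explicit ``lineage_of`` Series must be
    given. Raises :class:`DataError` on malformed input.
    """
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapping
        raise DataError(f"could not parse expression matrix {path}: {exc}") from exc
    if values.shape[1] == 0:
        raise DataError(f"expression matrix {path} has no cell line columns")
    if not all(np.issubdtype(dt, np.number) for dt in values.dtypes):
        raise DataError(f"non-numeric expression values in {path}")
    if lineage_of is None:
        if lineage_path is None:
            raise ConfigurationError("a lineage map is required to build an atlas")
        lmap = pd.read_csv(lineage_path, sep="\t")
        if lmap.shape[1] < 2:
            raise DataError(f"lineage map {lineage_path} needs two columns")
        lineage_of = lmap.set_index(lmap.columns[0])[lmap.columns[1]]
    return ExpressionAtlas(values, pd.Series(lineage_of))


def write_expression(atlas: ExpressionAtlas, matrix_path, lineage_path=None) -> None:
    """Write the TPM matrix (and optionally the lineage map) as TSV."""
    atlas.values.to_csv(matrix_path, sep="\t", index_label="transcript_id")
    if lineage_path is not None:
        atlas.lineage_of.rename_axis("cell_line").rename("lineage").to_csv(
            lineage_path, sep="\t"
        )


def prevalence_filter(
    atlas: ExpressionAtlas,
    min_tpm: float = 0.1,
    min_cells: int | None = 1,
    min_fraction: float | None = None,
    mode: str = "inclusive",
) -> ExpressionAtlas:
    """Keep transcripts detectably expressed in enough cell lines.

    Two dialects are used in practice and both are supported via ``mode``:

    * ``"inclusive"`` — expression >= min_tpm (atlas-building convention:
      >=0.1 TPM in at least one cell line);
    * ``"strict"`` — expression > min_tpm (drug-association convention:
      TPM > 0.1 in at least 20% of cell lines).

    ``min_cells`` gives an absolute count; ``min_fraction`` a fraction of
    the atlas' cell lines (takes precedence when given). Returns a new
    atlas; the input is untouched.
    """
    if min_tpm < 0:
        raise ConfigurationError("min_tpm must be nonnegative")
    if mode not in ("inclusive", "strict"):
        raise ConfigurationError(f"unknown prevalence mode {mode!r}")
    v = atlas.values.to_numpy()
    detected = v >= min_tpm if mode == "inclusive" else v > min_tpm
    n_detected = detected.sum(axis=1)
    if min_fraction is not None:
        if not 0 <= min_fraction <= 1:
            raise ConfigurationError("min_fraction must lie in [0, 1]")
        need = min_fraction * atlas.values.shape[1]
    else:
        if min_cells is None or min_cells < 1:
            raise ConfigurationError("min_cells must be a positive count")
        need = min_cells
    keep = n_detected >= need
    return ExpressionAtlas(atlas.values.loc[keep], atlas.lineage_of)


def aggregate_by_lineage(atlas: ExpressionAtlas, method: str = "mean") -> LineageProfile:
    """Aggregate cell-line columns into one column per lineage.

    ``method`` is one of ``mean`` (default), ``median`` or ``sum``; the
    scoring statistic downstream is scale invariant, so mean and sum give
    identical ratios when lineages are balanced. Transcripts with zero
    total aggregated expression are flagged undefined.
    """
    if method not in ("mean", "median", "sum"):
        raise ConfigurationError(f"unknown aggregation method {method!r}")
    counts = atlas.lineage_of.value_counts()
    if (counts < 1).any():  # pragma: no cover - value_counts never yields 0
        raise ConfigurationError("every lineage needs at least one cell line")
    grouped = atlas.values.T.groupby(atlas.lineage_of)
    x = getattr(grouped, method)().T
    x = x[sorted(x.columns)]
    totals = x.sum(axis=1)
    undefined = totals <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = x.div(totals, axis=0)
    p[undefined] = np.nan
    return LineageProfile(x=x, p=p, undefined=undefined)


def specificity_scores(profile: LineageProfile) -> pd.DataFrame:
    """Score every transcript with S_t = log2(N) - Shannon entropy of its
    lineage expression-ratio distribution.

    Uses the 0*log2(0) = 0 convention. Returns a DataFrame indexed by
    transcript with columns ``score``, ``top_lineage``, ``top_ratio``,
    ``second_ratio`` and ``undefined`` (all-zero transcripts carry NaN
    score and undefined=True).
    """
    p = profile.p.to_numpy(dtype=float)
    n = profile.n_lineages
    positive = p > 0  # NaN-safe; 0*log2(0) := 0
    p_safe = np.where(positive, p, 1.0)
    plogp = np.where(positive, p_safe * np.log2(p_safe), 0.0)
    entropy = -np.nansum(plogp, axis=1)
    score = np.log2(n) - entropy
    # clip the tiny negative/overshoot from float summation
    score = np.clip(score, 0.0, np.log2(n))
    order = np.sort(np.nan_to_num(p, nan=0.0), axis=1)
    top = order[:, -1]
    second = order[:, -2] if n >= 2 else np.zeros(len(p))
    lineages = np.asarray(profile.p.columns)
    top_idx = np.nanargmax(np.where(np.isnan(p), -1.0, p), axis=1)
    result = pd.DataFrame(
        {
            "score": score,
            "top_lineage": lineages[top_idx],
            "top_ratio": top,
            "second_ratio": second,
            "undefined": profile.undefined.to_numpy(),
        },
        index=profile.p.index,
    )
    result.loc[result["undefined"], ["score", "top_ratio", "second_ratio"]] = np.nan
    result.loc[result["undefined"], "top_lineage"] = None
    return result


def call_lineage_specific(
    scores: pd.DataFrame,
    score_min: float = 1.0,
    ratio_factor: float = 2.0,
    require_ratio: bool = True,
) -> pd.DataFrame:
    """Apply the lineage-specificity decision rule.

    ``is_specific`` is True when ``score > score_min`` and (if
    ``require_ratio``) ``top_ratio > ratio_factor * second_ratio``; both
    comparisons strict. ``called_lineage`` is the top-ratio lineage for
    specific transcripts, None otherwise. When the second ratio is exactly
    zero the ratio condition reduces to ``top_ratio > 0``.
    """
    out = scores.copy()
    ok = ~out["undefined"].astype(bool)
    passes = ok & (out["score"] > score_min)
    if require_ratio:
        passes &= out["top_ratio"] > ratio_factor * out["second_ratio"]
    out["is_specific"] = passes.fillna(False)
    out["called_lineage"] = out["top_lineage"].where(out["is_specific"], None)
    return out
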