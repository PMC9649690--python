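"""Integration of regulatory edges and drug associations into axes.

An RBP-transcript-drug axis exists when an RBP regulates a transcript
(high-confidence edge) and that same transcript's expression is associated
with sensitivity to a drug (called association): the axis table is the
relational join of the two tables on transcript id, so a transcript with
``r`` regulating RBPs and ``d`` associated drugs contributes ``r x d``
axes.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["build_axes", "summarize_axes"]


def build_axes(edges: pd.DataFrame, associations: pd.DataFrame) -> pd.DataFrame:
    """Join edges (rbp_id, transcript_id, direction, ...) with called
    associations (transcript_id, drug_id, score, direction, ...).

    Returns columns (rbp_id, transcript_id, drug_id, regulation_direction,
    association_direction, score). Warns when both inputs are nonempty yet
    share no transcript ids (likely an id-namespace mismatch).
    """
    cols = ["rbp_id", "transcript_id", "drug_id",
            "regulation_direction", "association_direction", "score"]
    if edges.empty or associations.empty:
        return pd.DataFrame(columns=cols)
    left = edges.rename(columns={"direction": "regulation_direction"})[
        ["rbp_id", "transcript_id", "regulation_direction"]
    ]
    right = associations.rename(
        columns={"direction": "association_direction"}
    )[["transcript_id", "drug_id", "association_direction", "score"]]
    if not set(left["transcript_id"]) & set(right["transcript_id"]):
        warnings.warn(
            "regulatory edges and drug associations share no transcript ids"
        )
    axes = left.merge(right, on="transcript_id", how="inner")
    return axes[cols].sort_values(
        ["rbp_id", "transcript_id", "drug_id"], ignore_index=True
    )


def summarize_axes(
    axes: pd.DataFrame, annotated_of: dict[str, bool] | pd.Series | None = None
) -> dict:
    """Count distinct nodes and, when an annotated/unannotated label per
    transcript is supplied, the share of bridging transcripts that are
    unannotated and the share of distinct (RBP, drug) connections linked
    only by unannotated transcripts."""
    summary = {
        "n_axes": int(len(axes)),
        "n_rbps": int(axes["rbp_id"].nunique()) if len(axes) else 0,
        "n_transcripts": int(axes["transcript_id"].nunique()) if len(axes) else 0,
        "n_drugs": int(axes["drug_id"].nunique()) if len(axes) else 0,
    }
    if annotated_of is not None and len(axes):
        annotated_of = pd.Series(annotated_of)
        bridging = axes["transcript_id"].unique()
        unann = {t for t in bridging if not annotated_of.get(t, True)}
        summary["frac_bridging_unannotated"] = len(unann) / len(bridging)
        conn = axes.assign(
            unannotated=axes["transcript_id"].isin(unann)
        ).groupby(["rbp_id", "drug_id"])["unannotated"].all()
        summary["n_rbp_drug_connections"] = int(len(conn))
        summary["frac_connections_only_unannotated"] = float(conn.mean())
    return summary
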