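"""Transcript-drug association by elastic net with bootstrap sign scoring.

The procedure, per drug:

1. **Spearman prefilter.** Rank-correlate every (prevalence-filtered)
   transcript with the drug's AUC vector over cell lines with a non-missing
   AUC; keep pairs with |rho| > 0.2 and BH FDR < 0.05 (FDR adjusted
   globally across all evaluated pairs by default).
2. **Prediction matrix.** Column-standardise the passing transcripts'
   expression (zero mean, unit sd per transcript; zero-variance columns are
   dropped with a warning).
3. **Hyperparameter search.** Random search over 25 (alpha, lambda)
   candidates — alpha (the L1/L2 mixing weight) uniform on [0.05, 1],
   lambda log-uniform on [1e-3 * lambda_max, lambda_max] — scored by mean
   RMSE of 10-fold cross-validation repeated 5 times; ties break toward the
   larger (sparser) lambda.
4. **Bootstrap scoring.** With the tuned penalty fixed, refit on B
   resamples of the cell lines (with replacement) and count, per
   transcript, resamples with a positive (f_pos) and negative (f_neg)
   coefficient. The predictive score is |f_pos - f_neg| / B, direction the
   majority sign (``none`` on a tie); exact zeros count in neither
   frequency. Scores >= 0.7 call an association.

Note on parametrisation: the mixing weight called alpha here (glmnet
convention) is scikit-learn's ``l1_ratio``, and the penalty strength lambda
is scikit-learn's ``alpha``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import RepeatedKFold
from statsmodels.stats.multitest import multipletests

from .atlas import ExpressionAtlas
from .errors import ConfigurationError

__all__ = [
    "ElasticNetConfig",
    "predictive_score",
    "spearman_prefilter",
    "build_prediction_matrix",
    "tune_elastic_net",
    "bootstrap_predictive_scores",
    "call_associations",
]

logger = logging.getLogger(__name__)


@dataclass
class ElasticNetConfig:
    """Hyperparameter-search settings (glmnet-style alpha/lambda naming)."""

    n_folds: int = 10
    n_repeats: int = 5
    n_candidates: int = 25
    alpha_min: float = 0.05
    lambda_ratio: float = 1e-3  # lambda_min = lambda_ratio * lambda_max
    search_seed: int = 0
    max_iter: int = 10_000


def predictive_score(f_pos: int, f_neg: int, B: int) -> tuple[float, str]:
    """Sign-frequency predictive score: |f_pos - f_neg| / B.

    Returns (score, direction); direction is the majority coefficient sign,
    ``none`` on a tie (score 0). f_pos + f_neg may be < B because exact
    zeros count in neither frequency.
    """
    if B <= 0 or f_pos < 0 or f_neg < 0 or f_pos + f_neg > B:
        raise ConfigurationError("need 0 <= f_pos + f_neg <= B with B > 0")
    if f_pos > f_neg:
        return (f_pos - f_neg) / B, "positive"
    if f_neg > f_pos:
        return (f_neg - f_pos) / B, "negative"
    return 0.0, "none"


def _rank_standardize(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """Average ranks along axis, z-scored; constant vectors -> NaN."""
    ranks = stats.rankdata(a, axis=axis)
    ranks = ranks - ranks.mean(axis=axis, keepdims=True)
    sd = ranks.std(axis=axis, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ranks / sd
    out[np.broadcast_to(sd == 0, out.shape)] = np.nan
    return out


def spearman_prefilter(
    atlas: ExpressionAtlas,
    auc: pd.DataFrame,
    rho_min: float = 0.2,
    fdr_max: float = 0.05,
    two_sided: bool = True,
    fdr_scope: str = "global",
    min_obs: int = 3,
) -> pd.DataFrame:
    """Spearman-correlate every transcript with every drug.

    ``auc``: cell line x drug matrix (NaN = missing response); only cell
    lines shared with the atlas and with a non-missing AUC enter each
    drug's correlation. Pairs with fewer than ``min_obs`` complete
    observations, or with a constant transcript/AUC vector, are skipped
    (returned with NaN rho and ``skipped`` = True).

    Returns a long DataFrame (transcript_id, drug_id, n, rho, pvalue, fdr,
    passes, skipped). ``passes`` applies |rho| > rho_min (or rho > rho_min
    when ``two_sided=False``) and BH FDR < fdr_max, the FDR family being
    all evaluated pairs (``fdr_scope="global"``) or each drug separately
    (``"per_drug"``).
    """
    if fdr_scope not in ("global", "per_drug"):
        raise ConfigurationError(f"unknown fdr_scope {fdr_scope!r}")
    shared = atlas.cell_line_ids.intersection(auc.index)
    if len(shared) == 0:
        raise ConfigurationError("atlas and drug matrix share no cell lines")
    expr = atlas.values[shared].to_numpy(dtype=float)  # transcripts x cells
    frames = []
    for drug in auc.columns:
        y = auc.loc[shared, drug].to_numpy(dtype=float)
        mask = ~np.isnan(y)
        n = int(mask.sum())
        tids = atlas.transcript_ids
        if n < min_obs:
            frames.append(pd.DataFrame({
                "transcript_id": tids, "drug_id": drug, "n": n,
                "rho": np.nan, "pvalue": np.nan,
            }))
            continue
        zy = _rank_standardize(y[mask])
        zx = _rank_standardize(expr[:, mask], axis=1)
        rho = np.clip(zx @ np.nan_to_num(zy) / n, -1.0, 1.0)
        rho[np.isnan(zx).any(axis=1) | np.isnan(zy).any()] = np.nan
        # t approximation for the null distribution of Spearman's rho
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        pvalue = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pvalue = np.where(np.isclose(np.abs(rho), 1.0), 0.0, pvalue)
        frames.append(pd.DataFrame({
            "transcript_id": tids, "drug_id": drug, "n": n,
            "rho": rho, "pvalue": pvalue,
        }))
    result = pd.concat(frames, ignore_index=True)
    result["skipped"] = result["rho"].isna()
    result["fdr"] = np.nan
    groups = [result.index] if fdr_scope == "global" else [
        idx for _, idx in result.groupby("drug_id").groups.items()
    ]
    for idx in groups:
        sub = result.loc[idx]
        ok = ~sub["skipped"]
        if ok.any():
            result.loc[sub.index[ok], "fdr"] = multipletests(
                sub.loc[ok, "pvalue"], method="fdr_bh"
            )[1]
    effect = result["rho"].abs() if two_sided else result["rho"]
    result["passes"] = (~result["skipped"]) & (effect > rho_min) & (
        result["fdr"] < fdr_max
    )
    return result


def build_prediction_matrix(
    atlas: ExpressionAtlas, transcript_ids, drug_cell_lines=None
) -> pd.DataFrame:
    """Cell line x transcript matrix of per-transcript z-scores.

    Restricted to ``drug_cell_lines`` when given (the drug's complete
    cases). Zero-variance columns are dropped with a warning.
    """
    transcript_ids = list(transcript_ids)
    if not transcript_ids:
        raise ConfigurationError("prediction matrix needs >= 1 transcript")
    cells = (
        atlas.cell_line_ids if drug_cell_lines is None
        else pd.Index(drug_cell_lines)
    )
    X = atlas.values.loc[transcript_ids, cells].T.astype(float)
    sd = X.std(axis=0, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} zero-variance transcript(s) from the "
            f"prediction matrix: {list(constant)[:5]}"
        )
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    return (X - X.mean(axis=0)) / sd


def _lambda_max(X: np.ndarray, y: np.ndarray, l1_ratio: float) -> float:
    n = X.shape[0]
    yc = y - y.mean()
    return float(np.abs(X.T @ yc).max() / (n * l1_ratio))


def tune_elastic_net(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    cfg: ElasticNetConfig | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Random-search (alpha, lambda) by repeated k-fold CV mean RMSE.

    Returns (alpha, lambda, search_table) with the table sorted by mean
    RMSE; ties break toward larger lambda. When n < 2 * n_folds the fold
    count is reduced (never below 2) with a warning.
    """
    cfg = cfg or ElasticNetConfig()
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = Xa.shape[0]
    n_folds = cfg.n_folds
    if n < 2 * n_folds:
        n_folds = max(2, n // 2)
        warnings.warn(
            f"n={n} too small for {cfg.n_folds}-fold CV; using {n_folds} folds"
        )
    rng = np.random.default_rng(cfg.search_seed)
    rows = []
    cv = RepeatedKFold(
        n_splits=n_folds, n_repeats=cfg.n_repeats,
        random_state=int(rng.integers(2**31 - 1)),
    )
    splits = list(cv.split(Xa))
    for _ in range(cfg.n_candidates):
        alpha = float(rng.uniform(cfg.alpha_min, 1.0))
        lam_max = max(_lambda_max(Xa, ya, alpha), 1e-12)
        lam = float(np.exp(rng.uniform(
            np.log(lam_max * cfg.lambda_ratio), np.log(lam_max)
        )))
        sq_errs = []
        for train, test in splits:
            model = ElasticNet(
                alpha=lam, l1_ratio=alpha, max_iter=cfg.max_iter
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                model.fit(Xa[train], ya[train])
            resid = ya[test] - model.predict(Xa[test])
            sq_errs.append(np.sqrt(np.mean(resid**2)))
        rows.append({"alpha": alpha, "lambda": lam,
                     "cv_rmse": float(np.mean(sq_errs))})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["cv_rmse", "lambda"], ascending=[True, False]
    ).iloc[0]
    return float(best["alpha"]), float(best["lambda"]), table


def bootstrap_predictive_scores(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float,
    lam: float,
    B: int = 1000,
    seed: int = 0,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """Fit the fixed-penalty elastic net on B row resamples and score each
    transcript by coefficient-sign frequency.

    Resamples are drawn over cell lines with replacement (size n); a
    resample with zero-variance response is redrawn (and logged). Returns a
    DataFrame indexed by transcript with columns f_pos, f_neg, B, score,
    direction.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n, t = Xa.shape
    rng = np.random.default_rng(seed)
    f_pos = np.zeros(t, dtype=int)
    f_neg = np.zeros(t, dtype=int)
    n_redrawn = 0
    model = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=max_iter)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        while np.ptp(ya[idx]) == 0:
            n_redrawn += 1
            idx = rng.integers(0, n, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xa[idx], ya[idx])
        f_pos += model.coef_ > 0
        f_neg += model.coef_ < 0
    if n_redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", n_redrawn)
    scores, directions = zip(
        *(predictive_score(int(p), int(q), B) for p, q in zip(f_pos, f_neg))
    )
    columns = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(t)
    return pd.DataFrame(
        {"f_pos": f_pos, "f_neg": f_neg, "B": B,
         "score": scores, "direction": directions},
        index=pd.Index(columns, name="transcript_id"),
    )


def call_associations(
    scores: pd.DataFrame, threshold: float = 0.7
) -> pd.DataFrame:
    """Retain pairs with predictive score >= threshold (inclusive)."""
    if scores.empty:
        return scores.copy()
    return scores.loc[scores["score"] >= threshold].copy()
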