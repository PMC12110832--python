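"""Consumers of the lncRNA short-list: immune-score associations, linear risk
scores with a median split, response labeling, and a log-rank utility."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import bh_adjust
from .errors import ConfigurationError, DegenerateDataError, IngestError, InsufficientDataError
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NON_RESPONDER = "non_responder"

#: RECIST code -> binary response group.
RECIST_MAP = {
    "CR": RESPONDER,
    "PR": RESPONDER,
    "SD": NON_RESPONDER,
    "PD": NON_RESPONDER,
}


@dataclass(frozen=True)
class AssociationRecord:
    lncRNA: str
    score_name: str
    rho: float
    p: float
    p_adj: float
    n_obs: int
    error: str = ""


@dataclass(frozen=True)
class RiskModel:
    """Linear model: per-lncRNA coefficients (externally fitted)."""

    coefficients: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        ids = [lid for lid, _ in self.coefficients]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate lncRNA id in risk model")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "RiskModel":
        return cls(coefficients=tuple(mapping.items()))


def spearman_association(
    expr: ExpressionMatrix,
    scores: pd.DataFrame,
    lnc_ids: Sequence[str],
) -> list[AssociationRecord]:
    """Spearman rho (average-rank ties) of each lncRNA against each score column.

    Samples are intersected per pair with pairwise-complete deletion; at least
    4 shared observations are required.  Undefined pairs (constant vectors,
    too few samples) are recorded with an ``error`` note rather than raised.
    The ``p_adj`` column is BH over all defined pairs.
    """
    shared = [s for s in expr.sample_ids if s in set(scores.index)]
    if len(shared) < 4:
        raise InsufficientDataError(f"only {len(shared)} shared sample(s)")
    results: list[AssociationRecord] = []
    defined: list[int] = []
    pvals: list[float] = []
    score_mat = scores.loc[shared]
    col_idx = {s: i for i, s in enumerate(expr.sample_ids)}
    take = [col_idx[s] for s in shared]
    for lnc in lnc_ids:
        x_full = expr.vector(lnc)[take]
        for name in scores.columns:
            y_full = score_mat[name].to_numpy(dtype=float)
            mask = np.isfinite(x_full) & np.isfinite(y_full)
            n = int(mask.sum())
            rec = None
            if n < 4:
                rec = AssociationRecord(lnc, name, np.nan, np.nan, np.nan, n,
                                        error="fewer than 4 complete pairs")
            else:
                x, y = x_full[mask], y_full[mask]
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rec = AssociationRecord(lnc, name, np.nan, np.nan, np.nan, n,
                                            error="constant vector")
            if rec is None:
                rho, p = stats.spearmanr(x, y)
                rec = AssociationRecord(lnc, name, float(rho), float(p), np.nan, n)
                defined.append(len(results))
                pvals.append(float(p))
            results.append(rec)
    if pvals:
        adj = bh_adjust(np.clip(pvals, 1e-300, 1.0))
        for pos, q in zip(defined, adj):
            r = results[pos]
            results[pos] = AssociationRecord(r.lncRNA, r.score_name, r.rho, r.p,
                                             float(q), r.n_obs)
    return results


def risk_score(
    expr: ExpressionMatrix, model: RiskModel
) -> tuple[pd.Series, pd.Series]:
    """Per-sample linear risk score plus the median-split high/low labels.

    The score is the dot product of the model coefficients with the sample's
    expression of the model lncRNAs.  Samples at or below the median are
    labeled ``low``, the rest ``high``.
    """
    if not model.coefficients:
        raise ConfigurationError("risk model has no coefficients")
    ids = [lid for lid, _ in model.coefficients]
    missing = [lid for lid in ids if lid not in set(expr.feature_ids)]
    if missing:
        raise ConfigurationError(f"model lncRNA(s) missing from expression: {missing}")
    betas = np.array([b for _, b in model.coefficients], dtype=float)
    mat = expr.values.loc[ids].to_numpy(dtype=float)
    scores = pd.Series(betas @ mat, index=expr.sample_ids, name="risk_score")
    if float(scores.max()) == float(scores.min()):
        raise DegenerateDataError(
            "all risk scores identical; the median split is degenerate "
            "(model is non-informative on this matrix)"
        )
    median = float(scores.median())
    labels = pd.Series(
        np.where(scores > median, "high", "low"), index=scores.index, name="risk_group"
    )
    return scores, labels


def label_response(recist: Mapping[str, str]) -> dict[str, str]:
    """Map RECIST codes to responder / non_responder (CR,PR -> responder)."""
    out: dict[str, str] = {}
    for sample, code in recist.items():
        if code not in RECIST_MAP:
            raise IngestError(f"sample {sample!r}: unknown RECIST code {code!r}")
        out[sample] = RECIST_MAP[code]
    return out


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence[str]
) -> tuple[float, float]:
    """Two-group log-rank test from first principles.

    Returns the chi-square statistic (1 df) and its p-value.  ``events`` is 1
    for an observed event, 0 for censoring.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ConfigurationError(f"log-rank test needs exactly 2 groups, got {labels.size}")
    in_a = groups == labels[0]
    observed_a = 0.0
    expected_a = 0.0
    variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & in_a).sum()
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0.0:
        raise DegenerateDataError("log-rank variance is zero (no comparable events)")
    chi2 = (observed_a - expected_a) ** 2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
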