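"""Scoring-power statistics: Pearson Rp, Spearman Rs, SD of errors, RMSE.

These summarize how well a scoring function reproduces measured binding
affinities.  Rp and Rs measure linear and rank agreement.  SD is the
standard deviation of errors about the least-squares line Y = b0 + b1*Yhat
(measured regressed on predicted) with an n-2 denominator, in -log K units.
RMSE is the plain root-mean-square error of the raw predictions.

Degenerate inputs (constant vectors, all-tied ranks) raise
``UndefinedStatisticError`` rather than returning NaN, so pipelines fail
loudly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError, UsageError


def _check_pair(y, yhat, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise UsageError(
            f"measured and predicted vectors must be 1-D of equal length, "
            f"got {y.shape} and {yhat.shape}"
        )
    if len(y) < min_n:
        raise UsageError(f"need at least {min_n} complexes, got {len(y)}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise UsageError("non-finite values in affinity vectors")
    return y, yhat


def pearson(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Pearson's correlation Rp between measured and predicted affinities."""
    y, yhat = _check_pair(y, yhat)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedStatisticError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(yhat, y).statistic)


def spearman(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Spearman's rank correlation Rs.

    Computed as the Pearson correlation of average ranks, which reproduces
    the classical 1 - 6*sum(d_i^2)/(n(n^2-1)) formula exactly when there are
    no ties and handles ties gracefully.
    """
    y, yhat = _check_pair(y, yhat)
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise UndefinedStatisticError("Spearman correlation undefined for an all-tied vector")
    return float(stats.spearmanr(yhat, y).statistic)


def sd_of_errors(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Standard deviation of errors about the fitted line Y = b0 + b1*Yhat.

    The measured affinities are regressed on the predictions by ordinary
    least squares; SD = sqrt( sum (y_i - (b0 + b1*yhat_i))^2 / (n - 2) ).
    """
    y, yhat = _check_pair(y, yhat)
    if np.ptp(yhat) == 0:
        raise UndefinedStatisticError("SD fit singular: constant predictions")
    fit = stats.linregress(yhat, y)
    resid = y - (fit.intercept + fit.slope * yhat)
    return float(np.sqrt(resid @ resid / (len(y) - 2)))


def rmse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root-mean-square error of the raw predictions."""
    y, yhat = _check_pair(y, yhat, min_n=1)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass(frozen=True)
class ScoringReport:
    """Scoring-power summary for one (model, dataset) pair."""

    model_label: str
    n: int
    rp: float
    rs: float
    sd: float
    rmse_test: float
    rmse_train: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def model_label(model_name: str, combo) -> str:
    """Render the ``Model::Features`` naming convention, e.g. ``BgN-Score::XARG``."""
    label = combo.label if hasattr(combo, "label") else str(combo)
    return f"{model_name}::{label}"


def build_report(
    model_label: str,
    y: Sequence[float],
    yhat: Sequence[float],
    rmse_train: float | None = None,
) -> ScoringReport:
    """Assemble all four statistics for one model on one dataset."""
    return ScoringReport(
        model_label=model_label,
        n=len(np.asarray(y)),
        rp=pearson(y, yhat),
        rs=spearman(y, yhat),
        sd=sd_of_errors(y, yhat),
        rmse_test=rmse(y, yhat),
        rmse_train=rmse_train,
    )


def render_table(reports: Sequence[ScoringReport], digits: int = 3) -> str:
    """Render reports as a TSV table sorted by descending Rp."""
    header = ["Scoring function", "N", "Rp", "Rs", "SD", "RMSE_test", "RMSE_train"]
    lines = ["\t".join(header)]
    for r in sorted(reports, key=lambda r: -r.rp):
        rmse_train = f"{r.rmse_train:.{digits}f}" if r.rmse_train is not None else "-"
        lines.append(
            "\t".join(
                [
                    r.model_label,
                    str(r.n),
                    f"{r.rp:.{digits}f}",
                    f"{r.rs:.{digits}f}",
                    f"{r.sd:.{digits}f}",
                    f"{r.rmse_test:.{digits}f}",
                    rmse_train,
                ]
            )
        )
    return "\n".join(lines) + "\n"
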