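"""Regression metrics for affinity prediction.

Mean squared error, the concordance index (CI) over pairs ordered by
true affinity with a 0/0.5/1 step function on prediction differences,
and the QSAR external-predictivity statistic r²m comparing squared
correlations with and without an intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

__all__ = ["MetricError", "MetricsReport", "mse", "step_function",
           "concordance_index", "rm_squared", "compute_report"]


class MetricError(ValueError):
    pass


@dataclass
class MetricsReport:
    mse: float
    ci: float | None
    rm2: float | None
    n_pairs: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def __str__(self) -> str:
        ci = "n/a" if self.ci is None else f"{self.ci:.4f}"
        rm2 = "n/a" if self.rm2 is None else f"{self.rm2:.4f}"
        return (f"n={self.n_pairs}  MSE={self.mse:.4f}  CI={ci}  "
                f"r2m={rm2}")


def _as_vectors(p, y):
    p = np.asarray(p, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if p.shape != y.shape:
        raise MetricError("prediction/truth length mismatch")
    if p.size == 0:
        raise MetricError("empty vectors")
    return p, y


def mse(predictions, truth) -> float:
    """Mean squared error (1/n) Σ (P_i − Y_i)²."""
    p, y = _as_vectors(predictions, truth)
    return float(np.mean((p - y) ** 2))


def step_function(x: float) -> float:
    """h(x): 1 for positive, 0.5 at zero, 0 for negative."""
    if x > 0:
        return 1.0
    if x == 0:
        return 0.5
    return 0.0


def concordance_index(predictions, truth) -> float:
    """CI = (1/Z) Σ_{δ_i > δ_j} h(b_i − b_j).

    Z counts the pairs whose true affinities strictly differ; pairs tied
    in truth enter neither the sum nor Z, and prediction ties score 0.5.
    """
    b, delta = _as_vectors(predictions, truth)
    if b.size < 2:
        raise MetricError("CI needs at least two samples")
    di = delta[:, None] > delta[None, :]
    z = int(di.sum())
    if z == 0:
        raise MetricError("all true affinities tied; CI undefined")
    diff = b[:, None] - b[None, :]
    h = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return float(h[di].sum() / z)


def rm_squared(predictions, truth) -> float:
    """r²m = r²·(1 − √|r² − r₀²|).

    r² is the squared Pearson correlation of predictions and truth
    (regression with intercept); r₀² the squared correlation coefficient
    of the least-squares fit through the origin, per the standard QSAR
    external-validation definition.
    """
    p, y = _as_vectors(predictions, truth)
    if p.size < 3:
        raise MetricError("r2m needs at least three samples")
    if np.std(p) == 0 or np.std(y) == 0:
        raise MetricError("degenerate variance; r2m undefined")
    # with intercept: ordinary squared correlation
    r2 = float(np.corrcoef(p, y)[0, 1] ** 2)
    # through the origin: k = Σ y·p / Σ p²; r0² = 1 − SS_res/SS_tot
    k = float(np.dot(y, p) / np.dot(p, p))
    ss_res = float(np.sum((y - k * p) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    return r2 * (1.0 - np.sqrt(abs(r2 - r02)))


def compute_report(predictions, truth) -> MetricsReport:
    """Full report; CI and r²m fall back to None where undefined
    (all-tied labels, degenerate variance) while MSE is always given."""
    p, y = _as_vectors(predictions, truth)
    try:
        ci = concordance_index(p, y)
    except MetricError:
        ci = None
    try:
        rm2 = rm_squared(p, y)
    except MetricError:
        rm2 = None
    return MetricsReport(mse=mse(p, y), ci=ci, rm2=rm2, n_pairs=int(p.size))
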