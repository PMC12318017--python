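"""Team-individual performance models and collaborative-event detection.

Three pieces connect the indicator system to outcomes:

* an observed-variable linear path model
  ``P_team = b1*C_spatial + b2*C_temporal + b3*sum_i w_i P_ind_i + e``
  quantifying direct (coordination) and indirect (individual-skill)
  contribution pathways;
* a logistic classifier on the four outcome-linked coordination metrics
  (TCR, CPR, SSI, ICC), fitted by iteratively reweighted least squares and
  evaluated with leave-one-session-out cross-validation;
* mean-shift change-point detection (binary segmentation, BIC-style
  penalty) and a configurable early-warning rule engine on indicator
  series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .session import EventTable, IndicatorSeries

OUTCOME_FEATURES = ("TCR", "CPR", "SSI", "ICC")


# ---------------------------------------------------------------------------
# path model
# ---------------------------------------------------------------------------

@dataclass
class PathModel:
    beta: np.ndarray                  # (b1, b2, b3)
    std_errors: np.ndarray
    r_squared: float
    residual_variance: float
    w: np.ndarray                     # per-athlete contribution weights
    fitted: bool = True

    def predict(self, C_spatial, C_temporal, P_ind) -> np.ndarray:
        comp = np.asarray(P_ind, float) @ self.w
        X = np.column_stack([C_spatial, C_temporal, comp])
        return X @ self.beta


def fit_path_model(P_team: np.ndarray, C_spatial: np.ndarray,
                   C_temporal: np.ndarray, P_ind: np.ndarray,
                   w: np.ndarray | None = None) -> PathModel:
    """Least-squares path coefficients over a table of sessions.

    ``P_ind`` is (n_sessions, n_athletes); the per-athlete contribution
    weights ``w`` default to uniform.  The three predictors must be
    identifiable (non-degenerate, condition number < 1e8).
    """
    P_team = np.asarray(P_team, float)
    n = P_team.size
    if n < 10:
        raise ValidationError("fit_path_model: need >= 10 sessions")
    P_ind = np.atleast_2d(np.asarray(P_ind, float))
    if w is None:
        w = np.full(P_ind.shape[1], 1.0 / P_ind.shape[1])
    w = np.asarray(w, float)
    comp = P_ind @ w
    X = np.column_stack([C_spatial, C_temporal, comp])
    names = ["C_spatial", "C_temporal", "P_ind_composite"]
    dead = [names[j] for j in range(3) if np.allclose(X[:, j], 0)]
    if dead:
        raise ValidationError(
            f"fit_path_model: unidentifiable predictors (all zero): {dead}")
    cond = np.linalg.cond(X)
    if cond > 1e8:
        corr = np.corrcoef(X, rowvar=False)
        worst = max(((i, j) for i in range(3) for j in range(i + 1, 3)),
                    key=lambda ij: abs(corr[ij]))
        raise ValidationError(
            f"fit_path_model: collinear design (cond={cond:.2e}); "
            f"offending predictors: {names[worst[0]]}, {names[worst[1]]}")
    beta, *_ = np.linalg.lstsq(X, P_team, rcond=None)
    resid = P_team - X @ beta
    dof = max(n - 3, 1)
    sigma2 = float(resid @ resid / dof)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    ss_tot = float(((P_team - P_team.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return PathModel(beta=beta, std_errors=np.sqrt(np.diag(cov)),
                     r_squared=r2, residual_variance=sigma2, w=w)


# ---------------------------------------------------------------------------
# outcome classifier
# ---------------------------------------------------------------------------

@dataclass
class OutcomeClassifier:
    coef: np.ndarray                  # intercept + one per feature
    feature_names: tuple = OUTCOME_FEATURES
    feature_mean: np.ndarray = None
    feature_scale: np.ndarray = None
    ridge: float = 1e-8
    separation_warning: bool = False
    n_iter: int = 0
    log_likelihood_trace: list[float] = field(default_factory=list)

    def _design(self, feats: np.ndarray) -> np.ndarray:
        z = (feats - self.feature_mean) / self.feature_scale
        return np.column_stack([np.ones(len(z)), z])

    def predict_proba(self, features) -> np.ndarray:
        feats = _feature_matrix(features, self.feature_names)
        eta = self._design(feats) @ self.coef
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))

    def predict(self, features) -> np.ndarray:
        return np.where(self.predict_proba(features) >= 0.5, "win", "loss")


def _feature_matrix(features, names) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features)
    if isinstance(features, dict):
        features = [features]
    return np.array([[f[n] for n in names] for f in features], float)


def fit_outcome_classifier(dataset: list[tuple[dict, str]],
                           ridge: float = 1e-8,
                           max_iter: int = 100) -> OutcomeClassifier:
    """Logistic regression on (TCR, CPR, SSI, ICC) by IRLS.

    Deterministic given the data.  Complete separation is detected from a
    diverging norm of the coefficients and handled by refitting with a
    stronger ridge penalty and a warning flag.
    """
    feats = _feature_matrix([f for f, _ in dataset], OUTCOME_FEATURES)
    y = np.array([1.0 if o == "win" else 0.0 for _, o in dataset])
    if y.min() == y.max():
        raise ValidationError("fit_outcome_classifier: both classes required")
    mean = feats.mean(axis=0)
    scale = feats.std(axis=0)
    scale[scale == 0] = 1.0
    clf = OutcomeClassifier(coef=np.zeros(feats.shape[1] + 1),
                            feature_mean=mean, feature_scale=scale, ridge=ridge)
    X = clf._design(feats)
    coef, trace, n_iter, separated = _irls(X, y, ridge, max_iter)
    if not separated:
        # complete separation: every training point classified with an
        # extreme margin means the unpenalized MLE does not exist
        margins = (2 * y - 1) * np.clip(X @ coef, -30, 30)
        separated = bool(margins.min() > 8.0)
    if separated:
        coef, trace, n_iter, _ = _irls(X, y, 1.0, max_iter)
        clf.separation_warning = True
        clf.ridge = 1.0
    clf.coef = coef
    clf.log_likelihood_trace = trace
    clf.n_iter = n_iter
    return clf


def _irls(X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int
          ) -> tuple[np.ndarray, list[float], int, bool]:
    beta = np.zeros(X.shape[1])
    trace = []
    for it in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = float((y * np.log(p + 1e-300) + (1 - y) * np.log(1 - p + 1e-300)).sum()
                   - 0.5 * ridge * (beta[1:] @ beta[1:]))
        trace.append(ll)
        s = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / s
        A = X.T @ (s[:, None] * X) + ridge * np.diag([0.0] + [1.0] * (X.shape[1] - 1))
        new = np.linalg.solve(A, X.T @ (s * z))
        if np.linalg.norm(new) > 1e4:
            return new, trace, it + 1, True
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta, trace, len(trace), False


def loso_accuracy(dataset: list[tuple[dict, str]]) -> float:
    """Leave-one-session-out accuracy of the outcome classifier."""
    n = len(dataset)
    hits = 0
    for k in range(n):
        train = dataset[:k] + dataset[k + 1:]
        labels = {o for _, o in train}
        if len(labels) < 2:
            continue
        clf = fit_outcome_classifier(train)
        pred = clf.predict(dataset[k][0])[0]
        hits += pred == dataset[k][1]
    return hits / n


# ---------------------------------------------------------------------------
# change-point detection
# ---------------------------------------------------------------------------

@dataclass
class ChangePointResult:
    change_indices: list[int]         # first index of each new segment
    gains: list[float]
    penalty: float


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Arg-max gain in residual sum of squares over all mean-shift splits."""
    n = x.size
    c = np.cumsum(x)
    c2 = np.cumsum(x ** 2)
    total = c2[-1] - c[-1] ** 2 / n
    ks = np.arange(1, n)
    left = c2[ks - 1] - c[ks - 1] ** 2 / ks
    right = (c2[-1] - c2[ks - 1]) - (c[-1] - c[ks - 1]) ** 2 / (n - ks)
    gains = total - (left + right)
    j = int(np.argmax(gains))
    return int(ks[j]), float(gains[j])


def detect_change_points(series: np.ndarray, penalty: float | None = None,
                         min_size: int = 2) -> ChangePointResult:
    """Binary segmentation for mean shifts with a BIC-style penalty.

    A split is accepted when its reduction in residual sum of squares
    exceeds ``penalty`` (default ``3 * sigma^2 * log n`` with sigma robustly
    estimated from first differences).  Returned indices mark the first
    sample of each new segment.
    """
    x = np.asarray(series, float)
    n = x.size
    if n < 20:
        raise ValidationError("detect_change_points: need >= 20 samples")
    if penalty is None:
        sigma = np.median(np.abs(np.diff(x))) / (np.sqrt(2) * 0.6745)
        penalty = max(3.0 * sigma ** 2 * np.log(n), 1e-12)
    found: list[tuple[int, float]] = []

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2 * min_size:
            return
        k, gain = _best_split(x[lo:hi])
        if gain > penalty and min_size <= k <= (hi - lo) - min_size:
            found.append((lo + k, gain))
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, n)
    found.sort()
    return ChangePointResult(change_indices=[k for k, _ in found],
                             gains=[g for _, g in found], penalty=float(penalty))


# ---------------------------------------------------------------------------
# early-warning rule engine
# ---------------------------------------------------------------------------

DEFAULT_RULES = [
    {"name": "defensive_intervention",
     "conditions": [
         {"indicator": "SSI", "op": "delta_gt", "threshold": 0.10},
         {"indicator": "TCR", "op": "gt", "threshold": 0.50},
     ]},
]

_OPS = ("gt", "lt", "delta_gt", "delta_lt")


def early_warning(indicators: IndicatorSeries,
                  rules: list[dict] | None = None) -> EventTable:
    """Evaluate threshold rules over indicator windows; one alert per firing.

    Each rule fires at a window where *all* its conditions hold; ``delta_*``
    operators compare the change from the previous window.  Unknown
    indicator names or operators raise a configuration error.
    """
    if rules is None:
        rules = []
    table = indicators.table
    alerts = []
    for rule in rules:
        conds = rule.get("conditions", [])
        for c in conds:
            if c["indicator"] not in table.columns:
                raise ConfigError(
                    f"early_warning: unknown indicator {c['indicator']!r} "
                    f"in rule {rule.get('name', '?')!r}")
            if c["op"] not in _OPS:
                raise ConfigError(f"early_warning: unknown op {c['op']!r}")
        if not conds:
            continue
        fired = np.ones(len(table), dtype=bool)
        for c in conds:
            v = table[c["indicator"]].to_numpy(float)
            if c["op"] == "gt":
                ok = v > c["threshold"]
            elif c["op"] == "lt":
                ok = v < c["threshold"]
            else:
                dv = np.diff(v, prepend=np.nan)
                ok = dv > c["threshold"] if c["op"] == "delta_gt" \
                    else dv < c["threshold"]
            fired &= np.nan_to_num(ok.astype(float), nan=0.0).astype(bool)
        for t in table.loc[fired, "t"]:
            alerts.append({"t": float(t), "event_type": "alert",
                           "athlete_id": None, "target_athlete_id": None,
                           "outcome": rule.get("name", "alert")})
    if not alerts:
        return EventTable()
    return EventTable(pd.DataFrame(alerts).sort_values("t").reset_index(drop=True))
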