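"""Multivariate recurrence signatures: least-squares fits scored by a
residual-sum-of-squares AIC, best-subset / stepwise selection, DeLong
comparison of correlated AUCs, and cross-scanner train/validation.

The signature is an affine score ``intercept + sum(coef * feature)`` fitted
by ordinary least squares to the 0/1 outcome (a linear-probability model).
Model selection minimises

    AIC = N * ln(SS / N) + 2 * (K + 1)

where ``N`` is the sample size, ``K`` the number of model features and
``SS`` the residual sum of squares. This least-squares AIC is the selection
criterion throughout; a deviance-based logistic AIC is available behind the
``criterion='logistic'`` flag but is off by default.

Published 4-feature signatures for the two scanner groups ship as JSON
fixtures (``signature_g1.json``, ``signature_g2.json``) and can be evaluated
without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .features import FEATURE_NAMES
from .stats import _outcome_vector, bootstrap_auc_ci, roc_auc

__all__ = [
    "aic",
    "LinearSignature",
    "AICSignatureSelector",
    "fit_linear_signature",
    "select_signature",
    "evaluate_signature",
    "delong_test",
    "cross_group_validation",
    "CrossGroupResult",
    "load_published_signature",
]


def aic(n: int, ss: float, k: int) -> float:
    """Least-squares Akaike information criterion.

    ``AIC = N * ln(SS/N) + 2 * (K + 1)`` for a model with ``K`` parameters
    (features), residual sum of squares ``SS`` and sample size ``N``.
    """
    if n < 1 or k < 0:
        raise ValueError("need N >= 1 and K >= 0")
    if ss <= 0:
        raise ValueError(f"residual sum of squares must be > 0, got {ss}")
    return float(n * np.log(ss / n) + 2.0 * (k + 1))


def _as_frame(X, feature_names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(feature_names))


class LinearSignature(BaseEstimator):
    """Affine recurrence score fitted by ordinary least squares.

    Parameters
    ----------
    features : list of str or None
        Feature subset to use; None means every column of ``X``.

    Attributes (after ``fit``)
    --------------------------
    intercept_ : float
    coef_ : pandas Series indexed by feature name
    se_ : pandas Series, standard errors (intercept under key ``"intercept"``)
    ss_res_ : float, residual sum of squares
    n_ : int, training sample size
    aic_ : float, least-squares AIC of the fit
    """

    def __init__(self, features: list[str] | None = None, training_group: str = "synthetic"):
        self.features = features
        self.training_group = training_group

    def fit(self, X, y):
        X = _as_frame(X)
        names = list(self.features) if self.features is not None else list(X.columns)
        missing = set(names) - set(X.columns)
        if missing:
            raise ValueError(f"features absent from X: {sorted(missing)}")
        y = np.asarray(y, dtype=float)
        A = np.column_stack([np.ones(len(X))] + [X[n].to_numpy(dtype=float) for n in names])
        if len(X) <= len(names) + 1:
            raise ValueError("need more rows than features + 1")
        beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < A.shape[1]:
            raise ValueError("design matrix is rank deficient")
        resid = y - A @ beta
        self.feature_names_in_ = names
        self.intercept_ = float(beta[0])
        self.coef_ = pd.Series(beta[1:], index=names)
        self.n_ = len(X)
        self.ss_res_ = float(resid @ resid)
        self.aic_ = aic(self.n_, max(self.ss_res_, np.finfo(float).tiny), len(names))
        dof = self.n_ - len(names) - 1
        sigma2 = self.ss_res_ / dof if dof > 0 else np.nan
        cov = sigma2 * np.linalg.inv(A.T @ A)
        self.se_ = pd.Series(np.sqrt(np.diag(cov)), index=["intercept"] + names)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signature score ``intercept + sum(coef * feature)`` per row."""
        X = _as_frame(X, self.feature_names_in_)
        vals = X[self.feature_names_in_].to_numpy(dtype=float)
        return self.intercept_ + vals @ self.coef_.to_numpy()

    predict = decision_function

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept_,
            "coefficients": {k: float(v) for k, v in self.coef_.items()},
            "training_group": self.training_group,
            "aic": getattr(self, "aic_", None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSignature":
        model = cls(features=list(d["coefficients"]), training_group=d.get("training_group", "synthetic"))
        model.feature_names_in_ = list(d["coefficients"])
        model.intercept_ = float(d["intercept"])
        model.coef_ = pd.Series({k: float(v) for k, v in d["coefficients"].items()})
        if d.get("aic") is not None:
            model.aic_ = float(d["aic"])
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "LinearSignature":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_linear_signature(cohort: pd.DataFrame, feature_subset, training_group: str = "synthetic") -> LinearSignature:
    """Least-squares fit of the outcome on a feature subset (thin wrapper)."""
    y = _outcome_vector(cohort).astype(float) if "outcome" in cohort else None
    if y is None:
        raise ValueError("cohort must carry an 'outcome' column")
    return LinearSignature(list(feature_subset), training_group).fit(cohort, y)


def _logistic_aic(Xs: np.ndarray, y: np.ndarray) -> float:
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
    lr.fit(Xs, y)
    p = np.clip(lr.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return 2.0 * (Xs.shape[1] + 1) - 2.0 * loglik


class AICSignatureSelector(BaseEstimator):
    """AIC-driven feature-subset selection for the linear signature.

    ``method='exhaustive'`` (default) scores every k-subset of the candidate
    features by the least-squares AIC of its fit and keeps the minimiser —
    for 11 candidates and k=4 that is C(11,4)=330 fits. ``method='stepwise'``
    performs bidirectional stepwise search from the full model using the same
    criterion and reports whatever size results.

    Attributes: ``subset_`` (tuple of names), ``model_`` (fitted
    :class:`LinearSignature`), ``aic_``.
    """

    def __init__(
        self,
        k: int = 4,
        method: str = "exhaustive",
        candidates: tuple[str, ...] | None = None,
        criterion: str = "ls",
        training_group: str = "synthetic",
    ):
        self.k = k
        self.method = method
        self.candidates = candidates
        self.criterion = criterion
        self.training_group = training_group

    def _score(self, X: pd.DataFrame, y: np.ndarray, subset) -> float:
        if self.criterion == "logistic":
            return _logistic_aic(X[list(subset)].to_numpy(dtype=float), y)
        model = LinearSignature(list(subset)).fit(X, y)
        return model.aic_

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        cand = list(self.candidates) if self.candidates is not None else [
            c for c in FEATURE_NAMES if c in X.columns
        ]
        if not cand:
            cand = list(X.columns)
        if self.method == "exhaustive":
            best, best_aic = None, np.inf
            for subset in combinations(cand, self.k):
                try:
                    a = self._score(X, y, subset)
                except (ValueError, np.linalg.LinAlgError) as err:
                    warnings.warn(f"skipping ill-conditioned subset {subset}: {err}", stacklevel=2)
                    continue
                if a < best_aic:
                    best, best_aic = subset, a
            if best is None:
                raise ValueError("no well-conditioned subset found")
        elif self.method == "stepwise":
            current = set(cand)
            best_aic = self._score(X, y, sorted(current))
            improved = True
            while improved:
                improved = False
                moves = [current - {f} for f in current if len(current) > 1]
                moves += [current | {f} for f in cand if f not in current]
                for m in moves:
                    try:
                        a = self._score(X, y, sorted(m))
                    except (ValueError, np.linalg.LinAlgError):
                        continue
                    if a < best_aic - 1e-12:
                        best_aic, current, improved = a, m, True
            best = tuple(sorted(current))
        else:
            raise ValueError(f"unknown method {self.method!r}")
        self.subset_ = tuple(best)
        self.model_ = LinearSignature(list(best), self.training_group).fit(X, y)
        self.aic_ = float(best_aic)
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.model_.decision_function(X)

    predict = decision_function


def select_signature(cohort: pd.DataFrame, k: int = 4, method: str = "exhaustive", training_group: str = "synthetic") -> LinearSignature:
    """Select the best k-feature signature of a cohort table (thin wrapper)."""
    y = _outcome_vector(cohort).astype(float)
    sel = AICSignatureSelector(k=k, method=method, training_group=training_group)
    sel.fit(cohort, y)
    return sel.model_


def evaluate_signature(model: LinearSignature, fv: dict | pd.Series | pd.DataFrame) -> float | np.ndarray:
    """Affine signature score of one feature vector (or one per row)."""
    if isinstance(fv, dict):
        fv = pd.Series(fv)
    if isinstance(fv, pd.Series):
        missing = set(model.feature_names_in_) - set(fv.index)
        if missing:
            raise ValueError(f"feature vector missing {sorted(missing)}")
        return float(model.intercept_ + sum(model.coef_[n] * fv[n] for n in model.feature_names_in_))
    return model.decision_function(fv)


# -- DeLong test ----------------------------------------------------------

def _placements(scores: np.ndarray, labels: np.ndarray):
    """Placement values and AUC of one score vector (midrank method)."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n          # per-positive: fraction of negatives below
    v01 = 1.0 - (tz[m:] - ty) / m    # per-negative: fraction of positives above
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return v10, v01, float(auc)


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided DeLong test for equality of two correlated ROC AUCs.

    Both score vectors must be measured on the same subjects (paired). The
    variance of the AUC difference uses the covariance of per-subject
    placement values. Degenerate zero-variance cases return p = 1 when the
    AUCs are equal and p = 0 otherwise.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned 1D arrays")
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes must be present")
    v10a, v01a, auc_a = _placements(scores_a, labels)
    v10b, v01b, auc_b = _placements(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2.0 * sps.norm.sf(abs(z)))


@dataclass
class CrossGroupResult:
    """Train/validation summary of one signature direction."""

    model: LinearSignature
    auc_train: float
    ci_train: tuple[float, float]
    auc_test: float
    ci_test: tuple[float, float]
    delong_vs_suvmax: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "auc_train": self.auc_train,
            "ci_train": list(self.ci_train),
            "auc_test": self.auc_test,
            "ci_test": list(self.ci_test),
            "delong_vs_suvmax": self.delong_vs_suvmax,
        }


def cross_group_validation(
    cohort: pd.DataFrame,
    train_group: str,
    test_group: str,
    k: int = 4,
    method: str = "exhaustive",
    n_boot: int = 2000,
    seed: int | None = 0,
) -> CrossGroupResult:
    """Select a signature on one scanner group and validate on the other.

    Returns train/test AUCs with stratified-bootstrap CIs and, per group,
    the DeLong p-value of the signature against SUVmax alone.
    """
    rng = np.random.default_rng(seed)
    tr = cohort[cohort["group"] == train_group]
    te = cohort[cohort["group"] == test_group]
    if len(tr) == 0 or len(te) == 0:
        raise ValueError("both groups must be populated")
    model = select_signature(tr, k=k, method=method, training_group=train_group)
    out: dict[str, float] = {}
    aucs, cis = {}, {}
    for name, sub in (("train", tr), ("test", te)):
        y = _outcome_vector(sub)
        s = model.decision_function(sub)
        aucs[name] = roc_auc(s, y)
        cis[name] = bootstrap_auc_ci(s, y, n_boot=n_boot, seed=rng)
        out[name] = delong_test(s, sub["SUVmax"].to_numpy(dtype=float), y)
    return CrossGroupResult(model, aucs["train"], cis["train"], aucs["test"], cis["test"], out)


def load_published_signature(group: str) -> LinearSignature:
    """Load the packaged published 4-feature signature for scanner group
    ``'G1'`` or ``'G2'`` (printed intercepts and coefficients; usable without
    refitting)."""
    name = {"G1": "signature_g1.json", "G2": "signature_g2.json"}.get(group.upper())
    if name is None:
        raise ValueError(f"unknown group {group!r}; expected 'G1' or 'G2'")
    text = resources.files("petrad.data").joinpath(name).read_text()
    return LinearSignature.from_dict(json.loads(text))
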