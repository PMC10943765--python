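"""NIPALS partial least squares: discriminant classification and calibration.

One latent-variable engine powers both tasks.  PLS-DA regresses a one-hot
dummy response onto the spectra and assigns each sample to the class with
the largest predicted membership; PLSR calibrates a univariate quantity
(here dry matter content, %) against the spectra.  Both are exposed as
model classes whose ``fit`` returns a results object carrying the
diagnostics used in chemometric practice: RMSEE/RMSECV/RMSEP, R2, Q2 and
permutation tests for classification; slope, RMSE, R2 and the residual
prediction deviation (RPD) for calibration.

The NIPALS algorithm extracts components maximising the covariance between
X scores and Y; X and Y are mean-centred (no variance scaling, the
spectroscopy convention), and with the full number of components on
full-rank data the fit coincides with ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "PlsModel",
    "pls_fit",
    "PLSDA",
    "PLSDAResults",
    "ClassificationReport",
    "PermutationResult",
    "PLSR",
    "PLSRResults",
    "RegressionReport",
    "classify_rpd",
    "select_factors",
]


# ---------------------------------------------------------------------------
# core NIPALS engine
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    """Mean-centred NIPALS decomposition.

    x_weights/x_loadings: (p, k); y_loadings: (q, k); x_scores: (n, k);
    coefficients: (p, q) regression matrix on centred data.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scores: np.ndarray = field(repr=False)
    coefficients: np.ndarray = field(repr=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[1] != len(self.x_mean):
            raise ValueError(
                f"model was fitted with {len(self.x_mean)} variables, got {x.shape[1]}"
            )
        return (x - self.x_mean) @ self.coefficients + self.y_mean


def pls_fit(x: np.ndarray, y: np.ndarray, n_lv: int,
            tol: float = 1e-12, max_iter: int = 1000) -> PlsModel:
    """Fit a PLS model by NIPALS with deflation of X and Y.

    Deterministic for fixed input.  Zero-variance X columns are kept but
    carry zero weight (a warning is emitted).
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")
    if np.any(x.std(axis=0) == 0.0):
        warnings.warn("zero-variance X columns carry no weight in the model",
                      stacklevel=2)

    x_mean, y_mean = x.mean(axis=0), y.mean(axis=0)
    e, f = x - x_mean, y - y_mean
    q_dim = y.shape[1]
    w_mat = np.zeros((p, n_lv))
    p_mat = np.zeros((p, n_lv))
    q_mat = np.zeros((q_dim, n_lv))
    t_mat = np.zeros((n, n_lv))

    for a in range(n_lv):
        # start u from the Y column with the largest residual variance
        u = f[:, int(np.argmax(f.var(axis=0)))].copy()
        if float(u @ u) == 0.0:  # Y residual exhausted
            n_lv = a
            break
        t_old = None
        for _ in range(max_iter):
            w = e.T @ u
            norm = np.linalg.norm(w)
            if norm == 0.0:
                break
            w /= norm
            t = e @ w
            q = f.T @ t / float(t @ t)
            qn = float(q @ q)
            u = f @ q / qn if qn > 0 else t
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t.copy()
        tt = float(t @ t)
        if tt == 0.0:
            n_lv = a
            break
        pv = e.T @ t / tt
        q = f.T @ t / tt
        e = e - np.outer(t, pv)
        f = f - np.outer(t, q)
        w_mat[:, a], p_mat[:, a], q_mat[:, a], t_mat[:, a] = w, pv, q, t

    w_mat, p_mat, q_mat, t_mat = (m[:, :n_lv] for m in (w_mat, p_mat, q_mat, t_mat))
    # B = W (P^T W)^-1 Q^T maps centred X to centred Y
    coef = w_mat @ np.linalg.solve(p_mat.T @ w_mat, q_mat.T)
    return PlsModel(
        n_lv=n_lv, x_mean=x_mean, y_mean=y_mean,
        x_weights=w_mat, x_loadings=p_mat, y_loadings=q_mat,
        x_scores=t_mat, coefficients=coef,
    )


def _rms(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(residuals))))


def dummy_matrix(labels: np.ndarray, classes: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One-hot dummy response; class column order is the sorted label set."""
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    y = (labels[:, None] == classes[None, :]).astype(float)
    if np.any(y.sum(axis=1) != 1):
        raise ValueError("labels contain classes unseen at fit time")
    return y, classes


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Discrimination diagnostics: accuracies in %, RMS errors on the dummy
    response, R2 (training) and cross-validated Q2."""

    n_lv: int
    accuracy_train: float
    accuracy_test: float
    rmsee: float
    rmsecv: float
    rmsep: float
    r2: float
    q2: float

    def summary(self) -> str:
        return (
            f"PLS-DA ({self.n_lv} LVs)\n"
            f"  R2 {self.r2:.3f}   Q2 {self.q2:.3f}\n"
            f"  RMSEE {self.rmsee:.3f}  RMSECV {self.rmsecv:.3f}  RMSEP {self.rmsep:.3f}\n"
            f"  accuracy: training {self.accuracy_train:.2f}%  "
            f"test {self.accuracy_test:.2f}%"
        )


@dataclass
class PermutationResult:
    """Label-permutation overfitting check (originals vs shuffled refits)."""

    r2_original: float
    q2_original: float
    r2_permuted: np.ndarray
    q2_permuted: np.ndarray
    label_correlation: np.ndarray

    def q2_quantile(self, q: float = 0.95) -> float:
        return float(np.quantile(self.q2_permuted, q))


class PLSDA:
    """Partial least squares discriminant analysis on spectra.

    Parameters
    ----------
    x : (n, p) feature matrix (preprocessed absorbance rows).
    labels : length-n class labels (e.g. harvest month 1-12).
    """

    def __init__(self, x: np.ndarray, labels: np.ndarray):
        self.x = np.atleast_2d(np.asarray(x, float))
        self.labels = np.asarray(labels)
        self.classes = np.unique(self.labels)
        if len(self.classes) < 2:
            raise ValueError("PLS-DA needs at least two classes")
        self.y_dummy, _ = dummy_matrix(self.labels, self.classes)

    def fit(self, n_lv: int) -> "PLSDAResults":
        model = pls_fit(self.x, self.y_dummy, n_lv)
        return PLSDAResults(self, model)


class PLSDAResults:
    """Fitted PLS-DA model with prediction and diagnostic methods.

    Two decision rules are available.  The default, ``rule='mahalanobis'``,
    assigns a sample to the nearest class centroid in latent-score space
    under the pooled within-class covariance metric (the distance-based
    prediction used by standard PLS-DA implementations such as mixOmics).
    ``rule='argmax'`` takes the largest predicted dummy-Y membership
    instead; with many classes spread along one dominant intensity
    continuum that rule inherits the class-masking defect of least-squares
    regression on indicator responses, so it is not the default.
    """

    def __init__(self, model_spec: PLSDA, model: PlsModel):
        self.spec = model_spec
        self.model = model
        self.n_lv = model.n_lv
        # rotation mapping centred X to scores: R = W (P^T W)^-1
        self._rotation = model.x_weights @ np.linalg.inv(
            model.x_loadings.T @ model.x_weights)
        t = self.scores(model_spec.x)
        self._centroids = np.vstack([
            t[model_spec.labels == c].mean(axis=0) for c in model_spec.classes])
        resid = t - self._centroids[
            np.searchsorted(model_spec.classes, model_spec.labels)]
        pooled = resid.T @ resid / max(len(t) - len(model_spec.classes), 1)
        pooled += np.eye(self.n_lv) * 1e-10 * max(np.trace(pooled), 1e-30)
        self._pooled_inv = np.linalg.pinv(pooled)

    def scores(self, x: np.ndarray) -> np.ndarray:
        """Latent-variable scores of new spectra."""
        x = np.atleast_2d(np.asarray(x, float))
        return (x - self.model.x_mean) @ self._rotation

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """Predicted dummy-Y memberships, one column per class.

        A value near 1 marks membership of that class, near 0 otherwise.
        """
        return self.model.predict(x)

    def predict(self, x: np.ndarray, rule: str = "mahalanobis") -> np.ndarray:
        if rule == "argmax":
            return self.spec.classes[np.argmax(self.decision_values(x), axis=1)]
        if rule != "mahalanobis":
            raise ValueError(f"unknown decision rule {rule!r}")
        t = self.scores(x)
        diff = t[:, None, :] - self._centroids[None, :, :]
        d2 = np.einsum("nck,kl,ncl->nc", diff, self._pooled_inv, diff)
        return self.spec.classes[np.argmin(d2, axis=1)]

    def membership(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Per-class 0/1 membership at the given dummy-Y threshold."""
        return (self.decision_values(x) >= threshold).astype(int)

    def accuracy(self, x: np.ndarray, labels: np.ndarray,
                 rule: str = "mahalanobis") -> float:
        return float(np.mean(self.predict(x, rule=rule) == np.asarray(labels)) * 100.0)

    def _cv(self, cv_folds: int) -> tuple[float, float]:
        """Pooled cross-validated RMSECV and Q2 on the training data."""
        x, y, labels = self.spec.x, self.spec.y_dummy, self.spec.labels
        press, n_cells = 0.0, 0
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=False)
        for tr, te in skf.split(x, labels):
            m = pls_fit(x[tr], y[tr], min(self.n_lv, min(len(tr) - 1, x.shape[1])))
            resid = y[te] - m.predict(x[te])
            press += float(np.sum(resid ** 2))
            n_cells += resid.size
        ss_tot = float(np.sum((y - y.mean(axis=0)) ** 2))
        q2 = 1.0 - press / ss_tot
        return float(np.sqrt(press / n_cells)), q2

    def evaluate(self, x_test: np.ndarray, labels_test: np.ndarray,
                 cv_folds: int = 7) -> ClassificationReport:
        """Full diagnostic report: training fit, k-fold CV, and test set."""
        if cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        x, y = self.spec.x, self.spec.y_dummy
        fitted = self.model.predict(x)
        rmsee = _rms(y - fitted)
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean(axis=0)) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        rmsecv, q2 = self._cv(cv_folds)
        y_test, _ = dummy_matrix(np.asarray(labels_test), self.spec.classes)
        rmsep = _rms(y_test - self.decision_values(x_test))
        return ClassificationReport(
            n_lv=self.n_lv,
            accuracy_train=self.accuracy(x, self.spec.labels),
            accuracy_test=self.accuracy(x_test, labels_test),
            rmsee=rmsee, rmsecv=rmsecv, rmsep=rmsep, r2=r2, q2=q2,
        )

    def permutation_test(self, n_perm: int = 200, seed: int = 0,
                         cv_folds: int = 7) -> PermutationResult:
        """Refit under shuffled labels to check for overfitting.

        For each of ``n_perm`` seeded shuffles the model is refitted and its
        R2/Q2 recorded together with the correlation of the shuffled dummy
        response with the original one.  A sound model shows the original Q2
        well above the permuted distribution.
        """
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        x, y = self.spec.x, self.spec.y_dummy
        fitted = self.model.predict(x)
        ss_tot = float(np.sum((y - y.mean(axis=0)) ** 2))
        r2_orig = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot
        _, q2_orig = self._cv(cv_folds)

        r2s, q2s, corrs = [], [], []
        for _ in range(n_perm):
            perm = rng.permutation(len(self.spec.labels))
            res = PLSDA(x, self.spec.labels[perm]).fit(self.n_lv)
            rep_fitted = res.model.predict(x)
            yp = res.spec.y_dummy
            ssp = float(np.sum((yp - yp.mean(axis=0)) ** 2))
            r2s.append(1.0 - float(np.sum((yp - rep_fitted) ** 2)) / ssp)
            _, q2p = res._cv(cv_folds)
            q2s.append(q2p)
            corrs.append(float(np.corrcoef(y.ravel(), yp.ravel())[0, 1]))
        return PermutationResult(
            r2_original=r2_orig, q2_original=q2_orig,
            r2_permuted=np.array(r2s), q2_permuted=np.array(q2s),
            label_correlation=np.array(corrs),
        )


# ---------------------------------------------------------------------------
# PLSR calibration
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    """Calibration diagnostics on an external test set."""

    factors: int
    slope: float
    rmse: float
    r2: float
    rpd: float

    @property
    def rpd_class(self) -> str:
        return classify_rpd(self.rpd)

    def summary(self) -> str:
        return (
            f"PLSR ({self.factors} factors)\n"
            f"  slope {self.slope:.3f}  RMSE {self.rmse:.3f}  "
            f"R2 {self.r2:.3f}  RPD {self.rpd:.2f} ({self.rpd_class})"
        )


class PLSR:
    """PLS calibration of a univariate quantity (e.g. dry matter content, %)
    against spectra."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        self.x = np.atleast_2d(np.asarray(x, float))
        self.y = np.asarray(y, float).ravel()
        if len(self.y) != self.x.shape[0]:
            raise ValueError("X and y lengths differ")

    def fit(self, factors: int) -> "PLSRResults":
        if factors < 1:
            raise ValueError("factors must be >= 1")
        model = pls_fit(self.x, self.y, factors)
        return PLSRResults(self, model)


class PLSRResults:
    def __init__(self, model_spec: PLSR, model: PlsModel):
        self.spec = model_spec
        self.model = model
        self.factors = model.n_lv

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x).ravel()

    def evaluate(self, x_test: np.ndarray, y_test: np.ndarray) -> RegressionReport:
        """Slope, RMSE, R2 and RPD of predictions on an external test set.

        RPD = SD(reference) / RMSEP, with the sample (n-1) standard
        deviation, so RPD * RMSE = SD(y_test) holds exactly.
        """
        y_test = np.asarray(y_test, float).ravel()
        pred = self.predict(x_test)
        resid = y_test - pred
        rmse = _rms(resid)
        sd = float(np.std(y_test, ddof=1))
        if sd == 0.0:
            raise ValueError("RPD undefined: test reference values have zero variance")
        yc = y_test - y_test.mean()
        slope = float(yc @ (pred - pred.mean()) / (yc @ yc))
        r2 = 1.0 - float(np.sum(resid ** 2)) / float(np.sum(yc ** 2))
        return RegressionReport(factors=self.factors, slope=slope, rmse=rmse,
                                r2=r2, rpd=sd / rmse)


def classify_rpd(rpd: float) -> str:
    """Qualitative RPD band: < 1.4 inadequate for quantitative work,
    1.4-2.0 semi-quantitative (accuracy needs improvement), > 2.0
    quantitatively reliable."""
    if rpd < 0:
        raise ValueError("RPD must be non-negative")
    if rpd < 1.4:
        return "inadequate"
    if rpd <= 2.0:
        return "semi_quantitative"
    return "quantitative"


def select_factors(x_train: np.ndarray, y_train: np.ndarray,
                   max_factors: int = 15, cv_folds: int = 7,
                   rule: str = "one_se") -> int:
    """Pick the factor count by cross-validated RMSECV.

    ``rule='one_se'`` (default) returns the smallest count whose RMSECV is
    within one standard error of the minimum; ``rule='min'`` the plain
    minimiser.  Contiguous-block folds keep the choice deterministic.
    """
    x = np.atleast_2d(np.asarray(x_train, float))
    y = np.asarray(y_train, float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    max_factors = min(max_factors, n - 1 - int(np.ceil(n / cv_folds)), x.shape[1])
    max_factors = max(max_factors, 1)
    kf = KFold(n_splits=cv_folds, shuffle=False)
    fold_mse = np.zeros((cv_folds, max_factors))
    for i, (tr, te) in enumerate(kf.split(x)):
        cap = min(max_factors, len(tr) - 1, x.shape[1])
        m_full = pls_fit(x[tr], y[tr], cap)
        for k in range(1, max_factors + 1):
            kk = min(k, cap)
            coef = (m_full.x_weights[:, :kk]
                    @ np.linalg.solve(m_full.x_loadings[:, :kk].T @ m_full.x_weights[:, :kk],
                                      m_full.y_loadings[:, :kk].T))
            pred = (x[te] - m_full.x_mean) @ coef + m_full.y_mean
            fold_mse[i, k - 1] = float(np.mean((y[te] - pred) ** 2))
    rmsecv = np.sqrt(fold_mse.mean(axis=0))
    k_min = int(np.argmin(rmsecv))
    if rule == "min":
        return k_min + 1
    se = float(np.std(fold_mse[:, k_min], ddof=1) / np.sqrt(cv_folds))
    # convert the MSE standard error to the RMSE scale around the minimum;
    # the small relative slack keeps the rule stable when the CV error is
    # numerically zero
    mse_min = fold_mse.mean(axis=0)[k_min]
    thresh = np.sqrt(mse_min + se) + 1e-9 * (1.0 + rmsecv.max())
    for k in range(k_min + 1):
        if rmsecv[k] <= thresh:
            return k + 1
    return k_min + 1
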