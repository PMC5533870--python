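"""Multivariate core: PCA screening with Hotelling T² outlier flagging,
OPLS-DA, stratified sevenfold cross-validation, permutation validation,
CV-ANOVA, VIP scores and regression-coefficient variable selection.

OPLS-DA here is the two-class case: the class variable is encoded +1/−1
(positive class is the case group), centred, and regressed on the scaled
bucket matrix after sequentially removing components orthogonal to the
class.  Because the predictive weight vector is proportional to X'y at
every deflation step, each orthogonal score is exactly uncorrelated with
the encoded class.  The regression vector ``b`` maps the original (scaled)
variables to predictions, which is what the coefficient-based variable
selection |b / b_cvSE| > 1 operates on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA screening
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    loadings: np.ndarray            # (k, a), orthonormal columns
    scores: np.ndarray              # (n, a)
    explained_variance_ratio: np.ndarray
    t2: np.ndarray                  # Hotelling T² per sample
    t2_crit: float
    alpha: float
    mean: np.ndarray
    sample_ids: list[str] | None = None


def _t2_critical(n: int, a: int, alpha: float) -> float:
    """Hotelling T² control limit for PCA scores estimated from the data."""
    if n <= a:
        return np.inf
    f = stats.f.ppf(1.0 - alpha, a, n - a)
    return a * (n - 1) * (n + 1) / (n * (n - a)) * f


def pca_fit(
    X: np.ndarray,
    n_components: int,
    alpha: float = 0.05,
    sample_ids: list[str] | None = None,
) -> PcaModel:
    """SVD principal components of a (scaled) matrix with T² statistics."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if not 1 <= n_components <= min(n - 1, k):
        raise ValueError("n_components must be in [1, min(n_samples-1, n_variables)]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate (zero) matrix")
    a = n_components
    loadings = Vt[:a].T
    scores = Xc @ loadings
    var = s**2 / (n - 1)
    evr = var[:a] / var.sum()
    score_var = scores.var(axis=0, ddof=1)
    t2 = ((scores**2) / score_var).sum(axis=1)
    return PcaModel(
        loadings, scores, evr, t2, _t2_critical(n, a, alpha), alpha, mean, sample_ids
    )


def flag_outliers(model: PcaModel, alpha: float | None = None) -> list[str]:
    """Samples whose Hotelling T² exceeds the F-based critical value.

    Flagging only — whether flagged samples are excluded is a pipeline
    configuration choice, not a side effect here.
    """
    n, a = model.scores.shape
    crit = model.t2_crit if alpha is None else _t2_critical(n, a, alpha)
    idx = np.nonzero(model.t2 > crit)[0]
    ids = model.sample_ids or [str(i) for i in range(n)]
    return [ids[i] for i in idx]


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def encode_labels(y: np.ndarray | list, positive_class: str | None = None):
    """Two-class ±1 encoding; returns (encoded, (negative, positive))."""
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if positive_class is None:
        positive_class = classes[1]
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not among {classes}")
    negative_class = classes[0] if classes[1] == positive_class else classes[1]
    enc = np.where(y == positive_class, 1.0, -1.0)
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    return enc, (negative_class, positive_class)


@dataclass
class OplsdaModel:
    """Fitted OPLS-DA: one predictive component plus orthogonal components."""

    w: np.ndarray                   # predictive weights (unit norm, original space of deflated X)
    p: np.ndarray                   # predictive loadings
    t: np.ndarray                   # predictive scores
    q: float                        # y-loading
    w_ortho: np.ndarray             # (n_orthogonal, k)
    p_ortho: np.ndarray
    t_ortho: np.ndarray             # (n, n_orthogonal)
    b: np.ndarray                   # regression vector in original (scaled) variable space
    n_orthogonal: int
    classes: tuple[str, str]        # (negative, positive)
    r2y: float
    x_mean: np.ndarray
    y_offset: float                 # mean of the ±1 encoding on training data

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous prediction on the ±1 class scale."""
        return (np.asarray(X, dtype=float) - self.x_mean) @ self.b + self.y_offset

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        yhat = self.predict(X)
        neg, pos = self.classes
        return np.where(yhat > 0, pos, neg)


def oplsda_fit(
    X: np.ndarray,
    y: np.ndarray | list,
    n_orthogonal: int = 1,
    positive_class: str | None = None,
) -> OplsdaModel:
    """Fit a two-class OPLS-DA model.

    Orthogonal components are estimated and removed by sequential deflation
    (w_o ∝ p − (wᵀp)w on the current deflated matrix), then a single
    predictive PLS component is fitted.  ``b`` composes the deflation with
    the predictive component so that predictions are a linear map of the
    original (scaled, uncentred) matrix.
    """
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    y_enc, classes = encode_labels(y, positive_class)
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    if n_orthogonal >= min(n - 1, k):
        raise ValueError("n_orthogonal must be below the matrix rank")

    x_mean = X.mean(axis=0)
    Xd = X - x_mean
    y_offset = y_enc.mean()
    yc = y_enc - y_offset

    w_os, p_os, t_os = [], [], []
    for _ in range(n_orthogonal):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 0:
            raise ValueError("degenerate X'y during deflation")
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        nwo = np.linalg.norm(w_o)
        if nwo <= 1e-12:
            logger.warning("orthogonal component degenerate; stopping deflation early")
            break
        w_o /= nwo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)

    # predictive component on the deflated matrix
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw <= 0:
        raise ValueError("degenerate X'y for the predictive component")
    w /= nw
    t = Xd @ w
    tt = t @ t
    if tt <= 0:
        raise ValueError("degenerate predictive score")
    p = Xd.T @ t / tt
    q = float(yc @ t / tt)

    # compose the deflation with the predictive component: for a new row x,
    # deflation applies x <- x(I - w_o p_o') in fitting order, so
    # b = (I - w_o1 p_o1') ... (I - w_oA p_oA') w q, applied right to left
    v = w.copy()
    for w_o, p_o in reversed(list(zip(w_os, p_os))):
        v = v - w_o * (p_o @ v)
    b = v * q
    yhat = t * q
    ss_res = float(((yc - yhat) ** 2).sum())
    ss_tot = float((yc**2).sum())
    r2y = 1.0 - ss_res / ss_tot

    return OplsdaModel(
        w=w,
        p=p,
        t=t,
        q=q,
        w_ortho=np.array(w_os).reshape(len(w_os), k),
        p_ortho=np.array(p_os).reshape(len(p_os), k),
        t_ortho=np.array(t_os).T.reshape(n, len(t_os)),
        b=b,
        n_orthogonal=len(w_os),
        classes=classes,
        r2y=r2y,
        x_mean=x_mean,
        y_offset=y_offset,
    )


def vip_scores(model: OplsdaModel) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt(k · Σ_a SSY_a w_aj² / Σ_a SSY_a); with a single predictive
    component and a unit-norm weight vector this is sqrt(k)·|w_j|, so the
    mean squared VIP is exactly 1.
    """
    k = len(model.w)
    return np.sqrt(k) * np.abs(model.w)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvResult:
    fold_assignments: np.ndarray        # fold index per sample
    b_folds: np.ndarray                 # (n_folds, k) regression vectors
    press: float
    q2y: float
    b_cvse: np.ndarray
    n_folds: int
    n_orthogonal: int
    seed: int
    press_per_fold: np.ndarray = field(default_factory=lambda: np.array([]))


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment where every training split keeps both
    classes; reshuffles (up to 10 attempts) if a split degenerates."""
    for attempt in range(10):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=(seed + attempt) % (2**31)
        )
        folds = np.empty(len(y), dtype=int)
        ok = True
        for f, (train, test) in enumerate(skf.split(np.zeros_like(y), y)):
            folds[test] = f
            if len(np.unique(np.asarray(y)[train])) < 2:
                ok = False
        if ok:
            if attempt:
                logger.warning("reshuffled folds %d time(s) to keep both classes", attempt)
            return folds
    raise ValueError("could not build folds with both classes in every training split")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray | list,
    n_orthogonal: int = 1,
    n_folds: int = 7,
    seed: int = 0,
    rescale: bool = True,
    positive_class: str | None = None,
) -> CvResult:
    """Stratified k-fold cross-validation of the OPLS-DA model.

    Per fold the model (and, when ``rescale`` is true, the unit-variance
    scaling) is refit on the training samples only and the held-out samples
    are predicted; Q²Y = 1 − PRESS / SS_tot(y).  Fold regression vectors are
    mapped back to the coordinates of the input matrix so they are
    comparable across folds, and b_cvSE is their delete-one-fold jackknife
    standard error: sqrt((g−1)/g · Σ_f (b_f − b̄)²) with g folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    y_enc, _ = encode_labels(y, positive_class)
    n, k = X.shape
    counts = np.bincount((y_enc > 0).astype(int))
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds the smaller class size {counts.min()}"
        )
    folds = _stratified_folds(y, n_folds, seed)

    press = 0.0
    press_per_fold = np.zeros(n_folds)
    b_folds = np.zeros((n_folds, k))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        Xtr, Xte = X[train], X[test]
        if rescale:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=1)
            sd = np.where(sd > 1e-12, sd, 1.0)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        model = oplsda_fit(Xtr, y[train], n_orthogonal, positive_class)
        yhat = model.predict(Xte)
        resid = y_enc[test] - yhat
        press_per_fold[f] = float(resid @ resid)
        press += press_per_fold[f]
        # chain rule maps the fold-scaled coefficients back to input coordinates
        b_folds[f] = model.b / sd if rescale else model.b

    ss_tot = float(((y_enc - y_enc.mean()) ** 2).sum())
    q2y = 1.0 - press / ss_tot
    # delete-one-fold jackknife: Var(b) = (g-1)/g * sum_f (b_f - mean)^2
    b_mean = b_folds.mean(axis=0)
    b_cvse = np.sqrt(
        (n_folds - 1) / n_folds * ((b_folds - b_mean) ** 2).sum(axis=0)
    )
    return CvResult(
        folds, b_folds, press, q2y, b_cvse, n_folds, n_orthogonal, seed, press_per_fold
    )


# ---------------------------------------------------------------------------
# Permutation testing, CV-ANOVA, selection
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    n_permutations: int
    correlations: np.ndarray        # |corr(permuted y, original y)|
    r2y_perm: np.ndarray
    q2y_perm: np.ndarray
    r2y_original: float
    q2y_original: float
    r2_intercept: float
    q2_intercept: float
    p_value: float


def _intercept(corrs: np.ndarray, values: np.ndarray, original: float) -> float:
    """Value at |corr| = 0 of the least-squares line through the permuted
    points plus the original point at |corr| = 1."""
    x = np.append(corrs, 1.0)
    v = np.append(values, original)
    slope, intercept = np.polyfit(x, v, 1)
    return float(intercept)


def permutation_test(
    X: np.ndarray,
    y: np.ndarray | list,
    n_orthogonal: int = 1,
    n_permutations: int = 100,
    seed: int = 0,
    n_folds: int = 7,
    rescale: bool = True,
    positive_class: str | None = None,
) -> PermutationResult:
    """Class-label permutation null for R²Y and Q²Y.

    Each permutation shuffles the labels, refits the full model (R²Y) and
    the cross-validation (Q²Y), and records |corr| between the permuted and
    the original encoded labels.  The empirical p-value for Q²Y uses the
    add-one convention: (1 + #{Q²_perm ≥ Q²_orig}) / (n_permutations + 1).
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    y_enc, _ = encode_labels(y, positive_class)

    model = oplsda_fit(X, y, n_orthogonal, positive_class)
    cv = cross_validate(X, y, n_orthogonal, n_folds, seed, rescale, positive_class)

    rng = np.random.default_rng(seed)
    corrs = np.zeros(n_permutations)
    r2s = np.zeros(n_permutations)
    q2s = np.zeros(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(y))
        y_perm = y[perm]
        corrs[i] = abs(float(np.corrcoef(y_enc, y_enc[perm])[0, 1]))
        m = oplsda_fit(X, y_perm, n_orthogonal, positive_class)
        r2s[i] = m.r2y
        cv_p = cross_validate(
            X, y_perm, n_orthogonal, n_folds,
            int(rng.integers(2**31)), rescale, positive_class,
        )
        q2s[i] = cv_p.q2y

    p = (1.0 + float((q2s >= cv.q2y).sum())) / (n_permutations + 1.0)
    return PermutationResult(
        n_permutations,
        corrs,
        r2s,
        q2s,
        model.r2y,
        cv.q2y,
        _intercept(corrs, r2s, model.r2y),
        _intercept(corrs, q2s, cv.q2y),
        p,
    )


def cv_anova(cv: CvResult, y: np.ndarray | list, positive_class: str | None = None) -> float:
    """Cross-validated ANOVA p-value for model significance.

    F compares the variance explained by the cross-validated predictions
    against the predictive residuals: F = ((SS_tot − PRESS)/ν1)/(PRESS/ν2)
    with ν1 = number of model components and ν2 = n − ν1 − 1.  A model no
    better than the mean (PRESS ≥ SS_tot) gives p = 1; zero residuals give
    p = 0.
    """
    y_enc, _ = encode_labels(np.asarray(y), positive_class)
    ss_tot = float(((y_enc - y_enc.mean()) ** 2).sum())
    press = cv.press
    if press <= 0:
        return 0.0
    n = len(y_enc)
    nu1 = 1 + cv.n_orthogonal
    nu2 = n - nu1 - 1
    if nu2 <= 0:
        raise ValueError("too few samples for CV-ANOVA degrees of freedom")
    f_stat = max(((ss_tot - press) / nu1) / (press / nu2), 0.0)
    return float(stats.f.sf(f_stat, nu1, nu2))


@dataclass
class SelectionResult:
    ratio: np.ndarray               # |b / b_cvSE|
    keep: np.ndarray                # boolean mask
    kept_indices: np.ndarray
    threshold: float


def select_variables(
    model: OplsdaModel, cv: CvResult, threshold: float = 1.0
) -> SelectionResult:
    """Coefficient-stability variable selection: keep |b / b_cvSE| > threshold.

    ``b`` comes from the full-data model, ``b_cvSE`` from the fold-wise
    coefficient spread.  A variable with zero SE and nonzero coefficient is
    maximally stable and is kept (logged).
    """
    b = model.b
    se = cv.b_cvse
    if b.shape != se.shape:
        raise ValueError("b and b_cvSE must have the same length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(b) / se
    zero_se = (se == 0) & (b != 0)
    if zero_se.any():
        logger.info("%d variable(s) with zero b_cvSE and nonzero b kept", zero_se.sum())
        ratio[zero_se] = np.inf
    ratio[(se == 0) & (b == 0)] = 0.0
    keep = ratio > threshold
    return SelectionResult(ratio, keep, np.nonzero(keep)[0], threshold)
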