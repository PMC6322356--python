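"""PCA and OPLS-DA with the diagnostics metabolomics studies report.

The discriminant model is orthogonal projections to latent structures
(O-PLS): X-variation is split into a single component predictive of the
binary class vector and ``n_orth`` components orthogonal to it, fitted by
the NIPALS-style deflation of Trygg & Wold.  Model quality is summarised by
R2X (X-variance captured), R2Y (1 - RSS/TSS on the centered class vector)
and Q2 (1 - PRESS/TSS under k-fold cross-validation).  Feature-level
diagnostics are the VIP score (normalised so mean VIP^2 = 1) and the S-plot
(covariance vs correlation of each scaled feature with the predictive
score).  Model validity is assessed by a label-permutation test on Q2.

Everything here operates on a :class:`~vkmet.features.ScaledMatrix`, i.e. a
column-centered samples-by-features array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import ScaledMatrix

__all__ = [
    "PcaModel",
    "OplsModel",
    "PermutationResult",
    "fit_pca",
    "fit_oplsda",
    "vip_scores",
    "s_plot",
    "permutation_test",
]


@dataclass
class PcaModel:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    r2x_per_component: np.ndarray
    r2x_cum: float
    n_components: int


@dataclass
class OplsModel:
    """Fitted OPLS-DA model: one predictive + ``n_orth`` orthogonal components."""

    w: np.ndarray  # predictive weights, unit norm
    t_pred: np.ndarray  # predictive scores
    p_pred: np.ndarray  # predictive loadings
    q: float  # y-loading of the predictive component
    w_orth: np.ndarray  # features x n_orth
    p_orth: np.ndarray
    t_orth: np.ndarray  # samples x n_orth
    r2x: float
    r2y: float
    q2: float
    n_orth: int
    y_mean: float
    classes: tuple

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        """Predictive score of new (already scaled/centered) rows."""
        xc = np.array(x, dtype=float, copy=True)
        for a in range(self.n_orth):
            t_o = xc @ self.w_orth[:, a]
            xc -= np.outer(t_o, self.p_orth[:, a])
        return xc @ self.w

    def predict_y(self, x: np.ndarray) -> np.ndarray:
        return self.predict_scores(x) * self.q + self.y_mean


@dataclass
class PermutationResult:
    observed_r2y: float
    observed_q2: float
    permuted_r2y: np.ndarray
    permuted_q2: np.ndarray
    p_q2: float


def fit_pca(x: ScaledMatrix | np.ndarray, n_components: int | str = "auto") -> PcaModel:
    """PCA by singular value decomposition of the centered matrix.

    ``auto`` keeps components whose variance exceeds the mean component
    variance (the scaled-data analogue of the eigenvalue-above-average
    rule), mirroring how chemometrics software auto-fits component counts.
    """
    xv = x.values if isinstance(x, ScaledMatrix) else np.asarray(x, float)
    n, p = xv.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    xc = xv - xv.mean(axis=0)
    max_rank = min(n - 1, p)
    if n_components != "auto":
        k = int(n_components)
        if k < 1 or k > max_rank:
            raise ValueError(f"n_components must be in [1, {max_rank}]")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    ss_tot = (xc**2).sum()
    var = s**2
    r2_all = var / ss_tot if ss_tot > 0 else np.zeros_like(var)
    if n_components == "auto":
        pos = var[var > ss_tot * 1e-12]
        k = max(1, int(np.sum(pos > pos.mean()))) if pos.size else 1
        k = min(k, max_rank)
    scores = u[:, :k] * s[:k]
    return PcaModel(
        scores=scores,
        loadings=vt[:k].T,
        r2x_per_component=r2_all[:k],
        r2x_cum=float(r2_all[:k].sum()),
        n_components=k,
    )


def _encode_y(y) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(y)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    y01 = (labels == classes[1]).astype(float)
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return y01, classes


def _opls_core(x: np.ndarray, yc: np.ndarray, n_orth: int):
    """Trygg-Wold O-PLS deflation for a single centered response."""
    xd = np.array(x, dtype=float, copy=True)
    p_feat = xd.shape[1]
    w_list, p_list, t_list = [], [], []
    for _ in range(n_orth):
        w = xd.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = xd @ w
        p = xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12 * max(1.0, np.linalg.norm(p)):
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = xd @ w_o
        p_o = xd.T @ t_o / (t_o @ t_o)
        xd -= np.outer(t_o, p_o)
        w_list.append(w_o)
        p_list.append(p_o)
        t_list.append(t_o)
    k = len(w_list)
    w = xd.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response carries no covariance with X")
    w /= nw
    t = xd @ w
    p = xd.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    w_orth = np.column_stack(w_list) if k else np.empty((p_feat, 0))
    p_orth = np.column_stack(p_list) if k else np.empty((p_feat, 0))
    t_orth = np.column_stack(t_list) if k else np.empty((len(yc), 0))
    return w, t, p, q, w_orth, p_orth, t_orth, k


def _cv_folds(y01: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic round-robin folds after a seeded shuffle, per class."""
    rng = np.random.default_rng(seed)
    assign = np.empty(len(y01), dtype=int)
    counter = 0
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        for i in idx:
            assign[i] = counter % n_folds
            counter += 1
    return [np.flatnonzero(assign == f) for f in range(n_folds)]


def _press(x: np.ndarray, y01: np.ndarray, n_orth: int, folds) -> float:
    press = 0.0
    for test in folds:
        if len(test) == 0:
            continue
        train = np.setdiff1d(np.arange(len(y01)), test)
        y_tr = y01[train]
        if len(set(y_tr.tolist())) < 2:
            continue
        yc_tr = y_tr - y_tr.mean()
        w, t, p, q, w_o, p_o, t_o, k = _opls_core(x[train], yc_tr, n_orth)
        xc = np.array(x[test], copy=True)
        for a in range(k):
            t_new = xc @ w_o[:, a]
            xc -= np.outer(t_new, p_o[:, a])
        y_hat = (xc @ w) * q + y_tr.mean()
        press += float(((y01[test] - y_hat) ** 2).sum())
    return press


def fit_oplsda(
    x: ScaledMatrix | np.ndarray,
    y,
    n_orth: int | str = "auto",
    cv_folds: int = 7,
    seed: int = 0,
) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    x : scaled matrix (samples x features), column-centered
    y : length-n sequence of two class labels
    n_orth : number of orthogonal components, or ``"auto"`` to add them
        while cross-validated Q2 improves by more than 0.01
    cv_folds : folds for Q2 (capped at n samples)
    seed : controls the fold shuffle only
    """
    xv = x.values if isinstance(x, ScaledMatrix) else np.asarray(x, float)
    y01, classes = _encode_y(y)
    n = len(y01)
    if xv.shape[0] != n:
        raise ValueError("x and y disagree on sample count")
    rank = np.linalg.matrix_rank(xv)
    folds = _cv_folds(y01, min(cv_folds, n), seed)
    yc = y01 - y01.mean()
    tss = float((yc**2).sum())

    def q2_at(k: int) -> float:
        return 1.0 - _press(xv, y01, k, folds) / tss

    if n_orth == "auto":
        best_k, best_q2 = 0, q2_at(0)
        k = 1
        while k <= max(0, rank - 2):
            q2k = q2_at(k)
            if q2k > best_q2 + 0.01:
                best_k, best_q2 = k, q2k
                k += 1
            else:
                break
        k_orth, q2 = best_k, best_q2
    else:
        k_orth = int(n_orth)
        if k_orth < 0 or k_orth > max(0, rank - 1):
            raise ValueError(f"n_orth must be in [0, {max(0, rank - 1)}]")
        q2 = q2_at(k_orth)

    w, t, p, q, w_o, p_o, t_o, k_eff = _opls_core(xv, yc, k_orth)
    y_hat = t * q
    rss = float(((yc - y_hat) ** 2).sum())
    r2y = 1.0 - rss / tss
    ss_x = float((xv**2).sum())
    explained = float((np.outer(t, p) ** 2).sum())
    for a in range(k_eff):
        explained += float((t_o[:, a] ** 2).sum() * (p_o[:, a] ** 2).sum())
    r2x = explained / ss_x if ss_x > 0 else 0.0
    return OplsModel(
        w=w,
        t_pred=t,
        p_pred=p,
        q=float(q),
        w_orth=w_o,
        p_orth=p_o,
        t_orth=t_o,
        r2x=min(r2x, 1.0),
        r2y=r2y,
        q2=q2,
        n_orth=k_eff,
        y_mean=float(y01.mean()),
        classes=classes,
    )


def vip_scores(m: OplsModel) -> np.ndarray:
    """Variable importance in projection for the predictive component.

    With a single Y-predictive component carrying all explained Y-variance,
    VIP_j = sqrt(p) * |w_j| (w unit-norm), hence mean(VIP^2) = 1 exactly.
    Orthogonal components explain no Y by construction and contribute zero
    weight — users comparing with software that reports a "total" VIP over
    all components should expect small differences.
    """
    p = len(m.w)
    return np.sqrt(p) * np.abs(m.w)


def s_plot(m: OplsModel, x: ScaledMatrix | np.ndarray):
    """Covariance/correlation of each scaled feature with the predictive score.

    Returns ``(p_cov, p_corr, zero_variance_flags)``.  Zero-variance features
    get p_corr = 0 with the flag set.
    """
    xv = x.values if isinstance(x, ScaledMatrix) else np.asarray(x, float)
    t = m.t_pred
    n = len(t)
    tc = t - t.mean()
    xc = xv - xv.mean(axis=0)
    p_cov = xc.T @ tc / (n - 1)
    sd_x = xv.std(axis=0, ddof=1)
    sd_t = t.std(ddof=1)
    flags = sd_x == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        p_corr = np.where(flags, 0.0, p_cov / (sd_x * sd_t))
    return p_cov, np.clip(p_corr, -1.0, 1.0), flags


def permutation_test(
    x: ScaledMatrix | np.ndarray,
    y,
    n_perm: int = 200,
    seed: int = 0,
    n_orth: int | str = None,
    cv_folds: int = 7,
) -> PermutationResult:
    """Label-permutation validation of an OPLS-DA model.

    The observed model is fitted, then the class labels are permuted
    ``n_perm`` times, the model refitted each time with the same number of
    orthogonal components, and the Q2 null distribution recorded.  The
    p-value is the add-one tail estimate
    ``(#{permuted Q2 >= observed Q2} + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xv = x.values if isinstance(x, ScaledMatrix) else np.asarray(x, float)
    y = np.asarray(y)
    obs = fit_oplsda(xv, y, n_orth="auto" if n_orth is None else n_orth,
                     cv_folds=cv_folds, seed=seed)
    rng = np.random.default_rng(seed)
    perm_r2y = np.empty(n_perm)
    perm_q2 = np.empty(n_perm)
    for i in range(n_perm):
        yp = rng.permutation(y)
        while len(set(yp[:2].tolist())) == 0:  # pragma: no cover - defensive
            yp = rng.permutation(y)
        try:
            mp = fit_oplsda(xv, yp, n_orth=obs.n_orth, cv_folds=cv_folds, seed=seed)
            perm_r2y[i] = mp.r2y
            perm_q2[i] = mp.q2
        except ValueError:
            perm_r2y[i] = np.nan
            perm_q2[i] = -np.inf
    p = (int(np.sum(perm_q2 >= obs.q2)) + 1) / (n_perm + 1)
    return PermutationResult(
        observed_r2y=obs.r2y,
        observed_q2=obs.q2,
        permuted_r2y=perm_r2y,
        permuted_q2=perm_q2,
        p_q2=p,
    )
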