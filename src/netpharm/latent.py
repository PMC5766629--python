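"""Supervised latent-variable models for two-class spectral data.

Implements PLS-DA (NIPALS PLS1 on a centered 0/1 dummy response) and
OPLS-DA (orthogonal-signal-corrected PLS with one predictive component),
in the Model / Results style: construct a model from ``X`` and class
labels, call :meth:`fit`, and read estimates, diagnostics and summaries
off the returned results object.

Diagnostics follow metabolomics conventions:

* R2X / R2Y — cumulative fraction of X / Y variance explained;
* Q2 — cross-validated predictive ability, 1 - PRESS/SS, by 7-fold
  venetian-blind cross-validation over sample order;
* VIP — variable importance in projection, normalized so the mean of
  VIP^2 over variables is exactly 1;
* permutation validation — the class vector is reshuffled ``n_perm``
  times and the model refitted; the original model is considered valid
  only if every permuted R2Y and Q2 falls strictly below the originals.

The decompositions themselves are computed in-repo (NIPALS and the
orthogonal filter); they are deliberately not delegated to a generic
PLS library so that the scaling, cross-validation and validation
conventions stay exactly as documented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "PLSDA",
    "OPLSDA",
    "PLSDAResults",
    "OPLSDAResults",
    "PermutationResult",
    "ConvergenceError",
]

Scaling = Literal["center", "uv", "pareto"]


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge, or no y-correlated variation remains."""


# ---------------------------------------------------------------------
# scaling and label handling
# ---------------------------------------------------------------------


def _scale_params(X: np.ndarray, scaling: Scaling) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if scaling == "center":
        scale = np.ones(X.shape[1])
    else:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant column: center only
        scale = sd if scaling == "uv" else np.sqrt(sd)
    return mean, scale


def _apply_scale(X: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (X - mean) / scale


def _encode_binary(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"need exactly 2 classes, got {classes.size}: {classes!r}"
        )
    y01 = (y == classes[1]).astype(float)
    counts = np.bincount(y01.astype(int))
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    return y01, classes


# ---------------------------------------------------------------------
# NIPALS PLS1 core
# ---------------------------------------------------------------------


def _nipals_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> dict[str, np.ndarray]:
    """NIPALS decomposition of (X, y), y univariate and centered.

    Returns weights W (p x A), scores T (n x A), X-loadings P (p x A)
    and y-loadings c (A,); X and y are deflated between components.
    """
    Xr = X.copy()
    yr = y.copy()
    n, p = X.shape
    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    P = np.empty((p, n_components))
    c = np.empty(n_components)
    for a in range(n_components):
        u = yr
        w_old = None
        for _ in range(max_iter):
            w = Xr.T @ u
            nrm = np.linalg.norm(w)
            if nrm < 1e-14:
                raise ConvergenceError(
                    f"no y-correlated variation left at component {a + 1}"
                )
            w /= nrm
            t = Xr @ w
            ca = (yr @ t) / (t @ t)
            u_new = yr * ca / (ca * ca) if ca != 0 else yr
            if w_old is not None and np.linalg.norm(w - w_old) < tol:
                break
            w_old = w
            u = u_new
        else:
            raise ConvergenceError(
                f"NIPALS did not converge at component {a + 1}"
            )
        t = Xr @ w
        pa = Xr.T @ t / (t @ t)
        ca = (yr @ t) / (t @ t)
        Xr = Xr - np.outer(t, pa)
        yr = yr - t * ca
        W[:, a], T[:, a], P[:, a], c[a] = w, t, pa, ca
    return {"W": W, "T": T, "P": P, "c": c, "X_res": Xr, "y_res": yr}


def _pls1_coef(W: np.ndarray, P: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Regression vector B with yhat = Xs @ B (Xs scaled, y centered)."""
    return W @ np.linalg.solve(P.T @ W, c)


def _vip(W: np.ndarray, T: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Variable importance in projection; sum of VIP^2 equals n_variables."""
    p = W.shape[0]
    ssy = c**2 * np.einsum("ij,ij->j", T, T)  # per-component explained SSY
    wsq = W**2 / np.sum(W**2, axis=0)
    return np.sqrt(p * (wsq @ ssy) / ssy.sum())


# ---------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a label-shuffling validation.

    ``valid`` is True only when every permuted R2Y *and* Q2 lies
    strictly below the corresponding statistic of the unpermuted model.
    """

    n_perm: int
    r2_perm: np.ndarray
    q2_perm: np.ndarray
    r2_orig: float
    q2_orig: float

    @property
    def valid(self) -> bool:
        return bool(
            np.all(self.r2_perm < self.r2_orig)
            and np.all(self.q2_perm < self.q2_orig)
        )


# ---------------------------------------------------------------------
# models
# ---------------------------------------------------------------------


class _LatentModelBase:
    """Shared validation, scaling and cross-validation plumbing."""

    def __init__(self, X, y, scaling: Scaling = "uv", cv_folds: int = 7):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D samples x variables matrix")
        if scaling not in ("center", "uv", "pareto"):
            raise ValueError(f"unknown scaling {scaling!r}")
        self.X = X
        self.y01, self.classes_ = _encode_binary(y)
        if len(self.y01) != X.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        self.scaling: Scaling = scaling
        self.cv_folds = min(cv_folds, X.shape[0])

    def _fold_ids(self) -> np.ndarray:
        # venetian blind: every cv_folds-th sample, by input order
        return np.arange(self.X.shape[0]) % self.cv_folds

    def _press(self, n_components: int) -> np.ndarray:
        """PRESS per cumulative component count over the CV folds."""
        folds = self._fold_ids()
        press = np.zeros(n_components)
        for f in range(self.cv_folds):
            test = folds == f
            Xtr, ytr = self.X[~test], self.y01[~test]
            if np.unique(ytr).size < 2:
                raise ValueError(
                    "a cross-validation training fold contains one class; "
                    "reorder samples or reduce cv_folds"
                )
            mean, scale = _scale_params(Xtr, self.scaling)
            ym = ytr.mean()
            fitted = self._fit_raw(
                _apply_scale(Xtr, mean, scale), ytr - ym, n_components
            )
            Xte = _apply_scale(self.X[test], mean, scale)
            preds = self._predict_components(fitted, Xte)  # (n_test, A)
            err = (self.y01[test][:, None] - (preds + ym)) ** 2
            press += err.sum(axis=0)
        return press

    def _q2(self, n_components: int) -> np.ndarray:
        ss = np.sum((self.y01 - self.y01.mean()) ** 2)
        return 1.0 - self._press(n_components) / ss

    # subclasses provide _fit_raw / _predict_components


class PLSDA(_LatentModelBase):
    """Partial least squares discriminant analysis for two classes.

    Parameters
    ----------
    X : array-like, samples x variables
        Feature matrix (e.g. normalized spectral bins).
    y : array-like
        Two-level class labels; the lexically larger level is coded 1.
    n_components : int or "auto"
        Number of latent components.  ``"auto"`` keeps adding components
        while each one improves Q2 by more than 0.01.
    scaling : {"uv", "pareto", "center"}
        Column scaling applied before decomposition (unit variance by
        default).
    cv_folds : int
        Folds for the venetian-blind Q2 cross-validation (default 7).
    """

    def __init__(self, X, y, n_components: int | str = 2,
                 scaling: Scaling = "uv", cv_folds: int = 7):
        super().__init__(X, y, scaling, cv_folds)
        n, p = self.X.shape
        cap = min(n, p) - 1
        if n_components == "auto":
            self._auto = True
            self.n_components = min(cap, 10)
        else:
            self._auto = False
            if not 1 <= int(n_components) <= cap:
                raise ValueError(
                    f"n_components must be in [1, {cap}] for this data"
                )
            self.n_components = int(n_components)

    @classmethod
    def from_binned(cls, binned, **kwargs) -> "PLSDA":
        """Build from a :class:`~netpharm.nmr.BinnedMatrix` (uses its
        ``X`` and ``groups``)."""
        return cls(binned.X, binned.groups, **kwargs)

    # raw machinery -----------------------------------------------------

    def _fit_raw(self, Xs, yc, n_components):
        return _nipals_pls1(Xs, yc, n_components)

    def _predict_components(self, fitted, Xs_new):
        W, P, c = fitted["W"], fitted["P"], fitted["c"]
        A = W.shape[1]
        out = np.empty((Xs_new.shape[0], A))
        for a in range(1, A + 1):
            B = _pls1_coef(W[:, :a], P[:, :a], c[:a])
            out[:, a - 1] = Xs_new @ B
        return out

    # public ------------------------------------------------------------

    def fit(self) -> "PLSDAResults":
        mean, scale = _scale_params(self.X, self.scaling)
        Xs = _apply_scale(self.X, mean, scale)
        ym = self.y01.mean()
        yc = self.y01 - ym

        q2_all = self._q2(self.n_components)
        if self._auto:
            a = 1
            while a < self.n_components and q2_all[a] - q2_all[a - 1] > 0.01:
                a += 1
            n_comp = a
        else:
            n_comp = self.n_components

        d = _nipals_pls1(Xs, yc, n_comp)
        ssx, ssy = np.sum(Xs**2), np.sum(yc**2)
        # cumulative explained variance after each component
        r2x_cum, r2y_cum = [], []
        Xr, yr = Xs.copy(), yc.copy()
        for a in range(n_comp):
            t, pa, ca = d["T"][:, a], d["P"][:, a], d["c"][a]
            Xr = Xr - np.outer(t, pa)
            yr = yr - t * ca
            r2x_cum.append(1.0 - np.sum(Xr**2) / ssx)
            r2y_cum.append(1.0 - np.sum(yr**2) / ssy)

        return PLSDAResults(
            model=self,
            n_components=n_comp,
            x_weights=d["W"],
            x_scores=d["T"],
            x_loadings=d["P"],
            y_loadings=d["c"],
            coef=_pls1_coef(d["W"], d["P"], d["c"]),
            x_mean=mean,
            x_scale=scale,
            y_mean=ym,
            r2x=float(r2x_cum[-1]),
            r2y=float(r2y_cum[-1]),
            q2=float(q2_all[n_comp - 1]),
            r2x_per_component=np.asarray(r2x_cum),
            r2y_per_component=np.asarray(r2y_cum),
            q2_per_component=q2_all[:n_comp],
            vip=_vip(d["W"], d["T"], d["c"]),
        )


class OPLSDA(_LatentModelBase):
    """Orthogonal PLS discriminant analysis (1 predictive component).

    Class-orthogonal variation is stripped from X by ``n_orth``
    orthogonal-signal-correction components before a single predictive
    component is extracted, concentrating between-class separation in
    one score.
    """

    def __init__(self, X, y, n_orth: int = 1, scaling: Scaling = "uv",
                 cv_folds: int = 7):
        super().__init__(X, y, scaling, cv_folds)
        if n_orth < 1:
            raise ValueError("n_orth must be >= 1")
        if n_orth + 1 >= min(self.X.shape):
            raise ValueError("n_orth too large for this data")
        self.n_orth = int(n_orth)

    @classmethod
    def from_binned(cls, binned, **kwargs) -> "OPLSDA":
        return cls(binned.X, binned.groups, **kwargs)

    # raw machinery -----------------------------------------------------

    def _fit_raw(self, Xs, yc, n_components=None):
        w = Xs.T @ yc
        nrm = np.linalg.norm(w)
        if nrm < 1e-14:
            raise ConvergenceError("y is orthogonal to X: no predictive direction")
        w /= nrm
        Xf = Xs.copy()
        W_o, T_o, P_o = [], [], []
        for _ in range(self.n_orth):
            t = Xf @ w
            pa = Xf.T @ t / (t @ t)
            w_o = pa - (w @ pa) * w
            n_o = np.linalg.norm(w_o)
            if n_o < 1e-12:
                break  # no orthogonal structure left
            w_o /= n_o
            t_o = Xf @ w_o
            p_o = Xf.T @ t_o / (t_o @ t_o)
            Xf = Xf - np.outer(t_o, p_o)
            W_o.append(w_o)
            T_o.append(t_o)
            P_o.append(p_o)
        t = Xf @ w
        pa = Xf.T @ t / (t @ t)
        ca = (yc @ t) / (t @ t)
        stack = (lambda v: np.column_stack(v) if v else np.empty((Xs.shape[1], 0)))
        return {
            "w": w, "t": t, "p": pa, "c": ca, "X_filtered": Xf,
            "W_o": stack(W_o),
            "T_o": np.column_stack(T_o) if T_o else np.empty((Xs.shape[0], 0)),
            "P_o": stack(P_o),
        }

    def _predict_components(self, fitted, Xs_new):
        Xf = Xs_new.copy()
        W_o, P_o = fitted["W_o"], fitted["P_o"]
        for j in range(W_o.shape[1]):
            t_o = Xf @ W_o[:, j]
            Xf = Xf - np.outer(t_o, P_o[:, j])
        return ((Xf @ fitted["w"]) * fitted["c"])[:, None]

    # public ------------------------------------------------------------

    def fit(self) -> "OPLSDAResults":
        mean, scale = _scale_params(self.X, self.scaling)
        Xs = _apply_scale(self.X, mean, scale)
        ym = self.y01.mean()
        yc = self.y01 - ym

        d = self._fit_raw(Xs, yc)
        t, pa, ca, w = d["t"], d["p"], d["c"], d["w"]
        ssx, ssy = np.sum(Xs**2), np.sum(yc**2)
        X_expl = np.sum(d["X_filtered"] ** 2) - np.sum(
            (d["X_filtered"] - np.outer(t, pa)) ** 2
        )
        r2x_orth = (ssx - np.sum(d["X_filtered"] ** 2)) / ssx
        r2x_pred = X_expl / ssx
        r2y = 1.0 - np.sum((yc - t * ca) ** 2) / ssy
        q2 = float(self._q2(1)[0])

        # S-plot: covariance / correlation of the predictive score with
        # each (centered, scaled) variable
        n = Xs.shape[0]
        cov = t @ Xs / (n - 1)
        sd_t = t.std(ddof=1)
        sd_x = Xs.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(sd_x > 0, cov / (sd_t * sd_x), 0.0)

        vip = np.sqrt(Xs.shape[1]) * np.abs(w)  # ||w|| = 1

        return OPLSDAResults(
            model=self,
            n_components=1,
            n_orth=d["W_o"].shape[1],
            x_weights=w[:, None],
            x_scores=t[:, None],
            x_loadings=pa[:, None],
            y_loadings=np.array([ca]),
            coef=None,
            x_mean=mean,
            x_scale=scale,
            y_mean=ym,
            r2x=float(r2x_pred + r2x_orth),
            r2y=float(r2y),
            q2=q2,
            r2x_per_component=np.array([r2x_pred]),
            r2y_per_component=np.array([r2y]),
            q2_per_component=np.array([q2]),
            vip=vip,
            orth_weights=d["W_o"],
            orth_scores=d["T_o"],
            orth_loadings=d["P_o"],
            r2x_orth=float(r2x_orth),
            splot_cov=cov,
            splot_corr=corr,
        )


# ---------------------------------------------------------------------
# results
# ---------------------------------------------------------------------


@dataclass
class PLSDAResults:
    """Fitted PLS-DA decomposition with diagnostics.

    Attributes mirror the usual reporting of metabolomics software:
    ``r2x``/``r2y`` (cumulative explained variance), ``q2``
    (cross-validated), ``vip`` per variable, plus scores, weights and
    loadings for plotting.
    """

    model: _LatentModelBase
    n_components: int
    x_weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray | None
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    r2x: float
    r2y: float
    q2: float
    r2x_per_component: np.ndarray
    r2y_per_component: np.ndarray
    q2_per_component: np.ndarray
    vip: np.ndarray

    @property
    def kind(self) -> str:
        return "PLS-DA"

    def predict(self, X_new) -> np.ndarray:
        """Continuous class prediction (around 0 for the first class,
        1 for the second)."""
        Xs = _apply_scale(np.asarray(X_new, float), self.x_mean, self.x_scale)
        if self.coef is not None:
            return Xs @ self.coef + self.y_mean
        raise NotImplementedError

    def permutation_test(self, n_permutations: int = 200,
                         seed: int | None = None) -> PermutationResult:
        """Refit under ``n_permutations`` random relabelings of the
        classes and compare R2Y / Q2 with the original fit.

        Shuffles are drawn uniformly; the accidental identity
        permutation is not excluded (its probability is negligible at
        the usual sample sizes).
        """
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        m = self.model
        r2s = np.empty(n_permutations)
        q2s = np.empty(n_permutations)
        for i in range(n_permutations):
            y_perm = rng.permutation(m.y01)
            res = type(m)(m.X, y_perm, **m._refit_kwargs()).fit()
            r2s[i], q2s[i] = res.r2y, res.q2
        return PermutationResult(
            n_perm=n_permutations, r2_perm=r2s, q2_perm=q2s,
            r2_orig=self.r2y, q2_orig=self.q2,
        )

    def summary(self) -> str:
        lines = [
            f"{self.kind} fit: {self.model.X.shape[0]} samples x "
            f"{self.model.X.shape[1]} variables, scaling={self.model.scaling}",
            f"classes: {self.model.classes_[0]} (0) vs {self.model.classes_[1]} (1)",
            f"components: {self.n_components}"
            + (f" predictive + {self.n_orth} orthogonal"
               if hasattr(self, "n_orth") else ""),
            f"R2X = {self.r2x:.3f}   R2Y = {self.r2y:.3f}   Q2 = {self.q2:.3f}",
        ]
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Scatter of the first two score dimensions, colored by class
        (for OPLS-DA: predictive vs first orthogonal score)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t1 = self.x_scores[:, 0]
        if self.x_scores.shape[1] > 1:
            t2 = self.x_scores[:, 1]
            ylabel = "t[2]"
        elif hasattr(self, "orth_scores") and self.orth_scores.shape[1]:
            t2 = self.orth_scores[:, 0]
            ylabel = "t_orth[1]"
        else:
            t2 = np.zeros_like(t1)
            ylabel = ""
        for cls in self.model.classes_:
            mask = np.asarray(self.model.y01 == (cls == self.model.classes_[1]))
            ax.scatter(t1[mask], t2[mask], label=str(cls))
        ax.set_xlabel("t[1]")
        ax.set_ylabel(ylabel)
        ax.legend()
        ax.set_title(f"{self.kind} scores")
        return ax


@dataclass
class OPLSDAResults(PLSDAResults):
    """Fitted OPLS-DA results: predictive + orthogonal parts and the
    S-plot statistics (covariance and correlation of each variable with
    the predictive score)."""

    n_orth: int = 0
    orth_weights: np.ndarray | None = None
    orth_scores: np.ndarray | None = None
    orth_loadings: np.ndarray | None = None
    r2x_orth: float = 0.0
    splot_cov: np.ndarray | None = None
    splot_corr: np.ndarray | None = None

    @property
    def kind(self) -> str:
        return "OPLS-DA"

    def predict(self, X_new) -> np.ndarray:
        Xs = _apply_scale(np.asarray(X_new, float), self.x_mean, self.x_scale)
        for j in range(self.orth_weights.shape[1]):
            t_o = Xs @ self.orth_weights[:, j]
            Xs = Xs - np.outer(t_o, self.orth_loadings[:, j])
        return (Xs @ self.x_weights[:, 0]) * self.y_loadings[0] + self.y_mean

    def plot_splot(self, ax=None):
        """S-plot: per-variable covariance vs correlation with the
        predictive score; biomarker candidates sit in the wings."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.splot_cov, self.splot_corr, s=8)
        ax.set_xlabel("p(cov) with t_pred")
        ax.set_ylabel("p(corr) with t_pred")
        ax.set_ylim(-1.05, 1.05)
        ax.set_title("S-plot")
        return ax


def permutation_validate(
    X,
    y,
    n_components: int | str = 2,
    scaling: Scaling = "uv",
    n_permutations: int = 200,
    seed: int | None = None,
    cv_folds: int = 7,
) -> PermutationResult:
    """Fit a PLS-DA model and validate it by label permutation in one
    call (see :meth:`PLSDAResults.permutation_test`)."""
    res = PLSDA(X, y, n_components=n_components, scaling=scaling,
                cv_folds=cv_folds).fit()
    return res.permutation_test(n_permutations, seed=seed)


def _plsda_refit_kwargs(self):
    return {"n_components": self.n_components if not self._auto else "auto",
            "scaling": self.scaling, "cv_folds": self.cv_folds}


def _oplsda_refit_kwargs(self):
    return {"n_orth": self.n_orth, "scaling": self.scaling,
            "cv_folds": self.cv_folds}


PLSDA._refit_kwargs = _plsda_refit_kwargs
OPLSDA._refit_kwargs = _oplsda_refit_kwargs
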