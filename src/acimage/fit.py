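"""ACI estimation: smoothness-penalized logistic regression.

The classification image is the coefficient map beta of a logistic
regression of the binary response r_i (0='da', 1='ga') on the flattened
cochleogram S_i of each noisy stimulus, with a quadratic roughness
penalty on the 54x81 lattice:

    minimize  D(beta, b) + lambda * (||D_t beta||^2 + ||D_f beta||^2)
                        + eps_ridge * lambda * ||beta||^2

where D is the binomial deviance, D_t / D_f are first-difference
operators along the time and frequency axes, and the small ridge term
removes the constant-map null space of the difference penalty so the
objective is strictly convex.  The intercept b is unpenalized.
Predictors are standardized per bin before fitting; the standardization
is stored with the model and re-applied at prediction time.

Model quality is scored by cross-validated deviance (CVD) and
cross-validated classification rate (CVR) over 10 folds, with the
proportions of correctly and incorrectly categorized trials equated in
every training and test set so that the listener's performance level
does not leak into the estimate.  The smoothing level is chosen as the
lambda with the lowest mean CVD (across all observers of a cohort when
several are fitted), and the final map is refit on the complete,
balanced dataset at that lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import expit

from acimage.cochleogram import (GammatoneFilterbank, build_filterbank,
                                 compute_cochleogram)
from acimage.stimuli import TargetSet, generate_noise, mix_at_snr

DEFAULT_SHAPE = (54, 81)
#: default smoothing grid: 10 log-spaced values, 1 .. 1e5
DEFAULT_LAMBDA_GRID = tuple(np.logspace(0.0, 5.0, 10))
EPS_RIDGE = 1e-3
PROBA_CLIP = 1e-12


# ---------------------------------------------------------------------------
# folds and balancing
# ---------------------------------------------------------------------------

def make_folds(n_trials: int, n_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Random equal partition of trials into folds 1..n_folds (seeded)."""
    if n_trials % n_folds:
        raise ValueError(
            f"{n_trials} trials cannot be split into {n_folds} equal folds")
    rng = np.random.default_rng(seed)
    folds = np.repeat(np.arange(1, n_folds + 1), n_trials // n_folds)
    rng.shuffle(folds)
    return folds


def balance_indices(correct: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices of a subset with #correct == #incorrect.

    The majority class is subsampled without replacement (seeded); the
    minority class is kept whole.  Raises if either class is absent.
    """
    correct = np.asarray(correct, dtype=bool)
    idx_c = np.flatnonzero(correct)
    idx_i = np.flatnonzero(~correct)
    if len(idx_c) == 0 or len(idx_i) == 0:
        raise ValueError("balancing requires both correct and incorrect "
                         "trials")
    rng = np.random.default_rng(seed)
    m = min(len(idx_c), len(idx_i))
    if len(idx_c) > m:
        idx_c = rng.choice(idx_c, size=m, replace=False)
    elif len(idx_i) > m:
        idx_i = rng.choice(idx_i, size=m, replace=False)
    return np.sort(np.concatenate([idx_c, idx_i]))


def balance_set(trials: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Trial-table view of :func:`balance_indices`."""
    return trials.iloc[balance_indices(trials["correct"].to_numpy(), seed)]


# ---------------------------------------------------------------------------
# penalty and solver
# ---------------------------------------------------------------------------

def roughness_penalty(shape: tuple[int, int] = DEFAULT_SHAPE,
                      eps_ridge: float = EPS_RIDGE) -> sp.csr_matrix:
    """Sparse P = D_f'D_f + D_t'D_t + eps_ridge*I on the flattened map.

    First differences along the frequency (channel) and time (frame)
    axes of the unflattened map; each bin couples only to its 4 lattice
    neighbours, so P has at most 5 nonzeros per row.
    """
    nf, nt = shape
    d_f = sp.diags([np.full(nf - 1, -1.0), np.ones(nf - 1)], [0, 1],
                   shape=(nf - 1, nf))
    d_t = sp.diags([np.full(nt - 1, -1.0), np.ones(nt - 1)], [0, 1],
                   shape=(nt - 1, nt))
    Df = sp.kron(d_f, sp.eye(nt))      # differences across channels
    Dt = sp.kron(sp.eye(nf), d_t)      # differences across frames
    P = (Df.T @ Df + Dt.T @ Dt + eps_ridge * sp.eye(nf * nt)).tocsr()
    return P


def standardize(S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin z-scoring; zero-variance bins get scale 1 (weight 0)."""
    mu = S.mean(axis=0)
    sd = S.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (S - mu) / sd, mu, sd


def _objective_parts(Z: np.ndarray, r: np.ndarray, Pl: sp.csr_matrix):
    """Closures for deviance + penalty objective, gradient, Hessian-vec.

    Parameter vector w = [intercept, beta]; Pl is the full (lambda-
    scaled) penalty matrix.
    """
    n, p = Z.shape

    def split(w):
        return w[0], w[1:]

    def fun(w):
        b, beta = split(w)
        z = b + Z @ beta
        # -2 sum [r z - log(1 + e^z)], numerically stable log1p(exp)
        dev = -2.0 * (r @ z - np.logaddexp(0.0, z).sum())
        return dev + beta @ (Pl @ beta)

    def grad(w):
        b, beta = split(w)
        z = b + Z @ beta
        resid = r - expit(z)
        g = np.empty(p + 1)
        g[0] = -2.0 * resid.sum()
        g[1:] = -2.0 * (Z.T @ resid) + 2.0 * (Pl @ beta)
        return g

    def hessp(w, v):
        b, beta = split(w)
        z = b + Z @ beta
        pr = expit(z)
        wgt = pr * (1.0 - pr)
        zv = v[0] + Z @ v[1:]
        h = np.empty(p + 1)
        h[0] = 2.0 * (wgt @ zv)
        h[1:] = 2.0 * (Z.T @ (wgt * zv)) + 2.0 * (Pl @ v[1:])
        return h

    return fun, grad, hessp


def fit_penalized_logistic(Z: np.ndarray, r: np.ndarray, lam: float,
                           shape: tuple[int, int] = DEFAULT_SHAPE,
                           penalty: sp.csr_matrix | None = None,
                           eps_ridge: float = EPS_RIDGE,
                           ridge: float | None = None,
                           tol: float = 1e-6,
                           max_iter: int = 500,
                           w0: np.ndarray | None = None
                           ) -> tuple[np.ndarray, float]:
    """Solve the penalized logistic regression; returns (beta, intercept).

    ``Z`` must already be standardized.  ``ridge`` (if given) is an
    absolute ridge coefficient replacing ``eps_ridge*lam``.  The convex
    objective is minimized by a trust-region Newton method exploiting
    the sparsity of the roughness penalty; convergence requires
    terminal gradient norm <= ``tol``, otherwise an error reporting the
    achieved gradient norm is raised.
    """
    Z = np.ascontiguousarray(Z, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = Z.shape
    if n < 2 or len(np.unique(r)) < 2:
        raise ValueError("need >= 2 trials with both response classes")
    if penalty is None:
        if p == int(np.prod(shape)):
            penalty = roughness_penalty(shape, eps_ridge=0.0)
        else:
            penalty = sp.csr_matrix((p, p))   # bare problems: ridge only
    ridge_coef = ridge if ridge is not None else eps_ridge * lam
    Pl = (lam * penalty + ridge_coef * sp.eye(p)).tocsr()
    fun, grad, hessp = _objective_parts(Z, r, Pl)
    if w0 is None:
        w0 = np.zeros(p + 1)
    w = _newton_cg(fun, grad, hessp, w0, Z, Pl, tol=tol, max_iter=max_iter)
    return w[1:], float(w[0])


def _newton_cg(fun, grad, hessp, w0, Z, Pl, tol: float, max_iter: int
               ) -> np.ndarray:
    """Damped Newton with preconditioned CG inner solves.

    The objective is strictly convex, so each (inexact) Newton
    direction is a descent direction; a backtracking line search keeps
    the objective non-increasing and the iteration runs until the
    gradient norm drops below ``tol``.
    """
    w = np.asarray(w0, dtype=np.float64).copy()
    f = fun(w)
    pen_diag = 2.0 * Pl.diagonal()
    for it in range(max_iter):
        g = grad(w)
        gnorm = float(np.linalg.norm(g))
        if gnorm <= tol:
            return w
        # Jacobi preconditioner from the current Hessian diagonal
        z = w[0] + Z @ w[1:]
        pr = expit(z)
        wgt = pr * (1.0 - pr)
        diag = np.empty_like(w)
        diag[0] = 2.0 * wgt.sum()
        diag[1:] = 2.0 * np.einsum("i,ij,ij->j", wgt, Z, Z) + pen_diag
        diag = np.maximum(diag, 1e-12)
        n_par = w.size
        if n_par <= 1500:
            # small problems: exact (dense) Newton solve is cheap and
            # robust even when the deviance part is nearly singular
            Zw = Z * np.sqrt(wgt)[:, None]
            H = np.empty((n_par, n_par))
            H[0, 0] = 2.0 * wgt.sum()
            H[0, 1:] = H[1:, 0] = 2.0 * (Z.T @ wgt)
            H[1:, 1:] = 2.0 * (Zw.T @ Zw) + 2.0 * Pl.toarray()
            try:
                d = np.linalg.solve(H + 1e-10 * np.eye(n_par), -g)
            except np.linalg.LinAlgError:
                d = np.linalg.lstsq(H, -g, rcond=None)[0]
        else:
            H = spla.LinearOperator((n_par, n_par),
                                    matvec=lambda v: hessp(w, v))
            # preconditioner: exact sparse penalty + deviance diagonal
            # (the lattice penalty factorizes cheaply)
            Mb = (2.0 * Pl + sp.diags(
                2.0 * np.einsum("i,ij,ij->j", wgt, Z, Z))).tocsc()
            lu = spla.splu(Mb)

            def m_solve(v):
                out = np.empty_like(v)
                out[0] = v[0] / diag[0]
                out[1:] = lu.solve(v[1:])
                return out

            M = spla.LinearOperator((n_par, n_par), matvec=m_solve)
            # Eisenstat-Walker forcing far from the optimum; one
            # high-accuracy solve for the terminal Newton step
            if gnorm < 1e3 * tol:
                eta, cg_iter = 1e-9, 5000
            else:
                eta, cg_iter = min(0.1, np.sqrt(gnorm / (1.0 + gnorm))), 1000
            d, _ = spla.cg(H, -g, rtol=max(eta, 1e-10), maxiter=cg_iter, M=M)
        if d @ g >= 0:                       # solver failure fallback
            d = -g / diag
        # near the optimum the objective decrement falls below float64
        # resolution; accept the Newton step on gradient-norm decrease
        # there, and use an Armijo objective search otherwise
        if gnorm < 1e-2:
            w_try = w + d
            if np.linalg.norm(grad(w_try)) < gnorm:
                w = w_try
                f = fun(w)
                continue
        step = 1.0
        for _ in range(40):
            f_new = fun(w + step * d)
            if f_new <= f + 1e-4 * step * (g @ d):
                break
            step *= 0.5
        w = w + step * d
        f = f_new
    gnorm = float(np.linalg.norm(grad(w)))
    if gnorm > tol:
        raise RuntimeError(
            f"penalized logistic fit did not converge: gradient norm "
            f"{gnorm:.3e} > tol {tol:.1e} after {max_iter} iterations")
    return w


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def deviance(r: np.ndarray, p: np.ndarray) -> float:
    """Binomial deviance -2 sum [r log p + (1-r) log(1-p)]."""
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    return float(-2.0 * (r @ np.log(p) + (1.0 - r) @ np.log1p(-p)))


def classification_rate(r: np.ndarray, p: np.ndarray) -> float:
    """Percent of trials with (p > 0.5) == r; p == 0.5 predicts r=1."""
    pred = np.asarray(p) >= 0.5
    return 100.0 * float(np.mean(pred == np.asarray(r, dtype=bool)))


# ---------------------------------------------------------------------------
# the fitted model
# ---------------------------------------------------------------------------

@dataclass
class ACIModel:
    """A fitted Auditory Classification Image.

    ``beta`` is the weight map in cochleogram (dB) units, i.e. the
    standardized-space coefficients divided by the per-bin scales;
    ``beta_std`` keeps the standardized-space coefficients used for
    prediction.  Positive weights push the decision towards 'ga' (r=1).
    """

    beta: np.ndarray                  # (54, 81) natural-units map
    intercept: float
    lam: float
    beta_std: np.ndarray = field(repr=False)        # flat, standardized space
    mean: np.ndarray = field(repr=False)            # per-bin predictor means
    scale: np.ndarray = field(repr=False)           # per-bin predictor scales
    cvd: float = np.nan               # mean cross-validated deviance
    cvr: float = np.nan               # mean cross-validated rate (%)
    fold_assignment: np.ndarray | None = field(default=None, repr=False)
    label: str = "observer"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")

    def predict_proba(self, S: np.ndarray) -> np.ndarray:
        """P(r=1) for raw (unstandardized) predictor rows ``S``."""
        S = np.atleast_2d(np.asarray(S, dtype=np.float64))
        if S.shape[1] != self.beta_std.size:
            raise ValueError(
                f"predictor dimension {S.shape[1]} does not match model "
                f"({self.beta_std.size})")
        z = self.intercept + ((S - self.mean) / self.scale) @ self.beta_std
        return np.clip(expit(z), PROBA_CLIP, 1.0 - PROBA_CLIP)

    def save(self, path) -> None:
        np.savez(path, beta=self.beta, beta_std=self.beta_std,
                 mean=self.mean, scale=self.scale,
                 intercept=self.intercept, lam=self.lam, cvd=self.cvd,
                 cvr=self.cvr,
                 fold_assignment=(self.fold_assignment
                                  if self.fold_assignment is not None
                                  else np.array([])),
                 label=np.array(self.label))

    @classmethod
    def load(cls, path) -> "ACIModel":
        d = np.load(path, allow_pickle=False)
        folds = d["fold_assignment"]
        return cls(beta=d["beta"], intercept=float(d["intercept"]),
                   lam=float(d["lam"]), beta_std=d["beta_std"],
                   mean=d["mean"], scale=d["scale"], cvd=float(d["cvd"]),
                   cvr=float(d["cvr"]),
                   fold_assignment=folds if folds.size else None,
                   label=str(d["label"]))


def predict_proba(model: ACIModel, S: np.ndarray) -> np.ndarray:
    """Functional alias of :meth:`ACIModel.predict_proba`."""
    return model.predict_proba(S)


# ---------------------------------------------------------------------------
# predictor matrix reconstruction
# ---------------------------------------------------------------------------

def predictor_matrix(trials: pd.DataFrame, targets: TargetSet,
                     filterbank: GammatoneFilterbank | None = None
                     ) -> np.ndarray:
    """Rebuild the (n_trials, n_bins) cochleogram predictors from a
    trial table (target label, noise seed, SNR fully determine each
    stimulus)."""
    if filterbank is None:
        filterbank = build_filterbank(sample_rate=targets.sample_rate)
    n_bins = filterbank.n_channels * 81
    X = np.empty((len(trials), n_bins), dtype=np.float32)
    for i, row in enumerate(trials.itertuples(index=False)):
        mix = mix_at_snr(targets.waveforms[row.target],
                         generate_noise(int(row.noise_seed),
                                        targets.total_duration_ms,
                                        targets.sample_rate),
                         float(row.snr_db))
        X[i] = compute_cochleogram(mix, filterbank).values.ravel(order="C")
    return X


# ---------------------------------------------------------------------------
# cross-validation and model selection
# ---------------------------------------------------------------------------

def cross_validate(X: np.ndarray, trials: pd.DataFrame,
                   lambda_grid=DEFAULT_LAMBDA_GRID,
                   seed: int = 0, n_folds: int = 10,
                   shape: tuple[int, int] = DEFAULT_SHAPE,
                   tol: float = 1e-6,
                   folds: np.ndarray | None = None) -> pd.DataFrame:
    """Per-lambda mean CVD and CVR over seeded folds.

    For each lambda and fold: the training trials (all other folds) are
    balanced, standardized and fitted; the held-out fold is balanced
    and scored by deviance and classification rate.  Returns a tidy
    DataFrame with one row per (lambda, fold) plus per-lambda means in
    the ``mean_cvd`` / ``mean_cvr`` attributes of the groupby; use
    :func:`summarize_cv` for the aggregated view.
    """
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
    if lambda_grid.size < 1:
        raise ValueError("need at least one lambda")
    r_all = trials["response"].to_numpy()
    correct = trials["correct"].to_numpy(dtype=bool)
    if folds is None:
        folds = make_folds(len(trials), n_folds=n_folds, seed=seed)
    rows = []
    penalty = roughness_penalty(shape, eps_ridge=0.0) \
        if X.shape[1] == int(np.prod(shape)) else None
    for f in np.unique(folds):
        train = folds != f
        test = ~train
        tr_idx = np.flatnonzero(train)
        te_idx = np.flatnonzero(test)
        tr_bal = tr_idx[balance_indices(correct[tr_idx],
                                        seed=seed * 1000 + int(f))]
        te_bal = te_idx[balance_indices(correct[te_idx],
                                        seed=seed * 1000 + 500 + int(f))]
        Ztr, mu, sd = standardize(X[tr_bal].astype(np.float64))
        r_tr = r_all[tr_bal]
        Zte = (X[te_bal].astype(np.float64) - mu) / sd
        r_te = r_all[te_bal]
        w0 = None
        for lam in lambda_grid[::-1]:       # warm-start from smoother fits
            beta, b = fit_penalized_logistic(
                Ztr, r_tr, lam, shape=shape, penalty=penalty, tol=tol,
                w0=w0)
            w0 = np.concatenate([[b], beta])
            p = np.clip(expit(b + Zte @ beta), PROBA_CLIP, 1 - PROBA_CLIP)
            rows.append({"lambda": lam, "fold": int(f),
                         "cvd": deviance(r_te, p),
                         "cvr": classification_rate(r_te, p),
                         "n_test": len(te_bal),
                         "cvd_per_trial": deviance(r_te, p) / len(te_bal)})
    return pd.DataFrame(rows)


def summarize_cv(cv: pd.DataFrame) -> pd.DataFrame:
    """Mean CVD/CVR per lambda over folds (and observers if present)."""
    return (cv.groupby("lambda")
              .agg(mean_cvd=("cvd", "mean"), mean_cvr=("cvr", "mean"))
              .reset_index())


def select_lambda(cv_results: pd.DataFrame | list[pd.DataFrame]) -> float:
    """Lambda with the lowest mean CVD over all observers' CV tables.

    Ties are broken toward the larger (smoother) lambda.
    """
    if isinstance(cv_results, pd.DataFrame):
        cv_results = [cv_results]
    if not cv_results:
        raise ValueError("need cv results for at least one observer")
    per_obs = [summarize_cv(cv).set_index("lambda")["mean_cvd"]
               for cv in cv_results]
    mean_cvd = pd.concat(per_obs, axis=1).mean(axis=1)
    best = mean_cvd.iloc[::-1].idxmin()     # reversed scan: ties -> larger
    return float(best)


def refit_full(X: np.ndarray, trials: pd.DataFrame, lam: float,
               seed: int = 0, shape: tuple[int, int] = DEFAULT_SHAPE,
               tol: float = 1e-6, cvd: float = np.nan, cvr: float = np.nan,
               folds: np.ndarray | None = None,
               label: str = "observer") -> ACIModel:
    """Final ACI: fit on the complete (balanced) dataset at ``lam``."""
    correct = trials["correct"].to_numpy(dtype=bool)
    bal = balance_indices(correct, seed=seed)
    Z, mu, sd = standardize(X[bal].astype(np.float64))
    beta, b = fit_penalized_logistic(Z, trials["response"].to_numpy()[bal],
                                     lam, shape=shape, tol=tol)
    return ACIModel(beta=(beta / sd).reshape(shape, order="C"),
                    intercept=b, lam=lam, beta_std=beta, mean=mu, scale=sd,
                    cvd=cvd, cvr=cvr, fold_assignment=folds, label=label)


def select_lambda_and_refit(datasets, cv_results,
                            seed: int = 0,
                            shape: tuple[int, int] = DEFAULT_SHAPE,
                            tol: float = 1e-6) -> list[ACIModel]:
    """Cohort-level model selection followed by per-observer refits.

    ``datasets`` is a list of ``(X, trials, label)`` triples;
    ``cv_results`` the matching list of CV tables.  One lambda* (lowest
    mean CVD averaged over the cohort) is shared by all observers, as
    in the standard ACI procedure.
    """
    lam = select_lambda(cv_results)
    models = []
    for (X, trials, label), cv in zip(datasets, cv_results):
        at = cv[cv["lambda"] == lam]
        models.append(refit_full(X, trials, lam, seed=seed, shape=shape,
                                 tol=tol, cvd=float(at["cvd"].mean()),
                                 cvr=float(at["cvr"].mean()),
                                 label=label))
    return models


def fit_aci(X: np.ndarray, trials: pd.DataFrame,
            lambda_grid=DEFAULT_LAMBDA_GRID, seed: int = 0,
            n_folds: int = 10, shape: tuple[int, int] = DEFAULT_SHAPE,
            tol: float = 1e-6, label: str = "observer") -> ACIModel:
    """Single-observer convenience pipeline: CV over the grid, select
    lambda by lowest mean CVD, refit on the full balanced data."""
    folds = make_folds(len(trials), n_folds=n_folds, seed=seed)
    cv = cross_validate(X, trials, lambda_grid=lambda_grid, seed=seed,
                        n_folds=n_folds, shape=shape, tol=tol, folds=folds)
    lam = select_lambda(cv)
    at = cv[cv["lambda"] == lam]
    return refit_full(X, trials, lam, seed=seed, shape=shape, tol=tol,
                      cvd=float(at["cvd"].mean()),
                      cvr=float(at["cvr"].mean()), folds=folds, label=label)
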