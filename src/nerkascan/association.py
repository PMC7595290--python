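"""Case/control association with structure covariates and permutation
significance.

Per-variant logistic regressions of a binary trait on (intercept,
covariates, dosage) are fit by Newton/IRLS, batched across variants in
numpy so that the 1000-permutation max-statistic threshold stays cheap.
Non-convergent or (quasi-)separated fits are flagged, never silently
dropped, and flagged variants are excluded from threshold maxima and peak
calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .variant_io import DosageMatrix

__all__ = [
    "AssocResult",
    "logistic_scan",
    "permutation_threshold",
    "run_association",
]

MAX_ITER = 60
TOL = 1e-8
ETA_LIMIT = 30.0  # fitted log-odds beyond this imply probabilities at 0/1
BETA_LIMIT = 15.0


@dataclass
class AssocResult:
    chrom: np.ndarray
    pos: np.ndarray
    beta: np.ndarray  # dosage log-odds
    se: np.ndarray
    chi2: np.ndarray  # Wald
    p: np.ndarray
    flagged: np.ndarray  # non-convergence or separation
    threshold: float = np.nan  # on the -log10(p) scale
    n_perm: int = 0
    alpha: float = 0.01

    def neglog10p(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return -np.log10(self.p)

    def significant(self) -> np.ndarray:
        """Indices exceeding the permutation threshold, flagged excluded."""
        if np.isnan(self.threshold):
            raise ValueError("permutation threshold not computed")
        nl = self.neglog10p()
        ok = ~self.flagged & np.isfinite(nl)
        return np.flatnonzero(ok & (nl > self.threshold))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom.astype(str),
                "pos": self.pos,
                "beta": self.beta,
                "se": self.se,
                "chi2": self.chi2,
                "p": self.p,
                "flagged": self.flagged,
            }
        )


def _batched_logistic(x: np.ndarray, y: np.ndarray, obs_w: np.ndarray):
    """Newton/IRLS logistic fit batched over variants.

    x: (m, n, c) design tensors; y: (n,) binary; obs_w: (m, n) 0/1
    observation weights (0 drops an individual with a missing dosage).
    Returns (beta, cov_diag, converged, separated) with shapes (m, c),
    (m, c), (m,), (m,).
    """
    m, n, c = x.shape
    beta = np.zeros((m, c))
    converged = np.zeros(m, dtype=bool)
    singular = np.zeros(m, dtype=bool)
    diverged = np.zeros(m, dtype=bool)
    active = np.arange(m)
    for _ in range(MAX_ITER):
        xa = x[active]
        eta = np.einsum("mnc,mc->mn", xa, beta[active])
        eta = np.clip(eta, -ETA_LIMIT - 5, ETA_LIMIT + 5)
        mu = expit(eta)
        wa = mu * (1.0 - mu) * obs_w[active]
        grad = np.einsum("mnc,mn->mc", xa, (y[None, :] - mu) * obs_w[active])
        info = np.einsum("mnc,mn,mnd->mcd", xa, wa, xa)
        eye = 1e-10 * np.eye(c)[None, :, :]
        try:
            step = np.linalg.solve(info + eye, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # fall back to per-variant solves, flagging singular systems
            step = np.zeros_like(grad)
            for k in range(len(active)):
                try:
                    step[k] = np.linalg.solve(info[k] + eye[0], grad[k])
                except np.linalg.LinAlgError:
                    singular[active[k]] = True
                    step[k] = 0.0
        beta[active] += step
        done_local = np.abs(step).max(axis=1) < TOL
        converged[active[done_local]] = True
        # runaway coefficients will be flagged as separated; stop iterating them
        runaway = np.abs(beta[active]).max(axis=1) > BETA_LIMIT * 2
        diverged[active[runaway]] = True
        active = active[~done_local & ~runaway & ~singular[active]]
        if active.size == 0:
            break
    eta = np.einsum("mnc,mc->mn", x, beta)
    mu = expit(np.clip(eta, -ETA_LIMIT - 5, ETA_LIMIT + 5))
    w = mu * (1.0 - mu) * obs_w
    info = np.einsum("mnc,mn,mnd->mcd", x, w, x)
    cov_diag = np.full((m, c), np.nan)
    sep = singular.copy()
    for i in range(m):
        try:
            cov = np.linalg.inv(info[i])
            cov_diag[i] = np.diag(cov)
        except np.linalg.LinAlgError:
            sep[i] = True
    # separation heuristics: runaway coefficients or saturated probabilities
    sep |= np.abs(beta).max(axis=1) > BETA_LIMIT
    sep |= np.where(obs_w > 0, np.abs(eta), 0.0).max(axis=1) > ETA_LIMIT
    return beta, cov_diag, converged, sep


def _design_tensor(values: np.ndarray, covariates: np.ndarray | None):
    """Stack (intercept, covariates, dosage) per variant; returns x, obs_w."""
    m, n = values.shape
    q = 0 if covariates is None else covariates.shape[1]
    x = np.empty((m, n, q + 2))
    x[:, :, 0] = 1.0
    if covariates is not None:
        x[:, :, 1 : 1 + q] = covariates[None, :, :]
    x[:, :, -1] = np.nan_to_num(values, nan=0.0)
    obs_w = np.isfinite(values).astype(np.float64)
    return x, obs_w


def _check_inputs(values, trait, covariates):
    y = np.asarray(trait, dtype=np.float64)
    if not np.all(np.isfinite(y)) or not np.all(np.isin(y[np.isfinite(y)], (0.0, 1.0))):
        raise ValueError("trait must be binary 0/1 without missing values")
    if y.min() == y.max():
        raise ValueError("trait is constant; association is undefined")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=np.float64)
        if cov.ndim == 1:
            cov = cov[:, None]
        aug = np.column_stack([np.ones(len(y)), cov])
        if np.linalg.matrix_rank(aug) < aug.shape[1]:
            raise ValueError("covariate matrix with intercept is rank deficient")
    return y, cov


def logistic_scan(
    dosages: DosageMatrix | np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
) -> AssocResult:
    """Per-variant logistic regression with a Wald test on the dosage term."""
    if isinstance(dosages, DosageMatrix):
        values, chrom, pos = dosages.values, dosages.chrom, dosages.pos
    else:
        values = np.asarray(dosages, dtype=np.float64)
        chrom = np.array(["?"] * values.shape[0], dtype=object)
        pos = np.arange(values.shape[0], dtype=np.int64)
    y, cov = _check_inputs(values, trait, covariates)
    x, obs_w = _design_tensor(values, cov)
    beta, cov_diag, converged, sep = _batched_logistic(x, y, obs_w)
    b = beta[:, -1]
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(cov_diag[:, -1])
        chi2 = (b / se) ** 2
    # monomorphic dosage within observed individuals is untestable
    mono = np.array(
        [len(np.unique(v[np.isfinite(v)])) < 2 for v in values], dtype=bool
    )
    flagged = ~converged | sep | mono | ~np.isfinite(chi2)
    p = np.where(flagged, np.nan, stats.chi2.sf(np.where(flagged, 0.0, chi2), df=1))
    return AssocResult(
        chrom=np.asarray(chrom),
        pos=np.asarray(pos),
        beta=b,
        se=se,
        chi2=chi2,
        p=p,
        flagged=flagged,
    )


def permutation_threshold(
    dosages: DosageMatrix | np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Genome-wide max-statistic permutation threshold.

    The trait labels are permuted ``n_perm`` times (seeded); for each
    permutation the full scan is refit (covariates included) and the maximum
    -log10 p over unflagged variants recorded.  The threshold is the
    empirical (1-alpha) quantile of those maxima, taken as the
    ``ceil((1-alpha)*n_perm)``-th order statistic.

    Returns ``(threshold, maxima)``.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives a coarse threshold")
    values = dosages.values if isinstance(dosages, DosageMatrix) else np.asarray(dosages)
    y, cov = _check_inputs(values, trait, covariates)
    x, obs_w = _design_tensor(values, cov)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        beta, cov_diag, converged, sep = _batched_logistic(x, yp, obs_w)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(cov_diag[:, -1])
            chi2 = (beta[:, -1] / se) ** 2
        ok = converged & ~sep & np.isfinite(chi2)
        if not ok.any():
            maxima[b] = 0.0
            continue
        p = stats.chi2.sf(chi2[ok], df=1)
        p = np.maximum(p, np.finfo(float).tiny)
        maxima[b] = float(np.max(-np.log10(p)))
    order_stat = int(np.ceil((1.0 - alpha) * n_perm)) - 1
    threshold = float(np.sort(maxima)[order_stat])
    return threshold, maxima


def run_association(
    dosages: DosageMatrix,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> AssocResult:
    """Observed scan plus permutation threshold, ready for peak calling."""
    res = logistic_scan(dosages, trait, covariates)
    threshold, _ = permutation_threshold(
        dosages, trait, covariates, n_perm=n_perm, alpha=alpha, seed=seed
    )
    res.threshold = threshold
    res.n_perm = n_perm
    res.alpha = alpha
    return res
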