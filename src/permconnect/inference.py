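"""Permutation inference for edge-wise group contrasts and brain-behaviour interactions.

Three pieces of machinery:

* **maxT familywise correction** (Westfall-Young): group labels are permuted,
  the same permutation is applied to all 55 edges, and each permutation
  contributes the maximum |t| over edges to a single null distribution.  The
  corrected p-value of an edge is the fraction of permutations whose maximum
  reaches its observed |t| (add-one convention), which controls the
  familywise error rate under exchangeability.  When the number of distinct
  label splits is no larger than the permutation budget the test enumerates
  all splits exactly instead of sampling.

* **Huber M-estimation**: confound residualization and the cognition
  regressions use a robust linear fit with the Huber loss (quadratic within
  ``epsilon`` scaled residuals, linear beyond), a small ridge penalty on the
  non-intercept coefficients, and jointly estimated scale.  Solved by
  iteratively reweighted least squares; a vectorized variant refits thousands
  of permuted responses against the fixed design in one pass, which is what
  makes the permutation regressions tractable.

* **Manly permutation** for regression coefficients: the raw response vector
  is permuted wholesale (unrestricted sampling), the full model
  ``score ~ edge + group + edge x group`` is refit per permutation, and each
  coefficient's two-sided p-value comes from its own permutation null.  No
  multiple-comparison correction is applied to these regressions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PermutationSettings",
    "HuberSettings",
    "EdgeTestResult",
    "InteractionResult",
    "two_sample_t",
    "maxt_permutation_test",
    "huber_fit",
    "huber_fit_batch",
    "huber_residualize",
    "interaction_regression",
    "manly_permutation_pvalues",
    "maxt_fwer_calibration",
    "manly_null_pvalues",
    "manly_power",
]


@dataclass
class PermutationSettings:
    n_permutations: int = 10_000
    seed: int = 0
    two_sided: bool = True
    correction: str = "maxT"  # {"maxT", "none"}

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.correction not in ("maxT", "none"):
            raise ValueError("correction must be 'maxT' or 'none'")


@dataclass
class HuberSettings:
    epsilon: float = 1.35
    alpha: float = 1e-3
    tol: float = 1e-5
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.epsilon <= 1:
            raise ValueError("epsilon must be > 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class EdgeTestResult:
    edge_key: tuple[str, str] | str
    observed_t: float
    p_corrected: float
    model: str = "raw"


@dataclass
class InteractionResult:
    score_name: str
    edge_key: tuple[str, str] | str
    beta_interaction: float
    p_perm: float
    model: str = "raw"
    all_betas: dict = field(default_factory=dict)
    all_pvalues: dict = field(default_factory=dict)
    ci_95: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# group contrasts with maxT correction
# ---------------------------------------------------------------------------


def two_sample_t(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Pooled-variance two-sample t; sign follows mean(A) - mean(B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    sp2 = ss / (na + nb - 2)
    if sp2 == 0:
        warnings.warn("zero pooled variance; t set to 0", stacklevel=2)
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def _batch_t(X: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled t for every (permutation mask, edge) pair.

    X is subjects x edges; ``masks`` is B x subjects boolean membership of
    group A (each row the same group size).  Returns B x edges.
    """
    n = X.shape[0]
    na = int(masks[0].sum())
    nb = n - na
    M = masks.astype(float)
    tot = X.sum(axis=0)
    tot2 = (X**2).sum(axis=0)
    s1 = M @ X
    ss1 = M @ (X**2)
    m1 = s1 / na
    m2 = (tot - s1) / nb
    within = (ss1 - s1**2 / na) + (tot2 - ss1 - (tot - s1) ** 2 / nb)
    sp2 = within / (n - 2)
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t


def maxt_permutation_test(
    edge_matrix: np.ndarray | pd.DataFrame,
    group_labels,
    settings: PermutationSettings | None = None,
    group_a=None,
    model: str = "raw",
    exhaustive: bool | None = None,
) -> list[EdgeTestResult]:
    """Edge-wise group contrast with permutation inference.

    The observed statistic per edge is the pooled two-sample t (group A minus
    group B).  Under ``correction="maxT"`` every permutation applies the SAME
    label shuffle to all edges and contributes max|t| to one null
    distribution; corrected p for edge e is
    ``(1 + #{perm max|t| >= |t_obs,e|}) / (B + 1)``.  Under
    ``correction="none"`` each edge is referred to its own permutation null.
    All ``C(n, n_A)`` label splits are enumerated exactly when that count does
    not exceed the permutation budget; ``exhaustive`` forces either mode
    (``True`` fails if the split count exceeds the budget, ``False`` always
    samples).
    """
    settings = settings or PermutationSettings()
    if isinstance(edge_matrix, pd.DataFrame):
        edge_names = list(edge_matrix.columns)
        X = edge_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(edge_matrix, dtype=float)
        edge_names = [f"edge{i}" for i in range(X.shape[1])]
    labels = np.asarray(group_labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("edge matrix rows must match group labels")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    if group_a is None:
        group_a = uniq[0]
    obs_mask = labels == group_a
    na, nb = int(obs_mask.sum()), int((~obs_mask).sum())
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    n = na + nb
    B = settings.n_permutations

    t_obs = _batch_t(X, obs_mask[None, :])[0]

    n_splits = math.comb(n, na)
    if exhaustive is None:
        exhaustive = n_splits <= B
    elif exhaustive and n_splits > B:
        raise ValueError(f"{n_splits} label splits exceed the budget B={B}")
    if exhaustive:
        masks = np.zeros((n_splits, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), na)):
            masks[i, list(idx)] = True
        t_null = np.abs(_batch_t(X, masks))
        denom = n_splits
        add_one = 0  # identity split is among the enumerated ones
        log.info("maxT: exhaustive enumeration over %d splits", n_splits)
    else:
        rng = np.random.default_rng(settings.seed)
        order = np.argsort(rng.random((B, n)), axis=1)
        masks = np.zeros((B, n), dtype=bool)
        np.put_along_axis(masks, order[:, :na], True, axis=1)
        t_null = np.abs(_batch_t(X, masks))
        denom = B + 1
        add_one = 1

    abs_obs = np.abs(t_obs)
    # tolerance absorbs floating-point ties (e.g. the complementary label
    # split, whose |t| equals the observed one exactly in real arithmetic)
    thresh = abs_obs - 1e-8 * np.maximum(1.0, abs_obs)
    if settings.correction == "maxT":
        max_null = t_null.max(axis=1)  # one shared null: max over edges per shuffle
        counts = (max_null[:, None] >= thresh[None, :]).sum(axis=0)
    else:
        counts = (t_null >= thresh[None, :]).sum(axis=0)
    pvals = (add_one + counts) / denom

    return [
        EdgeTestResult(edge_key=name, observed_t=float(t), p_corrected=float(p), model=model)
        for name, t, p in zip(edge_names, t_obs, pvals)
    ]


# ---------------------------------------------------------------------------
# Huber M-estimation (IRLS with concomitant scale)
# ---------------------------------------------------------------------------

_SIGMA_FLOOR = 1e-10


def _design_with_intercept(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(X.shape[0]), X])


def _huber_sigma(R: np.ndarray, epsilon: float, sigma: np.ndarray) -> np.ndarray:
    """Concomitant-scale fixed point: sigma^2 = mean(min(r^2, (eps*sigma)^2))."""
    for _ in range(30):
        new = np.sqrt(np.mean(np.minimum(R**2, (epsilon * sigma) ** 2), axis=0))
        new = np.maximum(new, _SIGMA_FLOOR)
        if np.all(np.abs(new - sigma) <= 1e-12 + 1e-8 * sigma):
            sigma = new
            break
        sigma = new
    return sigma


def huber_fit_batch(
    X: np.ndarray,
    Y: np.ndarray,
    settings: HuberSettings | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Huber regression of many responses on one fixed design.

    Minimizes, per response column, the Huber objective with jointly
    estimated scale and ridge penalty ``alpha`` on the non-intercept
    coefficients, by IRLS.  ``X`` is n x p (no intercept column — one is
    prepended); ``Y`` is n x B.  Returns (coefficients (B x (p+1), intercept
    first), converged flags (B,)).  Fitting B columns at once is what keeps
    permutation refits fast: each IRLS step is one batched (p+1)x(p+1) solve.
    """
    settings = settings or HuberSettings()
    eps, alpha, tol = settings.epsilon, settings.alpha, settings.tol
    Xd = _design_with_intercept(X)
    n, p1 = Xd.shape
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    B = Y.shape[1]
    D = np.eye(p1)
    D[0, 0] = 0.0  # intercept unpenalized

    # OLS start
    beta = np.linalg.lstsq(Xd, Y, rcond=None)[0].T  # B x p1
    R = Y - Xd @ beta.T
    sigma = np.maximum(R.std(axis=0), _SIGMA_FLOOR)
    converged = np.zeros(B, dtype=bool)

    half = settings.max_iterations // 2
    for it in range(settings.max_iterations):
        sigma = _huber_sigma(R, eps, sigma)
        absR = np.abs(R)
        cut = eps * sigma
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(absR <= cut, 1.0, cut / np.where(absR > 0, absR, 1.0))
        G = np.einsum("np,nb,nq->bpq", Xd, W, Xd)
        G += (alpha * sigma)[:, None, None] * D
        rhs = np.einsum("np,nb->bp", Xd, W * Y)
        new = np.linalg.solve(G, rhs[..., None])[..., 0]
        if it >= half:
            # damp late iterations: breaks two-cycles between weight sets
            new = 0.5 * (new + beta)
        delta = np.max(np.abs(new - beta), axis=1)
        scale = np.maximum(1.0, np.max(np.abs(new), axis=1))
        beta = new
        R = Y - Xd @ beta.T
        converged |= delta <= tol * scale
        if np.all(converged):
            break
    if not np.all(converged):
        warnings.warn(
            f"Huber IRLS: {int((~converged).sum())}/{B} fits not converged "
            f"after {settings.max_iterations} iterations",
            stacklevel=2,
        )
    if squeeze:
        return beta[0], converged[:1]
    return beta, converged


def huber_fit(X: np.ndarray, y: np.ndarray,
              settings: HuberSettings | None = None) -> tuple[np.ndarray, bool]:
    """Single-response Huber fit; returns (coefficients, converged).

    Coefficient vector is (intercept, slopes...).
    """
    beta, conv = huber_fit_batch(X, np.asarray(y, dtype=float), settings)
    return beta, bool(conv[0])


def huber_residualize(
    response: np.ndarray,
    covariates: np.ndarray | pd.DataFrame,
    settings: HuberSettings | None = None,
) -> tuple[np.ndarray, bool]:
    """Residuals of a robust (Huber) regression of response on covariates.

    Used to strip age and vascular-risk-factor effects from cognitive scores
    and edge values before the corrected-model tests.  Returns
    (residuals, converged); non-convergence yields residuals anyway with a
    warning already emitted by the solver.
    """
    y = np.asarray(response, dtype=float)
    C = covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame) else (
        np.asarray(covariates, dtype=float)
    )
    if C.ndim == 1:
        C = C[:, None]
    if np.isnan(C).any() or np.isnan(y).any():
        raise ValueError("missing values in response or covariates")
    beta, conv = huber_fit(C, y, settings)
    fitted = _design_with_intercept(C) @ beta
    return y - fitted, conv


COEF_NAMES = ("intercept", "edge", "group", "interaction")


def _interaction_design(edge: np.ndarray, group01: np.ndarray) -> np.ndarray:
    return np.column_stack([edge, group01, edge * group01])


def interaction_regression(
    score: np.ndarray,
    edge: np.ndarray,
    group01: np.ndarray,
    settings: HuberSettings | None = None,
) -> dict[str, float]:
    """Huber fit of ``score ~ intercept + edge + group + edge*group``.

    ``group01`` is the 0/1 contrast indicator.  Returns the named
    coefficients; the interaction term carries the group difference in the
    edge-cognition slope.
    """
    score = np.asarray(score, dtype=float)
    edge = np.asarray(edge, dtype=float)
    group01 = np.asarray(group01, dtype=float)
    if not (score.shape == edge.shape == group01.shape):
        raise ValueError("score, edge and group must have equal length")
    if len(np.unique(group01)) < 2:
        raise ValueError("both groups must be represented")
    if np.ptp(edge) == 0:
        raise ValueError("edge values are constant; interaction is undefined")
    beta, _ = huber_fit(_interaction_design(edge, group01), score, settings)
    return dict(zip(COEF_NAMES, map(float, beta)))


def manly_permutation_pvalues(
    score: np.ndarray,
    edge: np.ndarray,
    group01: np.ndarray,
    perm_settings: PermutationSettings | None = None,
    huber_settings: HuberSettings | None = None,
    score_name: str = "",
    edge_key="",
    model: str = "raw",
    bootstrap_ci: int = 0,
) -> InteractionResult:
    """Manly-scheme permutation p-values for every interaction-model coefficient.

    The raw response vector is permuted wholesale across subjects
    (unrestricted sampling) and the full Huber model refit per permutation;
    the two-sided p-value of each coefficient is
    ``(1 + #{|b_perm| >= |b_obs|}) / (B + 1)``.  No multiple-comparison
    correction is applied.  Optionally a percentile-bootstrap 95% CI for the
    interaction coefficient is attached (``bootstrap_ci`` resamples) — an
    extension beyond the permutation test itself.
    """
    perm_settings = perm_settings or PermutationSettings()
    score = np.asarray(score, dtype=float)
    Xint = _interaction_design(np.asarray(edge, dtype=float),
                               np.asarray(group01, dtype=float))
    obs = interaction_regression(score, edge, group01, huber_settings)
    b_obs = np.array([obs[k] for k in COEF_NAMES])

    rng = np.random.default_rng(perm_settings.seed)
    B = perm_settings.n_permutations
    perms = np.argsort(rng.random((B, score.size)), axis=1)
    Yperm = score[perms].T  # n x B
    betas, _ = huber_fit_batch(Xint, Yperm, huber_settings)
    abs_obs = np.abs(b_obs)
    counts = (np.abs(betas) >= (abs_obs - 1e-8 * np.maximum(1.0, abs_obs))[None, :]).sum(axis=0)
    pvals = (1 + counts) / (B + 1)
    p_named = dict(zip(COEF_NAMES, map(float, pvals)))

    ci = None
    if bootstrap_ci:
        idx = rng.integers(0, score.size, size=(bootstrap_ci, score.size))
        boots = np.empty(bootstrap_ci)
        for i, rows in enumerate(idx):
            if np.ptp(Xint[rows, 0]) == 0 or len(np.unique(Xint[rows, 1])) < 2:
                boots[i] = np.nan
                continue
            b, _ = huber_fit(Xint[rows], score[rows], huber_settings)
            boots[i] = b[3]
        boots = boots[np.isfinite(boots)]
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return InteractionResult(
        score_name=score_name,
        edge_key=edge_key,
        beta_interaction=float(b_obs[3]),
        p_perm=p_named["interaction"],
        model=model,
        all_betas=obs,
        all_pvalues=p_named,
        ci_95=ci,
    )


# ---------------------------------------------------------------------------
# calibration experiments (shared by the test suite and the acceptance script)
# ---------------------------------------------------------------------------


def maxt_fwer_calibration(
    n_a: int,
    n_b: int,
    precision: np.ndarray,
    n_timepoints: int = 160,
    n_replicates: int = 500,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical familywise error rate of the maxT test under the global null.

    Both groups' node signals are drawn from the SAME Gaussian graphical
    model, per-subject partial-correlation edges are computed, and the
    fraction of replicates where any corrected p <= alpha is returned.  For a
    calibrated test this fraction approaches alpha.
    """
    from .connectivity import partial_correlation

    omega = np.asarray(precision, dtype=float)
    N = omega.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(omega))
    n = n_a + n_b
    labels = np.array(["A"] * n_a + ["B"] * n_b)
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(n_replicates)
    iu = np.triu_indices(N, k=1)
    hits = 0
    for child in rep_seeds:
        rng = np.random.default_rng(child)
        X = np.empty((n, iu[0].size))
        for s in range(n):
            sig = rng.standard_normal((n_timepoints, N)) @ L.T
            cov = np.cov(sig, rowvar=False)
            om = np.linalg.inv(cov)
            d = np.sqrt(np.diag(om))
            X[s] = (-om / np.outer(d, d))[iu]
        res = maxt_permutation_test(
            X,
            labels,
            PermutationSettings(
                n_permutations=n_permutations,
                seed=int(rng.integers(2**31 - 1)),
            ),
        )
        if min(r.p_corrected for r in res) <= alpha:
            hits += 1
    return hits / n_replicates


def manly_null_pvalues(
    n_subjects: int = 60,
    n_replicates: int = 200,
    n_permutations: int = 500,
    seed: int = 0,
    huber_settings: HuberSettings | None = None,
) -> np.ndarray:
    """Interaction p-values over null replicates (b1 = b2 = b3 = 0).

    Under the null the returned p-values should be uniform on (0, 1] up to
    the discreteness of B permutations.
    """
    ss = np.random.SeedSequence(seed)
    group = np.repeat([0.0, 1.0], n_subjects // 2 + n_subjects % 2)[:n_subjects]
    out = np.empty(n_replicates)
    for i, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        edge = rng.standard_normal(n_subjects)
        score = rng.standard_normal(n_subjects)
        res = manly_permutation_pvalues(
            score, edge, group,
            PermutationSettings(n_permutations=n_permutations,
                                seed=int(rng.integers(2**31 - 1))),
            huber_settings,
        )
        out[i] = res.p_perm
    return out


def manly_power(
    n_subjects: int = 60,
    interaction_per_noise_sd: float = 1.0,
    n_replicates: int = 60,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    huber_settings: HuberSettings | None = None,
) -> float:
    """Detection rate for a planted edge-by-group interaction.

    The interaction coefficient is ``interaction_per_noise_sd`` residual
    standard deviations per unit edge; returns the fraction of replicates
    with p <= alpha.
    """
    ss = np.random.SeedSequence(seed)
    group = np.repeat([0.0, 1.0], n_subjects // 2 + n_subjects % 2)[:n_subjects]
    noise_sd = 1.0
    b3 = interaction_per_noise_sd * noise_sd
    hits = 0
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        edge = rng.standard_normal(n_subjects)
        score = b3 * edge * group + rng.normal(0, noise_sd, n_subjects)
        res = manly_permutation_pvalues(
            score, edge, group,
            PermutationSettings(n_permutations=n_permutations,
                                seed=int(rng.integers(2**31 - 1))),
            huber_settings,
        )
        hits += res.p_perm <= alpha
    return hits / n_replicates
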