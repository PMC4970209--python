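"""Proportional-odds modelling and hierarchical backward elimination.

The outcome is the four-level ordered CTP adequacy category.  The model
is the cumulative-logit (proportional-odds) model, oriented so that a
coefficient's exponential reads as the odds ratio of being assigned a
*higher* adequacy category:

    P(Y <= k | x) = expit(alpha_k - x' beta),   k = 1..K-1,

with strictly increasing thresholds ``alpha_k`` and a single slope vector
``beta`` shared across the K-1 cumulative logits (the proportional-odds
assumption).  Positive ``beta_j`` therefore shifts probability mass to
higher categories and ``exp(beta_j) < 1`` marks a disadvantaged level.

Model building follows the Andersen-Newman behavioural model in three
blocks — predisposing, enabling, pregnancy-related — with region fixed
from the first step.  Within each block, covariates are removed by
backward elimination on the multi-degree-of-freedom Wald test at a 0.05
stay level; survivors are carried forward as fixed.  Each step reports
the score test of the proportional-odds assumption, variance-inflation
diagnostics, and (for the final model) the percentage of concordant
pairs.

Fitting is direct maximum likelihood: BFGS on a monotonicity-preserving
threshold reparameterisation, followed by Newton polishing in the natural
parameterisation until the gradient's infinity norm falls below 1e-8
(at most 100 polish iterations).  Standard errors come from the inverse
observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ModelSpec",
    "Design",
    "OrdinalFit",
    "ScoreTestResult",
    "ConcordanceResult",
    "EliminationStep",
    "EliminationResult",
    "HierarchicalResult",
    "ConvergenceError",
    "RankError",
    "build_design",
    "fit_proportional_odds",
    "score_test_po",
    "percent_concordant",
    "backward_eliminate",
    "hierarchical_selection",
    "collinearity_check",
    "simulate_po_outcome",
]


class ConvergenceError(RuntimeError):
    """Likelihood maximisation failed (possible separation)."""


class RankError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class ModelSpec:
    """Outcome, covariate blocks and selection settings for the pipeline."""

    outcome: str
    blocks: list[tuple[str, list[str]]]
    fixed: list[str] = field(default_factory=lambda: ["region"])
    stay_level: float = 0.05
    reference_levels: dict[str, object] = field(default_factory=dict)
    outcome_order: list | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.stay_level < 1.0:
            raise ValueError("stay_level must be in (0, 1)")
        block_vars = [v for _, vars_ in self.blocks for v in vars_]
        overlap = set(self.fixed) & set(block_vars)
        if overlap:
            raise ValueError(f"fixed variables also listed in blocks: {sorted(overlap)}")


# --------------------------------------------------------------------------
# design construction

@dataclass
class Design:
    X: np.ndarray  # n x p, float
    columns: list[str]
    var_columns: dict[str, list[str]]  # covariate -> its design columns
    references: dict[str, object]


def build_design(
    data: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Mapping[str, object] | None = None,
) -> Design:
    """Dummy-code categorical covariates; numeric columns pass through.

    Each categorical covariate enters as a full dummy block with the
    configured reference level omitted (default: first level in sorted
    order), columns named ``var[level]``.
    """
    reference_levels = dict(reference_levels or {})
    cols: list[np.ndarray] = []
    names: list[str] = []
    var_columns: dict[str, list[str]] = {}
    references: dict[str, object] = {}
    for var in covariates:
        if var not in data.columns:
            raise ValueError(f"covariate {var!r} not in data")
        s = data[var]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
            cols.append(s.to_numpy(dtype=float))
            names.append(var)
            var_columns[var] = [var]
            continue
        if isinstance(s.dtype, pd.CategoricalDtype):
            levels = list(s.cat.categories)
        else:
            levels = sorted(s.dropna().unique(), key=str)
        ref = reference_levels.get(var, levels[0])
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} for {var!r} not among levels {levels}"
            )
        references[var] = ref
        block = []
        for level in levels:
            if level == ref:
                continue
            name = f"{var}[{level}]"
            cols.append((s == level).to_numpy(dtype=float))
            names.append(name)
            block.append(name)
        if not block:
            raise ValueError(f"covariate {var!r} has a single level")
        var_columns[var] = block
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    _check_rank(X, names)
    return Design(X=X, columns=names, var_columns=var_columns,
                  references=references)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    # thresholds play the intercept's role, so include a constant column
    M = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # identify aliased columns by pivoted QR magnitude
        _, R, piv = _qr_pivot(M)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(M.shape) * np.finfo(float).eps
        aliased_idx = sorted(piv[np.flatnonzero(diag < tol)])
        aliased = [(["(const)"] + names)[i] for i in aliased_idx]
        raise RankError(f"design is rank deficient; aliased columns: {aliased}")


def _qr_pivot(M: np.ndarray):
    from scipy.linalg import qr

    Q, R, piv = qr(M, mode="economic", pivoting=True)
    return Q, R, piv


def encode_outcome(series: pd.Series, order: Sequence | None = None):
    """Map an ordered outcome to integer codes 0..K-1."""
    if order is None:
        if isinstance(series.dtype, pd.CategoricalDtype) and series.cat.ordered:
            order = list(series.cat.categories)
        else:
            order = sorted(series.dropna().unique(), key=str)
    order = list(order)
    codes = series.map({c: i for i, c in enumerate(order)})
    if codes.isna().any():
        bad = series[codes.isna()].unique()
        raise ValueError(f"outcome values outside declared order: {list(bad)}")
    y = codes.to_numpy(dtype=int)
    observed = np.unique(y)
    if len(observed) < len(order):
        # drop unobserved levels so codes are dense 0..K-1
        remap = {v: i for i, v in enumerate(observed)}
        y = np.asarray([remap[v] for v in y], dtype=int)
        order = [order[i] for i in observed]
    return y, order


# --------------------------------------------------------------------------
# likelihood machinery

def _cum_probs(eta_up: np.ndarray, eta_lo: np.ndarray):
    g_up = special.expit(eta_up)
    g_lo = special.expit(eta_lo)
    return g_up, g_lo, g_up - g_lo


def _nll_grad_general(alpha: np.ndarray, B: np.ndarray, X: np.ndarray,
                      y: np.ndarray, K: int):
    """Negative log-likelihood and gradient of the cumulative-logit model
    with per-cutpoint slopes ``B`` (p x (K-1)); the proportional model is
    the special case of identical columns."""
    n, p = X.shape
    eta = alpha[None, :] - X @ B  # n x (K-1), eta_k = alpha_k - x'b_k
    big = np.full((n, 1), np.inf)
    eta_full = np.concatenate([-big, eta, big], axis=1)  # cut points -inf..inf
    idx = np.arange(n)
    eta_up = eta_full[idx, y + 1]
    eta_lo = eta_full[idx, y]
    g_up, g_lo, prob = _cum_probs(eta_up, eta_lo)
    if np.any(prob <= 0) or np.any(~np.isfinite(prob)):
        return np.inf, None, None
    nll = -float(np.sum(np.log(prob)))
    phi_up = g_up * (1.0 - g_up)
    phi_lo = g_lo * (1.0 - g_lo)
    w_up = phi_up / prob  # contribution of the upper cut point
    w_lo = phi_lo / prob
    g_alpha = np.zeros(K - 1)
    g_B = np.zeros_like(B)
    up_k = y  # observation with category c uses cut point index c (alpha_c)
    lo_k = y - 1
    up_valid = up_k <= K - 2
    lo_valid = lo_k >= 0
    # d loglik / d alpha_k
    np.add.at(g_alpha, up_k[up_valid], w_up[up_valid])
    np.add.at(g_alpha, lo_k[lo_valid], -w_lo[lo_valid])
    # d loglik / d b_k = -x * (same weights)
    for k in range(K - 1):
        sel_up = up_valid & (up_k == k)
        sel_lo = lo_valid & (lo_k == k)
        contrib = np.zeros(n)
        contrib[sel_up] -= w_up[sel_up]
        contrib[sel_lo] += w_lo[sel_lo]
        g_B[:, k] = X.T @ contrib
    # return gradient of the NEGATIVE log-likelihood
    return nll, -g_alpha, -g_B


def _nll_grad_prop(params: np.ndarray, X: np.ndarray, y: np.ndarray, K: int):
    alpha = params[: K - 1]
    beta = params[K - 1:]
    if np.any(np.diff(alpha) <= 0):
        return np.inf, None
    B = np.tile(beta[:, None], (1, K - 1))
    nll, ga, gB = _nll_grad_general(alpha, B, X, y, K)
    if not np.isfinite(nll):
        return np.inf, None
    return nll, np.concatenate([ga, gB.sum(axis=1)])


def _num_hessian(grad_fn, params: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    m = len(params)
    H = np.zeros((m, m))
    for j in range(m):
        h = step * max(1.0, abs(params[j]))
        up = params.copy(); up[j] += h
        dn = params.copy(); dn[j] -= h
        g_up = grad_fn(up)
        g_dn = grad_fn(dn)
        H[:, j] = (g_up - g_dn) / (2 * h)
    return 0.5 * (H + H.T)


# --------------------------------------------------------------------------
# fit

@dataclass
class OrdinalFit:
    thresholds: np.ndarray  # strictly increasing alpha_k
    beta: pd.Series
    se: pd.Series
    cov: pd.DataFrame  # covariance of beta (slopes only)
    cov_full: np.ndarray  # covariance of (alpha, beta)
    loglik: float
    n: int
    K: int
    outcome_order: list
    design: Design
    y: np.ndarray
    converged: bool
    grad_norm: float
    n_iter: int

    @property
    def odds_ratios(self) -> pd.DataFrame:
        """OR with Wald 95% CI per design column; OR > 1 means higher odds
        of a higher adequacy category."""
        z = stats.norm.ppf(0.975)
        lo = np.exp(self.beta - z * self.se)
        hi = np.exp(self.beta + z * self.se)
        wald_z = self.beta / self.se
        p = 2 * stats.norm.sf(np.abs(wald_z))
        return pd.DataFrame(
            {"OR": np.exp(self.beta), "ci_low": lo, "ci_high": hi,
             "p": p},
            index=self.beta.index,
        )

    def format_or(self, column: str) -> str:
        row = self.odds_ratios.loc[column]
        return f"{row['OR']:.2f} ({row['ci_low']:.2f}-{row['ci_high']:.2f})"

    def wald_test(self, var: str) -> tuple[float, int, float]:
        """Multi-df Wald test that all design columns of ``var`` are zero."""
        cols = self.design.var_columns[var]
        b = self.beta[cols].to_numpy()
        V = self.cov.loc[cols, cols].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        df = len(cols)
        return stat, df, float(stats.chi2.sf(stat, df))

    @property
    def latent_scores(self) -> np.ndarray:
        return self.design.X @ self.beta.to_numpy()


def _start_values(y: np.ndarray, K: int, p: int) -> np.ndarray:
    cum = np.cumsum(np.bincount(y, minlength=K)) / len(y)
    cum = np.clip(cum[:-1], 1e-4, 1 - 1e-4)
    alpha0 = special.logit(cum)
    alpha0 = np.maximum.accumulate(alpha0 + 1e-6 * np.arange(K - 1))
    return np.concatenate([alpha0, np.zeros(p)])


def _pack(theta: np.ndarray, K: int):
    """Monotone threshold reparameterisation used during BFGS."""
    a0 = theta[0]
    d = theta[1: K - 1]
    alpha = a0 + np.concatenate([[0.0], np.cumsum(np.exp(d))])
    return alpha, theta[K - 1:]


def fit_proportional_odds(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    *,
    reference_levels: Mapping[str, object] | None = None,
    outcome_order: Sequence | None = None,
    gtol: float = 1e-8,
    max_iter: int = 100,
) -> OrdinalFit:
    """Maximum-likelihood cumulative-logit fit.

    Raises :class:`RankError` for aliased designs and
    :class:`ConvergenceError` (with gradient diagnostics) when the
    gradient norm cannot be brought below ``gtol`` — typically complete
    or quasi-complete separation.
    """
    y, order = encode_outcome(data[outcome], outcome_order)
    K = len(order)
    if K < 2:
        raise ValueError("outcome must have at least 2 observed levels")
    design = build_design(data, covariates, reference_levels)
    X = design.X
    p = X.shape[1]

    params0 = _start_values(y, K, p)
    # BFGS stage in the monotone parameterisation
    theta0 = np.concatenate([
        [params0[0]],
        np.log(np.maximum(np.diff(params0[: K - 1]), 1e-3)),
        params0[K - 1:],
    ])

    def f_theta(theta):
        alpha, beta = _pack(theta, K)
        nll, g = _nll_grad_prop(np.concatenate([alpha, beta]), X, y, K)
        if g is None:
            return np.inf, np.zeros_like(theta)
        g_alpha, g_beta = g[: K - 1], g[K - 1:]
        d = np.exp(theta[1: K - 1])
        g_theta = np.concatenate([
            [g_alpha.sum()],
            d * np.flip(np.cumsum(np.flip(g_alpha[1:]))),
            g_beta,
        ])
        return nll, g_theta

    res = optimize.minimize(
        f_theta, theta0, jac=True, method="BFGS",
        options={"gtol": 1e-9, "maxiter": 500},
    )
    alpha, beta = _pack(res.x, K)
    params = np.concatenate([alpha, beta])

    def grad_only(pp):
        nll, g = _nll_grad_prop(pp, X, y, K)
        if g is None:
            raise ConvergenceError("thresholds collapsed during polishing")
        return g

    # Newton polishing in the natural parameterisation
    nll, g = _nll_grad_prop(params, X, y, K)
    it = 0
    while np.max(np.abs(g)) > gtol and it < max_iter:
        H = _num_hessian(grad_only, params)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        while scale > 1e-6:
            trial = params - scale * step
            nll_t, g_t = _nll_grad_prop(trial, X, y, K)
            if np.isfinite(nll_t) and nll_t <= nll + 1e-12:
                params, nll, g = trial, nll_t, g_t
                break
            scale /= 2
        else:
            break
        it += 1

    grad_norm = float(np.max(np.abs(g)))
    converged = grad_norm <= gtol
    # |log-odds| of 20 corresponds to probabilities ~1e-9: far outside any
    # plausible fit and the signature of (quasi-)complete separation, where
    # the gradient also vanishes as parameters diverge
    if not converged or np.max(np.abs(params)) > 20:
        raise ConvergenceError(
            f"fit did not converge: max|gradient| = {grad_norm:.3g}, "
            f"max|parameter| = {np.max(np.abs(params)):.3g} "
            "(possible separation or aliased predictors)"
        )

    H = _num_hessian(grad_only, params)
    try:
        cov_full = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular observed information: {exc}") from exc
    se_full = np.sqrt(np.maximum(np.diag(cov_full), 0.0))
    beta_s = pd.Series(params[K - 1:], index=design.columns, name="beta")
    se_s = pd.Series(se_full[K - 1:], index=design.columns, name="se")
    cov_beta = pd.DataFrame(
        cov_full[K - 1:, K - 1:], index=design.columns, columns=design.columns
    )
    return OrdinalFit(
        thresholds=params[: K - 1],
        beta=beta_s,
        se=se_s,
        cov=cov_beta,
        cov_full=cov_full,
        loglik=-nll,
        n=len(y),
        K=K,
        outcome_order=list(order),
        design=design,
        y=y,
        converged=converged,
        grad_norm=grad_norm,
        n_iter=it,
    )


# --------------------------------------------------------------------------
# proportional-odds score test

@dataclass
class ScoreTestResult:
    statistic: float | None
    df: int
    p: float | None
    note: str = ""

    @property
    def applicable(self) -> bool:
        return self.statistic is not None


def score_test_po(fit: OrdinalFit) -> ScoreTestResult:
    """Efficient score test of slope equality across the cumulative logits.

    The alternative gives every covariate its own slope per cut point;
    the score of that model is evaluated at the proportional fit, and the
    statistic is U' I^{-1} U on p x (K-2) degrees of freedom.  With only
    two outcome levels there is nothing to test.
    """
    K, X, y = fit.K, fit.design.X, fit.y
    p = X.shape[1]
    if K <= 2 or p == 0:
        return ScoreTestResult(None, 0, None,
                               note="not applicable: fewer than 3 outcome "
                                    "levels or no covariates")
    beta = fit.beta.to_numpy()
    alpha = fit.thresholds

    def full_grad(params):
        a = params[: K - 1]
        B = params[K - 1:].reshape(p, K - 1)
        nll, ga, gB = _nll_grad_general(a, B, X, y, K)
        if ga is None:
            raise ConvergenceError("non-monotone cumulative probabilities "
                                   "while evaluating the score test")
        return np.concatenate([ga, gB.ravel()])

    null_point = np.concatenate([alpha, np.tile(beta[:, None], (1, K - 1)).ravel()])
    U = -full_grad(null_point)  # score of the log-likelihood
    I = _num_hessian(full_grad, null_point)  # observed information of NLL
    try:
        stat = float(U @ np.linalg.solve(I, U))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular information matrix in score test: {exc}") from exc
    df = p * (K - 2)
    return ScoreTestResult(stat, df, float(stats.chi2.sf(stat, df)))


# --------------------------------------------------------------------------
# concordance

@dataclass
class ConcordanceResult:
    pct_concordant: float | None
    pct_discordant: float | None
    pct_tied: float | None
    n_pairs: int
    note: str = ""


def percent_concordant(fit: OrdinalFit) -> ConcordanceResult:
    """Share of outcome-discrepant observation pairs ordered the same way
    by the fitted latent score; score ties count as neither concordant
    nor discordant and are reported separately."""
    scores = fit.latent_scores
    y = fit.y
    levels = np.unique(y)
    groups = {k: np.sort(scores[y == k]) for k in levels}
    n_pairs = conc = disc = ties = 0
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            sa, sb = groups[a], groups[b]
            n_pairs += len(sa) * len(sb)
            # for each higher-outcome score, count lower-outcome scores below it
            lo = np.searchsorted(sa, sb, side="left")
            hi = np.searchsorted(sa, sb, side="right")
            conc += int(lo.sum())
            ties += int((hi - lo).sum())
            disc += int((len(sa) - hi).sum())
    if n_pairs == 0:
        return ConcordanceResult(None, None, None, 0,
                                 note="not applicable: no pairs with "
                                      "different outcome levels")
    return ConcordanceResult(
        100.0 * conc / n_pairs,
        100.0 * disc / n_pairs,
        100.0 * ties / n_pairs,
        n_pairs,
    )


# --------------------------------------------------------------------------
# collinearity

def collinearity_check(design: Design, flag_threshold: float = 10.0) -> pd.DataFrame:
    """Variance-inflation factor per design column (with intercept).

    VIF_j = 1 / (1 - R²_j) from regressing column j on the remaining
    columns plus a constant; aliased columns get infinite VIF and are
    flagged."""
    X = design.X
    n, p = X.shape
    rows = []
    ones = np.ones((n, 1))
    for j in range(p):
        xj = X[:, j]
        others = np.column_stack([ones, np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        tss = float(np.sum((xj - xj.mean()) ** 2))
        rss = float(np.sum(resid**2))
        if tss == 0 or rss / max(tss, 1e-300) < 1e-12:
            vif = np.inf
        else:
            vif = tss / rss
        rows.append({"column": design.columns[j], "vif": vif,
                     "flagged": bool(vif > flag_threshold)})
    return pd.DataFrame(rows, columns=["column", "vif", "flagged"])


# --------------------------------------------------------------------------
# selection

@dataclass
class EliminationStep:
    removed: str | None
    p_value: float | None
    wald_p: dict[str, float]


@dataclass
class EliminationResult:
    retained: list[str]
    trace: list[EliminationStep]
    final_fit: OrdinalFit


def backward_eliminate(
    data: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    fixed: Sequence[str] = (),
    stay_level: float = 0.05,
    *,
    reference_levels: Mapping[str, object] | None = None,
    outcome_order: Sequence | None = None,
) -> EliminationResult:
    """Backward elimination on multi-df Wald p-values at ``stay_level``.

    Each round refits with the surviving covariates, removes the
    candidate with the largest Wald p-value if it is at or above the stay
    level, and stops when every remaining candidate is below it.  Fixed
    covariates are never tested or removed.
    """
    overlap = set(candidates) & set(fixed)
    if overlap:
        raise ValueError(f"candidates also listed as fixed: {sorted(overlap)}")
    remaining = list(candidates)
    trace: list[EliminationStep] = []
    while True:
        fit = fit_proportional_odds(
            data, outcome, list(fixed) + remaining,
            reference_levels=reference_levels, outcome_order=outcome_order,
        )
        if not remaining:
            trace.append(EliminationStep(None, None, {}))
            return EliminationResult([], trace, fit)
        pvals = {v: fit.wald_test(v)[2] for v in remaining}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] >= stay_level:
            trace.append(EliminationStep(worst, pvals[worst], pvals))
            remaining.remove(worst)
        else:
            trace.append(EliminationStep(None, None, pvals))
            return EliminationResult(remaining, trace, fit)


@dataclass
class HierarchicalStep:
    block: str
    candidates: list[str]
    retained: list[str]
    elimination: EliminationResult
    score_test: ScoreTestResult
    vif: pd.DataFrame


@dataclass
class HierarchicalResult:
    steps: list[HierarchicalStep]
    final_fit: OrdinalFit
    concordance: ConcordanceResult

    @property
    def selected(self) -> list[str]:
        return [v for s in self.steps for v in s.retained]

    def report(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            st = s.score_test
            rows.append({
                "block": s.block,
                "candidates": ", ".join(s.candidates),
                "retained": ", ".join(s.retained) or "(none)",
                "score_test_p": st.p if st.applicable else np.nan,
                "max_vif": float(s.vif["vif"].replace(np.inf, np.nan).max())
                if len(s.vif) else np.nan,
            })
        return pd.DataFrame(rows)


def hierarchical_selection(data: pd.DataFrame, spec: ModelSpec) -> HierarchicalResult:
    """Three-block hierarchical backward elimination with region fixed.

    Block k's candidates are eliminated with everything retained from
    earlier blocks (plus the always-fixed covariates) held in the model;
    survivors become fixed for later blocks.  Deterministic given data
    and spec.
    """
    fixed = list(spec.fixed)
    steps: list[HierarchicalStep] = []
    for name, block_vars in spec.blocks:
        elim = backward_eliminate(
            data, spec.outcome, block_vars, fixed, spec.stay_level,
            reference_levels=spec.reference_levels,
            outcome_order=spec.outcome_order,
        )
        fit = elim.final_fit
        steps.append(HierarchicalStep(
            block=name,
            candidates=list(block_vars),
            retained=list(elim.retained),
            elimination=elim,
            score_test=score_test_po(fit),
            vif=collinearity_check(fit.design),
        ))
        fixed += elim.retained
    final_fit = fit_proportional_odds(
        data, spec.outcome, fixed,
        reference_levels=spec.reference_levels,
        outcome_order=spec.outcome_order,
    )
    return HierarchicalResult(
        steps=steps,
        final_fit=final_fit,
        concordance=percent_concordant(final_fit),
    )


# --------------------------------------------------------------------------
# simulation (used by the test suite and for power/size studies)

def simulate_po_outcome(
    X: np.ndarray,
    thresholds: Sequence[float],
    beta: Sequence[float],
    rng: np.random.Generator,
    slopes_per_cut: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ordinal outcomes from a cumulative-logit model.

    ``thresholds`` must be strictly increasing; ``slopes_per_cut``
    (p x (K-1)) overrides ``beta`` to generate non-parallel data for
    power studies of the proportional-odds score test (cumulative
    probabilities are clipped into monotone order if the chosen slopes
    make them cross for some x).
    """
    alpha = np.asarray(thresholds, dtype=float)
    X = np.asarray(X, dtype=float)
    if slopes_per_cut is None:
        B = np.tile(np.asarray(beta, dtype=float)[:, None], (1, len(alpha)))
    else:
        B = np.asarray(slopes_per_cut, dtype=float)
    gamma = special.expit(alpha[None, :] - X @ B)  # P(Y <= k)
    gamma = np.maximum.accumulate(gamma, axis=1)
    u = rng.random(len(X))
    return (u[:, None] > gamma).sum(axis=1)
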