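"""Cross-classified Gaussian multilevel model fitted by Gibbs sampling.

The outcome is standardized walking velocity for trials cross-classified
by participant and image:

    z_v[t] = x[t]' beta + u[participant(t)] + v[image(t)] + e[t]

with u ~ N(0, s2_u), v ~ N(0, s2_v), e ~ N(0, s2_e). Priors are diffuse:
Normal(0, 1e6) per coefficient and inverse-Gamma(0.001, 0.001) per
variance component (the convention of classic multilevel-modelling MCMC
software). All full conditionals are
conjugate, so the sampler cycles exact draws of (beta | .), (u | .),
(v | .) and the three variances. Model comparison uses the Deviance
Information Criterion with the conditional-deviance convention (random
effects at their draws); fixed effects are screened with Wald chi-squared
statistics on the posterior mean and SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve, qr, solve_triangular
from sklearn.base import BaseEstimator

from .config import McmcConfig

logger = logging.getLogger(__name__)

RANDOM_LEVELS = ("participant", "image", "trial")


# ---------------------------------------------------------------------------
# design preparation
# ---------------------------------------------------------------------------

def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot z-score constant column {x.name!r}")
    return (x - x.mean()) / sd


def prepare_design(gait_table: pd.DataFrame,
                   images: Optional[pd.DataFrame] = None,
                   predictors: Sequence[str] = ("ENV", "LIK", "TK", "FR"),
                   velocity_col: str = "mean_velocity") -> pd.DataFrame:
    """Build the modelling table from per-trial gait results and image
    metadata.

    Control trials are excluded (no liking/fractal values exist for
    them), QC-flagged trials are dropped, environment is dummy coded
    nature=0/urban=1 (ENV) and task memory=0/discomfort=1 (TK), and all
    continuous covariates plus the velocity outcome are transformed to
    z-scores over the included rows. Rows missing any required covariate
    are dropped with a logged count.
    """
    df = gait_table.copy()
    if images is not None:
        meta_cols = [c for c in images.columns if c != "image_id"]
        overlap = [c for c in meta_cols if c in df.columns]
        df = df.drop(columns=overlap).merge(images, on="image_id",
                                            how="left")
    n0 = len(df)
    df = df[df["environment"] != "control"]
    n_control = n0 - len(df)
    if "qc_flags" in df.columns:
        flagged = df["qc_flags"].fillna("").astype(str).str.len() > 0
        df = df[~flagged]
        if flagged.sum():
            logger.info("dropped %d QC-flagged trials", int(flagged.sum()))

    df = df.copy()
    df["ENV"] = (df["environment"] == "urban").astype(float)
    if "task" in df.columns:
        df["TK"] = (df["task"] == "discomfort").astype(float)
    source = {"LIK": "liking", "FR": "fractal_dim",
              "VD": "discomfort_rating"}
    required = []
    for name in predictors:
        if name in ("ENV", "TK"):
            required.append(name)
            continue
        col = source.get(name)
        if col is None or col not in df.columns:
            raise ValueError(f"unknown predictor {name!r}")
        required.append(name)
        df[name] = df[col].astype(float)
    before = len(df)
    df = df.dropna(subset=[c for c in required if c in df.columns]
                   + [velocity_col])
    dropped = before - len(df)
    if dropped:
        logger.info("dropped %d rows with missing covariates", dropped)
    if df.empty:
        raise ValueError("no rows remain after exclusions")
    for name in predictors:
        if name not in ("ENV", "TK"):
            df[name] = _zscore(df[name])
    df["z_velocity"] = _zscore(df[velocity_col])
    logger.info("modelling table: %d rows (%d control trials excluded)",
                len(df), n_control)
    keep = (["participant_id", "trial_id", "image_id"]
            + list(predictors) + ["z_velocity"])
    return df[[c for c in keep if c in df.columns]].reset_index(drop=True)


def build_design_matrix(table: pd.DataFrame,
                        fixed_effects: Sequence[str]
                        ) -> Tuple[np.ndarray, List[str]]:
    """Intercept plus the named columns; ``A*B`` terms are plain products
    of the already coded/z-scored columns (no re-centring)."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for term in fixed_effects:
        if "*" in term:
            a, b = (s.strip() for s in term.split("*", 1))
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[term].to_numpy(float))
        names.append(term)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR diagonal
        _, r, piv = qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(names))
               if diag[i] < 1e-8 * diag[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, names


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSummary:
    """Fitted-model summary: fixed effects, variance components, DIC."""

    fixed: pd.DataFrame          # estimate, sd, ci_low, ci_high, wald_x2, p
    random: pd.DataFrame         # variance components: estimate, sd, ci
    dic: float
    p_d: float
    mean_deviance: float
    n_obs: int
    fixed_effects: Tuple[str, ...]
    ess: Dict[str, float] = field(default_factory=dict)
    geweke_z: Dict[str, float] = field(default_factory=dict)

    @property
    def pvalues(self) -> pd.Series:
        return self.fixed["p"]


def wald_chisq(estimate: float, posterior_sd: float) -> Tuple[float, float]:
    """Wald statistic (estimate/SE)^2 referred to chi-squared with 1 df."""
    if posterior_sd <= 0:
        raise ValueError("posterior_sd must be positive")
    x2 = (estimate / posterior_sd) ** 2
    return float(x2), float(stats.chi2.sf(x2, df=1))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must be non-constant")
    return float(stats.pearsonr(x, y).statistic)


def dic_from_deviances(deviances: np.ndarray,
                       deviance_at_mean: float) -> Tuple[float, float]:
    """DIC = mean deviance + pD, with pD = mean deviance - D(theta_bar)."""
    dbar = float(np.mean(deviances))
    p_d = dbar - float(deviance_at_mean)
    return dbar + p_d, p_d


def _ess(x: np.ndarray, max_lag: int = 200) -> float:
    """Effective sample size from the initial positive autocorrelations."""
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0:
        return float(n)
    s = 0.0
    for lag in range(1, min(max_lag, n - 1)):
        rho = float(x[:-lag] @ x[lag:]) / ((n - lag) * var)
        if rho <= 0.05:
            break
        s += rho
    return n / (1.0 + 2.0 * s)


def _geweke(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: difference of early and late chain means
    scaled by their (crudely independent) standard errors."""
    n = x.size
    a = x[:int(first * n)]
    b = x[int((1 - last) * n):]
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

def _gibbs_chain(y: np.ndarray, X: np.ndarray, pidx: np.ndarray,
                 iidx: np.ndarray, n_p: int, n_i: int, mcmc: McmcConfig,
                 rng: np.random.Generator):
    """Run the conjugate Gibbs cycle; returns post-burn-in draws."""
    n, p = X.shape
    XtX = X.T @ X
    nj = np.bincount(pidx, minlength=n_p).astype(float)
    nk = np.bincount(iidx, minlength=n_i).astype(float)

    # deterministic start: OLS coefficients, zero random effects,
    # method-of-moments variance split
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    total_var = max(float(resid.var()), 1e-8)
    pm = np.bincount(pidx, weights=resid, minlength=n_p) / np.maximum(nj, 1)
    s2u = max(float(pm.var()), 1e-4)
    im = np.bincount(iidx, weights=resid, minlength=n_i) / np.maximum(nk, 1)
    s2v = max(float(im.var()), 1e-4)
    s2e = max(total_var - s2u - s2v, 1e-4)
    u = np.zeros(n_p)
    v = np.zeros(n_i)

    a0 = mcmc.prior_var_shape
    b0 = mcmc.prior_var_rate
    prior_prec = 1.0 / mcmc.prior_beta_variance
    eye_prior = prior_prec * np.eye(p)

    n_keep = mcmc.chain_length
    betas = np.empty((n_keep, p))
    variances = np.empty((n_keep, 3))
    deviances = np.empty(n_keep)
    u_sum = np.zeros(n_p)
    v_sum = np.zeros(n_i)

    for it in range(mcmc.burn_in + n_keep):
        # beta | rest
        r = y - u[pidx] - v[iidx]
        prec = XtX / s2e + eye_prior
        chol = np.linalg.cholesky(prec)
        mean = cho_solve((chol, True), X.T @ r / s2e)
        beta = mean + solve_triangular(chol.T, rng.standard_normal(p),
                                       lower=False)
        xb = X @ beta

        # u | rest
        r = y - xb - v[iidx]
        prec_u = nj / s2e + 1.0 / s2u
        mean_u = np.bincount(pidx, weights=r, minlength=n_p) / s2e / prec_u
        u = mean_u + rng.standard_normal(n_p) / np.sqrt(prec_u)

        # v | rest
        r = y - xb - u[pidx]
        prec_v = nk / s2e + 1.0 / s2v
        mean_v = np.bincount(iidx, weights=r, minlength=n_i) / s2e / prec_v
        v = mean_v + rng.standard_normal(n_i) / np.sqrt(prec_v)

        # translation ("sweep") moves: the likelihood only identifies
        # intercept + mean(u) + mean(v), so shift mass between them from
        # the exact conditional of the shift — this decorrelates the
        # intercept from the random-effect means and fixes its mixing
        for re_vec, n_re, s2_re in ((u, n_p, s2u), (v, n_i, s2v)):
            prec_t = prior_prec + n_re / s2_re
            mean_t = (-beta[0] * prior_prec
                      + re_vec.sum() / s2_re) / prec_t
            t_shift = mean_t + rng.standard_normal() / np.sqrt(prec_t)
            beta[0] += t_shift
            re_vec -= t_shift
            xb += t_shift

        # variance components | rest
        s2u = 1.0 / rng.gamma(a0 + 0.5 * n_p, 1.0 / (b0 + 0.5 * (u @ u)))
        s2v = 1.0 / rng.gamma(a0 + 0.5 * n_i, 1.0 / (b0 + 0.5 * (v @ v)))
        e = y - xb - u[pidx] - v[iidx]
        sse = float(e @ e)
        s2e = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * sse))

        k = it - mcmc.burn_in
        if k >= 0:
            betas[k] = beta
            variances[k] = (s2u, s2v, s2e)
            deviances[k] = n * np.log(2.0 * np.pi * s2e) + sse / s2e
            u_sum += u
            v_sum += v

    u_bar = u_sum / n_keep
    v_bar = v_sum / n_keep
    return betas, variances, deviances, u_bar, v_bar


def gibbs_fit(table: pd.DataFrame, fixed_effects: Sequence[str] = (),
              mcmc: Optional[McmcConfig] = None,
              outcome: str = "z_velocity",
              participant_col: str = "participant_id",
              image_col: str = "image_id",
              ess_warn: float = 200.0) -> PosteriorSummary:
    """Fit the cross-classified random-intercept model by MCMC.

    Rows are sorted by (participant, image, outcome) before the index
    arrays are built, so posterior summaries are invariant to the input
    row order under a fixed seed.
    """
    if table.empty:
        raise ValueError("table is empty")
    mcmc = mcmc or McmcConfig()
    fixed_effects = tuple(fixed_effects)

    base_cols = sorted({c.strip() for t in fixed_effects
                        for c in t.split("*")})
    work = table.sort_values(
        [participant_col, image_col, outcome] + base_cols,
        kind="mergesort").reset_index(drop=True)
    y = work[outcome].to_numpy(float)
    X, names = build_design_matrix(work, fixed_effects)
    p_keys, pidx = np.unique(work[participant_col], return_inverse=True)
    i_keys, iidx = np.unique(work[image_col], return_inverse=True)

    rng = np.random.default_rng(np.random.SeedSequence(mcmc.seed))
    betas, variances, deviances, u_bar, v_bar = _gibbs_chain(
        y, X, pidx, iidx, len(p_keys), len(i_keys), mcmc, rng)

    # deviance at the posterior means (beta, u, v, s2e)
    beta_bar = betas.mean(axis=0)
    s2e_bar = float(variances[:, 2].mean())
    e_bar = y - X @ beta_bar - u_bar[pidx] - v_bar[iidx]
    dev_at_mean = (len(y) * np.log(2.0 * np.pi * s2e_bar)
                   + float(e_bar @ e_bar) / s2e_bar)
    dic, p_d = dic_from_deviances(deviances, dev_at_mean)

    rows = []
    for j, name in enumerate(names):
        est = float(beta_bar[j])
        sd = float(betas[:, j].std(ddof=1))
        lo, hi = np.percentile(betas[:, j], [2.5, 97.5])
        x2, pval = wald_chisq(est, sd) if sd > 0 else (np.nan, np.nan)
        rows.append({"term": name, "estimate": est, "sd": sd,
                     "ci_low": float(lo), "ci_high": float(hi),
                     "wald_x2": x2, "p": pval})
    fixed = pd.DataFrame(rows).set_index("term")

    vrows = []
    for j, level in enumerate(RANDOM_LEVELS):
        draws = variances[:, j]
        lo, hi = np.percentile(draws, [2.5, 97.5])
        vrows.append({"level": level, "estimate": float(draws.mean()),
                      "sd": float(draws.std(ddof=1)),
                      "ci_low": float(lo), "ci_high": float(hi)})
    random = pd.DataFrame(vrows).set_index("level")

    ess = {}
    geweke = {}
    for j, name in enumerate(names):
        ess[name] = _ess(betas[:, j])
        geweke[name] = _geweke(betas[:, j])
    for j, level in enumerate(RANDOM_LEVELS):
        ess[f"var_{level}"] = _ess(variances[:, j])
        geweke[f"var_{level}"] = _geweke(variances[:, j])
    low = {k: round(v, 1) for k, v in ess.items() if v < ess_warn}
    if low:
        warnings.warn(
            f"low effective sample size (<{ess_warn:.0f}): {low}; "
            "consider a longer chain", RuntimeWarning, stacklevel=2)

    return PosteriorSummary(
        fixed=fixed, random=random, dic=float(dic), p_d=float(p_d),
        mean_deviance=float(np.mean(deviances)), n_obs=len(y),
        fixed_effects=fixed_effects, ess=ess, geweke_z=geweke,
    )


class CrossClassifiedModel(BaseEstimator):
    """sklearn-style estimator for the cross-classified velocity model.

    Parameters
    ----------
    fixed_effects : sequence of str
        Predictor columns (``"A*B"`` denotes an interaction product).
    burn_in, chain_length : int
        MCMC schedule; defaults follow the 500 / 10,000 convention.
    random_state : int
        Seed for the sampler.

    After ``fit(X)`` (X a modelling DataFrame) the fitted attributes are
    ``coef_``, ``coef_sd_``, ``conf_int_``, ``wald_``, ``pvalues_``,
    ``var_components_``, ``dic_`` and ``summary_``.
    """

    def __init__(self, fixed_effects: Sequence[str] = (),
                 outcome: str = "z_velocity",
                 participant_col: str = "participant_id",
                 image_col: str = "image_id",
                 burn_in: int = 500, chain_length: int = 10000,
                 random_state: int = 0,
                 prior_beta_variance: float = 1e6,
                 prior_var_shape: float = 0.001,
                 prior_var_rate: float = 0.001):
        self.fixed_effects = fixed_effects
        self.outcome = outcome
        self.participant_col = participant_col
        self.image_col = image_col
        self.burn_in = burn_in
        self.chain_length = chain_length
        self.random_state = random_state
        self.prior_beta_variance = prior_beta_variance
        self.prior_var_shape = prior_var_shape
        self.prior_var_rate = prior_var_rate

    def _mcmc_config(self) -> McmcConfig:
        return McmcConfig(
            burn_in=self.burn_in, chain_length=self.chain_length,
            seed=self.random_state,
            prior_beta_variance=self.prior_beta_variance,
            prior_var_shape=self.prior_var_shape,
            prior_var_rate=self.prior_var_rate,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "CrossClassifiedModel":
        summary = gibbs_fit(
            X, fixed_effects=tuple(self.fixed_effects),
            mcmc=self._mcmc_config(), outcome=self.outcome,
            participant_col=self.participant_col, image_col=self.image_col,
        )
        self.summary_ = summary
        self.coef_ = summary.fixed["estimate"]
        self.coef_sd_ = summary.fixed["sd"]
        self.conf_int_ = summary.fixed[["ci_low", "ci_high"]]
        self.wald_ = summary.fixed["wald_x2"]
        self.pvalues_ = summary.fixed["p"]
        self.var_components_ = summary.random
        self.dic_ = summary.dic
        self.n_obs_ = summary.n_obs
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Population-level prediction from the posterior-mean fixed
        effects (random effects at zero)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "summary_")
        Xm, _ = build_design_matrix(X, tuple(self.fixed_effects))
        return Xm @ self.coef_.to_numpy()


# ---------------------------------------------------------------------------
# staged predictor selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the two-stage predictor-selection procedure."""

    best_label: str
    best_fixed_effects: Tuple[str, ...]
    best: PosteriorSummary
    comparison: pd.DataFrame
    fits: Dict[str, PosteriorSummary]


def _significant_terms(summary: PosteriorSummary,
                       alpha: float) -> List[str]:
    return [t for t in summary.fixed.index
            if t != "Intercept" and summary.fixed.loc[t, "p"] < alpha]


def staged_selection(table: pd.DataFrame, candidates: Sequence[str],
                     mcmc: Optional[McmcConfig] = None,
                     alpha: float = 0.05,
                     outcome: str = "z_velocity") -> SelectionResult:
    """Two-stage fixed-effect selection with Wald screening and DIC choice.

    Model 1 is the random-intercepts-only null. Stage 1 (model 2) enters
    all candidates jointly; terms with Wald p >= alpha are discarded and
    the survivors refitted (model 2a; equal to model 1 when nothing
    survives). Stage 2 (model 3) augments the stage-1 survivors with
    their pairwise interactions with every other candidate, screens
    again, and refits (model 3a). The reported best model is the
    lowest-DIC stage winner; ties go to the model with fewer fixed
    effects.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    candidates = list(candidates)
    mcmc = mcmc or McmcConfig()
    seeds = np.random.SeedSequence(mcmc.seed).generate_state(8) % (2 ** 31)

    def fit(effects: Sequence[str], seed: int) -> PosteriorSummary:
        cfg = McmcConfig(
            burn_in=mcmc.burn_in, chain_length=mcmc.chain_length,
            seed=int(seed), prior_beta_variance=mcmc.prior_beta_variance,
            prior_var_shape=mcmc.prior_var_shape,
            prior_var_rate=mcmc.prior_var_rate,
        )
        return gibbs_fit(table, effects, cfg, outcome=outcome)

    fits: Dict[str, PosteriorSummary] = {}
    fits["1"] = fit((), seeds[0])
    fits["2"] = fit(tuple(candidates), seeds[1])
    retained = _significant_terms(fits["2"], alpha)
    if not retained:
        fits["2a"] = fits["1"]
    elif retained == candidates:
        fits["2a"] = fits["2"]
    else:
        fits["2a"] = fit(tuple(retained), seeds[2])

    if retained:
        interactions = []
        seen_pairs = set()
        for main in retained:
            for other in candidates:
                if other == main:
                    continue
                pair = frozenset((main, other))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                term = f"{main}*{other}"
                # keep the interaction only if it adds an independent column
                try:
                    build_design_matrix(
                        table, tuple(retained + interactions + [term]))
                except ValueError:
                    continue
                interactions.append(term)
        stage2 = tuple(retained + interactions)
        fits["3"] = fit(stage2, seeds[3])
        kept3 = _significant_terms(fits["3"], alpha)
        if not kept3:
            fits["3a"] = fits["1"]
        elif kept3 == retained:
            fits["3a"] = fits["2a"]
        elif tuple(kept3) == stage2:
            fits["3a"] = fits["3"]
        else:
            fits["3a"] = fit(tuple(kept3), seeds[4])
    else:
        fits["3"] = fits["1"]
        fits["3a"] = fits["1"]

    stage_winners = ["1", "2a", "3a"]
    best_label = min(
        stage_winners,
        key=lambda lbl: (round(fits[lbl].dic, 6),
                         len(fits[lbl].fixed_effects),
                         stage_winners.index(lbl)),
    )
    comparison = pd.DataFrame([
        {"model": lbl, "dic": fits[lbl].dic,
         "fixed": ", ".join(fits[lbl].fixed_effects),
         "random": "PT, IM, T"}
        for lbl in ("1", "2", "2a", "3", "3a")
    ])
    return SelectionResult(
        best_label=best_label,
        best_fixed_effects=fits[best_label].fixed_effects,
        best=fits[best_label],
        comparison=comparison,
        fits=fits,
    )
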