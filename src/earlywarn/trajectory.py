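"""Bayesian mixed-effects growth model for early non-response prediction.

The predictor at the heart of the pipeline: a two-level growth curve fitted
to each participant's weekly symptom scores from pre-treatment (week 0)
through treatment week 3,

    y_it = b0 + b1*f(t) + sum_k b_k x_ik + u0_i + u1_i*f(t) + e_it,

with change term f(t) in {log(t+1), t, t^2}, independent Gaussian random
intercepts/slopes (u0_i, u1_i) and residual e_it. Missing weekly ratings
simply drop out of the likelihood (missing-at-random).

Fitting marginalizes the random effects analytically — each participant's
observed score vector is multivariate normal with covariance
Z_i diag(s_u0^2, s_u1^2) Z_i' + s_e^2 I — leaving a low-dimensional posterior
over the fixed effects and the three variance components, which is sampled
by an affine-invariant ensemble MCMC (emcee). Weakly informative priors:
Normal(0, 10) on fixed effects and half-Normal(5) on SDs, sensible scales
for a 0-27 symptom score.

Prediction for a (possibly new) participant conditions their random effects
on whatever weeks 0..3 they did report (partial pooling): per posterior
draw, (u0_i, u1_i) is drawn from its Gaussian conditional given the observed
residuals, and the week-10 score is simulated including residual noise.
With few or no post-baseline ratings the conditional collapses toward zero
and the prediction shrinks to the population-average trajectory — the
behaviour that makes the model optimistic for sparsely rated participants.
The at-risk flag applies the response criterion to the posterior predictive
median (truncated to the scale bounds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import emcee
import numpy as np
import pandas as pd

from .criterion import CriterionConfig, classify_response

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "PosteriorPrediction",
    "ConvergenceError",
    "fit",
    "predict_post",
    "predict_cohort",
    "flag_at_risk",
]

CHANGE_TERMS = {
    "logarithmic": lambda t: np.log(np.asarray(t, dtype=float) + 1.0),
    "linear": lambda t: np.asarray(t, dtype=float),
    "quadratic": lambda t: np.asarray(t, dtype=float) ** 2,
}


class ConvergenceError(RuntimeError):
    """MCMC failed the split-R-hat check even after a doubled-draws retry."""


@dataclass(frozen=True)
class ModelSpec:
    """One candidate trajectory model: change-term family, covariates, MCMC plan."""

    change_term: str = "logarithmic"
    covariates: tuple[str, ...] = ("pid5bf",)
    beta_prior_scale: float = 10.0
    sd_prior_scale: float = 5.0
    walkers: int = 32
    warmup: int = 500
    draws: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.change_term not in CHANGE_TERMS:
            raise ValueError(
                f"change_term must be one of {sorted(CHANGE_TERMS)}, got {self.change_term!r}"
            )
        for name in ("walkers", "warmup", "draws"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_parameters(self) -> int:
        """Estimated parameters: intercept, slope, covariate effects, 3 SDs."""
        return 2 + len(self.covariates) + 3

    def f(self, t) -> np.ndarray:
        return CHANGE_TERMS[self.change_term](t)


@dataclass(frozen=True)
class PosteriorDraws:
    """Flattened posterior sample for one fitted trajectory model.

    beta has one column per fixed effect (intercept, change slope, then the
    covariates in spec order); sigma columns are (sd_u0, sd_u1, sd_e).
    Per-participant random effects are not sampled — they are marginalized
    in the likelihood — but their conditional draws given any participant's
    data are available through :func:`predict_post` / ``conditional_random_effects``.
    """

    beta: np.ndarray  # (n_draws, 2 + n_cov)
    sigma: np.ndarray  # (n_draws, 3), all positive
    spec: ModelSpec
    rhat: dict[str, float]
    n_participants: int

    @property
    def parameter_names(self) -> list[str]:
        return ["beta0", "beta1", *[f"beta_{c}" for c in self.spec.covariates],
                "sd_u0", "sd_u1", "sd_e"]

    def summary(self) -> pd.DataFrame:
        draws = np.column_stack([self.beta, self.sigma])
        return pd.DataFrame(
            {
                "mean": draws.mean(axis=0),
                "sd": draws.std(axis=0),
                "q2.5": np.percentile(draws, 2.5, axis=0),
                "median": np.percentile(draws, 50, axis=0),
                "q97.5": np.percentile(draws, 97.5, axis=0),
                "rhat": [self.rhat[p] for p in self.parameter_names],
            },
            index=self.parameter_names,
        )

    def conditional_random_effects(
        self, t_obs, y_obs, x, n_draws: int | None = None, seed: int = 0
    ) -> np.ndarray:
        """Draws of (u0, u1) for one participant given their observed weeks."""
        sub = _subsample(self, n_draws, seed)
        mean, chol = _conditional_moments(sub, np.asarray(t_obs), np.asarray(y_obs, float), np.asarray(x, float))
        rng = np.random.default_rng([seed, 31])
        z = rng.standard_normal((len(sub.beta), 2))
        return mean + np.einsum("dij,dj->di", chol, z)


@dataclass(frozen=True)
class PosteriorPrediction:
    """Predictive distribution of one participant's post-treatment score."""

    participant_id: str
    draws: np.ndarray  # posterior predictive week-10 scores
    median: float
    q_low: float
    q_high: float
    p_nonresponse: float | None = field(default=None)
    at_risk: bool | None = field(default=None)


# ---------------------------------------------------------------------------
# data marshalling

def _design(
    scores: pd.DataFrame,
    baseline: pd.DataFrame,
    spec: ModelSpec,
    max_week: int = 3,
):
    """Group participants by observed-week pattern for a vectorized likelihood.

    Returns (patterns, ids) where each pattern is (f_vec, Y, X) for the block
    of participants sharing one set of observed weeks.
    """
    obs = scores.dropna(subset=["qids"])
    obs = obs[obs["week"] <= max_week]
    ids = sorted(obs["participant_id"].unique())
    for c in spec.covariates:
        if c not in baseline.columns:
            raise ValueError(f"baseline table lacks covariate column {c!r}")
    groups: dict[tuple[int, ...], list[tuple[np.ndarray, np.ndarray]]] = {}
    by_pid = {pid: g for pid, g in obs.groupby("participant_id")}
    for pid in ids:
        g = by_pid[pid].sort_values("week")
        weeks = tuple(int(w) for w in g["week"])
        x = baseline.loc[pid, list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else np.empty(0)
        groups.setdefault(weeks, []).append((g["qids"].to_numpy(dtype=float), x))
    patterns = []
    for weeks, members in sorted(groups.items()):
        fvec = spec.f(np.array(weeks))
        Y = np.stack([m[0] for m in members])
        X = np.stack([m[1] for m in members])
        patterns.append((fvec, Y, X))
    return patterns, ids


# ---------------------------------------------------------------------------
# log posterior, vectorized over walkers

def _log_posterior(theta: np.ndarray, patterns, spec: ModelSpec) -> np.ndarray:
    """theta: (n_walkers, ndim) = betas then log-SDs; returns (n_walkers,)."""
    theta = np.atleast_2d(theta)
    nw = theta.shape[0]
    n_cov = len(spec.covariates)
    beta = theta[:, : 2 + n_cov]
    log_sd = theta[:, 2 + n_cov :]
    out = np.full(nw, -np.inf)
    ok = np.all(np.abs(log_sd) < 12.0, axis=1)
    if not ok.any():
        return out
    sd = np.exp(log_sd[ok])
    b = beta[ok]
    lp = (
        -0.5 * np.sum((b / spec.beta_prior_scale) ** 2, axis=1)
        - np.sum(sd**2, axis=1) / (2.0 * spec.sd_prior_scale**2)
        + np.sum(log_sd[ok], axis=1)  # Jacobian of the log-SD transform
    )
    var_u0 = sd[:, 0] ** 2
    var_u1 = sd[:, 1] ** 2
    var_e = sd[:, 2] ** 2
    for fvec, Y, X in patterns:
        k = len(fvec)
        n_g = Y.shape[0]
        # V_w = var_u0 J + var_u1 f f' + var_e I, shape (nw_ok, k, k)
        V = (
            var_u0[:, None, None]
            + var_u1[:, None, None] * np.outer(fvec, fvec)[None]
            + var_e[:, None, None] * np.eye(k)[None]
        )
        L = np.linalg.cholesky(V)
        mu = b[:, 0, None, None] + b[:, 1, None, None] * fvec[None, None, :]
        if n_cov:
            mu = mu + (X @ b[:, 2:].T).T[:, :, None]
        R = Y[None] - mu  # (nw_ok, n_g, k)
        z = np.linalg.solve(L, R.transpose(0, 2, 1))  # (nw_ok, k, n_g)
        qf = np.sum(z**2, axis=(1, 2))
        logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
        lp -= 0.5 * (qf + n_g * logdet + n_g * k * np.log(2.0 * np.pi))
    out[ok] = lp
    return out


def _initial_state(patterns, spec: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    """Moment-based centre: pooled OLS on f(t) plus rough variance splits."""
    ys, fs, xs = [], [], []
    for fvec, Y, X in patterns:
        ys.append(Y.ravel())
        fs.append(np.tile(fvec, Y.shape[0]))
        xs.append(np.repeat(X, len(fvec), axis=0))
    y = np.concatenate(ys)
    f = np.concatenate(fs)
    X = np.vstack(xs)
    D = np.column_stack([np.ones_like(f), f] + ([X] if X.shape[1] else []))
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid_sd = max(np.std(y - D @ coef), 0.5)
    centre = np.concatenate([
        coef,
        np.log([max(resid_sd, 1.0), max(resid_sd / 2.0, 0.5), max(resid_sd / 1.5, 0.5)]),
    ])
    return centre + 0.05 * rng.standard_normal((spec.walkers, len(centre)))


def _split_rhat(chain: np.ndarray, n_groups: int = 4) -> np.ndarray:
    """Split-R-hat per parameter for a (steps, walkers, ndim) ensemble chain.

    Interacting ensemble walkers are not independent chains, and per-walker
    samples are few relative to the autocorrelation time, so walkers are
    pooled into ``n_groups`` super-chains (each the concatenation of
    walkers/n_groups walkers) before the standard split-R-hat.
    """
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", FutureWarning)
        import arviz as az

    steps, walkers, ndim = chain.shape
    if walkers < 2 * n_groups:
        n_groups = max(walkers // 2, 2)
    per = walkers // n_groups
    grouped = (
        chain[:, : n_groups * per]
        .reshape(steps, n_groups, per, ndim)
        .transpose(1, 2, 0, 3)
        .reshape(n_groups, per * steps, ndim)
    )
    ds = az.convert_to_dataset(grouped)
    return az.rhat(ds)["x"].to_numpy()


def fit(
    train_scores: pd.DataFrame,
    baseline: pd.DataFrame,
    spec: ModelSpec | None = None,
    max_week: int = 3,
) -> PosteriorDraws:
    """Fit the growth model to weeks 0..max_week of a training cohort.

    Requires >= 10 participants, each with a week-0 observation. On a split
    R-hat above the spec threshold the sampler retries once with doubled
    draws, then raises :class:`ConvergenceError` naming the offenders.
    """
    spec = spec or ModelSpec()
    patterns, ids = _design(train_scores, baseline, spec, max_week=max_week)
    if len(ids) < 10:
        raise ValueError(f"need >= 10 participants to fit, got {len(ids)}")
    week0 = train_scores.dropna(subset=["qids"]).query("week == 0")["participant_id"]
    missing0 = set(ids) - set(week0)
    if missing0:
        raise ValueError(f"participants lack a week-0 score: {sorted(missing0)}")
    all_y = np.concatenate([Y.ravel() for _, Y, _ in patterns])
    if np.ptp(all_y) == 0:
        raise ValueError("degenerate data: all observed scores identical")

    ndim = 2 + len(spec.covariates) + 3
    names = ["beta0", "beta1", *[f"beta_{c}" for c in spec.covariates], "sd_u0", "sd_u1", "sd_e"]

    # differential-evolution moves mix much faster than the default stretch
    # move on this low-dimensional, nearly Gaussian posterior
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]

    def run(n_draws: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng([spec.seed, 7])
        sampler = emcee.EnsembleSampler(
            spec.walkers,
            ndim,
            _log_posterior,
            args=(patterns, spec),
            vectorize=True,
            moves=moves,
        )
        sampler.random_state = np.random.RandomState(spec.seed % (2**31)).get_state()
        p0 = _initial_state(patterns, spec, rng)
        state = sampler.run_mcmc(p0, spec.warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, n_draws, progress=False)
        chain = sampler.get_chain()  # (steps, walkers, ndim)
        rhat = _split_rhat(chain)
        return chain, rhat

    chain, rhat = run(spec.draws)
    if np.any(rhat > spec.rhat_threshold):
        chain, rhat = run(2 * spec.draws)
        if np.any(rhat > spec.rhat_threshold):
            bad = [f"{n}={r:.3f}" for n, r in zip(names, rhat) if r > spec.rhat_threshold]
            raise ConvergenceError(
                "split R-hat above "
                f"{spec.rhat_threshold} after doubled draws: {', '.join(bad)}"
            )
    flat = chain.reshape(-1, ndim)
    return PosteriorDraws(
        beta=flat[:, : 2 + len(spec.covariates)],
        sigma=np.exp(flat[:, 2 + len(spec.covariates) :]),
        spec=spec,
        rhat=dict(zip(names, (float(r) for r in rhat))),
        n_participants=len(ids),
    )


# ---------------------------------------------------------------------------
# prediction

def _subsample(draws: PosteriorDraws, n_draws: int | None, seed: int) -> PosteriorDraws:
    total = draws.beta.shape[0]
    if n_draws is None or n_draws >= total:
        return draws
    idx = np.random.default_rng([seed, 17]).choice(total, size=n_draws, replace=False)
    return replace(draws, beta=draws.beta[idx], sigma=draws.sigma[idx])


def _conditional_moments(
    draws: PosteriorDraws, t_obs: np.ndarray, y_obs: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw Gaussian conditional of (u0, u1) given observed residuals.

    Returns (mean (nd,2), cholesky (nd,2,2)) of
    N(D Z' V^{-1} r, D - D Z' V^{-1} Z D), the partial-pooling update.
    """
    spec = draws.spec
    fvec = spec.f(t_obs)
    Z = np.column_stack([np.ones_like(fvec), fvec])  # (k, 2)
    nd = draws.beta.shape[0]
    var_u = draws.sigma[:, :2] ** 2  # (nd, 2)
    var_e = draws.sigma[:, 2] ** 2
    mu = draws.beta[:, 0, None] + draws.beta[:, 1, None] * fvec[None, :]
    if len(spec.covariates):
        mu = mu + (draws.beta[:, 2:] @ x)[:, None]
    r = y_obs[None, :] - mu  # (nd, k)
    DZt = var_u[:, :, None] * Z.T[None, :, :]  # (nd, 2, k)
    V = (
        np.einsum("ki,di,ji->dkj", Z, var_u, Z)
        + var_e[:, None, None] * np.eye(len(fvec))[None]
    )
    Vinv_r = np.linalg.solve(V, r[:, :, None])[:, :, 0]  # (nd, k)
    mean = np.einsum("dik,dk->di", DZt, Vinv_r)  # (nd, 2)
    Vinv_ZD = np.linalg.solve(V, DZt.transpose(0, 2, 1))  # (nd, k, 2)
    cov = var_u[:, :, None] * np.eye(2)[None] - np.einsum(
        "dik,dkj->dij", DZt, Vinv_ZD
    )
    # guard tiny negative eigenvalues from round-off
    cov = cov + 1e-12 * np.eye(2)[None]
    chol = np.linalg.cholesky(cov)
    return mean, chol


def predict_post(
    draws: PosteriorDraws,
    t_obs,
    y_obs,
    x=(),
    horizon_week: int = 10,
    participant_id: str = "",
    n_draws: int | None = 2000,
    seed: int = 0,
) -> PosteriorPrediction:
    """Posterior predictive week-10 score for one participant.

    t_obs/y_obs are that participant's observed weeks 0..3 and scores; x the
    covariate values in spec order. Per retained posterior draw the random
    effects are drawn from their conditional given the observations, then the
    horizon-week score is simulated with residual noise. Point summary is the
    predictive median; the interval spans quantiles 2.5-97.5%.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    x = np.asarray(x, dtype=float)
    if t_obs.size == 0:
        raise ValueError(f"participant {participant_id!r} has no observations at all")
    sub = _subsample(draws, n_draws, seed)
    mean, chol = _conditional_moments(sub, t_obs, y_obs, x)
    nd = sub.beta.shape[0]
    rng = np.random.default_rng([seed, 23])
    u = mean + np.einsum("dij,dj->di", chol, rng.standard_normal((nd, 2)))
    fh = float(sub.spec.f(np.array([horizon_week]))[0])
    mu_h = sub.beta[:, 0] + sub.beta[:, 1] * fh
    if len(sub.spec.covariates):
        mu_h = mu_h + sub.beta[:, 2:] @ x
    y_h = mu_h + u[:, 0] + u[:, 1] * fh + rng.normal(0.0, sub.sigma[:, 2])
    return PosteriorPrediction(
        participant_id=participant_id,
        draws=y_h,
        median=float(np.median(y_h)),
        q_low=float(np.percentile(y_h, 2.5)),
        q_high=float(np.percentile(y_h, 97.5)),
    )


def flag_at_risk(
    prediction: PosteriorPrediction,
    pre_score: float,
    criterion: CriterionConfig | None = None,
) -> PosteriorPrediction:
    """Apply the response criterion to the predictive median.

    at_risk is True iff the criterion labels (pre, predicted post) a
    non-response; the posterior probability of non-response is attached
    alongside, for sensitivity calibration.
    """
    criterion = criterion or CriterionConfig()
    lo, hi = criterion.scale_min, criterion.scale_max
    point = float(np.clip(prediction.median, lo, hi))
    label = classify_response(pre_score, point, criterion)
    clipped = np.clip(prediction.draws, lo, hi)
    p_nr = float(
        np.mean(
            [
                not classify_response(pre_score, float(v), criterion).responder
                for v in clipped
            ]
        )
    )
    return replace(prediction, at_risk=not label.responder, p_nonresponse=p_nr)


def predict_cohort(
    draws: PosteriorDraws,
    scores: pd.DataFrame,
    baseline: pd.DataFrame,
    criterion: CriterionConfig | None = None,
    horizon_week: int = 10,
    max_week: int = 3,
    n_draws: int | None = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Week-3 predictions and at-risk flags for every participant in a table.

    The pre score for the criterion is the observed week-0 rating. Returns a
    frame indexed by participant_id with the predictive summaries, the
    non-response probability and the boolean at_risk flag.
    """
    criterion = criterion or CriterionConfig()
    obs = scores.dropna(subset=["qids"])
    obs = obs[obs["week"] <= max_week]
    rows = []
    for pid, g in obs.groupby("participant_id"):
        g = g.sort_values("week")
        x = (
            baseline.loc[pid, list(draws.spec.covariates)].to_numpy(dtype=float)
            if draws.spec.covariates
            else ()
        )
        pred = predict_post(
            draws,
            g["week"].to_numpy(),
            g["qids"].to_numpy(),
            x,
            horizon_week=horizon_week,
            participant_id=str(pid),
            n_draws=n_draws,
            seed=seed,
        )
        week0 = g[g["week"] == 0]
        if week0.empty:
            warnings.warn(f"participant {pid} lacks a week-0 score; skipped", stacklevel=2)
            continue
        pred = flag_at_risk(pred, float(week0["qids"].iloc[0]), criterion)
        rows.append(
            (pid, pred.median, pred.q_low, pred.q_high, pred.p_nonresponse, pred.at_risk)
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "median", "q2.5", "q97.5", "p_nonresponse", "at_risk"],
    ).set_index("participant_id")
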