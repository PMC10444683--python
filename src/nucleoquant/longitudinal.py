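"""Hierarchical model for log metabolite concentrations around surgery.

The model for the natural log of the creatinine-normalized concentration
(logDV) of metabolite *m* in sample *s* of patient *p* is

    logDV = beta(MET, TIME, MET:TIME) + b[p, m] + u[s] + eps,
    b[p, ·] ~ MVN(0, Sigma_ID),  u[s] ~ N(0, tau^2),
    eps ~ N(0, sigma_met[m]^2),

i.e. fixed metabolite, time and interaction effects under reference
coding; a per-patient random vector with one component per metabolite and
full covariance (the "(1 + MET | ID)" structure, reparameterized from
intercept-plus-contrasts to per-metabolite effects); a per-sample random
intercept shared by all metabolites of a urine sample, absorbing residual
between-sample diuresis differences that creatinine normalization did not
remove; and a per-metabolite residual SD (the distributional "sigma ~ MET"
term).

Because every layer is Gaussian, the random effects integrate out in
closed form and the marginal likelihood is a multivariate normal that is
block diagonal by patient.  The default estimation path maximizes the
REML criterion over the variance parameters with the fixed effects
profiled out by generalized least squares; a Bayesian path samples the
variance parameters with an affine-invariant ensemble sampler against the
same marginal likelihood and draws the fixed effects from their
conditional Gaussian.

Sparse late follow-up (few patients beyond two weeks) is handled by
pooling all post-24h time points into one "post" level by default.

Fold changes for a typical subject and typical diuresis (all random
effects at zero) are ``exp`` of the relevant fixed-effect contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from sklearn.base import BaseEstimator

from .exceptions import DomainError, InsufficientDataError
from .quantify import TIME_POINTS

__all__ = [
    "LmmParams",
    "DesignMatrices",
    "encode_design",
    "joint_log_likelihood",
    "LongitudinalMixedModel",
    "FoldChangeEstimate",
    "forest_table",
    "REFERENCE_BAND",
]

POOLED_LABEL = "post"
#: The 0.8- and 1.25-fold reference band (roughly a 20% change).
REFERENCE_BAND = (0.8, 1.25)


def pool_time_labels(labels, pooling: str = "pooled"):
    """Map the 7 collection labels to analysis time levels.

    ``pooling="pooled"`` (default) collapses every post-24h time point to
    one "post" level; ``pooling="none"`` keeps all 7 levels.
    """
    if pooling == "none":
        return list(labels)
    if pooling != "pooled":
        raise ValueError("pooling must be 'pooled' or 'none'")
    return [lbl if lbl in ("pre", "24h") else POOLED_LABEL for lbl in labels]


@dataclass
class DesignMatrices:
    """Fixed and random design information for one dataset."""

    X: np.ndarray
    fixed_names: list[str]
    y: np.ndarray
    metabolites: list[str]
    time_levels: list[str]
    met_idx: np.ndarray  # row -> position in metabolites
    patient_ids: list[str]
    patient_idx: np.ndarray  # row -> position in patient_ids
    sample_ids: list[str]
    sample_idx: np.ndarray  # row -> position in sample_ids
    time_per_row: np.ndarray


def _canonical_time_order(levels, pooling):
    if pooling == "pooled":
        order = ["pre", "24h", POOLED_LABEL]
    else:
        order = list(TIME_POINTS)
    known = [t for t in order if t in levels]
    extra = sorted(set(levels) - set(order))
    return known + extra


def encode_design(
    data: pd.DataFrame,
    pooling: str = "pooled",
    reference_metabolite: str | None = None,
    logdv_col: str = "logDV",
) -> DesignMatrices:
    """Reference-coded fixed design plus random-effect index maps.

    ``data`` needs columns ``patient_id, time_point, analyte_code`` and a
    log-concentration column; ``sample_id`` is synthesized from (patient,
    time) when absent.  Fixed columns: intercept, (M-1) metabolite
    contrasts, (T-1) time contrasts and their (M-1)(T-1) interactions,
    with the pre-surgery time and the reference metabolite (first
    alphabetically unless given) as reference levels.
    """
    df = data.copy()
    if logdv_col not in df.columns:
        raise ValueError(f"data lacks the {logdv_col!r} column")
    if "sample_id" not in df.columns:
        df["sample_id"] = df["patient_id"].astype(str) + "|" + df["time_point"].astype(str)
    # invariant checks: one (patient, time) per sample, one row per (sample, met)
    smap = df.groupby("sample_id")[["patient_id", "time_point"]].nunique()
    if (smap > 1).any().any():
        raise ValueError("a sample_id maps to more than one (patient, time point)")
    if df.duplicated(["sample_id", "analyte_code"]).any():
        raise ValueError("duplicate (sample, metabolite) rows")

    df["time_level"] = pool_time_labels(df["time_point"], pooling)
    mets = sorted(df["analyte_code"].unique())
    if len(mets) < 2 and len(df["time_level"].unique()) < 2:
        raise InsufficientDataError("need at least 2 time levels or 2 metabolites")
    ref_met = reference_metabolite if reference_metabolite is not None else mets[0]
    if ref_met not in mets:
        raise ValueError(f"reference metabolite {ref_met!r} not present")
    mets = [ref_met] + [m for m in mets if m != ref_met]
    times = _canonical_time_order(df["time_level"].unique(), pooling)

    baseline = set(df.loc[df["time_level"] == times[0], "analyte_code"])
    absent = [m for m in mets if m not in baseline]
    if absent:
        warnings.warn(
            f"metabolite(s) absent at the baseline time level: {absent}; "
            "their time contrasts are weakly identified",
            stacklevel=2,
        )

    met_pos = {m: i for i, m in enumerate(mets)}
    time_pos = {t: i for i, t in enumerate(times)}
    met_idx = df["analyte_code"].map(met_pos).to_numpy()
    time_idx = df["time_level"].map(time_pos).to_numpy()
    n = len(df)

    names = ["intercept"]
    cols = [np.ones(n)]
    for m in mets[1:]:
        names.append(f"MET[{m}]")
        cols.append((df["analyte_code"] == m).to_numpy(float))
    for t in times[1:]:
        names.append(f"TIME[{t}]")
        cols.append((df["time_level"] == t).to_numpy(float))
    for m in mets[1:]:
        for t in times[1:]:
            names.append(f"MET[{m}]:TIME[{t}]")
            cols.append(
                ((df["analyte_code"] == m) & (df["time_level"] == t)).to_numpy(float)
            )
    X = np.column_stack(cols)

    patients = list(dict.fromkeys(df["patient_id"].astype(str)))
    p_pos = {p: i for i, p in enumerate(patients)}
    samples = list(dict.fromkeys(df["sample_id"].astype(str)))
    s_pos = {s: i for i, s in enumerate(samples)}

    return DesignMatrices(
        X=X,
        fixed_names=names,
        y=df[logdv_col].to_numpy(float),
        metabolites=mets,
        time_levels=times,
        met_idx=met_idx,
        patient_ids=patients,
        patient_idx=df["patient_id"].astype(str).map(p_pos).to_numpy(),
        sample_ids=samples,
        sample_idx=df["sample_id"].astype(str).map(s_pos).to_numpy(),
        time_per_row=time_idx,
    )


@dataclass
class LmmParams:
    """Model parameters on their natural scales."""

    beta: np.ndarray
    Sigma_ID: np.ndarray  # M x M covariance of per-patient metabolite effects
    tau_sample: float
    sigma_met: np.ndarray  # residual SD per metabolite (log scale)

    def validate(self, n_met: int, n_beta: int) -> None:
        if self.Sigma_ID.shape != (n_met, n_met):
            raise ValueError("Sigma_ID has the wrong shape")
        if not np.allclose(self.Sigma_ID, self.Sigma_ID.T):
            raise ValueError("Sigma_ID must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma_ID) < -1e-10):
            raise DomainError("Sigma_ID must be positive semi-definite")
        if self.tau_sample < 0:
            raise DomainError("tau_sample must be non-negative")
        if np.any(self.sigma_met <= 0):
            raise DomainError("residual SDs must be positive")
        if self.beta.shape != (n_beta,):
            raise ValueError("beta has the wrong length")


def joint_log_likelihood(
    params: LmmParams,
    design: DesignMatrices,
    patient_effects: np.ndarray,
    sample_intercepts: np.ndarray,
) -> float:
    """Joint log density of the data and the realized random effects.

    ``patient_effects`` is (n_patients, M) of realized per-patient
    metabolite effects; ``sample_intercepts`` is (n_samples,) of realized
    per-sample diuresis intercepts.  The data term sums, per row, the
    normal log density of logDV around the fixed prediction plus the
    row's random contributions with SD ``sigma_met[MET]``; the random
    effects contribute their multivariate-normal and normal log densities.
    """
    M = len(design.metabolites)
    params.validate(M, design.X.shape[1])
    mean = (
        design.X @ params.beta
        + patient_effects[design.patient_idx, design.met_idx]
        + sample_intercepts[design.sample_idx]
    )
    sd = params.sigma_met[design.met_idx]
    data_term = float(np.sum(stats.norm.logpdf(design.y, loc=mean, scale=sd)))
    re_term = float(
        np.sum(
            stats.multivariate_normal.logpdf(
                patient_effects, mean=np.zeros(M), cov=params.Sigma_ID, allow_singular=True
            )
        )
    )
    if params.tau_sample > 0:
        re_term += float(
            np.sum(stats.norm.logpdf(sample_intercepts, scale=params.tau_sample))
        )
    elif np.any(sample_intercepts != 0):
        return -np.inf
    return data_term + re_term


# ---------------------------------------------------------------------------
# marginal likelihood machinery


def _theta_size(M: int, id_cov: str) -> int:
    id_n = M * (M + 1) // 2 if id_cov == "full" else M
    return id_n + 1 + M  # Sigma_ID params, log tau, log sigma_met


def _unpack_theta(theta: np.ndarray, M: int, id_cov: str):
    if id_cov == "full":
        k = M * (M + 1) // 2
        L = np.zeros((M, M))
        tril = np.tril_indices(M)
        vals = theta[:k].copy()
        L[tril] = vals
        # diagonal stored on the log scale for positivity
        L[np.diag_indices(M)] = np.exp(np.diag(L))
        Sigma = L @ L.T
    else:
        k = M
        Sigma = np.diag(np.exp(2.0 * theta[:k]))
    tau = float(np.exp(theta[k]))
    sigma = np.exp(theta[k + 1 :])
    return Sigma, tau, sigma


class _PatientBlocks:
    """Precomputed per-patient row partition for block marginal likelihood."""

    def __init__(self, design: DesignMatrices):
        self.design = design
        self.blocks = []
        for p in range(len(design.patient_ids)):
            rows = np.flatnonzero(design.patient_idx == p)
            met = design.met_idx[rows]
            samp = design.sample_idx[rows]
            same_sample = samp[:, None] == samp[None, :]
            self.blocks.append((rows, met, same_sample))

    def neg_marginal(self, theta, reml: bool, id_cov: str):
        d = self.design
        M = len(d.metabolites)
        Sigma, tau, sigma = _unpack_theta(theta, M, id_cov)
        p_fix = d.X.shape[1]
        XtViX = np.zeros((p_fix, p_fix))
        XtViy = np.zeros(p_fix)
        ytViy = 0.0
        logdet = 0.0
        for rows, met, same_sample in self.blocks:
            V = Sigma[np.ix_(met, met)] + tau**2 * same_sample
            V[np.diag_indices_from(V)] += sigma[met] ** 2
            try:
                c = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf, None, None
            logdet += 2.0 * float(np.sum(np.log(np.diag(c))))
            Xb = d.X[rows]
            yb = d.y[rows]
            cx = solve_triangular(c, Xb, lower=True)
            cy = solve_triangular(c, yb, lower=True)
            XtViX += cx.T @ cx
            XtViy += cx.T @ cy
            ytViy += float(cy @ cy)
        try:
            cf = np.linalg.cholesky(XtViX)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        beta = np.linalg.solve(XtViX, XtViy)
        quad = ytViy - float(beta @ XtViy)
        n = d.y.size
        nll = 0.5 * (logdet + quad + n * np.log(2.0 * np.pi))
        if reml:
            nll += float(np.sum(np.log(np.diag(cf))))  # 0.5 * logdet(X'V^-1 X)
            nll -= 0.5 * p_fix * np.log(2.0 * np.pi)
        return nll, beta, XtViX


@dataclass(frozen=True)
class FoldChangeEstimate:
    """Fold change vs the pre-surgery baseline for a typical subject."""

    metabolite: str
    contrast: str
    fold: float
    interval_50: tuple[float, float]
    interval_95: tuple[float, float]


class LongitudinalMixedModel(BaseEstimator):
    """Heteroscedastic crossed-random-effects model for longitudinal data.

    Parameters
    ----------
    pooling : {"pooled", "none"}, default="pooled"
        Collapse post-24h time points into one level (default) or keep
        all seven collection labels.
    backend : {"reml", "ml", "bayes"}, default="reml"
        Marginal REML (default) or ML via L-BFGS with profiled fixed
        effects, or ensemble MCMC over the variance parameters with
        weakly-informative priors.
    id_cov : {"full", "diagonal"}, default="full"
        Structure of the per-patient metabolite-effect covariance.  The
        full structure matches the correlated intercept-and-slope reading;
        the diagonal option is cheaper for large panels.
    reference_metabolite : str or None
        Reference level for metabolite coding (first alphabetically when
        None).  Fold changes are invariant to this choice.
    include_flagged : bool, default=True
        Keep rows whose quantification carried below-LOQ flags (column
        ``flags``, when present) rather than excluding them.
    seed : int or None
        Seed for the Bayesian backend.
    n_walkers, n_steps : int
        Ensemble-sampler size for ``backend="bayes"``.

    Attributes
    ----------
    beta_, beta_names_, beta_cov_ : fixed effects, labels, covariance.
    Sigma_ID_ : per-patient metabolite-effect covariance (M × M).
    tau_sample_ : SD of the per-sample diuresis intercept.
    sigma_met_ : dict of residual SD per metabolite.
    loglik_ : maximized marginal criterion (or mean posterior log prob).
    converged_ : bool.
    draws_ : posterior draws of fold-relevant quantities (bayes only).
    """

    def __init__(
        self,
        pooling: str = "pooled",
        backend: str = "reml",
        id_cov: str = "full",
        reference_metabolite: str | None = None,
        include_flagged: bool = True,
        seed: int | None = None,
        n_walkers: int = 32,
        n_steps: int = 1500,
    ):
        self.pooling = pooling
        self.backend = backend
        self.id_cov = id_cov
        self.reference_metabolite = reference_metabolite
        self.include_flagged = include_flagged
        self.seed = seed
        self.n_walkers = n_walkers
        self.n_steps = n_steps

    # -- fitting ------------------------------------------------------------

    def _prepare(self, data: pd.DataFrame) -> DesignMatrices:
        df = data.copy()
        if "logDV" not in df.columns:
            if "normalized_ratio" not in df.columns:
                raise ValueError("data needs a logDV or normalized_ratio column")
            if np.any(df["normalized_ratio"] <= 0):
                raise DomainError("normalized ratios must be positive to take logs")
            df["logDV"] = np.log(df["normalized_ratio"].astype(float))
        if not self.include_flagged and "flags" in df.columns:
            df = df[~df["flags"].fillna("").str.contains("below_loq")]
        return encode_design(
            df, pooling=self.pooling, reference_metabolite=self.reference_metabolite
        )

    def _start_theta(self, design: DesignMatrices) -> np.ndarray:
        # moment start: per-metabolite residual SD about the fixed OLS fit
        beta0, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        resid = design.y - design.X @ beta0
        M = len(design.metabolites)
        sig = np.array(
            [max(np.std(resid[design.met_idx == m]), 1e-2) for m in range(M)]
        )
        if self.id_cov == "full":
            theta_id = np.zeros(M * (M + 1) // 2)
            diag_pos = np.cumsum(np.arange(1, M + 1)) - 1
            theta_id[diag_pos] = np.log(0.5 * sig)
        else:
            theta_id = np.log(0.5 * sig)
        return np.concatenate([theta_id, [np.log(0.5 * np.mean(sig))], np.log(0.7 * sig)])

    def fit(self, X, y=None):
        design = self._prepare(X)
        blocks = _PatientBlocks(design)
        M = len(design.metabolites)
        reml = self.backend != "ml"
        theta0 = self._start_theta(design)

        def objective(theta):
            return blocks.neg_marginal(theta, reml=reml, id_cov=self.id_cov)[0]

        opt = optimize.minimize(
            objective, theta0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if not opt.success:
            # derivative-free polish from the gradient-based point; keep the
            # better of the two and accept if the criterion has stabilized
            polish = optimize.minimize(
                objective, opt.x, method="Nelder-Mead",
                options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
            )
            if polish.fun <= opt.fun:
                improved = opt.fun - polish.fun
                opt = polish
                opt.success = polish.success or improved < 1e-6
        nll, beta, XtViX = blocks.neg_marginal(opt.x, reml=reml, id_cov=self.id_cov)
        if not np.isfinite(nll) or beta is None:
            raise RuntimeError("marginal-likelihood optimization failed")
        Sigma, tau, sigma = _unpack_theta(opt.x, M, self.id_cov)

        self.design_ = design
        self.metabolites_ = list(design.metabolites)
        self.time_levels_ = list(design.time_levels)
        self.beta_ = beta
        self.beta_names_ = list(design.fixed_names)
        self.beta_cov_ = np.linalg.inv(XtViX)
        self.Sigma_ID_ = Sigma
        self.tau_sample_ = tau
        self.sigma_met_ = dict(zip(design.metabolites, sigma))
        self.theta_ = opt.x
        self.loglik_ = -nll
        self.converged_ = bool(opt.success)
        self.n_obs_ = design.y.size
        self.df_resid_ = design.y.size - design.X.shape[1]
        self.draws_ = None

        if self.backend == "bayes":
            self._sample_posterior(blocks, design)
        if not self.converged_:
            warnings.warn("model fit did not converge; estimates are flagged", stacklevel=2)
        return self

    def _sample_posterior(self, blocks: _PatientBlocks, design: DesignMatrices):
        """Ensemble MCMC over variance parameters; Gaussian conditional for beta.

        Priors: independent normal(0, 1) on the unconstrained (log-scale /
        log-Cholesky) variance parameters — a weakly-informative choice on
        SD scales of order one, appropriate for log-concentration data.
        """
        import emcee

        ndim = self.theta_.size

        def log_prob(theta):
            nll, _, _ = blocks.neg_marginal(theta, reml=True, id_cov=self.id_cov)
            if not np.isfinite(nll):
                return -np.inf
            return -nll - 0.5 * float(theta @ theta)

        rng = np.random.default_rng(self.seed)
        nwalkers = max(self.n_walkers, 2 * ndim + 2)
        p0 = self.theta_ + 0.05 * rng.standard_normal((nwalkers, ndim))
        sampler = emcee.EnsembleSampler(log_prob_fn=log_prob, nwalkers=nwalkers, ndim=ndim)
        state = sampler.run_mcmc(p0, self.n_steps, progress=False)
        burn = self.n_steps // 2
        chain = sampler.get_chain(discard=burn)  # (steps, walkers, ndim)
        self.rhat_ = _split_rhat(chain)
        self.converged_ = self.converged_ and bool(np.all(self.rhat_ < 1.05))

        thin = max(1, (self.n_steps - burn) // 50)
        thetas = chain[::thin].reshape(-1, ndim)
        M = len(design.metabolites)
        beta_draws = []
        for th in thetas:
            nll, beta, XtViX = blocks.neg_marginal(th, reml=True, id_cov=self.id_cov)
            if beta is None:
                continue
            cov = np.linalg.inv(XtViX)
            beta_draws.append(rng.multivariate_normal(beta, cov))
        self.draws_ = {"theta": thetas, "beta": np.array(beta_draws)}

    # -- derived quantities --------------------------------------------------

    def _contrast(self, metabolite: str, time_level: str) -> np.ndarray:
        c = np.zeros(len(self.beta_names_))
        c[self.beta_names_.index(f"TIME[{time_level}]")] = 1.0
        inter = f"MET[{metabolite}]:TIME[{time_level}]"
        if inter in self.beta_names_:
            c[self.beta_names_.index(inter)] = 1.0
        return c

    def fold_changes(self) -> list[FoldChangeEstimate]:
        """Fold change per metabolite and post-baseline time level.

        With random effects at zero ("typical subject, typical diuresis"),
        the log fold of metabolite *k* at time *t* vs baseline is the TIME
        coefficient plus the MET:TIME interaction; intervals come from the
        t-based Wald distribution of the contrast (or posterior draws for
        the Bayesian backend).  The baseline contrast is identically 1.
        """
        out = []
        have_draws = self.draws_ is not None and len(self.draws_["beta"])
        for met in self.metabolites_:
            for t in self.time_levels_[1:]:
                c = self._contrast(met, t)
                est = float(c @ self.beta_)
                if have_draws:
                    samples = self.draws_["beta"] @ c
                    q = np.quantile(samples, [0.025, 0.25, 0.75, 0.975])
                    i50 = (float(np.exp(q[1])), float(np.exp(q[2])))
                    i95 = (float(np.exp(q[0])), float(np.exp(q[3])))
                else:
                    se = float(np.sqrt(c @ self.beta_cov_ @ c))
                    t50 = stats.t.ppf(0.75, self.df_resid_)
                    t95 = stats.t.ppf(0.975, self.df_resid_)
                    i50 = (float(np.exp(est - t50 * se)), float(np.exp(est + t50 * se)))
                    i95 = (float(np.exp(est - t95 * se)), float(np.exp(est + t95 * se)))
                out.append(
                    FoldChangeEstimate(
                        metabolite=met,
                        contrast=f"{t} vs {self.time_levels_[0]}",
                        fold=float(np.exp(est)),
                        interval_50=i50,
                        interval_95=i95,
                    )
                )
        return out

    def baseline_fold(self, metabolite: str) -> float:
        """Fold change of the reference (baseline) contrast: exactly 1."""
        return 1.0


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-chain potential-scale-reduction factor per parameter."""
    steps, walkers, ndim = chain.shape
    half = steps // 2
    segs = np.concatenate([chain[:half], chain[half : 2 * half]], axis=1)  # (half, 2W, d)
    m = segs.shape[1]
    means = segs.mean(axis=0)
    variances = segs.var(axis=0, ddof=1)
    W = variances.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / W)


def forest_table(estimates: list[FoldChangeEstimate]) -> pd.DataFrame:
    """Forest-plot table of fold changes with reference-band annotation.

    Rows are ordered by metabolite then contrast; ``excludes_band`` marks
    estimates whose 95% interval lies entirely outside the 0.8–1.25 band
    (roughly a 20% change in either direction).
    """
    if not estimates:
        raise InsufficientDataError("no fold-change estimates to tabulate")
    rows = []
    for e in sorted(estimates, key=lambda e: (e.metabolite, e.contrast)):
        lo95, hi95 = e.interval_95
        rows.append(
            {
                "metabolite": e.metabolite,
                "contrast": e.contrast,
                "fold": e.fold,
                "q25": e.interval_50[0],
                "q75": e.interval_50[1],
                "q2.5": lo95,
                "q97.5": hi95,
                "band_low": REFERENCE_BAND[0],
                "band_high": REFERENCE_BAND[1],
                "excludes_band": bool(hi95 < REFERENCE_BAND[0] or lo95 > REFERENCE_BAND[1]),
            }
        )
    return pd.DataFrame(rows)
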