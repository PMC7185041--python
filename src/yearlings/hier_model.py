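"""Multispecies hierarchical model of yearling probability vs. greenness.

The age of year-unique adult individual *i* of species *j* captured at
station *k* in year *t* is a Bernoulli outcome (1 = yearling SY,
0 = older ASY) with

    logit(p_ijkt) = alpha_j + beta_j * evi_kt

where ``evi_kt`` is the centered station-year June EVI. Species intercepts
and slopes are partially pooled:

    alpha_j ~ Normal(mu_alpha, sigma_alpha)
    beta_j  ~ Normal(mu_beta,  sigma_beta)

with weakly informative hyperpriors (Normal(0, 10) on the means, Uniform(0,
10) on the standard deviations). Indeterminate (AHY) adults are unknown-age
outcomes: under this likelihood they are uninformative and are excluded from
the likelihood sum, which is exactly the missing-at-random treatment; an
optional post-hoc imputation draws their latent ages for reporting.

Sampling is by Metropolis-within-Gibbs: a joint random-walk update of each
species' (alpha_j, beta_j) pair — vectorised across species, which are
conditionally independent given the hyperparameters — a conjugate normal
update for each hypermean, and a bounded shrinkage slice update for each
hyper-standard-deviation. Because per-species slopes are only weakly
identified (the EVI covariate varies little within a species), the centered
Gibbs scheme alone mixes the hyperparameters poorly; interweaved
ancillarity-sufficiency moves — a translation that shifts a hypermean and
all its species effects together, and a scale move that expands a
hyper-standard-deviation and the effects' deviations around their mean —
restore mixing. Proposal scales adapt during warmup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .evi_habitat import StandardizedFit, center_covariate, standardized_ols

logger = logging.getLogger(__name__)

HYPER_NAMES = ("mu_alpha", "mu_beta", "sigma_alpha", "sigma_beta")


@dataclass
class Priors:
    """Hyperprior settings: Normal(0, mu_sd) on the hypermeans and
    Uniform(0, sigma_upper) on the hyper-standard-deviations."""

    mu_sd: float = 10.0
    sigma_upper: float = 10.0


@dataclass
class ModelData:
    """Design arrays for the hierarchical model.

    ``y`` is float with NaN marking unknown-age (AHY) adults — missing is
    never coded as 0. ``evi`` is the centered covariate per individual.
    """

    y: np.ndarray
    species_idx: np.ndarray
    evi: np.ndarray
    species_codes: list[str]
    evi_center: float
    station_ids: np.ndarray | None = None
    years: np.ndarray | None = None
    n_dropped_no_covariate: int = 0

    @property
    def n_species(self) -> int:
        return len(self.species_codes)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    def without_missing(self) -> "ModelData":
        """Copy restricted to rows with an observed (SY/ASY) outcome."""
        m = self.observed
        return ModelData(
            y=self.y[m], species_idx=self.species_idx[m], evi=self.evi[m],
            species_codes=list(self.species_codes),
            evi_center=self.evi_center,
            station_ids=None if self.station_ids is None
            else self.station_ids[m],
            years=None if self.years is None else self.years[m],
        )


def build_model_data(individuals: pd.DataFrame,
                     station_year_evi: pd.DataFrame,
                     target_species: list[str] | None = None) -> ModelData:
    """Join year-unique individuals to their station-year covariate.

    Outcomes are coded 1 for SY, 0 for ASY, NaN for AHY. The covariate is
    centered here (over the individuals entering the model, so the design
    column has mean zero by construction). Individuals whose station-year
    has no EVI value are dropped with a logged count.
    """
    df = individuals
    if target_species is not None:
        df = df[df["species_code"].isin(set(target_species))]
    merged = df.merge(station_year_evi[["station_id", "year", "evi"]],
                      on=["station_id", "year"], how="left")
    no_cov = merged["evi"].isna()
    if no_cov.any():
        logger.warning("dropping %d individual(s) with no station-year EVI",
                       int(no_cov.sum()))
    merged = merged.loc[~no_cov].reset_index(drop=True)

    codes = sorted(merged["species_code"].unique())
    code_idx = {c: i for i, c in enumerate(codes)}
    y = merged["resolved_age"].map({"SY": 1.0, "ASY": 0.0}).to_numpy(float)
    evi_centered, center = center_covariate(merged["evi"].to_numpy(float))
    return ModelData(
        y=y,
        species_idx=merged["species_code"].map(code_idx).to_numpy(np.int64),
        evi=evi_centered,
        species_codes=codes,
        evi_center=center,
        station_ids=merged["station_id"].to_numpy(),
        years=merged["year"].to_numpy(np.int64),
        n_dropped_no_covariate=int(no_cov.sum()),
    )


def predict_yearling_prob(alpha, beta, evi):
    """P(yearling) = logistic(alpha + beta * centered EVI)."""
    return expit(np.asarray(alpha) + np.asarray(beta) * np.asarray(evi))


def log_unnormalized_posterior(data: ModelData, mu_alpha: float,
                               mu_beta: float, sigma_alpha: float,
                               sigma_beta: float, alpha, beta,
                               priors: Priors | None = None) -> float:
    """Joint log density up to a constant.

    Bernoulli log-likelihood over observed outcomes only (unknown-age rows
    contribute nothing), plus normal log densities of the species effects
    given the hyperparameters, plus the hyperpriors. Returns ``-inf`` for
    any non-finite parameter or a sigma outside its support.
    """
    priors = priors or Priors()
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    params = np.concatenate([[mu_alpha, mu_beta, sigma_alpha, sigma_beta],
                             alpha, beta])
    if not np.all(np.isfinite(params)):
        return -np.inf
    if not (0 < sigma_alpha <= priors.sigma_upper
            and 0 < sigma_beta <= priors.sigma_upper):
        return -np.inf

    m = data.observed
    sp = data.species_idx[m]
    eta = alpha[sp] + beta[sp] * data.evi[m]
    # log Bernoulli(y | logistic(eta)) = y*eta - log(1 + exp(eta))
    loglik = float(np.sum(data.y[m] * eta) - np.sum(np.logaddexp(0.0, eta)))

    def _normal(x, mu, sd):
        x = np.asarray(x, dtype=float)
        return float(np.sum(-0.5 * ((x - mu) / sd) ** 2 - np.log(sd)
                            - 0.5 * np.log(2 * np.pi)))

    logprior = (_normal(alpha, mu_alpha, sigma_alpha)
                + _normal(beta, mu_beta, sigma_beta)
                + _normal([mu_alpha, mu_beta], 0.0, priors.mu_sd))
    # Uniform(0, upper) sigma hyperpriors contribute a constant
    return loglik + logprior


@dataclass
class Posterior:
    """MCMC draws and metadata.

    ``draws`` maps each hyperparameter name to a (chains, draws) array and
    ``alpha``/``beta`` to (chains, draws, J) arrays.
    """

    draws: dict
    species_codes: list[str]
    seed: int
    warnings: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    _summary: pd.DataFrame | None = None

    def to_arviz(self):
        import arviz as az
        return az.from_dict(posterior=self.draws)

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior mean, 95% credible interval, potential
        scale reduction (rhat) and bulk effective sample size."""
        if self._summary is not None:
            return self._summary
        import arviz as az
        idata = self.to_arviz()
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        rows = []

        def _one(name, arr, rh, es, label=None):
            lo, hi = np.quantile(arr, [0.025, 0.975])
            rows.append({"parameter": label or name,
                         "mean": float(arr.mean()),
                         "sd": float(arr.std(ddof=1)),
                         "ci_2.5": float(lo), "ci_97.5": float(hi),
                         "rhat": float(rh), "ess_bulk": float(es)})

        for name in HYPER_NAMES:
            _one(name, self.draws[name], rhat[name].values,
                 ess[name].values)
        for vec in ("alpha", "beta"):
            for j, code in enumerate(self.species_codes):
                _one(vec, self.draws[vec][:, :, j],
                     rhat[vec].values[j], ess[vec].values[j],
                     label=f"{vec}[{code}]")
        self._summary = pd.DataFrame(rows)
        return self._summary

    def hyper_interval(self, name: str, level: float = 0.95):
        """Equal-tailed credible interval for a hyperparameter."""
        a = (1 - level) / 2
        lo, hi = np.quantile(self.draws[name], [a, 1 - a])
        return float(lo), float(hi)

    def beta_point_estimates(self) -> pd.Series:
        """Posterior-mean EVI coefficient per species."""
        means = self.draws["beta"].mean(axis=(0, 1))
        return pd.Series(means, index=self.species_codes, name="beta_mean")

    def draws_frame(self) -> pd.DataFrame:
        """Long table: chain, draw, parameter, value — one row per draw of
        every monitored parameter."""
        frames = []
        for name in HYPER_NAMES:
            arr = self.draws[name]
            c, d = np.meshgrid(np.arange(arr.shape[0]),
                               np.arange(arr.shape[1]), indexing="ij")
            frames.append(pd.DataFrame({
                "chain": c.ravel(), "draw": d.ravel(),
                "parameter": name, "value": arr.ravel()}))
        for vec in ("alpha", "beta"):
            arr = self.draws[vec]
            for j, code in enumerate(self.species_codes):
                sub = arr[:, :, j]
                c, d = np.meshgrid(np.arange(sub.shape[0]),
                                   np.arange(sub.shape[1]), indexing="ij")
                frames.append(pd.DataFrame({
                    "chain": c.ravel(), "draw": d.ravel(),
                    "parameter": f"{vec}[{code}]", "value": sub.ravel()}))
        return pd.concat(frames, ignore_index=True)


def _species_loglik(alpha, beta, sp, y, evi, J):
    """Bernoulli log-likelihood summed within species (length-J vector)."""
    eta = alpha[sp] + beta[sp] * evi
    ll = y * eta - np.logaddexp(0.0, eta)
    return np.bincount(sp, weights=ll, minlength=J)


def _slice_sigma(rng, current, ss, n, upper):
    """Slice-sample sigma from p(sigma) ~ sigma^-n exp(-ss / (2 sigma^2)) on
    (0, upper), by shrinkage from the fixed bounded interval."""

    def logf(s):
        return -n * np.log(s) - ss / (2.0 * s * s)

    y = logf(current) - rng.exponential(1.0)
    lo, hi = 1e-12, upper
    for _ in range(200):
        prop = rng.uniform(lo, hi)
        if logf(prop) >= y:
            return prop
        if prop < current:
            lo = prop
        else:
            hi = prop
    return current  # pragma: no cover - shrinkage always terminates fast


def fit(data: ModelData, chains: int = 3, iterations: int = 2000,
        warmup: int = 2000, seed: int = 0, priors: Priors | None = None,
        target_accept: float = 0.35, adapt_window: int = 50,
        rhat_threshold: float = 1.1, ess_threshold: float = 400.0,
        fixed_hypers: dict | None = None) -> Posterior:
    """Fit the hierarchical model by MCMC.

    Parameters
    ----------
    chains, iterations, warmup
        Number of chains and post-warmup draws per chain; warmup draws are
        used for proposal adaptation and discarded.
    seed
        Base seed; chain c uses an independent child stream, so a run is
        reproducible end to end.
    fixed_hypers
        Optional mapping holding any of ``mu_alpha, mu_beta, sigma_alpha,
        sigma_beta`` to clamp (e.g. wide fixed priors for a single-species
        fit, or ``sigma_beta`` near zero to force complete pooling of
        slopes). Clamped hyperparameters are not updated.

    Returns a :class:`Posterior`; convergence problems (rhat above
    ``rhat_threshold`` or bulk ESS below ``ess_threshold`` on any monitored
    parameter) are reported as warnings on the result, never silently
    dropped.
    """
    priors = priors or Priors()
    fixed_hypers = fixed_hypers or {}
    J = data.n_species
    m = data.observed
    sp = data.species_idx[m]
    y = data.y[m]
    evi = data.evi[m]
    if J < 1 or y.size == 0:
        raise ValueError("model needs at least one species with observed "
                         "outcomes")

    counts_obs = np.bincount(sp, minlength=J)
    sy_counts = np.bincount(sp, weights=y, minlength=J)
    one_class = (sy_counts == 0) | (sy_counts == counts_obs) | (counts_obs == 0)
    warnings: list[str] = []
    if one_class.any():
        which = [data.species_codes[j] for j in np.flatnonzero(one_class)]
        warnings.append("species with a single observed outcome class "
                        f"(pooled estimates only): {which}")

    # data-informed start: empirical logit with a half-count shrink
    p0 = (sy_counts + 0.5) / (counts_obs + 1.0)
    alpha_start = np.log(p0 / (1 - p0))
    evi_scale = max(float(np.std(evi)), 1e-3)

    n_keep = iterations
    hyper_draws = {k: np.empty((chains, n_keep)) for k in HYPER_NAMES}
    alpha_draws = np.empty((chains, n_keep, J))
    beta_draws = np.empty((chains, n_keep, J))

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)

    for c in range(chains):
        rng = np.random.default_rng(chain_seeds[c])
        alpha = alpha_start + 0.5 * rng.standard_normal(J)
        beta = 0.5 * rng.standard_normal(J) / evi_scale * 0.2
        mu_a = fixed_hypers.get("mu_alpha",
                                float(alpha.mean() + 0.3 * rng.standard_normal()))
        mu_b = fixed_hypers.get("mu_beta", float(0.3 * rng.standard_normal()))
        sig_a = float(fixed_hypers.get("sigma_alpha", rng.uniform(0.3, 1.0)))
        sig_b = float(fixed_hypers.get("sigma_beta", rng.uniform(0.3, 1.0)))

        step = np.full(J, 0.4)
        base_a, base_b = 1.0, 1.0 / evi_scale
        acc = np.zeros(J)
        # interweaved moves: [alpha-translate, beta-translate,
        #                     alpha-scale, beta-scale]
        istep = np.array([0.2, 0.2 / evi_scale, 0.3, 0.3])
        iacc = np.zeros(4)
        ll = _species_loglik(alpha, beta, sp, y, evi, J)

        def total_ll(a, b):
            return float(_species_loglik(a, b, sp, y, evi, J).sum())

        for it in range(warmup + n_keep):
            # --- joint RW Metropolis update of (alpha_j, beta_j), all j ---
            prop_a = alpha + step * base_a * rng.standard_normal(J)
            prop_b = beta + step * base_b * rng.standard_normal(J)
            ll_prop = _species_loglik(prop_a, prop_b, sp, y, evi, J)
            logr = (ll_prop - ll
                    - 0.5 * ((prop_a - mu_a) ** 2 - (alpha - mu_a) ** 2)
                    / sig_a ** 2
                    - 0.5 * ((prop_b - mu_b) ** 2 - (beta - mu_b) ** 2)
                    / sig_b ** 2)
            accept = np.log(rng.random(J)) < logr
            alpha = np.where(accept, prop_a, alpha)
            beta = np.where(accept, prop_b, beta)
            ll = np.where(accept, ll_prop, ll)
            acc += accept

            # --- interweaved translation moves (hypermean + all effects) ---
            if "mu_alpha" not in fixed_hypers:
                delta = istep[0] * rng.standard_normal()
                lp = total_ll(alpha + delta, beta)
                logr = (lp - ll.sum()
                        - ((mu_a + delta) ** 2 - mu_a ** 2)
                        / (2 * priors.mu_sd ** 2))
                if np.log(rng.random()) < logr:
                    alpha = alpha + delta
                    mu_a += delta
                    ll = _species_loglik(alpha, beta, sp, y, evi, J)
                    iacc[0] += 1
            if "mu_beta" not in fixed_hypers:
                delta = istep[1] * rng.standard_normal()
                lp = total_ll(alpha, beta + delta)
                logr = (lp - ll.sum()
                        - ((mu_b + delta) ** 2 - mu_b ** 2)
                        / (2 * priors.mu_sd ** 2))
                if np.log(rng.random()) < logr:
                    beta = beta + delta
                    mu_b += delta
                    ll = _species_loglik(alpha, beta, sp, y, evi, J)
                    iacc[1] += 1

            # --- interweaved scale moves (hyper-sd + effect deviations) ---
            if "sigma_alpha" not in fixed_hypers:
                fac = np.exp(istep[2] * rng.standard_normal())
                if 0 < fac * sig_a <= priors.sigma_upper:
                    prop = mu_a + fac * (alpha - mu_a)
                    lp = total_ll(prop, beta)
                    if np.log(rng.random()) < lp - ll.sum() + np.log(fac):
                        alpha = prop
                        sig_a *= fac
                        ll = _species_loglik(alpha, beta, sp, y, evi, J)
                        iacc[2] += 1
            if "sigma_beta" not in fixed_hypers:
                fac = np.exp(istep[3] * rng.standard_normal())
                if 0 < fac * sig_b <= priors.sigma_upper:
                    prop = mu_b + fac * (beta - mu_b)
                    lp = total_ll(alpha, prop)
                    if np.log(rng.random()) < lp - ll.sum() + np.log(fac):
                        beta = prop
                        sig_b *= fac
                        ll = _species_loglik(alpha, beta, sp, y, evi, J)
                        iacc[3] += 1

            if it < warmup and (it + 1) % adapt_window == 0:
                rate = acc / adapt_window
                step *= np.exp(np.clip(rate - target_accept, -0.5, 0.5))
                acc[:] = 0.0
                irate = iacc / adapt_window
                istep *= np.exp(np.clip(irate - 0.44, -0.5, 0.5))
                iacc[:] = 0.0

            # --- hypermeans: conjugate normal updates ---
            if "mu_alpha" not in fixed_hypers:
                prec = J / sig_a ** 2 + 1.0 / priors.mu_sd ** 2
                mean = (alpha.sum() / sig_a ** 2) / prec
                mu_a = mean + rng.standard_normal() / np.sqrt(prec)
            if "mu_beta" not in fixed_hypers:
                prec = J / sig_b ** 2 + 1.0 / priors.mu_sd ** 2
                mean = (beta.sum() / sig_b ** 2) / prec
                mu_b = mean + rng.standard_normal() / np.sqrt(prec)

            # --- hyper-sds: bounded slice updates ---
            if "sigma_alpha" not in fixed_hypers:
                sig_a = _slice_sigma(rng, sig_a,
                                     float(((alpha - mu_a) ** 2).sum()), J,
                                     priors.sigma_upper)
            if "sigma_beta" not in fixed_hypers:
                sig_b = _slice_sigma(rng, sig_b,
                                     float(((beta - mu_b) ** 2).sum()), J,
                                     priors.sigma_upper)

            if it >= warmup:
                k = it - warmup
                hyper_draws["mu_alpha"][c, k] = mu_a
                hyper_draws["mu_beta"][c, k] = mu_b
                hyper_draws["sigma_alpha"][c, k] = sig_a
                hyper_draws["sigma_beta"][c, k] = sig_b
                alpha_draws[c, k] = alpha
                beta_draws[c, k] = beta

    draws = dict(hyper_draws)
    draws["alpha"] = alpha_draws
    draws["beta"] = beta_draws
    post = Posterior(draws=draws, species_codes=list(data.species_codes),
                     seed=seed, warnings=warnings,
                     config={"chains": chains, "iterations": iterations,
                             "warmup": warmup,
                             "fixed_hypers": dict(fixed_hypers)})

    monitored = [k for k in HYPER_NAMES if k not in fixed_hypers]
    if chains > 1:
        summ = post.summary()
        free = summ[summ["parameter"].isin(monitored)
                    | summ["parameter"].str.startswith(("alpha[", "beta["))]
        bad_rhat = free[free["rhat"] > rhat_threshold]
        bad_ess = free[free["ess_bulk"] < ess_threshold]
        if not bad_rhat.empty:
            msg = ("convergence warning: rhat > "
                   f"{rhat_threshold} for {list(bad_rhat['parameter'])}")
            warnings.append(msg)
            logger.warning(msg)
        if not bad_ess.empty:
            msg = ("convergence warning: bulk ESS < "
                   f"{ess_threshold:g} for {list(bad_ess['parameter'])}")
            warnings.append(msg)
            logger.warning(msg)
    return post


def impute_ahy(posterior: Posterior, data: ModelData,
               rng: np.random.Generator) -> pd.DataFrame:
    """Post-hoc latent ages for unknown-age (AHY) rows, for reporting only.

    For each missing outcome, the posterior yearling probability is averaged
    over the draws and one Bernoulli imputation is sampled from it. The
    likelihood never sees these values.
    """
    miss = ~posterior_mask(data)
    sp = data.species_idx[miss]
    evi = data.evi[miss]
    a = posterior.draws["alpha"].reshape(-1, len(posterior.species_codes))
    b = posterior.draws["beta"].reshape(-1, len(posterior.species_codes))
    p = expit(a[:, sp] + b[:, sp] * evi).mean(axis=0)
    return pd.DataFrame({
        "species_code": [data.species_codes[j] for j in sp],
        "p_yearling": p,
        "imputed_SY": (rng.random(p.size) < p).astype(int),
    })


def posterior_mask(data: ModelData) -> np.ndarray:
    return data.observed


def species_evi_profiles(individuals: pd.DataFrame,
                         station_year_evi: pd.DataFrame) -> pd.DataFrame:
    """Capture-weighted EVI use per species, with habitat-quartile groups.

    Each adult year-unique individual contributes its station-year (raw,
    uncentered) EVI; a species' ``evi_mean`` is the mean over its
    individuals and ``evi_range`` the max minus min of those values. Species
    are grouped by sample quartiles (linear interpolation) of the J species
    means: lowest quartile = successional, middle two = intermediate, top
    quartile = mature forest; a species exactly on a boundary goes to the
    lower group.
    """
    merged = individuals.merge(station_year_evi[["station_id", "year", "evi"]],
                               on=["station_id", "year"], how="inner")
    if merged.empty:
        raise ValueError("no individual has a station-year EVI value")
    g = merged.groupby("species_code")["evi"]
    prof = pd.DataFrame({
        "evi_mean": g.mean(),
        "evi_range": g.max() - g.min(),
        "n_captures": g.size(),
    }).reset_index()
    q25, q75 = np.quantile(prof["evi_mean"], [0.25, 0.75])
    group = np.where(prof["evi_mean"] <= q25, "successional",
                     np.where(prof["evi_mean"] <= q75, "intermediate",
                              "mature"))
    prof["habitat_group"] = group
    return prof.sort_values("species_code").reset_index(drop=True)


GROUP_ORDER = ("successional", "intermediate", "mature")


def group_coefficient_summary(posterior: Posterior,
                              profiles: pd.DataFrame) -> pd.DataFrame:
    """Posterior mean and 95% CI of the mean EVI coefficient within each
    habitat group: for every draw, average beta_j over the group's member
    species, then summarise across draws."""
    code_idx = {c: j for j, c in enumerate(posterior.species_codes)}
    beta = posterior.draws["beta"].reshape(-1, len(posterior.species_codes))
    rows = []
    for grp in GROUP_ORDER:
        members = profiles.loc[profiles["habitat_group"] == grp,
                               "species_code"]
        idx = [code_idx[c] for c in members if c in code_idx]
        if not idx:
            logger.warning("habitat group %r is empty", grp)
            rows.append({"habitat_group": grp, "n_species": 0,
                         "mean": np.nan, "ci_2.5": np.nan,
                         "ci_97.5": np.nan})
            continue
        gm = beta[:, idx].mean(axis=1)
        lo, hi = np.quantile(gm, [0.025, 0.975])
        rows.append({"habitat_group": grp, "n_species": len(idx),
                     "mean": float(gm.mean()), "ci_2.5": float(lo),
                     "ci_97.5": float(hi)})
    return pd.DataFrame(rows)


def coefficient_meta_regression(beta_point: pd.Series,
                                profiles: pd.DataFrame) -> StandardizedFit:
    """OLS of per-species EVI-coefficient point estimates on the species'
    EVI mean and EVI range (standardized coefficients, 95% CIs, R^2).

    Posterior means are used as point responses; posterior uncertainty in
    the coefficients is not propagated.
    """
    prof = profiles.set_index("species_code").loc[beta_point.index]
    if len(prof) < 4:
        raise ValueError("meta-regression needs at least 4 species")
    X = prof[["evi_mean", "evi_range"]]
    return standardized_ols(beta_point.to_numpy(), X)
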