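"""Independent reference implementations used to check the model module.

Everything here is deliberately written as plain scalar Python (math module,
explicit loops) so it shares no code path with the vectorised package
implementation it checks.
"""

import math


def scalar_log_posterior(y, species_idx, evi, mu_alpha, mu_beta,
                         sigma_alpha, sigma_beta, alpha, beta,
                         mu_sd=10.0):
    """Scalar-sum log unnormalized posterior for the hierarchical
    Bernoulli/logit model; missing outcomes (None/NaN) contribute
    nothing."""
    total = 0.0
    for yi, j, x in zip(y, species_idx, evi):
        if yi is None or (isinstance(yi, float) and math.isnan(yi)):
            continue
        eta = alpha[j] + beta[j] * x
        p = 1.0 / (1.0 + math.exp(-eta))
        total += math.log(p) if yi == 1 else math.log(1.0 - p)
    for j in range(len(alpha)):
        total += _norm_logpdf(alpha[j], mu_alpha, sigma_alpha)
        total += _norm_logpdf(beta[j], mu_beta, sigma_beta)
    total += _norm_logpdf(mu_alpha, 0.0, mu_sd)
    total += _norm_logpdf(mu_beta, 0.0, mu_sd)
    return total


def _norm_logpdf(x, mu, sd):
    return (-0.5 * ((x - mu) / sd) ** 2 - math.log(sd)
            - 0.5 * math.log(2.0 * math.pi))


def grid_search_mode(y, evi, mu_alpha, mu_beta, sigma_alpha, sigma_beta,
                     alpha_grid, beta_grid):
    """Brute-force argmax of the single-species unnormalized posterior over
    an (alpha, beta) lattice."""
    best = (None, None, -math.inf)
    for a in alpha_grid:
        for b in beta_grid:
            lp = scalar_log_posterior(y, [0] * len(y), evi, mu_alpha,
                                      mu_beta, sigma_alpha, sigma_beta,
                                      [a], [b])
            if lp > best[2]:
                best = (a, b, lp)
    return best
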