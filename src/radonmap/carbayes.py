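"""Bayesian hierarchical spatial Poisson regression (BYM convolution model).

Region counts O_i are modelled as

    O_i ~ Poisson(E_i * exp(alpha + x_i' beta + u_i + v_i))

with E_i the expected count from indirect standardization (offset), u an
intrinsic CAR (Besag) spatially structured effect on the region adjacency
graph, and v iid normal unstructured heterogeneity. The radon covariate is
scaled so that exp(beta) is the relative risk per 10 Bq/m^3. Coefficients get
flat normal priors (zero mean, very large variance); the ICAR and
unstructured precisions get Gamma(0.5, 0.0005) hyperpriors, a conventional
weakly-informative choice for disease mapping, exposed in the spec.

Inference is Metropolis-within-Gibbs: adaptive random-walk Metropolis for
alpha and beta, single-site Metropolis for u and v (u sites updated in
graph-colouring blocks, which is equivalent to a site-by-site scan because
no two sites in a block are neighbours), conjugate Gibbs draws for the two
precisions, and a sum-to-zero recentring of u (absorbed into alpha) after
every sweep. Convergence is monitored with the Gelman-Rubin statistic over
parallel chains started from over-dispersed, chain-indexed initial values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import gammaln

logger = logging.getLogger(__name__)


def quintile_groups(z) -> np.ndarray:
    """Assign values to quintiles 1..5 by rank.

    Group = floor(5 * rank / n) + 1 with ranks from a stable sort, so ties
    are broken by input order and group sizes differ by at most one (234
    values give sizes 47/47/47/47/46).
    """
    z = np.asarray(z, float)
    n = z.size
    order = np.argsort(z, kind="stable")
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    return (5 * rank) // n + 1


def build_design(
    region_radon, covariates: pd.DataFrame, sex: str = "male", adjusted: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the ecological regression.

    The radon column is concentration / 10, so exp(beta) is the relative
    risk per 10 Bq/m^3. ``adjusted=True`` adds the sex-specific smoking rate
    (centred) and indicator columns for deprivation quintiles 2-5 (quintile 1
    is the reference); ``adjusted=False`` is the crude, radon-only model.
    All-zero indicator columns (degenerate quintile assignments) are dropped
    with a warning; remaining rank deficiency is an error.
    """
    radon = np.asarray(region_radon, float)
    if len(covariates) != radon.size:
        raise ValueError("need exactly one covariate row per region")
    cols = [radon / 10.0]
    names = ["radon_per10"]
    if adjusted:
        smoke_col = f"smoking_{sex}"
        if smoke_col not in covariates:
            raise ValueError(f"covariates lack column {smoke_col!r}")
        smoke = covariates[smoke_col].to_numpy(float)
        cols.append(smoke - smoke.mean())
        names.append("smoking_centered")
        q = quintile_groups(covariates["deprivation_z"].to_numpy(float))
        for level in (2, 3, 4, 5):
            ind = (q == level).astype(float)
            if ind.sum() == 0:
                logger.warning(
                    "deprivation quintile %d is empty; dropping its indicator", level
                )
                continue
            cols.append(ind)
            names.append(f"di_q{level}")
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"design matrix is rank deficient; columns: {names}")
    return x, names


@dataclass
class CARModelSpec:
    """Data, design and priors for one BYM model fit."""

    observed: np.ndarray
    expected: np.ndarray
    design: np.ndarray
    colnames: list
    region_ids: list
    adjacency: frozenset
    beta_prior_sd: float = 1000.0  # Normal(0, 1e6) on alpha and each beta
    tau_shape: float = 0.5
    tau_rate: float = 0.0005
    include_u: bool = True
    include_v: bool = True
    alpha_prior: str = "normal"  # or "flat_exp": flat prior on exp(alpha)

    def __post_init__(self):
        self.observed = np.asarray(self.observed, float)
        self.expected = np.asarray(self.expected, float)
        self.design = np.asarray(self.design, float).reshape(len(self.observed), -1)
        n = len(self.observed)
        if len(self.expected) != n or len(self.region_ids) != n:
            raise ValueError("observed, expected and region_ids must align")
        if np.any(self.expected <= 0):
            raise ValueError("expected counts must be strictly positive")
        if np.any(self.observed < 0):
            raise ValueError("observed counts must be nonnegative")
        p = self.design.shape[1]
        if p and np.linalg.matrix_rank(self.design) < p:
            raise ValueError("design matrix is rank deficient")
        if self.alpha_prior not in ("normal", "flat_exp"):
            raise ValueError(f"unknown alpha prior {self.alpha_prior!r}")
        if self.include_u and n > 1:
            g = nx.Graph()
            g.add_nodes_from(self.region_ids)
            g.add_edges_from(self.adjacency)
            if not nx.is_connected(g):
                raise ValueError("CAR adjacency graph must be connected")

    @property
    def n_regions(self) -> int:
        return len(self.observed)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (i, j) of each unordered adjacency pair once."""
        pos = {rid: k for k, rid in enumerate(self.region_ids)}
        if not self.adjacency:
            return np.empty(0, int), np.empty(0, int)
        ei, ej = zip(*[(pos[a], pos[b]) for a, b in self.adjacency])
        return np.asarray(ei), np.asarray(ej)


@dataclass
class MCMCConfig:
    """Sampler settings; defaults follow the study protocol.

    Five parallel chains of 20,000 iterations, the first 5,000 discarded as
    burn-in, keeping every 5th draw. Step sizes adapt (Robbins-Monro towards
    0.44 acceptance) during burn-in only.
    """

    n_chains: int = 5
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0
    target_accept: float = 0.44
    adapt_decay: float = 0.6

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_kept(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class ChainState:
    """Full parameter state of one chain."""

    alpha: float
    beta: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau_u: float
    tau_v: float


@dataclass
class MCMCSamples:
    """Thinned post-burn-in draws from all chains.

    ``draws`` maps parameter name -> array of shape (n_chains, n_kept).
    """

    draws: dict
    colnames: list
    acceptance: dict = field(default_factory=dict)

    @property
    def parameters(self) -> list:
        return list(self.draws)

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()


def log_posterior(state: ChainState, spec: CARModelSpec) -> float:
    """Unnormalised log posterior density; -inf for invalid states."""
    o, e, x = spec.observed, spec.expected, spec.design
    eta = state.alpha + (x @ state.beta if x.shape[1] else 0.0)
    if spec.include_u:
        eta = eta + state.u
    if spec.include_v:
        eta = eta + state.v
    if not np.all(np.isfinite(eta)):
        return -np.inf
    with np.errstate(over="ignore"):
        mean = e * np.exp(eta)
    if not np.all(np.isfinite(mean)):
        return -np.inf
    lp = float(np.sum(o * (np.log(e) + eta) - mean - gammaln(o + 1)))

    s2 = spec.beta_prior_sd**2
    if spec.alpha_prior == "normal":
        lp -= state.alpha**2 / (2 * s2)
    else:  # flat on exp(alpha): p(alpha) propto exp(alpha)
        lp += state.alpha
    lp -= float(np.sum(state.beta**2)) / (2 * s2)

    n = spec.n_regions
    if spec.include_u:
        if state.tau_u <= 0:
            return -np.inf
        ei, ej = spec.edge_arrays()
        ss = float(np.sum((state.u[ei] - state.u[ej]) ** 2))
        lp += (n - 1) / 2 * np.log(state.tau_u) - state.tau_u / 2 * ss
        lp += (spec.tau_shape - 1) * np.log(state.tau_u) - spec.tau_rate * state.tau_u
    if spec.include_v:
        if state.tau_v <= 0:
            return -np.inf
        lp += n / 2 * np.log(state.tau_v) - state.tau_v / 2 * float(np.sum(state.v**2))
        lp += (spec.tau_shape - 1) * np.log(state.tau_v) - spec.tau_rate * state.tau_v
    return lp


def _color_classes(spec: CARModelSpec) -> list[np.ndarray]:
    """Greedy graph colouring: index blocks of mutually non-adjacent regions."""
    g = nx.Graph()
    g.add_nodes_from(range(spec.n_regions))
    ei, ej = spec.edge_arrays()
    g.add_edges_from(zip(ei.tolist(), ej.tolist()))
    coloring = nx.greedy_color(g, strategy="largest_first")
    classes: dict[int, list[int]] = {}
    for node, color in coloring.items():
        classes.setdefault(color, []).append(node)
    return [np.asarray(sorted(v)) for _, v in sorted(classes.items())]


def _run_chain(spec: CARModelSpec, config: MCMCConfig, rng, chain_index: int):
    o, e = spec.observed, spec.expected
    n, p = spec.n_regions, spec.design.shape[1]
    s2 = spec.beta_prior_sd**2
    # sample in a column-centred parameterisation: the raw intercept and the
    # coefficients are near-collinear when covariates have a large mean, which
    # stalls random-walk updates. Recorded alpha is shifted back, beta draws
    # are unaffected.
    x_mean = spec.design.mean(axis=0) if p else np.empty(0)
    x = spec.design - x_mean

    # over-dispersed chain-indexed starts
    m = config.n_chains
    offset = (chain_index - (m - 1) / 2) / max(m - 1, 1) if m > 1 else 0.0
    alpha = float(np.log(max(o.sum(), 0.5) / e.sum())) + offset
    beta = np.full(p, 0.2 * offset)
    u = np.zeros(n)
    v = np.zeros(n)
    tau_u = tau_v = spec.tau_shape / spec.tau_rate  # prior mean precision

    state0 = ChainState(alpha, beta.copy(), u, v, tau_u, tau_v)
    if not np.isfinite(log_posterior(state0, spec)):
        raise RuntimeError("non-finite log posterior at chain initialisation")

    ei, ej = spec.edge_arrays()
    if spec.include_u:
        w = sparse.csr_matrix(
            (np.ones(2 * len(ei)), (np.r_[ei, ej], np.r_[ej, ei])), shape=(n, n)
        )
        deg = np.asarray(w.sum(axis=1)).ravel()
        classes = _color_classes(spec)
        w_rows = [w[cls] for cls in classes]

    eta = alpha + (x @ beta if p else 0.0) + u + v
    eexp = e * np.exp(eta)
    ox = o @ x if p else np.empty(0)
    o_sum = o.sum()
    if spec.include_u and p:
        # edge-difference pieces of the interchange move (beta_j, u) ->
        # (beta_j + d, u - d x_j): likelihood-invariant, accepted on the
        # ICAR prior ratio alone; decorrelates beta from the spatial field
        dx_edges = x[ei] - x[ej]
        xss_edges = (dx_edges**2).sum(axis=0)

    ls_alpha = np.log(0.1)
    ls_beta = np.full(p, np.log(0.1))
    ls_swap = np.full(p, np.log(0.05))
    ls_vswap = np.full(p, np.log(0.05))
    ls_u = np.full(n, np.log(0.5))
    ls_v = np.full(n, np.log(0.5))
    acc_counts = {"alpha": 0, "beta": np.zeros(p), "u": 0.0, "v": 0.0}
    n_track = 0

    n_kept = config.n_kept
    names = ["alpha", *spec.colnames, "tau_u", "tau_v"]
    out = {name: np.empty(n_kept) for name in names}
    kept = 0

    for it in range(config.n_iter):
        adapting = it < config.burn_in
        gam = (it + 1) ** (-config.adapt_decay)

        # --- alpha: random-walk Metropolis on the cached total E*exp(eta)
        d = np.exp(ls_alpha) * rng.standard_normal()
        sum_eexp = eexp.sum()
        dlp = o_sum * d - (np.expm1(d)) * sum_eexp
        if spec.alpha_prior == "normal":
            dlp -= ((alpha + d) ** 2 - alpha**2) / (2 * s2)
        else:
            dlp += d
        acc = np.log(rng.uniform()) < dlp
        if acc:
            alpha += d
            eta += d
            eexp *= np.exp(d)
        if adapting:
            ls_alpha += gam * (acc - config.target_accept)
        elif not adapting:
            acc_counts["alpha"] += acc

        # --- beta: componentwise random-walk Metropolis
        for j in range(p):
            d = np.exp(ls_beta[j]) * rng.standard_normal()
            eta_new = eta + d * x[:, j]
            with np.errstate(over="ignore"):
                eexp_new = e * np.exp(eta_new)
            dlp = d * ox[j] - (eexp_new.sum() - eexp.sum())
            dlp -= ((beta[j] + d) ** 2 - beta[j] ** 2) / (2 * s2)
            if np.isfinite(dlp) and np.log(rng.uniform()) < dlp:
                beta[j] += d
                eta = eta_new
                eexp = eexp_new
                acc = True
            else:
                acc = False
            if adapting:
                ls_beta[j] += gam * (acc - config.target_accept)
            else:
                acc_counts["beta"][j] += acc

            if spec.include_u:
                # interchange move: beta_j and the spatial field trade a
                # multiple of the centred covariate; eta is unchanged
                d = np.exp(ls_swap[j]) * rng.standard_normal()
                cross = float((u[ei] - u[ej]) @ dx_edges[:, j])
                dss = -2.0 * d * cross + d * d * xss_edges[j]
                dlp = -tau_u / 2 * dss
                dlp -= ((beta[j] + d) ** 2 - beta[j] ** 2) / (2 * s2)
                acc = np.log(rng.uniform()) < dlp
                if acc:
                    beta[j] += d
                    u -= d * x[:, j]
                if adapting:
                    ls_swap[j] += gam * (acc - config.target_accept)

            if spec.include_v:
                # same interchange against the unstructured effects
                d = np.exp(ls_vswap[j]) * rng.standard_normal()
                dlp = -tau_v / 2 * (-2.0 * d * float(v @ x[:, j])
                                    + d * d * float(x[:, j] @ x[:, j]))
                dlp -= ((beta[j] + d) ** 2 - beta[j] ** 2) / (2 * s2)
                acc = np.log(rng.uniform()) < dlp
                if acc:
                    beta[j] += d
                    v -= d * x[:, j]
                if adapting:
                    ls_vswap[j] += gam * (acc - config.target_accept)

        # --- u: single-site Metropolis in colouring blocks, then recentring
        if spec.include_u:
            # proposal sd = multiplier / sqrt(deg_i * tau_u), the conditional
            # prior scale, so steps track the precision as it evolves
            u_scale = 1.0 / np.sqrt(deg * tau_u + 1e-12)
            for cls, wc in zip(classes, w_rows):
                d = np.exp(ls_u[cls]) * u_scale[cls] * rng.standard_normal(len(cls))
                u_old = u[cls]
                u_new = u_old + d
                nbr_sum = wc @ u
                dll = o[cls] * d - eexp[cls] * np.expm1(d)
                dpr = -tau_u / 2 * (
                    deg[cls] * (u_new**2 - u_old**2) - 2 * nbr_sum * d
                )
                acc_mask = np.log(rng.uniform(size=len(cls))) < dll + dpr
                if acc_mask.any():
                    sel = cls[acc_mask]
                    u[sel] = u_new[acc_mask]
                    eta[sel] += d[acc_mask]
                    eexp[sel] *= np.exp(d[acc_mask])
                if adapting:
                    ls_u[cls] += gam * (acc_mask - config.target_accept)
                else:
                    acc_counts["u"] += acc_mask.sum()
            # sum-to-zero constraint, shift absorbed into the intercept
            shift = u.mean()
            u -= shift
            alpha += shift
            # Gibbs update of the ICAR precision
            ss = float(np.sum((u[ei] - u[ej]) ** 2))
            tau_u = rng.gamma(spec.tau_shape + (n - 1) / 2,
                              1.0 / (spec.tau_rate + ss / 2))

        # --- v: all sites at once (conditionally independent given the rest)
        if spec.include_v:
            d = np.exp(ls_v) / np.sqrt(tau_v + 1e-12) * rng.standard_normal(n)
            dll = o * d - eexp * np.expm1(d)
            dpr = -tau_v / 2 * ((v + d) ** 2 - v**2)
            acc_mask = np.log(rng.uniform(size=n)) < dll + dpr
            if acc_mask.any():
                v[acc_mask] += d[acc_mask]
                eta[acc_mask] += d[acc_mask]
                eexp[acc_mask] *= np.exp(d[acc_mask])
            if adapting:
                ls_v += gam * (acc_mask - config.target_accept)
            else:
                acc_counts["v"] += acc_mask.sum()
            tau_v = rng.gamma(spec.tau_shape + n / 2,
                              1.0 / (spec.tau_rate + float(np.sum(v**2)) / 2))

        if not adapting:
            n_track += 1
            if (it - config.burn_in) % config.thin == 0:
                out["alpha"][kept] = alpha - (x_mean @ beta if p else 0.0)
                for j, name in enumerate(spec.colnames):
                    out[name][kept] = beta[j]
                out["tau_u"][kept] = tau_u
                out["tau_v"][kept] = tau_v
                kept += 1

    rates = {}
    if n_track:
        rates["alpha"] = acc_counts["alpha"] / n_track
        for j, name in enumerate(spec.colnames):
            rates[f"beta:{name}"] = acc_counts["beta"][j] / n_track
        if spec.include_u:
            rates["u"] = acc_counts["u"] / (n_track * n)
        if spec.include_v:
            rates["v"] = acc_counts["v"] / (n_track * n)
        for name, rate in rates.items():
            if not 0.1 <= rate <= 0.6:
                logger.warning(
                    "chain %d: acceptance rate %.3f for %s outside [0.1, 0.6]",
                    chain_index, rate, name,
                )
    final = ChainState(alpha, beta.copy(), u.copy(), v.copy(), tau_u, tau_v)
    return out, rates, final


def mcmc_run(spec: CARModelSpec, config: MCMCConfig) -> MCMCSamples:
    """Run parallel Metropolis-within-Gibbs chains; returns thinned draws.

    Per-chain RNG streams are spawned deterministically from ``config.seed``,
    so identical spec + config reproduce identical chains.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    names = ["alpha", *spec.colnames, "tau_u", "tau_v"]
    draws = {name: np.empty((config.n_chains, config.n_kept)) for name in names}
    acceptance = {}
    for c, ss in enumerate(streams):
        out, rates, _final = _run_chain(spec, config, np.random.default_rng(ss), c)
        for name in names:
            draws[name][c] = out[name]
        acceptance[f"chain{c}"] = rates
    if not spec.include_u:
        draws.pop("tau_u")
    if not spec.include_v:
        draws.pop("tau_v")
    return MCMCSamples(draws=draws, colnames=list(spec.colnames), acceptance=acceptance)


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor over parallel chains.

    R-hat = sqrt(((n-1)/n * W + B/n) / W), with W the mean within-chain
    variance and B = n * variance of the chain means (both with ddof=1).
    """
    c = np.asarray(chains, float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = c.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    w = float(np.mean(np.var(c, axis=1, ddof=1)))
    if w == 0:
        raise ValueError("degenerate chains: within-chain variance is zero")
    b = n * float(np.var(np.mean(c, axis=1), ddof=1))
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def effective_sample_size(chains) -> float:
    """Crude ESS: m*n / (1 + 2 * sum of positive initial autocorrelations)."""
    c = np.atleast_2d(np.asarray(chains, float))
    m, n = c.shape
    if n < 4:
        return float(m * n)
    rho_sum = 0.0
    for row in c:
        row = row - row.mean()
        var = row @ row / n
        if var == 0:
            continue
        acf = np.correlate(row, row, mode="full")[n - 1:] / (n * var)
        s = 0.0
        for k in range(1, n):
            if acf[k] <= 0:
                break
            s += acf[k]
        rho_sum += s
    rho = rho_sum / m
    return float(m * n / (1 + 2 * rho))


def summarize_posterior(
    samples: MCMCSamples,
    parameters: list | None = None,
    transform=np.exp,
    min_draws: int = 100,
) -> pd.DataFrame:
    """Posterior summaries on the log-RR and RR scales.

    Equal-tailed 95% credible intervals from linear-interpolation quantiles
    of the pooled draws; RR quantiles are exp of the log-scale quantiles
    (monotone transform), RR mean is the posterior mean of exp(draws).
    Gelman-Rubin R-hat and a crude effective sample size are attached.
    """
    if parameters is None:
        parameters = [p for p in samples.parameters if p not in ("tau_u", "tau_v")]
    rows = []
    for name in parameters:
        chains = samples.draws[name]
        pooled = chains.ravel()
        if pooled.size < min_draws:
            raise ValueError(
                f"only {pooled.size} pooled draws for {name!r}; "
                f"need >= {min_draws} for a summary"
            )
        q025, q500, q975 = np.quantile(pooled, [0.025, 0.5, 0.975])
        rhat = gelman_rubin(chains) if chains.shape[0] >= 2 else float("nan")
        rows.append(
            {
                "parameter": name,
                "mean": float(pooled.mean()),
                "median": float(q500),
                "q025": float(q025),
                "q975": float(q975),
                "rr_mean": float(np.mean(transform(pooled))),
                "rr_median": float(transform(q500)),
                "rr_q025": float(transform(q025)),
                "rr_q975": float(transform(q975)),
                "rhat": rhat,
                "ess": effective_sample_size(chains),
            }
        )
    return pd.DataFrame(rows)
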