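"""Bayesian random-effects network meta-analysis by Metropolis-within-Gibbs.

Model
-----
Arm-based likelihood.  For a dichotomous outcome, arm *k* of study *i*
contributes ``r_ik ~ Binomial(n_ik, p_ik)`` with
``logit(p_ik) = mu_i + delta_ik``; for a continuous outcome the observed arm
mean contributes ``xbar_ik ~ Normal(mu_i + delta_ik, sd_ik^2 / n_ik)``.
``delta_ik = 0`` for the study's baseline arm (its first treatment in
registry order).  Non-baseline arms receive exchangeable random effects

    delta_ik ~ Normal(d[t_ik] - d[t_i,base], tau^2)          (consistency)
    delta_ik ~ Normal(d_edge(base, t_ik), tau^2)             (UME)

with the usual 1/2 between-arm correlation in multi-arm trials, implemented
by sequential conditional sampling: the j-th non-baseline arm (j = 1, 2, ...)
has conditional mean ``md_j + (1/j) * sum_{l<j}(delta_l - md_l)`` and
variance ``tau^2 (j+1)/(2j)``.

Priors: ``d, mu ~ Normal(0, effect_prior_sd^2)`` (vague on the analysis
scale) and ``tau ~ Uniform(0, tau_upper)``.  The consistency model's basic
parameters are effects of each treatment versus the reference (first
registry treatment); every pairwise contrast is the per-draw difference of
basic parameters, so consistency relations such as
``d_AC = d_AB + d_BC`` hold exactly by construction.  The unrelated-mean-
effects (UME) model instead gives every directly observed comparison its own
unconstrained mean, which is the paper-style inconsistency check: agreement
between UME edge estimates and the consistency model's contrasts supports
the consistency assumption.

Sampling is single-site adaptive random-walk Metropolis within a Gibbs scan
(mu's, delta's, d's, tau); proposal scales adapt toward 44% acceptance during
burn-in only, so the post-burn-in chain is a valid time-homogeneous
Metropolis sampler.  Identical seeds give bit-identical draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataio import OutcomeDataset, build_geometry, connected_components, edge_key, treatment_sort_key
from .errors import ConvergenceWarning, DataValidationError, DisconnectedNetworkError

_ADAPT_BATCH = 50
_ADAPT_STEP = 0.1
_TARGET_ACCEPT = 0.44
_PSRF_WARN = 1.1


@dataclass(frozen=True)
class NMAModelSpec:
    """Model and sampler settings.

    ``effect_prior_sd`` and ``tau_upper`` default to ``None`` and are then
    resolved from the outcome scale at fit time: 30 and 5 on the log-OR
    scale (15x and 2.5x a scale constant of 2 log-odds units), and 15x /
    1x the largest observed arm SD for mean differences.
    """

    likelihood: str  # "binomial-logit" | "normal-identity"
    structure: str = "consistency"  # | "ume"
    effect_prior_sd: float | None = None
    tau_upper: float | None = None
    chains: int = 4
    burn_in: int = 20_000
    samples: int = 50_000
    thin: int = 1
    seed: int | None = None

    def validate(self) -> None:
        if self.likelihood not in ("binomial-logit", "normal-identity"):
            raise DataValidationError(f"unknown likelihood {self.likelihood!r}")
        if self.structure not in ("consistency", "ume"):
            raise DataValidationError(f"unknown structure {self.structure!r}")
        if self.chains < 2:
            raise DataValidationError("at least 2 chains are required for diagnostics")
        if self.samples < 1 or self.burn_in < 0 or self.thin < 1:
            raise DataValidationError("invalid sampler sizes")
        if self.seed is None:
            raise DataValidationError("an explicit seed is required (no silent nondeterminism)")
        for name in ("effect_prior_sd", "tau_upper"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DataValidationError(f"{name} must be > 0")


def spec_for_measure(measure: str, seed: int, **overrides) -> NMAModelSpec:
    """Convenience constructor mapping OR -> binomial-logit, WMD -> normal."""
    likelihood = "binomial-logit" if measure == "OR" else "normal-identity"
    return NMAModelSpec(likelihood=likelihood, seed=seed, **overrides)


@dataclass
class PosteriorDraws:
    """MCMC output: basic parameters, heterogeneity, baselines, random effects.

    ``d`` has one column per treatment (consistency; reference column is
    identically zero) or per directly observed edge (UME).  All arrays are
    (chains, iterations, ...).
    """

    treatments: tuple[str, ...]
    reference: str
    structure: str
    scale: str  # "OR" | "WMD"
    d: np.ndarray
    tau: np.ndarray
    mu: np.ndarray
    delta: np.ndarray
    study_ids: tuple[str, ...]
    edges: tuple[tuple[str, str], ...] = ()
    spec: NMAModelSpec | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.d.shape[0]

    def basic_flat(self) -> np.ndarray:
        """Draws pooled across chains: (chains*iters, columns of d)."""
        return self.d.reshape(-1, self.d.shape[2])

    def contrast_draws(self, pair: tuple[str, str]) -> np.ndarray:
        """Per-draw effect of pair[0] relative to pair[1] on the analysis
        scale, pooled across chains."""
        a, b = pair
        flat = self.basic_flat()
        if self.structure == "consistency":
            try:
                ia, ib = self.treatments.index(a), self.treatments.index(b)
            except ValueError as exc:
                raise DataValidationError(f"treatment {exc.args[0] if exc.args else pair!r} not in network") from exc
            return flat[:, ia] - flat[:, ib]
        key = edge_key(a, b)
        if key not in self.edges:
            raise DataValidationError(
                f"UME model has no direct-edge parameter for {pair}; observed edges: {self.edges}"
            )
        col = self.edges.index(key)
        # edge parameter is 'later vs earlier' in registry order: +d if a is the later one
        sign = 1.0 if a == key[1] else -1.0
        return sign * flat[:, col]


@dataclass(frozen=True)
class RelativeEffectSummary:
    """Posterior median and equal-tailed 95% credible interval for one
    ordered pairwise contrast, on the reporting scale (OR or WMD)."""

    pair: tuple[str, str]
    point: float
    cri95: tuple[float, float]
    scale: str

    @property
    def significant(self) -> bool:
        null = 1.0 if self.scale == "OR" else 0.0
        return not (self.cri95[0] <= null <= self.cri95[1])


@dataclass(frozen=True)
class RankProbabilities:
    treatments: tuple[str, ...]
    matrix: np.ndarray  # treatment x rank
    direction: str  # "lower" | "higher" is better
    sucra: dict[str, float]

    def best_first(self) -> list[str]:
        """Treatments ordered by SUCRA, best first."""
        return sorted(self.treatments, key=lambda t: -self.sucra[t])


# ----------------------------------------------------------------------------
# sampler internals


def _softplus(x):
    return np.logaddexp(0.0, x)


class _Problem:
    """Dataset unpacked into sampler-friendly arrays (two-arm studies
    vectorized; multi-arm studies handled per study)."""

    def __init__(self, ds: OutcomeDataset, spec: NMAModelSpec):
        self.measure = ds.measure
        self.binomial = spec.likelihood == "binomial-logit"
        if self.binomial != (ds.measure == "OR"):
            raise DataValidationError(
                f"likelihood {spec.likelihood!r} does not match measure {ds.measure!r}"
            )
        self.treatments = ds.treatments
        if len(self.treatments) < 2:
            raise DataValidationError("need at least 2 treatments")
        self.t_index = {t: i for i, t in enumerate(self.treatments)}
        # two-arm studies first, then multi-arm
        order = sorted(ds.studies, key=lambda s: (len(s.arms) > 2,))
        self.studies = order
        self.study_ids = tuple(s.study_id for s in order)
        self.S = len(order)
        geo = build_geometry(ds)
        self.edges: tuple[tuple[str, str], ...] = tuple(sorted(geo.edges))
        self.e_index = {e: i for i, e in enumerate(self.edges)}

        tb2, ta2, e2 = [], [], []
        yb2, ya2 = [], []  # r or observed mean
        sb2, sa2 = [], []  # n or precision
        self.multi = []
        delta_pos = 0
        self.delta_slices: list[slice] = []
        for si, s in enumerate(order):
            arms = sorted(s.arms, key=lambda a: treatment_sort_key(a.treatment))
            tidx = [self.t_index[a.treatment] for a in arms]
            if self.binomial:
                y = np.array([float(a.events) for a in arms])
                sc = np.array([float(a.size) for a in arms])
            else:
                y = np.array([a.mean for a in arms], dtype=float)
                sc = np.array([a.size / a.sd**2 for a in arms])  # precision of xbar
            J = len(arms) - 1
            self.delta_slices.append(slice(delta_pos, delta_pos + J))
            if J == 1:
                tb2.append(tidx[0]); ta2.append(tidx[1])
                yb2.append(y[0]); ya2.append(y[1])
                sb2.append(sc[0]); sa2.append(sc[1])
                e2.append(self.e_index[edge_key(arms[0].treatment, arms[1].treatment)])
            else:
                edges_i = [self.e_index[edge_key(arms[0].treatment, a.treatment)]
                           for a in arms[1:]]
                self.multi.append(
                    dict(study=si, tidx=np.array(tidx), y=y, sc=sc,
                         dslice=self.delta_slices[-1], edges=np.array(edges_i))
                )
            delta_pos += J
        self.A = delta_pos
        self.S2 = len(tb2)
        self.tb2 = np.array(tb2, dtype=int)
        self.ta2 = np.array(ta2, dtype=int)
        self.e2 = np.array(e2, dtype=int)
        self.yb2 = np.array(yb2, dtype=float)
        self.ya2 = np.array(ya2, dtype=float)
        self.sb2 = np.array(sb2, dtype=float)
        self.sa2 = np.array(sa2, dtype=float)
        # number of basic parameters
        self.T = len(self.treatments)
        self.n_basic = self.T - 1 if spec.structure == "consistency" else len(self.edges)

        # resolve priors from the outcome scale
        if self.binomial:
            scale_const = 2.0
            self.effect_prior_sd = spec.effect_prior_sd or 15.0 * scale_const
            self.tau_upper = spec.tau_upper or 5.0
        else:
            sds = [a.sd for s in ds.studies for a in s.arms]
            scale_const = max(sds) if sds else 1.0
            self.effect_prior_sd = spec.effect_prior_sd or 15.0 * scale_const
            self.tau_upper = spec.tau_upper or scale_const

    # --- likelihood pieces -------------------------------------------------
    def _ll(self, y, sc, eta):
        """Arm log-likelihood (up to constants): binomial r*eta - n*log(1+e^eta)
        or normal -0.5*prec*(xbar - eta)^2."""
        if self.binomial:
            return y * eta - sc * _softplus(eta)
        return -0.5 * sc * (y - eta) ** 2

    def md2(self, d_full, ume: bool) -> np.ndarray:
        """Random-effect prior means for the two-arm block."""
        if ume:
            return d_full[self.e2]
        return d_full[self.ta2] - d_full[self.tb2]

    def md_multi(self, st, d_full, ume: bool) -> np.ndarray:
        if ume:
            return d_full[st["edges"]]
        return d_full[st["tidx"][1:]] - d_full[st["tidx"][0]]

    def ma_prior_ll(self, deltas: np.ndarray, mds: np.ndarray, tau: float) -> float:
        """Factorized multivariate-normal prior (correlation 1/2) for one
        multi-arm study's random-effect vector."""
        ll = 0.0
        acc = 0.0
        for j in range(len(deltas)):
            if j == 0:
                mean, var = mds[0], tau * tau
            else:
                mean = mds[j] + acc / j
                var = tau * tau * (j + 1) / (2.0 * j)
            ll += -0.5 * (deltas[j] - mean) ** 2 / var - 0.5 * math.log(var)
            acc += deltas[j] - mds[j]
        return ll

    def delta_prior_ll(self, delta, d_full, tau, ume: bool) -> float:
        """Total log prior of all random effects given d and tau."""
        md = self.md2(d_full, ume)
        d2 = delta[: self.S2]
        ll = float(-0.5 * np.sum((d2 - md) ** 2) / tau**2 - self.S2 * math.log(tau))
        for st in self.multi:
            ll += self.ma_prior_ll(delta[st["dslice"]], self.md_multi(st, d_full, ume), tau)
        return ll


def fit(ds: OutcomeDataset, spec: NMAModelSpec) -> PosteriorDraws:
    """Run the MCMC and return posterior draws.

    The consistency model requires a connected treatment network; the UME
    model runs on any geometry.  Non-mixing (PSRF of any basic parameter or
    tau above 1.1) attaches a warning to the result rather than failing.
    """
    ds.validate()
    spec.validate()
    if spec.structure == "consistency":
        comps = connected_components(ds)
        if len(comps) > 1:
            raise DisconnectedNetworkError(
                "consistency model needs a connected network; components: "
                + "; ".join("{" + ", ".join(sorted(c)) + "}" for c in comps)
            )
    prob = _Problem(ds, spec)
    ume = spec.structure == "ume"
    n_iter = spec.burn_in + spec.samples * spec.thin

    d_out = np.empty((spec.chains, spec.samples, prob.n_basic if ume else prob.T))
    tau_out = np.empty((spec.chains, spec.samples))
    mu_out = np.empty((spec.chains, spec.samples, prob.S))
    delta_out = np.empty((spec.chains, spec.samples, prob.A))

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    for c in range(spec.chains):
        rng = np.random.default_rng(seeds[c])
        _run_chain(prob, spec, ume, rng, n_iter,
                   d_out[c], tau_out[c], mu_out[c], delta_out[c])

    draws = PosteriorDraws(
        treatments=prob.treatments,
        reference=prob.treatments[0],
        structure=spec.structure,
        scale="OR" if prob.binomial else "WMD",
        d=d_out,
        tau=tau_out,
        mu=mu_out,
        delta=delta_out,
        study_ids=prob.study_ids,
        edges=prob.edges,
        spec=spec,
    )
    diag = psrf(draws)
    bad = {k: v for k, v in diag.items() if v > _PSRF_WARN}
    if bad:
        msg = "PSRF above %.2f for: %s" % (
            _PSRF_WARN, ", ".join(f"{k}={v:.3f}" for k, v in sorted(bad.items()))
        )
        draws.warnings.append(msg)
        warnings.warn(msg, ConvergenceWarning)
    return draws


def _init_state(prob: _Problem, ume: bool, rng):
    """Deterministic data-driven initial values with small per-chain jitter
    (overdispersed starts make the PSRF diagnostic meaningful)."""
    mu = np.zeros(prob.S)
    delta = np.zeros(prob.A)
    if prob.binomial:
        eb = np.log((prob.yb2 + 0.5) / (prob.sb2 - prob.yb2 + 0.5))
        ea = np.log((prob.ya2 + 0.5) / (prob.sa2 - prob.ya2 + 0.5))
    else:
        eb, ea = prob.yb2, prob.ya2
    mu[: prob.S2] = eb
    delta[: prob.S2] = ea - eb
    for st in prob.multi:
        si = st["study"]
        if prob.binomial:
            e = np.log((st["y"] + 0.5) / (st["sc"] - st["y"] + 0.5))
        else:
            e = st["y"]
        mu[si] = e[0]
        delta[st["dslice"]] = e[1:] - e[0]
    scale = 1.0 if prob.binomial else max(prob.effect_prior_sd / 15.0, 1e-6)
    d = np.zeros(prob.n_basic if ume else prob.T)
    mu = mu + 0.25 * scale * rng.standard_normal(prob.S)
    delta = delta + 0.25 * scale * rng.standard_normal(prob.A)
    d[(0 if ume else 1):] += 0.25 * scale * rng.standard_normal(
        prob.n_basic)
    tau = (0.1 + 0.3 * rng.random()) * prob.tau_upper
    return mu, delta, d, tau


def _run_chain(prob, spec, ume, rng, n_iter, d_out, tau_out, mu_out, delta_out):
    mu, delta, d, tau = _init_state(prob, ume, rng)
    S2 = prob.S2
    prior_var = prob.effect_prior_sd**2
    scale = 1.0 if prob.binomial else max(prob.effect_prior_sd / 15.0, 1e-6)

    # adaptive log step sizes
    ls_mu = np.full(prob.S, math.log(0.5 * scale))
    ls_delta = np.full(prob.A, math.log(0.5 * scale))
    ls_d = np.full(prob.n_basic, math.log(0.3 * scale))
    ls_tau = math.log(0.3 * max(prob.tau_upper / 5.0, 1e-6))
    acc_mu = np.zeros(prob.S)
    acc_delta = np.zeros(prob.A)
    acc_d = np.zeros(prob.n_basic)
    acc_tau = 0.0

    basic_idx = range(prob.n_basic) if ume else range(1, prob.T)
    d_offset = 0 if ume else 1
    rec = 0
    for it in range(n_iter):
        # --- baselines mu (two-arm block, vectorized) ---------------------
        mu2 = mu[:S2]
        d2 = delta[:S2]
        prop = mu2 + np.exp(ls_mu[:S2]) * rng.standard_normal(S2)
        dll = (
            prob._ll(prob.yb2, prob.sb2, prop) - prob._ll(prob.yb2, prob.sb2, mu2)
            + prob._ll(prob.ya2, prob.sa2, prop + d2) - prob._ll(prob.ya2, prob.sa2, mu2 + d2)
            - 0.5 * (prop**2 - mu2**2) / prior_var
        )
        acc = np.log(rng.random(S2)) < dll
        mu[:S2] = np.where(acc, prop, mu2)
        acc_mu[:S2] += acc

        # --- random effects delta (two-arm block) -------------------------
        mu2 = mu[:S2]
        md = prob.md2(d, ume)
        prop = d2 + np.exp(ls_delta[:S2]) * rng.standard_normal(S2)
        dll = (
            prob._ll(prob.ya2, prob.sa2, mu2 + prop)
            - prob._ll(prob.ya2, prob.sa2, mu2 + d2)
            - 0.5 * ((prop - md) ** 2 - (d2 - md) ** 2) / tau**2
        )
        acc = np.log(rng.random(S2)) < dll
        delta[:S2] = np.where(acc, prop, d2)
        acc_delta[:S2] += acc

        # --- multi-arm studies (scalar updates) ---------------------------
        for st in prob.multi:
            si = st["study"]
            sl = st["dslice"]
            ds_i = delta[sl]
            mds = prob.md_multi(st, d, ume)
            eta = mu[si] + np.concatenate(([0.0], ds_i))
            prop_mu = mu[si] + math.exp(ls_mu[si]) * rng.standard_normal()
            dll = float(
                np.sum(prob._ll(st["y"], st["sc"], prop_mu + eta - mu[si])
                       - prob._ll(st["y"], st["sc"], eta))
            ) - 0.5 * (prop_mu**2 - mu[si] ** 2) / prior_var
            if math.log(rng.random()) < dll:
                mu[si] = prop_mu
                acc_mu[si] += 1
            for j in range(len(ds_i)):
                prop_j = ds_i.copy()
                step = math.exp(ls_delta[sl.start + j])
                prop_j[j] = ds_i[j] + step * rng.standard_normal()
                dll = (
                    float(prob._ll(st["y"][j + 1], st["sc"][j + 1], mu[si] + prop_j[j])
                          - prob._ll(st["y"][j + 1], st["sc"][j + 1], mu[si] + ds_i[j]))
                    + prob.ma_prior_ll(prop_j, mds, tau)
                    - prob.ma_prior_ll(ds_i, mds, tau)
                )
                if math.log(rng.random()) < dll:
                    ds_i = prop_j
                    acc_delta[sl.start + j] += 1
            delta[sl] = ds_i

        # --- basic parameters d -------------------------------------------
        for bi, k in enumerate(basic_idx):
            prop_d = d.copy()
            prop_d[k] = d[k] + math.exp(ls_d[bi]) * rng.standard_normal()
            dll = (
                prob.delta_prior_ll(delta, prop_d, tau, ume)
                - prob.delta_prior_ll(delta, d, tau, ume)
                - 0.5 * (prop_d[k] ** 2 - d[k] ** 2) / prior_var
            )
            if math.log(rng.random()) < dll:
                d = prop_d
                acc_d[bi] += 1

        # --- heterogeneity tau --------------------------------------------
        prop_tau = tau + math.exp(ls_tau) * rng.standard_normal()
        if 0.0 < prop_tau < prob.tau_upper:
            dll = prob.delta_prior_ll(delta, d, prop_tau, ume) - prob.delta_prior_ll(
                delta, d, tau, ume
            )
            if math.log(rng.random()) < dll:
                tau = prop_tau
                acc_tau += 1

        # --- adaptation (burn-in only) ------------------------------------
        if it < spec.burn_in and (it + 1) % _ADAPT_BATCH == 0:
            ls_mu += _ADAPT_STEP * np.sign(acc_mu / _ADAPT_BATCH - _TARGET_ACCEPT)
            ls_delta += _ADAPT_STEP * np.sign(acc_delta / _ADAPT_BATCH - _TARGET_ACCEPT)
            ls_d += _ADAPT_STEP * np.sign(acc_d / _ADAPT_BATCH - _TARGET_ACCEPT)
            ls_tau += _ADAPT_STEP * math.copysign(1.0, acc_tau / _ADAPT_BATCH - _TARGET_ACCEPT)
            acc_mu[:] = 0.0
            acc_delta[:] = 0.0
            acc_d[:] = 0.0
            acc_tau = 0.0

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            d_out[rec] = d
            tau_out[rec] = tau
            mu_out[rec] = mu
            delta_out[rec] = delta
            rec += 1


# ----------------------------------------------------------------------------
# posterior summaries


def relative_effects(draws: PosteriorDraws, pair: tuple[str, str]) -> RelativeEffectSummary:
    """Posterior median and 95% CrI for pair[0] vs pair[1] on the reporting
    scale.  ORs are exponentiated per draw before summarizing, so
    reversing the pair inverts the OR exactly."""
    a, b = pair
    if a == b:
        null = 1.0 if draws.scale == "OR" else 0.0
        return RelativeEffectSummary(pair=pair, point=null, cri95=(null, null), scale=draws.scale)
    x = draws.contrast_draws(pair)
    lo, mid, hi = np.percentile(x, [2.5, 50.0, 97.5])
    if draws.scale == "OR":
        # summarize on the log scale and exponentiate: equal-tailed
        # percentiles commute with the monotone exp transform, and this
        # keeps pair reversal an exact OR inversion
        lo, mid, hi = math.exp(lo), math.exp(mid), math.exp(hi)
    return RelativeEffectSummary(pair=pair, point=float(mid), cri95=(float(lo), float(hi)),
                                 scale=draws.scale)


def rank_probabilities(draws: PosteriorDraws, direction: str = "lower") -> RankProbabilities:
    """Probability of each treatment attaining each rank (rank 1 = best).

    ``direction`` says whether a lower effect versus the reference is better
    (e.g. fewer hypoglycemia events) or a higher one is.  Also reports the
    SUCRA summary (area under the cumulative rank curve).
    """
    if draws.structure != "consistency":
        raise DataValidationError("rank probabilities require a consistency fit")
    if direction not in ("lower", "higher"):
        raise DataValidationError("direction must be 'lower' or 'higher'")
    flat = draws.basic_flat()  # columns per treatment, reference = 0
    vals = flat if direction == "lower" else -flat
    T = vals.shape[1]
    order = np.argsort(vals, axis=1, kind="stable")
    ranks = np.argsort(order, axis=1, kind="stable")  # 0 = best
    matrix = np.empty((T, T))
    for t in range(T):
        matrix[t] = np.bincount(ranks[:, t], minlength=T) / vals.shape[0]
    cum = np.cumsum(matrix, axis=1)
    sucra = {trt: float(np.mean(cum[i, : T - 1])) for i, trt in enumerate(draws.treatments)}
    return RankProbabilities(treatments=draws.treatments, matrix=matrix,
                             direction=direction, sucra=sucra)


def psrf(draws: PosteriorDraws) -> dict[str, float]:
    """Classic Gelman–Rubin potential scale reduction factor per scalar
    parameter (basic parameters and tau), from >= 2 chains."""
    if draws.n_chains < 2:
        raise DataValidationError("PSRF needs at least 2 chains")
    out: dict[str, float] = {}
    if draws.structure == "consistency":
        names = [f"d[{t}]" for t in draws.treatments[1:]]
        cols = draws.d[:, :, 1:]
    else:
        names = [f"d[{a}:{b}]" for a, b in draws.edges]
        cols = draws.d
    for j, name in enumerate(names):
        out[name] = _gelman_rubin(cols[:, :, j])
    out["tau"] = _gelman_rubin(draws.tau)
    return out


def _gelman_rubin(chains: np.ndarray) -> float:
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = float(np.mean(chains.var(axis=1, ddof=1)))
    B_over_n = float(np.var(means, ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else float("inf")
    var_plus = (n - 1) / n * W + B_over_n
    return math.sqrt(var_plus / W)


def league_table(draws: PosteriorDraws, pairs: Sequence[tuple[str, str]] | None = None
                 ) -> list[RelativeEffectSummary]:
    """Relative-effect summaries for the given ordered pairs (default: all
    ordered pairs (i, j) with i before j in registry order)."""
    if pairs is None:
        t = draws.treatments
        pairs = [(t[i], t[j]) for i in range(len(t)) for j in range(i + 1, len(t))]
    return [relative_effects(draws, p) for p in pairs]
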