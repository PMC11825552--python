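"""Nonlinear mixed-effects estimation by first-order conditional estimation (FOCE).

The population model couples the structural disposition model of
:mod:`txapk.pk` with log-normal inter-individual variability
``P_i = TV(P) exp(eta_i)``, ``eta_i ~ N(0, omega^2)`` (diagonal), and a
combined additive + proportional residual error

    Cobs = Cpred + eps * sqrt(1 + (Cpred * sigma2 / sigma1)^2),
    eps ~ N(0, sigma1^2),

so the residual standard deviation around a prediction ``c`` is
``sqrt(sigma1^2 + (sigma2 c)^2)``.

The marginal likelihood has no closed form; it is approximated in the
FOCE-with-interaction fashion: for each subject the conditional mode
``eta_hat`` of the joint density is located (damped Gauss-Newton from
eta = 0), the model is linearized there, and the subject's contribution to
the objective function value (OFV, -2 x approximate log marginal
likelihood, additive constants ``n log 2pi`` dropped, as is conventional)
is

    OFV_i = r' V^-1 r + log|V|,
    r = y - f(eta_hat) + G eta_hat,   G = df/deta |_{eta_hat},
    V = G Omega G' + diag(sigma1^2 + (sigma2 f(eta_hat))^2).

``V^-1`` and ``log|V|`` are evaluated through the matrix-inversion lemma so
only K x K systems are solved (K = number of random effects).  In the
limit omega^2 -> 0 the objective collapses to the fixed-effect weighted
least-squares deviance, and for a linear model it is exact.

Population fitting minimizes the OFV over log-transformed typical values
and variance components (covariate exponents untransformed) with L-BFGS-B;
standard errors come from the inverse finite-difference Hessian of OFV/2,
propagated through the log transform.  Nested models are compared by the
likelihood-ratio test (chi-squared quantile, 6.635 for 1 df at p = 0.01),
and the shotgun covariate search fits every subset of candidate
covariate-parameter effects and applies the retain/remove rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .data import PopDataset, SubjectRecord
from .pk import CovariateEffect, covariate_value

__all__ = [
    "EngineError",
    "SigmaParams",
    "OmegaSpec",
    "PopModelSpec",
    "ParamSet",
    "FitOptions",
    "FitResult",
    "LRTResult",
    "CovariateSearchRow",
    "CovariateSearchTable",
    "residual_sd",
    "subject_objective",
    "ofv",
    "evaluate",
    "fit_population",
    "default_initial_params",
    "lrt",
    "shotgun_covariate_search",
]

LRT_ALPHA = 0.01  # significance level of the -2 l.l.d. test

#: hard bound on conditional random effects: |eta| <= 10 corresponds to a
#: 2e4-fold parameter deviation, far beyond anything biological, and keeps
#: the inner Newton iteration out of floating-point overflow territory
ETA_MAX = 10.0


class EngineError(RuntimeError):
    """Estimation failed in a way that invalidates the result."""


@dataclass(frozen=True)
class SigmaParams:
    """Combined residual-error magnitudes: additive SD (mg/L) and proportional SD."""

    sigma1: float
    sigma2: float = 0.0

    def __post_init__(self):
        if not self.sigma1 > 0:
            raise ValueError(f"sigma1 must be positive, got {self.sigma1}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be nonnegative, got {self.sigma2}")


#: Diagonal inter-individual variability: parameter name -> omega^2 (variance
#: of eta on the log scale).  A plain mapping; no eta covariances are modeled.
OmegaSpec = Mapping[str, float]


@dataclass(frozen=True)
class PopModelSpec:
    """Structural and stochastic model choice.

    ``n_compartments`` selects the disposition model (1 or 2),
    ``covariate_effects`` the power-law effects carried by the fixed
    effects, and ``iiv`` which parameters carry a log-normal random effect.
    """

    n_compartments: int = 2
    covariate_effects: tuple[CovariateEffect, ...] = ()
    iiv: tuple[str, ...] = ("cl1", "v1")

    def __post_init__(self):
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))
        object.__setattr__(self, "iiv", tuple(self.iiv))
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        names = self.theta_names
        for eff in self.covariate_effects:
            if eff.parameter not in names:
                raise ValueError(
                    f"covariate effect targets {eff.parameter!r}, not a parameter of "
                    f"a {self.n_compartments}-compartment model"
                )
        for p in self.iiv:
            if p not in names:
                raise ValueError(f"IIV on unknown parameter {p!r}")

    @property
    def theta_names(self) -> tuple[str, ...]:
        return ("v1", "cl1") if self.n_compartments == 1 else ("v1", "v2", "cl1", "cl2")


@dataclass(frozen=True)
class ParamSet:
    """One point in parameter space.

    ``theta``: typical values (L and L/h) keyed by parameter name;
    ``exponents``: covariate-effect exponents, aligned positionally with
    ``PopModelSpec.covariate_effects``; ``omega2``: eta variances keyed by
    parameter name; ``sigma``: residual-error magnitudes.
    """

    theta: Mapping[str, float]
    exponents: tuple[float, ...] = ()
    omega2: Mapping[str, float] = field(default_factory=dict)
    sigma: SigmaParams = field(default_factory=lambda: SigmaParams(1.0, 0.15))

    def __post_init__(self):
        object.__setattr__(self, "theta", dict(self.theta))
        object.__setattr__(self, "exponents", tuple(float(x) for x in self.exponents))
        object.__setattr__(self, "omega2", dict(self.omega2))
        for name, tv in self.theta.items():
            if not tv > 0:
                raise ValueError(f"typical value {name} must be positive, got {tv}")
        for name, w2 in self.omega2.items():
            if w2 < 0:
                raise ValueError(f"omega^2 for {name} must be nonnegative, got {w2}")

    def flat(self) -> dict[str, float]:
        """Flatten to plain name -> value pairs (for reports and bootstrap tables)."""
        out = {f"tv_{k}": v for k, v in self.theta.items()}
        out.update({f"expo_{i}": x for i, x in enumerate(self.exponents)})
        out.update({f"omega2_{k}": v for k, v in self.omega2.items()})
        out["sigma1"] = self.sigma.sigma1
        out["sigma2"] = self.sigma.sigma2
        return out


def residual_sd(cpred, sigma: SigmaParams):
    """SD of an observation around its prediction under the combined error model.

    ``sqrt(sigma1^2 + (sigma2 * cpred)^2)`` — the additive SD at zero
    concentration, asymptotically proportional at high concentration.
    """
    c = np.asarray(cpred, dtype=float)
    if np.any(c < 0):
        raise ValueError("predicted concentration must be nonnegative")
    out = np.sqrt(sigma.sigma1**2 + (sigma.sigma2 * c) ** 2)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# compiled dataset: flat arrays for vectorized likelihood evaluation
# --------------------------------------------------------------------------


class _Compiled:
    """Flat-array view of a dataset under a model specification.

    Precomputes, once per (dataset, model): the observation vector, the
    (observation, prior-dose) superposition pairs, per-effect covariate
    log-ratios (resolving ``reference=None`` to the dataset median), and the
    grouping indices needed to reduce per-observation quantities to
    per-subject ones with ``np.bincount``.
    """

    def __init__(self, dataset: PopDataset, model: PopModelSpec):
        self.model = model
        self.ids = [s.id for s in dataset.subjects]
        self.n_subj = len(dataset.subjects)
        y, t_obs, obs_subj = [], [], []
        pair_obs, pair_subj, pair_amt, pair_tau = [], [], [], []
        i_obs = 0
        for s_idx, sub in enumerate(dataset.subjects):
            for ob in sub.observations:
                if ob.missing:
                    continue
                y.append(ob.concentration)
                t_obs.append(ob.time)
                obs_subj.append(s_idx)
                for d in sub.doses:
                    if d.time <= ob.time:
                        pair_obs.append(i_obs)
                        pair_subj.append(s_idx)
                        pair_amt.append(d.amount)
                        pair_tau.append(ob.time - d.time)
                i_obs += 1
        self.n_obs = i_obs
        self.y = np.asarray(y, dtype=float)
        self.t_obs = np.asarray(t_obs, dtype=float)
        self.obs_subj = np.asarray(obs_subj, dtype=np.intp)
        self.pair_obs = np.asarray(pair_obs, dtype=np.intp)
        self.pair_subj = np.asarray(pair_subj, dtype=np.intp)
        self.pair_amt = np.asarray(pair_amt, dtype=float)
        self.pair_tau = np.asarray(pair_tau, dtype=float)
        # covariate log-ratios per effect, references resolved to medians
        self.effects: list[CovariateEffect] = []
        self.logratio = np.zeros((len(model.covariate_effects), self.n_subj))
        for e_idx, eff in enumerate(model.covariate_effects):
            vals = np.array(
                [covariate_value(s.covariates, eff.covariate) for s in dataset.subjects]
            )
            ref = eff.reference if eff.reference is not None else float(np.median(vals))
            self.effects.append(replace(eff, reference=ref))
            self.logratio[e_idx] = np.log(vals / ref)
        self.eff_by_param: dict[str, list[int]] = {}
        for e_idx, eff in enumerate(self.effects):
            self.eff_by_param.setdefault(eff.parameter, []).append(e_idx)
        self.iiv = model.iiv
        self.n_eta = len(model.iiv)
        self._slices = None  # lazy per-subject views for scalar fallbacks
        # pair -> observation segment starts for np.add.reduceat (every
        # observation has at least one prior dose by the dataset invariant)
        self._reduceat_ok = bool(
            self.n_obs > 0
            and self.pair_obs.size
            and np.array_equal(np.unique(self.pair_obs), np.arange(self.n_obs))
            and np.all(np.diff(self.pair_obs) >= 0)
        )
        if self._reduceat_ok:
            self.obs_starts = np.flatnonzero(
                np.r_[True, np.diff(self.pair_obs) > 0]
            )

    def subject_slices(self):
        """Per-subject observation/pair index views (built on first use)."""
        if self._slices is None:
            obs_of = [np.flatnonzero(self.obs_subj == s) for s in range(self.n_subj)]
            pairs_of = []
            pair_local = []
            for s in range(self.n_subj):
                pidx = np.flatnonzero(self.pair_subj == s)
                pairs_of.append(pidx)
                pair_local.append(np.searchsorted(obs_of[s], self.pair_obs[pidx]))
            self._slices = (obs_of, pairs_of, pair_local)
        return self._slices

    def conc_single(self, s: int, P: Mapping[str, float]) -> np.ndarray:
        """Concentrations at one subject's observations for scalar parameters."""
        obs_of, pairs_of, pair_local = self.subject_slices()
        pidx = pairs_of[s]
        tau = self.pair_tau[pidx]
        amt = self.pair_amt[pidx]
        v1 = P["v1"]
        if self.model.n_compartments == 1:
            term = amt / v1 * np.exp(-(P["cl1"] / v1) * tau)
        else:
            k10 = P["cl1"] / v1
            k12 = P["cl2"] / v1
            k21 = P["cl2"] / P["v2"]
            a = k10 + k12 + k21
            disc = math.sqrt(max(a * a - 4.0 * k10 * k21, 0.0))
            alpha = 0.5 * (a + disc)
            beta = k10 * k21 / max(alpha, 1e-300)
            if disc <= 1e-10 * alpha:
                prof = np.exp(-alpha * tau) * (1.0 + (k21 - alpha) * tau)
            else:
                A = (alpha - k21) / (alpha - beta)
                prof = A * np.exp(-alpha * tau) + (1.0 - A) * np.exp(-beta * tau)
            term = amt / v1 * prof
        return np.bincount(pair_local[s], weights=term, minlength=obs_of[s].size)

    # -- parameter maps ----------------------------------------------------

    def typical(self, params: ParamSet) -> dict[str, np.ndarray]:
        """Per-subject typical parameters after covariate effects (eta = 0)."""
        out = {}
        for name in self.model.theta_names:
            v = np.full(self.n_subj, params.theta[name])
            for e_idx in self.eff_by_param.get(name, ()):
                v = v * np.exp(params.exponents[e_idx] * self.logratio[e_idx])
            out[name] = v
        return out

    def conc_multi(self, typ: Mapping[str, np.ndarray], etas: np.ndarray) -> np.ndarray:
        """Predicted concentrations for a stack of eta matrices.

        ``etas`` has shape (V, n_subj, n_eta); the result has shape
        (V, n_obs).  One fused evaluation amortizes the per-call overhead
        of finite-difference gradients and simulation replicates.
        """
        V = etas.shape[0]
        S = self.n_subj
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            P: dict[str, np.ndarray] = {
                name: np.broadcast_to(typ[name], (V, S)) for name in self.model.theta_names
            }
            for k, name in enumerate(self.iiv):
                P[name] = typ[name][None, :] * np.exp(etas[:, :, k])
            ps, tau, amt = self.pair_subj, self.pair_tau, self.pair_amt
            v1 = P["v1"]
            if self.model.n_compartments == 1:
                kel = P["cl1"] / v1
                term = amt / v1[:, ps] * np.exp(-kel[:, ps] * tau)
            else:
                k10 = P["cl1"] / v1
                k12 = P["cl2"] / v1
                k21 = P["cl2"] / P["v2"]
                a = k10 + k12 + k21
                disc = np.sqrt(np.maximum(a * a - 4.0 * k10 * k21, 0.0))
                alpha = 0.5 * (a + disc)
                beta = k10 * k21 / np.maximum(alpha, 1e-300)
                degen = disc <= 1e-10 * alpha
                denom = np.where(degen, 1.0, alpha - beta)
                A = np.where(degen, 0.5, (alpha - k21) / denom)
                al, be = alpha[:, ps], beta[:, ps]
                Ap = A[:, ps]
                biexp = Ap * np.exp(-al * tau) + (1.0 - Ap) * np.exp(-be * tau)
                if degen.any():
                    repeated = np.exp(-al * tau) * (1.0 + (k21[:, ps] - al) * tau)
                    biexp = np.where(degen[:, ps], repeated, biexp)
                term = amt / v1[:, ps] * biexp
            if self._reduceat_ok:
                return np.add.reduceat(term, self.obs_starts, axis=1)
            out = np.zeros((V, self.n_obs))
            for i in range(V):
                out[i] = np.bincount(self.pair_obs, weights=term[i], minlength=self.n_obs)
            return out

    def conc(self, typ: Mapping[str, np.ndarray], eta: np.ndarray | None = None) -> np.ndarray:
        """Per-observation predicted concentration for per-subject parameters."""
        if eta is None or not eta.size:
            eta = np.zeros((self.n_subj, self.n_eta))
        return self.conc_multi(typ, eta[None])[0]

    def conc_and_gradient(self, typ, eta: np.ndarray, h: float = 1e-4):
        """Concentration and d(conc)/d(eta) (central differences) in one pass."""
        K = self.n_eta
        stack = np.empty((1 + 2 * K, self.n_subj, K))
        stack[0] = eta
        for k in range(K):
            stack[1 + 2 * k] = eta
            stack[1 + 2 * k][:, k] += h
            stack[2 + 2 * k] = eta
            stack[2 + 2 * k][:, k] -= h
        vals = self.conc_multi(typ, stack)
        G = np.empty((self.n_obs, K))
        for k in range(K):
            G[:, k] = (vals[1 + 2 * k] - vals[2 + 2 * k]) / (2.0 * h)
        return vals[0], G

    def eta_gradient(self, typ, eta: np.ndarray, h: float = 1e-4) -> np.ndarray:
        """d(conc)/d(eta) by central differences, shape (n_obs, n_eta)."""
        return self.conc_and_gradient(typ, eta, h)[1]


# --------------------------------------------------------------------------
# FOCE inner problem and objective
# --------------------------------------------------------------------------


def _subject_g(c: _Compiled, typ, omega2_vec, sigma: SigmaParams, eta):
    """Joint -2 log density per subject (constants dropped) and its ingredients."""
    f = c.conc(typ, eta)
    v = sigma.sigma1**2 + (sigma.sigma2 * f) ** 2
    r = c.y - f
    g = np.bincount(c.obs_subj, weights=r * r / v + np.log(v), minlength=c.n_subj)
    if eta is not None and eta.size:
        g = g + (eta * eta / np.maximum(omega2_vec, 1e-300)).sum(axis=1)
    return g, f, v, r


def _inner_etas(
    c: _Compiled,
    typ,
    omega2_vec,
    sigma: SigmaParams,
    eta0: np.ndarray | None = None,
    gtol: float = 1e-8,
    maxiter: int = 60,
) -> np.ndarray:
    """Conditional modes eta_hat for all subjects by damped Gauss-Newton.

    Starts from eta = 0 (or ``eta0``) and takes damped Newton steps on the
    joint -2 log density, vectorized across subjects.  The Hessian uses the
    exact curvature of the per-observation deviance with respect to the
    prediction (clamped below to keep it positive definite) contracted with
    the finite-difference sensitivities ``G = df/deta``; second derivatives
    of ``f`` itself are neglected.  A subject stops when its gradient
    sup-norm falls below ``gtol * (1 + |g|)`` or its Newton step falls
    below the finite-difference noise floor (the gradient computed through
    a differenced ``G`` cannot resolve much below ~1e-6, so tiny steps are
    the sharper criterion near the mode).  Any subject still carrying a
    substantial gradient afterwards is polished with a derivative-free
    Nelder-Mead minimization of the same objective.  Deterministic.
    """
    S, K = c.n_subj, c.n_eta
    if K == 0 or c.n_obs == 0:
        return np.zeros((S, K))
    inv_om = 1.0 / np.maximum(omega2_vec, 1e-300)
    eta = np.zeros((S, K)) if eta0 is None else np.array(eta0, dtype=float, copy=True)
    g = _subject_g(c, typ, omega2_vec, sigma, eta)[0]
    stalled = np.zeros(S, dtype=bool)
    s2sq = sigma.sigma2**2
    s1sq = sigma.sigma1**2
    grad = np.zeros((S, K))
    at_floor = np.zeros(S, dtype=bool)
    for _ in range(maxiter):
        f, G = c.conc_and_gradient(typ, eta)
        v = s1sq + s2sq * f * f
        r = c.y - f
        winv = 1.0 / v
        vf = 2.0 * s2sq * f  # d(variance)/d(prediction)
        cobs = (-2.0 * r * winv) + (winv - (r * r) * winv * winv) * vf
        # exact curvature of (y-f)^2/v + log v in f, clamped positive
        phi2 = (
            2.0 * winv
            + 4.0 * r * vf * winv * winv
            - vf * vf * winv * winv
            + 2.0 * s2sq * winv
            + 2.0 * (r * vf * winv) ** 2 * winv
            - 2.0 * s2sq * (r * winv) ** 2
        )
        phi2 = np.maximum(phi2, 0.1 * winv)
        grad = np.empty((S, K))
        H = np.empty((S, K, K))
        for k in range(K):
            grad[:, k] = (
                np.bincount(c.obs_subj, weights=cobs * G[:, k], minlength=S)
                + 2.0 * eta[:, k] * inv_om[k]
            )
            for k2 in range(k, K):
                hk = np.bincount(
                    c.obs_subj, weights=phi2 * G[:, k] * G[:, k2], minlength=S
                )
                H[:, k, k2] = hk
                H[:, k2, k] = hk
            H[:, k, k] += 2.0 * inv_om[k]
        active = (
            (np.abs(grad).max(axis=1) > gtol * (1.0 + np.abs(g))) & ~stalled & ~at_floor
        )
        if not active.any():
            break
        delta = np.zeros_like(eta)
        delta[active] = -np.linalg.solve(H[active], grad[active][..., None])[..., 0]
        delta = np.clip(delta, -2.0, 2.0)  # trust region against wild steps
        tiny = active & (np.abs(delta).max(axis=1) <= 1e-9 * (1.0 + np.abs(eta).max(axis=1)))
        at_floor |= tiny
        active &= ~tiny
        if not active.any():
            continue
        delta[~active] = 0.0
        slope = (grad * delta).sum(axis=1)
        step = np.where(active, 1.0, 0.0)
        accepted = ~active
        for _ls in range(20):
            trial = np.clip(eta + step[:, None] * delta, -ETA_MAX, ETA_MAX)
            g_try = _subject_g(c, typ, omega2_vec, sigma, trial)[0]
            ok = active & ~accepted & (g_try <= g + 1e-4 * step * slope)
            g = np.where(ok, g_try, g)
            accepted = accepted | ok
            if accepted.all():
                break
            step = np.where(accepted, step, step * 0.5)
        moved = accepted & active
        stalled = stalled | (active & ~accepted)
        eta = np.where(
            moved[:, None], np.clip(eta + step[:, None] * delta, -ETA_MAX, ETA_MAX), eta
        )
    # derivative-free polish for subjects still carrying a substantial gradient
    need = stalled | (np.abs(grad).max(axis=1) > 1e-3 * (1.0 + np.abs(g)))
    if need.any():
        for s in np.flatnonzero(need):
            res = optimize.minimize(
                lambda e: _g_single(c, typ, omega2_vec, sigma, s, e),
                eta[s],
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 500},
            )
            if res.fun <= g[s]:
                eta[s] = res.x
    return eta


def _g_single(c: _Compiled, typ, omega2_vec, sigma: SigmaParams, s: int, eta_s) -> float:
    """Joint -2 log density (constants dropped) of a single subject."""
    eta_s = np.asarray(eta_s, dtype=float)
    if np.any(np.abs(eta_s) > 2.0 * ETA_MAX):
        return np.inf
    P = {name: float(typ[name][s]) for name in c.model.theta_names}
    for k, nm in enumerate(c.iiv):
        P[nm] = P[nm] * math.exp(eta_s[k])
    f = c.conc_single(s, P)
    obs_idx = c.subject_slices()[0][s]
    y = c.y[obs_idx]
    v = sigma.sigma1**2 + (sigma.sigma2 * f) ** 2
    r = y - f
    prior = (eta_s * eta_s / np.maximum(omega2_vec, 1e-300)).sum()
    return float((r * r / v + np.log(v)).sum() + prior)


def _foce_ofv(c: _Compiled, typ, omega2_vec, sigma: SigmaParams, eta: np.ndarray) -> float:
    """FOCE-with-interaction OFV at given conditional modes."""
    f = c.conc(typ, eta)
    v = sigma.sigma1**2 + (sigma.sigma2 * f) ** 2
    if not np.all(np.isfinite(f)):
        bad = c.ids[c.obs_subj[int(np.argmax(~np.isfinite(f)))]]
        raise EngineError(f"non-finite prediction for subject {bad}")
    S, K = c.n_subj, c.n_eta
    if K == 0:
        r = c.y - f
        return float((r * r / v + np.log(v)).sum())
    G = c.eta_gradient(typ, eta)
    winv = 1.0 / v
    r = c.y - f + (G * eta[c.obs_subj]).sum(axis=1)
    a = np.stack(
        [np.bincount(c.obs_subj, weights=G[:, k] * winv * r, minlength=S) for k in range(K)],
        axis=1,
    )
    M = np.empty((S, K, K))
    inv_om = 1.0 / np.maximum(omega2_vec, 1e-300)
    for k in range(K):
        for k2 in range(k, K):
            m = np.bincount(c.obs_subj, weights=G[:, k] * G[:, k2] * winv, minlength=S)
            M[:, k, k2] = m
            M[:, k2, k] = m
        M[:, k, k] += inv_om[k]
    Minv_a = np.linalg.solve(M, a[..., None])[..., 0]
    quad = np.bincount(c.obs_subj, weights=r * r * winv, minlength=S) - (a * Minv_a).sum(axis=1)
    sign, logdetM = np.linalg.slogdet(M)
    if np.any(sign <= 0):
        bad = c.ids[int(np.argmax(sign <= 0))]
        raise EngineError(f"singular linearized covariance for subject {bad}")
    logdet = (
        np.bincount(c.obs_subj, weights=np.log(v), minlength=S)
        + np.log(np.maximum(omega2_vec, 1e-300)).sum()  # cancels against log|M|
        + logdetM
    )
    return float((quad + logdet).sum())


def _omega_vec(model: PopModelSpec, params: ParamSet) -> np.ndarray:
    try:
        return np.array([params.omega2[p] for p in model.iiv], dtype=float)
    except KeyError as exc:
        raise KeyError(f"omega^2 missing for IIV parameter {exc.args[0]!r}") from exc


def subject_objective(
    subject: SubjectRecord,
    model: PopModelSpec,
    params: ParamSet,
    eta: Mapping[str, float] | Sequence[float],
) -> float:
    """Joint -2 log density of one subject's data and random effects.

    ``sum_j [(Cobs - Cpred(eta))^2 / sd^2 + log sd^2]
    + sum_k [eta_k^2 / omega_k^2 + log omega_k^2]`` with 2*pi constants
    dropped — the quantity whose minimizer over eta is the conditional mode.
    """
    c = _Compiled(PopDataset((subject,)), model)
    if isinstance(eta, Mapping):
        evec = np.array([[eta.get(p, 0.0) for p in model.iiv]], dtype=float)
    else:
        evec = np.asarray(eta, dtype=float).reshape(1, len(model.iiv))
    om = _omega_vec(model, params)
    g = _subject_g(c, c.typical(params), om, params.sigma, evec)[0]
    return float(g[0] + np.log(om).sum())


def ofv(dataset: PopDataset, model: PopModelSpec, params: ParamSet) -> float:
    """FOCE objective function value of a dataset at fixed parameters.

    Deterministic: the inner optimization always starts from eta = 0.
    """
    c = _Compiled(dataset, model)
    typ = c.typical(params)
    om = _omega_vec(model, params)
    eta = _inner_etas(c, typ, om, params.sigma)
    return _foce_ofv(c, typ, om, params.sigma, eta)


# --------------------------------------------------------------------------
# population fit
# --------------------------------------------------------------------------


@dataclass
class FitOptions:
    """Numerical controls of the outer and inner optimizations."""

    maxiter: int = 400
    outer_ftol: float = 1e-10
    outer_gtol: float = 1e-5
    fd_step: float = 1e-6  # outer finite-difference gradient step (log scale)
    inner_gtol: float = 1e-8
    inner_maxiter: int = 60
    compute_se: bool = True
    hessian_step: float = 1e-4  # SE Hessian step (log scale)


@dataclass
class FitResult:
    """Estimation output: estimates, OFV, uncertainty, and per-unit diagnostics.

    ``se``/``rse`` are on the natural scale (``rse`` = 100*SE/estimate);
    ``eta`` holds the per-subject conditional modes (n_subj x n_eta, columns
    ordered as ``model.iiv``); ``pred``/``ipred``/``cwres`` are aligned with
    ``obs_subject``/``obs_time`` (one entry per non-missing observation).
    """

    model: PopModelSpec
    params: ParamSet
    ofv: float
    converged: bool
    message: str = ""
    n_iter: int = 0
    n_obj_evals: int = 0
    se: dict[str, float] | None = None
    rse: dict[str, float] | None = None
    eta: np.ndarray | None = None
    subject_ids: list | None = None
    pred: np.ndarray | None = None
    ipred: np.ndarray | None = None
    cwres: np.ndarray | None = None
    obs_subject: np.ndarray | None = None
    obs_time: np.ndarray | None = None


def default_initial_params(model: PopModelSpec) -> ParamSet:
    """Generic positive starting values for a fit (not tuned to any dataset)."""
    theta = {"v1": 10.0, "cl1": 5.0}
    if model.n_compartments == 2:
        theta.update({"v2": 10.0, "cl2": 5.0})
    return ParamSet(
        theta=theta,
        exponents=tuple(0.5 for _ in model.covariate_effects),
        omega2={p: 0.1 for p in model.iiv},
        sigma=SigmaParams(1.0, 0.2),
    )


def _pack(model: PopModelSpec, params: ParamSet):
    names: list[tuple[str, object]] = []
    x: list[float] = []
    bounds: list[tuple[float, float]] = []
    for p in model.theta_names:
        names.append(("theta", p))
        x.append(math.log(params.theta[p]))
        bounds.append((-7.0, 9.0))
    for i in range(len(model.covariate_effects)):
        names.append(("expo", i))
        x.append(params.exponents[i])
        bounds.append((-5.0, 5.0))
    for p in model.iiv:
        names.append(("omega2", p))
        x.append(math.log(max(params.omega2[p], 1e-6)))
        bounds.append((-14.0, 3.0))
    names.append(("sigma", "sigma1"))
    x.append(math.log(params.sigma.sigma1))
    bounds.append((-7.0, 5.0))
    names.append(("sigma", "sigma2"))
    x.append(math.log(max(params.sigma.sigma2, 1e-8)))
    bounds.append((-18.0, 2.0))
    return names, np.array(x), bounds


def _unpack(model: PopModelSpec, names, x) -> ParamSet:
    theta: dict[str, float] = {}
    expo = [0.0] * len(model.covariate_effects)
    omega2: dict[str, float] = {}
    sig = {}
    for (kind, key), xi in zip(names, x):
        if kind == "theta":
            theta[key] = math.exp(xi)
        elif kind == "expo":
            expo[key] = float(xi)
        elif kind == "omega2":
            omega2[key] = math.exp(xi)
        else:
            sig[key] = math.exp(xi)
    return ParamSet(theta, tuple(expo), omega2, SigmaParams(sig["sigma1"], sig["sigma2"]))


def _flat_names(names) -> list[str]:
    out = []
    for kind, key in names:
        if kind == "theta":
            out.append(f"tv_{key}")
        elif kind == "expo":
            out.append(f"expo_{key}")
        elif kind == "omega2":
            out.append(f"omega2_{key}")
        else:
            out.append(key)
    return out


def evaluate(dataset: PopDataset, model: PopModelSpec, params: ParamSet) -> FitResult:
    """Evaluate a model at fixed parameters: OFV, conditional modes, diagnostics.

    No optimization of the population parameters is performed; this is the
    entry point for simulation-based checks at known (e.g. generating)
    parameter values.
    """
    c = _Compiled(dataset, model)
    typ = c.typical(params)
    om = _omega_vec(model, params)
    eta = _inner_etas(c, typ, om, params.sigma)
    value = _foce_ofv(c, typ, om, params.sigma, eta)
    res = FitResult(
        model=model,
        params=replace(params),
        ofv=value,
        converged=True,
        message="evaluated at fixed parameters",
        eta=eta,
        subject_ids=list(c.ids),
        obs_subject=np.array([c.ids[i] for i in c.obs_subj], dtype=object),
        obs_time=c.t_obs.copy(),
    )
    res.pred, res.ipred, res.cwres = _gof_arrays(c, typ, om, params.sigma, eta)
    # resolve derived covariate references into the reported parameter set
    res.model = replace(model, covariate_effects=tuple(c.effects))
    return res


def fit_population(
    dataset: PopDataset,
    model: PopModelSpec,
    inits: ParamSet | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Estimate population parameters by minimizing the FOCE objective.

    The outer minimization runs on log-transformed typical values and
    variance components (covariate exponents untransformed) with L-BFGS-B
    and a finite-difference gradient; every objective evaluation re-solves
    the inner conditional-mode problem from eta = 0, so the objective is a
    deterministic function of the parameters.  Non-convergence is reported
    on the returned :class:`FitResult` (``converged=False``) with estimates
    still filled in.
    """
    opts = options or FitOptions()
    inits = inits or default_initial_params(model)
    c = _Compiled(dataset, model)
    n_fixed = len(model.theta_names) + len(model.covariate_effects)
    if c.n_obs < n_fixed:
        raise EngineError(
            f"{c.n_obs} observations cannot identify {n_fixed} fixed effects"
        )
    names, x0, bounds = _pack(model, inits)

    def objective(x: np.ndarray) -> float:
        try:
            params = _unpack(model, names, x)
            typ = c.typical(params)
            om = _omega_vec(model, params)
            eta = _inner_etas(
                c, typ, om, params.sigma, gtol=opts.inner_gtol, maxiter=opts.inner_maxiter
            )
            val = _foce_ofv(c, typ, om, params.sigma, eta)
        except (EngineError, FloatingPointError, OverflowError):
            return 1e12
        return val if np.isfinite(val) else 1e12

    lbfgsb_options = {
        "maxiter": opts.maxiter,
        "ftol": opts.outer_ftol,
        "gtol": opts.outer_gtol,
        "eps": opts.fd_step,
        "maxfun": 20000,
    }
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, options=lbfgsb_options
        )
        converged = bool(res.success)
        if not converged:
            # a line search can fail on the finite-difference noise floor even
            # at a stationary point; restart once and accept the point when no
            # material improvement remains
            res2 = optimize.minimize(
                objective, res.x, method="L-BFGS-B", bounds=bounds, options=lbfgsb_options
            )
            improvement = res.fun - res2.fun
            if res2.fun <= res.fun:
                res2.nit += res.nit
                res2.nfev += res.nfev
                res = res2
            converged = bool(res2.success) or 0 <= improvement < 0.1
    params_hat = _unpack(model, names, res.x)
    typ = c.typical(params_hat)
    om = _omega_vec(model, params_hat)
    eta = _inner_etas(c, typ, om, params_hat.sigma, gtol=opts.inner_gtol)
    final_ofv = _foce_ofv(c, typ, om, params_hat.sigma, eta)
    out = FitResult(
        model=replace(model, covariate_effects=tuple(c.effects)),
        params=params_hat,
        ofv=final_ofv,
        converged=bool(converged and np.isfinite(final_ofv)),
        message=str(res.message),
        n_iter=int(res.nit),
        n_obj_evals=int(res.nfev),
        eta=eta,
        subject_ids=list(c.ids),
        obs_subject=np.array([c.ids[i] for i in c.obs_subj], dtype=object),
        obs_time=c.t_obs.copy(),
    )
    out.pred, out.ipred, out.cwres = _gof_arrays(c, typ, om, params_hat.sigma, eta)
    if opts.compute_se:
        out.se, out.rse = _standard_errors(
            objective, res.x, names, params_hat, step=opts.hessian_step
        )
    return out


def _standard_errors(objective, x, names, params: ParamSet, step: float):
    """SEs from the inverse central-difference Hessian of OFV/2.

    The Hessian is taken on the transformed (log) scale and propagated to
    the natural scale by the delta method (SE_nat = estimate * SE_log for
    log-transformed components).  A non-positive-definite Hessian yields
    NaN standard errors rather than an error.
    """
    p = len(x)
    H = np.empty((p, p))
    f0 = objective(x) / 2.0

    def fh(dx):
        return objective(x + dx) / 2.0

    ei = np.eye(p)
    for i in range(p):
        H[i, i] = (fh(step * ei[i]) - 2.0 * f0 + fh(-step * ei[i])) / step**2
        for j in range(i + 1, p):
            val = (
                fh(step * (ei[i] + ei[j]))
                - fh(step * (ei[i] - ei[j]))
                - fh(step * (-ei[i] + ei[j]))
                + fh(-step * (ei[i] + ei[j]))
            ) / (4.0 * step**2)
            H[i, j] = H[j, i] = val
    flat = _flat_names(names)
    natural = params.flat()
    se: dict[str, float] = {}
    rse: dict[str, float] = {}
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance")
        se_t = np.sqrt(diag)
    except np.linalg.LinAlgError:
        se_t = np.full(p, np.nan)
    for (kind, _key), name, s in zip(names, flat, se_t):
        est = natural[name]
        se[name] = abs(est) * s if kind != "expo" else s
        rse[name] = 100.0 * se[name] / abs(est) if est != 0 else np.nan
    return se, rse


# --------------------------------------------------------------------------
# goodness-of-fit arrays (shared with txapk.diagnostics)
# --------------------------------------------------------------------------


def _gof_arrays(c: _Compiled, typ, omega2_vec, sigma: SigmaParams, eta: np.ndarray):
    """PRED, IPRED and CWRES per observation.

    PRED is the population prediction (eta = 0), IPRED the conditional one
    (eta = eta_hat).  CWRES decorrelates the FOCE residual
    ``y - f(eta_hat) + G eta_hat`` by the Cholesky factor of the linearized
    marginal covariance ``G Omega G' + diag(sd^2)``, the interaction variant
    evaluating sd at the conditional prediction.  With no random effects
    this reduces to ``(y - PRED) / residual_sd(PRED)``.
    """
    from scipy.linalg import solve_triangular

    S, K = c.n_subj, c.n_eta
    zeros = np.zeros((S, K))
    pred = c.conc(typ, zeros)
    ipred = c.conc(typ, eta)
    v = sigma.sigma1**2 + (sigma.sigma2 * ipred) ** 2
    cwres = np.empty(c.n_obs)
    if K == 0:
        cwres[:] = (c.y - pred) / np.sqrt(v)
        return pred, ipred, cwres
    G = c.eta_gradient(typ, eta)
    r = c.y - ipred + (G * eta[c.obs_subj]).sum(axis=1)
    Om = np.diag(omega2_vec)
    for s in range(S):
        idx = np.flatnonzero(c.obs_subj == s)
        if idx.size == 0:
            continue
        Gs = G[idx]
        V = Gs @ Om @ Gs.T + np.diag(v[idx])
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise EngineError(
                f"singular marginal covariance for subject {c.ids[s]}"
            ) from exc
        cwres[idx] = solve_triangular(L, r[idx], lower=True)
    return pred, ipred, cwres


# --------------------------------------------------------------------------
# model comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of nested fits by the -2 l.l.d. rule."""

    delta_ofv: float
    df: int
    threshold: float
    significant: bool


def lrt(parent: FitResult | float, extended: FitResult | float, df: int = 1) -> LRTResult:
    """Likelihood-ratio test between nested models.

    ``delta_ofv = OFV_extended - OFV_parent``; the extension is significant
    when the OFV *decrease* exceeds the chi-squared upper quantile at
    p = 0.01 for ``df`` degrees of freedom (6.635 for df = 1).
    """
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    ofv_p = parent.ofv if isinstance(parent, FitResult) else float(parent)
    ofv_e = extended.ofv if isinstance(extended, FitResult) else float(extended)
    delta = ofv_e - ofv_p
    threshold = float(stats.chi2.ppf(1.0 - LRT_ALPHA, df))
    return LRTResult(delta, df, threshold, bool(-delta > threshold))


# --------------------------------------------------------------------------
# shotgun covariate search
# --------------------------------------------------------------------------


@dataclass
class CovariateSearchRow:
    """One line of the model ladder (mirrors a covariate-search results table)."""

    number: int
    description: str
    subset: tuple[int, ...]
    parent: tuple[int, ...] | None
    ofv: float
    delta_ofv: float | None
    significant: bool | None
    converged: bool


@dataclass
class CovariateSearchTable:
    """Full shotgun ladder plus the selected final model."""

    rows: list[CovariateSearchRow]
    candidates: tuple[CovariateEffect, ...]
    selected: tuple[int, ...]
    selected_fit: FitResult
    fits: dict[tuple[int, ...], FitResult]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "model": r.number,
                    "description": r.description,
                    "OFV": r.ofv,
                    "dOFV": r.delta_ofv,
                    "significant": r.significant,
                    "converged": r.converged,
                }
                for r in self.rows
            ]
        )


def _describe(subset, candidates, base_no=None):
    if not subset:
        return "Base model"
    eff = candidates[subset[-1]]
    stem = f"Add {eff.covariate} on {eff.parameter}"
    return stem + (f" in model {base_no}" if base_no else "")


def shotgun_covariate_search(
    dataset: PopDataset,
    base_model: PopModelSpec,
    candidates: Sequence[CovariateEffect],
    inits: ParamSet | None = None,
    options: FitOptions | None = None,
) -> CovariateSearchTable:
    """Fit every subset of candidate covariate effects and select the final model.

    All ``2^k`` subsets (k <= 4) are fitted.  Each subset's parent is the
    same subset minus its last-added candidate, and its OFV drop versus the
    parent is tested at the -2 l.l.d. > 6.635 rule.  A subset qualifies for
    selection when dropping *any* of its effects worsens the OFV by more
    than the threshold (every retained covariate is significant) and its
    fit converged; among qualifying subsets the lowest OFV wins, ties going
    to the smaller model.  Non-convergent fits are kept in the table but
    excluded from selection.
    """
    candidates = tuple(candidates)
    k = len(candidates)
    if k > 4:
        raise ValueError(f"shotgun search supports at most 4 candidates, got {k}")
    if len({(e.parameter, e.covariate) for e in candidates}) != k:
        raise ValueError("candidate (parameter, covariate) pairs must be distinct")
    opts = options or FitOptions()
    base_inits = inits or default_initial_params(base_model)
    subsets: list[tuple[int, ...]] = [()]
    for size in range(1, k + 1):
        from itertools import combinations

        subsets.extend(tuple(s) for s in combinations(range(k), size))

    fits: dict[tuple[int, ...], FitResult] = {}
    base_fit = fit_population(dataset, base_model, base_inits, opts)
    fits[()] = base_fit
    for subset in subsets[1:]:
        model_s = replace(
            base_model,
            covariate_effects=base_model.covariate_effects
            + tuple(candidates[i] for i in subset),
        )
        sub_inits = ParamSet(
            theta=base_fit.params.theta,
            exponents=base_fit.params.exponents + tuple(0.5 for _ in subset),
            omega2=base_fit.params.omega2,
            sigma=base_fit.params.sigma,
        )
        fits[subset] = fit_population(dataset, model_s, sub_inits, opts)

    threshold = float(stats.chi2.ppf(1.0 - LRT_ALPHA, 1))
    numbers = {s: i + 1 for i, s in enumerate(subsets)}
    rows = []
    for subset in subsets:
        fit = fits[subset]
        if subset:
            parent = subset[:-1]
            delta = fit.ofv - fits[parent].ofv
            sig = -delta > threshold
            desc = _describe(subset, candidates, numbers[parent])
        else:
            parent, delta, sig = None, None, None
            desc = _describe(subset, candidates)
        rows.append(
            CovariateSearchRow(
                numbers[subset], desc, subset, parent, fit.ofv, delta, sig, fit.converged
            )
        )

    def qualifies(subset: tuple[int, ...]) -> bool:
        if not fits[subset].converged:
            return False
        for i in subset:
            reduced = tuple(j for j in subset if j != i)
            if not fits[reduced].converged:
                return False
            if not (fits[reduced].ofv - fits[subset].ofv > threshold):
                return False
        return True

    qualifying = [s for s in subsets if qualifies(s)]
    if not qualifying:
        qualifying = [()]
    selected = min(qualifying, key=lambda s: (fits[s].ofv, len(s)))
    return CovariateSearchTable(rows, candidates, selected, fits[selected], fits)
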