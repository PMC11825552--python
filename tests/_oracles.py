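"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: concentrations are
re-derived by numerical ODE integration, and the marginal likelihood is
integrated by adaptive Gauss-Hermite quadrature over the random effects
rather than by the engine's FOCE linearization.
"""

from itertools import product

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from scipy.special import logsumexp

from txapk import pk


def ode_conc(ts, doses, p, n_compartments=2):
    """Central concentration by stiff-safe ODE integration (oracle for predict_conc)."""
    ts = np.atleast_1d(np.asarray(ts, dtype=float))
    if n_compartments == 2:
        k10, k12, k21 = p.cl1 / p.v1, p.cl2 / p.v1, p.cl2 / p.v2

        def rhs(_t, A):
            return [-(k10 + k12) * A[0] + k21 * A[1], k12 * A[0] - k21 * A[1]]

        A = np.zeros(2)
    else:
        k10 = p.cl1 / p.v1

        def rhs(_t, A):
            return [-k10 * A[0]]

        A = np.zeros(1)
    dose_list = [(float(d.time), float(d.amount)) for d in doses]
    breakpoints = sorted(set([t for t, _ in dose_list] + ts.tolist()))
    out = np.zeros_like(ts)
    tcur = 0.0
    for bp in breakpoints:
        if bp > tcur:
            sol = solve_ivp(rhs, (tcur, bp), A, rtol=1e-11, atol=1e-13)
            A = sol.y[:, -1]
            tcur = bp
        for td, amt in dose_list:
            if td == bp:
                A[0] += amt
        out[ts == bp] = A[0] / p.v1
    return out


def exact_ofv_subject(subject, model, params, n_nodes=15):
    """-2 log marginal likelihood of one subject by adaptive Gauss-Hermite
    quadrature, with the same additive constants dropped as the engine
    (n * log 2pi), so the value is directly comparable to the engine OFV."""
    effects = tuple(
        pk.CovariateEffect(e.parameter, e.covariate, e.reference, x)
        for e, x in zip(model.covariate_effects, params.exponents)
    )
    typical = pk.apply_covariates(params.theta, effects, subject.covariates)
    times = np.array([o.time for o in subject.observations if not o.missing])
    y = np.array([o.concentration for o in subject.observations if not o.missing])
    iiv = model.iiv
    K = len(iiv)
    om = np.array([params.omega2[p] for p in iiv])
    s1, s2 = params.sigma.sigma1, params.sigma.sigma2

    def m2l(eta):
        # full joint -2 log density, all 2*pi constants included
        ind = pk.individualize(typical, dict(zip(iiv, eta)))
        f = pk.predict_conc(times, subject.doses, ind, model.n_compartments)
        v = s1**2 + (s2 * f) ** 2
        data = ((y - f) ** 2 / v + np.log(2 * np.pi * v)).sum()
        prior = (eta**2 / om + np.log(2 * np.pi * om)).sum()
        return float(data + prior)

    mode = minimize(
        m2l,
        np.zeros(K),
        method="Nelder-Mead",
        options={"xatol": 1e-11, "fatol": 1e-14, "maxiter": 4000, "maxfev": 8000},
    ).x
    # Hessian of -log joint density at the mode, by central differences
    h = 1e-4
    ei = np.eye(K)
    H = np.empty((K, K))
    f0 = m2l(mode) / 2
    for i in range(K):
        H[i, i] = (m2l(mode + h * ei[i]) / 2 - 2 * f0 + m2l(mode - h * ei[i]) / 2) / h**2
        for j in range(i + 1, K):
            H[i, j] = H[j, i] = (
                m2l(mode + h * (ei[i] + ei[j])) / 2
                - m2l(mode + h * (ei[i] - ei[j])) / 2
                - m2l(mode + h * (-ei[i] + ei[j])) / 2
                + m2l(mode - h * (ei[i] + ei[j])) / 2
            ) / (4 * h**2)
    L = np.linalg.cholesky(np.linalg.inv(H))
    z, w = np.polynomial.hermite.hermgauss(n_nodes)
    terms = []
    for idx in product(range(n_nodes), repeat=K):
        zv = np.array([z[i] for i in idx])
        eta = mode + np.sqrt(2.0) * (L @ zv)
        logw = float(np.log([w[i] for i in idx]).sum())
        terms.append(logw + float((zv**2).sum()) - 0.5 * m2l(eta))
    logI = logsumexp(terms) + K / 2 * np.log(2.0) + np.log(np.linalg.det(L))
    return float(-2.0 * logI - len(y) * np.log(2 * np.pi))


def exact_ofv(dataset, model, params, n_nodes=15):
    return sum(exact_ofv_subject(s, model, params, n_nodes) for s in dataset.subjects)
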