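"""Model evaluation: goodness-of-fit records, visual predictive check, bootstrap.

Three complementary checks of a fitted population PK model:

* per-observation goodness-of-fit quantities — population prediction
  (PRED, eta = 0), individual prediction (IPRED, eta = eta_hat) and
  conditional weighted residuals (CWRES), which should be standard-normal
  under the fitted model;
* the visual predictive check (VPC): many datasets simulated on the
  observed design, summarized as percentile bands against which the
  observed percentiles and the fraction of observations inside the central
  prediction interval are reported;
* the nonparametric bootstrap: subjects resampled with replacement, the
  model refitted per replicate, and the replicate estimates summarized as
  median, 2.5/97.5 percentiles, and %RSE (100 * SD / median).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import PopDataset
from .engine import (
    EngineError,
    FitOptions,
    FitResult,
    ParamSet,
    PopModelSpec,
    _Compiled,
    _inner_etas,
    _gof_arrays,
    _omega_vec,
    fit_population,
)

__all__ = [
    "DiagnosticRecord",
    "VPCResult",
    "BootstrapResult",
    "gof_diagnostics",
    "vpc",
    "bootstrap",
    "plot_gof",
]

#: default nominal sampling offsets per dose number, used for occasion binning
DEFAULT_OCCASIONS: dict[int, tuple[float, ...]] = {1: (0.5, 1.0, 2.0, 5.0), 2: (1.0, 6.0, 16.0)}


@dataclass(frozen=True)
class DiagnosticRecord:
    """Goodness-of-fit quantities for one observation."""

    subject_id: object
    time: float
    observed: float
    pred: float
    ipred: float
    cwres: float


def gof_diagnostics(fit: FitResult, dataset: PopDataset) -> list[DiagnosticRecord]:
    """PRED/IPRED/CWRES for every non-missing observation of ``dataset``.

    Quantities are recomputed at the fit's model and parameters (the
    conditional modes are re-solved), so the dataset need not be the one
    the model was fitted to.
    """
    c = _Compiled(dataset, fit.model)
    typ = c.typical(fit.params)
    om = _omega_vec(fit.model, fit.params)
    eta = _inner_etas(c, typ, om, fit.params.sigma)
    pred, ipred, cwres = _gof_arrays(c, typ, om, fit.params.sigma, eta)
    return [
        DiagnosticRecord(
            subject_id=c.ids[c.obs_subj[j]],
            time=float(c.t_obs[j]),
            observed=float(c.y[j]),
            pred=float(pred[j]),
            ipred=float(ipred[j]),
            cwres=float(cwres[j]),
        )
        for j in range(c.n_obs)
    ]


def diagnostics_frame(records: Sequence[DiagnosticRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ID": r.subject_id,
                "TIME": r.time,
                "DV": r.observed,
                "PRED": r.pred,
                "IPRED": r.ipred,
                "CWRES": r.cwres,
            }
            for r in records
        ]
    )


# --------------------------------------------------------------------------
# visual predictive check
# --------------------------------------------------------------------------


@dataclass
class VPCResult:
    """Binned VPC summary.

    ``bins`` labels each occasion ``(dose_number, nominal_offset)``;
    band arrays hold, per bin, the median across replicates of the
    replicate percentiles at (lower, 50, upper) where lower/upper bracket
    the central ``interval``; ``observed`` holds the same percentiles of
    the data.  ``fraction_inside`` is the share of observations between
    their bin's lower and upper band edges.
    """

    bins: list[tuple[int, float]]
    bin_n: np.ndarray
    band_lower: np.ndarray
    band_median: np.ndarray
    band_upper: np.ndarray
    observed_lower: np.ndarray
    observed_median: np.ndarray
    observed_upper: np.ndarray
    fraction_inside: float
    n_replicates: int
    interval: float
    seed: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_no": [b[0] for b in self.bins],
                "nominal_offset_h": [b[1] for b in self.bins],
                "n_obs": self.bin_n,
                "sim_lower": self.band_lower,
                "sim_median": self.band_median,
                "sim_upper": self.band_upper,
                "obs_lower": self.observed_lower,
                "obs_median": self.observed_median,
                "obs_upper": self.observed_upper,
            }
        )


def _occasion_labels(c: _Compiled, dataset: PopDataset, occasions: Mapping[int, Sequence[float]]):
    """Assign each observation to (dose number, nearest nominal offset)."""
    labels = []
    for sub in dataset.subjects:
        times = [o.time for o in sub.observations if not o.missing]
        for t in times:
            prior = [d for d in sub.doses if d.time <= t]
            dose_no = len(prior)
            offset = t - prior[-1].time
            offs = occasions.get(dose_no) or occasions[max(occasions)]
            nominal = min(offs, key=lambda o: abs(o - offset))
            labels.append((dose_no, float(nominal)))
    return labels


def vpc(
    fit: FitResult,
    dataset: PopDataset,
    n_replicates: int = 1000,
    interval: float = 0.90,
    seed=None,
    occasions: Mapping[int, Sequence[float]] | None = None,
) -> VPCResult:
    """Visual predictive check of ``fit`` against ``dataset``.

    Simulates ``n_replicates`` datasets on the observed design (same
    subjects, covariates, doses and times) with fresh eta and residual
    draws from the fitted parameters, truncating negative simulated
    concentrations at zero.  Observations are binned by nominal sampling
    occasion (the protocol times after each dose); per bin the replicate
    percentiles bracketing the central ``interval`` are summarized by
    their across-replicate median.  Occasion bins are induced by the
    observations themselves, so no bin is ever empty.  Fixing ``seed``
    makes the result fully reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0 < interval < 1:
        raise ValueError("interval must lie in (0, 1)")
    model, params = fit.model, fit.params
    c = _Compiled(dataset, model)
    typ = c.typical(params)
    om = _omega_vec(model, params)
    sigma = params.sigma
    rng = np.random.default_rng(seed)
    S, K = c.n_subj, c.n_eta
    lo_q = 100.0 * (1.0 - interval) / 2.0
    hi_q = 100.0 - lo_q
    sims = np.empty((n_replicates, c.n_obs))
    for rep in range(n_replicates):
        eta = rng.normal(0.0, np.sqrt(om), size=(S, K)) if K else np.zeros((S, 0))
        f = c.conc(typ, eta)
        sd = np.sqrt(sigma.sigma1**2 + (sigma.sigma2 * f) ** 2)
        ysim = f + rng.normal(0.0, 1.0, c.n_obs) * sd
        sims[rep] = np.maximum(ysim, 0.0)
    labels = _occasion_labels(c, dataset, occasions or DEFAULT_OCCASIONS)
    bins = sorted(set(labels))
    bin_idx = {b: np.array([j for j, l in enumerate(labels) if l == b]) for b in bins}
    nb = len(bins)
    band = np.empty((nb, 3))
    obs_pct = np.empty((nb, 3))
    inside = 0
    for bi, b in enumerate(bins):
        idx = bin_idx[b]
        rep_pct = np.percentile(sims[:, idx], [lo_q, 50.0, hi_q], axis=1)  # (3, R)
        band[bi] = np.median(rep_pct, axis=1)
        obs_pct[bi] = np.percentile(c.y[idx], [lo_q, 50.0, hi_q])
        inside += int(np.sum((c.y[idx] >= band[bi, 0]) & (c.y[idx] <= band[bi, 2])))
    return VPCResult(
        bins=bins,
        bin_n=np.array([bin_idx[b].size for b in bins]),
        band_lower=band[:, 0],
        band_median=band[:, 1],
        band_upper=band[:, 2],
        observed_lower=obs_pct[:, 0],
        observed_median=obs_pct[:, 1],
        observed_upper=obs_pct[:, 2],
        fraction_inside=inside / c.n_obs,
        n_replicates=n_replicates,
        interval=interval,
        seed=seed,
    )


# --------------------------------------------------------------------------
# nonparametric bootstrap
# --------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Replicate-estimate summaries: median, percentile CI and %RSE per parameter."""

    median: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    rse: dict[str, float]
    n_success: int
    n_requested: int
    seed: object = None

    def to_frame(self) -> pd.DataFrame:
        names = list(self.median)
        return pd.DataFrame(
            {
                "parameter": names,
                "median": [self.median[n] for n in names],
                "lower_2.5%": [self.lower[n] for n in names],
                "upper_97.5%": [self.upper[n] for n in names],
                "%RSE": [self.rse[n] for n in names],
            }
        )


def bootstrap(
    dataset: PopDataset,
    model: PopModelSpec,
    n_replicates: int = 1000,
    seed=None,
    fit: FitResult | None = None,
    inits: ParamSet | None = None,
    options: FitOptions | None = None,
) -> BootstrapResult:
    """Nonparametric bootstrap of the population fit.

    Each replicate resamples the subjects with replacement (keeping the
    cohort size), refits the model starting from the original point
    estimate (for speed and stability), and converged replicates are
    summarized per parameter as median, 2.5/97.5 percentiles and
    %RSE = 100 * SD / median.  If more than half the replicates fail to
    converge the bootstrap aborts with a diagnostic.
    """
    if len(dataset.subjects) < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    opts = options or FitOptions(compute_se=False)
    if fit is None:
        fit = fit_population(dataset, model, inits, replace(opts, compute_se=False))
        if not fit.converged:
            raise EngineError("point-estimate fit did not converge; bootstrap aborted")
    rng = np.random.default_rng(seed)
    point = fit.params
    rep_opts = replace(opts, compute_se=False)
    S = len(dataset.subjects)
    samples: list[dict[str, float]] = []
    failures = 0
    for _rep in range(n_replicates):
        pick = rng.integers(0, S, size=S)
        subs = tuple(
            replace(dataset.subjects[j], id=i + 1) for i, j in enumerate(pick)
        )
        ds_rep = PopDataset(subs, provenance={"bootstrap_of": dataset.provenance})
        try:
            fit_rep = fit_population(ds_rep, model, point, rep_opts)
        except EngineError:
            failures += 1
            continue
        if not fit_rep.converged:
            failures += 1
            continue
        samples.append(fit_rep.params.flat())
        if failures > n_replicates / 2:
            raise EngineError(
                f"bootstrap aborted: {failures} of {n_replicates} replicates failed"
            )
    if failures > n_replicates / 2 or not samples:
        raise EngineError(
            f"bootstrap aborted: {failures} of {n_replicates} replicates failed"
        )
    frame = pd.DataFrame(samples)
    med = frame.median()
    sd = frame.std(ddof=1) if len(frame) > 1 else frame.iloc[0] * 0.0
    return BootstrapResult(
        median=med.to_dict(),
        lower=frame.quantile(0.025).to_dict(),
        upper=frame.quantile(0.975).to_dict(),
        rse={k: (100.0 * sd[k] / abs(med[k]) if med[k] != 0 else math.nan) for k in frame},
        n_success=len(samples),
        n_requested=n_replicates,
        seed=seed,
    )


# --------------------------------------------------------------------------
# plots
# --------------------------------------------------------------------------


def plot_gof(records: Sequence[DiagnosticRecord], path) -> None:
    """Four-panel goodness-of-fit figure.

    Observed vs PRED, observed vs IPRED, CWRES vs PRED, and a CWRES
    normal quantile-quantile panel, written to ``path``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sstats

    df = diagnostics_frame(records)
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, xcol in zip(axes[0], ("PRED", "IPRED")):
        ax.scatter(df[xcol], df["DV"], s=10, alpha=0.6)
        lim = (0, max(df[xcol].max(), df["DV"].max()) * 1.05)
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(f"{xcol} (mg/L)")
        ax.set_ylabel("Observed (mg/L)")
    ax = axes[1][0]
    ax.scatter(df["PRED"], df["CWRES"], s=10, alpha=0.6)
    ax.axhline(0, color="k", lw=1)
    for y in (-2, 2):
        ax.axhline(y, color="r", lw=0.8, ls=":")
    ax.set_xlabel("PRED (mg/L)")
    ax.set_ylabel("CWRES")
    ax = axes[1][1]
    sstats.probplot(df["CWRES"], dist="norm", plot=ax)
    ax.set_title("")
    ax.set_xlabel("Standard normal quantiles")
    ax.set_ylabel("CWRES quantiles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
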