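"""Ligand-bias quantification.

Two complementary metrics are implemented:

**AUC coupling ratios.**  The area under the fitted concentration-response
curve (over the assayed log10-concentration window) captures potency, efficacy
and slope in a single number.  For each agonist the pairwise pathway ratios
AUC_i/AUC_j are formed and then divided element-wise by the reference
agonist's ratios; the reference therefore reads exactly 1 for every pathway
pair, and values above 1 mean preferential coupling to pathway i versus the
reference agonist.  The reference normalization cancels assay-scale
differences between biosensors.

**Operational-model bias factors.**  All agonist curves of one pathway are fit
jointly to the Black-Leff operational model with Em, Basal and the transducer
slope n shared; log KA is fixed at 0 for full agonists and estimated for
partial agonists, and each agonist gets its own transduction coefficient
log R = log10(tau/KA).  Within a pathway, Dlog(tau/KA) is taken against the
reference agonist; the between-pathway difference DDlog(tau/KA) gives the bias
factor 10**DDlog(tau/KA), with confidence intervals from a seed-controlled
residual-resampling bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .curves import operational_response
from .dose_response import HillFit, fit_dataset

__all__ = [
    "AUCCouplingProfile",
    "OperationalFitResult",
    "BiasTable",
    "compute_auc",
    "coupling_ratios",
    "fit_operational_global",
    "delta_logR",
    "bias_factor",
    "operational_bias_table",
    "classify_full_agonists",
]


# ---------------------------------------------------------------------------
# AUC-based coupling ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AUCCouplingProfile:
    """Per-agonist AUCs and pairwise pathway ratio matrices.

    ``ratios[agonist]`` and ``normalized[agonist]`` are pathway x pathway
    DataFrames; ``normalized`` is divided element-wise by the reference
    agonist's matrix, so ``normalized[reference]`` is all ones.
    """

    auc: pd.Series  # index (agonist, pathway)
    ratios: dict
    normalized: dict
    reference: str
    pathways: tuple


def compute_auc(fit: HillFit, window: tuple) -> float:
    """Area under the baseline-subtracted fitted curve over a log10-M window.

    Composite trapezoid on a 2001-point grid.  An unconverged fit propagates
    as NaN (missing) rather than raising.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("integration window must have positive width")
    if not fit.converged:
        return float("nan")
    x = np.linspace(lo, hi, 2001)
    from .curves import hill_response

    y = hill_response(10.0 ** x, fit.pec50, fit.top, fit.hill_n, 0.0)
    return float(np.trapezoid(y, x))


def coupling_ratios(
    aucs: Mapping[tuple, float],
    reference_agonist: str,
) -> AUCCouplingProfile:
    """Pairwise AUC ratio matrices, normalized to a reference agonist.

    ``aucs`` maps (agonist, pathway) -> AUC.  The reference agonist must have
    an AUC for every pathway appearing in the map; a zero reference AUC is an
    error naming the pathway.
    """
    series = pd.Series(dict(aucs))
    series.index = pd.MultiIndex.from_tuples(series.index, names=["agonist", "pathway"])
    agonists = series.index.get_level_values("agonist").unique()
    pathways = tuple(series.index.get_level_values("pathway").unique())
    if reference_agonist not in agonists:
        raise ValueError(f"reference agonist {reference_agonist!r} has no AUCs")
    for p in pathways:
        ref_auc = series.get((reference_agonist, p), np.nan)
        if np.isnan(ref_auc):
            raise ValueError(f"reference agonist lacks an AUC for pathway {p!r}")
        if ref_auc == 0:
            raise ValueError(f"reference agonist AUC is zero for pathway {p!r}")

    def matrix(agonist):
        vals = np.array([series.get((agonist, p), np.nan) for p in pathways])
        with np.errstate(divide="ignore", invalid="ignore"):
            m = vals[:, None] / vals[None, :]
        return pd.DataFrame(m, index=list(pathways), columns=list(pathways))

    ratios = {a: matrix(a) for a in agonists}
    ref = ratios[reference_agonist]
    normalized = {a: ratios[a] / ref for a in agonists}
    return AUCCouplingProfile(
        auc=series,
        ratios=ratios,
        normalized=normalized,
        reference=reference_agonist,
        pathways=pathways,
    )


# ---------------------------------------------------------------------------
# Operational model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperationalFitResult:
    """Joint operational fit of all agonist curves in one pathway.

    Em, Basal and n are shared across agonists; each agonist has its own
    log R (and log KA when classed as a partial agonist; full agonists have
    log KA fixed at 0).
    """

    pathway: str
    em: float
    basal: float
    n: float
    log_r: dict  # agonist -> logR
    log_ka: dict  # agonist -> logKA (0.0 fixed for full agonists)
    full_agonists: tuple
    rss: float
    converged: bool
    stderr: dict = field(default_factory=dict)
    message: str = ""


def _pack(theta, agonists, partials):
    em, basal, n = theta[0], theta[1], theta[2]
    log_r = dict(zip(agonists, theta[3 : 3 + len(agonists)]))
    log_ka = {a: 0.0 for a in agonists}
    for i, a in enumerate(partials):
        log_ka[a] = theta[3 + len(agonists) + i]
    return em, basal, n, log_r, log_ka


def _residuals(theta, agonists, partials, conc_by_agonist, y_by_agonist):
    em, basal, n, log_r, log_ka = _pack(theta, agonists, partials)
    res = []
    for a in agonists:
        pred = operational_response(conc_by_agonist[a], em, basal, n, log_ka[a], log_r[a])
        res.append(pred - y_by_agonist[a])
    return np.concatenate(res)


def _fit_operational_ls(agonists, partials, conc_by_agonist, y_by_agonist, theta0):
    n_par = len(theta0)
    lower = np.full(n_par, -np.inf)
    upper = np.full(n_par, np.inf)
    lower[2], upper[2] = 0.1, 10.0  # transducer slope
    lower[3 : 3 + len(agonists)] = -5.0
    upper[3 : 3 + len(agonists)] = 18.0
    if partials:
        lower[3 + len(agonists):] = -12.0
        upper[3 + len(agonists):] = 6.0
    theta0 = np.clip(theta0, lower + 1e-9, upper - 1e-9)
    return least_squares(
        _residuals,
        theta0,
        args=(agonists, partials, conc_by_agonist, y_by_agonist),
        bounds=(lower, upper),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )


def fit_operational_global(
    dataset: pd.DataFrame,
    full_agonists: Sequence[str],
    pathway: Optional[str] = None,
) -> OperationalFitResult:
    """Jointly fit all agonist curves of one pathway to the operational model.

    ``dataset`` is long-format; if it contains several pathways, ``pathway``
    selects one.  Deterministic multi-start: transducer-slope starts
    {0.5, 1, 2} with logR initialised from per-curve Hill pEC50s (for a full
    agonist with KA = 1 M and [A] << KA the half-max sits at [A] = 1/R, so
    pEC50 approximates logR); the best RSS wins.
    """
    df = dataset
    if pathway is not None:
        df = df[df["pathway"] == pathway]
    elif df["pathway"].nunique() > 1:
        raise ValueError("dataset has multiple pathways; pass pathway=...")
    if df.empty:
        raise ValueError(f"no data for pathway {pathway!r}")
    pathway_label = str(df["pathway"].iloc[0])
    agonists = list(df["agonist"].unique())
    if len(agonists) < 2:
        raise ValueError("global operational fit needs >= 2 agonists (sharing undefined)")
    for a in agonists:
        if df.loc[df["agonist"] == a, "conc_M"].nunique() < 4:
            raise ValueError(f"agonist {a!r}: need >= 4 distinct concentrations")
    full = [a for a in agonists if a in set(full_agonists)]
    partials = [a for a in agonists if a not in set(full_agonists)]

    conc_by_agonist = {a: df.loc[df["agonist"] == a, "conc_M"].to_numpy(float) for a in agonists}
    y_by_agonist = {a: df.loc[df["agonist"] == a, "response"].to_numpy(float) for a in agonists}

    hill = fit_dataset(df)
    pec50_init = {}
    for a in agonists:
        f = hill[(a, pathway_label)]
        pec50_init[a] = f.pec50 if f.converged and np.isfinite(f.pec50) else 6.0
    y_all = df["response"].to_numpy(float)
    em0 = float(np.max(y_all))
    basal0 = float(np.min(y_all))

    best = None
    for n0 in (0.5, 1.0, 2.0):
        # partial agonists start from logKA = 0 (full-agonist-like); the
        # optimizer moves it if the data demand it
        theta0 = np.array(
            [em0, basal0, n0] + [pec50_init[a] for a in agonists] + [0.0] * len(partials)
        )
        try:
            out = _fit_operational_ls(agonists, partials, conc_by_agonist, y_by_agonist, theta0)
        except Exception:
            continue
        rss = float(np.sum(out.fun ** 2))
        if best is None or rss < best[1] - 1e-12 * max(1.0, best[1]):
            best = (out, rss)
    if best is None:
        raise RuntimeError("operational fit failed from every start")
    out, rss = best
    em, basal, n, log_r, log_ka = _pack(out.x, agonists, partials)

    # stderr from the Gauss-Newton covariance (J^T J)^-1 * s^2
    stderr = {}
    dof = out.fun.size - out.x.size
    if dof > 0:
        try:
            jtj = out.jac.T @ out.jac
            cov = np.linalg.pinv(jtj) * (rss / dof)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            names = ["em", "basal", "n"] + [f"log_r[{a}]" for a in agonists] + [
                f"log_ka[{a}]" for a in partials
            ]
            stderr = dict(zip(names, se.tolist()))
        except np.linalg.LinAlgError:
            pass
    converged = bool(out.status > 0)
    message = ""
    if partials and not full:
        # with no full agonist anchoring KA, Em can be unidentifiable
        em_se = stderr.get("em", np.inf)
        if not np.isfinite(em_se) or em_se > 10 * max(abs(em), 1.0):
            converged = False
            message = "all agonists partial: Em poorly identified (CI unbounded)"
    return OperationalFitResult(
        pathway=pathway_label,
        em=float(em),
        basal=float(basal),
        n=float(n),
        log_r={a: float(v) for a, v in log_r.items()},
        log_ka={a: float(v) for a, v in log_ka.items()},
        full_agonists=tuple(full),
        rss=rss,
        converged=converged,
        stderr=stderr,
        message=message,
    )


def delta_logR(result: OperationalFitResult, agonist: str, reference: str) -> float:
    """Dlog(tau/KA) of ``agonist`` versus ``reference`` within one pathway."""
    for a in (agonist, reference):
        if a not in result.log_r:
            raise ValueError(f"agonist {a!r} not fitted in pathway {result.pathway!r}")
    return result.log_r[agonist] - result.log_r[reference]


def bias_factor(delta_pathway1: float, delta_pathway2: float) -> float:
    """Fold bias 10**DDlog(tau/KA) of pathway 1 over pathway 2.

    Both deltas must be normalized to the same reference agonist.  By
    construction bias(1,2) * bias(2,1) == 1.
    """
    return 10.0 ** (delta_pathway1 - delta_pathway2)


def classify_full_agonists(
    dataset: pd.DataFrame, reference: str, threshold: float = 0.9
) -> dict:
    """Per-pathway full/partial classification by fitted maximal response.

    An agonist is classed *full* in a pathway when its fitted top reaches at
    least ``threshold`` of the reference agonist's top there.  Returns
    {pathway: [full agonist labels]}; the reference is always full.
    """
    fits = fit_dataset(dataset)
    out = {}
    for pathway in dataset["pathway"].unique():
        ref_fit = fits.get((reference, pathway))
        if ref_fit is None or not ref_fit.converged:
            raise ValueError(f"reference curve missing/unconverged in pathway {pathway!r}")
        full = [reference]
        for (a, p), f in fits.items():
            if p != pathway or a == reference:
                continue
            if f.converged and f.top >= threshold * ref_fit.top:
                full.append(a)
        out[pathway] = full
    return out


# ---------------------------------------------------------------------------
# Bias table with bootstrap CIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasTable:
    """Dlog(tau/KA), DDlog(tau/KA) and fold bias per agonist and pathway pair.

    ``delta`` is agonist x pathway; ``bias`` has one row per
    (agonist, pathway_pair) with the fold bias 10**DDlog(tau/KA) and its
    percentile bootstrap 95% CI.  Sign convention: DD = pathway_a - pathway_b
    for the ordered pair reported in the row.
    """

    reference: str
    delta: pd.DataFrame
    bias: pd.DataFrame
    fits: dict  # pathway -> OperationalFitResult


def _bootstrap_pathway(result, df, n_boot, rng):
    """Residual-resampling bootstrap of per-agonist logR for one pathway."""
    agonists = list(result.log_r)
    partials = [a for a in agonists if a not in result.full_agonists]
    conc = {a: df.loc[df["agonist"] == a, "conc_M"].to_numpy(float) for a in agonists}
    y = {a: df.loc[df["agonist"] == a, "response"].to_numpy(float) for a in agonists}
    fitted = {
        a: operational_response(
            conc[a], result.em, result.basal, result.n, result.log_ka[a], result.log_r[a]
        )
        for a in agonists
    }
    residuals = np.concatenate([y[a] - fitted[a] for a in agonists])
    theta_hat = np.array(
        [result.em, result.basal, result.n]
        + [result.log_r[a] for a in agonists]
        + [result.log_ka[a] for a in partials]
    )
    draws = np.empty((n_boot, len(agonists)))
    for b in range(n_boot):
        y_star = {}
        for a in agonists:
            y_star[a] = fitted[a] + rng.choice(residuals, size=fitted[a].size, replace=True)
        out = _fit_operational_ls(agonists, partials, conc, y_star, theta_hat.copy())
        draws[b] = out.x[3 : 3 + len(agonists)]
    return agonists, draws


def operational_bias_table(
    dataset: pd.DataFrame,
    reference: str,
    pathways: Optional[Sequence[str]] = None,
    full_agonists: Optional[Mapping[str, Sequence[str]]] = None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> BiasTable:
    """Full operational-bias pipeline: global fits, deltas, bias factors, CIs.

    ``full_agonists`` maps pathway -> labels fitted with log KA fixed at 0;
    when omitted, agonists reaching >= 90% of the reference top are classed
    full automatically.  Set ``n_boot=0`` to skip the bootstrap.
    """
    if pathways is None:
        pathways = list(dataset["pathway"].unique())
    if full_agonists is None:
        full_agonists = classify_full_agonists(dataset, reference)
    rng = np.random.default_rng(seed)

    fits, boot = {}, {}
    for p in pathways:
        sub = dataset[dataset["pathway"] == p]
        fits[p] = fit_operational_global(sub, full_agonists.get(p, [reference]), pathway=p)
        if n_boot > 0:
            boot[p] = _bootstrap_pathway(fits[p], sub, n_boot, rng)

    agonists = sorted({a for p in pathways for a in fits[p].log_r})
    delta = pd.DataFrame(
        {
            p: {a: delta_logR(fits[p], a, reference) for a in fits[p].log_r}
            for p in pathways
        }
    )

    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for a in agonists:
        for p1, p2 in combinations(pathways, 2):
            dd = delta.loc[a, p1] - delta.loc[a, p2]
            row = {
                "agonist": a,
                "pathway_a": p1,
                "pathway_b": p2,
                "ddlog_tau_ka": dd,
                "bias_factor": 10.0 ** dd,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
            if n_boot > 0:
                ag1, d1 = boot[p1]
                ag2, d2 = boot[p2]
                i1, r1 = ag1.index(a), ag1.index(reference)
                i2, r2 = ag2.index(a), ag2.index(reference)
                dd_draws = (d1[:, i1] - d1[:, r1]) - (d2[:, i2] - d2[:, r2])
                factors = 10.0 ** dd_draws
                row["ci_low"] = float(np.quantile(factors, alpha))
                row["ci_high"] = float(np.quantile(factors, 1.0 - alpha))
            rows.append(row)
    return BiasTable(reference=reference, delta=delta, bias=pd.DataFrame(rows), fits=fits)
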