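"""Concentration-response preprocessing and variable-slope Hill fitting.

Datasets are long-format pandas DataFrames with columns
``agonist, pathway, conc_M, replicate, response`` (concentrations in molar,
responses in assay units such as uBRET or normalized GIRK current).

Fitting is unweighted least squares on the log10-concentration axis with a
deterministic multi-start strategy: a fixed grid of initial values is tried,
the best residual sum of squares wins, and ties go to the start with the
lowest initial pEC50.  This removes any dependence on optimizer heuristics so
a given dataset always yields the same fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np
import pandas as pd

from .curves import hill_response

__all__ = [
    "HillFit",
    "subtract_baseline",
    "normalize_to_reference",
    "fit_hill",
    "fit_dataset",
    "predict_curve",
]

CURVE_KEYS = ["agonist", "pathway"]


@dataclass(frozen=True)
class HillFit:
    """Result of a variable-slope sigmoid fit.

    ``top`` is the span above ``basal`` (the Emax of the curve); ``pec50`` is
    in -log10 molar.  ``extrapolated`` flags a pEC50 falling more than one log
    unit outside the fitted concentration window.
    """

    pec50: float
    top: float
    hill_n: float
    basal: float
    converged: bool
    rss: float
    n_points: int
    window: tuple  # (log10 cmin, log10 cmax)
    stderr: dict = field(default_factory=dict)
    extrapolated: bool = False
    message: str = ""


def _require_columns(df: pd.DataFrame, cols):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")


def subtract_baseline(dataset: pd.DataFrame, baselines: Optional[dict] = None) -> pd.DataFrame:
    """Subtract a per-curve baseline from all responses.

    ``baselines`` maps (agonist, pathway) -> value; for curves without an
    entry the mean response at the lowest assayed concentration is used.
    Applying the operation twice changes nothing beyond the first pass
    (the re-estimated baseline of a subtracted curve is ~0).
    """
    _require_columns(dataset, CURVE_KEYS + ["conc_M", "response"])
    out = dataset.copy()
    for key, sub in out.groupby(CURVE_KEYS, sort=False):
        if baselines is not None and key in baselines:
            b = baselines[key]
        else:
            cmin = sub["conc_M"].min()
            b = sub.loc[sub["conc_M"] == cmin, "response"].mean()
        out.loc[sub.index, "response"] = sub["response"] - b
    return out


def normalize_to_reference(
    dataset: pd.DataFrame,
    agonist: str,
    conc_M: float,
    pathway: Optional[str] = None,
    batch_col: Optional[str] = None,
) -> pd.DataFrame:
    """Divide all responses by the mean response of a reference condition.

    The reference is the response of ``agonist`` at ``conc_M`` (optionally in
    one ``pathway``); when ``batch_col`` is given the normalization is done
    per batch, mirroring protocols that normalize to a saturating reference
    agonist response in oocytes/cells from the same preparation.
    """
    _require_columns(dataset, CURVE_KEYS + ["conc_M", "response"])
    out = dataset.copy()

    def _norm(block: pd.DataFrame) -> pd.DataFrame:
        sel = (block["agonist"] == agonist) & np.isclose(block["conc_M"], conc_M)
        if pathway is not None:
            sel &= block["pathway"] == pathway
        if not sel.any():
            raise ValueError(
                f"reference condition ({agonist!r} at {conc_M} M) absent from dataset"
            )
        ref = block.loc[sel, "response"].mean()
        if ref <= 0:
            raise ValueError(f"reference mean response is non-positive ({ref})")
        block = block.copy()
        block["response"] = block["response"] / ref
        return block

    if batch_col is None:
        return _norm(out)
    parts = [_norm(sub) for _, sub in out.groupby(batch_col, sort=False)]
    return pd.concat(parts).sort_index()


def _hill_model(params, x):
    return hill_response(
        10.0 ** x,
        params["pec50"].value,
        params["top"].value,
        params["hill_n"].value,
        params["basal"].value,
    )


def fit_hill(
    conc_M,
    response,
    fix_basal: Optional[float] = None,
    n_starts: int = 5,
) -> HillFit:
    """Fit the variable-slope sigmoid to one curve's replicate-level points.

    Requires at least four distinct concentrations.  Non-convergence (e.g. a
    flat curve with no resolvable response) is reported through the
    ``converged`` flag rather than an exception.  The Hill slope is bounded to
    (0.1, 10) to exclude degenerate step fits.
    """
    conc = np.asarray(conc_M, dtype=float)
    y = np.asarray(response, dtype=float)
    if conc.size != y.size:
        raise ValueError("conc_M and response must be equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be strictly positive")
    distinct = np.unique(conc)
    n_free = 3 if fix_basal is not None else 4
    if distinct.size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if distinct.size < n_free:
        raise ValueError("fewer distinct concentrations than free parameters")

    x = np.log10(conc)
    window = (float(x.min()), float(x.max()))
    span = float(y.max() - y.min())
    scale = max(abs(float(y.max())), abs(float(y.min())), 1e-12)
    if span < 1e-9 * scale or span == 0.0:
        return HillFit(
            pec50=np.nan, top=0.0, hill_n=np.nan,
            basal=float(np.mean(y)), converged=False, rss=0.0,
            n_points=int(y.size), window=window,
            message="flat curve: no resolvable response",
        )

    pec50_starts = np.linspace(-window[1], -window[0], n_starts)
    n_grid = (0.5, 1.0, 2.0)
    best = None
    best_rss = np.inf
    for p0 in pec50_starts:  # ascending pEC50: ties resolved to lowest start
        for n0 in n_grid:
            params = lmfit.Parameters()
            params.add("pec50", value=p0, min=-window[1] - 3.0, max=-window[0] + 3.0)
            params.add("top", value=max(span, 1e-6), min=0.0)
            params.add("hill_n", value=n0, min=0.1, max=10.0)
            if fix_basal is not None:
                params.add("basal", value=fix_basal, vary=False)
            else:
                params.add("basal", value=float(y.min()))
            try:
                out = lmfit.minimize(
                    lambda p: _hill_model(p, x) - y, params,
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            rss = float(np.sum(out.residual ** 2))
            if best is None or rss < best_rss - 1e-12 * max(1.0, rss):
                best, best_rss = out, rss
    if best is None:
        return HillFit(
            pec50=np.nan, top=np.nan, hill_n=np.nan, basal=np.nan,
            converged=False, rss=np.inf, n_points=int(y.size), window=window,
            message="optimizer failed from every start",
        )
    p = best.params
    pec50 = float(p["pec50"].value)
    top = float(p["top"].value)
    converged = bool(best.success) and top > 1e-6 * span
    extrapolated = not (-window[1] - 1.0 <= pec50 <= -window[0] + 1.0)
    stderr = {
        name: (float(p[name].stderr) if p[name].stderr is not None else np.nan)
        for name in ("pec50", "top", "hill_n", "basal")
    }
    return HillFit(
        pec50=pec50,
        top=top,
        hill_n=float(p["hill_n"].value),
        basal=float(p["basal"].value),
        converged=converged,
        rss=best_rss,
        n_points=int(y.size),
        window=window,
        stderr=stderr,
        extrapolated=extrapolated,
    )


def fit_dataset(dataset: pd.DataFrame, fix_basal: Optional[float] = None) -> dict:
    """Fit every (agonist, pathway) curve in a long-format dataset.

    Returns {(agonist, pathway): HillFit}.
    """
    _require_columns(dataset, CURVE_KEYS + ["conc_M", "response"])
    return {
        key: fit_hill(sub["conc_M"], sub["response"], fix_basal=fix_basal)
        for key, sub in dataset.groupby(CURVE_KEYS, sort=False)
    }


def predict_curve(fit: HillFit, conc_M) -> np.ndarray:
    """Evaluate a fitted sigmoid at molar concentration(s)."""
    return hill_response(conc_M, fit.pec50, fit.top, fit.hill_n, fit.basal)
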