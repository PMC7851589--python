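"""Spatial regressions: logistic per-site fits, windowed OLS, permutations.

The headline statistic is the slope of a logistic regression of the per-site
substitution indicator on origin-relative distance,

    logit P(substitution at site) = b0 + b1 * distance,

fitted by iteratively reweighted least squares (IRLS).  b1 is reported per
base pair; with genome-scale distances it is tiny (1e-7-ish), so the design
is standardized internally and the estimate mapped back.  Supporting
analyses: ordinary least squares of window substitution totals on window
midpoints at several widths, an origin-shift permutation test (refit after
sliding the origin in 10-kb steps up to ±100 kb), and a taxon jackknife
that reruns the whole analysis with each taxon removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .replicon import Replicon, shift_origin, transform_distances
from .spatial import WINDOW_WIDTHS, window_aggregate

logger = logging.getLogger(__name__)

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8


@dataclass
class RegressionResult:
    model: str  # "logistic" | "linear"
    coefficient: float  # slope per bp of distance
    intercept: float
    se: float
    p_value: float
    n: int
    r_squared: Optional[float] = None  # linear fits only
    window: Optional[int] = None  # bp, or None for per-site fits
    flag: Optional[str] = None  # e.g. "separation", "not_converged"
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return np.isfinite(self.p_value) and self.p_value < 0.05


def fit_logistic(
    table: pd.DataFrame,
    response: str = "indicator",
    outlier_mask: Optional[np.ndarray] = None,
    **metadata,
) -> RegressionResult:
    """IRLS maximum-likelihood logistic fit of ``response`` on distance.

    Rows flagged in ``outlier_mask`` are excluded before fitting.  Complete
    or quasi-complete separation (a single response class, or divergent
    estimates) yields a flagged result rather than an exception.
    """
    d = table["distance"].to_numpy(dtype=float)
    y = table[response].to_numpy(dtype=float)
    if outlier_mask is not None:
        keep = ~np.asarray(outlier_mask, dtype=bool)
        d, y = d[keep], y[keep]
    n = d.shape[0]
    base = RegressionResult(
        model="logistic", coefficient=np.nan, intercept=np.nan, se=np.nan,
        p_value=np.nan, n=n, window=None, metadata=metadata,
    )
    if n == 0 or y.min() == y.max() or d.min() == d.max():
        base.flag = "separation" if n and y.min() == y.max() else "degenerate"
        return base

    scale = d.std()
    x = (d - d.mean()) / scale
    X = np.column_stack([np.ones(n), x])
    beta = np.zeros(2)
    ll_old = -np.inf
    converged = False
    for _ in range(MAX_IRLS_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            base.flag = "singular"
            return base
        ll = float(np.sum(y * eta - np.log1p(np.exp(np.clip(eta, -30, 30)))))
        if abs(ll - ll_old) < IRLS_TOL:
            converged = True
            break
        ll_old = ll
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se_scaled = np.sqrt(cov[1, 1])
    coef = beta[1] / scale
    se = se_scaled / scale
    zstat = beta[1] / se_scaled if se_scaled > 0 else np.nan
    base.coefficient = float(coef)
    base.intercept = float(beta[0] - beta[1] * d.mean() / scale)
    base.se = float(se)
    base.p_value = float(2 * stats.norm.sf(abs(zstat)))
    if not converged:
        base.flag = "not_converged"
    if abs(beta[1]) > 25:  # slope of 25 on standardized scale ~ separation
        base.flag = "separation"
    return base


def fit_window_linear(
    windows: pd.DataFrame,
    w: int,
    response: str = "n_events",
    exclude_outliers: bool = True,
    **metadata,
) -> Optional[RegressionResult]:
    """OLS of window substitution totals (or densities) on window midpoints."""
    data = windows.copy()
    data = data[np.isfinite(data["density"])]
    if exclude_outliers and "outlier" in data:
        data = data[~data["outlier"].astype(bool)]
    if len(data) < 3:
        logger.warning("window regression at w=%d skipped: %d windows", w, len(data))
        return None
    x = (data["start"] + data["end"]).to_numpy(dtype=float) / 2
    y = data[response].to_numpy(dtype=float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        model="linear",
        coefficient=float(fit.params[1]),
        intercept=float(fit.params[0]),
        se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=int(fit.nobs),
        r_squared=float(fit.rsquared),
        window=w,
        metadata={"response": response, **metadata},
    )


def fit_all_window_widths(
    table: pd.DataFrame,
    widths: Sequence[int] = WINDOW_WIDTHS,
    response: str = "n_events",
) -> List[RegressionResult]:
    results = []
    for w in widths:
        res = fit_window_linear(window_aggregate(table, w), w, response=response)
        if res is not None:
            results.append(res)
    return results


def origin_shift_permutation(
    table: pd.DataFrame,
    replicon: Replicon,
    step: int = 10_000,
    max_shift: int = 100_000,
    outlier_window: int = 10_000,
) -> pd.DataFrame:
    """Refit the logistic model after sliding the origin in ``step`` increments.

    Shifts run from −max_shift to +max_shift inclusive (21 fits at the
    defaults); shift 0 reproduces the base fit exactly.  The summary columns
    report whether the slope sign and significance survive each shift.
    """
    rows = []
    shifts = range(-max_shift, max_shift + step, step)
    for delta in shifts:
        try:
            rep_s = shift_origin(replicon, delta, max_shift=max_shift)
            shifted = table.copy()
            distance, signed = transform_distances(shifted["position"].to_numpy(), rep_s)
            shifted["distance"] = distance
            mask = _window_outlier_site_mask(shifted, outlier_window)
            res = fit_logistic(shifted, outlier_mask=mask, shift=delta)
        except Exception as exc:  # keep going; report the failing shift
            logger.warning("origin shift %+d failed: %s", delta, exc)
            rows.append({"shift": delta, "error": str(exc)})
            continue
        rows.append(
            {
                "shift": delta,
                "coefficient": res.coefficient,
                "se": res.se,
                "p_value": res.p_value,
                "n": res.n,
                "significant": res.significant,
                "sign": int(np.sign(res.coefficient)) if np.isfinite(res.coefficient) else 0,
                "flag": res.flag,
            }
        )
    out = pd.DataFrame(rows)
    good = out.dropna(subset=["coefficient"]) if "coefficient" in out else out.iloc[:0]
    out.attrs["sign_stable"] = bool(len(good) and good["sign"].nunique() == 1)
    out.attrs["significance_stable"] = bool(len(good) and good["significant"].all())
    return out


def _window_outlier_site_mask(table: pd.DataFrame, w: int) -> np.ndarray:
    """Per-site mask of rows lying in outlier density windows.

    The outlier rule operates on window densities; a site is excluded from
    the logistic fit when its window's density is an outlier.
    """
    if table.empty:
        return np.zeros(0, dtype=bool)
    win = window_aggregate(table, w)
    bad = set(win.loc[win["outlier"], "window"])
    if not bad:
        return np.zeros(len(table), dtype=bool)
    return (table["distance"] // w).astype(int).isin(bad).to_numpy()


def taxon_jackknife(
    taxa: Sequence[str],
    analysis_fn: Callable[[Optional[str]], RegressionResult],
    tree=None,
    min_taxa: int = 3,
) -> pd.DataFrame:
    """Rerun an analysis with each taxon removed and tabulate slope stability.

    ``analysis_fn(excluded)`` must rerun the full pipeline (block selection,
    reconstruction, regression) without the named taxon and return the
    logistic fit.  Removals flagged ``was_outgroup`` (the removed leaf was a
    child of the root) are the classic cause of sign flips: pruning the
    outgroup re-roots the effective comparison.
    """
    rows = []
    outgroups = set()
    if tree is not None:
        root = tree.nodes[tree.root]
        for c in root.children:
            t = tree.nodes[c].taxon
            if t is not None:
                outgroups.add(t)
    for taxon in taxa:
        if len(taxa) - 1 < min_taxa:
            logger.warning("removal of %s leaves <%d taxa; skipped", taxon, min_taxa)
            continue
        res = analysis_fn(taxon)
        rows.append(
            {
                "removed_taxon": taxon,
                "coefficient": res.coefficient,
                "se": res.se,
                "p_value": res.p_value,
                "n": res.n,
                "significant": res.significant,
                "sign": int(np.sign(res.coefficient)) if np.isfinite(res.coefficient) else 0,
                "was_outgroup": taxon in outgroups,
                "flag": res.flag,
            }
        )
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "window": r.window,
                "coefficient": r.coefficient,
                "intercept": r.intercept,
                "se": r.se,
                "p_value": r.p_value,
                "n": r.n,
                "r_squared": r.r_squared,
                "flag": r.flag,
                **{f"meta_{k}": v for k, v in r.metadata.items()},
            }
            for r in results
        ]
    )
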