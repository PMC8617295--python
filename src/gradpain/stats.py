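"""Group inference linking trend-surface parameters to pain sensitivity.

The central quantity is the partial coefficient of determination of the
9-column trend-surface block X over a nuisance design Z (age, sex,
menstrual-cycle day):

    R²_partial = (RSS_reduced − RSS_full) / RSS_reduced,

reduced = intercept + Z, full = reduced + X.  Its significance is assessed by
Freedman–Lane permutation: residuals of y on the reduced model are permuted,
added back to the reduced-model fit, and the statistic recomputed; the
p-value includes the observed statistic (p = (1 + #{null ≥ obs})/(1 + B)),
which guarantees validity and p > 0.  When the number of requested
permutations reaches n! the null is enumerated exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import scipy.stats

from gradpain.errors import DataError, NumericalError

log = logging.getLogger(__name__)


@dataclass
class PermutationResult:
    """Observed partial R², its permutation null and the resulting p-value."""

    observed: float
    null: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null, dtype=np.float64)
        if not (0.0 < self.p_value <= 1.0):
            raise NumericalError(f"permutation p-value {self.p_value} outside (0, 1]")


def _designs(y: np.ndarray, X: np.ndarray, Z: np.ndarray | None):
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n = y.shape[0]
    if Z is None or (hasattr(Z, "size") and np.asarray(Z).size == 0):
        Zm = np.empty((n, 0))
    else:
        Zm = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        if Zm.shape[0] != n:
            Zm = Zm.T
    if X.shape[0] != n or Zm.shape[0] != n:
        raise DataError("y, X and Z row counts differ")
    reduced = np.column_stack([np.ones(n), Zm])
    full = np.column_stack([reduced, X])
    if n <= full.shape[1]:
        cond = np.linalg.cond(full)
        raise NumericalError(
            f"full model has {full.shape[1]} columns for {n} observations (condition number {cond:.2e})"
        )
    return y, X, Zm, reduced, full


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    r = y - design @ beta
    return float(r @ r)


def partial_r2(y: np.ndarray, X: np.ndarray, Z: np.ndarray | None = None) -> float:
    """Fraction of variance in y explained by X over and above Z."""
    y, X, Zm, reduced, full = _designs(y, X, Z)
    rss_red = _rss(reduced, y)
    if rss_red <= 0:
        return 0.0  # nuisance already explains everything
    rss_full = _rss(full, y)
    return float(np.clip((rss_red - rss_full) / rss_red, 0.0, 1.0))


def _residual_projector(design: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(design)
    return np.eye(design.shape[0]) - Q @ Q.T


def permutation_test(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Freedman–Lane permutation test of the partial R² of X given Z.

    Reduced-model residuals are permuted, added back to the reduced-model
    fit, and the partial R² recomputed under each permutation.  Exact
    enumeration replaces Monte Carlo whenever n! ≤ n_perm.
    """
    if n_perm < 100:
        raise DataError("n_perm must be at least 100")
    y, X, Zm, reduced, full = _designs(y, X, Z)
    n = y.shape[0]
    R_red = _residual_projector(reduced)
    R_full = _residual_projector(full)
    yhat_red = y - R_red @ y
    resid = R_red @ y

    n_fact = math.factorial(n) if n <= 20 else None
    if n_fact is not None and n_fact <= n_perm:
        log.info("permutation_test: enumerating all %d permutations exactly", n_fact)
        perm_idx = np.array(list(iter_permutations(range(n))))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
        exhaustive = False

    Ystar = yhat_red[:, None] + resid[perm_idx].T  # n × B
    rss_red = np.sum((R_red @ Ystar) ** 2, axis=0)
    rss_full = np.sum((R_full @ Ystar) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        null = np.where(rss_red > 0, (rss_red - rss_full) / rss_red, 0.0)
    null = np.clip(null, 0.0, 1.0)

    obs_red = float(resid @ resid)
    obs_full = float(np.sum((R_full @ y) ** 2))
    observed = float(np.clip((obs_red - obs_full) / obs_red, 0.0, 1.0)) if obs_red > 0 else 0.0
    B = null.shape[0]
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + B)
    return PermutationResult(observed=observed, null=null, p_value=p, n_perm=B, seed=seed, exhaustive=exhaustive)


def per_coefficient_association(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Partial correlation of each trend-surface parameter with y given Z.

    Both y and each column of X are residualized on (intercept, Z); the
    Pearson correlation of the residuals is the partial correlation.  P-values
    come from a Freedman–Lane permutation of the y residuals (shared
    permutations across columns); Bonferroni adjustment multiplies by the
    number of parameters.
    """
    y, X, Zm, reduced, full = _designs(y, X, Z)
    n, p = X.shape
    R_red = _residual_projector(reduced)
    ry = R_red @ y
    RX = R_red @ X
    sdX = RX.std(axis=0)
    const = sdX <= 1e-12 * max(1.0, np.abs(X).max())
    if const.any():
        raise DataError(f"constant TSM parameter column(s) after residualization: {np.where(const)[0].tolist()}")
    if ry.std() <= 0:
        raise DataError("outcome has zero residual variance given nuisance")

    def _pcorrs(yv: np.ndarray) -> np.ndarray:
        yc = yv - yv.mean()
        Xc = RX - RX.mean(axis=0)
        return (Xc.T @ yc) / (np.sqrt((Xc**2).sum(axis=0)) * np.sqrt(yc @ yc))

    obs = _pcorrs(ry)
    rng = np.random.default_rng(seed)
    yhat_red = y - ry
    exceed = np.zeros(p)
    B = n_perm
    for _ in range(B):
        ystar = yhat_red + rng.permutation(ry)
        exceed += np.abs(_pcorrs(R_red @ ystar)) >= np.abs(obs)
    p_raw = (1.0 + exceed) / (1.0 + B)
    return pd.DataFrame(
        {
            "parameter": np.arange(p),
            "partial_r": obs,
            "p_raw": p_raw,
            "p_bonferroni": np.minimum(1.0, p * p_raw),
            "significant_bonferroni": np.minimum(1.0, p * p_raw) < 0.05,
        }
    )


def sex_comparison(tsm_table: np.ndarray | pd.DataFrame, sex: np.ndarray) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per TSM parameter between the sexes, with
    Bonferroni adjustment over the parameters of the hemisphere."""
    X = np.asarray(tsm_table, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    sex = np.asarray(sex)
    groups = np.unique(sex)
    if groups.size != 2:
        raise DataError(f"need exactly two sex groups, got {groups.tolist()}")
    a, b = X[sex == groups[0]], X[sex == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise DataError("both groups need at least 2 subjects")
    rows = []
    p_params = X.shape[1]
    for j in range(p_params):
        res = scipy.stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided", method="auto")
        p_adj = min(1.0, p_params * float(res.pvalue))
        rows.append((j, float(res.statistic), float(res.pvalue), p_adj))
    return pd.DataFrame(rows, columns=["parameter", "U", "p_raw", "p_bonferroni"])


def quintile_gradient_curves(
    connectopies: np.ndarray,
    composite: np.ndarray,
    axis_coordinate: np.ndarray,
    n_bins: int = 10,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Mean gradient curves of the low/high pain-sensitivity quintiles.

    ``connectopies`` is subjects × voxels (aligned, shared ROI), ``composite``
    the per-subject composite score and ``axis_coordinate`` the per-voxel
    posteroanterior position.  Subjects below the 20th / above the 80th
    percentile form the low/high groups; curves are group means of per-subject
    bin means over normalized position, with bootstrap-over-subjects 95%
    percentile bands.
    """
    C = np.atleast_2d(np.asarray(connectopies, dtype=np.float64))
    composite = np.asarray(composite, dtype=np.float64).ravel()
    coord = np.asarray(axis_coordinate, dtype=np.float64).ravel()
    n_subj, n_vox = C.shape
    if composite.shape[0] != n_subj or coord.shape[0] != n_vox:
        raise DataError("shape mismatch between connectopies, scores and coordinate")
    if n_bins > n_vox:
        raise DataError(f"n_bins {n_bins} exceeds ROI extent {n_vox} voxels")
    lo_cut, hi_cut = np.percentile(composite, [20, 80])
    low = composite < lo_cut
    high = composite > hi_cut
    if low.sum() < 5 or high.sum() < 5:
        raise DataError(f"need >= 5 subjects per quintile, got {int(low.sum())}/{int(high.sum())}")
    pos = (coord - coord.min()) / max(coord.max() - coord.min(), 1e-300)
    bins = np.clip((pos * n_bins).astype(int), 0, n_bins - 1)
    # subjects × bins matrix of bin means
    M = np.full((n_subj, n_bins), np.nan)
    for b in range(n_bins):
        sel = bins == b
        if sel.any():
            M[:, b] = C[:, sel].mean(axis=1)
    rng = np.random.default_rng(seed)
    out = {"bin_centers": (np.arange(n_bins) + 0.5) / n_bins}
    for name, grp in (("low", low), (("high"), high)):
        G = M[grp]
        curve = np.nanmean(G, axis=0)
        boots = np.empty((n_boot, n_bins))
        idx = np.arange(G.shape[0])
        for t in range(n_boot):
            boots[t] = np.nanmean(G[rng.choice(idx, size=idx.size, replace=True)], axis=0)
        ci = np.nanpercentile(boots, [2.5, 97.5], axis=0)
        out[name] = {"curve": curve, "ci_low": ci[0], "ci_high": ci[1], "n_subjects": int(grp.sum())}
    return out
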