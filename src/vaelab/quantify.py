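"""First-level analysis: outlier rejection, bias/gain regression, contrasts.

For each participant x condition cell, trials are screened for multivariate
outliers in the (stimulus, response) plane using robust Mahalanobis
distances from a minimum-covariance-determinant (MCD) fit, then the
perceived azimuth is regressed on the stimulus azimuth by ordinary least
squares.  The intercept is the spatial bias, the slope the spatial gain.
The ventriloquism-aftereffect magnitude for a fixation-condition x duration
cell is the bias difference between the -20 and +20 degree disparity blocks
(-20 > +20); the analogous slope difference is the gain change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.covariance import EmpiricalCovariance, MinCovDet

logger = logging.getLogger(__name__)

__all__ = ["BiasGainEstimate", "ContrastEstimate", "remove_outliers",
           "fit_bias_gain", "contrast_disparities", "first_level_pipeline"]


@dataclass(frozen=True)
class BiasGainEstimate:
    """OLS intercept (bias, degrees) and slope (gain) for one cell."""

    bias: float
    gain: float
    se_bias: float
    se_gain: float
    n_used: int
    n_rejected: int


@dataclass(frozen=True)
class ContrastEstimate:
    """-20 > +20 disparity differences in bias and gain for one cell."""

    vae_magnitude: float
    gain_change: float


def remove_outliers(
    stimulus_az: np.ndarray,
    response_az: np.ndarray,
    alpha: float = 0.01,
    random_state: int = 0,
) -> np.ndarray:
    """Boolean keep-mask from robust Mahalanobis screening.

    Location and scatter of the bivariate (stimulus, response) sample are
    estimated by MCD with subset fraction 0.75; squared robust distances are
    compared against the chi-squared quantile with 2 df at 1 - alpha.  On a
    singular robust scatter the classical covariance is used instead (with a
    warning); if that is singular too, nothing is rejected.
    """
    x = np.column_stack([np.asarray(stimulus_az, float),
                         np.asarray(response_az, float)])
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 trials for outlier screening, got {n}")
    if alpha <= 0:
        return np.ones(n, dtype=bool)
    cutoff = sps.chi2.ppf(1 - alpha, df=2)
    h = int(np.ceil(0.75 * n))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mcd = MinCovDet(support_fraction=h / n, random_state=random_state).fit(x)
        d2 = mcd.mahalanobis(x)
        if not np.all(np.isfinite(d2)):
            raise ValueError("non-finite robust distances")
    except (ValueError, np.linalg.LinAlgError):
        logger.warning("singular robust scatter; falling back to classical covariance")
        try:
            emp = EmpiricalCovariance().fit(x)
            d2 = emp.mahalanobis(x)
            if not np.all(np.isfinite(d2)):
                raise ValueError
        except (ValueError, np.linalg.LinAlgError):
            logger.warning("classical covariance singular too; rejecting nothing")
            return np.ones(n, dtype=bool)
    return d2 <= cutoff


def fit_bias_gain(
    stimulus_az: np.ndarray,
    response_az: np.ndarray,
    n_rejected: int = 0,
) -> BiasGainEstimate:
    """OLS regression of response on stimulus azimuth with coefficient SEs."""
    x = np.asarray(stimulus_az, float)
    y = np.asarray(response_az, float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 trials to fit bias/gain, got {len(x)}")
    if len(np.unique(x)) < 2:
        raise ValueError("rank-deficient design: all stimulus azimuths identical")
    res = sps.linregress(x, y)
    return BiasGainEstimate(
        bias=float(res.intercept), gain=float(res.slope),
        se_bias=float(res.intercept_stderr), se_gain=float(res.stderr),
        n_used=len(x), n_rejected=n_rejected)


def contrast_disparities(neg: BiasGainEstimate, pos: BiasGainEstimate) -> ContrastEstimate:
    """-20 > +20 contrast: positive VAE = recalibration toward the visual offset."""
    return ContrastEstimate(vae_magnitude=neg.bias - pos.bias,
                            gain_change=neg.gain - pos.gain)


REQUIRED_COLUMNS = ("participant", "condition", "duration_s", "disparity",
                    "cycle", "stimulus_az", "response_az")


def first_level_pipeline(
    trials: pd.DataFrame,
    alpha: float = 0.01,
    cycle: int | None = None,
) -> pd.DataFrame:
    """Outlier screening, per-cell regression, and disparity contrasts.

    Returns one row per participant x condition x duration with columns
    ``vae_magnitude`` and ``gain_change`` plus bias/gain per disparity and
    rejection counts.  ``cycle`` restricts the analysis to a single
    adapt/test cycle (1..4) for per-cycle re-analysis.  The overall rejection
    percentage is logged.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if cycle is not None:
        trials = trials[trials["cycle"] == cycle]
        if trials.empty:
            raise ValueError(f"no trials in cycle {cycle}")

    fits: dict[tuple, BiasGainEstimate] = {}
    n_total = n_rej = 0
    for key, grp in trials.groupby(["participant", "condition",
                                    "duration_s", "disparity"], sort=True):
        stim = grp["stimulus_az"].to_numpy()
        resp = grp["response_az"].to_numpy()
        # canonical order: FastMCD's subset search is row-order dependent,
        # so sort to make the pipeline invariant to trial order
        order = np.lexsort((resp, stim))
        stim, resp = stim[order], resp[order]
        if len(stim) >= 10:
            keep = remove_outliers(stim, resp, alpha=alpha)
        else:
            keep = np.ones(len(stim), dtype=bool)
        rejected = int((~keep).sum())
        n_total += len(stim)
        n_rej += rejected
        fits[key] = fit_bias_gain(stim[keep], resp[keep], n_rejected=rejected)
    if n_total:
        logger.info("outlier rejection: %d/%d trials (%.2f%%)",
                    n_rej, n_total, 100.0 * n_rej / n_total)

    rows = []
    cells = sorted({(p, c, d) for (p, c, d, _) in fits})
    for p, c, d in cells:
        try:
            neg, pos = fits[(p, c, d, -20)], fits[(p, c, d, 20)]
        except KeyError as e:
            raise ValueError(
                f"missing disparity block for participant={p}, condition={c}, "
                f"duration={d}") from e
        contrast = contrast_disparities(neg, pos)
        rows.append({
            "participant": p, "condition": c, "duration_s": d,
            "vae_magnitude": contrast.vae_magnitude,
            "gain_change": contrast.gain_change,
            "bias_neg": neg.bias, "bias_pos": pos.bias,
            "gain_neg": neg.gain, "gain_pos": pos.gain,
            "n_rejected": neg.n_rejected + pos.n_rejected,
            "n_used": neg.n_used + pos.n_used,
        })
    out = pd.DataFrame(rows)
    out.attrs["rejection_rate"] = n_rej / n_total if n_total else float("nan")
    return out
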