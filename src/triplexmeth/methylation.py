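"""Differential CpG methylation classification on beta-value matrices.

Each probe of a two-group (mutation carrier vs wild-type) beta matrix is
tested for increased methylation in the carrier group and assigned one of
three classes:

* ``HM``  (hypermethylated):      q <= fdr_threshold and delta >= delta_threshold
* ``NHM`` (non-hypermethylated):  q >  fdr_threshold and |delta| < delta_threshold
* ``OTHER``:                      everything else

where ``delta = mean(mut) - mean(wt)`` on the beta scale, p-values come
from a two-sided t-test (Welch by default, given the typically strong
group-size imbalance) and q-values from Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ClassifierParams", "welch_t_test", "bh_fdr", "classify_cpgs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierParams:
    fdr_threshold: float = 0.05
    delta_threshold: float = 0.1
    test_variant: str = "welch"

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not 0.0 < self.delta_threshold < 1.0:
            raise ValueError("delta_threshold must be in (0, 1)")
        if self.test_variant not in ("welch", "student"):
            raise ValueError("test_variant must be 'welch' or 'student'")


def welch_t_test(x, y, variant: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch (unpooled) variance by default.

    Degenerate inputs follow fixed conventions: zero variance in both
    groups with equal means gives (0, 1); zero variance with unequal means
    gives (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        logger.warning("zero variance in both groups with unequal means; p -> 0")
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(t), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    return multipletests(p, method="fdr_bh")[1]


def classify_cpgs(beta: pd.DataFrame, groups: pd.Series,
                  probes: pd.DataFrame | None = None,
                  params: ClassifierParams = ClassifierParams()) -> pd.DataFrame:
    """Classify every probe of a beta matrix into HM / NHM / OTHER.

    Parameters
    ----------
    beta
        Probes x samples methylation fractions in [0, 1].
    groups
        Per-sample labels, 'mut' or 'wt'; every beta column must be
        labelled and each group needs >= 2 samples.
    probes
        Optional coordinates (index probe_id, columns ``chrom``/``pos``)
        merged into the output.

    Returns a frame with columns probe_id, chrom, pos, delta, p_value,
    q_value, klass.  Probes with missing values in either group are
    excluded (and logged), so HM + NHM + OTHER partitions the tested set.
    """
    missing = [c for c in beta.columns if c not in groups.index]
    if missing:
        raise ValueError(f"samples without group labels: {missing[:5]}")
    g = groups.loc[beta.columns]
    mut = beta.loc[:, (g == "mut").to_numpy()]
    wt = beta.loc[:, (g == "wt").to_numpy()]
    if mut.shape[1] < 2 or wt.shape[1] < 2:
        raise ValueError("each group needs at least two samples")
    vals = beta.to_numpy(dtype=float)
    if np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9:
        raise ValueError("beta values must lie in [0, 1]")

    complete = ~np.isnan(vals).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d probes with missing beta values", n_dropped)
    xm = mut.to_numpy(dtype=float)[complete]
    xw = wt.to_numpy(dtype=float)[complete]

    delta = xm.mean(axis=1) - xw.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision-loss warning; those rows
        # are overwritten by the degenerate-variance conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(xm, xw, axis=1,
                               equal_var=(params.test_variant == "student"))
    # degenerate-variance conventions (constant = all values identical)
    both_const = (np.ptp(xm, axis=1) == 0) & (np.ptp(xw, axis=1) == 0)
    equal_means = both_const & (delta == 0)
    p = np.where(equal_means, 1.0, p)
    t = np.where(equal_means, 0.0, t)
    flat_diff = both_const & (delta != 0)
    if flat_diff.any():
        logger.warning("%d probes have zero variance but unequal means; p -> 0",
                       int(flat_diff.sum()))
        p = np.where(flat_diff, 0.0, p)
        with np.errstate(invalid="ignore"):
            t = np.where(flat_diff, np.sign(delta) * np.inf, t)

    q = bh_fdr(p)
    klass = np.full(delta.shape, "OTHER", dtype=object)
    klass[(q <= params.fdr_threshold) & (delta >= params.delta_threshold)] = "HM"
    klass[(q > params.fdr_threshold) & (np.abs(delta) < params.delta_threshold)] = "NHM"

    out = pd.DataFrame({
        "probe_id": beta.index[complete],
        "delta": delta,
        "p_value": p,
        "q_value": q,
        "klass": klass,
    })
    if probes is not None:
        coords = probes[["chrom", "pos"]]
        out = out.join(coords, on="probe_id")
        out = out[["probe_id", "chrom", "pos", "delta", "p_value", "q_value", "klass"]]
    return out.reset_index(drop=True)
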