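"""Activity-assay reduction and light x genotype binomial models.

Beam-break time series (5-second intervals) are reduced to one binomial
observation per individual: the number of intervals with at least one
beam-break out of the intervals retained after an acclimation window.
Activity is then modelled with three nested weighted binomial GLMs

    Model 1:  activity ~ Light + Clone + Block
    Model 2:  activity ~ Light + Genotype + Clone + Block
    Model 3:  activity ~ Light + Genotype + Light:Genotype + Clone + Block

compared by likelihood-ratio tests. Clone and Block enter as fixed
categorical effects; because each clone carries a single genotype, raw
clone dummies would be collinear with Genotype, so clone enters as
within-genotype deviation contrasts (each genotype's clones sum to zero).
That keeps the three models strictly nested with Genotype identifiable,
while absorbing clone-level variation exactly as a fixed-effect analogue
of a random clone intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2 as chi2_dist


def reduce_activity(raw: pd.DataFrame, exclude_first: float = 60.0,
                    interval_s: float = 5.0, min_breaks: int = 1
                    ) -> pd.DataFrame:
    """Collapse per-interval beam-break counts into per-individual
    activity.

    ``raw`` needs columns individual, interval (0-based index) and
    beam_breaks, plus any metadata columns (clone_id, genotype, light,
    block) which are carried through. Intervals within the first
    ``exclude_first`` minutes are dropped; an interval is active iff it has
    >= ``min_breaks`` beam-breaks. Individuals with no remaining intervals
    are excluded.
    """
    n_skip = int(exclude_first * 60.0 / interval_s)
    kept = raw[raw["interval"] >= n_skip]
    meta_cols = [c for c in raw.columns
                 if c not in ("interval", "beam_breaks")]
    rows = []
    for ind, grp in kept.groupby("individual", sort=False):
        n_int = len(grp)
        if n_int == 0:
            continue
        n_active = int((grp["beam_breaks"] >= min_breaks).sum())
        meta = grp.iloc[0][[c for c in meta_cols if c != "individual"]]
        rows.append({"individual": ind, **meta.to_dict(),
                     "n_intervals": n_int, "n_active": n_active})
    return pd.DataFrame(rows)


@dataclass
class ActivityModelFit:
    model_id: int
    params: pd.Series
    bse: pd.Series
    loglik: float
    n_params: int
    n_obs: int
    cov: pd.DataFrame | None = None


def _design(tab: pd.DataFrame, model_id: int):
    """Design matrix for the requested nested model (treatment coding with
    the first level as reference; clone as within-genotype sum-to-zero
    deviation contrasts)."""
    X = pd.DataFrame({"Intercept": np.ones(len(tab))}, index=tab.index)
    lights = sorted(tab["light"].unique())
    genotypes = sorted(tab["genotype"].unique())
    for lv in lights[1:]:
        X[f"light[{lv}]"] = (tab["light"] == lv).astype(float)
    if model_id >= 2:
        for gv in genotypes[1:]:
            X[f"genotype[{gv}]"] = (tab["genotype"] == gv).astype(float)
    if model_id >= 3:
        for gv in genotypes[1:]:
            for lv in lights[1:]:
                X[f"light[{lv}]:genotype[{gv}]"] = (
                    (tab["light"] == lv) & (tab["genotype"] == gv)
                ).astype(float)
    # clone deviations within genotype: for clones c1..ck of one genotype,
    # columns 1[c_i] - 1[c_k] (i < k); spans within-genotype contrasts only
    for gv in genotypes:
        clones = sorted(tab.loc[tab["genotype"] == gv, "clone_id"].unique())
        last = clones[-1]
        for cv in clones[:-1]:
            X[f"clone[{cv}]"] = ((tab["clone_id"] == cv).astype(float)
                                 - (tab["clone_id"] == last).astype(float))
    blocks = sorted(tab["block"].unique())
    for bv in blocks[1:]:
        X[f"block[{bv}]"] = (tab["block"] == bv).astype(float)
    return X


def fit_activity_models(tab: pd.DataFrame, models=(1, 2, 3)) -> dict:
    """Fit the nested binomial GLMs; returns {model_id: ActivityModelFit}.

    ``tab`` is a reduced activity table (columns clone_id, genotype, light,
    block, n_intervals, n_active). Raises on singular designs, naming the
    offending term.
    """
    if tab["light"].nunique() < 2 or tab["genotype"].nunique() < 2:
        raise ValueError("need >= 2 light levels and >= 2 genotypes")
    endog = np.column_stack([tab["n_active"],
                             tab["n_intervals"] - tab["n_active"]])
    fits = {}
    for mid in models:
        X = _design(tab, mid)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # identify a collinear column for the error message
            for drop in X.columns[::-1]:
                if np.linalg.matrix_rank(X.drop(columns=drop).to_numpy()) == rank:
                    raise ValueError(f"singular design in model {mid}: "
                                     f"term {drop!r} is collinear")
            raise ValueError(f"singular design in model {mid}")
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        fits[mid] = ActivityModelFit(model_id=mid, params=res.params,
                                     bse=res.bse, loglik=float(res.llf),
                                     n_params=X.shape[1], n_obs=len(tab),
                                     cov=res.cov_params())
    return fits


@dataclass
class LrtResult:
    chi2: float
    df: int
    p_value: float


def lrt(fit_small: ActivityModelFit, fit_big: ActivityModelFit) -> LrtResult:
    """Likelihood-ratio test between two nested fits on the same data."""
    if fit_big.n_obs != fit_small.n_obs:
        raise ValueError("fits are on different data")
    if fit_big.n_params < fit_small.n_params:
        raise ValueError("fit_big must be the larger model")
    small_terms = set(fit_small.params.index)
    if not small_terms <= set(fit_big.params.index):
        raise ValueError("models are not nested")
    stat = max(0.0, 2.0 * (fit_big.loglik - fit_small.loglik))
    df = fit_big.n_params - fit_small.n_params
    if df == 0:
        return LrtResult(chi2=stat, df=0, p_value=1.0)
    p = float(chi2_dist.sf(stat, df))
    return LrtResult(chi2=stat, df=df, p_value=p)
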