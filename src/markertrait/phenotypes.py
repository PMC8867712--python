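"""Phenotype derivation: budburst metrics, height cleaning, correlations, ANOVA.

Trait labels follow the TRAITYEAR convention (``BS2010``, ``BB2011``,
``H2013``, ``I2013``): bud set and budburst in days, height and annual
increment in mm.  The in-memory phenotype container is a wide DataFrame
(individuals x trait labels); :func:`to_long`/:func:`from_long` convert to
the delimited long format used on disk.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PhenotypeDataError", "derive_budburst_metrics", "clean_height_series",
           "trait_correlations", "nested_anova", "to_long", "from_long"]


class PhenotypeDataError(ValueError):
    pass


def to_long(pheno: pd.DataFrame) -> pd.DataFrame:
    long = pheno.reset_index().melt(id_vars=pheno.index.name or "index",
                                    var_name="trait_label", value_name="value")
    long.columns = ["individual_id", "trait_label", "value"]
    return long


def from_long(long: pd.DataFrame) -> pd.DataFrame:
    wide = long.pivot(index="individual_id", columns="trait_label", values="value")
    wide.columns.name = None
    return wide


# -- budburst -------------------------------------------------------------

def derive_budburst_metrics(obs: pd.DataFrame, stages=range(1, 8),
                            duration_stages=(4, 6), site: pd.Series | None = None
                            ) -> pd.DataFrame:
    """Per-individual budburst timing per stage plus core duration.

    ``obs`` has columns ``individual_id``, ``day`` (assessment day index)
    and ``stage`` (1-7).  The day a tree reaches a stage is the first
    assessment at which its recorded stage is >= that stage; a stage skipped
    between two assessments gets the midpoint of the two assessment dates.
    Timing is reported in days since the first tree site-wide reached that
    stage; duration is the raw-day difference between the two
    ``duration_stages``.  A stage never reached is missing.
    """
    required = {"individual_id", "day", "stage"}
    if not required.issubset(obs.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    stages = list(stages)
    reach = {}
    for ind, grp in obs.groupby("individual_id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(dtype=float)
        st = grp["stage"].to_numpy(dtype=float)
        if np.any(np.diff(st) < 0):
            raise PhenotypeDataError(
                f"decreasing budburst stage sequence for individual {ind!r}")
        row = {}
        for s in stages:
            idx = np.nonzero(st >= s)[0]
            if idx.size == 0:
                row[s] = np.nan
                continue
            j = idx[0]
            if st[j] == s or j == 0:
                row[s] = days[j]
            else:
                # skipped between assessments: midpoint of the bracketing dates
                row[s] = 0.5 * (days[j - 1] + days[j])
        reach[ind] = row
    raw = pd.DataFrame.from_dict(reach, orient="index").sort_index(axis=1)
    raw.index.name = "individual_id"
    if site is None:
        site_of = pd.Series("_all", index=raw.index)
    else:
        site_of = site.reindex(raw.index)
    timing = raw.copy()
    for _, members in raw.groupby(site_of).groups.items():
        block = raw.loc[members]
        timing.loc[members] = block - block.min(axis=0)
    s_lo, s_hi = duration_stages
    out = timing.rename(columns={s: f"timing_stage{s}" for s in stages})
    out["duration"] = raw[s_hi] - raw[s_lo]
    return out


# -- height cleaning ------------------------------------------------------

def clean_height_series(heights: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set physically impossible height reversals to missing.

    ``heights`` is individuals x years (columns in chronological order).
    A height lower than the last retained (non-missing) height is set to
    missing.  Increments are computed only between adjacent years where both
    endpoints survive cleaning; an increment spanning a cleaned-away year is
    left missing rather than back-filled.
    """
    H = heights.to_numpy(dtype=float).copy()
    n, m = H.shape
    for i in range(n):
        last = np.nan
        for j in range(m):
            v = H[i, j]
            if np.isnan(v):
                continue
            if not np.isnan(last) and v < last:
                H[i, j] = np.nan
            else:
                last = v
    cleaned = pd.DataFrame(H, index=heights.index, columns=heights.columns)
    inc_cols = {}
    cols = list(heights.columns)
    for j in range(1, m):
        inc_cols[cols[j]] = cleaned[cols[j]] - cleaned[cols[j - 1]]
    increments = pd.DataFrame(inc_cols, index=heights.index)
    return cleaned, increments


# -- correlations ---------------------------------------------------------

def trait_correlations(pheno: pd.DataFrame, groups: pd.Series | None = None,
                       min_pairs: int = 3) -> dict:
    """Pairwise-complete Pearson correlations per group.

    Returns ``{group: (r, p, n)}`` DataFrames over trait columns.  Cells
    with fewer than ``min_pairs`` complete pairs or a constant vector are
    missing (with a warning).
    """
    if groups is None:
        groups = pd.Series("_all", index=pheno.index)
    out = {}
    cols = list(pheno.columns)
    for gname, idx in pheno.groupby(groups.reindex(pheno.index)).groups.items():
        block = pheno.loc[idx]
        k = len(cols)
        r = np.full((k, k), np.nan)
        p = np.full((k, k), np.nan)
        n = np.zeros((k, k), dtype=int)
        for a in range(k):
            for b in range(a, k):
                pair = block[[cols[a], cols[b]]].dropna() if a != b \
                    else block[[cols[a]]].dropna()
                m = len(pair)
                n[a, b] = n[b, a] = m
                if a == b:
                    r[a, a] = 1.0
                    p[a, a] = 0.0
                    continue
                if m < min_pairs:
                    warnings.warn(f"fewer than {min_pairs} complete pairs for "
                                  f"({cols[a]}, {cols[b]}) in group {gname!r}")
                    continue
                x, y = pair.iloc[:, 0], pair.iloc[:, 1]
                if x.nunique() < 2 or y.nunique() < 2:
                    warnings.warn(f"constant vector for ({cols[a]}, {cols[b]}) "
                                  f"in group {gname!r}; correlation undefined")
                    continue
                res = stats.pearsonr(x, y)
                r[a, b] = r[b, a] = res.statistic
                p[a, b] = p[b, a] = res.pvalue
        mk = lambda arr: pd.DataFrame(arr, index=cols, columns=cols)
        out[gname] = (mk(r), mk(p), mk(n))
    return out


# -- nested ANOVA ---------------------------------------------------------

def nested_anova(data: pd.DataFrame, value: str = "value",
                 population: str = "population", family: str = "family",
                 block: str = "block") -> dict:
    """Mixed model with population fixed, family-in-population and block random.

    REML variance components are estimated with statsmodels' linear mixed
    model; the population effect is tested with a joint Wald test.  A block
    factor with a single level is dropped with a warning.

    Returns a dict with ``variance_components`` (family, block, residual),
    ``population_wald`` (statistic, p_value, df) and the fitted results.
    """
    import statsmodels.formula.api as smf

    df = data[[value, population, family, block]].dropna().copy()
    for col in (population, family, block):
        df[col] = df[col].astype(str)
        if col != block and df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    if df[population].nunique() == df[family].nunique() and \
            df.groupby(family)[population].nunique().max() == 1 and \
            df.groupby(population)[family].nunique().max() == 1:
        raise ValueError("family is confounded with population (singular design)")
    vc = {"family": f"0 + C({family})"}
    if df[block].nunique() >= 2:
        vc["block"] = f"0 + C({block})"
    else:
        warnings.warn("block factor has one level; dropped from the model")
    df["_grp"] = 1
    model = smf.mixedlm(f"{value} ~ C({population})", df, groups="_grp",
                        re_formula="0", vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs")
    vcs = {"family": float(fit.vcomp[list(vc).index("family")]),
           "residual": float(fit.scale)}
    vcs["block"] = float(fit.vcomp[list(vc).index("block")]) if "block" in vc else np.nan
    pop_terms = [name for name in fit.fe_params.index if name.startswith(f"C({population})")]
    contrast = np.zeros((len(pop_terms), len(fit.params)))
    names = list(fit.params.index)
    for i, t in enumerate(pop_terms):
        contrast[i, names.index(t)] = 1.0
    wald = fit.wald_test(contrast, scalar=True)
    return {"variance_components": vcs,
            "population_wald": {"statistic": float(wald.statistic),
                                "p_value": float(wald.pvalue),
                                "df": len(pop_terms)},
            "fit": fit}
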