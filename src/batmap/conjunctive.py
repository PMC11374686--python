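"""Conjunctive coding of human identity and landing location.

Mean peri-landing rates are modeled with a linear model carrying two
non-ordinal categorical predictors — the identity of the human at landing
and the landing location — plus their interaction, with sum-to-zero
(effects) coding.  Per-term significance comes from nested-model F tests
(type-II: each main effect against the model without it, the interaction
last), threshold p < 0.05.  The significance pattern maps to a coding
class:

- additive:      human and location significant, interaction not
- conjunctive:   significant interaction (with significant human and/or
                 location terms; a strict reading requiring a main effect
                 is available behind a flag)
- human_only:    only the human term
- location_only: only the location term
- none:          nothing significant (excluded from further analysis)
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

logger = logging.getLogger("batmap")


@dataclass
class LandingModelResult:
    unit_id: str
    analyzable: bool = True
    note: str = ""
    p_human: float = np.nan
    p_location: float = np.nan
    p_interaction: float = np.nan
    coding_class: str = "none"


def fit_landing_model(rates, human_labels, location_labels,
                      unit_id: str = "", alpha: float = 0.05,
                      strict_interaction: bool = False) -> LandingModelResult:
    """Fit rate ~ human * location (effects coding) and classify the unit."""
    df = pd.DataFrame({
        "rate": np.asarray(rates, float),
        "human": pd.Categorical([str(h) for h in human_labels]),
        "location": pd.Categorical([str(l) for l in location_labels]),
    })
    res = LandingModelResult(unit_id)
    if df["human"].nunique() < 2 or df["location"].nunique() < 2:
        res.analyzable = False
        res.note = "needs >=2 humans and >=2 locations represented"
        return res
    if np.allclose(df["rate"], df["rate"].iloc[0]):
        res.p_human = res.p_location = res.p_interaction = 1.0
        res.coding_class = "none"
        return res
    cells = df.groupby(["human", "location"], observed=True).size()
    full_cross = df["human"].nunique() * df["location"].nunique()
    if len(cells) < full_cross:
        logger.info("unit %s: %d empty human x location cells; interaction "
                    "estimated on observed cells only", unit_id,
                    full_cross - len(cells))
    model = smf.ols("rate ~ C(human, Sum) * C(location, Sum)", data=df).fit()
    try:
        table = anova_lm(model, typ=2)
    except Exception as exc:
        res.analyzable = False
        res.note = f"rank-deficient design: {exc}"
        return res
    # the interaction row contains ':', main-effect rows do not
    main_h = [i for i in table.index if "human" in i and ":" not in i]
    main_l = [i for i in table.index if "location" in i and ":" not in i]
    inter = [i for i in table.index if ":" in i]
    res.p_human = float(table.loc[main_h[0], "PR(>F)"]) if main_h else 1.0
    res.p_location = float(table.loc[main_l[0], "PR(>F)"]) if main_l else 1.0
    res.p_interaction = float(table.loc[inter[0], "PR(>F)"]) if inter else 1.0
    for name in ("p_human", "p_location", "p_interaction"):
        if not np.isfinite(getattr(res, name)):
            setattr(res, name, 1.0)
    res.coding_class = classify_coding(res.p_human, res.p_location,
                                       res.p_interaction, alpha,
                                       strict_interaction)
    return res


def classify_coding(p_human: float, p_location: float, p_interaction: float,
                    alpha: float = 0.05,
                    strict_interaction: bool = False) -> str:
    """Deterministic class from the three term p-values.

    Total over the 8 significance patterns.  With ``strict_interaction``,
    an interaction with neither main effect maps to 'none' instead of
    'conjunctive'.
    """
    h, l, x = p_human < alpha, p_location < alpha, p_interaction < alpha
    if x:
        if h or l or not strict_interaction:
            return "conjunctive"
        return "none"
    if h and l:
        return "additive"
    if h:
        return "human_only"
    if l:
        return "location_only"
    return "none"


def count_multilocation_modulation(perm_results, min_locations: int = 4) -> dict:
    """Histogram of #significantly modulated locations per unit.

    ``perm_results`` maps unit id -> list of PermTestResult (identity tests).
    Units analyzable at fewer than ``min_locations`` location/event families
    are excluded.  Returns unit id -> number of significant locations.
    """
    out = {}
    for unit_id, results in perm_results.items():
        analyzable = [r for r in results if r.analyzable]
        locs = {r.location_id for r in analyzable}
        if len(locs) < min_locations:
            continue
        sig_locs = {r.location_id for r in analyzable if r.significant}
        out[unit_id] = len(sig_locs)
    return out
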