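"""Allometric size adjustment of linear morphometric traits.

Linear traits (body depth, caudal peduncle depth, head length, snout
length) scale allometrically with body size, so raw values confound shape
with size.  Each trait M_o measured on a fish of standard length SL_o is
rescaled to the grand mean standard length SL-bar via the power formula

    M_adj = M_o * (SL_bar / SL_o)^b

where b is the common within-population allometric slope: the coefficient
of log10(SL) in the ANCOVA  log10(M) ~ log10(SL) + population.  Fitting on
the log scale is what makes the power-law back-transform exact; the
additive population term absorbs population mean differences so b reflects
within-population scaling only (the standard Reist / common-slope
procedure).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

MORPH_TRAITS = ("body_depth", "caudal_peduncle_depth", "head_length", "snout_length")


class SingularFitError(ValueError):
    """ANCOVA design is singular (e.g. constant standard length)."""


def ancova_slope(trait, sl, population) -> float:
    """Common allometric slope b of log10(trait) on log10(SL).

    Fits the additive ANCOVA ``log10(trait) ~ log10(SL) + C(population)``
    pooled across populations and returns the shared slope.

    Parameters
    ----------
    trait, sl : array-like, positive
        Trait values and standard lengths (cm).
    population : array-like
        Population labels (>= 2 levels recommended; 1 level reduces to a
        simple log-log regression).
    """
    trait = np.asarray(trait, dtype=float)
    sl = np.asarray(sl, dtype=float)
    population = np.asarray(population)
    if len(trait) < 3:
        raise ValueError("need at least 3 fish to estimate a slope")
    if np.any(trait <= 0) or np.any(sl <= 0):
        raise ValueError("traits and standard lengths must be positive")
    if np.ptp(np.log10(sl)) == 0:
        raise SingularFitError("standard length is constant; slope undefined")
    df = pd.DataFrame(
        {
            "log_trait": np.log10(trait),
            "log_sl": np.log10(sl),
            "population": population,
        }
    )
    fit = smf.ols("log_trait ~ log_sl + C(population)", data=df).fit()
    return float(fit.params["log_sl"])


def size_adjust(m_o, sl_o, sl_bar, b) -> float:
    """Adjusted trait M_o * (SL_bar / SL_o)^b; identity when SL_o = SL_bar or b = 0."""
    m_o = np.asarray(m_o, dtype=float)
    sl_o = np.asarray(sl_o, dtype=float)
    if np.any(m_o <= 0) or np.any(sl_o <= 0) or sl_bar <= 0:
        raise ValueError("trait and standard-length inputs must be positive")
    out = m_o * (sl_bar / sl_o) ** b
    return float(out) if out.ndim == 0 else out


def adjust_morphology(
    morph: pd.DataFrame, traits=MORPH_TRAITS, sl_col: str = "standard_length"
) -> tuple[pd.DataFrame, dict]:
    """Size-adjust every trait column; returns (table with ``_adj`` columns, slopes).

    SL-bar is the grand mean standard length over all measured fish (not
    per population).  Each trait gets its own fitted slope.
    """
    out = morph.copy()
    sl = morph[sl_col].to_numpy(dtype=float)
    sl_bar = float(sl.mean())
    slopes = {}
    for trait in traits:
        b = ancova_slope(morph[trait], sl, morph["population"])
        slopes[trait] = b
        out[f"{trait}_adj"] = size_adjust(morph[trait].to_numpy(), sl, sl_bar, b)
    out.attrs["sl_bar"] = sl_bar
    out.attrs["slopes"] = slopes
    return out, slopes
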