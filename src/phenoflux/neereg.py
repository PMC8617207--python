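"""Forward-stepwise regression of daily NEE on meteorology.

The candidate design is the full factorial expansion of air temperature
(T), vapour pressure deficit (VPD) and photosynthetic photon flux
density (PAR):

    NEE ~ b0 + b1 T + b2 VPD + b3 PAR
          + b4 T:VPD + b5 T:PAR + b6 VPD:PAR + b7 T:VPD:PAR

Terms enter one at a time, each step admitting the candidate with the
smallest partial p-value provided it is below the entry threshold
(default 0.05); there is no removal step.  All seven terms are
candidates throughout — hierarchy is not enforced because the candidate
set lists main effects and interactions symmetrically.  Ties in p-value
break on the fixed candidate order, which also makes selection
invariant to the ordering of input rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

CANDIDATE_TERMS = (
    "T", "VPD", "PAR", "T:VPD", "T:PAR", "VPD:PAR", "T:VPD:PAR",
)


def _design(df: pd.DataFrame) -> pd.DataFrame:
    t = df["T"].to_numpy(dtype=float)
    v = df["VPD"].to_numpy(dtype=float)
    p = df["PAR"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "T": t,
            "VPD": v,
            "PAR": p,
            "T:VPD": t * v,
            "T:PAR": t * p,
            "VPD:PAR": v * p,
            "T:VPD:PAR": t * v * p,
        }
    )


class StepwiseNEE:
    """Forward-stepwise NEE ~ meteorology model.

    Parameters
    ----------
    nee : array-like
        Daily mean NEE (umol CO2 m-2 s-1), growing-season days.
    t, vpd, par : array-like
        Daily mean air temperature (degC), VPD (hPa) and PAR
        (umol photon m-2 s-1) on the same days.
    """

    def __init__(self, nee, t, vpd, par):
        df = pd.DataFrame({"NEE": nee, "T": t, "VPD": vpd, "PAR": par})
        df = df.dropna().reset_index(drop=True)
        if len(df) < 30:
            raise ValueError(
                f"need >= 30 complete growing-season days, got {len(df)}"
            )
        self.endog = df["NEE"].to_numpy(dtype=float)
        self.design = _design(df)
        self.nobs = len(df)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, nee="NEE", t="T",
                       vpd="VPD", par="PAR") -> "StepwiseNEE":
        return cls(df[nee], df[t], df[vpd], df[par])

    def fit(self, p_enter: float = 0.05) -> "StepwiseNEEResults":
        """Run forward selection and fit the final OLS model."""
        included: list[str] = []
        remaining = list(CANDIDATE_TERMS)
        y = self.endog
        while remaining:
            best = None
            for term in remaining:
                cols = included + [term]
                x = sm.add_constant(self.design[cols].to_numpy())
                if np.linalg.matrix_rank(x) < x.shape[1]:
                    continue  # collinear with current model
                res = sm.OLS(y, x).fit()
                p = res.pvalues[-1]
                if best is None or p < best[1]:
                    best = (term, p)
            if best is None or best[1] >= p_enter:
                break
            included.append(best[0])
            remaining.remove(best[0])

        x = sm.add_constant(self.design[included].to_numpy()) if included \
            else np.ones((self.nobs, 1))
        if included and np.linalg.matrix_rank(x) < x.shape[1]:
            warnings.warn("dropping collinear term from final model",
                          stacklevel=2)
            included = included[:-1]
            x = sm.add_constant(self.design[included].to_numpy()) if included \
                else np.ones((self.nobs, 1))
        res = sm.OLS(y, x).fit()
        return StepwiseNEEResults(self, included, res, p_enter)


class StepwiseNEEResults:
    """Final model of a forward-stepwise fit.

    Attributes
    ----------
    included_terms : list of str
        Terms in entry order.
    params, bse, pvalues : pandas.Series
        Coefficients, standard errors and p-values indexed by term name
        (``const`` first).
    rsquared : float
    """

    def __init__(self, model, included, olsres, p_enter):
        self.model = model
        self.included_terms = list(included)
        self._res = olsres
        self.p_enter = p_enter
        names = ["const"] + self.included_terms
        self.params = pd.Series(olsres.params, index=names)
        self.bse = pd.Series(olsres.bse, index=names)
        self.pvalues = pd.Series(olsres.pvalues, index=names)
        self.rsquared = float(olsres.rsquared)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def summary(self) -> pd.DataFrame:
        """Tidy coefficient table of the final model."""
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "p": self.pvalues,
            }
        ).assign(rsquared=self.rsquared, n=self.nobs)

    def __repr__(self):
        terms = " + ".join(self.included_terms) or "(intercept only)"
        return (f"<StepwiseNEEResults: NEE ~ {terms}, "
                f"R2={self.rsquared:.3f}, n={self.nobs}>")


def stepwise_nee_regression(nee, t, vpd, par, p_enter: float = 0.05):
    """Functional wrapper: build the model and fit in one call."""
    return StepwiseNEE(nee, t, vpd, par).fit(p_enter=p_enter)
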