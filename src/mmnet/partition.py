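"""Average-weight variance partition across classifications.

A multiple-membership variance component sigma2_k cannot be compared
directly with the individual-level variance: individual i's contribution
from classification k is sigma2_k * sum_j w_ij^2, which under equal weights
is sigma2_k / n_i and shrinks with the number of memberships.  Averaging
over individuals gives the *average membership factor*

    f_k = (1/n) * sum_i sum_j w_ij^2      (isolates contribute 0),

so the average contribution of classification k to the variance of an
individual response is A_k = sigma2_k * f_k.  For a single-membership
classification f_k = 1 exactly.  For a standardized response the raw total
sigma2_e + sum_k A_k should be close to 1, and the share of variation
attributed to each level is A_k / (sigma2_e + sum_k A_k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gibbs import MMMCRegressor
from .weights import WeightMatrix

__all__ = ["VariancePartition", "average_membership_factor", "variance_shares"]


def average_membership_factor(W) -> float:
    """f = (1/n) sum_i sum_j w[i,j]^2 for one classification's weight matrix."""
    if isinstance(W, WeightMatrix):
        W = W.W
    W = sp.csr_matrix(W)
    n = W.shape[0]
    return float(np.sum(W.data**2) / n)


@dataclass
class VariancePartition:
    """Per-classification variance components, factors, contributions, shares."""

    components: Mapping[str, float]      # raw sigma2_k
    factors: Mapping[str, float]         # f_k
    contributions: Mapping[str, float]   # A_k = sigma2_k * f_k
    sigma2_e: float
    raw_total: float                     # sigma2_e + sum A_k
    unadjusted_total: float              # sigma2_e + sum sigma2_k
    shares: Mapping[str, float]          # A_k / raw_total, plus "individual"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "classification": k,
                "variance": self.components[k],
                "factor": self.factors[k],
                "avg_contribution": self.contributions[k],
                "share": self.shares[k],
            }
            for k in self.components
        ]
        rows.append(
            {
                "classification": "individual",
                "variance": self.sigma2_e,
                "factor": 1.0,
                "avg_contribution": self.sigma2_e,
                "share": self.shares["individual"],
            }
        )
        return pd.DataFrame(rows)


def variance_shares(result, factors: Mapping[str, float]) -> VariancePartition:
    """Partition the response variance across classifications.

    Parameters
    ----------
    result : fitted :class:`~mmnet.gibbs.MMMCRegressor` or mapping
        Either a fitted model (posterior-mean variance components are used)
        or a mapping {name: sigma2_k, ..., "individual": sigma2_e}.
    factors : mapping
        Average membership factor per classification
        (:func:`average_membership_factor`); must cover exactly the model's
        classifications.
    """
    if isinstance(result, MMMCRegressor):
        comps = dict(result.variance_components_)
    else:
        comps = dict(result)
    sigma2_e = comps.pop("individual")
    if set(comps) != set(factors):
        raise ValueError(
            f"classification mismatch: model has {sorted(comps)}, "
            f"factors given for {sorted(factors)}"
        )
    contributions = {k: comps[k] * factors[k] for k in comps}
    raw_total = sigma2_e + sum(contributions.values())
    shares = {k: contributions[k] / raw_total for k in comps}
    shares["individual"] = sigma2_e / raw_total
    return VariancePartition(
        components=comps,
        factors=dict(factors),
        contributions=contributions,
        sigma2_e=sigma2_e,
        raw_total=raw_total,
        unadjusted_total=sigma2_e + sum(comps.values()),
        shares=shares,
    )
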