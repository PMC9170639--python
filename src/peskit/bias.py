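"""Analytic and numerical bias models for unequally weighted RT mixtures.

When congruent and incongruent RTs are pooled before taking a central
tendency, the result is the central tendency of a two-component mixture whose
weights are the (possibly imbalanced) trial proportions.  For the mean the
bias relative to the unweighted midpoint of the component means is exactly
linear in the interference effect I = mean(incon) - mean(con) and the
imbalance:

    RT_bias = I / 100 * (deviation from 50%, in percentage points)

e.g. a 100-ms interference with 70% congruent trials gives a 20-ms bias.  For
the median the bias is a non-linear function of interference, imbalance and
the component SD, and is always at least as large (same sign) as the mean
bias; it is computed here by root-finding on the mixture CDF.

Sign conventions
----------------
``mean_bias`` follows the deviation-from-50% formula: positive when congruent
(fast) trials are over-represented.  Because the surplus of fast trials pulls
the *pooled* cell value down, this equals (unweighted midpoint) - (pooled
value) of the cell.  The grid functions report cell-level bias directly as
(weighted central) - (unweighted midpoint), i.e. the negative of
``mean_bias`` for the mean; PES-level bias composes as baseline-cell bias
minus post-error-cell bias (see :func:`predicted_pes_bias`), matching the
uncorrected-minus-corrected difference of the estimators exactly for means.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .estimate import Central

__all__ = [
    "MixtureSpec",
    "mean_bias",
    "mixture_central",
    "bias_grid",
    "predicted_pes_bias",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component normal RT mixture for one trial-type cell.

    ``interference_ms`` is mean(incongruent) - mean(congruent); both
    components share ``sd_ms``.  ``prop_congruent`` is the mixture weight of
    the (faster) congruent component.  ``mu_con_ms`` anchors the congruent
    component; bias results do not depend on it.
    """

    interference_ms: float
    prop_congruent: float
    sd_ms: float = 50.0
    central: Central = Central.MEAN
    mu_con_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_ms < 0:
            raise ValueError("sd_ms must be non-negative")
        if not 0.0 <= self.prop_congruent <= 1.0:
            raise ValueError("prop_congruent must lie in [0, 1]")

    @property
    def mu_incon_ms(self) -> float:
        return self.mu_con_ms + self.interference_ms

    @property
    def midpoint_ms(self) -> float:
        """Unweighted midpoint of the component means (the corrected value)."""
        return self.mu_con_ms + self.interference_ms / 2.0


def mean_bias(interference_ms: float, prop_congruent: float) -> float:
    """Analytic mean-estimation bias of a pooled cell, in ms.

    ``interference_ms / 100 * deviation-from-50%``: positive when congruent
    trials are over-represented (equivalently, the unweighted mean exceeds
    the pooled mean by this amount, since congruent trials are faster).
    Linear in both arguments; independent of the component SD.
    """
    deviation_pp = 100.0 * (prop_congruent - 0.5)
    return interference_ms / 100.0 * deviation_pp


def mixture_central(spec: MixtureSpec) -> float:
    """Central tendency of the weighted two-normal mixture, in ms.

    Mean: closed-form weighted mean of the component means.  Median: the root
    ``m`` of ``w * Phi((m - mu_con)/sd) + (1-w) * Phi((m - mu_incon)/sd) =
    1/2``, bracketed and solved to 0.01-ms tolerance (the mixture CDF is
    strictly increasing).  With ``sd = 0`` the mixture CDF is a two-step
    function: the median is the majority component's mean, or the midpoint at
    ``w = 1/2``.
    """
    w = spec.prop_congruent
    mu_c, mu_i = spec.mu_con_ms, spec.mu_incon_ms
    if spec.central is Central.MEAN:
        return w * mu_c + (1.0 - w) * mu_i
    if spec.sd_ms == 0:
        if w > 0.5:
            return mu_c
        if w < 0.5:
            return mu_i
        return (mu_c + mu_i) / 2.0
    sd = spec.sd_ms

    def cdf_half(m: float) -> float:
        return w * norm.cdf((m - mu_c) / sd) + (1.0 - w) * norm.cdf((m - mu_i) / sd) - 0.5

    lo = min(mu_c, mu_i) - 10.0 * sd
    hi = max(mu_c, mu_i) + 10.0 * sd
    return float(brentq(cdf_half, lo, hi, xtol=0.01))


def cell_bias(spec: MixtureSpec) -> float:
    """Cell-level bias: (weighted central) - (unweighted midpoint), in ms.

    Negative when congruent (fast) trials are over-represented.  For the mean
    this equals ``-mean_bias(interference, prop_congruent)`` exactly.
    """
    return mixture_central(spec) - spec.midpoint_ms


def predicted_pes_bias(baseline: MixtureSpec, post_error: MixtureSpec) -> float:
    """Predicted uncorrected-minus-corrected PES bias from two cell specs.

    PES subtracts the baseline cell from the post-error cell, so cell-level
    biases enter with opposite signs:

        bias(PES) = cell_bias(post_error) - cell_bias(baseline)

    For mean-based cells this reduces to ``mean_bias(baseline) -
    mean_bias(post_error)`` and matches :func:`peskit.estimate.pes_bias`
    exactly when the per-cell interference and imbalance values are plugged
    in.
    """
    return cell_bias(post_error) - cell_bias(baseline)


def bias_grid(interference_range: Sequence[float] = tuple(np.arange(0.0, 201.0, 5.0)),
              imbalance_range: Sequence[float] = (0.55, 0.60, 0.65, 0.70),
              sd_values: Sequence[float] = (50.0, 100.0),
              centrals: Iterable[Central] = (Central.MEAN, Central.MEDIAN)
              ) -> pd.DataFrame:
    """Cell-level bias over a grid of interference, imbalance, SD and central.

    Columns: ``interference_ms``, ``prop_congruent``, ``sd_ms``, ``central``,
    ``bias_ms`` with ``bias_ms = (weighted central) - (unweighted midpoint)``.
    Mean rows are identical across SD values; median rows are not, and their
    bias magnitude is at least the mean's at every point.
    """
    if not (len(interference_range) and len(imbalance_range) and len(sd_values)):
        raise ValueError("grid ranges must be non-empty")
    rows = []
    for interference, prop, sd, central in itertools.product(
        interference_range, imbalance_range, sd_values, centrals
    ):
        spec = MixtureSpec(
            interference_ms=float(interference),
            prop_congruent=float(prop),
            sd_ms=float(sd),
            central=central,
        )
        rows.append(
            {
                "interference_ms": float(interference),
                "prop_congruent": float(prop),
                "sd_ms": float(sd),
                "central": central.value,
                "bias_ms": cell_bias(spec),
            }
        )
    return pd.DataFrame(rows)
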