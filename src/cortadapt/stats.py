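"""Validation statistics for observed-vs-predicted thickness-change maps.

Thickness-change fields are far from normal (pixel quantisation, masked
artefact regions, heavy right tails where growth concentrates), which a
one-sample Kolmogorov-Smirnov check makes explicit; comparisons therefore
use Kendall's tau rank correlation (tau-b, tie-corrected) rather than a
parametric coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .thickness import ThicknessChangeMap

__all__ = ["CorrelationResult", "kendall_tau", "ks_normality",
           "compare_maps", "compare_sweep"]


@dataclass
class CorrelationResult:
    tau: float
    p_value: float
    n: int
    method: str = "tau-b"


def kendall_tau(x, y) -> CorrelationResult:
    """Kendall's tau-b between paired samples.

    Pairs where either value is missing (NaN) are dropped first; ties are
    handled by the tau-b correction.  The p-value is exact for small
    tie-free samples and uses the normal approximation otherwise (the
    regime of the binned thickness maps, which are large and tied).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("need at least 2 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for all-tied input")
    res = sps.kendalltau(x, y, variant="b", method="auto")
    return CorrelationResult(float(res.statistic), float(res.pvalue),
                             int(x.size))


def ks_normality(values) -> tuple[float, float]:
    """One-sample KS statistic of the standardised values against N(0, 1).

    Returns (D, asymptotic p).  Used to justify the non-parametric choice:
    thickness-change data reject normality decisively.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("need at least 10 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    z = (v - v.mean()) / sd
    res = sps.kstest(z, "norm", mode="asymp")
    return float(res.statistic), float(res.pvalue)


def compare_maps(observed: ThicknessChangeMap,
                 predicted: ThicknessChangeMap) -> CorrelationResult:
    """Rank correlation over co-defined, masked-in bins of two maps."""
    if observed.dth.shape != predicted.dth.shape:
        raise ValueError("maps must share a grid")
    if not (np.allclose(observed.theta_edges, predicted.theta_edges)
            and np.allclose(observed.z, predicted.z)):
        raise ValueError("maps must share a grid")
    ok = (observed.mask & predicted.mask
          & np.isfinite(observed.dth) & np.isfinite(predicted.dth))
    if ok.sum() < 10:
        raise ValueError("fewer than 10 co-defined masked bins")
    return kendall_tau(observed.dth[ok], predicted.dth[ok])


def compare_sweep(observed: ThicknessChangeMap,
                  predictions: list[tuple[float, ThicknessChangeMap]]
                  ) -> pd.DataFrame:
    """tau-vs-threshold table for a sweep of apposition thresholds."""
    rows = []
    for psi_a, pred in predictions:
        r = compare_maps(observed, pred)
        rows.append({"psi_A_um_s": psi_a, "tau": r.tau, "p": r.p_value,
                     "n": r.n})
    return pd.DataFrame(rows)
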