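"""Phase-based synchrony: cluster-phase rho and the Kuramoto weak-null test.

Rho scores one recording by how tightly the variables' phases concentrate
around the group's aggregate (cluster) phase after removing each variable's
own mean offset.  The weak-null test scores a *sample* of recordings: under
a chance model that allows autocorrelation within variables but assumes
independence between them, the time-averaged squared order parameter has
expectation 1/N for N variables, and a one-sample t test asks whether the
sample exceeds it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .core import DegenerateSignalError, ValidationError, as_array
from .phase import (
    PhaseMatrix,
    UniformityReport,
    as_phase_array,
    order_parameter,
    phase_uniformity_check,
    wrap_phase,
)

__all__ = ["RhoResult", "WeakNullResult", "cluster_phase_rho", "kuramoto_weak_null",
           "mean_dyadic_correlation"]


@dataclass
class RhoResult:
    """Time-varying rho(t) plus its time average as the overall score."""

    rho_t: np.ndarray
    rho_overall: float


def cluster_phase_rho(phases) -> RhoResult:
    """Cluster-phase rho of one recording's phase matrix.

    Procedure: (i) the cluster phase q(t) is the argument of the
    across-variable mean unit vector; (ii) each variable's relative phase is
    phi_k(t) = wrap(theta_k(t) - q(t)); (iii) its mean offset phi_bar_k is
    the argument of the time-mean unit vector of phi_k; (iv) rho(t) is the
    modulus of the across-variable mean of unit vectors at
    phi_k(t) - phi_bar_k; (v) the overall score is the time mean of rho(t).
    Constant pairwise offsets are absorbed by phi_bar_k, so a rigidly
    rotating ensemble scores 1.0.
    """
    angles = as_phase_array(phases)
    if angles.shape[0] < 2:
        raise ValidationError("cluster-phase rho needs >= 2 variables")
    cluster = np.angle(np.exp(1j * angles).mean(axis=0))
    relative = wrap_phase(angles - cluster[np.newaxis, :])
    mean_offset = np.angle(np.exp(1j * relative).mean(axis=1))
    rho_t = np.abs(np.exp(1j * (relative - mean_offset[:, np.newaxis])).mean(axis=0))
    return RhoResult(rho_t=rho_t, rho_overall=float(rho_t.mean()))


@dataclass
class WeakNullResult:
    """Outcome of the weak-null t test over a sample of recordings."""

    p_value: float
    t_statistic: float
    dof: int
    per_recording_statistic: np.ndarray
    null_expectation: float
    uniformity: list[UniformityReport]

    @property
    def uniformity_warning(self) -> bool:
        """True when any recording's phases look clearly non-uniform.

        Skewed phase distributions (e.g. long periods of stillness) violate
        the chance model and can grossly overstate significance.
        """
        return any(rep.any_flagged for rep in self.uniformity)


def kuramoto_weak_null(
    recordings: Sequence[PhaseMatrix | np.ndarray],
    alternative: str = "greater",
    uniformity_threshold: float = 0.1,
) -> WeakNullResult:
    """Test a sample of phase recordings against the weak null of no coupling.

    Inputs must be phase matrices (not raw amplitudes), all with the same
    number of variables N, since N sets the chance expectation.  For each
    recording the statistic is the time average of r(t)^2; the sample of
    statistics is compared to 1/N with a one-sample t test (one-sided
    "greater" by default, dof = M - 1 for M recordings).  A per-recording
    phase-uniformity report is attached as an advisory diagnostic.
    """
    matrices = [as_phase_array(p) for p in recordings]
    if len(matrices) < 2:
        raise ValidationError("weak-null test needs >= 2 recordings")
    n_vars = {m.shape[0] for m in matrices}
    if len(n_vars) != 1:
        raise ValidationError(f"recordings mix variable counts {sorted(n_vars)}")
    n = n_vars.pop()
    if n < 2:
        raise ValidationError("weak-null test needs >= 2 variables")
    statistics = np.array([float((order_parameter(m).r ** 2).mean()) for m in matrices])
    null = 1.0 / n
    res = stats.ttest_1samp(statistics, popmean=null, alternative=alternative)
    uniformity = [phase_uniformity_check(m, threshold=uniformity_threshold)
                  for m in matrices]
    return WeakNullResult(
        p_value=float(res.pvalue),
        t_statistic=float(res.statistic),
        dof=len(matrices) - 1,
        per_recording_statistic=statistics,
        null_expectation=null,
        uniformity=uniformity,
    )


def mean_dyadic_correlation(series) -> float:
    """Lag-0 Pearson correlation averaged over all unordered channel pairs.

    The standard dyadic reference metric for comparison with the
    multivariate scores.
    """
    values = as_array(series)
    if values.shape[0] < 2:
        raise ValidationError("mean dyadic correlation needs >= 2 variables")
    if np.any(values.std(axis=1) == 0):
        bad = int(np.flatnonzero(values.std(axis=1) == 0)[0])
        raise DegenerateSignalError(f"variable {bad} is constant; correlation undefined")
    corr = np.corrcoef(values)
    pairs = [corr[i, j] for i, j in combinations(range(values.shape[0]), 2)]
    return float(np.mean(pairs))
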