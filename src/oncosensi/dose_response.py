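"""Radiation dose-response curves and the RT_AUC statistic.

Viability (percent of unirradiated control) is plotted against the dose
ladder (default 0/2/4/8 Gy) and summarized by the trapezoid-rule area
under the curve.  On the 0-8 Gy grid, 100% viability at every dose gives
the attainable maximum of 800 percent*Gy; fully radiosensitive samples
approach 0.  A standard error propagates per-dose replicate SEMs through
the trapezoid weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

DEFAULT_DOSES_GY = (0.0, 2.0, 4.0, 8.0)


@dataclass(frozen=True)
class DoseResponseRecord:
    doses_gy: tuple[float, ...]
    viability_pct: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_gy, dtype=float)
        v = np.asarray(self.viability_pct, dtype=float)
        if d.size != v.size:
            raise ValueError("doses and viabilities must align")
        if d.size and np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("viability cannot be negative")


@dataclass(frozen=True)
class DoseResponseSummary:
    auc: float
    se: float
    n_replicates: int


def auc_trapezoid(record: "DoseResponseRecord | None" = None, *,
                  doses_gy=None, viability_pct=None) -> float:
    """Trapezoid-rule area under the viability-vs-dose curve (percent*Gy)."""
    if record is None:
        record = DoseResponseRecord(tuple(doses_gy), tuple(viability_pct))
    d = np.asarray(record.doses_gy, dtype=float)
    v = np.asarray(record.viability_pct, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two dose points")
    return float(np.trapezoid(v, d))


def trapezoid_weights(doses_gy) -> np.ndarray:
    """Per-point weights w_i such that AUC = sum(w_i * v_i).

    Interior points weigh (d_{i+1} - d_{i-1})/2, endpoints half their single
    adjacent gap; for 0/2/4/8 Gy the weights are (1, 2, 3, 2).
    """
    d = np.asarray(doses_gy, dtype=float)
    if d.size < 2:
        raise ValueError("need at least two dose points")
    w = np.empty_like(d)
    w[0] = (d[1] - d[0]) / 2.0
    w[-1] = (d[-1] - d[-2]) / 2.0
    if d.size > 2:
        w[1:-1] = (d[2:] - d[:-2]) / 2.0
    return w


def auc_standard_error(per_dose_sems, doses_gy=DEFAULT_DOSES_GY) -> float:
    """SE of the trapezoid AUC from independent per-dose replicate SEMs.

    SE = sqrt(sum((w_i * SEM_i)^2)) with the trapezoid weights above.
    """
    sems = np.asarray(per_dose_sems, dtype=float)
    d = np.asarray(doses_gy, dtype=float)
    if sems.shape != d.shape:
        raise ValueError("one SEM per dose required")
    if np.any(sems < 0):
        raise ValueError("SEMs cannot be negative")
    w = trapezoid_weights(d)
    return float(np.sqrt(np.sum((w * sems) ** 2)))


def summarize(replicate_viabilities, doses_gy=DEFAULT_DOSES_GY) -> DoseResponseSummary:
    """AUC of the mean curve plus propagated SE from per-dose replicates.

    ``replicate_viabilities`` is an (n_replicates, n_doses) array.
    """
    reps = np.atleast_2d(np.asarray(replicate_viabilities, dtype=float))
    d = np.asarray(doses_gy, dtype=float)
    if reps.shape[1] != d.size:
        raise ValueError("replicate columns must match doses")
    mean_v = reps.mean(axis=0)
    n = reps.shape[0]
    sems = reps.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(d)
    return DoseResponseSummary(
        auc=auc_trapezoid(doses_gy=d, viability_pct=mean_v),
        se=auc_standard_error(sems, d),
        n_replicates=n,
    )


def replicate_concordance(viability_a, viability_b) -> float:
    """R^2 of the simple linear regression of method B on method A.

    Used to compare viability readouts between irradiation methods; values
    above ~0.7 indicate the two deliveries agree.
    """
    a = np.asarray(viability_a, dtype=float)
    b = np.asarray(viability_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(a) == 0:
        raise ValueError("R^2 undefined: no variance in method A")
    fit = _stats.linregress(a, b)
    return float(fit.rvalue**2)
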