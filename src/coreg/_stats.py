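"""Shared statistical primitives: p-to-Z conversion in log space, two-sample
T-test Z-scores and correlation-derived Z-scores.

All Z-scores here are signed two-sided probit transforms: for a two-sided
p-value ``p`` and an effect direction ``s`` in {-1, +1},

    Z = s * Phi^{-1}(1 - p/2)

computed from the log of the one-sided tail probability so that Z up to the
cap is exact even for p far below the smallest positive float. |Z| is capped
at ``Z_MAX`` (40), with the cap reported to the caller where it matters.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special, stats

Z_MAX = 40.0

__all__ = [
    "Z_MAX",
    "z_from_log_sf",
    "two_sided_p_at_z",
    "t_test_z",
    "t_test_z_from_moments",
    "pearson_r_to_z",
]


def z_from_log_sf(log_sf: np.ndarray | float, sign: np.ndarray | float):
    """Signed Z from the log one-sided tail probability log(p/2).

    Returns ``(z, capped)`` where ``capped`` marks entries clipped at Z_MAX.
    """
    log_sf = np.asarray(log_sf, dtype=float)
    # Phi^{-1}(1 - p/2) = -Phi^{-1}(p/2); ndtri_exp takes log(p/2) directly.
    with np.errstate(over="ignore"):
        z = -special.ndtri_exp(log_sf)
    capped = (z > Z_MAX) | ~np.isfinite(z)
    z = np.where(capped, Z_MAX, z)
    z = z * np.sign(sign)
    if z.ndim == 0:
        return float(z), bool(capped)
    return z, capped


def two_sided_p_at_z(z: float) -> float:
    """Two-sided normal tail probability at |Z| = z (e.g. ~5.7e-7 at z=5)."""
    return float(2.0 * special.ndtr(-abs(z)))


def _t_to_z(t: np.ndarray | float, df: np.ndarray | float):
    t = np.asarray(t, dtype=float)
    log_sf = stats.t.logsf(np.abs(t), df)
    return z_from_log_sf(log_sf, np.sign(t))


def t_test_z_from_moments(
    mean1, var1, n1, mean2, var2, n2, *, welch: bool = False
):
    """Vectorized signed Z for the two-sample T-test from group moments.

    ``var`` are unbiased (ddof=1) variances. Student's pooled-variance test by
    default; Welch's unequal-variance test when ``welch`` is set. Degenerate
    components (zero pooled variance) map to Z=0 when the means agree and to
    the capped +/-Z_MAX otherwise.
    """
    mean1, var1, mean2, var2 = (
        np.asarray(a, dtype=float) for a in (mean1, var1, mean2, var2)
    )
    diff = mean1 - mean2
    if welch:
        se2 = var1 / n1 + var2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (var1 / n1) ** 2 / (n1 - 1) + (var2 / n2) ** 2 / (n2 - 1)
            )
    else:
        sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.broadcast_to(float(n1 + n2 - 2), diff.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    zero_se = ~(np.asarray(se2) > 0)
    z, capped = _t_to_z(np.where(zero_se, 0.0, t), np.where(zero_se, 1.0, df))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    capped = np.atleast_1d(np.asarray(capped))
    zero_se, diff = np.atleast_1d(zero_se), np.atleast_1d(diff)
    if np.any(zero_se):
        degenerate_diff = zero_se & (diff != 0)
        z[zero_se & (diff == 0)] = 0.0
        z[degenerate_diff] = Z_MAX * np.sign(diff[degenerate_diff])
        capped = capped | degenerate_diff
    if np.ndim(mean1) == 0:
        return float(z[0]), bool(capped[0])
    return z, capped


def t_test_z(in_group, out_group, *, welch: bool = False) -> float:
    """Signed Z comparing the mean of ``in_group`` against ``out_group``.

    Positive Z means the in-group mean exceeds the out-group mean. Requires
    at least two observations per group.
    """
    x = np.asarray(in_group, dtype=float)
    y = np.asarray(out_group, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"each group needs >=2 observations (got {x.size} and {y.size})"
        )
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        warnings.warn("both groups constant and equal; returning Z=0")
        return 0.0
    z, _ = t_test_z_from_moments(
        x.mean(), x.var(ddof=1), x.size, y.mean(), y.var(ddof=1), y.size,
        welch=welch,
    )
    return float(z)


def pearson_r_to_z(r: np.ndarray | float, k: int):
    """Signed Z for the Pearson correlation of ``k`` paired observations.

    Uses the exact t transform t = r*sqrt(k-2)/sqrt(1-r^2) with k-2 degrees
    of freedom, then the two-sided probit. |r| = 1 maps to the capped Z.
    Returns ``(z, capped)``.
    """
    if k < 3:
        raise ValueError(f"need k >= 3 paired observations, got {k}")
    scalar_input = np.ndim(r) == 0
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(k - 2) / np.sqrt(1.0 - r**2)
    at_unity = np.abs(r) == 1.0
    z, capped = _t_to_z(np.where(at_unity, 0.0, t), k - 2)
    z = np.atleast_1d(np.asarray(z, dtype=float))
    capped = np.atleast_1d(np.asarray(capped))
    at_unity, r = np.atleast_1d(at_unity), np.atleast_1d(r)
    if np.any(at_unity):
        z[at_unity] = Z_MAX * np.sign(r[at_unity])
        capped = capped | at_unity
    if scalar_input:
        return float(z[0]), bool(capped[0])
    return z, capped
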