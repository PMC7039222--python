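"""Accuracy and reproducibility statistics for joint-angle series.

Accuracy of a measured angle series against a reference (here: synthetic
ground truth standing in for an optical system):

* ``rmse`` — root mean square of the per-sample difference;
* ``delta_rom`` — absolute difference of the two ranges of motion;
* ``drift`` — absolute difference at the final sample, the residual of
  angular-rate integration error.

All differences are wrapped to (-180, 180] degrees first.

Reproducibility of the range of motion across repeated calibrations, from a
subjects x repetitions table:

* ``icc`` — intraclass correlation; default form ICC(2,1), the two-way
  random-effects, absolute-agreement, single-measurement coefficient
  computed from ANOVA mean squares (ICC(3,1) available as an option);
* ``sem`` — standard error of measurement, ``SD * sqrt(1 - ICC)`` with the
  between+within (total) SD by default (``sqrt(MS_error)`` as an option),
  and SEM% = SEM / grand-mean x 100.

ICC interpretation bands: >= 0.90 excellent, 0.70-0.89 good, 0.40-0.69
acceptable, < 0.40 low; SEM% above 10% is flagged as high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rotations import wrap_deg

__all__ = [
    "AccuracyResult",
    "ReproducibilityResult",
    "rmse",
    "delta_rom",
    "drift",
    "icc",
    "sem",
    "icc_band",
    "accuracy_table",
    "reproducibility_table",
]

PLANES = ("sagittal", "frontal", "transverse")


@dataclass(frozen=True)
class AccuracyResult:
    joint_id: str
    plane: str
    rmse_deg: float
    delta_rom_deg: float
    drift_deg: float


@dataclass(frozen=True)
class ReproducibilityResult:
    joint_id: str
    plane: str
    mean_rom_deg: float
    icc: float
    sem_deg: float
    sem_pct: float
    high_sem_pct: bool


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"series length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least two samples")
    return a, b


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square angular difference (deg), wrap-aware."""
    a, b = _check_pair(a, b)
    d = wrap_deg(a - b)
    return float(np.sqrt(np.mean(d**2)))


def delta_rom(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute difference of the two ranges of motion (deg)."""
    a, b = _check_pair(a, b)
    return float(abs(np.ptp(a) - np.ptp(b)))


def drift(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute wrapped difference at the final sample (deg)."""
    a, b = _check_pair(a, b)
    return float(abs(wrap_deg(a[-1] - b[-1])))


# ---------------------------------------------------------------------------
# reliability statistics
# ---------------------------------------------------------------------------

def _anova_mean_squares(table: np.ndarray) -> tuple[float, float, float, int, int]:
    """Two-way (subjects x repetitions) ANOVA mean squares.

    Returns (MS_rows, MS_cols, MS_error, n_subjects, n_repetitions).
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a table of >= 2 subjects x >= 2 repetitions")
    if np.isnan(x).any():
        raise ValueError("reliability table has missing cells")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_err), n, k


def icc(table: np.ndarray, form: str = "ICC(2,1)") -> float:
    """Intraclass correlation of a subjects x repetitions table.

    ``ICC(2,1)``: two-way random effects, absolute agreement, single
    measurement; ``ICC(3,1)``: two-way mixed, consistency.  Raises on zero
    total variance (the coefficient is undefined, not 1).
    """
    ms_r, ms_c, ms_e, n, k = _anova_mean_squares(table)
    if ms_r + ms_c + ms_e <= 0 or np.ptp(np.asarray(table)) == 0:
        raise ValueError("ICC undefined: table has zero total variance")
    if form == "ICC(2,1)":
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    elif form == "ICC(3,1)":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unsupported ICC form {form!r}")
    if denom == 0:
        raise ValueError("ICC undefined: zero denominator")
    return float((ms_r - ms_e) / denom)


def sem(
    table: np.ndarray,
    form: str = "ICC(2,1)",
    sd_mode: str = "total",
    icc_value: float | None = None,
) -> tuple[float, float]:
    """Standard error of measurement (deg) and SEM% of a ROM table.

    ``sd_mode='total'``: SEM = SD_total * sqrt(1 - ICC) with the SD over all
    cells (between + within variance); ``sd_mode='ms_error'``: SEM =
    sqrt(MS_error).  SEM% = SEM / grand-mean x 100 (grand mean must be > 0).
    """
    x = np.asarray(table, dtype=float)
    if icc_value is None:
        icc_value = icc(x, form=form)
    if sd_mode == "total":
        sd = float(np.std(x, ddof=1))
        s = sd * np.sqrt(max(0.0, 1.0 - icc_value))
    elif sd_mode == "ms_error":
        _, _, ms_e, _, _ = _anova_mean_squares(x)
        s = float(np.sqrt(ms_e))
    else:
        raise ValueError(f"unsupported sd_mode {sd_mode!r}")
    grand = float(x.mean())
    if grand <= 0:
        raise ValueError("SEM%% undefined for non-positive grand mean ROM")
    return s, 100.0 * s / grand


def icc_band(value: float) -> str:
    """Interpretation band: excellent / good / acceptable / low."""
    if value >= 0.90:
        return "excellent"
    if value >= 0.70:
        return "good"
    if value >= 0.40:
        return "acceptable"
    return "low"


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def accuracy_table(
    measured: dict[str, np.ndarray],
    reference: dict[str, np.ndarray],
) -> pd.DataFrame:
    """One accuracy row per joint x plane.

    Inputs map joint id -> (N, 3) angle array (flexion, abduction, rotation).
    Returns a tidy DataFrame with columns joint, plane, rmse_deg,
    delta_rom_deg, drift_deg.
    """
    missing = set(measured) ^ set(reference)
    if missing:
        raise ValueError(f"joints present in only one input: {sorted(missing)}")
    rows = []
    for joint in measured:
        m = np.asarray(measured[joint], dtype=float)
        r = np.asarray(reference[joint], dtype=float)
        for col, plane in enumerate(PLANES):
            rows.append(
                {
                    "joint": joint,
                    "plane": plane,
                    "rmse_deg": rmse(m[:, col], r[:, col]),
                    "delta_rom_deg": delta_rom(m[:, col], r[:, col]),
                    "drift_deg": drift(m[:, col], r[:, col]),
                }
            )
    return pd.DataFrame(rows)


def reproducibility_table(
    rom_tables: dict[tuple[str, str], np.ndarray],
    form: str = "ICC(2,1)",
    sd_mode: str = "total",
) -> pd.DataFrame:
    """Reliability row per joint x plane from subjects x repetitions ROM tables.

    ``rom_tables`` maps (joint, plane) -> 2D ROM array.  Columns: joint,
    plane, mean_rom_deg, icc, icc_band, sem_deg, sem_pct, high_sem_pct.
    """
    rows = []
    for (joint, plane), table in rom_tables.items():
        x = np.asarray(table, dtype=float)
        icc_v = icc(x, form=form)
        sem_deg, sem_pct = sem(x, form=form, sd_mode=sd_mode, icc_value=icc_v)
        rows.append(
            {
                "joint": joint,
                "plane": plane,
                "mean_rom_deg": float(x.mean()),
                "icc": icc_v,
                "icc_band": icc_band(icc_v),
                "sem_deg": sem_deg,
                "sem_pct": sem_pct,
                "high_sem_pct": bool(sem_pct > 10.0),
            }
        )
    return pd.DataFrame(rows)
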