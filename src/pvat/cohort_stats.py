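"""Cohort comparisons and automation-agreement statistics.

Two comparisons mirror the study design: an *inter-individual* two-sample
t-test of a fat-attenuation marker between the aneurysmal sections of AAA
patients and the infrarenal sections of controls, and an *intra-individual*
paired t-test between the aneurysmal and non-aneurysmal abdominal sections
within AAA patients.  Both tests are two-tailed; the independent test uses
the classic equal-variance form by default with Welch's correction available
via a flag.  Measurements flagged invalid (shell volume < 0.3 cm³ or an
empty shell) are excluded and reported by patient id and reason.

Agreement between two measurement routes (e.g. automatic vs manual
segmentation) is summarised by the Dice overlap of the masks, a two-way
random-effects absolute-agreement single-measure ICC — ICC(2,1) — with an
F-distribution 95% CI, and the mean per-patient marker difference with a
percentile bootstrap CI (1000 resamples by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .densitometry import PVATMeasurement

MARKERS = {"hu_delta": "hu_delta", "hu_ratio": "hu_ratio_pct", "hu_ratio_pct": "hu_ratio_pct"}


def _marker_attr(marker: str) -> str:
    try:
        return MARKERS[marker]
    except KeyError:
        raise ValueError(f"unknown marker {marker!r}; choose from {sorted(set(MARKERS))}")


@dataclass
class ComparisonResult:
    comparison: str  # "inter_individual" | "intra_individual"
    marker: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    t_statistic: float
    p_value: float
    excluded: list[tuple[str, str]] = field(default_factory=list)
    degenerate: str | None = None
    mean_difference: float | None = None  # paired comparison only

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "marker": self.marker,
            "group_means": self.group_means,
            "group_sds": self.group_sds,
            "group_ns": self.group_ns,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "excluded": [list(e) for e in self.excluded],
            "degenerate": self.degenerate,
            "mean_difference": self.mean_difference,
        }


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    resamples: int


def _split_valid(measurements: list[PVATMeasurement], attr: str):
    values, excluded = [], []
    for m in measurements:
        if m.valid and math.isfinite(getattr(m, attr)):
            values.append((m.patient_id, getattr(m, attr)))
        else:
            reason = (
                f"shell volume below 0.3 cm3 (close {m.vol_close_cm3:.2f}, "
                f"distant {m.vol_distant_cm3:.2f})"
            )
            excluded.append((m.patient_id, reason))
    return values, excluded


def compare_inter(
    aaa: list[PVATMeasurement],
    ctrl: list[PVATMeasurement],
    marker: str = "hu_delta",
    equal_var: bool = True,
) -> ComparisonResult:
    """Two-sample two-tailed t-test of a marker, AAA vs control sections."""
    attr = _marker_attr(marker)
    a_vals, a_exc = _split_valid(aaa, attr)
    c_vals, c_exc = _split_valid(ctrl, attr)
    if len(a_vals) < 2 or len(c_vals) < 2:
        raise ValueError(
            f"need at least 2 valid measurements per group, got "
            f"{len(a_vals)} AAA and {len(c_vals)} control"
        )
    a = np.array([v for _, v in a_vals])
    c = np.array([v for _, v in c_vals])
    t, p = stats.ttest_ind(a, c, equal_var=equal_var)
    return ComparisonResult(
        comparison="inter_individual",
        marker=marker,
        group_means={"aaa": float(a.mean()), "control": float(c.mean())},
        group_sds={"aaa": float(a.std(ddof=1)), "control": float(c.std(ddof=1))},
        group_ns={"aaa": len(a), "control": len(c)},
        t_statistic=float(t),
        p_value=float(p),
        excluded=a_exc + c_exc,
    )


def compare_intra(
    measurements: list[PVATMeasurement],
    marker: str = "hu_delta",
    section_a: str = "aneurysmal",
    section_b: str = "non_aneurysmal_abdominal",
) -> ComparisonResult:
    """Paired two-tailed t-test of a marker across two sections per patient.

    Patients lacking a valid measurement in either section are excluded and
    reported.  If the within-pair differences have zero variance the t
    statistic is undefined; the result is flagged degenerate rather than
    coerced to a number.
    """
    attr = _marker_attr(marker)
    by_patient: dict[str, dict[str, PVATMeasurement]] = {}
    for m in measurements:
        by_patient.setdefault(m.patient_id, {})[m.section] = m

    pairs, excluded = [], []
    for pid in sorted(by_patient):
        secs = by_patient[pid]
        bad = None
        for sec in (section_a, section_b):
            m = secs.get(sec)
            if m is None:
                bad = f"missing section {sec!r}"
            elif not (m.valid and math.isfinite(getattr(m, attr))):
                bad = (
                    f"section {sec!r} shell volume below 0.3 cm3 "
                    f"(close {m.vol_close_cm3:.2f}, distant {m.vol_distant_cm3:.2f})"
                )
            if bad:
                break
        if bad:
            excluded.append((pid, bad))
        else:
            pairs.append((getattr(secs[section_a], attr), getattr(secs[section_b], attr)))
    if len(pairs) < 2:
        raise ValueError(f"need at least 2 complete pairs, got {len(pairs)}")

    a = np.array([x for x, _ in pairs])
    b = np.array([y for _, y in pairs])
    diff = a - b
    result = ComparisonResult(
        comparison="intra_individual",
        marker=marker,
        group_means={section_a: float(a.mean()), section_b: float(b.mean())},
        group_sds={section_a: float(a.std(ddof=1)), section_b: float(b.std(ddof=1))},
        group_ns={section_a: len(a), section_b: len(b)},
        t_statistic=math.nan,
        p_value=math.nan,
        excluded=excluded,
        mean_difference=float(diff.mean()),
    )
    if np.ptp(diff) == 0.0:
        result.degenerate = "degenerate: no within-pair variability"
        return result
    t, p = stats.ttest_rel(a, b)
    result.t_statistic = float(t)
    result.p_value = float(p)
    return result


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def icc(pairs: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``pairs`` is (n_subjects, k_raters); the CI follows the McGraw–Wong
    F-distribution construction.  With zero residual variance the ICC is 1 by
    the mean-squares formula and the CI collapses to [1, 1].
    """
    y = np.asarray(pairs, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("pairs must be (n_subjects, k>=2) measurements")
    n, k = y.shape
    if n < 5:
        raise ValueError(f"need at least 5 subjects for a stable ICC, got {n}")

    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((y - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0, n=n)
    value = (msr - mse) / denom
    if mse <= 0.0 and msc <= 0.0:
        return ICCResult(icc=float(value), ci_low=1.0, ci_high=1.0, n=n)

    a = k * value / (n * (1.0 - value)) if value < 1.0 else math.inf
    b = 1.0 + k * value * (n - 1.0) / (n * (1.0 - value)) if value < 1.0 else math.inf
    if not (math.isfinite(a) and math.isfinite(b)):
        return ICCResult(icc=float(value), ci_low=1.0, ci_high=1.0, n=n)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
    )
    f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
    f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return ICCResult(icc=float(value), ci_low=float(lower), ci_high=float(upper), n=n)


def bootstrap_mean_diff(
    pairs: np.ndarray, resamples: int = 1000, seed: int = 0, alpha: float = 0.05
) -> BootstrapResult:
    """Mean per-subject difference with a percentile bootstrap CI."""
    y = np.asarray(pairs, dtype=float)
    if y.ndim == 2 and y.shape[1] == 2:
        diffs = y[:, 0] - y[:, 1]
    elif y.ndim == 1:
        diffs = y
    else:
        raise ValueError("pairs must be (n, 2) measurements or a 1-D difference vector")
    if len(diffs) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(diffs)}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diffs), size=(resamples, len(diffs)))
    boot_means = diffs[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        estimate=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n=len(diffs),
        resamples=resamples,
    )


@dataclass
class AgreementResult:
    dice_per_case: dict[str, float]
    dice_mean: float
    icc_by_marker: dict[str, ICCResult]
    mean_diff_by_marker: dict[str, BootstrapResult]
    end_dev_mean: dict[str, float] | None = None
    end_dev_sd: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "dice_per_case": self.dice_per_case,
            "dice_mean": self.dice_mean,
            "icc": {
                m: {"icc": r.icc, "ci95": [r.ci_low, r.ci_high], "n": r.n}
                for m, r in self.icc_by_marker.items()
            },
            "mean_diff": {
                m: {"estimate": r.estimate, "ci95": [r.ci_low, r.ci_high], "n": r.n}
                for m, r in self.mean_diff_by_marker.items()
            },
        }
        if self.end_dev_mean is not None:
            out["end_deviation_mm"] = {
                "mean": self.end_dev_mean,
                "sd": self.end_dev_sd,
            }
        return out


def agreement_summary(
    dice_per_case: dict[str, float],
    marker_pairs: dict[str, np.ndarray],
    end_deviations: list[dict[str, float]] | None = None,
    resamples: int = 1000,
    seed: int = 0,
) -> AgreementResult:
    """Assemble the automation-agreement block from per-case ingredients.

    ``marker_pairs`` maps a marker name to an (n, 2) array of
    (reference, predicted) values per patient; ``end_deviations`` is the
    per-patient output of :func:`pvat.geometry.end_deviation`.
    """
    icc_by = {m: icc(p) for m, p in marker_pairs.items()}
    # reference minus predicted, matching the per-patient difference read-out
    md_by = {
        m: bootstrap_mean_diff(np.abs(p[:, 0] - p[:, 1]), resamples=resamples, seed=seed)
        for m, p in marker_pairs.items()
    }
    end_mean = end_sd = None
    if end_deviations:
        end_mean, end_sd = {}, {}
        for key in ("inferior", "superior", "mean"):
            vals = np.array([d[key] for d in end_deviations])
            end_mean[key] = float(vals.mean())
            end_sd[key] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return AgreementResult(
        dice_per_case=dice_per_case,
        dice_mean=float(np.mean(list(dice_per_case.values()))) if dice_per_case else math.nan,
        icc_by_marker=icc_by,
        mean_diff_by_marker=md_by,
        end_dev_mean=end_mean,
        end_dev_sd=end_sd,
    )
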