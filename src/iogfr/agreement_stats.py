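"""Method-agreement statistics for repeated-measures GFR comparisons.

Implements the statistic set used to judge a test method against a
reference method: Bland-Altman bias and limits of agreement, Lin's
concordance correlation coefficient (CCC), the total deviation index (TDI),
coverage probability (CP), P10/P15 accuracy percentages, the folded-
percentile mountain curve, a patient-level random-intercept regression, and
patient-clustered bootstrap confidence intervals.

Headline statistics are computed on all pairs pooled; the repeated-measures
structure enters through the clustered bootstrap (patients resampled with
replacement, all their studies retained).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PairedGfr",
    "AgreementConfig",
    "AgreementReport",
    "MixedModelResult",
    "MountainCurve",
    "differences",
    "ccc",
    "tdi",
    "coverage_probability",
    "p_within",
    "bland_altman",
    "mountain_curve",
    "random_intercept_regression",
    "cluster_bootstrap_ci",
    "baseline_subset",
    "agreement_report",
    "pairs_from_frame",
]

Scale = Literal["absolute", "percent_of_reference"]


@dataclass(frozen=True)
class PairedGfr:
    """Reference and test GFR (mL/min/1.73 m^2) for one clearance study."""

    patient_id: str
    study_index: int
    ref_value: float
    test_value: float

    def __post_init__(self) -> None:
        for v in (self.ref_value, self.test_value):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("GFR values must be positive and finite")


def pairs_from_frame(
    df: pd.DataFrame,
    ref_col: str,
    test_col: str,
    patient_col: str = "patient_id",
    study_col: str = "study_index",
) -> list[PairedGfr]:
    """Build pairs from a per-study GFR table (one method per column)."""
    missing = [c for c in (patient_col, study_col, ref_col, test_col) if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    return [
        PairedGfr(str(r[patient_col]), int(r[study_col]),
                  float(r[ref_col]), float(r[test_col]))
        for _, r in df.iterrows()
    ]


def _arrays(pairs: Sequence[PairedGfr]) -> tuple[np.ndarray, np.ndarray]:
    if not pairs:
        raise ValueError("no pairs supplied")
    ordered = sorted(pairs, key=lambda p: (p.patient_id, p.study_index))
    ref = np.array([p.ref_value for p in ordered], dtype=float)
    test = np.array([p.test_value for p in ordered], dtype=float)
    return ref, test


def differences(
    pairs: Sequence[PairedGfr], scale: Scale = "percent_of_reference"
) -> np.ndarray:
    """test - ref differences, ordered stably by (patient, study).

    Percent scale is 100 * (test - ref) / ref.
    """
    ref, test = _arrays(pairs)
    if scale == "absolute":
        return test - ref
    if scale == "percent_of_reference":
        if np.any(ref == 0):
            raise ValueError("zero reference value with percent scale")
        return 100.0 * (test - ref) / ref
    raise ValueError(f"unknown scale {scale!r}")


def ccc(pairs: Sequence[PairedGfr]) -> float:
    """Lin's concordance correlation coefficient.

    2*s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2), population moments.
    """
    ref, test = _arrays(pairs)
    if len(ref) < 3:
        raise ValueError("ccc needs at least 3 pairs")
    sxy = np.mean((ref - ref.mean()) * (test - test.mean()))
    denom = ref.var() + test.var() + (ref.mean() - test.mean()) ** 2
    if denom == 0:
        raise ValueError("degenerate pairs: zero variance and zero bias")
    return float(2.0 * sxy / denom)


def tdi(
    pairs: Sequence[PairedGfr],
    p: float = 0.90,
    scale: Scale = "percent_of_reference",
    method: Literal["normal", "empirical"] = "normal",
) -> float:
    """Total deviation index: the boundary containing a fraction p of the
    between-method differences.

    The normal approximation is z_((1+p)/2) * sqrt(mean(d)^2 + var(d));
    the empirical variant is the p-th quantile of |d|.
    """
    d = differences(pairs, scale)
    if len(d) < 3:
        raise ValueError("tdi needs at least 3 pairs")
    if method == "empirical":
        return float(np.quantile(np.abs(d), p))
    z = norm.ppf((1.0 + p) / 2.0)
    var = d.var(ddof=1) if len(d) > 1 else 0.0
    return float(z * math.sqrt(d.mean() ** 2 + var))


def coverage_probability(
    pairs: Sequence[PairedGfr],
    delta: float = 5.0,
    scale: Scale = "absolute",
    method: Literal["normal", "empirical"] = "normal",
) -> float:
    """Percent probability that |test - ref| lies within the tolerance delta.

    Normal variant: 100 * [Phi((delta-mu)/sigma) - Phi((-delta-mu)/sigma)];
    empirical variant: 100 * proportion of |d| <= delta.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    d = differences(pairs, scale)
    if method == "empirical":
        return float(100.0 * np.mean(np.abs(d) <= delta))
    mu = d.mean()
    sigma = d.std(ddof=1) if len(d) > 1 else 0.0
    if sigma == 0:
        return 100.0 if abs(mu) < delta else 0.0
    return float(100.0 * (norm.cdf((delta - mu) / sigma) - norm.cdf((-delta - mu) / sigma)))


def p_within(pairs: Sequence[PairedGfr], threshold_pct: float) -> float:
    """Percent of studies whose test value is within +/- threshold_pct of ref."""
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    d = differences(pairs, "percent_of_reference")
    return float(100.0 * np.mean(np.abs(d) <= threshold_pct))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


def bland_altman(
    pairs: Sequence[PairedGfr], scale: Scale = "percent_of_reference"
) -> BlandAltman:
    """Bias (mean difference) and 1.96-SD limits of agreement."""
    if len(pairs) < 3:
        raise ValueError("bland_altman needs at least 3 pairs")
    ref, test = _arrays(pairs)
    d = differences(pairs, scale)
    sd = d.std(ddof=1)
    bias = float(d.mean())
    return BlandAltman(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        means=(ref + test) / 2.0,
        diffs=d,
    )


@dataclass(frozen=True)
class MountainCurve:
    """Ranked differences with folded percentiles (apex at the median)."""

    diffs: np.ndarray
    folded_percentile: np.ndarray


def mountain_curve(
    pairs: Sequence[PairedGfr],
    scale: Scale = "percent_of_reference",
    orientation: Literal["ref_minus_test", "test_minus_ref"] = "ref_minus_test",
) -> MountainCurve:
    """Folded empirical percentile of ranked differences.

    Rank i of n maps to percentile 100*i/(n+1), folded as min(p, 100-p).
    Default orientation is reference minus test, so overestimation by the
    test method shifts the apex left of zero.
    """
    if len(pairs) < 2:
        raise ValueError("mountain_curve needs at least 2 pairs")
    d = differences(pairs, scale)
    if orientation == "ref_minus_test":
        d = -d
    d = np.sort(d)
    n = len(d)
    pct = 100.0 * np.arange(1, n + 1) / (n + 1)
    folded = np.minimum(pct, 100.0 - pct)
    return MountainCurve(diffs=d, folded_percentile=folded)


@dataclass(frozen=True)
class MixedModelResult:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    random_intercept_sd: float
    residual_sd: float
    ols_fallback: bool = False


def random_intercept_regression(pairs: Sequence[PairedGfr]) -> MixedModelResult:
    """test = intercept + slope * ref + patient random intercept + residual.

    Maximum-likelihood fit with Wald 95% intervals; a singular mixed fit
    falls back to ordinary least squares with ``ols_fallback=True``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    ordered = sorted(pairs, key=lambda p: (p.patient_id, p.study_index))
    if len({p.patient_id for p in ordered}) < 2 or len(ordered) < 3:
        raise ValueError("need >= 2 patients and >= 3 studies")
    df = pd.DataFrame(
        {
            "patient": [p.patient_id for p in ordered],
            "ref": [p.ref_value for p in ordered],
            "test": [p.test_value for p in ordered],
        }
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("test ~ ref", df, groups=df["patient"])
            fit = model.fit(reml=False)
        if not np.all(np.isfinite(fit.bse_fe)):
            raise np.linalg.LinAlgError("non-finite standard errors")
        slope = float(fit.fe_params["ref"])
        intercept = float(fit.fe_params["Intercept"])
        z = norm.ppf(0.975)
        s_se = float(fit.bse_fe["ref"])
        i_se = float(fit.bse_fe["Intercept"])
        re_var = float(np.asarray(fit.cov_re)[0, 0])
        return MixedModelResult(
            slope=slope,
            intercept=intercept,
            slope_ci=(slope - z * s_se, slope + z * s_se),
            intercept_ci=(intercept - z * i_se, intercept + z * i_se),
            random_intercept_sd=math.sqrt(max(re_var, 0.0)),
            residual_sd=math.sqrt(float(fit.scale)),
        )
    except (np.linalg.LinAlgError, ValueError):
        X = sm.add_constant(df["ref"].to_numpy())
        ols = sm.OLS(df["test"].to_numpy(), X).fit()
        ci = ols.conf_int(alpha=0.05)
        return MixedModelResult(
            slope=float(ols.params[1]),
            intercept=float(ols.params[0]),
            slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
            intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
            random_intercept_sd=0.0,
            residual_sd=math.sqrt(float(ols.scale)),
            ols_fallback=True,
        )


def cluster_bootstrap_ci(
    statistic: Callable[[Sequence[PairedGfr]], float],
    pairs: Sequence[PairedGfr],
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval resampling patients (clusters).

    All studies of a sampled patient are kept together.  A resample on
    which the statistic fails is redrawn; redraws are capped and a cap
    overflow raises rather than silently biasing the interval.
    """
    if B < 200:
        raise ValueError("B must be >= 200")
    by_patient: dict[str, list[PairedGfr]] = {}
    for p in pairs:
        by_patient.setdefault(p.patient_id, []).append(p)
    ids = sorted(by_patient)
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            chosen = rng.choice(len(ids), size=len(ids), replace=True)
            resample = [p for i in chosen for p in by_patient[ids[i]]]
            try:
                values[b] = statistic(resample)
                break
            except (ValueError, ZeroDivisionError):
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError(
                        f"bootstrap: statistic failed on > {max_redraws} resamples"
                    )
    return (
        float(np.quantile(values, alpha / 2.0)),
        float(np.quantile(values, 1.0 - alpha / 2.0)),
    )


def baseline_subset(pairs: Sequence[PairedGfr]) -> list[PairedGfr]:
    """Earliest (baseline) study per patient; errors on a duplicate baseline."""
    by_patient: dict[str, list[PairedGfr]] = {}
    for p in pairs:
        by_patient.setdefault(p.patient_id, []).append(p)
    out: list[PairedGfr] = []
    for pid in sorted(by_patient):
        studies = by_patient[pid]
        first = min(s.study_index for s in studies)
        base = [s for s in studies if s.study_index == first]
        if len(base) > 1:
            raise ValueError(f"patient {pid}: duplicate baseline study index {first}")
        out.append(base[0])
    return out


@dataclass(frozen=True)
class AgreementConfig:
    tdi_p: float = 0.90
    tdi_scale: Scale = "percent_of_reference"
    cp_delta: float = 5.0
    cp_scale: Scale = "absolute"
    ba_scale: Scale = "percent_of_reference"
    bootstrap_B: int = 2000
    seed: int = 0


@dataclass(frozen=True)
class AgreementReport:
    n_patients: int
    n_studies: int
    bias: float
    loa_lower: float
    loa_upper: float
    ccc: float
    tdi_p: float
    cp_delta: float
    p10: float
    p15: float
    ci_bias: tuple[float, float]
    ci_ccc: tuple[float, float]
    ci_tdi: tuple[float, float]
    ci_cp: tuple[float, float]
    ci_p10: tuple[float, float]
    ci_p15: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_studies": self.n_studies,
            "bias": self.bias,
            "loa_lower": self.loa_lower,
            "loa_upper": self.loa_upper,
            "ccc": self.ccc,
            "tdi": self.tdi_p,
            "cp": self.cp_delta,
            "p10": self.p10,
            "p15": self.p15,
            "ci": {
                "bias": list(self.ci_bias),
                "ccc": list(self.ci_ccc),
                "tdi": list(self.ci_tdi),
                "cp": list(self.ci_cp),
                "p10": list(self.ci_p10),
                "p15": list(self.ci_p15),
            },
        }


def agreement_report(
    pairs: Sequence[PairedGfr], config: AgreementConfig = AgreementConfig()
) -> AgreementReport:
    """Assemble the full statistic set with clustered bootstrap intervals.

    Deterministic given the configured seed: each statistic's bootstrap
    uses an independent seed derived from it.
    """
    ba = bland_altman(pairs, config.ba_scale)
    stats: dict[str, Callable[[Sequence[PairedGfr]], float]] = {
        "bias": lambda ps: float(differences(ps, config.ba_scale).mean()),
        "ccc": ccc,
        "tdi": lambda ps: tdi(ps, config.tdi_p, config.tdi_scale),
        "cp": lambda ps: coverage_probability(ps, config.cp_delta, config.cp_scale),
        "p10": lambda ps: p_within(ps, 10.0),
        "p15": lambda ps: p_within(ps, 15.0),
    }
    seeds = np.random.SeedSequence(config.seed).spawn(len(stats))
    cis = {
        name: cluster_bootstrap_ci(fn, pairs, B=config.bootstrap_B,
                                   seed=int(ss.generate_state(1)[0]))
        for (name, fn), ss in zip(stats.items(), seeds)
    }
    return AgreementReport(
        n_patients=len({p.patient_id for p in pairs}),
        n_studies=len(pairs),
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        ccc=ccc(pairs),
        tdi_p=tdi(pairs, config.tdi_p, config.tdi_scale),
        cp_delta=coverage_probability(pairs, config.cp_delta, config.cp_scale),
        p10=p_within(pairs, 10.0),
        p15=p_within(pairs, 15.0),
        ci_bias=cis["bias"],
        ci_ccc=cis["ccc"],
        ci_tdi=cis["tdi"],
        ci_cp=cis["cp"],
        ci_p10=cis["p10"],
        ci_p15=cis["p15"],
    )
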