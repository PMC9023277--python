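"""Integrative accept/reject filter for candidate structural models.

A candidate model of a higher-order quadruplex is kept only when it is
simultaneously consistent with every observable that was measured:

* CD stack count — the model's number of stacked G-tetrads must match the
  calibration-line prediction within a tolerance (0.5 stacks by default,
  operationalising the ~7% scatter of known three-stack references about
  the calibration line);
* sedimentation — the observed s20,w must fall inside the model's
  calculated range, widened by 0.1 S on each side;
* size — the calculated Rg must be within 5% of the measured Rg
  (the +-5% band of the reference-library regression);
* scattering fit — the reduced chi^2 must not exceed the reference-library
  mean by more than k standard deviations (2.1 + 2*0.7 = 3.5 by default).

Observables not supplied are marked "not evaluated" and can never fail a
model on their own; a model with no evaluated criteria is "indeterminate".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError

__all__ = [
    "FilterThresholds",
    "CriterionResult",
    "ConsistencyReport",
    "assess_model",
    "chi2_zscore",
]

#: reference-library chi^2 statistics (14 known G4 structures)
LIBRARY_CHI2_MEAN = 2.1
LIBRARY_CHI2_SD = 0.7


@dataclass(frozen=True)
class FilterThresholds:
    cd_tolerance_stacks: float = 0.5
    s_margin: float = 0.1  # Svedberg, added on both sides of the calc range
    rg_rel_tolerance: float = 0.05
    chi2_library_mean: float = LIBRARY_CHI2_MEAN
    chi2_library_sd: float = LIBRARY_CHI2_SD
    chi2_k: float = 2.0

    def __post_init__(self) -> None:
        if min(
            self.cd_tolerance_stacks,
            self.s_margin,
            self.rg_rel_tolerance,
            self.chi2_library_sd,
            self.chi2_k,
        ) <= 0 and self.s_margin < 0:
            raise ParameterError("thresholds must be positive")
        if (
            self.cd_tolerance_stacks <= 0
            or self.rg_rel_tolerance <= 0
            or self.chi2_library_sd <= 0
            or self.chi2_k <= 0
            or self.s_margin < 0
        ):
            raise ParameterError("thresholds must be positive")


@dataclass(frozen=True)
class CriterionResult:
    name: str
    passed: bool | None  # None = not evaluated
    detail: str


@dataclass(frozen=True)
class ConsistencyReport:
    criteria: tuple[CriterionResult, ...]
    verdict: str  # {consistent, inconsistent, indeterminate}

    def as_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "criteria": {
                c.name: {"passed": c.passed, "detail": c.detail} for c in self.criteria
            },
        }


def chi2_zscore(
    chi2: float, lib_mean: float = LIBRARY_CHI2_MEAN, lib_sd: float = LIBRARY_CHI2_SD
) -> float:
    """How many library standard deviations a fit's chi^2 sits above the mean."""
    if lib_sd <= 0:
        raise ParameterError("library SD must be positive")
    return (chi2 - lib_mean) / lib_sd


def assess_model(
    model_tetrads: int | None = None,
    cd_pred: float | None = None,
    s_obs: float | None = None,
    s_calc_range: tuple[float, float] | None = None,
    rg_obs: float | None = None,
    rg_calc: float | None = None,
    chi2: float | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> ConsistencyReport:
    """Combine CD, AUC, Rg and chi^2 evidence into a single verdict.

    A criterion is evaluated only when every quantity it needs was supplied;
    the verdict is "consistent" iff all evaluated criteria pass,
    "inconsistent" if any fails, and "indeterminate" when nothing could be
    evaluated.
    """
    t = thresholds
    crits: list[CriterionResult] = []

    if model_tetrads is not None and cd_pred is not None:
        dev = abs(cd_pred - model_tetrads)
        crits.append(
            CriterionResult(
                "cd_stack_count",
                dev <= t.cd_tolerance_stacks,
                f"|{cd_pred:.1f} - {model_tetrads}| = {dev:.2f} stacks"
                f" (tol {t.cd_tolerance_stacks})",
            )
        )
    else:
        crits.append(CriterionResult("cd_stack_count", None, "not evaluated"))

    if s_obs is not None and s_calc_range is not None:
        lo, hi = s_calc_range
        if lo > hi:
            raise ParameterError("s_calc_range must be (lo, hi) with lo <= hi")
        ok = (lo - t.s_margin) <= s_obs <= (hi + t.s_margin)
        crits.append(
            CriterionResult(
                "sedimentation",
                ok,
                f"s_obs {s_obs:.2f} S vs calc [{lo:.2f}, {hi:.2f}] +- {t.s_margin} S",
            )
        )
    else:
        crits.append(CriterionResult("sedimentation", None, "not evaluated"))

    if rg_obs is not None and rg_calc is not None:
        if rg_obs <= 0:
            raise ParameterError("rg_obs must be positive")
        rel = abs(rg_calc - rg_obs) / rg_obs
        crits.append(
            CriterionResult(
                "radius_of_gyration",
                rel <= t.rg_rel_tolerance,
                f"|{rg_calc:.1f} - {rg_obs:.1f}|/{rg_obs:.1f} = {rel:.3f}"
                f" (tol {t.rg_rel_tolerance})",
            )
        )
    else:
        crits.append(CriterionResult("radius_of_gyration", None, "not evaluated"))

    if chi2 is not None:
        cut = t.chi2_library_mean + t.chi2_k * t.chi2_library_sd
        crits.append(
            CriterionResult(
                "scattering_chi2",
                chi2 <= cut,
                f"chi2 {chi2:.2f} vs library cut {cut:.2f}"
                f" (z = {chi2_zscore(chi2, t.chi2_library_mean, t.chi2_library_sd):+.2f})",
            )
        )
    else:
        crits.append(CriterionResult("scattering_chi2", None, "not evaluated"))

    evaluated = [c for c in crits if c.passed is not None]
    if not evaluated:
        verdict = "indeterminate"
    elif all(c.passed for c in evaluated):
        verdict = "consistent"
    else:
        verdict = "inconsistent"
    return ConsistencyReport(tuple(crits), verdict)
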