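"""End-to-end convenience drivers tying the stages together.

Used by the CLI-independent regression tests and the acceptance report:
generate a virtual patient, calibrate both model variants on its two
scans, and forecast to surgery.
"""

from __future__ import annotations

from .calibrate import calibrate, downsample_problem
from .forecast import ModelComparison, compare_models, predict_to_surgery
from .synthetic import SyntheticPatientSpec, generate_longitudinal_study, reference_patient_pair

__all__ = ["calibrate_and_forecast", "run_reference_pair"]


def calibrate_and_forecast(
    spec: SyntheticPatientSpec,
    factor: int = 4,
    k_support_dilation: int = 1,
    max_outer: int = 2,
    max_nfev_globals: int = 150,
    max_nfev_k: int = 15,
) -> ModelComparison:
    """Full per-patient pipeline: synthesize, calibrate both variants on the
    down-sampled two-scan problem, forecast each to surgery."""
    dataset, truth = generate_longitudinal_study(spec)
    problem = downsample_problem(
        truth.cellularity_scan1,
        truth.cellularity_scan2,
        truth.drug_fields,
        dataset.domain,
        factor,
        config=spec.config,
        k_support_dilation=k_support_dilation,
        mechanics_cadence=spec.mechanics_cadence,
    )
    preds = {}
    for variant in ("mri", "pet_mri"):
        calib = calibrate(
            problem, variant,
            max_outer=max_outer,
            max_nfev_globals=max_nfev_globals,
            max_nfev_k=max_nfev_k,
        )
        preds[variant] = predict_to_surgery(
            calib,
            problem.scan2,
            problem.drug_fields,
            problem.schedule,
            variant,
            problem.domain,
            baseline=problem.scan1,
            mechanics_cadence=spec.mechanics_cadence,
        )
    return compare_models(preds["mri"], preds["pet_mri"])


def run_reference_pair(seed: int = 11) -> tuple[ModelComparison, ModelComparison]:
    """Calibrate and forecast the packaged pCR-like / non-pCR-like pair."""
    pcr_spec, non_spec = reference_patient_pair(seed)
    return calibrate_and_forecast(pcr_spec), calibrate_and_forecast(non_spec)
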