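"""Ingestion and validation of published species models.

Published environmentally explicit IPMs (e.g. database entries for
*Berberis thunbergii*, *Calathea crotalifera* and *Heliconia tortuosa*)
are re-encoded by hand into the package's JSON model format; their
coefficient values are data, not code, so the package ships only
manifests describing what a correct transcription must look like: the
expected environmental drivers and the stochastic growth regime the
published model inhabits.  ``validate_model`` checks a transcribed model
against its manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


from .dynamics import stochastic_growth
from .env_series import generate_driver_matrix
from .ipm_core import EnvironmentalIPM, build_kernel, build_kernel_sequence, dominant_eigenvalue

__all__ = [
    "ModelManifest",
    "ValidationReport",
    "validate_model",
    "builtin_manifests",
    "load_manifest",
    "save_manifest",
]


@dataclass(frozen=True)
class ModelManifest:
    """What a transcribed species model must provide.

    ``expected_lambda_regime`` is ">1" (long-term growth) or "<1"
    (long-term decline); ``reported_lambda_s`` is the published value, kept
    for reporting only.
    """

    species: str
    source: str
    driver_names: tuple[str, ...]
    expected_lambda_regime: str
    reported_lambda_s: float | None = None

    def __post_init__(self) -> None:
        if self.expected_lambda_regime not in (">1", "<1"):
            raise ValueError("expected_lambda_regime must be '>1' or '<1'")


@dataclass(frozen=True)
class ValidationReport:
    species: str
    passed: bool
    checks: tuple[tuple[str, bool, str], ...]
    lambda_s: float | None
    lambda_1: float | None
    warnings: tuple[str, ...] = ()


def builtin_manifests() -> dict[str, ModelManifest]:
    """Manifests for the three published perennial-plant models.

    *B. thunbergii* responds to five environmental variables; the two
    tropical herbs respond to canopy openness and photosynthetic rate.
    """
    return {
        "berberis_thunbergii": ModelManifest(
            species="Berberis thunbergii",
            source="PADRINO IPM database entry (Merow et al. parameterization)",
            driver_names=(
                "temp_warmest_month",
                "may_precipitation",
                "par",
                "soil_nitrogen",
                "soil_ph",
            ),
            expected_lambda_regime=">1",
            reported_lambda_s=1.378,
        ),
        "calathea_crotalifera": ModelManifest(
            species="Calathea crotalifera",
            source="PADRINO IPM database entry (Westerband & Horvitz parameterization)",
            driver_names=("canopy_openness", "photosynthetic_rate"),
            expected_lambda_regime="<1",
            reported_lambda_s=0.976,
        ),
        "heliconia_tortuosa": ModelManifest(
            species="Heliconia tortuosa",
            source="PADRINO IPM database entry (Westerband & Horvitz parameterization)",
            driver_names=("canopy_openness", "photosynthetic_rate"),
            expected_lambda_regime=">1",
            reported_lambda_s=1.367,
        ),
    }


def validate_model(
    ipm: EnvironmentalIPM,
    manifest: ModelManifest,
    phi: float = 0.0,
    sigma2_prop: float = 1.0,
    T: int = 1000,
    burn_in: int = 200,
    seed: int = 0,
) -> ValidationReport:
    """Check a transcribed model against its manifest.

    Driver count and names are asserted; a baseline stochastic growth rate
    is simulated and reported, with a warning (not a failure) when it
    falls on the wrong side of 1 — a single realization of lambda_s is
    stochastic, so the value is evidence, not proof.
    """
    checks: list[tuple[str, bool, str]] = []
    warns: list[str] = []

    model_names = set(ipm.driver_names)
    want = set(manifest.driver_names)
    count_ok = len(ipm.drivers) == len(manifest.driver_names)
    checks.append(
        (
            "driver_count",
            count_ok,
            f"model declares {len(ipm.drivers)} drivers, manifest expects "
            f"{len(manifest.driver_names)}",
        )
    )
    missing = sorted(want - model_names)
    extra = sorted(model_names - want)
    names_ok = not missing and not extra
    checks.append(
        (
            "driver_names",
            names_ok,
            f"missing: {missing or 'none'}; unexpected: {extra or 'none'}",
        )
    )

    lam_s = lam_1 = None
    if count_ok and names_ok:
        lam_1 = dominant_eigenvalue(build_kernel(ipm, ipm.driver_means()).K)
        env = generate_driver_matrix(ipm, phi, sigma2_prop, T, seed=seed)
        seq = build_kernel_sequence(ipm, env)
        lam_s = stochastic_growth(seq, burn_in=burn_in, seed=seed).lambda_s
        grows = manifest.expected_lambda_regime == ">1"
        if (lam_s > 1.0) != grows:
            warns.append(
                f"baseline lambda_s = {lam_s:.4f} is on the wrong side of 1 for the "
                f"manifest regime {manifest.expected_lambda_regime}"
            )
        if lam_1 is not None and grows and lam_1 < 0.5:
            warns.append(
                f"lambda_1 = {lam_1:.4f} is far below the manifest's growth regime"
            )

    return ValidationReport(
        species=manifest.species,
        passed=all(ok for _, ok, _ in checks),
        checks=tuple(checks),
        lambda_s=lam_s,
        lambda_1=lam_1,
        warnings=tuple(warns),
    )


def save_manifest(manifest: ModelManifest, path: str | Path) -> None:
    doc = {
        "species": manifest.species,
        "source": manifest.source,
        "driver_names": list(manifest.driver_names),
        "expected_lambda_regime": manifest.expected_lambda_regime,
        "reported_lambda_s": manifest.reported_lambda_s,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def load_manifest(path: str | Path) -> ModelManifest:
    with open(path) as fh:
        doc = json.load(fh)
    return ModelManifest(
        species=doc["species"],
        source=doc.get("source", ""),
        driver_names=tuple(doc["driver_names"]),
        expected_lambda_regime=doc["expected_lambda_regime"],
        reported_lambda_s=doc.get("reported_lambda_s"),
    )
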