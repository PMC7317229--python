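"""Shared fixtures: corrected disease variants and pacing results are
session-scoped because pre-pacing and peak-matching dominate runtime."""

from __future__ import annotations

import numpy as np
import pytest

from ltccmicro import myocyte as myo


@pytest.fixture(scope="session")
def control_variant():
    return myo.build_cell_variant("control")


@pytest.fixture(scope="session")
def corrected_variants(control_variant):
    """Control plus peak-matched ICM/DCM (and kinase-blocked) variants."""
    out = {"control": control_variant}
    for key, (variant, kw) in {
        "ICM": ("ICM", {}),
        "DCM": ("DCM", {}),
        "ICM_pka_block": ("ICM", {"pka_block": True}),
        "DCM_camkii_block": ("DCM", {"camkii_block": True}),
    }.items():
        out[key] = myo.compute_current_correction(
            myo.build_cell_variant(variant, **kw), control_variant
        )
    return out


@pytest.fixture(scope="session")
def clamp_results(corrected_variants):
    return {k: myo.run_voltage_clamp(v) for k, v in corrected_variants.items()}


@pytest.fixture(scope="session")
def pacing_results(corrected_variants):
    return {k: myo.run_pacing(v) for k, v in corrected_variants.items()}


@pytest.fixture(scope="session")
def cable_runs():
    """Skipped-beat protocol on control, ICM-patch and DCM-patch cables."""
    from ltccmicro import cable as cb

    out = {}
    for key, variant in [("control", None), ("ICM", "ICM"), ("DCM", "DCM")]:
        out[key] = cb.run_cable(cb.CableConfig(n_cells=60, patch_variant=variant))
    return out
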