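"""Shared fixtures: glutamine-style targets, methods and synthetic runs."""

from __future__ import annotations

import numpy as np
import pytest

from midquant.method import Method, MzTolerance, TargetIon, TracerSpec, parse_formula

GLN_FORMULA = "C5H11N2O3"  # [M+H]+ ion of glutamine
GLN_BASE_MZ = 147.07642


def make_gln_target(
    dual: bool = False,
    expected_rt: float = 60.0,
    rt_window: float = 20.0,
) -> TargetIon:
    if dual:
        tracers = (TracerSpec("C", 13, 5), TracerSpec("N", 15, 2))
        isotopologues = [(i, j) for i in range(6) for j in range(3)]
    else:
        tracers = (TracerSpec("C", 13, 5),)
        isotopologues = [0, 1, 2, 3, 4, 5]
    return TargetIon(
        compound_name="glutamine",
        ion_name="Gln [M+H]+",
        formula=parse_formula(GLN_FORMULA),
        charge=1,
        base_mz=GLN_BASE_MZ,
        tracers=tracers,
        expected_rt=expected_rt,
        rt_window=rt_window,
        is_characteristic=True,
        quantified_isotopologues=isotopologues,
    )


def make_method(dual: bool = False, **kwargs) -> Method:
    return Method(
        targets=[make_gln_target(dual=dual)],
        mz_tolerance=MzTolerance(10, "ppm"),
        resolution_mode="high_res",
        **kwargs,
    )


@pytest.fixture
def gln_target() -> TargetIon:
    return make_gln_target()


@pytest.fixture
def gln_method() -> Method:
    return make_method()


@pytest.fixture
def gln_dual_method() -> Method:
    return make_method(dual=True)


def gaussian_eic(
    apex_rt: float = 60.0,
    sigma: float = 4.0,
    apex: float = 1e6,
    rt_start: float = 0.0,
    rt_end: float = 120.0,
    dt: float = 0.5,
    baseline: float = 0.0,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    mz: float = 150.0,
):
    from midquant.chromatography import EIC

    t = np.arange(rt_start, rt_end + dt / 2, dt)
    y = apex * np.exp(-((t - apex_rt) ** 2) / (2 * sigma**2))
    y = y + baseline + drift * (t - rt_start)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return EIC(rt=t, intensity=np.clip(y, 0, None), target_mz=mz)
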