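"""Shared fixtures: small phantoms and an end-to-end recovery helper."""

import numpy as np
import pytest

import pulmoperf as pp


def recover_global(spec, series, truth, mode="multivolume"):
    """Run the estimator chain on a simulated series; return (FlowMap, curve)."""
    curve = pp.extract_aif(series, pp.arterial_voi(spec))
    base, peak, dt = pp.select_base_peak(curve)
    c_in = pp.mean_input_concentration(curve, mode)
    flow = pp.compute_perfusion(
        pp.PerfusionInputs(
            v1=series[base], v2=series[peak], lung_mask=truth.lung_mask,
            c_in=c_in, delta_t_s=dt,
        )
    )
    return flow, curve


def mass_weighted_truth(truth):
    """Ground-truth global perfusion: tissue-fraction-weighted lung mean."""
    w = truth.tissue_fraction[truth.lung_mask]
    return float((truth.perfusion_map[truth.lung_mask] * w).sum() / w.sum())


@pytest.fixture(scope="session")
def small_spec():
    return pp.PhantomSpec(grid_shape=(24, 24, 24), noise_sd=0.0, rng_seed=0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return pp.simulate_series(small_spec)


@pytest.fixture(scope="session")
def noisefree_flow(small_phantom, small_spec):
    series, truth = small_phantom
    curve = pp.extract_aif(series, pp.arterial_voi(small_spec))
    base, peak, dt = pp.select_base_peak(curve)
    c_in = pp.mean_input_concentration(curve, "multivolume")
    flow = pp.compute_perfusion(
        pp.PerfusionInputs(
            v1=series[base], v2=series[peak], lung_mask=truth.lung_mask,
            c_in=c_in, delta_t_s=dt,
        )
    )
    return flow, curve, truth
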