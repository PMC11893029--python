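"""Shared fixtures: the in-sequence dictionary/subspace and one compact
phantom acquisition reconstructed by every method, reused across tests.

The phantom study runs at a reduced grid (12^3, 32 preparation repeats)
so the full paired comparison (subspace vs. temporal binning, plus the
regularization sweep) fits in a routine test run; all operators and the
solver are dimension-independent.
"""

from __future__ import annotations

import numpy as np
import pytest

import subangio as sa
from subangio.recon import SubspaceOperator, data_to_flat
from subangio.subspace import expand

PHANTOM_N = 12
N_REPEATS = 32
SAMPLES_PER_SPOKE = 24
SUBSPACE_ITER = 250
BINNED_ITER = 100


@pytest.fixture(scope="session")
def seq():
    return sa.SequenceParams()


@pytest.fixture(scope="session")
def dict40(seq):
    """The full 40^3-entry dictionary over the physiological ranges."""
    return sa.build_dictionary(sa.parameter_grid(), seq)


@pytest.fixture(scope="session")
def sub40(dict40):
    return sa.extract_subspace(dict40, 12)


@pytest.fixture(scope="session")
def dict12(seq):
    """Coarser 12^3 dictionary for cheap matching tests."""
    return sa.build_dictionary(sa.parameter_grid(n_per_axis=12), seq)


@pytest.fixture(scope="session")
def phantom_run(seq, sub40):
    """Simulated single-vessel acquisition shared by the recon tests."""
    n = PHANTOM_N
    phantom = sa.make_vessel_phantom(n)
    series = sa.phantom_series(phantom, seq).astype(complex)
    sampling = sa.build_sampling(seq, n_repeats=N_REPEATS, matrix_size=n,
                                 samples_per_spoke=SAMPLES_PER_SPOKE)
    nufft = sa.Nufft3(sampling.coords_flat(), (n, n, n))
    raw = sa.simulate_kspace(series, sampling, nufft=nufft)
    data, factor = sa.scale_kspace(raw)
    mask = np.zeros((n, n, n), bool)
    mask[phantom.vessel_indices] = True
    return {
        "phantom": phantom, "series": series, "sampling": sampling,
        "nufft": nufft, "raw": raw, "data": data, "factor": factor,
        "mask": mask,
    }


@pytest.fixture(scope="session")
def subspace_op(phantom_run, sub40):
    """One subspace forward operator (and its cached Toeplitz gram)."""
    return SubspaceOperator(phantom_run["sampling"], sub40,
                            nufft=phantom_run["nufft"])


@pytest.fixture(scope="session")
def recon_subspace(phantom_run, sub40, subspace_op):
    cfg = sa.ReconConfig(lam=5e-4, n_iterations=SUBSPACE_ITER, patch_size=4)
    coeffs, trace = sa.reconstruct_subspace(
        phantom_run["data"], phantom_run["sampling"], sub40,
        config=cfg, nufft=phantom_run["nufft"], operator=subspace_op)
    rec = expand(coeffs, sub40) * phantom_run["factor"]
    return {"coeffs": coeffs, "trace": trace, "series": rec}


@pytest.fixture(scope="session")
def recon_binned(phantom_run):
    cfg = sa.ReconConfig(lam=1e-1, n_iterations=BINNED_ITER, patch_size=4,
                         bin_size=12)
    frames, trace = sa.reconstruct_binned(
        phantom_run["data"], phantom_run["sampling"], config=cfg,
        nufft=phantom_run["nufft"])
    return {"frames": frames * phantom_run["factor"], "trace": trace}


@pytest.fixture(scope="session")
def recon_unregularized(phantom_run, sub40, subspace_op):
    """lam = 0 least-squares recon of consistent (in-subspace, in-band) data.

    The acquisition only measures spatial frequencies inside the radial
    Nyquist ball, and signal outside the temporal subspace cannot be
    represented, so the recoverable ground truth is the subspace-projected,
    ball-limited series; simulating from it makes the system consistent.
    """
    n = PHANTOM_N
    series = phantom_run["series"]
    proj = np.tensordot(sub40.basis @ sub40.basis.T, series, axes=(1, 0))
    freqs = np.fft.fftfreq(n)
    fx, fy, fz = np.meshgrid(freqs, freqs, freqs, indexing="ij")
    ball = fx**2 + fy**2 + fz**2 <= 0.25
    truth = np.fft.ifftn(np.fft.fftn(proj, axes=(1, 2, 3)) * ball,
                         axes=(1, 2, 3))
    data = sa.simulate_kspace(truth, phantom_run["sampling"],
                              nufft=phantom_run["nufft"])
    cfg = sa.ReconConfig(lam=0.0, n_iterations=150, patch_size=4)
    coeffs, trace = sa.reconstruct_subspace(
        data, phantom_run["sampling"], sub40, config=cfg,
        nufft=phantom_run["nufft"], operator=subspace_op)
    resid = np.linalg.norm(subspace_op.forward(coeffs)
                           - data_to_flat(data, phantom_run["sampling"]))
    resid /= np.linalg.norm(data)
    return {"coeffs": coeffs, "trace": trace, "truth": truth,
            "series": expand(coeffs, sub40), "relative_residual": resid}


@pytest.fixture(scope="session")
def fitted_maps(phantom_run, seq, dict40, recon_subspace, recon_binned):
    maps_sub = sa.fit_volume(recon_subspace["series"], seq, dict40,
                             mask=phantom_run["mask"])
    maps_bin = sa.fit_volume(recon_binned["frames"], seq, dict40,
                             mask=phantom_run["mask"])
    return {"subspace": maps_sub, "binned": maps_bin}


@pytest.fixture(scope="session")
def sweep_rows(phantom_run, seq, sub40, dict40):
    cfg = sa.ReconConfig(n_iterations=SUBSPACE_ITER, patch_size=4)
    return sa.lambda_sweep(phantom_run["data"], phantom_run["sampling"],
                           sub40, phantom_run["phantom"], seq, dict40,
                           config=cfg, nufft=phantom_run["nufft"],
                           mask=phantom_run["mask"])
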