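import numpy as np
import pytest

import nucqc as nq


def make_track(data: dict, role: str = "occupancy",
               normalized: bool = False) -> nq.SignalTrack:
    """Wrap raw per-chromosome vectors in a SignalTrack."""
    arrays = {c: np.asarray(v, dtype=float) for c, v in data.items()}
    return nq.SignalTrack(role=role, data=arrays, resolution=1,
                          normalized=normalized,
                          chrom_lengths={c: v.size for c, v in arrays.items()})


def gaussian_bumps(length: int, centers, sigma: float = 15.0,
                   heights=None, baseline: float = 0.0) -> np.ndarray:
    """Sum of Gaussian bumps: a clean stand-in for stacked nucleosome reads."""
    x = np.arange(length, dtype=float)
    out = np.full(length, baseline)
    heights = heights or [1.0] * len(centers)
    for c, h in zip(centers, heights):
        out += h * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return out


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """One deeply sequenced synthetic sample with its FASTA on disk."""
    sim = nq.simulate_sample(nq.SyntheticSpec(seed=1))
    nq.write_sample(sim, tmp_path_factory.mktemp("sim_seed1"))
    return sim


@pytest.fixture(scope="session")
def occ(default_sim):
    return nq.build_occupancy_track(default_sim.fragments, default_sim.assembly)


@pytest.fixture(scope="session")
def arr(occ):
    return nq.build_array_track(occ)
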