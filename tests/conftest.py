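import numpy as np
import pytest

from baroshift import (
    gen_dihedral_series,
    gen_distance_series,
    gen_latent_chain,
    gen_pressure_series,
    load_preset,
    segment_subensembles,
)

N_ENSEMBLE_FRAMES = 50_000


@pytest.fixture(scope="session")
def wt():
    return load_preset("WT_AP")


@pytest.fixture(scope="session")
def d76n():
    return load_preset("D76N_AP")


@pytest.fixture(scope="session")
def wt_hp():
    return load_preset("WT_HP")


@pytest.fixture(scope="session")
def wt_series(wt):
    """Noisy default wild-type pressure series (82 residues, 10 pressures)."""
    return gen_pressure_series(
        wt.shift_model(), wt.pressures, noise_sd=wt.noise_sd_h, seed=11
    )


@pytest.fixture(scope="session")
def wt_series_noiseless(wt):
    return gen_pressure_series(wt.shift_model(), wt.pressures, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def wt_ensemble(wt):
    """Latent labels, dihedrals, distances and segmentation for WT_AP."""
    labels = gen_latent_chain(wt.chain(), N_ENSEMBLE_FRAMES, seed=13)
    dihedrals = gen_dihedral_series(wt.dihedral_model(), labels, seed=13)
    distances = gen_distance_series(wt.distance_means, wt.distance_sds, labels, seed=13)
    segmentation = segment_subensembles(distances)
    return {
        "labels": labels,
        "dihedrals": dihedrals,
        "distances": distances,
        "segmentation": segmentation,
    }


@pytest.fixture(scope="session")
def d76n_ensemble(d76n):
    labels = gen_latent_chain(d76n.chain(), N_ENSEMBLE_FRAMES, seed=13)
    dihedrals = gen_dihedral_series(d76n.dihedral_model(), labels, seed=17)
    return {"labels": labels, "dihedrals": dihedrals}


def cosine(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


@pytest.fixture(scope="session")
def weighted():
    """Stack (H, N/5) per-residue pairs into the weighted row-space vector."""

    def _weighted(h, n):
        out = np.empty(2 * len(h))
        out[0::2] = h
        out[1::2] = np.asarray(n) * 0.2
        return out

    return _weighted
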