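import numpy as np
import pytest

from pescar import AnalysisConfig, CoherenceMap, SimulationScenario, build_dataset


def make_synthetic_coherence_maps(
    rng, n_subjects, pair_shape=(2, 2), grid=(6, 8), effects=None
):
    """Synthetic CoherenceMap collection (stand-in for wavelet output).

    ``effects``: optional {pair: (freq_slice, time_slice, delta)} adding a
    consistent condition-1 excess inside a TF block of that pair.
    """
    n_f, n_t = grid
    pairs = [(i, j) for i in range(pair_shape[0]) for j in range(pair_shape[1])]
    maps = []
    for s in range(n_subjects):
        for cond in ("C1", "C2"):
            coh = rng.uniform(0.2, 0.4, size=(len(pairs), n_f, n_t))
            if cond == "C1" and effects:
                for pair, (fs, ts, delta) in effects.items():
                    k = pairs.index(pair)
                    coh[k, fs, ts] += delta
            maps.append(
                CoherenceMap(
                    subject_id=s,
                    condition_id=cond,
                    coh=np.clip(coh, 0.0, 1.0),
                    pair_index=pairs,
                    freqs=np.arange(n_f, dtype=float) + 10.0,
                    times=np.arange(n_t, dtype=float) / 100.0,
                )
            )
    return maps


@pytest.fixture(scope="session")
def tiny_scenario():
    """Small but structurally complete study: 4 subjects, 3+3 sub-ROIs."""
    return SimulationScenario(
        n_subjects=4,
        n_subrois_per_roi=3,
        n_epochs=12,
        scenario_type="continuous",
        n_active_subrois=1,
        signal_scale=0.08,
        noise_fraction=0.5,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scenario):
    return build_dataset(tiny_scenario)


@pytest.fixture(scope="session")
def tiny_config():
    """Coarse TF grid keeping runtimes negligible."""
    return AnalysisConfig(
        freqs=np.arange(12.0, 25.0, 4.0), decim=12, n_perm=200, seed=0
    )
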