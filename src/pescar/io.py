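"""On-disk formats: HDF5 datasets, NPZ fixtures, YAML scenarios, result bundles.

Canonical dataset layout (HDF5)::

    /subject_<s>/<condition>/data   (n_subrois, n_epochs, n_times)
    /times, /roi_membership         shared axes
    attrs: sampling_rate

Every result bundle carries a verbatim config echo, the package version
and the seed, which together suffice to reproduce it.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import re

import h5py
import numpy as np
import yaml

from .simulate import EpochSet, SimulationScenario

__all__ = [
    "save_dataset",
    "load_dataset",
    "save_dataset_npz",
    "load_dataset_npz",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "save_coherence_maps",
    "load_coherence_maps",
    "save_results_bundle",
]


def save_dataset(path, dataset):
    """Write a collection of EpochSets to HDF5 (canonical layout)."""
    epoch_sets = list(dataset)
    if not epoch_sets:
        raise ValueError("nothing to save")
    ref = epoch_sets[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=ref.times)
        f.create_dataset("roi_membership", data=ref.roi_membership)
        f.attrs["sampling_rate"] = ref.sampling_rate
        for es in epoch_sets:
            grp = f.require_group(f"subject_{es.subject_id}")
            grp.create_dataset(str(es.condition_id), data=es.data)
    return pathlib.Path(path)


def load_dataset(path) -> list[EpochSet]:
    """Read a canonical HDF5 dataset back into EpochSets."""
    out = []
    with h5py.File(path, "r") as f:
        times = f["times"][()]
        roi = f["roi_membership"][()]
        sfreq = float(f.attrs["sampling_rate"])
        for name in sorted(f.keys()):
            m = re.fullmatch(r"subject_(\d+)", name)
            if not m:
                continue
            for cond in sorted(f[name].keys()):
                out.append(
                    EpochSet(
                        subject_id=int(m.group(1)),
                        condition_id=cond,
                        data=f[name][cond][()],
                        times=times,
                        roi_membership=roi,
                        sampling_rate=sfreq,
                    )
                )
    if not out:
        raise ValueError(f"no subject groups found in {path}")
    return out


def save_dataset_npz(path, dataset):
    """Compact NPZ writer for small fixtures."""
    epoch_sets = list(dataset)
    ref = epoch_sets[0]
    arrays = {
        f"data__{es.subject_id}__{es.condition_id}": es.data for es in epoch_sets
    }
    np.savez(
        path,
        times=ref.times,
        roi_membership=ref.roi_membership,
        sampling_rate=np.array(ref.sampling_rate),
        **arrays,
    )
    return pathlib.Path(path)


def load_dataset_npz(path) -> list[EpochSet]:
    with np.load(path) as z:
        times = z["times"]
        roi = z["roi_membership"]
        sfreq = float(z["sampling_rate"])
        out = []
        for key in sorted(z.files):
            if not key.startswith("data__"):
                continue
            _, subj, cond = key.split("__", 2)
            out.append(
                EpochSet(
                    subject_id=int(subj),
                    condition_id=cond,
                    data=z[key],
                    times=times,
                    roi_membership=roi,
                    sampling_rate=sfreq,
                )
            )
    return out


# ---------------------------------------------------------------------
# scenario YAML


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer, np.floating)):
        return value.item()
    if isinstance(value, tuple):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_jsonable(v) for v in value]
    return value


def scenario_to_yaml(scenario, path=None) -> str:
    """Serialize every SimulationScenario field as a YAML key."""
    payload = {k: _jsonable(v) for k, v in dataclasses.asdict(scenario).items()}
    text = yaml.safe_dump(payload, sort_keys=True)
    if path is not None:
        pathlib.Path(path).write_text(text)
    return text


def scenario_from_yaml(source) -> SimulationScenario:
    """Load a scenario from a YAML string or file path, validating keys."""
    src = pathlib.Path(source)
    text = src.read_text() if src.exists() else str(source)
    payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ValueError("scenario YAML must be a mapping")
    known = {f.name for f in dataclasses.fields(SimulationScenario)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    for key in ("epoch_window", "signal_window", "freq_set"):
        if key in payload and payload[key] is not None:
            payload[key] = tuple(payload[key])
    if payload.get("active_subrois") is not None:
        payload["active_subrois"] = {
            int(s): tuple(tuple(x) for x in v)
            for s, v in payload["active_subrois"].items()
        }
    scenario = SimulationScenario(**payload)
    scenario.validate()
    return scenario


# ---------------------------------------------------------------------
# coherence maps


def save_coherence_maps(path, maps):
    with h5py.File(path, "w") as f:
        ref = maps[0]
        f.create_dataset("freqs", data=ref.freqs)
        f.create_dataset("times", data=ref.times)
        f.create_dataset("pair_index", data=np.asarray(ref.pair_index, dtype=int))
        for m in maps:
            grp = f.require_group(f"subject_{m.subject_id}")
            d = grp.create_dataset(str(m.condition_id), data=m.coh)
            d.attrs["n_degenerate"] = m.n_degenerate
    return pathlib.Path(path)


def load_coherence_maps(path):
    from .tf import CoherenceMap

    out = []
    with h5py.File(path, "r") as f:
        freqs = f["freqs"][()]
        times = f["times"][()]
        pairs = [tuple(p) for p in f["pair_index"][()]]
        for name in sorted(f.keys()):
            m = re.fullmatch(r"subject_(\d+)", name)
            if not m:
                continue
            for cond in sorted(f[name].keys()):
                d = f[name][cond]
                out.append(
                    CoherenceMap(
                        subject_id=int(m.group(1)),
                        condition_id=cond,
                        coh=d[()],
                        pair_index=pairs,
                        freqs=freqs,
                        times=times,
                        n_degenerate=int(d.attrs.get("n_degenerate", 0)),
                    )
                )
    return out


# ---------------------------------------------------------------------
# result bundles


def _config_echo(config):
    return {k: _jsonable(v) for k, v in dataclasses.asdict(config).items()}


def save_results_bundle(results, out_dir, plots=False, method="pescar", extra=None):
    """Write a result bundle: JSON summary, CSV matrices, HDF5 arrays, PNGs.

    Works for both PescarResults and ConventionalResults (the latter is
    tagged ``method="conventional"`` and stores its single cluster test).
    """
    from . import __version__
    from .baseline import ConventionalResults

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(results, ConventionalResults):
        method = "conventional"
        summary = {
            "method": method,
            "min_cluster_p": results.min_cluster_p,
            "significant_0.05": bool(results.significant()),
            "clusters": [
                {"sign": int(c.sign), "mass": float(c.mass), "p": float(c.p_cluster)}
                for c in results.result.clusters
            ],
            "n_null": results.n_null,
            "exhaustive": results.exhaustive,
            "t_threshold": results.result.t_threshold,
        }
        arrays = {
            "tmap": results.result.tmap.t,
            "null_max_masses": results.null_max_masses,
            "freqs": results.result.tmap.freqs,
            "times": results.result.tmap.times,
        }
    else:
        summary = {
            "method": method,
            "A12": results.A12,
            "A21": results.A21,
            "k12": results.k12,
            "k21": results.k21,
            "p12": results.p12,
            "p21": results.p21,
            "p12_adj": results.p12_adj,
            "p21_adj": results.p21_adj,
            "n_null": results.n_null,
            "exhaustive": results.exhaustive,
            "t_threshold": results.t_threshold,
            "n_subjects": len(results.subjects),
            "pair_shape": list(results.pair_shape),
        }
        arrays = {
            "a12_matrix": results.a12.a,
            "a21_matrix": results.a21.a,
            "null12": results.null12.values,
            "null21": results.null21.values,
            "tf_unweighted_c1_gt_c2": results.tf_maps["unweighted"]["C1>C2"],
            "tf_unweighted_c2_gt_c1": results.tf_maps["unweighted"]["C2>C1"],
            "tf_weighted_c1_gt_c2": results.tf_maps["weighted"]["C1>C2"],
            "tf_weighted_c2_gt_c1": results.tf_maps["weighted"]["C2>C1"],
            "freqs": results.freqs,
            "times": results.times,
        }
        import pandas as pd

        pd.DataFrame(results.a12.a).to_csv(out / f"{method}_a12_matrix.csv")
        pd.DataFrame(results.a21.a).to_csv(out / f"{method}_a21_matrix.csv")
    summary["config"] = _config_echo(results.config)
    summary["seed"] = results.seed
    summary["version"] = __version__
    if extra:
        summary.update(extra)
    (out / f"{method}_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    with h5py.File(out / f"{method}_arrays.h5", "w") as f:
        for name, arr in arrays.items():
            if arr is not None:
                f.create_dataset(name, data=np.asarray(arr))
    if plots and method == "pescar":
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        for direction, tag in (("C1>C2", "c1_gt_c2"), ("C2>C1", "c2_gt_c1")):
            ax = results.plot_matrix(direction)
            ax.figure.savefig(out / f"matrix_{tag}.png", dpi=150)
            plt.close(ax.figure)
            ax = results.plot_tf_map(direction)
            ax.figure.savefig(out / f"tf_map_{tag}.png", dpi=150)
            plt.close(ax.figure)
    return out
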