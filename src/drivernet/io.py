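"""Serialization: MatrixMarket weights, TSV spikes and state, run manifests.

Topologies are written as one MatrixMarket coordinate file per connection
class (1-based indices, real entries = weights) plus a plain-text sidecar
with the population sizes and, if present, torus positions as TSV.
Spike records are TSV with a comment header carrying the population sizes
and duration.  All formatting is locale-independent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp

from .dynamics import NetworkState, SpikeRecord
from .topology import CLASSES, Topology

__all__ = [
    "write_weights_mtx", "read_weights_mtx",
    "write_topology", "read_topology",
    "write_spikes", "read_spikes",
    "write_state", "read_state",
    "write_trajectory",
    "RunManifest", "write_manifest",
]


def write_weights_mtx(topology: Topology, cls: str, path) -> None:
    """One connection class as MatrixMarket coordinate (real, general)."""
    if cls not in CLASSES:
        raise ValueError(f"unknown connection class {cls!r}")
    scipy.io.mmwrite(str(path), topology.w[cls].tocoo())


def read_weights_mtx(path) -> sp.csr_matrix:
    m = scipy.io.mmread(str(path)).tocsr()
    return m


def write_topology(topology: Topology, outdir) -> None:
    """Four MTX files (weights_<class>.mtx) plus topology.txt sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cls in CLASSES:
        write_weights_mtx(topology, cls, outdir / f"weights_{cls}.mtx")
    with open(outdir / "topology.txt", "w") as fh:
        fh.write(f"n_e\t{topology.n_e}\n")
        fh.write(f"n_i\t{topology.n_i}\n")
        if topology.positions is not None:
            fh.write("positions\tid\tu\tv\n")
            for i, (u, v) in enumerate(topology.positions):
                fh.write(f"pos\t{i}\t{float(u)!r}\t{float(v)!r}\n")


def read_topology(outdir) -> Topology:
    outdir = Path(outdir)
    n_e = n_i = None
    positions = []
    with open(outdir / "topology.txt") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "n_e":
                n_e = int(parts[1])
            elif parts[0] == "n_i":
                n_i = int(parts[1])
            elif parts[0] == "pos":
                positions.append((float(parts[2]), float(parts[3])))
    if n_e is None or n_i is None:
        raise ValueError("sidecar missing population sizes")
    w = {cls: read_weights_mtx(outdir / f"weights_{cls}.mtx")
         for cls in CLASSES}
    pos = np.asarray(positions) if positions else None
    return Topology(n_e, n_i, w, positions=pos)


def write_spikes(spikes: SpikeRecord, path, decimals: int = 1) -> None:
    """TSV spike record: header comment + (time_ms, neuron_id) rows.

    Times are fixed-point with ``decimals`` places (1 decimal is exact at
    the default dt = 0.1 ms).
    """
    with open(path, "w") as fh:
        fh.write(f"# n_e={spikes.n_e} n_i={spikes.n_i} "
                 f"duration={spikes.duration!r}\n")
        fh.write("time_ms\tneuron_id\n")
        fmt = f"{{:.{decimals}f}}\t{{}}\n"
        for t, i in zip(spikes.times, spikes.ids):
            fh.write(fmt.format(t, i))


def read_spikes(path) -> SpikeRecord:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing spike-file header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        cols = fh.readline().rstrip("\n").split("\t")
        if cols != ["time_ms", "neuron_id"]:
            raise ValueError("unexpected spike-file columns")
        times, ids = [], []
        for line in fh:
            t_s, i_s = line.split("\t")
            times.append(float(t_s))
            ids.append(int(i_s))
    times = np.asarray(times)
    ids = np.asarray(ids, dtype=np.int64)
    if times.size and times.min() < 0:
        raise ValueError("negative spike times")
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("spike times must be sorted")
    return SpikeRecord(times, ids, int(meta["n_e"]), int(meta["n_i"]),
                       float(meta["duration"]))


def write_state(state: NetworkState, path) -> None:
    """NetworkState snapshot as TSV (id, V, g_e, g_i, refractory_remaining)."""
    with open(path, "w") as fh:
        fh.write(f"# t={float(state.t)!r}\n")
        fh.write("id\tV\tg_e\tg_i\trefractory_remaining\n")
        for i in range(state.V.size):
            fh.write(f"{i}\t{float(state.V[i])!r}\t{float(state.g_e[i])!r}"
                     f"\t{float(state.g_i[i])!r}"
                     f"\t{float(state.refractory_remaining[i])!r}\n")


def read_state(path) -> NetworkState:
    with open(path) as fh:
        header = fh.readline()
        t = float(header.split("=")[1])
        fh.readline()
        rows = [line.split("\t") for line in fh]
    arr = np.asarray([[float(x) for x in r[1:]] for r in rows])
    return NetworkState(arr[:, 0].copy(), arr[:, 1].copy(), arr[:, 2].copy(),
                        arr[:, 3].copy(), t)


def write_trajectory(trajectory, path) -> None:
    """Weight-trajectory summary TSV: t_ms then mean/var per class."""
    with open(path, "w") as fh:
        fh.write("t_ms\t" + "\t".join(
            f"{cls}_{m}" for cls in CLASSES for m in ("mean", "var")) + "\n")
        for t, stats in trajectory:
            cells = [f"{float(t)!r}"]
            for cls in CLASSES:
                mean, var = stats[cls]
                cells += [repr(mean), repr(var)]
            fh.write("\t".join(cells) + "\n")


class RunManifest:
    """Reproducibility record of one run: config snapshot path, seeds and
    an inventory of output files with SHA-256 checksums."""

    def __init__(self, master_seed: int, config_file: str | None = None,
                 version: str | None = None):
        from . import __version__
        self.master_seed = int(master_seed)
        self.config_file = config_file
        self.version = version or __version__
        self.components: dict[str, int] = {}
        self.files: dict[str, str] = {}

    def register_component(self, tag: str, seed: int) -> None:
        self.components[tag] = int(seed)

    def register_file(self, path) -> None:
        path = Path(path)
        h = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[path.name] = h

    def to_dict(self) -> dict:
        return {"version": self.version, "master_seed": self.master_seed,
                "config_file": self.config_file,
                "component_seeds": self.components, "files": self.files}


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
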