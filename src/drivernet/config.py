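"""Configuration files and full-parameter bundles.

INI-style files with sections [neuron], [synapse], [topology],
[plasticity], [drive], [protocol]; every model parameter has a named key
whose default is the base model's published value, so an empty file
yields the complete default parameter set.  Unknown sections or keys are
rejected.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

from .dynamics import DriveSpec
from .plasticity import (NormalizationParams, PlasticityConfig, ScalingParams,
                         STDPParams)
from .topology import ConnectivityProfile, NeuronParams, SynapseParams

__all__ = ["TopologySettings", "ProtocolSettings", "Config",
           "load_config", "save_config"]


@dataclass
class TopologySettings:
    kind: str = "random"          # random | homogeneous | torus
    n_e: int = 4000
    n_i: int = 1000
    p: float = 0.02
    k_e_in: int = 80
    k_i_in: int = 20
    epsilon_e: float = 0.2
    sigma_e: float = 0.1
    epsilon_i: float = 0.8
    sigma_i: float = 0.05
    i_placement: str = "uniform"

    def __post_init__(self) -> None:
        if self.kind not in ("random", "homogeneous", "torus"):
            raise ValueError("topology kind must be random, homogeneous or torus")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.n_e < 0 or self.n_i < 0:
            raise ValueError("population sizes must be non-negative")
        # profile invariants checked here as well
        ConnectivityProfile(self.epsilon_e, self.sigma_e)
        ConnectivityProfile(self.epsilon_i, self.sigma_i)


@dataclass
class ProtocolSettings:
    duration: float = 5 * 3600 * 1000.0   # transient length (ms)
    dt: float = 0.1                       # ms
    seed: int = 0
    snapshot_interval: float = 600_000.0  # ms
    ks_tolerance: float = 0.01
    record_tail: float = 100_000.0        # ms
    rate_ceiling: float = 100.0           # Hz

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")


@dataclass
class Config:
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    topology: TopologySettings = field(default_factory=TopologySettings)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    drive: DriveSpec = field(default_factory=DriveSpec)
    protocol: ProtocolSettings = field(default_factory=ProtocolSettings)

    def build_topology(self, seed: int):
        from . import topology as T
        ts = self.topology
        if ts.kind == "random":
            topo = T.build_random_topology(ts.n_e, ts.n_i, ts.p, seed)
        elif ts.kind == "homogeneous":
            topo = T.build_homogeneous_topology(ts.n_e, ts.n_i, ts.k_e_in,
                                                ts.k_i_in, seed)
        else:
            topo = T.build_torus_topology(
                ts.n_e, ts.n_i,
                ConnectivityProfile(ts.epsilon_e, ts.sigma_e),
                ConnectivityProfile(ts.epsilon_i, ts.sigma_i),
                ts.i_placement, seed)
        return T.init_weights(topo, "constant", {"value": 1.0}, seed,
                              self.synapse)


# section -> (dataclass factory keys, type coercions)
_BOOLS = {"true": True, "false": False, "1": True, "0": False,
          "yes": True, "no": False}


def _coerce(value: str, like):
    if isinstance(like, bool):
        v = value.strip().lower()
        if v not in _BOOLS:
            raise ValueError(f"expected a boolean, got {value!r}")
        return _BOOLS[v]
    if isinstance(like, int):
        return int(value)
    if isinstance(like, float):
        return float(value)
    return value


# plasticity is flattened into named keys
_PLASTICITY_DEFAULTS = {
    "ee_stdp": True,
    "ie_stdp": True,
    "ee_mode": "additive",
    "a_plus_ee": 1e-3,
    "a_minus_ee": 1.05e-3,
    "a_plus_ie": 4e-3,
    "a_minus_ie": 1e-3,
    "tau_plus": 20.0,
    "tau_minus": 20.0,
    "homeostasis": "normalization",   # normalization | scaling | none
    "norm_interval": 100.0,
    "target_mean": 1.0,
    "gamma": 1e-6,
    "nu_0": 0.0,
    "scaling_interval": 50.0,
    "rate_window": 100.0,
}

_DRIVE_DEFAULTS = {"mode": "constant", "depolarization": 11.0,
                   "rate": -1.0, "unit_weight": 1.0}


def _plasticity_from(vals: dict, synapse: SynapseParams) -> PlasticityConfig:
    ee = None
    if vals["ee_stdp"]:
        ee = STDPParams(vals["a_plus_ee"], vals["a_minus_ee"],
                        vals["tau_plus"], vals["tau_minus"],
                        vals["ee_mode"], synapse.w_e_max)
    ie = None
    if vals["ie_stdp"]:
        ie = STDPParams(vals["a_plus_ie"], vals["a_minus_ie"],
                        vals["tau_plus"], vals["tau_minus"],
                        "additive", synapse.w_i_max)
    norm = scal = None
    if vals["homeostasis"] == "normalization":
        norm = NormalizationParams(vals["norm_interval"], vals["target_mean"])
    elif vals["homeostasis"] == "scaling":
        scal = ScalingParams(vals["gamma"], vals["nu_0"],
                             vals["scaling_interval"], vals["rate_window"])
    elif vals["homeostasis"] != "none":
        raise ValueError("homeostasis must be normalization, scaling or none")
    return PlasticityConfig(ee, ie, norm, scal)


def load_config(path) -> Config:
    """Read an INI config; unspecified keys get the published defaults,
    unknown sections/keys raise, invariants are validated."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cp = configparser.ConfigParser()
    cp.read(path)

    def section(name, defaults: dict) -> dict:
        vals = dict(defaults)
        if cp.has_section(name):
            for key, raw in cp.items(name):
                if key not in vals:
                    raise ValueError(f"unknown key {key!r} in section [{name}]")
                vals[key] = _coerce(raw, vals[key])
        return vals

    known = {"neuron", "synapse", "topology", "plasticity", "drive",
             "protocol"}
    for sec in cp.sections():
        if sec not in known:
            raise ValueError(f"unknown section [{sec}]")

    nv = section("neuron", {"tau_m": 20.0, "e_l": -60.0, "v_thres": -50.0,
                            "v_reset": -60.0, "tau_ref": 2.0})
    neuron = NeuronParams(tau_m=nv["tau_m"], E_L=nv["e_l"],
                          V_thres=nv["v_thres"], V_reset=nv["v_reset"],
                          tau_ref=nv["tau_ref"])
    synapse = SynapseParams(**section("synapse", {
        "tau_e": 5.0, "tau_i": 10.0, "c_e_norm": 1.0, "c_i_norm": -9.0,
        "w_e_max": 20.0, "w_i_max": 5.0}))
    topo = TopologySettings(**section("topology", {
        "kind": "random", "n_e": 4000, "n_i": 1000, "p": 0.02,
        "k_e_in": 80, "k_i_in": 20, "epsilon_e": 0.2, "sigma_e": 0.1,
        "epsilon_i": 0.8, "sigma_i": 0.05, "i_placement": "uniform"}))
    plast = _plasticity_from(section("plasticity", _PLASTICITY_DEFAULTS),
                             synapse)
    dv = section("drive", _DRIVE_DEFAULTS)
    drive = DriveSpec(dv["mode"], dv["depolarization"],
                      None if dv["rate"] < 0 else dv["rate"],
                      dv["unit_weight"])
    proto = ProtocolSettings(**section("protocol", {
        "duration": 5 * 3600 * 1000.0, "dt": 0.1, "seed": 0,
        "snapshot_interval": 600_000.0, "ks_tolerance": 0.01,
        "record_tail": 100_000.0, "rate_ceiling": 100.0}))
    return Config(neuron, synapse, topo, plast, drive, proto)


def save_config(config: Config, path) -> None:
    """Write the full parameter set as an INI file (locale-independent)."""
    cp = configparser.ConfigParser()
    n, s, t, d, p = (config.neuron, config.synapse, config.topology,
                     config.drive, config.protocol)
    cp["neuron"] = {"tau_m": repr(n.tau_m), "e_l": repr(n.E_L),
                    "v_thres": repr(n.V_thres), "v_reset": repr(n.V_reset),
                    "tau_ref": repr(n.tau_ref)}
    cp["synapse"] = {k: repr(getattr(s, k)) for k in
                     ("tau_e", "tau_i", "c_e_norm", "c_i_norm",
                      "w_e_max", "w_i_max")}
    cp["topology"] = {k: str(getattr(t, k)) for k in
                      ("kind", "n_e", "n_i", "p", "k_e_in", "k_i_in",
                       "epsilon_e", "sigma_e", "epsilon_i", "sigma_i",
                       "i_placement")}
    pl = config.plasticity
    cp["plasticity"] = {
        "ee_stdp": str(pl.ee_stdp is not None).lower(),
        "ie_stdp": str(pl.ie_stdp is not None).lower(),
        "homeostasis": ("normalization" if pl.normalization is not None
                        else "scaling" if pl.scaling is not None else "none"),
    }
    if pl.ee_stdp is not None:
        cp["plasticity"].update({
            "ee_mode": pl.ee_stdp.mode,
            "a_plus_ee": repr(pl.ee_stdp.A_plus),
            "a_minus_ee": repr(pl.ee_stdp.A_minus),
            "tau_plus": repr(pl.ee_stdp.tau_plus),
            "tau_minus": repr(pl.ee_stdp.tau_minus)})
    if pl.ie_stdp is not None:
        cp["plasticity"].update({
            "a_plus_ie": repr(pl.ie_stdp.A_plus),
            "a_minus_ie": repr(pl.ie_stdp.A_minus)})
    if pl.normalization is not None:
        cp["plasticity"].update({
            "norm_interval": repr(pl.normalization.interval),
            "target_mean": repr(pl.normalization.target_mean)})
    if pl.scaling is not None:
        cp["plasticity"].update({
            "gamma": repr(pl.scaling.gamma), "nu_0": repr(pl.scaling.nu_0),
            "scaling_interval": repr(pl.scaling.step_interval),
            "rate_window": repr(pl.scaling.rate_window)})
    cp["drive"] = {"mode": d.mode, "depolarization": repr(d.depolarization),
                   "rate": repr(-1.0 if d.rate is None else d.rate),
                   "unit_weight": repr(d.unit_weight)}
    cp["protocol"] = {k: repr(getattr(p, k)) for k in
                      ("duration", "dt", "seed", "snapshot_interval",
                       "ks_tolerance", "record_tail", "rate_ceiling")}
    with open(path, "w") as fh:
        cp.write(fh)
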