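"""Plain-text serialization of specs, realizations and spike data.

Configs are flat INI-style key=value sections ([neuron], [structure],
[weights], [heterogeneity], [drive], [sim]); realizations go to a columnar
text file with a commented header, a threshold table and an edge list; spike
data to two-column text. All formats round-trip bit-exactly.
"""

from __future__ import annotations

import configparser
import io
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from hetnet.core import (
    HeterogeneityLevels,
    NetworkRealization,
    NetworkSpec,
    NeuronConstants,
    PopulationStructure,
    SynapticWeights,
)
from hetnet.simulator import DriveSpec, SimConfig, SpikeData

__all__ = [
    "spec_to_config",
    "spec_from_config",
    "write_config",
    "read_config",
    "write_realization",
    "read_realization",
    "write_spikes",
    "read_spikes",
]

_FLOAT_FMT = "%.17g"


def _f(x) -> str:
    return _FLOAT_FMT % float(x)


def spec_to_config(
    spec: NetworkSpec,
    drive: DriveSpec | None = None,
    sim: SimConfig | None = None,
) -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    nc, st, w, h = spec.constants, spec.structure, spec.weights, spec.heterogeneity
    cp["neuron"] = {
        "tau_m": _f(nc.tau_m),
        "V_r": _f(nc.V_r),
        "theta_mean": _f(nc.theta_mean),
        "tau_ref": _f(nc.tau_ref),
    }
    cp["structure"] = {"N": str(st.N), "gamma": _f(st.gamma), "eps": _f(st.eps)}
    cp["weights"] = {
        "J_EE": _f(w.J_EE),
        "J_IE": _f(w.J_IE),
        "J_EI": _f(w.J_EI),
        "J_II": _f(w.J_II),
    }
    cp["heterogeneity"] = {"w_E": _f(h.w_E), "w_I": _f(h.w_I)}
    if drive is not None:
        cp["drive"] = {
            "mu": _f(drive.mu),
            "mu0": _f(drive.mu0),
            "sigma": _f(drive.sigma),
            "S0": _f(drive.S0),
            "f_s": _f(drive.f_s),
        }
    if sim is not None:
        cp["sim"] = {
            "duration": _f(sim.duration),
            "dt": _f(sim.dt),
            "transient": _f(sim.transient),
            "n_trials": str(sim.n_trials),
            "master_seed": str(sim.master_seed),
        }
    return cp


def spec_from_config(
    cp: configparser.ConfigParser,
) -> tuple[NetworkSpec, DriveSpec | None, SimConfig | None]:
    n = cp["neuron"]
    spec = NetworkSpec(
        constants=NeuronConstants(
            tau_m=n.getfloat("tau_m"),
            V_r=n.getfloat("V_r"),
            theta_mean=n.getfloat("theta_mean"),
            tau_ref=n.getfloat("tau_ref"),
        ),
        structure=PopulationStructure(
            N=cp["structure"].getint("N"),
            gamma=cp["structure"].getfloat("gamma"),
            eps=cp["structure"].getfloat("eps"),
        ),
        weights=SynapticWeights(
            J_EE=cp["weights"].getfloat("J_EE"),
            J_IE=cp["weights"].getfloat("J_IE"),
            J_EI=cp["weights"].getfloat("J_EI"),
            J_II=cp["weights"].getfloat("J_II"),
        ),
        heterogeneity=HeterogeneityLevels(
            w_E=cp["heterogeneity"].getfloat("w_E"),
            w_I=cp["heterogeneity"].getfloat("w_I"),
        ),
    )
    drive = None
    if cp.has_section("drive"):
        d = cp["drive"]
        drive = DriveSpec(
            mu=d.getfloat("mu"),
            mu0=d.getfloat("mu0"),
            sigma=d.getfloat("sigma"),
            S0=d.getfloat("S0", fallback=0.0),
            f_s=d.getfloat("f_s", fallback=0.0),
        )
    sim = None
    if cp.has_section("sim"):
        s = cp["sim"]
        sim = SimConfig(
            duration=s.getfloat("duration"),
            dt=s.getfloat("dt"),
            transient=s.getfloat("transient"),
            n_trials=s.getint("n_trials"),
            master_seed=s.getint("master_seed"),
        )
    return spec, drive, sim


def write_config(
    path: str | Path,
    spec: NetworkSpec,
    drive: DriveSpec | None = None,
    sim: SimConfig | None = None,
) -> None:
    cp = spec_to_config(spec, drive, sim)
    with open(path, "w") as fh:
        cp.write(fh)


def read_config(path: str | Path) -> tuple[NetworkSpec, DriveSpec | None, SimConfig | None]:
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    return spec_from_config(cp)


def write_realization(path: str | Path, real: NetworkRealization) -> None:
    """Columnar text dump: spec header, threshold table, edge list."""
    buf = io.StringIO()
    cp = spec_to_config(real.spec)
    spec_txt = io.StringIO()
    cp.write(spec_txt)
    for line in spec_txt.getvalue().splitlines():
        buf.write(f"# {line}\n")
    buf.write(f"# seed_record = {real.seed_record}\n")
    buf.write("# thresholds: index label theta_mV\n")
    buf.write(f"@thresholds {real.N}\n")
    for i in range(real.N):
        lab = "E" if real.is_exc[i] else "I"
        buf.write(f"{i} {lab} {_f(real.thresholds[i])}\n")
    coo = real.connectivity.tocoo()
    order = np.lexsort((coo.row, coo.col))
    buf.write("# edges: post pre weight_mV\n")
    buf.write(f"@edges {coo.nnz}\n")
    for post, pre, wt in zip(coo.row[order], coo.col[order], coo.data[order]):
        buf.write(f"{post} {pre} {_f(wt)}\n")
    Path(path).write_text(buf.getvalue())


def read_realization(path: str | Path) -> NetworkRealization:
    text = Path(path).read_text().splitlines()
    seed = 0
    cfg_lines = []
    for raw in text:
        if not raw.startswith("# "):
            continue
        ln = raw[2:]
        if ln.startswith("seed_record"):
            seed = int(ln.split("=")[1])
        elif ln.startswith("[") or "=" in ln:
            cfg_lines.append(ln)
    cp = configparser.ConfigParser()
    cp.read_string("\n".join(cfg_lines))
    spec, _, _ = spec_from_config(cp)

    it = iter(text)
    thresholds = labels = None
    posts, pres, wts = [], [], []
    for ln in it:
        if ln.startswith("@thresholds"):
            n = int(ln.split()[1])
            thresholds = np.empty(n)
            labels = np.zeros(n, dtype=bool)
            for _ in range(n):
                idx, lab, th = next(it).split()
                thresholds[int(idx)] = float(th)
                labels[int(idx)] = lab == "E"
        elif ln.startswith("@edges"):
            m = int(ln.split()[1])
            for _ in range(m):
                post, pre, wt = next(it).split()
                posts.append(int(post))
                pres.append(int(pre))
                wts.append(float(wt))
    if thresholds is None:
        raise ValueError(f"no threshold table found in {path}")
    N = thresholds.shape[0]
    conn = sp.csc_matrix((wts, (posts, pres)), shape=(N, N))
    return NetworkRealization(
        spec=spec, thresholds=thresholds, is_exc=labels, connectivity=conn, seed_record=seed
    )


def write_spikes(path: str | Path, spikes: SpikeData) -> None:
    """Two-column plain text (time_ms, neuron_index) with a commented header."""
    with open(path, "w") as fh:
        fh.write("# spike data: time_ms neuron_index\n")
        fh.write(f"# n_neurons = {spikes.n_neurons}\n")
        fh.write(f"# duration_ms = {_f(spikes.duration)}\n")
        fh.write("# labels = " + "".join("E" if e else "I" for e in spikes.is_exc) + "\n")
        for t, i in zip(spikes.times, spikes.indices):
            fh.write(f"{_f(t)} {i}\n")


def read_spikes(path: str | Path) -> SpikeData:
    n_neurons = duration = labels = None
    times, idx = [], []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                if "n_neurons" in ln:
                    n_neurons = int(ln.split("=")[1])
                elif "duration_ms" in ln:
                    duration = float(ln.split("=")[1])
                elif "labels" in ln:
                    labels = np.array([c == "E" for c in ln.split("=")[1].strip()])
                continue
            t, i = ln.split()
            times.append(float(t))
            idx.append(int(i))
    if n_neurons is None or duration is None or labels is None:
        raise ValueError(f"missing header metadata in {path}")
    return SpikeData(
        times=np.asarray(times),
        indices=np.asarray(idx, dtype=np.int64),
        n_neurons=n_neurons,
        is_exc=labels,
        duration=duration,
    )
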