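"""Spike raster and voltage trace containers with plain-text round trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import NetworkGeometry, POP_E, POP_I


@dataclass
class SpikeRaster:
    """Timestamped spikes labeled by population, cluster and neuron index.

    Records are sorted by time; spikes emitted within one cascade instant
    share a timestamp.  ``t`` is in ms.
    """

    t: np.ndarray
    pop: np.ndarray           # 0=E, 1=I
    j: np.ndarray             # orientation index
    k: np.ndarray             # hypercolumn index
    l: np.ndarray             # within-population index
    geometry: NetworkGeometry = field(default_factory=NetworkGeometry)
    duration: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        for name in ("pop", "j", "k", "l"):
            setattr(self, name, np.asarray(getattr(self, name), np.int32))

    def __len__(self) -> int:
        return self.t.shape[0]

    def select(self, pop: int | None = None, j: int | None = None,
               k: int | None = None) -> "SpikeRaster":
        m = np.ones(len(self), bool)
        if pop is not None:
            m &= self.pop == pop
        if j is not None:
            m &= self.j == j
        if k is not None:
            m &= self.k == k
        return SpikeRaster(self.t[m], self.pop[m], self.j[m], self.k[m],
                           self.l[m], self.geometry, self.duration, self.seed)

    def neuron_ids(self) -> np.ndarray:
        """Global neuron index per spike (cluster-major, E before I)."""
        g = self.geometry
        c = self.k * g.n_orientations + self.j
        return c * g.cluster_size + np.where(self.pop == POP_E, 0, g.N_E) + self.l

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_ms": self.t, "Q": np.where(self.pop == POP_E, "E", "I"),
                             "j": self.j, "k": self.k, "l": self.l})

    def save(self, path: str | Path) -> Path:
        """Columnar text: comment header with metadata, then t_ms Q j k l."""
        path = Path(path)
        g = self.geometry
        with open(path, "w") as fh:
            fh.write(f"# duration_ms={self.duration!r} seed={self.seed}\n")
            fh.write(f"# n_hypercolumns={g.n_hypercolumns} n_orientations="
                     f"{g.n_orientations} N_E={g.N_E} N_I={g.N_I}\n")
            fh.write("t_ms\tQ\tj\tk\tl\n")
            for i in range(len(self)):
                fh.write(f"{float(self.t[i])!r}\t{'EI'[self.pop[i]]}\t"
                         f"{self.j[i]}\t{self.k[i]}\t{self.l[i]}\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SpikeRaster":
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k_, v = tok.split("=", 1)
                        meta[k_] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        geom = NetworkGeometry(
            n_hypercolumns=int(meta.get("n_hypercolumns", 8)),
            n_orientations=int(meta.get("n_orientations", 3)),
            N_E=int(meta.get("N_E", 128)), N_I=int(meta.get("N_I", 128)))
        seed = meta.get("seed")
        return cls(df["t_ms"].to_numpy(), (df["Q"] == "I").to_numpy().astype(np.int32),
                   df["j"].to_numpy(), df["k"].to_numpy(), df["l"].to_numpy(),
                   geometry=geom, duration=float(meta.get("duration_ms", 0.0)),
                   seed=None if seed in (None, "None") else int(seed))


@dataclass
class VoltageTrace:
    """Sampled subthreshold voltages.

    ``cluster_mean`` has shape ``(n_samples, n_clusters, 2)`` holding the
    population-averaged voltage per cluster for E (index 0) and I (index 1);
    this population average is the model's LFP proxy.  ``monitored`` holds
    full per-neuron traces for the monitored subset (may be empty).
    """

    times: np.ndarray                     # (n_samples,) ms
    cluster_mean: np.ndarray              # (n_samples, n_clusters, 2)
    monitored: np.ndarray                 # (n_samples, n_monitored)
    monitor_ids: np.ndarray               # global neuron indices
    geometry: NetworkGeometry = field(default_factory=NetworkGeometry)

    @property
    def sample_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def lfp(self, j: int, k: int, pop: int = POP_E) -> np.ndarray:
        """Population-averaged voltage of one cluster (the LFP proxy)."""
        c = k * self.geometry.n_orientations + j
        return self.cluster_mean[:, c, pop]

    def save(self, path: str | Path) -> Path:
        """npz container (runtime artifact; not a repo fixture format)."""
        path = Path(path)
        np.savez_compressed(
            path, times=self.times, cluster_mean=self.cluster_mean,
            monitored=self.monitored, monitor_ids=self.monitor_ids,
            geometry=np.array([self.geometry.n_hypercolumns,
                               self.geometry.n_orientations,
                               self.geometry.N_E, self.geometry.N_I]))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VoltageTrace":
        z = np.load(path)
        hk, j, ne, ni = z["geometry"]
        return cls(z["times"], z["cluster_mean"], z["monitored"], z["monitor_ids"],
                   NetworkGeometry(int(hk), int(j), int(ne), int(ni)))
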