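"""Cluster/hypercolumn architecture and sparse synaptic weight matrices.

The model is a 2D array of *clusters* (orientation domains): ``J``
orientations in each of ``K`` hypercolumns, every cluster holding ``N_E``
excitatory and ``N_I`` inhibitory integrate-and-fire neurons.  Connectivity
is random and statistically homogeneous; whether a connection exists, and
its strength if it does, depend only on

* the presynaptic and postsynaptic types ``Q', Q`` (E or I),
* whether the two neurons share an orientation (``delta_jj'``),
* whether they share a hypercolumn (``delta_kk'``).

Within a hypercolumn all type pairs connect (6 local strengths
``S_fast^{QQ'}`` and ``S_slow^{QE}``); across hypercolumns only excitatory
neurons broadcast long-range connections, and only to clusters of the same
orientation (4 strengths ``L_fast^{QE}``, ``L_slow^{QE}``).  The slow
(NMDA-like) conductance is excitatory only, so slow weights of inhibitory
senders are identically zero.

Strength names are receiver-first: ``S_fast_EI`` is the fast weight onto an
E neuron from an I neuron.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import yaml

POP_E, POP_I = 0, 1


@dataclass(frozen=True)
class NetworkGeometry:
    n_hypercolumns: int = 8
    n_orientations: int = 3
    N_E: int = 128
    N_I: int = 128

    def __post_init__(self):
        for name in ("n_hypercolumns", "n_orientations", "N_E", "N_I"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def n_clusters(self) -> int:
        return self.n_hypercolumns * self.n_orientations

    @property
    def cluster_size(self) -> int:
        return self.N_E + self.N_I

    @property
    def n_neurons(self) -> int:
        return self.n_clusters * self.cluster_size

    def cluster_index(self, j: int, k: int) -> int:
        """Flat cluster index for orientation ``j`` in hypercolumn ``k``."""
        return k * self.n_orientations + j


@dataclass(frozen=True)
class ConnectivityParams:
    """Connection probabilities and coupling strengths.

    Probabilities are keyed by the *presynaptic* type: I neurons arborize
    more densely than E neurons.  ``cross_factor`` scales the within-cluster
    probabilities for pairs in different clusters of the same hypercolumn;
    ``p_long`` (per sender-E pair, across hypercolumns, same orientation)
    defaults to the same reduced value as the cross-cluster one.
    """

    p_E_local: float = 0.20        # from an E sender, same cluster
    p_I_local: float = 0.50        # from an I sender, same cluster
    cross_factor: float = 0.5      # cross-cluster (same hypercolumn) multiplier
    p_long: float | None = None    # across hypercolumns (E senders only)

    # 6 local strengths
    S_fast_EE: float = 0.0
    S_fast_EI: float = 0.0
    S_fast_IE: float = 0.0
    S_fast_II: float = 0.0
    S_slow_EE: float = 0.0
    S_slow_IE: float = 0.0
    # 4 long-range strengths (E senders only)
    L_fast_EE: float = 0.0
    L_fast_IE: float = 0.0
    L_slow_EE: float = 0.0
    L_slow_IE: float = 0.0

    horizontal_delay_ms: float = 0.0   # synaptic delay on long-range connections

    def __post_init__(self):
        for name, p in self.probabilities().items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        for f in ("S_fast_EE", "S_fast_EI", "S_fast_IE", "S_fast_II",
                  "S_slow_EE", "S_slow_IE", "L_fast_EE", "L_fast_IE",
                  "L_slow_EE", "L_slow_IE"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        if self.horizontal_delay_ms < 0:
            raise ValueError("horizontal delay must be nonnegative")

    def probabilities(self) -> dict[str, float]:
        p_long = self.p_long if self.p_long is not None else self.p_E_local * self.cross_factor
        return {
            "E_local": self.p_E_local,
            "I_local": self.p_I_local,
            "E_cross": self.p_E_local * self.cross_factor,
            "I_cross": self.p_I_local * self.cross_factor,
            "E_long": p_long,
        }

    def connection_prob(self, sender_pop: int, same_j: bool, same_k: bool) -> float:
        """Probability that an ordered pair in the given class is connected."""
        p = self.probabilities()
        if same_k:
            key = "E" if sender_pop == POP_E else "I"
            return p[f"{key}_local"] if same_j else p[f"{key}_cross"]
        if same_j and sender_pop == POP_E:
            return p["E_long"]
        return 0.0

    def weights(self, receiver_pop: int, sender_pop: int,
                same_j: bool, same_k: bool) -> tuple[float, float]:
        """(fast, slow) strength for a connected pair in the given class."""
        r = "E" if receiver_pop == POP_E else "I"
        s = "E" if sender_pop == POP_E else "I"
        if same_k:
            fast = getattr(self, f"S_fast_{r}{s}")
            slow = getattr(self, f"S_slow_{r}E") if s == "E" else 0.0
            return fast, slow
        if same_j and s == "E":
            return getattr(self, f"L_fast_{r}E"), getattr(self, f"L_slow_{r}E")
        return 0.0, 0.0


@dataclass
class Network:
    """Built network: neuron table plus fast/slow weight matrices.

    ``W_fast`` and ``W_slow`` are CSC matrices indexed ``[receiver, sender]``
    (CSC makes a sender's target list contiguous, which is what cascade
    resolution traverses).
    """

    geometry: NetworkGeometry
    connectivity: ConnectivityParams
    seed: int
    pop: np.ndarray        # (N,) 0=E, 1=I
    j: np.ndarray          # (N,) orientation index
    k: np.ndarray          # (N,) hypercolumn index
    l: np.ndarray          # (N,) within-population index
    W_fast: sp.csc_matrix
    W_slow: sp.csc_matrix

    @property
    def n_neurons(self) -> int:
        return self.pop.shape[0]

    def cluster_of(self) -> np.ndarray:
        return self.k * self.geometry.n_orientations + self.j

    def neurons_in(self, j: int, k: int, pop: int | None = None) -> np.ndarray:
        m = (self.j == j) & (self.k == k)
        if pop is not None:
            m &= self.pop == pop
        return np.flatnonzero(m)


def _neuron_table(geom: NetworkGeometry):
    """Cluster-major layout: within each cluster, E neurons then I neurons."""
    pops, js, ks, ls = [], [], [], []
    for k in range(geom.n_hypercolumns):
        for j in range(geom.n_orientations):
            pops.append(np.repeat([POP_E, POP_I], [geom.N_E, geom.N_I]))
            js.append(np.full(geom.cluster_size, j))
            ks.append(np.full(geom.cluster_size, k))
            ls.append(np.concatenate([np.arange(geom.N_E), np.arange(geom.N_I)]))
    return (np.concatenate(pops).astype(np.int8), np.concatenate(js).astype(np.int32),
            np.concatenate(ks).astype(np.int32), np.concatenate(ls).astype(np.int32))


def build_network(geometry: NetworkGeometry | None = None,
                  connectivity: ConnectivityParams | None = None,
                  seed: int = 0) -> Network:
    """Sample the random connectivity and assemble the weight matrices.

    Each ordered (sender, receiver) pair is connected independently with the
    probability of its (sender type, delta_jj', delta_kk') class; connected
    pairs carry the class weights.  No self-connections.  Reproducible given
    ``seed``.
    """
    geom = geometry or NetworkGeometry()
    conn = connectivity or ConnectivityParams()
    rng = np.random.default_rng(seed)
    pop, j_arr, k_arr, l_arr = _neuron_table(geom)
    cs = geom.cluster_size
    nc = geom.n_clusters

    rows, cols, wf, ws = [], [], [], []
    # cluster-block offsets; within each cluster E occupies [0, N_E) and I
    # [N_E, cs)
    pop_slices = {POP_E: slice(0, geom.N_E), POP_I: slice(geom.N_E, cs)}
    pop_sizes = {POP_E: geom.N_E, POP_I: geom.N_I}
    for ck_r in range(geom.n_hypercolumns):
        for cj_r in range(geom.n_orientations):
            off_r = geom.cluster_index(cj_r, ck_r) * cs
            for ck_s in range(geom.n_hypercolumns):
                for cj_s in range(geom.n_orientations):
                    same_j = cj_r == cj_s
                    same_k = ck_r == ck_s
                    off_s = geom.cluster_index(cj_s, ck_s) * cs
                    for ps in (POP_E, POP_I):
                        p = conn.connection_prob(ps, same_j, same_k)
                        if p == 0.0:
                            continue
                        ns = pop_sizes[ps]
                        for pr in (POP_E, POP_I):
                            nr = pop_sizes[pr]
                            fast, slow = conn.weights(pr, ps, same_j, same_k)
                            mask = rng.random((nr, ns)) < p
                            if same_j and same_k and pr == ps:
                                np.fill_diagonal(mask, False)
                            r, c = np.nonzero(mask)
                            if r.size == 0:
                                continue
                            rows.append(r + off_r + pop_slices[pr].start)
                            cols.append(c + off_s + pop_slices[ps].start)
                            wf.append(np.full(r.size, fast))
                            ws.append(np.full(r.size, slow))
    N = geom.n_neurons
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        wf = np.concatenate(wf)
        ws = np.concatenate(ws)
    else:  # fully disconnected configuration
        rows = np.array([], int); cols = np.array([], int)
        wf = np.array([], float); ws = np.array([], float)
    shape = (N, N)
    # keep explicit zeros out of the fast matrix but retain edge identity:
    # an edge with zero configured strength still exists structurally, so we
    # store it in both matrices (sum_duplicates not needed - pairs unique).
    W_fast = sp.csc_matrix((wf, (rows, cols)), shape=shape)
    W_slow = sp.csc_matrix((ws, (rows, cols)), shape=shape)
    return Network(geometry=geom, connectivity=conn, seed=seed,
                   pop=pop, j=j_arr, k=k_arr, l=l_arr,
                   W_fast=W_fast, W_slow=W_slow)


class NetworkInvariantError(AssertionError):
    """A structural invariant of the architecture is violated."""


def validate_network(network: Network) -> dict[str, float]:
    """Assert the architectural zero-structure and weight homogeneity;
    return empirical connection fractions per class.

    Checks, by construction class:

    * slow weights of I senders are identically zero;
    * across hypercolumns, only E senders with matching orientation connect;
    * all nonzero weights within one (Q, Q', delta_jj', delta_kk') class are
      equal to the configured class strength.
    """
    net = network
    coo = net.W_slow.tocoo()
    if np.any((net.pop[coo.col] == POP_I) & (coo.data != 0)):
        raise NetworkInvariantError("W_slow has nonzero entries from I senders")
    fast = net.W_fast.tocoo()
    slow = net.W_slow.tocoo()
    # structural edge set is shared between the two matrices by construction
    edges_r = fast.row
    edges_c = fast.col
    same_k = net.k[edges_r] == net.k[edges_c]
    same_j = net.j[edges_r] == net.j[edges_c]
    sender_I = net.pop[edges_c] == POP_I
    bad = ~same_k & (sender_I | ~same_j)
    if bad.any():
        raise NetworkInvariantError(
            "illegal long-range edge (cross-hypercolumn edges must have an E "
            "sender and matching orientation)")
    # weight homogeneity per class
    conn = net.connectivity
    for pr in (POP_E, POP_I):
        for ps in (POP_E, POP_I):
            for sj in (True, False):
                for sk in (True, False):
                    m = ((net.pop[edges_r] == pr) & (net.pop[edges_c] == ps)
                         & (same_j == sj) & (same_k == sk))
                    if not m.any():
                        continue
                    f_exp, s_exp = conn.weights(pr, ps, sj, sk)
                    if not (np.all(fast.data[m] == f_exp)
                            and np.all(slow.data[m] == s_exp)):
                        raise NetworkInvariantError(
                            f"inhomogeneous weights in class (Q={pr}, Q'={ps}, "
                            f"same_j={sj}, same_k={sk})")
    # empirical connection fractions per sender class
    report: dict[str, float] = {}
    geom = net.geometry
    n_per = {POP_E: geom.N_E, POP_I: geom.N_I}
    adj = net.W_fast.astype(bool)
    adj_csr = adj.tocsr()
    counts: dict[str, int] = {}
    pairs: dict[str, int] = {}
    cluster = net.cluster_of()
    sj_e = net.j[edges_r] == net.j[edges_c]
    for name, m_sender, cond in [
        ("E_local", POP_E, same_k & same_j),
        ("I_local", POP_I, same_k & same_j),
        ("E_cross", POP_E, same_k & ~same_j),
        ("I_cross", POP_I, same_k & ~same_j),
        ("E_long", POP_E, ~same_k & same_j),
    ]:
        n_edges = int(np.sum(cond & (net.pop[edges_c] == m_sender)))
        counts[name] = n_edges
    J, K = geom.n_orientations, geom.n_hypercolumns
    nc = geom.n_clusters
    tot = geom.cluster_size
    for name, sender in [("E_local", POP_E), ("I_local", POP_I)]:
        n_s = n_per[sender]
        pairs[name] = nc * (n_s * tot - n_s)   # ordered pairs, no self
    for name, sender in [("E_cross", POP_E), ("I_cross", POP_I)]:
        n_s = n_per[sender]
        pairs[name] = K * J * (J - 1) * n_s * tot
    pairs["E_long"] = J * K * (K - 1) * geom.N_E * tot
    for name in counts:
        report[name] = counts[name] / pairs[name] if pairs[name] else float("nan")
    return report


# ---------------------------------------------------------------------------
# serialization: sparse-triplet text container, bit-exact round trip
# ---------------------------------------------------------------------------

def save_network(net: Network, directory: str | Path) -> Path:
    """Write a network as plain-text files under ``directory``.

    ``edges.tsv`` holds one ``sender receiver w_fast w_slow`` triplet row per
    structural edge with full-precision floats; ``neurons.tsv`` the neuron
    table; ``network.yaml`` geometry, connectivity and build seed.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fast = net.W_fast.tocoo()
    slow = net.W_slow.tocoo()
    # both matrices are built from the same (row, col) arrays, so their
    # canonical COO orderings are aligned entry for entry
    buf = io.StringIO()
    buf.write("sender\treceiver\tw_fast\tw_slow\n")
    for r, c, wf, ws in zip(fast.row, fast.col, fast.data, slow.data):
        buf.write(f"{c}\t{r}\t{float(wf)!r}\t{float(ws)!r}\n")
    (d / "edges.tsv").write_text(buf.getvalue())
    buf = io.StringIO()
    buf.write("index\tpop\tj\tk\tl\n")
    for i in range(net.n_neurons):
        buf.write(f"{i}\t{'EI'[net.pop[i]]}\t{net.j[i]}\t{net.k[i]}\t{net.l[i]}\n")
    (d / "neurons.tsv").write_text(buf.getvalue())
    meta = {
        "geometry": asdict(net.geometry),
        "connectivity": asdict(net.connectivity),
        "seed": int(net.seed),
    }
    (d / "network.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return d


def load_network(directory: str | Path) -> Network:
    """Inverse of :func:`save_network`; bit-exact round trip."""
    d = Path(directory)
    meta = yaml.safe_load((d / "network.yaml").read_text())
    geom = NetworkGeometry(**meta["geometry"])
    conn = ConnectivityParams(**meta["connectivity"])
    pop, j_arr, k_arr, l_arr = _neuron_table(geom)
    senders, receivers, wfs, wss = [], [], [], []
    with open(d / "edges.tsv") as fh:
        next(fh)
        for line in fh:
            s, r, wf, ws = line.split("\t")
            senders.append(int(s)); receivers.append(int(r))
            wfs.append(float(wf)); wss.append(float(ws))
    shape = (geom.n_neurons, geom.n_neurons)
    W_fast = sp.csc_matrix((wfs, (receivers, senders)), shape=shape)
    W_slow = sp.csc_matrix((wss, (receivers, senders)), shape=shape)
    return Network(geometry=geom, connectivity=conn, seed=meta["seed"],
                   pop=pop, j=j_arr, k=k_arr, l=l_arr,
                   W_fast=W_fast, W_slow=W_slow)
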