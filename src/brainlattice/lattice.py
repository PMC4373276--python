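"""Self-organizing map (Kohonen lattice) over behavioral-term brain maps.

A planar grid of nodes, each carrying a weight vector in voxel space, is
trained online: draw a training map at random, find its Best Matching Unit
(BMU, nearest node by Euclidean distance), and pull every node within the
current neighborhood radius toward the sample,

    W(t+1) = W(t) + L(t) * (V(t) - W(t)),

with the neighborhood width shrinking exponentially,

    sigma(t) = sigma0 * exp(-t / lambda),

until it is the size of the BMU alone. As printed, the update applies the
full learning rate to every node inside the neighborhood; a Gaussian
falloff by grid distance is available behind ``kernel="gaussian"``. The
learning rate decays with the same time constant, L(t) = L0 * exp(-t/lambda).

After training each term is assigned to its BMU, labeling grid regions with
behavioral meaning; each node's weight vector can be reshaped back into a
3D volume for comparison with new maps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .revinf import LabelMap
from .volgrid import Grid

#: Grid dimensions used at full corpus scale (506 nodes).
FULL_SCALE_DIMS = (22, 23)


@dataclass
class SOMSchedule:
    """Training schedule: neighborhood width, learning rate and length.

    sigma0   initial neighborhood radius, in grid units
    lam      time constant of the exponential decays
    learn0   initial learning rate, in (0, 1]
    n_iter   iteration cap (training may stop earlier, when sigma < 1)
    seed     RNG seed for weight init and sampling
    """

    sigma0: float
    lam: float
    learn0: float = 0.05
    n_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.learn0 <= 1:
            raise ValueError("learn0 must be in (0, 1]")

    @classmethod
    def default_for(
        cls, n_maps: int, dims: tuple[int, int], seed: int = 0, learn0: float = 0.05
    ) -> "SOMSchedule":
        """Defaults: sigma0 = max(dims)/2; n_iter = 500*n_maps capped at
        20,000; lam chosen so sigma decays to ~1 by n_iter."""
        sigma0 = max(dims) / 2.0
        n_iter = min(500 * max(n_maps, 1), 20_000)
        lam = n_iter / math.log(sigma0) if sigma0 > 1 else float(n_iter)
        return cls(sigma0=sigma0, lam=lam, learn0=learn0, n_iter=n_iter, seed=seed)


def sigma(t: float, sched: SOMSchedule) -> float:
    """Neighborhood width at iteration t: sigma0 * exp(-t / lambda)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return sched.sigma0 * math.exp(-t / sched.lam)


def learning_rate(t: float, sched: SOMSchedule) -> float:
    """Learning rate at iteration t: learn0 * exp(-t / lambda)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return sched.learn0 * math.exp(-t / sched.lam)


@dataclass
class Lattice:
    """A trained (or training) SOM grid.

    Node ``(r, c)`` has linear index ``r*cols + c``; ``weights`` is
    (rows*cols, n_voxels). ``labels`` maps node index -> list of term ids
    whose BMU it is.
    """

    rows: int
    cols: int
    weights: np.ndarray
    labels: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.rows * self.cols:
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{self.rows}x{self.cols} grid"
            )
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite weights")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]

    def grid_pos(self, node: int) -> tuple[int, int]:
        if not 0 <= node < self.n_nodes:
            raise ValueError(f"node {node} out of range")
        return divmod(node, self.cols)

    def grid_positions(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) per node, in linear-index order."""
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c])


def find_bmu(v: np.ndarray, lattice: Lattice) -> int:
    """Best Matching Unit: node minimizing Euclidean distance to ``v``.

    Ties break to the lowest (row, col) — i.e. lowest linear index.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (lattice.n_voxels,):
        raise ValueError("vector length does not match lattice weights")
    d2 = ((lattice.weights - v) ** 2).sum(axis=1)
    return int(np.argmin(d2))  # argmin returns the first minimum

def update_weights(
    lattice: Lattice,
    v: np.ndarray,
    bmu: int,
    t: float,
    sched: SOMSchedule,
    kernel: str = "flat",
) -> Lattice:
    """In-place neighborhood update around the BMU at iteration ``t``.

    Every node whose grid (row, col) Euclidean distance to the BMU is at
    most sigma(t) moves toward ``v`` by the full learning rate L(t)
    (``kernel="flat"``); with ``kernel="gaussian"`` the step is additionally
    damped by exp(-d^2 / (2 sigma(t)^2)).
    """
    if kernel not in ("flat", "gaussian"):
        raise ValueError("kernel must be 'flat' or 'gaussian'")
    v = np.asarray(v, dtype=float)
    s = sigma(t, sched)
    lr = learning_rate(t, sched)
    pos = lattice.grid_positions().astype(float)
    d = np.linalg.norm(pos - pos[bmu], axis=1)
    inside = d <= s
    if kernel == "flat":
        step = np.where(inside, lr, 0.0)
    else:
        step = np.where(inside, lr * np.exp(-(d**2) / (2.0 * s**2)), 0.0)
    lattice.weights += step[:, None] * (v - lattice.weights)
    return lattice


def train(
    term_maps: dict[str, LabelMap | np.ndarray],
    dims: tuple[int, int],
    sched: SOMSchedule | None = None,
    kernel: str = "flat",
    allow_resampling: bool = False,
) -> Lattice:
    """Train a lattice on term maps (flattened z-vectors).

    Weights initialize uniform at random within the per-voxel min/max of
    the training data (seeded); each iteration samples a training map
    uniformly with replacement, finds its BMU and updates the neighborhood.
    The neighborhood decay is complete once sigma(t) < 1 — from then on
    only the BMU itself is updated — and training runs to ``sched.n_iter``
    (node specialization happens in that BMU-only tail; without it a
    two-node grid, whose nodes are always mutual neighbors, could never
    split apart). Finally every term is labeled onto its BMU.

    The grid may not exceed the number of training maps (each node should
    be reachable without resampling) unless ``allow_resampling=True``.
    """
    if not term_maps:
        raise ValueError("no training maps")
    rows, cols = dims
    if rows <= 0 or cols <= 0:
        raise ValueError("grid dims must be positive")
    ids = sorted(term_maps)
    X = np.vstack(
        [
            term_maps[i].z if isinstance(term_maps[i], LabelMap) else np.asarray(term_maps[i], float)
            for i in ids
        ]
    )
    n_maps, n_vox = X.shape
    if rows * cols > n_maps and not allow_resampling:
        raise ValueError(
            f"{rows}x{cols} grid has {rows * cols} nodes but only {n_maps} "
            "training maps; a node count above the training-set size requires "
            "resampling (pass allow_resampling=True to override)"
        )
    if sched is None:
        sched = SOMSchedule.default_for(n_maps, dims)
    rng = np.random.default_rng(sched.seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    weights = rng.uniform(size=(rows * cols, n_vox)) * (hi - lo) + lo
    lattice = Lattice(rows=rows, cols=cols, weights=weights)
    for t in range(sched.n_iter):
        v = X[rng.integers(n_maps)]
        bmu = find_bmu(v, lattice)
        update_weights(lattice, v, bmu, t, sched, kernel=kernel)
    labels: dict[int, list[str]] = {}
    for i, term in enumerate(ids):
        bmu = find_bmu(X[i], lattice)
        labels.setdefault(bmu, []).append(term)
    lattice.labels = labels
    return lattice


def node_volume(lattice: Lattice, node: int, grid: Grid) -> np.ndarray:
    """Reshape one node's weight vector back into a 3D volume (0 off-mask)."""
    if not 0 <= node < lattice.n_nodes:
        raise ValueError(f"node {node} out of range")
    return grid.unvectorize(lattice.weights[node])


def save_lattice(lattice: Lattice, sched: SOMSchedule | None, path) -> None:
    """Serialize to ``<path>.npz`` (weights) + ``<path>.json`` sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), weights=lattice.weights)
    sidecar = {
        "rows": lattice.rows,
        "cols": lattice.cols,
        "labels": {str(k): v for k, v in lattice.labels.items()},
        "schedule": None if sched is None else vars(sched).copy(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_lattice(path) -> tuple[Lattice, SOMSchedule | None]:
    path = Path(path)
    weights = np.load(path.with_suffix(".npz"))["weights"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    lattice = Lattice(
        rows=sidecar["rows"],
        cols=sidecar["cols"],
        weights=weights,
        labels={int(k): v for k, v in sidecar["labels"].items()},
    )
    sched = None
    if sidecar.get("schedule"):
        sched = SOMSchedule(**sidecar["schedule"])
    return lattice, sched
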