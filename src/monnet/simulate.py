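"""Synthetic modular neuronal network (MoNNet) generator.

A MoNNet is a culture of interconnected neuronal spheroids: neurons inside a
spheroid fire together almost deterministically, while activity propagates
between spheroids with a probability that decays with physical distance.  The
simulator emulates that structure so every downstream analysis stage
(segmentation, dF/F, synchrony graphs, consensus modules, treatment
comparison) can be exercised and validated against known ground truth.

Generative mechanism
--------------------
* Each spheroid emits Poisson events at ``baseline_rate`` events/s.
* An event recruits each member neuron of its home spheroid with probability
  ``p_local``.
* An event in spheroid ``a`` propagates (single hop, no relaying) to spheroid
  ``b`` with probability ``rho * w_global * exp(-d_ab / lambda_decay)`` where
  ``d_ab`` is the centroid distance; a propagated event recruits the members
  of ``b`` with probability ``p_local`` in the same frame.
* Spikes drive a stable second-order autoregressive calcium kernel
  ``c_t = g1 c_{t-1} + g2 c_{t-2} + s_t`` and fluorescence is
  ``F_t = f0 * (1 + c_t) + eps_t`` with i.i.d. Gaussian noise.

``rho`` is the genotype coupling factor: 1 is wild-type-like, values below 1
weaken inter-spheroid coupling the way schizophrenia-risk mutant cultures
show much-reduced global synchrony with intact local synchrony.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimulationConfig",
    "MoNNetLayout",
    "GeneSetFixture",
    "PackingError",
    "generate_layout",
    "simulate_activity",
    "render_movie",
    "generate_gene_fixture",
    "phase_preset",
    "PHASE_PRESETS",
]


class PackingError(RuntimeError):
    """Raised when a layout cannot be packed into the field of view."""


def _check_ar2_stable(g1: float, g2: float) -> None:
    # stability of 1 - g1 z - g2 z^2 (roots outside the unit circle)
    if not (g1 + g2 < 1 and g2 > -1 and g2 - g1 < 1):
        raise ValueError(
            f"unstable AR(2) kernel (g1={g1}, g2={g2}); require "
            "g1+g2<1, g2>-1, g2-g1<1"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic MoNNet.

    Spatial units are micrometres, time in seconds, rates in events/s.
    ``rho`` scales inter-spheroid propagation (1 = wild-type-like,
    < 1 = mutant-like).  ``g1``/``g2`` are the AR(2) calcium kernel
    coefficients; the default pair corresponds to a fast indicator decay
    sampled at 30 Hz.
    """

    n_spheroids: int = 9
    neurons_per_spheroid: int = 6
    duration: float = 120.0
    frame_rate: float = 30.0
    baseline_rate: float = 0.05
    p_local: float = 0.9
    w_global: float = 0.95
    lambda_decay: float = 1500.0
    rho: float = 1.0
    g1: float = 1.7
    g2: float = -0.712
    noise_sd: float = 0.03
    f0: float = 1.0
    seed: int = 0
    # layout geometry
    field_size: float = 600.0
    radius_log_mean: float = 3.6  # log-normal location, log(um); exp(3.6) ~ 37 um
    radius_log_sigma: float = 0.25
    min_gap: float = 10.0  # extra clearance between spheroid rims, um
    # optional n_spheroids x n_spheroids coupling matrix overriding w_global
    coupling: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_spheroids < 1 or self.neurons_per_spheroid < 1:
            raise ValueError("n_spheroids and neurons_per_spheroid must be >= 1")
        for name in ("p_local", "w_global", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if self.duration * self.frame_rate < 2:
            raise ValueError("duration * frame_rate must be >= 2 frames")
        _check_ar2_stable(self.g1, self.g2)
        if self.coupling is not None:
            W = np.asarray(self.coupling, dtype=float)
            if W.shape != (self.n_spheroids, self.n_spheroids):
                raise ValueError("coupling matrix must be n_spheroids x n_spheroids")
            if np.any(W < 0) or np.any(W > 1):
                raise ValueError("coupling entries must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def coupling_matrix(self) -> np.ndarray:
        """Inter-spheroid coupling scale, defaulting to uniform ``w_global``."""
        if self.coupling is not None:
            return np.asarray(self.coupling, dtype=float)
        return np.full((self.n_spheroids, self.n_spheroids), self.w_global)

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["coupling"] is not None:
            d["coupling"] = np.asarray(d["coupling"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("coupling") is not None:
            d["coupling"] = tuple(map(tuple, d["coupling"]))
        return cls(**d)


@dataclass
class MoNNetLayout:
    """Geometric scaffold: spheroid centroids/radii and neuron membership."""

    spheroid_centroids: np.ndarray  # (n_spheroids, 2) um
    spheroid_radii: np.ndarray  # (n_spheroids,) um
    neuron_positions: np.ndarray  # (n_neurons, 2) um
    membership: np.ndarray  # (n_neurons,) int spheroid index

    def __post_init__(self) -> None:
        self.spheroid_centroids = np.asarray(self.spheroid_centroids, float)
        self.spheroid_radii = np.asarray(self.spheroid_radii, float)
        self.neuron_positions = np.asarray(self.neuron_positions, float)
        self.membership = np.asarray(self.membership, int)
        if np.any(self.spheroid_radii <= 0):
            raise ValueError("spheroid radii must be > 0")
        if self.membership.min(initial=0) < 0 or (
            self.membership.max(initial=0) >= len(self.spheroid_radii)
        ):
            raise ValueError("membership indices out of range")

    @property
    def n_spheroids(self) -> int:
        return len(self.spheroid_radii)

    @property
    def n_neurons(self) -> int:
        return len(self.membership)

    def centroid_distances(self) -> np.ndarray:
        """Pairwise centre-to-centre distances between spheroids (um)."""
        diff = self.spheroid_centroids[:, None, :] - self.spheroid_centroids[None, :, :]
        return np.hypot(diff[..., 0], diff[..., 1])

    def to_json(self) -> str:
        return json.dumps(
            {
                "spheroid_centroids": self.spheroid_centroids.tolist(),
                "spheroid_radii": self.spheroid_radii.tolist(),
                "neuron_positions": self.neuron_positions.tolist(),
                "membership": self.membership.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "MoNNetLayout":
        d = json.loads(s)
        return cls(
            np.array(d["spheroid_centroids"]),
            np.array(d["spheroid_radii"]),
            np.array(d["neuron_positions"]),
            np.array(d["membership"]),
        )


def generate_layout(config: SimulationConfig) -> MoNNetLayout:
    """Place spheroids of log-normal radii in the field of view.

    Centroids are rejection-sampled uniformly subject to a non-overlap
    constraint (centre separation >= sum of radii + ``min_gap``).  Neuron
    positions are uniform within each spheroid's disc.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    radii = rng.lognormal(config.radius_log_mean, config.radius_log_sigma,
                          size=config.n_spheroids)
    L = config.field_size
    centroids = np.empty((config.n_spheroids, 2))
    max_attempts = 10_000
    for i, r in enumerate(radii):
        if 2 * r >= L:
            raise PackingError(
                f"spheroid {i} (radius {r:.1f} um) does not fit in a "
                f"{L:.0f} um field"
            )
        for _ in range(max_attempts):
            cand = rng.uniform(r, L - r, size=2)
            sep = np.hypot(*(centroids[:i] - cand).T) if i else np.array([])
            if np.all(sep >= radii[:i] + r + config.min_gap):
                centroids[i] = cand
                break
        else:
            raise PackingError(
                f"could not place spheroid {i} (radius {r:.1f} um) after "
                f"{max_attempts} attempts; field too crowded"
            )
    membership = np.repeat(np.arange(config.n_spheroids),
                           config.neurons_per_spheroid)
    # uniform in the disc: sqrt-radius transform
    u = rng.uniform(size=len(membership))
    theta = rng.uniform(0, 2 * np.pi, size=len(membership))
    rr = radii[membership] * np.sqrt(u)
    positions = centroids[membership] + np.stack(
        [rr * np.cos(theta), rr * np.sin(theta)], axis=1
    )
    return MoNNetLayout(centroids, radii, positions, membership)


def simulate_activity(
    layout: MoNNetLayout, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ground-truth spikes and fluorescence.

    Returns
    -------
    spikes : (n_neurons, n_frames) int array of spike counts
    F : (n_neurons, n_frames) float array of fluorescence
    """
    rng = np.random.default_rng(config.seed + 1)  # independent of layout draw
    n_frames = config.n_frames
    n_neurons = layout.n_neurons
    n_sph = layout.n_spheroids
    dist = layout.centroid_distances()
    W = config.coupling_matrix()
    prop_p = config.rho * W * np.exp(-dist / config.lambda_decay)
    np.fill_diagonal(prop_p, 0.0)

    # per-spheroid Poisson event frames
    p_event = min(config.baseline_rate / config.frame_rate, 1.0)
    events = rng.random((n_sph, n_frames)) < p_event  # origin events

    # single-hop propagation: spheroid b is active in frame t if it has its
    # own event or receives one from an originating spheroid
    active = events.copy()
    origin_sph, origin_t = np.nonzero(events)
    for a, t in zip(origin_sph, origin_t):
        recv = rng.random(n_sph) < prop_p[a]
        active[recv, t] = True

    spikes = np.zeros((n_neurons, n_frames), dtype=np.int64)
    recruit = rng.random((n_neurons, n_frames)) < config.p_local
    spikes[recruit & active[layout.membership]] = 1

    # AR(2) calcium and fluorescence
    c = np.zeros((n_neurons, n_frames))
    s = spikes.astype(float)
    g1, g2 = config.g1, config.g2
    c[:, 0] = s[:, 0]
    if n_frames > 1:
        c[:, 1] = g1 * c[:, 0] + s[:, 1]
    for t in range(2, n_frames):
        c[:, t] = g1 * c[:, t - 1] + g2 * c[:, t - 2] + s[:, t]
    F = config.f0 * (1.0 + c)
    if config.noise_sd > 0:
        F = F + rng.normal(0.0, config.noise_sd, size=F.shape)
    return spikes, F


def ar2_impulse_response(g1: float, g2: float, n: int) -> np.ndarray:
    """Impulse response of ``c_t = g1 c_{t-1} + g2 c_{t-2} + s_t``."""
    _check_ar2_stable(g1, g2)
    h = np.zeros(n)
    h[0] = 1.0
    if n > 1:
        h[1] = g1
    for t in range(2, n):
        h[t] = g1 * h[t - 1] + g2 * h[t - 2]
    return h


def render_movie(
    layout: MoNNetLayout,
    F: np.ndarray,
    pixel_size: float,
    noise_sd: float = 0.0,
    shape: tuple[int, int] | None = None,
    footprint_sigma: float = 6.0,
    seed: int = 0,
) -> np.ndarray:
    """Render fluorescence traces into an image stack.

    Each neuron contributes a Gaussian spatial footprint (SD
    ``footprint_sigma`` um) scaled by its fluorescence; pixel noise is
    additive Gaussian.  Returns a (frames, height, width) float array.
    """
    F = np.asarray(F, float)
    if shape is None:
        n = int(np.ceil((layout.spheroid_centroids + layout.spheroid_radii[:, None]).max()
                        / pixel_size)) + 1
        shape = (n, n)
    h_px, w_px = shape
    ys = np.arange(h_px) * pixel_size
    xs = np.arange(w_px) * pixel_size
    extent = max(layout.neuron_positions.max(initial=0.0),
                 (layout.spheroid_centroids + layout.spheroid_radii[:, None]).max())
    if extent > max(ys[-1], xs[-1]) + pixel_size:
        raise ValueError(
            f"frame of {h_px}x{w_px} px at {pixel_size} um/px does not cover "
            f"the layout extent ({extent:.0f} um)"
        )
    # footprints: (n_neurons, h, w), separable Gaussian
    px = layout.neuron_positions[:, 0]
    py = layout.neuron_positions[:, 1]
    gx = np.exp(-0.5 * ((xs[None, :] - px[:, None]) / footprint_sigma) ** 2)
    gy = np.exp(-0.5 * ((ys[None, :] - py[:, None]) / footprint_sigma) ** 2)
    footprints = gy[:, :, None] * gx[:, None, :]
    stack = np.einsum("nt,nhw->thw", F, footprints)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack


@dataclass
class GeneSetFixture:
    """Gene universe with a target set and query set of known overlap."""

    universe: list[str]
    targets: list[str]
    query: list[str]
    planted_overlap: int

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if not set(self.targets) <= uni or not set(self.query) <= uni:
            raise ValueError("targets and query must be subsets of the universe")
        k = len(set(self.targets) & set(self.query))
        if k != self.planted_overlap:
            raise ValueError(
                f"actual overlap {k} != planted_overlap {self.planted_overlap}"
            )


def generate_gene_fixture(
    n_universe: int,
    n_targets: int,
    n_query: int,
    planted_overlap: int,
    seed: int = 0,
) -> GeneSetFixture:
    """Build a gene universe with target/query sets of exact planted overlap."""
    if planted_overlap > min(n_targets, n_query):
        raise ValueError("planted_overlap exceeds min(n_targets, n_query)")
    if max(n_targets, n_query) > n_universe:
        raise ValueError("set sizes exceed universe size")
    if n_targets + n_query - planted_overlap > n_universe:
        raise ValueError("universe too small for the requested disjoint parts")
    rng = np.random.default_rng(seed)
    universe = [f"gene{idx:05d}" for idx in range(n_universe)]
    perm = rng.permutation(n_universe)
    shared = perm[:planted_overlap]
    t_only = perm[planted_overlap : n_targets]
    q_only = perm[n_targets : n_targets + n_query - planted_overlap]
    targets = sorted(universe[i] for i in np.concatenate([shared, t_only]))
    query = sorted(universe[i] for i in np.concatenate([shared, q_only]))
    return GeneSetFixture(universe, targets, query, planted_overlap)


def phase_preset(name: str, **overrides) -> SimulationConfig:
    """Named configurations for the three stages of global synchrony.

    ``phaseI`` is the pre-synchronization stage (weak inter-spheroid
    coupling), ``phaseII`` the synchronized stage (strong uniform coupling),
    and ``phaseIII`` the post-synchronization stage where coupling is
    block-structured so hierarchically organized super-modules emerge.
    ``wt`` and ``mutant`` expose the genotype contrast (mutant: rho = 0.2).
    """
    base = SimulationConfig(**overrides) if overrides else SimulationConfig()
    if name == "phaseI":
        return base.replace(w_global=0.05)
    if name in ("phaseII", "wt"):
        return base.replace(w_global=0.95)
    if name == "mutant":
        return base.replace(rho=0.2)
    if name == "phaseIII":
        # hierarchically modular stage: full propagation within each of 3
        # super-modules, weak across; a denser event train and tighter
        # recruitment so the hierarchy is expressed within one recording
        n = base.n_spheroids
        groups = np.arange(n) * 3 // n
        W = np.where(groups[:, None] == groups[None, :], 1.0, 0.05)
        over = {}
        if "baseline_rate" not in overrides:
            over["baseline_rate"] = 0.1
        if "p_local" not in overrides:
            over["p_local"] = 0.95
        return base.replace(coupling=tuple(map(tuple, W.tolist())), **over)
    raise ValueError(f"unknown preset {name!r}")


PHASE_PRESETS = ("phaseI", "phaseII", "phaseIII", "wt", "mutant")
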