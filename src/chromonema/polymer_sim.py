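"""Coarse-grained bottle-brush polymer simulator for the coiled chromatid.

Chromatin is a beads-on-a-string homo-polymer (one bead = one nucleosome
plus linker, 200 bp, 10 nm; a 1 kb/bead coarsening is supported for desk
scale).  The chain is organized into consecutive exponential-length major
loops, each subdivided into minor loops.  Five forces act:

1. harmonic bonds between chain neighbours (rest 10 nm, 1 nm wiggle,
   i.e. spring constant kBT / wiggle^2);
2. a harmonic angular force along the chain (1 kBT/rad^2, straight rest);
3. a soft truncated repulsion, U(0) = 1.5 kBT (2.5 in the wide-cylinder
   variants), decaying smoothly to zero at one bead diameter — the finite
   barrier lets chain segments cross, mimicking topoisomerase II;
4. a harmonic tether (4 kBT/nm^2) pinning major-loop base beads to a
   helical path;
5. optional harmonic cylindrical confinement (10 kBT/nm^2) around that
   path, with radius set by an 11^3 nm^3 per-monomer volume budget
   (or overridden, e.g. 650 nm).

Dynamics are Langevin (BAOAB splitting, exact Ornstein-Uhlenbeck noise),
run in blocks; after each block the model contact-probability curve is
computed and the run stops once consecutive curves agree within a
log10 tolerance ("equilibrated contact probability").

Internal units: length nm, energy kBT = 1, bead mass 1.  Temperature
enters only through the kBT scaling of the stated force constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .helix_geometry import HelixParams

__all__ = [
    "LoopArchitecture",
    "SimulationParams",
    "Conformation",
    "sample_loop_architecture",
    "init_conformation",
    "apply_half_helical",
    "cylinder_radius",
    "simulate",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LoopArchitecture:
    """Nested loop layout: major-loop base indices partition the chain;
    minor-loop bases lie strictly inside major loops."""

    n_monomers: int
    bp_per_monomer: int
    major_bases: np.ndarray
    minor_bases: np.ndarray
    major_mean_bp: float
    minor_mean_bp: float
    seed: int

    @property
    def genome_bp(self) -> int:
        return self.n_monomers * self.bp_per_monomer

    def loop_spans(self) -> list[tuple[int, int]]:
        b = self.major_bases
        return [(int(b[k]), int(b[k + 1])) for k in range(len(b) - 1)]

    def to_json_dict(self) -> dict:
        return {
            "n_monomers": int(self.n_monomers),
            "bp_per_monomer": int(self.bp_per_monomer),
            "major_bases": [int(v) for v in self.major_bases],
            "minor_bases": [int(v) for v in self.minor_bases],
            "major_mean_bp": float(self.major_mean_bp),
            "minor_mean_bp": float(self.minor_mean_bp),
            "seed": int(self.seed),
        }


@dataclass
class SimulationParams:
    """Force constants (kBT units), geometry and run control."""

    temperature: float = 300.0          # K; informational, kBT = 1 internally
    collision_rate: float = 0.001       # 1/ps, informational (see friction)
    bond_rest: float = 10.0             # nm
    bond_wiggle: float = 1.0            # nm; spring constant = kBT/wiggle^2
    angle_k: float = 1.0                # kBT/rad^2
    repulsion_trunc: float = 1.5        # kBT barrier at zero separation
    repulsion_cutoff: float = 10.0      # nm (bead diameter)
    tether_k: float = 4.0               # kBT/nm^2
    confinement_k: float = 10.0         # kBT/nm^2
    volume_per_monomer: float = 11.0 ** 3  # nm^3
    cylinder_radius_override: float | None = None  # nm (650 in variants)
    contact_radius: float = 51.0        # nm
    seed: int = 0
    equil_tolerance: float = 0.05       # max |Delta log10 P_C| between blocks
    # integrator (internal reduced units)
    timestep: float = 0.08
    friction: float = 0.1
    steps_per_block: int = 2000

    def __post_init__(self) -> None:
        for name in ("bond_rest", "bond_wiggle", "angle_k", "repulsion_trunc",
                     "repulsion_cutoff", "tether_k", "confinement_k",
                     "volume_per_monomer", "contact_radius", "timestep",
                     "friction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimulationParams.{name} must be positive")

    @property
    def bond_k(self) -> float:
        return 1.0 / self.bond_wiggle ** 2


@dataclass
class Conformation:
    """N beads x 3 spatial coordinates (nm) plus bookkeeping."""

    coords: np.ndarray
    bp_per_monomer: int
    architecture: LoopArchitecture | None = None
    step_count: int = 0
    anchors: np.ndarray | None = None      # tether targets for anchor_idx
    anchor_idx: np.ndarray | None = None   # bead indices of major-loop bases

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be N x 3")
        if self.architecture is not None and len(self.coords) != self.architecture.n_monomers:
            raise ValueError("bead count does not match architecture")

    @property
    def n_monomers(self) -> int:
        return len(self.coords)

    def write_csv(self, path) -> None:
        import pandas as pd
        bp = np.arange(self.n_monomers) * self.bp_per_monomer
        pd.DataFrame({"bead": np.arange(self.n_monomers), "bp": bp,
                      "x": self.coords[:, 0], "y": self.coords[:, 1],
                      "z": self.coords[:, 2]}).to_csv(path, index=False,
                                                      float_format="%.4f")

    def write_xyz(self, path, element: str = "C") -> None:
        with open(path, "wt") as fh:
            fh.write(f"{self.n_monomers}\nconformation (nm), step {self.step_count}\n")
            for x, y, z in self.coords:
                fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")


# ---------------------------------------------------------------------------
# loop architecture sampling
# ---------------------------------------------------------------------------

def _exponential_partition(rng, n_start: int, n_end: int, mean_monomers: float) -> np.ndarray:
    """Interior boundaries splitting [n_start, n_end] into consecutive
    exponential-length segments of >= 1 monomer each."""
    bounds = []
    pos = n_start
    while True:
        step = max(1, int(round(rng.exponential(mean_monomers))))
        pos = pos + step
        if pos >= n_end:
            break
        bounds.append(pos)
    return np.asarray(bounds, dtype=np.int64)


def sample_loop_architecture(genome_bp: int, m: int = 200,
                             major_mean_bp: float = 3_000_000,
                             minor_mean_bp: float = 500_000,
                             seed: int = 0) -> LoopArchitecture:
    """Draw the nested loop layout.

    Consecutive loop lengths follow an exponential distribution around the
    stated means (truncated at one monomer); the final loop is truncated
    at the chain end.  Reproducible for a fixed seed.
    """
    if not (0 < minor_mean_bp < major_mean_bp < genome_bp):
        raise ValueError("require 0 < minor_mean_bp < major_mean_bp < genome_bp")
    n_monomers = int(genome_bp) // int(m)
    if n_monomers < 3:
        raise ValueError("genome too short for the requested monomer size")
    rng = np.random.default_rng(seed)
    interior = _exponential_partition(rng, 0, n_monomers - 1, major_mean_bp / m)
    major_bases = np.concatenate([[0], interior, [n_monomers - 1]]).astype(np.int64)
    minors = []
    for lo, hi in zip(major_bases[:-1], major_bases[1:]):
        minors.append(_exponential_partition(rng, int(lo), int(hi), minor_mean_bp / m))
    minor_bases = (np.concatenate(minors) if minors else np.empty(0, np.int64))
    return LoopArchitecture(n_monomers=n_monomers, bp_per_monomer=int(m),
                            major_bases=major_bases, minor_bases=minor_bases,
                            major_mean_bp=float(major_mean_bp),
                            minor_mean_bp=float(minor_mean_bp), seed=int(seed))


# ---------------------------------------------------------------------------
# initial conformation
# ---------------------------------------------------------------------------

def apply_half_helical(anchor_coords: np.ndarray) -> np.ndarray:
    """Fold a helical anchor set into the half-helical arrangement:
    only |x| is kept from the cylindrical-to-Cartesian conversion; y and z
    are unchanged.  Handedness then reverses every half turn."""
    out = np.array(anchor_coords, dtype=np.float64, copy=True)
    out[:, 0] = np.abs(out[:, 0])
    return out


def cylinder_radius(n_monomers: int, volume_per_monomer: float, height: float) -> float:
    """Confinement radius granting ``volume_per_monomer`` to each bead."""
    return float(np.sqrt(n_monomers * volume_per_monomer / (np.pi * height)))


def _helix_anchor_coords(n_anchors: int, n_turns: float, turn_height: float,
                         radius: float) -> np.ndarray:
    """Anchors equally separated along a constant-radius helical path."""
    t = np.arange(n_anchors) / max(n_anchors - 1, 1) * n_turns
    theta = 2 * np.pi * t
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            turn_height * t])


def init_conformation(arch: LoopArchitecture, path_params: HelixParams,
                      turn_length_bp: float = 30_000_000, n_turns: float = 5,
                      radius_override: float | None = None,
                      variant: str = "helical",
                      radial_bias_nm: float = 50.0,
                      bond_rest: float = 10.0,
                      seed: int = 0) -> Conformation:
    """Starting conformation: major-loop bases on a helical path with
    ``n_turns`` turns, loops emerging radially.

    Bases are equally separated along the path.  Loop interiors are laid
    out as closed random bridges around their bases with an outward radial
    bias, so loop apices sit farther from the cylinder axis than the bases
    while bond lengths start near their rest value.  ``variant`` may be
    ``"helical"`` or ``"half_helical"`` (|x| fold of the base positions).
    """
    span = n_turns * turn_length_bp
    if abs(arch.genome_bp - span) > arch.bp_per_monomer:
        raise ValueError(
            f"architecture spans {arch.genome_bp} bp but n_turns x turn_length = {span:.0f} bp")
    bases = arch.major_bases
    n_anchors = len(bases)
    if radius_override is not None:
        radius = float(radius_override)
    else:
        from .helix_geometry import turn_radius
        per_turn = (n_anchors - 1) / n_turns
        radius = turn_radius(per_turn, path_params)
    anchors = _helix_anchor_coords(n_anchors, n_turns, path_params.turn_height, radius)
    if variant == "half_helical":
        anchors = apply_half_helical(anchors)
    elif variant != "helical":
        raise ValueError("variant must be 'helical' or 'half_helical'")

    rng = np.random.default_rng(seed)
    coords = np.empty((arch.n_monomers, 3))
    coords[bases] = anchors
    for k in range(n_anchors - 1):
        i0, i1 = int(bases[k]), int(bases[k + 1])
        L = i1 - i0
        if L < 2:
            continue
        steps = rng.standard_normal((L, 3))
        steps *= bond_rest / np.linalg.norm(steps, axis=1)[:, None]
        walk = coords[i0] + np.cumsum(steps, axis=0)
        # close the bridge onto the next anchor
        corr = (coords[i1] - walk[-1])
        frac = (np.arange(1, L + 1) / L)[:, None]
        walk += corr * frac
        # outward radial bias peaking mid-loop (loops emerge radially)
        mid = 0.5 * (coords[i0] + coords[i1])
        u = np.array([mid[0], mid[1], 0.0])
        norm = np.linalg.norm(u)
        u = u / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        tent = 1.0 - np.abs(2.0 * np.arange(1, L + 1) / L - 1.0)
        walk += radial_bias_nm * tent[:, None] * u[None, :]
        coords[i0 + 1:i1 + 1] = walk
        coords[i1] = anchors[k + 1]
    return Conformation(coords=coords, bp_per_monomer=arch.bp_per_monomer,
                        architecture=arch, step_count=0, anchors=anchors,
                        anchor_idx=np.asarray(bases, dtype=np.int64))


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _build_pairs(coords, cutoff):
    """Cell-list neighbour search; returns index arrays of unordered pairs
    with centre distance < cutoff."""
    n = coords.shape[0]
    minx = np.empty(3)
    for d in range(3):
        mn = coords[0, d]
        for i in range(1, n):
            if coords[i, d] < mn:
                mn = coords[i, d]
        minx[d] = mn
    inv = 1.0 / cutoff
    cix = np.empty(n, np.int64)
    ciy = np.empty(n, np.int64)
    ciz = np.empty(n, np.int64)
    nx = ny = nz = 1
    for i in range(n):
        cix[i] = int((coords[i, 0] - minx[0]) * inv)
        ciy[i] = int((coords[i, 1] - minx[1]) * inv)
        ciz[i] = int((coords[i, 2] - minx[2]) * inv)
        if cix[i] + 1 > nx:
            nx = cix[i] + 1
        if ciy[i] + 1 > ny:
            ny = ciy[i] + 1
        if ciz[i] + 1 > nz:
            nz = ciz[i] + 1
    cell = (cix * ny + ciy) * nz + ciz
    order = np.argsort(cell, kind="mergesort")
    sorted_cell = cell[order]
    cut2 = cutoff * cutoff
    cap = 16 * n
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    cnt = 0
    for a in range(n):
        p = order[a]
        cx0, cy0, cz0 = cix[p], ciy[p], ciz[p]
        for dx in range(-1, 2):
            cx = cx0 + dx
            if cx < 0 or cx >= nx:
                continue
            for dy in range(-1, 2):
                cy = cy0 + dy
                if cy < 0 or cy >= ny:
                    continue
                for dz in range(-1, 2):
                    cz = cz0 + dz
                    if cz < 0 or cz >= nz:
                        continue
                    cid = (cx * ny + cy) * nz + cz
                    lo = np.searchsorted(sorted_cell, cid, side="left")
                    hi = np.searchsorted(sorted_cell, cid, side="right")
                    for b in range(lo, hi):
                        q = order[b]
                        if q <= p:
                            continue
                        ddx = coords[p, 0] - coords[q, 0]
                        ddy = coords[p, 1] - coords[q, 1]
                        ddz = coords[p, 2] - coords[q, 2]
                        r2 = ddx * ddx + ddy * ddy + ddz * ddz
                        if r2 < cut2:
                            if cnt >= cap:
                                cap *= 2
                                npi = np.empty(cap, np.int64)
                                npj = np.empty(cap, np.int64)
                                npi[:cnt] = pi[:cnt]
                                npj[:cnt] = pj[:cnt]
                                pi = npi
                                pj = npj
                            pi[cnt] = p
                            pj[cnt] = q
                            cnt += 1
    return pi[:cnt], pj[:cnt]


@njit(cache=True)
def _forces(coords, f, bond_i, bond_j, bond_k, bond_r0,
            angle_k, rep_eps, rep_rc, pair_i, pair_j,
            anchor_idx, anchors, tether_k, conf_r, conf_k):
    n = coords.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    # harmonic bonds (chain + loop-closure bridges)
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fac = bond_k * (r - bond_r0) / r
        f[i, 0] += fac * dx
        f[i, 1] += fac * dy
        f[i, 2] += fac * dz
        f[j, 0] -= fac * dx
        f[j, 1] -= fac * dy
        f[j, 2] -= fac * dz
    # angular force along the chain, U = 0.5 k (theta - pi)^2
    for i in range(1, n - 1):
        ax = coords[i - 1, 0] - coords[i, 0]
        ay = coords[i - 1, 1] - coords[i, 1]
        az = coords[i - 1, 2] - coords[i, 2]
        bx = coords[i + 1, 0] - coords[i, 0]
        by = coords[i + 1, 1] - coords[i, 1]
        bz = coords[i + 1, 2] - coords[i, 2]
        ra = np.sqrt(ax * ax + ay * ay + az * az)
        rb = np.sqrt(bx * bx + by * by + bz * bz)
        if ra < 1e-12 or rb < 1e-12:
            continue
        c = (ax * bx + ay * by + az * bz) / (ra * rb)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        # dU/dtheta = k (theta - pi); near theta = pi use the finite limit
        if s < 1e-6:
            coef = -angle_k  # limit of k*(theta-pi)/sin(theta)
        else:
            coef = angle_k * (th - np.pi) / s
        # gradients of cos(theta)
        gax = (bx / (ra * rb)) - c * ax / (ra * ra)
        gay = (by / (ra * rb)) - c * ay / (ra * ra)
        gaz = (bz / (ra * rb)) - c * az / (ra * ra)
        gbx = (ax / (ra * rb)) - c * bx / (rb * rb)
        gby = (ay / (ra * rb)) - c * by / (rb * rb)
        gbz = (az / (ra * rb)) - c * bz / (rb * rb)
        f[i - 1, 0] += coef * gax
        f[i - 1, 1] += coef * gay
        f[i - 1, 2] += coef * gaz
        f[i + 1, 0] += coef * gbx
        f[i + 1, 1] += coef * gby
        f[i + 1, 2] += coef * gbz
        f[i, 0] -= coef * (gax + gbx)
        f[i, 1] -= coef * (gay + gby)
        f[i, 2] -= coef * (gaz + gbz)
    # soft truncated repulsion U = eps (1 - 3x^2 + 2x^3), x = r/rc
    for p in range(pair_i.shape[0]):
        i = pair_i[p]
        j = pair_j[p]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rep_rc * rep_rc or r2 < 1e-16:
            continue
        r = np.sqrt(r2)
        x = r / rep_rc
        fmag = rep_eps * 6.0 * x * (1.0 - x) / rep_rc  # = -dU/dr, repulsive
        fac = fmag / r
        f[i, 0] -= fac * dx
        f[i, 1] -= fac * dy
        f[i, 2] -= fac * dz
        f[j, 0] += fac * dx
        f[j, 1] += fac * dy
        f[j, 2] += fac * dz
    # tether of major-loop bases to the helical path
    for a in range(anchor_idx.shape[0]):
        i = anchor_idx[a]
        f[i, 0] += tether_k * (anchors[a, 0] - coords[i, 0])
        f[i, 1] += tether_k * (anchors[a, 1] - coords[i, 1])
        f[i, 2] += tether_k * (anchors[a, 2] - coords[i, 2])
    # cylindrical confinement (radial, around the z axis)
    if conf_r > 0.0:
        for i in range(n):
            rho = np.sqrt(coords[i, 0] ** 2 + coords[i, 1] ** 2)
            if rho > conf_r and rho > 1e-12:
                fac = conf_k * (conf_r - rho) / rho
                f[i, 0] += fac * coords[i, 0]
                f[i, 1] += fac * coords[i, 1]


@njit(cache=True)
def _run_block(coords, vel, bond_i, bond_j, bond_k, bond_r0, angle_k,
               rep_eps, rep_rc, anchor_idx, anchors, tether_k,
               conf_r, conf_k, dt, gamma, nsteps, rebuild_every,
               pair_cutoff, block_seed):
    np.random.seed(block_seed)
    n = coords.shape[0]
    f = np.zeros((n, 3))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)  # kBT = mass = 1
    pair_i, pair_j = _build_pairs(coords, pair_cutoff)
    _forces(coords, f, bond_i, bond_j, bond_k, bond_r0, angle_k,
            rep_eps, rep_rc, pair_i, pair_j, anchor_idx, anchors,
            tether_k, conf_r, conf_k)
    for step in range(nsteps):
        if step > 0 and step % rebuild_every == 0:
            pair_i, pair_j = _build_pairs(coords, pair_cutoff)
        # BAOAB
        vel += 0.5 * dt * f
        coords += 0.5 * dt * vel
        noise = np.random.standard_normal((n, 3))
        for i in range(n):
            vel[i, 0] = c1 * vel[i, 0] + c2 * noise[i, 0]
            vel[i, 1] = c1 * vel[i, 1] + c2 * noise[i, 1]
            vel[i, 2] = c1 * vel[i, 2] + c2 * noise[i, 2]
        coords += 0.5 * dt * vel
        _forces(coords, f, bond_i, bond_j, bond_k, bond_r0, angle_k,
                rep_eps, rep_rc, pair_i, pair_j, anchor_idx, anchors,
                tether_k, conf_r, conf_k)
        vel += 0.5 * dt * f


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def _loop_closure_bonds(arch: LoopArchitecture) -> tuple[np.ndarray, np.ndarray]:
    """Bridging bonds between consecutive loop anchors: within each major
    loop the chain of [major base, minor bases..., next major base] is
    linked pairwise, realizing side-by-side minor loops."""
    bi, bj = [], []
    minors = np.sort(arch.minor_bases)
    for lo, hi in arch.loop_spans():
        inside = minors[(minors > lo) & (minors < hi)]
        seq = [lo, *inside.tolist(), hi]
        for a, b in zip(seq[:-1], seq[1:]):
            if b - a > 1:  # chain bond already covers adjacent beads
                bi.append(a)
                bj.append(b)
    return np.asarray(bi, np.int64), np.asarray(bj, np.int64)


def simulate(conf: Conformation, arch: LoopArchitecture | None = None,
             params: SimulationParams | None = None,
             max_blocks: int = 30, tether: str = "helical",
             bins=None, confinement_radius: float | None = None,
             verbose: bool = False):
    """Langevin dynamics in blocks until the contact probability stops
    changing (or ``max_blocks`` is reached).

    ``tether`` selects the helical or half-helical (|x|-folded) anchor
    arrangement.  Only major-loop base beads feel the tether.  With
    ``confinement_radius`` set (or derivable from the volume budget via
    :func:`cylinder_radius`) a radial harmonic wall is active.
    Returns ``(conformation, summary)``; the summary records blocks run,
    convergence, and the per-block contact curves.

    ``max_blocks = 0`` returns the initial conformation unchanged.
    """
    if arch is None:
        arch = conf.architecture
    if arch is None:
        raise ValueError("no architecture supplied")
    if params is None:
        params = SimulationParams()
    if conf.n_monomers != arch.n_monomers:
        raise ValueError("conformation does not match architecture")
    if tether not in ("helical", "half_helical"):
        raise ValueError("tether must be 'helical' or 'half_helical'")

    if max_blocks == 0:
        return conf, {"blocks": 0, "converged": False, "curves": []}

    from .model_contacts import conformation_contacts, model_contact_probability

    anchors = conf.anchors
    if anchors is None:
        raise ValueError("conformation carries no tether anchors")
    if tether == "half_helical":
        anchors = apply_half_helical(anchors)
    anchor_idx = conf.anchor_idx.astype(np.int64)

    chain_i = np.arange(arch.n_monomers - 1, dtype=np.int64)
    chain_j = chain_i + 1
    loop_i, loop_j = _loop_closure_bonds(arch)
    bond_i = np.concatenate([chain_i, loop_i])
    bond_j = np.concatenate([chain_j, loop_j])

    conf_r = -1.0 if confinement_radius is None else float(confinement_radius)

    coords = np.array(conf.coords, copy=True)
    rng = np.random.default_rng(params.seed)
    vel = rng.standard_normal(coords.shape)  # Maxwell-Boltzmann at kBT = m = 1
    pair_cutoff = params.repulsion_cutoff + 4.0  # Verlet skin

    curves = []
    prev_logp = None
    converged = False
    blocks_run = 0
    for block in range(max_blocks):
        block_seed = int((params.seed * 100003 + block * 7919 + 1) % (2 ** 31 - 1))
        _run_block(coords, vel, bond_i, bond_j, params.bond_k, params.bond_rest,
                   params.angle_k, params.repulsion_trunc, params.repulsion_cutoff,
                   anchor_idx, anchors, params.tether_k, conf_r,
                   params.confinement_k, params.timestep, params.friction,
                   params.steps_per_block, 20, pair_cutoff, block_seed)
        blocks_run += 1
        if not np.isfinite(coords).all():
            raise FloatingPointError("integration unstable, reduce step")
        snap = Conformation(coords=coords.copy(), bp_per_monomer=conf.bp_per_monomer,
                            architecture=arch)
        pairs = conformation_contacts(snap, params.contact_radius)
        curve = model_contact_probability([pairs], conf.bp_per_monomer,
                                          n_monomers=arch.n_monomers, bins=bins)
        curves.append(curve)
        with np.errstate(divide="ignore"):
            logp = np.where(curve.p > 0, np.log10(np.where(curve.p > 0, curve.p, 1.0)),
                            np.nan)
        # sparse bins fluctuate by counting noise alone; convergence is
        # judged on bins with meaningful statistics in the current block
        logp[curve.n_obs < 50] = np.nan
        if prev_logp is not None:
            both = np.isfinite(logp) & np.isfinite(prev_logp)
            if both.any():
                delta = float(np.max(np.abs(logp[both] - prev_logp[both])))
                if verbose:
                    print(f"block {block}: max |dlog10 P| = {delta:.4f}")
                if delta < params.equil_tolerance:
                    converged = True
                    break
        prev_logp = logp

    out = Conformation(coords=coords, bp_per_monomer=conf.bp_per_monomer,
                       architecture=arch,
                       step_count=conf.step_count + blocks_run * params.steps_per_block,
                       anchors=anchors, anchor_idx=conf.anchor_idx)
    summary = {"blocks": blocks_run, "converged": converged, "curves": curves}
    return out, summary


def run_small_comparison_model(seed: int, tether: str = "helical",
                               genome_bp: int = 10_000_000,
                               bp_per_monomer: int = 1000,
                               turn_length_bp: float = 2_000_000,
                               turn_height: float = 100.0,
                               major_mean_bp: float = 100_000,
                               minor_mean_bp: float = 10_000,
                               path_radius: float = 100.0,
                               max_blocks: int = 8) -> tuple[Conformation, dict]:
    """The small helical-versus-half-helical comparison model.

    A 10 Mb region with 2 Mb turn length, 100 nm turn height, 100 kb major
    and 10 kb minor loops on a 100 nm-radius helical path, without
    cylindrical confinement, coarsened to 1 kb per bead for desk scale.
    Loop architecture is resampled per seed.
    """
    arch = sample_loop_architecture(genome_bp, bp_per_monomer,
                                    major_mean_bp, minor_mean_bp, seed=seed)
    hp = HelixParams(m=bp_per_monomer, l0=max(major_mean_bp / bp_per_monomer, 1.0),
                     turn_height=turn_height)
    n_turns = genome_bp / turn_length_bp
    conf = init_conformation(arch, hp, turn_length_bp, n_turns,
                             radius_override=path_radius, variant=tether, seed=seed)
    params = SimulationParams(seed=seed, steps_per_block=1500)
    return simulate(conf, arch, params, max_blocks=max_blocks, tether=tether)
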