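"""Synthetic Hi-C-like contact pairs and conformations with known helical
structure.

Every pipeline stage can be exercised without external data: metaphase-like
contact pairs whose separation distribution is an exponential decay plus a
Gaussian bump at the helical turn length, interphase-like power-law pairs
without a bump, and 3D bead conformations on an ideal helical path with
optional positional blur (mimicking stochastic loop placement inside the
chromonema).  All generators are deterministic for a fixed seed.

Defaults follow the metaphase signal shape used throughout the package:
bump weight 0.3, bump sigma 5 Mb, exponential scale 5 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic_contacts import ContactPairs
from .helix_geometry import HelixParams, build_helical_path
from .polymer_sim import Conformation

__all__ = [
    "HelicalSignalSpec",
    "generate_helical_pairs",
    "generate_interphase_pairs",
    "generate_ideal_helix_conformation",
]

MB = 1_000_000


@dataclass
class HelicalSignalSpec:
    """Parameters of the metaphase-like contact-distance mixture.

    ``turn_length`` may be a constant (bp) or a callable mapping a genomic
    position to the local turn length (a gradient track).
    """

    chrom_length: int
    turn_length: float | object = 30 * MB
    exp_scale: float = 5 * MB
    bump_sigma: float = 5 * MB
    bump_weight: float = 0.3
    n_pairs: int = 100_000
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if not (0.0 <= self.bump_weight <= 1.0):
            raise ValueError("bump_weight must lie in [0, 1]")
        if self.chrom_length <= 0 or self.n_pairs < 0:
            raise ValueError("invalid chrom_length or n_pairs")
        if not callable(self.turn_length):
            t = float(self.turn_length)
            if not (0 < t < self.chrom_length):
                raise ValueError("turn_length must lie in (0, chrom_length)")

    def local_turn(self, pos: np.ndarray) -> np.ndarray:
        if callable(self.turn_length):
            return np.asarray([float(self.turn_length(x)) for x in pos])
        return np.full(len(pos), float(self.turn_length))


def generate_helical_pairs(spec: HelicalSignalSpec) -> ContactPairs:
    """Draw contact pairs with a helical-arrangement distance signature.

    For each pair the left endpoint is uniform on the chromosome and the
    separation is drawn from the mixture
    ``(1 - w) * Exp(exp_scale) + w * Normal(turn_length(left), bump_sigma)``.
    Pairs whose right endpoint falls off the chromosome (or with
    non-positive separation) are redrawn entirely, so the bump is not
    distorted by clipping; edge regions simply receive fewer bump pairs.
    """
    rng = np.random.default_rng(spec.seed)
    L = int(spec.chrom_length)
    n = int(spec.n_pairs)
    a_out = np.empty(n, dtype=np.int64)
    b_out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        todo = n - filled
        draw = max(int(todo * 1.3) + 16, 64)
        a = rng.integers(0, L, size=draw)
        is_bump = rng.random(draw) < spec.bump_weight
        s = rng.exponential(spec.exp_scale, size=draw)
        if is_bump.any():
            centres = spec.local_turn(a[is_bump])
            s[is_bump] = rng.normal(centres, spec.bump_sigma)
        s = np.rint(s).astype(np.int64)
        b = a + s
        keep = (s >= 1) & (b < L)
        a, b = a[keep], b[keep]
        take = min(len(a), todo)
        a_out[filled:filled + take] = a[:take]
        b_out[filled:filled + take] = b[:take]
        filled += take
    df = pd.DataFrame({"chrom1": spec.chrom, "pos1": a_out,
                       "chrom2": spec.chrom, "pos2": b_out})
    return ContactPairs(df=df, chrom_sizes={spec.chrom: L})


def generate_interphase_pairs(chrom_length: int, exponent: float = -1.0,
                              n_pairs: int = 100_000, seed: int = 0,
                              s_min: int = 100_000,
                              chrom: str = "chrS") -> ContactPairs:
    """Power-law separations (no helical bump), emulating interphase decay.

    Separations follow ``s^exponent`` truncated to [s_min, chrom_length);
    the left endpoint is uniform on the admissible range for each s.
    """
    if exponent >= 0:
        raise ValueError("exponent must be negative")
    rng = np.random.default_rng(seed)
    L = int(chrom_length)
    lo, hi = float(s_min), float(L)
    u = rng.random(n_pairs)
    g = exponent + 1.0
    if abs(g) < 1e-12:
        s = lo * (hi / lo) ** u
    else:
        s = (lo ** g + u * (hi ** g - lo ** g)) ** (1.0 / g)
    s = np.minimum(np.rint(s).astype(np.int64), L - 1)
    a = (rng.random(n_pairs) * (L - s)).astype(np.int64)
    df = pd.DataFrame({"chrom1": chrom, "pos1": a, "chrom2": chrom, "pos2": a + s})
    return ContactPairs(df=df, chrom_sizes={chrom: L})


def generate_ideal_helix_conformation(turn_length_bp: float, n_turns: float,
                                      params: HelixParams | None = None,
                                      loop_blur_nm: float = 0.0,
                                      seed: int = 0) -> Conformation:
    """Beads on the analytic helical path plus isotropic Gaussian blur.

    One bead per path monomer (``m * l0`` bp of chromatin).  The blur
    emulates the stochastic positioning of chromatin loops inside the
    chromonema; at zero blur the geometry is exact.
    """
    if params is None:
        params = HelixParams()
    path = build_helical_path(float(turn_length_bp),
                              span_bp=n_turns * turn_length_bp, params=params)
    coords = path.cartesian
    if loop_blur_nm > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, loop_blur_nm, size=coords.shape)
    return Conformation(coords=coords, bp_per_monomer=int(params.bp_per_monomer))
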