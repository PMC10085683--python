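"""Variable-radius helical path of the chromonema, turn counting and
physical predictions.

The coiled chromatid is described as a helical path of constant turn
height whose radius varies with the local genomic turn length.  For a
path monomer i carrying a local turn length ``l_i`` (bp), with monomer
size ``m`` (bp) and mean major-loop size ``l0`` (monomers):

    n_i = l_i / m / l0                      (monomers per turn)
    z_i = z_{i-1} + H / n_i                 (axial rise, H = turn height)
    theta_i = theta_{i-1} + 360 / n_i       (cumulative angle, degrees)
    (d * n_i)^2 = (2 pi r_i)^2 + H^2        (radius from the Pythagorean
                                             identity; d = spacing of
                                             consecutive path monomers)

Angles are stored cumulatively (unwrapped), which makes turn counting
exact: the number of turns is the number of cycles of cos(theta), i.e.
total theta / 360.  The canonical turn-counting parameterization uses
m = 1 Mb and l0 = 1.

Also included: extrapolation of physical chromosome length from turn
counts, chromatin volume density, and a geometric classifier for sister
chromatid exchange (SCE) segments against the chromonema constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HelixParams",
    "HelicalPath",
    "SCESegment",
    "monomers_per_turn",
    "turn_radius",
    "build_helical_path",
    "count_turns",
    "extrapolate_physical_length",
    "chromatin_density",
    "classify_sce_segment",
]

MB = 1_000_000


@dataclass(frozen=True)
class HelixParams:
    """Geometry parameters of the helical path.

    m : monomer size in bp (200 bp = one nucleosome plus linker;
        1 Mb for turn counting).
    l0 : mean major-loop size in monomers (so one path monomer represents
        ``m * l0`` bp of chromatin; 1 for turn counting).
    turn_height : axial rise per full turn, nm.
    d_sep : spatial separation of consecutive path monomers, nm
        (default 50; 20 and 100 nm are studied variants).
    handedness : +1 right-handed (default), -1 left-handed.
    """

    m: float = 200.0
    l0: float = 15000.0
    turn_height: float = 400.0
    d_sep: float = 50.0
    handedness: int = 1

    def __post_init__(self) -> None:
        if self.m <= 0 or self.l0 <= 0 or self.turn_height <= 0 or self.d_sep <= 0:
            raise ValueError("HelixParams values must be strictly positive")
        if self.handedness not in (-1, 1):
            raise ValueError("handedness must be +1 or -1")

    @property
    def bp_per_monomer(self) -> float:
        return self.m * self.l0


@dataclass
class HelicalPath:
    """Ordered path monomers with cylindrical and Cartesian coordinates."""

    params: HelixParams
    turn_length_track: np.ndarray  # l_i, bp per monomer
    n_per_turn: np.ndarray         # n_i
    theta_deg: np.ndarray          # cumulative, degrees
    z_nm: np.ndarray
    r_nm: np.ndarray

    @property
    def n_monomers(self) -> int:
        return len(self.theta_deg)

    @property
    def total_theta_deg(self) -> float:
        """Angle swept over the whole path, including the last monomer's
        own increment (each monomer covers one inter-monomer interval)."""
        return float(self.theta_deg[-1] + 360.0 / self.n_per_turn[-1])

    @property
    def z_extent_nm(self) -> float:
        """Axial extent covered by the path, including the last monomer's rise."""
        return float(self.z_nm[-1] + self.params.turn_height / self.n_per_turn[-1])

    @property
    def cartesian(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg) * self.params.handedness
        return np.column_stack([self.r_nm * np.cos(th),
                                self.r_nm * np.sin(th),
                                self.z_nm])

    def to_frame(self) -> pd.DataFrame:
        xyz = self.cartesian
        bp = np.arange(self.n_monomers) * self.params.bp_per_monomer
        return pd.DataFrame({
            "index": np.arange(self.n_monomers), "bp": bp,
            "n_i": self.n_per_turn, "theta_deg": self.theta_deg,
            "r_nm": self.r_nm, "z_nm": self.z_nm,
            "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    def write_xyz(self, path, element: str = "C") -> None:
        xyz = self.cartesian
        with open(path, "wt") as fh:
            fh.write(f"{len(xyz)}\nhelical path (nm)\n")
            for x, y, z in xyz:
                fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")


@dataclass(frozen=True)
class SCESegment:
    """Measured sister-chromatid-exchange segment (nm)."""

    height: float
    width: float
    chromatid_width: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0 or self.chromatid_width <= 0:
            raise ValueError("SCESegment dimensions must be positive")
        if self.width > self.chromatid_width * (1 + 1e-9):
            raise ValueError("segment width cannot exceed chromatid width")


# ---------------------------------------------------------------------------

def monomers_per_turn(l_i: float, params: HelixParams) -> float:
    """Path monomers per helical turn: ``l_i / m / l0`` (real-valued)."""
    if l_i <= 0:
        raise ValueError("turn length l_i must be positive")
    return l_i / params.m / params.l0


def turn_radius(n_i: float, params: HelixParams) -> float:
    """Helix radius for ``n_i`` monomers per turn (Pythagorean identity)."""
    circumference_sq = (params.d_sep * n_i) ** 2 - params.turn_height ** 2
    if circumference_sq < 0:
        raise ValueError(
            f"turn too short for pitch: d_sep*n = {params.d_sep * n_i:.3g} nm "
            f"< turn height {params.turn_height:.3g} nm (no real radius)")
    return float(np.sqrt(circumference_sq) / (2 * np.pi))


def _track_from_profile(profile, span_bp: float, params: HelixParams) -> np.ndarray:
    """Per-monomer turn length by piecewise-constant lookup of the region
    containing each monomer's genomic midpoint."""
    bp_per = params.bp_per_monomer
    n = int(round(span_bp / bp_per))
    if n < 1:
        raise ValueError("span shorter than one path monomer")
    mids = (np.arange(n) + 0.5) * bp_per
    if np.isscalar(profile) or isinstance(profile, (int, float)):
        return np.full(n, float(profile))
    if callable(profile):
        return np.asarray([float(profile(x)) for x in mids])
    # TurnLengthProfile-like: entries with chrom/start/end/turn_length
    entries = profile.entries if hasattr(profile, "entries") else profile
    track = np.empty(n)
    for k, x in enumerate(mids):
        hit = None
        for e in entries:
            if e["start"] <= x < e["end"] and np.isfinite(e["turn_length"]):
                hit = e["turn_length"]
                break
        if hit is None:
            raise ValueError(f"profile does not cover genomic position {x:.0f} bp")
        track[k] = hit
    return track


def build_helical_path(profile, span_bp: float | None = None,
                       params: HelixParams = HelixParams()) -> HelicalPath:
    """Build the variable-radius helical path from a turn-length profile.

    ``profile`` may be a constant (bp), a callable bp -> bp, or a
    TurnLengthProfile; ``span_bp`` is required unless the profile itself
    bounds the span.  z and theta start at 0 and accumulate per monomer;
    the first monomer sits at (theta=0, z=0).
    """
    if span_bp is None:
        if hasattr(profile, "entries"):
            span_bp = max(e["end"] for e in profile.entries)
        else:
            raise ValueError("span_bp required for constant or callable profiles")
    track = _track_from_profile(profile, span_bp, params)
    n_per = track / params.m / params.l0
    if np.any(track <= 0):
        raise ValueError("turn length track contains non-positive values")
    r = np.empty_like(n_per)
    for i, n_i in enumerate(n_per):
        try:
            r[i] = turn_radius(n_i, params)
        except ValueError as exc:
            raise ValueError(f"monomer {i} (l={track[i]:.3g} bp): {exc}") from exc
    dtheta = 360.0 / n_per
    dz = params.turn_height / n_per
    theta = np.concatenate([[0.0], np.cumsum(dtheta[1:])])
    z = np.concatenate([[0.0], np.cumsum(dz[1:])])
    return HelicalPath(params=params, turn_length_track=track, n_per_turn=n_per,
                       theta_deg=theta, z_nm=z, r_nm=r)


def count_turns(path: HelicalPath) -> float:
    """Number of helical turns = cycles of cos(theta) = total theta / 360.

    Because theta is stored cumulatively the count is exact; it equals the
    number of positive-going zero crossings of cos(theta) plus the
    fractional remainder.  Includes the increment that would carry the
    path to its next monomer (so a constant profile of length L with turn
    length l yields exactly L / l).
    """
    if path.n_monomers == 0:
        raise ValueError("empty path")
    return path.total_theta_deg / 360.0


def extrapolate_physical_length(turns: float,
                                per_turn_height_range: tuple[float, float]) -> tuple[float, float]:
    """Physical chromosome length range (um) = turns x per-turn height (nm)."""
    lo, hi = per_turn_height_range
    if turns <= 0:
        raise ValueError("turns must be positive")
    if lo > hi:
        raise ValueError("inverted height range")
    return (turns * lo / 1000.0, turns * hi / 1000.0)


def chromatin_density(volume_um3: float, dna_mb: float) -> float:
    """Chromatin packing density, um^3 of volume per Mb of DNA."""
    if volume_um3 <= 0 or dna_mb <= 0:
        raise ValueError("volume and DNA content must be positive")
    return volume_um3 / dna_mb


# ---------------------------------------------------------------------------
# SCE segment classification
# ---------------------------------------------------------------------------

SCE_SUBTURN = "subturn_consistent"
SCE_MULTITURN = "multiturn_consistent"
SCE_TALL_NARROW = "violation_tall_narrow"
SCE_TOO_SHORT = "violation_too_short"


def classify_sce_segment(seg: SCESegment, chromonema_thickness: float = 400.0,
                         thickness_band: tuple[float, float] = (300.0, 550.0),
                         width_tolerance: float = 0.10) -> str:
    """Classify an SCE segment against the helical chromonema constraints.

    A helically coiled ~400 nm chromonema allows only two kinds of
    exchanged segments: sub-turn exchanges (height about one chromonema
    thickness, incomplete chromatid width) and multi-turn exchanges
    (height >= thickness, full chromatid width).  Segments taller than
    the thickness band yet narrower than the chromatid, or shorter than
    the 300 nm floor, are geometric violations of the model.
    """
    floor, ceil = thickness_band
    full_width = seg.width >= (1.0 - width_tolerance) * seg.chromatid_width
    if seg.height < floor:
        return SCE_TOO_SHORT
    if full_width:
        return SCE_MULTITURN
    if seg.height <= ceil:
        return SCE_SUBTURN
    return SCE_TALL_NARROW
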