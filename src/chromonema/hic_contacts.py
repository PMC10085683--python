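"""Contact pairs and contact-probability P(s) curves.

Genome-wide Hi-C analytics for metaphase/interphase comparison: parsing of
4DN-style ``.pairs`` files, log-binned contact probability versus genomic
separation, log-log derivatives and metaphase/interphase ratio tracks.

Conventions
-----------
* Positions are 0-based and must satisfy ``0 <= pos < chrom_length``.
  (The official 4DN dialect is 1-based; files written by this package use
  the 0-based convention throughout, which keeps genomic separations exact.)
* Distance bins are half-open ``[edge_i, edge_{i+1})`` on a logarithmic
  grid, by default 100 kb .. 1 Gb at 10 bins per decade.
* Undefined bins (no possible locus pairs, or zero denominator) carry NaN,
  never 0.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ContactPairs",
    "DistanceBins",
    "ContactCurve",
    "DerivativeTrack",
    "read_pairs",
    "write_pairs",
    "contact_probability",
    "normalize",
    "log_derivative",
    "ratio_curve",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ContactPairs:
    """A set of genomic contact records plus chromosome sizes.

    ``df`` holds columns ``chrom1, pos1, chrom2, pos2`` (positions in bp,
    0-based) and a boolean ``intra`` flag.
    """

    df: pd.DataFrame
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        required = {"chrom1", "pos1", "chrom2", "pos2"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"ContactPairs frame missing columns {sorted(missing)}")
        if "intra" not in self.df.columns:
            self.df = self.df.assign(intra=self.df["chrom1"].values == self.df["chrom2"].values)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_intra(self) -> int:
        return int(self.df["intra"].sum())

    def intra_separations(self, chrom: str | None = None) -> np.ndarray:
        """|pos2 - pos1| for intra-chromosomal pairs (optionally one chromosome)."""
        sel = self.df[self.df["intra"]]
        if chrom is not None:
            sel = sel[sel["chrom1"] == chrom]
        return np.abs(sel["pos2"].to_numpy(np.int64) - sel["pos1"].to_numpy(np.int64))


@dataclass(frozen=True)
class DistanceBins:
    """Log-spaced genomic-distance bins, half-open ``[edge_i, edge_{i+1})``."""

    edges: np.ndarray
    lo: int = 100_000
    hi: int = 1_000_000_000
    bins_per_decade: int = 10

    @classmethod
    def log_spaced(cls, lo: int = 100_000, hi: int = 1_000_000_000,
                   bins_per_decade: int = 10) -> "DistanceBins":
        if not (0 < lo < hi):
            raise ValueError("require 0 < lo < hi")
        n = int(round(bins_per_decade * np.log10(hi / lo)))
        if n < 1:
            raise ValueError("range too narrow for the requested bins_per_decade")
        edges = np.geomspace(float(lo), float(hi), n + 1)
        edges[0], edges[-1] = float(lo), float(hi)
        return cls(edges=edges, lo=lo, hi=hi, bins_per_decade=bins_per_decade)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing, length >= 2")
        ratios = e[1:] / e[:-1]
        if np.max(np.abs(ratios / ratios[0] - 1.0)) > 1e-9:
            raise ValueError("edges are not log-spaced (constant ratio violated)")
        object.__setattr__(self, "edges", e)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def mids(self) -> np.ndarray:
        """Geometric bin midpoints (bp)."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def index_of(self, s: float) -> int:
        """Bin index containing separation ``s`` (half-open convention)."""
        if not (self.edges[0] <= s < self.edges[-1]):
            raise ValueError(f"separation {s} outside [{self.edges[0]}, {self.edges[-1]})")
        return int(np.searchsorted(self.edges, s, side="right") - 1)

    def same_as(self, other: "DistanceBins") -> bool:
        return self.n_bins == other.n_bins and np.allclose(self.edges, other.edges, rtol=1e-12)


@dataclass
class ContactCurve:
    """Contact probability per distance bin; NaN marks undefined bins."""

    bins: DistanceBins
    p: np.ndarray
    n_obs: np.ndarray
    n_possible: np.ndarray
    normalized_at: int | None = None

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "s_mid": self.bins.mids,
            "p": self.p,
            "n_obs": self.n_obs,
            "n_possible": self.n_possible,
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class DerivativeTrack:
    """d log10(p) / d log10(s) at bin midpoints."""

    s_mid: np.ndarray
    slope: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s_mid": self.s_mid, "dlog10p_dlog10s": self.slope})


# ---------------------------------------------------------------------------
# .pairs I/O
# ---------------------------------------------------------------------------

_PAIRS_COLUMNS = ("readID", "chr1", "pos1", "chr2", "pos2", "strand1", "strand2")


def _open_text(path):
    p = str(path)
    if p.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(p, "rb"))
    return open(p, "rt")


def read_pairs(path, chrom_sizes: dict[str, int] | None = None) -> ContactPairs:
    """Parse a 4DN-style ``.pairs`` file (plain or gzip).

    Columns: ``readID chr1 pos1 chr2 pos2 strand1 strand2``; lines starting
    with ``#`` are header/comment.  Chromosome sizes come from ``#chromsize:``
    header lines or the ``chrom_sizes`` argument (argument wins).  Positions
    are interpreted 0-based and validated against chromosome lengths.
    """
    header_sizes: dict[str, int] = {}
    chrom1, pos1, chrom2, pos2 = [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].strip().split()
                if toks and toks[0].rstrip(":") == "chromsize" and len(toks) >= 3:
                    header_sizes[toks[1]] = int(toks[2])
                continue
            toks = line.split("\t")
            if len(toks) == 1:
                toks = line.split()
            if len(toks) < 5:
                raise ValueError(f"{path}: malformed pairs line {lineno}: {line!r}")
            try:
                p1, p2 = int(toks[2]), int(toks[4])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed pairs line {lineno}: {line!r}") from exc
            chrom1.append(toks[1]); pos1.append(p1)
            chrom2.append(toks[3]); pos2.append(p2)

    sizes = dict(header_sizes)
    if chrom_sizes:
        sizes.update(chrom_sizes)
    if not sizes:
        raise ValueError("no chromosome sizes: provide chrom_sizes or #chromsize headers")

    df = pd.DataFrame({
        "chrom1": chrom1, "pos1": np.asarray(pos1, np.int64),
        "chrom2": chrom2, "pos2": np.asarray(pos2, np.int64),
    })
    for side in ("1", "2"):
        chroms = df[f"chrom{side}"]
        unknown = ~chroms.isin(sizes.keys())
        if unknown.any():
            i = int(np.flatnonzero(unknown.values)[0])
            raise ValueError(f"record {i}: unknown chromosome {chroms.iloc[i]!r}")
        lengths = chroms.map(sizes).to_numpy(np.int64)
        pos = df[f"pos{side}"].to_numpy(np.int64)
        bad = (pos < 0) | (pos >= lengths)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"record {i}: position {pos[i]} out of range for chromosome "
                f"{chroms.iloc[i]!r} (length {lengths[i]})")
    return ContactPairs(df=df, chrom_sizes=sizes)


def write_pairs(pairs: ContactPairs, path) -> None:
    """Write a minimal ``.pairs`` file with ``#chromsize:`` headers."""
    with open(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        fh.write("#columns: " + " ".join(_PAIRS_COLUMNS) + "\n")
        for chrom, size in pairs.chrom_sizes.items():
            fh.write(f"#chromsize: {chrom} {size}\n")
        df = pairs.df
        c1 = df["chrom1"].to_numpy(); c2 = df["chrom2"].to_numpy()
        p1 = df["pos1"].to_numpy(); p2 = df["pos2"].to_numpy()
        for i in range(len(df)):
            fh.write(f"r{i}\t{c1[i]}\t{p1[i]}\t{c2[i]}\t{p2[i]}\t+\t-\n")


# ---------------------------------------------------------------------------
# contact probability
# ---------------------------------------------------------------------------

def _possible_pairs_per_bin(chrom_sizes: dict[str, int], bins: DistanceBins,
                            bin_size: int) -> np.ndarray:
    """Locus pairs per distance bin, loci = non-overlapping bin_size tiles.

    For a chromosome with ``n`` complete tiles there are ``n - k`` locus
    pairs at separation ``k * bin_size``; counts are summed over
    chromosomes (pooled denominator).
    """
    total = np.zeros(bins.n_bins, dtype=np.int64)
    for length in chrom_sizes.values():
        n = int(length) // int(bin_size)
        if n < 2:
            continue
        k = np.arange(1, n, dtype=np.int64)
        seps = k * int(bin_size)
        counts = (n - k).astype(np.int64)
        hist, _ = np.histogram(seps, bins=bins.edges, weights=counts)
        total += hist.astype(np.int64)
    return total


def contact_probability(pairs: ContactPairs, bins: DistanceBins | None = None,
                        bin_size: int = 100_000) -> ContactCurve:
    """Observed/possible contact probability versus genomic separation.

    The numerator counts intra-chromosomal pairs whose separation falls in
    each log-spaced distance bin; the denominator counts ordered locus
    pairs (non-overlapping ``bin_size`` tiles, pooled over chromosomes)
    within the same distance range.  Bins with zero possible pairs are NaN.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if bins is None:
        bins = DistanceBins.log_spaced()
    seps = pairs.intra_separations()
    if seps.size == 0:
        raise ValueError("no usable contacts: input has no intra-chromosomal pairs")
    n_obs, _ = np.histogram(seps, bins=bins.edges)
    n_possible = _possible_pairs_per_bin(pairs.chrom_sizes, bins, bin_size)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_possible > 0, n_obs / np.maximum(n_possible, 1), np.nan)
    return ContactCurve(bins=bins, p=p.astype(float), n_obs=n_obs.astype(np.int64),
                        n_possible=n_possible)


def normalize(curve: ContactCurve, at: int = 100_000) -> ContactCurve:
    """Scale the curve so the bin containing ``at`` equals exactly 1.

    Idempotent: normalizing an already-normalized curve is a no-op.
    """
    idx = curve.bins.index_of(at)
    ref = curve.p[idx]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(f"cannot normalize: bin containing {at} bp is undefined or zero")
    return replace(curve, p=curve.p / ref, normalized_at=int(at))


def log_derivative(curve: ContactCurve) -> DerivativeTrack:
    """Central-difference d log10(p)/d log10(s) at bin midpoints.

    Interior bins use central differences over their immediate neighbours;
    the first and last defined positions use one-sided differences.
    Undefined (NaN or non-positive) bins propagate NaN.
    """
    p = curve.p
    ok = np.isfinite(p) & (p > 0)
    if ok.sum() < 3:
        raise ValueError("log_derivative needs >= 3 bins with defined positive p")
    x = np.log10(curve.bins.mids)
    y = np.where(ok, np.log10(np.where(ok, p, 1.0)), np.nan)
    n = len(p)
    slope = np.full(n, np.nan)
    for i in range(n):
        if not ok[i]:
            continue
        left = i - 1 if i > 0 and ok[i - 1] else i
        right = i + 1 if i < n - 1 and ok[i + 1] else i
        if left == right:
            continue
        slope[i] = (y[right] - y[left]) / (x[right] - x[left])
    return DerivativeTrack(s_mid=curve.bins.mids, slope=slope)


def ratio_curve(meta: ContactCurve, inter: ContactCurve) -> ContactCurve:
    """Elementwise metaphase/interphase ratio (P_CM / P_CI).

    Bins where the interphase curve is undefined or zero become NaN; no
    division error is raised.
    """
    if not meta.bins.same_as(inter.bins):
        raise ValueError("ratio_curve: bin grids differ")
    denom_ok = np.isfinite(inter.p) & (inter.p > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(denom_ok, meta.p / np.where(denom_ok, inter.p, 1.0), np.nan)
    return ContactCurve(bins=meta.bins, p=ratio,
                        n_obs=meta.n_obs.copy(), n_possible=meta.n_possible.copy())
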