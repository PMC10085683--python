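"""Contact-probability read-out of simulated conformations.

Monomer pairs closer than a spatial contact radius (51 nm, centre to
centre) are counted, grouped by genomic separation |i - j| * bp_per_monomer,
divided by the number of possible monomer pairs at that separation, and
normalized so the curve equals 1 at the 100 kb point — directly comparable
with the Hi-C P(s) curves of :mod:`chromonema.hic_contacts`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .hic_contacts import ContactCurve, DistanceBins, normalize

__all__ = [
    "conformation_contacts",
    "model_contact_probability",
    "find_turn_peak",
    "compare_to_hic",
]


def conformation_contacts(conf, contact_radius: float = 51.0) -> np.ndarray:
    """All unordered monomer pairs (i, j), j > i, within ``contact_radius``.

    Uses a k-d tree (scales ~N log N) whose result is identical to the
    exhaustive all-pairs distance check.  Returns an (n_pairs, 2) int array.
    """
    coords = np.asarray(conf.coords if hasattr(conf, "coords") else conf, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("conformation has non-finite coordinates")
    pairs = cKDTree(coords).query_pairs(r=float(contact_radius), output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order].astype(np.int64)


def _default_model_bins(bp_per_monomer: int, genome_bp: int) -> DistanceBins:
    lo = int(bp_per_monomer)
    hi = int(genome_bp)
    return DistanceBins.log_spaced(lo, hi, 10)


def model_contact_probability(pair_lists, bp_per_monomer: int,
                              n_monomers: int | list[int] | None = None,
                              bins: DistanceBins | None = None,
                              normalize_at: int = 100_000) -> ContactCurve:
    """Contact probability versus genomic separation from monomer pairs.

    ``pair_lists`` is one (n, 2) pair array per conformation; conformations
    are pooled (counts summed, possible-pair denominators summed) before
    normalization.  Separations below one monomer are excluded.  When the
    normalization point is below one monomer the smallest-separation bin is
    used instead, with a warning.
    """
    if isinstance(pair_lists, np.ndarray):
        pair_lists = [pair_lists]
    if len(pair_lists) == 0:
        raise ValueError("need at least one conformation's pairs")
    if n_monomers is None:
        raise ValueError("n_monomers required to count possible pairs")
    if isinstance(n_monomers, (int, np.integer)):
        n_monomers = [int(n_monomers)] * len(pair_lists)
    if len(n_monomers) != len(pair_lists):
        raise ValueError("one n_monomers per conformation required")

    genome = max(n_monomers) * bp_per_monomer
    if bins is None:
        bins = _default_model_bins(bp_per_monomer, genome)

    n_obs = np.zeros(bins.n_bins, dtype=np.int64)
    n_possible = np.zeros(bins.n_bins, dtype=np.int64)
    empty = True
    for pairs, n in zip(pair_lists, n_monomers):
        pairs = np.asarray(pairs)
        if pairs.size:
            empty = False
            sep = np.abs(pairs[:, 1] - pairs[:, 0]).astype(np.int64) * bp_per_monomer
            sep = sep[sep >= bp_per_monomer]
            hist, _ = np.histogram(sep, bins=bins.edges)
            n_obs += hist.astype(np.int64)
        k = np.arange(1, n, dtype=np.int64)
        hist_p, _ = np.histogram(k * bp_per_monomer, bins=bins.edges,
                                 weights=(n - k).astype(np.int64))
        n_possible += hist_p.astype(np.int64)
    if empty:
        warnings.warn("no spatial contacts found; returning all-zero curve")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_possible > 0, n_obs / np.maximum(n_possible, 1), np.nan)
    curve = ContactCurve(bins=bins, p=p.astype(float), n_obs=n_obs,
                         n_possible=n_possible)
    if normalize_at is not None:
        at = int(normalize_at)
        if at < bp_per_monomer or at < bins.edges[0]:
            warnings.warn(
                f"normalization point {at} below one monomer; using the "
                "smallest separation bin instead")
            defined = np.flatnonzero(np.isfinite(curve.p) & (curve.p > 0))
            if defined.size == 0:
                return curve
            at = int(np.ceil(bins.edges[defined[0]]))
        try:
            curve = normalize(curve, at)
        except ValueError:
            warnings.warn("normalization point undefined; curve left unnormalized")
    return curve


def find_turn_peak(curve: ContactCurve, s_min: float | None = None,
                   s_max: float | None = None, smooth: int = 3,
                   min_prominence: float = 0.1) -> float:
    """Genomic separation (bp) of the interior local maximum of the curve.

    The log-curve is smoothed with a short moving average, strict local
    maxima of log p versus log s are located within [s_min, s_max], and
    the largest-separation one is refined by quadratic interpolation in
    log-log space.  For a helically arranged polymer this is the helical
    turn length; by default the search spans one bin above the smallest
    separation up to half the modelled span (beyond which counts are
    unreliable).

    A candidate maximum must rise at least ``min_prominence`` (log10
    units) above the lowest point of the curve between the window start
    and the candidate — the contact decay ahead of a genuine full-turn
    peak passes through a marked minimum, whereas statistical wiggles on
    a monotone decay do not.  Raises ``ValueError`` when no qualifying
    peak exists.
    """
    mids = curve.bins.mids
    ok = np.isfinite(curve.p) & (curve.p > 0)
    if not ok.any():
        raise ValueError("curve has no defined positive bins")
    if s_max is None:
        s_max = mids[-1] / 2
    if s_min is None:
        s_min = mids[0]
    logp = np.where(ok, np.log10(np.where(ok, curve.p, 1.0)), np.nan)
    # a measured zero (possible pairs exist, none observed) is a real low
    # value, not missing data; place it below the smallest positive bin
    zero = np.isfinite(curve.p) & (curve.p == 0) & (curve.n_possible > 0)
    logp[zero] = logp[ok].min() - 2.0
    if smooth > 1:
        # binomial weights: centre-peaked, avoids plateau ties of a flat mean
        kernel = np.array([1.0, 2.0, 1.0]) if smooth == 3 else np.ones(smooth)
        kernel = kernel / kernel.sum()
        valid = np.isfinite(logp).astype(float)
        filled = np.where(np.isfinite(logp), logp, 0.0)
        num = np.convolve(filled, kernel, mode="same")
        den = np.convolve(valid, kernel, mode="same")
        with np.errstate(invalid="ignore"):
            logp = np.where(den > 0, num / den, np.nan)
    in_window = np.flatnonzero((mids >= s_min) & (mids <= s_max))
    candidates = []
    for i in range(1, len(mids) - 1):
        if not (s_min <= mids[i] <= s_max):
            continue
        if not (np.isfinite(logp[i - 1]) and np.isfinite(logp[i]) and np.isfinite(logp[i + 1])):
            continue
        if logp[i] > logp[i - 1] and logp[i] > logp[i + 1]:
            before = logp[in_window[0]:i]
            before = before[np.isfinite(before)]
            prominence = logp[i] - before.min() if before.size else np.inf
            if prominence >= min_prominence:
                candidates.append(i)
    if not candidates:
        raise ValueError("no interior local maximum in the requested range")
    i = candidates[-1]  # largest-separation peak = full-turn feature
    x = np.log10(mids[i - 1:i + 2])
    y = logp[i - 1:i + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if abs(denom) < 1e-15:
        return float(mids[i])
    shift = 0.5 * (y[0] - y[2]) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(10 ** (x[1] + shift * (x[2] - x[1])))


def compare_to_hic(model: ContactCurve, hic: ContactCurve) -> dict:
    """Per-bin log-ratio divergence between a model curve and a Hi-C curve.

    Both curves must be normalized at the same point and share a bin grid;
    reports the per-bin log10 ratio plus max-abs and RMS log-distance over
    the overlapping defined bins.
    """
    if not model.bins.same_as(hic.bins):
        raise ValueError("curves are on different bin grids")
    if model.normalized_at is None or hic.normalized_at is None:
        raise ValueError("both curves must be normalized before comparison")
    ok = (np.isfinite(model.p) & (model.p > 0)
          & np.isfinite(hic.p) & (hic.p > 0))
    if not ok.any():
        raise ValueError("no overlapping defined bins")
    log_ratio = np.full(model.bins.n_bins, np.nan)
    log_ratio[ok] = np.log10(model.p[ok] / hic.p[ok])
    return {
        "s_mid": model.bins.mids,
        "log_ratio": log_ratio,
        "max_abs_log": float(np.max(np.abs(log_ratio[ok]))),
        "rms_log": float(np.sqrt(np.mean(log_ratio[ok] ** 2))),
        "n_bins": int(ok.sum()),
    }
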