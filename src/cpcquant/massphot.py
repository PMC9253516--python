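"""Mass accounting and peak extraction for mass-photometry event lists.

A mass photometer reports one molecular mass per landing event (kD).  The
analysis here mirrors common practice: a Gaussian kernel density estimate
over the event list, local maxima above a density floor as peaks, and a
mean +/- SD summary of the events near each peak.  Candidate complex
stoichiometries (e.g. a 2:2 assembly of two homodimers) are scored by their
summed monomer masses and assigned to the nearest peak within a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde

__all__ = [
    "ComplexComposition",
    "MassPeak",
    "complex_mass",
    "kde_peaks",
    "assign_species",
    "silverman_bandwidth",
]


@dataclass
class ComplexComposition:
    """A candidate assembly: (subunit name, monomer mass kD, copy number)."""

    components: list[tuple[str, float, int]]
    name: str = ""

    def validate(self) -> None:
        if not self.components:
            raise ValueError("empty composition")
        for nm, mass, copies in self.components:
            if mass <= 0:
                raise ValueError(f"{nm}: monomer mass must be positive")
            if int(copies) != copies or copies < 1:
                raise ValueError(f"{nm}: copies must be a positive integer")


@dataclass
class MassPeak:
    location_kD: float
    sd_kD: float
    weight: float


def complex_mass(comp: ComplexComposition) -> float:
    """Calculated molecular weight: sum of copies x monomer mass (kD)."""
    comp.validate()
    return float(sum(mass * copies for _, mass, copies in comp.components))


def silverman_bandwidth(masses: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth in kD."""
    m = np.asarray(masses, dtype=float)
    n = m.size
    sd = m.std(ddof=1)
    iqr = np.subtract(*np.percentile(m, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return 0.9 * scale * n ** (-1.0 / 5.0)


def kde_peaks(
    masses,
    bandwidth_kD: float | None = None,
    weight_floor: float = 0.05,
    grid_step_kD: float = 0.5,
) -> list[MassPeak]:
    """Call peaks in a mass-event sample by Gaussian kernel density.

    Local density maxima above ``weight_floor`` x the global maximum become
    peaks; each peak's mean +/- SD summarizes the events within +/-2
    bandwidths of the maximum, and its weight is the fraction of events in
    that window.  Bandwidth defaults to Silverman's rule.
    """
    m = np.asarray(masses, dtype=float)
    if m.size < 10:
        raise ValueError("need at least 10 events")
    if bandwidth_kD is None:
        bandwidth_kD = silverman_bandwidth(m)
    if bandwidth_kD <= 0:
        raise ValueError("bandwidth must be positive (all-identical masses?)")
    if np.ptp(m) == 0:
        # degenerate but well-posed: a delta of events smoothed by the kernel
        return [MassPeak(location_kD=float(m[0]), sd_kD=0.0, weight=1.0)]

    kde = gaussian_kde(m, bw_method=bandwidth_kD / m.std(ddof=1))
    lo = m.min() - 3 * bandwidth_kD
    hi = m.max() + 3 * bandwidth_kD
    grid = np.arange(lo, hi + grid_step_kD, grid_step_kD)
    dens = kde(grid)
    floor = weight_floor * dens.max()
    (maxima,) = argrelmax(dens)
    # an interior plateau or single-point ends: ensure global max is kept
    if dens.argmax() not in maxima:
        maxima = np.sort(np.append(maxima, dens.argmax()))

    # merge sampling bumps: maxima closer than 2 bandwidths collapse onto
    # the highest-density representative
    kept: list[int] = []
    for k in sorted(maxima, key=lambda k: -dens[k]):
        if all(abs(grid[k] - grid[j]) > 2.0 * bandwidth_kD for j in kept):
            kept.append(int(k))

    peaks: list[MassPeak] = []
    for k in sorted(kept):
        if dens[k] < floor:
            continue
        loc = grid[k]
        window = np.abs(m - loc) <= 2.0 * bandwidth_kD
        if not window.any():
            continue
        sel = m[window]
        peaks.append(
            MassPeak(
                location_kD=float(sel.mean()),
                sd_kD=float(sel.std(ddof=1)) if sel.size > 1 else 0.0,
                weight=float(window.mean()),
            )
        )
    peaks.sort(key=lambda p: p.location_kD)
    return peaks


def assign_species(
    peaks: list[MassPeak],
    candidates: list[ComplexComposition],
    tol_sd: float = 1.0,
) -> pd.DataFrame:
    """Assign each peak to the candidate stoichiometry closest in mass.

    A peak takes the candidate minimizing |peak - calculated| provided the
    distance does not exceed ``tol_sd`` x the peak SD; otherwise it is
    reported as unassigned.  Exact ties go to the smaller calculated mass
    and are noted.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    calc = [(c.name or "+".join(n for n, _, _ in c.components), complex_mass(c)) for c in candidates]
    rows = []
    for p in peaks:
        dists = sorted(
            ((abs(p.location_kD - mass), mass, name) for name, mass in calc),
            key=lambda t: (t[0], t[1]),
        )
        d, mass, name = dists[0]
        tie = len(dists) > 1 and dists[1][0] == d
        ok = d <= tol_sd * p.sd_kD
        rows.append(
            {
                "peak_kD": p.location_kD,
                "peak_sd_kD": p.sd_kD,
                "assigned": name if ok else "unassigned",
                "calc_kD": mass if ok else np.nan,
                "distance_kD": d,
                "tie_broken_to_smaller": bool(tie and ok),
            }
        )
    return pd.DataFrame(rows)
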