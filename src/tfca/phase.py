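"""Time-frequency phase shift between ABP and CBFV oscillations.

The phase map is the argument of the smoothed cross distribution, kept only
where the time-frequency coherence is significantly high (>= ``T_h``, 0.9 by
default).  The sign convention is physiological: positive phase means CBFV
(the second input of the coherence computation) leads ABP.

Phase values live on (-pi, pi]; a true phase difference drifting across the
boundary "wraps", producing regions that simultaneously contain values near
+pi and -pi.  Such regions would corrupt arithmetic averages and are excised
from the valid mask before any summary (``exclude_wrap_regions``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .coherence import BandDefinition, CoherenceMap

__all__ = [
    "PhaseMap",
    "NoValidArea",
    "tf_phase",
    "atfps",
    "component_time_course",
    "exclude_wrap_regions",
    "chirp_corridor",
]


class NoValidArea:
    """Distinguished result when a band holds no significantly coherent
    points: unlike a silent NaN it carries the band it refers to."""

    def __init__(self, band: str = "") -> None:
        self.band = band

    def __repr__(self) -> str:  # pragma: no cover
        return f"NoValidArea(band={self.band!r})"


@dataclass
class PhaseMap:
    """Masked time-frequency phase (radians, (-pi, pi]).

    ``values`` are meaningful only on ``valid_mask`` (coherence >= threshold
    and inside the coherence's defined region).  ``wrap_excluded`` records
    regions removed by :func:`exclude_wrap_regions`.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    t_axis: np.ndarray
    f_axis: np.ndarray
    threshold: float = 0.9
    wrap_excluded: list = field(default_factory=list)

    def band_bins(self, band: BandDefinition) -> np.ndarray:
        sel = (self.f_axis >= band.f_low) & (self.f_axis < band.f_high)
        if not sel.any():
            raise ValueError(f"band {band.name} outside the frequency axis")
        return sel


def tf_phase(coh: CoherenceMap, th: float = 0.9) -> PhaseMap:
    """Phase map from the coherence computation's own smoothed cross
    spectrum, masked at coherence >= ``th``.

    The coherence must have been computed as ``tf_coherence(abp, cbfv)``; the
    returned phase is ``arg(conj(S_xy^c))`` so that a leading second input
    (CBFV) gives positive phase.
    """
    if not 0 <= th <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if coh.smoothed_cross is None:
        raise ValueError("coherence map carries no smoothed cross spectrum")
    values = np.angle(np.conj(coh.smoothed_cross))
    valid = coh.defined_mask & (coh.values >= th)
    return PhaseMap(
        values=values,
        valid_mask=valid,
        t_axis=coh.t_axis,
        f_axis=coh.f_axis,
        threshold=th,
    )


def exclude_wrap_regions(pmap: PhaseMap, guard_deg: float = 160.0) -> PhaseMap:
    """Remove phase-wrap regions from the valid mask.

    A wrap shows up as an 8-connected patch of extreme phases (beyond
    ``guard_deg``) containing *both* signs: a true phase drifting across
    +/-180 deg produces exactly this signature, and averaging across it would
    cancel rather than track the drift.  Only the offending extreme-phase
    patch is excised, so well-behaved parts of a large coherent region are
    kept.  Removed regions are logged on the returned map (pixel counts).
    """
    guard = np.deg2rad(guard_deg)
    extreme = pmap.valid_mask & (np.abs(pmap.values) > guard)
    labels, n_lab = ndimage.label(extreme, structure=np.ones((3, 3), dtype=int))
    mask = pmap.valid_mask.copy()
    excluded = []
    for lab in range(1, n_lab + 1):
        region = labels == lab
        vals = pmap.values[region]
        if (vals > guard).any() and (vals < -guard).any():
            mask[region] = False
            excluded.append({"label": lab, "n_points": int(region.sum())})
    return PhaseMap(
        values=pmap.values,
        valid_mask=mask,
        t_axis=pmap.t_axis,
        f_axis=pmap.f_axis,
        threshold=pmap.threshold,
        wrap_excluded=pmap.wrap_excluded + excluded,
    )


def atfps(pmap: PhaseMap, band: BandDefinition, circular: bool = False):
    """Band-averaged time-frequency phase shift in degrees (aTFPS).

    Arithmetic mean of the valid phase values inside the band (the map should
    have had wrap regions excluded first); ``circular=True`` switches to the
    circular mean.  Returns :class:`NoValidArea` when the band holds no valid
    points.
    """
    sel = pmap.band_bins(band)
    vals = pmap.values[:, sel][pmap.valid_mask[:, sel]]
    if vals.size == 0:
        return NoValidArea(band.name)
    if circular:
        return float(np.rad2deg(np.angle(np.exp(1j * vals).mean())))
    return float(np.rad2deg(vals.mean()))


def component_time_course(pmap: PhaseMap, region: np.ndarray) -> np.ndarray:
    """Frequency-average of valid phases inside ``region`` at each time
    instant (degrees); instants with no valid point are NaN.

    ``region`` is a boolean (time x frequency) mask delimiting one signal
    component, e.g. a corridor around a chirp trajectory.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != pmap.values.shape:
        raise ValueError("region shape does not match the phase map")
    use = region & pmap.valid_mask
    if not use.any():
        raise ValueError("region does not intersect the valid mask")
    sums = np.where(use, pmap.values, 0.0).sum(axis=1)
    counts = use.sum(axis=1)
    with np.errstate(invalid="ignore"):
        course = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return np.rad2deg(course)


def chirp_corridor(
    t_axis: np.ndarray,
    f_axis: np.ndarray,
    freq_of_t: np.ndarray,
    half_width: float = 0.01,
) -> np.ndarray:
    """Boolean (time x frequency) corridor of +/- ``half_width`` Hz around an
    instantaneous-frequency trajectory, for use as a component region."""
    freq_of_t = np.asarray(freq_of_t, dtype=float)
    if freq_of_t.shape != np.shape(t_axis):
        raise ValueError("freq_of_t must be given per time sample")
    return np.abs(f_axis[None, :] - freq_of_t[:, None]) <= half_width
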