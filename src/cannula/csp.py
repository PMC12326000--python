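"""Chemical-shift-perturbation mapping.

Combined amide shift changes are the weighted Euclidean norm
``sqrt(dH^2 + (w * dN)^2)`` of the 1H and 15N changes; significance is
judged against an outlier-corrected standard deviation about zero
(sigma0_corr), with 2*sigma0_corr marking strong perturbations that
likely belong to the binding site itself.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .io_core import PeakList, ResidueId

#: Conventional 15N weight from the gyromagnetic-ratio scale of the two nuclei.
DEFAULT_WEIGHT_N = 0.2

#: Default multiple of sigma beyond which a value is excluded as an outlier.
DEFAULT_EXCLUSION_FACTOR = 3.0

CLASS_NONE = "none"
CLASS_SIGNIFICANT = "significant"
CLASS_STRONG = "strong"


def delta_comb(delta_H: float, delta_N: float, weight_N: float = DEFAULT_WEIGHT_N) -> float:
    """Combined 1H/15N shift change in ppm (symmetric in the sign of inputs)."""
    if weight_N <= 0:
        raise ValidationError("weight_N must be > 0")
    return math.hypot(delta_H, weight_N * delta_N)


def sigma0_corr(
    deltas: Sequence[float],
    exclusion_factor: float = DEFAULT_EXCLUSION_FACTOR,
) -> float:
    """Outlier-corrected standard deviation about zero.

    Iteratively recomputes the RMS about zero of the retained values and
    removes every value exceeding ``exclusion_factor`` times the current
    RMS, until a pass removes nothing.  Shifted residues (the signal) are
    thereby excluded from the noise estimate.
    """
    values = np.asarray(deltas, dtype=float)
    if values.size < 3:
        raise InsufficientDataError(
            f"sigma0_corr needs at least 3 values, got {values.size}"
        )
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValidationError("deltas must be finite and non-negative")
    if exclusion_factor <= 1:
        raise ValidationError("exclusion_factor must be > 1")
    retained = values
    while True:
        sigma = float(np.sqrt(np.mean(retained**2)))
        keep = retained <= exclusion_factor * sigma
        if keep.all():
            return sigma
        if keep.sum() < 3:  # refuse to erode the estimate below the minimum
            return sigma
        retained = retained[keep]


def classify(value: float, sigma0: float) -> str:
    if value > 2 * sigma0:
        return CLASS_STRONG
    if value > sigma0:
        return CLASS_SIGNIFICANT
    return CLASS_NONE


@dataclass
class CspEntry:
    residue: ResidueId
    delta_comb: float  # ppm
    csp_class: str


@dataclass
class CspProfile:
    """Per-residue combined shift changes with significance classes."""

    entries: list[CspEntry]
    sigma0_corr: float  # ppm
    unassessed: list[ResidueId] = field(default_factory=list)
    weight_N: float = DEFAULT_WEIGHT_N

    def by_class(self, csp_class: str) -> list[CspEntry]:
        return [e for e in self.entries if e.csp_class == csp_class]

    def counts(self) -> dict[str, int]:
        out = {CLASS_NONE: 0, CLASS_SIGNIFICANT: 0, CLASS_STRONG: 0}
        for e in self.entries:
            out[e.csp_class] += 1
        return out


def csp_profile(
    reference: PeakList,
    perturbed: PeakList,
    weight_N: float = DEFAULT_WEIGHT_N,
    exclusion_factor: float = DEFAULT_EXCLUSION_FACTOR,
) -> CspProfile:
    """Combined shift changes between two conditions, classified per residue.

    Residues present in only one of the lists cannot be assessed (the peak
    may have broadened away or be unassigned); they are reported in
    ``unassessed``, never as zero change.
    """
    ref, per = reference.by_position(), perturbed.by_position()
    shared = sorted(set(ref) & set(per))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"need >= 3 shared residues, got {len(shared)}"
        )
    entries = []
    for pos in shared:
        d = delta_comb(
            per[pos].delta_H - ref[pos].delta_H,
            per[pos].delta_N - ref[pos].delta_N,
            weight_N,
        )
        entries.append(CspEntry(ref[pos].residue, d, CLASS_NONE))
    sigma0 = sigma0_corr([e.delta_comb for e in entries], exclusion_factor)
    for e in entries:
        e.csp_class = classify(e.delta_comb, sigma0)
    unassessed = sorted(
        [ref[p].residue for p in set(ref) - set(per)]
        + [per[p].residue for p in set(per) - set(ref)],
        key=lambda r: r.position,
    )
    return CspProfile(
        entries=entries,
        sigma0_corr=sigma0,
        unassessed=unassessed,
        weight_N=weight_N,
    )


def exchange_upper_bound(delta_shift: float, larmor_frequency: float) -> float:
    """Upper bound on the exchange rate between two slowly exchanging states.

    Two resolved resonances separated by ``delta_shift`` (ppm) at a nucleus
    Larmor frequency of ``larmor_frequency`` (MHz) imply exchange slower
    than the coalescence rate pi * dnu / sqrt(2), with dnu the splitting
    in Hz.  Returned in 1/s.
    """
    if delta_shift < 0 or larmor_frequency <= 0:
        raise ValidationError("delta_shift must be >= 0 and larmor_frequency > 0")
    dnu_hz = delta_shift * larmor_frequency  # ppm * MHz = Hz
    return math.pi * dnu_hz / math.sqrt(2.0)
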