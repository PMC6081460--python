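"""Methylation-state mass ladders and MALDI spectrum quantitation.

Each added methyl group shifts a peptide's monoisotopic mass by one CH2
(14.015650 Da).  Given the m/z of the unmethylated species, the ladder of
me0..me3 masses is fixed; state abundances are read out of a spectrum by
matching the local-maximum peak nearest each expected mass within a ppm
tolerance and normalizing the matched apex intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import argrelextrema

from oncomark.errors import InvalidInputError

#: monoisotopic mass of CH2 (12C + 2x 1H), Da
METHYL_DELTA_DA = 14.015650

#: standard monoisotopic residue masses (Da) for base-m/z from a sequence
MONOISOTOPIC_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MONO = 18.010565
PROTON_MONO = 1.007276


def peptide_mh(sequence: str) -> float:
    """Monoisotopic [M+H]+ m/z of a peptide from its one-letter sequence."""
    try:
        mass = sum(MONOISOTOPIC_RESIDUE_MASS[aa] for aa in sequence.upper())
    except KeyError as exc:
        raise InvalidInputError(f"unknown residue {exc.args[0]!r}") from exc
    return mass + WATER_MONO + PROTON_MONO


@dataclass(frozen=True)
class MethylSeries:
    """Expected m/z ladder for me0..me(n-1) states of one peptide."""

    base_mz: float
    n_states: int = 4
    delta_methyl: float = METHYL_DELTA_DA
    states: tuple = field(init=False)

    def __post_init__(self) -> None:
        if self.base_mz <= 0:
            raise InvalidInputError("base_mz must be positive")
        if self.n_states < 1:
            raise InvalidInputError("need at least one methylation state")
        object.__setattr__(
            self,
            "states",
            tuple(self.base_mz + k * self.delta_methyl for k in range(self.n_states)),
        )


@dataclass
class Spectrum:
    """A centroided or profile mass spectrum with strictly increasing m/z."""

    mz: np.ndarray
    intensity: np.ndarray
    window: tuple = (1200.0, 3500.0)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise InvalidInputError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise InvalidInputError("mz values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise InvalidInputError("intensities must be non-negative")


@dataclass
class MethylProfile:
    """Relative abundance per methylation state plus peak-match diagnostics."""

    abundances: np.ndarray           # length n_states, sums to 1 unless nothing matched
    matched_mz: np.ndarray           # NaN where a state found no peak
    mass_error_ppm: np.ndarray       # NaN where unmatched
    no_peaks_found: bool = False


def methyl_mass_series(base_mz: float, n_states: int = 4) -> MethylSeries:
    """Ladder of expected m/z values spaced by one CH2 per methyl group."""
    return MethylSeries(base_mz=base_mz, n_states=n_states)


def _local_maxima(spectrum: Spectrum, noise_mad_factor: float = 3.0) -> np.ndarray:
    """Indices of local intensity maxima above a median + k*MAD noise floor."""
    y = spectrum.intensity
    if y.size < 3:
        return np.array([], dtype=int)
    floor = np.median(y) + noise_mad_factor * np.median(np.abs(y - np.median(y)))
    idx = argrelextrema(y, np.greater_equal, order=1)[0]
    # greater_equal admits flat tops; keep one index per plateau
    keep = []
    for i in idx:
        if y[i] <= floor:
            continue
        if keep and i == keep[-1] + 1 and y[i] == y[keep[-1]]:
            continue
        keep.append(i)
    return np.array(keep, dtype=int)


def assign_methyl_states(
    spectrum: Spectrum,
    series: MethylSeries,
    tolerance_ppm: float = 200.0,
    noise_mad_factor: float = 3.0,
) -> MethylProfile:
    """Match ladder states to spectrum peaks and normalize their intensities.

    For each expected mass, the local-maximum peak nearest in m/z within
    ``tolerance_ppm`` is taken (apex intensity); abundances are matched
    intensities normalized to sum one, with unmatched states at zero.  If
    no state matches, an all-zero profile with ``no_peaks_found`` is
    returned (not fatal).
    """
    n = series.n_states
    matched_mz = np.full(n, np.nan)
    matched_int = np.zeros(n)
    errs = np.full(n, np.nan)
    peaks = _local_maxima(spectrum, noise_mad_factor)
    if peaks.size:
        peak_mz = spectrum.mz[peaks]
        peak_int = spectrum.intensity[peaks]
        for k, expected in enumerate(series.states):
            tol = expected * tolerance_ppm * 1e-6
            d = np.abs(peak_mz - expected)
            j = int(np.argmin(d))
            if d[j] <= tol:
                matched_mz[k] = peak_mz[j]
                matched_int[k] = peak_int[j]
                errs[k] = (peak_mz[j] - expected) / expected * 1e6
    total = matched_int.sum()
    if total <= 0:
        return MethylProfile(
            abundances=np.zeros(n),
            matched_mz=matched_mz,
            mass_error_ppm=errs,
            no_peaks_found=True,
        )
    return MethylProfile(
        abundances=matched_int / total,
        matched_mz=matched_mz,
        mass_error_ppm=errs,
    )
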