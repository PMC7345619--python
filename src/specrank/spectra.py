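"""Core containers for MS/MS peak lists.

A :class:`Spectrum` holds one acquisition (a query) or one predicted
fragmentation pattern (a library entry) as an ordered list of
(m/z, intensity) pairs together with its precursor context.  Peak lists are
canonicalised to ascending m/z on construction so that all downstream
operations are invariant to input peak order.

A :class:`PredictedSpectrumSet` groups the predicted spectra of one library
compound by collision energy.  The workflow uses three nominal energies
(10, 20 and 40 eV); any subset may be present for a given compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .errors import SpectrumError

POSITIVE = "positive"
NEGATIVE = "negative"
POLARITIES = (POSITIVE, NEGATIVE)

#: Collision energies (eV) at which library spectra are predicted.
ENERGY_LEVELS = (10, 20, 40)


class Peak(NamedTuple):
    """One fragment peak: m/z in Da and a non-negative abundance."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """An MS/MS peak list with precursor context.

    Parameters
    ----------
    spectrum_id : str
        Free-text label (query file stem or ``<compound>_e<energy>``).
    precursor_mz : float
        Precursor ion m/z in Da; must be positive.
    polarity : str
        ``"positive"`` or ``"negative"`` ionisation mode.
    peaks : tuple of Peak
        Non-empty peak list; sorted ascending by m/z on construction.
    collision_energy : float, optional
        Nominal collision energy in eV, if known.
    """

    spectrum_id: str
    precursor_mz: float
    polarity: str
    peaks: tuple[Peak, ...]
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        peaks = tuple(Peak(float(m), float(i)) for m, i in self.peaks)
        if not peaks:
            raise SpectrumError(f"spectrum {self.spectrum_id!r}: empty peak list")
        for p in peaks:
            if not p.mz > 0:
                raise SpectrumError(
                    f"spectrum {self.spectrum_id!r}: non-positive m/z {p.mz}"
                )
            if p.intensity < 0:
                raise SpectrumError(
                    f"spectrum {self.spectrum_id!r}: negative intensity {p.intensity}"
                )
        if not float(self.precursor_mz) > 0:
            raise SpectrumError(
                f"spectrum {self.spectrum_id!r}: non-positive precursor m/z"
            )
        if self.polarity not in POLARITIES:
            raise SpectrumError(
                f"spectrum {self.spectrum_id!r}: polarity must be one of {POLARITIES}"
            )
        object.__setattr__(self, "peaks", tuple(sorted(peaks)))
        object.__setattr__(self, "precursor_mz", float(self.precursor_mz))
        if self.collision_energy is not None:
            object.__setattr__(self, "collision_energy", float(self.collision_energy))

    @property
    def mz(self) -> np.ndarray:
        """Peak m/z values as a float array (ascending)."""
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity(self) -> np.ndarray:
        """Peak intensities as a float array, aligned with :attr:`mz`."""
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class PredictedSpectrumSet:
    """Predicted spectra of one compound keyed by collision energy (eV)."""

    compound_id: str
    spectra: Mapping[int, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spectra = {int(e): s for e, s in self.spectra.items()}
        bad = set(spectra) - set(ENERGY_LEVELS)
        if bad:
            raise SpectrumError(
                f"compound {self.compound_id!r}: unsupported energies {sorted(bad)}; "
                f"allowed: {ENERGY_LEVELS}"
            )
        object.__setattr__(self, "spectra", spectra)

    @property
    def energies(self) -> tuple[int, ...]:
        return tuple(sorted(self.spectra))

    def __len__(self) -> int:
        return len(self.spectra)


def merge_spectra(
    spectra: Iterable[Spectrum],
    spectrum_id: str,
    precursor_mz: float,
    polarity: str,
) -> Spectrum:
    """Merge several peak lists into one spectrum.

    Peaks with exactly equal m/z have their intensities summed; all other
    peaks are concatenated.  Used to combine per-energy acquisitions (or
    predictions) into the single challenge-style spectrum the merged scoring
    mode consumes.
    """
    acc: dict[float, float] = {}
    for s in spectra:
        for p in s.peaks:
            acc[p.mz] = acc.get(p.mz, 0.0) + p.intensity
    if not acc:
        raise SpectrumError(f"merge for {spectrum_id!r}: no peaks to merge")
    peaks = tuple(Peak(m, i) for m, i in sorted(acc.items()))
    return Spectrum(spectrum_id, precursor_mz, polarity, peaks)
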