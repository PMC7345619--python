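"""Compound library: records, predicted spectra, and precursor-mass retrieval.

The library stores neutral monoisotopic masses (MS-Ready convention: the
desalted, neutral structure form whose mass relates to the observed ion).
Candidate retrieval converts a query precursor m/z to a neutral mass under
the [M+H]+ / [M-H]- adduct assumption and returns every record whose mass
lies within a symmetric relative (ppm) window.

The ppm deviation is computed against the candidate's library mass; at the
default 10 ppm tolerance the difference from using the query-derived mass as
denominator is negligible, but the convention is fixed here so results are
reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, LibraryError
from .spectra import NEGATIVE, POSITIVE, PredictedSpectrumSet

#: Mass of a proton in Da, used for the [M+H]+ / [M-H]- adduct correction.
PROTON_MASS = 1.007276

#: Default precursor search tolerance (ppm).
DEFAULT_TOL_PPM = 10.0

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


@dataclass(frozen=True)
class CompoundRecord:
    """One library compound with its mass, identifiers and ranking metadata.

    ``ds_count`` is the data-source count: the number of curated datasets in
    the underlying database that contain the chemical.  It serves as a prior
    on how likely a candidate is to be encountered, and is the sole metadata
    term in the default combined ranking.  The remaining metadata columns
    (PubMed references, PubChem sources, NORMAN SusDat presence) are carried
    for reporting but excluded from the default combined score, since
    combining multiple counts does not outperform the data-source count
    alone.
    """

    compound_id: str
    monoisotopic_mass: float
    name: str = ""
    inchikey: str = ""
    formula: str = ""
    ds_count: int = 0
    pubmed_count: int = 0
    pubchem_sources: int = 0
    norman_susdat: bool = False
    isotope_labeled: bool = False
    charged: bool = False

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise LibraryError("compound_id must be non-empty")
        if not self.monoisotopic_mass > 0:
            raise LibraryError(
                f"{self.compound_id}: monoisotopic mass must be positive"
            )
        for fld in ("ds_count", "pubmed_count", "pubchem_sources"):
            if getattr(self, fld) < 0:
                raise LibraryError(f"{self.compound_id}: {fld} must be >= 0")
        if self.inchikey and not _INCHIKEY_RE.match(self.inchikey):
            raise LibraryError(
                f"{self.compound_id}: InChIKey {self.inchikey!r} does not match "
                "the 14-10-1 hyphenated pattern"
            )


class SpectralLibrary:
    """Compound records plus their predicted spectra, indexed by neutral mass.

    Records may lack predicted spectra; such compounds are still retrieved by
    a precursor search (they can be metadata-ranked) but receive a raw MS/MS
    score of zero, flagged as having no predicted data.  Use
    :func:`build_library` or :meth:`from_files` to construct.
    """

    def __init__(
        self,
        records: dict[str, CompoundRecord],
        predicted: dict[str, PredictedSpectrumSet],
    ) -> None:
        records = dict(records)
        predicted = dict(predicted)
        for cid in predicted:
            if cid not in records:
                raise LibraryError(f"predicted spectra for unknown compound {cid!r}")
        self.records = records
        self.predicted = predicted
        order = sorted(records.values(), key=lambda r: (r.monoisotopic_mass, r.compound_id))
        self._masses = np.array([r.monoisotopic_mass for r in order], dtype=float)
        self._ids_by_mass = [r.compound_id for r in order]

    @classmethod
    def from_files(cls, msp_path, metadata_path) -> "SpectralLibrary":
        """Assemble a library from an MSP predicted-spectrum file and a metadata CSV."""
        from .io_formats import read_library_msp, read_metadata_csv

        return build_library(read_metadata_csv(metadata_path), read_library_msp(msp_path))

    @property
    def mass_index(self) -> list[tuple[float, str]]:
        """Records as (mass, compound_id) pairs sorted ascending by mass."""
        return list(zip(self._masses.tolist(), self._ids_by_mass))

    def has_predicted(self, compound_id: str) -> bool:
        return compound_id in self.predicted and len(self.predicted[compound_id]) > 0

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.records


def build_library(
    records: Iterable[CompoundRecord],
    predicted: Iterable[tuple[str, PredictedSpectrumSet]] = (),
) -> SpectralLibrary:
    """Assemble a :class:`SpectralLibrary`, validating id uniqueness and linkage.

    Raises
    ------
    LibraryError
        On duplicate compound ids, or a predicted-spectrum set referencing a
        compound id absent from the records.
    """
    rec_map: dict[str, CompoundRecord] = {}
    for rec in records:
        if rec.compound_id in rec_map:
            raise LibraryError(f"duplicate compound_id {rec.compound_id!r}")
        rec_map[rec.compound_id] = rec
    pred_map: dict[str, PredictedSpectrumSet] = {}
    for cid, pset in predicted:
        if cid not in rec_map:
            raise LibraryError(f"predicted spectra for unknown compound {cid!r}")
        if cid in pred_map:
            raise LibraryError(f"duplicate predicted-spectrum set for {cid!r}")
        pred_map[cid] = pset
    return SpectralLibrary(rec_map, pred_map)


def neutral_mass_from_precursor(precursor_mz: float, polarity: str) -> float:
    """Neutral monoisotopic mass implied by a precursor m/z.

    Positive mode assumes the [M+H]+ species (subtract one proton mass);
    negative mode assumes [M-H]- (add one proton mass).

    Raises
    ------
    DomainError
        If the implied neutral mass is not positive.
    """
    if polarity == POSITIVE:
        mass = precursor_mz - PROTON_MASS
    elif polarity == NEGATIVE:
        mass = precursor_mz + PROTON_MASS
    else:
        raise DomainError(f"unknown polarity {polarity!r}")
    if not mass > 0:
        raise DomainError(
            f"precursor m/z {precursor_mz} in {polarity} mode implies "
            f"non-positive neutral mass {mass}"
        )
    return mass


def search_by_precursor(
    library: SpectralLibrary,
    precursor_mz: float,
    polarity: str,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> list[CompoundRecord]:
    """Retrieve the candidate set for a precursor m/z within a ppm window.

    Returns exactly the records whose neutral monoisotopic mass ``m``
    satisfies ``|neutral - m| / m * 1e6 <= tol_ppm``, where ``neutral`` is the
    adduct-corrected query mass.  Result order is deterministic: ascending
    mass, compound_id as tiebreak.  An empty result is valid.
    """
    if not tol_ppm > 0:
        raise DomainError("tol_ppm must be positive")
    neutral = neutral_mass_from_precursor(precursor_mz, polarity)
    if len(library) == 0:
        return []
    rel = tol_ppm * 1e-6
    # |neutral - m| <= rel * m  <=>  neutral/(1+rel) <= m <= neutral/(1-rel)
    lo = neutral / (1.0 + rel)
    hi = neutral / (1.0 - rel) if rel < 1.0 else np.inf
    i0 = int(np.searchsorted(library._masses, lo, side="left"))
    i1 = int(np.searchsorted(library._masses, hi, side="right"))
    out: list[CompoundRecord] = []
    for idx in range(i0, i1):
        m = library._masses[idx]
        if abs(neutral - m) / m * 1e6 <= tol_ppm:
            out.append(library.records[library._ids_by_mass[idx]])
    return out


def candidate_flags(
    library: SpectralLibrary, candidates: Sequence[CompoundRecord]
) -> list[bool]:
    """Per-candidate flag: True when the record has no predicted spectra."""
    return [not library.has_predicted(r.compound_id) for r in candidates]
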