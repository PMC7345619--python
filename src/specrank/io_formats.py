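"""Readers and writers for the on-disk text formats.

Three dialects are defined, all plain text / UTF-8:

* Query spectra — one ``mz intensity`` pair per line, whitespace separated,
  with optional ``# key value`` header lines (``id``, ``precursor_mz``,
  ``polarity``, ``energy``).  This is the single canonical dialect; source
  files from other conventions should be converted to it (precursor masses
  that ship separately can be supplied as arguments and are inserted on
  write).
* Predicted-spectrum libraries — MSP-like records::

      Name: <name>
      DB#: <compound id>
      Comment: energy=<10|20|40>
      PrecursorMZ: <Da>
      Num Peaks: <K>
      <K "mz intensity" lines>
      <blank line>

  Unknown fields are ignored; consecutive records sharing a ``DB#`` are
  grouped into one per-compound set of energies.
* Metadata and reports — CSV with a header row and "." decimal separator.

Numbers are written with full repr precision so write -> read round-trips
are text-faithful.  Zero-intensity peaks are retained on read (parsing is
lossless); the scoring layer excludes them.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError
from .library import CompoundRecord
from .spectra import ENERGY_LEVELS, Peak, PredictedSpectrumSet, Spectrum, SpectrumError

logger = logging.getLogger(__name__)

_QUERY_HEADER_KEYS = ("id", "precursor_mz", "polarity", "energy")


def _format_float(x: float) -> str:
    return repr(float(x))


def read_query_spectrum(
    path,
    precursor_mz: float | None = None,
    polarity: str | None = None,
    spectrum_id: str | None = None,
) -> Spectrum:
    """Parse a query spectrum text file.

    Header lines (``# key value``) may provide the precursor m/z, polarity,
    collision energy and id; explicit arguments take precedence and must be
    given when the file lacks the corresponding header.  Peak lines hold two
    numeric tokens.  Zero-intensity peaks are retained.

    Raises
    ------
    FormatError
        On an empty file, no parseable peak lines, a malformed peak line,
        a negative intensity, or a missing precursor m/z / polarity.
    """
    path = Path(path)
    header: dict[str, str] = {}
    peaks: list[Peak] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            tokens = line.lstrip("#").strip().split(None, 1)
            if len(tokens) == 2 and tokens[0].lower() in _QUERY_HEADER_KEYS:
                header[tokens[0].lower()] = tokens[1].strip()
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected two numeric tokens, got {line!r}"
            )
        try:
            mz, intensity = float(tokens[0]), float(tokens[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric peak line {line!r}") from exc
        if intensity < 0:
            raise FormatError(f"{path}:{lineno}: negative intensity {intensity}")
        peaks.append(Peak(mz, intensity))
    if not peaks:
        raise FormatError(f"{path}: no peak lines found")
    if precursor_mz is None:
        if "precursor_mz" not in header:
            raise FormatError(f"{path}: precursor m/z neither in header nor supplied")
        precursor_mz = float(header["precursor_mz"])
    if polarity is None:
        if "polarity" not in header:
            raise FormatError(f"{path}: polarity neither in header nor supplied")
        polarity = header["polarity"]
    if spectrum_id is None:
        spectrum_id = header.get("id", path.stem)
    energy = float(header["energy"]) if "energy" in header else None
    try:
        return Spectrum(spectrum_id, precursor_mz, polarity, tuple(peaks), energy)
    except SpectrumError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_query_spectrum(spectrum: Spectrum, path) -> None:
    """Write a query spectrum in the canonical dialect (exact text round-trip)."""
    lines = [
        f"# id {spectrum.spectrum_id}",
        f"# precursor_mz {_format_float(spectrum.precursor_mz)}",
        f"# polarity {spectrum.polarity}",
    ]
    if spectrum.collision_energy is not None:
        lines.append(f"# energy {_format_float(spectrum.collision_energy)}")
    for p in spectrum.peaks:
        lines.append(f"{_format_float(p.mz)} {_format_float(p.intensity)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _finish_msp_record(
    fields: dict[str, str], peaks: list[Peak], path, lineno: int
) -> tuple[str, int, Spectrum]:
    cid = fields.get("db#") or fields.get("name")
    if not cid:
        raise FormatError(f"{path}:{lineno}: MSP record lacks a compound id (DB#/Name)")
    declared = fields.get("num peaks")
    if declared is None:
        raise FormatError(f"{path}:{lineno}: MSP record for {cid!r} lacks 'Num Peaks'")
    if int(declared) != len(peaks):
        raise FormatError(
            f"{path}:{lineno}: record {cid!r} declares {declared} peaks, "
            f"found {len(peaks)}"
        )
    energy = None
    comment = fields.get("comment", "")
    for token in comment.replace(";", " ").split():
        if token.lower().startswith("energy="):
            energy = int(float(token.split("=", 1)[1]))
    if energy is None:
        raise FormatError(
            f"{path}:{lineno}: record {cid!r} lacks an energy annotation "
            "('Comment: energy=N')"
        )
    if energy not in ENERGY_LEVELS:
        raise FormatError(
            f"{path}:{lineno}: record {cid!r} has energy {energy}; "
            f"expected one of {ENERGY_LEVELS}"
        )
    if "precursormz" in fields:
        precursor = float(fields["precursormz"])
    else:
        precursor = max(p.mz for p in peaks)
    spec = Spectrum(f"{cid}_e{energy}", precursor, "positive", tuple(peaks), energy)
    return cid, energy, spec


def read_library_msp(path) -> list[tuple[str, PredictedSpectrumSet]]:
    """Parse an MSP-like predicted-spectrum library.

    Records for the same compound id are grouped into one
    :class:`PredictedSpectrumSet`; compound order follows first appearance.
    Unknown header fields are ignored.
    """
    path = Path(path)
    grouped: dict[str, dict[int, Spectrum]] = {}
    order: list[str] = []
    fields: dict[str, str] = {}
    peaks: list[Peak] = []
    expecting_peaks = False

    def flush(lineno: int) -> None:
        nonlocal fields, peaks, expecting_peaks
        if not fields and not peaks:
            return
        cid, energy, spec = _finish_msp_record(fields, peaks, path, lineno)
        if cid not in grouped:
            grouped[cid] = {}
            order.append(cid)
        if energy in grouped[cid]:
            raise FormatError(
                f"{path}:{lineno}: duplicate {energy} eV record for {cid!r}"
            )
        grouped[cid][energy] = spec
        fields, peaks, expecting_peaks = {}, [], False

    lineno = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            flush(lineno)
            continue
        if not expecting_peaks and ":" in stripped:
            key, _, value = stripped.partition(":")
            key = key.strip().lower()
            fields[key] = value.strip()
            if key == "num peaks":
                expecting_peaks = True
            continue
        tokens = stripped.split()
        if len(tokens) != 2:
            raise FormatError(f"{path}:{lineno}: malformed peak line {stripped!r}")
        try:
            peaks.append(Peak(float(tokens[0]), float(tokens[1])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric peak line") from exc
    flush(lineno + 1)
    return [
        (cid, PredictedSpectrumSet(cid, grouped[cid])) for cid in order
    ]


def write_library_msp(
    entries: Iterable[tuple[str, PredictedSpectrumSet]], path, names: dict | None = None
) -> None:
    """Write predicted-spectrum sets in the MSP-like dialect."""
    names = names or {}
    blocks: list[str] = []
    for cid, pset in entries:
        for energy in sorted(pset.spectra):
            spec = pset.spectra[energy]
            lines = [
                f"Name: {names.get(cid, cid)}",
                f"DB#: {cid}",
                f"Comment: energy={energy}",
                f"PrecursorMZ: {_format_float(spec.precursor_mz)}",
                f"Num Peaks: {len(spec.peaks)}",
            ]
            lines += [
                f"{_format_float(p.mz)} {_format_float(p.intensity)}"
                for p in spec.peaks
            ]
            blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n")


_META_REQUIRED = ("compound_id", "monoisotopic_mass")
_META_INT_DEFAULTS = ("ds_count", "pubmed_count", "pubchem_sources")
_META_BOOL_DEFAULTS = ("norman_susdat", "isotope_labeled", "charged")
_META_STR_DEFAULTS = ("name", "inchikey", "formula")

_TRUTHY = {"true", "1", "yes", "t", "y"}


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in _TRUTHY


def read_metadata_csv(path) -> list[CompoundRecord]:
    """Parse a compound-metadata CSV into typed records.

    The header must name ``compound_id`` and ``monoisotopic_mass``; the
    metadata columns (``ds_count``, ``pubmed_count``, ``pubchem_sources``,
    ``norman_susdat``) are optional and blank cells default to 0 / False with
    a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str})
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    n_defaulted = 0
    records: list[CompoundRecord] = []
    for row in df.to_dict("records"):
        kwargs = {
            "compound_id": str(row["compound_id"]),
            "monoisotopic_mass": float(row["monoisotopic_mass"]),
        }
        for col in _META_STR_DEFAULTS:
            val = row.get(col)
            kwargs[col] = "" if val is None or (isinstance(val, float) and math.isnan(val)) else str(val)
        for col in _META_INT_DEFAULTS:
            val = row.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                if col in df.columns:
                    n_defaulted += 1
                kwargs[col] = 0
            else:
                kwargs[col] = int(val)
        for col in _META_BOOL_DEFAULTS:
            val = row.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                if col in df.columns:
                    n_defaulted += 1
                kwargs[col] = False
            else:
                kwargs[col] = _as_bool(val)
        records.append(CompoundRecord(**kwargs))
    if n_defaulted:
        logger.warning(
            "%s: %d blank metadata cell(s) defaulted to 0/False", path, n_defaulted
        )
    return records


def write_metadata_csv(records: Sequence[CompoundRecord], path) -> None:
    """Write compound records as a metadata CSV (full float precision)."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "inchikey": r.inchikey,
                "formula": r.formula,
                "monoisotopic_mass": _format_float(r.monoisotopic_mass),
                "ds_count": r.ds_count,
                "pubmed_count": r.pubmed_count,
                "pubchem_sources": r.pubchem_sources,
                "norman_susdat": r.norman_susdat,
                "isotope_labeled": r.isotope_labeled,
                "charged": r.charged,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
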