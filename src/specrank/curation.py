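"""Dataset-assembly audit via InChIKey skeleton matching.

Standard InChIKeys have a 14-10-1 hyphenated structure; the first block (the
"skeleton") encodes molecular connectivity without stereochemistry.  Mapping
an input key list against a library by skeleton finds stereo-agnostic hits;
comparing full keys then exposes second-block mismatches (typically
incomplete or differing stereochemistry between the input set and the
library).  Isotopically labelled and charged library forms can be excluded
from the mapping, as they differ in mass/formula from the neutral input;
exclusion is driven by explicit record flags — no structure perception is
performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ValidationError
from .library import CompoundRecord, SpectralLibrary

_BLOCK_PATTERN = re.compile(r"^([A-Z]{14})-([A-Z]{10})-([A-Z])$")


@dataclass
class CurationEntry:
    """Audit outcome for one input InChIKey.

    Exactly one of ``absent`` (no skeleton hits), ``full_match`` (some hit's
    full key equals the input) or ``second_block_mismatch`` (hits exist, none
    matches beyond the first block) is true.
    """

    input_inchikey: str
    skeleton: str
    n_hits: int = 0
    hit_ids: list[str] = field(default_factory=list)
    full_match: bool = False
    second_block_mismatch: bool = False
    absent: bool = False


@dataclass
class CurationSummary:
    """Dataset-level audit counts."""

    n_inputs: int = 0
    n_full_match: int = 0
    n_second_block_mismatch: int = 0
    n_absent: int = 0
    n_multiple_hit: int = 0


def validate_inchikey(key: str) -> str:
    """Validate and standardise an InChIKey string.

    Accepts the 27-character 14-10-1 hyphenated uppercase pattern,
    normalising case and surrounding whitespace.

    Raises
    ------
    ValidationError
        With a reason, when block lengths or characters are wrong.
    """
    if not isinstance(key, str):
        raise ValidationError(f"InChIKey must be a string, got {type(key).__name__}")
    cleaned = key.strip().upper()
    parts = cleaned.split("-")
    if len(parts) != 3:
        raise ValidationError(
            f"{key!r}: expected three hyphen-separated blocks, got {len(parts)}"
        )
    lengths = tuple(len(p) for p in parts)
    if lengths != (14, 10, 1):
        raise ValidationError(
            f"{key!r}: block lengths {lengths} differ from the standard (14, 10, 1)"
        )
    if not _BLOCK_PATTERN.match(cleaned):
        raise ValidationError(f"{key!r}: blocks must contain only letters A-Z")
    return cleaned


def first_block(key: str) -> str:
    """The 14-character skeleton (characters before the first hyphen)."""
    return validate_inchikey(key)[:14]


def audit_dataset(
    input_keys: Iterable[str],
    library: SpectralLibrary | Sequence[CompoundRecord],
    exclude_isotope_labeled: bool = True,
    exclude_charged: bool = True,
) -> tuple[list[CurationEntry], CurationSummary]:
    """Audit input InChIKeys against a library by skeleton search.

    For each input key, hits are the library records sharing its first
    block, minus records flagged isotope-labelled or charged when the
    corresponding exclusion is on.  Entries are classified as full match,
    second-block mismatch, or absent; the summary gives the dataset-level
    counts (including how many inputs returned multiple hits).
    """
    records = (
        list(library.records.values())
        if isinstance(library, SpectralLibrary)
        else list(library)
    )
    by_skeleton: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        if not rec.inchikey:
            continue
        if exclude_isotope_labeled and rec.isotope_labeled:
            continue
        if exclude_charged and rec.charged:
            continue
        by_skeleton.setdefault(rec.inchikey[:14], []).append(rec)

    entries: list[CurationEntry] = []
    summary = CurationSummary()
    for raw_key in input_keys:
        key = validate_inchikey(raw_key)
        skeleton = key[:14]
        hits = sorted(by_skeleton.get(skeleton, []), key=lambda r: r.compound_id)
        entry = CurationEntry(
            input_inchikey=key,
            skeleton=skeleton,
            n_hits=len(hits),
            hit_ids=[r.compound_id for r in hits],
        )
        if not hits:
            entry.absent = True
        elif any(r.inchikey == key for r in hits):
            entry.full_match = True
        else:
            entry.second_block_mismatch = True
        entries.append(entry)
        summary.n_inputs += 1
        summary.n_full_match += entry.full_match
        summary.n_second_block_mismatch += entry.second_block_mismatch
        summary.n_absent += entry.absent
        summary.n_multiple_hit += entry.n_hits > 1
    return entries, summary
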