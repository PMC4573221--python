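"""Reading per-sample KO annotation profiles from files.

An annotation profile is the tabular output of read-level functional
annotation: one row per (read, reference-sequence) alignment hit, with the
alignment e-value and the KO identifiers attached to the reference
sequence.  The dialect here is a frozen minimal 4-column TSV — exactly the
fields the downstream abundance math needs — rather than an emulation of
any particular annotation service's download format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

ANNOTATION_HEADER = ("read_id", "subject_id", "e_value", "ko_ids")


@dataclass(frozen=True)
class AnnotationRecord:
    """One read -> reference-sequence hit.

    ``ko_ids`` is the ordered, deduplicated tuple of KO identifiers
    annotating the subject (a subject annotated twice with the same KO is
    one annotation); it is nonempty — KO-less rows are dropped at read time.
    """

    read_id: str
    subject_id: str
    e_value: float
    ko_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(
                f"record {self.read_id}/{self.subject_id}: negative e-value"
            )
        if not self.ko_ids:
            raise ValidationError(
                f"record {self.read_id}/{self.subject_id}: empty ko_ids"
            )


@dataclass
class AnnotationProfile:
    """All annotation records of one sample.

    ``n_dropped_no_ko`` counts data rows discarded because their KO field
    was empty (the KO filtering step); ``n_dropped_e_value`` counts rows
    discarded by an optional e-value ceiling.  Retained records plus both
    drop counts equal the number of data rows in the source file.
    """

    sample_id: str
    records: list[AnnotationRecord] = field(default_factory=list)
    n_dropped_no_ko: int = 0
    n_dropped_e_value: int = 0

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be nonempty")


def _dedup_preserve(items: Iterable[str]) -> tuple[str, ...]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x not in seen:
            seen.add(x)
            out.append(x)
    return tuple(out)


def read_annotation_profile(
    path: str | Path,
    sample_id: str,
    max_e_value: float | None = None,
) -> AnnotationProfile:
    """Read one sample's annotation profile.

    The dialect is tab-separated UTF-8 with header
    ``read_id<TAB>subject_id<TAB>e_value<TAB>ko_ids``; ``ko_ids`` is
    semicolon-separated and may be empty (such rows are dropped and
    counted).  E-values are parsed as floats (scientific notation
    accepted).  ``max_e_value``, when given, drops hits with a larger
    e-value; by default no cutoff is applied.

    Raises
    ------
    ParseError
        Wrong column count or unparseable/negative e-value, with line number.
    ValidationError
        Duplicate (read_id, subject_id) pair.
    """
    path = Path(path)
    records: list[AnnotationRecord] = []
    dropped_no_ko = 0
    dropped_e = 0
    seen_pairs: set[tuple[str, str]] = set()
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ANNOTATION_HEADER:
            raise FormatError(
                f"{path}: bad annotation header {header!r}; "
                f"expected {list(ANNOTATION_HEADER)}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(cols)}")
            read_id, subject_id, e_str, ko_str = cols
            try:
                e_value = float(e_str)
            except ValueError:
                raise ParseError(path, lineno, f"unparseable e-value {e_str!r}") from None
            if e_value < 0:
                raise ParseError(path, lineno, f"negative e-value {e_str!r}")
            key = (read_id, subject_id)
            if key in seen_pairs:
                raise ValidationError(
                    f"{path}: duplicate (read_id, subject_id) pair {key!r}"
                )
            seen_pairs.add(key)
            ko_ids = _dedup_preserve(t.strip() for t in ko_str.split(";") if t.strip())
            if not ko_ids:
                dropped_no_ko += 1
                continue
            if max_e_value is not None and e_value > max_e_value:
                dropped_e += 1
                continue
            records.append(AnnotationRecord(read_id, subject_id, e_value, ko_ids))
    if dropped_no_ko:
        logger.info(
            "%s: dropped %d rows without KO annotation", sample_id, dropped_no_ko
        )
    if dropped_e:
        logger.info(
            "%s: dropped %d rows above e-value %g", sample_id, dropped_e, max_e_value
        )
    return AnnotationProfile(
        sample_id=sample_id,
        records=records,
        n_dropped_no_ko=dropped_no_ko,
        n_dropped_e_value=dropped_e,
    )


def write_annotation_profile(profile: AnnotationProfile, path: str | Path) -> None:
    """Write a profile in the dialect read by :func:`read_annotation_profile`.

    E-values are formatted with ``%.12g`` so that re-reading reproduces the
    parsed floats exactly (tied e-values stay byte-identical in the file).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for rec in profile.records:
            fh.write(
                f"{rec.read_id}\t{rec.subject_id}\t{rec.e_value:.12g}\t"
                + ";".join(rec.ko_ids)
                + "\n"
            )
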