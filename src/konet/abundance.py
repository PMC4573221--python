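"""Enzymatic-gene abundance estimation from annotation profiles.

Each sequencing read contributes total weight 1, distributed by two
even-split guidelines:

1. a read matching a single reference sequence annotated with several KOs
   splits its count evenly between those KOs;
2. a read matching several reference sequences at the same (best) e-value
   splits its count evenly between the KOs of all tied references.

Hits worse than the read's best e-value are discarded; KOs pooled across
tied subjects are deduplicated before splitting, so a KO present on two
tied subjects gets one share.  Relative abundances divide each sample's
per-KO counts by the sample's total split-weight mass (the number of
KO-assigned reads), which normalizes away sequencing depth and makes each
nonzero row sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import AnnotationProfile
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: relative tolerance for "the same e-value" — annotation services print
#: rounded exponents, so parsed floats that agree to 1e-9 are tied
E_VALUE_RTOL = 1e-9


@dataclass
class AbundanceTable:
    """Samples x KOs count and relative-abundance matrices.

    ``counts[s, k]`` is the (possibly fractional) split-weight of KO ``k``
    in sample ``s``; ``relative`` is the row-normalized version (all-zero
    rows stay zero).  ``state_labels`` optionally maps each sample to a
    biological state for two-group comparisons.
    """

    sample_ids: list[str]
    ko_ids: list[str]
    counts: np.ndarray
    relative: np.ndarray
    state_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.relative = np.asarray(self.relative, dtype=float)
        ns, nk = len(self.sample_ids), len(self.ko_ids)
        if self.counts.shape != (ns, nk) or self.relative.shape != (ns, nk):
            raise ValidationError(
                f"matrix shape {self.counts.shape} does not match "
                f"{ns} samples x {nk} KOs"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        if self.state_labels is not None:
            missing = set(self.sample_ids) - set(self.state_labels)
            if missing:
                raise ValidationError(f"state_labels missing samples: {sorted(missing)}")

    @classmethod
    def from_counts(
        cls,
        sample_ids: Sequence[str],
        ko_ids: Sequence[str],
        counts: np.ndarray,
        state_labels: Mapping[str, str] | None = None,
    ) -> "AbundanceTable":
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            relative = np.where(totals > 0, counts / np.where(totals > 0, totals, 1), 0.0)
        return cls(
            sample_ids=list(sample_ids),
            ko_ids=list(ko_ids),
            counts=counts,
            relative=relative,
            state_labels=dict(state_labels) if state_labels is not None else None,
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValidationError(f"unknown sample_id {sample_id!r}") from None

    def samples_in_state(self, state: str) -> list[int]:
        if self.state_labels is None:
            raise ValidationError("table has no state labels")
        return [
            i for i, s in enumerate(self.sample_ids) if self.state_labels[s] == state
        ]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.ko_ids)

    def relative_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.relative, index=self.sample_ids, columns=self.ko_ids)


def estimate_abundance(profile: AnnotationProfile) -> dict[str, float]:
    """Per-KO split-weight counts for one sample.

    For each read: keep only the hits whose e-value ties the read's minimum
    (relative tolerance ``E_VALUE_RTOL``), pool the unique KO ids across
    the kept hits, and give each pooled KO ``1/n_pooled``.  Every read with
    at least one KO-annotated hit thus contributes exactly weight 1.
    """
    by_read: dict[str, list] = {}
    for rec in profile.records:
        by_read.setdefault(rec.read_id, []).append(rec)

    counts: dict[str, float] = {}
    for recs in by_read.values():
        e_min = min(r.e_value for r in recs)
        cutoff = e_min * (1.0 + E_VALUE_RTOL)
        pooled: list[str] = []
        seen: set[str] = set()
        for r in recs:
            if r.e_value <= cutoff:
                for ko in r.ko_ids:
                    if ko not in seen:
                        seen.add(ko)
                        pooled.append(ko)
        if not pooled:
            continue
        w = 1.0 / len(pooled)
        for ko in pooled:
            counts[ko] = counts.get(ko, 0.0) + w
    return counts


def build_abundance_table(
    profiles: Sequence[AnnotationProfile],
    state_labels: Mapping[str, str] | None = None,
) -> AbundanceTable:
    """Assemble per-sample count maps into a samples x KOs table.

    The KO axis is the sorted union over samples (absent KOs count 0);
    relative abundances are the row normalization of counts.  Samples with
    no KO-assigned reads keep an all-zero row and are reported with a
    warning.
    """
    sample_ids = [p.sample_id for p in profiles]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"duplicate sample_ids: {dupes}")

    per_sample = [estimate_abundance(p) for p in profiles]
    ko_ids = sorted(set().union(*per_sample)) if per_sample else []
    ko_index = {k: j for j, k in enumerate(ko_ids)}

    counts = np.zeros((len(sample_ids), len(ko_ids)))
    for i, cmap in enumerate(per_sample):
        for ko, w in cmap.items():
            counts[i, ko_index[ko]] = w

    for i, s in enumerate(sample_ids):
        if counts[i].sum() == 0:
            logger.warning("sample %s has no KO-annotated reads (all-zero row)", s)

    return AbundanceTable.from_counts(sample_ids, ko_ids, counts, state_labels)
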