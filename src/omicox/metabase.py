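"""Merge filtered single-source matrices into one MERGE metabase.

Feature ids are prefixed with their source tag (``EXPR:``, ``MIRNA:``,
``CNA:``, ``MUT:``) so that source attribution of selected features is
lossless and two sources may share a raw feature name.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import SOURCES, OmicsMatrix, ValidationError

PREFIX_SEP = ":"


def tag(source: str, feature_id: str) -> str:
    return f"{source}{PREFIX_SEP}{feature_id}"


def split_tag(feature_id: str) -> tuple:
    """(source, raw id) of a prefixed feature id; raises on untagged ids."""
    source, sep, raw = feature_id.partition(PREFIX_SEP)
    if not sep or source not in SOURCES:
        raise ValidationError(f"feature id {feature_id!r} carries no source tag")
    return source, raw


def gene_of(feature_id: str) -> str:
    """Raw feature name with any source prefix stripped (network lookup)."""
    source, sep, raw = feature_id.partition(PREFIX_SEP)
    return raw if sep and source in SOURCES else feature_id


@dataclass
class MergedMatrix:
    """Row-concatenation of the filtered sources over common patients."""

    df: pd.DataFrame  # features x patients, source-prefixed index
    source = "MERGE"

    @property
    def feature_ids(self) -> list:
        return list(self.df.index)

    @property
    def patient_ids(self) -> list:
        return list(self.df.columns)

    @property
    def values(self):
        return self.df.to_numpy(dtype=float)

    def source_of(self, feature_id: str) -> str:
        return split_tag(feature_id)[0]

    def subset_patients(self, patient_ids) -> "MergedMatrix":
        return MergedMatrix(self.df[list(patient_ids)])

    def project(self, source: str) -> OmicsMatrix:
        """Recover one source's matrix (raw feature ids) from the metabase."""
        rows = [f for f in self.df.index if f.startswith(source + PREFIX_SEP)]
        sub = self.df.loc[rows].copy()
        sub.index = [split_tag(f)[1] for f in rows]
        return OmicsMatrix(source, sub)


def build_metabase(filtered: dict) -> MergedMatrix:
    """Stack filtered matrices; all inputs must share one patient order."""
    if not filtered:
        raise ValidationError("no matrices to merge")
    orders = [tuple(m.patient_ids) for m in filtered.values()]
    if len(set(orders)) != 1:
        raise ValidationError("patient orders differ between sources")
    parts = []
    for source in SOURCES:
        if source not in filtered:
            continue
        m = filtered[source]
        part = m.df.copy()
        part.index = [tag(source, f) for f in m.feature_ids]
        parts.append(part)
    return MergedMatrix(pd.concat(parts, axis=0))
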