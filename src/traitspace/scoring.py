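"""Keyed scoring, subject filtering, standardization and trait totals.

The scoring pipeline is: raw responses -> :func:`apply_key` (reverse-keying,
graded/binary modes, range validation) -> :func:`exclude_subjects` ->
:func:`zscore_columns` / :func:`score_traits`.

Responses live in a :class:`ResponseMatrix`: a subjects x items integer
DataFrame plus per-subject metadata (age, sex, exclusion flag and reason).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import QuestionnaireSchema

__all__ = [
    "ResponseMatrix",
    "ZScoreMatrix",
    "TraitScoreTable",
    "ScoringError",
    "apply_key",
    "exclude_subjects",
    "zscore_columns",
    "score_traits",
    "load_responses",
]

log = logging.getLogger(__name__)

METADATA_COLUMNS = ("age", "sex", "excluded", "exclusion_reason")


class ScoringError(ValueError):
    pass


@dataclass
class ResponseMatrix:
    """Subjects x items integer scores plus subject metadata.

    ``values`` is indexed by subject id with one column per item id;
    ``metadata`` shares the index and carries at least the columns
    ``age``, ``sex``, ``excluded`` and ``exclusion_reason``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.metadata.index):
            raise ScoringError("values and metadata must share the subject index")
        if self.values.isna().any().any():
            raise ScoringError("response matrix contains missing values")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def items(self) -> pd.Index:
        return self.values.columns

    def to_csv(self, path: str | Path) -> None:
        pd.concat([self.metadata[list(METADATA_COLUMNS)], self.values], axis=1).to_csv(
            path, index_label="subject"
        )


@dataclass
class ZScoreMatrix:
    """Column-standardized scores; each column has mean 0 and sample sd 1."""

    values: pd.DataFrame
    source: ResponseMatrix | None = field(default=None, repr=False)


@dataclass
class TraitScoreTable:
    """Per-subject trait totals and subdomain totals.

    ``traits`` has one column per trait; ``subdomains`` one column per
    ``"trait:subdomain"`` pair.  Totals follow each instrument's scoring
    rule (sum or mean of keyed item scores).
    """

    traits: pd.DataFrame
    subdomains: pd.DataFrame


def load_responses(
    path: str | Path,
    *,
    missing: str = "error",
) -> ResponseMatrix:
    """Load a responses CSV (one row per subject, item-id header + metadata columns).

    ``missing='error'`` rejects any row with a missing item response;
    ``missing='drop'`` removes such rows (listwise deletion) with a log entry.
    Silent imputation is deliberately not offered: it would distort the
    correlation structure every downstream stage depends on.
    """
    df = pd.read_csv(path, index_col="subject")
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    meta = df[meta_cols].copy()
    for col in METADATA_COLUMNS:
        if col not in meta:
            meta[col] = False if col == "excluded" else None
    meta["excluded"] = meta["excluded"].fillna(False).astype(bool)
    values = df.drop(columns=meta_cols)
    incomplete = values.isna().any(axis=1)
    if incomplete.any():
        if missing == "drop":
            log.info("dropping %d subjects with missing responses", int(incomplete.sum()))
            values, meta = values.loc[~incomplete], meta.loc[~incomplete]
        else:
            bad = values.index[incomplete].tolist()
            raise ScoringError(f"missing responses for subjects {bad[:5]}{'...' if len(bad) > 5 else ''}")
    return ResponseMatrix(values.astype(int), meta)


def apply_key(
    raw: pd.DataFrame,
    schema: QuestionnaireSchema,
    *,
    metadata: pd.DataFrame | None = None,
    binary_mode: bool = False,
) -> ResponseMatrix:
    """Apply the scoring key: reverse-keyed items become ``min + max - v``.

    Raw responses must lie within each item's declared scale range.
    Instruments declaring ``alt_scoring='binary'`` (the autism quotient)
    are scored on their graded range by default; with ``binary_mode=True``
    their responses collapse to 0/1 (agree-side of the scale scores 1
    after reverse-keying).

    Raises
    ------
    ScoringError
        If a response is out of range (naming subject, item and value) or
        an item id is unknown to the schema.
    """
    unknown = set(raw.columns) - set(schema.item_ids)
    if unknown:
        raise ScoringError(f"unknown item ids in responses: {sorted(unknown)[:5]}")
    out = raw.copy()
    for inst in schema.instruments:
        lo, hi = inst.scale
        present = [it for it in inst.items if it.id in out.columns]
        for it in present:
            col = out[it.id]
            bad = (col < lo) | (col > hi)
            if bad.any():
                subj = col.index[bad][0]
                raise ScoringError(
                    f"response {col.loc[subj]} out of range [{lo}, {hi}] "
                    f"for subject {subj!r}, item {it.id!r}"
                )
            if it.reverse:
                out[it.id] = lo + hi - col
        if binary_mode and inst.alt_scoring == "binary":
            mid = (lo + hi) / 2.0
            for it in present:
                out[it.id] = (out[it.id] > mid).astype(int)
    if metadata is None:
        metadata = pd.DataFrame(
            {"age": np.nan, "sex": None, "excluded": False, "exclusion_reason": None},
            index=out.index,
        )
    return ResponseMatrix(out, metadata)


def exclude_subjects(rm: ResponseMatrix, policy: set[str] | None = None) -> ResponseMatrix:
    """Drop flagged subjects; ``policy`` optionally restricts to given reasons.

    With ``policy=None`` every subject with ``excluded=True`` is dropped
    (the study's default: participants reporting mental or brain-related
    problems).  Counts per exclusion reason are logged.
    """
    flagged = rm.metadata["excluded"].astype(bool)
    if policy is not None:
        flagged = flagged & rm.metadata["exclusion_reason"].isin(policy)
    counts = rm.metadata.loc[flagged, "exclusion_reason"].value_counts(dropna=False)
    for reason, n in counts.items():
        log.info("excluding %d subjects (reason=%s)", n, reason)
    keep = ~flagged
    if not keep.any():
        raise ScoringError("exclusion policy removed every subject")
    return ResponseMatrix(rm.values.loc[keep].copy(), rm.metadata.loc[keep].copy())


def zscore_columns(rm: ResponseMatrix | pd.DataFrame) -> ZScoreMatrix:
    """Standardize each item across subjects: ``(v - mean) / sd`` with sample sd (n-1)."""
    df = rm.values if isinstance(rm, ResponseMatrix) else rm
    sd = df.std(axis=0, ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        raise ScoringError(f"constant column(s), cannot z-score: {constant[:5]}")
    z = (df - df.mean(axis=0)) / sd
    return ZScoreMatrix(z, rm if isinstance(rm, ResponseMatrix) else None)


def score_traits(rm: ResponseMatrix, schema: QuestionnaireSchema) -> TraitScoreTable:
    """Per-subject trait totals and subdomain totals per the instrument scoring rule."""
    missing = set(schema.item_ids) - set(rm.items)
    if missing:
        raise ScoringError(f"responses missing schema items: {sorted(missing)[:5]}")
    traits = {}
    subs = {}
    for inst in schema.instruments:
        block = rm.values[list(inst.item_ids)]
        agg = block.mean(axis=1) if inst.scoring == "mean" else block.sum(axis=1)
        traits[inst.trait] = agg
        for sd_name in inst.subdomains:
            ids = [it.id for it in inst.subdomain_items(sd_name)]
            sub_block = rm.values[ids]
            subs[f"{inst.trait}:{sd_name}"] = (
                sub_block.mean(axis=1) if inst.scoring == "mean" else sub_block.sum(axis=1)
            )
    return TraitScoreTable(pd.DataFrame(traits), pd.DataFrame(subs, index=rm.subjects))
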