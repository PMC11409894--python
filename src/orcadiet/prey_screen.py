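"""Sample- and species-level screening rules for diet count tables.

Three rules applied between calibration and the diet statistics:

* replicate deduplication — among biological/technical replicates of one
  sample, keep only the member with the highest total read count;
* prey classification — a species is *major* prey when it exceeds 1% of
  reads (strictly) in at least 4 samples, *minor* when it does so in 1–3
  samples, and *excluded* otherwise;
* table filtering — restrict the table to a label class (major by default),
  dropping samples left with zero retained reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from orcadiet.errors import EmptyResultError

__all__ = [
    "PreyClassification",
    "dedupe_replicates",
    "classify_prey",
    "filter_table",
]

logger = logging.getLogger(__name__)

MAJOR_MIN_SUPPORT = 4
PRESENCE_THRESHOLD = 0.01


@dataclass
class PreyClassification:
    """Per-species prey labels with their supporting sample counts.

    ``support`` counts samples in which the species exceeds the presence
    threshold (strictly); labels partition the species set:
    major (support ≥ 4), minor (support 1–3), excluded (support 0).
    """

    labels: pd.Series
    support: pd.Series
    threshold: float = PRESENCE_THRESHOLD

    def __post_init__(self) -> None:
        expected = pd.Series("excluded", index=self.support.index)
        expected[self.support >= 1] = "minor"
        expected[self.support >= MAJOR_MIN_SUPPORT] = "major"
        if not self.labels.equals(expected):
            raise ValueError("labels inconsistent with support counts")

    def species(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels, "n_samples": self.support})


def _replicate_groups(metadata: pd.DataFrame) -> pd.Series:
    """Connected-component replicate groups from metadata.

    Samples are linked when they share a declared technical-replicate group,
    or when they share individual *and* date (biological replicates).  Uses
    union-find over the sample index.
    """
    samples = list(metadata.index)
    parent = {s: s for s in samples}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    def link_by(key: pd.Series) -> None:
        valid = key[key.notna() & (key.astype(str) != "")]
        for _, members in valid.groupby(valid):
            ids = list(members.index)
            for other in ids[1:]:
                union(ids[0], other)

    if "replicate_group" in metadata:
        link_by(metadata["replicate_group"])
    if "individual" in metadata and "date" in metadata:
        ok = metadata["individual"].notna() & metadata["date"].notna()
        ok &= (metadata["individual"].astype(str) != "") & (
            metadata["date"].astype(str) != ""
        )
        key = (
            metadata.loc[ok, "individual"].astype(str)
            + "@"
            + metadata.loc[ok, "date"].astype(str)
        )
        link_by(key)
    return pd.Series({s: find(s) for s in samples}, name="replicate_root")


def dedupe_replicates(table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate groups, keeping the highest-read-count member.

    Replicates are samples sharing a declared ``replicate_group`` or the
    same ``individual`` and ``date``.  Ties (and all-zero groups, which are
    logged) are broken toward the lexicographically smallest sample ID.
    """
    meta = metadata.reindex(table.index)
    groups = _replicate_groups(meta)
    totals = table.sum(axis=1)
    keep = []
    for _, members in sorted(groups.groupby(groups)):
        ids = sorted(members.index)
        top = max(totals[s] for s in ids)
        tied = [s for s in ids if totals[s] == top]
        best = tied[0]
        if top == 0 and len(ids) > 1:
            logger.warning(
                "replicate group %s has all-zero totals; keeping %s", ids, best
            )
        keep.append(best)
    return table.loc[sorted(keep)]


def classify_prey(
    table: pd.DataFrame, threshold: float = PRESENCE_THRESHOLD
) -> PreyClassification:
    """Classify species as major / minor / excluded prey.

    Support = number of samples where the species' share of the sample's
    reads strictly exceeds ``threshold`` (default 1%).  Classification is
    depth-invariant because it is computed on per-sample proportions.
    """
    if len(table) == 0:
        raise EmptyResultError("cannot classify prey on an empty table")
    totals = table.sum(axis=1)
    nonzero = table.loc[totals > 0]
    props = nonzero.div(nonzero.sum(axis=1), axis=0)
    support = (props > threshold).sum(axis=0).astype(int)
    labels = pd.Series("excluded", index=table.columns)
    labels[support >= 1] = "minor"
    labels[support >= MAJOR_MIN_SUPPORT] = "major"
    return PreyClassification(labels=labels, support=support, threshold=threshold)


def filter_table(
    table: pd.DataFrame,
    classification: PreyClassification,
    keep: tuple[str, ...] = ("major",),
) -> pd.DataFrame:
    """Restrict a count table to species with the given labels.

    Samples whose retained total is 0 are dropped (logged); raises
    :class:`EmptyResultError` if nothing survives.  Downstream proportions
    are recomputed over the retained species only.
    """
    cols = [s for s in table.columns if classification.labels.get(s) in keep]
    out = table[cols]
    if len(cols) == 0:
        raise EmptyResultError(f"no species with label(s) {keep}")
    empty = out.sum(axis=1) == 0
    if empty.any():
        logger.warning(
            "dropping %d sample(s) with no reads from retained species: %s",
            int(empty.sum()),
            list(out.index[empty]),
        )
        out = out.loc[~empty]
    if len(out) == 0:
        raise EmptyResultError("all samples dropped by species filter")
    return out


def to_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions over the table's species (rows sum to 1)."""
    totals = table.sum(axis=1)
    if (totals <= 0).any():
        raise EmptyResultError("zero-total samples; filter them first")
    return table.div(totals, axis=0)
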