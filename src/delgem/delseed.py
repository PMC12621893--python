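"""DEL selection-count aggregation and seed selection.

Replicate read counts from a DNA-encoded library selection are converted to
per-replicate enrichments (observed reads over the uniform-sampling
expectation), aggregated across replicates by geometric mean, and ranked to
pick seed compounds. The geometric mean is deliberately harsh on
irreproducible signal: a member with a large count in one replicate but zero
in the other aggregates to zero, which is the desired behaviour for
Poisson-noisy selections.

An optional synthon-level view pools member enrichments over shared building
blocks (mono/di-synthon aggregation) by arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class DELRecord:
    """One library member: replicate counts plus the aggregated enrichment."""

    member_id: str
    counts: tuple[int, ...]
    enrichment: float
    synthon_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.counts) < 1:
            raise ConfigError(f"{self.member_id}: needs >= 1 replicate count")
        if any(c < 0 for c in self.counts):
            raise ConfigError(f"{self.member_id}: negative count")
        if self.enrichment < 0:
            raise ConfigError(f"{self.member_id}: negative enrichment")


def enrichment_per_replicate(count: int, total_reads: int, library_size: int) -> float:
    """Observed/expected read ratio: ``count / (total_reads / library_size)``.

    1.0 means the member was read exactly as often as expected under uniform
    sampling of the library.
    """
    if total_reads <= 0:
        raise ConfigError(f"total_reads must be > 0, got {total_reads}")
    if library_size <= 0:
        raise ConfigError(f"library_size must be > 0, got {library_size}")
    if count < 0:
        raise ConfigError(f"count must be >= 0, got {count}")
    return count / (total_reads / library_size)


def aggregate_replicates(per_replicate: Sequence[float]) -> float:
    """Geometric mean of per-replicate enrichments; 0 if any replicate is 0."""
    if len(per_replicate) == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    vals = np.asarray(per_replicate, dtype=float)
    if np.any(vals < 0):
        raise ConfigError("negative enrichment value")
    if np.any(vals == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def compute_enrichments(
    counts: pd.DataFrame,
    library_size: Optional[int] = None,
    synthon_columns: Sequence[str] = (),
) -> list[DELRecord]:
    """Build :class:`DELRecord`s from a count table.

    ``counts`` must have a ``member_id`` column and one or more
    ``count_rep*`` columns. Per-replicate totals are taken from the table
    itself; ``library_size`` defaults to the number of rows (the usual case
    where the table covers the whole library).
    """
    if "member_id" not in counts.columns:
        raise ConfigError("count table needs a member_id column")
    rep_cols = [c for c in counts.columns if c.startswith("count_rep")]
    if not rep_cols:
        raise ConfigError("count table needs count_rep* columns")
    lib = library_size if library_size is not None else len(counts)
    totals = [int(counts[c].sum()) for c in rep_cols]
    records = []
    for row in counts.itertuples(index=False):
        per_rep = [
            enrichment_per_replicate(int(getattr(row, c)), totals[j], lib)
            for j, c in enumerate(rep_cols)
        ]
        synthons = tuple(str(getattr(row, c)) for c in synthon_columns) or None
        records.append(
            DELRecord(
                member_id=str(row.member_id),
                counts=tuple(int(getattr(row, c)) for c in rep_cols),
                enrichment=aggregate_replicates(per_rep),
                synthon_ids=synthons,
            )
        )
    return records


def select_seeds(records: Sequence[DELRecord], k: int) -> list[DELRecord]:
    """Top-k records by aggregated enrichment, descending.

    Ties break by member_id lexicographic ascending, so selection is fully
    deterministic. ``k`` larger than the record count returns everything,
    sorted.
    """
    if k < 0:
        raise ConfigError(f"k must be >= 0, got {k}")
    ranked = sorted(records, key=lambda r: (-r.enrichment, r.member_id))
    return ranked[:k]


def synthon_enrichment(
    records: Sequence[DELRecord], position: int
) -> pd.DataFrame:
    """Mono-synthon aggregation: mean member enrichment per building block.

    ``position`` indexes into each record's ``synthon_ids``. Returns a table
    ``synthon_id, mean_enrichment, n_members`` sorted by mean descending,
    ties by synthon_id.
    """
    rows: dict[str, list[float]] = {}
    for r in records:
        if r.synthon_ids is None or position >= len(r.synthon_ids):
            raise ConfigError(f"{r.member_id}: no synthon at position {position}")
        rows.setdefault(r.synthon_ids[position], []).append(r.enrichment)
    df = pd.DataFrame(
        [
            {"synthon_id": s, "mean_enrichment": float(np.mean(v)), "n_members": len(v)}
            for s, v in rows.items()
        ]
    )
    return df.sort_values(
        ["mean_enrichment", "synthon_id"], ascending=[False, True]
    ).reset_index(drop=True)


def read_counts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "member_id" not in df.columns:
        raise ConfigError(f"{path}: missing member_id column")
    return df


def write_enrichment_csv(path, records: Sequence[DELRecord]) -> None:
    """Persist ranked enrichments as ``member_id, enrichment, rank``."""
    ranked = select_seeds(records, len(records))
    pd.DataFrame(
        {
            "member_id": [r.member_id for r in ranked],
            "enrichment": [r.enrichment for r in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    ).to_csv(path, index=False)
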