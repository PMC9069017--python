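"""Length/domain filtering, domain trimming, greedy clustering, subsampling.

The retention thresholds mirror the mining workflow: candidates must be at
least 400 residues long and carry at least one hit of 325+ residues
(e-value <= 1e-10) to the Family A polymerase domain superfamily
(cl02626). Retained sequences are trimmed to their longest qualifying
domain hit, clustered greedily at 75% identity with 80% bidirectional
coverage within each (source, 762-class) stratum, and cluster
representatives are subsampled to at most 225 per stratum.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import AlignmentParams, pairwise_align
from .seqio import DomainHit, ProteinRecord

__all__ = [
    "FilterConfig",
    "Stratum",
    "Cluster",
    "filter_length",
    "filter_domain",
    "trim_to_domain",
    "greedy_cluster",
    "stratified_subsample",
]

#: Family A DNA polymerase domain superfamily accession.
POLA_DOMAIN_MODEL = "cl02626"


@dataclass(frozen=True)
class FilterConfig:
    """Retention thresholds; all comparisons are inclusive."""

    min_length: int = 400
    min_hit_span: int = 325
    max_evalue: float = 1e-10
    domain_model: str = POLA_DOMAIN_MODEL

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.min_hit_span <= 0 or self.max_evalue <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True, order=True)
class Stratum:
    """A (source database, 762 class) clustering stratum."""

    source: str
    class762: str

    def __post_init__(self) -> None:
        if self.class762 not in ("F", "L", "Y"):
            raise ValueError(f"stratum class762 must be F, L or Y, got {self.class762!r}")


@dataclass(frozen=True)
class Cluster:
    representative_id: str
    member_ids: tuple[str, ...]
    stratum: Stratum | None = None

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member of its cluster")


def filter_length(
    records: Sequence[ProteinRecord], config: FilterConfig | None = None
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Retain records of at least ``min_length`` residues (inclusive)."""
    config = config or FilterConfig()
    retained = [r for r in records if len(r) >= config.min_length]
    rejected = [r for r in records if len(r) < config.min_length]
    return retained, rejected


def _qualifying_hits(
    hits_by_query: Mapping[str, list[DomainHit]], record: ProteinRecord, config: FilterConfig
) -> list[DomainHit]:
    return [
        h
        for h in hits_by_query.get(record.id, [])
        if h.model_id == config.domain_model
        and h.evalue <= config.max_evalue
        and h.hit_length >= config.min_hit_span
    ]


def _index_hits(
    hits: Sequence[DomainHit], known_ids: set[str]
) -> dict[str, list[DomainHit]]:
    by_query: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        if h.query_id not in known_ids:
            raise ValueError(f"hit references unknown sequence id {h.query_id!r}")
        by_query[h.query_id].append(h)
    return by_query


def filter_domain(
    records: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    config: FilterConfig | None = None,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Retain records with >=1 qualifying hit to the polymerase domain model."""
    config = config or FilterConfig()
    by_query = _index_hits(hits, {r.id for r in records})
    retained, rejected = [], []
    for r in records:
        (retained if _qualifying_hits(by_query, r, config) else rejected).append(r)
    return retained, rejected


def trim_to_domain(
    record: ProteinRecord,
    hits: Sequence[DomainHit],
    config: FilterConfig | None = None,
) -> ProteinRecord:
    """Trim a record to its longest qualifying domain hit.

    Ties on hit length are broken by the smaller start coordinate. Raises
    if the record has no qualifying hit (it should have been filtered out).
    """
    config = config or FilterConfig()
    mine = [
        h
        for h in hits
        if h.query_id == record.id
        and h.model_id == config.domain_model
        and h.evalue <= config.max_evalue
        and h.hit_length >= config.min_hit_span
    ]
    if not mine:
        raise ValueError(f"record {record.id!r} has no qualifying domain hit")
    best = min(mine, key=lambda h: (-h.hit_length, h.query_start))
    if best.query_end > len(record):
        raise ValueError(
            f"hit span {best.query_start}..{best.query_end} exceeds "
            f"record {record.id!r} length {len(record)}"
        )
    return replace(record, residues=record.residues[best.query_start - 1 : best.query_end])


def greedy_cluster(
    records: Sequence[ProteinRecord],
    stratum: Stratum | None = None,
    params: AlignmentParams | None = None,
    min_identity: float = 0.75,
    min_coverage: float = 0.8,
) -> list[Cluster]:
    """Greedy incremental clustering at identity/coverage thresholds.

    Records are sorted by (length descending, id ascending) and processed in
    that order: each joins the first existing representative (in cluster
    creation order) whose local alignment to it reaches ``min_identity``
    with coverage of *both* sequences at least ``min_coverage``; otherwise
    it founds a new cluster. Sorting makes the partition independent of the
    input order.
    """
    params = params or AlignmentParams(mode="local")
    if params.mode != "local":
        raise ValueError("clustering uses local alignments")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        placed = False
        for i, rep in enumerate(reps):
            if rec.id == rep.id:
                continue
            aln = pairwise_align(rep, rec, params)
            if (
                aln.n_columns > 0
                and aln.identity >= min_identity
                and aln.coverage_a >= min_coverage
                and aln.coverage_b >= min_coverage
            ):
                members[i].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec.id])
    return [
        Cluster(representative_id=rep.id, member_ids=tuple(m), stratum=stratum)
        for rep, m in zip(reps, members)
    ]


def stratified_subsample(
    representatives: Mapping[Stratum, Sequence[str]],
    n: int = 225,
    seed: int | None = None,
) -> dict[Stratum, list[str]]:
    """Uniform without-replacement subsample of size min(n, |stratum|) per stratum.

    Strata are visited in sorted order and ids sorted before sampling, so a
    given seed yields the same subsample regardless of platform or input
    ordering. Sampled ids are returned sorted.
    """
    if n <= 0:
        raise ValueError("subsample size must be positive")
    if seed is None:
        raise ValueError("a seed is required for reproducible subsampling")
    rng = np.random.default_rng(seed)
    out: dict[Stratum, list[str]] = {}
    for stratum in sorted(representatives):
        ids = sorted(representatives[stratum])
        if len(ids) <= n:
            out[stratum] = ids
        else:
            chosen = rng.choice(len(ids), size=n, replace=False)
            out[stratum] = sorted(ids[i] for i in chosen)
    return out
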