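"""Reading and writing of sequence and hit-table formats, plus stage accounting.

All coordinates handled here are 1-based and inclusive, matching the
protein-position convention used for active-site residues (e.g. the 762
position in *E. coli* PolA numbering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SOURCES",
    "ProteinRecord",
    "DomainHit",
    "StageLedger",
    "read_fasta",
    "write_fasta",
    "read_hits_table",
    "write_hits_table",
    "ledger_total",
]

#: Recognized sequence provenance labels.
SOURCES = ("refseq", "imgvr", "gov", "serc", "imgm", "uniprot", "synthetic")

_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity codes accepted on input and normalized to X.
_AMBIGUOUS = set("BZJUO")


@dataclass(frozen=True)
class ProteinRecord:
    """A candidate protein sequence with provenance.

    ``residues`` is an upper-case amino-acid string over the 20 canonical
    letters plus X; gap characters are not permitted.
    """

    id: str
    residues: str
    source: str = "synthetic"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be nonempty")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r}: residues must be nonempty")
        bad = set(self.residues) - _CANONICAL - {"X"}
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """One conserved-domain hit on a query protein.

    Coordinates are 1-based inclusive residue positions on the query.
    E-values are consumed from upstream search output (or the synthetic
    generator), never computed here.
    """

    query_id: str
    model_id: str
    evalue: float
    query_start: int
    query_end: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit on {self.query_id!r}: negative e-value")
        if self.query_start < 1 or self.query_end < self.query_start:
            raise ValueError(
                f"hit on {self.query_id!r}: invalid span "
                f"{self.query_start}..{self.query_end}"
            )

    @property
    def hit_length(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass
class StageLedger:
    """Ordered accounting of sequence counts through the filter chain.

    Every stage satisfies input = retained + rejected, and the retained
    count of one stage is the input count of the next. The final stage may
    carry a per-source breakdown of the retained sequences, which is what
    :func:`ledger_total` reports.
    """

    stages: list[dict] = field(default_factory=list)

    def add_stage(
        self,
        name: str,
        n_input: int,
        n_retained: int,
        per_source: Mapping[str, int] | None = None,
    ) -> None:
        if n_retained > n_input or n_retained < 0:
            raise ValueError(f"stage {name!r}: retained {n_retained} of {n_input}")
        if self.stages and n_input != self.stages[-1]["retained"]:
            raise ValueError(
                f"stage {name!r}: input {n_input} != previous retained "
                f"{self.stages[-1]['retained']}"
            )
        if per_source is not None and sum(per_source.values()) != n_retained:
            raise ValueError(f"stage {name!r}: per-source counts do not sum to retained")
        self.stages.append(
            {
                "name": name,
                "input": n_input,
                "retained": n_retained,
                "rejected": n_input - n_retained,
                "per_source": dict(per_source) if per_source else None,
            }
        )

    def to_tsv(self) -> str:
        lines = ["stage\tinput\tretained\trejected"]
        for s in self.stages:
            lines.append(f"{s['name']}\t{s['input']}\t{s['retained']}\t{s['rejected']}")
        return "\n".join(lines) + "\n"


def ledger_total(
    ledger: StageLedger | Mapping[str, int],
) -> tuple[dict[str, int], int]:
    """Per-source retained counts of the final stage and their grand total.

    Accepts either a finalized :class:`StageLedger` whose last stage carries
    a per-source breakdown, or a plain ``{source: count}`` mapping (e.g. the
    printed per-source tree-input counts).
    """
    if isinstance(ledger, StageLedger):
        if not ledger.stages:
            return {}, 0
        per_source = ledger.stages[-1]["per_source"]
        if per_source is None:
            last = ledger.stages[-1]
            return {"all": last["retained"]}, last["retained"]
        return dict(per_source), sum(per_source.values())
    counts = dict(ledger)
    return counts, sum(counts.values())


def _normalize_residues(record_id: str, raw: str) -> str:
    seq = raw.upper().strip("*")
    if "*" in seq:
        raise ValueError(f"record {record_id!r}: internal stop symbol")
    ambiguous = set(seq) & _AMBIGUOUS
    if ambiguous:
        warnings.warn(
            f"record {record_id!r}: non-canonical residues {sorted(ambiguous)} "
            "replaced with X",
            stacklevel=3,
        )
        for ch in ambiguous:
            seq = seq.replace(ch, "X")
    return seq


def read_fasta(path: str | Path, source: str = "synthetic") -> list[ProteinRecord]:
    """Read protein FASTA into :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited header token; the rest of
    the header becomes the description. Residues are upper-cased, terminal
    '*' stop symbols stripped, and ambiguity codes (B, Z, J, U, O) replaced
    with X with a warning. Duplicate ids raise an error naming the id.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            ProteinRecord(
                id=rec.id,
                residues=_normalize_residues(rec.id, str(rec.seq)),
                source=source,
                description=desc,
            )
        )
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, one line per sequence."""
    recs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        _BioSeqIO.write(recs, fh, "fasta-2line")


_HIT_COLUMNS = ("query_id", "model_id", "evalue", "query_start", "query_end")


def read_hits_table(path: str | Path) -> list[DomainHit]:
    """Read a BLAST-tabular-style TSV of conserved-domain hits.

    Expected columns: query_id, model_id, evalue, query_start, query_end
    (a header row with these names is accepted and skipped). Malformed rows
    raise an error naming the 1-based line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[: len(_HIT_COLUMNS)] == list(_HIT_COLUMNS):
                continue
            if len(parts) < 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns, got {len(parts)}")
            qid, mid, ev, qs, qe = parts[:5]
            try:
                evalue = float(ev)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric e-value {ev!r}") from None
            try:
                start, end = int(qs), int(qe)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            try:
                hits.append(DomainHit(qid, mid, evalue, start, end))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return hits


def write_hits_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.model_id}\t{h.evalue:g}\t{h.query_start}\t{h.query_end}\n")
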