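"""Active-site validation and 762-class assignment for PolA candidates.

Candidate sequences are validated PASV-style: each query is globally
aligned to the *E. coli* PolA reference and the residues aligned to the
catalytic anchors R688, D705, K758 and to the variable 762 position
(*E. coli* numbering) are extracted. A query passes when all three
catalytic anchors are intact and position 762 carries phenylalanine,
leucine or tyrosine; the 762 residue defines its class.

The packaged reference is a synthetic stand-in for *E. coli* K12 PolA
(it carries the correct anchor residues at the correct coordinates but
not the natural sequence); any reference with the anchors in place can
be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import AlignmentParams, map_reference_position, pairwise_align
from .seqio import ProteinRecord, StageLedger

__all__ = [
    "ANCHOR_POSITIONS",
    "REQUIRED_RESIDUES",
    "SignatureScheme",
    "SignatureResult",
    "load_reference",
    "default_scheme",
    "extract_signature",
    "classify_batch",
    "write_signature_report",
]

#: Anchor positions in *E. coli* PolA numbering (ordered).
ANCHOR_POSITIONS = (688, 705, 758, 762)

#: Residues accepted at each anchor.
REQUIRED_RESIDUES: Mapping[int, frozenset[str]] = {
    688: frozenset("R"),
    705: frozenset("D"),
    758: frozenset("K"),
    762: frozenset("FLY"),
}

#: 762 classes that validate a candidate.
PASSING_CLASSES = ("F", "L", "Y")


@dataclass(frozen=True)
class SignatureScheme:
    """Reference sequence plus the anchor positions and accepted residues."""

    reference: ProteinRecord
    anchor_positions: tuple[int, ...] = ANCHOR_POSITIONS
    required: Mapping[int, frozenset[str]] = field(
        default_factory=lambda: dict(REQUIRED_RESIDUES)
    )
    #: Queries whose global alignment score to the reference is at or below
    #: this floor are rejected even if the anchors match, guarding against
    #: chance anchor coincidence in unrelated sequences.
    min_score: float = 0.0

    def __post_init__(self) -> None:
        if list(self.anchor_positions) != sorted(set(self.anchor_positions)):
            raise ValueError("anchor positions must be strictly increasing")
        for pos in self.anchor_positions:
            if not (1 <= pos <= len(self.reference)):
                raise ValueError(f"anchor {pos} outside reference length {len(self.reference)}")


@dataclass(frozen=True)
class SignatureResult:
    """Anchor residues of one query in reference numbering, plus verdict."""

    query_id: str
    residues: Mapping[int, str]  # position -> residue letter or "gap"
    passes: bool
    class762: str  # one of F, L, Y, other, gap
    alignment_score: float


def load_reference() -> ProteinRecord:
    """The packaged synthetic *E. coli* K12 PolA stand-in (928 aa)."""
    data = resources.files("polascreen").joinpath(
        "data/synthetic_pola_reference.fasta"
    ).read_text()
    lines = data.splitlines()
    header = lines[0][1:]
    rec_id = header.split()[0]
    residues = "".join(lines[1:])
    return ProteinRecord(
        id=rec_id,
        residues=residues,
        source="uniprot",
        description=header[len(rec_id):].strip(),
    )


def default_scheme() -> SignatureScheme:
    return SignatureScheme(reference=load_reference())


def extract_signature(
    query: ProteinRecord,
    scheme: SignatureScheme | None = None,
    params: AlignmentParams | None = None,
) -> SignatureResult:
    """Extract anchor residues from one query and assign its verdict.

    The reference is globally aligned to the query; each anchor position is
    mapped through the alignment and the query residue there recorded
    (``"gap"`` if the anchor sits opposite a gap — a missing catalytic
    residue can never validate).
    """
    scheme = scheme or default_scheme()
    params = params or AlignmentParams()
    aln = pairwise_align(scheme.reference, query, params)
    residues: dict[int, str] = {}
    for pos in scheme.anchor_positions:
        qpos = map_reference_position(aln, pos)
        residues[pos] = "gap" if qpos is None else query.residues[qpos - 1]
    passes = aln.score > scheme.min_score and all(
        residues[pos] in scheme.required[pos] for pos in scheme.anchor_positions
    )
    res762 = residues.get(762, "gap")
    if res762 == "gap":
        class762 = "gap"
    elif res762 in PASSING_CLASSES:
        class762 = res762
    else:
        class762 = "other"
    return SignatureResult(
        query_id=query.id,
        residues=residues,
        passes=passes,
        class762=class762,
        alignment_score=aln.score,
    )


def classify_batch(
    queries: Sequence[ProteinRecord],
    scheme: SignatureScheme | None = None,
    params: AlignmentParams | None = None,
    ledger: StageLedger | None = None,
) -> tuple[list[SignatureResult], list[SignatureResult], dict[str, int]]:
    """Classify a batch of queries; returns (retained, rejected, class counts).

    Classification is per-sequence, so the partition is independent of the
    input order. Counts are keyed by 762 class over the retained sequences.
    """
    ids = [q.id for q in queries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate query ids in batch")
    scheme = scheme or default_scheme()
    retained: list[SignatureResult] = []
    rejected: list[SignatureResult] = []
    for q in queries:
        res = extract_signature(q, scheme, params)
        (retained if res.passes else rejected).append(res)
    counts: dict[str, int] = {c: 0 for c in PASSING_CLASSES}
    for r in retained:
        counts[r.class762] += 1
    if ledger is not None:
        ledger.add_stage("signature_screen", len(queries), len(retained))
    return retained, rejected, counts


def write_signature_report(
    results: Iterable[SignatureResult], path: str | Path
) -> None:
    """TSV report: query_id, the four anchor residues, verdict and class."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\tresidue688\tresidue705\tresidue758\tresidue762\tpasses\tclass762\n"
        )
        for r in results:
            fh.write(
                f"{r.query_id}\t{r.residues[688]}\t{r.residues[705]}\t"
                f"{r.residues[758]}\t{r.residues[762]}\t{r.passes}\t{r.class762}\n"
            )
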