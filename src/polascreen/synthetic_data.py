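"""Synthetic sequence families, hit tables and contigs with planted truth.

The generator emulates the structure of a PolA mining run: clades of
homologous sequences evolved from the packaged reference with planted 762
residues and protected catalytic anchors, decoy sequences engineered to
fail exactly one pipeline stage, matching domain-hit tables, and
polA-bearing contigs whose helicase neighbors follow per-class
association probabilities. Every generated item is covered by a truth
table so recovery can be checked stage by stage.

E-values in generated hit tables are fixed constants keyed to the truth
(they are consumed metadata, not modeled quantities), and substitutions
are drawn uniformly over the 19 alternative residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .neighborhood import HELICASE_CLASSES, ContigAnnotation, Orf
from .seqio import DomainHit, ProteinRecord
from .signature import ANCHOR_POSITIONS, load_reference

__all__ = [
    "FamilySpec",
    "SequenceTruth",
    "ContigTruth",
    "TruthTable",
    "generate_family",
    "generate_contigs",
    "generate_contigs_from_assignments",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: E-values planted in generated hit tables.
PASSING_EVALUE = 1e-50
FAILING_EVALUE = 1e-5

#: Reference window (1-based, inclusive) kept free of indels so planted
#: anchors stay recoverable by alignment; substitutions elsewhere are free.
_ANCHOR_WINDOW = (660, 790)

_HELICASE_PRODUCTS = {
    "gp4": "gp4 ring-shaped replicative DNA helicase",
    "DnaB": "DnaB-like replicative helicase",
    "SNF2": "SNF2 helicase-associated protein",
    "UvrD": "UvrD-like DNA helicase",
    "RecBD": "RecB/RecD type helicase",
}


@dataclass(frozen=True)
class FamilySpec:
    """Planted structure of a synthetic PolA family.

    Divergences are expected substitutions per site. ``clade_class762``
    assigns one of F/L/Y to each clade. Decoy counts plant sequences that
    must fail exactly one stage: ``short`` (< 400 aa, anchors intact),
    ``no_domain`` (no qualifying domain hit), ``bad_anchor`` (a catalytic
    anchor mutated), ``random`` (unrelated sequence).
    """

    seed: int
    n_clades: int = 3
    seqs_per_clade: int | tuple[int, ...] = 10
    clade_class762: tuple[str, ...] = ("F", "L", "Y")
    within_divergence: float = 0.03
    between_divergence: float = 0.35
    anchor_mutation_prob: float = 0.0
    indel_rate: float = 0.002
    indel_mean_length: float = 3.0
    decoys: Mapping[str, int] = field(
        default_factory=lambda: {"short": 0, "no_domain": 0, "bad_anchor": 0, "random": 0}
    )

    def __post_init__(self) -> None:
        if self.n_clades < 1:
            raise ValueError("need at least one clade")
        if len(self.clade_class762) != self.n_clades:
            raise ValueError("clade_class762 must assign a class to every clade")
        if isinstance(self.seqs_per_clade, tuple):
            if len(self.seqs_per_clade) != self.n_clades:
                raise ValueError("seqs_per_clade tuple must have one entry per clade")
            if any(s < 1 for s in self.seqs_per_clade):
                raise ValueError("clade sizes must be positive")
        elif self.seqs_per_clade < 1:
            raise ValueError("clade sizes must be positive")
        if any(c not in "FLY" for c in self.clade_class762):
            raise ValueError("clade classes must be F, L or Y")
        for v in (self.within_divergence, self.between_divergence):
            if not (0 <= v < 1):
                raise ValueError("divergences must be in [0, 1)")
        if not (0 <= self.anchor_mutation_prob <= 1):
            raise ValueError("anchor_mutation_prob must be in [0, 1]")
        unknown = set(self.decoys) - {"short", "no_domain", "bad_anchor", "random"}
        if unknown:
            raise ValueError(f"unknown decoy modes {sorted(unknown)}")

    @property
    def clade_sizes(self) -> tuple[int, ...]:
        if isinstance(self.seqs_per_clade, tuple):
            return self.seqs_per_clade
        return (self.seqs_per_clade,) * self.n_clades


@dataclass(frozen=True)
class SequenceTruth:
    seq_id: str
    clade: int | None
    class762: str | None
    anchors_intact: bool
    #: None for sequences meant to survive; otherwise the stage at which
    #: the sequence must be rejected ("signature", "length", "domain").
    expected_fail_stage: str | None


@dataclass(frozen=True)
class ContigTruth:
    contig_id: str
    class762: str
    helicase: str | None
    offset: int | None


@dataclass
class TruthTable:
    sequences: dict[str, SequenceTruth] = field(default_factory=dict)
    contigs: dict[str, ContigTruth] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["seq_id\tclade\tclass762\tanchors_intact\texpected_fail_stage"]
        for t in self.sequences.values():
            lines.append(
                f"{t.seq_id}\t{t.clade if t.clade is not None else ''}\t"
                f"{t.class762 or ''}\t{t.anchors_intact}\t{t.expected_fail_stage or ''}"
            )
        if self.contigs:
            lines.append("")
            lines.append("contig_id\tclass762\thelicase\toffset")
            for c in self.contigs.values():
                lines.append(
                    f"{c.contig_id}\t{c.class762}\t{c.helicase or ''}\t"
                    f"{c.offset if c.offset is not None else ''}"
                )
        return "\n".join(lines) + "\n"


def _mutate(
    seq: np.ndarray, rate: float, rng: np.random.Generator, protected: set[int]
) -> np.ndarray:
    """Substitute residues at Bernoulli(rate) sites, uniformly over the 19
    alternatives; 0-based positions in ``protected`` are never touched."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        if int(i) in protected:
            continue
        alternatives = _AA[_AA != out[i]]
        out[i] = rng.choice(alternatives)
    return out


def _apply_indels(
    seq: np.ndarray, spec: FamilySpec, rng: np.random.Generator
) -> np.ndarray:
    """Insert/delete short runs outside the anchor window."""
    n_indels = rng.poisson(spec.indel_rate * len(seq))
    out = list(seq)
    lo, hi = _ANCHOR_WINDOW
    for _ in range(n_indels):
        length = 1 + rng.geometric(1.0 / spec.indel_mean_length)
        # candidate 0-based start positions clear of the anchor window
        pos = int(rng.integers(0, max(1, len(out) - length)))
        if lo - length <= pos <= hi:
            pos = int(rng.integers(0, max(1, lo - length)))
        if rng.random() < 0.5:
            out[pos : pos + length] = []
        else:
            out[pos:pos] = list(rng.choice(_AA, size=length))
    return np.array(out)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def generate_family(
    spec: FamilySpec, reference: ProteinRecord | None = None
) -> tuple[list[ProteinRecord], list[DomainHit], TruthTable]:
    """Generate a planted PolA family with matching hit table and truth.

    Clade ancestors are evolved from the reference at the between-clade
    divergence with the clade's 762 residue planted; members are evolved
    from their ancestor at the within-clade divergence with all anchors
    protected (unless ``anchor_mutation_prob`` fires, in which case one
    catalytic anchor is randomized and the event recorded in the truth
    table). Non-decoy sequences get a whole-length qualifying domain hit.
    """
    reference = reference or load_reference()
    if max(ANCHOR_POSITIONS) > len(reference):
        raise ValueError("reference does not contain all anchor positions")
    rng = np.random.default_rng(spec.seed)
    ref = np.array(list(reference.residues))
    anchors0 = {p - 1 for p in ANCHOR_POSITIONS}

    records: list[ProteinRecord] = []
    hits: list[DomainHit] = []
    truth = TruthTable()

    def add_hit(rec: ProteinRecord, evalue: float) -> None:
        hits.append(DomainHit(rec.id, "cl02626", evalue, 1, len(rec)))

    for clade in range(spec.n_clades):
        cls = spec.clade_class762[clade]
        ancestor = _mutate(ref, spec.between_divergence, rng, anchors0)
        ancestor[761] = cls  # plant the clade's 762 residue
        for k in range(spec.clade_sizes[clade]):
            seq = _mutate(ancestor, spec.within_divergence, rng, anchors0)
            anchors_intact = True
            if spec.anchor_mutation_prob and rng.random() < spec.anchor_mutation_prob:
                pos = int(rng.choice([687, 704, 757]))
                seq[pos] = rng.choice(_AA[_AA != seq[pos]])
                anchors_intact = False
            seq = _apply_indels(seq, spec, rng)
            rec = ProteinRecord(
                id=f"clade{clade}_{cls}_{k:03d}",
                residues="".join(seq),
                source="synthetic",
                description=f"planted clade {clade} class {cls}",
            )
            records.append(rec)
            add_hit(rec, PASSING_EVALUE)
            truth.sequences[rec.id] = SequenceTruth(
                seq_id=rec.id,
                clade=clade,
                class762=cls,
                anchors_intact=anchors_intact,
                expected_fail_stage=None if anchors_intact else "signature",
            )

    decoys = dict(spec.decoys)
    lo = 660 - 210  # short decoys: a 351-aa window containing the anchors
    for k in range(decoys.get("short", 0)):
        window = ref[lo - 1 : lo - 1 + 351].copy()
        # diverged enough that short decoys never co-cluster, anchors
        # protected (shifted into window coordinates)
        shifted = {p - (lo - 1) for p in anchors0 if lo - 1 <= p < lo - 1 + 351}
        window = _mutate(window, 0.2, rng, shifted)
        rec = ProteinRecord(
            id=f"decoy_short_{k:03d}", residues="".join(window), source="synthetic"
        )
        records.append(rec)
        add_hit(rec, PASSING_EVALUE)
        truth.sequences[rec.id] = SequenceTruth(rec.id, None, "F", True, "length")
    for k in range(decoys.get("no_domain", 0)):
        seq = _mutate(ref, 0.35, rng, anchors0)
        rec = ProteinRecord(
            id=f"decoy_nodomain_{k:03d}", residues="".join(seq), source="synthetic"
        )
        records.append(rec)
        add_hit(rec, FAILING_EVALUE)
        truth.sequences[rec.id] = SequenceTruth(rec.id, None, "F", True, "domain")
    for k in range(decoys.get("bad_anchor", 0)):
        seq = _mutate(ref, 0.10, rng, anchors0)
        pos = int(rng.choice([687, 704, 757]))
        seq[pos] = rng.choice(_AA[_AA != seq[pos]])
        rec = ProteinRecord(
            id=f"decoy_badanchor_{k:03d}", residues="".join(seq), source="synthetic"
        )
        records.append(rec)
        add_hit(rec, PASSING_EVALUE)
        truth.sequences[rec.id] = SequenceTruth(rec.id, None, None, False, "signature")
    for k in range(decoys.get("random", 0)):
        rec = ProteinRecord(
            id=f"decoy_random_{k:03d}",
            residues=_random_protein(rng, int(rng.integers(420, 620))),
            source="synthetic",
        )
        records.append(rec)
        truth.sequences[rec.id] = SequenceTruth(rec.id, None, None, False, "signature")

    return records, hits, truth


# ---------------------------------------------------------------------------
# Contigs


def _build_contig(
    contig_id: str,
    class762: str,
    helicase: str | None,
    rng: np.random.Generator,
) -> tuple[ContigAnnotation, int | None]:
    n_orfs = int(rng.integers(9, 13))
    pol_index = n_orfs // 2
    offset: int | None = None
    if helicase is not None:
        candidates = [
            o
            for o in range(-5, 6)
            if o != 0 and 0 <= pol_index + o < n_orfs
        ]
        offset = int(rng.choice(candidates))
    orfs: list[Orf] = []
    pos = 1
    for i in range(n_orfs):
        length = int(rng.integers(600, 1500))
        if i == pol_index:
            product = "DNA polymerase I"
        elif helicase is not None and i == pol_index + offset:
            product = _HELICASE_PRODUCTS[helicase]
        else:
            product = "hypothetical protein"
        strand = "+" if rng.random() < 0.7 else "-"
        orfs.append(
            Orf(
                orf_id=f"{contig_id}_orf{i + 1:02d}",
                start=pos,
                end=pos + length - 1,
                strand=strand,
                product=product,
            )
        )
        pos += length + int(rng.integers(20, 120))
    return ContigAnnotation(contig_id=contig_id, orfs=tuple(orfs)), offset


def generate_contigs_from_assignments(
    assignments: Mapping[str, Sequence[str | None]], seed: int
) -> tuple[list[ContigAnnotation], TruthTable]:
    """Contigs with an explicit helicase assignment per locus.

    ``assignments`` maps each 762 class to a sequence of helicase classes
    (or None for no helicase), one entry per contig to generate.
    """
    rng = np.random.default_rng(seed)
    contigs: list[ContigAnnotation] = []
    truth = TruthTable()
    for cls in sorted(assignments):
        for k, helicase in enumerate(assignments[cls]):
            if helicase is not None and helicase not in HELICASE_CLASSES:
                raise ValueError(f"unknown helicase class {helicase!r}")
            cid = f"contig_{cls}_{k:03d}"
            contig, offset = _build_contig(cid, cls, helicase, rng)
            contigs.append(contig)
            truth.contigs[cid] = ContigTruth(cid, cls, helicase, offset)
    return contigs, truth


def generate_contigs(
    locus_counts: Mapping[str, int],
    association: Mapping[str, Mapping[str, float]],
    seed: int,
) -> tuple[list[ContigAnnotation], TruthTable]:
    """Contigs whose helicase neighbors follow per-class probabilities.

    ``association[class762]`` is a probability vector over the helicase
    classes plus ``"none"``; one contig is generated per locus with its
    polA ORF placed centrally and any helicase ORF at a random offset of
    1–5 genes on either side.
    """
    rng = np.random.default_rng(seed)
    options = list(HELICASE_CLASSES) + ["none"]
    assignments: dict[str, list[str | None]] = {}
    for cls in sorted(locus_counts):
        probs_map = association.get(cls, {})
        unknown = set(probs_map) - set(options)
        if unknown:
            raise ValueError(f"unknown helicase classes in association row: {sorted(unknown)}")
        p = np.array([probs_map.get(o, 0.0) for o in options], dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"association row for {cls!r} is not a probability vector")
        draws = rng.choice(len(options), size=locus_counts[cls], p=p)
        assignments[cls] = [
            None if options[i] == "none" else options[i] for i in draws
        ]
    return generate_contigs_from_assignments(
        assignments, seed=int(rng.integers(0, 2**31 - 1))
    )
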