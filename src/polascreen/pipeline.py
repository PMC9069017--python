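"""End-to-end orchestration of the PolA mining stages.

Stage order follows the mining workflow: ingest sequences and domain
hits, validate active sites and assign 762 classes, cluster within
(source, 762-class) strata, length/domain-filter the cluster
representatives, trim them to the polymerase domain, optionally
subsample per stratum, build the reference-anchored NJ tree rooted on
the reference, and assess per-class monophyly. Every stage writes a
plain file (FASTA/TSV/Newick) so runs are independently inspectable,
and a ledger accounts for every sequence at every stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import filter_cluster as fc
from . import phylo, signature
from .align import AlignmentParams
from .seqio import (
    DomainHit,
    ProteinRecord,
    StageLedger,
    read_fasta,
    read_hits_table,
    write_fasta,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_KNOWN_KEYS = {
    "fasta",
    "hits",
    "out_dir",
    "source",
    "min_length",
    "min_hit_span",
    "max_evalue",
    "domain_model",
    "min_identity",
    "min_coverage",
    "subsample_n",
    "seed",
    "bootstrap_replicates",
    "min_shared_columns",
}


@dataclass
class PipelineConfig:
    """Flat configuration for a full run; unknown keys are rejected."""

    fasta: str
    hits: str
    out_dir: str
    source: str = "synthetic"
    min_length: int = 400
    min_hit_span: int = 325
    max_evalue: float = 1e-10
    domain_model: str = fc.POLA_DOMAIN_MODEL
    min_identity: float = 0.75
    min_coverage: float = 0.8
    subsample_n: int | None = None  # None disables subsampling
    seed: int = 0
    bootstrap_replicates: int | None = None
    min_shared_columns: int = 100

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value config file."""
        kv: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in _KNOWN_KEYS:
                raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
            kv[key] = value
        ints = {"min_length", "min_hit_span", "subsample_n", "seed",
                "bootstrap_replicates", "min_shared_columns"}
        floats = {"max_evalue", "min_identity", "min_coverage"}
        kwargs: dict = {}
        for k, v in kv.items():
            if k in ints:
                kwargs[k] = int(v)
            elif k in floats:
                kwargs[k] = float(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class PipelineResult:
    out_dir: Path
    ledger: StageLedger
    class_counts: dict[str, int]
    n_representatives: int
    n_tree_leaves: int
    monophyly: phylo.MonophylyReport | None
    tree: phylo.PhyloTree | None


_SUBSTITUTION_NOTICE = (
    "# polascreen report\n"
    "# Tool notes: pairwise affine-gap DP (BLOSUM62) is used for all\n"
    "# alignments; clustering is single-pass greedy (CD-HIT style); the\n"
    "# tree is neighbor joining on p-distances from a reference-anchored\n"
    "# alignment, rooted on the reference sequence.\n"
)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages; deterministic given the config and its seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")

    fconf = fc.FilterConfig(
        min_length=config.min_length,
        min_hit_span=config.min_hit_span,
        max_evalue=config.max_evalue,
        domain_model=config.domain_model,
    )
    scheme = signature.default_scheme()
    ledger = StageLedger()

    records = read_fasta(config.fasta, source=config.source)
    hits = read_hits_table(config.hits)
    ledger.add_stage("ingest", len(records), len(records))

    # 1. active-site screen
    retained_sig, rejected_sig, counts = signature.classify_batch(
        records, scheme, ledger=ledger
    )
    signature.write_signature_report(
        list(retained_sig) + list(rejected_sig), out / "signature.tsv"
    )
    by_id = {r.id: r for r in records}
    class_of = {r.query_id: r.class762 for r in retained_sig}
    passing = [by_id[r.query_id] for r in retained_sig]

    # 2. greedy clustering within (source, class) strata
    strata: dict[fc.Stratum, list[ProteinRecord]] = {}
    for rec in passing:
        stratum = fc.Stratum(source=rec.source, class762=class_of[rec.id])
        strata.setdefault(stratum, []).append(rec)
    clusters: list[fc.Cluster] = []
    for stratum in sorted(strata):
        clusters.extend(
            fc.greedy_cluster(
                strata[stratum],
                stratum,
                min_identity=config.min_identity,
                min_coverage=config.min_coverage,
            )
        )
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("representative_id\tmember_id\tsource\tclass762\n")
        for cl in clusters:
            for member in cl.member_ids:
                fh.write(
                    f"{cl.representative_id}\t{member}\t"
                    f"{cl.stratum.source}\t{cl.stratum.class762}\n"
                )
    reps = [by_id[cl.representative_id] for cl in clusters]
    ledger.add_stage("cluster_representatives", len(passing), len(reps))

    # 3. length and domain filters on representatives
    len_ok, _ = fc.filter_length(reps, fconf)
    ledger.add_stage("length_filter", len(reps), len(len_ok))
    len_ok_ids = {r.id for r in len_ok}
    known_hits = [h for h in hits if h.query_id in len_ok_ids]
    dom_ok, _ = fc.filter_domain(len_ok, known_hits, fconf)
    ledger.add_stage("domain_filter", len(len_ok), len(dom_ok))

    # 4. trim to the longest qualifying domain hit
    trimmed = [fc.trim_to_domain(r, known_hits, fconf) for r in dom_ok]
    write_fasta(trimmed, out / "representatives_trimmed.fasta")

    # 5. optional per-stratum subsample
    if config.subsample_n is not None:
        rep_ids = {
            stratum: [
                cl.representative_id
                for cl in clusters
                if cl.stratum == stratum
                and cl.representative_id in {r.id for r in dom_ok}
            ]
            for stratum in sorted(strata)
        }
        sampled = fc.stratified_subsample(rep_ids, n=config.subsample_n, seed=config.seed)
        keep = {i for ids in sampled.values() for i in ids}
        trimmed = [r for r in trimmed if r.id in keep]
    per_source: dict[str, int] = {}
    for r in trimmed:
        per_source[r.source] = per_source.get(r.source, 0) + 1
    ledger.add_stage("tree_input", len(dom_ok), len(trimmed), per_source=per_source)

    # 6. anchored alignment, NJ tree, rooting, monophyly
    tree = None
    report = None
    if len(trimmed) >= 3:
        ref = scheme.reference
        ref_domain = ref  # anchor columns are reference positions
        msa = phylo.build_anchored_msa(trimmed, ref_domain)
        if config.bootstrap_replicates:
            unrooted = phylo.bootstrap_support(
                msa,
                n_replicates=config.bootstrap_replicates,
                seed=config.seed,
                min_shared_columns=config.min_shared_columns,
            )
        else:
            ids, d = phylo.p_distance_matrix(
                msa, min_shared_columns=config.min_shared_columns
            )
            unrooted = phylo.nj_tree(ids, d)
        tree = phylo.root_on(unrooted, ref.id)
        leaf_classes = dict(class_of)
        # The reference roots the tree; keeping it out of the F group stops
        # the outgroup from dragging every F MRCA up to the root.
        leaf_classes[ref.id] = "outgroup"
        leaf_sources = {r.id: r.source for r in trimmed}
        leaf_sources[ref.id] = ref.source
        phylo.annotate_tree(
            tree,
            leaf_classes,
            leaf_sources,
            newick_path=out / "tree.nwk",
            tsv_path=out / "leaf_annotations.tsv",
        )
        report = phylo.assess_group_monophyly(
            tree, {k: v for k, v in leaf_classes.items() if k in set(tree.leaf_names())}
        )

    (out / "ledger.tsv").write_text(ledger.to_tsv())
    lines = [_SUBSTITUTION_NOTICE, ledger.to_tsv()]
    lines.append("class762 counts after screen: " + json.dumps(counts))
    if report is not None:
        for g in report.groups.values():
            lines.append(
                f"group {g.group}: {g.verdict} "
                f"(members {g.n_members}, clade {g.clade_size}, "
                f"intruders {len(g.intruders)} in {g.n_intruder_subclades} subclades)"
            )
    (out / "report.txt").write_text("\n".join(lines) + "\n")

    return PipelineResult(
        out_dir=out,
        ledger=ledger,
        class_counts=counts,
        n_representatives=len(reps),
        n_tree_leaves=len(trimmed) + (1 if tree is not None else 0),
        monophyly=report,
        tree=tree,
    )
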