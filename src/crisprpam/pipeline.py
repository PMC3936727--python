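"""End-to-end orchestration: config -> hits -> PAM report; proteins -> clusters -> tree.

Two entry points mirror the two halves of the analysis:

* :func:`run_pam_discovery` — spacers vs targets, flank extraction, one PAM
  profile per strain group (loci sharing a group label pool their evidence,
  emulating the practice of pooling closely related strains of one species)
  plus per-source-class partitions (phage/plasmid vs genome), so a
  self-tolerant chromosomal PAM variant is visible as a partition
  difference.
* :func:`run_cluster_tree` — length filter, coverage-threshold clustering,
  NJ tree with optional column bootstrap, and a per-cluster monophyly
  verdict (concordance of sequence clusters with tree groups).

Reports carry provenance (config hash, package version, seed) and are
reproducible from the recorded config and the inputs alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .cluster import (
    ClusterSet,
    all_pair_stats,
    filter_by_length,
    greedy_cluster,
)
from .pam import (
    DEFAULT_COVERAGE,
    DEFAULT_FLANK_LEN,
    DEFAULT_MIN_SUPPORT,
    NoFlanksError,
    PamProfile,
    extract_flank,
    partition_by_source,
    profile_from_flanks,
)
from .phylo import Alignment, Tree, bootstrap_support, distance_matrix, nj_tree
from .search import (
    ProtospacerHit,
    SearchUsageError,
    classify_sources,
    find_protospacers,
)
from .seqio import CrisprLocus, SequenceRecord, read_fasta, read_locus_table

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class EmptyResultError(RuntimeError):
    """The run produced no usable results (e.g. no protospacer hits)."""


@dataclass
class PipelineConfig:
    """All paths and thresholds for one run; YAML-serialisable (schema v1)."""

    loci_table: str | None = None
    targets_fasta: str | None = None
    target_metadata: str | None = None
    proteins_fasta: str | None = None
    msa_fasta: str | None = None
    min_identity: float = 0.90
    flank_len: int = DEFAULT_FLANK_LEN
    coverage: float = DEFAULT_COVERAGE
    min_support: int = DEFAULT_MIN_SUPPORT
    dedup_flanks: bool = True
    min_len: int = 800
    length_cov: float = 0.8
    score_cov: float = 0.8
    bootstrap: int = 0
    seed: int = 0
    groups: dict = field(default_factory=dict)   # locus_id -> group label
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1):
            raise ConfigError("min_identity outside (0, 1]")
        if not (0 < self.coverage <= 1):
            raise ConfigError("coverage outside (0, 1]")
        if not (0 <= self.length_cov <= 1 and 0 <= self.score_cov <= 1):
            raise ConfigError("coverage thresholds outside [0, 1]")
        if self.flank_len < 1:
            raise ConfigError("flank_len must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "package": "crisprpam",
        "version": __version__,
        "config_sha256_16": config.digest(),
        "seed": config.seed,
    }


@dataclass
class PamReport:
    profiles: dict[str, PamProfile]          # group label -> profile
    source_profiles: dict[str, PamProfile]   # source class -> profile
    hits: list[ProtospacerHit]
    n_flanks_used: dict[str, int]
    config: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "profiles": {k: p.to_dict() for k, p in self.profiles.items()},
                "source_profiles": {k: p.to_dict() for k, p in self.source_profiles.items()},
                "n_hits": len(self.hits),
                "n_flanks_used": self.n_flanks_used,
                "config": self.config,
                "provenance": self.provenance,
            },
            indent=2,
        )


def run_pam_discovery(
    loci: Sequence[CrisprLocus],
    targets: Sequence[SequenceRecord],
    config: PipelineConfig | None = None,
    target_classes: Mapping[str, str] | None = None,
) -> PamReport:
    """Spacers -> hits -> flanks -> per-group and per-source PAM profiles."""
    config = config or PipelineConfig()
    if not loci:
        raise SearchUsageError("no loci supplied")
    if not targets:
        raise SearchUsageError("no targets supplied")

    hits = find_protospacers(loci, targets, min_identity=config.min_identity)
    if target_classes:
        hits = classify_sources(hits, target_classes)
    if not hits:
        raise EmptyResultError(
            "no protospacer hits in any group; add targets (e.g. from closely "
            "related strains of the same species) or relax min_identity"
        )

    by_target = {t.id: t for t in targets}
    group_of = {locus.locus_id: config.groups.get(locus.locus_id, locus.species) for locus in loci}

    flanks_by_group: dict[str, list[str]] = {}
    seen: set[tuple[str, str, str]] = set()
    for hit in hits:
        flank = extract_flank(hit, by_target[hit.target_id], config.flank_len)
        if flank is None:
            continue
        group = group_of.get(hit.locus_id, "ungrouped")
        if config.dedup_flanks:
            key = (group, hit.protospacer_seq, flank)
            if key in seen:
                log.info("duplicate protospacer+flank for %s dropped", hit.spacer_id)
                continue
            seen.add(key)
        flanks_by_group.setdefault(group, []).append(flank)

    if not any(flanks_by_group.values()):
        raise EmptyResultError("hits found but no full-length flanks; targets too short")

    profiles: dict[str, PamProfile] = {}
    for group, flanks in sorted(flanks_by_group.items()):
        if len(flanks) < config.min_support:
            log.warning(
                "group %s has only %d flank(s) (< %d); no consensus called — "
                "consider pooling closely related strains", group, len(flanks), config.min_support
            )
            continue
        profiles[group] = profile_from_flanks(
            flanks,
            width=config.flank_len,
            coverage=config.coverage,
            min_support=config.min_support,
            partition_label=group,
        )
    if not profiles:
        raise EmptyResultError("no group reached the minimum flank support")

    source_profiles: dict[str, PamProfile] = {}
    if target_classes:
        try:
            source_profiles = partition_by_source(
                hits, targets, flank_len=config.flank_len, coverage=config.coverage
            )
        except NoFlanksError:
            source_profiles = {}

    return PamReport(
        profiles=profiles,
        source_profiles=source_profiles,
        hits=list(hits),
        n_flanks_used={g: len(f) for g, f in sorted(flanks_by_group.items())},
        config=config.to_dict(),
        provenance=_provenance(config),
    )


@dataclass
class ClusterTreeReport:
    clusters: ClusterSet
    tree: Tree
    concordance: list[dict]
    config: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_clusters": self.clusters.n_clusters,
                "clusters": [list(c) for c in self.clusters.clusters],
                "newick": self.tree.newick(),
                "concordance": self.concordance,
                "config": self.config,
                "provenance": self.provenance,
            },
            indent=2,
        )


def run_cluster_tree(
    proteins: Sequence[SequenceRecord],
    msa: Sequence[SequenceRecord] | None = None,
    config: PipelineConfig | None = None,
) -> ClusterTreeReport:
    """Length filter -> clusters -> NJ tree (+ bootstrap) -> monophyly verdicts.

    Tree distances come from the supplied MSA when given; otherwise the
    retained proteins must all have equal length (substitution-only
    families, e.g. the synthetic ones), in which case they are treated as
    positionally aligned.
    """
    config = config or PipelineConfig()
    retained = filter_by_length(proteins, config.min_len)
    if len(retained) < 3:
        raise EmptyResultError(
            f"only {len(retained)} protein(s) of >= {config.min_len} aa; a tree needs >= 3"
        )

    stats = all_pair_stats(retained)
    clusters = greedy_cluster(retained, config.length_cov, config.score_cov, stats=stats)

    if msa is not None:
        retained_ids = {r.id for r in retained}
        aln = Alignment.from_records([r for r in msa if r.id in retained_ids])
    else:
        lengths = {len(r) for r in retained}
        if len(lengths) > 1:
            raise ConfigError(
                "retained proteins are not equal-length; supply an MSA for the tree"
            )
        aln = Alignment.from_records(retained)

    if config.bootstrap > 0:
        tree = bootstrap_support(aln, B=config.bootstrap, seed=config.seed)
    else:
        from .phylo import select_informative_columns

        informative, _ = select_informative_columns(aln)
        tree = nj_tree(distance_matrix(informative))

    concordance = []
    for i, members in enumerate(clusters.clusters):
        in_tree = [m for m in members if m in tree.leaves]
        verdict = tree.check_monophyly(in_tree) if in_tree else None
        concordance.append(
            {"cluster_id": f"cluster_{i + 1}", "size": len(members), "monophyletic": verdict}
        )

    return ClusterTreeReport(
        clusters=clusters,
        tree=tree,
        concordance=concordance,
        config=config.to_dict(),
        provenance=_provenance(config),
    )


def run_pam_discovery_from_paths(config: PipelineConfig) -> PamReport:
    if not config.loci_table or not config.targets_fasta:
        raise ConfigError("loci_table and targets_fasta are required")
    loci = read_locus_table(config.loci_table)
    targets = read_fasta(config.targets_fasta)
    classes = None
    if config.target_metadata:
        from .search import read_target_metadata

        classes = read_target_metadata(config.target_metadata)
    return run_pam_discovery(loci, targets, config=config, target_classes=classes)


def run_cluster_tree_from_paths(config: PipelineConfig) -> ClusterTreeReport:
    if not config.proteins_fasta:
        raise ConfigError("proteins_fasta is required")
    proteins = read_fasta(config.proteins_fasta, moltype="protein")
    msa = read_fasta(config.msa_fasta, moltype="protein") if config.msa_fasta else None
    return run_cluster_tree(proteins, msa=msa, config=config)
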