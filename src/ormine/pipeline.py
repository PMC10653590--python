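"""End-to-end OR mining: genome in, classified repertoire out.

Chains the stages in the canonical order: profile scan of the six-frame
translation, merge of block matches into loci, 98%-identity redundancy
clustering, per-representative phylogenetic non-OR filtering, family
assignment, disruption detection anchored on the best family's seed, and
the functional / sub-7TM / pseudogene rules. One record is emitted per
deduplicated representative; filter verdicts propagate from the
representative to its cluster members.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .classify import (
    ORRecord,
    STATUS_REMOVED,
    classify_status,
    detect_pseudogene_features,
)
from .families import UNASSIGNED
from .filtering import FamilyCall, FilterVerdict, ReferencePanel, assign_family, phylo_filter
from .profiles import (
    ClusteringResult,
    FamilyProfile,
    GenomeHit,
    SeedFamilySet,
    dedup_cluster,
    scan_genome,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    hits: list[GenomeHit]
    clustering: ClusteringResult
    verdicts: dict[str, FilterVerdict]
    family_calls: dict[str, FamilyCall]
    records: list[ORRecord]
    manifest: dict = field(default_factory=dict)


def _frame0_protein(nt: str) -> str:
    return str(Seq(nt[: len(nt) // 3 * 3]).translate()).rstrip("*")


def run_pipeline(
    genome,
    profiles: Sequence[FamilyProfile],
    panel: ReferencePanel,
    seeds: Sequence[SeedFamilySet],
    evalue: float = 1e-10,
    dedup_threshold: float = 0.98,
) -> PipelineResult:
    """Mine one genome for OR genes and classify every representative.

    ``seeds`` supplies per-family reference coding sequences for anchoring
    stop/frameshift detection (the first seed of the assigned family is
    used; unassigned candidates fall back to unanchored evidence).
    """
    hits = scan_genome(profiles, genome, evalue=evalue)
    clustering = dedup_cluster(hits, threshold=dedup_threshold)
    seed_ref = {s.family_id: s.sequences[0] for s in seeds}

    verdicts: dict[str, FilterVerdict] = {}
    family_calls: dict[str, FamilyCall] = {}
    records: list[ORRecord] = []
    for rep in clustering.representatives:
        prot = _frame0_protein(rep.sequence)
        # proteins of disrupted loci are ragged; the filter only needs a
        # rough placement, so fall back to the longest stop-free stretch
        placeable = max(prot.split("*"), key=len) if "*" in prot else prot
        try:
            verdict = phylo_filter(rep.key, placeable, panel)
        except ValueError:
            # too short/ambiguous to place: keep, let classification decide
            verdict = FilterVerdict(rep.key, True, "", ())
        verdicts[rep.key] = verdict
        if not verdict.keep:
            records.append(
                ORRecord(rep.key, rep.sequence, STATUS_REMOVED, None, None, None, None)
            )
            continue
        call = assign_family(rep.key, placeable, profiles)
        family_calls[rep.key] = call
        ref_label, ref_nt = (None, None)
        if call.family_id != UNASSIGNED and call.family_id in seed_ref:
            ref_label, ref_nt = seed_ref[call.family_id]
        evidence = detect_pseudogene_features(
            rep.sequence, ref_nt, reference_id=ref_label or ""
        )
        records.append(
            classify_status(rep.key, rep.sequence, evidence, call.family_id)
        )

    manifest = {
        "evalue": evalue,
        "dedup_threshold": dedup_threshold,
        "n_hits": len(hits),
        "n_representatives": len(clustering.representatives),
        "n_removed_nonor": sum(1 for v in verdicts.values() if not v.keep),
    }
    return PipelineResult(hits, clustering, verdicts, family_calls, records, manifest)
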