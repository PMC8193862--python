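"""Greedy merging of near-identical UMI groups.

Sequencing errors inside the barcode split one molecule's reads across
several UMI keys. Merging repairs this: the unassigned group with the most
reads seeds a cluster and absorbs every remaining group whose UMI lies
within ``UMIdistance`` (Hamming) of the seed's AND whose first-pass
consensus insert lies within ``sequenceDistance`` of the seed's (both mates
must pass independently for paired data). Absorbed groups leave the pool,
the next-largest survivor seeds the next cluster, and so on — seed-centric,
with no transitive chaining. Each cluster's final consensus is recomputed
from the pooled raw reads of all its groups, so every original read
contributes with its own weight.
"""

from __future__ import annotations

from dataclasses import dataclass

from .consensus import ConsensusRead, consensus_read
from .grouping import RunConfig, UmiGroup


def hamming(s1: str, s2: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(s1) != len(s2):
        raise ValueError(f"hamming: unequal lengths {len(s1)} vs {len(s2)}")
    return sum(a != b for a, b in zip(s1, s2))


@dataclass
class CorrectedGroup:
    """A UMI group together with its first-pass consensus read(s)."""

    group: UmiGroup
    consensus_r1: ConsensusRead
    consensus_r2: ConsensusRead | None = None

    @property
    def umi(self) -> str:
        return self.group.umi

    @property
    def count(self) -> int:
        return self.group.count


@dataclass
class MergeCluster:
    """A merged set of UMI groups represented by its largest member's UMI."""

    representative_umi: str
    absorbed_umis: list[str]
    pooled_count: int
    final_r1: ConsensusRead
    final_r2: ConsensusRead | None = None


def correct_groups(groups: list[UmiGroup]) -> list[CorrectedGroup]:
    """First-pass consensus per UMI group (the merge step's inputs)."""
    out = []
    for g in groups:
        cons_r2 = consensus_read(g.mates) if g.mates is not None else None
        out.append(CorrectedGroup(g, consensus_read(g.members), cons_r2))
    return out


def _passes(seed: CorrectedGroup, cand: CorrectedGroup, config: RunConfig) -> bool:
    if hamming(seed.umi, cand.umi) > config.UMIdistance:
        return False
    if (
        hamming(seed.consensus_r1.sequence, cand.consensus_r1.sequence)
        > config.sequenceDistance
    ):
        return False
    if seed.consensus_r2 is not None:
        assert cand.consensus_r2 is not None
        if (
            hamming(seed.consensus_r2.sequence, cand.consensus_r2.sequence)
            > config.sequenceDistance
        ):
            return False
    return True


def merge_umi_groups(
    groups: list[CorrectedGroup], config: RunConfig
) -> list[MergeCluster]:
    """Greedy max-count clustering of UMI groups.

    Clusters are returned in creation order; every input group lands in
    exactly one cluster. The result is independent of input order: the pool
    is sorted by descending read count with lexicographic UMI tie-break
    before the greedy loop starts.
    """
    pool = sorted(groups, key=lambda cg: (-cg.count, cg.umi))
    clusters: list[MergeCluster] = []
    while pool:
        seed = pool[0]
        absorbed = [cg for cg in pool[1:] if _passes(seed, cg, config)]
        absorbed_ids = {id(cg) for cg in absorbed}
        pool = [cg for cg in pool[1:] if id(cg) not in absorbed_ids]

        cluster_groups = [seed] + absorbed
        pooled_r1 = [m for cg in cluster_groups for m in cg.group.members]
        final_r1 = consensus_read(pooled_r1)
        final_r2 = None
        if seed.group.mates is not None:
            pooled_r2 = [m for cg in cluster_groups for m in (cg.group.mates or [])]
            final_r2 = consensus_read(pooled_r2)
        clusters.append(
            MergeCluster(
                representative_umi=seed.umi,
                absorbed_umis=[cg.umi for cg in absorbed],
                pooled_count=sum(cg.count for cg in cluster_groups),
                final_r1=final_r1,
                final_r2=final_r2,
            )
        )
    return clusters
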