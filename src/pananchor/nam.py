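"""Joint-linkage mapping of tags in nested biparental RIL families.

Three steps, run per tag:

1. The same binomial test as the population scan, restricted to each
   family's taxa with MAF recomputed within the family; a family in which
   the best p-value is below the per-family threshold (default 0.05) is
   *segregating* for the tag.
2. Segregating families are grouped by the chromosome their best SNP is on.
3. The taxa of the largest group are pooled and the tag is re-mapped on
   that chromosome only, with pooled counts and pooled-subset MAF; the tag
   is mapped (method J) when the pooled best p-value clears the threshold.

Tie-breaks are deterministic: equal group sizes go to the group with the
larger summed per-family evidence (equivalently the smaller product of best
p-values), then the lower chromosome index; equal p-values within a scan go
to the smaller global position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import bitset
from .datamodel import GenomePosition, SNPGenotypeMatrix, TagPresenceMatrix
from .gwas import MappingResult, UnmappedTag, _neg_log10_tail

log = logging.getLogger(__name__)


@dataclass
class FamilyScanResult:
    family_id: str
    segregating: bool
    pos: GenomePosition | None
    best_snp_index: int | None  # index into the full SNP matrix
    neg_log10_p: float


class NamMapper:
    """Precomputes per-family data so per-tag scans stay cheap.

    Family membership comes from the TaxaList family labels; taxa without a
    label are excluded from joint-linkage mapping.  Pooled group matrices
    (step 3) are cached keyed by (family set, chromosome) since the same
    winning groups recur across tags.
    """

    def __init__(
        self,
        tags: TagPresenceMatrix,
        snps: SNPGenotypeMatrix,
        threshold: float = 0.05,
        restrict_to_chromosome: bool = True,
        alternative: str = "two-sided",
    ):
        if tags.taxa != snps.taxa:
            raise ValueError("tag and SNP matrices must share the same taxa order")
        members = snps.taxa.family_members()
        if not members:
            raise ValueError("no family labels on the taxa list")
        for fam, idx in members.items():
            if len(idx) == 0:
                raise ValueError(f"family {fam} is empty")
        self.tags = tags
        self.snps = snps
        self.threshold = threshold
        self.thr_neglog = -np.log10(threshold)
        self.restrict = restrict_to_chromosome
        self.alternative = alternative
        self.family_ids = sorted(members)
        self.family_idx = {f: members[f] for f in self.family_ids}
        self.family_snps = {
            f: snps.subset_taxa(members[f]) for f in self.family_ids
        }
        # tag presence unpacked once; per-family packed slices built lazily
        self._presence = np.unpackbits(
            tags.presence_packed, axis=1, count=len(tags.taxa)
        ).astype(bool)
        self._family_presence = {
            f: np.packbits(self._presence[:, members[f]], axis=1)
            for f in self.family_ids
        }
        self._pool_cache: dict[tuple[frozenset, int | None], tuple] = {}

    # -- step 1 -----------------------------------------------------------
    def scan_family(self, tag_index: int, family_id: str) -> FamilyScanResult:
        """Binomial scan of one tag within one family (monomorphic SNPs skipped)."""
        fsnps = self.family_snps[family_id]
        presence = self._family_presence[family_id][tag_index]
        poly = fsnps.mafs > 0.0
        if not poly.any():
            return FamilyScanResult(family_id, False, None, None, 0.0)
        n = bitset.intersect_count_many(fsnps.call_packed, presence)
        x = bitset.intersect_count_many(fsnps.minor_packed, presence)
        neglog = np.zeros(len(fsnps))
        neglog[poly] = _neg_log10_tail(
            x[poly], n[poly], fsnps.mafs[poly], self.alternative
        )
        order = np.lexsort((fsnps.global_positions, -neglog))
        best = int(order[0])
        seg = bool(neglog[best] > self.thr_neglog)
        return FamilyScanResult(
            family_id,
            seg,
            GenomePosition(int(fsnps.chromosomes[best]), int(fsnps.positions[best]))
            if seg
            else None,
            best if seg else None,
            float(neglog[best]),
        )

    # -- steps 2 + 3 ------------------------------------------------------
    def joint_linkage_map(
        self, tag_index: int, min_tag_count: int = 30
    ) -> MappingResult | UnmappedTag:
        seq = self.tags.sequences[tag_index]
        count = int(self.tags.counts[tag_index])
        if count < min_tag_count:
            return UnmappedTag(tag_index, seq, "below-count")
        scans = [self.scan_family(tag_index, f) for f in self.family_ids]
        seg = [s for s in scans if s.segregating]
        if not seg:
            return UnmappedTag(tag_index, seq, "no-segregating-family")

        groups: dict[int, list[FamilyScanResult]] = {}
        for s in seg:
            groups.setdefault(s.pos.chromosome, []).append(s)
        # largest group; ties -> larger summed evidence, then lower chromosome
        def rank(item):
            chrom, members = item
            return (-len(members), -sum(m.neg_log10_p for m in members), chrom)

        win_chrom, win_members = min(groups.items(), key=rank)
        win_fams = frozenset(m.family_id for m in win_members)

        pooled, orig_idx, pooled_presence = self._pooled(win_fams, win_chrom)
        presence = pooled_presence[tag_index]
        poly = pooled.mafs > 0.0
        if not poly.any():
            return UnmappedTag(tag_index, seq, "no-significant-SNP")
        n = bitset.intersect_count_many(pooled.call_packed, presence)
        x = bitset.intersect_count_many(pooled.minor_packed, presence)
        neglog = np.zeros(len(pooled))
        neglog[poly] = _neg_log10_tail(
            x[poly], n[poly], pooled.mafs[poly], self.alternative
        )
        order = np.lexsort((pooled.global_positions, -neglog))
        best = int(order[0])
        if not (neglog[best] > self.thr_neglog):
            return UnmappedTag(tag_index, seq, "no-significant-SNP")
        sig = np.flatnonzero(neglog > self.thr_neglog)
        return MappingResult(
            tag_index=tag_index,
            sequence=seq,
            method="J",
            pos=GenomePosition(int(pooled.chromosomes[best]), int(pooled.positions[best])),
            best_snp_index=int(orig_idx[best]),
            p_value=float(10.0 ** (-neglog[best])) if neglog[best] < 320 else 0.0,
            neg_log10_p=float(neglog[best]),
            second_best_neg_log10_p=0.0,
            n=int(n[best]),
            x=int(x[best]),
            tag_count=count,
            n_sig_snps=int(len(sig)),
            sig_snp_indices=orig_idx[sig],
            sig_neg_log10_p=neglog[sig],
            n_segregating_families=len(seg),
            group_family_count=len(win_members),
            n_families=len(self.family_ids),
        )

    def _pooled(self, fams: frozenset, chrom: int):
        key = (fams, chrom if self.restrict else None)
        hit = self._pool_cache.get(key)
        if hit is not None:
            return hit
        idx = np.sort(np.concatenate([self.family_idx[f] for f in fams]))
        sub = self.snps.subset_taxa(idx)
        if self.restrict:
            site_mask = sub.chromosomes == chrom
        else:
            site_mask = np.ones(len(sub), dtype=bool)
        orig_idx = np.flatnonzero(site_mask)
        pooled = SNPGenotypeMatrix(
            sub.taxa,
            [sub.snp_ids[i] for i in orig_idx],
            sub.chromosomes[site_mask],
            sub.positions[site_mask],
            sub.mafs[site_mask],
            sub.minor_packed[site_mask],
            sub.call_packed[site_mask],
        )
        pooled_presence = np.packbits(self._presence[:, idx], axis=1)
        value = (pooled, orig_idx, pooled_presence)
        self._pool_cache[key] = value
        return value


def map_all_nam(
    tags: TagPresenceMatrix,
    snps: SNPGenotypeMatrix,
    min_tag_count: int = 30,
    threshold: float = 0.05,
    restrict_to_chromosome: bool = True,
    alternative: str = "two-sided",
) -> tuple[list[MappingResult], list[UnmappedTag]]:
    """Joint-linkage map every tag; see :class:`NamMapper`."""
    mapper = NamMapper(tags, snps, threshold, restrict_to_chromosome, alternative)
    mapped, unmapped = [], []
    for i in range(len(tags)):
        r = mapper.joint_linkage_map(i, min_tag_count)
        (mapped if isinstance(r, MappingResult) else unmapped).append(r)
    reasons: dict[str, int] = {}
    for u in unmapped:
        reasons[u.reason] = reasons.get(u.reason, 0) + 1
    log.info(
        "joint-linkage scan: %d/%d tags mapped (unmapped reasons: %s)",
        len(mapped), len(tags), reasons or "none",
    )
    return mapped, unmapped
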