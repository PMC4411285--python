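"""Core data structures for tag mapping.

A mapping run pairs two matrices over one fixed, ordered taxa list:

* :class:`SNPGenotypeMatrix` — biallelic SNPs as packed minor-allele and
  call-mask bitsets, with minor-allele frequency (MAF) per site.  This is the
  anchor grid the tags are mapped onto.
* :class:`TagPresenceMatrix` — 64-bp sequence tags as packed presence/absence
  bitsets.  Each tag's pattern is treated as a binary trait.

Genome coordinates are 1-based throughout.  A single integer "global
position" ``chromosome * 1e9 + position`` linearises the genome so that the
distance between a genetic and a physical position is a plain subtraction;
see :func:`global_position` for the edge cases this transform has.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from . import bitset

CHROM_SCALE = 1_000_000_000

_ACGT = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class GenomePosition:
    """1-based genomic coordinate."""

    chromosome: int
    position: int

    def __post_init__(self) -> None:
        if self.chromosome < 1:
            raise ValueError(f"chromosome must be >= 1, got {self.chromosome}")
        if not (1 <= self.position < CHROM_SCALE):
            raise ValueError(
                f"position must be in [1, 1e9), got {self.position}"
            )


def global_position(pos: GenomePosition) -> int:
    """Linearise (chromosome, position) as ``chromosome * 1e9 + position``.

    Injective and order-preserving over valid positions.  Note the artefact:
    the end of chromosome c and the start of chromosome c+1 are numerically
    close, so cross-chromosome pairs near chromosome boundaries can *look*
    close in this scale.  Chromosome-agreement statistics are therefore always
    computed from the chromosome field, never from distance bands.
    """
    return pos.chromosome * CHROM_SCALE + pos.position


def genetic_distance(a: int, b: int) -> int:
    """|a - b| between two global positions (bp; huge across chromosomes)."""
    return abs(a - b)


class TaxaList:
    """Ordered, unique taxon names; order defines bitset columns for a dataset.

    Optional per-taxon family labels (NAM joint-linkage mode) and
    subpopulation labels (synthetic ground truth for structure checks).
    """

    def __init__(
        self,
        names: Sequence[str],
        families: Sequence[str] | None = None,
        subpops: Sequence[str] | None = None,
    ):
        self.names = list(names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("taxon names must be unique")
        if families is not None and len(families) != len(self.names):
            raise ValueError("family labels must match taxa count")
        if subpops is not None and len(subpops) != len(self.names):
            raise ValueError("subpop labels must match taxa count")
        self.families = list(families) if families is not None else None
        self.subpops = list(subpops) if subpops is not None else None
        self._index = {n: i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxaList) and self.names == other.names

    def index_of(self, name: str) -> int:
        return self._index[name]

    def family_members(self) -> dict[str, np.ndarray]:
        """Map family label -> taxon index array; unlabeled taxa excluded."""
        if self.families is None:
            return {}
        out: dict[str, list[int]] = {}
        for i, fam in enumerate(self.families):
            if fam:
                out.setdefault(fam, []).append(i)
        return {k: np.asarray(v, dtype=np.int64) for k, v in out.items()}


@dataclass
class SNPRecord:
    """One biallelic site: packed minor-allele carriers and call mask."""

    snp_id: str
    pos: GenomePosition
    maf: float
    minor_presence: np.ndarray  # packed uint8, 1 = carries minor allele
    call_mask: np.ndarray  # packed uint8, 1 = genotype non-missing

    def validate(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"MAF must be in (0, 0.5], got {self.maf}")
        if bitset.intersect_count(self.minor_presence, ~self.call_mask):
            raise ValueError("minor allele recorded at a missing call")


class SNPGenotypeMatrix:
    """Biallelic SNPs x taxa, array-backed for the association scan.

    Sites are stored sorted by (chromosome, position).  Row-wise access
    yields :class:`SNPRecord` views; the packed 2-D arrays are exposed for
    the vectorised scan.
    """

    def __init__(
        self,
        taxa: TaxaList,
        snp_ids: Sequence[str],
        chromosomes: np.ndarray,
        positions: np.ndarray,
        mafs: np.ndarray,
        minor_packed: np.ndarray,
        call_packed: np.ndarray,
    ):
        self.taxa = taxa
        self.snp_ids = list(snp_ids)
        self.chromosomes = np.asarray(chromosomes, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.mafs = np.asarray(mafs, dtype=np.float64)
        self.minor_packed = minor_packed
        self.call_packed = call_packed
        nb = bitset.n_bytes(len(taxa))
        if minor_packed.shape != (len(self.snp_ids), nb):
            raise ValueError("minor_packed shape mismatch")
        if call_packed.shape != (len(self.snp_ids), nb):
            raise ValueError("call_packed shape mismatch")
        order = np.lexsort((self.positions, self.chromosomes))
        if not np.array_equal(order, np.arange(len(order))):
            self.snp_ids = [self.snp_ids[i] for i in order]
            self.chromosomes = self.chromosomes[order]
            self.positions = self.positions[order]
            self.mafs = self.mafs[order]
            self.minor_packed = self.minor_packed[order]
            self.call_packed = self.call_packed[order]
        self.global_positions = self.chromosomes * CHROM_SCALE + self.positions

    def __len__(self) -> int:
        return len(self.snp_ids)

    def record(self, i: int) -> SNPRecord:
        return SNPRecord(
            snp_id=self.snp_ids[i],
            pos=GenomePosition(int(self.chromosomes[i]), int(self.positions[i])),
            maf=float(self.mafs[i]),
            minor_presence=self.minor_packed[i],
            call_mask=self.call_packed[i],
        )

    def __iter__(self) -> Iterator[SNPRecord]:
        return (self.record(i) for i in range(len(self)))

    def subset_taxa(self, idx: np.ndarray) -> "SNPGenotypeMatrix":
        """Restrict to a taxa subset, recomputing MAF within the subset.

        Sites monomorphic in the subset are kept with maf 0 and must be
        skipped by callers (the per-family scan does).
        """
        minor = np.unpackbits(self.minor_packed, axis=1, count=len(self.taxa))[:, idx]
        call = np.unpackbits(self.call_packed, axis=1, count=len(self.taxa))[:, idx]
        called = call.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called > 0, minor.sum(axis=1) / np.maximum(called, 1), 0.0)
        maf = np.minimum(freq, 1.0 - freq)
        maf = np.where(called == 0, 0.0, maf)
        names = [self.taxa.names[i] for i in idx]
        fams = [self.taxa.families[i] for i in idx] if self.taxa.families else None
        subs = [self.taxa.subpops[i] for i in idx] if self.taxa.subpops else None
        # where frequency exceeds 0.5 in the subset the minor allele flips
        flip = freq > 0.5
        minor[flip] = (1 - minor[flip]) & call[flip]
        return SNPGenotypeMatrix(
            TaxaList(names, fams, subs),
            self.snp_ids,
            self.chromosomes.copy(),
            self.positions.copy(),
            maf,
            np.packbits(minor, axis=1),
            np.packbits(call, axis=1),
        )


@dataclass
class TagRecord:
    """One sequence tag and its presence pattern over the taxa."""

    sequence: str
    presence: np.ndarray  # packed uint8
    count: int = field(default=0)

    def __post_init__(self) -> None:
        if not set(self.sequence) <= _ACGT:
            raise ValueError("tag sequence must be ACGT only")
        if self.count == 0:
            self.count = bitset.popcount(self.presence)
        if self.count < 1:
            raise ValueError("tag must be present in at least one taxon")


class TagPresenceMatrix:
    """Tags x taxa presence bitsets; taxa order must match the SNP matrix."""

    def __init__(self, taxa: TaxaList, sequences: Sequence[str], presence_packed: np.ndarray):
        self.taxa = taxa
        self.sequences = list(sequences)
        self.presence_packed = presence_packed
        if presence_packed.shape != (len(self.sequences), bitset.n_bytes(len(taxa))):
            raise ValueError("presence matrix shape mismatch")
        self.counts = np.bitwise_count(presence_packed).sum(axis=1, dtype=np.int64)
        if len(self.sequences) and self.counts.min() < 1:
            raise ValueError("every tag must be present in at least one taxon")

    def __len__(self) -> int:
        return len(self.sequences)

    def record(self, i: int) -> TagRecord:
        return TagRecord(self.sequences[i], self.presence_packed[i], int(self.counts[i]))

    def __iter__(self) -> Iterator[TagRecord]:
        return (self.record(i) for i in range(len(self)))


@dataclass
class Anchor:
    """A selected tag: genetic position that passed the accuracy filter."""

    sequence: str
    method: str  # G | J | GJ
    pos: GenomePosition
    p_value: float
    predicted_distance: float
    pav_flag: bool = False
    physical_pos: GenomePosition | None = None
    best_snp_id: str | None = None


class AnchorSet:
    """The pipeline's product: accuracy-filtered tags with positions."""

    def __init__(self, anchors: Sequence[Anchor]):
        self.anchors = sorted(anchors, key=lambda a: a.sequence)

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self) -> Iterator[Anchor]:
        return iter(self.anchors)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnchorSet) or len(self) != len(other):
            return False
        for a, b in zip(self.anchors, other.anchors):
            if (
                a.sequence != b.sequence
                or a.method != b.method
                or a.pos != b.pos
                or a.pav_flag != b.pav_flag
                or a.physical_pos != b.physical_pos
                or abs(a.p_value - b.p_value) > 1e-300 + 1e-9 * abs(b.p_value)
                or abs(a.predicted_distance - b.predicted_distance) > 1e-6 * (1 + abs(b.predicted_distance))
            ):
                return False
        return True
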