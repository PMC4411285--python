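"""Synthetic populations for exercising the anchor-mapping pipeline.

Two designs are generated, mirroring the population types the mapping
methods assume:

* **NAM mode** — nested association mapping: several biparental RIL families
  that share a common parent, each family selfed to near-homozygosity.
* **Panel mode** — a structured diversity panel: founders drawn from a few
  ancestral subpopulations (Balding–Nichols differentiated allele
  frequencies).  Panel parents are *ancestral mosaics* of the founder
  haplotypes — segment lengths follow the Poisson process accumulated over
  ``ancestral_generations`` of random mating in a large population — so the
  panel carries the deep recombination history that gives diverse panels
  their fast LD decay, which a biparental family does not have.  Individuals
  are within-subpopulation crosses of two mosaics (with a small admixture
  rate), then selfed.

Inheritance is tracked as founder-ancestry mosaics along each chromosome
under a Haldane (no-interference) crossover model.  SNP genotypes follow
from founder alleles; each tag marks one founder's haplotype at one locus,
so a taxon carries the tag iff it inherited that founder's segment there.
This reproduces the two statistical features the pipeline relies on: local
LD between a tag and nearby SNPs, and population-structure confounding of
tag presence.

A configurable fraction of tags are presence/absence variants (PAVs):
their sequence is left out of the generated reference genome entirely, or
planted once as a distant decoy, so both PAV branches (no alignment /
alignment far from the genetic position) are exercised.  Everything is
driven by one seed; identical seeds give bit-identical bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import SNPGenotypeMatrix, TagPresenceMatrix, TaxaList

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """All knobs of the simulator, with desk-scale defaults.

    The default scale — 400 taxa, 2 chromosomes x 50 Mb, 2,000 SNPs,
    1,000 tags, 26% PAV — is the standard benchmark used throughout the
    test-suite and the acceptance script.
    """

    seed: int = 0
    mode: str = "panel"  # "panel" | "nam"
    n_chromosomes: int = 2
    chromosome_length_bp: int = 50_000_000
    n_founders: int = 6
    n_ancestral_subpops: int = 3
    fst: float = 0.1
    admix_rate: float = 0.45
    n_families: int = 5
    ril_per_family: int = 80
    n_taxa: int = 400  # panel mode size; NAM size = n_families * ril_per_family
    n_snps: int = 2000
    n_tags: int = 1000
    tag_length: int = 64
    pav_fraction: float = 0.26
    decoy_fraction: float = 0.5
    decoy_min_distance_bp: int = 50_000_000
    decoy_mismatches: int = 2
    recombination_rate: float = 2.0  # Morgans per chromosome per meiosis
    ancestral_generations: int = 150  # depth of panel-mode recombination history
    missing_rate: float = 0.10
    tag_dropout_rate: float = 0.05
    selfing_generations: int = 6

    def validate(self) -> None:
        if self.mode not in ("panel", "nam"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in (
            "n_chromosomes", "chromosome_length_bp", "n_founders", "n_snps",
            "n_tags", "tag_length", "selfing_generations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.pav_fraction <= 1.0):
            raise ValueError("pav_fraction must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mode == "nam":
            if self.n_families < 1 or self.ril_per_family < 1:
                raise ValueError("NAM mode needs n_families and ril_per_family >= 1")
            if self.n_founders < self.n_families + 1:
                raise ValueError("NAM mode needs n_founders >= n_families + 1")
        if self.mode == "panel":
            if self.n_taxa < 1:
                raise ValueError("panel mode needs n_taxa >= 1")
            if self.n_ancestral_subpops < 1:
                raise ValueError("panel mode needs n_ancestral_subpops >= 1")
            if self.n_founders < 2:
                raise ValueError("panel mode needs >= 2 founders")


@dataclass
class Founders:
    """Founder haplotypes over a common locus grid (SNP loci + tag loci)."""

    cfg: SimConfig
    chrom_of_locus: np.ndarray  # (n_loci,)
    pos_of_locus: np.ndarray  # (n_loci,)
    chrom_bounds: np.ndarray  # (n_chromosomes + 1,) slice offsets into loci
    snp_locus_idx: np.ndarray  # (n_snps,)
    tag_locus_idx: np.ndarray  # (n_tags,)
    founder_alleles: np.ndarray  # (n_founders, n_snps) in {0, 1}
    subpop_of_founder: np.ndarray  # (n_founders,)
    tag_source: np.ndarray  # (n_tags,) founder id whose haplotype carries the tag

    @property
    def mobile_founders(self) -> np.ndarray:
        """Founders whose haplotypes migrate between subpopulations.

        The second (and later) founder of each subpopulation is mobile; the
        first stays private, so the panel carries both structure-confounded
        and well-mixed haplotypes.
        """
        n_sub = int(self.subpop_of_founder.max()) + 1
        ids = np.arange(len(self.subpop_of_founder))
        return ids[ids // n_sub >= 1]

    @property
    def n_loci(self) -> int:
        return len(self.pos_of_locus)


@dataclass
class SimBundle:
    """Everything a pipeline run needs, plus the ground truth to judge it."""

    config: SimConfig
    snps: SNPGenotypeMatrix
    tags: TagPresenceMatrix
    truth: pd.DataFrame  # tag_sequence, chromosome, position, pav, source_founder, aln_*
    reference: dict[str, str] = field(repr=False)


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> Founders:
    """Lay out SNP and tag loci and draw founder haplotypes.

    Panel mode differentiates founder allele frequencies across ancestral
    subpopulations with a Balding–Nichols Beta model at the configured Fst;
    with one subpopulation (or in NAM mode) all founders are exchangeable
    draws from a common frequency.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    # --- loci ---
    per_chrom_snps = _split(cfg.n_snps, cfg.n_chromosomes)
    per_chrom_tags = _split(cfg.n_tags, cfg.n_chromosomes)
    chroms, poss, kinds = [], [], []  # kind 0 = SNP, 1 = tag
    for c in range(cfg.n_chromosomes):
        sp = _unique_positions(rng, per_chrom_snps[c], 1, cfg.chromosome_length_bp)
        tp = _spaced_positions(
            rng, per_chrom_tags[c], 1, cfg.chromosome_length_bp - cfg.tag_length + 1,
            min_gap=cfg.tag_length,
        )
        chroms.append(np.full(len(sp) + len(tp), c + 1))
        poss.append(np.concatenate([sp, tp]))
        kinds.append(np.concatenate([np.zeros(len(sp), int), np.ones(len(tp), int)]))
    chrom_of = np.concatenate(chroms)
    pos_of = np.concatenate(poss)
    kind_of = np.concatenate(kinds)
    order = np.lexsort((kind_of, pos_of, chrom_of))
    chrom_of, pos_of, kind_of = chrom_of[order], pos_of[order], kind_of[order]
    snp_idx = np.flatnonzero(kind_of == 0)
    tag_idx = np.flatnonzero(kind_of == 1)
    # bounds[c] = first locus of chromosome c+1; bounds[-1] = n_loci
    bounds = np.searchsorted(chrom_of, np.arange(1, cfg.n_chromosomes + 2))

    # --- founder subpopulations and alleles ---
    n_sub = cfg.n_ancestral_subpops if cfg.mode == "panel" else 1
    subpop_of_founder = np.arange(cfg.n_founders) % n_sub
    p_anc = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    if n_sub > 1 and 0.0 < cfg.fst < 1.0:
        a = p_anc * (1 - cfg.fst) / cfg.fst
        b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
        sub_freq = rng.beta(a, b, size=(n_sub, cfg.n_snps))
    else:
        sub_freq = np.broadcast_to(p_anc, (n_sub, cfg.n_snps)).copy()
    founder_alleles = (
        rng.random((cfg.n_founders, cfg.n_snps)) < sub_freq[subpop_of_founder]
    ).astype(np.uint8)

    # tags must mark haplotypes that can actually segregate: in a NAM design
    # only the common parent (founder 0) and the family founders are crossed
    n_usable = cfg.n_families + 1 if cfg.mode == "nam" else cfg.n_founders
    tag_source = rng.integers(0, n_usable, size=cfg.n_tags)
    return Founders(
        cfg=cfg,
        chrom_of_locus=chrom_of,
        pos_of_locus=pos_of,
        chrom_bounds=bounds,
        snp_locus_idx=snp_idx,
        tag_locus_idx=tag_idx,
        founder_alleles=founder_alleles,
        subpop_of_founder=subpop_of_founder,
        tag_source=tag_source,
    )


def meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    positions: np.ndarray,
    length_bp: int,
    recombination_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from two parental haplotypes on one chromosome.

    Crossover count is Poisson(recombination_rate) with breakpoints uniform
    on the chromosome (Haldane model); the gamete alternates between the
    parents at each breakpoint, starting from a random parent.
    """
    if hap_a.shape != hap_b.shape or hap_a.shape != positions.shape:
        raise ValueError("haplotype/position length mismatch")
    n_x = rng.poisson(recombination_rate)
    start = rng.integers(0, 2)
    if n_x == 0:
        return (hap_a if start == 0 else hap_b).copy()
    breaks = np.sort(rng.uniform(0, length_bp, size=n_x))
    parity = (np.searchsorted(breaks, positions) + start) % 2
    return np.where(parity == 0, hap_a, hap_b)


def _gamete_genome(f: Founders, hap_a, hap_b, rng) -> np.ndarray:
    out = np.empty_like(hap_a)
    for c in range(f.cfg.n_chromosomes):
        s, e = f.chrom_bounds[c], f.chrom_bounds[c + 1]
        out[s:e] = meiosis(
            hap_a[s:e], hap_b[s:e], f.pos_of_locus[s:e],
            f.cfg.chromosome_length_bp, f.cfg.recombination_rate, rng,
        )
    return out


def _make_inbred(f: Founders, h1: np.ndarray, h2: np.ndarray, rng) -> np.ndarray:
    """Cross two parental haplotypes and self ``selfing_generations`` times."""
    for _ in range(f.cfg.selfing_generations):
        g1 = _gamete_genome(f, h1, h2, rng)
        g2 = _gamete_genome(f, h1, h2, rng)
        h1, h2 = g1, g2
    return np.stack([h1, h2])


def build_nam(cfg: SimConfig, founders: Founders, rng: np.random.Generator) -> tuple[np.ndarray, TaxaList]:
    """Ancestry mosaics for a NAM design: founder 0 is the common parent.

    Family parents are the raw founder lines — a biparental cross has no
    recombination history beyond the pedigree's own meioses.
    """
    names, fams, rows = [], [], []
    for fam in range(1, cfg.n_families + 1):
        h_common = np.full(founders.n_loci, 0, dtype=np.int16)
        h_fam = np.full(founders.n_loci, fam, dtype=np.int16)
        for j in range(cfg.ril_per_family):
            rows.append(_make_inbred(founders, h_common, h_fam, rng))
            names.append(f"F{fam}_RIL{j:03d}")
            fams.append(f"fam{fam}")
    return np.stack(rows), TaxaList(names, families=fams)


def _ancestral_mosaic(
    f: Founders, pool: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One haplotype after ``ancestral_generations`` of random mating.

    Under random mating in a large population, a present-day haplotype is a
    mosaic of founder segments whose breakpoints accumulate as a Poisson
    process of total intensity generations x recombination rate, each
    segment tracing back to a uniformly drawn founder of the subpopulation
    pool.  Sampling the mosaic directly costs O(segments) and avoids the
    drift and fixation a small forward-simulated pool would suffer.
    """
    cfg = f.cfg
    depth = cfg.ancestral_generations * cfg.recombination_rate
    out = np.empty(f.n_loci, dtype=np.int16)
    for c in range(cfg.n_chromosomes):
        s, e = f.chrom_bounds[c], f.chrom_bounds[c + 1]
        n_x = rng.poisson(depth)
        breaks = np.sort(rng.uniform(0, cfg.chromosome_length_bp, size=n_x))
        # per-segment admixture: most segments trace to the subpopulation
        # pool, a fraction to the *mobile* founders of any subpopulation —
        # lineages differ in how much their material migrated, so some
        # founders' haplotypes stay subpopulation-private (tags on them are
        # structure-confounded) while others spread panel-wide
        seg_founder = pool[rng.integers(0, len(pool), size=n_x + 1)]
        mobile = f.mobile_founders
        admixed = rng.random(n_x + 1) < cfg.admix_rate
        if admixed.any() and len(mobile):
            seg_founder = seg_founder.copy()
            seg_founder[admixed] = mobile[
                rng.integers(0, len(mobile), size=admixed.sum())
            ]
        out[s:e] = seg_founder[np.searchsorted(breaks, f.pos_of_locus[s:e])]
    return out


def build_panel(cfg: SimConfig, founders: Founders, rng: np.random.Generator) -> tuple[np.ndarray, TaxaList]:
    """Ancestry mosaics for a structured diversity panel."""
    n_sub = int(founders.subpop_of_founder.max()) + 1
    by_sub = [np.flatnonzero(founders.subpop_of_founder == s) for s in range(n_sub)]
    all_founders = np.arange(cfg.n_founders)
    names, subs, rows = [], [], []
    for j in range(cfg.n_taxa):
        s = j % n_sub
        h1 = _ancestral_mosaic(founders, by_sub[s], rng)
        h2 = _ancestral_mosaic(founders, by_sub[s], rng)
        rows.append(_make_inbred(founders, h1, h2, rng))
        names.append(f"P{j:04d}")
        subs.append(f"pop{s}")
    return np.stack(rows), TaxaList(names, subpops=subs)


def _random_tag_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        codes = rng.integers(0, 4, size=length)
        s = _BASES[codes].tobytes().decode()
        if s not in seqs:
            seqs.add(s)
            out.append(s)
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_population(cfg: SimConfig) -> SimBundle:
    """Full generator: founders -> population -> genotypes, tags, reference, truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    founders = simulate_founders(cfg, rng)
    if cfg.mode == "nam":
        ancestry, taxa = build_nam(cfg, founders, rng)
    else:
        ancestry, taxa = build_panel(cfg, founders, rng)
    return assemble_bundle(cfg, founders, ancestry, taxa, rng)


def assemble_bundle(
    cfg: SimConfig,
    founders: Founders,
    ancestry: np.ndarray,
    taxa: TaxaList,
    rng: np.random.Generator,
) -> SimBundle:
    """Turn ancestry mosaics into observable matrices, reference and truth."""
    n_taxa = len(taxa)

    # --- SNP genotypes ---
    # genotype calls are homozygous: reported allele = first haplotype's.
    # After several selfing generations residual heterozygosity is a couple
    # of percent, and GBS callers on inbreds emit hom calls, so the panel's
    # MAF is exactly the per-taxon allele-vote frequency the readers use.
    anc_snp = ancestry[:, 0, founders.snp_locus_idx]  # (taxa, snps)
    col = np.arange(len(founders.snp_locus_idx))
    allele = founders.founder_alleles[anc_snp, col]  # (taxa, snps) in {0, 1}
    called = rng.random(allele.shape) >= cfg.missing_rate
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = (allele * called).sum(axis=0) / np.maximum(n_called, 1)
    minor_is_1 = freq1 <= 0.5
    maf = np.where(minor_is_1, freq1, 1.0 - freq1)
    keep = (n_called > 0) & (maf > 0.0)
    carrier = (allele == minor_is_1[None, :].astype(np.uint8)) & called
    chroms = founders.chrom_of_locus[founders.snp_locus_idx]
    poss = founders.pos_of_locus[founders.snp_locus_idx]
    kidx = np.flatnonzero(keep)
    log.info("simulated %d SNPs (%d dropped as monomorphic)", keep.sum(), (~keep).sum())
    snps = SNPGenotypeMatrix(
        taxa,
        [f"S{c}_{p}" for c, p in zip(chroms[kidx], poss[kidx])],
        chroms[kidx],
        poss[kidx],
        maf[kidx],
        np.packbits(carrier[:, kidx].T, axis=1),
        np.packbits(called[:, kidx].T, axis=1),
    )

    # --- tags ---
    anc_tag = ancestry[:, :, founders.tag_locus_idx]  # (taxa, 2, tags)
    present_true = (anc_tag == founders.tag_source[None, None, :]).any(axis=1)
    observed = present_true & (rng.random(present_true.shape) >= cfg.tag_dropout_rate)
    tag_chrom = founders.chrom_of_locus[founders.tag_locus_idx]
    tag_pos = founders.pos_of_locus[founders.tag_locus_idx]
    seqs = _random_tag_sequences(rng, cfg.n_tags, cfg.tag_length)
    is_pav = rng.random(cfg.n_tags) < cfg.pav_fraction
    has_decoy = is_pav & (rng.random(cfg.n_tags) < cfg.decoy_fraction)

    keep_tag = observed.any(axis=0)
    log.info("simulated %d tags observed in >=1 taxon (of %d)", keep_tag.sum(), cfg.n_tags)

    # --- reference with planted tags and PAV decoys ---
    reference, aln_chrom, aln_pos = _build_reference(
        cfg, rng, seqs, tag_chrom, tag_pos, is_pav, has_decoy
    )

    tidx = np.flatnonzero(keep_tag)
    tags = TagPresenceMatrix(
        taxa, [seqs[i] for i in tidx], np.packbits(observed[:, tidx].T, axis=1)
    )
    truth = pd.DataFrame(
        {
            "tag_sequence": [seqs[i] for i in tidx],
            "chromosome": tag_chrom[tidx],
            "position": tag_pos[tidx],
            "pav": is_pav[tidx].astype(int),
            "source_founder": founders.tag_source[tidx],
            "aln_chromosome": pd.array(
                [aln_chrom[i] for i in tidx], dtype="Int64"
            ),
            "aln_position": pd.array([aln_pos[i] for i in tidx], dtype="Int64"),
        }
    )
    return SimBundle(config=cfg, snps=snps, tags=tags, truth=truth, reference=reference)


def _build_reference(cfg, rng, seqs, tag_chrom, tag_pos, is_pav, has_decoy):
    """Random ACGT chromosomes with each non-PAV tag planted exactly once.

    PAV tags are absent, except that a configurable half receive one decoy
    occurrence at least ``decoy_min_distance_bp`` away (on another
    chromosome when the chromosome is too short to hold that distance).
    Decoy copies carry ``decoy_mismatches`` substitutions: a distant copy
    of sequence missing from its orthologous region is a diverged paralog,
    so a perfect full-length duplicate would be unrealistic — and an exact
    matcher must not rediscover it.
    """
    L = cfg.chromosome_length_bp
    chrom_codes = [rng.integers(0, 4, size=L, dtype=np.uint8) for _ in range(cfg.n_chromosomes)]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(cfg.n_chromosomes)]
    aln_chrom: list[int | None] = [None] * cfg.n_tags
    aln_pos: list[int | None] = [None] * cfg.n_tags

    code_of = np.zeros(128, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        code_of[ord(b)] = i

    def plant(c: int, pos: int, seq: str) -> None:
        codes = code_of[np.frombuffer(seq.encode(), dtype=np.uint8)]
        chrom_codes[c - 1][pos - 1 : pos - 1 + len(seq)] = codes
        occupied[c - 1].append((pos, pos + len(seq) - 1))

    def overlaps(c: int, pos: int, length: int) -> bool:
        end = pos + length - 1
        return any(s <= end and pos <= e for s, e in occupied[c - 1])

    for i, seq in enumerate(seqs):
        if not is_pav[i]:
            plant(int(tag_chrom[i]), int(tag_pos[i]), seq)
            aln_chrom[i], aln_pos[i] = int(tag_chrom[i]), int(tag_pos[i])
    for i, seq in enumerate(seqs):
        if is_pav[i] and has_decoy[i]:
            c, p = _decoy_site(cfg, rng, int(tag_chrom[i]), int(tag_pos[i]), overlaps)
            if c is not None:
                plant(c, p, _mutate(seq, cfg.decoy_mismatches, rng))
                aln_chrom[i], aln_pos[i] = c, p

    reference = {
        f"chr{c + 1}": _BASES[chrom_codes[c]].tobytes().decode()
        for c in range(cfg.n_chromosomes)
    }
    return reference, aln_chrom, aln_pos


def _mutate(seq: str, n_mismatches: int, rng: np.random.Generator) -> str:
    if n_mismatches <= 0:
        return seq
    out = list(seq)
    for i in rng.choice(len(seq), size=min(n_mismatches, len(seq)), replace=False):
        out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def _decoy_site(cfg, rng, true_chrom, true_pos, overlaps):
    L = cfg.chromosome_length_bp
    for _ in range(100):
        c = int(rng.integers(1, cfg.n_chromosomes + 1))
        p = int(rng.integers(1, L - cfg.tag_length + 2))
        if c == true_chrom:
            if abs(p - true_pos) < cfg.decoy_min_distance_bp:
                continue
        if not overlaps(c, p, cfg.tag_length):
            return c, p
    return None, None  # no admissible decoy site (e.g. single short chromosome)


# --- trait simulation (test utility for the enrichment stage) ---

def simulate_trait(
    snps: SNPGenotypeMatrix,
    causal_idx: np.ndarray,
    effect_size: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive trait: ``effect_size`` per minor allele at each causal SNP, unit noise."""
    n_taxa = len(snps.taxa)
    y = rng.standard_normal(n_taxa)
    for j in causal_idx:
        g = np.unpackbits(snps.minor_packed[j], count=n_taxa).astype(float)
        y += effect_size * g
    return y


def single_marker_pvalues(snps: SNPGenotypeMatrix, y: np.ndarray) -> np.ndarray:
    """Per-SNP simple-regression p-values (test utility, not a GWAS).

    Pearson correlation t-test of trait against the 0/1 minor-allele
    indicator over non-missing calls.
    """
    from scipy import stats

    n_taxa = len(snps.taxa)
    out = np.ones(len(snps))
    for j in range(len(snps)):
        g = np.unpackbits(snps.minor_packed[j], count=n_taxa).astype(float)
        m = np.unpackbits(snps.call_packed[j], count=n_taxa).astype(bool)
        if g[m].std() == 0 or y[m].std() == 0:
            continue
        r, p = stats.pearsonr(g[m], y[m])
        out[j] = p
    return out


# --- truth-table I/O ---

def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"aln_chromosome": "Int64", "aln_position": "Int64"}
    )


# --- helpers ---

def _split(n: int, k: int) -> list[int]:
    base = n // k
    return [base + (1 if i < n % k else 0) for i in range(k)]


def _unique_positions(rng, n, lo, hi) -> np.ndarray:
    pos = np.unique(rng.integers(lo, hi + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(lo, hi + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos)


def _spaced_positions(rng, n, lo, hi, min_gap) -> np.ndarray:
    """n sorted positions in [lo, hi] pairwise at least min_gap apart."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if (hi - lo) < (n - 1) * min_gap:
        raise ValueError("chromosome too short for requested tag density")
    for _ in range(1000):
        pos = np.sort(rng.integers(lo, hi + 1, size=n))
        if n == 1 or np.diff(pos).min() >= min_gap:
            return pos
        # keep the conforming prefix, redraw the rest
        bad = np.flatnonzero(np.diff(pos) < min_gap)
        pos = np.delete(pos, bad + 1)
        extra = _spaced_positions(rng, n - len(pos), lo, hi, min_gap)
        merged = np.sort(np.concatenate([pos, extra]))
        if np.diff(merged).min() >= min_gap:
            return merged
    raise RuntimeError("could not place tags with required spacing")
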