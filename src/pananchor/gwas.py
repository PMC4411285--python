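"""Population-wide binomial association scan.

Each tag's presence/absence pattern is tested against every SNP.  Under the
null of no linkage, the number of minor-allele carriers among the taxa that
carry the tag is X ~ B(n, p), where n is the popcount of
``tag_presence AND snp_call_mask`` and p is the SNP's panel-wide MAF.  A tag
co-segregating with either allele of a nearby SNP produces an extreme X, so
the test is two-sided (doubled smaller tail) by default.  The SNP with the
lowest p-value locates the tag; tags are mapped when that p-value clears a
genome-wide threshold (default 1e-6) and the tag is carried by at least
``min_tag_count`` taxa (default 30).

Population structure is deliberately not corrected here — the scan trades
that for speed, and structure-driven mismapping is handled downstream by
the accuracy model's attributes.

p-values are computed in log space: with hundreds of taxa in perfect LD the
tail probability underflows double precision, so ranking and the attribute
extraction use ``neg_log10_p`` while ``p_value`` carries the (possibly
underflowed) probability for reporting.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from . import bitset
from .datamodel import GenomePosition, SNPGenotypeMatrix, TagPresenceMatrix

log = logging.getLogger(__name__)

MAX_PROFILE_SNPS = 1000  # retained sub-threshold profile cap per tag

_LN10 = np.log(10.0)


def binomial_tail_p(x: int, n: int, p: float, alternative: str = "two-sided") -> float:
    """Exact binomial tail p-value for X ~ B(n, p).

    Two-sided value is ``min(1, 2 * min(P(X<=x), P(X>=x)))``; evaluated via
    the regularized incomplete beta function, accurate to ~1e-12 relative
    for n up to 1e4.  ``n == 0`` returns 1 (no data).
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if x < 0 or x > n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    if n == 0:
        return 1.0
    lower = binom.cdf(x, n, p)
    upper = binom.sf(x - 1, n, p)
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * min(lower, upper)))
    if alternative == "greater":
        return float(upper)
    if alternative == "less":
        return float(lower)
    raise ValueError(f"unknown alternative {alternative!r}")


def _neg_log10_tail(x: np.ndarray, n: np.ndarray, p: np.ndarray, alternative: str) -> np.ndarray:
    """Vectorised -log10 of the tail p-value, stable far below underflow."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = binom.logcdf(x, n, p)
        hi = binom.logsf(x - 1, n, p)
    if alternative == "two-sided":
        lnp = np.minimum(0.0, np.log(2.0) + np.minimum(lo, hi))
    elif alternative == "greater":
        lnp = np.minimum(0.0, hi)
    else:
        lnp = np.minimum(0.0, lo)
    lnp = np.where(np.asarray(n) == 0, 0.0, lnp)
    return -lnp / _LN10


@dataclass
class MappingResult:
    """Best association of one tag: its genetic position and evidence profile."""

    tag_index: int
    sequence: str
    method: str  # G | J (GJ assigned at the pipeline level)
    pos: GenomePosition
    best_snp_index: int
    p_value: float
    neg_log10_p: float
    second_best_neg_log10_p: float  # best evidence on a different chromosome
    n: int
    x: int
    tag_count: int
    n_sig_snps: int
    sig_snp_indices: np.ndarray = field(repr=False)
    sig_neg_log10_p: np.ndarray = field(repr=False)
    # joint-linkage extras (J method only)
    n_segregating_families: int | None = None
    group_family_count: int | None = None
    n_families: int | None = None


@dataclass
class UnmappedTag:
    tag_index: int
    sequence: str
    reason: str  # below-count | no-significant-SNP


def map_tag_gwas(
    tag_index: int,
    tags: TagPresenceMatrix,
    snps: SNPGenotypeMatrix,
    min_tag_count: int = 30,
    threshold: float = 1e-6,
    alternative: str = "two-sided",
) -> MappingResult | UnmappedTag:
    """Scan one tag against every SNP; see module docstring for the model."""
    if tags.taxa != snps.taxa:
        raise ValueError("tag and SNP matrices must share the same taxa order")
    seq = tags.sequences[tag_index]
    count = int(tags.counts[tag_index])
    if count < min_tag_count:
        return UnmappedTag(tag_index, seq, "below-count")
    presence = tags.presence_packed[tag_index]
    n = bitset.intersect_count_many(snps.call_packed, presence)
    x = bitset.intersect_count_many(snps.minor_packed, presence)
    neglog = _neg_log10_tail(x, n, snps.mafs, alternative)
    return _best_result(
        tag_index, seq, "G", count, n, x, neglog, snps, threshold,
        snps.global_positions,
    )


def _best_result(tag_index, seq, method, count, n, x, neglog, snps, threshold, global_pos):
    """Pick the lowest p-value (ties -> smallest global position); build the profile."""
    thr_neglog = -np.log10(threshold)
    order = np.lexsort((global_pos, -neglog))
    best = order[0]
    if not (neglog[best] > thr_neglog):
        return UnmappedTag(tag_index, seq, "no-significant-SNP")
    sig = np.flatnonzero(neglog > thr_neglog)
    n_sig = len(sig)
    if n_sig > MAX_PROFILE_SNPS:
        keep = np.argsort(-neglog[sig], kind="stable")[:MAX_PROFILE_SNPS]
        sig = np.sort(sig[keep])
    other = snps.chromosomes != snps.chromosomes[best]
    second = float(neglog[other].max()) if other.any() else 0.0
    return MappingResult(
        tag_index=tag_index,
        sequence=seq,
        method=method,
        pos=GenomePosition(int(snps.chromosomes[best]), int(snps.positions[best])),
        best_snp_index=int(best),
        p_value=float(10.0 ** (-min(neglog[best], 320.0)))
        if neglog[best] < 320
        else 0.0,
        neg_log10_p=float(neglog[best]),
        second_best_neg_log10_p=second,
        n=int(n[best]),
        x=int(x[best]),
        tag_count=count,
        n_sig_snps=int(n_sig),
        sig_snp_indices=sig,
        sig_neg_log10_p=neglog[sig],
    )


def map_all_gwas(
    tags: TagPresenceMatrix,
    snps: SNPGenotypeMatrix,
    min_tag_count: int = 30,
    threshold: float = 1e-6,
    alternative: str = "two-sided",
    workers: int = 1,
) -> tuple[list[MappingResult], list[UnmappedTag]]:
    """Scan every tag.  Results are identical for any worker count."""

    def run_chunk(idx):
        return [
            map_tag_gwas(i, tags, snps, min_tag_count, threshold, alternative)
            for i in idx
        ]

    indices = np.arange(len(tags))
    if workers <= 1 or len(tags) < 2:
        outputs = run_chunk(indices)
    else:
        chunks = np.array_split(indices, workers * 4)
        with ThreadPoolExecutor(max_workers=workers) as pool:
            outputs = [r for part in pool.map(run_chunk, chunks) for r in part]
    mapped = [r for r in outputs if isinstance(r, MappingResult)]
    unmapped = [r for r in outputs if isinstance(r, UnmappedTag)]
    reasons: dict[str, int] = {}
    for u in unmapped:
        reasons[u.reason] = reasons.get(u.reason, 0) + 1
    log.info(
        "GWAS scan: %d/%d tags mapped (unmapped reasons: %s)",
        len(mapped), len(tags), reasons or "none",
    )
    return mapped, unmapped
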