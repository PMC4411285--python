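"""Presence/absence variant (PAV) calling.

A mapped tag whose sequence has no alignment on the chromosome of its
genetic position within a 10-Mb window is classified as a PAV — it tags
sequence that is missing from the orthologous region of the reference.
Two branches exist: the tag aligns nowhere at all, or it aligns only far
from (or on a different chromosome than) its genetic position.

Alignments are ingested from SAM/BED/TSV produced by an external aligner,
or computed by the built-in exact matcher, which reports every perfect
occurrence of each tag (both strands) in a reference FASTA.  The matcher
uses a vectorised 64-mer rolling hash (odd base, arithmetic mod 2^64, so
per-window hashes are recovered with modular inverses) with candidate hits
verified by direct string comparison.

PAV density along the genome is reported per 1-Mb window as the ratio of
PAV tags to reference tags in the window, normalising away the restriction
-site and methylation biases that make raw tag counts uneven.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import Anchor, GenomePosition, global_position

log = logging.getLogger(__name__)

PAV_WINDOW_BP = 10_000_000
DENSITY_WINDOW_BP = 1_000_000

_HASH_BASE = np.uint64(0x100000001B3)  # odd, so invertible mod 2^64


@dataclass
class TagAlignment:
    """All reference alignments of one tag."""

    tag_id: str  # the tag sequence
    positions: list[GenomePosition]
    perfect: list[bool]

    @property
    def unique_hit(self) -> bool:
        return len(self.positions) == 1

    @property
    def is_uabt(self) -> bool:
        """Uniquely aligned reference tag: exactly one hit, perfect match."""
        return self.unique_hit and self.perfect[0]


@dataclass
class PavCall:
    tag_id: str
    pav_flag: bool
    reason: str | None  # no-alignment | no-alignment-within-window
    nearest_distance: int | None  # global-position distance to nearest alignment


# --------------------------------------------------------------------------
# alignment ingestion
# --------------------------------------------------------------------------

def ingest_alignments(path: str | Path, format: str | None = None) -> list[TagAlignment]:
    """Read alignments from SAM, BED or alignment TSV.

    Positions are returned 1-based.  SAM unmapped records yield empty
    alignment lists; the perfect-match flag requires full-length,
    edit-distance-0 evidence (NM tag 0 and an all-match CIGAR) and is False
    when that evidence is absent.  BED intervals (0-based half-open) are
    converted to 1-based starts.
    """
    path = Path(path)
    if format is None:
        format = {".sam": "sam", ".bed": "bed"}.get(path.suffix.lower(), "tsv")
    if format == "sam":
        return _ingest_sam(path)
    if format == "bed":
        return _ingest_bed(path)
    if format == "tsv":
        return _ingest_tsv(path)
    raise ValueError(f"unknown alignment format {format!r}")


def _chrom_number(name: str) -> int:
    return int(str(name).lower().removeprefix("chr"))


def _ingest_sam(path: Path) -> list[TagAlignment]:
    import pysam

    by_tag: dict[str, TagAlignment] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            # tags are identified by sequence; aligner input usually names
            # the read with it, so the query name is the id, falling back
            # to the query sequence (secondary records keep the name)
            tag_id = rec.query_name or rec.query_sequence
            if tag_id is None:
                log.warning("skipping SAM record with no resolvable tag id")
                continue
            aln = by_tag.setdefault(tag_id, TagAlignment(tag_id, [], []))
            if rec.is_unmapped:
                continue
            perfect = False
            if rec.cigartuples is not None:
                full = all(op in (0, 7) for op, _ in rec.cigartuples)
                nm = rec.get_tag("NM") if rec.has_tag("NM") else None
                perfect = full and nm == 0
            aln.positions.append(
                GenomePosition(_chrom_number(rec.reference_name), rec.reference_start + 1)
            )
            aln.perfect.append(perfect)
    return list(by_tag.values())


def _ingest_bed(path: Path) -> list[TagAlignment]:
    by_tag: dict[str, TagAlignment] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs chrom,start,end,name")
            aln = by_tag.setdefault(f[3], TagAlignment(f[3], [], []))
            aln.positions.append(GenomePosition(_chrom_number(f[0]), int(f[1]) + 1))
            aln.perfect.append(False)
    return list(by_tag.values())


def _ingest_tsv(path: Path) -> list[TagAlignment]:
    """Columns: tag, chr, pos, perfect (0/1); pos empty for an unaligned tag."""
    by_tag: dict[str, TagAlignment] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["tag", "chr", "pos", "perfect"]:
            raise ValueError(f"{path}: unexpected alignment TSV header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            aln = by_tag.setdefault(f[0], TagAlignment(f[0], [], []))
            if f[1]:
                aln.positions.append(GenomePosition(int(f[1]), int(f[2])))
                aln.perfect.append(bool(int(f[3])))
    return list(by_tag.values())


def write_alignments(alignments: list[TagAlignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tchr\tpos\tperfect\tn_hits\n")
        for a in alignments:
            if not a.positions:
                fh.write(f"{a.tag_id}\t\t\t\t0\n")
            for p, perf in zip(a.positions, a.perfect):
                fh.write(
                    f"{a.tag_id}\t{p.chromosome}\t{p.position}\t{int(perf)}\t{len(a.positions)}\n"
                )


# --------------------------------------------------------------------------
# built-in exact matcher
# --------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _seq_codes(seq: str) -> np.ndarray:
    table = np.zeros(128, dtype=np.uint64)
    for i, b in enumerate(b"ACGT"):
        table[b] = i + 1  # 0 left for non-ACGT so they never match
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling hash of every k-window: sum codes[i+j] * BASE^(k-1-j) mod 2^64."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    with np.errstate(over="ignore"):
        powers = np.empty(n, dtype=np.uint64)
        powers[0] = 1
        powers[1:] = np.multiply.accumulate(np.full(n - 1, _HASH_BASE, dtype=np.uint64))
        inv_base = np.uint64(pow(int(_HASH_BASE), -1, 1 << 64))
        inv_powers = np.empty(n - k + 1, dtype=np.uint64)
        inv_powers[0] = 1
        if n - k > 0:
            inv_powers[1:] = np.multiply.accumulate(
                np.full(n - k, inv_base, dtype=np.uint64)
            )
        weighted = codes * powers[::-1]  # codes[t] * BASE^(n-1-t)
        prefix = np.cumsum(weighted, dtype=np.uint64)
        win = prefix[k - 1 :].copy()
        win[1:] -= prefix[: n - k]
        # win[i] = hash(i) * BASE^(n-k-i); multiply by the inverse power
        win *= inv_powers[::-1]
    return win


def _hash_sequence(seq: str) -> np.uint64:
    codes = _seq_codes(seq)
    with np.errstate(over="ignore"):
        k = len(codes)
        powers = np.empty(k, dtype=np.uint64)
        powers[0] = 1
        if k > 1:
            powers[1:] = np.multiply.accumulate(np.full(k - 1, _HASH_BASE, dtype=np.uint64))
        return np.uint64((codes * powers[::-1]).sum(dtype=np.uint64))


def exact_match_align(
    sequences: list[str], reference: dict[str, str]
) -> list[TagAlignment]:
    """All exact occurrences of each tag in the reference, both strands.

    Every reported hit is a perfect match by construction.  Hit positions
    are 1-based leftmost reference coordinates regardless of strand.
    """
    if not sequences:
        return []
    k = len(sequences[0])
    if any(len(s) != k for s in sequences):
        raise ValueError("all tag sequences must have equal length")
    lookup: dict[int, list[int]] = {}
    queries: list[tuple[int, str]] = []  # (tag index, oriented sequence)
    for i, s in enumerate(sequences):
        for orient in (s, _revcomp(s)):
            h = int(_hash_sequence(orient))
            lookup.setdefault(h, []).append(len(queries))
            queries.append((i, orient))
    hash_keys = np.sort(np.fromiter(lookup.keys(), dtype=np.uint64, count=len(lookup)))

    hits: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(sequences))}
    for chrom_name, seq in reference.items():
        chrom = _chrom_number(chrom_name)
        codes = _seq_codes(seq)
        win = _window_hashes(codes, k)
        # membership against the small sorted key set; np.isin would sort
        # the ~chromosome-length hash array instead
        pos_in_keys = np.searchsorted(hash_keys, win)
        pos_in_keys[pos_in_keys == len(hash_keys)] = 0
        cand = np.flatnonzero(hash_keys[pos_in_keys] == win)
        for pos0 in cand:
            sub = seq[pos0 : pos0 + k]
            for qi in lookup.get(int(win[pos0]), []):
                ti, oriented = queries[qi]
                if sub == oriented:
                    hit = (chrom, int(pos0) + 1)
                    if hit not in hits[ti]:
                        hits[ti].append(hit)
        del codes, win
    out = []
    for i, s in enumerate(sequences):
        pos = sorted(hits[i])
        out.append(
            TagAlignment(s, [GenomePosition(c, p) for c, p in pos], [True] * len(pos))
        )
    return out


# --------------------------------------------------------------------------
# classification and density
# --------------------------------------------------------------------------

def classify_pav(
    anchor: Anchor, alignment: TagAlignment | None, window_bp: int = PAV_WINDOW_BP
) -> PavCall:
    """PAV iff no alignment on the anchor's chromosome within window_bp.

    The window is read as a maximum distance of ``window_bp`` from the
    genetic position on the same chromosome (use window_bp/2 for the
    symmetric-region reading).
    """
    if alignment is None or not alignment.positions:
        return PavCall(anchor.sequence, True, "no-alignment", None)
    g = global_position(anchor.pos)
    nearest = min(abs(global_position(p) - g) for p in alignment.positions)
    within = any(
        p.chromosome == anchor.pos.chromosome
        and abs(p.position - anchor.pos.position) <= window_bp
        for p in alignment.positions
    )
    if within:
        return PavCall(anchor.sequence, False, None, nearest)
    return PavCall(anchor.sequence, True, "no-alignment-within-window", nearest)


def pav_density(
    calls: list[PavCall],
    anchors: "AnchorSetLike",
    alignments: dict[str, TagAlignment],
    window_bp: int = DENSITY_WINDOW_BP,
) -> pd.DataFrame:
    """Per-window PAV density: count(PAV anchors) / count(reference-tag anchors).

    PAV anchors are binned at their genetic position, reference tags (those
    with at least one perfect alignment) at their alignment position.
    Windows with zero reference tags get a missing value, not infinity.
    """
    pav_of = {c.tag_id: c.pav_flag for c in calls}
    pav_bins: dict[tuple[int, int], int] = {}
    ref_bins: dict[tuple[int, int], int] = {}
    max_win: dict[int, int] = {}

    def bump(bins, chrom, pos):
        w = (pos - 1) // window_bp
        bins[(chrom, w)] = bins.get((chrom, w), 0) + 1
        max_win[chrom] = max(max_win.get(chrom, 0), w)

    for a in anchors:
        if pav_of.get(a.sequence, False):
            bump(pav_bins, a.pos.chromosome, a.pos.position)
        else:
            aln = alignments.get(a.sequence)
            if aln and any(aln.perfect):
                p = aln.positions[aln.perfect.index(True)]
                bump(ref_bins, p.chromosome, p.position)
    rows = []
    for chrom in sorted(max_win):
        for w in range(max_win[chrom] + 1):
            n_pav = pav_bins.get((chrom, w), 0)
            n_ref = ref_bins.get((chrom, w), 0)
            rows.append(
                {
                    "chromosome": chrom,
                    "window_start": w * window_bp + 1,
                    "window_end": (w + 1) * window_bp,
                    "n_pav": n_pav,
                    "n_reference": n_ref,
                    "density": n_pav / n_ref if n_ref > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
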