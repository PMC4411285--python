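"""Readers and writers for the pipeline's plain-text formats.

Formats:

* HapMap-style genotype TSV: columns ``rs  alleles  chrom  pos`` then one
  column per taxon holding a single IUPAC letter (homozygous base, het code,
  or N for missing).  The usual exchange format for inbred GBS genotypes.
* VCF 4.x via pysam: biallelic SNP records only; anything else is skipped
  with a warning.
* Tag presence TSV: ``tag_sequence`` then one 0/1 column per taxon; or a
  FASTA of tag sequences plus a TSV listing the taxa each tag is present in.
* Anchor TSV: the pipeline product, one row per selected tag.

MAF is computed panel-wide over non-missing calls, each inbred taxon counted
once.  A frequency tie at 0.5 takes the lexicographically smaller allele as
minor, for determinism.
"""

from __future__ import annotations

import logging
from pathlib import Path
import numpy as np

from . import bitset
from .datamodel import (
    Anchor,
    AnchorSet,
    GenomePosition,
    SNPGenotypeMatrix,
    TagPresenceMatrix,
    TaxaList,
)

log = logging.getLogger(__name__)

# IUPAC heterozygote codes -> allele pair
_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
_HOM = {"A", "C", "G", "T"}


class ParseError(ValueError):
    pass


def _finalize_site(
    allele_of: list[str | None], het_policy: str
) -> tuple[np.ndarray, np.ndarray, float, str, str] | None:
    """Turn per-taxon allele calls into (minor bits, call bits, maf, minor, major).

    ``allele_of[i]`` is a base letter, a het code, or None (missing).
    Returns None for monomorphic / MAF-0 / multi-allelic sites.
    """
    counts: dict[str, float] = {}
    called = np.zeros(len(allele_of), dtype=bool)
    dose: list[dict[str, float]] = []
    for i, a in enumerate(allele_of):
        d: dict[str, float] = {}
        if a is None:
            dose.append(d)
            continue
        if a in _HOM:
            d[a] = 1.0
        elif a in _HET:
            if het_policy == "missing":
                dose.append(d)
                continue
            x, y = _HET[a]
            d[x] = 0.5
            d[y] = 0.5
        else:
            raise ParseError(f"unrecognised genotype letter {a!r}")
        called[i] = True
        for b, w in d.items():
            counts[b] = counts.get(b, 0.0) + w
        dose.append(d)
    alleles = sorted(counts)
    if len(alleles) != 2:
        if len(alleles) > 2:
            log.warning("skipping multi-allelic site (%d alleles)", len(alleles))
        return None
    total = counts[alleles[0]] + counts[alleles[1]]
    f0 = counts[alleles[0]] / total
    # minor = rarer allele; tie at 0.5 -> lexicographically smaller
    minor = alleles[0] if f0 <= 0.5 else alleles[1]
    major = alleles[1] if minor == alleles[0] else alleles[0]
    maf = counts[minor] / total
    if maf <= 0.0:
        return None
    minor_bits = np.zeros(len(allele_of), dtype=bool)
    for i, d in enumerate(dose):
        # het under policy "minor": the taxon carries the minor allele
        if d.get(minor, 0.0) > 0:
            minor_bits[i] = True
    return minor_bits, called, maf, minor, major


def read_snp_matrix(
    path: str | Path, format: str = "hapmap", het_policy: str = "minor"
) -> SNPGenotypeMatrix:
    """Read a genotype matrix from HapMap-style TSV or VCF.

    Monomorphic and MAF-0 sites are dropped (count logged); multi-allelic
    sites are skipped with a warning.  ``het_policy`` is "minor" (a het taxon
    counts as carrying the minor allele; the default — heterozygotes are rare
    in inbred panels) or "missing".
    """
    if het_policy not in ("minor", "missing"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    if format == "hapmap":
        return _read_hapmap(Path(path), het_policy)
    if format == "vcf":
        return _read_vcf(Path(path), het_policy)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_hapmap(path: Path, het_policy: str) -> SNPGenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5 or header[:4] != ["rs", "alleles", "chrom", "pos"]:
            raise ParseError(f"{path}: not a HapMap-style header")
        taxa_names = header[4:]
        ids, chroms, poss, mafs, minors, calls = [], [], [], [], [], []
        dropped = 0
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4 + len(taxa_names):
                raise ParseError(f"{path}:{lineno}: expected {4 + len(taxa_names)} fields")
            try:
                chrom, pos = int(fields[2]), int(fields[3])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: bad coordinate") from e
            allele_of = [g if g != "N" else None for g in fields[4:]]
            site = _finalize_site(allele_of, het_policy)
            if site is None:
                dropped += 1
                continue
            minor_bits, called, maf, _, _ = site
            ids.append(fields[0])
            chroms.append(chrom)
            poss.append(pos)
            mafs.append(maf)
            minors.append(minor_bits)
            calls.append(called)
    if dropped:
        log.info("%s: dropped %d monomorphic/multi-allelic sites", path, dropped)
    return _build_matrix(TaxaList(taxa_names), ids, chroms, poss, mafs, minors, calls)


def _read_vcf(path: Path, het_policy: str) -> SNPGenotypeMatrix:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        taxa_names = list(vf.header.samples)
        ids, chroms, poss, mafs, minors, calls = [], [], [], [], [], []
        dropped = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                log.warning("skipping non-biallelic-SNP record at %s:%d", rec.chrom, rec.pos)
                continue
            bases = (rec.ref, rec.alts[0])
            allele_of: list[str | None] = []
            for name in taxa_names:
                gt = rec.samples[name]["GT"]
                a = [g for g in gt if g is not None]
                if not a:
                    allele_of.append(None)
                elif len(set(a)) == 1:
                    allele_of.append(bases[a[0]])
                else:  # heterozygote: synthesize the IUPAC code
                    pair = tuple(sorted(bases))
                    code = {v: k for k, v in _HET.items()}[pair]
                    allele_of.append(code)
            site = _finalize_site(allele_of, het_policy)
            if site is None:
                dropped += 1
                continue
            minor_bits, called, maf, _, _ = site
            ids.append(rec.id or f"{rec.chrom}_{rec.pos}")
            chroms.append(int(str(rec.chrom).lstrip("chr")))
            poss.append(rec.pos)
            mafs.append(maf)
            minors.append(minor_bits)
            calls.append(called)
    if dropped:
        log.info("%s: dropped %d monomorphic sites", path, dropped)
    return _build_matrix(TaxaList(taxa_names), ids, chroms, poss, mafs, minors, calls)


def _build_matrix(taxa, ids, chroms, poss, mafs, minors, calls) -> SNPGenotypeMatrix:
    n = len(ids)
    nb = bitset.n_bytes(len(taxa))
    if n == 0:
        return SNPGenotypeMatrix(
            taxa, [], np.empty(0, int), np.empty(0, int), np.empty(0),
            np.empty((0, nb), np.uint8), np.empty((0, nb), np.uint8),
        )
    minor_packed = np.packbits(np.asarray(minors, dtype=bool), axis=1)
    call_packed = np.packbits(np.asarray(calls, dtype=bool), axis=1)
    return SNPGenotypeMatrix(taxa, ids, np.asarray(chroms), np.asarray(poss),
                             np.asarray(mafs), minor_packed, call_packed)


def write_snp_matrix(matrix: SNPGenotypeMatrix, path: str | Path) -> None:
    """Write HapMap-style TSV; minor allele written as A, major as C.

    Simulated genotypes carry no nucleotide identity, so fixed bases are
    used.  The minor allele gets the lexicographically smaller base so that
    re-reading a 50/50 site keeps the same minor designation; the round
    trip then reproduces bitsets and MAFs exactly.
    """
    n_taxa = len(matrix.taxa)
    with open(path, "w") as fh:
        fh.write("\t".join(["rs", "alleles", "chrom", "pos"] + matrix.taxa.names) + "\n")
        for i in range(len(matrix)):
            minor = np.unpackbits(matrix.minor_packed[i], count=n_taxa)
            call = np.unpackbits(matrix.call_packed[i], count=n_taxa)
            geno = np.where(call == 0, "N", np.where(minor == 1, "A", "C"))
            fh.write(
                "\t".join(
                    [matrix.snp_ids[i], "A/C", str(matrix.chromosomes[i]), str(matrix.positions[i])]
                    + list(geno)
                )
                + "\n"
            )


def read_tag_matrix(
    path: str | Path,
    format: str = "tsv",
    presence_path: str | Path | None = None,
    taxa: TaxaList | None = None,
) -> TagPresenceMatrix:
    """Read a tag presence matrix.

    ``tsv``: header ``tag_sequence`` + taxa names, 0/1 cells.  ``fasta``:
    ``path`` is a FASTA of tag sequences and ``presence_path`` a TSV of
    ``tag_id<TAB>comma-separated taxa``; requires the companion ``taxa``.
    When a companion ``taxa`` is given and the file's taxa order differs,
    columns are reordered by name; unresolvable names are an error.
    Duplicate sequences are merged by OR of presence (logged); tags absent
    everywhere are dropped with a warning.
    """
    if format == "tsv":
        seqs, rows, file_taxa = _read_tag_tsv(Path(path))
    elif format == "fasta":
        if presence_path is None or taxa is None:
            raise ValueError("fasta format needs presence_path and companion taxa")
        seqs, rows, file_taxa = _read_tag_fasta(Path(path), Path(presence_path), taxa)
    else:
        raise ValueError(f"unknown tag format {format!r}")

    if taxa is not None and file_taxa != taxa.names:
        try:
            perm = [file_taxa.index(n) for n in taxa.names]
        except ValueError as e:
            raise ParseError("tag matrix taxa cannot be matched to companion taxa") from e
        rows = [r[perm] for r in rows]
        file_taxa = taxa.names

    merged: dict[str, np.ndarray] = {}
    dup = 0
    for s, r in zip(seqs, rows):
        if s in merged:
            merged[s] = merged[s] | r
            dup += 1
        else:
            merged[s] = r
    if dup:
        log.info("merged %d duplicate tag sequences by OR", dup)
    kept_seqs, kept_rows = [], []
    empty = 0
    for s, r in merged.items():
        if r.any():
            kept_seqs.append(s)
            kept_rows.append(r)
        else:
            empty += 1
    if empty:
        log.warning("dropped %d tags absent in all taxa", empty)
    out_taxa = taxa if taxa is not None else TaxaList(file_taxa)
    packed = (
        np.packbits(np.asarray(kept_rows, dtype=bool), axis=1)
        if kept_rows
        else np.empty((0, bitset.n_bytes(len(out_taxa))), np.uint8)
    )
    return TagPresenceMatrix(out_taxa, kept_seqs, packed)


def _read_tag_tsv(path: Path):
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "tag_sequence":
            raise ParseError(f"{path}: first column must be tag_sequence")
        file_taxa = header[1:]
        seqs, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 1 + len(file_taxa):
                raise ParseError(f"{path}:{lineno}: field count mismatch")
            seqs.append(fields[0])
            try:
                rows.append(np.array([int(v) for v in fields[1:]], dtype=bool))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: presence cells must be 0/1") from e
    return seqs, rows, file_taxa


def _read_tag_fasta(fasta_path: Path, presence_path: Path, taxa: TaxaList):
    from Bio import SeqIO

    seq_of = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    seqs, rows = [], []
    with open(presence_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tag_id, _, taxa_field = line.rstrip("\n").partition("\t")
            if tag_id not in seq_of:
                raise ParseError(f"{presence_path}:{lineno}: unknown tag id {tag_id!r}")
            row = np.zeros(len(taxa), dtype=bool)
            for name in filter(None, taxa_field.split(",")):
                row[taxa.index_of(name)] = True
            seqs.append(seq_of[tag_id])
            rows.append(row)
    return seqs, rows, taxa.names


def write_tag_matrix(tags: TagPresenceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["tag_sequence"] + tags.taxa.names) + "\n")
        for i in range(len(tags)):
            bits = np.unpackbits(tags.presence_packed[i], count=len(tags.taxa))
            fh.write(tags.sequences[i] + "\t" + "\t".join(map(str, bits)) + "\n")


ANCHOR_COLUMNS = [
    "tag_sequence",
    "method",
    "chromosome",
    "position",
    "p_value",
    "predicted_distance_bp",
    "pav_flag",
    "physical_chromosome",
    "physical_position",
]


def write_anchors(anchors: AnchorSet, path: str | Path) -> None:
    """Write the anchor TSV (rows sorted by tag sequence; empty set is an error)."""
    if len(anchors) == 0:
        raise ValueError("refusing to write an empty anchor set")
    with open(path, "w") as fh:
        fh.write("\t".join(ANCHOR_COLUMNS) + "\n")
        for a in anchors:
            phys_c = str(a.physical_pos.chromosome) if a.physical_pos else ""
            phys_p = str(a.physical_pos.position) if a.physical_pos else ""
            fh.write(
                "\t".join(
                    [
                        a.sequence,
                        a.method,
                        str(a.pos.chromosome),
                        str(a.pos.position),
                        repr(a.p_value),
                        f"{a.predicted_distance:.1f}",
                        str(int(a.pav_flag)),
                        phys_c,
                        phys_p,
                    ]
                )
                + "\n"
            )


def read_anchors(path: str | Path) -> AnchorSet:
    anchors = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ANCHOR_COLUMNS:
            raise ParseError(f"{path}: unexpected anchor header")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(ANCHOR_COLUMNS):
                raise ParseError(f"{path}:{lineno}: field count mismatch")
            phys = GenomePosition(int(f[7]), int(f[8])) if f[7] else None
            anchors.append(
                Anchor(
                    sequence=f[0],
                    method=f[1],
                    pos=GenomePosition(int(f[2]), int(f[3])),
                    p_value=float(f[4]),
                    predicted_distance=float(f[5]),
                    pav_flag=bool(int(f[6])),
                    physical_pos=phys,
                )
            )
    return AnchorSet(anchors)


def read_families(path: str | Path) -> dict[str, str]:
    """Families file: ``taxon<TAB>family_id`` per line."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                taxon, _, fam = line.rstrip("\n").partition("\t")
                out[taxon] = fam
    return out


def write_families(taxa: TaxaList, path: str | Path) -> None:
    if taxa.families is None:
        raise ValueError("taxa carry no family labels")
    with open(path, "w") as fh:
        for name, fam in zip(taxa.names, taxa.families):
            fh.write(f"{name}\t{fam}\n")


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key=value`` config file; '#' starts a comment."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                k, _, v = line.partition("=")
                out[k.strip()] = v.strip()
    return out


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k}={v}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
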