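"""Attributes that predict per-tag mapping accuracy.

The accuracy model consumes a fixed attribute vector per mapped tag.  The
attributes capture the mechanisms known to drive mismapping: strength and
sharpness of the association profile (a tag whose evidence is spread over
several chromosomes is suspect), tag frequency, the best SNP's MAF, and the
correlation of the tag's presence pattern with population structure —
structure-confounded tags map poorly, and that correlation is the model's
handle on it.

Model classes:

* ``G`` — tags mapped by the population scan only: 9 attributes.
* ``J`` — tags mapped by joint linkage only: the 9 base attributes of the J
  scan plus segregating-family counts.
* ``GJ`` — mapped by both: the G attributes, the joint-linkage extras, and
  two cross-method agreement attributes (distance between the two genetic
  positions, chromosome agreement).

Attributes are normalised by a Box–Cox power transform fitted per attribute
on the training set (with a shift enforcing positivity) and applied
unchanged to new data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import SNPGenotypeMatrix, TagPresenceMatrix, global_position, genetic_distance
from .gwas import MappingResult

G_ATTRIBUTES = [
    "neg_log_p",
    "chrom_gap",
    "n_sig_snps",
    "sig_span_bp",
    "sig_frac_best_chrom",
    "tag_count",
    "tag_freq",
    "best_snp_maf",
    "structure_r",
]
J_EXTRAS = ["n_seg_families", "group_frac", "pooled_neg_log_p"]
GJ_EXTRAS = ["gj_log_distance", "chrom_agreement"]

ATTRIBUTE_NAMES = {
    "G": G_ATTRIBUTES,
    "J": G_ATTRIBUTES + ["n_seg_families", "group_frac"],
    "GJ": G_ATTRIBUTES + J_EXTRAS + GJ_EXTRAS,
}


@dataclass
class AttributeVector:
    model_class: str  # G | J | GJ
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("attribute name/value length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attributes must be finite")


@dataclass
class PCAResult:
    """First-k principal components of the taxa on a random SNP sample."""

    scores: np.ndarray  # (n_taxa, k), centered
    variance_explained: np.ndarray  # (k,)


def structure_pca(
    snps: SNPGenotypeMatrix, n_snps_sample: int = 5000, k: int = 3, seed: int = 0
) -> PCAResult:
    """PCA of taxa on up to ``n_snps_sample`` randomly chosen SNPs.

    The input matrix is taxa x 0/1 minor-allele indicators (missing calls
    count as major), mean-centred; deterministic given the seed.
    """
    from sklearn.decomposition import PCA

    n_taxa = len(snps.taxa)
    if n_taxa <= k:
        raise ValueError(f"need more than k={k} taxa for {k} components")
    rng = np.random.default_rng(seed)
    n_sample = min(n_snps_sample, len(snps))
    idx = np.sort(rng.choice(len(snps), size=n_sample, replace=False))
    mat = np.unpackbits(snps.minor_packed[idx], axis=1, count=n_taxa).T.astype(np.float64)
    if mat.std(axis=0).sum() == 0:
        raise ValueError("degenerate (constant) genotype matrix")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(mat)
    return PCAResult(scores=scores, variance_explained=pca.explained_variance_ratio_)


def tag_structure_correlation(presence: np.ndarray, pca: PCAResult) -> float:
    """max |Pearson r| between a 0/1 presence vector and the PC scores.

    A constant presence vector has no defined correlation and returns 0.
    """
    v = np.asarray(presence, dtype=np.float64)
    if v.std() == 0:
        return 0.0
    vc = v - v.mean()
    best = 0.0
    for j in range(pca.scores.shape[1]):
        s = pca.scores[:, j]
        sc = s - s.mean()
        denom = np.sqrt((vc**2).sum() * (sc**2).sum())
        if denom > 0:
            best = max(best, abs(float((vc * sc).sum() / denom)))
    return best


def extract_attributes(
    result: MappingResult,
    companion: MappingResult | None,
    snps: SNPGenotypeMatrix,
    tags: TagPresenceMatrix,
    pca: PCAResult,
) -> AttributeVector:
    """Build the attribute vector for one mapped tag.

    ``result`` is the mapping whose position the tag reports (the G result
    for GJ tags); ``companion`` is the other method's result when the tag
    was mapped by both.
    """
    if result.method == "G":
        model_class = "GJ" if companion is not None else "G"
    else:
        model_class = "J"
    base = _base_attributes(result, snps, tags, pca)
    values = list(base)
    if model_class == "J":
        values += [
            float(result.n_segregating_families),
            result.group_family_count / result.n_segregating_families,
        ]
    elif model_class == "GJ":
        d = genetic_distance(
            global_position(result.pos), global_position(companion.pos)
        )
        values += [
            float(companion.n_segregating_families),
            companion.group_family_count / companion.n_segregating_families,
            companion.neg_log10_p,
            np.log10(d + 1.0),
            1.0 if result.pos.chromosome == companion.pos.chromosome else 0.0,
        ]
    return AttributeVector(model_class, ATTRIBUTE_NAMES[model_class], np.asarray(values))


def _base_attributes(result, snps, tags, pca) -> list[float]:
    sig = result.sig_snp_indices
    on_best = snps.chromosomes[sig] == result.pos.chromosome
    span = float(snps.positions[sig][on_best].max() - snps.positions[sig][on_best].min()) if on_best.any() else 0.0
    frac = float(on_best.mean()) if len(sig) else 1.0
    presence = np.unpackbits(
        tags.presence_packed[result.tag_index], count=len(tags.taxa)
    )
    return [
        result.neg_log10_p,
        result.neg_log10_p - result.second_best_neg_log10_p,
        float(result.n_sig_snps),
        span,
        frac,
        float(result.tag_count),
        result.tag_count / len(tags.taxa),
        float(snps.mafs[result.best_snp_index]),
        tag_structure_correlation(presence, pca),
    ]


@dataclass
class BoxCoxParams:
    """Per-attribute Box–Cox lambda, positivity shift, and output moments.

    The transformed columns are standardised with the training mean and
    standard deviation so downstream least squares sees comparably scaled,
    well-conditioned attributes whatever the lambda did to the raw range.
    """

    names: list[str]
    lambdas: np.ndarray
    shifts: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def to_lines(self) -> list[str]:
        return [
            f"{n}\t{float(l)!r}\t{float(s)!r}\t{float(m)!r}\t{float(sd)!r}"
            for n, l, s, m, sd in zip(
                self.names, self.lambdas, self.shifts, self.means, self.sds
            )
        ]

    @classmethod
    def from_lines(cls, lines: list[str]) -> "BoxCoxParams":
        cols = [line.split("\t") for line in lines]
        return cls(
            [c[0] for c in cols],
            np.array([float(c[1]) for c in cols]),
            np.array([float(c[2]) for c in cols]),
            np.array([float(c[3]) for c in cols]),
            np.array([float(c[4]) for c in cols]),
        )


def _transform(v: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.log(v)
    return (v**lam - 1.0) / lam


def boxcox_fit(matrix: np.ndarray, names: list[str]) -> BoxCoxParams:
    """Fit per-attribute lambda by maximum likelihood on shifted-positive values.

    Lambda is bounded to [-2, 2]: outside that range the power transform
    overflows double precision on genomic-scale attributes while adding no
    usable shape change.  Constant attributes get lambda 1 (shape-
    preserving).  Requires at least 30 training rows.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape[0] < 30:
        raise ValueError(f"need >= 30 training rows, got {matrix.shape[0]}")
    lambdas, shifts, means, sds = [], [], [], []
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        scale = col.max() - col.min()
        shift = -col.min() + max(1e-6, 1e-3 * scale) if col.min() <= 0 else 0.0
        if scale == 0:
            lambdas.append(1.0)
            shifts.append(shift)
            means.append(float(_transform(col[0] + shift, 1.0)))
            sds.append(1.0)
            continue
        lam = float(
            np.clip(stats.boxcox_normmax(col + shift, method="mle"), -2.0, 2.0)
        )
        t = _transform(col + shift, lam)
        lambdas.append(lam)
        shifts.append(float(shift))
        means.append(float(t.mean()))
        sds.append(float(t.std()) or 1.0)
    return BoxCoxParams(
        list(names), np.asarray(lambdas), np.asarray(shifts),
        np.asarray(means), np.asarray(sds),
    )


def boxcox_apply(params: BoxCoxParams, values: np.ndarray) -> np.ndarray:
    """Apply training-set transforms to a vector or matrix of raw attributes.

    New values that fall at or below the shifted-domain boundary are clamped
    to a small positive value rather than producing -inf.
    """
    v = np.atleast_2d(np.asarray(values, dtype=np.float64)).copy()
    v += params.shifts[None, :]
    np.clip(v, 1e-12, None, out=v)
    out = np.empty_like(v)
    for j, lam in enumerate(params.lambdas):
        out[:, j] = (_transform(v[:, j], lam) - params.means[j]) / params.sds[j]
    return out[0] if np.ndim(values) == 1 else out
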