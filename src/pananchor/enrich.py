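"""PAV-SNP vs ordinary-SNP GWAS enrichment comparison.

PAVs cannot be genotyped directly in a SNP panel, but each mapped PAV tag
co-segregates with its best SNP, so that SNP serves as a proxy for the
PAV's genetic effect.  SNPs hosting at least one PAV anchor form the "PAV"
class; all other SNPs are "ordinary".  Because PAVs detectable by genetic
mapping skew towards common alleles, the two classes are put on an equal
footing by dropping SNPs with MAF below a cutoff (default 0.095) before
comparing externally supplied trait-GWAS p-values.  The comparison is a QQ
profile per class plus a tail-enrichment statistic — the ratio of class
proportions below each of a grid of significance thresholds, with a
one-sided two-proportion z-test per threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnchorSet, SNPGenotypeMatrix

log = logging.getLogger(__name__)

MAF_MIN = 0.095
THRESHOLD_GRID = (1e-3, 1e-4, 1e-5, 1e-6)


def classify_snps(
    anchors: AnchorSet,
    snps: SNPGenotypeMatrix,
    best_snp_of_anchor: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Partition SNPs into PAV class (>=1 PAV anchor maps there) vs ordinary.

    Anchor-to-SNP identity comes from ``best_snp_id`` on the anchors, or the
    explicit ``best_snp_of_anchor`` map (tag sequence -> SNP row index).
    """
    is_pav_snp = np.zeros(len(snps), dtype=bool)
    id_to_row = {sid: i for i, sid in enumerate(snps.snp_ids)}
    for a in anchors:
        if not a.pav_flag:
            continue
        if best_snp_of_anchor is not None and a.sequence in best_snp_of_anchor:
            is_pav_snp[best_snp_of_anchor[a.sequence]] = True
        elif a.best_snp_id is not None and a.best_snp_id in id_to_row:
            is_pav_snp[id_to_row[a.best_snp_id]] = True
    table = pd.DataFrame(
        {
            "snp_id": snps.snp_ids,
            "maf": snps.mafs,
            "snp_class": np.where(is_pav_snp, "PAV", "ordinary"),
        }
    )
    log.info(
        "classified SNPs: %d PAV, %d ordinary",
        int(is_pav_snp.sum()), int((~is_pav_snp).sum()),
    )
    return table


def maf_match(table: pd.DataFrame, maf_min: float = MAF_MIN) -> tuple[pd.DataFrame, dict]:
    """Drop SNPs with MAF < maf_min; report per-class medians and a KS diagnostic.

    The cutoff equalised the two MAF distributions on the data this
    procedure was designed for; on arbitrary data it may not, so the KS
    statistic is reported rather than enforced.
    """
    kept = table[table["maf"] >= maf_min].copy()
    classes = kept["snp_class"].unique()
    if {"PAV", "ordinary"} - set(classes):
        raise ValueError("MAF filter emptied a SNP class")
    pav = kept.loc[kept["snp_class"] == "PAV", "maf"].to_numpy()
    ordn = kept.loc[kept["snp_class"] == "ordinary", "maf"].to_numpy()
    ks = stats.ks_2samp(pav, ordn)
    diag = {
        "median_maf_pav": float(np.median(pav)),
        "median_maf_ordinary": float(np.median(ordn)),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_pav": len(pav),
        "n_ordinary": len(ordn),
    }
    return kept, diag


@dataclass
class EnrichmentReport:
    trait: str
    qq: pd.DataFrame  # snp_class, observed_neglog_p, expected_neglog_p
    tail: pd.DataFrame  # threshold, prop_pav, prop_ordinary, ratio, z, p_value


def qq_enrichment(table: pd.DataFrame, trait: str) -> EnrichmentReport:
    """QQ data and tail-enrichment test for one trait's p-value column.

    ``table`` must carry the MAF-matched classes and a ``p_<trait>`` (or
    ``<trait>``) column of GWAS p-values.  The enrichment ratio at threshold
    t is the proportion of PAV-class p-values below t divided by the
    ordinary-class proportion; the test is a one-sided two-proportion
    z-test (PAV more enriched).  A class with no p-values below a threshold
    reports a missing ratio, not 0.
    """
    col = trait if trait in table.columns else f"p_{trait}"
    if col not in table.columns:
        raise ValueError(f"trait column {trait!r} absent from the table")
    qq_rows = []
    by_class: dict[str, np.ndarray] = {}
    for cls, grp in table.groupby("snp_class"):
        p = np.sort(grp[col].to_numpy())
        by_class[cls] = p
        m = len(p)
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        qq_rows.append(
            pd.DataFrame(
                {
                    "snp_class": cls,
                    "observed_neglog_p": -np.log10(np.maximum(p, 1e-300)),
                    "expected_neglog_p": expected[::-1],
                }
            )
        )
    tail_rows = []
    pav, ordn = by_class["PAV"], by_class["ordinary"]
    for t in THRESHOLD_GRID:
        k1, n1 = int((pav < t).sum()), len(pav)
        k2, n2 = int((ordn < t).sum()), len(ordn)
        prop1, prop2 = k1 / n1, k2 / n2
        ratio = prop1 / prop2 if prop2 > 0 else (np.nan if k1 == 0 else np.inf)
        z, pv = _two_proportion_test(k1, n1, k2, n2)
        tail_rows.append(
            {
                "threshold": t,
                "prop_pav": prop1,
                "prop_ordinary": prop2,
                "ratio": ratio,
                "z": z,
                "p_value": pv,
            }
        )
    return EnrichmentReport(trait, pd.concat(qq_rows, ignore_index=True), pd.DataFrame(tail_rows))


def _two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """One-sided pooled two-proportion z-test of prop1 > prop2."""
    if k1 + k2 == 0:
        return 0.0, 1.0
    p_pool = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (k1 / n1 - k2 / n2) / se
    return float(z), float(stats.norm.sf(z))
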