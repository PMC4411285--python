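"""End-to-end orchestration: scan -> classify -> train -> filter -> PAV.

Stage order:

1. population-wide binomial scan (method G) of every tag;
2. joint-linkage scan (method J) when the taxa carry family labels;
3. class assignment — every mapped tag lands in exactly one of G-only,
   J-only, or GJ (mapped by both; reports its G position by default);
4. attribute extraction (including the structure PCA);
5. alignment of tags to the reference (built-in exact matcher, or ingested
   SAM/BED/TSV) and identification of uniquely-aligned reference tags, the
   training truth;
6. per-class M5Rules training on those tags and prediction for all mapped
   tags; anchors are the tags whose predicted error clears the class
   threshold;
7. PAV classification of the anchors and density profiling;
8. optional enrichment stage against externally supplied trait p-values.

Every run is reproducible: the configuration carries all thresholds and
seeds, and the run summary includes a content hash of the input matrices.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enrich as enrich_mod
from . import features, gwas, m5rules, nam, pav
from .datamodel import (
    Anchor,
    AnchorSet,
    SNPGenotypeMatrix,
    TagPresenceMatrix,
    genetic_distance,
    global_position,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the published procedure."""

    gwas_threshold: float = 1e-6
    family_threshold: float = 0.05
    min_tag_count: int = 30
    selection_thresholds: dict = field(
        default_factory=lambda: dict(m5rules.DEFAULT_THRESHOLDS)
    )
    pav_window_bp: int = pav.PAV_WINDOW_BP
    density_window_bp: int = pav.DENSITY_WINDOW_BP
    pca_n_snps: int = 5000
    pca_k: int = 3
    pca_seed: int = 0
    min_training: int = 100
    min_leaf: int | None = None  # None -> cross-validated leaf size
    sd_stop_fraction: float = 0.05
    smoothing: bool = True
    max_rules: int | None = None
    workers: int = 1
    alternative: str = "two-sided"
    restrict_to_chromosome: bool = True
    prefer_j_position: bool = False
    maf_min: float = enrich_mod.MAF_MIN


@dataclass
class ClassifiedTag:
    sequence: str
    model_class: str  # G | J | GJ
    result: gwas.MappingResult  # the mapping whose position the tag reports
    companion: gwas.MappingResult | None  # the other method's result (GJ only)
    attributes: features.AttributeVector | None = None
    predicted_distance: float | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    classified: dict[str, ClassifiedTag]
    g_unmapped: list
    j_unmapped: list
    pca: features.PCAResult
    alignments: dict[str, pav.TagAlignment]
    models: dict[str, m5rules.RuleModel]
    anchors: AnchorSet
    pav_calls: list[pav.PavCall]
    density: pd.DataFrame
    enrichment: list
    summary: dict


def input_hash(snps: SNPGenotypeMatrix, tags: TagPresenceMatrix) -> str:
    h = hashlib.sha256()
    h.update(snps.minor_packed.tobytes())
    h.update(snps.call_packed.tobytes())
    h.update(np.ascontiguousarray(snps.global_positions).tobytes())
    h.update(tags.presence_packed.tobytes())
    h.update("".join(tags.sequences).encode())
    return h.hexdigest()[:16]


def assign_classes(
    g_mapped: list[gwas.MappingResult],
    j_mapped: list[gwas.MappingResult],
    prefer_j_position: bool = False,
) -> dict[str, ClassifiedTag]:
    """Partition mapped tags into G-only / J-only / GJ (exactly one class each)."""
    g_by_seq = {r.sequence: r for r in g_mapped}
    j_by_seq = {r.sequence: r for r in j_mapped}
    out: dict[str, ClassifiedTag] = {}
    for seq, rg in g_by_seq.items():
        rj = j_by_seq.get(seq)
        if rj is None:
            out[seq] = ClassifiedTag(seq, "G", rg, None)
        elif prefer_j_position:
            out[seq] = ClassifiedTag(seq, "GJ", rj, rg)
        else:
            out[seq] = ClassifiedTag(seq, "GJ", rg, rj)
    for seq, rj in j_by_seq.items():
        if seq not in g_by_seq:
            out[seq] = ClassifiedTag(seq, "J", rj, None)
    return out


def run_pipeline(
    snps: SNPGenotypeMatrix,
    tags: TagPresenceMatrix,
    reference: dict[str, str] | None = None,
    alignments: list[pav.TagAlignment] | None = None,
    pvalues: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    if reference is None and alignments is None:
        raise RuntimeError("stage alignment failed: need a reference FASTA or alignments")
    summary: dict = {"input_hash": input_hash(snps, tags), "n_tags": len(tags), "n_snps": len(snps)}

    # --- stage: map-gwas ---
    g_mapped, g_un = gwas.map_all_gwas(
        tags, snps, cfg.min_tag_count, cfg.gwas_threshold, cfg.alternative, cfg.workers
    )
    summary["mapped_g"] = len(g_mapped)

    # --- stage: map-nam ---
    j_mapped: list[gwas.MappingResult] = []
    j_un: list = []
    if snps.taxa.families is not None and any(snps.taxa.families):
        j_mapped, j_un = nam.map_all_nam(
            tags, snps, cfg.min_tag_count, cfg.family_threshold,
            cfg.restrict_to_chromosome, cfg.alternative,
        )
    summary["mapped_j"] = len(j_mapped)

    # --- stage: class assignment ---
    classified = assign_classes(g_mapped, j_mapped, cfg.prefer_j_position)
    for cls in ("G", "J", "GJ"):
        summary[f"class_{cls}"] = sum(1 for t in classified.values() if t.model_class == cls)

    # --- stage: attributes ---
    pca = features.structure_pca(snps, cfg.pca_n_snps, cfg.pca_k, cfg.pca_seed)
    for t in classified.values():
        t.attributes = features.extract_attributes(t.result, t.companion, snps, tags, pca)

    # --- stage: alignment ---
    if alignments is None:
        alignments = pav.exact_match_align(tags.sequences, reference)
    aln_by_tag = {a.tag_id: a for a in alignments}

    # --- stage: train + filter ---
    models: dict[str, m5rules.RuleModel] = {}
    candidates: list[tuple[ClassifiedTag, str, float]] = []
    for cls in ("G", "J", "GJ"):
        members = [t for t in classified.values() if t.model_class == cls]
        if not members:
            continue
        train = [
            t for t in members
            if (a := aln_by_tag.get(t.sequence)) is not None and a.is_uabt
        ]
        if len(train) < cfg.min_training:
            log.warning(
                "class %s: only %d uniquely-aligned training tags (< %d); "
                "no anchors selected from this class", cls, len(train), cfg.min_training,
            )
            summary[f"train_{cls}"] = len(train)
            continue
        names = features.ATTRIBUTE_NAMES[cls]
        X = np.array([t.attributes.values for t in train])
        d = np.array(
            [
                genetic_distance(
                    global_position(t.result.pos),
                    global_position(aln_by_tag[t.sequence].positions[0]),
                )
                for t in train
            ],
            dtype=float,
        )
        model = m5rules.train_accuracy_model(
            X, d, cls, names, cfg.min_leaf, cfg.sd_stop_fraction, cfg.smoothing, cfg.max_rules
        )
        models[cls] = model
        summary[f"train_{cls}"] = len(train)
        summary[f"r2_{cls}"] = round(model.training_r2, 4)
        summary[f"rules_{cls}"] = len(model.rules)
        preds = model.predict_raw(np.array([t.attributes.values for t in members]))
        for t, yhat in zip(members, preds):
            t.predicted_distance = max(0.0, 10.0**yhat - 1.0)
            candidates.append((t, cls, t.predicted_distance))

    selected = m5rules.select_anchors(candidates, cfg.selection_thresholds)
    anchors = []
    for t, cls, pred in selected:
        aln = aln_by_tag.get(t.sequence)
        phys = aln.positions[0] if (aln is not None and aln.is_uabt) else None
        anchors.append(
            Anchor(
                sequence=t.sequence,
                method=cls,
                pos=t.result.pos,
                p_value=t.result.p_value,
                predicted_distance=pred,
                physical_pos=phys,
                best_snp_id=snps.snp_ids[t.result.best_snp_index],
            )
        )
    anchor_set = AnchorSet(anchors)
    summary["anchors_selected"] = len(anchor_set)

    # --- stage: pav ---
    calls = [
        pav.classify_pav(a, aln_by_tag.get(a.sequence), cfg.pav_window_bp)
        for a in anchor_set
    ]
    for a, c in zip(anchor_set, calls):
        a.pav_flag = c.pav_flag
    density = (
        pav.pav_density(calls, anchor_set, aln_by_tag, cfg.density_window_bp)
        if len(anchor_set)
        else pd.DataFrame()
    )
    n_pav = sum(c.pav_flag for c in calls)
    summary["pav_count"] = n_pav
    summary["pav_fraction"] = round(n_pav / len(anchor_set), 4) if len(anchor_set) else 0.0

    # --- stage: enrich (optional) ---
    reports = []
    if pvalues is not None and len(anchor_set):
        table = enrich_mod.classify_snps(anchor_set, snps)
        merged = table.merge(pvalues, on="snp_id", how="inner")
        matched, diag = enrich_mod.maf_match(merged, cfg.maf_min)
        summary["maf_match"] = diag
        for col in pvalues.columns:
            if col != "snp_id":
                reports.append(enrich_mod.qq_enrichment(matched, col))

    return PipelineResult(
        config=cfg,
        classified=classified,
        g_unmapped=g_un,
        j_unmapped=j_un,
        pca=pca,
        alignments=aln_by_tag,
        models=models,
        anchors=anchor_set,
        pav_calls=calls,
        density=density,
        enrichment=reports,
        summary=summary,
    )


def mapping_table(result: PipelineResult) -> pd.DataFrame:
    """Flat per-tag mapping table (one row per mapped tag)."""
    rows = []
    for t in result.classified.values():
        r = t.result
        rows.append(
            {
                "tag": t.sequence,
                "method": t.model_class,
                "chr": r.pos.chromosome,
                "pos": r.pos.position,
                "pvalue": r.p_value,
                "neg_log10_p": r.neg_log10_p,
                "n": r.n,
                "x": r.x,
                "second_best_pvalue": 10.0 ** -r.second_best_neg_log10_p,
                "n_sig_snps": r.n_sig_snps,
                "predicted_distance_bp": t.predicted_distance,
            }
        )
    return pd.DataFrame(rows).sort_values("tag").reset_index(drop=True)
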