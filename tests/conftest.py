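"""Shared fixtures: small synthetic bundles built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from pananchor.datamodel import SNPGenotypeMatrix, TagPresenceMatrix, TaxaList
from pananchor.simpop import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_panel():
    """Small diversity panel: quick to build, enough signal to map tags."""
    cfg = SimConfig(
        seed=11, mode="panel", n_taxa=300, n_snps=600, n_tags=150,
        chromosome_length_bp=20_000_000,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def small_nam():
    """Small NAM design: 3 families x 60 RILs."""
    cfg = SimConfig(
        seed=12, mode="nam", n_families=3, ril_per_family=80, n_snps=600,
        n_tags=150, chromosome_length_bp=20_000_000,
    )
    return simulate_population(cfg)


def toy_matrices(
    n_taxa: int = 40,
    patterns: list[np.ndarray] | None = None,
    mafs: list[float] | None = None,
    chroms: list[int] | None = None,
    positions: list[int] | None = None,
    taxa: TaxaList | None = None,
):
    """Hand-built SNP matrix from explicit minor-carrier patterns (full calls)."""
    if taxa is None:
        taxa = TaxaList([f"t{i}" for i in range(n_taxa)])
    n = len(patterns)
    minor = np.array(patterns, dtype=bool)
    call = np.ones_like(minor)
    maf = np.asarray(
        mafs if mafs is not None else minor.mean(axis=1).clip(max=0.5)
    )
    return SNPGenotypeMatrix(
        taxa,
        [f"s{i}" for i in range(n)],
        np.asarray(chroms if chroms else [1] * n),
        np.asarray(positions if positions else list(range(1000, 1000 + n))),
        maf,
        np.packbits(minor, axis=1),
        np.packbits(call, axis=1),
    )


def toy_tags(taxa: TaxaList, patterns: list[np.ndarray], seqs: list[str] | None = None):
    rng = np.random.default_rng(0)
    if seqs is None:
        seqs = [
            "".join(rng.choice(list("ACGT"), 64)) for _ in patterns
        ]
    return TagPresenceMatrix(taxa, seqs, np.packbits(np.array(patterns, dtype=bool), axis=1))
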