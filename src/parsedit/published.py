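"""Headline counts from the HepG2 ADAR1-knockdown PARS-seq experiment.

These are the published feature counts and merged region sizes behind the
reported enrichment folds: editing sites and differential editing sites (DES)
inside structure-changed (SSC) versus unchanged 3'UTR exons at three
coverage tiers, and editing/DES/Alu/inverted-repeat-Alu content of
destabilized-while-edited (DSWE) versus stabilized-while-edited (SWE) gene
sets.  The folds are fully determined by these numbers through
:func:`parsedit.downstream.region_enrichment`; they are kept here so the
analyses can recompute every fold from first principles.
"""

from __future__ import annotations

from .downstream import EnrichmentResult, region_enrichment

# (feature count in SSC set, SSC bases, feature count in non-SSC set, non-SSC bases)
SSC_3UTR_ENRICHMENT: dict[str, tuple[int, int, int, int]] = {
    # editing sites, by minimum average read starts per exon
    "editing_sites_rs50": (1479, 2_274_485, 9157, 19_443_239),
    "editing_sites_rs200": (1293, 1_550_212, 8227, 16_311_452),
    "editing_sites_rs1000": (618, 433_095, 5303, 9_328_336),
    # differential editing sites, same tiers
    "des_rs50": (213, 2_274_485, 1215, 19_443_239),
    "des_rs200": (206, 1_550_212, 1152, 16_311_452),
    "des_rs1000": (121, 433_095, 891, 9_328_336),
}

# (feature count in DSWE genes, DSWE bases, feature count in SWE genes, SWE bases)
DSWE_VS_SWE_ENRICHMENT: dict[str, tuple[int, int, int, int]] = {
    "editing_sites": (4156, 14_121_576, 24_256, 100_526_979),
    "des": (186, 14_121_576, 1109, 100_526_979),
    "alu": (9587, 14_121_576, 65_706, 100_526_979),
    "alu_in_ir": (7215, 14_121_576, 47_881, 100_526_979),
}

# Differentially edited sites split by direction: sites whose editing level
# drops under ADAR1 knockdown are ADAR1 targets; the few that rise track the
# compensatory ADAR2 up-regulation.
N_SITES_LOWER_IN_KD = 5644
N_SITES_HIGHER_IN_KD = 174


def enrichment_folds() -> dict[str, EnrichmentResult]:
    """Recompute every published enrichment fold from the raw counts."""
    out = {}
    for key, (n1, s1, n2, s2) in SSC_3UTR_ENRICHMENT.items():
        out[f"ssc_3utr_{key}"] = region_enrichment(n1, s1, n2, s2)
    for key, (n1, s1, n2, s2) in DSWE_VS_SWE_ENRICHMENT.items():
        out[f"dswe_vs_swe_{key}"] = region_enrichment(n1, s1, n2, s2)
    return out


def adar1_adar2_target_ratio() -> float:
    """Ratio of ADAR1-attributable to ADAR2-attributable differential sites
    (~32-fold), computed from the direction-split site counts."""
    return N_SITES_LOWER_IN_KD / N_SITES_HIGHER_IN_KD
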