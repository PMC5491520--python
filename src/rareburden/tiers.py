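"""Per-gene and per-tier association testing over the eight filtering
scenarios, Bonferroni accounting, and report tables.

The six candidate-gene tiers carry 6, 26, 51, 5, 7 and 24 genes (119 total):
human obesity alone; obesity with developmental delay; mouse loss-of-function;
mouse gain-of-function; anorectic molecules; complex metabolic effects.  The
shipped default is a tier skeleton with placeholder gene symbols of the right
sizes -- the pipeline needs the structure, user gene lists supply identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import (RareVariantAssociation, allele_count_table,
                          odds_ratio)
from .classify import ALL_SCENARIOS, FilterScenario, select_scenario_variants

__all__ = [
    "TIER_SIZES",
    "default_gene_tiers",
    "bonferroni_threshold",
    "AnalysisDataset",
    "AssociationRow",
    "run_gene_tests",
    "run_tier_tests",
    "summarize",
]

TIER_SIZES = {
    "ObesityAlone": 6, "ObesityAndDelay": 26, "LoFMice": 51, "GoFMice": 5,
    "AnorecticMolecules": 7, "ComplexMetabolicEffects": 24,
}

#: Bonferroni levels: two primary tests per unit over 125 units, and twelve
#: once the ten secondary tests are included
PRIMARY_TESTS_PER_UNIT = 2
ALL_TESTS_PER_UNIT = 12
N_UNITS = 125


def default_gene_tiers() -> pd.DataFrame:
    """Tier skeleton with placeholder symbols and the canonical tier sizes."""
    rows = []
    for tier, n in TIER_SIZES.items():
        for i in range(1, n + 1):
            rows.append({"gene": f"{tier}_{i:02d}", "tier": tier})
    return pd.DataFrame(rows)


def bonferroni_threshold(n_units: int, n_tests_per_unit: int) -> float:
    """0.05 / (tests per unit x units)."""
    if n_units < 1 or n_tests_per_unit < 1:
        raise ValueError("counts must be >= 1")
    return 0.05 / (n_tests_per_unit * n_units)


@dataclass
class AnalysisDataset:
    """Bundle of genotypes, sample metadata and classified variants.

    ``genotypes`` rows align with ``samples`` rows; ``variants`` rows carry a
    ``g_index`` column pointing into genotype columns plus the gene and
    classification columns.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame        # needs status, cohort columns
    variants: pd.DataFrame       # needs gene, g_index, classification columns
    beta_weights: tuple = (1.0, 25.0)

    @property
    def status(self) -> np.ndarray:
        return self.samples["status"].to_numpy(int)


@dataclass
class AssociationRow:
    """One Table-style result row for a unit (gene or tier) x scenario."""

    unit: str
    tier: str
    scenario: str
    n_variants: int
    case_ts_alleles: float
    case_wes_alleles: float
    control_alleles: float
    oddsratio: float
    adjusted_oddsratio: float
    ci_low: float
    ci_high: float
    p_burden: float
    p_skat: float
    p_skato: float
    no_test: bool = False
    sig_primary: bool = False
    sig_all: bool = False


def _test_unit(dataset: AnalysisDataset, unit: str, tier: str,
               variants: pd.DataFrame, scenario: FilterScenario,
               thr_primary: float, thr_all: float) -> AssociationRow:
    sub = select_scenario_variants(variants, scenario)
    if sub.empty:
        return AssociationRow(unit=unit, tier=tier, scenario=scenario.label,
                              n_variants=0, case_ts_alleles=0,
                              case_wes_alleles=0, control_alleles=0,
                              oddsratio=np.nan, adjusted_oddsratio=np.nan,
                              ci_low=np.nan, ci_high=np.nan, p_burden=np.nan,
                              p_skat=np.nan, p_skato=np.nan, no_test=True)
    cols = sub["g_index"].to_numpy(int)
    G = dataset.genotypes[:, cols].astype(float)
    y = dataset.status
    model = RareVariantAssociation(y, G, beta_weights=dataset.beta_weights)
    res_o = model.fit("skato")
    res_b = model.fit("burden")
    res_s = model.fit("skat")

    cohort = dataset.samples["cohort"].to_numpy()
    with np.errstate(invalid="ignore"):
        dose = np.nan_to_num(G)
    case_ts = float(dose[(cohort == "SCOOP_TS")].sum())
    case_wes = float(dose[(cohort == "SCOOP_WES")].sum())
    table = allele_count_table(G, y)
    orr = odds_ratio(table)

    p_b, p_o = res_b.p_value, res_o.p_value
    return AssociationRow(
        unit=unit, tier=tier, scenario=scenario.label,
        n_variants=int(len(sub)),
        case_ts_alleles=case_ts, case_wes_alleles=case_wes,
        control_alleles=float(table.c),
        oddsratio=orr.oddsratio, adjusted_oddsratio=orr.adjusted_oddsratio,
        ci_low=orr.ci_low, ci_high=orr.ci_high,
        p_burden=p_b, p_skat=res_s.p_value, p_skato=p_o,
        no_test=res_o.no_test,
        sig_primary=bool(min(p_b, p_o) < thr_primary) if np.isfinite(p_b) else False,
        sig_all=bool(min(p_b, p_o) < thr_all) if np.isfinite(p_b) else False,
    )


def run_gene_tests(dataset: AnalysisDataset, gene: str,
                   scenarios=ALL_SCENARIOS, tier: str = "",
                   n_units: int = N_UNITS) -> list[AssociationRow]:
    """Burden + SKAT + SKAT-O for one gene under each scenario."""
    thr_p = bonferroni_threshold(n_units, PRIMARY_TESTS_PER_UNIT)
    thr_a = bonferroni_threshold(n_units, ALL_TESTS_PER_UNIT)
    gv = dataset.variants[dataset.variants["gene"] == gene]
    return [_test_unit(dataset, gene, tier, gv, sc, thr_p, thr_a)
            for sc in scenarios]


def run_tier_tests(dataset: AnalysisDataset, gene_tiers: pd.DataFrame,
                   scenarios=ALL_SCENARIOS,
                   n_units: int = N_UNITS) -> list[AssociationRow]:
    """Pooled tests per tier, plus the all-genes-combined unit.

    Variants of all genes in a tier are pooled into a single testing unit;
    a tier of one gene is identical to that gene's own test.
    """
    thr_p = bonferroni_threshold(n_units, PRIMARY_TESTS_PER_UNIT)
    thr_a = bonferroni_threshold(n_units, ALL_TESTS_PER_UNIT)
    rows = []
    for tier, genes in gene_tiers.groupby("tier", sort=True):
        tv = dataset.variants[dataset.variants["gene"].isin(genes["gene"])]
        for sc in scenarios:
            rows.append(_test_unit(dataset, tier, tier, tv, sc, thr_p, thr_a))
    all_v = dataset.variants[dataset.variants["gene"].isin(gene_tiers["gene"])]
    for sc in scenarios:
        rows.append(_test_unit(dataset, "AllGenes", "AllGenes", all_v, sc,
                               thr_p, thr_a))
    return rows


def summarize(results: list[AssociationRow]):
    """(nominally significant Table-style report, full OR/CI scenario table).

    The first table keeps units with burden or SKAT-O p < 0.05; the second
    lists OR and CI for every unit x scenario.  Rows are ordered by tier then
    unit then scenario for deterministic output.
    """
    if not results:
        raise ValueError("no results to summarise")
    df = pd.DataFrame([r.__dict__ for r in results])
    df = df.sort_values(["tier", "unit", "scenario"]).reset_index(drop=True)
    nominal = df[(df["p_burden"] < 0.05) | (df["p_skato"] < 0.05)]
    table1 = nominal[["unit", "tier", "scenario", "n_variants",
                      "case_ts_alleles", "case_wes_alleles", "control_alleles",
                      "oddsratio", "adjusted_oddsratio", "p_skato", "p_burden",
                      "sig_primary", "sig_all"]].reset_index(drop=True)
    fig5 = df[["unit", "tier", "scenario", "n_variants", "oddsratio",
               "adjusted_oddsratio", "ci_low", "ci_high", "p_burden",
               "p_skat", "p_skato"]].reset_index(drop=True)
    return table1, fig5
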