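"""Variant classification cascade: consequence, rarity/novelty against 20
reference frequency panels, deleteriousness strata, the eight filtering
scenarios, and the clinical-variant triage.

Rules implemented:

* A variant is *functional* when its governing consequence belongs to the
  fixed set {essential splice site, stop gained, stop lost, complex indel,
  frameshift coding, non synonymous coding, within mature miRNA, partial
  codon}.  For genes with a configured clinically relevant transcript (the
  known human obesity genes) the governing consequence is that transcript's;
  otherwise the most severe consequence across transcripts governs.
* A variant is *excluded* from rare-variant analysis when its pooled
  allele-count MAF across the 13 internal panels exceeds 1%, OR any single
  internal panel MAF exceeds 10%, OR any of the 7 external panels' MAF
  exceeds 1%.  It is *novel* when unobserved in all 20 panels, and *rare*
  otherwise.
* Deleteriousness strata from SIFT ("deleterious"), PolyPhen ("probably
  damaging"/"damaging") and Condel ("deleterious"): at-least-one vs all-three.
* Clinical triage retains novel functional variants plus rare functional
  variants with ClinVar Pathogenic / Likely pathogenic status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .simulate import EXTERNAL_PANEL_IDS, INTERNAL_PANEL_IDS

__all__ = [
    "FUNCTIONAL_CONSEQUENCES",
    "SEVERITY_ORDER",
    "FilterScenario",
    "ALL_SCENARIOS",
    "VariantRecord",
    "classify_consequence",
    "classify_rarity",
    "deleteriousness_stratum",
    "classify_variants",
    "select_scenario_variants",
    "clinvar_triage",
    "carrier_prevalence",
]

FUNCTIONAL_CONSEQUENCES = frozenset({
    "essential splice site", "stop gained", "stop lost", "complex indel",
    "frameshift coding", "non synonymous coding", "within mature miRNA",
    "partial codon",
})

#: most-severe-first ranking used to pick the governing consequence across
#: transcripts; overridable wherever a severity order is accepted
SEVERITY_ORDER = (
    "essential splice site", "stop gained", "stop lost", "frameshift coding",
    "complex indel", "non synonymous coding", "partial codon",
    "within mature miRNA", "synonymous coding", "other",
)

PATHOGENIC_CLINVAR = frozenset({"Pathogenic", "Likely pathogenic"})

_DELETERIOUS = {
    "sift": frozenset({"deleterious"}),
    "polyphen": frozenset({"probably damaging", "damaging"}),
    "condel": frozenset({"deleterious"}),
}


@dataclass(frozen=True)
class FilterScenario:
    """One of the eight (rarity, function-class) filtering scenarios."""

    rarity: str          # "rare" | "novel"
    function_class: str  # "synonymous" | "functional" | "functional_1plus_del"
                         # | "functional_all_del"

    def __post_init__(self):
        if self.rarity not in ("rare", "novel"):
            raise ValueError(f"unknown rarity class {self.rarity!r}")
        if self.function_class not in (
                "synonymous", "functional", "functional_1plus_del",
                "functional_all_del"):
            raise ValueError(f"unknown function class {self.function_class!r}")

    @property
    def label(self) -> str:
        return f"{self.rarity}_{self.function_class}"


ALL_SCENARIOS = tuple(
    FilterScenario(r, f)
    for r in ("rare", "novel")
    for f in ("synonymous", "functional", "functional_1plus_del",
              "functional_all_del")
)


@dataclass
class VariantRecord:
    """One bi-allelic site with its annotations and panel frequencies."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript_consequences: dict  # transcript id -> consequence term
    clinically_relevant_transcript: str | None = None
    sift: str = ""
    polyphen: str = ""
    condel: str = ""
    clinvar: str = ""
    # panel id -> dict(ac, an, observed)
    panel_frequencies: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("positions are 1-based")
        if not self.transcript_consequences:
            raise ValueError("a variant needs at least one transcript consequence")


def _severity_rank(term: str, order=SEVERITY_ORDER) -> int:
    try:
        return order.index(term)
    except ValueError:
        return len(order)  # unknown terms rank below "other"


def classify_consequence(variant: VariantRecord, known_gene: bool,
                         severity_order=SEVERITY_ORDER) -> str:
    """-> "functional" | "synonymous" | "other".

    ``known_gene=True`` selects the clinically-relevant-transcript rule (a
    configured transcript is then mandatory); otherwise the most severe
    consequence on any transcript governs.
    """
    cons = variant.transcript_consequences
    if known_gene:
        tx = variant.clinically_relevant_transcript
        if tx is None or tx not in cons:
            raise ConfigurationError(
                f"no clinically relevant transcript configured for "
                f"{variant.gene} {variant.chrom}:{variant.pos}")
        governing = cons[tx]
    else:
        governing = min(cons.values(), key=lambda t: _severity_rank(t, severity_order))
    if governing in FUNCTIONAL_CONSEQUENCES:
        return "functional"
    if governing == "synonymous coding":
        return "synonymous"
    return "other"


def classify_rarity(variant: VariantRecord, panel_sizes: dict | None = None,
                    pooled_rule: str = "allele_counts",
                    pooled_threshold: float = 0.01,
                    single_internal_threshold: float = 0.10,
                    external_threshold: float = 0.01) -> str:
    """-> "rare" | "novel" | "excluded" against the 20 configured panels.

    ``pooled_rule`` selects how the across-internal-panels MAF is formed:
    ``"allele_counts"`` pools allele counts (the default, matching how
    joint-called cohorts are summarised) or ``"mean_maf"`` averages per-panel
    MAFs.  The three thresholds default to the canonical cascade (pooled
    internal > 1%, any internal > 10%, any external > 1%); relaxing any of
    them can only grow the rare set.
    """
    panels = variant.panel_frequencies
    for pid in INTERNAL_PANEL_IDS + EXTERNAL_PANEL_IDS:
        if pid not in panels:
            raise ConfigurationError(f"panel {pid} missing for variant "
                                     f"{variant.chrom}:{variant.pos}")
    internal = [panels[p] for p in INTERNAL_PANEL_IDS]
    external = [panels[p] for p in EXTERNAL_PANEL_IDS]

    if pooled_rule == "allele_counts":
        pooled = sum(p["ac"] for p in internal) / sum(p["an"] for p in internal)
    elif pooled_rule == "mean_maf":
        pooled = float(np.mean([p["ac"] / p["an"] for p in internal]))
    else:
        raise ValueError(f"unknown pooled_rule {pooled_rule!r}")

    if pooled > pooled_threshold:
        return "excluded"
    if any(p["observed"] and p["ac"] / p["an"] > single_internal_threshold
           for p in internal):
        return "excluded"
    if any(p["observed"] and p["ac"] / p["an"] > external_threshold
           for p in external):
        return "excluded"
    if not any(p["observed"] for p in internal + external):
        return "novel"
    return "rare"


def deleteriousness_stratum(variant: VariantRecord) -> str:
    """-> "none" | "one_plus" | "all_three".

    Absent predictor labels (non-missense variants) count as not deleterious;
    labels outside the accepted sets (e.g. PolyPhen "possibly damaging") do
    too.
    """
    flags = [variant.sift in _DELETERIOUS["sift"],
             variant.polyphen in _DELETERIOUS["polyphen"],
             variant.condel in _DELETERIOUS["condel"]]
    if all(flags):
        return "all_three"
    if any(flags):
        return "one_plus"
    return "none"


# ---------------------------------------------------------------------------
# table-level cascade
# ---------------------------------------------------------------------------

def _records_from_tables(annotations: pd.DataFrame, panels: pd.DataFrame,
                         panel_sizes: dict) -> list[VariantRecord]:
    by_site = {k: g for k, g in panels.groupby("site_index")}
    records = []
    for i, row in annotations.iterrows():
        site = by_site.get(row["site_index"] if "site_index" in row else i)
        pf = {}
        if site is not None:
            for _, p in site.iterrows():
                pf[p["panel_id"]] = {"ac": int(p["ac"]), "an": int(p["an"]),
                                     "observed": bool(p["observed"])}
        tx_ids = str(row["transcript_ids"]).split(",")
        tx_cons = str(row["transcript_consequences"]).split(",")
        records.append(VariantRecord(
            chrom=str(row.get("chrom", "1")), pos=int(row["pos"]),
            ref=str(row["ref"]), alt=str(row["alt"]), gene=str(row["gene"]),
            transcript_consequences=dict(zip(tx_ids, tx_cons)),
            clinically_relevant_transcript=row.get(
                "clinically_relevant_transcript") or None,
            sift=str(row.get("sift", "") or ""),
            polyphen=str(row.get("polyphen", "") or ""),
            condel=str(row.get("condel", "") or ""),
            clinvar=str(row.get("clinvar", "") or ""),
            panel_frequencies=pf,
        ))
    return records


def classify_variants(annotations: pd.DataFrame, panels: pd.DataFrame,
                      known_genes=(), panel_sizes: dict | None = None,
                      pooled_rule: str = "allele_counts",
                      severity_order=SEVERITY_ORDER) -> pd.DataFrame:
    """Run the full cascade over annotation + panel tables.

    Returns the annotation table with ``consequence_class``, ``rarity_class``
    and ``deleteriousness`` columns appended.  ``known_genes`` lists the genes
    for which the clinically-relevant-transcript rule applies.
    """
    records = _records_from_tables(annotations, panels, panel_sizes or {})
    known = set(known_genes)
    out = annotations.reset_index(drop=True).copy()
    out["consequence_class"] = [
        classify_consequence(v, v.gene in known, severity_order) for v in records]
    out["rarity_class"] = [classify_rarity(v, panel_sizes or {}, pooled_rule)
                           for v in records]
    out["deleteriousness"] = [deleteriousness_stratum(v) for v in records]
    return out


def select_scenario_variants(classified: pd.DataFrame,
                             scenario: FilterScenario) -> pd.DataFrame:
    """Subset of classified variants falling in one filtering scenario.

    Rarity classes are disjoint strata (novel is never folded into rare);
    the functional strata nest: all_del <= 1plus_del <= functional.
    """
    if not isinstance(scenario, FilterScenario):
        raise ValueError("scenario must be a FilterScenario")
    m = classified["rarity_class"] == scenario.rarity
    fc = scenario.function_class
    if fc == "synonymous":
        m &= classified["consequence_class"] == "synonymous"
    else:
        m &= classified["consequence_class"] == "functional"
        if fc == "functional_1plus_del":
            m &= classified["deleteriousness"].isin(["one_plus", "all_three"])
        elif fc == "functional_all_del":
            m &= classified["deleteriousness"] == "all_three"
    return classified[m]


def clinvar_triage(classified: pd.DataFrame) -> pd.DataFrame:
    """Clinical triage: keep novel functional variants plus rare functional
    variants with ClinVar Pathogenic / Likely pathogenic status."""
    functional = classified["consequence_class"] == "functional"
    novel = classified["rarity_class"] == "novel"
    rare_path = (classified["rarity_class"] == "rare") \
        & classified["clinvar"].isin(PATHOGENIC_CLINVAR)
    return classified[functional & (novel | rare_path)]


def carrier_prevalence(n_carriers: int, n_cases: int) -> float:
    """Carrier prevalence as a percentage of cases, rounded to the nearest
    whole percent (the resolution at which such yields are reported)."""
    if n_cases <= 0:
        raise ValueError("n_cases must be positive")
    return round(100.0 * n_carriers / n_cases)
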