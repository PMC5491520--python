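"""Sample quality-control cascade.

Exclusions are applied in a fixed order -- contamination, read depth,
array concordance, genotype missingness, ancestry, relatedness -- with the
count of samples removed recorded at each stage, mirroring how sequencing
cohorts report their QC accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "QCThresholds",
    "QCResult",
    "exclude_contaminated",
    "exclude_low_depth",
    "exclude_discordant",
    "exclude_high_missingness",
    "assign_ancestry",
    "prune_related",
    "run_qc_cascade",
]

logger = logging.getLogger(__name__)

#: removal preference when breaking degree ties in relatedness pruning:
#: diseased controls go first, cases are kept longest
_GROUP_REMOVAL_PRIORITY = {"diseased_control": 0, "non_diseased_control": 1,
                           "case": 2}


@dataclass
class QCThresholds:
    freemix: float = 0.03          # contamination fraction
    depth_sd: float = 3.0          # SDs below the mean depth
    concordance: float = 0.90      # array concordance floor
    missing_rate: float = 0.50     # genotype missingness ceiling
    ancestry_k_sd: float = 6.0     # robust SDs around the European centroid
    ibd: float = 0.1875            # pi-hat above which a pair is related


def exclude_contaminated(qc: pd.DataFrame, freemix_threshold: float = 0.03) -> set:
    """freemix >= threshold OR the skewed-hets flag."""
    m = (qc["freemix"] >= freemix_threshold)
    if "skewed_hets" in qc:
        m |= qc["skewed_hets"].astype(bool)
    return set(qc.loc[m, "sample_id"])


def exclude_low_depth(qc: pd.DataFrame, n_sd: float = 3.0) -> set:
    """mean_depth below mean - n_sd * SD, both computed over the stage input.

    With fewer than 2 samples the statistic is undefined; with zero depth
    variance nobody is excluded (logged as a degenerate case).
    """
    if len(qc) < 2:
        raise ValueError("need at least 2 samples to form a depth threshold")
    depths = qc["mean_depth"].to_numpy(float)
    sd = depths.std(ddof=0)
    if sd == 0.0:
        logger.warning("zero depth variance; no depth exclusions")
        return set()
    cutoff = depths.mean() - n_sd * sd
    return set(qc.loc[qc["mean_depth"] < cutoff, "sample_id"])


def exclude_discordant(qc: pd.DataFrame, threshold: float = 0.90) -> set:
    """concordance strictly below threshold; samples without array data pass."""
    conc = qc["concordance"]
    m = conc.notna() & (conc < threshold)
    return set(qc.loc[m, "sample_id"])


def exclude_high_missingness(qc: pd.DataFrame, threshold: float = 0.50) -> set:
    """missing_rate strictly above threshold."""
    return set(qc.loc[qc["missing_rate"] > threshold, "sample_id"])


def assign_ancestry(qc: pd.DataFrame, reference_pcs: pd.DataFrame,
                    k_sd: float = 6.0, population: str = "EUR"):
    """Label samples European by proximity to the reference centroid.

    A sample is genetically European when both PC1 and PC2 fall within
    ``k_sd`` robust SDs (median absolute deviation scaled to the normal) of
    the labelled reference centroid.  Samples non-European either genetically
    or by reported ancestry are excluded.

    Returns (labels Series indexed like qc, exclusion set).
    """
    ref = reference_pcs[reference_pcs["population"] == population]
    if ref.empty:
        raise ConfigurationError(f"no reference samples labelled {population}")
    labels = []
    within = np.ones(len(qc), dtype=bool)
    for pc in ("pc1", "pc2"):
        med = ref[pc].median()
        rsd = 1.4826 * (ref[pc] - med).abs().median()
        if rsd == 0:
            rsd = ref[pc].std(ddof=0) or 1e-12
        within &= (qc[pc] - med).abs().to_numpy() <= k_sd * rsd
    labels = pd.Series(np.where(within, "European", "non-European"),
                       index=qc.index)
    reported_bad = qc.get("reported_ancestry", pd.Series("", index=qc.index))
    reported_bad = reported_bad.fillna("").astype(str)
    reported_bad = ~reported_bad.isin(["", "European"])
    excluded = set(qc.loc[(~within) | reported_bad.to_numpy(), "sample_id"])
    return labels, excluded


def prune_related(ibd: pd.DataFrame, samples: pd.DataFrame,
                  ibd_threshold: float = 0.1875) -> set:
    """Sequential relatedness pruning; returns the retained sample ids.

    One individual is removed at a time from the graph of pairs with
    pi-hat > threshold, chosen by (1) largest number of remaining
    relationships, ties broken by (2) group removal preference (diseased
    controls, then non-diseased controls, then cases), then (3) lower mean
    sequencing depth, then (4) sample id (logged).  Deterministic.
    """
    info = samples.set_index("sample_id")
    edges = {}
    for _, row in ibd.iterrows():
        a, b = row["id_a"], row["id_b"]
        if row["pi_hat"] > ibd_threshold and a in info.index and b in info.index:
            edges.setdefault(a, set()).add(b)
            edges.setdefault(b, set()).add(a)
    removed = set()
    while any(edges.values()):
        active = [s for s, nb in edges.items() if nb]
        max_deg = max(len(edges[s]) for s in active)
        cands = [s for s in active if len(edges[s]) == max_deg]
        if len(cands) > 1:
            best = min(_GROUP_REMOVAL_PRIORITY.get(info.loc[s, "group"], 3)
                       for s in cands)
            cands = [s for s in cands
                     if _GROUP_REMOVAL_PRIORITY.get(info.loc[s, "group"], 3) == best]
        if len(cands) > 1 and "mean_depth" in info.columns:
            lo = min(info.loc[s, "mean_depth"] for s in cands)
            cands = [s for s in cands if info.loc[s, "mean_depth"] == lo]
        if len(cands) > 1:
            logger.info("relatedness tie among %s broken by sample id", cands)
        victim = sorted(cands)[0]
        removed.add(victim)
        for nb in edges.pop(victim, set()):
            edges[nb].discard(victim)
    return set(samples["sample_id"]) - removed


@dataclass
class QCResult:
    retained: set
    exclusions: pd.DataFrame        # sample_id, stage, reason
    stage_counts: dict = field(default_factory=dict)
    ancestry_labels: pd.Series | None = None


_STAGES = ("contamination", "depth", "concordance", "missingness",
           "ancestry", "relatedness")


def run_qc_cascade(qc: pd.DataFrame, ibd: pd.DataFrame,
                   reference_pcs: pd.DataFrame,
                   thresholds: QCThresholds | None = None,
                   samples: pd.DataFrame | None = None) -> QCResult:
    """Apply the six-stage exclusion cascade in order.

    ``samples`` provides group membership for relatedness tie-breaking; when
    omitted, the ``group``/``mean_depth`` columns of ``qc`` are used.
    Stage statistics (e.g. the depth threshold) are computed on the samples
    entering that stage.
    """
    thr = thresholds or QCThresholds()
    current = qc.copy()
    records = []
    counts = {"input": len(current)}

    def drop(ids: set, stage: str):
        nonlocal current
        for sid in sorted(ids):
            records.append({"sample_id": sid, "stage": stage, "reason": stage})
        current = current[~current["sample_id"].isin(ids)]
        counts[stage] = len(ids)

    drop(exclude_contaminated(current, thr.freemix), "contamination")
    drop(exclude_low_depth(current, thr.depth_sd), "depth")
    drop(exclude_discordant(current, thr.concordance), "concordance")
    drop(exclude_high_missingness(current, thr.missing_rate), "missingness")
    labels, anc_excl = assign_ancestry(current, reference_pcs, thr.ancestry_k_sd)
    drop(anc_excl, "ancestry")

    meta = samples if samples is not None else current
    if "group" not in meta.columns:
        meta = meta.assign(group="case")
    meta = meta[meta["sample_id"].isin(current["sample_id"])]
    if "mean_depth" not in meta.columns:
        meta = meta.merge(current[["sample_id", "mean_depth"]], on="sample_id")
    retained = prune_related(ibd, meta, thr.ibd)
    drop(set(current["sample_id"]) - retained, "relatedness")

    counts["retained"] = len(current)
    for stage in _STAGES:
        logger.info("QC stage %-12s excluded %d", stage, counts.get(stage, 0))
    exclusions = pd.DataFrame(records, columns=["sample_id", "stage", "reason"])
    return QCResult(retained=set(current["sample_id"]), exclusions=exclusions,
                    stage_counts=counts, ancestry_labels=labels)
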