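"""Synthetic cohort generation.

Produces every input the analysis pipeline consumes -- haplotypes, case-control
genotypes, frequency-panel tables, variant annotations, QC metrics and IBD
pairs -- with the statistical structure the method assumes:

* a rare-variant-dominated site-frequency spectrum (density ~ MAF^-shape on
  [1/n_haplotypes, 0.5], independent sites);
* a logistic disease model whose per-site log-odds effects grow with rarity,
  ``beta_j = min(c * |log10 MAF_j|, beta_max)``, all in the same direction,
  capped at 1.6 (the cap attained at MAF 1e-4 for the default scale c = 0.4);
* 13 "internal" and 7 "external" reference frequency panels with binomial
  sampling noise, so genuinely novel (never-observed) sites occur;
* planted sample-QC failures recorded in a truth table.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import SimulationError

__all__ = [
    "HaplotypePool",
    "PhenotypeModel",
    "CohortDesign",
    "OutlierSpec",
    "INTERNAL_PANEL_IDS",
    "EXTERNAL_PANEL_IDS",
    "DEFAULT_PANEL_SIZES",
    "simulate_haplotype_pool",
    "simulate_case_control",
    "simulate_reference_panels",
    "simulate_annotations",
    "simulate_qc_metrics",
    "make_reference_pcs",
    "effect_sizes",
]

INTERNAL_PANEL_IDS = tuple(f"internal_{i:02d}" for i in range(1, 14))
EXTERNAL_PANEL_IDS = (
    "external_wgs", "external_esp_ea", "external_esp_aa",
    "external_1kg_afr", "external_1kg_amr", "external_1kg_asn",
    "external_1kg_eur",
)

#: default diploid sample counts per panel (13 internal disease-cohort-sized
#: exome sets; external sets sized like WGS / ESP / 1000G continental panels)
DEFAULT_PANEL_SIZES = dict(
    {pid: n for pid, n in zip(INTERNAL_PANEL_IDS,
                              (380, 420, 510, 260, 640, 300, 450,
                               550, 330, 470, 610, 280, 390))},
    external_wgs=3781, external_esp_ea=4300, external_esp_aa=2217,
    external_1kg_afr=246, external_1kg_amr=181, external_1kg_asn=286,
    external_1kg_eur=379,
)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# haplotype pool
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePool:
    """Pool of binary haplotypes over independently drawn sites."""

    n_haplotypes: int
    region_length: int
    site_positions: np.ndarray   # 1-based, strictly increasing
    site_ref: np.ndarray
    site_alt: np.ndarray
    haplotype_matrix: np.ndarray  # (n_haplotypes, n_sites) uint8
    seed: int

    @property
    def n_sites(self) -> int:
        return self.site_positions.size

    @property
    def frequencies(self) -> np.ndarray:
        """Realised per-site alternate-allele frequency (in (0,1))."""
        return self.haplotype_matrix.mean(axis=0)

    def subregion(self, start: int, end: int) -> "HaplotypePool":
        """Pool restricted to sites with start <= pos < end (1-based)."""
        mask = (self.site_positions >= start) & (self.site_positions < end)
        return HaplotypePool(
            n_haplotypes=self.n_haplotypes,
            region_length=end - start,
            site_positions=self.site_positions[mask],
            site_ref=self.site_ref[mask],
            site_alt=self.site_alt[mask],
            haplotype_matrix=self.haplotype_matrix[:, mask],
            seed=self.seed,
        )


def simulate_haplotype_pool(n_haplotypes: int, region_length: int,
                            sfs_shape: float = 1.0, seed: int = 0,
                            site_density: float = 0.01) -> HaplotypePool:
    """Generate a haplotype pool with a power-law site-frequency spectrum.

    Site frequencies are drawn with density ~ f^(-sfs_shape) truncated to
    [1/n_haplotypes, 0.5]; shape 1 is the neutral-theory 1/f spectrum, under
    which the pool is dominated by rare variants.  Sites are independent (no
    linkage disequilibrium).  ``site_density`` is sites per base pair; the
    default (1 per 100 bp) mimics the site density of exome sequence data.
    """
    if n_haplotypes < 100 or region_length < 100:
        raise ValueError("need n_haplotypes >= 100 and region_length >= 100")
    if sfs_shape < 0:
        raise ValueError("sfs_shape must be nonnegative")
    rng = np.random.default_rng(seed)
    n_sites = max(2, int(round(region_length * site_density)))
    positions = np.sort(rng.choice(region_length, size=n_sites, replace=False)) + 1

    fmin, fmax = 1.0 / n_haplotypes, 0.5
    u = rng.random(n_sites)
    if abs(sfs_shape - 1.0) < 1e-12:
        freqs = fmin * (fmax / fmin) ** u
    else:
        e = 1.0 - sfs_shape
        freqs = (fmin**e + u * (fmax**e - fmin**e)) ** (1.0 / e)

    # realised counts conditioned to keep every site polymorphic
    counts = rng.binomial(n_haplotypes, freqs)
    counts = np.clip(counts, 1, n_haplotypes - 1)
    H = np.zeros((n_haplotypes, n_sites), dtype=np.uint8)
    for j, k in enumerate(counts):
        carriers = rng.choice(n_haplotypes, size=k, replace=False)
        H[carriers, j] = 1

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    return HaplotypePool(
        n_haplotypes=n_haplotypes, region_length=region_length,
        site_positions=positions, site_ref=_BASES[ref_idx],
        site_alt=_BASES[alt_idx], haplotype_matrix=H, seed=seed,
    )


# ---------------------------------------------------------------------------
# disease model and case-control sampling
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeModel:
    """Logistic disease model with MAF-dependent log-odds effects.

    The effect of causal site j is ``direction * min(c*|log10 f_j|, cap)``;
    with the defaults the cap 1.6 is attained exactly at MAF 1e-4.
    """

    baseline_prevalence: float = 0.01
    causal_fraction: float = 0.3
    causal_maf_threshold: float = 0.01
    effect_scale: float = 0.4
    effect_cap: float = 1.6
    direction: int = 1

    def __post_init__(self):
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0,1)")
        if not 0.0 <= self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must be in [0,1]")


@dataclass
class CohortDesign:
    """Case/control counts and the gene map (gene, tier, 1-based [start,end))."""

    n_cases_ts: int = 1811
    n_cases_wes: int = 737
    n_controls: int = 1117
    genes: list = field(default_factory=list)

    @property
    def n_cases(self) -> int:
        return self.n_cases_ts + self.n_cases_wes

    def __post_init__(self):
        if min(self.n_cases_ts, self.n_cases_wes) < 0 or self.n_controls <= 0 \
                or self.n_cases <= 0:
            raise ValueError("cohort counts must be positive")


def effect_sizes(mafs, c: float = 0.4, beta_max: float = 1.6) -> np.ndarray:
    """Per-site log-odds effects ``min(c * |log10 maf|, beta_max)``."""
    maf = np.asarray(mafs, dtype=float)
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    return np.minimum(c * np.abs(np.log10(maf)), beta_max)


def _solve_intercept(scores: np.ndarray, prevalence: float) -> float:
    """Bisection for alpha so that mean expit(alpha + score) == prevalence,
    over the realised genotype-score distribution."""
    lo, hi = -40.0, 10.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if expit(mid + scores).mean() > prevalence:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-12:
            break
    return 0.5 * (lo + hi)


def simulate_case_control(pool: HaplotypePool, model: PhenotypeModel,
                          design: CohortDesign, seed: int = 0,
                          max_batches: int = 200):
    """Sample a case-control cohort from the pool under the logistic model.

    Individuals are random haplotype pairs; disease status is Bernoulli with
    ``logit P = alpha + sum_j beta_j g_j`` over the causal sites, where alpha
    is solved by bisection to match the baseline prevalence on the realised
    genotype distribution.  Rejection sampling continues until exactly the
    designed case and control counts are collected.

    Returns
    -------
    genotypes : ndarray (n_samples, n_sites)
    samples : DataFrame with id, cohort, group, status
    truth : dict with causal site indices, betas, intercept
    """
    if pool.n_sites == 0:
        raise SimulationError("empty haplotype pool")
    rng = np.random.default_rng(seed)
    freqs = pool.frequencies
    maf = np.minimum(freqs, 1.0 - freqs)
    eligible = np.where((maf < model.causal_maf_threshold) & (maf > 0))[0]
    n_causal = int(round(model.causal_fraction * eligible.size))
    causal = np.sort(rng.choice(eligible, size=n_causal, replace=False)) \
        if n_causal else np.array([], dtype=int)
    betas = (model.direction
             * effect_sizes(maf[causal], model.effect_scale, model.effect_cap)
             if n_causal else np.array([]))

    H = pool.haplotype_matrix
    Hc = H[:, causal].astype(np.float64) if n_causal else None

    batch = max(20000, int(4 * design.n_cases / model.baseline_prevalence
                           / max(1, max_batches // 50)))
    batch = min(batch, 2_000_000)

    # solve the intercept on an initial realised-genotype sample
    i1 = rng.integers(0, pool.n_haplotypes, size=batch)
    i2 = rng.integers(0, pool.n_haplotypes, size=batch)
    scores = (Hc[i1] + Hc[i2]) @ betas if n_causal else np.zeros(batch)
    alpha = _solve_intercept(scores, model.baseline_prevalence)

    case_idx, ctrl_idx = [], []
    n_cases, n_controls = design.n_cases, design.n_controls
    for b in range(max_batches):
        if b > 0:
            i1 = rng.integers(0, pool.n_haplotypes, size=batch)
            i2 = rng.integers(0, pool.n_haplotypes, size=batch)
            scores = (Hc[i1] + Hc[i2]) @ betas if n_causal else np.zeros(batch)
        y = rng.random(batch) < expit(alpha + scores)
        need_cases = n_cases - sum(len(a) for a in case_idx)
        need_ctrls = n_controls - sum(len(a) for a in ctrl_idx)
        cs = np.flatnonzero(y)[:need_cases]
        ct = np.flatnonzero(~y)[:need_ctrls]
        if cs.size:
            case_idx.append(np.column_stack([i1[cs], i2[cs]]))
        if ct.size:
            ctrl_idx.append(np.column_stack([i1[ct], i2[ct]]))
        if (sum(len(a) for a in case_idx) >= n_cases
                and sum(len(a) for a in ctrl_idx) >= n_controls):
            break
    else:
        raise SimulationError(
            f"could not collect {n_cases} cases / {n_controls} controls in "
            f"{max_batches} batches; prevalence unattainable?")

    pairs = np.vstack(case_idx + ctrl_idx)
    G = (H[pairs[:, 0]] + H[pairs[:, 1]]).astype(np.int16)
    status = np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
    cohort = (["SCOOP_TS"] * design.n_cases_ts
              + ["SCOOP_WES"] * design.n_cases_wes
              + ["CONTROL_WES"] * n_controls)
    group = ["case"] * n_cases + ["diseased_control"] * n_controls
    samples = pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n_cases + n_controls)],
        "cohort": cohort, "group": group, "status": status,
    })
    truth = {"causal_sites": causal.tolist(),
             "betas": np.asarray(betas).tolist(), "intercept": float(alpha)}
    return G, samples, truth


# ---------------------------------------------------------------------------
# reference frequency panels
# ---------------------------------------------------------------------------

def simulate_reference_panels(pool: HaplotypePool, panel_sizes=None,
                              dropout: float = 0.02,
                              private_rate: float = 0.05,
                              private_maf_threshold: float = 0.005,
                              seed: int = 0) -> pd.DataFrame:
    """Binomial resampling of the pool frequencies into 20 reference panels.

    Returns a long-format table (panel_id, panel_type, site_index, ac, an,
    maf, observed, private).  A site with zero sampled copies in a panel --
    or dropped with probability ``dropout``, emulating sites the panel does
    not cover -- is marked unobserved there.  Sites unobserved in all 20
    panels are genuinely novel; at realistic panel sizes that happens
    essentially only for cohort-private variation, which is modelled
    directly: a site with pool MAF below ``private_maf_threshold`` is, with
    probability ``private_rate``, private to the study cohort and absent
    from every reference panel.
    """
    sizes = dict(DEFAULT_PANEL_SIZES if panel_sizes is None else panel_sizes)
    missing = [p for p in INTERNAL_PANEL_IDS + EXTERNAL_PANEL_IDS if p not in sizes]
    if missing:
        raise ValueError(f"panel sizes missing for: {missing}")
    if any(n <= 0 for n in sizes.values()):
        raise ValueError("panel sizes must be positive")
    rng = np.random.default_rng(seed)
    freqs = pool.frequencies
    maf = np.minimum(freqs, 1.0 - freqs)
    private = (maf < private_maf_threshold) \
        & (rng.random(pool.n_sites) < private_rate)
    rows = []
    for pid in INTERNAL_PANEL_IDS + EXTERNAL_PANEL_IDS:
        an = 2 * int(sizes[pid])
        ac = rng.binomial(an, freqs)
        dropped = (rng.random(pool.n_sites) < dropout) | private
        ac = np.where(dropped, 0, ac)
        observed = ac > 0
        ptype = "internal" if pid in INTERNAL_PANEL_IDS else "external"
        rows.append(pd.DataFrame({
            "panel_id": pid, "panel_type": ptype,
            "site_index": np.arange(pool.n_sites),
            "ac": ac, "an": an,
            "maf": np.where(observed, ac / an, np.nan),
            "observed": observed, "private": private,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

DEFAULT_CLASS_PROBS = {
    "non synonymous coding": 0.42, "synonymous coding": 0.30,
    "stop gained": 0.04, "essential splice site": 0.03,
    "frameshift coding": 0.04, "stop lost": 0.01, "complex indel": 0.01,
    "within mature miRNA": 0.005, "partial codon": 0.005,
    "intronic": 0.10, "upstream": 0.04,
}
DEFAULT_DELETERIOUS_PROBS = {"sift": 0.4, "polyphen": 0.4, "condel": 0.4}
DEFAULT_CLINVAR_PROBS = {None: 0.93, "Pathogenic": 0.01,
                         "Likely pathogenic": 0.01, "Benign": 0.03,
                         "Uncertain significance": 0.02}


def _check_probs(probs: dict, name: str):
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
        raise ValueError(f"{name} must be nonnegative and sum to 1")


def simulate_annotations(variants: pd.DataFrame, class_probabilities=None,
                         deleterious_probabilities=None,
                         clinvar_probabilities=None, seed: int = 0,
                         max_transcripts: int = 3) -> pd.DataFrame:
    """Fabricate per-variant consequence, predictor and ClinVar annotations.

    ``variants`` needs chrom/pos/ref/alt/gene columns.  Each variant receives
    a worst-consequence label on 1..max_transcripts transcripts; missense
    variants additionally get SIFT/PolyPhen/Condel labels (deleterious with
    the configured per-predictor probabilities); every variant gets an
    optional ClinVar status.
    """
    class_probabilities = dict(DEFAULT_CLASS_PROBS if class_probabilities is None
                               else class_probabilities)
    deleterious_probabilities = dict(
        DEFAULT_DELETERIOUS_PROBS if deleterious_probabilities is None
        else deleterious_probabilities)
    clinvar_probabilities = dict(DEFAULT_CLINVAR_PROBS if clinvar_probabilities is None
                                 else clinvar_probabilities)
    _check_probs(class_probabilities, "class_probabilities")
    _check_probs(clinvar_probabilities, "clinvar_probabilities")
    if any(not 0 <= p <= 1 for p in deleterious_probabilities.values()):
        raise ValueError("deleterious probabilities must be in [0,1]")

    rng = np.random.default_rng(seed)
    n = len(variants)
    cons_labels = list(class_probabilities)
    cons_p = np.array([class_probabilities[c] for c in cons_labels])
    n_tx = rng.integers(1, max_transcripts + 1, size=n)

    primary, tx_lists, tx_ids = [], [], []
    for i in range(n):
        labels = rng.choice(cons_labels, size=n_tx[i], p=cons_p)
        primary.append(labels[0])
        tx_lists.append(",".join(labels))
        tx_ids.append(",".join(f"T{i}.{k}" for k in range(n_tx[i])))

    def predictor(label_del, label_ok, p):
        dele = rng.random(n) < p
        return np.where(dele, label_del, label_ok)

    sift = predictor("deleterious", "tolerated", deleterious_probabilities["sift"])
    polyphen = predictor("probably damaging", "benign",
                         deleterious_probabilities["polyphen"])
    condel = predictor("deleterious", "neutral", deleterious_probabilities["condel"])
    is_missense = np.array([("non synonymous coding" in t) for t in tx_lists])
    sift = np.where(is_missense, sift, "")
    polyphen = np.where(is_missense, polyphen, "")
    condel = np.where(is_missense, condel, "")

    cv_labels = list(clinvar_probabilities)
    cv_p = np.array([clinvar_probabilities[c] for c in cv_labels])
    clinvar = rng.choice([c if c is not None else "" for c in cv_labels],
                         size=n, p=cv_p)

    out = variants.reset_index(drop=True).copy()
    out["transcript_ids"] = tx_ids
    out["transcript_consequences"] = tx_lists
    # the clinically relevant transcript is taken to be the first
    out["clinically_relevant_transcript"] = [t.split(",")[0] for t in tx_ids]
    out["sift"] = sift
    out["polyphen"] = polyphen
    out["condel"] = condel
    out["clinvar"] = clinvar
    return out


# ---------------------------------------------------------------------------
# QC metrics, ancestry references and IBD pairs
# ---------------------------------------------------------------------------

@dataclass
class OutlierSpec:
    """Planted QC failures; each count picks distinct, disjoint samples."""

    n_contaminated: int = 0
    n_low_depth: int = 0
    n_discordant: int = 0
    n_high_missing: int = 0
    n_non_european: int = 0
    n_reported_non_european: int = 0
    related_groups: tuple = ()  # e.g. (2, 3) -> one pair and one trio

    @property
    def total(self) -> int:
        return (self.n_contaminated + self.n_low_depth + self.n_discordant
                + self.n_high_missing + self.n_non_european
                + self.n_reported_non_european + sum(self.related_groups))


# PC coordinates of continental reference centroids (arbitrary units chosen
# so that continental clouds are well separated relative to their spread)
_CENTROIDS = {"EUR": (0.0, 0.0), "AFR": (0.10, 0.04), "EAS": (0.02, 0.10),
              "SAS": (0.05, 0.05), "AMR": (0.04, 0.02)}
_PC_SD = 0.004


def make_reference_pcs(n_per_pop: int = 100, seed: int = 0) -> pd.DataFrame:
    """Labelled reference PC coordinates mimicking a 1000-Genomes projection."""
    rng = np.random.default_rng(seed)
    rows = []
    for pop, (c1, c2) in _CENTROIDS.items():
        rows.append(pd.DataFrame({
            "population": pop,
            "pc1": rng.normal(c1, _PC_SD, n_per_pop),
            "pc2": rng.normal(c2, _PC_SD, n_per_pop),
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_qc_metrics(sample_ids, outlier_spec: OutlierSpec | None = None,
                        seed: int = 0, depth_mean: float = 30.0,
                        depth_sd: float = 3.0):
    """Per-sample QC metrics and pairwise IBD estimates with planted failures.

    Baseline metrics are drawn from well-behaved distributions (all passing
    the default thresholds); exactly the requested numbers of contamination,
    low-depth, discordance, missingness, ancestry and relatedness outliers
    are planted on disjoint samples and recorded in the returned truth table.

    Returns (qc DataFrame, ibd DataFrame, truth dict).
    """
    spec = outlier_spec or OutlierSpec()
    ids = list(sample_ids)
    n = len(ids)
    if spec.total > n:
        raise ValueError("more planted outliers than samples")
    rng = np.random.default_rng(seed)

    qc = pd.DataFrame({
        "sample_id": ids,
        "freemix": rng.uniform(0.0, 0.01, n),
        "skewed_hets": False,
        "mean_depth": rng.normal(depth_mean, depth_sd, n),
        "concordance": 1.0 - rng.uniform(0.0, 0.05, n),
        "missing_rate": rng.uniform(0.0, 0.10, n),
        "pc1": rng.normal(_CENTROIDS["EUR"][0], _PC_SD, n),
        "pc2": rng.normal(_CENTROIDS["EUR"][1], _PC_SD, n),
        "reported_ancestry": "",
    })

    pool = rng.permutation(n)
    cursor = 0

    def take(k):
        nonlocal cursor
        out = pool[cursor:cursor + k]
        cursor += k
        return out

    truth = {}
    idx = take(spec.n_contaminated)
    # half by FREEMIX, half by the skewed-hets flag alone
    for j, i in enumerate(idx):
        if j % 2 == 0:
            qc.loc[i, "freemix"] = rng.uniform(0.08, 0.25)
        else:
            qc.loc[i, "skewed_hets"] = True
    truth["contaminated"] = sorted(qc.loc[idx, "sample_id"])

    idx = take(spec.n_low_depth)
    qc.loc[idx, "mean_depth"] = depth_mean - 6.0 * depth_sd
    truth["low_depth"] = sorted(qc.loc[idx, "sample_id"])

    idx = take(spec.n_discordant)
    qc.loc[idx, "concordance"] = rng.uniform(0.70, 0.85, idx.size)
    truth["discordant"] = sorted(qc.loc[idx, "sample_id"])

    idx = take(spec.n_high_missing)
    qc.loc[idx, "missing_rate"] = rng.uniform(0.60, 0.90, idx.size)
    truth["high_missing"] = sorted(qc.loc[idx, "sample_id"])

    idx = take(spec.n_non_european)
    qc.loc[idx, "pc1"] = rng.normal(_CENTROIDS["AFR"][0], _PC_SD, idx.size)
    qc.loc[idx, "pc2"] = rng.normal(_CENTROIDS["AFR"][1], _PC_SD, idx.size)
    genetic_non_eur = sorted(qc.loc[idx, "sample_id"])

    idx = take(spec.n_reported_non_european)
    qc.loc[idx, "reported_ancestry"] = "non-European"
    truth["non_european"] = sorted(genetic_non_eur
                                   + sorted(qc.loc[idx, "sample_id"]))

    ibd_rows, related = [], []
    for size in spec.related_groups:
        members = qc.loc[take(size), "sample_id"].tolist()
        related.append(sorted(members))
        for a in range(size):
            for b in range(a + 1, size):
                ibd_rows.append((members[a], members[b],
                                 rng.uniform(0.45, 0.55)))
    truth["related_groups"] = related

    # background unrelated pairs
    n_bg = min(5 * n, 200)
    for _ in range(n_bg):
        a, b = rng.choice(n, size=2, replace=False)
        ibd_rows.append((ids[a], ids[b], rng.uniform(0.0, 0.05)))
    ibd = pd.DataFrame(ibd_rows, columns=["id_a", "id_b", "pi_hat"])
    return qc, ibd, truth
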