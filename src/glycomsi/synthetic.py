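"""Seeded synthetic cohort generators.

These generators produce bulk-tissue and cell-line expression matrices,
a single-cell count matrix, survival records, and IHC records with the
statistical structure the downstream analyses assume:

* bulk/cell-line expression is Gaussian on the log2 scale around group
  means, with a planted mean shift (``effect_log2fc``) on a small set of
  up/down genes in MSI samples;
* single-cell counts are Poisson with per-gene rates, zeroed by
  independent Bernoulli dropout; the MSI-cell rate of planted genes is
  calibrated so the *observed* mean log2(count+1) difference between MSI
  and MSS tumor-epithelial cells equals ``effect_log2fc`` in expectation;
* survival times are exponential with a group-linked log hazard ratio and
  independent exponential censoring calibrated by bisection to a target
  censoring fraction;
* IHC records carry MMR status, staining intensity/positivity (hence an
  H-score), and PD-L1 status drawn from stated conditional probabilities.

Every generator is a pure function of its spec, including the seed:
identical specs give bit-identical output. Randomness is drawn from
named substreams of one root seed so stages do not contaminate each
other.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from math import log, inf, isinf

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .signature import GLYCO_MSI_V1

__all__ = [
    "default_gene_universe",
    "BulkCohortSpec",
    "SingleCellSpec",
    "SurvivalSimSpec",
    "IHCSimSpec",
    "generate_bulk_cohort",
    "generate_single_cell",
    "generate_survival",
    "generate_ihc_cohort",
    "default_bulk_spec",
    "default_cellline_spec",
    "default_single_cell_spec",
]

CELL_TYPES = ("tumor_epithelial", "normal_epithelial", "stromal", "immune")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of a root seed; stable across processes."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**32), zlib.crc32(stream.encode())])
    )


def default_gene_universe(n: int = 188) -> list[str]:
    """Gene universe of ``n`` symbols containing the five signature genes.

    The real screening universe is a curated glycosyltransferase list;
    here the five signature genes are embedded among synthetic filler
    symbols (``GT0001`` ...) so planted-effect experiments use the same
    universe size as the study design.
    """
    sig = list(GLYCO_MSI_V1.genes)
    if n < len(sig):
        raise ValueError(f"universe size {n} smaller than signature ({len(sig)})")
    filler = [f"GT{i:04d}" for i in range(1, n - len(sig) + 1)]
    genes = sorted(sig + filler)
    return genes


# ---------------------------------------------------------------------------
# bulk / cell-line cohorts


@dataclass(frozen=True)
class BulkCohortSpec:
    """Specification of a bulk (or cell-line) MSI/MSS expression cohort."""

    n_msi: int = 76
    n_mss: int = 450
    gene_universe: tuple[str, ...] = field(
        default_factory=lambda: tuple(default_gene_universe())
    )
    planted_up: tuple[str, ...] = GLYCO_MSI_V1.up_genes
    planted_down: tuple[str, ...] = GLYCO_MSI_V1.down_genes
    effect_log2fc: float = 0.8
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_msi < 2 or self.n_mss < 2:
            raise ValueError("need at least 2 samples per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        up, down = set(self.planted_up), set(self.planted_down)
        if up & down:
            raise ValueError(f"planted sets overlap: {sorted(up & down)}")
        missing = (up | down) - set(self.gene_universe)
        if missing:
            raise ValueError(f"planted genes not in universe: {sorted(missing)}")


def generate_bulk_cohort(
    spec: BulkCohortSpec, prefix: str = "S"
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a log2-scale expression matrix with MSI/MSS labels.

    Returns
    -------
    matrix : DataFrame, genes x samples
    labels : Series of {"MSI", "MSS"} indexed by sample id
    """
    genes = list(spec.gene_universe)
    n = spec.n_msi + spec.n_mss
    samples = [f"{prefix}{i + 1:04d}" for i in range(n)]
    labels = pd.Series(
        ["MSI"] * spec.n_msi + ["MSS"] * spec.n_mss, index=samples, name="msi_status"
    )
    rng = _rng(spec.seed, "bulk")
    values = spec.baseline_mean + rng.normal(0.0, spec.noise_sd, size=(len(genes), n))
    is_msi = (labels == "MSI").to_numpy()
    gidx = {g: i for i, g in enumerate(genes)}
    for g in spec.planted_up:
        values[gidx[g], is_msi] += spec.effect_log2fc
    for g in spec.planted_down:
        values[gidx[g], is_msi] -= spec.effect_log2fc
    return pd.DataFrame(values, index=genes, columns=samples), labels


def default_bulk_spec(seed: int = 0, **overrides) -> BulkCohortSpec:
    """Bulk-tissue cohort spec mirroring a 76 MSI / 450 MSS design."""
    return BulkCohortSpec(seed=seed, **overrides)


def default_cellline_spec(seed: int = 0, **overrides) -> BulkCohortSpec:
    """Cell-line panel spec mirroring a 20 MSI / 34 MSS design."""
    overrides.setdefault("n_msi", 20)
    overrides.setdefault("n_mss", 34)
    return BulkCohortSpec(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# single cell


@dataclass(frozen=True)
class SingleCellSpec:
    """Specification of a single-cell MSI/MSS count dataset.

    ``effect_log2fc`` is the target difference in mean log2(count+1)
    between MSI and MSS tumor-epithelial cells for planted genes, *after*
    dropout; the underlying Poisson rate shift is calibrated to achieve
    it (see :func:`_calibrate_rate`).
    """

    n_cells_tumor_epithelial: int = 2000
    n_cells_other: int = 600
    frac_patients_msi: float = 4 / 23
    n_patients: int = 23
    dropout_rate: float = 0.5
    effect_log2fc: float = 0.8
    base_rate: float = 5.0
    gene_universe: tuple[str, ...] = field(
        default_factory=lambda: tuple(default_gene_universe())
    )
    planted_up: tuple[str, ...] = GLYCO_MSI_V1.up_genes
    planted_down: tuple[str, ...] = GLYCO_MSI_V1.down_genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_tumor_epithelial + self.n_cells_other <= 0:
            raise ValueError("zero cells requested")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0.0 < self.frac_patients_msi < 1.0):
            raise ValueError("frac_patients_msi must be in (0, 1)")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        up, down = set(self.planted_up), set(self.planted_down)
        if up & down:
            raise ValueError(f"planted sets overlap: {sorted(up & down)}")
        missing = (up | down) - set(self.gene_universe)
        if missing:
            raise ValueError(f"planted genes not in universe: {sorted(missing)}")


#: Largest Poisson rate the calibration will request. With heavy dropout a
#: target observed fold change may be unattainable (the required rate grows
#: like 2^(delta/(1-dropout))); the planted effect then saturates here.
_RATE_CAP = 1e4


def _mean_log2_poisson(rate: float) -> float:
    """E[log2(X+1)] for X ~ Poisson(rate), by truncated summation."""
    if rate <= 0:
        return 0.0
    from scipy.special import gammaln

    kmax = int(rate + 12 * rate**0.5 + 30)
    k = np.arange(kmax + 1)
    logpmf = k * log(rate) - rate - gammaln(k + 1)
    return float(np.sum(np.exp(logpmf) * np.log2(k + 1)))


@lru_cache(maxsize=256)
def _calibrate_rate(base_rate: float, dropout: float, delta_log2: float) -> float:
    """Poisson rate whose dropout-adjusted mean log2(count+1) differs from
    the base rate's by ``delta_log2``.

    Solves (1-d) * (m(r) - m(base)) = delta_log2 where
    m(r) = E[log2(Poisson(r)+1)].
    """
    if delta_log2 == 0.0:
        return base_rate
    target = _mean_log2_poisson(base_rate) + delta_log2 / (1.0 - dropout)
    if target <= 0:
        return 0.0
    if target >= _mean_log2_poisson(_RATE_CAP):
        return _RATE_CAP  # unattainable under this dropout: saturate

    def f(r: float) -> float:
        return _mean_log2_poisson(r) - target

    lo, hi = 1e-9, base_rate
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def generate_single_cell(spec: SingleCellSpec) -> ad.AnnData:
    """Simulate a single-cell count dataset as an AnnData (cells x genes).

    ``obs`` carries ``cell_type``, ``tissue``, ``patient_id`` and
    ``patient_msi``; ``X`` is a dense integer count matrix (the gene
    universe is small, so sparsity buys nothing here).
    """
    genes = list(spec.gene_universe)
    n_cells = spec.n_cells_tumor_epithelial + spec.n_cells_other
    rng = _rng(spec.seed, "single_cell")

    n_msi_pat = max(1, round(spec.frac_patients_msi * spec.n_patients))
    n_msi_pat = min(n_msi_pat, spec.n_patients - 1)
    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    patient_msi = {
        p: ("MSI" if i < n_msi_pat else "MSS") for i, p in enumerate(patients)
    }

    cell_type = np.array(
        ["tumor_epithelial"] * spec.n_cells_tumor_epithelial
        + [
            CELL_TYPES[1 + (i % 3)]  # normal_epithelial / stromal / immune
            for i in range(spec.n_cells_other)
        ]
    )
    tissue = np.where(cell_type == "normal_epithelial", "normal", "tumor")
    patient_id = rng.choice(patients, size=n_cells)
    msi_of_cell = np.array([patient_msi[p] for p in patient_id])

    rates = np.full((n_cells, len(genes)), spec.base_rate)
    msi_tumor = (cell_type == "tumor_epithelial") & (msi_of_cell == "MSI")
    gidx = {g: i for i, g in enumerate(genes)}
    for g in spec.planted_up:
        rates[msi_tumor, gidx[g]] = _calibrate_rate(
            spec.base_rate, spec.dropout_rate, spec.effect_log2fc
        )
    for g in spec.planted_down:
        rates[msi_tumor, gidx[g]] = _calibrate_rate(
            spec.base_rate, spec.dropout_rate, -spec.effect_log2fc
        )

    counts = rng.poisson(rates)
    if spec.dropout_rate > 0:
        keep = rng.random(counts.shape) >= spec.dropout_rate
        counts = counts * keep

    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical(cell_type, categories=list(CELL_TYPES)),
            "tissue": tissue,
            "patient_id": patient_id,
            "patient_msi": msi_of_cell,
        },
        index=[f"CELL{i + 1:05d}" for i in range(n_cells)],
    )
    return ad.AnnData(
        X=counts.astype(np.float64), obs=obs, var=pd.DataFrame(index=genes)
    )


def default_single_cell_spec(seed: int = 0, **overrides) -> SingleCellSpec:
    return SingleCellSpec(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Two-group exponential survival simulation with target censoring."""

    n: int = 300
    log_hr: float = 0.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    admin_horizon: float = inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")


def _censoring_hazard(event_hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_i c/(c+lambda_i) = target."""

    def f(c: float) -> float:
        return float(np.mean(c / (c + event_hazards))) - target

    lo, hi = 1e-12, float(event_hazards.max())
    while f(hi) < 0:
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def generate_survival(groups, spec: SurvivalSimSpec) -> pd.DataFrame:
    """Simulate time-to-event records for binary ``groups``.

    Event times are exponential with hazard
    ``baseline_hazard * exp(log_hr * group)``; censoring is independent
    exponential, its rate calibrated by bisection so the expected
    censored fraction equals ``censoring_rate``, plus administrative
    censoring at ``admin_horizon``.

    Returns a DataFrame with columns sample_id, time, event, group.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != spec.n:
        raise ValueError(f"expected {spec.n} group labels, got {groups.shape[0]}")
    uniq = np.unique(groups)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"group labels must be binary 0/1, got {uniq}")
    groups = groups.astype(float)

    rng = _rng(spec.seed, "survival")
    hazards = spec.baseline_hazard * np.exp(spec.log_hr * groups)
    t_event = rng.exponential(1.0 / hazards)
    if spec.censoring_rate > 0:
        c = _censoring_hazard(hazards, spec.censoring_rate)
        t_cens = rng.exponential(1.0 / c, size=spec.n)
    else:
        t_cens = np.full(spec.n, inf)
    if not isinf(spec.admin_horizon):
        t_cens = np.minimum(t_cens, spec.admin_horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(spec.n)],
            "time": time,
            "event": event,
            "group": groups.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# IHC


@dataclass(frozen=True)
class IHCSimSpec:
    """MMR-stratified IHC cohort with conditional GALNT7-High and PD-L1.

    Defaults follow the observed cohort structure: ~8% dMMR, GALNT7-High
    in about two thirds of dMMR and a fifth of pMMR tumors, and PD-L1
    positivity depleted in GALNT7-High dMMR tumors.
    """

    n: int = 619
    p_dmmr: float = 52 / 619
    p_high_given_dmmr: float = 0.654
    p_high_given_pmmr: float = 0.213
    p_pdl1_given_high_dmmr: float = 0.238
    p_pdl1_given_low_dmmr: float = 0.588
    p_pdl1_given_mss: float = 0.10
    tn_shift: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_dmmr",
            "p_high_given_dmmr",
            "p_high_given_pmmr",
            "p_pdl1_given_high_dmmr",
            "p_pdl1_given_low_dmmr",
            "p_pdl1_given_mss",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


# (intensity, positivity category) pairs by whether their product reaches
# the GALNT7-High cut (H-score >= 8)
_PAIRS = [(i, c) for i in range(4) for c in range(1, 5)]
_HIGH_PAIRS = [(i, c) for i, c in _PAIRS if i * c >= 8]
_LOW_PAIRS = [(i, c) for i, c in _PAIRS if i * c < 8]


def generate_ihc_cohort(spec: IHCSimSpec) -> pd.DataFrame:
    """Simulate IHC records (one row per tumor).

    Columns: sample_id, mmr_status, intensity, positivity_category,
    h_score, galnt7_class, pdl1_tumor, tn_h_score, cd8, cd4, foxp3, cd163.
    """
    rng = _rng(spec.seed, "ihc")
    n = spec.n
    dmmr = rng.random(n) < spec.p_dmmr
    p_high = np.where(dmmr, spec.p_high_given_dmmr, spec.p_high_given_pmmr)
    high = rng.random(n) < p_high

    pair_idx_high = rng.integers(0, len(_HIGH_PAIRS), size=n)
    pair_idx_low = rng.integers(0, len(_LOW_PAIRS), size=n)
    intensity = np.where(
        high,
        [_HIGH_PAIRS[i][0] for i in pair_idx_high],
        [_LOW_PAIRS[i][0] for i in pair_idx_low],
    )
    category = np.where(
        high,
        [_HIGH_PAIRS[i][1] for i in pair_idx_high],
        [_LOW_PAIRS[i][1] for i in pair_idx_low],
    )
    h = intensity * category

    p_pdl1 = np.where(
        dmmr,
        np.where(high, spec.p_pdl1_given_high_dmmr, spec.p_pdl1_given_low_dmmr),
        spec.p_pdl1_given_mss,
    )
    pdl1 = (rng.random(n) < p_pdl1).astype(int)

    # Tn antigen H-score tracks GALNT7 class; TIL densities are gamma
    # distributed with heavier CD8 infiltration in dMMR tumors.
    tn = np.clip(
        rng.normal(3.0 + spec.tn_shift * high, 2.0), 0.0, 12.0
    ).round(1)
    cd8 = rng.gamma(2.0, np.where(dmmr, 60.0, 25.0))
    cd4 = rng.gamma(2.0, 30.0, size=n)
    foxp3 = rng.gamma(2.0, 15.0, size=n)
    cd163 = rng.gamma(2.0, 40.0, size=n)

    return pd.DataFrame(
        {
            "sample_id": [f"T{i + 1:04d}" for i in range(n)],
            "mmr_status": np.where(dmmr, "dMMR_MSI", "pMMR_MSS"),
            "intensity": intensity.astype(int),
            "positivity_category": category.astype(int),
            "h_score": h.astype(int),
            "galnt7_class": np.where(high, "High", "Low"),
            "pdl1_tumor": pdl1,
            "tn_h_score": tn,
            "cd8": cd8.round(1),
            "cd4": cd4.round(1),
            "foxp3": foxp3.round(1),
            "cd163": cd163.round(1),
        }
    )
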