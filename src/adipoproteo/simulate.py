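"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the data model of a label-free adipose-tissue
proteomics study with a plasma-metabolomics arm:

* log-normal protein intensities with protein baselines and per-sample
  scale effects;
* a tissue structure: adipose-elevated signature genes high in every sample,
  blood-elevated signature genes high only in blood-contaminated samples,
  where a contaminated sample is a convex log-scale mixture
  ``(1 - lambda) * adipose profile + lambda * blood profile`` (default three
  patient and three control samples, matching the study this emulates);
* planted group effects (patient-vs-control log-scale shifts of fixed
  magnitude and random sign) on a known protein subset disjoint from the
  tissue signatures;
* intensity-dependent zeros: the probability that a cell is recorded as zero
  decreases logistically with latent log-intensity (missing not at random);
* clinical covariates with realistic group dependence — presurgery weight
  loss only in patients (mean ~7%), sex imbalance, higher sleep-apnea and
  medication rates in patients;
* a serum metabolite panel with known per-1-SD log odds ratios, realized by
  conditional location shifts calibrated so that the planted value is the
  log-OR per pooled SD of the log-measure.

All randomness flows from ``SynthConfig.seed`` through named
``numpy.random.SeedSequence`` child streams, so any stage's inputs can be
regenerated bit-identically in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    IntensityMatrix,
    MetaboliteTable,
    SampleMetadata,
    SignatureSet,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_proteome",
    "generate_metabolites",
    "generate_pathway_sets",
    "multiplicative_additive_matrix",
]

# named SeedSequence child streams (documented splitting scheme)
_STREAMS = {
    "structure": 0,      # signature/DE membership, contaminated-sample choice
    "intensity": 1,      # baselines, sample effects, residual noise
    "missing": 2,        # zero indicators
    "metadata": 3,       # covariates
    "junk": 4,           # decoy/contaminant/low-evidence rows
    "metabolites": 5,    # serum panel
    "pathways": 6,       # random pathway sets for the enrichment stage
}


def _stream(seed: int, name: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[name]])


@dataclass(frozen=True)
class SynthConfig:
    """Study-scale defaults: 39 patients + 16 controls, ~2400 quantified
    proteins, 168-gene adipose and 207-gene blood signatures, three
    contaminated samples per group; tests shrink the dimensions explicitly.

    ``effect_size`` is the magnitude of the planted patient-minus-control
    shift on the log-intensity scale (random sign per protein);
    ``sigma_protein`` is the residual log-intensity SD per observation.
    ``metabolite_log_or`` is the per-pooled-SD log odds ratio planted for the
    non-null serum measures (15 lowered and 10 raised in obesity by default,
    mirroring the panel structure this emulates).
    """

    seed: int
    n_proteins: int = 2412
    n_patients: int = 39
    n_controls: int = 16
    frac_de: float = 0.02
    effect_size: float = 1.5
    sigma_protein: float = 0.4
    sigma_baseline: float = 1.5
    sigma_sample: float = 0.15
    mean_log_intensity: float = 16.0
    missing_steepness: float = 3.0
    missing_rate: float = 0.12
    de_baseline_quantile: float = 0.4
    n_contaminated_patients: int = 3
    n_contaminated_controls: int = 3
    contamination_mix: float = 0.8
    adipose_size: int = 168
    blood_size: int = 207
    signature_effect: float = 2.0
    frac_reverse: float = 0.04
    frac_contaminant: float = 0.03
    frac_single_peptide: float = 0.05
    weightloss_mean: float = 7.0
    weightloss_sd: float = 2.5
    n_measures: int = 30
    n_measures_down: int = 15
    n_measures_up: int = 10
    metabolite_log_or: float = 1.0
    metabolite_missing: float = 0.0

    def __post_init__(self) -> None:
        for name in ("frac_de", "contamination_mix", "frac_reverse", "frac_contaminant",
                     "frac_single_peptide", "missing_rate", "metabolite_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("n_proteins", "n_patients", "n_controls", "n_measures"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_de + self.adipose_size + self.blood_size > self.n_proteins:
            raise ValidationError(
                "n_proteins too small for the requested DE fraction plus signatures"
            )
        if self.n_contaminated_patients > self.n_patients or \
                self.n_contaminated_controls > self.n_controls:
            raise ValidationError("more contaminated samples than samples")
        if self.n_measures_down + self.n_measures_up > self.n_measures:
            raise ValidationError("more non-null measures than measures")

    @property
    def n_de(self) -> int:
        return int(round(self.frac_de * self.n_proteins))

    @property
    def n_samples(self) -> int:
        return self.n_patients + self.n_controls


@dataclass
class GroundTruth:
    """Planted truth accompanying one generated dataset."""

    de_proteins: set[str] = field(default_factory=set)
    de_effects: dict[str, float] = field(default_factory=dict)
    contaminated_samples: set[str] = field(default_factory=set)
    metabolite_log_ors: dict[str, float] = field(default_factory=dict)


def _generate_metadata(cfg: SynthConfig, contaminated: set[str]) -> list[SampleMetadata]:
    rng = _stream(cfg.seed, "metadata")
    meta = []
    ids = [f"PAT{i + 1:02d}" for i in range(cfg.n_patients)] + \
          [f"CTL{i + 1:02d}" for i in range(cfg.n_controls)]
    for sid in ids:
        is_patient = sid.startswith("PAT")
        if is_patient:
            wl = float(np.clip(rng.normal(cfg.weightloss_mean, cfg.weightloss_sd), 0.5, None))
            sex = "female" if rng.random() < 0.9 else "male"
            apnea = bool(rng.random() < 0.45)
            lipid = bool(rng.random() < 0.30)
            bp = bool(rng.random() < 0.50)
        else:
            wl = 0.0
            sex = "female" if rng.random() < 0.45 else "male"
            apnea = bool(rng.random() < 0.05)
            lipid = bool(rng.random() < 0.10)
            bp = bool(rng.random() < 0.15)
        age = float(np.clip(rng.normal(40.0, 12.0), 18.0, 60.0))
        meta.append(
            SampleMetadata(
                sample_id=sid, group="patient" if is_patient else "control",
                sex=sex, presurgery_weightloss_pct=wl, sleep_apnea=apnea,
                lipid_med=lipid, bp_med=bp, age=age,
                t2dm=bool(rng.random() < (0.3 if is_patient else 0.02)),
            )
        )
    return meta


def generate_proteome(
    cfg: SynthConfig,
) -> tuple[IntensityMatrix, list[SampleMetadata], SignatureSet, SignatureSet, GroundTruth]:
    """Generate the raw protein table plus metadata, signatures, and truth.

    The returned matrix is *raw*: it contains decoy, contaminant, and
    low-evidence rows and encodes censored cells as zeros, exactly as the
    filtering and zero-handling stages expect to receive them.
    """
    rng_struct = _stream(cfg.seed, "structure")
    rng_int = _stream(cfg.seed, "intensity")
    rng_miss = _stream(cfg.seed, "missing")
    rng_junk = _stream(cfg.seed, "junk")

    n, p = cfg.n_proteins, cfg.n_samples
    genes = np.array([f"GENE{i + 1:05d}" for i in range(n)], dtype=object)
    accs = np.array([f"P{i + 1:05d}" for i in range(n)], dtype=object)

    baseline = rng_int.normal(0.0, cfg.sigma_baseline, size=n)

    perm = rng_struct.permutation(n)
    adipose_idx = perm[: cfg.adipose_size]
    blood_idx = perm[cfg.adipose_size: cfg.adipose_size + cfg.blood_size]
    # plant group effects on quantifiable proteins: candidates outside the
    # tissue signatures with baseline abundance above the censoring zone
    # (spike-in benchmark convention — recovery of a shift is only a
    # well-posed question for proteins the instrument reliably quantifies)
    non_sig = np.setdiff1d(np.arange(n), np.concatenate([adipose_idx, blood_idx]))
    cut_q = float(np.quantile(baseline, cfg.de_baseline_quantile))
    eligible = non_sig[baseline[non_sig] >= cut_q]
    if len(eligible) < cfg.n_de:
        raise ValidationError("too few quantifiable proteins to plant the DE subset")
    de_idx = rng_struct.choice(eligible, size=cfg.n_de, replace=False)
    de_signs = rng_struct.choice([-1.0, 1.0], size=cfg.n_de)

    pat_ids = [f"PAT{i + 1:02d}" for i in range(cfg.n_patients)]
    ctl_ids = [f"CTL{i + 1:02d}" for i in range(cfg.n_controls)]
    sample_ids = pat_ids + ctl_ids
    cont = {str(s) for s in rng_struct.choice(pat_ids, size=cfg.n_contaminated_patients,
                                              replace=False)}
    cont |= {str(s) for s in rng_struct.choice(ctl_ids, size=cfg.n_contaminated_controls,
                                               replace=False)}
    lam = np.array([cfg.contamination_mix if s in cont else 0.0 for s in sample_ids])
    # tissue-elevated genes are heterogeneously elevated (mean 1 multipliers)
    adipose_amp = rng_struct.gamma(4.0, 0.25, size=cfg.adipose_size)
    blood_amp = rng_struct.gamma(4.0, 0.25, size=cfg.blood_size)

    sample_eff = rng_int.normal(0.0, cfg.sigma_sample, size=p)
    L = cfg.mean_log_intensity + baseline[:, None] + sample_eff[None, :]
    # tissue structure: adipose genes elevated by (1 - lambda), blood by lambda
    L[adipose_idx, :] += cfg.signature_effect * adipose_amp[:, None] * (1.0 - lam)[None, :]
    L[blood_idx, :] += cfg.signature_effect * blood_amp[:, None] * lam[None, :]
    # planted group effects: patient minus control, random sign
    is_patient = np.array([s in set(pat_ids) for s in sample_ids], dtype=float)
    effects = de_signs * cfg.effect_size
    L[de_idx, :] += effects[:, None] * is_patient[None, :]
    L += rng_int.normal(0.0, cfg.sigma_protein, size=(n, p))

    # intensity-dependent zeros (left-censoring of faint signals)
    cut = np.quantile(L, cfg.missing_rate) if cfg.missing_rate > 0 else -np.inf
    with np.errstate(over="ignore"):
        p_zero = 1.0 / (1.0 + np.exp(cfg.missing_steepness * (L - cut)))
    zero = rng_miss.random(size=(n, p)) < p_zero
    intensity = np.exp(L)
    intensity[zero] = 0.0

    records = pd.DataFrame(
        {
            "accession": accs,
            "gene": genes,
            "n_unique_peptides": 2 + rng_junk.poisson(6, size=n),
            "is_reverse": False,
            "is_contaminant": False,
        }
    )
    values = pd.DataFrame(intensity, index=pd.Index(accs, name="accession"),
                          columns=sample_ids)

    # decoy / contaminant / low-evidence rows that the filter must remove
    extra_records, extra_rows = [], []
    n_rev = int(round(cfg.frac_reverse * n))
    n_con = int(round(cfg.frac_contaminant * n))
    n_low = int(round(cfg.frac_single_peptide * n))
    for kind, count in (("REV", n_rev), ("CON", n_con), ("LOW", n_low)):
        for j in range(count):
            acc = f"{kind}__Q{j + 1:04d}"
            extra_records.append(
                {
                    "accession": acc,
                    "gene": f"{kind}GENE{j + 1:04d}",
                    "n_unique_peptides": 1 if kind == "LOW" else 2 + int(rng_junk.poisson(4)),
                    "is_reverse": kind == "REV",
                    "is_contaminant": kind == "CON",
                }
            )
            extra_rows.append(np.exp(rng_junk.normal(cfg.mean_log_intensity - 2, 1.0, size=p)))
    if extra_records:
        records = pd.concat([records, pd.DataFrame(extra_records)], ignore_index=True)
        extra_vals = pd.DataFrame(np.vstack(extra_rows),
                                  index=[r["accession"] for r in extra_records],
                                  columns=sample_ids)
        values = pd.concat([values, extra_vals])
        order = rng_junk.permutation(len(records))
        records = records.iloc[order].reset_index(drop=True)
        values = values.iloc[order]
    values.index.name = "accession"

    matrix = IntensityMatrix(records=records, values=values, normalized=False)
    meta = _generate_metadata(cfg, cont)
    adipose = SignatureSet("adipose_elevated", frozenset(genes[adipose_idx]))
    blood = SignatureSet("blood_elevated", frozenset(genes[blood_idx]))
    truth = GroundTruth(
        de_proteins=set(accs[de_idx]),
        de_effects={a: float(e) for a, e in zip(accs[de_idx], effects)},
        contaminated_samples=cont,
    )
    return matrix, meta, adipose, blood, truth


def _shift_for_log_or(beta: float, pq: float) -> float:
    """Location shift Delta with z|control ~ N(0,1), z|case ~ N(Delta,1) such
    that the log-OR per *pooled* SD equals ``beta``.

    The pooled variance is 1 + pq * Delta^2, so Delta solves
    ``Delta * sqrt(1 + pq * Delta^2) = beta`` (closed form below).
    """
    if beta == 0.0:
        return 0.0
    if pq <= 0:
        raise ValidationError("need both groups present to plant a log-OR")
    u = (math.sqrt(1.0 + 4.0 * pq * beta * beta) - 1.0) / (2.0 * pq)
    return math.copysign(math.sqrt(u), beta)


def generate_metabolites(
    cfg: SynthConfig, meta: list[SampleMetadata]
) -> tuple[MetaboliteTable, GroundTruth]:
    """Log-normal serum measures with planted per-pooled-SD log odds ratios.

    The first ``n_measures_down`` measures are lowered in patients (log-OR
    ``-metabolite_log_or``), the next ``n_measures_up`` raised, the rest null.
    """
    rng = _stream(cfg.seed, "metabolites")
    ids = [m.sample_id for m in meta]
    is_patient = np.array([m.group == "patient" for m in meta], dtype=float)
    frac = is_patient.mean()
    pq = frac * (1.0 - frac)

    betas = np.concatenate(
        [
            np.full(cfg.n_measures_down, -cfg.metabolite_log_or),
            np.full(cfg.n_measures_up, cfg.metabolite_log_or),
            np.zeros(cfg.n_measures - cfg.n_measures_down - cfg.n_measures_up),
        ]
    )
    names = [f"M{i + 1:03d}" for i in range(cfg.n_measures)]
    cols = {}
    truth = GroundTruth()
    for name, beta in zip(names, betas):
        delta = _shift_for_log_or(float(beta), pq)
        z = rng.normal(0.0, 1.0, size=len(ids)) + delta * is_patient
        mu = rng.uniform(-1.0, 2.0)
        sigma = rng.uniform(0.2, 0.6)
        x = np.exp(mu + sigma * z)
        if cfg.metabolite_missing > 0:
            x = np.where(rng.random(len(ids)) < cfg.metabolite_missing, np.nan, x)
        cols[name] = x
        truth.metabolite_log_ors[name] = float(beta)
    tbl = MetaboliteTable(values=pd.DataFrame(cols, index=pd.Index(ids, name="sample_id")))
    return tbl, truth


def generate_pathway_sets(
    cfg: SynthConfig, n_sets: int = 20, size_range: tuple[int, int] = (10, 50)
) -> list[SignatureSet]:
    """Random flat gene sets over the generated gene universe, for exercising
    the pathway-enrichment stage (no planted structure)."""
    rng = _stream(cfg.seed, "pathways")
    genes = np.array([f"GENE{i + 1:05d}" for i in range(cfg.n_proteins)], dtype=object)
    sets = []
    for k in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(SignatureSet(f"PATHWAY_{k + 1:02d}", frozenset(members)))
    return sets


def multiplicative_additive_matrix(
    n_proteins: int,
    n_samples: int,
    s_mult: float = 0.15,
    sigma_add: float = 50.0,
    mean_log: float = 7.0,
    sd_log: float = 1.5,
    seed: int = 0,
) -> IntensityMatrix:
    """Matrix drawn from the additive+multiplicative error model
    ``x = m * exp(eta) + eps`` with ``eta ~ N(0, s_mult^2)`` and
    ``eps ~ N(0, sigma_add^2)``; draws below zero are left-censored to
    missing.  This is the noise model under which the glog transform is
    variance stabilizing, used to exercise that property.
    """
    rng = np.random.default_rng(seed)
    m = np.exp(rng.normal(mean_log, sd_log, size=n_proteins))
    eta = rng.normal(0.0, s_mult, size=(n_proteins, n_samples))
    eps = rng.normal(0.0, sigma_add, size=(n_proteins, n_samples))
    x = m[:, None] * np.exp(eta) + eps
    x[x < 0] = np.nan
    accs = [f"P{i + 1:05d}" for i in range(n_proteins)]
    records = pd.DataFrame(
        {
            "accession": accs,
            "gene": [f"GENE{i + 1:05d}" for i in range(n_proteins)],
            "n_unique_peptides": 2,
            "is_reverse": False,
            "is_contaminant": False,
        }
    )
    values = pd.DataFrame(x, index=pd.Index(accs, name="accession"),
                          columns=[f"S{j + 1:02d}" for j in range(n_samples)])
    return IntensityMatrix(records=records, values=values, normalized=False)
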