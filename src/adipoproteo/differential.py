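"""Per-protein covariate-adjusted linear models for the patient/control contrast.

Each protein's normalized abundance is regressed on group plus clinical
covariates by ordinary least squares on complete cases (samples where the
protein is present).  Group follows the deposited coding 0 = patients,
2 = controls, so a positive group coefficient means higher abundance in
controls and coefficient magnitudes are per 2 coding units (the full
patient-to-control difference is coefficient x 2).  Two-sided t-tests per
coefficient; Benjamini–Hochberg adjustment per model term across all tested
proteins.  With one sample per subject no random-effect grouping is
identifiable, so the model is fixed-effects only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ContractError, ValidationError
from .gsea import RankedList
from .io_formats import IntensityMatrix, SampleMetadata, metadata_frame

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "DifferentialResult",
    "fit_protein_models",
    "bh_adjust",
    "ranking_for_gsea",
    "differential_table",
]

OK = "ok"
SKIPPED_MIN_N = "skipped_min_n"
SKIPPED_RANK = "skipped_rank_deficient"

GROUP_TERM = "group"
DEFAULT_COVARIATES = ("presurgery_weightloss_pct", "sex", "sleep_apnea", "lipid_med", "bp_med")


@dataclass(frozen=True)
class DesignSpec:
    """Fixed-effects design for the per-protein model.

    ``group_coding`` maps the group levels onto the numeric contrast
    (deposited convention: patients 0, controls 2); binary covariates are
    coded 0/1 (sex: female 0, male 1).  T2DM is available as an optional
    covariate but off by default — an initial screen in the source study
    showed no effect.
    """

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    group_coding: dict = field(default_factory=lambda: {"patient": 0.0, "control": 2.0})
    include_t2dm: bool = False

    @property
    def coding_gap(self) -> float:
        vals = sorted(self.group_coding.values())
        return float(vals[1] - vals[0])

    def terms(self) -> list[str]:
        extra = ("t2dm",) if self.include_t2dm else ()
        return ["const", GROUP_TERM, *self.covariates, *extra]

    def build_matrix(self, meta: list[SampleMetadata]) -> pd.DataFrame:
        """Design matrix (samples x terms) as floats, indexed by sample_id."""
        df = metadata_frame(meta)
        X = pd.DataFrame(index=df.index)
        X["const"] = 1.0
        X[GROUP_TERM] = df["group"].map(self.group_coding).astype(float)
        if X[GROUP_TERM].isna().any():
            raise ValidationError("group level outside the design coding")
        for cov in self.covariates:
            if cov == "sex":
                X[cov] = (df["sex"] == "male").astype(float)
            elif cov in ("sleep_apnea", "lipid_med", "bp_med"):
                X[cov] = df[cov].astype(float)
            else:
                X[cov] = pd.to_numeric(df[cov]).astype(float)
        if self.include_t2dm:
            if df["t2dm"].isna().any():
                raise ValidationError("include_t2dm=True but t2dm is missing for some samples")
            X["t2dm"] = df["t2dm"].astype(float)
        return X


@dataclass
class DifferentialResult:
    """Coefficients, p-values, and FDR for one protein (per model term)."""

    accession: str
    gene: str
    n_used: int
    status: str
    coef: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    tstat: dict[str, float] = field(default_factory=dict)
    pval: dict[str, float] = field(default_factory=dict)
    fdr: dict[str, float] = field(default_factory=dict)

    @property
    def coef_group(self) -> float:
        return self.coef.get(GROUP_TERM, np.nan)

    @property
    def pval_group(self) -> float:
        return self.pval.get(GROUP_TERM, np.nan)

    @property
    def fdr_group(self) -> float:
        return self.fdr.get(GROUP_TERM, np.nan)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1).

    Input order is preserved: the i-th output corresponds to the i-th input.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _check_global_design(X: pd.DataFrame) -> None:
    """Fail early when the full design matrix is rank deficient."""
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the terms involved in an (almost) exact linear dependence
        # (constant columns yield zero variance; silence the 0/0 there)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(A[:, 1:], rowvar=False)
        pairs = []
        cols = list(X.columns[1:])
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if abs(corr[i, j]) > 0.999:
                    pairs.append(f"{cols[i]}~{cols[j]}")
        raise ConfigurationError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"collinear terms: {pairs or 'not pairwise — check level coverage'}"
        )


def fit_protein_models(
    m: IntensityMatrix,
    meta: list[SampleMetadata],
    design: DesignSpec | None = None,
    min_n: int = 10,
    min_n_per_group: int = 3,
    min_present_fraction: float = 0.5,
) -> list[DifferentialResult]:
    """OLS per protein on complete cases, with BH-FDR per term across proteins.

    Proteins observed in fewer than ``min_n`` samples, in fewer than
    ``min_n_per_group`` samples of either group, or in less than
    ``min_present_fraction`` of all samples are reported with a skipped
    status and excluded from the FDR pool, as are proteins whose local design
    (restricted to the samples where they are present) is rank deficient.
    The presence-fraction default reflects standard label-free practice:
    proteins observed only near the detection limit carry intensity-dependent
    (not-at-random) missingness whose selection bias ordinary least squares
    cannot absorb, so their nominal p-values are not trustworthy.
    """
    design = design or DesignSpec()
    if not m.normalized:
        raise ContractError("fit_protein_models expects a normalized matrix")
    X_full = design.build_matrix(meta)
    missing = [s for s in m.samples if s not in X_full.index]
    if missing:
        raise ContractError(f"samples without metadata: {missing[:5]}")
    X_full = X_full.loc[m.samples]
    _check_global_design(X_full)
    terms = design.terms()
    p_terms = len(terms)
    min_n = max(min_n, p_terms + 1)

    A = X_full.to_numpy(dtype=float)
    Y = m.values.to_numpy(dtype=float)
    present = ~np.isnan(Y)
    accs = m.records["accession"].to_numpy()
    genes = m.gene_symbols().to_numpy(dtype=object)

    results: list[DifferentialResult] = [None] * len(accs)  # type: ignore[list-item]

    # batch proteins sharing a missingness pattern: one matrix factorization each
    patterns: dict[bytes, list[int]] = {}
    for i in range(len(accs)):
        patterns.setdefault(present[i].tobytes(), []).append(i)

    is_ctrl = A[:, terms.index(GROUP_TERM)] != 0.0
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        n_used = int(mask.sum())
        n_ctl = int((mask & is_ctrl).sum())
        if (n_used < min_n or n_ctl < min_n_per_group
                or (n_used - n_ctl) < min_n_per_group
                or n_used < min_present_fraction * len(mask)):
            for i in rows:
                results[i] = DifferentialResult(accs[i], genes[i], n_used, SKIPPED_MIN_N)
            continue
        Xs = A[mask]
        XtX = Xs.T @ Xs
        if np.linalg.matrix_rank(Xs) < p_terms:
            for i in rows:
                results[i] = DifferentialResult(accs[i], genes[i], n_used, SKIPPED_RANK)
            continue
        XtX_inv = np.linalg.inv(XtX)
        Ys = Y[np.ix_(rows, np.flatnonzero(mask))].T  # n_used x k
        beta = XtX_inv @ (Xs.T @ Ys)  # p x k
        resid = Ys - Xs @ beta
        dof = n_used - p_terms
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, beta / se, 0.0)
        pv = 2.0 * stats.t.sf(np.abs(tval), dof)
        for col, i in enumerate(rows):
            results[i] = DifferentialResult(
                accs[i], genes[i], n_used, OK,
                coef={t: float(beta[j, col]) for j, t in enumerate(terms)},
                se={t: float(se[j, col]) for j, t in enumerate(terms)},
                tstat={t: float(tval[j, col]) for j, t in enumerate(terms)},
                pval={t: float(pv[j, col]) for j, t in enumerate(terms)},
            )

    tested = [r for r in results if r.status == OK]
    if tested:
        for t in terms:
            if t == "const":
                continue
            adj = bh_adjust([r.pval[t] for r in tested])
            for r, q in zip(tested, adj):
                r.fdr[t] = float(q)
    n_skip = len(results) - len(tested)
    if n_skip:
        logger.info("differential: %d of %d proteins skipped", n_skip, len(results))
    return results


def ranking_for_gsea(
    results: list[DifferentialResult], orientation: str = "obesity"
) -> RankedList:
    """Group-term t-statistics as a GSEA ranking.

    Under the deposited coding a positive t means higher in controls;
    ``orientation="obesity"`` flips the sign so that a positive statistic
    means higher in severe obesity (matching the volcano/NES orientation of
    the analysis this reproduces).  Skipped proteins are excluded; duplicate
    gene symbols keep the largest absolute statistic.
    """
    if orientation not in ("obesity", "control"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if not results:
        raise ValidationError("no differential results")
    flip = -1.0 if orientation == "obesity" else 1.0
    genes, stats_ = [], []
    for r in results:
        if r.status != OK:
            continue
        genes.append(r.gene if r.gene else r.accession)
        stats_.append(flip * r.tstat[GROUP_TERM])
    genes = np.asarray(genes, dtype=object)
    stats_ = np.asarray(stats_, dtype=float)
    order = np.argsort(-np.abs(stats_), kind="stable")
    seen: dict[str, int] = {}
    for i in order:
        seen.setdefault(genes[i], i)
    if len(seen) < len(genes):
        logger.warning("%d duplicate gene symbols collapsed in GSEA ranking",
                       len(genes) - len(seen))
    idx = np.sort(np.fromiter(seen.values(), dtype=int))
    return RankedList(genes[idx], stats_[idx])


def differential_table(results: list[DifferentialResult], term: str = GROUP_TERM) -> pd.DataFrame:
    """Flat per-protein table for one model term.

    ``coef`` follows the deposited sign convention (positive = higher in
    controls for the group term); ``coef_obesity`` is the negated column for
    volcano-plot orientation.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "accession": r.accession,
                "gene": r.gene,
                "coef": r.coef.get(term, np.nan),
                "coef_obesity": -r.coef.get(term, np.nan) if term == GROUP_TERM else np.nan,
                "se": r.se.get(term, np.nan),
                "t": r.tstat.get(term, np.nan),
                "pval": r.pval.get(term, np.nan),
                "fdr": r.fdr.get(term, np.nan),
                "n_used": r.n_used,
                "status": r.status,
            }
        )
    return pd.DataFrame(rows)
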