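"""Per-sample blood-contamination scoring of adipose-tissue proteomes.

Adipose biopsies can carry residual blood; a blood-dominated sample looks like
plasma, not fat.  Each sample is scored by ranking its proteins by deviation
from the across-sample mean and running preranked GSEA against two
tissue-elevated signatures (adipose and blood, Human Protein Atlas style).
The score

    score = [(1 - p_adipose) * sign(ES_adipose) - (1 - p_blood) * sign(ES_blood)] / 2

ranges from +1 (pure adipose character) to -1 (pure blood character);
samples strictly below the cutoff (default -0.75) are flagged for removal
before any downstream statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, QCError, ValidationError
from .gsea import OK, RankedList, gsea_preranked
from .io_formats import IntensityMatrix, SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreInputs",
    "ContaminationScore",
    "sample_ranking_stat",
    "contamination_score",
    "score_samples",
    "scores_table",
]


@dataclass(frozen=True)
class ScoreInputs:
    """Enrichment outcomes of the two tissue signatures for one sample.

    p-values are per-set permutation p-values (no multiplicity adjustment —
    the score formula uses each set's own significance).  The open boundary
    p = 0 is accepted as the limiting case of a vanishing p-value.
    """

    p_adipose: float
    es_adipose: float
    p_blood: float
    es_blood: float

    def __post_init__(self) -> None:
        for name in ("p_adipose", "p_blood"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0) or not math.isfinite(p):
                raise ValidationError(f"{name}={p} outside [0, 1]")
        for name in ("es_adipose", "es_blood"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")


@dataclass(frozen=True)
class ContaminationScore:
    sample_id: str
    score: float
    keep: bool


def sample_ranking_stat(
    m: IntensityMatrix, sample: str, min_present: int = 50
) -> RankedList:
    """Rank one sample's proteins by deviation from their across-sample mean.

    The statistic for protein i is ``value(i, sample) - mean_s(value(i, s))``
    with the mean over present values only.  Proteins missing in this sample
    are excluded.  Items are gene symbols (accession fallback when the symbol
    is empty); duplicate symbols keep the occurrence with the largest
    absolute statistic.
    """
    if not m.normalized:
        raise ContractError("sample_ranking_stat expects a normalized matrix")
    if sample not in m.values.columns:
        raise ContractError(f"sample {sample!r} not in matrix")
    X = m.values.to_numpy(dtype=float)
    col = m.values.columns.get_loc(sample)
    present = ~np.isnan(X)
    counts = present.sum(axis=1)
    means = np.nansum(np.where(present, X, 0.0), axis=1) / np.maximum(counts, 1)
    stat = X[:, col] - means
    sel = present[:, col]
    if int(sel.sum()) < min_present:
        raise QCError(
            f"sample {sample!r} has only {int(sel.sum())} present proteins "
            f"(< {min_present}); contamination score would be unreliable"
        )
    genes = m.gene_symbols().to_numpy(dtype=object)[sel]
    stats = stat[sel]
    # deduplicate symbols, keeping the largest |stat|
    order = np.argsort(-np.abs(stats), kind="stable")
    seen: dict[str, int] = {}
    for i in order:
        seen.setdefault(genes[i], i)
    if len(seen) < len(genes):
        logger.warning("%d duplicate gene symbols collapsed for sample %r",
                       len(genes) - len(seen), sample)
    idx = np.sort(np.fromiter(seen.values(), dtype=int))
    return RankedList(genes[idx], stats[idx])


def contamination_score(inputs: ScoreInputs) -> float:
    """Evaluate the tissue-signature score; sign(0) = 0, so a degenerate zero
    enrichment contributes nothing."""
    sa = float(np.sign(inputs.es_adipose))
    sb = float(np.sign(inputs.es_blood))
    return ((1.0 - inputs.p_adipose) * sa - (1.0 - inputs.p_blood) * sb) / 2.0


def score_samples(
    m: IntensityMatrix,
    adipose: SignatureSet,
    blood: SignatureSet,
    cutoff: float = -0.75,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_present: int = 50,
) -> list[ContaminationScore]:
    """Score every sample and flag those strictly below ``cutoff`` for removal.

    The tissue signatures bypass the pathway-analysis set-size limits.  Each
    sample uses an independent, reproducible permutation stream derived from
    ``seed``.
    """
    if not m.normalized:
        raise ContractError("score_samples expects a normalized matrix")
    genes = set(m.gene_symbols())
    for sig in (adipose, blood):
        overlap = len(sig.genes & genes)
        if overlap < 5:
            raise ConfigurationError(
                f"signature {sig.name!r} overlaps the matrix by only {overlap} genes (< 5)"
            )
    child_seeds = np.random.SeedSequence(seed).generate_state(len(m.samples)) % (2**31)
    out: list[ContaminationScore] = []
    for sample, sub_seed in zip(m.samples, child_seeds):
        ranked = sample_ranking_stat(m, sample, min_present=min_present)
        results = gsea_preranked(
            ranked, [adipose, blood], n_perm=n_perm, min_size=1, max_size=None,
            weight_exponent=weight_exponent, seed=int(sub_seed),
        )
        by_name = {r.set_name: r for r in results}
        ra, rb = by_name[adipose.name], by_name[blood.name]
        if ra.status != OK or rb.status != OK:
            raise ConfigurationError(
                f"signature enrichment unavailable for sample {sample!r}"
            )
        score = contamination_score(
            ScoreInputs(p_adipose=ra.pval, es_adipose=ra.es,
                        p_blood=rb.pval, es_blood=rb.es)
        )
        out.append(ContaminationScore(sample_id=sample, score=score, keep=score >= cutoff))
    return out


def scores_table(scores: list[ContaminationScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in scores],
            "score": [s.score for s in scores],
            "keep": [s.keep for s in scores],
        }
    )
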