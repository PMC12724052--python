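"""Spearman correlation screens of protein abundances against clinical or
metabolite variables, and correlation-ranked GSEA.

Correlations use mid-rank ties and the t approximation for the p-value, and
are computed only when at least ``min_n`` (default 10) paired measurements
exist — pairs below that are omitted entirely, not reported as NA.  No
per-correlation multiplicity adjustment is applied; in this pipeline FDR
control happens at the enrichment stage.  Screens can be restricted to a
stratum (all samples, patients only, controls only) because whole-population
and within-group associations answer different questions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ValidationError
from .gsea import GseaResult, RankedList, gsea_preranked
from .io_formats import IntensityMatrix, MetaboliteTable, SampleMetadata, metadata_frame

logger = logging.getLogger(__name__)

__all__ = ["CorrelationResult", "spearman_screen", "correlation_ranked_gsea", "correlation_table"]

OK = "ok"
UNDEFINED = "undefined_constant"


@dataclass(frozen=True)
class CorrelationResult:
    accession: str
    gene: str
    variable: str
    rho: float
    pval: float
    n: int
    stratum: str = "all"
    status: str = OK


def _as_variable_frame(variables, samples: list[str]) -> pd.DataFrame:
    if isinstance(variables, MetaboliteTable):
        df = variables.values
    elif isinstance(variables, pd.DataFrame):
        df = variables
    elif isinstance(variables, pd.Series):
        df = variables.to_frame()
    else:
        raise ValidationError("variables must be a MetaboliteTable, DataFrame, or Series")
    missing = [s for s in samples if s not in df.index]
    if missing:
        raise ContractError(f"variables lack samples: {missing[:5]}")
    return df.loc[samples].astype(float)


def spearman_screen(
    m: IntensityMatrix,
    variables,
    min_n: int = 10,
    meta: list[SampleMetadata] | None = None,
    stratum: str = "all",
) -> list[CorrelationResult]:
    """Spearman rho of every protein against every variable.

    ``variables`` is a :class:`MetaboliteTable` or a samples-indexed
    DataFrame/Series.  Pairs with fewer than ``min_n`` complete observations
    are omitted; a constant protein or variable vector yields a result with
    an undefined-rho status instead of propagating NaN.  ``stratum`` is
    ``all``, ``patient``, or ``control`` (the latter two need ``meta``).
    """
    if not m.normalized:
        raise ContractError("spearman_screen expects a normalized matrix")
    samples = m.samples
    if stratum != "all":
        if meta is None:
            raise ValidationError("stratified screen needs sample metadata")
        groups = metadata_frame(meta)["group"]
        if stratum not in ("patient", "control"):
            raise ValidationError(f"unknown stratum {stratum!r}")
        samples = [s for s in samples if s in groups.index and groups[s] == stratum]
    V = _as_variable_frame(variables, samples)
    X = m.values[samples].to_numpy(dtype=float)
    genes = m.gene_symbols().to_numpy(dtype=object)
    accs = m.records["accession"].to_numpy()

    out: list[CorrelationResult] = []
    for var in V.columns:
        v = V[var].to_numpy(dtype=float)
        v_ok = ~np.isnan(v)
        for i in range(X.shape[0]):
            pair = v_ok & ~np.isnan(X[i])
            n = int(pair.sum())
            if n < min_n:
                continue
            x, y = X[i, pair], v[pair]
            if np.all(x == x[0]) or np.all(y == y[0]):
                out.append(CorrelationResult(accs[i], genes[i], var, np.nan, np.nan,
                                             n, stratum, UNDEFINED))
                continue
            rho, pval = stats.spearmanr(x, y)
            out.append(CorrelationResult(accs[i], genes[i], var, float(rho), float(pval),
                                         n, stratum))
    return out


def correlation_ranked_gsea(
    results: list[CorrelationResult],
    sets,
    n_perm: int = 10_000,
    min_size: int = 5,
    max_size: int | None = 500,
    weight_exponent: float = 1.0,
    seed: int = 0,
    min_proteins: int = 50,
) -> list[GseaResult]:
    """Preranked GSEA on one variable's correlation screen, ranked by rho.

    ``results`` must all belong to a single variable (and stratum); duplicate
    gene symbols keep the largest absolute rho.
    """
    usable = [r for r in results if r.status == OK]
    variables = {r.variable for r in usable}
    if len(variables) != 1:
        raise ValidationError(f"results must cover exactly one variable, got {sorted(variables)}")
    if len(usable) < min_proteins:
        raise ValidationError(
            f"only {len(usable)} proteins with defined rho (< {min_proteins})"
        )
    genes = np.asarray([r.gene if r.gene else r.accession for r in usable], dtype=object)
    rhos = np.asarray([r.rho for r in usable], dtype=float)
    order = np.argsort(-np.abs(rhos), kind="stable")
    seen: dict[str, int] = {}
    for i in order:
        seen.setdefault(genes[i], i)
    idx = np.sort(np.fromiter(seen.values(), dtype=int))
    ranked = RankedList(genes[idx], rhos[idx])
    return gsea_preranked(ranked, sets, n_perm=n_perm, min_size=min_size,
                          max_size=max_size, weight_exponent=weight_exponent, seed=seed)


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [r.accession for r in results],
            "gene": [r.gene for r in results],
            "variable": [r.variable for r in results],
            "rho": [r.rho for r in results],
            "pval": [r.pval for r in results],
            "n": [r.n for r in results],
            "stratum": [r.stratum for r in results],
            "status": [r.status for r in results],
        }
    )
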