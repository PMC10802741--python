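"""Reference-based cell-type deconvolution and rich/poor stratification.

Bulk samples are modeled as non-negative mixtures of cell-type signature
profiles: per sample, fractions are estimated by non-negative least squares
on the basis genes and renormalized to sum to one.  Patients are then
stratified rich/poor per cell type at the median of patient-mean fractions
(strictly greater than the median is rich; ties are poor), and response
rates between strata are compared with Fisher's exact test over samples.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .clinical import fisher_test

__all__ = ["deconvolve", "stratify_rich_poor", "response_rate_test"]


def deconvolve(sample_expr: pd.DataFrame, basis: pd.DataFrame,
               exclude_types: Sequence[str] = ()) -> pd.DataFrame:
    """Estimate cell-type fractions per sample (samples x types).

    ``sample_expr`` is genes x samples on the same (linear, non-negative)
    scale as the genes x types ``basis``.  Types listed in
    ``exclude_types`` (e.g. non-circulating populations) are dropped after
    the fit and fractions renormalized.  The residual norm per sample is
    attached as ``attrs['residual_norm']``.
    """
    common = basis.index.intersection(sample_expr.index)
    if common.empty:
        raise ValueError("no overlap between basis genes and expression genes")
    B = basis.loc[common].to_numpy(float)
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ValueError("basis columns are linearly dependent")
    Y = sample_expr.loc[common].to_numpy(float)

    coefs = np.empty((sample_expr.shape[1], basis.shape[1]))
    resid = np.empty(sample_expr.shape[1])
    for j in range(Y.shape[1]):
        coefs[j], resid[j] = scipy.optimize.nnls(B, Y[:, j])
    fractions = pd.DataFrame(coefs, index=sample_expr.columns,
                             columns=basis.columns)
    if exclude_types:
        fractions = fractions.drop(columns=list(exclude_types),
                                   errors="ignore")
    totals = fractions.sum(axis=1)
    if (totals <= 0).any():
        warnings.warn("samples with all-zero fractions left unnormalized")
    fractions = fractions.div(totals.where(totals > 0, 1.0), axis=0)
    fractions.attrs["residual_norm"] = pd.Series(
        resid, index=sample_expr.columns)
    return fractions


def stratify_rich_poor(fractions: pd.DataFrame,
                       patients: Optional[Sequence] = None) -> pd.DataFrame:
    """Label patients rich/poor per cell type at the median fraction.

    With ``patients`` given (one patient id per sample row), fractions are
    averaged per patient first; the median is taken across patients.  A
    patient is rich in a type iff its (mean) fraction is strictly greater
    than the median; ties are poor.  The medians used are attached as
    ``attrs['median']``.
    """
    if patients is not None:
        values = fractions.groupby(np.asarray(patients)).mean()
    else:
        values = fractions.copy()
    if len(values) < 2:
        raise ValueError("need at least two patients to stratify")
    medians = values.median(axis=0)
    labels = pd.DataFrame(
        np.where(values.to_numpy() > medians.to_numpy(), "rich", "poor"),
        index=values.index, columns=values.columns)
    for ct in values.columns:
        if values[ct].nunique() == 1:
            warnings.warn(f"all fractions identical for {ct!r}; "
                          "every patient labeled poor")
    labels.attrs["median"] = medians
    return labels


def response_rate_test(labels: pd.DataFrame,
                       sample_patients: Sequence,
                       sample_responses: Sequence,
                       drug: str = "") -> pd.DataFrame:
    """Response-rate difference between rich and poor strata per cell type.

    Rates are computed over samples (fraction of responder samples in each
    stratum); the p-value is the two-sided Fisher exact test on the
    2x2 stratum-by-response table.  Cell types with an empty stratum get an
    NA row with a flag.
    """
    sample_patients = np.asarray(sample_patients)
    responder = np.asarray(sample_responses) == "responder"
    rows = []
    for ct in labels.columns:
        stratum = labels[ct].reindex(sample_patients).to_numpy()
        rich = stratum == "rich"
        poor = stratum == "poor"
        base = {"drug": drug, "cell_type": ct,
                "n_rich": int(rich.sum()), "n_poor": int(poor.sum())}
        if not rich.any() or not poor.any():
            rows.append({**base, "rate_rich": np.nan, "rate_poor": np.nan,
                         "fisher_p": np.nan, "flag": "empty_stratum"})
            continue
        a = int((rich & responder).sum())
        b = int((rich & ~responder).sum())
        c = int((poor & responder).sum())
        d = int((poor & ~responder).sum())
        rows.append({**base,
                     "rate_rich": a / rich.sum(),
                     "rate_poor": c / poor.sum(),
                     "fisher_p": fisher_test([[a, b], [c, d]]),
                     "flag": ""})
    return pd.DataFrame(rows)
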